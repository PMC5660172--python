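"""Recording/event containers, file I/O, filtering and epoch segmentation.

All signal amplitudes are held in microvolts (µV) internally; readers apply
the physical scaling declared by the file format on load.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve, firwin

__all__ = [
    "Recording",
    "EventList",
    "EpochSet",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "notch_filter",
    "bandpass_filter",
    "segment_epochs",
    "design_bandpass",
    "design_notch",
    "zero_phase_filter",
]


@dataclass
class Recording:
    """Multichannel EEG recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in µV.
    fs : float
        Sampling rate in Hz.
    labels : tuple of str
        Unique channel names, e.g. ``("PFC_L", "PFC_R", "CA1_L", ...)``.
    start_time : float
        Offset of the first sample in seconds.
    """

    data: np.ndarray
    fs: float
    labels: tuple[str, ...]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.labels = tuple(str(l) for l in self.labels)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(
                f"unknown channel {label!r}; have {list(self.labels)}"
            ) from None

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]

    def copy_with(self, data: np.ndarray) -> "Recording":
        return Recording(data=data, fs=self.fs, labels=self.labels,
                         start_time=self.start_time)


@dataclass
class EventList:
    """Stimulus/annotation events: onsets in seconds plus a string code each."""

    onsets: np.ndarray
    codes: list[str]

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.codes = [str(c) for c in self.codes]
        if self.onsets.ndim != 1 or len(self.codes) != self.onsets.size:
            raise ValueError("onsets and codes must be 1-D and equal length")
        if self.onsets.size and np.any(np.diff(self.onsets) < 0):
            raise ValueError("event onsets must be non-decreasing")

    def __len__(self) -> int:
        return self.onsets.size

    def select(self, code: str) -> "EventList":
        keep = [i for i, c in enumerate(self.codes) if c == code]
        return EventList(self.onsets[keep], [self.codes[i] for i in keep])


@dataclass
class EpochSet:
    """Fixed-length segments (epochs x channels x samples) with per-epoch metadata.

    ``meta`` columns: ``state`` (waking/NREM/REM/unknown), ``condition``,
    ``artifact`` (bool) and ``onset`` (seconds of first sample in the source
    recording).  ``tmin`` is the time of the first sample relative to the
    epoch's alignment point (0 for plain segmentation, -0.05 s for
    stimulus-locked ERP epochs).
    """

    epochs: np.ndarray
    fs: float
    epoch_length: float
    labels: tuple[str, ...]
    meta: pd.DataFrame = field(default=None)
    tmin: float = 0.0

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.labels = tuple(self.labels)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (epochs x channels x samples)")
        n = self.epochs.shape[0]
        if self.meta is None:
            self.meta = pd.DataFrame({
                "state": ["unknown"] * n,
                "condition": ["none"] * n,
                "artifact": [False] * n,
                "onset": [np.nan] * n,
            })
        if len(self.meta) != n:
            raise ValueError("meta length must equal epoch count")
        expected = int(round(self.epoch_length * self.fs))
        if n and self.epochs.shape[2] != expected:
            raise ValueError(
                f"epoch length {self.epochs.shape[2]} samples != "
                f"round(epoch_length*fs) = {expected}"
            )

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel {label!r}") from None

    def usable(self) -> "EpochSet":
        """Epochs not flagged as artifact."""
        keep = ~self.meta["artifact"].to_numpy(dtype=bool)
        return EpochSet(self.epochs[keep], self.fs, self.epoch_length,
                        self.labels, self.meta[keep].reset_index(drop=True))


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a multichannel recording from EDF or delimited text.

    ``format`` is inferred from the suffix when not given (``.edf`` vs
    anything else as TSV). TSV files carry one header row of channel labels
    and one column per channel; the sampling rate lives in a ``<path>.meta``
    sidecar with ``key=value`` lines.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"recording file not found: {path}")
    if path.stat().st_size == 0:
        raise IOError(f"recording file is empty: {path}")
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        return _read_edf(path)
    if format == "delimited":
        return _read_tsv(path)
    raise ValueError(f"unknown recording format {format!r}")


def write_recording(rec: Recording, path: str | Path,
                    format: str | None = None) -> Path:
    """Write a recording as EDF or TSV (+ ``.meta`` sidecar)."""
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        _write_edf(rec, path)
    elif format == "delimited":
        _write_tsv(rec, path)
    else:
        raise ValueError(f"unknown recording format {format!r}")
    return path


def _read_tsv(path: Path) -> Recording:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001 - re-raise with the path attached
        raise IOError(f"cannot parse delimited recording {path}: {exc}") from exc
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise IOError(f"recording file has no data: {path}")
    meta_path = Path(str(path) + ".meta")
    if not meta_path.exists():
        raise IOError(f"missing sidecar metadata file: {meta_path}")
    meta = {}
    for line in meta_path.read_text().splitlines():
        line = line.strip()
        if line and "=" in line:
            k, v = line.split("=", 1)
            meta[k.strip()] = v.strip()
    if "fs" not in meta:
        raise IOError(f"sidecar {meta_path} does not declare fs")
    if df.isna().any().any():
        raise IOError(f"inconsistent channel lengths in {path}")
    return Recording(data=df.to_numpy().T, fs=float(meta["fs"]),
                     labels=tuple(df.columns),
                     start_time=float(meta.get("start_time", 0.0)))


def _write_tsv(rec: Recording, path: Path) -> None:
    pd.DataFrame(rec.data.T, columns=list(rec.labels)).to_csv(
        path, sep="\t", index=False, float_format="%.6f")
    Path(str(path) + ".meta").write_text(
        f"fs={rec.fs}\nstart_time={rec.start_time}\nunits=uV\n")


def _read_edf(path: Path) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"cannot read EDF file {path}: {exc}") from exc
    # mne returns volts for EEG channels; internal convention is µV
    return Recording(data=raw.get_data() * 1e6, fs=float(raw.info["sfreq"]),
                     labels=tuple(raw.ch_names))


def _write_edf(rec: Recording, path: Path) -> None:
    """Minimal continuous 16-bit EDF writer (one 1-s data record per second).

    A trailing partial second is zero-padded; amplitudes are quantized to the
    per-channel physical range over 2^16 digital steps.
    """
    if abs(rec.fs - round(rec.fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(rec.fs))
    n_ch, n_samp = rec.data.shape
    n_rec = int(np.ceil(n_samp / fs))
    padded = np.zeros((n_ch, n_rec * fs))
    padded[:, :n_samp] = rec.data

    def fx(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    phys_min = np.minimum(padded.min(axis=1), -1.0)
    phys_max = np.maximum(padded.max(axis=1), 1.0)
    dig_min, dig_max = -32768, 32767

    hdr = b"".join([
        fx("0", 8), fx("X X X X", 80), fx("Startdate X X X X", 80),
        fx("01.01.00", 8), fx("00.00.00", 8),
        fx(str(256 * (n_ch + 1)), 8), fx("", 44),
        fx(str(n_rec), 8), fx("1", 8), fx(str(n_ch), 4),
    ])
    sig = b"".join([
        b"".join(fx(l, 16) for l in rec.labels),
        b"".join(fx("", 80) for _ in rec.labels),
        b"".join(fx("uV", 8) for _ in rec.labels),
        b"".join(fx(f"{v:.6g}"[:8], 8) for v in phys_min),
        b"".join(fx(f"{v:.6g}"[:8], 8) for v in phys_max),
        b"".join(fx(str(dig_min), 8) for _ in rec.labels),
        b"".join(fx(str(dig_max), 8) for _ in rec.labels),
        b"".join(fx("", 80) for _ in rec.labels),
        b"".join(fx(str(fs), 8) for _ in rec.labels),
        b"".join(fx("", 32) for _ in rec.labels),
    ])
    pmin = np.array([float(f"{v:.6g}"[:8]) for v in phys_min])
    pmax = np.array([float(f"{v:.6g}"[:8]) for v in phys_max])
    gain = (pmax - pmin) / (dig_max - dig_min)
    digital = np.round((padded - pmin[:, None]) / gain[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(hdr)
        fh.write(sig)
        for r in range(n_rec):
            fh.write(digital[:, r * fs:(r + 1) * fs].tobytes())


def read_events(path: str | Path) -> EventList:
    """Read an event table (TSV with columns ``onset_s``, ``code``)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"event file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    if not {"onset_s", "code"}.issubset(df.columns):
        raise IOError(f"event file {path} must have columns onset_s, code")
    return EventList(df["onset_s"].to_numpy(float), list(df["code"].astype(str)))


def write_events(events: EventList, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"onset_s": events.onsets, "code": events.codes}).to_csv(
        path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def design_bandpass(lo: float, hi: float, fs: float,
                    transition: float | None = None) -> np.ndarray:
    """Symmetric FIR band-pass taps (Hamming window, >= 50 dB stop-band).

    ``lo``/``hi`` are passband edges: gain is ~1 across [lo, hi] and rolls
    off over ``transition`` Hz outside it (the -6 dB cutoffs sit half a
    transition width beyond the edges).
    """
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"band [{lo}, {hi}] Hz invalid for fs={fs} Hz")
    if transition is None:
        transition = float(np.clip(lo / 2, 0.25, 10.0))
    numtaps = int(np.ceil(3.3 * fs / transition)) | 1
    c_lo = max(lo - transition / 2, lo / 4)
    c_hi = min(hi + transition / 2, (hi + fs / 2) / 2)
    return firwin(numtaps, [c_lo, c_hi], pass_zero=False, fs=fs)


def design_notch(f0: float, fs: float, width: float = 4.0,
                 transition: float = 1.0) -> np.ndarray:
    """Symmetric FIR band-stop taps centred on ``f0`` (default 50 Hz mains)."""
    if not 0 < f0 < fs / 2:
        raise ValueError(f"notch frequency {f0} Hz must lie in (0, fs/2)")
    numtaps = int(np.ceil(3.3 * fs / transition)) | 1
    return firwin(numtaps, [f0 - width / 2, f0 + width / 2],
                  pass_zero="bandstop", fs=fs)


def zero_phase_filter(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply odd-length symmetric FIR taps with exactly zero phase.

    Centred convolution of a linear-phase (type-I) FIR introduces no group
    delay, so a single pass suffices; edges are reflection-padded.
    """
    x = np.asarray(x, dtype=float)
    pad = len(taps) // 2
    if x.ndim == 1:
        xp = np.pad(x, pad, mode="reflect")
        return fftconvolve(xp, taps, mode="same")[pad:-pad]
    xp = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)], mode="reflect")
    out = fftconvolve(xp, taps[None, :], mode="same", axes=-1)
    return out[..., pad:-pad]


def notch_filter(rec: Recording, f0: float = 50.0) -> Recording:
    """Remove mains interference with a zero-phase FIR notch at ``f0`` Hz."""
    return rec.copy_with(zero_phase_filter(rec.data, design_notch(f0, rec.fs)))


def bandpass_filter(rec: Recording, lo: float, hi: float) -> Recording:
    """Zero-phase FIR band-pass; default acquisition band is 1-100 Hz."""
    return rec.copy_with(
        zero_phase_filter(rec.data, design_bandpass(lo, hi, rec.fs)))


# ---------------------------------------------------------------------------
# Epoch segmentation
# ---------------------------------------------------------------------------

def segment_epochs(rec: Recording, epoch_length: float = 4.0,
                   artifact_threshold: float = 1000.0,
                   flat_var_threshold: float = 1e-3,
                   state_labels: list[str] | None = None) -> EpochSet:
    """Cut a recording into consecutive non-overlapping epochs.

    Epoch boundaries are half-open ``[t, t + epoch_length)``; a trailing
    partial epoch is discarded.  An epoch is flagged as artifact when any
    sample's absolute value exceeds ``artifact_threshold`` µV, or when every
    channel is flat (variance below ``flat_var_threshold`` µV², a
    lost-electrode guard).  ``state_labels``, when given, must have one
    vigilance label per produced epoch.
    """
    n_per = int(round(epoch_length * rec.fs))
    if n_per < 2:
        raise ValueError("epoch_length x fs must be at least 2 samples")
    n_ep = rec.n_samples // n_per
    data = rec.data[:, :n_ep * n_per].reshape(rec.n_channels, n_ep, n_per)
    epochs = np.transpose(data, (1, 0, 2)).copy()

    amp_bad = np.abs(epochs).max(axis=(1, 2)) > artifact_threshold
    flat_bad = (epochs.var(axis=2) < flat_var_threshold).all(axis=1) if n_ep \
        else np.zeros(0, bool)
    artifact = amp_bad | flat_bad

    if state_labels is not None:
        if len(state_labels) != n_ep:
            raise ValueError(
                f"{len(state_labels)} state labels for {n_ep} epochs")
        states = list(state_labels)
    else:
        states = ["unknown"] * n_ep
    onsets = rec.start_time + np.arange(n_ep) * epoch_length
    meta = pd.DataFrame({"state": states, "condition": ["none"] * n_ep,
                         "artifact": artifact, "onset": onsets})
    if n_ep and artifact.all():
        warnings.warn("all epochs flagged as artifact", stacklevel=2)
    return EpochSet(epochs, rec.fs, epoch_length, rec.labels, meta)
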