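"""Relative EEG power spectra at 1 Hz resolution and band summaries.

Spectral estimates follow the Welch recipe used throughout the pipeline:
Hanning-tapered FFT of 4-s windows with 50% overlap, averaged over windows
and epochs, native 0.25 Hz bins aggregated to 1 Hz, and power expressed per
channel as the fraction of total power over the analysis range (1-100 Hz by
default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import get_window

from .core_io import EpochSet

__all__ = ["PowerSpectrum", "power_spectrum", "band_power",
           "longitudinal_ratio", "DEFAULT_BANDS"]

#: delta / theta / gamma ranges (Hz, half-open intervals)
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 12.0),
    "gamma": (25.0, 100.0),
}


@dataclass
class PowerSpectrum:
    """Per-channel spectrum on a 1 Hz grid.

    ``abs_power`` is µV² per 1-Hz bin; ``rel_power`` is the fraction of the
    channel's total power over the analysis range (rows sum to 1).
    """

    freqs: np.ndarray            # bin centres, Hz
    rel_power: np.ndarray        # (n_channels, n_bins)
    abs_power: np.ndarray        # (n_channels, n_bins)
    labels: tuple[str, ...]
    n_epochs: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, ch in enumerate(self.labels):
            for j, f in enumerate(self.freqs):
                rows.append((ch, f, self.rel_power[i, j], self.abs_power[i, j]))
        return pd.DataFrame(rows, columns=["channel", "freq_hz",
                                           "rel_power", "abs_power_uv2"])


def _welch_psd(epochs: np.ndarray, fs: float, window_s: float = 4.0
               ) -> tuple[np.ndarray, np.ndarray, int]:
    """Hann-tapered PSD averaged over 50%-overlapping windows of all epochs.

    Returns (freqs, psd density in µV²/Hz of shape channels x freqs,
    total window count).
    """
    n_ep, n_ch, n_samp = epochs.shape
    nper = min(int(round(window_s * fs)), n_samp)
    step = max(nper // 2, 1)
    win = get_window("hann", nper)
    norm = fs * (win ** 2).sum()
    starts = range(0, n_samp - nper + 1, step)
    acc = np.zeros((n_ch, nper // 2 + 1))
    count = 0
    for ep in range(n_ep):
        for s in starts:
            seg = epochs[ep, :, s:s + nper]
            seg = seg - seg.mean(axis=1, keepdims=True)
            spec = np.fft.rfft(seg * win, axis=1)
            p = (np.abs(spec) ** 2) / norm
            p[:, 1:-1] *= 2.0  # one-sided
            acc += p
            count += 1
    if count == 0:
        raise ValueError("no usable analysis windows")
    freqs = np.fft.rfftfreq(nper, 1.0 / fs)
    return freqs, acc / count, count


def _aggregate_1hz(freqs: np.ndarray, psd: np.ndarray,
                   fmin: float, fmax: float) -> tuple[np.ndarray, np.ndarray]:
    """Sum native-resolution density bins into 1-Hz bins labelled by centre."""
    df = freqs[1] - freqs[0]
    centres = np.arange(int(np.ceil(fmin)), int(np.floor(fmax)) + 1, dtype=float)
    power = np.empty((psd.shape[0], centres.size))
    for j, c in enumerate(centres):
        mask = (freqs >= c - 0.5) & (freqs < c + 0.5)
        power[:, j] = psd[:, mask].sum(axis=1) * df
    return centres, power


def power_spectrum(epochs: EpochSet, fmin: float = 1.0, fmax: float = 100.0,
                   window_s: float = 4.0) -> PowerSpectrum:
    """Relative power spectrum of the artifact-free epochs.

    Raises ``ValueError`` when no usable epoch remains or when ``fmax``
    reaches the Nyquist frequency.
    """
    if fmax >= epochs.fs / 2:
        raise ValueError(f"fmax={fmax} must be below Nyquist ({epochs.fs / 2})")
    usable = epochs.usable()
    if usable.n_epochs == 0:
        raise ValueError("no artifact-free epochs to analyse")
    freqs, psd, count = _welch_psd(usable.epochs, usable.fs, window_s)
    centres, abs_power = _aggregate_1hz(freqs, psd, fmin, fmax)
    total = abs_power.sum(axis=1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("zero total power in at least one channel")
    return PowerSpectrum(freqs=centres, rel_power=abs_power / total,
                         abs_power=abs_power, labels=usable.labels,
                         n_epochs=usable.n_epochs)


def band_power(spec: PowerSpectrum,
               bands: dict[str, tuple[float, float]] | None = None
               ) -> pd.DataFrame:
    """Summed relative power per channel and named band (half-open [lo, hi))."""
    bands = DEFAULT_BANDS if bands is None else bands
    lo_grid, hi_grid = spec.freqs[0], spec.freqs[-1]
    rows = []
    for name, (lo, hi) in bands.items():
        if lo >= hi or lo < lo_grid - 0.5 or hi > hi_grid + 0.5:
            raise ValueError(
                f"band {name} [{lo}, {hi}) outside spectrum range "
                f"[{lo_grid}, {hi_grid}]")
        mask = (spec.freqs >= lo) & (spec.freqs < hi)
        for i, ch in enumerate(spec.labels):
            rows.append((ch, name, lo, hi, spec.rel_power[i, mask].sum()))
    return pd.DataFrame(rows, columns=["channel", "band", "lo_hz", "hi_hz",
                                       "rel_power"])


def longitudinal_ratio(sessions: list[PowerSpectrum]) -> pd.DataFrame:
    """Per-session, per-channel, per-bin power ratio against the first session.

    Quantifies longitudinal change as the ratio of each session's mean
    absolute spectral power to the first (reference) session, bin by bin.
    Reference bins with zero power yield NaN ratios and are counted in the
    ``undefined`` column rather than silently producing infinities.
    """
    if len(sessions) < 2:
        raise ValueError("need at least two sessions for a longitudinal ratio")
    ref = sessions[0]
    for s in sessions[1:]:
        if s.labels != ref.labels or not np.array_equal(s.freqs, ref.freqs):
            raise ValueError("sessions differ in channels or frequency grid")
    rows = []
    with np.errstate(divide="ignore", invalid="ignore"):
        for si, s in enumerate(sessions):
            ratio = np.where(ref.abs_power > 0,
                             s.abs_power / ref.abs_power, np.nan)
            for i, ch in enumerate(s.labels):
                for j, f in enumerate(s.freqs):
                    rows.append((si, ch, f, ratio[i, j],
                                 bool(ref.abs_power[i, j] <= 0)))
    return pd.DataFrame(rows, columns=["session", "channel", "freq_hz",
                                       "ratio", "undefined"])
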