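"""Passive-oddball auditory ERP analysis.

Stimulus-locked epochs span -50 to +450 ms around tone onset, are baseline
corrected against the pre-stimulus interval, and averaged per condition
(standard vs deviant).  Component peaks P1/N1/P2/N2 are extracted as local
extrema inside configurable latency windows, and event-related oscillations
are quantified with a fixed-cycle Morlet wavelet transform (total power:
transform each trial, then average).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import EpochSet, EventList, Recording

__all__ = ["ERPAverage", "TFMap", "extract_erp_epochs", "average_erp",
           "grand_average", "detect_components", "morlet_spectrogram",
           "evoked_band_power", "DEFAULT_COMPONENT_WINDOWS"]

logger = logging.getLogger(__name__)

#: default component search windows, ms (half-open); positive components are
#: detected as maxima (P1, P2), negative ones as minima (N1, N2)
DEFAULT_COMPONENT_WINDOWS: dict[str, tuple[float, float]] = {
    "P1": (10.0, 30.0),
    "N1": (30.0, 50.0),
    "P2": (50.0, 100.0),
    "N2": (100.0, 200.0),
}


@dataclass
class ERPAverage:
    """Condition-averaged evoked waveform, baseline-corrected to [-50, 0) ms."""

    times: np.ndarray            # ms relative to stimulus onset
    waveform: np.ndarray         # (n_channels, n_times), µV
    labels: tuple[str, ...]
    condition: str
    n_trials: int

    def channel(self, label: str) -> np.ndarray:
        return self.waveform[self.labels.index(label)]


@dataclass
class TFMap:
    """Time-frequency power (µV²) per channel, trial-averaged."""

    times: np.ndarray            # ms
    freqs: np.ndarray            # Hz
    power: np.ndarray            # (n_channels, n_freqs, n_times)
    labels: tuple[str, ...]
    condition: str
    n_trials: int


def extract_erp_epochs(rec: Recording, events: EventList,
                       window_ms: tuple[float, float] = (-50.0, 450.0)
                       ) -> EpochSet:
    """One epoch per stimulus event, condition label copied from the code.

    Events coded ``artifact`` are dropped; events whose window would run off
    the recording are skipped and counted in a log message.  Raises when no
    event is extractable.
    """
    tmin, tmax = window_ms[0] / 1000.0, window_ms[1] / 1000.0
    n_pre = int(round(-tmin * rec.fs))
    n_samp = int(round((tmax - tmin) * rec.fs))
    segs, conds, onsets = [], [], []
    skipped = 0
    for onset, code in zip(events.onsets, events.codes):
        if code == "artifact":
            continue
        i0 = int(round((onset - rec.start_time) * rec.fs)) - n_pre
        if i0 < 0 or i0 + n_samp > rec.n_samples:
            skipped += 1
            continue
        segs.append(rec.data[:, i0:i0 + n_samp])
        conds.append(code)
        onsets.append(onset)
    if skipped:
        logger.info("extract_erp_epochs: skipped %d events outside recording "
                    "bounds", skipped)
    if not segs:
        raise ValueError("no extractable events within the recording")
    meta = pd.DataFrame({"state": ["unknown"] * len(segs),
                         "condition": conds,
                         "artifact": [False] * len(segs),
                         "onset": onsets})
    return EpochSet(np.stack(segs), rec.fs, n_samp / rec.fs, rec.labels,
                    meta, tmin=tmin)


def _times_ms(epochs: EpochSet) -> np.ndarray:
    n = epochs.epochs.shape[2]
    return (np.arange(n) / epochs.fs + epochs.tmin) * 1000.0


def average_erp(epochs: EpochSet, condition: str,
                baseline_ms: tuple[float, float] = (-50.0, 0.0)) -> ERPAverage:
    """Baseline-correct each epoch of a condition and average across trials."""
    sel = (epochs.meta["condition"] == condition) & ~epochs.meta["artifact"]
    data = epochs.epochs[sel.to_numpy()]
    if data.shape[0] == 0:
        raise ValueError(f"no epochs with condition {condition!r}")
    times = _times_ms(epochs)
    base = (times >= baseline_ms[0]) & (times < baseline_ms[1])
    if not base.any():
        raise ValueError("baseline interval selects no samples")
    corrected = data - data[:, :, base].mean(axis=2, keepdims=True)
    return ERPAverage(times=times, waveform=corrected.mean(axis=0),
                      labels=epochs.labels, condition=condition,
                      n_trials=int(data.shape[0]))


def grand_average(erps: list[ERPAverage]) -> ERPAverage:
    """Unweighted mean waveform across animals (same grid and condition)."""
    if not erps:
        raise ValueError("empty ERP list")
    ref = erps[0]
    for e in erps[1:]:
        if e.condition != ref.condition:
            raise ValueError("cannot grand-average mixed conditions")
        if not np.allclose(e.times, ref.times) or e.labels != ref.labels:
            raise ValueError("ERP time grids or channels differ")
    return ERPAverage(times=ref.times,
                      waveform=np.mean([e.waveform for e in erps], axis=0),
                      labels=ref.labels, condition=ref.condition,
                      n_trials=len(erps))


def _peak_in_window(wave: np.ndarray, times: np.ndarray,
                    window: tuple[float, float], polarity: int
                    ) -> tuple[float, float] | None:
    """Largest local extremum of the given polarity inside [lo, hi) ms.

    Candidates are strict local extrema of the full waveform (rising into the
    sample, non-rising out for maxima — so a plateau's first sample counts);
    monotone or flat windows yield None.  Ties go to the earlier latency.
    """
    w = wave * polarity
    interior = np.zeros(w.size, dtype=bool)
    interior[1:-1] = (w[1:-1] > w[:-2]) & (w[1:-1] >= w[2:])
    mask = interior & (times >= window[0]) & (times < window[1])
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return None
    best = idx[np.argmax(w[idx])]  # argmax returns the first of equals
    return float(wave[best]), float(times[best])


def detect_components(erp: ERPAverage,
                      windows: dict[str, tuple[float, float]] | None = None
                      ) -> pd.DataFrame:
    """P1/N1/P2/N2 peak amplitudes (µV) and latencies (ms) per channel.

    Returns one row per channel with ``<comp>_amp``/``<comp>_lat`` columns
    (NaN when no extremum of the expected polarity exists in the window) and
    the peak-to-peak complex amplitudes ``N1_P1`` (P1 - N1) and ``N1_P2``
    (P2 - N1), undefined when a constituent peak is missing.
    """
    windows = DEFAULT_COMPONENT_WINDOWS if windows is None else windows
    lo_t, hi_t = erp.times[0], erp.times[-1]
    order = sorted(windows, key=lambda k: windows[k][0])
    for name, (lo, hi) in windows.items():
        if lo >= hi or lo < lo_t or hi > hi_t + 1e-9:
            raise ValueError(f"component window {name} [{lo}, {hi}) outside "
                             f"epoch times [{lo_t:.0f}, {hi_t:.0f}] ms")
    rows = []
    for i, ch in enumerate(erp.labels):
        row: dict = {"channel": ch, "condition": erp.condition}
        for name in order:
            polarity = 1 if name.upper().startswith("P") else -1
            peak = _peak_in_window(erp.waveform[i], erp.times,
                                   windows[name], polarity)
            row[f"{name}_amp"] = np.nan if peak is None else peak[0]
            row[f"{name}_lat"] = np.nan if peak is None else peak[1]
        row["N1_P1"] = row.get("P1_amp", np.nan) - row.get("N1_amp", np.nan)
        row["N1_P2"] = row.get("P2_amp", np.nan) - row.get("N1_amp", np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def morlet_spectrogram(epochs: EpochSet, condition: str | None = None,
                       freqs: np.ndarray | None = None,
                       n_cycles: float = 6.0) -> TFMap:
    """Trial-averaged Morlet wavelet power (fixed cycles per frequency).

    Power is computed per trial and then averaged, i.e. total
    (evoked + induced) power.  The default grid is 1-100 Hz in 1 Hz steps;
    frequencies whose ``n_cycles``-cycle wavelet does not fit in the epoch
    raise with the minimum feasible frequency.
    """
    from mne.time_frequency import tfr_array_morlet

    if condition is None:
        sel = ~epochs.meta["artifact"]
    else:
        sel = (epochs.meta["condition"] == condition) & ~epochs.meta["artifact"]
    data = epochs.epochs[sel.to_numpy()]
    if data.shape[0] == 0:
        raise ValueError(f"no epochs with condition {condition!r}")
    freqs = np.arange(1.0, 101.0) if freqs is None else np.asarray(freqs, float)
    if freqs.max() >= epochs.fs / 2:
        raise ValueError(f"max frequency {freqs.max()} Hz >= Nyquist "
                         f"({epochs.fs / 2} Hz)")
    duration = data.shape[2] / epochs.fs
    # mne's wavelet support is ~10 sigma_t = 10*n_cycles/(2*pi*f)
    f_feasible = 10.0 * n_cycles / (2.0 * np.pi * duration)
    if freqs.min() < f_feasible:
        raise ValueError(
            f"wavelet at {freqs.min()} Hz is longer than the {duration * 1e3:.0f} ms "
            f"epoch; use frequencies >= {np.ceil(f_feasible):.0f} Hz or fewer cycles")
    power = tfr_array_morlet(data, sfreq=epochs.fs, freqs=freqs,
                             n_cycles=n_cycles, output="avg_power",
                             verbose="error")
    return TFMap(times=_times_ms(epochs), freqs=freqs, power=power,
                 labels=epochs.labels,
                 condition="all" if condition is None else condition,
                 n_trials=int(data.shape[0]))


def evoked_band_power(tf: TFMap, band: tuple[float, float] = (40.0, 80.0),
                      window_ms: tuple[float, float] = (0.0, 200.0),
                      channel: str | None = None) -> float:
    """Mean power over a frequency band x time window of the TF map.

    ``channel=None`` averages all channels; the default band is the evoked
    gamma range 40-80 Hz.
    """
    fmask = (tf.freqs >= band[0]) & (tf.freqs <= band[1])
    tmask = (tf.times >= window_ms[0]) & (tf.times < window_ms[1])
    if not fmask.any() or not tmask.any():
        raise ValueError(f"band {band} Hz / window {window_ms} ms selects no "
                         "cells of the TF map")
    sub = tf.power[:, fmask][:, :, tmask]
    if channel is not None:
        sub = sub[[tf.labels.index(channel)]]
    return float(sub.mean())
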