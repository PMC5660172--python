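"""Pairwise magnitude-squared coherence between electrode sites.

Coherence is the Welch estimator Coh(f) = |S_AB(f)|² / (S_AA(f) S_BB(f)),
with the cross- and auto-spectra averaged over Hanning-tapered 4-s windows
(50% overlap) *before* the quotient is formed — single-window coherence is
identically 1, so the averaging order matters.  The estimator carries the
usual ~1/M small-sample bias for M independent windows; no bias correction
is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import get_window

from .core_io import EpochSet

__all__ = ["CoherenceSpectrum", "msc_coherence", "band_coherence",
           "group_compare"]


@dataclass
class CoherenceSpectrum:
    """Magnitude-squared coherence of one channel pair on a 1 Hz grid."""

    pair: tuple[str, str]
    freqs: np.ndarray
    coh: np.ndarray
    n_segments: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pair": "-".join(self.pair), "freq_hz": self.freqs,
                             "coherence": self.coh})


def _cross_spectra(x: np.ndarray, y: np.ndarray, fs: float, window_s: float
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Accumulate Sxy, Sxx, Syy over 50%-overlapping Hann windows of each epoch."""
    n_ep, n_samp = x.shape
    nper = min(int(round(window_s * fs)), n_samp)
    step = max(nper // 2, 1)
    win = get_window("hann", nper)
    freqs = np.fft.rfftfreq(nper, 1.0 / fs)
    sxx = np.zeros(freqs.size)
    syy = np.zeros(freqs.size)
    sxy = np.zeros(freqs.size, dtype=complex)
    count = 0
    for ep in range(n_ep):
        for s in range(0, n_samp - nper + 1, step):
            xs = x[ep, s:s + nper]
            ys = y[ep, s:s + nper]
            fx = np.fft.rfft((xs - xs.mean()) * win)
            fy = np.fft.rfft((ys - ys.mean()) * win)
            sxx += np.abs(fx) ** 2
            syy += np.abs(fy) ** 2
            sxy += fx * np.conj(fy)
            count += 1
    return freqs, sxy, sxx, syy, count


def msc_coherence(epochs: EpochSet, pair: tuple[str, str],
                  fmin: float = 1.0, fmax: float = 100.0,
                  window_s: float = 4.0) -> CoherenceSpectrum:
    """Magnitude-squared coherence between two channels, 1 Hz bins.

    Uses only artifact-free epochs; requires at least two analysis windows
    (coherence from a single window is degenerate).  The quotient is formed
    on the native Welch grid (self-coherence is exactly 1 there) and the
    resulting coherence values are averaged into 1-Hz bins, preserving the
    estimator's ~1/M small-sample bias for M windows.
    """
    ia = epochs.channel_index(pair[0])
    ib = epochs.channel_index(pair[1])
    usable = epochs.usable()
    if usable.n_epochs == 0:
        raise ValueError("no artifact-free epochs")
    if fmax >= epochs.fs / 2:
        raise ValueError(f"fmax={fmax} must be below Nyquist")
    freqs, sxy, sxx, syy, count = _cross_spectra(
        usable.epochs[:, ia, :], usable.epochs[:, ib, :], usable.fs, window_s)
    if count < 2:
        raise ValueError(
            f"coherence needs >= 2 windows, got {count}; provide more epochs")
    centres = np.arange(int(np.ceil(fmin)), int(np.floor(fmax)) + 1,
                        dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(sxx * syy > 0, np.abs(sxy) ** 2 / (sxx * syy), 0.0)
    coh = np.empty(centres.size)
    for j, c in enumerate(centres):
        mask = (freqs >= c - 0.5) & (freqs < c + 0.5)
        coh[j] = raw[mask].mean() if mask.any() else 0.0
    return CoherenceSpectrum(pair=(pair[0], pair[1]), freqs=centres,
                             coh=coh, n_segments=count)


def band_coherence(cs: CoherenceSpectrum, band: tuple[float, float]) -> float:
    """Arithmetic mean of coherence over bins with centre in [lo, hi)."""
    lo, hi = band
    mask = (cs.freqs >= lo) & (cs.freqs < hi)
    if lo >= hi or not mask.any():
        raise ValueError(f"band [{lo}, {hi}) selects no coherence bins")
    return float(cs.coh[mask].mean())


def group_compare(values_a: np.ndarray, values_b: np.ndarray,
                  alpha: float = 0.05) -> dict:
    """Independent-samples Student t (pooled variance) with a CI on the
    mean difference, as used for between-group coherence comparisons.

    Returns ``{"t", "df", "p", "mean_diff", "ci_low", "ci_high"}`` where the
    CI is at confidence level 1 - alpha and the difference is a - b.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=True)
    ci = res.confidence_interval(confidence_level=1 - alpha)
    return {
        "t": float(res.statistic),
        "df": float(a.size + b.size - 2),
        "p": float(res.pvalue),
        "mean_diff": float(a.mean() - b.mean()),
        "ci_low": float(ci.low),
        "ci_high": float(ci.high),
    }
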