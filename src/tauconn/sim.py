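"""Synthetic cohorts emulating tau-seeding EEG/oddball/IHC experiments.

The generator produces, with full ground truth and master-seed determinism:

* multichannel background EEG: 1/f ("pink") noise plus band-limited
  oscillators per channel;
* shared band-limited sources mixed into several channels, so that
  inter-channel coherence follows the common-source closed form;
* theta-phase-modulated gamma carriers with tunable coupling strength
  kappa, whose modulation index has the closed form kappa*A0/2;
* passive-oddball sessions (240 standard / 60 deviant tones, ISI 4 s by
  default) with Gaussian-bump P1/N1/P2/N2 templates and evoked gamma
  bursts injected at each tone onset;
* two-group studies (buffer vs K18 tau-seeded) where the K18 profile
  multiplies theta amplitude, shared-source share, kappa, ERP amplitude
  and evoked gamma;
* RGB micrographs with an exactly constructed DAB-positive pixel fraction.

Group effects act multiplicatively on generator *amplitudes*; measured
band power therefore scales with the square of the factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .core_io import EventList, Recording, design_bandpass, zero_phase_filter

__all__ = [
    "Oscillator", "SharedSource", "PACComponent", "GroupEffect", "SimSpec",
    "OddballSpec", "default_study_spec", "default_oddball_spec",
    "apply_group_effect", "simulate_recording", "simulate_pac_signal",
    "simulate_oddball_session", "simulate_group_study", "simulate_dab_image",
    "erp_template_waveform", "DEFAULT_ERP_TEMPLATES",
]

STUDY_LABELS = ("PFC_L", "PFC_R", "CA1_L", "CA1_R", "CA3_L", "CA3_R")

#: Gaussian-bump ERP templates per condition: (amplitude µV, centre ms, sigma ms)
DEFAULT_ERP_TEMPLATES: dict[str, tuple[tuple[float, float, float], ...]] = {
    "standard": ((20.0, 20.0, 6.0), (-40.0, 40.0, 8.0),
                 (25.0, 80.0, 15.0), (-15.0, 150.0, 25.0)),
    "deviant": ((20.0, 20.0, 6.0), (-52.0, 40.0, 8.0),
                (25.0, 80.0, 15.0), (-15.0, 150.0, 25.0)),
}


@dataclass
class Oscillator:
    """Band-limited noise oscillator: centre (Hz), bandwidth (Hz), RMS (µV)."""

    f_center: float
    bandwidth: float
    rms: float

    def __post_init__(self) -> None:
        if self.rms < 0:
            raise ValueError("oscillator RMS must be non-negative")
        if self.f_center <= 0 or self.bandwidth <= 0:
            raise ValueError("oscillator frequencies must be positive")


@dataclass
class SharedSource:
    """A common source mixed into several channels (drives coherence).

    ``band=None`` means broadband white; ``weights`` maps channel label to
    mixing weight.
    """

    weights: dict[str, float]
    rms: float
    band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.rms < 0:
            raise ValueError("source RMS must be non-negative")
        if not all(np.isfinite(list(self.weights.values()))):
            raise ValueError("mixing weights must be finite")


@dataclass
class PACComponent:
    """Deterministic theta-modulated gamma carrier on one channel.

    Adds ``slow_amp*cos(phi) + carrier_amp*(1 + kappa*cos(phi))*cos(2*pi*f_high*t)``
    with ``phi = 2*pi*f_low*t + phi0``; the modulation index at
    (f_low, f_high) is kappa*carrier_amp/2 in the noise-free limit.
    """

    f_low: float
    f_high: float
    kappa: float
    carrier_amp: float
    slow_amp: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError(f"kappa must be in [0, 1], got {self.kappa}")
        if self.carrier_amp < 0 or self.slow_amp < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.f_low >= self.f_high:
            raise ValueError("f_low must be below f_high")


@dataclass
class GroupEffect:
    """Multiplicative K18 effect profile on generator parameters."""

    theta_amplitude: float = 1.0
    source_share: float = 1.0
    kappa: float = 1.0
    erp_scale: float = 1.0
    gamma_scale: float = 1.0


@dataclass
class SimSpec:
    """Full parameterization of one simulated animal's ongoing EEG."""

    seed: int
    fs: float = 2000.0
    duration: float = 60.0
    labels: tuple[str, ...] = STUDY_LABELS
    background_rms: float = 50.0
    background_exponent: float = 1.0
    oscillators: dict[str, tuple[Oscillator, ...]] = field(default_factory=dict)
    sources: tuple[SharedSource, ...] = ()
    pac: dict[str, PACComponent] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        if self.background_rms < 0:
            raise ValueError("background RMS must be non-negative")


@dataclass
class OddballSpec:
    """Passive-oddball session design and injected evoked responses."""

    n_standard: int = 240
    p_deviant: float = 0.20
    isi: float = 4.0
    tone_duration_ms: float = 20.0
    lead_in: float = 2.0
    erp_templates: dict[str, tuple[tuple[float, float, float], ...]] = \
        field(default_factory=lambda: dict(DEFAULT_ERP_TEMPLATES))
    gamma_amp: dict[str, float] = \
        field(default_factory=lambda: {"standard": 10.0, "deviant": 15.0})
    gamma_freq: float = 60.0
    gamma_center_ms: float = 100.0
    gamma_sigma_ms: float = 25.0
    erp_scale: float = 1.0
    gamma_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_deviant < 1.0:
            raise ValueError("p_deviant must lie strictly between 0 and 1")
        if self.isi <= 0.5:
            raise ValueError("inter-stimulus interval must exceed the 0.5 s "
                             "epoch window")

    @property
    def n_total(self) -> int:
        exact = self.n_standard / (1.0 - self.p_deviant)
        n = int(round(exact))
        if abs(exact - n) > 1e-9:
            warnings.warn(
                f"event count {exact:.2f} rounded to {n}", stacklevel=2)
        return n

    @property
    def n_deviant(self) -> int:
        return self.n_total - self.n_standard


def default_study_spec(seed: int, duration: float = 60.0,
                       fs: float = 500.0) -> SimSpec:
    """Base (buffer) animal: shared theta source across PFC/HPC, per-channel
    theta oscillators, and theta-gamma coupling on the CA1 sites."""
    theta_osc = {ch: (Oscillator(7.5, 3.0, 15.0),) for ch in STUDY_LABELS}
    theta_source = SharedSource(weights={ch: 1.0 for ch in STUDY_LABELS},
                                rms=40.0, band=(6.0, 9.0))
    pac = {ch: PACComponent(f_low=8.0, f_high=70.0, kappa=0.5,
                            carrier_amp=10.0, slow_amp=30.0)
           for ch in ("CA1_L", "CA1_R")}
    return SimSpec(seed=seed, fs=fs, duration=duration,
                   oscillators=theta_osc, sources=(theta_source,), pac=pac)


def default_oddball_spec() -> OddballSpec:
    return OddballSpec()


def apply_group_effect(base: SimSpec, oddball: OddballSpec,
                       effect: GroupEffect) -> tuple[SimSpec, OddballSpec]:
    """Return new specs with the K18 multipliers applied.

    ``theta_amplitude`` scales oscillators and shared sources whose band
    overlaps 4-12 Hz as well as the PAC slow component; ``source_share``
    scales every shared source; ``kappa`` scales coupling strength
    (clipped to 1).
    """
    def _theta(lo: float, hi: float) -> bool:
        return lo < 12.0 and hi > 4.0

    oscs = {
        ch: tuple(
            replace(o, rms=o.rms * effect.theta_amplitude)
            if _theta(o.f_center - o.bandwidth / 2, o.f_center + o.bandwidth / 2)
            else o
            for o in lst)
        for ch, lst in base.oscillators.items()}
    sources = tuple(
        replace(s, rms=s.rms * effect.source_share *
                (effect.theta_amplitude
                 if s.band is not None and _theta(*s.band) else 1.0))
        for s in base.sources)
    pac = {ch: replace(p, kappa=min(p.kappa * effect.kappa, 1.0),
                       slow_amp=p.slow_amp * effect.theta_amplitude)
           for ch, p in base.pac.items()}
    new_base = replace(base, oscillators=oscs, sources=sources, pac=pac)
    new_odd = replace(oddball,
                      erp_scale=oddball.erp_scale * effect.erp_scale,
                      gamma_scale=oddball.gamma_scale * effect.gamma_scale)
    return new_base, new_odd


# ---------------------------------------------------------------------------
# Signal building blocks
# ---------------------------------------------------------------------------

def _pink_noise(n: int, fs: float, exponent: float, rms: float,
                rng: np.random.Generator) -> np.ndarray:
    """1/f^exponent noise by spectral shaping of white noise."""
    if rms == 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n)
    return x * (rms / np.std(x))


def _narrowband_noise(n: int, fs: float, lo: float, hi: float, rms: float,
                      rng: np.random.Generator) -> np.ndarray:
    if rms == 0 or n == 0:
        return np.zeros(n)
    taps = design_bandpass(lo, hi, fs, transition=max((hi - lo) / 2, 0.5))
    x = zero_phase_filter(rng.standard_normal(n), taps)
    return x * (rms / np.std(x))


def _pac_component(p: PACComponent, n: int, fs: float,
                   rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / fs
    phi0, psi0 = rng.uniform(0.0, 2.0 * np.pi, size=2)
    phi = 2.0 * np.pi * p.f_low * t + phi0
    slow = p.slow_amp * np.cos(phi)
    carrier = p.carrier_amp * (1.0 + p.kappa * np.cos(phi)) * \
        np.cos(2.0 * np.pi * p.f_high * t + psi0)
    return slow + carrier


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def simulate_recording(spec: SimSpec,
                       rng: np.random.Generator | None = None) -> Recording:
    """Ongoing multichannel EEG per the spec; bit-identical under a seed."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n = int(round(spec.duration * spec.fs))
    data = np.zeros((len(spec.labels), n))
    for i, ch in enumerate(spec.labels):
        data[i] += _pink_noise(n, spec.fs, spec.background_exponent,
                               spec.background_rms, rng)
        for osc in spec.oscillators.get(ch, ()):
            data[i] += _narrowband_noise(
                n, spec.fs, osc.f_center - osc.bandwidth / 2,
                osc.f_center + osc.bandwidth / 2, osc.rms, rng)
    for src in spec.sources:
        if src.band is None:
            s = rng.standard_normal(n)
            s /= np.std(s)
        else:
            s = _narrowband_noise(n, spec.fs, src.band[0], src.band[1], 1.0, rng)
        for ch, w in src.weights.items():
            if ch in spec.labels:
                data[spec.labels.index(ch)] += w * src.rms * s
    for ch, p in spec.pac.items():
        if ch in spec.labels:
            data[spec.labels.index(ch)] += _pac_component(p, n, spec.fs, rng)
    return Recording(data=data, fs=spec.fs, labels=spec.labels)


def simulate_pac_signal(f_low: float, f_high: float, kappa: float,
                        duration: float, fs: float, noise_rms: float = 0.0,
                        seed: int | None = None, carrier_amp: float = 1.0,
                        slow_amp: float = 1.0, phi0: float = 0.0
                        ) -> Recording:
    """Single-channel test signal with analytically known coupling:

    x(t) = slow_amp*cos(phi) + carrier_amp*(1 + kappa*cos(phi))*cos(2*pi*f_high*t)
           + white noise,  phi = 2*pi*f_low*t + phi0.
    """
    if not 0.0 <= kappa <= 1.0:
        raise ValueError(f"kappa must be in [0, 1], got {kappa}")
    if not 0 < f_low < f_high < fs / 2:
        raise ValueError("need 0 < f_low < f_high < fs/2")
    if noise_rms < 0:
        raise ValueError("noise RMS must be non-negative")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    phi = 2.0 * np.pi * f_low * t + phi0
    x = slow_amp * np.cos(phi) + \
        carrier_amp * (1.0 + kappa * np.cos(phi)) * np.cos(2.0 * np.pi * f_high * t)
    if noise_rms > 0:
        x = x + np.random.default_rng(seed).standard_normal(n) * noise_rms
    return Recording(data=x[None, :], fs=fs, labels=("PAC",))


def erp_template_waveform(template: tuple[tuple[float, float, float], ...],
                          fs: float, duration_ms: float = 300.0) -> np.ndarray:
    """Sum of Gaussian bumps starting at stimulus onset (t = 0)."""
    t = np.arange(int(round(duration_ms / 1000.0 * fs))) / fs * 1000.0
    wave = np.zeros_like(t)
    for amp, centre, sigma in template:
        wave += amp * np.exp(-0.5 * ((t - centre) / sigma) ** 2)
    return wave


def _nonadjacent_positions(n_total: int, n_pick: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Uniform random subset of positions with no two adjacent."""
    if n_pick > (n_total + 1) // 2:
        raise ValueError("cannot place that many non-adjacent deviants")
    base = np.sort(rng.choice(n_total - n_pick + 1, size=n_pick, replace=False))
    return base + np.arange(n_pick)


def simulate_oddball_session(ospec: OddballSpec, base: SimSpec,
                             rng: np.random.Generator | None = None
                             ) -> tuple[Recording, EventList]:
    """Ongoing EEG with a tone train and injected evoked responses.

    Deviant positions are seeded-random with no two consecutive deviants;
    onsets are spaced by exactly ``isi``.  Condition-specific ERP templates
    and gamma bursts (scaled by ``erp_scale``/``gamma_scale``) are added to
    every channel at each onset.
    """
    rng = np.random.default_rng(base.seed) if rng is None else rng
    n_total, n_dev = ospec.n_total, ospec.n_deviant
    required = ospec.lead_in + (n_total - 1) * ospec.isi + 1.0
    spec = base if base.duration >= required else replace(base, duration=required)
    rec = simulate_recording(spec, rng=rng)

    dev_pos = set(_nonadjacent_positions(n_total, n_dev, rng).tolist())
    onsets = ospec.lead_in + np.arange(n_total) * ospec.isi
    codes = ["deviant" if i in dev_pos else "standard" for i in range(n_total)]

    waves = {cond: ospec.erp_scale *
             erp_template_waveform(ospec.erp_templates[cond], spec.fs)
             for cond in ospec.erp_templates}
    tb = np.arange(int(round(0.3 * spec.fs))) / spec.fs
    env = np.exp(-0.5 * ((tb * 1000.0 - ospec.gamma_center_ms) /
                         ospec.gamma_sigma_ms) ** 2)
    bursts = {cond: ospec.gamma_scale * amp * env *
              np.cos(2.0 * np.pi * ospec.gamma_freq * tb)
              for cond, amp in ospec.gamma_amp.items()}

    for onset, code in zip(onsets, codes):
        i0 = int(round(onset * spec.fs))
        w = waves[code] + bursts[code]
        i1 = min(i0 + w.size, rec.n_samples)
        rec.data[:, i0:i1] += w[:i1 - i0]
    return rec, EventList(onsets, codes)


def simulate_group_study(n_per_group: tuple[int, int], base: SimSpec,
                         oddball: OddballSpec, k18_effect: GroupEffect,
                         seed: int) -> dict[str, list[tuple[Recording, EventList]]]:
    """Two cohorts of oddball sessions: buffer (base spec) vs K18 (effect
    multipliers applied).  Per-animal randomness is spawned from the master
    seed, so every animal is independently reproducible.
    """
    n_buf, n_k18 = n_per_group
    if n_buf < 2 or n_k18 < 2:
        raise ValueError("need at least 2 animals per group")
    k18_base, k18_odd = apply_group_effect(base, oddball, k18_effect)
    children = np.random.SeedSequence(seed).spawn(n_buf + n_k18)
    out: dict[str, list[tuple[Recording, EventList]]] = {"buffer": [], "k18": []}
    for i in range(n_buf):
        out["buffer"].append(simulate_oddball_session(
            oddball, base, rng=np.random.default_rng(children[i])))
    for i in range(n_k18):
        out["k18"].append(simulate_oddball_session(
            k18_odd, k18_base, rng=np.random.default_rng(children[n_buf + i])))
    return out


def simulate_dab_image(width: int, height: int, positive_fraction: float,
                       roi: np.ndarray | None = None,
                       seed: int | None = None, threshold: float = 0.5
                       ) -> tuple[np.ndarray, np.ndarray]:
    """RGB micrograph with an exactly constructed DAB-positive fraction.

    Exactly ``round(positive_fraction * roi_pixels)`` pixels inside the ROI
    satisfy (R - G)/B >= threshold (brown DAB chromogen); every other pixel
    sits strictly below it (hematoxylin-blue tissue / white background).
    Channel values are in [0, 1]; same seed, same image.
    """
    if not 0.0 <= positive_fraction <= 1.0:
        raise ValueError("positive_fraction must be in [0, 1]")
    if roi is None:
        roi = np.ones((height, width), dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != (height, width):
        raise ValueError("roi mask shape must be (height, width)")
    if not roi.any():
        raise ValueError("ROI mask is empty")
    rng = np.random.default_rng(seed)
    img = np.empty((height, width, 3))
    # background: near-white, (R-G)/B = 0
    img[..., 0] = img[..., 1] = 0.90
    img[..., 2] = 0.95

    flat_idx = np.flatnonzero(roi.ravel())
    n_pos = int(round(positive_fraction * flat_idx.size))
    order = rng.permutation(flat_idx.size)
    pos = flat_idx[order[:n_pos]]
    neg = flat_idx[order[n_pos:]]
    yx = np.unravel_index(pos, roi.shape)
    b = 0.30 + 0.15 * rng.random(n_pos)
    margin = 0.02 + 0.4 * rng.random(n_pos)
    g = 0.15 + 0.10 * rng.random(n_pos)
    img[yx[0], yx[1], 2] = b
    img[yx[0], yx[1], 1] = g
    img[yx[0], yx[1], 0] = np.minimum(g + b * (threshold + margin), 1.0)
    yx = np.unravel_index(neg, roi.shape)
    bn = 0.55 + 0.25 * rng.random(neg.size)
    rn = 0.25 + 0.15 * rng.random(neg.size)
    img[yx[0], yx[1], 2] = bn
    img[yx[0], yx[1], 0] = rn
    img[yx[0], yx[1], 1] = rn + 0.05 + 0.10 * rng.random(neg.size)
    return img, roi
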