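# Methods

`tauconn` re-implements, as a tested pipeline, the EEG/ERP/immunohistochemistry
analysis stack of a two-group (buffer vs K18 tau-seeded) mouse study, together
with a synthetic-data generator that emulates the study's recordings so every
stage can be verified against known ground truth at desk scale.

## Signal model and containers

Recordings are channels × samples matrices in µV with a sampling rate
(2 kHz in the emulated acquisition; analyses are rate-agnostic) and unique
channel labels for the six electrode sites (bilateral PFC, HPC CA1, HPC CA3).
Epochs are consecutive non-overlapping 4-s segments, half-open `[t, t+4)`,
with the trailing partial epoch discarded. An epoch is flagged as artifact
when any sample exceeds an absolute threshold (default 1000 µV, configurable)
or when all channels are flat (variance < 1e-3 µV²). The amplitude threshold
is a deliberately simple, reproducible stand-in: the original study's artifact
and vigilance-scoring criteria are not public, so vigilance states are
accepted as pre-computed per-epoch labels and never inferred.

## Filtering

All filters are odd-length symmetric (type-I linear-phase) FIR designs
applied by centred convolution, which is exactly zero-phase in a single
pass — component latencies are never shifted. Band-pass arguments are
*passband edges*: gain is ~1 across `[lo, hi]` and rolls off over one
transition width outside it, with the Hamming-window design giving ≥ 50 dB
stop-band rejection. This matters for phase-amplitude coupling: the
modulation side-bands at `f_H ± f_L` must pass at full gain, and placing
the −6 dB cutoff *at* `f_H ± f_L` (the textbook reading of "bandwidth
2·f_L") halves the recovered modulation depth. The mains notch is a 4-Hz-wide
FIR band-stop centred at 50 Hz.

## Spectra

Power spectral density uses the Welch recipe: Hanning-tapered FFT of 4-s
windows with 50% overlap, averaged over windows and epochs, mean removed per
window. Native 0.25-Hz bins are summed into 1-Hz bins labelled by their
centre (`[c−0.5, c+0.5)`); relative power is each channel's fraction of total
power over the analysis range (1–100 Hz by default, 1–50 Hz supported via
`fmin`/`fmax`, with the normalising total always taken over the selected
range). Band summaries use half-open intervals, delta 1–4, theta 4–12,
gamma 25–100 Hz. Longitudinal change is the per-bin ratio of each session's
absolute power to the first session's; zero-power reference bins yield NaN
and are counted, never silent infinities.

## Coherence

Magnitude-squared coherence `|S_AB|²/(S_AA·S_BB)` is estimated with cross-
and auto-spectra averaged over Hanning-tapered 4-s windows (50% overlap
within continuous stretches) *before* the quotient — single-window coherence
is identically 1, so the averaging order is essential. The quotient is formed
on the native Welch grid, where self-coherence is exactly 1, and coherence
values are then averaged into 1-Hz bins. No small-sample bias correction is
applied; the estimator's ~1/M bias for M independent windows is documented
and covered by tests instead. Group differences in band-averaged coherence
use the pooled-variance independent-samples t test with a confidence interval
on the mean difference, as in the original analysis; the study's linear mixed
models are deliberately out of scope.

## Phase-amplitude coupling

The coupling statistic is the mean-vector modulation index
`MI = |mean_t A_H(t)·exp(i·φ_L(t))|`, with `A_H` and `φ_L` from the Hilbert
transform of zero-phase band-passed signal. Grid: phase frequencies 2–12 Hz
(step 2, bandwidth 2 Hz), amplitude frequencies 10–200 Hz (step 5, bandwidth
`max(10, 2·f_L)` per cell to admit the modulation side-bands; lower band
edges are clipped at 0.5 Hz where the rule would cross zero, which affects
only the lowest amplitude rows against the highest phase rows). One filter
length is excluded at each end of every analytic series before averaging.
For a sinusoidally modulated envelope `A = A₀(1 + κ·cos φ)` with phase
covering whole cycles, MI converges to `κ·A₀/2`; this closed form anchors
the unit tests to 1% on 60 s of signal.

Surrogates circularly time-shift the amplitude series by seeded random
offsets of at least 1 s, preserving both spectra while destroying the
phase-amplitude alignment; 50 surrogates are used and
`z = (MI − mean_surr)/sd_surr` is reported per cell. Significance is the
point where this package departs from a common but miscalibrated recipe:
under no coupling the time-averaged complex vector is approximately
isotropic bivariate normal, so null MI is **Rayleigh** distributed, and
thresholding z against a one-sided *normal* critical value (even
Bonferroni-corrected over the 234 cells) inflates the family-wise error to
~0.4 in our null simulations. We therefore compute the Rayleigh tail
probability `p = exp(−MI²/E[MI²])`, estimating the second moment from the
surrogates, and call a cell significant when `p < α/234` (α = 0.05). This
corresponds to z ≳ 4.3 and is empirically calibrated (family-wise error
≤ α on white-noise nulls). Cells whose surrogate spread is degenerate are
marked undefined and never significant. One inherent limitation: a *purely
periodic* deterministic modulator is invariant under circular shifts up to
phase, so surrogates cannot flag it — significance is meaningful for
stochastic (physiological) modulators, while the MI value itself is always
valid.

## Oddball ERP analysis

Epochs span −50 to +450 ms around tone onset; events whose window runs off
the recording are skipped and counted. Each epoch is baseline-corrected by
subtracting its mean over [−50, 0) ms before averaging per condition;
grand averages are unweighted means across animals. Component peaks are the
largest strict local extrema of the expected polarity (positive-up
convention; N components are minima) inside configurable windows — defaults
P1 [10, 30), N1 [30, 50), P2 [50, 100), N2 [100, 200) ms, anchored on the
30–50 ms negativity — with ties broken by earliest latency and monotone or
flat windows reported as not-found rather than returning an endpoint.
Complex amplitudes are peak-to-peak: `N1-P1 = P1 − N1`, `N1-P2 = P2 − N1`.
Event-related oscillations use a Morlet wavelet transform at a fixed 6
cycles per frequency, computed per trial and then averaged (total power,
i.e. evoked + induced; a phase-locked-only variant would transform the
average instead — the package computes total power and documents this as a
choice, since the two are not distinguished in the emulated analysis).
Frequencies whose 6-cycle wavelet exceeds the epoch raise with the minimum
feasible frequency rather than zero-padding silently. Evoked gamma is the
mean power over 40–80 Hz in a post-stimulus window.

## Synthetic data

The generator's defaults encode the emulated study's design: 240 standard
and 60 deviant tones (deviant probability 0.20), inter-stimulus interval
4 s, ERP window −50..450 ms, PAC grid and 50 surrogates as above. Ongoing
EEG per channel is 1/f pink noise (spectral shaping of white noise, exponent
1, 50 µV RMS — a declared convention, since absolute µV scales per structure
are not published) plus band-limited oscillator noise, plus shared
band-limited sources mixed across channels so that coherence follows the
common-source closed form
`C = a₁²a₂²σ_s⁴ / ((a₁²σ_s² + σ_n1²)(a₂²σ_s² + σ_n2²))`.
PAC carriers are deterministic sinusoids, `A₀(1 + κ·cos φ_L)·cos(2π f_H t)`
riding on a slow sinusoid, so the generated MI has the exact closed form
`κ·A₀/2`. ERP templates are sums of Gaussian bumps (standard: +20 µV @ 20 ms,
−40 @ 40, +25 @ 80, −15 @ 150; deviant N1 scaled to −52 µV), and each tone
adds a 60 Hz gamma burst (Gaussian envelope at 100 ± 25 ms; deviant 1.5×
standard amplitude). Deviant positions are uniform over non-adjacent
placements (no two consecutive deviants). The K18 effect profile multiplies
theta-band oscillator/source amplitudes, coupling κ, ERP amplitude and
evoked-gamma amplitude; because effects act on amplitudes, measured power
scales with the square of the factor. A master `SeedSequence` spawns
independent per-animal streams, so whole studies are bit-reproducible.

What the generator does *not* emulate: non-stationarity across vigilance
states, real artifact morphology (movement, chewing), volume-conduction
mixing beyond the explicit shared sources, spike-wave or epileptiform
events, and stochastic trial-to-trial ERP latency jitter. Passing tests
therefore demonstrate estimator correctness and sensitivity under the
declared generative model, not robustness to every pathology of real
recordings.

IHC micrographs are constructed with an exact DAB-positive pixel count:
brown pixels satisfy `(R − G)/B ≥ 0.5` with margin, all other pixels sit
strictly below threshold. The quantifier counts a pixel positive iff
`B > 0` and `(R − G)/B ≥ threshold` (B = 0 pixels are non-positive by
definition and tallied), restricted to a supplied ROI mask — atlas-based
ROI delineation is an input, not a computation.

## Problem sizes and numerical choices

Desk-scale analyses use 250–1000 Hz sampling and 10–60 s recordings; the
scaled group studies use 9 vs 8 animals with 48-standard oddball sessions at
1-s ISI, which preserves every design ratio (deviant fraction, effect sizes)
at a fraction of the full session length. Calibration checks use 40–100
null replicates and 50 replicate zero-effect studies. Tolerances in tests
come from the underlying statistics: 1% for the MI closed form (limited by
partial-cycle truncation), 0.02 for band-mean coherence at 200 windows
(per-bin estimates have SE ≈ 0.02 and are checked at the band level), 3
Monte-Carlo standard errors for flatness/bias checks, and exact equality
where construction guarantees it (DAB fractions, oddball counts,
self-coherence, relative-power normalisation at 1e-9).

## Known limitations

- EDF output uses a minimal 16-bit writer (1-s records, per-channel
  physical scaling); trailing partial seconds are zero-padded, and
  round-trips are exact only to the 16-bit quantization step.
- The artifact criterion and the surrogate construction are declared
  stand-ins where the emulated study's exact procedures are unpublished.
- `group_compare` implements only the pooled-variance t/CI comparison;
  hierarchical (mixed-model) inference is out of scope.
- Evoked gamma bursts are small relative to ongoing broadband power, so the
  gamma endpoint is the least sensitive of the group-study measures — as in
  real recordings.
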