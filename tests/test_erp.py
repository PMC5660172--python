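import numpy as np
import pandas as pd
import pytest

from tauconn.core_io import EpochSet, EventList, Recording
from tauconn.erp import (ERPAverage, average_erp, detect_components,
                         evoked_band_power, extract_erp_epochs, grand_average,
                         morlet_spectrogram)


def bump_waveform(times_ms, bumps):
    """Sum of narrow Gaussian bumps: (amplitude, centre ms, sigma ms)."""
    w = np.zeros_like(times_ms)
    for amp, centre, sigma in bumps:
        w += amp * np.exp(-0.5 * ((times_ms - centre) / sigma) ** 2)
    return w


def make_erp(waveform, fs=1000.0, labels=("A",), condition="standard"):
    times = (np.arange(waveform.size) / fs - 0.05) * 1000.0
    return ERPAverage(times=times, waveform=np.tile(waveform, (len(labels), 1)),
                      labels=labels, condition=condition,
                      n_trials=1)


def epochs_from_trials(trials, fs=1000.0, condition="standard"):
    """trials: (n, n_times) single-channel array aligned at -50 ms."""
    data = np.asarray(trials)[:, None, :]
    meta = pd.DataFrame({"state": ["unknown"] * len(trials),
                         "condition": [condition] * len(trials),
                         "artifact": [False] * len(trials),
                         "onset": np.arange(len(trials), dtype=float)})
    return EpochSet(data, fs, data.shape[2] / fs, ("A",), meta, tmin=-0.05)


class TestExtractEpochs:
    def test_epoch_per_event_with_labels(self, rng):
        fs = 500.0
        rec = Recording(rng.standard_normal((2, int(30 * fs))), fs, ("A", "B"))
        onsets = 1.0 + np.arange(20) * 1.0
        codes = ["deviant" if i % 5 == 0 else "standard" for i in range(20)]
        ep = extract_erp_epochs(rec, EventList(onsets, codes))
        assert ep.n_epochs == 20
        assert ep.epochs.shape[2] == int(0.5 * fs)
        assert ep.meta["condition"].tolist() == codes

    def test_boundary_events_skipped(self, rng):
        fs = 500.0
        rec = Recording(rng.standard_normal((1, int(5 * fs))), fs, ("A",))
        ep = extract_erp_epochs(rec, EventList([0.01, 2.0, 4.9],
                                               ["standard"] * 3))
        assert ep.n_epochs == 1  # first underruns, last overruns

    def test_no_events_errors(self, rng):
        rec = Recording(rng.standard_normal((1, 1000)), 500.0, ("A",))
        with pytest.raises(ValueError):
            extract_erp_epochs(rec, EventList([0.001], ["standard"]))


class TestAverageErp:
    def test_identical_epochs_identity(self):
        fs = 1000.0
        times = (np.arange(500) / fs - 0.05) * 1000
        w = bump_waveform(times, [(5.0, 100.0, 10.0)]) + 2.0  # +offset
        ep = epochs_from_trials(np.tile(w, (7, 1)))
        avg = average_erp(ep, "standard")
        base = (avg.times >= -50) & (avg.times < 0)
        corrected = w - w[base].mean()
        assert np.allclose(avg.waveform[0], corrected)
        assert avg.n_trials == 7

    def test_baseline_zero_mean(self, rng):
        ep = epochs_from_trials(rng.standard_normal((40, 500)) * 30)
        avg = average_erp(ep, "standard")
        base = (avg.times >= -50) & (avg.times < 0)
        assert abs(avg.waveform[0, base].mean()) < 1e-9

    def test_sqrt_n_noise_reduction(self, rng):
        fs, sigma, n = 1000.0, 20.0, 240
        times = (np.arange(500) / fs - 0.05) * 1000
        tmpl = bump_waveform(times, [(5, 20, 6), (-8, 40, 8), (6, 80, 15)])
        trials = tmpl + rng.standard_normal((n, 500)) * sigma
        avg = average_erp(epochs_from_trials(trials), "standard")
        rmse = np.sqrt(np.mean((avg.waveform[0] - tmpl) ** 2))
        assert abs(rmse - sigma / np.sqrt(n)) / (sigma / np.sqrt(n)) < 0.2

    def test_averaging_linearity(self, rng):
        fs = 1000.0
        times = (np.arange(500) / fs - 0.05) * 1000
        tmpl = bump_waveform(times, [(10.0, 120.0, 20.0)])
        trials = rng.standard_normal((15, 500)) * 10
        a = average_erp(epochs_from_trials(trials), "standard")
        b = average_erp(epochs_from_trials(trials + tmpl), "standard")
        base = (times >= -50) & (times < 0)
        tmpl_corr = tmpl - tmpl[base].mean()
        assert np.allclose(b.waveform[0], a.waveform[0] + tmpl_corr,
                           atol=1e-9)

    def test_missing_condition_errors(self, rng):
        ep = epochs_from_trials(rng.standard_normal((5, 500)))
        with pytest.raises(ValueError):
            average_erp(ep, "deviant")


class TestGrandAverage:
    def test_identity_symmetry_and_mean(self):
        fs = 1000.0
        times = (np.arange(500) / fs - 0.05) * 1000
        tmpl = bump_waveform(times, [(4.0, 60.0, 10.0)])
        erps = [make_erp(s * tmpl) for s in (1.0, 2.0, 3.0)]
        assert np.allclose(grand_average([erps[0]]).waveform,
                           erps[0].waveform)
        opp = [make_erp(tmpl), make_erp(-tmpl)]
        assert np.abs(grand_average(opp).waveform).max() < 1e-12
        ga = grand_average(erps)
        assert np.allclose(ga.waveform[0], 2.0 * tmpl)

    def test_mixed_conditions_error(self):
        a = make_erp(np.zeros(500), condition="standard")
        b = make_erp(np.zeros(500), condition="deviant")
        with pytest.raises(ValueError):
            grand_average([a, b])


class TestDetectComponents:
    def test_constructed_bumps_recovered(self):
        fs = 1000.0
        times = (np.arange(500) / fs - 0.05) * 1000
        w = bump_waveform(times, [(5.0, 20.0, 3.0), (-8.0, 40.0, 3.0),
                                  (6.0, 80.0, 5.0), (-3.0, 150.0, 8.0)])
        row = detect_components(make_erp(w, fs=fs)).iloc[0]
        assert row["P1_amp"] == pytest.approx(5.0, abs=1e-3)
        assert row["P1_lat"] == pytest.approx(20.0)
        assert row["N1_amp"] == pytest.approx(-8.0, abs=1e-3)
        assert row["N1_lat"] == pytest.approx(40.0)
        assert row["P2_amp"] == pytest.approx(6.0, abs=1e-3)
        assert row["N2_amp"] == pytest.approx(-3.0, abs=1e-3)
        assert row["N1_P1"] == pytest.approx(13.0, abs=2e-3)
        assert row["N1_P2"] == pytest.approx(14.0, abs=2e-3)

    def test_flat_waveform_not_found(self):
        table = detect_components(make_erp(np.zeros(500)))
        assert table.iloc[0][["P1_amp", "N1_amp", "P2_amp", "N2_amp",
                              "N1_P1", "N1_P2"]].isna().all()

    def test_monotone_segment_not_found(self):
        w = np.linspace(0.0, 10.0, 500)  # rising ramp: no local maximum
        row = detect_components(make_erp(w)).iloc[0]
        assert np.isnan(row["P1_amp"]) and np.isnan(row["N1_amp"])

    def test_tie_broken_by_earlier_latency(self):
        w = np.zeros(500)
        w[65] = w[75] = 4.0  # equal maxima at 15 ms and 25 ms
        row = detect_components(make_erp(w)).iloc[0]
        assert row["P1_lat"] == pytest.approx(15.0)

    def test_translation_covariance(self):
        fs = 1000.0
        times = (np.arange(500) / fs - 0.05) * 1000
        bumps = [(5.0, 20.0, 3.0), (-8.0, 40.0, 3.0)]
        base = detect_components(make_erp(bump_waveform(times, bumps), fs=fs),
                                 windows={"P1": (10, 30), "N1": (30, 50)})
        delta = 20.0
        shifted_w = bump_waveform(times, [(a, c + delta, s)
                                          for a, c, s in bumps])
        shifted = detect_components(
            make_erp(shifted_w, fs=fs),
            windows={"P1": (10 + delta, 30 + delta),
                     "N1": (30 + delta, 50 + delta)})
        assert shifted.iloc[0]["P1_lat"] == pytest.approx(
            base.iloc[0]["P1_lat"] + delta)
        assert shifted.iloc[0]["N1_lat"] == pytest.approx(
            base.iloc[0]["N1_lat"] + delta)

    def test_bad_window_errors(self):
        with pytest.raises(ValueError):
            detect_components(make_erp(np.zeros(500)),
                              windows={"P1": (400.0, 900.0)})


class TestMorlet:
    def test_single_burst_ridge(self):
        fs = 1000.0
        t = np.arange(500) / fs
        env = np.exp(-0.5 * ((t - 0.15) / 0.02) ** 2)  # 100 ms post-stimulus
        sig = env * np.cos(2 * np.pi * 60 * t)
        ep = epochs_from_trials(np.tile(sig, (5, 1)), fs=fs)
        tf = morlet_spectrogram(ep, "standard", freqs=np.arange(20.0, 101.0))
        burst = (tf.times >= 50) & (tf.times <= 150)
        ridge = tf.freqs[np.argmax(tf.power[0][:, burst].mean(axis=1))]
        # a 20 ms Gaussian burst is ~8 Hz wide; allow one 1-Hz bin of slack
        assert abs(ridge - 60.0) <= 1.0
        assert (tf.power >= 0).all()

    def test_two_disjoint_ridges(self):
        fs = 1000.0
        t = np.arange(500) / fs
        sig = (np.exp(-0.5 * ((t - 0.12) / 0.015) ** 2) * np.cos(2 * np.pi * 30 * t)
               + np.exp(-0.5 * ((t - 0.35) / 0.015) ** 2) * np.cos(2 * np.pi * 70 * t))
        ep = epochs_from_trials(np.tile(sig, (3, 1)), fs=fs)
        tf = morlet_spectrogram(ep, "standard", freqs=np.arange(20.0, 101.0))
        early = (tf.times >= 50) & (tf.times <= 90)
        late = (tf.times >= 280) & (tf.times <= 320)
        early_ridge = tf.freqs[np.argmax(tf.power[0][:, early].mean(axis=1))]
        late_ridge = tf.freqs[np.argmax(tf.power[0][:, late].mean(axis=1))]
        assert abs(early_ridge - 30.0) <= 1.0
        assert abs(late_ridge - 70.0) <= 1.0

    def test_infeasible_frequencies_error(self, rng):
        ep = epochs_from_trials(rng.standard_normal((3, 500)))
        with pytest.raises(ValueError):
            morlet_spectrogram(ep, "standard", freqs=np.arange(1.0, 101.0))
        with pytest.raises(ValueError):
            morlet_spectrogram(ep, "standard", freqs=np.array([600.0]))


class TestEvokedBandPower:
    def test_constant_map(self):
        from tauconn.erp import TFMap
        tf_times = np.linspace(-50, 450, 250)
        tf = TFMap(times=tf_times, freqs=np.arange(20.0, 101.0),
                   power=np.full((1, 81, 250), 3.5), labels=("A",),
                   condition="standard", n_trials=1)
        assert evoked_band_power(tf, (40, 80), (0, 200)) == pytest.approx(3.5)
        with pytest.raises(ValueError):
            evoked_band_power(tf, (500, 600), (0, 200))

    def test_burst_above_prestimulus(self, rng):
        fs = 1000.0
        t = np.arange(500) / fs
        env = np.exp(-0.5 * ((t - 0.15) / 0.02) ** 2)
        trials = (env * np.cos(2 * np.pi * 60 * t)
                  + rng.standard_normal((20, 500)) * 0.1)
        ep = epochs_from_trials(trials, fs=fs)
        tf = morlet_spectrogram(ep, "standard", freqs=np.arange(30.0, 91.0))
        post = evoked_band_power(tf, (40, 80), (50, 150))
        pre = evoked_band_power(tf, (40, 80), (-50, 0))
        assert post > pre
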