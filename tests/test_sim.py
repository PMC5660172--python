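import numpy as np
import pytest

from tauconn.core_io import segment_epochs
from tauconn.sim import (GroupEffect, OddballSpec, Oscillator, PACComponent,
                         SharedSource, SimSpec, apply_group_effect,
                         default_study_spec, erp_template_waveform,
                         simulate_dab_image, simulate_group_study,
                         simulate_oddball_session, simulate_pac_signal,
                         simulate_recording, DEFAULT_ERP_TEMPLATES)
from tauconn.spectral import band_power, power_spectrum
from tauconn.erp import average_erp, extract_erp_epochs
from tauconn.histo import dab_positive_fraction


class TestSpecValidation:
    def test_kappa_bounds(self):
        with pytest.raises(ValueError):
            PACComponent(8.0, 70.0, kappa=1.5, carrier_amp=1.0)
        with pytest.raises(ValueError):
            simulate_pac_signal(8.0, 70.0, -0.1, 10.0, 500.0)

    def test_negative_rms_rejected(self):
        with pytest.raises(ValueError):
            Oscillator(8.0, 2.0, rms=-1.0)
        with pytest.raises(ValueError):
            SharedSource({"A": 1.0}, rms=-5.0)

    def test_oddball_spec_bounds(self):
        with pytest.raises(ValueError):
            OddballSpec(p_deviant=0.0)
        with pytest.raises(ValueError):
            OddballSpec(isi=0.3)


class TestSimulateRecording:
    def test_seed_determinism(self):
        spec = default_study_spec(seed=5, duration=10.0, fs=500.0)
        a = simulate_recording(spec)
        b = simulate_recording(spec)
        assert np.array_equal(a.data, b.data)

    def test_theta_rms_doubling_quadruples_power(self):
        def theta_abs(rms, seed):
            spec = SimSpec(seed=seed, fs=250.0, duration=120.0, labels=("A",),
                           background_rms=5.0,
                           oscillators={"A": (Oscillator(7.5, 3.0, rms),)})
            spec_out = power_spectrum(
                segment_epochs(simulate_recording(spec)), 1.0, 100.0)
            sel = (spec_out.freqs >= 6) & (spec_out.freqs <= 9)
            return spec_out.abs_power[0, sel].sum()

        ratios = [theta_abs(40.0, s) / theta_abs(20.0, s) for s in (1, 2, 3)]
        assert abs(np.mean(ratios) - 4.0) / 4.0 < 0.1

    def test_common_source_coherence_level(self):
        # weights (1, 1), white background; sigma_s^2 chosen for coh = 0.5
        share = np.sqrt(np.sqrt(0.5) / (1 - np.sqrt(0.5)))  # sigma_s/sigma_n
        spec = SimSpec(seed=9, fs=250.0, duration=800.0, labels=("A", "B"),
                       background_rms=10.0, background_exponent=0.0,
                       sources=(SharedSource({"A": 1.0, "B": 1.0},
                                             rms=10.0 * share),))
        from tauconn.connectivity import band_coherence, msc_coherence
        cs = msc_coherence(segment_epochs(simulate_recording(spec)),
                           ("A", "B"), fmax=100.0)
        assert abs(band_coherence(cs, (10.0, 90.0)) - 0.5) < 0.05


class TestSimulatePacSignal:
    def test_closed_form_mi(self):
        from tauconn.pac import comodulogram
        rec = simulate_pac_signal(8.0, 70.0, 0.8, 30.0, 500.0)
        com = comodulogram(rec, "PAC", 0.0, 30.0)
        cell = com.mi[com.phase_freqs == 8.0][0, com.amp_freqs == 70.0][0]
        assert abs(cell - 0.4) / 0.4 < 0.01

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            simulate_pac_signal(70.0, 8.0, 0.5, 10.0, 500.0)


class TestOddballSession:
    def test_design_counts_and_spacing(self):
        base = default_study_spec(seed=3, fs=500.0)
        rec, ev = simulate_oddball_session(OddballSpec(), base)
        assert len(ev) == 300
        assert ev.codes.count("deviant") == 60
        assert ev.codes.count("standard") == 240
        assert np.allclose(np.diff(ev.onsets), 4.0)

    def test_no_consecutive_deviants(self):
        for seed in range(5):
            base = default_study_spec(seed=seed, fs=250.0)
            _, ev = simulate_oddball_session(
                OddballSpec(n_standard=40, isi=1.0), base)
            dev = [c == "deviant" for c in ev.codes]
            assert not any(a and b for a, b in zip(dev, dev[1:]))

    def test_non_integral_allocation_warns(self):
        with pytest.warns(UserWarning):
            OddballSpec(n_standard=10, p_deviant=0.17).n_total

    def test_template_recovery(self):
        base = default_study_spec(seed=3, fs=500.0)
        ospec = OddballSpec()
        rec, ev = simulate_oddball_session(ospec, base)
        avg = average_erp(extract_erp_epochs(rec, ev), "standard")
        tmpl = erp_template_waveform(DEFAULT_ERP_TEMPLATES["standard"], rec.fs)
        tb = np.arange(int(round(0.3 * rec.fs))) / rec.fs
        burst = (ospec.gamma_amp["standard"]
                 * np.exp(-0.5 * ((tb * 1000 - 100) / 25) ** 2)
                 * np.cos(2 * np.pi * 60 * tb))
        injected = tmpl + burst
        mask = (avg.times >= 0) & (avg.times < 300)
        rmse = np.sqrt(np.mean((avg.channel("CA3_L")[mask] - injected) ** 2))
        assert rmse < 0.10 * np.abs(injected).max()


class TestGroupStudy:
    def test_master_seed_reproducibility(self):
        base = default_study_spec(seed=0, fs=250.0, duration=10.0)
        ospec = OddballSpec(n_standard=8, isi=1.0)
        eff = GroupEffect(theta_amplitude=0.7)
        a = simulate_group_study((2, 2), base, ospec, eff, seed=42)
        b = simulate_group_study((2, 2), base, ospec, eff, seed=42)
        for grp in ("buffer", "k18"):
            for (ra, ea), (rb, eb) in zip(a[grp], b[grp]):
                assert np.array_equal(ra.data, rb.data)
                assert ea.codes == eb.codes

    def test_effect_multipliers_applied(self):
        base = default_study_spec(seed=0)
        ospec = OddballSpec()
        eff = GroupEffect(theta_amplitude=0.7, kappa=0.5, erp_scale=0.7)
        k18_base, k18_odd = apply_group_effect(base, ospec, eff)
        assert k18_base.oscillators["PFC_L"][0].rms == pytest.approx(
            base.oscillators["PFC_L"][0].rms * 0.7)
        assert k18_base.sources[0].rms == pytest.approx(
            base.sources[0].rms * 0.7)  # theta-band source
        assert k18_base.pac["CA1_R"].kappa == pytest.approx(
            base.pac["CA1_R"].kappa * 0.5)
        assert k18_odd.erp_scale == pytest.approx(0.7)

    def test_invalid_group_size(self):
        base = default_study_spec(seed=0)
        with pytest.raises(ValueError):
            simulate_group_study((1, 5), base, OddballSpec(), GroupEffect(), 0)


class TestDabImage:
    def test_exact_fraction_and_determinism(self):
        img, roi = simulate_dab_image(100, 100, 0.37, seed=7)
        res = dab_positive_fraction(img, roi)
        assert res.fraction == pytest.approx(0.37, abs=1e-12)
        img2, _ = simulate_dab_image(100, 100, 0.37, seed=7)
        assert np.array_equal(img, img2)

    def test_zero_fraction(self):
        img, roi = simulate_dab_image(50, 40, 0.0, seed=1)
        assert dab_positive_fraction(img, roi).fraction == 0.0

    def test_validation(self):
        with pytest.raises(ValueError):
            simulate_dab_image(10, 10, 1.5)
        with pytest.raises(ValueError):
            simulate_dab_image(10, 10, 0.5, roi=np.zeros((10, 10), bool))
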