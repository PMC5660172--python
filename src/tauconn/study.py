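"""Cohort-level endpoint extraction for simulated two-group studies.

Reduces one animal's oddball session to the scalar endpoints the group
comparison uses: theta-band PFC-HPC coherence, theta-gamma modulation index
at the coupled CA1 site, the N1-P1 complex amplitude of the standard ERP,
relative theta power, and evoked gamma power.
"""

from __future__ import annotations

import numpy as np

from . import connectivity, erp, pac, spectral
from .core_io import EventList, Recording, segment_epochs

__all__ = ["analyze_session", "study_endpoints"]

THETA = (4.0, 12.0)


def analyze_session(rec: Recording, events: EventList,
                    coh_pairs: tuple[tuple[str, str], ...] = (
                        ("PFC_L", "CA1_L"), ("PFC_R", "CA1_R")),
                    pac_channel: str = "CA1_R",
                    pac_cell: tuple[float, float] = (8.0, 70.0),
                    erp_channel: str = "PFC_R",
                    with_gamma: bool = True) -> dict[str, float]:
    """Scalar endpoints of one animal's session."""
    epochs = segment_epochs(rec)
    out: dict[str, float] = {}

    coh = [connectivity.band_coherence(
        connectivity.msc_coherence(epochs, p, fmax=min(100.0, rec.fs / 2 - 1)),
        THETA) for p in coh_pairs]
    out["theta_coherence"] = float(np.mean(coh))

    spec = spectral.power_spectrum(epochs, 1.0, min(100.0, rec.fs / 2 - 1))
    bp = spectral.band_power(spec, {"theta": THETA})
    out["theta_rel_power"] = float(bp["rel_power"].mean())

    f_low, f_high = pac_cell
    ph = pac.analytic_decompose(rec, pac_channel, f_low, 2.0)
    am = pac.analytic_decompose(rec, pac_channel, f_high,
                                max(10.0, 2.0 * f_low))
    edge = max(ph.n_edge, am.n_edge)
    sl = slice(edge, rec.n_samples - edge)
    out["theta_gamma_mi"] = pac.modulation_index(ph.phase[sl],
                                                 am.amplitude[sl])

    ep = erp.extract_erp_epochs(rec, events)
    comp = erp.detect_components(erp.average_erp(ep, "standard"))
    row = comp[comp["channel"] == erp_channel].iloc[0]
    out["n1_p1"] = float(row["N1_P1"])

    if with_gamma:
        tf = erp.morlet_spectrogram(ep, "standard",
                                    freqs=np.arange(30.0, 91.0))
        out["evoked_gamma"] = erp.evoked_band_power(
            tf, (40.0, 80.0), (50.0, 150.0), channel=erp_channel)
    return out


def study_endpoints(cohorts: dict[str, list], **kwargs
                    ) -> dict[str, dict[str, np.ndarray]]:
    """Per-group arrays of endpoints, ready for :func:`connectivity.group_compare`."""
    out: dict[str, dict[str, np.ndarray]] = {}
    for group, sessions in cohorts.items():
        vals: dict[str, list[float]] = {}
        for rec, events in sessions:
            for k, v in analyze_session(rec, events, **kwargs).items():
                vals.setdefault(k, []).append(v)
        out[group] = {k: np.asarray(v) for k, v in vals.items()}
    return out
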