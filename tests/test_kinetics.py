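import numpy as np
import pandas as pd
import pytest

import porekinetics as pk
from porekinetics.events import EVENT_COLUMNS, EventTable
from porekinetics.exceptions import UsageError, ValidationError
from porekinetics.kinetics import (ConcentrationSeries, compute_kd, conductance,
                                   estimate_concentration, fit_koff, fit_kon,
                                   mode_interevent_durations, mode_probabilities)


def _hsumo1_series(order=(0, 1, 2)):
    c = np.array([65e-9, 130e-9, 260e-9])[list(order)]
    ton = np.array([0.125, 0.069, 0.035])[list(order)]
    toff = np.array([0.015, 0.016, 0.014])[list(order)]
    return ConcentrationSeries(concentrations=c, tau_on=ton, tau_off=toff)


class TestFitKon:
    def test_through_origin_slope_on_published_dwell_means(self):
        k = fit_kon(_hsumo1_series())
        assert k.value == pytest.approx(1.11e8, rel=0.005)
        assert k.diagnostics["method"] == "through_origin"

    def test_single_entry_falls_back_to_reciprocal(self):
        s = ConcentrationSeries(concentrations=[65e-9], tau_on=[0.125],
                                tau_off=[0.015])
        with pytest.warns(UserWarning, match="single concentration"):
            k = fit_kon(s)
        assert k.value == pytest.approx(1.0 / (65e-9 * 0.125), rel=1e-12)

    def test_exactly_proportional_data_gives_slope_to_machine_precision(self):
        slope = 7.7e7
        c = np.array([1e-8, 5e-8, 2e-7])
        s = ConcentrationSeries(concentrations=c, tau_on=1.0 / (slope * c),
                                tau_off=np.full(3, 0.01))
        k = fit_kon(s)
        assert k.value == pytest.approx(slope, rel=1e-12)
        assert k.se == pytest.approx(0.0, abs=slope * 1e-9)


class TestFitKoff:
    def test_mean_reciprocal_of_published_capture_durations(self):
        k = fit_koff(_hsumo1_series())
        assert k.value == pytest.approx(66.9, abs=0.1)

    def test_identical_durations_give_zero_se(self):
        s = ConcentrationSeries(concentrations=[1e-8, 2e-8],
                                tau_on=[0.1, 0.05], tau_off=[0.02, 0.02])
        k = fit_koff(s)
        assert k.value == pytest.approx(50.0)
        assert k.se == pytest.approx(0.0)


class TestComputeKd:
    @pytest.mark.parametrize("kon,koff,kd_nM", [
        (1.12e8, 74.5, 665.0),   # hSUMO1
        (0.83e8, 72.4, 872.0),   # WDR5
        (6.62e7, 12.0, 181.0),   # EGFR short-lived mode
        (2.89e7, 1.01, 34.9),    # EGFR long-lived mode
        (1.0, 1.0, 1e9),
    ])
    def test_published_rate_pairs(self, kon, koff, kd_nM):
        kd = compute_kd(kon, koff)
        assert kd.value * 1e9 == pytest.approx(kd_nM, rel=0.005)

    def test_se_propagation(self):
        kd = compute_kd((1.0e8, 0.1e8), (50.0, 5.0))
        rel = np.sqrt(0.1 ** 2 + 0.1 ** 2)
        assert kd.se == pytest.approx(kd.value * rel, rel=1e-9)

    def test_zero_kon_rejected(self):
        with pytest.raises(ValidationError):
            compute_kd(0.0, 70.0)

    def test_invariant_under_concentration_relabeling(self):
        for order in ((0, 1, 2), (2, 0, 1), (1, 2, 0)):
            s = _hsumo1_series(order)
            kd = compute_kd(fit_kon(s), fit_koff(s))
            assert kd.value == pytest.approx(
                compute_kd(fit_kon(_hsumo1_series()), fit_koff(_hsumo1_series())).value,
                rel=1e-12)


def _labeled_table(pattern):
    """pattern: list of (cls, duration, mode, censored)."""
    rows, t = [], 0.0
    for cls, dur, mode, cens in pattern:
        rows.append(dict(start_s=t, duration_s=dur, cls=cls, mean_current_pA=10.0,
                         blockade_fraction=0.5 if cls == "captured" else np.nan,
                         mode=mode, censored=cens))
        t += dur
    return EventTable(df=pd.DataFrame(rows, columns=EVENT_COLUMNS), deadtime=1e-4)


class TestModeProbabilities:
    def test_binomial_fractions(self):
        pattern = []
        for i in range(1000):
            mode = 1 if i < 720 else 2
            pattern.append(("released", 0.1, mode, i == 0))
            pattern.append(("captured", 0.05, mode, False))
        p = mode_probabilities(_labeled_table(pattern))
        assert p[1].value == pytest.approx(0.72)
        assert p[1].se == pytest.approx(np.sqrt(0.72 * 0.28 / 1000), rel=1e-6)

    def test_unlabeled_events_rejected(self):
        pattern = [("released", 0.1, 0, True), ("captured", 0.05, 0, False),
                   ("released", 0.1, 0, False)]
        with pytest.raises(UsageError):
            mode_probabilities(_labeled_table(pattern))


class TestModeInterevent:
    def test_released_time_is_summed_between_same_mode_captures(self):
        pattern = [
            ("released", 0.5, 2, True),      # censored lead-in
            ("captured", 0.05, 2, False),
            ("released", 0.3, 1, False),
            ("captured", 0.02, 1, False),    # mode-1 capture intervenes
            ("released", 0.4, 2, False),
            ("captured", 0.06, 2, False),    # wait for this: 0.3 + 0.4
            ("released", 0.2, 2, False),
            ("captured", 0.07, 2, False),    # wait: 0.2
            ("released", 0.1, 0, True),
        ]
        waits = mode_interevent_durations(_labeled_table(pattern), mode=2)
        np.testing.assert_allclose(waits, [0.7, 0.2])

    def test_mode_specific_wait_matches_per_mode_rate(self, egfr_scheme):
        conc = 20e-9
        path = pk.simulate_path(egfr_scheme, conc, 1500.0, seed=31)
        # perfect idealization straight from the generator path
        rows, t = [], 0.0
        for s, d in zip(path.states[:-1], path.dwells[:-1]):
            cls = "released" if s == 0 else "captured"
            rows.append((cls, d, int(s), False))
        rows[0] = (rows[0][0], rows[0][1], rows[0][2], True)
        table = _labeled_table(rows)
        waits = mode_interevent_durations(table, mode=2)
        expect = 1.0 / (2.89e7 * conc)
        se = waits.std(ddof=1) / np.sqrt(len(waits))
        assert abs(waits.mean() - expect) < 3 * se


class TestQuantification:
    def test_serum_level_from_long_mode_calibration(self):
        q = estimate_concentration(1.7, 2.9e7)
        assert q.concentration_nM == pytest.approx(20.3, abs=0.05)

    def test_reciprocal_identity(self):
        q = estimate_concentration(1.0 / 2.9e7, 2.9e7)
        assert q.concentration == pytest.approx(1.0)

    def test_se_propagation(self):
        q = estimate_concentration(1.7, 2.9e7, tau_on_se=0.5, k_on_se=0.2e7)
        rel = np.sqrt((0.5 / 1.7) ** 2 + (0.2 / 2.9) ** 2)
        assert q.se == pytest.approx(q.concentration * rel, rel=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            estimate_concentration(0.0, 2.9e7)


class TestConductance:
    @pytest.mark.parametrize("i,psi,g", [
        (32.1, 40.0, 0.80),   # FN3SUMO-tFhuA open current
        (39.5, 40.0, 0.99),   # Mb4-tFhuA open current
        (0.0, 40.0, 0.0),
    ])
    def test_values(self, i, psi, g):
        assert conductance(i, psi) == pytest.approx(g, abs=0.005)

    def test_zero_potential_rejected(self):
        with pytest.raises(ValidationError):
            conductance(10.0, 0.0)


def test_free_intercept_consistent_with_zero_on_simulated_series(hsumo1_scheme):
    rows = {"c": [], "ton": [], "toff": []}
    for i, conc in enumerate((65e-9, 130e-9, 260e-9)):
        path = pk.simulate_path(hsumo1_scheme, conc, 120.0, seed=50 + i)
        rows["c"].append(conc)
        rows["ton"].append(path.state_dwells(0).mean())
        rows["toff"].append(path.state_dwells(1).mean())
    s = ConcentrationSeries(concentrations=rows["c"], tau_on=rows["ton"],
                            tau_off=rows["toff"])
    k = fit_kon(s)
    d = k.diagnostics
    assert abs(d["free_intercept"]) < 3 * d["free_intercept_se"]
    assert k.value == pytest.approx(1.12e8, rel=0.1)
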