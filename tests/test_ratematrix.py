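import numpy as np
import pytest
from scipy import integrate, stats

import porekinetics as pk
from porekinetics.dwell import DwellSample
from porekinetics.exceptions import UsageError
from porekinetics.ratematrix import (AggregatedMarkovModel, AggregatedMarkovResults,
                                     SchemeComparison, apparent_substate_events,
                                     compare_schemes, dwell_pdf,
                                     fit_scheme_from_path)

LEVELS3 = {"O_on": 18.2, "O_off1": 6.4, "O_off2": 2.3}
EGFR_RATES = {"k_on_1": 6.62e7, "k_on_2": 2.89e7, "k_off_1": 12.0, "k_off_2": 1.01}
DEADTIME = 0.3321 / 3000.0


def _scheme(topology="two_mode", **extra):
    return pk.build_scheme(topology, {**EGFR_RATES, **extra}, LEVELS3)


class TestDwellPdf:
    def test_single_captured_state_is_plain_exponential(self):
        s = pk.build_scheme("bimolecular", {"k_on": 1e8, "k_off": 74.5},
                            {"O_on": 32.1, "O_off": 2.9})
        dens = dwell_pdf(s, 100e-9, "captured")
        t = np.linspace(0, 0.1, 200)
        np.testing.assert_allclose(dens.pdf(t), 74.5 * np.exp(-74.5 * t),
                                   rtol=1e-10, atol=1e-10)

    def test_independent_substates_reduce_to_entry_weighted_mixture(self):
        dens = dwell_pdf(_scheme(), 20e-9, "captured")
        w1 = 6.62 / (6.62 + 2.89)
        t = np.linspace(1e-4, 6.0, 500)
        mix = w1 * 12.0 * np.exp(-12.0 * t) + (1 - w1) * 1.01 * np.exp(-1.01 * t)
        assert np.max(np.abs(dens.pdf(t) - mix)) < 1e-10

    @pytest.mark.parametrize("topology,extra", [
        ("two_mode", {}),
        ("interconversion", {"k_12": 5.0, "k_21": 3.0}),
    ])
    def test_density_normalizes(self, topology, extra):
        dens = dwell_pdf(_scheme(topology, **extra), 20e-9, "captured")
        tmax = 50.0 / 1.01
        val, _ = integrate.quad(dens.pdf, 0, tmax, limit=300)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_matches_monte_carlo_dwells(self):
        s = _scheme("interconversion", k_12=8.0, k_21=4.0)
        dens = dwell_pdf(s, 20e-9, "captured")
        dw = pk.sample_class_dwells(s, 20e-9, "captured", 20_000, seed=5)
        assert stats.kstest(dw, dens.cdf).pvalue > 0.01


class TestSchemeFits:
    def _sim(self, scheme, duration, seed):
        return pk.simulate_path(scheme, 20e-9, duration, seed=seed)

    def test_two_mode_rates_recovered_within_3_se(self):
        scheme = _scheme()
        path = self._sim(scheme, 1200.0, seed=21)
        res = fit_scheme_from_path(path, scheme, "two_mode", 20e-9, DEADTIME, seed=0)
        truth = EGFR_RATES
        for name, true_val in truth.items():
            se = res.bse[name]
            assert np.isfinite(se) and se > 0
            assert abs(res.rates[name] - true_val) < 3.5 * se, name

    def test_interconversion_rates_hit_zero_boundary_on_null_data(self):
        scheme = _scheme()
        path = self._sim(scheme, 800.0, seed=22)
        res = fit_scheme_from_path(path, scheme, "interconversion", 20e-9,
                                   DEADTIME, seed=0)
        assert res.rates["k_12"] <= 0.05 * res.rates["k_off_1"]
        assert res.rates["k_21"] <= 0.05 * res.rates["k_off_1"]

    def test_strong_interconversion_rates_recovered(self):
        scheme = _scheme("interconversion", k_12=20.0, k_21=20.0)
        path = self._sim(scheme, 600.0, seed=23)
        res = fit_scheme_from_path(path, scheme, "interconversion", 20e-9,
                                   DEADTIME, seed=0)
        assert res.rates["k_12"] == pytest.approx(20.0, rel=0.35)
        assert res.rates["k_21"] == pytest.approx(20.0, rel=0.35)

    def test_marginal_fit_from_event_durations(self):
        scheme = _scheme()
        path = self._sim(scheme, 800.0, seed=24)
        rel = DwellSample(path.class_dwells(scheme, "released"), cls="released")
        cap = DwellSample(path.class_dwells(scheme, "captured"), cls="captured")
        res = AggregatedMarkovModel(rel, cap, "two_mode", 20e-9).fit(seed=0)
        assert res.rates["k_off_1"] == pytest.approx(12.0, rel=0.3)
        assert res.rates["k_off_2"] == pytest.approx(1.01, rel=0.3)


class TestCompare:
    def _result(self, topology, llf, nobs=100):
        class _M:  # minimal stand-in carrying the compared attributes
            pass
        m = _M()
        m.t_rel = np.zeros(nobs // 2)
        m.t_cap = np.zeros(nobs - nobs // 2)
        m.nobs = nobs
        return AggregatedMarkovResults(model=m, topology=topology, rates={},
                                       bse={}, llf=llf, concentration=20e-9)

    def test_identical_models_are_not_superior(self):
        m = self._result("two_mode", -100.0)
        cmp = compare_schemes(m, self._result("interconversion", -100.0))
        assert cmp.stat == 0.0
        assert not cmp.superior

    def test_boundary_llr_value_is_not_superior(self):
        # 2*dlogL exactly at the chi-square quantile: strict inequality
        thr = stats.chi2.ppf(0.95, 2)
        m1 = self._result("two_mode", 0.0)
        m2 = self._result("interconversion", thr / 2)
        cmp = compare_schemes(m1, m2, confidence=0.95)
        assert cmp.stat == pytest.approx(5.991, abs=1e-3)
        assert not cmp.superior

    def test_non_nested_order_rejected(self):
        m1 = self._result("interconversion", 0.0)
        m2 = self._result("two_mode", 0.0)
        with pytest.raises(UsageError):
            compare_schemes(m1, m2)


class TestObservationModel:
    def test_short_released_gaps_create_apparent_hops(self):
        scheme = _scheme()
        path = pk.StatePath(
            states=np.array([0, 1, 0, 2, 0, 1, 0]),
            dwells=np.array([0.5, 0.1, 5e-5, 0.2, 0.3, 0.1, 0.4]),
            total_duration=1.60005, censored_last=True,
        )
        rel, seqs = apparent_substate_events(path, scheme, deadtime=1e-4)
        assert len(seqs) == 2
        labels, durs = seqs.sequences[0]
        np.testing.assert_array_equal(labels, [0, 1])
        assert durs[0] == pytest.approx(0.1 + 5e-5)
        assert durs[1] == pytest.approx(0.2)
        np.testing.assert_array_equal(seqs.sequences[1][0], [0])
        # boundary released dwells are censored; only the interior one counts
        np.testing.assert_allclose(rel.durations, [0.3])

    def test_sufficient_stats_count_entries_hops_and_exits(self):
        seqs = pk.ratematrix.SubstateSequences(sequences=[
            (np.array([0, 1, 0]), np.array([0.1, 0.2, 0.3])),
            (np.array([1]), np.array([0.4])),
        ], deadtime=1e-4)
        st_ = seqs.sufficient_stats()
        np.testing.assert_array_equal(st_["B"], [1, 1])
        np.testing.assert_allclose(st_["T"], [0.4, 0.6])
        np.testing.assert_array_equal(st_["N"], [[0, 1], [1, 0]])
        np.testing.assert_array_equal(st_["E"], [1, 1])
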