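import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import porekinetics as pk
from porekinetics.events import (EVENT_COLUMNS, AmplitudeMixture, EventTable,
                                 assign_modes, normalized_blockade)
from porekinetics.exceptions import ValidationError


def _flat_trace(level, sigma, duration=2.0, fs=50_000.0, seed=0):
    rng = np.random.default_rng(seed)
    n = int(duration * fs)
    x = np.full(n, level) + (rng.normal(0, sigma, n) if sigma else 0.0)
    return pk.Trace(samples=x, dt=1.0 / fs, metadata={"filter_cutoff": None})


class TestBaseline:
    def test_recovers_open_level_under_noise(self):
        trace = _flat_trace(32.1, 1.0, seed=1)
        b = pk.estimate_baseline(trace)
        assert b.i0 == pytest.approx(32.1, abs=0.05)
        assert b.sigma == pytest.approx(1.0, rel=0.15)

    def test_noiseless_constant_trace_is_exact(self):
        b = pk.estimate_baseline(_flat_trace(18.2, 0.0))
        assert b.i0 == 18.2
        assert b.sigma < 1e-6

    def test_bimodal_trace_picks_the_open_peak(self, hsumo1_events):
        # ~9% occupancy in the blocked substate must not bias I_0
        assert hsumo1_events["baseline"].i0 == pytest.approx(32.1, rel=0.01)


def _rect_trace(blocks, duration=1.0, fs=50_000.0, i0=30.0, i_off=3.0):
    """Noiseless rectangular blockades: blocks = [(start_s, dur_s), ...]."""
    n = int(duration * fs)
    x = np.full(n, i0)
    for start, dur in blocks:
        a = int(start * fs)
        x[a:a + int(dur * fs)] = i_off
    return pk.Trace(samples=x, dt=1.0 / fs, metadata={"filter_cutoff": None})


class TestDetect:
    def test_rectangular_blockades_are_recovered(self):
        trace = _rect_trace([(0.2, 0.010), (0.5, 0.020)])
        b = pk.BaselineModel(i0=30.0, sigma=0.01)
        ev = pk.detect_events(trace, b, deadtime=0.001)
        cap = ev.captured()
        assert len(cap) == 2
        np.testing.assert_allclose(
            np.sort(cap["duration_s"]), [0.010, 0.020], atol=2 / 50_000.0)

    def test_subdeadtime_blockade_is_merged_away(self):
        trace = _rect_trace([(0.2, 0.0005), (0.5, 0.020)])
        b = pk.BaselineModel(i0=30.0, sigma=0.01)
        ev = pk.detect_events(trace, b, deadtime=0.001)
        assert len(ev.captured()) == 1
        # the dropped blockade's time stays inside the flanking released event
        total = ev.df["duration_s"].sum()
        assert total == pytest.approx(trace.duration, abs=2 / 50_000.0)

    def test_event_classes_alternate_and_times_conserve(self, hsumo1_events):
        ev = hsumo1_events["events"]
        cls = ev.df["cls"].to_numpy()
        assert np.all(cls[1:] != cls[:-1])
        assert ev.df["duration_s"].sum() == pytest.approx(
            hsumo1_events["trace"].duration,
            abs=len(ev.df) * hsumo1_events["trace"].dt)

    def test_roundtrip_recovers_dwells_beyond_deadtime(self, hsumo1_events):
        """simulate -> render (noise on) -> detect recovers >= 99 % of dwells
        longer than 5x deadtime, each within 2 samples."""
        path, scheme = hsumo1_events["path"], hsumo1_events["scheme"]
        ev = hsumo1_events["events"]
        dt = hsumo1_events["trace"].dt
        deadtime = ev.deadtime
        truth = path.dwells[path.states == 1][:-1 if path.states[-1] == 1 else None]
        truth = truth[truth > 5 * deadtime]
        detected = np.sort(ev.captured()["duration_s"].to_numpy())
        matched = 0
        for t in truth:
            err = np.min(np.abs(detected - t)) if len(detected) else np.inf
            matched += err <= 2.5 * dt
        assert matched / len(truth) >= 0.99

    def test_spike_filter_removes_brief_events(self):
        trace = _rect_trace([(0.2, 0.002), (0.5, 0.050)])
        b = pk.BaselineModel(i0=30.0, sigma=0.01)
        ev = pk.detect_events(trace, b, deadtime=0.0005, spike_cutoff=0.005)
        assert len(ev.captured()) == 1
        assert ev.captured()["duration_s"].iloc[0] == pytest.approx(0.050, abs=1e-4)


class TestBlockade:
    @pytest.mark.parametrize("i0,i_off,expected", [
        (32.1, 2.9, 0.910),    # deep hSUMO1-like blockade
        (18.2, 6.4, 0.648),    # shallow EGFR mode-1 blockade
        (5.0, 5.0, 0.0),
    ])
    def test_normalized_blockade_values(self, i0, i_off, expected):
        assert normalized_blockade(i0, i_off) == pytest.approx(expected, abs=5e-4)

    @given(i0=st.floats(0.1, 1000), frac=st.floats(0.0, 1.0),
           c=st.floats(0.01, 100))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, i0, frac, c):
        i_off = i0 * (1 - frac)
        assert normalized_blockade(c * i0, c * i_off) == pytest.approx(
            normalized_blockade(i0, i_off), abs=1e-9)

    def test_enhanced_current_flagged(self):
        with pytest.warns(UserWarning, match="enhanced"):
            v = normalized_blockade(10.0, 12.0)
        assert v < 0


def _mixture_table(n=1700, seed=0, means=(0.65, 0.86), sds=(0.03, 0.03), w1=0.72):
    rng = np.random.default_rng(seed)
    k = rng.random(n) < w1
    bf = np.where(k, rng.normal(means[0], sds[0], n), rng.normal(means[1], sds[1], n))
    rows = []
    t = 0.0
    for i, b in enumerate(bf):
        rows.append(dict(start_s=t, duration_s=0.01, cls="released",
                         mean_current_pA=20.0, blockade_fraction=np.nan,
                         mode=0, censored=i == 0))
        t += 0.01
        rows.append(dict(start_s=t, duration_s=0.01, cls="captured",
                         mean_current_pA=20 * (1 - b), blockade_fraction=b,
                         mode=0, censored=False))
        t += 0.01
    import pandas as pd
    table = EventTable(df=pd.DataFrame(rows, columns=EVENT_COLUMNS),
                       deadtime=1e-4)
    return table, k


class TestAmplitudeMixture:
    def test_two_peak_parameters_recovered(self):
        table, _ = _mixture_table()
        mix = pk.fit_amplitude_mixture(table, k=2, seed=0)
        (m1, s1, w1), (m2, s2, w2) = mix.peaks
        assert m1 == pytest.approx(0.65, abs=0.01)
        assert m2 == pytest.approx(0.86, abs=0.01)
        assert w1 == pytest.approx(0.72, abs=0.03)
        assert w2 == pytest.approx(0.28, abs=0.03)

    def test_single_gaussian_recovery(self):
        table, _ = _mixture_table(means=(0.5, 0.5), sds=(0.04, 0.04), w1=1.0)
        mix = pk.fit_amplitude_mixture(table, k=1, seed=0)
        m, s, w = mix.peaks[0]
        assert m == pytest.approx(0.5, abs=0.005)
        assert s == pytest.approx(0.04, abs=0.005)

    def test_extra_component_never_lowers_loglik(self):
        table, _ = _mixture_table()
        l1 = pk.fit_amplitude_mixture(table, k=1, seed=0).logL
        l2 = pk.fit_amplitude_mixture(table, k=2, seed=0).logL
        assert l2 > l1


class TestAssignModes:
    def _fig_mixture(self):
        return AmplitudeMixture(peaks=[(0.65, 0.03, 0.72), (0.86, 0.03, 0.28)],
                                logL=0.0, N=1000)

    def test_low_amplitude_event_is_mode_1(self):
        table, _ = _mixture_table(n=50)
        out = assign_modes(table, self._fig_mixture())
        cap = out.captured()
        low = cap[np.abs(cap["blockade_fraction"] - 0.65) < 0.02]
        assert (low["mode"] == 1).all()

    def test_posterior_tie_goes_to_lower_mode(self):
        mix = AmplitudeMixture(peaks=[(0.4, 0.05, 0.5), (0.8, 0.05, 0.5)],
                               logL=0.0, N=10)
        post = mix.posterior(np.array([0.6]))
        assert post[0, 0] == pytest.approx(post[0, 1])
        assert int(np.argmax(post[0])) == 0  # documented tie-break

    def test_labels_agree_with_generator_truth(self):
        table, truth_mode1 = _mixture_table(n=1000, seed=3)
        out = assign_modes(table, self._fig_mixture())
        cap = out.captured()
        labels = cap["mode"].to_numpy()
        agree = np.mean((labels == 1) == truth_mode1)
        assert agree >= 0.95

    def test_released_events_inherit_following_capture_mode(self):
        table, _ = _mixture_table(n=20, seed=4)
        out = assign_modes(table, self._fig_mixture())
        df = out.df
        rel_idx = df.index[df["cls"] == "released"]
        for i in rel_idx:
            if i + 1 in df.index:
                assert df.loc[i, "mode"] == df.loc[i + 1, "mode"]


def test_event_table_rejects_non_alternating_classes():
    import pandas as pd
    rows = [dict(start_s=0, duration_s=1, cls="released", mean_current_pA=30,
                 blockade_fraction=np.nan, mode=0, censored=True)] * 2
    with pytest.raises(ValidationError):
        EventTable(df=pd.DataFrame(rows, columns=EVENT_COLUMNS), deadtime=1e-4)
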