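"""Robust thresholding, peak coincidence, percentile split, Keeling
regression, delta notation, drift correction."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from antnest_seep import scenario
from antnest_seep.gaschem import (
    cluster_intercepts,
    coincident_peaks,
    delta_from_ratio,
    drift_correct,
    flag_ch4_peaks,
    flag_d13c_peaks,
    keeling_fit,
    keeling_per_window,
    mad_threshold,
    percentile_summary,
)
from antnest_seep.synthetic_data import simulate_gas

from conftest import noiseless


class TestMadThreshold:
    def test_constant_series_threshold_is_the_constant(self):
        assert mad_threshold([4.2] * 10) == 4.2

    def test_hand_computed_example(self):
        # median 3, MAD = median(|x-3|) = median(2,1,0,1,97) = 1 -> 3 + 2*1
        assert mad_threshold([1, 2, 3, 4, 100]) == 5.0

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=50),
           st.randoms())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_invariant_under_reordering(self, xs, rnd):
        shuffled = list(xs)
        rnd.shuffle(shuffled)
        assert mad_threshold(shuffled) == mad_threshold(xs)

    def test_robust_to_quarter_contamination(self, rng):
        base = rng.normal(2.0, 0.01, 100)
        clean = mad_threshold(base)
        contaminated = base.copy()
        contaminated[:25] = 1e6
        assert abs(mad_threshold(contaminated) - clean) < 0.1

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            mad_threshold([np.nan, np.nan, 1.0])


class TestFlags:
    def test_ch4_all_below_threshold(self):
        assert not flag_ch4_peaks([1.8, 1.9, 2.0], 2.1).any()

    def test_ch4_threshold_just_below_min(self):
        x = np.array([1.8, 1.9, 2.0])
        assert flag_ch4_peaks(x, 1.8 - 1e-9).all()

    def test_ch4_strict_inequality(self):
        assert not flag_ch4_peaks([2.0], 2.0).any()

    def test_d13c_literal_rule_as_written(self):
        x = np.array([-34.0, -36.0, 1.0, -0.5])
        got = flag_d13c_peaks(x, mode="literal")
        assert list(got) == [False, True, True, False]

    def test_d13c_deviation_rule_flags_injections(self):
        cfg = scenario("microbial-default", seed=1)
        gas = simulate_gas(noiseless(cfg))
        nest = gas[gas.channel == "nest"].reset_index(drop=True)
        flags = flag_d13c_peaks(nest.d13c, mode="deviation")
        t = np.arange(len(nest), dtype=float)
        in_event = np.zeros(len(nest), bool)
        for src in cfg.sources:
            in_event |= (t >= src.start) & (t < src.start + src.duration)
        assert not flags[~in_event].any()
        assert flags[in_event].sum() > 0

    def test_mode_must_be_explicit(self):
        with pytest.raises(ValueError):
            flag_d13c_peaks([1.0], mode="auto")


class TestCoincidence:
    ts = pd.date_range("2016-08-04", periods=120, freq="s", tz="UTC")

    def test_disjoint_flags_empty(self):
        a = np.zeros(120, bool)
        b = np.zeros(120, bool)
        a[10:30] = True
        b[60:90] = True
        assert len(coincident_peaks(self.ts, a, b)) == 0

    def test_identical_flags_windows_equal_runs(self):
        a = np.zeros(120, bool)
        a[10:30] = a[100:115] = True
        pk = coincident_peaks(self.ts, a, a, min_gap=5, min_samples=1,
                              min_run=1)
        assert len(pk) == 2
        assert pk.windows.start.iloc[0] == self.ts[10]
        assert pk.windows.end.iloc[0] == self.ts[29]
        assert pk.windows.n.tolist() == [20, 15]

    def test_short_and_fragmented_windows_filtered(self):
        a = np.zeros(120, bool)
        a[10:14] = True  # 4 consecutive < min_run 5
        every3 = np.zeros(120, bool)
        every3[40:80:3] = True  # 14 members, no run >= 2
        pk = coincident_peaks(self.ts, a | every3, a | every3)
        assert len(pk) == 0

    def test_tolerance_dilation_pairs_near_misses(self):
        a = np.zeros(120, bool)
        b = np.zeros(120, bool)
        a[50:70] = True
        b[52:72] = True  # offset by 2 s
        strict = coincident_peaks(self.ts, a, b, min_samples=1, min_run=1)
        tol = coincident_peaks(self.ts, a, b, tolerance=2.0, min_samples=1,
                               min_run=1)
        assert tol.windows.n.iloc[0] > strict.windows.n.iloc[0]

    def test_eight_event_scenario_recovers_eight_windows(self):
        cfg = scenario("microbial-default", seed=3)
        gas = simulate_gas(cfg)
        nest = gas[gas.channel == "nest"].reset_index(drop=True)
        thr = mad_threshold(nest.ch4)
        pk = coincident_peaks(
            nest.timestamp,
            flag_ch4_peaks(nest.ch4.to_numpy(), thr),
            flag_d13c_peaks(nest.d13c.to_numpy(), mode="deviation"))
        assert len(pk) == 8
        # every window lies inside one configured injection (allowing a few
        # chained merge gaps for chance flags at the window shoulders)
        slack = pd.Timedelta(seconds=300)
        starts = pd.DatetimeIndex(pk.windows.start)
        for src, w in zip(cfg.sources, starts):
            lo = cfg.start + pd.Timedelta(seconds=src.start)
            assert lo - slack <= w <= lo + pd.Timedelta(seconds=src.duration)


class TestPercentileSummary:
    def test_equal_values_above_q_empty(self):
        all_s, above = percentile_summary([5.0] * 10)
        assert all_s.n == 10
        assert above.n == 0

    def test_1_to_100_oracle(self):
        all_s, above = percentile_summary(np.arange(1.0, 101.0), q=0.9)
        assert above.n == 10
        assert above.mean == pytest.approx(95.5)
        assert above.min == 91.0
        assert all_s.mean == pytest.approx(50.5)
        assert all_s.se == pytest.approx(np.std(np.arange(1., 101.), ddof=1)
                                         / 10.0)

    def test_count_conservation(self, rng):
        x = rng.normal(size=500)
        all_s, above = percentile_summary(x, q=0.9)
        below_eq = int((x <= np.quantile(x, 0.9)).sum())
        assert all_s.n == above.n + below_eq


class TestKeeling:
    def test_exact_mixing_recovers_minus_69(self, mixing_points):
        fit = keeling_fit(*mixing_points)
        assert fit.intercept == pytest.approx(-69.0, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.ci95[0] <= fit.intercept <= fit.ci95[1]

    def test_exact_mixing_recovers_minus_37(self):
        c_a, d_a, d_s = 1.82, -47.0, -37.0
        excess = np.linspace(0.1, 0.9, 30)
        c = c_a + excess
        d = (c_a * d_a + excess * d_s) / c
        assert keeling_fit(c, d).intercept == pytest.approx(-37.0, abs=1e-9)

    def test_matches_normal_equation_oracle(self, rng):
        c = rng.uniform(1.9, 2.9, 200)
        d = rng.normal(-50, 2, 200)
        x = 1.0 / c
        # hand-solved 2x2 normal equations
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (d - d.mean())).sum() / sxx
        intercept = d.mean() - slope * x.mean()
        fit = keeling_fit(c, d)
        assert fit.slope == pytest.approx(slope, rel=1e-10)
        assert fit.intercept == pytest.approx(intercept, rel=1e-10)

    def test_unbiased_under_symmetric_noise(self, rng):
        """Mean intercept over 200 noisy repetitions stays within one CI
        width of the true signature."""
        c_a, d_a, d_s = 1.82, -47.0, -69.0
        excess = np.linspace(0.2, 1.0, 60)
        c = c_a + excess
        d_true = (c_a * d_a + excess * d_s) / c
        est, widths = [], []
        for _ in range(200):
            fit = keeling_fit(c, d_true + rng.normal(0, 0.8, c.size))
            est.append(fit.intercept)
            widths.append(fit.ci95[1] - fit.ci95[0])
        assert abs(np.mean(est) - d_s) < np.mean(widths)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            keeling_fit([2.0, 2.0, 2.0], [-50, -51, -52])
        with pytest.raises(ValueError):
            keeling_fit([2.0, 2.1], [-50, -51])

    def test_cluster_intercepts_two_sources(self):
        labels, centers = cluster_intercepts([-68.9, -37.2, -69.3, -36.8])
        assert list(labels) == [0, 1, 0, 1]
        assert centers[0] == pytest.approx(-69.1)
        assert centers[1] == pytest.approx(-37.0)


class TestDeltaNotation:
    def test_standard_gives_zero(self):
        assert delta_from_ratio(0.0112372, 0.0112372) == 0.0

    def test_one_percent_depletion(self):
        assert delta_from_ratio(0.99 * 0.0112372, 0.0112372) == \
            pytest.approx(-10.0)

    def test_small_enrichment(self):
        assert delta_from_ratio(1.001, 1.0) == pytest.approx(1.0)

    @given(st.floats(0.5, 1.5))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_ratio_roundtrip(self, f):
        d = delta_from_ratio(f * 0.0112372, 0.0112372)
        assert f == pytest.approx(1 + d / 1000.0)

    def test_zero_standard_rejected(self):
        with pytest.raises(ValueError):
            delta_from_ratio(1.0, 0.0)


class TestDriftCorrect:
    def _gas(self, drift=0.0, noise=0.0):
        cfg = scenario("null-default", seed=8)
        return dataclasses.replace(cfg, drift_ch4_per_day=drift,
                                   ch4_noise_sd=noise, d13c_noise_sd=0.0), \
            simulate_gas(dataclasses.replace(
                cfg, drift_ch4_per_day=drift, ch4_noise_sd=noise,
                d13c_noise_sd=0.0))

    def test_zero_drift_is_identity(self):
        cfg, gas = self._gas()
        out = drift_correct(gas, cfg.reference_ch4, cfg.reference_d13c)
        pd.testing.assert_frame_equal(out, gas)

    def test_constant_offset_removed(self):
        cfg, gas = self._gas()
        shifted = gas.copy()
        shifted["ch4"] = shifted["ch4"] + 0.05
        out = drift_correct(shifted, cfg.reference_ch4, cfg.reference_d13c)
        nest = out[out.channel == "nest"]
        assert np.allclose(nest.ch4, cfg.background_ch4, atol=1e-9)

    def test_linear_drift_reduced_below_noise(self):
        cfg, gas = self._gas(drift=0.05, noise=0.005)
        out = drift_correct(gas, cfg.reference_ch4, cfg.reference_d13c)
        nest = out[out.channel == "nest"]
        resid = nest.ch4 - cfg.background_ch4
        # interior of the reference bracketing; residual drift < noise SD
        assert abs(resid.mean()) < cfg.ch4_noise_sd

    def test_implausible_reference_run_excluded(self):
        cfg, gas = self._gas()
        bad = gas.copy()
        ref_idx = bad.index[bad.channel == "reference"][:300]
        bad.loc[ref_idx, "ch4"] += 5.0  # one absurd run
        out = drift_correct(bad, cfg.reference_ch4, cfg.reference_d13c)
        nest = out[out.channel == "nest"]
        assert np.allclose(nest.ch4, cfg.background_ch4, atol=1e-9)


class TestPipelineRecovery:
    @pytest.mark.parametrize("name,true", [("microbial-default", -69.0),
                                           ("fault-default", -37.0)])
    def test_signature_within_fit_ci_across_seeds(self, name, true):
        """End-to-end peak->Keeling chain: the configured end member lands
        inside the pooled fit's 95% CI in >= 90% of seeded runs."""
        hits = 0
        seeds = range(6)
        for seed in seeds:
            gas = simulate_gas(scenario(name, seed=seed))
            nest = gas[gas.channel == "nest"].reset_index(drop=True)
            pk = coincident_peaks(
                nest.timestamp,
                flag_ch4_peaks(nest.ch4.to_numpy(),
                               mad_threshold(nest.ch4)),
                flag_d13c_peaks(nest.d13c.to_numpy(), mode="deviation"))
            fits = keeling_per_window(nest, pk)
            pooled = keeling_fit(
                *_pool(nest, pk))
            hits += pooled.ci95[0] <= true <= pooled.ci95[1]
            assert len(fits) == 8
        assert hits / len(list(seeds)) >= 0.9


def _pool(nest, pk):
    ts = pd.DatetimeIndex(nest.timestamp)
    span = np.zeros(len(nest), bool)
    for _, w in pk.windows.iterrows():
        span |= (ts >= w.start) & (ts <= w.end)
    return nest.ch4[span], nest.d13c[span]
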