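"""Dwell-time rate estimation: CDF fits, model selection, bootstrap."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import dockfret as df
from dockfret.idealize import DOCKED, UNDOCKED, Dwell
from dockfret.kinetics import (DwellDistribution, ExponentialFit, KineticsConfig,
                               UnanalyzableState, bootstrap_rate,
                               cumulative_dwell_distribution, fit_dwell_cdf,
                               weighted_average_rate)

from conftest import sidecar_dwell_lists


def make_dwells(durations, state=UNDOCKED, dt=0.06):
    return [Dwell(state=state, n_frames=max(int(round(d / dt)), 1), duration=float(d),
                  left_censored=False, right_censored=False, mean_fret=0.5,
                  molecule_id="m") for d in durations]


def exp_dwells(k, n, seed, state=UNDOCKED):
    rng = np.random.default_rng(seed)
    return make_dwells(rng.exponential(1.0 / k, n), state=state)


class TestCumulativeDistribution:
    def test_worked_example(self):
        cfg = KineticsConfig(min_dwells=4, dead_time_frames=0)
        dist = cumulative_dwell_distribution(make_dwells([1, 2, 2, 5]), UNDOCKED, cfg)
        np.testing.assert_array_equal(dist.tau, [1, 2, 2, 5])
        np.testing.assert_array_equal(dist.y, [1, 3, 3, 4])

    def test_censored_dwells_excluded_by_default(self):
        dwells = make_dwells([1.0, 2.0]) + [
            Dwell(UNDOCKED, 10, 0.6, True, False, 0.5, "m"),
            Dwell(UNDOCKED, 10, 0.6, False, True, 0.5, "m"),
        ]
        cfg = KineticsConfig(min_dwells=2, dead_time_frames=0)
        dist = cumulative_dwell_distribution(dwells, UNDOCKED, cfg)
        assert dist.n_dwells == 2

    def test_dead_time_exclusion_sets_origin(self):
        dwells = make_dwells([0.06, 0.12, 0.3, 0.6, 1.2, 2.4] * 3)
        cfg = KineticsConfig(min_dwells=5)
        dist = cumulative_dwell_distribution(dwells, UNDOCKED, cfg)
        assert dist.t0 == pytest.approx(0.06)
        assert np.all(dist.tau > 0.06)

    def test_too_few_dwells_flagged(self):
        with pytest.raises(UnanalyzableState):
            cumulative_dwell_distribution(make_dwells([1.0] * 3), UNDOCKED)

    @given(st.lists(st.floats(0.1, 50.0), min_size=10, max_size=60))
    def test_cumulative_counts_non_decreasing(self, durations):
        cfg = KineticsConfig(min_dwells=10, dead_time_frames=0)
        dist = cumulative_dwell_distribution(make_dwells(durations), UNDOCKED, cfg)
        assert np.all(np.diff(dist.y) >= 0)
        assert dist.y[-1] == dist.n_dwells

    def test_exponential_median_is_ln2_over_k(self):
        dwells = exp_dwells(1.0, 10_000, seed=1)
        dist = cumulative_dwell_distribution(dwells, UNDOCKED,
                                             KineticsConfig(dead_time_frames=0))
        assert np.median(dist.tau) == pytest.approx(np.log(2), rel=0.05)


class TestCdfFit:
    def test_exact_single_exponential_recovery(self):
        """Noiseless CDF sampled at 50 points recovers k to <0.1%."""
        k, a = 1.35, 200.0
        tau = np.linspace(0.05, 4.0, 50)
        y = a * (1 - np.exp(-k * tau))
        dist = DwellDistribution(UNDOCKED, tau, y, 50, t0=0.0)
        fit = fit_dwell_cdf(dist)
        assert fit.params["k"] == pytest.approx(k, rel=1e-3)
        assert fit.params["A"] == pytest.approx(a, rel=1e-3)

    def test_simulated_sample_recovery(self):
        dwells = exp_dwells(0.5, 1000, seed=2)
        dist = cumulative_dwell_distribution(dwells, UNDOCKED)
        fit = fit_dwell_cdf(dist)
        assert weighted_average_rate(fit) == pytest.approx(0.5, rel=0.10)

    def test_genuine_two_component_sample_selects_double(self):
        rng = np.random.default_rng(3)
        fast = rng.exponential(1 / 5.0, 1000)
        slow = rng.exponential(1 / 0.5, 1000)
        dwells = make_dwells(np.concatenate([fast, slow]))
        dist = cumulative_dwell_distribution(dwells, UNDOCKED,
                                             KineticsConfig(dead_time_frames=0))
        fit = fit_dwell_cdf(dist)
        assert fit.model == "double"
        truth = 0.5 * 5.0 + 0.5 * 0.5
        assert weighted_average_rate(fit) == pytest.approx(truth, rel=0.15)

    def test_model_selection_specificity(self):
        """Double is never chosen over single truth (<=200 dwells, 100 runs)."""
        doubles = 0
        for s in range(100):
            dwells = exp_dwells(1.0, 200, seed=1000 + s)
            dist = cumulative_dwell_distribution(dwells, UNDOCKED)
            doubles += fit_dwell_cdf(dist).model == "double"
        assert doubles <= 5

    def test_consistency_error_shrinks_with_n(self):
        errs = []
        for n in (100, 400, 1600):
            rel = [abs(weighted_average_rate(fit_dwell_cdf(
                cumulative_dwell_distribution(exp_dwells(1.0, n, seed=s * 7 + n),
                                              UNDOCKED))) - 1.0)
                   for s in range(8)]
            errs.append(np.mean(rel))
        assert errs[2] < errs[0]


class TestWeightedAverage:
    def test_single_model_passthrough(self):
        fit = ExponentialFit("single", {"A": 1.0, "k": 2.0}, {}, 0.0, 50)
        assert weighted_average_rate(fit) == 2.0

    def test_double_model_arithmetic(self):
        fit = ExponentialFit("double", {"A1": 0.5, "k1": 2.0, "A2": 0.5, "k2": 4.0},
                             {}, 0.0, 50)
        assert weighted_average_rate(fit) == pytest.approx(3.0)

    @given(st.floats(0.01, 10), st.floats(0.01, 10), st.floats(0.01, 100),
           st.floats(0.01, 100))
    def test_average_bounded_by_components(self, a1, a2, k1, k2):
        fit = ExponentialFit("double", {"A1": a1, "k1": k1, "A2": a2, "k2": k2},
                             {}, 0.0, 50)
        avg = weighted_average_rate(fit)
        assert min(k1, k2) - 1e-9 <= avg <= max(k1, k2) + 1e-9


class TestBootstrap:
    def test_identical_traces_give_zero_sd(self):
        trace = exp_dwells(1.0, 30, seed=5)
        res = bootstrap_rate([trace] * 10, UNDOCKED, B=50, seed=0)
        assert res.sd == 0.0

    def test_sd_stabilizes_with_replicates(self):
        cfg = df.SimulationConfig(rng_seed=17)
        _, sc = df.simulate_condition_dataset(cfg, 25)
        lists = sidecar_dwell_lists(sc)
        sd1 = bootstrap_rate(lists, UNDOCKED, B=1000, seed=0).sd
        sd2 = bootstrap_rate(lists, UNDOCKED, B=4000, seed=1).sd
        assert abs(sd1 - sd2) < 0.15 * sd1

    def test_needs_two_traces(self):
        with pytest.raises(ValueError):
            bootstrap_rate([exp_dwells(1.0, 30, seed=5)], UNDOCKED, B=10, seed=0)


class TestConditionEstimates:
    def test_state_label_swap_swaps_estimates(self):
        cfg = df.SimulationConfig(rng_seed=19)
        ds, _ = df.simulate_condition_dataset(cfg, 60)
        acc, _ = df.select_traces(ds)
        its = [df.idealize_two_state(a) for a in acc]
        kd, ku = df.estimate_rates_for_condition(its, bootstrap=False)
        flipped = []
        for it in its:
            f = df.IdealizedTrace(
                molecule_id=it.molecule_id,
                state_path=(1 - it.state_path).astype(np.int8),
                efficiency=it.efficiency,
                state_means=it.state_means[::-1].copy(),
                state_sds=it.state_sds[::-1].copy(),
                frame_interval=it.frame_interval,
                n_transitions=it.n_transitions,
            )
            flipped.append(f)
        kd2, ku2 = df.estimate_rates_for_condition(flipped, bootstrap=False)
        assert kd2.value == pytest.approx(ku.value, rel=1e-9)
        assert ku2.value == pytest.approx(kd.value, rel=1e-9)

    def test_fast_undocking_underestimated_but_flagged(self):
        """k_undock = 11/s sits at the 60 ms resolution: biased low, warned."""
        cfg = df.SimulationConfig(rng_seed=2, k_dock=4.3, k_undock=11.0, mu_undock=0.73)
        ds, _ = df.simulate_condition_dataset(cfg, 120)
        acc, _ = df.select_traces(ds)
        its = [df.idealize_two_state(a) for a in acc]
        _, ku = df.estimate_rates_for_condition(its, bootstrap=False)
        assert ku.value == pytest.approx(11.0, rel=0.4)
        assert ku.warnings  # time-resolution flag raised

    def test_no_dynamic_traces_is_unanalyzable(self):
        cfg = df.SimulationConfig(rng_seed=1, static_fraction=1.0)
        ds, _ = df.simulate_condition_dataset(cfg, 15)
        acc, _ = df.select_traces(ds)
        its = [df.idealize_two_state(a) for a in acc]
        with pytest.raises(UnanalyzableState):
            df.estimate_rates_for_condition(its, bootstrap=False)
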