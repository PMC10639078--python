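"""Two-state idealization, dwell extraction and transition maps."""

import numpy as np
import pytest

import dockfret as df
from dockfret.idealize import DOCKED, UNDOCKED, extract_dwells
from dockfret.qc import compute_fret

from conftest import two_level_trace


class TestIdealization:
    def test_noiseless_alternation_recovered_exactly(self):
        path = np.tile(np.r_[np.zeros(50), np.ones(50)], 5).astype(int)
        ft = compute_fret(two_level_trace(path))
        it = df.idealize_two_state(ft)
        np.testing.assert_array_equal(it.state_path, path[: len(it.state_path)])
        assert it.state_means == pytest.approx([0.5, 0.95], abs=1e-9)
        assert it.n_transitions == 9

    def test_constant_trace_is_static(self):
        rng = np.random.default_rng(3)
        eff = 0.6 + rng.normal(0, 0.1, 500)
        tr = df.IntensityTrace((1 - eff) * 500, eff * 500, 0.06)
        it = df.idealize_two_state(compute_fret(tr))
        assert it.n_transitions == 0 and not it.is_dynamic
        assert it.state_means[0] == it.state_means[1] == pytest.approx(np.mean(eff), abs=0.02)

    def test_frame_accuracy_at_study_conditions(self):
        """>=95% of frames labeled correctly at SNR 5, mu 0.57/0.98."""
        cfg = df.SimulationConfig(rng_seed=7)
        ds, sc = df.simulate_condition_dataset(cfg, 40)
        acc, _ = df.select_traces(ds)
        scmap = {s.molecule_id: s for s in sc}
        ok = tot = 0
        for ft in acc:
            s = scmap[ft.molecule_id]
            if s.static:
                continue
            it = df.idealize_two_state(ft)
            n = min(len(it.state_path), len(s.state_path))
            ok += np.sum(it.state_path[:n] == s.state_path[:n])
            tot += n
        assert tot > 1000
        assert ok / tot >= 0.95

    def test_label_order_is_canonical(self, accepted_traces):
        for ft in accepted_traces:
            it = df.idealize_two_state(ft)
            assert it.state_means[0] <= it.state_means[1]

    def test_agrees_with_hmmlearn_on_dynamic_trace(self):
        """Independent HMM implementation assigns the same frames (>=97%)."""
        from hmmlearn.hmm import GaussianHMM

        cfg = df.SimulationConfig(rng_seed=13)
        ds, _ = df.simulate_condition_dataset(cfg, 6)
        acc, _ = df.select_traces(ds)
        ft = next(a for a in acc if df.idealize_two_state(a).is_dynamic)
        it = df.idealize_two_state(ft)
        x = ft.prebleach.reshape(-1, 1)
        m = GaussianHMM(n_components=2, covariance_type="diag", n_iter=200,
                        init_params="", params="stmc", tol=1e-5)
        m.startprob_ = np.array([0.5, 0.5])
        m.transmat_ = np.array([[0.95, 0.05], [0.05, 0.95]])
        lo, hi = np.percentile(x, [10, 90])
        m.means_ = np.array([[lo], [hi]])
        m.covars_ = np.array([[0.01], [0.01]])
        m.fit(x)
        ref = m.predict(x)
        if m.means_[0, 0] > m.means_[1, 0]:
            ref = 1 - ref
        assert np.mean(ref == it.state_path) >= 0.97

    def test_static_high_fret_molecules_not_split_by_noise_tail(self):
        cfg = df.SimulationConfig(rng_seed=4, static_fraction=1.0)
        ds, _ = df.simulate_condition_dataset(cfg, 25)
        acc, _ = df.select_traces(ds)
        its = [df.idealize_two_state(a) for a in acc]
        frac_static = np.mean([not it.is_dynamic for it in its])
        assert frac_static >= 0.9


class TestDwells:
    def test_worked_example(self):
        path = np.r_[np.zeros(10), np.ones(20), np.zeros(5)].astype(int)
        ft = compute_fret(two_level_trace(path))
        it = df.idealize_two_state(ft)
        d = extract_dwells(it)
        assert len(d) == 3
        assert (d[0].state, d[0].duration, d[0].left_censored) == (UNDOCKED, pytest.approx(0.6), True)
        assert (d[1].state, d[1].duration, d[1].censored) == (DOCKED, pytest.approx(1.2), False)
        assert (d[2].state, d[2].duration, d[2].right_censored) == (UNDOCKED, pytest.approx(0.3), True)

    def test_static_trace_single_fully_censored_dwell(self):
        path = np.zeros(200, int)
        ft = compute_fret(two_level_trace(path))
        d = extract_dwells(df.idealize_two_state(ft))
        assert len(d) == 1
        assert d[0].left_censored and d[0].right_censored

    def test_durations_sum_to_analyzed_duration(self, accepted_traces):
        for ft in accepted_traces:
            it = df.idealize_two_state(ft)
            total = sum(d.duration for d in extract_dwells(it))
            assert total == pytest.approx(len(it.state_path) * it.frame_interval, abs=1e-9)


class TestTransitionMaps:
    def _itraces(self, seed=4, static=0.0, n=40):
        cfg = df.SimulationConfig(rng_seed=seed, static_fraction=static)
        ds, _ = df.simulate_condition_dataset(cfg, n)
        acc, _ = df.select_traces(ds)
        return [df.idealize_two_state(a) for a in acc]

    def test_tdp_single_transition_lobe(self):
        path = np.r_[np.zeros(120), np.ones(120)].astype(int)
        it = df.idealize_two_state(compute_fret(two_level_trace(path)))
        tdp = df.build_tdp([it])
        assert len(tdp.entries) == 1
        x, y, w = tdp.entries[0]
        assert (x, y) == pytest.approx((0.5, 0.95), abs=1e-9)
        iy, ix = np.unravel_index(np.argmax(tdp.grid), tdp.grid.shape)
        centers = 0.5 * (tdp.edges[:-1] + tdp.edges[1:])
        assert centers[ix] == pytest.approx(0.5, abs=0.01)
        assert centers[iy] == pytest.approx(0.95, abs=0.01)

    def test_tdp_lobes_near_true_state_means(self):
        its = self._itraces()
        tdp = df.build_tdp(its)
        ups = [(x, y) for x, y, _ in tdp.entries if y > x]
        xs, ys = np.mean([p[0] for p in ups]), np.mean([p[1] for p in ups])
        assert xs == pytest.approx(0.57, abs=0.03)
        assert ys == pytest.approx(0.98, abs=0.03)

    def test_todp_weight_is_one_per_molecule(self):
        its = self._itraces(static=0.3)
        todp = df.build_todp(its)
        assert todp.total_weight == pytest.approx(len(its), abs=1e-9)

    def test_todp_all_static_on_diagonal(self):
        cfg = df.SimulationConfig(rng_seed=10, static_fraction=1.0)
        ds, _ = df.simulate_condition_dataset(cfg, 20)
        acc, _ = df.select_traces(ds)
        its = [df.idealize_two_state(a) for a in acc]
        todp = df.build_todp(its)
        assert todp.diagonal_fraction == pytest.approx(1.0, abs=0.05)

    def test_todp_all_dynamic_off_diagonal(self):
        its = [it for it in self._itraces() if it.is_dynamic]
        todp = df.build_todp(its)
        assert todp.diagonal_fraction == pytest.approx(0.0, abs=1e-9)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            df.build_tdp([])
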