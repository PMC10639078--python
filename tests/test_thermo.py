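"""Histograms, two-Gaussian populations, free energies, m-values, Phi."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import dockfret as df
from dockfret.constants import RT_KCAL_PER_MOL
from dockfret.qc import compute_fret
from dockfret.thermo import (FretHistogram, TitrationPoint, build_fret_histogram,
                             compute_delta_g, compute_phi, delta_g_from_keq,
                             fit_m_value, fit_two_gaussians)

from conftest import two_level_trace


def hist_from_values(values, n_molecules=1):
    counts, edges = np.histogram(values, bins=70, range=(-0.2, 1.2))
    return FretHistogram(edges=edges, counts=counts.astype(float),
                         n_molecules=n_molecules)


class TestHistogram:
    def test_pools_first_100_frames_per_molecule(self):
        traces = [compute_fret(two_level_trace(np.zeros(150, int), molecule_id=f"m{i}"))
                  for i in range(2)]
        hist = build_fret_histogram(traces)
        assert hist.counts.sum() == 200

    def test_single_value_occupies_one_bin(self):
        ft = compute_fret(two_level_trace(np.zeros(120, int), mu=(0.5, 0.9)))
        hist = build_fret_histogram([ft])
        assert np.count_nonzero(hist.counts) == 1

    def test_bimodal_modes_near_state_means(self):
        cfg = df.SimulationConfig(rng_seed=12)
        ds, _ = df.simulate_condition_dataset(cfg, 80)
        acc, _ = df.select_traces(ds)
        hist = build_fret_histogram(acc)
        fit = fit_two_gaussians(hist)
        assert fit.mu_undock == pytest.approx(0.57, abs=0.03)
        assert fit.mu_dock == pytest.approx(0.98, abs=0.03)


class TestTwoGaussians:
    def test_recovery_of_printed_populations(self):
        """Mixture at the published means/weights (0.57 61% / 0.98 39%)."""
        rng = np.random.default_rng(1)
        n = 20_000
        docked = rng.random(n) < 0.39
        vals = np.where(docked, rng.normal(0.98, 0.06, n), rng.normal(0.57, 0.12, n))
        fit = fit_two_gaussians(hist_from_values(vals, 200))
        assert fit.mu_undock == pytest.approx(0.57, abs=0.02)
        assert fit.mu_dock == pytest.approx(0.98, abs=0.02)
        frac = fit.fractions
        assert frac[0] == pytest.approx(0.61, abs=0.05)
        assert frac[1] == pytest.approx(0.39, abs=0.05)

    def test_equal_mixture_has_unit_auc_ratio(self):
        rng = np.random.default_rng(2)
        n = 20_000
        vals = np.concatenate([rng.normal(0.5, 0.08, n // 2),
                               rng.normal(0.95, 0.08, n // 2)])
        fit = fit_two_gaussians(hist_from_values(vals))
        assert fit.auc_high / fit.auc_mid == pytest.approx(1.0, abs=0.05)

    def test_unimodal_sample_flagged_near_degenerate(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0.6, 0.03, 20_000)
        fit = fit_two_gaussians(hist_from_values(vals))
        assert fit.near_degenerate or min(fit.fractions) < 0.02

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(4)
        vals = np.concatenate([rng.normal(0.5, 0.1, 5000), rng.normal(0.9, 0.1, 2000)])
        fit = fit_two_gaussians(hist_from_values(vals))
        assert sum(fit.fractions) == pytest.approx(1.0, abs=1e-9)


class TestDeltaG:
    def test_equal_areas_give_zero(self):
        assert delta_g_from_keq(1.0) == 0.0

    def test_keq_e_gives_minus_rt(self):
        assert delta_g_from_keq(np.e) == pytest.approx(-RT_KCAL_PER_MOL, abs=1e-9)
        assert delta_g_from_keq(np.e) == pytest.approx(-0.5825, abs=1e-4)

    def test_reciprocity(self):
        for k in (0.2, 1.7, 42.0):
            assert delta_g_from_keq(1 / k) == pytest.approx(-delta_g_from_keq(k), abs=1e-12)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            delta_g_from_keq(0.0)


class TestMValue:
    @staticmethod
    def points(concs, dgs, sds=None):
        sds = sds or [float("nan")] * len(concs)
        return [TitrationPoint(c, float(np.exp(-g / RT_KCAL_PER_MOL)), g, sd)
                for c, g, sd in zip(concs, dgs, sds)]

    def test_exact_line_recovered(self):
        c = [0.0, 1.0, 2.0, 3.0, 4.0]
        pts = self.points(c, [0.26 + 0.32 * ci for ci in c])
        fit = fit_m_value(pts)
        assert fit.m_value == pytest.approx(0.32, abs=1e-12)
        assert fit.intercept == pytest.approx(0.26, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_free_energy_means_zero_m(self):
        fit = fit_m_value(self.points([0, 1, 2, 3], [0.5] * 4))
        assert fit.m_value == pytest.approx(0.0, abs=1e-12)

    def test_weighted_fit_uses_bootstrap_errors(self):
        c = [0.0, 1.0, 2.0, 3.0]
        dgs = [0.0, 0.3, 0.65, 0.9]
        fit_w = fit_m_value(self.points(c, dgs, sds=[0.05] * 4), weighted=True)
        assert fit_w.slope_se == pytest.approx(0.05 / np.sqrt(5.0), rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_m_value(self.points([0, 1], [0, 1]))


class TestPhi:
    def test_published_endpoint_values(self):
        bsu = compute_phi({0.0: (1.35, 0.5), 4.0: (0.1, 2.3)})
        tte = compute_phi({0.0: (4.3, 1.2), 4.0: (0.5, 11.0)})
        assert round(bsu.phi, 2) == 0.63
        assert round(tte.phi, 2) == 0.49

    def test_constant_k_undock_gives_exactly_one(self):
        res = compute_phi({0.0: (1.35, 0.5), 2.0: (0.7, 0.5), 4.0: (0.31, 0.5)})
        assert res.phi == 1.0

    def test_endpoint_and_slope_agree_on_exact_lfe(self):
        gt = df.TitrationGroundTruth(m_eq=0.32, phi=0.63)
        rates = {c: df.titration_rates(gt, c)[:2] for c in gt.concentrations}
        pe = compute_phi(rates, "endpoint").phi
        ps = compute_phi(rates, "slope").phi
        assert pe == pytest.approx(0.63, abs=1e-9)
        assert ps == pytest.approx(pe, abs=1e-9)

    def test_unchanged_equilibrium_is_undefined(self):
        with pytest.raises(ValueError):
            compute_phi({0.0: (1.0, 1.0), 4.0: (2.0, 2.0)})

    @given(st.floats(0.1, 5), st.floats(0.1, 5), st.floats(0.1, 5))
    def test_phi_invariant_to_rate_rescaling(self, kd0, ku0, scale):
        """Multiplying all rates by one factor leaves Phi unchanged."""
        base = {0.0: (kd0, ku0), 4.0: (kd0 * 0.2, ku0 * 3.0)}
        scaled = {c: (kd * scale, ku * scale) for c, (kd, ku) in base.items()}
        assert compute_phi(scaled).phi == pytest.approx(compute_phi(base).phi, rel=1e-9)


class TestKineticThermodynamicConsistency:
    def test_histogram_and_kinetic_keq_agree(self):
        """Same simulated condition: population Keq vs k_dock/k_undock."""
        cfg = df.SimulationConfig(rng_seed=14, k_dock=0.676, k_undock=0.751)
        ds, _ = df.simulate_condition_dataset(cfg, 100)
        acc, _ = df.select_traces(ds)
        its = [df.idealize_two_state(a) for a in acc]
        kd, ku = df.estimate_rates_for_condition(its, bootstrap=False)
        keq_kin = kd.value / ku.value
        point = compute_delta_g(fit_two_gaussians(build_fret_histogram(acc)))
        # the two estimators carry opposite-sign camera-resolution biases
        # of up to ~15% each plus sampling noise; they must still agree on
        # the log scale within 0.5 (a factor ~1.6)
        assert abs(np.log(point.keq) - np.log(keq_kin)) < 0.5
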