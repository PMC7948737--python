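"""Reciprocal-line diagnostics, global fitting, model comparison and bootstrap."""

import numpy as np
import pytest

from glycokinetics.data import NoiseSpec
from glycokinetics.mechanism_inference import (
    FitOptions,
    aicc,
    bootstrap_uncertainty,
    compare_mechanisms,
    cooperativity_fold,
    fit_global,
    fit_reciprocal_lines,
)
from glycokinetics.mechanism_inference import (
    test_parallel_vs_intersecting as parallel_vs_intersecting,
)
from glycokinetics.mechanism_inference import (
    test_yaxis_intersection as yaxis_intersection,
)
from glycokinetics.rate_laws import (
    KineticParameters,
    Mechanism,
    intersection_point,
    reciprocal_line_analytic,
)
from glycokinetics.synthetic_data import simulate_velocity_dataset
from glycokinetics.data import VelocityDataset, VelocityObservation


def exact_data(params, mechanism, replicates=1):
    return simulate_velocity_dataset(
        params, replicates=replicates, noise=NoiseSpec(), mechanism=mechanism
    )


class TestReciprocalLines:
    def test_exact_data_matches_analytic_lines(self, exact_dataset, reported_params):
        lines = fit_reciprocal_lines(exact_dataset, varying="B")
        assert len(lines) == 5
        for line in lines:
            ref = reciprocal_line_analytic(
                Mechanism.RANDOM_RAPID_EQUILIBRIUM,
                reported_params,
                line.fixed_cosubstrate_conc,
                "B",
            )
            assert line.slope == pytest.approx(ref.slope, rel=1e-9)
            assert line.intercept == pytest.approx(ref.intercept, rel=1e-9)

    def test_single_fixed_level_rejected(self, reported_params):
        ds = simulate_velocity_dataset(
            reported_params, a_levels=[250.0], b_levels=[1560.0, 6250.0, 25000.0],
            replicates=1, noise=NoiseSpec(),
        )
        with pytest.raises(ValueError, match="2 usable"):
            fit_reciprocal_lines(ds, varying="B")

    def test_nonpositive_velocities_excluded_with_warning(self, exact_dataset):
        obs = list(exact_dataset.observations)
        broken = obs[:-1] + [
            VelocityObservation(
                a_conc=obs[-1].a_conc, b_conc=obs[-1].b_conc, velocity=-obs[-1].velocity
            )
        ]
        ds = VelocityDataset(tuple(broken), exact_dataset.enzyme_conc)
        with pytest.warns(UserWarning, match="nonpositive velocity"):
            lines = fit_reciprocal_lines(ds, varying="B")
        assert sum(l.n_points for l in lines) == 24

    def test_fitted_lines_intersect_at_closed_form_point(self, exact_dataset, reported_params):
        lines = fit_reciprocal_lines(exact_dataset, varying="B")
        x_ref, y_ref = intersection_point(reported_params, "B")
        # pairwise intersections of the fitted lines collapse onto the oracle point
        for l1, l2 in zip(lines[:-1], lines[1:]):
            x = -(l1.intercept - l2.intercept) / (l1.slope - l2.slope)
            y = l1.y_at(x)
            assert x == pytest.approx(x_ref, rel=1e-6)
            assert y == pytest.approx(y_ref, rel=1e-6)


class TestDiagnostics:
    def test_exact_random_data_intersecting_and_off_axis(self, exact_dataset):
        d1 = parallel_vs_intersecting(exact_dataset)
        d2 = yaxis_intersection(exact_dataset)
        assert d1.decision == "intersecting"
        assert d2.decision == "off_y_axis"
        assert d1.p_value < 1e-6 and d2.p_value < 1e-6

    def test_exact_ping_pong_data_parallel(self, reported_params):
        ds = exact_data(reported_params, Mechanism.PING_PONG)
        d = parallel_vs_intersecting(ds)
        assert d.decision == "parallel"
        assert d.statistic == 0.0

    def test_exact_ordered_data_on_y_axis(self, reported_params):
        ds = exact_data(reported_params, Mechanism.ORDERED_RAPID_EQUILIBRIUM_A_FIRST)
        assert yaxis_intersection(ds).decision == "on_y_axis"
        # but the lines do intersect (not parallel)
        assert parallel_vs_intersecting(ds).decision == "intersecting"

    def test_identical_lines_flagged_degenerate(self):
        # one substrate saturating at every "fixed" level: all lines coincide
        obs = []
        for a in (1e9, 2e9):
            for b in (100.0, 200.0, 400.0, 800.0):
                v = 10.0 * b / (50.0 + b)
                obs.append(VelocityObservation(a_conc=a, b_conc=b, velocity=v))
        ds = VelocityDataset(tuple(obs), enzyme_conc=1.0)
        assert parallel_vs_intersecting(ds).decision == "degenerate"

    def test_small_alpha_intercepts_still_distinguished_on_exact_data(self):
        """Near the alpha->0 boundary the intercept spread shrinks but exact data
        still resolves it; the decision threshold only matters under noise."""
        p = KineticParameters(k_cat=35.8, K_A=216.0, K_B=8990.0, alpha=1e-3, enzyme_conc=1.25)
        ds = exact_data(p, Mechanism.RANDOM_RAPID_EQUILIBRIUM)
        assert yaxis_intersection(ds).decision == "off_y_axis"


class TestGlobalFit:
    @pytest.mark.parametrize("mechanism", list(Mechanism))
    def test_noiseless_roundtrip_recovers_generators(self, reported_params, mechanism):
        ds = exact_data(reported_params, mechanism)
        res = fit_global(ds, mechanism)
        assert res.converged
        assert res.estimates.k_cat == pytest.approx(reported_params.k_cat, rel=1e-6)
        assert res.estimates.K_A == pytest.approx(reported_params.K_A, rel=1e-6)
        assert res.estimates.K_B == pytest.approx(reported_params.K_B, rel=1e-6)
        if mechanism is Mechanism.RANDOM_RAPID_EQUILIBRIUM:
            assert res.estimates.alpha == pytest.approx(reported_params.alpha, rel=1e-6)

    def test_no_cooperativity_data_recovers_alpha_one(self):
        p = KineticParameters(k_cat=35.8, K_A=216.0, K_B=8990.0, alpha=1.0, enzyme_conc=1.25)
        ds = exact_data(p, Mechanism.RANDOM_RAPID_EQUILIBRIUM)
        res = fit_global(ds, Mechanism.RANDOM_RAPID_EQUILIBRIUM)
        assert abs(res.estimates.alpha - 1.0) < 1e-4

    def test_fit_invariant_to_observation_order(self, exact_dataset):
        res1 = fit_global(exact_dataset, Mechanism.RANDOM_RAPID_EQUILIBRIUM)
        shuffled = VelocityDataset(
            tuple(np.random.default_rng(1).permutation(np.array(exact_dataset.observations, dtype=object))),
            exact_dataset.enzyme_conc,
        )
        res2 = fit_global(shuffled, Mechanism.RANDOM_RAPID_EQUILIBRIUM)
        assert res1.estimates.K_A == pytest.approx(res2.estimates.K_A, rel=1e-9)
        assert res1.estimates.alpha == pytest.approx(res2.estimates.alpha, rel=1e-9)

    def test_fit_invariant_to_consistent_unit_rescaling(self, exact_dataset):
        """Scaling velocities and enzyme by the same factor leaves (k_cat, K, alpha) fixed."""
        scale = 10.0
        obs = tuple(
            VelocityObservation(o.a_conc, o.b_conc, o.velocity * scale)
            for o in exact_dataset.observations
        )
        ds = VelocityDataset(obs, exact_dataset.enzyme_conc * scale)
        res = fit_global(ds, Mechanism.RANDOM_RAPID_EQUILIBRIUM)
        ref = fit_global(exact_dataset, Mechanism.RANDOM_RAPID_EQUILIBRIUM)
        assert res.estimates.k_cat == pytest.approx(ref.estimates.k_cat, rel=1e-8)
        assert res.estimates.K_B == pytest.approx(ref.estimates.K_B, rel=1e-8)

    def test_single_substrate_level_rejected(self, reported_params):
        ds = simulate_velocity_dataset(
            reported_params, a_levels=[250.0], b_levels=[1560.0, 25000.0],
            replicates=2, noise=NoiseSpec(),
        )
        with pytest.raises(ValueError, match="2 distinct levels"):
            fit_global(ds, Mechanism.RANDOM_RAPID_EQUILIBRIUM)

    def test_noiseless_standard_errors_are_tiny(self, exact_dataset):
        res = fit_global(exact_dataset, Mechanism.RANDOM_RAPID_EQUILIBRIUM)
        for se in res.standard_errors.values():
            assert 0 <= se < 1e-6


class TestModelComparison:
    @pytest.mark.parametrize("mechanism", list(Mechanism))
    def test_noiseless_data_selects_generating_mechanism(self, reported_params, mechanism):
        ds = exact_data(reported_params, mechanism)
        comparison = compare_mechanisms(ds, with_diagnostics=False)
        assert comparison.selected is mechanism
        assert comparison.delta_aicc[mechanism] == 0.0

    def test_diagnostics_attached_and_consistent(self, exact_dataset):
        comparison = compare_mechanisms(exact_dataset)
        decisions = {d.test_name: d.decision for d in comparison.diagnostics}
        assert decisions["parallel_vs_intersecting"] == "intersecting"
        assert decisions["yaxis_intersection"] == "off_y_axis"

    def test_aicc_formula(self):
        # direct evaluation of n ln(RSS/n) + 2k + 2k(k+1)/(n-k-1)
        assert aicc(2.0, 25, 4) == pytest.approx(
            25 * np.log(2.0 / 25) + 8 + 2 * 4 * 5 / 20
        )
        assert aicc(1.0, 5, 4) == np.inf  # n <= k+1 unscorable


class TestBootstrap:
    def test_same_seed_gives_identical_intervals(self, reported_params):
        ds = simulate_velocity_dataset(
            reported_params, replicates=3, noise=NoiseSpec(cv=0.05, seed=5)
        )
        b1 = bootstrap_uncertainty(ds, Mechanism.RANDOM_RAPID_EQUILIBRIUM, n_boot=120, seed=9)
        b2 = bootstrap_uncertainty(ds, Mechanism.RANDOM_RAPID_EQUILIBRIUM, n_boot=120, seed=9)
        assert b1.intervals == b2.intervals

    def test_noiseless_intervals_degenerate(self, exact_dataset):
        b = bootstrap_uncertainty(exact_dataset, Mechanism.RANDOM_RAPID_EQUILIBRIUM, n_boot=120, seed=0)
        for lo, hi in b.intervals.values():
            assert hi - lo == pytest.approx(0.0, abs=1e-6 * max(abs(hi), 1.0))

    def test_small_n_boot_warns(self, exact_dataset):
        with pytest.warns(UserWarning, match="n_boot"):
            bootstrap_uncertainty(exact_dataset, Mechanism.RANDOM_RAPID_EQUILIBRIUM, n_boot=50, seed=0)


class TestCooperativity:
    def test_reported_alpha_reads_as_fourfold(self, exact_dataset):
        res = fit_global(exact_dataset, Mechanism.RANDOM_RAPID_EQUILIBRIUM)
        fold = cooperativity_fold(res)
        assert fold.fold == pytest.approx(1 / 0.24, rel=1e-6)
        assert fold.rounded == 4

    @pytest.mark.parametrize("alpha, expected", [(1.0, 1.0), (0.5, 2.0)])
    def test_simple_folds(self, alpha, expected):
        p = KineticParameters(k_cat=35.8, K_A=216.0, K_B=8990.0, alpha=alpha, enzyme_conc=1.25)
        ds = exact_data(p, Mechanism.RANDOM_RAPID_EQUILIBRIUM)
        res = fit_global(ds, Mechanism.RANDOM_RAPID_EQUILIBRIUM)
        assert cooperativity_fold(res).fold == pytest.approx(expected, rel=1e-4)
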