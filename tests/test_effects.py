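"""Functional effects, Shapley values, interactions, correlations, epistasis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import subcomm as sc
from subcomm.landscape import landscape_from_values
from conftest import random_params


class TestFunctionalEffects:
    def test_p2_worked_example(self, landscape2):
        """v({})=0, v({A})=3, v({B})=1, v({A,B})=5: effects of A are 3 and 4."""
        edges = sc.functional_effects(landscape2, "A")
        by_bg = {e.background: e.delta_function for e in edges}
        assert by_bg[(0, 0)] == pytest.approx(3.0)
        assert by_bg[(0, 1)] == pytest.approx(4.0)

    def test_constant_landscape_zero_effects(self, panel3):
        params = sc.LandscapeParams(panel3, 9.0, np.zeros(3), np.zeros((3, 3)))
        land = sc.generate_landscape(params)
        for strain in panel3.strain_ids:
            assert all(e.delta_function == 0 for e in sc.functional_effects(land, strain))

    def test_edge_count_on_complete_p8(self):
        land = sc.generate_landscape(sc.study_preset(seed=0))
        assert len(sc.functional_effects(land, "NS1")) == 128

    def test_noiseless_effect_formula(self, panel3):
        """sigma=0: Delta_i(S) = beta_i + sum_{j in S} gamma_ij exactly."""
        rng = np.random.default_rng(8)
        params = random_params(panel3, rng)
        land = sc.generate_landscape(params)
        for i, strain in enumerate(panel3.strain_ids):
            for e in sc.functional_effects(land, strain):
                expected = params.beta[i] + sum(
                    params.gamma[i, j] for j in range(3) if e.background[j]
                )
                assert e.delta_function == pytest.approx(expected, abs=1e-10)

    def test_incomplete_landscape_partial_edges(self, panel2):
        land = landscape_from_values(panel2, {(0, 0): 1.0, (1, 0): 4.0, (0, 1): 2.0})
        assert len(sc.functional_effects(land, "A")) == 1
        with pytest.raises(ValueError, match="B"):
            sc.functional_effects(
                landscape_from_values(panel2, {(1, 0): 4.0}), "B"
            )


class TestShapley:
    def test_p2_worked_example(self, landscape2):
        phi = sc.shapley_exact(landscape2).phi
        assert np.allclose(phi, [3.5, 1.5])
        assert np.allclose(sc.shapley_by_orderings(landscape2).phi, [3.5, 1.5])

    def test_additive_landscape_phi_equals_beta(self, panel3):
        beta = np.array([2.0, -1.0, 0.25])
        params = sc.LandscapeParams(panel3, 5.0, beta, np.zeros((3, 3)))
        land = sc.generate_landscape(params)
        assert np.allclose(sc.shapley_exact(land).phi, beta, atol=1e-12)

    def test_p1_ordering_oracle(self):
        panel = sc.StrainPanel(("X",))
        land = landscape_from_values(panel, {(0,): 2.0, (1,): 7.0})
        assert sc.shapley_by_orderings(land).phi[0] == pytest.approx(5.0)

    @given(st.integers(0, 10_000), st.integers(2, 6))
    @settings(max_examples=25, deadline=None)
    def test_exact_equals_orderings(self, seed, p):
        """Subset-weighted Shapley == all-orderings average, p <= 6 random landscapes."""
        panel = sc.default_panel(p)
        params = random_params(panel, np.random.default_rng(seed), sigma=1.0, n_reps=2)
        land = sc.generate_landscape(params)
        a = sc.shapley_exact(land).phi
        b = sc.shapley_by_orderings(land).phi
        assert np.allclose(a, b, atol=1e-10)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_efficiency(self, seed):
        """Sum of phi = v(full) - v(degrader alone), machine precision."""
        panel = sc.default_panel(4)
        params = random_params(panel, np.random.default_rng(seed), sigma=2.0, n_reps=3)
        land = sc.generate_landscape(params)
        means = land.mean_function()
        total = means[(1, 1, 1, 1)] - means[(0, 0, 0, 0)]
        assert sc.shapley_exact(land).phi.sum() == pytest.approx(total, abs=1e-10)

    def test_dummy_player(self, panel3):
        """A strain with zero effects everywhere: phi=0 and zero interactions."""
        beta = np.array([3.0, 0.0, -2.0])
        gamma = np.zeros((3, 3))
        gamma[0, 2] = gamma[2, 0] = 1.5
        params = sc.LandscapeParams(panel3, 1.0, beta, gamma)
        land = sc.generate_landscape(params)
        assert sc.shapley_exact(land).phi[1] == pytest.approx(0.0, abs=1e-12)
        inter = sc.interaction_matrix(land)
        dummy = inter[(inter["focal"] == "NS2") | (inter["partner"] == "NS2")]
        assert np.allclose(dummy["strength"], 0.0, atol=1e-12)

    def test_incomplete_refuses_with_missing_list(self, panel2):
        land = landscape_from_values(panel2, {(0, 0): 1.0, (1, 1): 4.0})
        with pytest.raises(ValueError, match="missing"):
            sc.shapley_exact(land)
        with pytest.raises(ValueError, match="missing"):
            sc.shapley_by_orderings(land)

    def test_factorial_guard(self):
        panel = sc.default_panel(4)
        params = sc.LandscapeParams(panel, 0.0, np.zeros(4), np.zeros((4, 4)))
        land = sc.generate_landscape(params)
        with pytest.raises(ValueError, match="shapley_exact"):
            sc.shapley_by_orderings(land, max_p=3)

    def test_recovery_matches_closed_form_sigma0(self):
        """phi-hat on a noiseless p=8 landscape equals beta + gamma/2 row sums."""
        params = sc.study_preset(seed=0, sigma_noise=0.0, n_reps=1)
        land = sc.generate_landscape(params)
        assert np.allclose(sc.shapley_exact(land).phi, sc.closed_form_shapley(params), atol=1e-10)


class TestInteractions:
    def test_additive_landscape_all_zero(self, panel3):
        params = sc.LandscapeParams(panel3, 1.0, np.array([1.0, 2.0, 3.0]), np.zeros((3, 3)))
        inter = sc.interaction_matrix(sc.generate_landscape(params))
        assert np.allclose(inter["strength"], 0.0, atol=1e-12)
        assert not inter["significant"].fillna(False).any()

    def test_noiseless_recovery_of_gamma(self, panel3):
        gamma = np.zeros((3, 3))
        gamma[0, 1] = gamma[1, 0] = 2.0
        params = sc.LandscapeParams(panel3, 0.0, np.array([1.0, 1.0, 1.0]), gamma)
        inter = sc.interaction_matrix(sc.generate_landscape(params))
        got = sc.strength_matrix(inter, panel3.strain_ids)
        assert np.allclose(got.to_numpy(), gamma, atol=1e-12)

    def test_symmetry_on_complete_landscape(self):
        params = sc.study_preset(seed=4)
        inter = sc.interaction_matrix(sc.generate_landscape(params))
        mat = sc.strength_matrix(inter, params.panel.strain_ids).to_numpy()
        assert np.allclose(mat, mat.T, atol=1e-9)

    def test_group_sizes_p8(self):
        inter = sc.interaction_matrix(sc.generate_landscape(sc.study_preset(seed=0)))
        assert (inter["n_with"] == 64).all() and (inter["n_without"] == 64).all()

    def test_welch_matches_r_ttest_convention(self, panel3):
        """Cross-check one pair's t/p against statsmodels' Welch t-test."""
        from statsmodels.stats.weightstats import ttest_ind as sm_ttest

        params = sc.LandscapeParams(
            panel3, 0.0, np.ones(3), np.zeros((3, 3)), sigma_noise=1.0, n_reps=4, seed=9
        )
        land = sc.generate_landscape(params)
        inter = sc.interaction_matrix(land)
        row = inter[(inter["focal"] == "NS1") & (inter["partner"] == "NS2")].iloc[0]
        edges = sc.functional_effects(land, "NS1")
        a = [e.delta_function for e in edges if e.background[1] == 1]
        b = [e.delta_function for e in edges if e.background[1] == 0]
        t_sm, p_sm, _ = sm_ttest(a, b, usevar="unequal")
        assert row["t"] == pytest.approx(t_sm, rel=1e-10)
        assert row["p"] == pytest.approx(p_sm, rel=1e-10)

    def test_bh_correction_is_more_conservative(self):
        params = sc.study_preset(seed=0)
        land = sc.generate_landscape(params)
        raw = sc.interaction_matrix(land)
        adj = sc.interaction_matrix(land, correction="bh")
        assert adj["significant"].sum() <= raw["significant"].sum()
        assert (adj["p_adjusted"] >= adj["p"] - 1e-15).all()

    def test_tiny_group_flagged(self, panel2):
        inter = sc.interaction_matrix(sc.generate_landscape(
            sc.LandscapeParams(panel2, 0.0, np.ones(2), np.zeros((2, 2)))
        ))
        assert inter["flagged"].all()  # p=2: one background per group
        assert inter["p"].isna().all()


class TestGrowthCorrelationAndEpistasis:
    def test_constant_growth_delta_flagged(self, panel3):
        params = sc.LandscapeParams(panel3, 1.0, np.array([1.0, 2.0, 3.0]), np.zeros((3, 3)))
        coupling = sc.GrowthCouplingParams(delta=np.zeros(3), kappa=np.zeros(3))
        land = sc.generate_growth_coupled_landscape(params, coupling)
        corr = sc.growth_function_correlation(land)
        assert corr["flagged"].all()
        assert corr["r"].isna().all()

    def test_no_growth_column_raises(self, landscape2):
        with pytest.raises(ValueError, match="growth"):
            sc.growth_function_correlation(landscape2)

    def test_star_coding(self):
        from subcomm.effects import significance_stars

        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.2) == ""

    def test_additive_noiseless_epistasis_slope_zero(self, panel3):
        params = sc.LandscapeParams(panel3, 1.0, np.array([1.0, -1.0, 2.0]), np.zeros((3, 3)))
        fit = sc.global_epistasis_fit(sc.generate_landscape(params))
        assert np.allclose(fit["slope"], 0.0, atol=1e-10)

    def test_constant_background_flagged(self, panel2):
        land = landscape_from_values(
            sc.StrainPanel(("A", "B")), {(0, 0): 1.0, (1, 0): 2.0, (0, 1): 1.0, (1, 1): 2.0}
        )
        fit = sc.global_epistasis_fit(land)
        # strain A: backgrounds {} and {B} both have v=1 -> degenerate predictor
        assert bool(fit.loc[fit["strain"] == "A", "flagged"].iloc[0])


class TestEstimatorConsistency:
    def test_rmse_decreases_with_replicates(self):
        """Monte-Carlo: Shapley and interaction RMSE shrink as n_reps grows."""
        panel = sc.default_panel(4)
        rng = np.random.default_rng(21)
        base = random_params(panel, rng)
        truth_phi = sc.closed_form_shapley(base)
        truth_gamma = base.gamma
        rmse_phi, rmse_gam = [], []
        for n_reps in (1, 4, 16):
            errs_p, errs_g = [], []
            for k in range(30):
                params = sc.LandscapeParams(
                    panel, base.beta0, base.beta, base.gamma,
                    sigma_noise=1.0, n_reps=n_reps, seed=1000 + k,
                )
                land = sc.generate_landscape(params)
                errs_p.append(np.mean((sc.shapley_exact(land).phi - truth_phi) ** 2))
                got = sc.strength_matrix(
                    sc.interaction_matrix(land), panel.strain_ids
                ).to_numpy()
                errs_g.append(np.mean((got - truth_gamma)[np.triu_indices(4, 1)] ** 2))
            rmse_phi.append(np.sqrt(np.mean(errs_p)))
            rmse_gam.append(np.sqrt(np.mean(errs_g)))
        assert rmse_phi[0] > rmse_phi[1] > rmse_phi[2]
        assert rmse_gam[0] > rmse_gam[1] > rmse_gam[2]
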