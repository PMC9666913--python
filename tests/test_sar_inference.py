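"""Spatial-error ML estimation, AICc arithmetic, averaging, sensitivity rerun."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from vertistrat.sar_inference import (
    SARFit,
    aicc,
    all_subsets,
    drop_genera,
    fit_sar_error,
    model_average,
    pseudo_r2,
    sensitivity_rerun,
    weights_eigenvalues,
    zscore,
)
from vertistrat.spatial_stats import build_weights
from vertistrat.synthetic_world import simulate_sar_field


def _lattice_weights(n_side):
    xs, ys = np.meshgrid(np.arange(n_side, dtype=float), np.arange(n_side, dtype=float))
    coords = np.column_stack([xs.ravel(), ys.ravel()])
    return build_weights(coords, 1.0, fn="binary", style="row_standardized")


class TestFitSarError:
    def test_lambda_zero_reduces_to_ols(self):
        W = _lattice_weights(8)
        rng = np.random.default_rng(0)
        X = rng.standard_normal((64, 2))
        y = X @ np.array([1.5, -1.0]) + rng.standard_normal(64)
        fit = fit_sar_error(y, pd.DataFrame(X, columns=["a", "b"]), W, fixed_lambda=0.0)
        ols = sm.OLS(y, sm.add_constant(X)).fit()
        assert abs(fit.coefficients["intercept"] - ols.params[0]) < 1e-6
        assert abs(fit.coefficients["a"] - ols.params[1]) < 1e-6
        assert abs(fit.coefficients["b"] - ols.params[2]) < 1e-6
        assert abs(fit.log_likelihood - ols.llf) < 1e-8

    def test_free_lambda_near_zero_on_iid_data(self):
        W = _lattice_weights(10)
        rng = np.random.default_rng(1)
        X = rng.standard_normal((100, 2))
        y = X @ np.array([1.0, 0.5]) + rng.standard_normal(100)
        fit = fit_sar_error(y, pd.DataFrame(X, columns=["a", "b"]), W)
        assert abs(fit.lambda_) < 0.25

    def test_parameter_recovery_smoke(self):
        # small version of the 100-replicate recovery study
        W = _lattice_weights(20)
        eigs = weights_eigenvalues(W)
        rng = np.random.default_rng(2)
        lams, b1s = [], []
        for _ in range(10):
            X = rng.standard_normal((400, 2))
            y = simulate_sar_field(W, X, [1.5, -1.0], 0.6, 1.0, rng)
            fit = fit_sar_error(y, pd.DataFrame(X, columns=["a", "b"]), W, eigs=eigs)
            lams.append(fit.lambda_)
            b1s.append(fit.coefficients["a"])
        assert abs(np.mean(lams) - 0.6) < 0.1
        assert abs(np.mean(b1s) - 1.5) < 0.1

    def test_loglik_jacobian_matches_dense_logdet(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 6, (30, 2))
        W = build_weights(coords, 3.0, allow_islands=True)
        X = rng.standard_normal((30, 1))
        y = simulate_sar_field(W, X, [1.0], 0.3, 1.0, rng)
        fit = fit_sar_error(y, pd.DataFrame(X, columns=["a"]), W)
        # dense recomputation of the maximized likelihood
        lam = fit.lambda_
        n = 30
        A = np.eye(n) - lam * W.matrix
        Xb = np.hstack([np.ones((n, 1)), X])
        ys, Xs = A @ y, A @ Xb
        beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        e = ys - Xs @ beta
        sigma2 = e @ e / n
        _, logdet = np.linalg.slogdet(A)
        ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet
        assert abs(fit.log_likelihood - ll) < 1e-8

    def test_optimum_beats_grid_perturbations(self):
        W = _lattice_weights(7)
        eigs = weights_eigenvalues(W)
        rng = np.random.default_rng(4)
        X = rng.standard_normal((49, 1))
        y = simulate_sar_field(W, X, [1.0], 0.5, 1.0, rng)
        fit = fit_sar_error(y, pd.DataFrame(X, columns=["a"]), W, eigs=eigs)
        lo, hi = 1.0 / eigs.min() + 1e-4, 1.0 / eigs.max() - 1e-4
        for lam in np.linspace(lo, hi, 100):
            other = fit_sar_error(y, pd.DataFrame(X, columns=["a"]), W, eigs=eigs, fixed_lambda=lam)
            assert fit.log_likelihood >= other.log_likelihood - 1e-9

    def test_rank_deficient_design_rejected(self):
        W = _lattice_weights(5)
        X = np.ones((25, 2))
        with pytest.raises(ValueError, match="rank"):
            fit_sar_error(np.random.default_rng(5).normal(size=25), X, W)


class TestAicc:
    def test_closed_form_example(self):
        assert np.isclose(aicc(-5.0, 2, 10), 14 + 12 / 7)

    def test_converges_to_aic_for_large_n(self):
        assert abs(aicc(-100.0, 3, 100_000_000) - (200 + 6)) < 1e-6

    def test_undefined_for_small_n(self):
        with pytest.raises(ValueError):
            aicc(-5.0, 4, 5)

    def test_k_counts_all_free_parameters(self):
        W = _lattice_weights(6)
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.standard_normal((36, 3)), columns=list("abc"))
        fit = fit_sar_error(rng.normal(size=36), X, W)
        assert fit.K == 6  # 3 betas + intercept + lambda + sigma^2


def _dummy_fit(predictors, logl, n=100, coef=1.0):
    coefs = {"intercept": 0.0, **{p: coef for p in predictors}}
    return SARFit(tuple(predictors), coefs, 0.0, 1.0, logl, n, np.zeros(n))


class TestModelAverage:
    def test_delta_two_weights(self):
        # two models with identical K and Delta-AICc {0, 2}
        fits = [_dummy_fit(["a"], -10.0), _dummy_fit(["b"], -11.0)]
        avg = model_average(fits)
        w = avg.table.sort_values("delta_AICc")["weight"].to_numpy()
        assert np.allclose(w, [0.7311, 0.2689], atol=1e-4)
        assert np.isclose(avg.table["weight"].sum(), 1.0, atol=1e-12)
        assert np.isclose(avg.table["delta_AICc"].min(), 0.0)

    def test_singleton_average_is_the_model(self):
        fits = [_dummy_fit(["a", "b"], -5.0, coef=2.5)]
        avg = model_average(fits)
        assert np.isclose(avg.table["weight"].iloc[0], 1.0)
        assert np.isclose(avg.coefficients["a"], 2.5)
        assert np.isclose(avg.importance["a"], 1.0)

    def test_always_present_variable_importance_one(self):
        fits = [_dummy_fit(["a"], -10.0), _dummy_fit(["a", "b"], -9.5)]
        avg = model_average(fits)
        assert np.isclose(avg.importance["a"], 1.0)
        assert avg.importance["b"] < 1.0

    def test_shrinkage_averaging_zeros_absent_variables(self):
        fits = [_dummy_fit(["a"], -10.0), _dummy_fit(["b"], -10.0)]
        avg = model_average(fits)
        # each model has weight 1/2; each coefficient averages 1.0 * 0.5
        assert np.isclose(avg.coefficients["a"], 0.5)
        assert np.isclose(avg.coefficients["b"], 0.5)

    def test_empty_fit_list_rejected(self):
        with pytest.raises(ValueError):
            model_average([])


class TestAllSubsets:
    def test_two_predictors_four_models(self):
        W = _lattice_weights(6)
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.standard_normal((36, 2)), columns=["a", "b"])
        fits = all_subsets(rng.normal(size=36), X, W)
        assert len(fits) == 4
        assert len({f.predictors for f in fits}) == 4

    def test_guardrail_on_large_p(self):
        W = _lattice_weights(6)
        X = pd.DataFrame(np.random.default_rng(8).standard_normal((36, 16)))
        X.columns = [f"v{j}" for j in range(16)]
        with pytest.raises(ValueError, match="screen"):
            all_subsets(np.zeros(36), X, W)


class TestPseudoR2:
    def test_perfect_fit(self):
        y = np.arange(10.0)
        assert np.isclose(pseudo_r2(y, y), 1.0)

    def test_affine_invariance(self):
        y = np.random.default_rng(9).normal(size=50)
        assert np.isclose(pseudo_r2(3.0 * y - 2.0, y), 1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(10)
        assert pseudo_r2(rng.normal(size=10_000), rng.normal(size=10_000)) < 0.01

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pseudo_r2(np.ones(10), np.arange(10.0))


class TestSensitivity:
    def test_drop_genera_noop_and_degenerate(self, toy_pam):
        same = drop_genera(toy_pam, [])
        assert same is toy_pam
        with pytest.raises(ValueError):
            drop_genera(toy_pam, ["s1", "s2", "s3"])

    def test_arboreal_exclusion_shrinks_tree_cover_effect(self):
        # a world whose verticality-tree_cover link is carried by one
        # arboreal genus: removing it must shrink the tree_cover coefficient
        from vertistrat.null_ses import NullSpec
        from vertistrat.synthetic_world import WorldConfig, generate_world
        from vertistrat.trait_metrics import species_metrics

        cfg = WorldConfig(seed=17, n_rows=10, n_cols=8, n_species=60, range_fill=0.3)
        world = generate_world(cfg)
        # rename every arboreal/semiarboreal species into one marker genus
        arb = world.traits.index[world.traits["habit"].isin(["arboreal", "semiarboreal"])]
        mapping = {s: (f"Arbogenus_{s}" if s in set(arb) else f"Other_{s}") for s in world.traits.index}
        traits = world.traits.rename(index=mapping)
        pam = world.pam
        renamed = type(pam)(pam.cells, tuple(mapping[s] for s in pam.species), pam.matrix)
        metrics = species_metrics(traits)["verticality"]
        coords = world.grid.cells.set_index("cell_id")[["x", "y"]]
        env = world.env[["tree_cover", "annual_mean_temperature", "sand"]]
        res = sensitivity_rerun(
            renamed,
            metrics,
            env,
            coords,
            ["Arbogenus"],
            null_spec=NullSpec(n_reps=100, seed=3),
            min_richness=5,
        )
        main_tc = abs(res.main.coefficients["tree_cover"])
        red_tc = abs(res.reduced.coefficients["tree_cover"])
        assert len(res.excluded_species) == len(arb)
        assert red_tc < main_tc

    def test_zscore_standardizes(self):
        z = zscore(np.random.default_rng(11).normal(3.0, 2.0, size=(200, 2)))
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-12)
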