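import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import optimize

from mtlcox import (
    CoxLikelihoodContext,
    FitOptions,
    SurvivalTask,
    RegularizationPath,
    SimulationConfig,
    fit,
    fit_cox_newton,
    generate,
    joint_loss,
    l21_norm,
    lambda_max,
    neg_log_partial_likelihood,
    prox_l21,
    select_lambda,
)
from mtlcox.mtl_solver import refit_on_support, stratified_event_folds

from conftest import make_dataset, random_task


def numerical_prox_row(g: np.ndarray, thr: float) -> np.ndarray:
    """Independent minimizer of 0.5||b - g||^2 + thr ||b||_2 for one row."""

    def f(b):
        return 0.5 * np.sum((b - g) ** 2) + thr * np.linalg.norm(b)

    def jac(b):
        nb = np.linalg.norm(b)
        return (b - g) + (thr * b / nb if nb > 0 else np.zeros_like(b))

    res = optimize.minimize(
        f, g.copy(), jac=jac, method="L-BFGS-B",
        options={"ftol": 1e-18, "gtol": 1e-12, "maxiter": 2000},
    )
    return min([np.zeros_like(g), res.x], key=f)


class TestL21Norm:
    def test_zero_matrix(self):
        assert l21_norm(np.zeros((4, 3))) == 0.0

    def test_single_column_equals_l1(self, rng):
        b = rng.normal(0, 1, (6, 1))
        assert l21_norm(b) == pytest.approx(np.abs(b).sum())

    def test_three_four_five_rows(self):
        assert l21_norm(np.array([[3.0, 4.0], [0.0, 0.0]])) == 5.0


class TestProxL21:
    def test_zero_threshold_is_identity(self, rng):
        G = rng.normal(0, 1, (5, 3))
        np.testing.assert_array_equal(prox_l21(G, 0.0), G)

    def test_small_rows_zeroed(self):
        G = np.array([[0.3, 0.4], [3.0, 4.0]])
        out = prox_l21(G, 0.5)
        np.testing.assert_array_equal(out[0], [0.0, 0.0])  # norm 0.5 <= threshold
        np.testing.assert_allclose(out[1], G[1] * (1 - 0.5 / 5.0))

    def test_matches_numerical_minimization(self, rng):
        # row-separable oracle: quasi-Newton minimization of each row's
        # objective 0.5||b - g||^2 + thr ||b||, kink at zero checked explicitly
        for _ in range(30):
            G = rng.normal(0, 2, (6, 3))
            thr = float(rng.uniform(0, 3))
            out = prox_l21(G, thr)
            for p in range(6):
                expected = numerical_prox_row(G[p], thr)
                np.testing.assert_allclose(out[p], expected, atol=1e-8)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        arrays(np.float64, (5, 3), elements=st.floats(-50, 50)),
        st.floats(0, 100),
    )
    def test_rows_shrink_colinearly(self, G, thr):
        # every output row is the input row scaled by a factor in [0, 1],
        # and surviving rows lose exactly `thr` of their Euclidean norm
        out = prox_l21(G, thr)
        for p in range(G.shape[0]):
            gn = np.linalg.norm(G[p])
            on = np.linalg.norm(out[p])
            if gn <= thr:
                assert on == 0.0
            else:
                assert on == pytest.approx(gn - thr, rel=1e-9, abs=1e-9)
                np.testing.assert_allclose(out[p] * gn, G[p] * on, atol=1e-7 * max(1, gn))

    def test_nonexpansive(self, rng):
        G1, G2 = rng.normal(0, 1, (4, 2)), rng.normal(0, 1, (4, 2))
        assert np.linalg.norm(prox_l21(G1, 0.7) - prox_l21(G2, 0.7)) <= np.linalg.norm(
            G1 - G2
        ) + 1e-12


class TestJointLoss:
    def test_matches_per_task_nll_over_n(self, rng):
        tasks = [random_task(rng, n=30, p=4, name=f"t{i}") for i in range(3)]
        ds = make_dataset(tasks)
        B = rng.normal(0, 0.5, (4, 3))
        expected = sum(
            neg_log_partial_likelihood(B[:, k], CoxLikelihoodContext.from_task(t))
            / t.n_subjects
            for k, t in enumerate(tasks)
        )
        assert joint_loss(B, ds) == pytest.approx(expected, abs=1e-12)

    def test_k1_reduces_to_single_task(self, rng):
        task = random_task(rng, n=25, p=3)
        ds = make_dataset([task])
        b = rng.normal(0, 0.5, 3)
        ctx = CoxLikelihoodContext.from_task(task)
        assert joint_loss(b[:, None], ds) == pytest.approx(
            neg_log_partial_likelihood(b, ctx) / task.n_subjects
        )


class TestLambdaMax:
    def test_fit_above_lambda_max_is_exactly_zero(self, rng):
        ds = make_dataset([random_task(rng, n=40, p=4, name=f"t{i}") for i in range(2)])
        lm = lambda_max(ds)
        res = fit(ds, 1.01 * lm)
        assert np.all(res.coefficients.values == 0.0)

    def test_fit_below_lambda_max_has_nonzero_row(self, rng):
        ds = make_dataset([random_task(rng, n=40, p=4, name=f"t{i}") for i in range(2)])
        res = fit(ds, 0.5 * lambda_max(ds))
        assert np.any(res.coefficients.values != 0.0)

    def test_zero_feature_column_contributes_zero(self, rng):
        task = random_task(rng, n=30, p=3)
        task.features[:, 1] = 0.0
        ds = make_dataset([task])
        from mtlcox.mtl_solver import joint_gradient

        G0 = joint_gradient(np.zeros((3, 1)), ds)
        assert G0[1, 0] == 0.0


class TestFit:
    def test_k1_unpenalized_matches_newton(self, rng):
        task = random_task(rng, n=120, p=4)
        ds = make_dataset([task])
        newton = fit_cox_newton(task)
        res = fit(ds, 0.0, FitOptions(tol_obj=1e-12, tol_coef=1e-10, max_iter=20000))
        np.testing.assert_allclose(
            res.coefficients.values[:, 0], newton.coefficients, atol=1e-4
        )

    def test_objective_history_nonincreasing(self, rng):
        sim = generate(SimulationConfig(n_tasks=3, n_features=10, support_size=4,
                                        n_per_task=150, seed=11))
        res = fit(sim.dataset, 0.2 * lambda_max(sim.dataset))
        assert np.all(np.diff(res.objective_history) <= 1e-12)

    def test_recovers_exact_zero_rows_at_moderate_lambda(self):
        sim = generate(
            SimulationConfig(n_tasks=3, n_features=20, support_size=5, n_per_task=400, seed=5)
        )
        res = fit(sim.dataset, 0.3 * lambda_max(sim.dataset))
        support = res.coefficients.support()
        true_support = sim.true_coefficients.support()
        # off-support rows are exactly zero, and zeros are shared across tasks
        assert np.all(res.coefficients.values[~support] == 0.0)
        assert np.all(support[~true_support] == False)  # noqa: E712
        assert support[true_support].sum() >= 4

    def test_zero_rows_shared_across_tasks(self, rng):
        sim = generate(SimulationConfig(n_tasks=4, n_features=12, support_size=3,
                                        n_per_task=200, seed=3))
        res = fit(sim.dataset, 0.25 * lambda_max(sim.dataset))
        B = res.coefficients.values
        row_zero = np.all(B == 0.0, axis=1)
        row_norm_zero = np.linalg.norm(B, axis=1) == 0.0
        np.testing.assert_array_equal(row_zero, row_norm_zero)

    def test_warm_start_accepted(self, rng):
        ds = make_dataset([random_task(rng, n=60, p=3)])
        lam = 0.1 * lambda_max(ds)
        tight = FitOptions(tol_obj=1e-10, tol_coef=1e-9, max_iter=20000)
        cold = fit(ds, lam, tight)
        warm = fit(ds, lam, tight, B0=cold.coefficients.values)
        np.testing.assert_allclose(
            warm.coefficients.values, cold.coefficients.values, atol=1e-4
        )

    def test_negative_lambda_rejected(self, rng):
        ds = make_dataset([random_task(rng, n=30, p=2)])
        with pytest.raises(ValueError):
            fit(ds, -0.1)

    def test_refit_on_support_removes_shrinkage(self):
        sim = generate(
            SimulationConfig(n_tasks=2, n_features=8, support_size=3, n_per_task=500, seed=9)
        )
        lam = 0.15 * lambda_max(sim.dataset)
        res = fit(sim.dataset, lam)
        deb = refit_on_support(sim.dataset, res.coefficients)
        truth = sim.true_coefficients.values
        sup = sim.true_coefficients.support() & res.coefficients.support()
        err_pen = np.abs(res.coefficients.values[sup] - truth[sup]).mean()
        err_deb = np.abs(deb.values[sup] - truth[sup]).mean()
        assert err_deb < err_pen
        # support preserved
        np.testing.assert_array_equal(deb.support(), res.coefficients.support())


class TestRegularizationPath:
    def test_grid_defaults_and_shape(self):
        grid = RegularizationPath().build(2.0)
        assert len(grid) == 50
        assert grid[0] == pytest.approx(2.0)
        assert grid[-1] == pytest.approx(0.02)
        assert np.all(np.diff(grid) < 0)

    def test_degenerate_single_point(self):
        grid = RegularizationPath(n_lambdas=1).build(1.5)
        np.testing.assert_allclose(grid, [1.5])


class TestSelectLambda:
    def test_single_point_path_returns_it(self, rng):
        ds = make_dataset([random_task(rng, n=80, p=3)])
        sel = select_lambda(ds, RegularizationPath(n_lambdas=1), folds=3, seed=0)
        assert sel.lam == pytest.approx(lambda_max(ds))

    @staticmethod
    def _null_dataset(seed, n=150, p=6):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, p))
        T = -np.log(rng.uniform(size=n)) / 0.2  # no feature effect
        ev = (rng.uniform(size=n) > 0.3).astype(int)
        return make_dataset([SurvivalTask("null", X, T, ev)])

    def test_pure_noise_one_se_rule_selects_near_lambda_max(self):
        # the conservative rule collapses to (near) the null model on noise
        hits = 0
        for seed in range(10):
            ds = self._null_dataset(seed)
            sel = select_lambda(
                ds, RegularizationPath(n_lambdas=15), folds=3, seed=seed, rule="one_se"
            )
            if sel.lam >= 0.25 * lambda_max(ds):
                hits += 1
        assert hits >= 8

    def test_pure_noise_shows_no_cv_signal(self):
        # under the default argmax rule the best CV concordance stays at chance
        best_scores = [
            select_lambda(
                self._null_dataset(seed), RegularizationPath(n_lambdas=15), folds=3, seed=seed
            ).mean_scores.max()
            for seed in range(5)
        ]
        assert np.mean(best_scores) < 0.58

    def test_strong_signal_selects_interior_lambda(self):
        sim = generate(
            SimulationConfig(n_tasks=2, n_features=10, support_size=3, n_per_task=400, seed=21)
        )
        sel = select_lambda(sim.dataset, RegularizationPath(n_lambdas=20), folds=3, seed=21)
        assert sel.lam < lambda_max(sim.dataset)
        best = sel.mean_scores.max()
        assert best > 0.6

    def test_folds_keep_events_in_every_task(self, rng):
        ds = make_dataset([random_task(rng, n=50, p=2, name=f"t{i}") for i in range(2)])
        folds = stratified_event_folds(ds, 5, np.random.default_rng(0))
        for val_masks in folds:
            for k, t in enumerate(ds.tasks):
                assert t.event[~val_masks[k]].sum() > 0  # training events present
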