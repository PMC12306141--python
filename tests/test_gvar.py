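import numpy as np
import pytest
from scipy import stats

from idionet.data import EMAValidationError, LaggedPair, pairs_to_arrays
from idionet.gvar import (
    NetworkPair,
    PenaltyGrid,
    ebic_score,
    extract_networks,
    fit_gvar,
    select_model,
    standardize_pairs,
)
from idionet.simulate import make_truth, simulate_latent

from conftest import make_dataset
from idionet.data import Schedule, to_lagged_pairs


def latent_pairs(seed=0, n=300, p_per_community=2, restart_every=None):
    truth = make_truth(p_per_community=p_per_community, seed=seed)
    series = simulate_latent(truth, n + 1, seed=seed + 1, restart_every=restart_every)
    pairs = [
        LaggedPair(series[t], series[t + 1], day=1 + t // 5, within_day=True)
        for t in range(n)
    ]
    return truth, pairs


class TestStandardize:
    def test_pooled_mean_zero_variance_one(self):
        _, pairs = latent_pairs(seed=2)
        std, info = standardize_pairs(pairs)
        X, Y = pairs_to_arrays(std)
        pooled = np.vstack([X, Y])
        assert np.allclose(pooled.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(pooled.std(axis=0), 1, atol=1e-10)

    def test_inverse_transform_round_trip(self):
        _, pairs = latent_pairs(seed=3, n=50)
        std, info = standardize_pairs(pairs)
        for raw, z in zip(pairs, std):
            assert np.allclose(z.predictor * info.scale + info.mean, raw.predictor, atol=1e-10)
            assert np.allclose(z.outcome * info.scale + info.mean, raw.outcome, atol=1e-10)

    def test_constant_node_raises(self):
        pairs = [
            LaggedPair(np.array([1.0, 5.0]), np.array([1.0, 6.0]), day=1, within_day=True),
            LaggedPair(np.array([1.0, 6.0]), np.array([1.0, 4.0]), day=1, within_day=True),
        ]
        with pytest.raises(EMAValidationError, match="zero-variance"):
            standardize_pairs(pairs, nodes=["a", "b"])


class TestFitGvar:
    def test_zero_penalty_matches_per_equation_least_squares(self):
        _, pairs = latent_pairs(seed=4, n=400, p_per_community=2)
        std, _ = standardize_pairs(pairs)
        X, Y = pairs_to_arrays(std)
        fit = fit_gvar(std, lambda_beta=0.0, lambda_kappa=0.0)
        ols = np.linalg.lstsq(X, Y, rcond=None)[0].T
        assert np.allclose(fit.B, ols, atol=1e-6)

    def test_full_shrinkage_empties_both_networks(self):
        _, pairs = latent_pairs(seed=5, n=200)
        std, _ = standardize_pairs(pairs)
        fit = fit_gvar(std, lambda_beta=50.0, lambda_kappa=50.0)
        assert np.all(fit.B == 0)
        assert np.allclose(fit.K - np.diag(np.diag(fit.K)), 0, atol=1e-10)

    def test_loglik_matches_multivariate_normal_density(self):
        _, pairs = latent_pairs(seed=6, n=150)
        std, _ = standardize_pairs(pairs)
        fit = fit_gvar(std, lambda_beta=0.05, lambda_kappa=0.05)
        X, Y = pairs_to_arrays(std)
        resid = Y - X @ fit.B.T
        oracle = stats.multivariate_normal(np.zeros(fit.p), np.linalg.inv(fit.K)).logpdf(resid).sum()
        assert fit.loglik == pytest.approx(oracle, abs=1e-8)

    def test_scale_equivariance_of_standardized_fit(self):
        truth, pairs = latent_pairs(seed=7, n=200)
        scaled = [
            LaggedPair(p.predictor * np.array([3.0, 1, 1, 0.5]), p.outcome * np.array([3.0, 1, 1, 0.5]),
                       day=p.day, within_day=p.within_day)
            for p in pairs
        ]
        fit_a = fit_gvar(standardize_pairs(pairs)[0], 0.05, 0.05)
        fit_b = fit_gvar(standardize_pairs(scaled)[0], 0.05, 0.05)
        assert np.allclose(fit_a.B, fit_b.B, atol=1e-8)
        assert np.allclose(fit_a.K, fit_b.K, atol=1e-8)


class TestEbic:
    def test_gamma_zero_reduces_to_bic(self):
        _, pairs = latent_pairs(seed=8, n=120)
        std, _ = standardize_pairs(pairs)
        fit = fit_gvar(std, 0.1, 0.1)
        from idionet.gvar import _degrees_of_freedom

        df = _degrees_of_freedom(fit.B, fit.K)
        assert ebic_score(fit, gamma=0.0) == pytest.approx(
            -2 * fit.loglik + np.log(fit.n_pairs) * df
        )
        assert ebic_score(fit, gamma=0.5) > ebic_score(fit, gamma=0.0) or df == 0

    def test_non_positive_definite_precision_rejected(self):
        _, pairs = latent_pairs(seed=9, n=100)
        std, _ = standardize_pairs(pairs)
        fit = fit_gvar(std, 0.1, 0.1)
        fit.K = np.array(fit.K)
        fit.K[0, 0] = -1.0
        with pytest.raises(EMAValidationError, match="positive definite"):
            ebic_score(fit)


class TestSelectModel:
    def test_single_point_grid_returns_that_fit(self):
        _, pairs = latent_pairs(seed=10, n=150)
        std, _ = standardize_pairs(pairs)
        grid = PenaltyGrid(np.array([0.1]), np.array([0.1]))
        fit, table = select_model(std, grid)
        assert len(table) == 1
        assert fit.lambda_beta == 0.1 and fit.lambda_kappa == 0.1

    def test_selected_model_minimizes_ebic_over_grid(self):
        _, pairs = latent_pairs(seed=11, n=250)
        std, _ = standardize_pairs(pairs)
        fit, table = select_model(std)
        assert fit.ebic <= table.ebic.min() + 1e-9

    def test_largest_penalties_give_no_more_edges_than_smallest(self):
        _, pairs = latent_pairs(seed=12, n=250)
        std, _ = standardize_pairs(pairs)
        _, table = select_model(std)
        lb_max, lk_max = table.lambda_beta.max(), table.lambda_kappa.max()
        lb_min, lk_min = table.lambda_beta.min(), table.lambda_kappa.min()
        densest = table.query("lambda_beta == @lb_min and lambda_kappa == @lk_min").iloc[0]
        sparsest = table.query("lambda_beta == @lb_max and lambda_kappa == @lk_max").iloc[0]
        assert sparsest.n_edges_temporal <= densest.n_edges_temporal
        assert sparsest.n_edges_contemporaneous <= densest.n_edges_contemporaneous

    def test_invalid_grid_rejected(self):
        with pytest.raises(EMAValidationError):
            PenaltyGrid(np.array([0.1, 0.2]), np.array([0.1]))  # ascending
        with pytest.raises(EMAValidationError):
            PenaltyGrid(np.array([]), np.array([0.1]))


class TestExtractNetworks:
    def test_two_node_precision_gives_partial_correlation_half(self):
        fit = fit_from_K(np.array([[1.0, -0.5], [-0.5, 1.0]]))
        pair = extract_networks(fit)
        assert pair.contemporaneous[0, 1] == pytest.approx(0.5)

    def test_diagonal_precision_gives_empty_contemporaneous_network(self):
        fit = fit_from_K(np.diag([1.0, 2.0, 3.0]))
        assert np.all(extract_networks(fit).contemporaneous == 0)

    def test_partial_correlations_match_regression_residual_oracle(self):
        rng = np.random.default_rng(13)
        p = 6
        A = rng.standard_normal((p, p))
        K = A @ A.T + p * np.eye(p)
        pair = extract_networks(fit_from_K(K))
        sigma = np.linalg.inv(K)
        for i in range(p):
            for j in range(i + 1, p):
                rest = [k for k in range(p) if k not in (i, j)]
                # residual covariance of (i, j) after regressing both on the rest
                s = sigma[np.ix_([i, j], [i, j])] - sigma[np.ix_([i, j], rest)] @ np.linalg.solve(
                    sigma[np.ix_(rest, rest)], sigma[np.ix_(rest, [i, j])]
                )
                oracle = s[0, 1] / np.sqrt(s[0, 0] * s[1, 1])
                assert pair.contemporaneous[i, j] == pytest.approx(oracle, abs=1e-8)

    def test_contemporaneous_matrix_is_valid_for_random_pd_precision(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            p = 5
            A = rng.standard_normal((p, p))
            K = A @ A.T + p * np.eye(p)
            C = extract_networks(fit_from_K(K)).contemporaneous
            assert np.allclose(C, C.T)
            assert np.all(np.diag(C) == 0)
            assert np.all(np.abs(C) <= 1)


def fit_from_K(K):
    from idionet.gvar import GVARFit

    p = K.shape[0]
    return GVARFit(
        nodes=[f"n{i}" for i in range(p)], B=np.zeros((p, p)), K=np.asarray(K, dtype=float),
        lambda_beta=0.0, lambda_kappa=0.0, ebic=0.0, loglik=0.0,
        n_pairs=10, converged=True, n_iter=1,
    )


def test_detrended_pairs_remove_linear_day_trend():
    from idionet.gvar import detrend_pairs

    rng = np.random.default_rng(15)
    schedule = Schedule(n_days=21, beeps_per_day=5)
    trend = np.linspace(0, 30, schedule.size)[:, None] * np.ones((1, 8))
    values = np.clip(30 + trend + 5 * rng.standard_normal((schedule.size, 8)), 0, 100)
    ds = make_dataset(values, schedule=schedule)
    pairs = to_lagged_pairs(ds, ds.item_ids)
    detrended = detrend_pairs(pairs)
    X, _ = pairs_to_arrays(detrended)
    days = np.array([p.day for p in detrended])
    corr = np.corrcoef(days, X[:, 0])[0, 1]
    assert abs(corr) < 0.2  # trend association removed
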