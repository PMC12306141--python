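"""Sparse graphical VAR estimation for idiographic symptom networks.

The model: standardized symptom scores y_t follow a lag-1 vector
autoregression

    y_t = B y_{t-1} + e_t,      e_t ~ N(0, K^{-1}),

where B is the temporal coefficient matrix (entry B[i, j] is the effect of
node j at t-1 on node i at t) and K the precision matrix of the innovations.
Off-diagonal structure of K, rescaled to partial correlations, is the
contemporaneous network; B is the temporal network.

Both matrices are estimated jointly by L1-penalized maximum likelihood
(penalty ``lambda_beta`` on B, ``lambda_kappa`` on off-diagonal K), via
alternating optimization: with K fixed, B is updated by coordinate descent
on the penalized weighted least-squares objective (the rows of B couple
through K); with B fixed, K is a graphical-lasso problem on the residual
covariance. The penalty pair is selected over a grid by the extended BIC
(EBIC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit
from sklearn.covariance import graphical_lasso

from .data import EMAValidationError, LaggedPair, pairs_to_arrays

__all__ = [
    "GVARFit",
    "PenaltyGrid",
    "NetworkPair",
    "Standardization",
    "standardize_pairs",
    "detrend_pairs",
    "fit_gvar",
    "ebic_score",
    "select_model",
    "extract_networks",
    "edge_list",
    "write_graphml",
]

#: entries with magnitude at or below this are treated as structural zeros
#: (the graphical-lasso step can leave numerical dust on shrunk entries)
SUPPORT_TOL = 1e-8


@dataclass
class GVARFit:
    """Estimated graphical VAR: temporal coefficients and residual precision."""

    nodes: list[str]
    B: np.ndarray
    K: np.ndarray
    lambda_beta: float
    lambda_kappa: float
    ebic: float
    loglik: float
    n_pairs: int
    converged: bool
    n_iter: int

    @property
    def p(self) -> int:
        return len(self.nodes)


@dataclass
class PenaltyGrid:
    """Descending penalty sequences and the EBIC hyperparameter gamma."""

    lambda_beta: np.ndarray
    lambda_kappa: np.ndarray
    gamma: float = 0.5

    def __post_init__(self) -> None:
        self.lambda_beta = np.asarray(self.lambda_beta, dtype=float)
        self.lambda_kappa = np.asarray(self.lambda_kappa, dtype=float)
        for name, seq in (("lambda_beta", self.lambda_beta), ("lambda_kappa", self.lambda_kappa)):
            if seq.size == 0:
                raise EMAValidationError(f"{name} grid is empty")
            if np.any(np.diff(seq) >= 0):
                raise EMAValidationError(f"{name} grid must be strictly descending")
            if np.any(seq[:-1] <= 0) or seq[-1] < 0:
                raise EMAValidationError(f"{name} grid must be positive (optional terminal 0)")
        if self.gamma < 0:
            raise EMAValidationError("gamma must be >= 0")


@dataclass
class NetworkPair:
    """Contemporaneous (symmetric, signed) and temporal (directed) networks.

    ``contemporaneous[i, j]`` is the partial contemporaneous correlation of
    nodes i and j; ``temporal[i, j]`` is the standardized lag-1 coefficient
    of node j at t-1 on node i at t (edge j -> i). Temporal self-loops
    (autoregressive effects) sit on the diagonal.
    """

    contemporaneous: np.ndarray
    temporal: np.ndarray
    nodes: list[str]

    def __post_init__(self) -> None:
        C = self.contemporaneous
        if not np.allclose(C, C.T, atol=1e-8):
            raise EMAValidationError("contemporaneous matrix must be symmetric")
        if np.any(np.abs(np.diag(C)) > 0):
            raise EMAValidationError("contemporaneous diagonal must be zero")
        if np.any(np.abs(C) > 1 + 1e-8):
            raise EMAValidationError("partial correlations must lie in [-1, 1]")


@dataclass(frozen=True)
class Standardization:
    """Per-node location/scale used to z-score the pooled pair observations."""

    nodes: tuple[str, ...]
    mean: np.ndarray
    scale: np.ndarray


# ---------------------------------------------------------------------------
# Pre-processing
# ---------------------------------------------------------------------------


def standardize_pairs(
    pairs: Sequence[LaggedPair], nodes: Sequence[str] | None = None
) -> tuple[list[LaggedPair], Standardization]:
    """Center and scale each node to pooled mean 0, variance 1.

    Pooling stacks predictor and outcome occurrences so a single transform
    applies to both sides of every pair.
    """
    if len(pairs) < 2:
        raise EMAValidationError("need at least 2 lagged pairs to standardize")
    X, Y = pairs_to_arrays(pairs)
    pooled = np.vstack([X, Y])
    mean = pooled.mean(axis=0)
    scale = pooled.std(axis=0)  # population SD so pooled variance is exactly 1
    zero = np.flatnonzero(scale == 0)
    if zero.size:
        names = [nodes[i] for i in zero] if nodes is not None else list(zero)
        raise EMAValidationError(f"zero-variance node(s): {names}")
    out = [
        LaggedPair(
            (p.predictor - mean) / scale,
            (p.outcome - mean) / scale,
            day=p.day,
            within_day=p.within_day,
        )
        for p in pairs
    ]
    node_names = tuple(nodes) if nodes is not None else tuple(str(i) for i in range(X.shape[1]))
    return out, Standardization(node_names, mean, scale)


def detrend_pairs(pairs: Sequence[LaggedPair]) -> list[LaggedPair]:
    """Remove a per-node linear-in-day trend from the pooled observations.

    Optional pre-processing: slow within-study drift otherwise inflates
    lag-1 coefficients. The trend is fit on predictor and outcome
    occurrences pooled, against the pair's day index.
    """
    X, Y = pairs_to_arrays(pairs)
    days = np.array([p.day for p in pairs], dtype=float)
    pooled = np.vstack([X, Y])
    pooled_days = np.concatenate([days, days])
    design = np.column_stack([np.ones_like(pooled_days), pooled_days])
    coef, *_ = np.linalg.lstsq(design, pooled, rcond=None)
    trend_x = design[: len(pairs)] @ coef
    trend_y = trend_x  # same day index for both sides of a pair
    mean = pooled.mean(axis=0)
    return [
        LaggedPair(
            p.predictor - trend_x[i] + mean,
            p.outcome - trend_y[i] + mean,
            day=p.day,
            within_day=p.within_day,
        )
        for i, p in enumerate(pairs)
    ]


# ---------------------------------------------------------------------------
# Penalized estimation
# ---------------------------------------------------------------------------


@njit(cache=False)
def _cd_beta(B, K, Sxx, Syx, lam, max_sweeps, tol):  # pragma: no cover - numba
    """Coordinate descent for B at fixed K.

    Minimizes tr[(Syy - Syx B' - B Syx' + B Sxx B') K] + lam * sum|B|.
    M = B @ Sxx is maintained incrementally; the gradient entry is
    G[r, c] = 2 * sum_k K[r, k] (M[k, c] - Syx[k, c]).
    """
    p = B.shape[0]
    M = B @ Sxx
    n_sweeps = 0
    for _ in range(max_sweeps):
        n_sweeps += 1
        max_delta = 0.0
        for r in range(p):
            for c in range(p):
                g = 0.0
                for k in range(p):
                    g += K[r, k] * (M[k, c] - Syx[k, c])
                g *= 2.0
                a = 2.0 * K[r, r] * Sxx[c, c]
                z = B[r, c] - g / a
                thr = lam / a
                if z > thr:
                    new = z - thr
                elif z < -thr:
                    new = z + thr
                else:
                    new = 0.0
                delta = new - B[r, c]
                if delta != 0.0:
                    B[r, c] = new
                    for j in range(p):
                        M[r, j] += delta * Sxx[c, j]
                    ad = abs(delta)
                    if ad > max_delta:
                        max_delta = ad
        if max_delta < tol:
            break
    return n_sweeps


def _residual_cov(B, Sxx, Syx, Syy):
    return Syy - Syx @ B.T - B @ Syx.T + B @ Sxx @ B.T


def _gaussian_loglik(B, K, Sxx, Syx, Syy, n, p):
    S_res = _residual_cov(B, Sxx, Syx, Syy)
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        raise EMAValidationError("precision matrix is not positive definite")
    return 0.5 * n * (logdet - p * np.log(2 * np.pi) - np.trace(S_res @ K))


def _degrees_of_freedom(B: np.ndarray, K: np.ndarray) -> int:
    p = B.shape[0]
    off = ~np.eye(p, dtype=bool)
    nnz_b = int(np.sum(np.abs(B[off]) > SUPPORT_TOL))
    upper = np.triu_indices(p, k=1)
    nnz_k = int(np.sum(np.abs(K[upper]) > SUPPORT_TOL))
    return nnz_b + nnz_k + 2 * p  # both diagonals always free


def fit_gvar(
    pairs: Sequence[LaggedPair],
    lambda_beta: float,
    lambda_kappa: float,
    nodes: Sequence[str] | None = None,
    gamma: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 200,
    warm_start: tuple[np.ndarray, np.ndarray] | None = None,
) -> GVARFit:
    """Jointly estimate (B, K) at one penalty pair by alternating optimization.

    Expects standardized pairs. At ``lambda_beta == 0`` the B-step is the
    exact per-equation least-squares solution; at ``lambda_kappa == 0`` the
    K-step inverts the residual covariance directly (an error suggests a
    positive penalty if that matrix is singular).
    """
    X, Y = pairs_to_arrays(pairs)
    n, p = X.shape
    if p < 2:
        raise EMAValidationError("need at least 2 nodes")
    if n < p + 1:
        warnings.warn(f"only {n} lagged pairs for {p} nodes; estimates will be unstable")
    node_names = list(nodes) if nodes is not None else [str(i) for i in range(p)]
    Sxx = X.T @ X / n
    Syx = Y.T @ X / n
    Syy = Y.T @ Y / n

    if warm_start is not None:
        B = warm_start[0].copy()
        K = warm_start[1].copy()
    else:
        B = np.zeros((p, p))
        K = np.eye(p)

    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        B_old, K_old = B.copy(), K.copy()
        # B-step at fixed K
        if lambda_beta == 0.0:
            B = np.linalg.solve(Sxx, Syx.T).T  # OLS; independent of K
        else:
            _cd_beta(B, K, Sxx, Syx, float(lambda_beta), 1000, 0.1 * tol)
        # K-step at fixed B
        S_res = _residual_cov(B, Sxx, Syx, Syy)
        S_res = (S_res + S_res.T) / 2
        if lambda_kappa == 0.0:
            if np.linalg.cond(S_res) > 1e12:
                raise EMAValidationError(
                    "residual covariance is singular at lambda_kappa=0; use a positive penalty"
                )
            K = np.linalg.inv(S_res)
        else:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, K = graphical_lasso(S_res, alpha=float(lambda_kappa), max_iter=200)
            except FloatingPointError:
                warnings.warn("graphical lasso failed to converge at this penalty")
                K = K_old
                break
        K = (K + K.T) / 2
        delta = max(np.max(np.abs(B - B_old)), np.max(np.abs(K - K_old)))
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"gVAR fit did not converge in {n_iter} iterations "
            f"(lambda_beta={lambda_beta:g}, lambda_kappa={lambda_kappa:g})"
        )

    loglik = _gaussian_loglik(B, K, Sxx, Syx, Syy, n, p)
    fit = GVARFit(
        nodes=node_names,
        B=B,
        K=K,
        lambda_beta=float(lambda_beta),
        lambda_kappa=float(lambda_kappa),
        ebic=np.nan,
        loglik=float(loglik),
        n_pairs=n,
        converged=converged,
        n_iter=n_iter,
    )
    fit.ebic = ebic_score(fit, gamma)
    return fit


def ebic_score(fit: GVARFit, gamma: float = 0.5) -> float:
    """Extended BIC: -2 loglik + log(n) df + 4 gamma log(p) df; lower is better.

    df counts the nonzero off-diagonal entries of B, the nonzero
    upper-triangle off-diagonal entries of K, and the two diagonals.
    At gamma = 0 this is the ordinary BIC.
    """
    try:
        np.linalg.cholesky(fit.K)
    except np.linalg.LinAlgError:
        raise EMAValidationError("precision matrix is not positive definite")
    df = _degrees_of_freedom(fit.B, fit.K)
    return float(-2.0 * fit.loglik + np.log(fit.n_pairs) * df + 4.0 * gamma * np.log(fit.p) * df)


def default_grid(
    pairs: Sequence[LaggedPair],
    n_lambda: int = 10,
    ratio: float = 0.01,
    gamma: float = 0.5,
) -> PenaltyGrid:
    """Data-driven log-spaced penalty grid.

    The largest beta penalty is the smallest value that zeroes all of B at
    K = I; the largest kappa penalty likewise empties the precision
    off-diagonals at B = 0. Both sequences descend to ``ratio`` times the
    maximum.
    """
    X, Y = pairs_to_arrays(pairs)
    n = X.shape[0]
    Syx = Y.T @ X / n
    Syy = Y.T @ Y / n
    lam_b_max = 2.0 * np.max(np.abs(Syx))
    off = ~np.eye(Syy.shape[0], dtype=bool)
    lam_k_max = np.max(np.abs(Syy[off]))
    lb = np.geomspace(lam_b_max, ratio * lam_b_max, n_lambda)
    lk = np.geomspace(lam_k_max, ratio * lam_k_max, n_lambda)
    return PenaltyGrid(lb, lk, gamma)


def refit_on_support(fit: GVARFit, pairs: Sequence[LaggedPair]) -> GVARFit:
    """Post-lasso refit: re-estimate the selected support without penalty.

    Each row of B is refit by ordinary least squares on its selected
    predictors, then K is re-estimated on the refit residuals at the fit's
    own kappa penalty. The lasso support is kept but the shrinkage bias on
    the surviving coefficients is removed, which makes likelihood-based
    model comparison honest: an extra edge can then only pay for its own
    information content, not for releasing bias elsewhere.
    """
    X, Y = pairs_to_arrays(pairs)
    n, p = X.shape
    Sxx = X.T @ X / n
    Syx = Y.T @ X / n
    Syy = Y.T @ Y / n
    B = np.zeros_like(fit.B)
    for i in range(p):
        cols = np.flatnonzero(np.abs(fit.B[i]) > SUPPORT_TOL)
        if cols.size:
            coef, *_ = np.linalg.lstsq(Sxx[np.ix_(cols, cols)], Syx[i, cols], rcond=None)
            B[i, cols] = coef
    S_res = _residual_cov(B, Sxx, Syx, Syy)
    S_res = (S_res + S_res.T) / 2
    if fit.lambda_kappa == 0.0:
        K = np.linalg.inv(S_res)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, K = graphical_lasso(S_res, alpha=float(fit.lambda_kappa), max_iter=200)
    K = (K + K.T) / 2
    loglik = _gaussian_loglik(B, K, Sxx, Syx, Syy, n, p)
    refit = GVARFit(
        nodes=list(fit.nodes), B=B, K=K,
        lambda_beta=fit.lambda_beta, lambda_kappa=fit.lambda_kappa,
        ebic=np.nan, loglik=float(loglik), n_pairs=n,
        converged=fit.converged, n_iter=fit.n_iter,
    )
    return refit


def select_model(
    pairs: Sequence[LaggedPair],
    grid: PenaltyGrid | None = None,
    nodes: Sequence[str] | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    refit: bool = True,
) -> tuple[GVARFit, pd.DataFrame]:
    """Fit every penalty pair on the grid and return the EBIC minimizer.

    The grid is walked from larger to smaller penalties with warm starts;
    ties break toward larger penalties (the sparser model). With ``refit``
    (the default) each candidate is scored — and the winner returned — after
    a post-lasso refit of its support (see :func:`refit_on_support`). The
    full score table is returned for diagnostics.
    """
    if grid is None:
        grid = default_grid(pairs)
    rows = []
    best: GVARFit | None = None
    warm_row: tuple[np.ndarray, np.ndarray] | None = None
    for lb in grid.lambda_beta:
        warm = warm_row
        for lk in grid.lambda_kappa:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = fit_gvar(
                        pairs, lb, lk, nodes=nodes, gamma=grid.gamma,
                        tol=tol, max_iter=max_iter, warm_start=warm,
                    )
            except EMAValidationError:
                continue
            warm = (fit.B, fit.K)
            if lk == grid.lambda_kappa[0]:
                warm_row = warm
            if refit:
                try:
                    candidate = refit_on_support(fit, pairs)
                    candidate.ebic = ebic_score(candidate, grid.gamma)
                    fit = candidate
                except (EMAValidationError, np.linalg.LinAlgError, FloatingPointError):
                    pass  # keep the penalized fit if the refit is degenerate
            off = ~np.eye(fit.p, dtype=bool)
            rows.append(
                {
                    "lambda_beta": float(lb),
                    "lambda_kappa": float(lk),
                    "ebic": fit.ebic,
                    "loglik": fit.loglik,
                    "df": _degrees_of_freedom(fit.B, fit.K),
                    "converged": fit.converged,
                    "n_edges_temporal": int(np.sum(np.abs(fit.B[off]) > SUPPORT_TOL)),
                    "n_edges_contemporaneous": int(
                        np.sum(np.abs(fit.K[np.triu_indices(fit.p, k=1)]) > SUPPORT_TOL)
                    ),
                }
            )
            if fit.converged and (best is None or fit.ebic < best.ebic):
                best = fit
    table = pd.DataFrame(rows)
    if best is None:
        raise EMAValidationError(
            "no penalty pair converged; score table: "
            + (table.to_string() if len(table) else "(empty)")
        )
    return best, table


# ---------------------------------------------------------------------------
# Network extraction and export
# ---------------------------------------------------------------------------


def extract_networks(fit: GVARFit) -> NetworkPair:
    """Turn a fit into signed weighted networks.

    Contemporaneous edge (i, j) is the partial contemporaneous correlation
    -K[i,j] / sqrt(K[i,i] K[j,j]); temporal edge j -> i is the standardized
    coefficient B[i, j]. Numerical dust below ``SUPPORT_TOL`` is snapped to
    exactly zero so edge lists are clean.
    """
    try:
        np.linalg.cholesky(fit.K)
    except np.linalg.LinAlgError:
        raise EMAValidationError("precision matrix is not positive definite")
    d = np.sqrt(np.diag(fit.K))
    C = -fit.K / np.outer(d, d)
    np.fill_diagonal(C, 0.0)
    C[np.abs(C) <= SUPPORT_TOL] = 0.0
    C = (C + C.T) / 2
    T = fit.B.copy()
    T[np.abs(T) <= SUPPORT_TOL] = 0.0
    return NetworkPair(contemporaneous=C, temporal=T, nodes=list(fit.nodes))


def edge_list(pair: NetworkPair) -> pd.DataFrame:
    """Long edge table: source, target, weight, type, is_self_loop.

    Contemporaneous edges appear once (i < j); temporal edges are directed
    source -> target and include self-loops.
    """
    rows = []
    p = len(pair.nodes)
    for i in range(p):
        for j in range(i + 1, p):
            w = pair.contemporaneous[i, j]
            if w != 0.0:
                rows.append((pair.nodes[i], pair.nodes[j], w, "contemporaneous", False))
    for i in range(p):
        for j in range(p):
            w = pair.temporal[i, j]
            if w != 0.0:
                rows.append((pair.nodes[j], pair.nodes[i], w, "temporal", i == j))
    return pd.DataFrame(rows, columns=["source", "target", "weight", "type", "is_self_loop"])


def write_graphml(pair: NetworkPair, contemporaneous_path, temporal_path) -> None:
    import networkx as nx

    G = nx.Graph()
    G.add_nodes_from(pair.nodes)
    D = nx.DiGraph()
    D.add_nodes_from(pair.nodes)
    for row in edge_list(pair).itertuples():
        attrs = {"weight": float(row.weight)}
        if row.type == "contemporaneous":
            G.add_edge(row.source, row.target, **attrs)
        else:
            D.add_edge(row.source, row.target, is_self_loop=bool(row.is_self_loop), **attrs)
    nx.write_graphml(G, contemporaneous_path)
    nx.write_graphml(D, temporal_path)
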