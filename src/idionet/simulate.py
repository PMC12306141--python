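"""Synthetic EMA generation from a known graphical VAR ground truth.

The raw study data are not distributable, so every pipeline stage is
exercised against simulated participants with known structure: a stable
lag-1 coefficient matrix B_true (spectral radius < 1), a sparse positive
definite innovation precision K_true, a per-node location/scale mapping the
latent Gaussian series onto the 0-100 slider scale (with clipping at the
bounds), a 21-day x 5-beep schedule, and completely-at-random missingness at
the beep level (a skipped survey loses all items at once, the way EMA
nonresponse actually arises).

Under the within-day lag policy each day restarts from the stationary
distribution, consistent with excluding overnight lags from estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

from .data import (
    Community,
    DayBoundary,
    EMADataset,
    EMARecord,
    EMAValidationError,
    Schedule,
)
from .gvar import SUPPORT_TOL, GVARFit

__all__ = [
    "SyntheticTruth",
    "RecoveryMetrics",
    "make_truth",
    "simulate_ema",
    "simulate_latent",
    "stationary_covariance",
    "study_like_trio",
    "recovery_metrics",
]

#: completed-beep counts of the three study-like reference participants
STUDY_LIKE_COMPLETED = (96, 75, 45)

_DEFAULT_ED = ["feel_fat", "fear_weight", "worth_weight", "skip_meals_urge"]
_DEFAULT_SUI = ["desire_live", "fear_death", "reasons_die", "passive_ideation_1"]


@dataclass
class SyntheticTruth:
    """Ground-truth generating structure for one synthetic participant."""

    nodes: list[str]
    communities: dict[str, Community]
    B_true: np.ndarray
    K_true: np.ndarray
    location: np.ndarray  # 0-100 scale mean per node
    scale: np.ndarray  # latent-to-score multiplier per node
    missing_rate: float
    seed: int

    @property
    def p(self) -> int:
        return len(self.nodes)


@dataclass
class RecoveryMetrics:
    """Support/sign/weight agreement between a fit and the generating truth."""

    temporal_precision: float
    temporal_recall: float
    temporal_f1: float
    contemporaneous_precision: float
    contemporaneous_recall: float
    contemporaneous_f1: float
    sign_agreement: float
    weight_correlation: float
    seed: int | None = None


def make_truth(
    p_per_community: int = 4,
    edge_density: float = 0.15,
    effect_size_range: tuple[float, float] = (0.25, 0.4),
    seed: int = 0,
    missing_rate: float = 0.3,
    max_spectral_radius: float = 0.9,
) -> SyntheticTruth:
    """Draw a sparse, stable, bridge-containing ground truth.

    Autoregressive diagonals are uniform in [0.2, 0.5]; off-diagonal
    temporal and precision edges appear with the given density, magnitudes
    uniform in ``effect_size_range`` and random sign. At least one
    inter-community edge is forced into each matrix so bridge statistics are
    non-trivial, and B is rescaled if its spectral radius exceeds
    ``max_spectral_radius``. Locations/scales put the score means in
    [35, 65] with SDs in [10, 16], mimicking slider-scale item summaries.
    """
    if p_per_community < 1 or (p_per_community < 2 and edge_density >= 1):
        raise EMAValidationError("infeasible community size")
    if not (0 < edge_density <= 1):
        raise EMAValidationError("edge_density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    p = 2 * p_per_community
    if p_per_community == 4:
        nodes = _DEFAULT_ED + _DEFAULT_SUI
    else:
        nodes = [f"ed_{i+1}" for i in range(p_per_community)] + [
            f"sui_{i+1}" for i in range(p_per_community)
        ]
    communities = {
        n: (Community.ED if i < p_per_community else Community.SUI) for i, n in enumerate(nodes)
    }
    cross = np.zeros((p, p), dtype=bool)
    cross[:p_per_community, p_per_community:] = True
    cross[p_per_community:, :p_per_community] = True

    def _draw_magnitudes(shape):
        lo, hi = effect_size_range
        mags = rng.uniform(lo, hi, size=shape)
        signs = rng.choice([-1.0, 1.0], size=shape)
        return mags * signs

    # temporal matrix
    B = np.diag(rng.uniform(0.2, 0.5, size=p))
    off = ~np.eye(p, dtype=bool)
    mask_b = off & (rng.random((p, p)) < edge_density)
    B[mask_b] = _draw_magnitudes(int(mask_b.sum()))
    if not (mask_b & cross).any():
        i = int(rng.integers(p_per_community))
        j = int(p_per_community + rng.integers(p_per_community))
        B[i, j] = _draw_magnitudes(1)[0]
    radius = np.max(np.abs(np.linalg.eigvals(B)))
    if radius > max_spectral_radius:
        B *= max_spectral_radius / radius

    # precision matrix via partial correlations on unit diagonal
    upper = np.triu_indices(p, k=1)
    mask_k = rng.random(len(upper[0])) < edge_density
    if not mask_k[np.array([cross[i, j] for i, j in zip(*upper)])].any():
        cross_positions = [idx for idx, (i, j) in enumerate(zip(*upper)) if cross[i, j]]
        mask_k[int(rng.choice(cross_positions))] = True
    pcor = np.zeros(len(upper[0]))
    pcor[mask_k] = _draw_magnitudes(int(mask_k.sum()))
    K = np.eye(p)
    K[upper] = -pcor
    K = K + np.triu(K, k=1).T
    # shrink off-diagonals until comfortably positive definite
    while np.linalg.eigvalsh(K).min() < 0.05:
        K[~np.eye(p, dtype=bool)] *= 0.9

    sigma = solve_discrete_lyapunov(B, np.linalg.inv(K))
    latent_sd = np.sqrt(np.diag(sigma))
    target_mean = rng.uniform(35, 65, size=p)
    target_sd = rng.uniform(10, 16, size=p)
    return SyntheticTruth(
        nodes=nodes,
        communities=communities,
        B_true=B,
        K_true=K,
        location=target_mean,
        scale=target_sd / latent_sd,
        missing_rate=float(missing_rate),
        seed=int(seed),
    )


def stationary_covariance(truth: SyntheticTruth) -> np.ndarray:
    """Latent stationary covariance: the solution of S = B S B' + K^{-1}."""
    return solve_discrete_lyapunov(truth.B_true, np.linalg.inv(truth.K_true))


def simulate_latent(
    truth: SyntheticTruth, n_steps: int, seed: int, restart_every: int | None = None
) -> np.ndarray:
    """Raw latent VAR(1) series (no scaling, clipping or missingness).

    ``restart_every`` optionally redraws from the stationary distribution
    every that many steps (day-boundary semantics); None gives one unbroken
    chain, which is what stationary-covariance checks want.
    """
    rng = np.random.default_rng(seed)
    sigma = stationary_covariance(truth)
    chol_stat = np.linalg.cholesky(sigma)
    chol_inno = np.linalg.cholesky(np.linalg.inv(truth.K_true))
    p = truth.p
    out = np.empty((n_steps, p))
    x = chol_stat @ rng.standard_normal(p)
    for t in range(n_steps):
        if restart_every is not None and t % restart_every == 0:
            x = chol_stat @ rng.standard_normal(p)
        elif t > 0:
            x = truth.B_true @ x + chol_inno @ rng.standard_normal(p)
        out[t] = x
    return out


def simulate_ema(
    truth: SyntheticTruth,
    schedule: Schedule | None = None,
    day_boundary_policy: DayBoundary = DayBoundary.WITHIN_DAY,
    missing_rate: float | None = None,
    seed: int = 0,
    item_level_missing: bool = False,
    participant_id: str | None = None,
) -> EMADataset:
    """Simulate one synthetic participant's EMA dataset.

    Latent series per day follow x_t = B_true x_{t-1} + e_t; under the
    WITHIN_DAY policy each day restarts from the stationary distribution
    (overnight carry-over is not modelled), under ACROSS_ALL the chain runs
    unbroken across days. Scores are location + scale * x clipped to
    [0, 100]; beeps (or items, if ``item_level_missing``) are then deleted
    completely at random at ``missing_rate``.
    """
    schedule = schedule or Schedule()
    rate = truth.missing_rate if missing_rate is None else float(missing_rate)
    if not (0 <= rate < 1):
        raise EMAValidationError("missing_rate must be in [0, 1)")
    policy = DayBoundary(day_boundary_policy)
    restart = schedule.beeps_per_day if policy is DayBoundary.WITHIN_DAY else None
    latent = simulate_latent(truth, schedule.size, seed=seed, restart_every=restart)
    raw = truth.location + truth.scale * latent
    scores = np.clip(raw, 0.0, 100.0)
    clip_rate = np.mean((raw < 0) | (raw > 100))
    if clip_rate > 0.05:
        warnings.warn(f"{clip_rate:.1%} of simulated scores clipped at the scale bounds")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    records = []
    pos = 0
    for day in range(1, schedule.n_days + 1):
        for beep in range(1, schedule.beeps_per_day + 1):
            row = scores[pos]
            pos += 1
            if item_level_missing:
                keep = rng.random(truth.p) >= rate
                if not keep.any():
                    continue
                rec_scores = {n: float(row[i]) for i, n in enumerate(truth.nodes) if keep[i]}
            else:
                if rng.random() < rate:
                    continue
                rec_scores = {n: float(row[i]) for i, n in enumerate(truth.nodes)}
            records.append(EMARecord(day, beep, rec_scores))
    from .data import SymptomItem

    manifest = [
        SymptomItem(n, n.replace("_", " ").capitalize(), n, truth.communities[n])
        for n in truth.nodes
    ]
    return EMADataset(
        participant_id=participant_id or f"sim-{truth.seed}-{seed}",
        manifest=manifest,
        schedule=schedule,
        records=records,
    )


def study_like_trio(seed: int = 0) -> list[EMADataset]:
    """Three synthetic participants with exactly 96, 75 and 45 completed beeps.

    Mirrors the study-like availability range (45-96 of 105): complete
    datasets are simulated and a seeded random subset of beeps is deleted to
    hit each completion count exactly.
    """
    datasets = []
    for idx, completed in enumerate(STUDY_LIKE_COMPLETED):
        truth = make_truth(seed=seed + idx)
        full = simulate_ema(
            truth, missing_rate=0.0, seed=seed + 100 + idx,
            participant_id=f"synthetic-patient-{idx + 1}",
        )
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2, idx]))
        keep = set(rng.choice(len(full.records), size=completed, replace=False).tolist())
        records = [rec for i, rec in enumerate(full.records) if i in keep]
        datasets.append(
            EMADataset(full.participant_id, full.manifest, full.schedule, records)
        )
    return datasets


def _support_scores(true_mask, est_mask):
    tp = int(np.sum(true_mask & est_mask))
    fp = int(np.sum(~true_mask & est_mask))
    fn = int(np.sum(true_mask & ~est_mask))
    precision = 1.0 if (tp + fp) == 0 else tp / (tp + fp)  # no predicted edges: vacuous
    recall = 1.0 if (tp + fn) == 0 else tp / (tp + fn)
    f1 = 0.0 if (precision + recall) == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def recovery_metrics(
    truth: SyntheticTruth, fit: GVARFit, threshold: float = SUPPORT_TOL
) -> RecoveryMetrics:
    """Compare a fit's edge supports, signs and weights to the truth."""
    if list(fit.nodes) != list(truth.nodes):
        raise EMAValidationError(
            f"fit nodes {list(fit.nodes)} do not match truth nodes {list(truth.nodes)}"
        )
    p = truth.p
    off = ~np.eye(p, dtype=bool)
    upper = np.triu_indices(p, k=1)

    t_true = np.abs(truth.B_true[off]) > threshold
    t_est = np.abs(fit.B[off]) > threshold
    tp_, tr_, tf_ = _support_scores(t_true, t_est)
    c_true = np.abs(truth.K_true[upper]) > threshold
    c_est = np.abs(fit.K[upper]) > threshold
    cp_, cr_, cf_ = _support_scores(c_true, c_est)

    true_w = np.concatenate([truth.B_true[off], -truth.K_true[upper]])
    est_w = np.concatenate([fit.B[off], -fit.K[upper]])
    common = np.concatenate([t_true & t_est, c_true & c_est])
    sign_agreement = (
        float(np.mean(np.sign(true_w[common]) == np.sign(est_w[common]))) if common.any() else 1.0
    )
    union = np.concatenate([t_true | t_est, c_true | c_est])
    if union.sum() >= 2 and np.std(true_w[union]) > 0 and np.std(est_w[union]) > 0:
        weight_corr = float(np.corrcoef(true_w[union], est_w[union])[0, 1])
    else:
        weight_corr = float("nan")
    return RecoveryMetrics(
        temporal_precision=tp_, temporal_recall=tr_, temporal_f1=tf_,
        contemporaneous_precision=cp_, contemporaneous_recall=cr_, contemporaneous_f1=cf_,
        sign_agreement=sign_agreement, weight_correlation=weight_corr,
    )
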