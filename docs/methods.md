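# Methods

## Data model and sampling protocol

One participant's data are item scores on a bounded 0–100 slider scale,
collected on a fixed schedule: `n_days` days (default 21) with
`beeps_per_day` surveys per day (default 5), one every 2.5 h inside a 12-h
waking window, each open for 2 h — 105 scheduled assessment points under
the defaults. The canonical time axis is the integer (day, beep) grid;
wall-clock timestamps are treated as optional metadata only, so the model
assumes equally spaced within-day beeps.

Missingness is explicit and score `0` is always a valid observation, never
a missing marker. Availability percentages are reported per item as
`100 * n_observed / (n_days * beeps_per_day)`, rounded **half-up** to two
decimals (so 96/105 prints as 91.43% and 75/105 as 71.43%). One
deliberately unreplicated curiosity from the literature this protocol
follows: a published availability of 42.45% alongside 45 observed
timepoints is inconsistent with 45/105 = 42.86% (it matches a 106
denominator); this package always uses the schedule size as denominator.

## Node selection

Networks are estimated over a small subset of the item pool: the `k`
(default 4) items with the highest observed mean within each of the two
clinically pre-defined communities (ED, SUI), giving an 8-node network by
default. Means and sample SDs (n−1) use observed values only. Ties at the
k-th rank break by higher SD (more dynamic range carries more information
after standardization), then lexicographic item id; zero-variance items are
skipped by default since they cannot carry edges once standardized. Every
tie-break and skip is logged into the selection notes and the run manifest.
`k` is configurable because the ideal node count for single-subject
networks with 75–100 observations is plausibly closer to six.

## Lag structure and missing data

Estimation consumes lag-1 pairs `(y_{t-1}, y_t)` built from consecutive
scheduled beeps at which **all** selected nodes are observed — listwise
deletion at the pair level, no imputation. The default day-boundary policy
is `within_day`: the overnight gap (≈14 h versus the 2.5 h beep interval)
violates the equal-interval VAR assumption, so pairs never span days. The
`across_all` policy (pairing the last beep of a day with the first of the
next) is available for sensitivity analysis.

No detrending is applied by default; an optional per-node linear-in-day
detrend is provided because slow within-study drift can masquerade as lag-1
dependence.

## Estimation

With pairs stacked as predictors `X` and outcomes `Y` (each node centered
and scaled to unit pooled variance), the model is

    y_t = B y_{t-1} + e_t,   e_t ~ N(0, K^{-1}),

and the penalized negative log-likelihood (up to constants)

    tr(S_res(B) K) − log det K + λ_β Σ|B_ij| + λ_κ Σ_{i≠j} |K_ij|

is minimized by alternating optimization:

* **B-step** (K fixed): coordinate descent on all entries of `B` (diagonal
  included). The rows of `B` couple through `K`, so the update of `B[r, c]`
  uses the full gradient `2 K (B S_xx − S_yx)`; the kernel maintains
  `B S_xx` incrementally and is JIT-compiled (numba). With `K = I` this
  reduces to independent row-wise lasso regressions. At `λ_β = 0` the step
  is solved exactly in closed form (per-equation least squares).
* **K-step** (B fixed): graphical lasso on the residual covariance
  (scikit-learn's `graphical_lasso`); at `λ_κ = 0`, a direct inverse, with
  an explicit error if the residual covariance is singular.

Alternation stops when the maximum absolute parameter change falls below
1e-6 (at most 200 outer iterations); non-convergence is flagged, never
hidden. Entries with magnitude ≤ 1e-8 are treated as structural zeros when
counting edges and degrees of freedom, absorbing numerical dust from the
glasso step.

## Model selection

Penalty pairs are scored on a 10 × 10 log-spaced grid from data-driven
maxima (`λ_β^max = 2 max|S_yx|`, the smallest penalty zeroing B at K = I;
`λ_κ^max = max off-diagonal |S_yy|`) down to 0.01 × the maximum, by the
extended BIC

    EBIC(γ) = −2 loglik + log(n) · df + 4 γ log(p) · df,   γ = 0.5,

where `df` counts nonzero off-diagonal B entries, nonzero upper-triangle K
entries, and the two diagonals (a constant offset that never affects the
argmin). Ties break toward larger penalties (the sparser model).

**Post-lasso scoring.** Each candidate is scored — and the winner returned —
after refitting its selected support without penalty: rows of `B` by
restricted least squares, then `K` re-estimated on the refit residuals at
the candidate's own `λ_κ`. Scoring the shrunken path directly makes the
EBIC systematically prefer denser models, because decreasing `λ_β` buys
large likelihood gains simply by releasing bias on strong true edges, and
noise edges ride along. After refit, an extra edge can only pay for its own
information content, which restores the criterion's false-edge control;
this is the relaxed-lasso / post-selection refit idea long used with
BIC-type criteria. The practical effect is visible in the package's own
benchmarks: near-empty selected networks on white-noise data and high
support-recovery F1 under known truths.

Temporal edge weights are reported as standardized regression coefficients;
contemporaneous weights as partial correlations
`−K_ij/√(K_ii K_jj)`.

## Centrality and target nomination

Six statistics per node: contemporaneous strength, contemporaneous bridge
strength, temporal InStrength/OutStrength, bridge InStrength/OutStrength.
Default conventions, each configurable and recorded in the output:

* **Absolute values**: statistics sum `|w|` (the dominant convention in
  this toolchain); a signed expected-influence variant exists because
  estimated networks contain negative edges.
* **Self-loops excluded** from In/OutStrength: an autoregressive edge is
  not influence on *other* symptoms.
* Bridge statistics sum only edges whose endpoints lie in different
  communities; communities are clinically pre-defined, never detected.

Useful identities that the tests enforce: Σ InStrength = Σ OutStrength
(each directed edge contributes once to each side), bridge ≤ total per
node, and all bridge values are invariant to swapping the two community
labels.

Nomination takes the top two nodes on each of four statistics —
contemporaneous strength, contemporaneous bridge strength, OutStrength,
bridge OutStrength ("temporal strength" is read as OutStrength, the
outgoing-influence sum; incoming variants are computed but do not nominate,
since a symptom that merely receives influence is a poor lever). The pooled
nominations are deduplicated; each target keeps every nominating statistic
and value, and is matched against an editable symptom → intervention-options
registry (shipped as JSON data, not code). Ties are broken by aggregate
centrality across all six statistics, then node id, and always flagged —
clinically they warrant human review. Targets missing from the registry are
flagged unmatched, never dropped.

## Synthetic generator

`make_truth` draws a ground truth per synthetic participant: AR diagonals
uniform in [0.2, 0.5]; off-diagonal temporal and partial-correlation edges
at density 0.15 with magnitudes uniform in [0.25, 0.40] and random sign; at
least one inter-community edge forced into each matrix (so bridge
statistics are exercised); `B` rescaled to spectral radius ≤ 0.9 for
stationarity; `K` kept comfortably positive definite by off-diagonal
shrinkage. Score means land in [35, 65] and SDs in [10, 16], matching the
magnitude of published slider-scale item summaries.

`simulate_ema` runs the latent VAR per day, restarting each day from the
stationary distribution (the closed-form solution of the discrete Lyapunov
equation Σ = BΣB′ + K⁻¹), consistent with the within-day lag policy;
`across_all` simulation runs one unbroken chain. Latent values are mapped
by per-node location/scale and clipped to [0, 100]; the default scaling
keeps clipping below ~5% (a warning fires beyond that), since heavy
clipping would break the Gaussianity the estimator assumes — clipping, not
a logit transform, because it is what a bounded slider actually does.
Missingness deletes whole beeps completely at random (survey-level
nonresponse; default rate 0.3, inside the 45–96-of-105 completion range the
protocol reports); item-level MCAR is an option. `study_like_trio` deletes
seeded random beep subsets to hit 96, 75 and 45 completed beeps exactly.

What the generator does **not** emulate: missing-not-at-random mechanisms
(e.g., skipping surveys when symptomatic), diurnal cycles, reactive
measurement effects, floor-inflated item distributions, or any real
patient's values. Passing tests therefore demonstrate correctness of the
machinery and recoverability under an MCAR, stationary, Gaussian-ish world
— not robustness to every feature of clinical EMA data.

## Problem sizes used in tests and benchmarks

Unit oracles run at n of a few hundred pairs; the unpenalized-estimator
oracle uses 2 000 pairs at p = 6; support recovery uses 20 replicates of a
210-day schedule (≈ 840 within-day pairs, ten times the 21-day protocol);
the null (white-noise) check uses 20 replicates at the protocol length; the
simulator-fidelity check uses a 50 000-step unclipped chain. The analysis
drivers use 10 replicates for a faster read of the same quantities.

## Known limitations

* Single-participant estimation only; no pooled/multilevel variant.
* Gaussian likelihood on a bounded, clipped scale — adequate when scores
  stay off the bounds, optimistic otherwise.
* Equal-interval assumption within days; actual response latencies within
  the 2-h window are ignored.
* With p = 8 nodes and 40–90 usable pairs (typical at protocol length and
  realistic missingness), temporal edges are conservatively selected; the
  pipeline completes but flags low-data conditions in the run manifest.
* Target nomination encodes one defensible reading of the four-statistic
  rule; which statistics *should* drive treatment selection remains an open
  clinical question, which is why the statistic set is configurable.
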