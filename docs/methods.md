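# Methods

## Model and likelihood

Traits are modeled on a rooted, time-calibrated (usually ultrametric)
phylogeny whose branches are painted with selective regimes.  Under the
multi-optimum Ornstein–Uhlenbeck process with pull `α` (1/My), diffusion
rate `σ²` (trait²/My) and regime optima `θ_k` (trait units, here
dimensionless ln-residuals), tip values are jointly Gaussian.  The
package uses the **fixed-root, non-stationary** formulation: the root
state is a fixed quantity, expectations decay from it toward the optima
along each lineage's regime history, and the covariance of tips *i, j*
is `σ²/(2α) e^{−α(T_i+T_j−2t_a)}(1−e^{−2αt_a})` with `t_a` the height of
their most recent common ancestor.  The stationary formulation (root
drawn from the stationary distribution) is a different, also defensible
choice; fixed-root was selected because it has a well-defined BM limit
(`α → 0` gives exactly the BM expectation and covariance, verified to
1e-4 in lnL at `α = 1e-9`) and keeps the root-state policy explicit.
Trees need not be exactly ultrametric: per-tip depths `T_i` enter every
formula, and a non-ultrametric input only triggers a warning with the
tip-depth spread.

**Root-state policy.**  By default the root state equals the optimum of
the root (background) regime, so an OU model with `k` optima has
`p = 2 + k` free parameters (α, σ², θ₁..θ_k) and BM has `p = 2`
(X₀, σ²).  A free-root-state policy (`p = 3 + k`) is available on every
`ModelSpec`; it changes SIC through `p`, which is why the policy is an
explicit, recorded setting rather than a hidden backend default.

## Fitting

Expectations are linear in the optima (and root state, if free), and the
covariance factors as `σ² V₀(α)`.  Both facts are exploited: at fixed
`α`, the optima are the GLS solution against `V₀(α)` and the ML `σ̂²` is
the whitened mean squared residual, so the profile likelihood is exact
and the whole fit reduces to a **one-dimensional deterministic search
over `ln α`**.  The search evaluates a fixed grid of 17 starts spanning
half-lives from `0.01 T` to `10 T` (T = tree depth), then refines around
the best start with bounded Brent iteration (tolerance 1e-4 in `ln α`).
This reaches the same maximum as a joint `(ln α, ln σ²)` search at a
fraction of the cost, with no stochastic restarts to make runs differ.
`α` is capped at `10⁴/T`; a fit at the cap is flagged.  Ties in model
ranking are broken by lower SIC, then fewer parameters, then the fixed
model order (BM1, OU1, OU2_foss, OU2_arb&Ma, OU2_arb&Xe, OU3).

**Batch refitting.**  The bootstrap stages refit thousands of simulated
datasets on one tree.  `FitEngine.fit_batch` evaluates the profile on a
shared 25-point `ln α` grid — one Cholesky factorization per grid point
serves *all* datasets — then refines each dataset by parabolic
interpolation with exact re-evaluation at the interpolated point, so the
reported lnL is always an exactly evaluated profile value.  Agreement
with the scalar fitter is asserted in the test suite (≤ 0.005 lnL on
125-tip data); the residual difference is far below the width of any
bootstrap ratio distribution it feeds.

## Simulation

`simulate_traits` draws exactly from the model's Gaussian distribution
via one Cholesky factor (default), with an independent preorder
recursive simulator — exact OU transitions segment by segment — kept as
a distributional oracle; the two routes are compared at 4 Monte Carlo
SEs in the tests.  Each batch derives per-dataset substreams from one
root seed, so results are identical under any execution order.

## Pipeline order and the sensitivity filter

The allometric regression always runs on the **unpruned** species set,
and its residuals are then restricted to the analysis phylogeny; the
opposite order gives different residuals and is deliberately not
offered.  The permutation test (type-I sums of squares; for a single
continuous predictor this reduces to permuting the response against the
regression sum of squares) affects only the reported p-value, never the
residuals.

The sensitivity filter emulates single-specimen sampling: each replicate
draws one value per species from Normal(species value, SD) on the
residual scale, re-scores all six models, and tabulates which model is
SIC-best.  The SD defaults to one pooled within-species SD estimated
from species with ≥ 2 specimens (within-species SDs pass through the
allometric line unchanged, because the predictor is constant within a
species); per-species SDs or an explicit value are accepted.  The
allometric regression is *not* re-run inside replicates — a documented
simplification, togglable in principle, chosen because specimen noise
in one trait perturbs the fitted line negligibly at n ≈ 125–186.  A
trait passes when the modal simulated winner equals the empirical
winner; a trait advances to pairwise comparison when it passes *and*
the homoplasy model ranks first, or second behind OU3 (the only model
nesting it).

## Pairwise parametric bootstrap

`δ_emp = 2(lnL_focal − lnL_alt)`; the factor 2 follows the standard
likelihood-ratio-statistic convention and cancels in every CI-membership
decision.  For each side, `n_sim` datasets (default 5,000) are simulated
at that side's *fitted* parameters and both models are refit to every
dataset, giving two ratio distributions; CIs are two-sided empirical
[2.5%, 97.5%] percentiles with boundary values counting as inside.  The
classification is four-way; the fourth case (inside the alternative CI
only) completes the logic even though well-behaved analyses rarely
produce it.  More than 1% non-finite refits aborts the comparison.

**Calibration.**  The validation harness measures CI calibration with
the ratio distribution simulated at the *generating* parameters: the
empirical ratio is then a fresh draw from the same distribution and the
empirical 95% CI covers it at its nominal rate (measured 93–95% over
300 runs at n_sim = 500).  The CI computed inside the comparison itself
uses fitted parameters, which track the data; that interval *over*-covers
(~99% under the same conditions) — the familiar conservative bias of
non-pivotal parametric bootstrap.  Both variants are exposed
(`pmc_calibration(..., ci_at="truth" | "fitted")`); the conservatism
means the procedure errs toward "cannot discriminate", never toward
spurious support for the focal model, which the false-positive harness
confirms directly (BM-generated data yield a `+` for the homoplasy model
in ≈ 2–4% of runs, within the CI's own error rate).

## Synthetic studies

The generator reproduces the study geometry exactly: pure-birth (Yule)
crown trees per group, rescaled and grafted so that the two derived
clades are monophyletic with stems at configurable ages (defaults 24.5
and 31.3 My on a 70 My tree, 76/43/6 tips).  Pure birth with grafting
was chosen over a joint birth–death process because it gives exact,
seed-deterministic control of group sizes, depth and stem ages — the
quantities the design actually conditions on.  ln-body-mass evolves as
BM (σ² = 0.01) plus constant group offsets (+1.0 for the large derived
clade, +0.3 for the small one) so groups differ in mass range; traits
are built as allometric line (default slope 0.33) + model residual +
Normal specimen noise.

Default trait-generating settings — the "strong-signal" conditions used
by every harness — are `t½ = 2` My, `σ² = 0.05`, and derived optima 4
stationary SDs (`√(σ²/2α)` ≈ 0.27) from the background.  For OU3 the two
derived optima depart in *opposite* directions (±4 SDs): with both on
the same side the three-optimum model is nearly indistinguishable from
the homoplasy model, which would test confusability rather than
consistency.  BM1 uses σ² = 0.002, giving tip SDs comparable to the OU
traits.  What the generator does **not** emulate: measurement error
structure beyond iid Normal specimen noise, fossil (non-contemporaneous)
tips, mass-by-regime interaction slopes, and correlated evolution across
traits — so passing harnesses demonstrate correctness of the inference
machinery under the model, not robustness to those violations.

## Problem sizes and numerical choices

Harness sizes are chosen so the full validation battery (oracle checks,
100-replicate recovery with 100-refit bootstraps, 6 × 200 selection
replicates, 50 false-positive and 300 calibration runs at n_sim = 500,
and the resampling-filter checks) completes in a few minutes on one CPU;
production analyses use the full n_sim = 5,000 and 1,000 sensitivity
replicates by default.  Cholesky factorization is used everywhere a
covariance is inverted; a non-positive-definite matrix raises with the
smallest eigenvalue named.  `(1 − e^{−2αt})` is computed with `expm1`
so the BM limit is stable down to `α = 1e-9`.  Degenerate inputs are
handled explicitly: zero intraspecific SD short-circuits the resampling
filter (every replicate is the empirical dataset), `σ² = 0` simulation
returns the expectation vector, and `σ̂²` is floored at 1e-300 before
taking logs.

## Known limitations

Single-trait (univariate) models only; one α and σ² shared across
regimes; no small-sample SIC correction; no analytic (χ²) likelihood
ratio tests — the bootstrap null replaces them by design.  The painting
API rejects nested clade assignments (shifts within shifts) in this
version.  Stem ages reported by `stem_age` assume the clade's stem
begins at its parent node, which is exact for the painted-shift
convention used throughout.
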