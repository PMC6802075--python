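# ouregimes

Multi-regime Ornstein–Uhlenbeck model comparison on painted phylogenies,
with parametric-bootstrap (phylogenetic Monte Carlo) model discrimination.

## The problem

When two clades independently enter the same selective regime — say, two
squirrel lineages that each abandoned an arboreal lifestyle for a
fossorial one — do their traits evolve toward a **shared** new optimum
(trait-optimum homoplasy, i.e. convergence at the level of adaptive
peaks), or is some other scenario more likely?  A significant difference
between "fossorial" and "arboreal" species is not enough: one large
clade can dominate the signal while the small clade never left the
ancestral optimum.

`ouregimes` implements the full inference pipeline for this question on
continuous (ln-scale) traits:

1. **Allometric residualization** — OLS of ln(trait) on ln(body mass)
   over the *full* species sample (no phylogenetic correction), with a
   residual-randomization permutation test; residuals are then pruned to
   the analysis phylogeny.
2. **Regime painting** — selective regimes assigned to branches of an
   ultrametric time tree, with shifts placed at the base of each derived
   clade's stem lineage.
3. **Six-model SIC scoring** — maximum-likelihood fits of
   BM1, OU1, OU2_foss (homoplasy), OU2 with either single clade retaining
   the ancestral optimum, and OU3, ranked by the Schwarz information
   criterion `SIC = −2 lnL + p ln n`.
4. **Specimen-resampling sensitivity filter** — hypothetical populations
   around each species value are resampled one specimen at a time
   (default 1,000 replicates); a trait whose modal re-scored winner is
   not the empirical winner is dismissed.
5. **Advance rule** — only traits whose homoplasy model ranks first (or
   second behind OU3, the sole more-complex model) advance.
6. **Pairwise parametric bootstrap** — for each alternative model, data
   are simulated under both fitted models (default 5,000 datasets each),
   both models are refit to every dataset, and the empirical likelihood
   ratio `δ_emp = 2(lnL_focal − lnL_alt)` is classified against the two
   95% CIs: favored (`+`), equally plausible (`=`), equally implausible
   (`/`), or alternative-favored (`−`).  Bootstrap percentile CIs flag
   unreliable parameter estimates.

## The model

Under the Hansen (multi-optimum OU) process a trait `x` on a lineage in
regime `k` follows

    dx = α (θ_k − x) dt + σ dW,

with adaptive pull `α` (per My), regime optimum `θ_k`, and diffusion
`σ²`.  On a painted tree the tips are jointly Gaussian with

    E_i   = X₀ e^{−αT_i} + Σ_seg θ(seg) (e^{−α(T_i−t_end)} − e^{−α(T_i−t_start)})
    V_ij  = σ²/(2α) · e^{−α(T_i+T_j−2t_a)} (1 − e^{−2α t_a}),

where `t_a` is the height of the pair's most recent common ancestor
(fixed-root, non-stationary formulation).  Brownian motion is the α → 0
limit (`V_ij = σ² t_a`).  The phylogenetic half-life `t½ = ln2/α` is the
time for a lineage to cover half the distance to a new optimum.  Optima
(and the root state, if free) are profiled out by GLS and `σ²`
analytically, so each fit is a deterministic one-dimensional search over
`ln α` from a multi-start grid spanning `t½ ∈ [0.01 T, 10 T]`.

A first-class synthetic-study generator (`ouregimes.synthetic_data`)
emulates the two-clade study design — a 125-tip ultrametric tree
(76-species paraphyletic background + monophyletic derived clades of 43
and 6 species with stems at ~24.5 and ~31.3 My), body masses as BM plus
group offsets, and specimen-level traits as allometric line + OU/BM
residual + measurement noise — so every stage is testable against a
known truth without any external data.

## Worked example

```python
import numpy as np
from ouregimes import (generate_study, score_models, sampling_sensitivity,
                       advance_rule, pmc_compare)

study = generate_study(seed=7)          # 125-tip synthetic study
tree, painting, specs = study.tree, study.painting, study.specs

# residual vector of the homoplasy-generated trait (tree tip order)
cfg = study.configs["trait_OU2_foss"]
means = study.trait_table.query("trait == 'trait_OU2_foss'") \
                         .groupby("species")["value"].mean()
x = np.array([means[s] - cfg.intercept - cfg.slope * study.ln_mass[s]
              for s in tree.tip_names])

table = score_models(tree, painting, x, trait="trait_OU2_foss", specs=specs)
for m in table.order:
    f = table.fits[m]
    print(m, round(f.sic, 3), f.t_half)

sens = sampling_sensitivity(tree, painting, x, 0.05, n_replicates=1000,
                            seed=7, specs=specs)
ok, reason = advance_rule(table, sens)
res = pmc_compare(tree, painting, x, specs["OU2_foss"], specs["BM1"],
                  n_sim=5000, seed=7)
```

Output:

```
SIC per model:
  OU2_foss     SIC=    5.084  t1/2=  1.11 My
  OU3          SIC=    9.474  t1/2=  1.11 My
  OU2_arb&Xe   SIC=   71.538  t1/2=  7.41 My
  OU2_arb&Ma   SIC=   86.111  t1/2= 13.49 My
  OU1          SIC=   94.031  t1/2= 16.57 My
  BM1          SIC=  113.784
sensitivity: modal=OU2_foss (100.0%), passed=True
advance to pairwise comparison: True (OU2_foss ranked first by SIC)
OU2_foss vs BM1: delta_emp=118.4, focal CI=(85.6, 154.4),
                 alt CI=(-0.3, 8.3) -> focal_favored (+)
```

The trait was generated under the homoplasy model with its optima four
stationary standard deviations apart, so the homoplasy model scores
lowest (best) by a wide margin, survives the single-specimen resampling
filter, and the empirical likelihood ratio falls inside the homoplasy
model's simulated ratio distribution but far outside BM's — the `+`
outcome.  A full multi-trait run (residuals → scores → sensitivity →
advance → pairwise bootstrap, with CSV/JSON/figure outputs) is driven by
`ouregimes.pipeline.run_study` or the CLI:

```sh
ouregimes simulate --seed 1 --out study/
ouregimes run --config config.yaml
```

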