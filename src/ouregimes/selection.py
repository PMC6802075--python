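"""Six-model SIC scoring, the specimen-resampling sensitivity filter,
and the rule deciding which traits advance to pairwise comparison.

The sensitivity simulation emulates sampling a single specimen per
species: hypothetical populations are Normal around the observed species
value with an intraspecific SD (by default one pooled SD estimated from
species with >= 2 specimens), a single specimen is drawn per species,
all six models are re-scored, and the frequency with which each model
attains the lowest SIC is tabulated.  A trait passes the filter when the
modal simulated best model equals the empirical best.  The allometric
regression is not re-run inside replicates (noise is added on the
residual scale); this simplification is flagged on the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .oumodels import FitEngine, FitOptions, ModelFit, ModelSpec, six_model_specs
from .phylo import Painting, TimeTree

#: deterministic tie-break order (after lower SIC, then lower p)
MODEL_TIEBREAK = ("BM1", "OU1", "OU2_foss", "OU2_arb&Ma", "OU2_arb&Xe", "OU3")


@dataclass
class ScoreTable:
    trait: str
    fits: dict[str, ModelFit]
    order: list[str]            # model names, best first

    @property
    def best(self) -> str:
        return self.order[0]

    @property
    def sics(self) -> dict[str, float]:
        return {m: f.sic for m, f in self.fits.items()}

    @property
    def warnings(self) -> list[str]:
        return [m for m, f in self.fits.items() if not f.converged]

    def rank(self, model: str) -> int:
        return self.order.index(model) + 1

    def to_row(self) -> dict:
        row: dict = {"trait": self.trait}
        for m, f in self.fits.items():
            row[f"SIC_{m}"] = f.sic
        row["best"] = self.best
        return row


@dataclass
class SensitivityResult:
    trait: str
    n_replicates: int
    frequencies: dict[str, float]   # model -> % of replicates with lowest SIC
    modal: str
    empirical_best: str
    seed: int
    noise_sd: float | np.ndarray
    passed: bool = field(init=False)
    reran_allometry: bool = False

    def __post_init__(self):
        self.passed = self.modal == self.empirical_best


def _rank_models(fits: dict[str, ModelFit]) -> list[str]:
    def key(m: str):
        f = fits[m]
        idx = MODEL_TIEBREAK.index(m) if m in MODEL_TIEBREAK else len(MODEL_TIEBREAK)
        return (f.sic, f.spec.p, idx)

    return sorted(fits, key=key)


class ModelSet:
    """The six hypothesis models on one (tree, painting), with cached
    per-model fitting engines so repeated scoring is cheap."""

    def __init__(self, tree: TimeTree, painting: Painting,
                 specs: dict[str, ModelSpec] | None = None,
                 options: FitOptions | None = None):
        regs = painting.regimes
        if specs is None:
            bg = painting.background
            derived = [r for r in regs if r != bg]
            if len(derived) != 2:
                raise ValueError("the six-model set needs exactly two derived regimes")
            specs = six_model_specs(bg, derived[0], derived[1])
        self.specs = specs
        self.options = options or FitOptions()
        self.engines = {name: FitEngine(tree, painting, spec)
                        for name, spec in specs.items()}
        self.tree = tree
        self.painting = painting

    def fit_all(self, x: np.ndarray, warm: dict[str, float] | None = None
                ) -> dict[str, ModelFit]:
        out = {}
        for name, engine in self.engines.items():
            extra = (warm[name],) if warm and warm.get(name) else ()
            out[name] = engine.fit(x, options=self.options,
                                   extra_alpha_starts=extra)
        return out

    def score(self, x: np.ndarray, trait: str = "trait",
              warm: dict[str, float] | None = None) -> ScoreTable:
        fits = self.fit_all(x, warm=warm)
        return ScoreTable(trait=trait, fits=fits, order=_rank_models(fits))

    def score_batch(self, X: np.ndarray, warm: dict[str, float] | None = None
                    ) -> tuple[list[str], dict[str, np.ndarray]]:
        """Best model per dataset (rows of X) and per-model SIC arrays.

        SIC ties are broken exactly as in :meth:`score`: lower parameter
        count first, then the fixed model order.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        sics = {}
        for name, engine in self.engines.items():
            extra = (warm[name],) if warm and warm.get(name) else ()
            sics[name] = engine.fit_batch(X, options=self.options,
                                          extra_alpha_starts=extra).sic
        prefer = sorted(self.specs, key=lambda m: (
            self.specs[m].p,
            MODEL_TIEBREAK.index(m) if m in MODEL_TIEBREAK else len(MODEL_TIEBREAK)))
        stacked = np.stack([sics[m] for m in prefer])  # argmin is first-wins
        best_idx = np.argmin(stacked, axis=0)
        return [prefer[i] for i in best_idx], sics


def score_models(
    tree: TimeTree,
    painting: Painting,
    x: np.ndarray,
    trait: str = "trait",
    specs: dict[str, ModelSpec] | None = None,
    options: FitOptions | None = None,
) -> ScoreTable:
    """Fit all six models to one residual vector and rank them by SIC."""
    return ModelSet(tree, painting, specs=specs, options=options).score(x, trait=trait)


def pooled_specimen_sd(trait_table: pd.DataFrame, trait: str) -> float:
    """Pooled within-species SD (ln scale) from species with >= 2 specimens.

    On the residual scale this equals the raw within-species SD, because
    the allometric prediction is constant within a species.
    """
    sub = trait_table[trait_table["trait"] == trait]
    g = sub.groupby("species")["value"]
    counts = g.count()
    multi = counts[counts >= 2].index
    if len(multi) == 0:
        raise ValueError(
            f"no species with >= 2 specimens for trait {trait!r}; "
            "supply an intraspecific SD explicitly")
    num = 0.0
    den = 0
    for s in multi:
        vals = sub[sub["species"] == s]["value"].to_numpy(dtype=float)
        num += ((vals - vals.mean()) ** 2).sum()
        den += len(vals) - 1
    return float(np.sqrt(num / den))


def sampling_sensitivity(
    tree: TimeTree,
    painting: Painting,
    means: np.ndarray,
    noise_sd,
    trait: str = "trait",
    n_replicates: int = 1000,
    seed: int = 0,
    specs: dict[str, ModelSpec] | None = None,
    options: FitOptions | None = None,
    model_set: ModelSet | None = None,
) -> SensitivityResult:
    """Single-specimen resampling filter.

    ``means`` is the observed species vector on the residual scale (tree
    tip order); ``noise_sd`` is a scalar pooled SD or a per-species
    vector.  Each replicate draws one specimen per species from
    Normal(mean, SD), re-scores the six models, and records the
    SIC-lowest one.
    """
    ms = model_set or ModelSet(tree, painting, specs=specs, options=options)
    means = np.asarray(means, dtype=float)
    sd = np.broadcast_to(np.asarray(noise_sd, dtype=float), means.shape)
    if np.any(sd < 0):
        raise ValueError("intraspecific SDs must be >= 0")
    empirical = ms.score(means, trait=trait)
    warm = {m: (f.alpha or 0.0) for m, f in empirical.fits.items()}
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    counts = {m: 0 for m in ms.specs}
    if not sd.any():
        # degenerate: every replicate is the empirical dataset
        counts[empirical.best] = n_replicates
    else:
        X = rng.normal(means[None, :], sd[None, :], size=(n_replicates, means.size))
        best, _ = ms.score_batch(X, warm=warm)
        for b in best:
            counts[b] += 1
    freqs = {m: 100.0 * c / n_replicates for m, c in counts.items()}
    # modal model; frequency ties broken by the fixed model order
    modal = min(freqs, key=lambda m: (-freqs[m],
                                      MODEL_TIEBREAK.index(m)
                                      if m in MODEL_TIEBREAK else len(MODEL_TIEBREAK)))
    return SensitivityResult(
        trait=trait, n_replicates=n_replicates, frequencies=freqs,
        modal=modal, empirical_best=empirical.best, seed=seed,
        noise_sd=noise_sd,
    )


def advance_rule(table: ScoreTable, sens: SensitivityResult) -> tuple[bool, str]:
    """Decide whether a trait advances to pairwise model comparison.

    A trait advances when the sensitivity filter passed AND the homoplasy
    model (OU2_foss) either ranks first by SIC or ranks second behind
    OU3, the only model more complex than it.
    """
    if not sens.passed:
        return False, (
            f"sensitivity: empirical best {sens.empirical_best} != modal "
            f"simulated best {sens.modal}")
    r = table.rank("OU2_foss")
    if r == 1:
        return True, "OU2_foss ranked first by SIC"
    if r == 2 and table.best == "OU3":
        return True, "OU2_foss ranked second behind OU3"
    return False, f"OU2_foss ranked {r} (best: {table.best})"
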