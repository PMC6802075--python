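"""Allometric residualization: OLS of ln(trait) on ln(body mass).

The regression is deliberately fit on the *full, unpruned* species set
(no phylogenetic correction), and the residual table is pruned to the
analysis species afterwards — the ordering matters and is asserted by
the pipeline.  A residual-randomization permutation test (type-I sums of
squares) reports significance of the allometric slope; the residuals
themselves come from the plain OLS fit and are invariant to the number
of permutation rounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TRAIT_COLUMNS = ("species", "specimen", "trait", "value")


@dataclass
class AllometryFit:
    trait: str
    intercept: float
    slope: float
    residuals: dict[str, float]  # species -> ln-residual (species mean)
    r_squared: float
    n_used: int
    p_permutation: float | None = None
    excluded: list[str] = field(default_factory=list)


def species_means(traits: pd.DataFrame, trait: str) -> pd.Series:
    """Mean ln-value per species for one trait, pooling specimens."""
    sub = traits[traits["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no rows for trait {trait!r}")
    return sub.groupby("species")["value"].mean()


def fit_allometry(
    traits: pd.DataFrame,
    mass: Mapping[str, float],
    trait: str,
    n_permutations: int = 0,
    seed: int = 0,
) -> AllometryFit:
    """OLS of ln(trait) on ln(mass) over all species with both values.

    Species without a mass entry are excluded (and listed on the fit).
    With ``n_permutations > 0`` a permutation p-value for the slope is
    computed by shuffling the response; it does not alter the residuals.
    """
    means = species_means(traits, trait)
    excluded = sorted(s for s in means.index if s not in mass or not np.isfinite(mass[s]))
    kept = [s for s in means.index if s not in set(excluded)]
    if len(kept) < 3:
        raise ValueError(f"need >= 3 species with trait and mass, got {len(kept)}")
    y = means.loc[kept].to_numpy(dtype=float)
    m = np.array([mass[s] for s in kept], dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite trait values")
    if np.ptp(m) == 0:
        raise ValueError("zero variance in ln-mass; slope is not identifiable")
    mc = m - m.mean()
    sxx = float(mc @ mc)
    slope = float(mc @ (y - y.mean()) / sxx)
    intercept = float(y.mean() - slope * m.mean())
    pred = intercept + slope * m
    resid = y - pred
    sst = float(((y - y.mean()) ** 2).sum())
    ssr = float((resid ** 2).sum())
    r2 = 1.0 - ssr / sst if sst > 0 else 0.0

    p_perm = None
    if n_permutations > 0:
        # type-I SS for a single predictor reduces to the squared slope
        # times Sxx; permuting the response gives the null distribution
        rng = np.random.default_rng(seed)
        obs = slope * slope * sxx
        hits = 0
        yc = y - y.mean()
        for _ in range(n_permutations):
            yp = rng.permutation(yc)
            b = float(mc @ yp / sxx)
            if b * b * sxx >= obs:
                hits += 1
        p_perm = (hits + 1) / (n_permutations + 1)

    return AllometryFit(
        trait=trait, intercept=intercept, slope=slope,
        residuals={s: float(r) for s, r in zip(kept, resid)},
        r_squared=r2, n_used=len(kept), p_permutation=p_perm,
        excluded=excluded,
    )


def residual_matrix(
    fits: Sequence[AllometryFit],
    keep: Iterable[str],
    tip_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Species-by-trait residual matrix restricted to ``keep``.

    Row order follows ``tip_order`` when given (the tree's tip order),
    otherwise the sorted species names.  A kept species missing from any
    fit is an error.
    """
    keep = list(keep)
    order = list(tip_order) if tip_order is not None else sorted(keep)
    if set(order) != set(keep):
        raise ValueError("tip_order must contain exactly the kept species")
    missing = [(s, f.trait) for f in fits for s in keep if s not in f.residuals]
    if missing:
        raise KeyError(f"missing residuals for (species, trait): {missing}")
    data = {f.trait: [f.residuals[s] for s in order] for f in fits}
    return pd.DataFrame(data, index=pd.Index(order, name="species"))


def read_trait_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    missing = set(TRAIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trait table missing columns: {sorted(missing)}")
    if not np.all(np.isfinite(df["value"].to_numpy(dtype=float))):
        raise ValueError("trait table contains non-finite values")
    dup = df.duplicated(subset=["species", "trait", "specimen"])
    if dup.any():
        raise ValueError("duplicate (species, trait, specimen) rows")
    return df


def read_mass_table(path, ln_transform: bool = True) -> dict[str, float]:
    df = pd.read_csv(path, sep=None, engine="python")
    if "species" not in df.columns:
        raise ValueError("mass table needs a 'species' column")
    col = "mass_g" if "mass_g" in df.columns else "ln_mass"
    vals = df[col].to_numpy(dtype=float)
    if col == "mass_g" and ln_transform:
        vals = np.log(vals)
    return dict(zip(df["species"], map(float, vals)))
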