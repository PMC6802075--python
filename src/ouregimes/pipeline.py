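"""End-to-end orchestration: residuals -> prune -> score -> sensitivity
-> advance rule -> pairwise bootstrap, with tabular/JSON outputs.

Stage order mirrors the study design: the allometric regression runs on
the full unpruned species set, the residual table is pruned to the
analysis phylogeny afterwards, the sensitivity filter is applied before
the advance rule, and the pairwise parametric bootstrap runs only for
traits that advanced.  Per-trait failures are isolated and reported;
other traits continue.
"""

from __future__ import annotations

import json
import pathlib
import traceback
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .allometry import fit_allometry, read_mass_table, read_trait_table, residual_matrix
from .oumodels import FitOptions, six_model_specs
from .phylo import TimeTree, paint_regimes
from .pmc import plot_pmc, pmc_compare, bootstrap_refits, parameter_cis
from .selection import (ModelSet, advance_rule, pooled_specimen_sd,
                        sampling_sensitivity)


@dataclass
class CladeSpec:
    regime: str
    tips: list[str]
    include_stem: bool = True


@dataclass
class RunConfig:
    tree_path: str
    traits_path: str
    mass_path: str
    clades: list[CladeSpec]
    background: str = "arb"
    outdir: str = "ouregimes_out"
    traits: list[str] | None = None          # default: all traits in the table
    keep_species: list[str] | None = None    # default: tree tips with residuals
    n_permutations: int = 10000
    n_replicates: int = 1000                 # sensitivity
    n_sim: int = 5000                        # parametric bootstrap
    n_boot_ci: int = 0                       # bootstrap parameter CIs (0 = skip)
    seed: int = 0
    root_policy: str = "root-regime"
    intraspecific_sd: float | None = None    # fallback when no multi-specimen data
    run_sensitivity: bool = True
    run_pmc: bool = True
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        clades = [CladeSpec(**c) for c in raw.pop("clades")]
        return cls(clades=clades, **raw)


def run_study(config: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns a summary dict (also written as ``run_log.json``) with the
    per-trait scores, sensitivity frequencies, advance decisions and
    pairwise classifications.
    """
    out = pathlib.Path(config.outdir)
    (out / "fits").mkdir(parents=True, exist_ok=True)
    if config.make_plots:
        (out / "figures").mkdir(exist_ok=True)

    tree_full = TimeTree.from_file(config.tree_path)
    traits_df = read_trait_table(config.traits_path)
    if traits_df.empty:
        raise ValueError("trait table is empty")
    mass = read_mass_table(config.mass_path, ln_transform=False) \
        if _mass_is_ln(config.mass_path) else read_mass_table(config.mass_path)
    trait_names = config.traits or sorted(traits_df["trait"].unique())
    if not trait_names:
        raise ValueError("no traits to analyze")

    ss = np.random.SeedSequence(config.seed)
    seeds = {name: s for name, s in zip(
        ("allometry", "sensitivity", "pmc", "boot"), ss.spawn(4))}

    # 1) allometric residuals on the full species set
    fits_allo = [fit_allometry(traits_df, mass, t,
                               n_permutations=config.n_permutations,
                               seed=_seed32(seeds["allometry"], i))
                 for i, t in enumerate(trait_names)]

    # 2) prune to the analysis species and paint regimes
    with_resid = set.intersection(*(set(f.residuals) for f in fits_allo))
    keep = set(config.keep_species) if config.keep_species else \
        set(tree_full.tip_names) & with_resid
    tree = tree_full.prune(keep) if keep != set(tree_full.tip_names) else tree_full
    resid = residual_matrix(fits_allo, keep, tip_order=tree.tip_names)
    painting = paint_regimes(
        tree, [(c.tips, c.regime, c.include_stem) for c in config.clades],
        background=config.background)
    derived = [c.regime for c in config.clades]
    specs = six_model_specs(config.background, derived[0], derived[1],
                            root_policy=config.root_policy)
    model_set = ModelSet(tree, painting, specs=specs)

    score_rows, pmc_rows, results = [], [], {}
    alternatives = [m for m in specs if m != "OU2_foss"]
    for i, tname in enumerate(trait_names):
        try:
            x = resid[tname].to_numpy()
            table = model_set.score(x, trait=tname)
            entry: dict = {"scores": table.to_row(),
                           "ranks": table.order,
                           "fit_warnings": table.warnings}
            for m, f in table.fits.items():
                with open(out / "fits" / f"{_safe(tname)}__{_safe(m)}.json", "w") as fh:
                    fh.write(f.to_json())
            row = table.to_row()

            if config.run_sensitivity:
                sd = _intraspecific_sd(traits_df, tname, config)
                sens = sampling_sensitivity(
                    tree, painting, x, sd, trait=tname,
                    n_replicates=config.n_replicates,
                    seed=_seed32(seeds["sensitivity"], i), model_set=model_set)
                entry["sensitivity"] = {"frequencies": sens.frequencies,
                                        "modal": sens.modal,
                                        "passed": sens.passed,
                                        "noise_sd": float(np.mean(sens.noise_sd))}
                for m, fr in sens.frequencies.items():
                    row[f"freq_{m}"] = fr
                advance, reason = advance_rule(table, sens)
            else:
                advance, reason = advance_rule(
                    table, _trivial_pass(table, tname))
            entry["advance"] = advance
            entry["advance_reason"] = reason
            score_rows.append(row)

            if advance and config.run_pmc:
                pmc_row = {"trait": tname}
                entry["pmc"] = {}
                for j, alt in enumerate(alternatives):
                    res = pmc_compare(
                        tree, painting, x, specs["OU2_foss"], specs[alt],
                        n_sim=config.n_sim,
                        seed=_seed32(seeds["pmc"], i * len(alternatives) + j))
                    pmc_row[alt] = res.symbol
                    entry["pmc"][alt] = {k: v for k, v in res.to_dict().items()
                                         if not k.startswith("deltas")}
                    with open(out / "fits" /
                              f"{_safe(tname)}__pmc_{_safe(alt)}.json", "w") as fh:
                        json.dump(res.to_dict(), fh)
                    if config.make_plots:
                        plot_pmc(res, out / "figures" /
                                 f"{_safe(tname)}__pmc_{_safe(alt)}.png")
                pmc_rows.append(pmc_row)

            if config.n_boot_ci >= 100:
                best_fit = table.fits[table.best]
                refits = bootstrap_refits(tree, painting, best_fit,
                                          config.n_boot_ci,
                                          seed=_seed32(seeds["boot"], i))
                cis = parameter_cis(refits, best_fit)
                entry["param_cis"] = [asdict(c) for c in cis]
            results[tname] = entry
        except Exception as exc:  # isolate per-trait failures
            results[tname] = {"error": f"{type(exc).__name__}: {exc}",
                              "traceback": traceback.format_exc()}

    scores = pd.DataFrame(score_rows)
    scores.to_csv(out / "scores.csv", index=False)
    if pmc_rows:
        pd.DataFrame(pmc_rows).to_csv(out / "pmc_summary.csv", index=False)

    log = {
        "version": __version__,
        "seed": config.seed,
        "n_species": tree.n_tips,
        "n_traits": len(trait_names),
        "tree_depth": tree.depth,
        "config": {**{k: v for k, v in asdict(config).items() if k != "clades"},
                   "clades": [asdict(c) for c in config.clades]},
        "results": results,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    return log


# -- helpers ----------------------------------------------------------------

def _safe(name: str) -> str:
    return "".join(c if c.isalnum() or c in "-_" else "_" for c in name)


def _seed32(ss: np.random.SeedSequence, i: int) -> int:
    return int(ss.generate_state(i + 1, np.uint32)[i]) & 0x7FFFFFFF


def _mass_is_ln(path) -> bool:
    head = pd.read_csv(path, sep=None, engine="python", nrows=1)
    return "ln_mass" in head.columns


def _intraspecific_sd(traits_df, tname, config):
    try:
        return pooled_specimen_sd(traits_df, tname)
    except ValueError:
        if config.intraspecific_sd is None:
            raise
        return config.intraspecific_sd


def _trivial_pass(table, tname):
    from .selection import SensitivityResult
    return SensitivityResult(
        trait=tname, n_replicates=0,
        frequencies={table.best: 100.0}, modal=table.best,
        empirical_best=table.best, seed=0, noise_sd=0.0)
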