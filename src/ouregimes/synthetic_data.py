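"""Synthetic studies emulating the sciuromorph two-clade design.

A study consists of an ultrametric 125-tip tree (by default) holding a
paraphyletic arboreal background (76 tips) and two monophyletic derived
fossorial clades grafted into it (43-tip "Ma" with a ~24.5 My stem and
6-tip "Xe" with a ~31.3 My stem, echoing the reconstruction ages of the
real groups), ln-body-mass evolved as BM on the tree plus constant group
offsets (the groups differ in mass, as marmotines do), and specimen-level
ln-trait measurements built as allometric line + OU/BM residual + normal
specimen noise.  Generating parameters are recorded so every pipeline
stage can be tested against a known truth.

Trees are pure-birth within groups with deterministic grafting: the
simplest generator whose group sizes, depth and stem ages exactly match
the configured study design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .oumodels import ModelParams, ModelSpec, six_model_specs, FitEngine, half_life
from .phylo import Painting, TimeTree, paint_regimes
from .traitsim import simulate_traits


# ---------------------------------------------------------------------------
# pure-birth tree machinery
# ---------------------------------------------------------------------------

def _sub_seed(ss: np.random.SeedSequence) -> int:
    """Deterministic 31-bit child seed distinct across spawned substreams."""
    return int(ss.generate_state(1, np.uint32)[0]) & 0x7FFFFFFF


class _Node:
    __slots__ = ("children", "blen", "name", "birth")

    def __init__(self, birth: float, name: str | None = None):
        self.children: list[_Node] = []
        self.blen = 0.0
        self.name = name
        self.birth = birth


def _yule_crown(n: int, rng: np.random.Generator, prefix: str) -> tuple[_Node, float]:
    """Pure-birth crown tree with n tips; returns (root, crown depth)."""
    if n < 2:
        raise ValueError("need >= 2 tips for a crown group")
    root = _Node(0.0)
    a, b = _Node(0.0), _Node(0.0)
    root.children = [a, b]
    active = [a, b]
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / len(active))
        i = rng.integers(len(active))
        node = active[i]
        node.blen = t - node.birth
        c1, c2 = _Node(t), _Node(t)
        node.children = [c1, c2]
        active[i] = c1
        active.append(c2)
    t_end = t + rng.exponential(1.0 / n)
    for i, node in enumerate(active):
        node.blen = t_end - node.birth
    # name tips left-to-right for determinism
    counter = [0]

    def name_tips(v: _Node):
        if not v.children:
            counter[0] += 1
            v.name = f"{prefix}{counter[0]:03d}"
        for c in v.children:
            name_tips(c)

    name_tips(root)
    return root, t_end


def _rescale(root: _Node, factor: float) -> None:
    stack = [root]
    while stack:
        v = stack.pop()
        v.blen *= factor
        v.birth *= factor
        stack.extend(v.children)


def _heights(root: _Node) -> dict[_Node, tuple[float, float]]:
    """Map node -> (top height, bottom height) of its branch."""
    out = {}
    stack = [(root, 0.0)]
    while stack:
        v, h0 = stack.pop()
        out[v] = (h0, h0 + v.blen)
        for c in v.children:
            stack.append((c, h0 + v.blen))
    return out


def _edges_spanning(root: _Node, h: float) -> list[_Node]:
    hs = _heights(root)
    return [v for v, (a, b) in hs.items() if v is not root and a < h < b]


def _graft(bg_root: _Node, edge: _Node, h_attach: float, sub_root: _Node,
           sub_crown_start: float) -> None:
    """Bisect ``edge`` at height ``h_attach`` and hang ``sub_root`` there
    with a stem reaching down to ``sub_crown_start``."""
    hs = _heights(bg_root)
    top, _bottom = hs[edge]
    parent = _find_parent(bg_root, edge)
    join = _Node(h_attach)
    join.blen = 0.0
    # rewire: parent -> join -> (edge remainder, grafted subtree)
    parent.children[parent.children.index(edge)] = join
    join.blen = h_attach - top
    edge.blen = hs[edge][1] - h_attach
    sub_root.blen = sub_crown_start - h_attach
    join.children = [edge, sub_root]


def _find_parent(root: _Node, target: _Node) -> _Node:
    stack = [root]
    while stack:
        v = stack.pop()
        if target in v.children:
            return v
        stack.extend(v.children)
    raise RuntimeError("node not found")


def _to_newick(root: _Node) -> str:
    def rec(v: _Node) -> str:
        if not v.children:
            return f"{v.name}:{v.blen:.12f}"
        inner = ",".join(rec(c) for c in v.children)
        return f"({inner}):{v.blen:.12f}"

    inner = ",".join(rec(c) for c in root.children)
    return f"({inner});"


def generate_tree(
    n_bg: int = 76,
    n_clade_a: int = 43,
    n_clade_b: int = 6,
    depth: float = 70.0,
    seed: int = 0,
    stem_age_a: float = 24.5,
    stem_age_b: float = 31.3,
    crown_fraction: float = 0.7,
    prefixes: tuple[str, str, str] = ("Arb", "Ma", "Xe"),
) -> tuple[TimeTree, dict[str, str]]:
    """Backbone + two grafted monophyletic clades; exact depth and stem ages.

    Returns the tree and a tip -> group map (groups named by prefix).
    """
    if min(n_bg, n_clade_a) < 2 or n_clade_b < 2 or depth <= 0:
        raise ValueError("need >= 2 tips per group and depth > 0")
    if not (0 < stem_age_a < depth and 0 < stem_age_b < depth):
        raise ValueError("stem ages must lie inside (0, depth)")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    bg, bg_depth = _yule_crown(n_bg, rng, prefixes[0])
    _rescale(bg, depth / bg_depth)
    grafts = []
    for n_c, stem, prefix in ((n_clade_a, stem_age_a, prefixes[1]),
                              (n_clade_b, stem_age_b, prefixes[2])):
        sub, sub_depth = _yule_crown(n_c, rng, prefix)
        crown = crown_fraction * stem
        _rescale(sub, crown / sub_depth)
        h_attach = depth - stem
        candidates = _edges_spanning(bg, h_attach)
        if not candidates:
            raise ValueError(f"no background edge spans height {h_attach}")
        edge = candidates[rng.integers(len(candidates))]
        grafts.append((edge, h_attach, sub, depth - crown))
    # both edges chosen on the pristine background; ensure they are distinct
    if grafts[0][0] is grafts[1][0] and abs(grafts[0][1] - grafts[1][1]) < 1e-9:
        raise ValueError("derived clades collided on one edge; change the seed")
    # graft deepest first so the shallower graft may legally land on a
    # piece of the same original edge
    grafts.sort(key=lambda g: g[1])
    for edge, h_attach, sub, crown_start in grafts:
        _graft(bg, edge, h_attach, sub, crown_start)
    tree = TimeTree.from_newick(_to_newick(bg))
    groups = {}
    for name in tree.tip_names:
        for prefix, label in zip(prefixes, ("bg", "cladeA", "cladeB")):
            if name.startswith(prefix):
                groups[name] = prefix
    return tree, groups


# ---------------------------------------------------------------------------
# trait and study generation
# ---------------------------------------------------------------------------

@dataclass
class TraitConfig:
    """Generating recipe for one trait (all on the natural-log scale)."""

    name: str
    model: str = "OU2_foss"   # one of the six model names, or "BM1"/"OU1"
    t_half: float = 2.0       # My; ignored for BM1
    sigma2: float = 0.05      # trait^2 / My
    optima_separation: float | None = None  # in stationary SDs; derived optima
    theta_bg: float = 0.0
    slope: float = 0.33       # allometric slope on ln-mass
    intercept: float = 1.0
    specimen_sd: float = 0.0
    n_specimens: int = 1

    @property
    def alpha(self) -> float:
        return math.log(2.0) / self.t_half

    @property
    def stationary_sd(self) -> float:
        return math.sqrt(self.sigma2 / (2.0 * self.alpha))

    def params(self, specs: dict[str, ModelSpec]) -> ModelParams:
        spec = specs[self.model]
        sep = self.optima_separation if self.optima_separation is not None else 4.0
        delta = sep * self.stationary_sd
        if spec.family == "BM":
            return ModelParams(spec=spec, sigma2=self.sigma2, alpha=None,
                               theta={}, x0=self.theta_bg)
        theta = {}
        derived = [o for o in spec.optima if o != spec.optima[0] and o != "all"]
        for o in spec.optima:
            if o in ("all",) or o == spec.optima[0]:
                theta[o] = self.theta_bg
            elif o == "foss":
                theta[o] = self.theta_bg - delta
            else:
                # OU2 single-departer: below background; OU3: the two
                # derived optima depart in opposite directions, so all
                # three optima are mutually separated by >= delta
                j = derived.index(o)
                theta[o] = self.theta_bg + delta * (-1.0 if j % 2 == 0 else 1.0)
        return ModelParams(spec=spec, sigma2=self.sigma2, alpha=self.alpha,
                           theta=theta, x0=self.theta_bg)


@dataclass
class SyntheticStudy:
    tree: TimeTree
    groups: dict[str, str]
    painting: Painting
    ln_mass: dict[str, float]
    trait_table: pd.DataFrame
    configs: dict[str, TraitConfig]
    generating: dict[str, ModelParams]
    specs: dict[str, ModelSpec]
    seed: int

    @property
    def regimes(self) -> tuple[str, str, str]:
        return ("arb", "Ma", "Xe")

    def species_of(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    def write(self, outdir) -> None:
        import pathlib
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.tree.write(out / "tree.nwk")
        self.trait_table.to_csv(out / "traits.csv", index=False)
        pd.DataFrame({"species": list(self.ln_mass), "ln_mass": list(self.ln_mass.values())}
                     ).to_csv(out / "mass.csv", index=False)
        self.painting.to_table(self.tree).to_csv(out / "painting.csv", index=False)
        pd.DataFrame({"species": list(self.groups), "group": list(self.groups.values())}
                     ).to_csv(out / "groups.csv", index=False)


def default_trait_configs() -> dict[str, TraitConfig]:
    """One trait per generating scenario, at the strong-signal settings the
    simulation harnesses use (optima 4 stationary SDs apart, t1/2 = 2 My)."""
    return {
        "trait_OU2_foss": TraitConfig("trait_OU2_foss", model="OU2_foss"),
        "trait_OU1": TraitConfig("trait_OU1", model="OU1"),
        "trait_BM1": TraitConfig("trait_BM1", model="BM1", sigma2=0.002),
    }


def generate_study(
    n_bg: int = 76,
    n_clade_a: int = 43,
    n_clade_b: int = 6,
    depth: float = 70.0,
    seed: int = 0,
    trait_configs: dict[str, TraitConfig] | None = None,
    mass_sigma2: float = 0.01,
    mass_base: float = 6.0,
    mass_offsets: tuple[float, float, float] = (0.0, 1.0, 0.3),
    root_policy: str = "root-regime",
) -> SyntheticStudy:
    """Full synthetic study: tree, painting, masses, specimen trait table.

    Bit-for-bit reproducible from ``seed``: tree, masses, every trait and
    every specimen are drawn from substreams spawned deterministically
    from it.
    """
    ss = np.random.SeedSequence(seed)
    s_tree, s_mass, s_traits = ss.spawn(3)
    tree, groups = generate_tree(n_bg, n_clade_a, n_clade_b, depth,
                                 seed=_sub_seed(s_tree),
                                 prefixes=("Arb", "Ma", "Xe"))
    clade_a = [s for s, g in groups.items() if g == "Ma"]
    clade_b = [s for s, g in groups.items() if g == "Xe"]
    painting = paint_regimes(
        tree, [(clade_a, "Ma", True), (clade_b, "Xe", True)], background="arb")
    specs = six_model_specs("arb", "Ma", "Xe", root_policy=root_policy)

    # ln-body-mass: BM along the tree plus constant group offsets
    bm_params = ModelParams(spec=specs["BM1"], sigma2=mass_sigma2, x0=mass_base)
    mass_draw = simulate_traits(tree, None, bm_params, 1,
                                seed=_sub_seed(s_mass)).values[0]
    off = dict(zip(("arb", "Ma", "Xe"), mass_offsets))
    group_of = {s: {"Arb": "arb", "Ma": "Ma", "Xe": "Xe"}[groups[s]] for s in groups}
    ln_mass = {s: float(mass_draw[i] + off[group_of[s]])
               for i, s in enumerate(tree.tip_names)}

    configs = trait_configs if trait_configs is not None else default_trait_configs()
    rows = []
    generating: dict[str, ModelParams] = {}
    trait_seeds = s_traits.spawn(len(configs))
    for (tname, cfg), tseed in zip(configs.items(), trait_seeds):
        params = cfg.params(specs)
        generating[tname] = params
        sub_resid, sub_spec = tseed.spawn(2)
        resid = simulate_traits(tree, painting, params, 1,
                                seed=_sub_seed(sub_resid)).values[0]
        rng = np.random.default_rng(sub_spec)
        for i, s in enumerate(tree.tip_names):
            mean = cfg.intercept + cfg.slope * ln_mass[s] + resid[i]
            for k in range(cfg.n_specimens):
                val = mean if cfg.specimen_sd == 0 else rng.normal(mean, cfg.specimen_sd)
                rows.append({"species": s, "specimen": f"sp{k + 1}",
                             "trait": tname, "value": float(val)})
    table = pd.DataFrame(rows, columns=["species", "specimen", "trait", "value"])
    return SyntheticStudy(tree=tree, groups=group_of, painting=painting,
                          ln_mass=ln_mass, trait_table=table, configs=dict(configs),
                          generating=generating, specs=specs, seed=seed)


def recover_parameters(study: SyntheticStudy, trait: str) -> dict:
    """Refit the generating model to a trait's model residual and report
    bias and relative error against the known truth."""
    params = study.generating[trait]
    cfg = study.configs[trait]
    tree, painting = study.tree, study.painting
    # reconstruct the model residual from the species means
    means = study.trait_table[study.trait_table["trait"] == trait].groupby(
        "species")["value"].mean()
    x = np.array([means[s] - cfg.intercept - cfg.slope * study.ln_mass[s]
                  for s in tree.tip_names])
    engine = FitEngine(tree, painting, params.spec)
    fit = engine.fit(x)
    report = {"trait": trait, "model": params.spec.name, "lnL": fit.lnl,
              "sic": fit.sic}
    report["sigma2_true"] = params.sigma2
    report["sigma2_hat"] = fit.sigma2
    report["sigma2_rel_error"] = fit.sigma2 / params.sigma2 - 1.0
    if params.alpha is not None:
        report["alpha_true"] = params.alpha
        report["alpha_hat"] = fit.alpha
        report["t_half_hat"] = half_life(fit.alpha)
        for o in params.spec.optima:
            report[f"theta_{o}_true"] = params.theta[o]
            report[f"theta_{o}_hat"] = fit.theta[o]
            report[f"theta_{o}_bias"] = fit.theta[o] - params.theta[o]
    return report
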