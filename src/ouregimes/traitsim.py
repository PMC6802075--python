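"""Exact simulation of tip traits under fitted or specified BM/OU models.

Two equivalent-in-distribution routes are provided:

* ``"mvn"`` (default) — one Cholesky factor of the model covariance
  applied to standard-normal draws; exact and vectorized over datasets.
* ``"recursive"`` — preorder simulation along branches, segment by
  segment, using the exact OU transition (mean decay toward the segment
  optimum, innovation variance ``sigma2/(2 alpha) (1 - e^{-2 alpha dt})``).
  Kept as the independent oracle for the matrix route.

Reproducibility: one root seed per batch; each dataset uses an
independent substream spawned from it, so batches are identical whether
datasets are drawn serially or in parallel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .oumodels import FitEngine, ModelFit, ModelParams
from .phylo import Painting, TimeTree, lineage_histories


@dataclass
class SimBatch:
    params: ModelParams
    seed: int
    n_datasets: int
    values: np.ndarray  # (n_datasets, n_tips)
    tip_names: list[str]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.tip_names)
        df.insert(0, "dataset_id", np.arange(self.n_datasets))
        return df

    @staticmethod
    def read_frame(df: pd.DataFrame) -> np.ndarray:
        return df.drop(columns=["dataset_id"]).to_numpy(dtype=float)


def _as_params(fit_or_params) -> ModelParams:
    if isinstance(fit_or_params, ModelFit):
        return fit_or_params.params
    if isinstance(fit_or_params, ModelParams):
        return fit_or_params
    raise TypeError("expected a ModelFit or ModelParams")


def simulate_traits(
    tree: TimeTree,
    painting: Painting | None,
    fit_or_params,
    n_datasets: int,
    seed: int,
    method: str = "mvn",
) -> SimBatch:
    """Draw ``n_datasets`` tip trait vectors from the model's distribution."""
    params = _as_params(fit_or_params)
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    if params.sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if params.spec.family == "OU" and (params.alpha is None or params.alpha <= 0):
        raise ValueError("OU simulation needs alpha > 0")
    if method == "mvn":
        values = _simulate_mvn(tree, painting, params, n_datasets, seed)
    elif method == "recursive":
        values = _simulate_recursive(tree, painting, params, n_datasets, seed)
    else:
        raise ValueError(f"unknown method {method!r}")
    return SimBatch(params=params, seed=seed, n_datasets=n_datasets,
                    values=values, tip_names=list(tree.tip_names))


def _simulate_mvn(tree, painting, params, n_datasets, seed) -> np.ndarray:
    engine = FitEngine(tree, painting, params.spec)
    E, V = engine.moments(params)
    n = tree.n_tips
    # tiny jitter-free handling of the degenerate sigma2 -> 0 limit
    if params.sigma2 == 0:
        return np.tile(E, (n_datasets, 1))
    L = np.linalg.cholesky(V)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_datasets)
    out = np.empty((n_datasets, n))
    for d in range(n_datasets):
        z = np.random.default_rng(children[d]).standard_normal(n)
        out[d] = E + L @ z
    return out


def _simulate_recursive(tree, painting, params, n_datasets, seed) -> np.ndarray:
    spec = params.spec
    is_bm = spec.family == "BM"
    if not is_bm:
        if painting is None:
            from .phylo import uniform_painting
            painting = uniform_painting(tree, next(iter(spec.regime_map)))
        theta_by_regime = params.theta_by_regime()
        segs_by_branch = painting.segments
        alpha = params.alpha
    sigma2 = params.sigma2
    n = tree.n_tips
    tip_pos = {int(t): i for i, t in enumerate(tree.tip_ids)}
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_datasets)
    out = np.empty((n_datasets, n))
    order = list(range(tree.n_nodes))  # preorder
    for d in range(n_datasets):
        rng = np.random.default_rng(children[d])
        state = np.empty(tree.n_nodes)
        for v in order:
            x = params.x0 if tree.parent[v] == -1 else state[tree.parent[v]]
            if is_bm:
                dt = tree.blen[v]
                if dt > 0:
                    x += rng.normal(0.0, np.sqrt(sigma2 * dt))
            else:
                for t0, t1, r in segs_by_branch.get(v, []):
                    dt = t1 - t0
                    if dt <= 0:
                        continue
                    th = theta_by_regime[r]
                    decay = np.exp(-alpha * dt)
                    var = sigma2 / (2.0 * alpha) * -np.expm1(-2.0 * alpha * dt)
                    x = th + (x - th) * decay + rng.normal(0.0, np.sqrt(var))
            state[v] = x
            if v in tip_pos:
                out[d, tip_pos[v]] = x
    return out
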