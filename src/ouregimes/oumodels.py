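"""Likelihood core for single-rate BM and multi-optimum OU trait models.

Model
-----
A continuous trait x evolves along a painted time tree.  Under the
mean-reverting (Hansen) Ornstein-Uhlenbeck process with pull ``alpha``
toward the optimum ``theta`` of the prevailing selective regime and
diffusion rate ``sigma2``, the tip values are jointly Gaussian with

* expectation per tip i (root state X0, forward time 0..T_i)::

    E_i = X0 e^{-alpha T_i}
          + sum_seg theta(seg) (e^{-alpha (T_i - t_end)} - e^{-alpha (T_i - t_start)})

* covariance in the fixed-root (non-stationary) formulation::

    V_ij = sigma2/(2 alpha) * e^{-alpha (T_i + T_j - 2 t_a)} * (1 - e^{-2 alpha t_a})

  where ``t_a`` is the height of the most recent common ancestor of tips
  i and j above the origin.  Brownian motion is the ``alpha -> 0`` limit:
  ``E_i = X0`` and ``V_ij = sigma2 * t_a``.

Fitting
-------
Because E is linear in the optima (and X0, if free) and V factors as
``sigma2 * V0(alpha)``, both the optima and ``sigma2`` can be profiled
out analytically — generalized least squares gives the optima at any
``alpha``, and the profiled ML diffusion rate is the whitened mean
squared residual.  Maximization therefore reduces to a one-dimensional
search over ``ln alpha``, run from a deterministic multi-start grid
spanning phylogenetic half-lives from 0.01 T to 10 T, followed by
bounded local refinement.  This reaches the same maximum as a joint
``(ln alpha, ln sigma2)`` search, deterministically and at a fraction of
the cost.

The Schwarz information criterion is ``SIC = -2 lnL + p ln(n)`` with p
counting all free parameters; under the default root policy (the root
state equals the optimum of the root regime) an OU model with k optima
has p = 2 + k, and BM has p = 2 (X0, sigma2).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg as sla
from scipy.optimize import minimize_scalar

from .phylo import Painting, TimeTree, lineage_histories, uniform_painting

MODEL_ORDER = ("BM1", "OU1", "OU2_foss", "OU2_arb&Ma", "OU2_arb&Xe", "OU3")

_LN2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# specs and parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """One hypothesis model: family, regime-to-optimum map, root policy."""

    name: str
    family: str  # "BM" | "OU"
    optima: tuple[str, ...] = ()
    regime_map: Mapping[str, str] = field(default_factory=dict)
    root_policy: str = "root-regime"  # or "free-x0"

    def __post_init__(self):
        if self.family not in ("BM", "OU"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "OU":
            if not self.optima:
                raise ValueError("OU spec needs at least one optimum")
            missing = set(self.regime_map.values()) - set(self.optima)
            if missing:
                raise ValueError(f"regime_map targets unknown optima {missing}")
        if self.root_policy not in ("root-regime", "free-x0"):
            raise ValueError(f"unknown root policy {self.root_policy!r}")

    @property
    def k(self) -> int:
        return len(self.optima)

    @property
    def p(self) -> int:
        """Number of free parameters entering the SIC penalty."""
        if self.family == "BM":
            return 2
        return 2 + self.k + (1 if self.root_policy == "free-x0" else 0)


@dataclass
class ModelParams:
    """Concrete parameter values for simulation or likelihood evaluation."""

    spec: ModelSpec
    sigma2: float
    alpha: float | None = None          # None for BM
    theta: dict[str, float] = field(default_factory=dict)  # optimum label -> value
    x0: float = 0.0

    def theta_by_regime(self) -> dict[str, float]:
        return {r: self.theta[o] for r, o in self.spec.regime_map.items()}


@dataclass
class ModelFit:
    """Maximum-likelihood fit of one model to one trait vector."""

    spec: ModelSpec
    params: ModelParams
    lnl: float
    sic: float
    n: int
    converged: bool = True
    n_starts: int = 0
    n_evals: int = 0
    at_bound: bool = False
    message: str = ""

    @property
    def alpha(self) -> float | None:
        return self.params.alpha

    @property
    def sigma2(self) -> float:
        return self.params.sigma2

    @property
    def theta(self) -> dict[str, float]:
        return self.params.theta

    @property
    def x0(self) -> float:
        return self.params.x0

    @property
    def t_half(self) -> float | None:
        """Phylogenetic half-life ln(2)/alpha (My); None for BM."""
        if self.params.alpha is None:
            return None
        return half_life(self.params.alpha)

    def flat_params(self) -> dict[str, float]:
        out: dict[str, float] = {}
        if self.params.alpha is not None:
            out["alpha"] = self.params.alpha
        out["sigma2"] = self.params.sigma2
        for o in self.spec.optima:
            out[f"theta_{o}"] = self.params.theta[o]
        if self.spec.family == "BM" or self.spec.root_policy == "free-x0":
            out["x0"] = self.params.x0
        return out

    def to_dict(self) -> dict:
        d = {
            "model": self.spec.name,
            "family": self.spec.family,
            "p": self.spec.p,
            "n": self.n,
            "lnL": self.lnl,
            "SIC": self.sic,
            "t_half": self.t_half,
            "converged": self.converged,
            "n_starts": self.n_starts,
            "n_evals": self.n_evals,
            "at_bound": self.at_bound,
        }
        d.update(self.flat_params())
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


# ---------------------------------------------------------------------------
# closed-form building blocks
# ---------------------------------------------------------------------------

def ou_expectation(histories, alpha: float, theta: Mapping[str, float], x0: float) -> np.ndarray:
    """Tip expectations under OU with piecewise-constant optima.

    ``theta`` maps regime id -> optimum value.  Each lineage's segments
    contribute ``theta (e^{-a(T-t1)} - e^{-a(T-t0)})`` and the root state
    decays as ``x0 e^{-a T}``.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    E = np.empty(len(histories))
    for i, h in enumerate(histories):
        T = h.depth
        acc = x0 * math.exp(-alpha * T)
        for t0, t1, r in h.segments:
            if r not in theta:
                raise KeyError(f"regime {r!r} has no optimum")
            acc += theta[r] * (math.exp(-alpha * (T - t1)) - math.exp(-alpha * (T - t0)))
        E[i] = acc
    return E


def ou_covariance(tree: TimeTree, alpha: float, sigma2: float) -> np.ndarray:
    """Fixed-root OU tip covariance matrix (non-stationary formulation)."""
    if not (np.isfinite(alpha) and np.isfinite(sigma2)):
        raise ValueError("alpha and sigma2 must be finite")
    if alpha <= 0 or sigma2 <= 0:
        raise ValueError("alpha and sigma2 must be > 0")
    ta = tree.mrca_heights()
    T = tree.tip_heights
    D = T[:, None] + T[None, :] - 2.0 * ta
    return (sigma2 / (2.0 * alpha)) * np.exp(-alpha * D) * (-np.expm1(-2.0 * alpha * ta))


def bm_covariance(tree: TimeTree, sigma2: float) -> np.ndarray:
    """BM tip covariance: sigma2 times shared path length to the origin."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    return sigma2 * tree.mrca_heights()


def loglik(x: np.ndarray, E: np.ndarray, V: np.ndarray) -> float:
    """Gaussian log-likelihood via Cholesky; fails loudly if V is not PD."""
    x = np.asarray(x, dtype=float)
    E = np.asarray(E, dtype=float)
    n = x.shape[0]
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        smallest = float(np.linalg.eigvalsh(V)[0])
        raise ValueError(
            f"covariance is not positive definite (smallest eigenvalue {smallest:.3e})"
        ) from None
    w = sla.solve_triangular(L, x - E, lower=True, check_finite=False)
    return float(-0.5 * n * _LN2PI - np.log(np.diag(L)).sum() - 0.5 * w @ w)


def sic(lnl: float, p: int, n: int) -> float:
    """Schwarz information criterion, -2 lnL + p ln n (lower is better)."""
    if p < 1:
        raise ValueError("p must be >= 1")
    if n < 2:
        raise ValueError("n must be >= 2")
    return -2.0 * lnl + p * math.log(n)


def half_life(alpha: float) -> float:
    """Phylogenetic half-life t1/2 = ln(2)/alpha, in My."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    return math.log(2.0) / alpha


# ---------------------------------------------------------------------------
# the six-model hypothesis set
# ---------------------------------------------------------------------------

def six_model_specs(
    background: str = "arb",
    clade_a: str = "Ma",
    clade_b: str = "Xe",
    root_policy: str = "root-regime",
) -> dict[str, ModelSpec]:
    """The standard six-model comparison for two independently derived clades.

    * BM1 — random walk, no optimum.
    * OU1 — every regime shares one optimum (ancestral constraint).
    * OU2_foss — both derived clades share a novel optimum departing from
      the background: the trait-optimum homoplasy (convergence) model.
    * OU2_<bg>&<A> — clade A retains the background optimum, only clade B
      departs.
    * OU2_<bg>&<B> — the mirror image.
    * OU3 — both clades depart, toward distinct optima.
    """
    bg, a, b = background, clade_a, clade_b
    return {
        "BM1": ModelSpec("BM1", "BM"),
        "OU1": ModelSpec(
            "OU1", "OU", optima=("all",),
            regime_map={bg: "all", a: "all", b: "all"}, root_policy=root_policy),
        "OU2_foss": ModelSpec(
            "OU2_foss", "OU", optima=(bg, "foss"),
            regime_map={bg: bg, a: "foss", b: "foss"}, root_policy=root_policy),
        f"OU2_{bg}&{a}": ModelSpec(
            f"OU2_{bg}&{a}", "OU", optima=(bg, b),
            regime_map={bg: bg, a: bg, b: b}, root_policy=root_policy),
        f"OU2_{bg}&{b}": ModelSpec(
            f"OU2_{bg}&{b}", "OU", optima=(bg, a),
            regime_map={bg: bg, a: a, b: bg}, root_policy=root_policy),
        "OU3": ModelSpec(
            "OU3", "OU", optima=(bg, a, b),
            regime_map={bg: bg, a: a, b: b}, root_policy=root_policy),
    }


# ---------------------------------------------------------------------------
# fitting engine
# ---------------------------------------------------------------------------

@dataclass
class FitOptions:
    grid_size: int = 17
    thalf_span: tuple[float, float] = (0.01, 10.0)  # as multiples of tree depth
    alpha_max_factor: float = 1e4                   # alpha upper bound = factor / T
    refine_xatol: float = 1e-4                      # in ln(alpha)
    extra_alpha_starts: tuple[float, ...] = ()
    batch_grid_size: int = 25                       # alpha grid for batch fits
    batch_polish_iters: int = 2                     # exact re-evals per dataset


@dataclass
class BatchFit:
    """Vectorized fit of one model to many datasets (rows of X)."""

    spec: ModelSpec
    lnl: np.ndarray       # (m,)
    sic: np.ndarray       # (m,)
    alpha: np.ndarray | None   # (m,) or None for BM
    sigma2: np.ndarray    # (m,)
    beta: np.ndarray      # (m, k) GLS coefficients (optima / X0)
    n: int
    root_col: int = 0

    def model_fit(self, d: int) -> ModelFit:
        """Materialize dataset ``d`` as a ModelFit record."""
        spec = self.spec
        if spec.family == "BM":
            params = ModelParams(spec=spec, sigma2=float(self.sigma2[d]),
                                 alpha=None, theta={}, x0=float(self.beta[d, 0]))
        else:
            theta = {o: float(self.beta[d, j]) for j, o in enumerate(spec.optima)}
            x0 = float(self.beta[d, spec.k]) if spec.root_policy == "free-x0" \
                else float(self.beta[d, self.root_col])
            params = ModelParams(spec=spec, sigma2=float(self.sigma2[d]),
                                 alpha=float(self.alpha[d]), theta=theta, x0=x0)
        return ModelFit(spec=spec, params=params, lnl=float(self.lnl[d]),
                        sic=float(self.sic[d]), n=self.n, converged=True)


class FitEngine:
    """Precomputed structures for repeatedly fitting one model spec on one
    (tree, painting) pair — the workhorse behind batch refitting."""

    def __init__(self, tree: TimeTree, painting: Painting | None, spec: ModelSpec):
        self.tree = tree
        self.spec = spec
        self.n = tree.n_tips
        self.T = tree.tip_heights.copy()
        self.ta = tree.mrca_heights().copy()
        self.D = self.T[:, None] + self.T[None, :] - 2.0 * self.ta
        self.depth = tree.depth
        if spec.family == "OU":
            if painting is None:
                if spec.k != 1:
                    raise ValueError("multi-optimum spec needs a painting")
                painting = uniform_painting(tree, next(iter(spec.regime_map)))
            hists = lineage_histories(tree, painting)
            missing = {r for h in hists for _, _, r in h.segments} - set(spec.regime_map)
            if missing:
                raise ValueError(f"painting regimes without an optimum: {sorted(missing)}")
            tip_idx, opt_idx, t0s, t1s = [], [], [], []
            col = {o: j for j, o in enumerate(spec.optima)}
            for i, h in enumerate(hists):
                for t0, t1, r in h.segments:
                    tip_idx.append(i)
                    opt_idx.append(col[spec.regime_map[r]])
                    t0s.append(t0)
                    t1s.append(t1)
            self._seg_tip = np.array(tip_idx, dtype=int)
            self._seg_opt = np.array(opt_idx, dtype=int)
            self._seg_t0 = np.array(t0s)
            self._seg_t1 = np.array(t1s)
            # the painting's designated background regime is the root
            # regime (a derived clade's stem may start at the root
            # itself, so the first lineage segment is not a safe guide)
            root_regime = painting.background
            if root_regime not in spec.regime_map:
                root_regime = hists[0].segments[0][2]
            self._root_col = col[spec.regime_map[root_regime]]
        else:
            # BM: V0 is alpha-free; factor it once
            self._bm_chol = np.linalg.cholesky(self.ta)
            self._bm_logdet = float(np.log(np.diag(self._bm_chol)).sum())
            self._bm_W = sla.solve_triangular(
                self._bm_chol, np.ones((self.n, 1)), lower=True, check_finite=False)

    # -- design matrix -------------------------------------------------

    def design(self, alpha: float) -> np.ndarray:
        """Design matrix mapping optima (and X0 if free) to expectations."""
        k = self.spec.k
        free_x0 = self.spec.root_policy == "free-x0"
        W = np.zeros((self.n, k + (1 if free_x0 else 0)))
        Ti = self.T[self._seg_tip]
        contrib = np.exp(-alpha * (Ti - self._seg_t1)) - np.exp(-alpha * (Ti - self._seg_t0))
        np.add.at(W, (self._seg_tip, self._seg_opt), contrib)
        decay = np.exp(-alpha * self.T)
        if free_x0:
            W[:, k] = decay
        else:
            W[:, self._root_col] += decay
        return W

    def v0_cholesky(self, alpha: float) -> np.ndarray:
        V0 = np.exp(-alpha * self.D) * (-np.expm1(-2.0 * alpha * self.ta)) / (2.0 * alpha)
        return np.linalg.cholesky(V0)

    # -- profile likelihood --------------------------------------------

    def profile(self, alpha: float | None, x: np.ndarray):
        """Profiled lnL at fixed alpha; optima and sigma2 are solved for
        analytically (GLS + whitened mean squared residual)."""
        if self.spec.family == "BM":
            L, logdet, Wt = self._bm_chol, self._bm_logdet, self._bm_W
        else:
            L = self.v0_cholesky(alpha)
            logdet = float(np.log(np.diag(L)).sum())
            Wt = sla.solve_triangular(L, self.design(alpha), lower=True, check_finite=False)
        xt = sla.solve_triangular(L, x, lower=True, check_finite=False)
        beta, *_ = np.linalg.lstsq(Wt, xt, rcond=None)
        resid = xt - Wt @ beta
        q = float(resid @ resid)
        n = self.n
        sigma2 = max(q / n, 1e-300)
        lnl = -0.5 * n * (_LN2PI + 1.0) - 0.5 * n * math.log(sigma2) - logdet
        return lnl, beta, sigma2

    def _params_from(self, alpha: float | None, beta: np.ndarray, sigma2: float) -> ModelParams:
        spec = self.spec
        if spec.family == "BM":
            return ModelParams(spec=spec, sigma2=sigma2, alpha=None, theta={},
                               x0=float(beta[0]))
        theta = {o: float(beta[j]) for j, o in enumerate(spec.optima)}
        if spec.root_policy == "free-x0":
            x0 = float(beta[spec.k])
        else:
            x0 = float(beta[self._root_col])
        return ModelParams(spec=spec, sigma2=sigma2, alpha=float(alpha),
                           theta=theta, x0=x0)

    # -- maximization ---------------------------------------------------

    def fit(self, x: np.ndarray, options: FitOptions | None = None,
            extra_alpha_starts: Sequence[float] = ()) -> ModelFit:
        opts = options or FitOptions()
        x = np.asarray(x, dtype=float)
        n = self.n
        if x.shape != (n,):
            raise ValueError(f"trait vector has shape {x.shape}, expected ({n},)")
        if self.spec.family == "BM":
            lnl, beta, sigma2 = self.profile(None, x)
            params = self._params_from(None, beta, sigma2)
            return ModelFit(spec=self.spec, params=params, lnl=lnl,
                            sic=sic(lnl, self.spec.p, n), n=n,
                            converged=True, n_starts=1, n_evals=1)

        T = self.depth
        lo, hi = opts.thalf_span
        ln_a_min = math.log(math.log(2.0) / (hi * T))
        ln_a_max = math.log(min(math.log(2.0) / (lo * T), opts.alpha_max_factor / T))
        grid = np.linspace(ln_a_min, ln_a_max, opts.grid_size)
        starts = list(grid)
        for a in list(opts.extra_alpha_starts) + list(extra_alpha_starts):
            if a and a > 0:
                starts.append(min(max(math.log(a), ln_a_min), ln_a_max))
        evals = {}

        def obj(ln_a: float) -> float:
            if ln_a not in evals:
                evals[ln_a] = self.profile(math.exp(ln_a), x)
            return -evals[ln_a][0]

        vals = [obj(s) for s in starts]
        best_i = int(np.argmin(vals))
        best_s = starts[best_i]
        step = (ln_a_max - ln_a_min) / (opts.grid_size - 1)
        lo_b = max(best_s - step, ln_a_min)
        hi_b = min(best_s + step, ln_a_max)
        converged = True
        msg = ""
        try:
            res = minimize_scalar(obj, bounds=(lo_b, hi_b), method="bounded",
                                  options={"xatol": opts.refine_xatol})
            converged = bool(res.success)
            msg = str(getattr(res, "message", ""))
        except Exception as exc:  # pragma: no cover - defensive
            converged = False
            msg = f"refinement failed: {exc}"
        best_ln_a = min(evals, key=lambda k: -evals[k][0])
        lnl, beta, sigma2 = evals[best_ln_a]
        alpha = math.exp(best_ln_a)
        at_bound = bool(best_ln_a >= ln_a_max - 1e-9
                        and best_ln_a >= math.log(opts.alpha_max_factor / T) - 1e-9)
        params = self._params_from(alpha, beta, sigma2)
        return ModelFit(spec=self.spec, params=params, lnl=lnl,
                        sic=sic(lnl, self.spec.p, n), n=n,
                        converged=converged, n_starts=len(starts),
                        n_evals=len(evals), at_bound=at_bound, message=msg)

    # -- vectorized batch fitting ---------------------------------------

    def profile_batch(self, alpha: float | None, X: np.ndarray):
        """Profiled (lnl, beta, sigma2) for every row of X at one alpha.

        One Cholesky factor is shared by all datasets; per-dataset work
        is two triangular solves and a small least-squares solve, so the
        cost per dataset is a small fraction of a scalar profile call.
        """
        m, n = X.shape
        if self.spec.family == "BM":
            L, logdet = self._bm_chol, self._bm_logdet
            Wt = self._bm_W
        else:
            L = self.v0_cholesky(alpha)
            logdet = float(np.log(np.diag(L)).sum())
            Wt = sla.solve_triangular(L, self.design(alpha), lower=True,
                                      check_finite=False)
        Xt = sla.solve_triangular(L, X.T, lower=True, check_finite=False)  # (n, m)
        Q, R = np.linalg.qr(Wt)
        beta = sla.solve_triangular(R, Q.T @ Xt, lower=False,
                                    check_finite=False)                    # (k, m)
        resid = Xt - Wt @ beta
        q = np.einsum("ij,ij->j", resid, resid)
        sigma2 = np.maximum(q / n, 1e-300)
        lnl = -0.5 * n * (_LN2PI + 1.0) - 0.5 * n * np.log(sigma2) - logdet
        return lnl, beta.T, sigma2

    def fit_batch(self, X: np.ndarray, options: FitOptions | None = None,
                  extra_alpha_starts: Sequence[float] = ()) -> BatchFit:
        """Fit one model to every row of X.

        OU models are maximized over ln(alpha) on a shared grid followed
        by per-dataset parabolic refinement with exact re-evaluation;
        the returned lnl is always an exactly evaluated profile value at
        the best alpha found (never an interpolation).
        """
        opts = options or FitOptions()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        m, n = X.shape
        if n != self.n:
            raise ValueError(f"datasets have {n} tips, tree has {self.n}")
        if self.spec.family == "BM":
            lnl, beta, sigma2 = self.profile_batch(None, X)
            return BatchFit(spec=self.spec, lnl=lnl,
                            sic=-2.0 * lnl + self.spec.p * math.log(n),
                            alpha=None, sigma2=sigma2, beta=beta, n=n)
        T = self.depth
        lo, hi = opts.thalf_span
        ln_a_min = math.log(math.log(2.0) / (hi * T))
        ln_a_max = math.log(min(math.log(2.0) / (lo * T), opts.alpha_max_factor / T))
        grid = list(np.linspace(ln_a_min, ln_a_max, opts.batch_grid_size))
        for a in extra_alpha_starts:
            if a and a > 0:
                grid.append(min(max(math.log(a), ln_a_min), ln_a_max))
        grid = np.array(sorted(grid))
        G = len(grid)
        lnl_grid = np.empty((G, m))
        betas = {}
        sig = {}
        for g, ln_a in enumerate(grid):
            lnl_grid[g], betas[g], sig[g] = self.profile_batch(math.exp(ln_a), X)
        best_g = np.argmax(lnl_grid, axis=0)
        best_lnl = lnl_grid[best_g, np.arange(m)]
        best_a = grid[best_g]
        best_beta = np.stack([betas[g][d] for d, g in enumerate(best_g)])
        best_sig = np.array([sig[g][d] for d, g in enumerate(best_g)])

        # parabolic refinement in ln(alpha), with exact re-evaluation
        cur_a = best_a.copy()
        for _ in range(opts.batch_polish_iters):
            gi = np.clip(best_g, 1, G - 2)
            x0g, x1g, x2g = grid[gi - 1], grid[gi], grid[gi + 1]
            y0 = lnl_grid[gi - 1, np.arange(m)]
            y1 = lnl_grid[gi, np.arange(m)]
            y2 = lnl_grid[gi + 1, np.arange(m)]
            denom = (y0 - 2 * y1 + y2)
            with np.errstate(divide="ignore", invalid="ignore"):
                vertex = x1g - 0.5 * (x2g - x1g) * (y2 - y0) / denom
            vertex = np.where(np.isfinite(vertex) & (denom < 0), vertex, cur_a)
            vertex = np.clip(vertex, ln_a_min, ln_a_max)
            # exact evaluation per dataset at its own vertex (grouped to
            # reuse factors when vertices coincide)
            for d in range(m):
                va = vertex[d]
                if abs(va - cur_a[d]) < 1e-12:
                    continue
                lnl_v, beta_v, sig_v = self.profile(math.exp(va), X[d])
                if lnl_v > best_lnl[d]:
                    best_lnl[d] = lnl_v
                    best_beta[d] = beta_v
                    best_sig[d] = sig_v
                    cur_a[d] = va
        alpha = np.exp(cur_a)
        return BatchFit(spec=self.spec, lnl=best_lnl,
                        sic=-2.0 * best_lnl + self.spec.p * math.log(n),
                        alpha=alpha, sigma2=best_sig, beta=best_beta, n=n,
                        root_col=getattr(self, "_root_col", 0))

    # -- expectation/covariance at given parameters ---------------------

    def moments(self, params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
        if self.spec.family == "BM":
            E = np.full(self.n, params.x0)
            V = params.sigma2 * self.ta
            return E, V
        alpha = params.alpha
        beta = np.array([params.theta[o] for o in self.spec.optima])
        if self.spec.root_policy == "free-x0":
            beta = np.append(beta, params.x0)
        E = self.design(alpha) @ beta
        V0 = np.exp(-alpha * self.D) * (-np.expm1(-2.0 * alpha * self.ta)) / (2.0 * alpha)
        return E, params.sigma2 * V0


def fit_model(
    tree: TimeTree,
    painting: Painting | None,
    x: np.ndarray,
    spec: ModelSpec,
    options: FitOptions | None = None,
) -> ModelFit:
    """Maximum-likelihood fit of one model; see :class:`FitEngine`."""
    return FitEngine(tree, painting, spec).fit(x, options=options)
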