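"""Time-calibrated phylogenies and selective-regime paintings.

A :class:`TimeTree` wraps a rooted tree with branch lengths in units of
time (million years throughout this package).  Node *heights* are measured
forward from the process origin (t = 0 at the root, or at the top of the
root's stem edge when one is present) to the tips; *ages* are reported
backward from the tips, which is how divergence times are usually quoted.

A :class:`Painting` assigns every branch segment to a selective regime.
Regime shifts are placed at the base of a derived clade's stem branch, so
in the common case each branch carries a single regime; the segment
representation is kept general so that mid-branch shifts round-trip
through the sidecar table format.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd


class NewickError(ValueError):
    """Raised when a Newick source violates the tree invariants."""


class PaintingError(ValueError):
    """Raised when a regime painting is inconsistent with its tree."""


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


class TimeTree:
    """Rooted time tree with preorder-indexed nodes.

    Nodes are indexed 0..m-1 in preorder (root = 0).  A branch is
    identified by the index of its child node; the root's own entry holds
    the stem ("trunk") edge length, 0 when absent.  Tip order is the
    left-to-right Newick order and is the canonical order for every
    vector/matrix this package exchanges with the likelihood core.
    """

    def __init__(self, dtree: dendropy.Tree):
        self._index(dtree)
        self._validate()
        self._mrca_cache: np.ndarray | None = None

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "TimeTree":
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises assorted parse errors
            raise NewickError(f"malformed Newick: {exc}") from exc
        return cls(dtree)

    @classmethod
    def from_file(cls, path) -> "TimeTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def _index(self, dtree: dendropy.Tree) -> None:
        nodes = list(dtree.preorder_node_iter())
        m = len(nodes)
        idx = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(m, -1, dtype=int)
        blen = np.zeros(m)
        labels: list[str | None] = [None] * m
        children: list[list[int]] = [[] for _ in range(m)]
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = idx[id(nd.parent_node)]
                parent[i] = p
                children[p].append(i)
                if nd.edge.length is None:
                    raise NewickError(
                        f"missing branch length on edge above "
                        f"{nd.taxon.label if nd.taxon else 'an internal node'}"
                    )
                blen[i] = float(nd.edge.length)
            else:
                blen[i] = float(nd.edge.length or 0.0)
            if nd.is_leaf():
                if nd.taxon is not None:
                    labels[i] = str(nd.taxon.label)
                elif nd.label:
                    labels[i] = str(nd.label)
                else:
                    raise NewickError("unlabeled tip")
        self.parent = parent
        self.blen = blen
        self.children = children
        self.labels = labels
        self.tip_ids = np.array([i for i in range(m) if not children[i]], dtype=int)
        self.n_tips = len(self.tip_ids)
        self.tip_names: list[str] = [labels[i] for i in self.tip_ids]  # type: ignore[misc]
        heights = np.zeros(m)
        heights[0] = blen[0]
        for i in range(1, m):
            heights[i] = heights[parent[i]] + blen[i]
        self.heights = heights

    def _validate(self) -> None:
        seen: set[str] = set()
        for name in self.tip_names:
            if name in seen:
                raise NewickError(f"duplicate tip name: {name!r}")
            seen.add(name)
        if not np.all(np.isfinite(self.blen)) or np.any(self.blen < 0):
            raise NewickError("branch lengths must be finite and >= 0")
        if self.depth <= 0:
            raise NewickError("tree depth must be > 0")
        spread = self.ultrametric_spread
        if spread > 1e-6 * self.depth:
            warnings.warn(
                f"tree is not ultrametric: tip-depth spread {spread:.6g} "
                f"(depth {self.depth:.6g}); per-tip depths will be used",
                stacklevel=3,
            )

    # -- basic properties ---------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.blen)

    @property
    def root(self) -> int:
        return 0

    @property
    def tip_heights(self) -> np.ndarray:
        return self.heights[self.tip_ids]

    @property
    def depth(self) -> float:
        """Maximum root-to-tip distance (total tree depth T, My)."""
        return float(self.tip_heights.max())

    @property
    def ultrametric_spread(self) -> float:
        th = self.tip_heights
        return float(th.max() - th.min())

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        return self.ultrametric_spread <= rtol * self.depth

    @property
    def total_branch_length(self) -> float:
        return float(self.blen.sum())

    def tip_index(self, name: str) -> int:
        try:
            return self.tip_names.index(name)
        except ValueError:
            raise KeyError(f"unknown tip name: {name!r}") from None

    # -- topology queries ---------------------------------------------

    def postorder(self) -> list[int]:
        return list(range(self.n_nodes - 1, -1, -1)) if False else self._postorder()

    def _postorder(self) -> list[int]:
        # preorder reversed is a valid postorder for this indexing
        return list(range(self.n_nodes))[::-1]

    def subtree_nodes(self, node: int) -> list[int]:
        out = [node]
        stack = [node]
        while stack:
            v = stack.pop()
            for c in self.children[v]:
                out.append(c)
                stack.append(c)
        return sorted(set(out))

    def subtree_tips(self, node: int) -> list[str]:
        return [self.labels[i] for i in self.subtree_nodes(node) if not self.children[i]]

    def mrca(self, tip_names: Iterable[str]) -> int:
        names = set(tip_names)
        if not names:
            raise ValueError("empty tip set")
        unknown = names - set(self.tip_names)
        if unknown:
            raise KeyError(f"unknown tip name(s): {sorted(unknown)}")
        node_ids = [self.tip_ids[self.tip_index(n)] for n in names]
        paths = []
        for v in node_ids:
            path = []
            while v != -1:
                path.append(v)
                v = self.parent[v]
            paths.append(path[::-1])
        mrca = paths[0][0]
        for depth in range(min(len(p) for p in paths)):
            col = {p[depth] for p in paths}
            if len(col) == 1:
                mrca = col.pop()
            else:
                break
        return mrca

    def path_to_tip(self, tip_idx: int) -> list[int]:
        """Node indices from root to the given tip (by tip order index)."""
        v = int(self.tip_ids[tip_idx])
        path = []
        while v != -1:
            path.append(v)
            v = self.parent[v]
        return path[::-1]

    def mrca_heights(self) -> np.ndarray:
        """n x n matrix of the height of MRCA(i, j); diagonal = tip depths.

        The root's stem edge (when present) counts as shared history for
        every pair, so entries are bounded below by the trunk length.
        """
        if self._mrca_cache is not None:
            return self._mrca_cache
        n = self.n_tips
        tip_pos = {int(t): i for i, t in enumerate(self.tip_ids)}
        below: list[list[int]] = [[] for _ in range(self.n_nodes)]
        M = np.zeros((n, n))
        for v in self._postorder():
            if not self.children[v]:
                below[v] = [tip_pos[v]]
                continue
            groups = [below[c] for c in self.children[v]]
            h = self.heights[v]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for i in groups[a]:
                        for j in groups[b]:
                            M[i, j] = M[j, i] = h
            below[v] = [i for g in groups for i in g]
        np.fill_diagonal(M, self.tip_heights)
        self._mrca_cache = M
        return M

    # -- serialization ------------------------------------------------

    def to_newick(self) -> str:
        def rec(v: int) -> str:
            if not self.children[v]:
                return f"{self.labels[v]}:{_fmt(self.blen[v])}"
            inner = ",".join(rec(c) for c in self.children[v])
            return f"({inner}):{_fmt(self.blen[v])}"

        if not self.children[0]:
            raise NewickError("tree must have at least one internal node")
        inner = ",".join(rec(c) for c in self.children[0])
        if self.blen[0] > 0:
            return f"({inner}):{_fmt(self.blen[0])};"
        return f"({inner});"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # -- pruning ------------------------------------------------------

    def prune(self, keep: Iterable[str]) -> "TimeTree":
        """Induced subtree on ``keep``; root-to-tip distances preserved.

        Internal degree-2 nodes are merged; any pendant path above the
        new basal split is retained as a root stem edge so that tip
        depths (and hence trait covariances) are unchanged.
        """
        keep = set(keep)
        unknown = keep - set(self.tip_names)
        if unknown:
            raise KeyError(f"unknown tip name(s): {sorted(unknown)}")
        if len(keep) < 2:
            raise ValueError("need at least 2 tips to prune to")

        def rec(v: int) -> tuple[str, float] | None:
            # returns (newick fragment without length, accumulated length)
            if not self.children[v]:
                if self.labels[v] in keep:
                    return (str(self.labels[v]), float(self.blen[v]))
                return None
            sub = [rec(c) for c in self.children[v]]
            sub = [s for s in sub if s is not None]
            if not sub:
                return None
            if len(sub) == 1:
                frag, ln = sub[0]
                return (frag, ln + float(self.blen[v]))
            inner = ",".join(f"{frag}:{_fmt(ln)}" for frag, ln in sub)
            return (f"({inner})", float(self.blen[v]))

        res = rec(0)
        assert res is not None
        frag, root_len = res
        if not frag.startswith("("):
            raise ValueError("pruned tree has a single tip")
        nwk = f"{frag}:{_fmt(root_len)};" if root_len > 0 else f"{frag};"
        return TimeTree.from_newick(nwk)


@dataclass
class LineageHistory:
    """Regime history of one root-to-tip lineage, in forward time."""

    tip: str
    segments: list[tuple[float, float, str]]  # (t_start, t_end, regime)
    depth: float

    def validate(self, tol: float = 1e-9) -> None:
        t = 0.0
        for t0, t1, _ in self.segments:
            if abs(t0 - t) > tol or t1 < t0 - tol:
                raise PaintingError(f"history of {self.tip} does not partition [0, T]")
            t = t1
        if abs(t - self.depth) > tol:
            raise PaintingError(f"history of {self.tip} ends at {t}, expected {self.depth}")


@dataclass
class Painting:
    """Per-branch regime segments, keyed by child-node index."""

    background: str
    segments: dict[int, list[tuple[float, float, str]]] = field(default_factory=dict)

    @property
    def regimes(self) -> list[str]:
        seen: dict[str, None] = {self.background: None}
        for segs in self.segments.values():
            for _, _, r in segs:
                seen.setdefault(r, None)
        return list(seen)

    def painted_length(self) -> float:
        return float(sum(t1 - t0 for segs in self.segments.values() for t0, t1, _ in segs))

    def validate(self, tree: TimeTree, tol: float = 1e-9) -> None:
        branches = set(range(tree.n_nodes))
        if tree.blen[0] == 0:
            branches.discard(0)
        if set(self.segments) != branches:
            raise PaintingError("painting does not cover exactly the tree's branches")
        for b, segs in self.segments.items():
            lo = tree.heights[tree.parent[b]] if tree.parent[b] != -1 else 0.0
            hi = tree.heights[b]
            t = lo
            for t0, t1, _ in segs:
                if abs(t0 - t) > tol or t1 < t0 - tol:
                    raise PaintingError(f"branch {b}: segments not contiguous")
                t = t1
            if abs(t - hi) > tol:
                raise PaintingError(f"branch {b}: segments sum to {t - lo}, branch length {hi - lo}")

    def to_table(self, tree: TimeTree) -> pd.DataFrame:
        rows = []
        for b in sorted(self.segments):
            name = tree.labels[b] if tree.labels[b] else f"node{b}"
            for t0, t1, r in self.segments[b]:
                rows.append({"branch_id": b, "branch_label": name,
                             "start": t0, "end": t1, "regime": r})
        return pd.DataFrame(rows)

    def to_simmap(self, tree: TimeTree) -> str:
        """SIMMAP-style annotated Newick (per-branch {regime,duration:...},
        listed tipward-first as phytools writes them)."""

        def annot(v: int) -> str:
            segs = self.segments.get(v, [])
            parts = ":".join(f"{r},{_fmt(t1 - t0)}" for t0, t1, r in reversed(segs))
            return "{" + parts + "}" if parts else "{" + f"{self.background},0" + "}"

        def rec(v: int) -> str:
            if not tree.children[v]:
                return f"{tree.labels[v]}:{annot(v)}"
            inner = ",".join(rec(c) for c in tree.children[v])
            return f"({inner}):{annot(v)}"

        inner = ",".join(rec(c) for c in tree.children[0])
        return f"({inner});"


def paint_regimes(
    tree: TimeTree,
    clades: Sequence[tuple[Iterable[str], str, bool]],
    background: str = "bg",
) -> Painting:
    """Paint derived-regime clades onto a tree.

    Each clade is given as ``(tip_names, regime_id, include_stem)``.  All
    branches inside the clade's crown group carry the clade regime; when
    ``include_stem`` is true the shift is placed at the base of the stem
    branch, so the stem also carries the derived regime.  Every other
    branch carries the background regime.  Clades must be non-nested and
    non-overlapping.
    """
    assignment: dict[int, str] = {}
    for tips, regime, include_stem in clades:
        mrca = tree.mrca(tips)
        tip_set = set(tips)
        clade_tips = set(tree.subtree_tips(mrca))
        if not tip_set <= clade_tips:
            raise PaintingError(f"clade spec for regime {regime!r} did not resolve")
        nodes = tree.subtree_nodes(mrca)
        if not include_stem:
            nodes = [v for v in nodes if v != mrca]
        if mrca == tree.root:
            raise PaintingError(f"clade for regime {regime!r} is the whole tree")
        for v in nodes:
            if v in assignment:
                raise PaintingError(
                    f"overlapping clade assignments at node {v} "
                    f"({assignment[v]!r} vs {regime!r}); nested clades are not supported"
                )
            assignment[v] = regime
    segments: dict[int, list[tuple[float, float, str]]] = {}
    for v in range(tree.n_nodes):
        if v == tree.root and tree.blen[0] == 0:
            continue
        lo = tree.heights[tree.parent[v]] if tree.parent[v] != -1 else 0.0
        hi = tree.heights[v]
        segments[v] = [(float(lo), float(hi), assignment.get(v, background))]
    painting = Painting(background=background, segments=segments)
    painting.validate(tree)
    return painting


def uniform_painting(tree: TimeTree, regime: str = "bg") -> Painting:
    """All branches in a single regime."""
    return paint_regimes(tree, [], background=regime)


def lineage_histories(tree: TimeTree, painting: Painting) -> list[LineageHistory]:
    """One forward-time regime history per tip, root (t=0) to tip (t=T_i)."""
    painting.validate(tree)
    out = []
    for i in range(tree.n_tips):
        path = tree.path_to_tip(i)
        segs: list[tuple[float, float, str]] = []
        for v in path:
            for t0, t1, r in painting.segments.get(v, []):
                if segs and segs[-1][2] == r:
                    segs[-1] = (segs[-1][0], t1, r)
                else:
                    segs.append((t0, t1, r))
        depth = float(tree.tip_heights[i])
        hist = LineageHistory(tip=tree.tip_names[i], segments=segs, depth=depth)
        hist.validate()
        out.append(hist)
    return out


def stem_age(tree: TimeTree, clade_tips: Iterable[str]) -> float:
    """Age (My before present) of the base of a clade's stem branch.

    This is the height of the parent of the clade's MRCA, converted to an
    age using the maximum tip depth (equal to every tip depth on an
    ultrametric tree).
    """
    mrca = tree.mrca(clade_tips)
    if mrca == tree.root:
        raise ValueError("clade is the whole tree; it has no stem")
    parent = tree.parent[mrca]
    return float(tree.depth - tree.heights[parent])
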