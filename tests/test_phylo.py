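"""Tree reading, pruning, regime painting and lineage histories."""

import numpy as np
import pytest

from ouregimes.phylo import (NewickError, PaintingError, TimeTree,
                             lineage_histories, paint_regimes, stem_age,
                             uniform_painting)
from ouregimes.synthetic_data import _to_newick, _yule_crown, generate_tree


class TestReadNewick:
    def test_three_tip_ultrametric(self, three_tip_tree):
        t = three_tip_tree
        assert sorted(t.tip_names) == ["A", "B", "C"]
        assert t.depth == pytest.approx(2.0)
        assert t.is_ultrametric()

    def test_non_ultrametric_reports_spread(self):
        with pytest.warns(UserWarning, match="not ultrametric"):
            t = TimeTree.from_newick("((A:1,B:1):1,C:3);")
        assert t.ultrametric_spread == pytest.approx(1.0)

    def test_duplicate_tip_name_rejected(self):
        with pytest.raises(NewickError, match="[Dd]uplicate"):
            TimeTree.from_newick("((A:1,A:1):1,C:2);")

    def test_missing_branch_length_rejected(self):
        with pytest.raises(NewickError, match="branch length"):
            TimeTree.from_newick("((A:1,B):1,C:2);")

    def test_malformed_newick(self):
        with pytest.raises(NewickError):
            TimeTree.from_newick("((A:1,B:1:1,C:2);")

    def test_newick_roundtrip(self, three_tip_tree):
        again = TimeTree.from_newick(three_tip_tree.to_newick())
        assert again.tip_names == three_tip_tree.tip_names
        np.testing.assert_allclose(again.tip_heights, three_tip_tree.tip_heights)


class TestPrune:
    def test_two_tip_depths_preserved(self, three_tip_tree):
        t2 = three_tip_tree.prune({"A", "B"})
        assert t2.n_tips == 2
        np.testing.assert_allclose(t2.tip_heights, [2.0, 2.0])

    def test_prune_to_all_is_identity(self, three_tip_tree):
        t2 = three_tip_tree.prune(set(three_tip_tree.tip_names))
        assert t2.to_newick() == three_tip_tree.to_newick()

    def test_unknown_tip_listed(self, three_tip_tree):
        with pytest.raises(KeyError, match="ZZ"):
            three_tip_tree.prune({"A", "ZZ"})

    def test_study_tree_prunes_to_analysis_set(self):
        # 186-species acquisition set pruned to the 125 analysis species
        tree, groups = generate_tree(n_bg=137, n_clade_a=43, n_clade_b=6,
                                     depth=70.0, seed=5)
        assert tree.n_tips == 186
        drop = [s for s in tree.tip_names if groups[s] == "Arb"][:61]
        pruned = tree.prune(set(tree.tip_names) - set(drop))
        assert pruned.n_tips == 125
        assert pruned.depth == pytest.approx(tree.depth, rel=1e-12)

    def test_prune_idempotent_and_distance_preserving(self, rng):
        for _ in range(25):
            root, _ = _yule_crown(int(rng.integers(5, 12)), rng, "s")
            tree = TimeTree.from_newick(_to_newick(root))
            keep = set(rng.choice(tree.tip_names,
                                  size=int(rng.integers(2, tree.n_tips)),
                                  replace=False))
            p1 = tree.prune(keep)
            p2 = p1.prune(keep)
            assert p1.to_newick() == p2.to_newick()
            for name in keep:
                orig = tree.tip_heights[tree.tip_index(name)]
                new = p1.tip_heights[p1.tip_index(name)]
                assert abs(orig - new) <= 1e-12 * max(1.0, orig)


class TestPainting:
    def test_stem_and_crown_painted(self, three_tip_tree):
        p = paint_regimes(three_tip_tree, [(["A", "B"], "foss", True)], "bg")
        hists = {h.tip: h for h in lineage_histories(three_tip_tree, p)}
        assert hists["A"].segments == [(0.0, 2.0, "foss")]
        assert hists["C"].segments == [(0.0, 2.0, "bg")]

    def test_crown_only_when_stem_excluded(self, three_tip_tree):
        p = paint_regimes(three_tip_tree, [(["A", "B"], "foss", False)], "bg")
        hists = {h.tip: h for h in lineage_histories(three_tip_tree, p)}
        assert hists["A"].segments == [(0.0, 1.0, "bg"), (1.0, 2.0, "foss")]

    def test_painted_length_conserved_on_study_tree(self):
        tree, groups = generate_tree(seed=3)
        ma = [s for s, g in groups.items() if g == "Ma"]
        xe = [s for s, g in groups.items() if g == "Xe"]
        p = paint_regimes(tree, [(ma, "Ma", True), (xe, "Xe", True)], "arb")
        assert set(p.regimes) == {"arb", "Ma", "Xe"}
        assert p.painted_length() == pytest.approx(tree.total_branch_length,
                                                   abs=1e-12)

    def test_unknown_tip_in_clade_spec(self, three_tip_tree):
        with pytest.raises(KeyError, match="nope"):
            paint_regimes(three_tip_tree, [(["A", "nope"], "r", True)], "bg")

    def test_nested_clades_rejected(self):
        t = TimeTree.from_newick("(((A:1,B:1):1,C:2):1,D:3);")
        with pytest.raises(PaintingError, match="overlapping|nested"):
            paint_regimes(t, [(["A", "B", "C"], "r1", True),
                              (["A", "B"], "r2", True)], "bg")

    def test_sidecar_table_roundtrips_segments(self, three_tip_tree):
        p = paint_regimes(three_tip_tree, [(["A", "B"], "foss", True)], "bg")
        df = p.to_table(three_tip_tree)
        assert set(df["regime"]) == {"bg", "foss"}
        assert df["end"].sub(df["start"]).sum() == pytest.approx(
            three_tip_tree.total_branch_length)

    def test_simmap_export_contains_regimes(self, three_tip_tree):
        p = paint_regimes(three_tip_tree, [(["A", "B"], "foss", True)], "bg")
        s = p.to_simmap(three_tip_tree)
        assert "{foss," in s and "{bg," in s and s.endswith(";")


class TestLineageHistories:
    def test_uniform_painting_single_segment(self, three_tip_tree):
        p = uniform_painting(three_tip_tree, "r")
        for h in lineage_histories(three_tip_tree, p):
            assert len(h.segments) == 1
            assert h.segments[0] == (0.0, h.depth, "r")

    def test_partition_property_random_paintings(self, rng):
        # segments of every lineage partition [0, T_i] exactly
        for _ in range(1000):
            root, _ = _yule_crown(int(rng.integers(4, 9)), rng, "s")
            tree = TimeTree.from_newick(_to_newick(root))
            internals = [v for v in range(tree.n_nodes)
                         if tree.children[v] and v != tree.root]
            if internals:
                shift = internals[rng.integers(len(internals))]
                p = paint_regimes(tree, [(tree.subtree_tips(shift), "d",
                                          bool(rng.random() < 0.5))], "b")
            else:
                p = uniform_painting(tree, "b")
            for h in lineage_histories(tree, p):
                h.validate(tol=1e-9)
                total = sum(t1 - t0 for t0, t1, _ in h.segments)
                assert total == pytest.approx(h.depth, abs=1e-9)


class TestStemAge:
    def test_cherry_stem_is_root_age(self, three_tip_tree):
        assert stem_age(three_tip_tree, ["A", "B"]) == pytest.approx(2.0)

    def test_monotypic_clade_uses_parent(self, three_tip_tree):
        assert stem_age(three_tip_tree, ["C"]) == pytest.approx(2.0)

    def test_whole_tree_has_no_stem(self, three_tip_tree):
        with pytest.raises(ValueError, match="no stem"):
            stem_age(three_tip_tree, ["A", "B", "C"])

    def test_synthetic_study_stem_ages_match_design(self):
        tree, groups = generate_tree(seed=9)
        ma = [s for s, g in groups.items() if g == "Ma"]
        xe = [s for s, g in groups.items() if g == "Xe"]
        assert stem_age(tree, ma) == pytest.approx(24.5, abs=1e-6)
        assert stem_age(tree, xe) == pytest.approx(31.3, abs=1e-6)
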