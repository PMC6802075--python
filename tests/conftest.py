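import numpy as np
import pytest

from ouregimes.oumodels import six_model_specs
from ouregimes.phylo import TimeTree, paint_regimes
from ouregimes.synthetic_data import generate_tree


@pytest.fixture(scope="session")
def small_frame():
    """A reduced study frame (24 tips) for fast model-level tests."""
    tree, groups = generate_tree(n_bg=12, n_clade_a=8, n_clade_b=4, depth=50.0,
                                 seed=42, stem_age_a=20.0, stem_age_b=25.0)
    clade_a = [s for s, g in groups.items() if g == "Ma"]
    clade_b = [s for s, g in groups.items() if g == "Xe"]
    painting = paint_regimes(tree, [(clade_a, "Ma", True), (clade_b, "Xe", True)],
                             background="arb")
    specs = six_model_specs("arb", "Ma", "Xe")
    return tree, painting, specs


@pytest.fixture
def three_tip_tree():
    return TimeTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
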