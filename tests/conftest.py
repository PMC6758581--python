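import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from nectarevol import Phylogeny, SyndromeMap, TraitVector
from nectarevol.regimes import RegimePainting
from nectarevol.simulate import generate_study_like_dataset, simulate_yule_tree

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture
def cherry():
    """((A:1,B:1):0;) — a single cherry of height 1."""
    return Phylogeny(parent=[2, 2, -1], edge_length=[1.0, 1.0, 0.0],
                     tip_labels=["A", "B"])


@pytest.fixture
def balanced4():
    """(((A:1,B:1):1,(C:1,D:1):1):0;) — balanced ultrametric 4-tip tree."""
    return Phylogeny(
        parent=[4, 4, 5, 5, 6, 6, -1],
        edge_length=[1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 0.0],
        tip_labels=["A", "B", "C", "D"],
    )


@pytest.fixture(scope="session")
def yule57():
    return simulate_yule_tree(57, 22.0, seed=11)


@pytest.fixture(scope="session")
def bundle():
    return generate_study_like_dataset(seed=7)


def small_trees(n_max=6, seeds=(0, 1, 2, 3)):
    """Deterministic battery of small ultrametric test trees."""
    trees = []
    for n in range(3, n_max + 1):
        for s in seeds:
            trees.append(simulate_yule_tree(n, 10.0, seed=100 * n + s))
    return trees


def two_regime_painting(tree, split_state_a="bird", split_state_b="fly"):
    """Paint the two root subtrees with different regimes."""
    kids = tree.children[tree.root]
    regime = {}
    for root_child, st in zip(kids, [split_state_a, split_state_b] * len(kids)):
        stack = [root_child]
        while stack:
            v = stack.pop()
            regime[v] = st
            stack.extend(tree.children[v])
    regime[tree.root] = split_state_a
    return RegimePainting(branch_regime=regime, root_regime=split_state_a,
                          states=(split_state_a, split_state_b))


def trait_from(tree, values):
    return TraitVector(pd.Series(np.asarray(values, dtype=float),
                                 index=tree.tip_labels))
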