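import dendropy
import numpy as np
import pytest

from edge2 import (
    AssessmentTable,
    PhyloTree,
    SimConfig,
    build_ge2_curve,
    simulate_tree,
)


def tree_from_newick(newick: str) -> PhyloTree:
    return PhyloTree(
        dendropy.Tree.get(data=newick, schema="newick", rooting="default-rooted")
    )


@pytest.fixture(scope="session")
def curve():
    return build_ge2_curve()


@pytest.fixture
def cherry_tree():
    """((A:2,B:2):4,C:10); — a cherry plus an outgroup."""
    return tree_from_newick("((A:2,B:2):4,C:10);")


@pytest.fixture
def star_tree():
    return tree_from_newick("(A:1,B:1,C:1);")


def random_trees(n_trees: int, max_tips: int, seed: int):
    """Deterministic stream of small simulated trees with random p maps."""
    rng = np.random.default_rng(seed)
    for _ in range(n_trees):
        n_tips = int(rng.integers(3, max_tips + 1))
        tree = simulate_tree(SimConfig(n_tips=n_tips, seed=int(rng.integers(2**31))))
        p = {t: float(rng.uniform(0.0001, 0.9999)) for t in tree.tip_labels}
        yield tree, p


def median_mc_se(curve, category: str, n: int) -> float:
    """Asymptotic SE of the sample median of n category draws.

    Draws are a monotone transform g of a uniform rank, so the sample median
    is g(sample median of rank); SE = interval width x g'(midpoint) / (2 sqrt n).
    """
    if category in ("DD", "NE"):
        lo, hi = 0.0, 1.0
    else:
        lo, hi = curve.rank_intervals[category]
    mid = (lo + hi) / 2.0
    deriv = np.polynomial.polynomial.polyval(
        mid, np.polynomial.polynomial.polyder(np.asarray(curve.coefficients))
    )
    return float((hi - lo) * deriv / (2.0 * np.sqrt(n)))


@pytest.fixture
def mixed_table():
    return AssessmentTable(
        categories={"A": "CR", "B": "LC", "C": "EN"},
        tags={"A": frozenset({"Possibly Extinct"})},
    )
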