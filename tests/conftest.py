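"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import dendropy
import numpy as np
import pytest

import rbfcoevo as rc
from rbfcoevo import synth


@pytest.fixture(scope="session")
def catalog():
    return rc.default_catalog()


@pytest.fixture(scope="session")
def paper_like(catalog):
    """The study-condition synthetic matrix (seed fixed for the session)."""
    matrix, truth = synth.gen_matrix(synth.paper_like_cpr_config(), catalog,
                                     seed=11)
    return matrix, truth


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_mi(n11: int, n10: int, n01: int, n00: int,
                   base: str = "nat") -> float:
    """MI by direct summation over the four joint cells (plug-in).

    Independent of the entropy-decomposition route used by the package.
    """
    n = n11 + n10 + n01 + n00
    scale = math.log(2.0) if base == "2" else 1.0
    pa = {1: (n11 + n10) / n, 0: (n01 + n00) / n}
    pb = {1: (n11 + n01) / n, 0: (n10 + n00) / n}
    joint = {(1, 1): n11 / n, (1, 0): n10 / n,
             (0, 1): n01 / n, (0, 0): n00 / n}
    total = 0.0
    for (a, b), p in joint.items():
        if p > 0:
            total += p * math.log(p / (pa[a] * pb[b]))
    return total / scale


def brute_force_parsimony(tree: dendropy.Tree,
                          leaf_states: dict[str, int]) -> int:
    """Minimum change count over all 2^k internal-node labelings."""
    internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    leaves = [nd for nd in tree.leaf_node_iter()]
    best = math.inf
    for assignment in itertools.product((0, 1), repeat=len(internal)):
        states = {id(nd): s for nd, s in zip(internal, assignment)}
        for lf in leaves:
            states[id(lf)] = leaf_states[lf.taxon.label]
        changes = sum(
            1 for nd in tree.preorder_node_iter()
            if nd.parent_node is not None
            and states[id(nd)] != states[id(nd.parent_node)]
        )
        best = min(best, changes)
    return int(best)


def columns_from_counts(n11, n10, n01, n00):
    """Binary column pair realizing a 2x2 contingency table."""
    a = np.array([1] * n11 + [1] * n10 + [0] * n01 + [0] * n00)
    b = np.array([1] * n11 + [0] * n10 + [1] * n01 + [0] * n00)
    return a, b
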