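"""Shared fixtures and brute-force oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest

from collemsel.phylo_io import DatedTree, Node, TraitTable
import collemsel as cs


@pytest.fixture(scope="session")
def fixture_tree_traits():
    return cs.load_fixture()


@pytest.fixture(scope="session")
def ingroup(fixture_tree_traits):
    tree, traits = fixture_tree_traits
    clade = tree.mrca(list(traits.assignments))
    return tree.extract_clade(clade), traits


def random_tree(rng: np.random.Generator, n_tips: int,
                max_bl: float = 2.0) -> DatedTree:
    """Random rooted topology with uniform branch lengths (not ultrametric)."""
    nodes = [Node(f"t{i + 1}", float(rng.uniform(0.05, max_bl)))
             for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        parent = Node(None, float(rng.uniform(0.05, max_bl)))
        parent.children = [a, b]
        nodes = [nd for k, nd in enumerate(nodes) if k not in (int(i), int(j))]
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return DatedTree(root)


def brute_force_parsimony(tree: DatedTree, traits: TraitTable) -> int:
    """Minimum changes over all full internal labelings (exhaustive)."""
    internals = [nd for nd in tree.postorder_nodes if not nd.is_leaf]
    states = traits.states
    best = None
    import itertools
    for labeling in itertools.product(states, repeat=len(internals)):
        assign = dict(zip(internals, labeling))
        for lf in tree.leaves:
            assign[lf] = traits.assignments[lf.label]
        changes = sum(1 for nd in tree.branches()
                      if assign[nd] != assign[nd.parent])
        if best is None or changes < best:
            best = changes
    return best


def brute_force_mk_likelihood(tree: DatedTree, traits: TraitTable,
                              Q: np.ndarray, prior: np.ndarray) -> float:
    """Likelihood by explicit summation over internal-node states."""
    from scipy.linalg import expm

    P = {nd: expm(Q * nd.length) for nd in tree.branches()}
    internals = [nd for nd in tree.postorder_nodes if not nd.is_leaf]
    k = traits.k
    sidx = {s: i for i, s in enumerate(traits.states)}
    total = 0.0
    import itertools
    for labeling in itertools.product(range(k), repeat=len(internals)):
        assign = dict(zip(internals, labeling))
        for lf in tree.leaves:
            assign[lf] = sidx[traits.assignments[lf.label]]
        term = prior[assign[tree.root]]
        for nd in tree.branches():
            term *= P[nd][assign[nd.parent], assign[nd]]
        total += term
    return total
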