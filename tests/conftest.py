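"""Shared fixtures: small trees, toy cognate data, random generators."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import phylolex as px
from phylolex.cognates import ClassLabel, CognateDataset
from phylolex.substitution import TransitionKernel


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def balanced_tree():
    """((A:1,B:1):1,(C:1.5,D:1.5):0.5); root at 2 ka, all tips extant."""
    return px.TimeTree.from_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")


@pytest.fixture
def toy_dataset():
    """Five languages, one concept; classes A/A/B/{A,B}/missing."""
    langs = ["L1", "L2", "L3", "L4", "L5"]
    entries = {
        ("L1", "hand"): frozenset([ClassLabel("A")]),
        ("L2", "hand"): frozenset([ClassLabel("A")]),
        ("L3", "hand"): frozenset([ClassLabel("B")]),
        ("L4", "hand"): frozenset([ClassLabel("A"), ClassLabel("B")]),
    }
    return CognateDataset(langs, ["hand"], entries)


def brute_force_site_log_likelihood(tree, model, pattern, languages,
                                    clock_rate=1.0):
    """Independent oracle: sum over all internal-node state assignments."""
    kernel = TransitionKernel(model)
    pi = kernel.stationary
    ns = model.n_states
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    tip_idx = {l: i for i, l in enumerate(languages)}
    total = 0.0
    for assign in itertools.product(range(ns), repeat=len(internals)):
        amap = dict(zip(internals, assign))
        prob = pi[amap[tree.root]]
        for n in nodes:
            if n.parent is None:
                continue
            P = kernel.transition_matrix(n.duration * n.rate * clock_rate)
            if n.is_leaf:
                obs = pattern[tip_idx[n.label]]
                if obs == 2:
                    term = 1.0
                elif ns == 4:
                    term = P[amap[n.parent], obs] + P[amap[n.parent], obs + 2]
                else:
                    term = P[amap[n.parent], obs]
            else:
                term = P[amap[n.parent], amap[n]]
            prob *= term
        total += prob
    return float(np.log(total))


@pytest.fixture
def brute_force_site():
    return brute_force_site_log_likelihood


def all_rooted_topologies(labels):
    """All labeled rooted binary topologies over the given tips (ages 0,
    internal ages stacked upward)."""
    def build(tips):
        if len(tips) == 1:
            return [px.Node(tips[0], 0.0)]
        out = []
        first, rest = tips[0], tips[1:]
        for k in range(1, len(tips)):
            for left_rest in itertools.combinations(rest, k - 1):
                left = (first,) + left_rest
                right = tuple(t for t in rest if t not in left_rest)
                for lsub in build(left):
                    for rsub in build(right):
                        node = px.Node()
                        node.add_child(_clone(lsub))
                        node.add_child(_clone(rsub))
                        out.append(node)
        return out

    def _clone(n):
        m = px.Node(n.label, n.age)
        for c in n.children:
            m.add_child(_clone(c))
        return m

    trees = []
    for root in build(tuple(labels)):
        # stack internal ages so every parent is older than its children
        def set_ages(node):
            if node.is_leaf:
                return 0.0
            h = max(set_ages(c) for c in node.children) + 1.0
            node.age = h
            return h
        set_ages(root)
        trees.append(px.TimeTree(root))
    return trees


@pytest.fixture
def rooted_4tip_topologies():
    return all_rooted_topologies(["A", "B", "C", "D"])
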