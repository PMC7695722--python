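"""Posterior tree summarization: clade supports, root-split support,
HPD intervals, and the maximum clade credibility (MCC) tree.

Clades are keyed by their tip sets.  The MCC tree is the *sampled* tree
maximizing the sum of log clade posterior frequencies; its nodes are
annotated with the clade's posterior probability and the mean, median and
95% HPD of the clade's MRCA age across all sampled trees containing it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trees import Node, TimeTree

__all__ = ["CladeSupportTable", "AnnotatedTree", "clade_frequencies",
           "root_split_support", "hpd_interval", "mcc_tree",
           "read_trees_nexus", "read_trees_newick"]


@dataclass
class CladeSupportTable:
    frequencies: dict[frozenset[str], float]
    n_trees: int

    def to_dataframe(self) -> pd.DataFrame:
        """Descending frequency, ties broken lexicographically."""
        rows = sorted(self.frequencies.items(),
                      key=lambda kv: (-kv[1], sorted(kv[0])))
        return pd.DataFrame(
            [{"clade": ";".join(sorted(k)), "size": len(k), "support": v}
             for k, v in rows])

    def support(self, taxa) -> float:
        return self.frequencies.get(frozenset(taxa), 0.0)


def _check_common_tips(trees: list[TimeTree]) -> frozenset[str]:
    if not trees:
        raise ValueError("empty tree sample")
    tipset = frozenset(trees[0].tip_labels)
    for t in trees[1:]:
        if frozenset(t.tip_labels) != tipset:
            raise ValueError("trees are not on a common tip set")
    return tipset


def clade_frequencies(trees: list[TimeTree]) -> CladeSupportTable:
    """Posterior frequency of every clade observed in the sample."""
    _check_common_tips(trees)
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for clade in set(t.clades().values()):
            counts[clade] = counts.get(clade, 0) + 1
    n = len(trees)
    return CladeSupportTable({k: v / n for k, v in counts.items()}, n)


def root_split_support(trees: list[TimeTree], taxa) -> float:
    """Fraction of trees in which ``taxa`` is exactly one root child."""
    tipset = _check_common_tips(trees)
    taxa = frozenset(taxa)
    if not taxa or not taxa < tipset:
        raise ValueError("taxa must be a nonempty proper subset of the tips")
    hits = 0
    for t in trees:
        clades = t.clades()
        if any(clades[c] == taxa for c in t.root.children):
            hits += 1
    return hits / len(trees)


def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ceil(mass * n) sorted
    samples; ties resolved toward the smallest lower bound."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 1:
        raise ValueError("empty sample")
    if n == 1:
        return float(x[0]), float(x[0])
    if not (0.0 < mass <= 1.0):
        raise ValueError("mass must be in (0, 1]")
    m = int(np.ceil(mass * n))
    m = max(2, min(m, n))
    widths = x[m - 1:] - x[:n - m + 1]
    i = int(np.argmin(widths))  # argmin takes the first minimum
    return float(x[i]), float(x[i + m - 1])


@dataclass
class NodeAnnotation:
    posterior: float
    age_mean: float
    age_median: float
    age_hpd: tuple[float, float]


@dataclass
class AnnotatedTree:
    tree: TimeTree
    annotations: dict[frozenset[str], NodeAnnotation]

    def to_newick(self) -> str:
        """Newick with bracketed node comments (posterior, ages)."""
        clades = self.tree.clades()

        def fmt(n: Node) -> str:
            if n.is_leaf:
                core = n.label
            else:
                core = "(" + ",".join(fmt(c) for c in n.children) + ")"
            ann = self.annotations.get(clades[n])
            if ann is not None and not n.is_leaf:
                core += (f"[&posterior={ann.posterior:.6g},"
                         f"age_mean={ann.age_mean:.6g},"
                         f"age_median={ann.age_median:.6g},"
                         f"age_hpd_low={ann.age_hpd[0]:.6g},"
                         f"age_hpd_high={ann.age_hpd[1]:.6g}]")
            if n.parent is not None:
                core += f":{n.duration:.10g}"
            return core

        return fmt(self.tree.root) + ";"


def mcc_tree(trees: list[TimeTree], mass: float = 0.95) -> AnnotatedTree:
    """Maximum clade credibility tree with age annotations.

    Scores every sampled tree by the sum of log posterior frequencies of
    its clades and returns the first maximizer in sample order.
    """
    table = clade_frequencies(trees)
    freqs = table.frequencies
    best, best_score = None, -np.inf
    for t in trees:
        score = float(sum(np.log(freqs[c]) for c in set(t.clades().values())))
        if score > best_score + 1e-12:
            best, best_score = t, score
    assert best is not None
    # clade -> MRCA ages across all trees containing it
    ages: dict[frozenset[str], list[float]] = {}
    for t in trees:
        for node, clade in t.clades().items():
            ages.setdefault(clade, []).append(node.age)
    chosen = best.copy()
    annotations: dict[frozenset[str], NodeAnnotation] = {}
    for node, clade in chosen.clades().items():
        a = np.asarray(ages[clade])
        hpd = hpd_interval(a, mass) if len(a) > 1 else (float(a[0]),
                                                        float(a[0]))
        annotations[clade] = NodeAnnotation(
            posterior=freqs[clade],
            age_mean=float(a.mean()),
            age_median=float(np.median(a)),
            age_hpd=hpd,
        )
        if not node.is_leaf:
            node.age = float(a.mean())
    return AnnotatedTree(chosen, annotations)


# ----------------------------------------------------------------------
# reading tree samples
# ----------------------------------------------------------------------
def read_trees_nexus(path) -> list[TimeTree]:
    import dendropy
    tl = dendropy.TreeList.get(path=str(path), schema="nexus")
    return [TimeTree.from_newick(
        t.as_string(schema="newick").strip()) for t in tl]


def read_trees_newick(path) -> list[TimeTree]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(TimeTree.from_newick(line))
    if not out:
        raise ValueError(f"{path}: no trees found")
    return out
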