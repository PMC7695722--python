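"""Construction of a valid starting state for MCMC.

The starting tree must satisfy every hard calibration (fixed extinct-tip
ages, minimum MRCA ages) and monophyly constraint before sampling begins:
constrained taxon groups are built as subtrees first, node ages are
stacked upward, and calibrated MRCAs are pushed above their bounds.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .priors import Calibration, MonophylyConstraint
from .trees import Node, TimeTree

__all__ = ["initial_tree"]


def _ladder(tips: list[Node], rng: np.random.Generator,
            step_scale: float) -> Node:
    nodes = sorted(tips, key=lambda n: n.age)
    while len(nodes) > 1:
        a = nodes.pop(0)
        b = nodes.pop(0)
        parent = Node(age=max(a.age, b.age)
                      + step_scale * (0.5 + rng.random()))
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
        nodes.sort(key=lambda n: n.age)
    return nodes[0]


def initial_tree(languages: Sequence[str],
                 tip_dates: Optional[dict[str, float]] = None,
                 constraints: Sequence[MonophylyConstraint] = (),
                 calibrations: Sequence[Calibration] = (),
                 rng: Optional[np.random.Generator] = None,
                 root_age_guess: float = 10.0) -> TimeTree:
    """Build a dated starting tree over the named languages.

    Constrained groups become subtrees (an outgroup constraint makes its
    group one child of the root); minimum-age calibrations are enforced by
    lifting the calibrated MRCA and its ancestors.  Constraint groups must
    be disjoint.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if len(languages) < 2:
        raise ValueError("need at least two languages")
    tip_dates = tip_dates or {}
    for cal in calibrations:
        if cal.kind == "tip_date":
            (name,) = cal.taxa
            tip_dates.setdefault(name, cal.age_ka)
    tips = {l: Node(l, tip_dates.get(l, 0.0)) for l in languages}
    step = root_age_guess / max(4, len(languages))

    groups: list[tuple[frozenset[str], bool]] = []
    used: set[str] = set()
    for con in constraints:
        if con.taxa & used:
            raise ValueError("overlapping monophyly constraints are not "
                             "supported in the initial tree builder")
        unknown = con.taxa - set(languages)
        if unknown:
            raise KeyError(f"constraint names unknown taxa {sorted(unknown)}")
        groups.append((con.taxa, con.as_outgroup))
        used |= con.taxa
    rest = [l for l in languages if l not in used]

    subtrees: list[Node] = []
    outgroup_sub: Optional[Node] = None
    for taxa, as_outgroup in groups:
        sub = (_ladder([tips[t] for t in sorted(taxa)], rng, step)
               if len(taxa) > 1 else tips[next(iter(taxa))])
        if as_outgroup and outgroup_sub is None:
            outgroup_sub = sub
        else:
            subtrees.append(sub)
    subtrees.extend(tips[l] for l in rest)

    if outgroup_sub is not None:
        ingroup = (_ladder(subtrees, rng, step) if len(subtrees) > 1
                   else subtrees[0])
        root = Node(age=max(outgroup_sub.age, ingroup.age)
                    + step * (0.5 + rng.random()))
        root.add_child(outgroup_sub)
        root.add_child(ingroup)
    else:
        root = _ladder(subtrees, rng, step)
    tree = TimeTree(root)

    # lift calibrated MRCAs above their bounds, then restore age ordering
    for cal in calibrations:
        if cal.kind != "mrca_min_age":
            continue
        node = tree.mrca(sorted(cal.taxa))
        if node.age < cal.age_ka:
            node.age = cal.age_ka * 1.05 + step
    for node in tree.postorder():
        if node.parent is not None and node.parent.age <= node.age:
            node.parent.age = node.age + 0.5 * step
    tree.validate()
    return tree
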