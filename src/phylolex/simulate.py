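"""Forward simulators: FBD trees, branch rates, covarion characters, and
fully structured synthetic cognate datasets with recorded ground truth.

The generator emulates the structure of curated lexical datasets: ~110
concepts, each partitioned into cognate classes that innovate along the
branches of a dated tree with extinct tips; per-branch rate variation;
a fraction of loanwords (always flagged); occasional synonyms (two classes
in one language); and missing entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cognates import ClassLabel, CognateDataset
from .fbd import FBDParams
from .substitution import SubstModel, TransitionKernel
from .trees import Node, TimeTree

__all__ = [
    "SimulationConfig", "GroundTruth", "simulate_fbd_tree",
    "simulate_branch_rates", "simulate_covarion_characters",
    "simulate_binary_alignment", "make_cognate_dataset",
]

_MAX_LINEAGES = 200_000


# ----------------------------------------------------------------------
# trees
# ----------------------------------------------------------------------
def simulate_fbd_tree(p: FBDParams, root_age: float,
                      rng: np.random.Generator,
                      min_tips: int = 3,
                      n_tips: Optional[int] = None,
                      max_tries: int = 1000) -> TimeTree:
    """Forward-simulate a sampled FBD tree conditioned on its root age.

    Two lineages start at ``root_age``; births, deaths and serial samples
    occur at their respective rates; serial sampling removes the lineage
    (an extinct tip at its sampling age); extant survivors are kept with
    probability ``rho``.  Unsampled lineages are pruned.  Trees are
    rejected until both root children have at least one sampled
    descendant and at least ``min_tips`` (or exactly ``n_tips``) tips are
    sampled.
    """
    if root_age <= 0:
        raise ValueError("root age must be positive")
    for _ in range(max_tries):
        root = Node(age=root_age)
        ok = True
        total = 0
        stack = []
        for _ in range(2):
            child = root.add_child(Node())
            stack.append(child)
        sampled: dict[Node, bool] = {}
        rate = p.birth + p.death + p.psi
        while stack:
            node = stack.pop()
            total += 1
            if total > _MAX_LINEAGES:
                ok = False
                break
            start = node.parent.age
            wait = rng.exponential(1.0 / rate) if rate > 0 else np.inf
            t = start - wait
            if t <= 0:
                node.age = 0.0
                sampled[node] = bool(rng.random() < p.rho)
                continue
            u = rng.random() * rate
            if u < p.birth:
                node.age = t
                for _ in range(2):
                    stack.append(node.add_child(Node()))
            elif u < p.birth + p.death:
                node.age = t
                sampled[node] = False
            else:
                node.age = t
                sampled[node] = True
        if not ok:
            continue
        pruned = _prune_unsampled(root, sampled)
        if pruned is None or pruned.is_leaf or len(pruned.children) != 2:
            continue
        if abs(pruned.age - root_age) > 1e-12:
            continue  # root split lost a side: reject, keep conditioning
        tree = TimeTree(pruned)
        k = tree.n_tips
        if n_tips is not None and k != n_tips:
            continue
        if k < min_tips:
            continue
        _label_tips(tree)
        return tree
    raise RuntimeError(
        f"no acceptable tree after {max_tries} tries; parameters may give "
        f"almost-sure extinction or the wrong tip count")


def _prune_unsampled(root: Node, sampled: dict[Node, bool]) -> Optional[Node]:
    def prune(node: Node) -> Optional[Node]:
        if node.is_leaf:
            return node if sampled.get(node, False) else None
        kept = [c for c in (prune(ch) for ch in node.children)
                if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        node.children = []
        for c in kept:
            node.add_child(c)
        return node

    out = prune(root)
    if out is not None:
        out.parent = None
    return out


def _label_tips(tree: TimeTree) -> None:
    for i, tip in enumerate(tree.tips(), start=1):
        tip.label = f"L{i:03d}"


# ----------------------------------------------------------------------
# branch rates
# ----------------------------------------------------------------------
def simulate_branch_rates(tree: TimeTree, mu: float, sigma: float,
                          rng: np.random.Generator) -> dict[Node, float]:
    """Assign iid lognormal multipliers (real-space mean ``mu``) to every
    branch, writing them onto ``Node.rate`` and returning the mapping."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    out: dict[Node, float] = {}
    log_mean = np.log(mu) - 0.5 * sigma ** 2
    for node in tree.postorder():
        if node.parent is None:
            continue
        r = float(np.exp(rng.normal(log_mean, sigma))) if sigma > 0 else mu
        node.rate = r
        out[node] = r
    return out


# ----------------------------------------------------------------------
# characters
# ----------------------------------------------------------------------
def simulate_covarion_characters(tree: TimeTree, model: SubstModel,
                                 n_sites: int, rng: np.random.Generator,
                                 clock_rate: float = 1.0) -> dict[str, np.ndarray]:
    """Simulate visible tip states for ``n_sites`` binary characters.

    The root state is drawn from the model's stationary distribution and
    states evolve along each branch by exact sampling from the CTMC's
    transition matrix (hidden covarion states are simulated and then
    discarded).  Branch rate multipliers are read from ``Node.rate``.
    """
    if n_sites < 1:
        raise ValueError("need at least one site")
    kernel = TransitionKernel(model)
    n_states = model.n_states
    pi = kernel.stationary
    states: dict[Node, np.ndarray] = {}
    root_u = rng.random(n_sites)
    states[tree.root] = np.searchsorted(np.cumsum(pi), root_u).astype(np.int64)
    np.clip(states[tree.root], 0, n_states - 1, out=states[tree.root])
    for node in tree.preorder():
        if node.parent is None:
            continue
        t = node.duration * node.rate * clock_rate
        P = kernel.transition_matrix(t)
        cum = np.cumsum(P, axis=1)
        cum[:, -1] = 1.0
        u = rng.random(n_sites)
        parent_states = states[node.parent]
        states[node] = (u[:, None] > cum[parent_states]).sum(axis=1)
    out: dict[str, np.ndarray] = {}
    for tip in tree.tips():
        visible = states[tip] % 2 if n_states == 4 else states[tip]
        out[tip.label] = visible.astype(np.int8)
    return out


def simulate_binary_alignment(tree: TimeTree, model: SubstModel,
                              n_sites: int, rng: np.random.Generator,
                              clock_rate: float = 1.0):
    """Tip states packed as (languages, int8 matrix) for direct inference."""
    sim = simulate_covarion_characters(tree, model, n_sites, rng, clock_rate)
    languages = tree.tip_labels
    matrix = np.stack([sim[l] for l in languages])
    return languages, matrix


# ----------------------------------------------------------------------
# cognate datasets
# ----------------------------------------------------------------------
@dataclass
class SimulationConfig:
    fbd: FBDParams = field(default_factory=lambda: FBDParams(
        birth=0.78, death=0.2, psi=0.05, rho=0.8))
    root_age: float = 8.0            # ka BP
    n_tips: Optional[int] = None     # exact tip count (rejection), or free
    clock_rate: float = 0.2          # substitutions per ka
    clock_mu: float = 1.0
    clock_sigma: float = 0.1
    n_concepts: int = 110
    innovation_rate: float = 0.06    # new cognate classes per lineage-ka
    #: if set, overrides innovation_rate with one scaled to the simulated
    #: tree's length so concepts carry about this many cognate classes
    target_classes_per_concept: Optional[float] = None
    loan_rate: float = 0.02          # per (language, concept)
    synonym_rate: float = 0.03       # per (language, concept)
    missing_rate: float = 0.05       # per (language, concept)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("loan_rate", "synonym_rate", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability")
        if self.innovation_rate < 0:
            raise ValueError("innovation_rate must be nonnegative")
        if self.n_concepts < 1:
            raise ValueError("need at least one concept")


@dataclass
class GroundTruth:
    tree: TimeTree
    branch_rates: dict[str, float]      # keyed by child clade tip set repr
    config: SimulationConfig
    seed: int


def _simulate_concept_classes(tree: TimeTree, rate: float,
                              rng: np.random.Generator) -> dict[str, str]:
    """One concept: ancestral class at the root plus Poisson innovations
    along branches, each replacing the carrier lineage's class."""
    counter = [0]
    assignment: dict[Node, int] = {tree.root: 0}
    for node in tree.preorder():
        if node.parent is None:
            continue
        current = assignment[node.parent]
        k = rng.poisson(rate * node.duration) if rate > 0 else 0
        for _ in range(k):
            counter[0] += 1
            current = counter[0]
        assignment[node] = current
    return {tip.label: f"c{assignment[tip]}" for tip in tree.tips()}


def make_cognate_dataset(cfg: SimulationConfig
                         ) -> tuple[CognateDataset, GroundTruth]:
    """Simulate a complete cognate dataset plus its generating truth."""
    rng = np.random.default_rng(cfg.seed)
    tree = simulate_fbd_tree(cfg.fbd, cfg.root_age, rng, n_tips=cfg.n_tips,
                             max_tries=20_000 if cfg.n_tips else 1000)
    rates = simulate_branch_rates(tree, cfg.clock_mu, cfg.clock_sigma, rng)
    innovation_rate = cfg.innovation_rate
    if cfg.target_classes_per_concept is not None:
        # innovations are thinned by overwriting and lineage loss; the
        # empirical survival factor below was calibrated once by simulation
        innovation_rate = (1.08 * (cfg.target_classes_per_concept - 1.0)
                           / max(tree.total_branch_length(), 1e-9))
    languages = tree.tip_labels
    concepts = [f"concept_{i+1}" for i in range(cfg.n_concepts)]
    siblings = _sibling_map(tree)

    entries: dict[tuple[str, str], set[ClassLabel]] = {}
    for con in concepts:
        classes = _simulate_concept_classes(tree, innovation_rate, rng)
        for lang, cls in classes.items():
            entries[(lang, con)] = {ClassLabel(cls, False)}
        # synonyms: a second class for the meaning in one language
        for lang in languages:
            if rng.random() < cfg.synonym_rate:
                pool = sorted({c for v in classes.values() for c in [v]}
                              - {classes[lang]})
                if pool:
                    extra = pool[int(rng.integers(len(pool)))]
                    entries[(lang, con)].add(ClassLabel(extra, False))
        # loans: copy a donor's class to a non-sister recipient, flagged
        for lang in languages:
            if rng.random() < cfg.loan_rate:
                donors = [d for d in languages
                          if d != lang and d != siblings.get(lang)
                          and classes[d] != classes[lang]]
                if donors:
                    donor = donors[int(rng.integers(len(donors)))]
                    entries[(lang, con)].add(ClassLabel(classes[donor], True))
    # missing data
    for lang in languages:
        for con in concepts:
            if rng.random() < cfg.missing_rate:
                entries.pop((lang, con), None)

    ds = CognateDataset(
        languages=list(languages),
        concepts=concepts,
        entries={k: frozenset(v) for k, v in entries.items()},
        tip_dates={t.label: t.age for t in tree.tips()},
    )
    truth = GroundTruth(
        tree=tree,
        branch_rates={_branch_key(tree, n): r for n, r in rates.items()},
        config=cfg,
        seed=cfg.seed,
    )
    return ds, truth


def _sibling_map(tree: TimeTree) -> dict[str, str]:
    out: dict[str, str] = {}
    for node in tree.internal_nodes():
        a, b = node.children
        if a.is_leaf and b.is_leaf:
            out[a.label] = b.label
            out[b.label] = a.label
    return out


def _branch_key(tree: TimeTree, node: Node) -> str:
    return "|".join(sorted(tree.tip_set(node)))
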