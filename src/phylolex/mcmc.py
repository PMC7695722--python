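"""Metropolis-Hastings sampler over trees, node ages and model parameters.

The operator suite is the standard time-tree toolbox: uniform node-age
slides, a root-age multiplier, narrow and wide exchanges, Wilson-Balding
subtree transplants, multiplier ("scale") moves on every positive scalar,
a reflected random walk on the sampling proportion rho, and single-branch
rate-multiplier scales under the relaxed clock.  Moves that violate a hard
calibration or monophyly constraint are proposable but score -inf and are
rejected.  All randomness flows through one seeded generator per chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
import dendropy

from .cognates import SitePatterns
from .likelihood import data_log_likelihood
from .priors import PriorSpec, joint_log_prior
from .state import ModelState
from .trees import Node, TimeTree

__all__ = ["MCMCConfig", "PosteriorSample", "propose", "run_chain",
           "run_chains", "DEFAULT_WEIGHTS", "available_moves"]

# move-kind -> relative weight; grouped roughly as
# topology 30%, node ages 30%, clock/branch rates 20%, other scalars 20%
DEFAULT_WEIGHTS: dict[str, float] = {
    "narrow_exchange": 12.0,
    "wide_exchange": 8.0,
    "wilson_balding": 10.0,
    "node_age_slide": 22.0,
    "root_scale": 8.0,
    "clock_rate_scale": 10.0,
    "branch_rate_scale": 10.0,
    "gain_scale": 4.0,
    "loss_scale": 4.0,
    "switch_on_scale": 2.0,
    "switch_off_scale": 2.0,
    "gamma_shape_scale": 2.0,
    "birth_scale": 2.0,
    "death_scale": 2.0,
    "psi_scale": 2.0,
    "rho_walk": 2.0,
}

# moves whose acceptance does not require a likelihood recomputation
PRIOR_ONLY_MOVES = {"birth_scale", "death_scale", "psi_scale", "rho_walk"}


@dataclass
class MCMCConfig:
    chain_length: int = 100_000
    burn_in: int = 10_000
    sample_every: int = 100
    n_chains: int = 1
    seed: int = 1
    kappa: float = 1.5              # multiplier-move tuning, fixed
    rho_window: float = 0.1
    proposal_weights: Optional[dict[str, float]] = None
    beta: float = 1.0               # likelihood power (stepping stone)
    ascertainment: bool = False
    debug_check_every: int = 0      # recompute-and-assert caches every N

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.chain_length):
            raise ValueError("need 0 <= burn_in < chain_length")
        if (self.chain_length - self.burn_in) % self.sample_every:
            raise ValueError("sample_every must divide the post-burn-in length")

    @property
    def n_samples(self) -> int:
        return (self.chain_length - self.burn_in) // self.sample_every


@dataclass
class PosteriorSample:
    trees: list[TimeTree]
    trace: pd.DataFrame
    acceptance: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.trees) != len(self.trace):
            raise ValueError("tree and trace sample counts differ")

    def write_trace(self, path) -> None:
        """BEAST-style tab-separated trace log."""
        self.trace.to_csv(path, sep="\t", index=False)

    def write_trees_nexus(self, path) -> None:
        taxa = dendropy.TaxonNamespace()
        tl = dendropy.TreeList(taxon_namespace=taxa)
        for t in self.trees:
            tl.append(dendropy.Tree.get(data=t.to_newick(), schema="newick",
                                        taxon_namespace=taxa))
        tl.write(path=str(path), schema="nexus",
                 translate_tree_taxa=True)


# ----------------------------------------------------------------------
# proposals
# ----------------------------------------------------------------------
def available_moves(state: ModelState,
                    weights: Optional[dict[str, float]] = None
                    ) -> tuple[list[str], np.ndarray]:
    """Move kinds applicable to this state, with normalized weights."""
    w = dict(DEFAULT_WEIGHTS if weights is None else weights)
    if state.subst.covarion is None:
        w.pop("switch_on_scale", None)
        w.pop("switch_off_scale", None)
    if state.subst.gamma is None:
        w.pop("gamma_shape_scale", None)
    if not state.clock.is_relaxed:
        w.pop("branch_rate_scale", None)
    if state.tree.n_tips < 3:
        for k in ("narrow_exchange", "wide_exchange", "wilson_balding",
                  "node_age_slide"):
            w.pop(k, None)
    elif state.tree.n_tips < 4:
        w.pop("wilson_balding", None)
        w.pop("wide_exchange", None)
    kinds = sorted(w)
    probs = np.array([w[k] for k in kinds], dtype=float)
    return kinds, probs / probs.sum()


def _multiplier(rng: np.random.Generator, kappa: float) -> tuple[float, float]:
    logf = rng.uniform(-np.log(kappa), np.log(kappa))
    return float(np.exp(logf)), float(logf)


def _scale_param(state: ModelState, name: str, f: float) -> ModelState:
    if name in ("gain", "loss", "switch_on", "switch_off", "shape"):
        kw = {("shape" if name == "shape" else name):
              getattr_nested(state, name) * f}
        state.subst = state.subst.with_params(**kw)
    elif name == "clock_rate":
        state.clock.clock_rate *= f
    elif name in ("birth", "death", "psi"):
        state.fbd = replace(state.fbd, **{name: getattr(state.fbd, name) * f})
    else:  # pragma: no cover
        raise ValueError(name)
    return state


def getattr_nested(state: ModelState, name: str) -> float:
    if name in ("gain", "loss"):
        return getattr(state.subst.m1p, name)
    if name in ("switch_on", "switch_off"):
        return getattr(state.subst.covarion, name)
    if name == "shape":
        return state.subst.gamma.shape
    raise ValueError(name)  # pragma: no cover


_PARAM_OF_MOVE = {
    "gain_scale": "gain", "loss_scale": "loss",
    "switch_on_scale": "switch_on", "switch_off_scale": "switch_off",
    "gamma_shape_scale": "shape", "clock_rate_scale": "clock_rate",
    "birth_scale": "birth", "death_scale": "death", "psi_scale": "psi",
}


def propose(state: ModelState, move: str, rng: np.random.Generator,
            kappa: float = 1.5, rho_window: float = 0.1
            ) -> tuple[Optional[ModelState], float]:
    """Propose a new state; returns (state-or-None, log Hastings ratio).

    ``None`` means the move had no valid realization (auto-reject).
    """
    if move in _PARAM_OF_MOVE:
        f, logf = _multiplier(rng, kappa)
        new = state.copy()
        try:
            new = _scale_param(new, _PARAM_OF_MOVE[move], f)
        except ValueError:
            return None, 0.0
        return new, logf
    if move == "rho_walk":
        new = state.copy()
        r = state.fbd.rho + rng.uniform(-rho_window, rho_window)
        while r < 0.0 or r > 1.0:  # reflect at the boundaries
            r = -r if r < 0.0 else 2.0 - r
        new.fbd = replace(new.fbd, rho=r)
        return new, 0.0
    if move == "branch_rate_scale":
        new = state.copy()
        nodes = [n for n in new.tree.postorder() if n.parent is not None]
        node = nodes[int(rng.integers(len(nodes)))]
        f, logf = _multiplier(rng, kappa)
        node.rate *= f
        return new, logf
    if move == "node_age_slide":
        new = state.copy()
        nodes = [n for n in new.tree.internal_nodes(include_root=False)]
        if not nodes:
            return None, 0.0
        node = nodes[int(rng.integers(len(nodes)))]
        lo = max(c.age for c in node.children)
        hi = node.parent.age
        if hi <= lo:
            return None, 0.0
        node.age = rng.uniform(lo, hi)
        return new, 0.0
    if move == "root_scale":
        new = state.copy()
        root = new.tree.root
        f, logf = _multiplier(rng, kappa)
        new_age = root.age * f
        if new_age <= max(c.age for c in root.children):
            return None, 0.0
        root.age = new_age
        return new, logf
    if move == "narrow_exchange":
        return _narrow_exchange(state, rng)
    if move == "wide_exchange":
        return _wide_exchange(state, rng)
    if move == "wilson_balding":
        return _wilson_balding(state, rng)
    raise ValueError(f"unknown move kind {move!r}")


def _narrow_exchange(state: ModelState, rng) -> tuple[Optional[ModelState], float]:
    new = state.copy()
    tree = new.tree
    inner = tree.internal_nodes(include_root=False)
    if not inner:
        return None, 0.0
    p = inner[int(rng.integers(len(inner)))]
    g = p.parent
    uncle = g.children[0] if g.children[1] is p else g.children[1]
    if uncle.age >= p.age:
        return None, 0.0
    c = p.children[int(rng.integers(2))]
    g.children[g.children.index(uncle)] = c
    c.parent = g
    p.children[p.children.index(c)] = uncle
    uncle.parent = p
    return new, 0.0


def _wide_exchange(state: ModelState, rng) -> tuple[Optional[ModelState], float]:
    new = state.copy()
    tree = new.tree
    nodes = [n for n in tree.postorder() if n.parent is not None]
    i = nodes[int(rng.integers(len(nodes)))]
    j = nodes[int(rng.integers(len(nodes)))]
    if i is j or i.parent is j.parent:
        return None, 0.0
    if _is_ancestor(i, j) or _is_ancestor(j, i):
        return None, 0.0
    if i.parent.age <= j.age or j.parent.age <= i.age:
        return None, 0.0
    pi, pj = i.parent, j.parent
    pi.children[pi.children.index(i)] = j
    pj.children[pj.children.index(j)] = i
    i.parent, j.parent = pj, pi
    return new, 0.0


def _wilson_balding(state: ModelState, rng) -> tuple[Optional[ModelState], float]:
    new = state.copy()
    tree = new.tree
    nodes = [n for n in tree.postorder() if n.parent is not None]
    i = nodes[int(rng.integers(len(nodes)))]
    p = i.parent
    if p.parent is None:  # re-rooting transplant not part of this suite
        return None, 0.0
    j = nodes[int(rng.integers(len(nodes)))]
    if j is i or j is p or _is_ancestor(i, j):
        return None, 0.0
    g = p.parent
    s = p.children[0] if p.children[1] is i else p.children[1]
    # reverse-move window: reattaching i into the edge (g, s)
    lo_rev = max(i.age, s.age)
    hi_rev = g.age
    # detach: g adopts s in place of p
    g.children[g.children.index(p)] = s
    s.parent = g
    pj = j.parent
    lo = max(i.age, j.age)
    hi = pj.age
    if hi <= lo or hi_rev <= lo_rev:
        return None, 0.0
    # insert p into the edge (pj, j)
    pj.children[pj.children.index(j)] = p
    p.parent = pj
    p.children = [i, j]
    i.parent = p
    j.parent = p
    p.age = rng.uniform(lo, hi)
    log_hr = float(np.log(hi - lo) - np.log(hi_rev - lo_rev))
    return new, log_hr


def _is_ancestor(a: Node, b: Node) -> bool:
    node = b.parent
    while node is not None:
        if node is a:
            return True
        node = node.parent
    return False


# ----------------------------------------------------------------------
# the chain
# ----------------------------------------------------------------------
def _log_likelihood(state: ModelState, data: Optional[SitePatterns],
                    ascertainment: bool) -> float:
    if data is None:
        return 0.0
    return data_log_likelihood(
        state.tree, None, state.subst, data,
        clock_rate=state.clock.clock_rate, ascertainment=ascertainment)


def run_chain(data: Optional[SitePatterns], init: ModelState,
              spec: PriorSpec, cfg: MCMCConfig,
              chain_index: int = 0) -> PosteriorSample:
    """Run one Metropolis-Hastings chain; deterministic given the seed.

    ``data=None`` samples from the prior alone (likelihood identically 0),
    which is how the operator suite is validated against forward
    simulation.  ``cfg.beta`` tempers the likelihood for stepping-stone
    estimation.
    """
    rng = np.random.default_rng(cfg.seed + chain_index)
    state = init.copy()
    state.log_prior = joint_log_prior(state, spec)
    if not np.isfinite(state.log_prior):
        raise ValueError("initial state violates the prior "
                         "(constraint or calibration)")
    # fixed tip ages never move during the chain, so tip-date calibrations
    # are checked once above and dropped from the per-iteration prior
    loop_spec = spec
    if any(c.kind == "tip_date" for c in spec.calibrations):
        from dataclasses import replace as _dc_replace
        loop_spec = _dc_replace(
            spec, calibrations=[c for c in spec.calibrations
                                if c.kind != "tip_date"])
    spec = loop_spec
    state.log_likelihood = _log_likelihood(state, data, cfg.ascertainment)
    if not np.isfinite(state.log_likelihood):
        raise ValueError("initial state has zero likelihood")

    kinds, probs = available_moves(state, cfg.proposal_weights)
    move_idx = rng.choice(len(kinds), size=cfg.chain_length, p=probs)
    accept_u = np.log(rng.random(cfg.chain_length))

    trees: list[TimeTree] = []
    rows: list[dict[str, float]] = []
    n_prop = {k: 0 for k in kinds}
    n_acc = {k: 0 for k in kinds}

    for it in range(1, cfg.chain_length + 1):
        move = kinds[move_idx[it - 1]]
        n_prop[move] += 1
        prop, log_hr = propose(state, move, rng, cfg.kappa, cfg.rho_window)
        if prop is not None:
            prop.log_prior = joint_log_prior(prop, spec)
            if np.isfinite(prop.log_prior):
                if move in PRIOR_ONLY_MOVES or data is None:
                    prop.log_likelihood = state.log_likelihood
                else:
                    prop.log_likelihood = _log_likelihood(
                        prop, data, cfg.ascertainment)
                delta = (cfg.beta * (prop.log_likelihood
                                     - state.log_likelihood)
                         + prop.log_prior - state.log_prior)
                if accept_u[it - 1] < delta + log_hr:
                    state = prop
                    n_acc[move] += 1
        if cfg.debug_check_every and it % cfg.debug_check_every == 0:
            fresh_prior = joint_log_prior(state, spec)
            fresh_lik = _log_likelihood(state, data, cfg.ascertainment)
            if (abs(fresh_prior - state.log_prior) > 1e-8
                    or abs(fresh_lik - state.log_likelihood) > 1e-8):
                raise AssertionError("cached posterior terms drifted")
        if it > cfg.burn_in and (it - cfg.burn_in) % cfg.sample_every == 0:
            row = {"Sample": float(it),
                   "posterior": cfg.beta * state.log_likelihood
                   + state.log_prior,
                   "likelihood": state.log_likelihood,
                   "prior": state.log_prior}
            row.update(state.scalar_parameters())
            rows.append(row)
            trees.append(state.tree.copy())

    acceptance = {k: (n_acc[k] / n_prop[k] if n_prop[k] else 0.0)
                  for k in kinds}
    return PosteriorSample(trees, pd.DataFrame(rows), acceptance)


def run_chains(data, init, spec, cfg) -> list[PosteriorSample]:
    """Run ``cfg.n_chains`` chains with seed offsets (chain index)."""
    return [run_chain(data, init, spec, cfg, chain_index=i)
            for i in range(cfg.n_chains)]
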