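"""Felsenstein pruning over dated trees for binary / covarion models.

The engine works on compressed site patterns: all patterns are propagated
simultaneously as (n_patterns, n_states) partial-likelihood arrays, with
per-node rescaling to avoid underflow.  Branch lengths in expected
substitutions are ``duration * branch_rate * clock_rate``; under discrete
gamma the per-pattern likelihood is the equal-weight average over category
likelihoods; the root is closed with the model's stationary distribution.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np

from .cognates import MISSING, SitePatterns
from .substitution import SubstModel, TransitionKernel
from .trees import Node, TimeTree

__all__ = [
    "tip_partials", "site_log_likelihood", "data_log_likelihood",
    "pattern_log_likelihoods", "prob_all_absent",
]

_SYM_TO_CODE = {"0": 0, "1": 1, "?": MISSING, 0: 0, 1: 1, MISSING: MISSING}


def tip_partials(observed, model: SubstModel) -> np.ndarray:
    """Partial-likelihood vector for one observed tip symbol.

    The covarion's hidden on/off state is unobserved, so a visible 0 is
    compatible with both (0·on) and (0·off); '?' is all ones.
    """
    try:
        code = _SYM_TO_CODE[observed]
    except KeyError:
        raise ValueError(f"unknown observed symbol {observed!r}") from None
    n = model.n_states
    v = np.zeros(n)
    if code == MISSING:
        v[:] = 1.0
    elif n == 2:
        v[code] = 1.0
    else:  # states (0 on, 1 on, 0 off, 1 off)
        v[code] = 1.0
        v[code + 2] = 1.0
    return v


def _kernel_for(model: SubstModel) -> TransitionKernel:
    # models are frozen dataclasses, so a tiny memo works across the many
    # likelihood calls of an MCMC run that leave the model untouched
    cached = _KERNEL_CACHE.get(model)
    if cached is None:
        cached = TransitionKernel(model)
        if len(_KERNEL_CACHE) > 16:
            _KERNEL_CACHE.clear()
        _KERNEL_CACHE[model] = cached
    return cached


_KERNEL_CACHE: dict[SubstModel, TransitionKernel] = {}


def _tip_partial_matrices(patterns: SitePatterns,
                          n_states: int) -> dict[str, np.ndarray]:
    """Per-language tip partial matrices, cached on the patterns object."""
    cache = getattr(patterns, "_tip_partial_cache", None)
    if cache is None:
        cache = {}
        patterns._tip_partial_cache = cache
    if n_states not in cache:
        pats = patterns.patterns
        n_patterns = pats.shape[0]
        per_lang = {}
        for i, lbl in enumerate(patterns.languages):
            col = pats[:, i]
            part = np.zeros((n_patterns, n_states))
            part[col == MISSING] = 1.0
            part[col == 0, 0] = 1.0
            part[col == 1, 1] = 1.0
            if n_states == 4:
                part[col == 0, 2] = 1.0
                part[col == 1, 3] = 1.0
            per_lang[lbl] = part
        cache[n_states] = per_lang
    return cache[n_states]


def _resolve_rates(tree: TimeTree,
                   branch_rates: Optional[dict]) -> Optional[dict]:
    if branch_rates is None:
        return None
    missing = [n for n in tree.postorder()
               if n.parent is not None and n not in branch_rates]
    if missing:
        raise ValueError("branch_rates missing entries for some branches")
    return branch_rates


def pattern_log_likelihoods(tree: TimeTree, model: SubstModel,
                            patterns: SitePatterns,
                            branch_rates: Optional[dict] = None,
                            clock_rate: float = 1.0) -> np.ndarray:
    """Per-pattern log-likelihoods, shape (n_patterns,)."""
    rates = _resolve_rates(tree, branch_rates)
    order = list(tree.postorder())
    tips = [n for n in order if n.is_leaf]
    tip_part_by_lang = _tip_partial_matrices(patterns, model.n_states)
    for node in tips:
        if node.label not in tip_part_by_lang:
            raise ValueError(f"pattern languages do not cover tip "
                             f"{node.label!r}")
    if len(tips) != len(patterns.languages):
        raise ValueError("tip count does not match pattern length")

    kernel = _kernel_for(model)
    pi = kernel.stationary
    n_patterns = patterns.patterns.shape[0]

    nonroot = [n for n in order if n.parent is not None]
    base_t = np.array([
        n.duration * (n.rate if rates is None else rates[n]) * clock_rate
        for n in nonroot])
    if np.any(base_t < -1e-12):
        raise ValueError("negative branch length")
    base_t = np.maximum(base_t, 0.0)
    branch_index = {n: i for i, n in enumerate(nonroot)}

    cat_rates = model.category_rates
    cat_log_liks = np.empty((len(cat_rates), n_patterns))
    for ci, r in enumerate(cat_rates):
        P_all = kernel.transition_matrices(base_t * r)
        partials: dict[Node, np.ndarray] = {}
        for node in order:
            if node.is_leaf:
                partials[node] = tip_part_by_lang[node.label]
                continue
            a, b = node.children
            acc = (partials[a] @ P_all[branch_index[a]].T)
            acc *= partials[b] @ P_all[branch_index[b]].T
            partials[node] = acc
        root_lik = partials[tree.root] @ pi
        if np.all(root_lik > 0.0):
            cat_log_liks[ci] = np.log(root_lik)
        else:  # underflow on deep trees: redo with per-node rescaling
            cat_log_liks[ci] = _scaled_pass(order, tip_part_by_lang, P_all,
                                            branch_index, pi, n_patterns)
    if len(cat_rates) == 1:
        return cat_log_liks[0]
    m = cat_log_liks.max(axis=0)
    with np.errstate(invalid="ignore"):
        out = m + np.log(np.exp(cat_log_liks - m).mean(axis=0))
    return np.where(np.isfinite(m), out, -np.inf)


def _scaled_pass(order, tip_part_by_lang, P_all, branch_index, pi,
                 n_patterns) -> np.ndarray:
    partials: dict[Node, np.ndarray] = {}
    log_scale = np.zeros(n_patterns)
    root = None
    for node in order:
        root = node
        if node.is_leaf:
            partials[node] = tip_part_by_lang[node.label]
            continue
        a, b = node.children
        acc = (partials[a] @ P_all[branch_index[a]].T)
        acc *= partials[b] @ P_all[branch_index[b]].T
        mx = acc.max(axis=1)
        mx = np.where(mx > 0, mx, 1.0)
        acc /= mx[:, None]
        log_scale += np.log(mx)
        partials[node] = acc
    root_lik = partials[root] @ pi
    with np.errstate(divide="ignore"):
        return np.log(root_lik) + log_scale


def site_log_likelihood(tree: TimeTree, branch_rates: Optional[dict],
                        model: SubstModel,
                        pattern: Union[str, Sequence[int]],
                        languages: Optional[Sequence[str]] = None,
                        clock_rate: float = 1.0) -> float:
    """Log-likelihood of a single site pattern.

    ``pattern`` is a sequence over {0, 1, '?'} in the order of
    ``languages`` (default: the tree's tip order).
    """
    if languages is None:
        languages = tree.tip_labels
    codes = np.array([_SYM_TO_CODE[s] for s in pattern], dtype=np.int8)
    if len(codes) != len(languages):
        raise ValueError("pattern length does not match languages")
    pats = SitePatterns(list(languages), codes[None, :], np.array([1]))
    return float(pattern_log_likelihoods(
        tree, model, pats, branch_rates, clock_rate)[0])


def prob_all_absent(tree: TimeTree, model: SubstModel,
                    languages: Sequence[str],
                    branch_rates: Optional[dict] = None,
                    clock_rate: float = 1.0) -> float:
    """Probability of the all-zero column (for ascertainment correction)."""
    zeros = np.zeros((1, len(languages)), dtype=np.int8)
    pats = SitePatterns(list(languages), zeros, np.array([1]))
    ll = pattern_log_likelihoods(tree, model, pats, branch_rates, clock_rate)
    return float(np.exp(ll[0]))


def data_log_likelihood(tree: TimeTree, branch_rates: Optional[dict],
                        model: SubstModel, patterns: SitePatterns,
                        clock_rate: float = 1.0,
                        ascertainment: bool = False) -> float:
    """Weighted log-likelihood over compressed patterns.

    With ``ascertainment=True`` the result is conditioned on cognate
    classes being observable at all: ``n_sites * log(1 - P(all-absent))``
    is subtracted (off by default).
    """
    per_pattern = pattern_log_likelihoods(
        tree, model, patterns, branch_rates, clock_rate)
    total = float(np.dot(patterns.weights, per_pattern))
    if ascertainment:
        p0 = prob_all_absent(tree, model, patterns.languages,
                             branch_rates, clock_rate)
        total -= patterns.n_sites * np.log1p(-p0)
    return total
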