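"""Fossilized birth-death (FBD) prior density for serially sampled time trees.

The process: lineages branch at rate ``birth`` (lambda), die at rate
``death`` (mu), are sampled-and-removed through time at rate ``psi`` (an
extinct language observed at its last-seen date), and surviving lineages
are sampled at the present with probability ``rho``.  The density of the
sampled, dated tree is expressed with the standard helper functions

    c1 = |sqrt((lambda - mu - psi)^2 + 4 lambda psi)|
    c2 = -(lambda - mu - 2 lambda rho - psi) / c1
    q(t) = 4 e^{-c1 t} / (e^{-c1 t} (1 - c2) + (1 + c2))^2

and is conditioned on the root age with at least one sampled descendant
on each side of the root (division by (1 - p0(root))^2, where p0 is the
probability of leaving no sample).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .trees import TimeTree

__all__ = ["FBDParams", "fbd_log_density", "log_q", "prob_no_sample"]

EXTANT_TOL = 1e-9


@dataclass(frozen=True)
class FBDParams:
    birth: float = 1.0        # lambda, per ka per lineage
    death: float = 0.0        # mu
    psi: float = 0.0          # serial sampling rate
    rho: float = 1.0          # extant sampling proportion

    def __post_init__(self) -> None:
        if self.birth <= 0:
            raise ValueError("birth rate must be positive")
        if self.death < 0 or self.psi < 0:
            raise ValueError("death and sampling rates must be nonnegative")
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must lie in [0, 1]")


def _c1_c2(p: FBDParams) -> tuple[float, float]:
    lam, mu, psi, rho = p.birth, p.death, p.psi, p.rho
    c1 = abs(np.sqrt((lam - mu - psi) ** 2 + 4.0 * lam * psi))
    if c1 == 0.0:
        # lam == mu and psi == 0: degenerate critical case
        c1 = 1e-300
    c2 = -(lam - mu - 2.0 * lam * rho - psi) / c1
    return c1, c2


def log_q(t, p: FBDParams):
    """log q(t); vectorized over ``t``."""
    c1, c2 = _c1_c2(p)
    t = np.asarray(t, dtype=float)
    e = np.exp(-c1 * t)
    denom = e * (1.0 - c2) + (1.0 + c2)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log(4.0) - c1 * t - 2.0 * np.log(np.abs(denom))
    return out if out.shape else float(out)


def prob_no_sample(t, p: FBDParams):
    """p0(t): probability a lineage alive at age ``t`` is never sampled."""
    lam, mu, psi = p.birth, p.death, p.psi
    c1, c2 = _c1_c2(p)
    t = np.asarray(t, dtype=float)
    e = np.exp(-c1 * t)
    frac = (e * (1.0 - c2) - (1.0 + c2)) / (e * (1.0 - c2) + (1.0 + c2))
    out = (lam + mu + psi + c1 * frac) / (2.0 * lam)
    out = np.clip(out, 0.0, 1.0)
    return out if out.shape else float(out)


def fbd_log_density(tree: TimeTree, p: FBDParams) -> float:
    """Log density of a sampled dated tree, conditioned on its root age.

    Tips at age 0 (within tolerance) are rho-sampled extant languages;
    tips at positive age are psi-sampled extinct ones (sampling removes
    the lineage, so a last-seen date terminates its branch).
    """
    extinct_ages = []
    inner_ages = []
    n = 0
    root = tree.root
    for node in tree.postorder():
        if node.is_leaf:
            if node.age <= EXTANT_TOL:
                n += 1
            else:
                extinct_ages.append(node.age)
        elif node is not root:
            inner_ages.append(node.age)
    m = len(extinct_ages)
    if m > 0 and p.psi == 0.0:
        warnings.warn("tree has extinct tips but psi = 0; density is zero",
                      stacklevel=2)
        return -np.inf
    if n > 0 and p.rho == 0.0:
        return -np.inf

    logd = (n + m - 2) * np.log(p.birth)
    if m:
        logd += m * np.log(p.psi)
        logd -= float(np.sum(log_q(extinct_ages, p)))
    if n:
        logd += n * np.log(p.rho)
    logd += 2.0 * log_q(root.age, p)
    if inner_ages:
        logd += float(np.sum(log_q(inner_ages, p)))
    p0 = prob_no_sample(root.age, p)
    if p0 >= 1.0:
        return -np.inf
    logd -= 2.0 * np.log1p(-p0)
    return float(logd)
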