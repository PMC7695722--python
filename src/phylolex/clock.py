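"""Clock models: strict and lognormal relaxed.

Under the relaxed clock each branch carries an independent lognormal rate
multiplier with *real-space* mean ``mu`` (default 1.0) and log-space
standard deviation ``sigma`` (default 0.1); expected substitutions on a
branch are ``duration * multiplier * clock_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trees import Node, TimeTree

__all__ = ["ClockModel", "clock_branch_lengths", "branch_rate_log_prior",
           "lognormal_log_density"]


@dataclass
class ClockModel:
    kind: str = "strict"          # strict | relaxed-lognormal
    clock_rate: float = 1.0       # substitutions per ka
    mu: float = 1.0               # real-space mean of multipliers
    sigma: float = 0.1            # log-space stdev of multipliers

    def __post_init__(self) -> None:
        if self.kind not in ("strict", "relaxed-lognormal"):
            raise ValueError(f"unknown clock kind {self.kind!r}")
        if self.clock_rate <= 0:
            raise ValueError("clock rate must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")

    @property
    def is_relaxed(self) -> bool:
        return self.kind == "relaxed-lognormal"

    @property
    def log_mean(self) -> float:
        """Mean of log multipliers giving real-space mean ``mu``."""
        return float(np.log(self.mu) - 0.5 * self.sigma ** 2)


def clock_branch_lengths(tree: TimeTree, clock: ClockModel) -> dict[Node, float]:
    """Expected substitutions per branch, keyed by the branch's child node."""
    out: dict[Node, float] = {}
    for node in tree.postorder():
        if node.parent is None:
            continue
        mult = node.rate if clock.is_relaxed else 1.0
        if mult is None:
            raise ValueError("branch missing a rate multiplier")
        out[node] = node.duration * mult * clock.clock_rate
    return out


def lognormal_log_density(x, mu_real: float, sigma: float):
    """Lognormal log pdf parameterized by real-space mean and log-sd."""
    x = np.asarray(x, dtype=float)
    m = np.log(mu_real) - 0.5 * sigma ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            x > 0,
            -np.log(x * sigma * np.sqrt(2 * np.pi))
            - (np.log(np.where(x > 0, x, 1.0)) - m) ** 2 / (2 * sigma ** 2),
            -np.inf)
    return out if out.shape else float(out)


def branch_rate_log_prior(tree: TimeTree, clock: ClockModel) -> float:
    """Sum of lognormal log densities of the branch multipliers.

    For a strict clock the multipliers are not free parameters and the
    contribution is zero by contract.
    """
    if not clock.is_relaxed:
        return 0.0
    rates = np.array([n.rate for n in tree.postorder() if n.parent is not None])
    if np.any(rates <= 0):
        return -np.inf
    return float(np.sum(lognormal_log_density(rates, clock.mu, clock.sigma)))
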