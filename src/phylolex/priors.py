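"""Priors: calibrations, monophyly constraints, parameter priors, joint prior.

Calibrations are hard bounds (indicator priors): an extinct tip must sit
exactly at its last-seen date, and a calibrated clade's most recent common
ancestor must be at least as old as the earliest historical record of its
descendants.  Transition rates carry exponential priors with mean 10; the
extant sampling proportion is uniform on [0, 1]; remaining positive scalars
default to exponential priors with mean 1 (overridable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .clock import branch_rate_log_prior
from .fbd import fbd_log_density
from .state import ModelState
from .trees import TimeTree

__all__ = [
    "Calibration", "MonophylyConstraint", "PriorSpec",
    "calibration_log_prior", "constraint_satisfied", "joint_log_prior",
    "exponential_log_density",
]

TIP_DATE_TOL = 1e-6


@dataclass(frozen=True)
class Calibration:
    kind: str                      # tip_date | mrca_min_age
    taxa: frozenset[str]
    age_ka: float

    def __post_init__(self) -> None:
        if self.kind not in ("tip_date", "mrca_min_age"):
            raise ValueError(f"unknown calibration kind {self.kind!r}")
        if self.kind == "tip_date" and len(self.taxa) != 1:
            raise ValueError("tip_date names exactly one taxon")
        if self.kind == "mrca_min_age" and len(self.taxa) < 2:
            raise ValueError("mrca_min_age needs at least two taxa")
        if self.age_ka < 0:
            raise ValueError("calibration ages are in ka BP and nonnegative")


@dataclass(frozen=True)
class MonophylyConstraint:
    taxa: frozenset[str]
    as_outgroup: bool = False

    def __post_init__(self) -> None:
        if not self.taxa:
            raise ValueError("constraint needs at least one taxon")


def calibration_log_prior(tree: TimeTree, cals: list[Calibration]) -> float:
    """0 if every hard calibration holds, else -inf."""
    labels = set(tree.tip_labels)
    for cal in cals:
        unknown = cal.taxa - labels
        if unknown:
            raise KeyError(f"calibration names unknown taxa {sorted(unknown)}")
        if cal.kind == "tip_date":
            (name,) = cal.taxa
            if abs(tree.find_tip(name).age - cal.age_ka) > TIP_DATE_TOL:
                return -np.inf
        else:
            if tree.mrca(sorted(cal.taxa)).age < cal.age_ka - TIP_DATE_TOL:
                return -np.inf
    return 0.0


def constraint_satisfied(tree: TimeTree, con: MonophylyConstraint) -> bool:
    """True iff the taxa form a clade (and, if required, a root child)."""
    labels = frozenset(tree.tip_labels)
    if not con.taxa <= labels:
        raise KeyError(f"constraint names unknown taxa "
                       f"{sorted(con.taxa - labels)}")
    if not con.taxa < labels:
        raise ValueError("constraint taxa must be a proper subset of tips")
    clades = tree.clades()
    if con.as_outgroup:
        return any(clades[c] == con.taxa for c in tree.root.children)
    return con.taxa in clades.values()


def exponential_log_density(x: float, mean: float) -> float:
    if x < 0:
        return -np.inf
    return -np.log(mean) - x / mean


@dataclass
class PriorSpec:
    """Priors over every free scalar, plus calibrations and constraints."""

    transition_rate_mean: float = 10.0   # exp prior mean on gain/loss
    switch_rate_mean: float = 1.0        # exp prior mean on s1, s2
    gamma_shape_mean: float = 1.0
    clock_rate_mean: float = 1.0
    birth_mean: float = 1.0
    death_mean: float = 1.0
    psi_mean: float = 1.0
    root_age_mean: Optional[float] = 10.0   # exp prior on root age; None = flat
    calibrations: list[Calibration] = field(default_factory=list)
    constraints: list[MonophylyConstraint] = field(default_factory=list)

    def parameter_log_prior(self, state: ModelState) -> float:
        s = state.subst
        total = exponential_log_density(s.m1p.gain, self.transition_rate_mean)
        total += exponential_log_density(s.m1p.loss, self.transition_rate_mean)
        if s.covarion is not None:
            total += exponential_log_density(s.covarion.switch_on,
                                             self.switch_rate_mean)
            total += exponential_log_density(s.covarion.switch_off,
                                             self.switch_rate_mean)
        if s.gamma is not None:
            total += exponential_log_density(s.gamma.shape,
                                             self.gamma_shape_mean)
        total += exponential_log_density(state.clock.clock_rate,
                                         self.clock_rate_mean)
        total += exponential_log_density(state.fbd.birth, self.birth_mean)
        total += exponential_log_density(state.fbd.death, self.death_mean)
        total += exponential_log_density(state.fbd.psi, self.psi_mean)
        # rho ~ Uniform[0, 1]: log density 0 on support
        if not (0.0 <= state.fbd.rho <= 1.0):
            return -np.inf
        if self.root_age_mean is not None:
            total += exponential_log_density(state.tree.root_age,
                                             self.root_age_mean)
        return total


def joint_log_prior(state: ModelState, spec: PriorSpec) -> float:
    """Sum of tree prior, parameter priors, branch-rate prior, calibrations
    and monophyly constraints (hard terms contribute 0 or -inf)."""
    if state.tree is None:
        raise ValueError("state has no tree")
    for con in spec.constraints:
        if not constraint_satisfied(state.tree, con):
            return -np.inf
    cal = calibration_log_prior(state.tree, spec.calibrations)
    if not np.isfinite(cal):
        return -np.inf
    total = cal
    total += fbd_log_density(state.tree, state.fbd)
    if not np.isfinite(total):
        return -np.inf
    total += spec.parameter_log_prior(state)
    total += branch_rate_log_prior(state.tree, state.clock)
    return float(total)
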