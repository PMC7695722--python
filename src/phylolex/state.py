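"""The full sampled state of one MCMC iteration."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from .clock import ClockModel
from .fbd import FBDParams
from .substitution import SubstModel
from .trees import TimeTree

__all__ = ["ModelState"]


@dataclass
class ModelState:
    """Tree plus every scalar parameter, with cached posterior terms.

    Branch-rate multipliers live on the tree's nodes (``Node.rate``); the
    caches are refreshed by the sampler and can be asserted against a
    from-scratch recomputation in debug runs.
    """

    tree: TimeTree
    subst: SubstModel
    clock: ClockModel
    fbd: FBDParams
    log_likelihood: Optional[float] = None
    log_prior: Optional[float] = None

    def copy(self) -> "ModelState":
        return ModelState(self.tree.copy(), self.subst,
                          replace(self.clock), self.fbd,
                          self.log_likelihood, self.log_prior)

    @property
    def log_posterior(self) -> float:
        if self.log_likelihood is None or self.log_prior is None:
            raise ValueError("state caches not populated")
        return self.log_likelihood + self.log_prior

    def scalar_parameters(self) -> dict[str, float]:
        """Every scalar sampled or fixed in this state, by name."""
        out = {
            "gain_rate": self.subst.m1p.gain,
            "loss_rate": self.subst.m1p.loss,
            "clock_rate": self.clock.clock_rate,
            "birth_rate": self.fbd.birth,
            "death_rate": self.fbd.death,
            "psi": self.fbd.psi,
            "rho": self.fbd.rho,
            "root_age": self.tree.root_age,
            "tree_length": self.tree.total_branch_length(),
        }
        if self.subst.covarion is not None:
            out["switch_on"] = self.subst.covarion.switch_on
            out["switch_off"] = self.subst.covarion.switch_off
        if self.subst.gamma is not None:
            out["gamma_shape"] = self.subst.gamma.shape
        return out
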