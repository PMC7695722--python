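"""Stepping-stone marginal-likelihood estimation and Bayes factors.

The marginal likelihood Z is bridged from prior (beta = 0) to posterior
(beta = 1) through a sequence of power posteriors prior x likelihood^beta.
With samples drawn at each beta_k,

    log Z = sum_k log[ (1/n) sum_i L_i^(beta_{k+1} - beta_k) ],

computed in log space.  The default schedule places the beta_k at the
quantiles of a Beta(0.3, 1) distribution, concentrating steps near the
prior where the integrand changes fastest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .cognates import SitePatterns
from .mcmc import MCMCConfig, run_chain
from .priors import PriorSpec
from .state import ModelState

__all__ = ["PowerSchedule", "MarginalLikelihoodResult", "BayesFactor",
           "make_schedule", "stepping_stone", "stepping_stone_phylo",
           "bayes_factor"]


@dataclass(frozen=True)
class PowerSchedule:
    betas: tuple[float, ...]   # beta_0 = 0 < ... < beta_K = 1

    def __post_init__(self) -> None:
        b = np.asarray(self.betas)
        if len(b) < 3 or b[0] != 0.0 or b[-1] != 1.0:
            raise ValueError("schedule must run from 0 to 1 with K >= 2")
        if np.any(np.diff(b) <= 0):
            raise ValueError("schedule must be strictly increasing")

    @property
    def n_steps(self) -> int:
        return len(self.betas) - 1


def make_schedule(K: int, shape: float = 0.3) -> PowerSchedule:
    """K stepping stones at Beta(shape, 1) quantiles of k/K."""
    if K < 2:
        raise ValueError("need at least two steps")
    if shape <= 0:
        raise ValueError("shape must be positive")
    ks = np.arange(K + 1) / K
    betas = ks ** (1.0 / shape)
    betas[0], betas[-1] = 0.0, 1.0
    return PowerSchedule(tuple(float(b) for b in betas))


@dataclass
class MarginalLikelihoodResult:
    log_marginal: float
    per_step: np.ndarray       # per-step log contributions, sums to total
    se: float

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.per_step)) - self.log_marginal) > 1e-8:
            raise ValueError("per-step contributions do not sum to total")


# A power-posterior sampler: (beta, n_samples, rng, warm_start) ->
# (log-likelihood samples, final state for the next step's warm start).
PowerSampler = Callable[[float, int, np.random.Generator, object],
                        tuple[np.ndarray, object]]


def stepping_stone(sampler: PowerSampler, schedule: PowerSchedule,
                   samples_per_step: int,
                   rng: np.random.Generator) -> MarginalLikelihoodResult:
    """Generic stepping-stone estimator over any power-posterior sampler."""
    betas = schedule.betas
    contribs = []
    variances = []
    state: object = None
    for k in range(schedule.n_steps):
        logliks, state = sampler(betas[k], samples_per_step, rng, state)
        logliks = np.asarray(logliks, dtype=float)
        if betas[k] > 0.0 and not np.all(np.isfinite(logliks)):
            raise FloatingPointError(
                f"non-finite log-likelihood samples at step {k} "
                f"(beta = {betas[k]:.6g})")
        delta = betas[k + 1] - betas[k]
        scaled = delta * logliks
        m = scaled.max()
        w = np.exp(scaled - m)
        mean_w = w.mean()
        contribs.append(m + np.log(mean_w))
        # delta-method variance of log mean(w), ignoring autocorrelation
        variances.append(w.var(ddof=1) / (len(w) * mean_w ** 2))
    per_step = np.array(contribs)
    return MarginalLikelihoodResult(
        log_marginal=float(per_step.sum()),
        per_step=per_step,
        se=float(np.sqrt(np.sum(variances))),
    )


def stepping_stone_phylo(data: SitePatterns, init: ModelState,
                         spec: PriorSpec, cfg: MCMCConfig,
                         schedule: PowerSchedule,
                         samples_per_step: int,
                         burn_frac: float = 0.1) -> MarginalLikelihoodResult:
    """Stepping stone over the phylogenetic model.

    Each step runs an MCMC chain targeting prior x likelihood^beta,
    warm-started from the previous step's final state, discarding
    ``burn_frac`` of each step as burn-in.
    """
    rng = np.random.default_rng(cfg.seed)
    sample_every = max(1, cfg.sample_every)

    def sampler(beta, n, rng_, warm):
        start = warm if warm is not None else init
        length = n * sample_every
        burn = max(sample_every,
                   int(np.ceil(burn_frac * length / sample_every))
                   * sample_every)
        step_cfg = MCMCConfig(
            chain_length=length + burn, burn_in=burn,
            sample_every=sample_every, seed=int(rng_.integers(2 ** 31)),
            kappa=cfg.kappa, rho_window=cfg.rho_window,
            proposal_weights=cfg.proposal_weights, beta=beta,
            ascertainment=cfg.ascertainment)
        out = run_chain(data, start, spec, step_cfg)
        final = ModelState(out.trees[-1], init.subst, init.clock, init.fbd)
        # rebuild final scalar state from the trace's last row
        last = out.trace.iloc[-1]
        final.subst = init.subst.with_params(
            gain=last["gain_rate"], loss=last["loss_rate"],
            **({"switch_on": last["switch_on"],
                "switch_off": last["switch_off"]}
               if init.subst.covarion is not None else {}),
            **({"shape": last["gamma_shape"]}
               if init.subst.gamma is not None else {}))
        final.clock = type(init.clock)(
            kind=init.clock.kind, clock_rate=float(last["clock_rate"]),
            mu=init.clock.mu, sigma=init.clock.sigma)
        from .fbd import FBDParams
        final.fbd = FBDParams(float(last["birth_rate"]),
                              float(last["death_rate"]),
                              float(last["psi"]), float(last["rho"]))
        return out.trace["likelihood"].to_numpy(), final

    return stepping_stone(sampler, schedule, samples_per_step, rng)


@dataclass(frozen=True)
class BayesFactor:
    log_bf: float
    se: float


def bayes_factor(m1: MarginalLikelihoodResult,
                 m2: MarginalLikelihoodResult) -> BayesFactor:
    """log BF = log Z1 - log Z2, with combined Monte-Carlo SE."""
    if not (np.isfinite(m1.log_marginal) and np.isfinite(m2.log_marginal)):
        raise ValueError("marginal likelihoods must be finite")
    return BayesFactor(
        log_bf=float(m1.log_marginal - m2.log_marginal),
        se=float(np.hypot(m1.se, m2.se)),
    )
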