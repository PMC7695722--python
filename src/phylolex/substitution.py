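"""Substitution models for binary cognate characters.

Three nested models are supported:

* ``m1p`` — the two-state continuous-time Markov chain with a gain rate
  ``a`` (0 -> 1) and a loss rate ``b`` (1 -> 0); stationary frequencies
  (b, a)/(a + b).
* ``m1p+G4`` — m1p with discrete-gamma rate heterogeneity across
  cognate sets (k equal-probability categories represented by their
  category means, renormalized to mean one).
* ``m1p+CV`` — m1p wrapped in a binary covarion: every character carries a
  hidden on/off switch; gains and losses happen only while "on", and the
  switch itself flips at rates s1 (off -> on) and s2 (on -> off).  The
  hidden state is never observed, so the likelihood marginalizes over a
  four-state space ordered (0·on, 1·on, 0·off, 1·off).

With ``normalize=True`` generators are rescaled so the expected *visible*
substitution rate at stationarity is one, making the clock rate
interpretable in expected substitutions per ka.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

__all__ = [
    "M1pParams", "GammaHeterogeneity", "CovarionParams", "SubstModel",
    "m1p_generator", "covarion_generator", "gamma_category_rates",
    "m1p_transition_matrix", "TransitionKernel", "stationary_distribution",
]


@dataclass(frozen=True)
class M1pParams:
    """Gain/loss rates of the two-state model, per ka."""
    gain: float = 1.0   # a: 0 -> 1
    loss: float = 1.0   # b: 1 -> 0

    def __post_init__(self) -> None:
        if self.gain <= 0 or self.loss <= 0:
            raise ValueError("gain and loss rates must be positive")

    @property
    def stationary(self) -> np.ndarray:
        a, b = self.gain, self.loss
        return np.array([b, a]) / (a + b)


@dataclass(frozen=True)
class CovarionParams:
    """Hidden on/off switching rates."""
    switch_on: float = 1.0    # s1: off -> on
    switch_off: float = 1.0   # s2: on -> off

    def __post_init__(self) -> None:
        if self.switch_on <= 0 or self.switch_off <= 0:
            raise ValueError("switch rates must be positive")

    @property
    def pi_on(self) -> float:
        return self.switch_on / (self.switch_on + self.switch_off)


@dataclass(frozen=True)
class GammaHeterogeneity:
    """Discrete-gamma rate variation across characters."""
    shape: float = 1.0
    n_categories: int = 4

    def __post_init__(self) -> None:
        if self.shape <= 0:
            raise ValueError("gamma shape must be positive")
        if self.n_categories < 1:
            raise ValueError("need at least one rate category")

    @property
    def rates(self) -> np.ndarray:
        return gamma_category_rates(self.shape, self.n_categories)


@dataclass(frozen=True)
class SubstModel:
    kind: str = "m1p"  # m1p | m1p+G4 | m1p+CV
    m1p: M1pParams = field(default_factory=M1pParams)
    gamma: Optional[GammaHeterogeneity] = None
    covarion: Optional[CovarionParams] = None
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("m1p", "m1p+G4", "m1p+CV"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if (self.kind == "m1p+CV") != (self.covarion is not None):
            raise ValueError("covarion parameters present iff kind is m1p+CV")
        if (self.kind == "m1p+G4") != (self.gamma is not None):
            raise ValueError("gamma parameters present iff kind is m1p+G4")

    @property
    def n_states(self) -> int:
        return 4 if self.kind == "m1p+CV" else 2

    @property
    def category_rates(self) -> np.ndarray:
        if self.gamma is None:
            return np.ones(1)
        return self.gamma.rates

    def with_params(self, **kw) -> "SubstModel":
        """Return a copy with m1p/covarion/gamma scalars replaced."""
        m1p_kw = {k: kw.pop(k) for k in ("gain", "loss") if k in kw}
        cov_kw = {k: kw.pop(k) for k in ("switch_on", "switch_off") if k in kw}
        gam_kw = {k: kw.pop(k) for k in ("shape",) if k in kw}
        if kw:
            raise TypeError(f"unknown parameters {sorted(kw)}")
        out = self
        if m1p_kw:
            out = replace(out, m1p=replace(out.m1p, **m1p_kw))
        if cov_kw:
            if out.covarion is None:
                raise ValueError("model has no covarion component")
            out = replace(out, covarion=replace(out.covarion, **cov_kw))
        if gam_kw:
            if out.gamma is None:
                raise ValueError("model has no gamma component")
            out = replace(out, gamma=replace(out.gamma, **gam_kw))
        return out


# ----------------------------------------------------------------------
# generators
# ----------------------------------------------------------------------
def m1p_generator(p: M1pParams, normalize: bool = False) -> np.ndarray:
    a, b = p.gain, p.loss
    Q = np.array([[-a, a], [b, -b]], dtype=float)
    if normalize:
        Q = Q / _m1p_rate(p)
    return Q


def _m1p_rate(p: M1pParams) -> float:
    # expected substitution rate at stationarity: pi0*a + pi1*b
    a, b = p.gain, p.loss
    return 2.0 * a * b / (a + b)


def covarion_generator(p: M1pParams, c: CovarionParams,
                       normalize: bool = False) -> np.ndarray:
    """Four-state generator, states (0·on, 1·on, 0·off, 1·off).

    Visible 0<->1 changes occur only in the "on" block; switching on/off
    never changes the visible state; the "off" block is frozen.
    """
    a, b = p.gain, p.loss
    s1, s2 = c.switch_on, c.switch_off
    Q = np.array([
        [-(a + s2),      a,       s2,     0.0],
        [b,       -(b + s2),     0.0,      s2],
        [s1,            0.0,     -s1,     0.0],
        [0.0,            s1,     0.0,     -s1],
    ], dtype=float)
    if normalize:
        Q = Q / (c.pi_on * _m1p_rate(p))
    return Q


def stationary_distribution(model: SubstModel) -> np.ndarray:
    pi_vis = model.m1p.stationary
    if model.covarion is None:
        return pi_vis
    pi_on = model.covarion.pi_on
    return np.concatenate([pi_on * pi_vis, (1 - pi_on) * pi_vis])


def model_generator(model: SubstModel) -> np.ndarray:
    if model.covarion is not None:
        return covarion_generator(model.m1p, model.covarion,
                                  normalize=model.normalize)
    return m1p_generator(model.m1p, normalize=model.normalize)


# ----------------------------------------------------------------------
# gamma discretization
# ----------------------------------------------------------------------
def gamma_category_rates(shape: float, k: int) -> np.ndarray:
    """Equal-probability category means under Gamma(shape, rate=shape).

    The mean of category i is computed in closed form from the regularized
    incomplete gamma function, then the vector is renormalized so its mean
    is exactly one (guarding floating-point drift).
    """
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    if k < 1:
        raise ValueError("need at least one category")
    if k == 1:
        return np.ones(1)
    probs = np.arange(1, k) / k
    bounds = gamma_dist.ppf(probs, shape, scale=1.0 / shape)
    bounds = np.concatenate([[0.0], bounds, [np.inf]])
    # E[X; X in (lo, hi)] = P(shape+1, shape*hi) - P(shape+1, shape*lo)
    upper = np.where(np.isinf(bounds[1:]), 1.0,
                     gammainc(shape + 1, shape * bounds[1:]))
    lower = gammainc(shape + 1, shape * np.minimum(bounds[:-1], 1e300))
    rates = k * (upper - lower)
    rates = np.maximum(rates, 0.0)
    return rates / rates.mean()


# ----------------------------------------------------------------------
# transition probabilities
# ----------------------------------------------------------------------
def m1p_transition_matrix(p: M1pParams, t: float,
                          normalize: bool = False) -> np.ndarray:
    """Closed-form two-state transition matrix over duration ``t``."""
    if t < 0:
        raise ValueError("negative duration")
    a, b = p.gain, p.loss
    if normalize:
        scale = 1.0 / _m1p_rate(p)
        a, b = a * scale, b * scale
    s = a + b
    e = np.exp(-s * t)
    return np.array([
        [(b + a * e) / s, (a - a * e) / s],
        [(b - b * e) / s, (a + b * e) / s],
    ])


class TransitionKernel:
    """Cached spectral decomposition of a model's generator.

    Both supported generators are reversible with respect to their
    stationary distribution, so the symmetrized generator is diagonalized
    with a real orthogonal eigenbasis; ``P(t)`` is then two small matrix
    products per call.
    """

    def __init__(self, model: SubstModel):
        self.model = model
        self.Q = model_generator(model)
        self.stationary = stationary_distribution(model)
        pi = self.stationary
        d = np.sqrt(pi)
        B = (self.Q * d[:, None]) / d[None, :]
        B = 0.5 * (B + B.T)  # exact symmetry
        w, V = np.linalg.eigh(B)
        self.eigenvalues = w
        self._right = V * d[:, None]
        # P(t) = D^{-1/2} V e^{wt} V^T D^{1/2}

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("negative duration")
        ew = np.exp(self.eigenvalues * t)
        P = (self._right * ew) @ self._right.T
        P = P / self.stationary[:, None]
        # clip tiny negative round-off
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transition_matrices(self, ts: np.ndarray) -> np.ndarray:
        """Transition matrices for a batch of durations, shape (B, n, n).

        Vectorized over branches; round-off is floored at zero but rows
        are not renormalized (the error is ~1e-15).
        """
        ts = np.asarray(ts, dtype=float)
        if np.any(ts < 0):
            raise ValueError("negative duration")
        ew = np.exp(np.multiply.outer(ts, self.eigenvalues))   # (B, k)
        P = np.einsum("bk,ik,jk->bij", ew, self._right, self._right)
        P /= self.stationary[None, :, None]
        np.maximum(P, 0.0, out=P)
        return P
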