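"""Convergence diagnostics for MCMC traces: ESS and multi-chain R-hat."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["effective_sample_size", "rhat", "multichain_diagnostics"]


def _autocorrelations(x: np.ndarray) -> np.ndarray:
    n = len(x)
    x = x - x.mean()
    m = 1
    while m < 2 * n:
        m <<= 1
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conj(f))[:n] / n
    return acov / acov[0]


def effective_sample_size(trace) -> float:
    """ESS = n / (1 + 2 * sum of autocorrelations), with the sum truncated
    at the first nonpositive autocorrelation (initial positive sequence).

    A constant trace returns n by convention (with a warning); an
    anticorrelated trace, whose raw estimator would exceed n, is capped at
    n and flagged with a warning.
    """
    x = np.asarray(trace, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 samples")
    if np.ptp(x) == 0.0:
        warnings.warn("constant trace: ESS = n by convention", stacklevel=2)
        return float(n)
    rho = _autocorrelations(x)
    if rho[1] < 0:
        warnings.warn("anticorrelated trace: raw ESS exceeds n; capped at n",
                      stacklevel=2)
        return float(n)
    total = 0.0
    for k in range(1, n):
        if rho[k] <= 0:
            break
        total += rho[k]
    return float(n / (1.0 + 2.0 * total))


def rhat(chains) -> float:
    """Between/within-chain variance ratio.

    R-hat = sqrt((W + B) / W) with W the mean within-chain variance and B
    the variance of the chain means; identical chains give exactly 1.
    """
    arrs = [np.asarray(c, dtype=float) for c in chains]
    if len(arrs) < 2:
        raise ValueError("need at least two chains")
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ValueError("chains must have equal length")
    W = float(np.mean([a.var(ddof=1) for a in arrs]))
    B = float(np.var([a.mean() for a in arrs], ddof=1))
    if W == 0.0:
        return 1.0 if B == 0.0 else np.inf
    return float(np.sqrt((W + B) / W))


def multichain_diagnostics(samples, rhat_threshold: float = 1.05
                           ) -> pd.DataFrame:
    """Per-parameter R-hat and pooled ESS across chains.

    ``samples`` is a list of :class:`~phylolex.mcmc.PosteriorSample`; every
    scalar column of the trace (everything except the iteration counter)
    is diagnosed, and parameters with R-hat above the threshold are
    flagged.
    """
    if len(samples) < 2:
        raise ValueError("need at least two chains")
    cols = [c for c in samples[0].trace.columns if c != "Sample"]
    for s in samples[1:]:
        if [c for c in s.trace.columns if c != "Sample"] != cols:
            raise ValueError("chains trace different parameters")
    rows = []
    for col in cols:
        chains = [s.trace[col].to_numpy() for s in samples]
        r = rhat(chains)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ess = sum(effective_sample_size(c) for c in chains)
        rows.append({"parameter": col, "rhat": r, "ess": ess,
                     "flagged": bool(r > rhat_threshold)})
    return pd.DataFrame(rows)
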