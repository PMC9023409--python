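"""Rubin's rules for combining multiply-imputed estimates.

For M point estimates Q_m with within-imputation variances U_m:

    Qbar = mean(Q_m)
    W    = mean(U_m)                     (within-imputation variance)
    B    = var(Q_m, ddof=1)              (between-imputation variance)
    T    = W + (1 + 1/M) B               (total variance)
    df   = (M - 1) (1 + W / ((1 + 1/M) B))^2   (classic Rubin df; +inf if B = 0)

A small-sample (Barnard-Rubin) df adjustment is available via
``complete_df`` but the classic df is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class PoolingError(ValueError):
    """Invalid pooling inputs."""


@dataclass(frozen=True)
class PooledEstimate:
    point: float
    within: float
    between: float
    total: float
    M: int
    df: float


def rubin_pool(estimates, variances, complete_df: float | None = None) -> PooledEstimate:
    """Pool scalar estimates and their variances by Rubin's rules.

    Parameters
    ----------
    estimates, variances : sequences of length M >= 2
        Per-imputation point estimates and (nonnegative) squared SEs.
    complete_df : float, optional
        Complete-data degrees of freedom; if given, the Barnard-Rubin
        small-sample adjustment is applied to the returned df.
    """
    q = np.asarray(list(estimates), dtype=float)
    u = np.asarray(list(variances), dtype=float)
    if len(q) != len(u):
        raise PoolingError("estimates and variances must have equal length")
    M = len(q)
    if M < 2:
        raise PoolingError("need at least two imputations")
    if np.any(u < 0):
        raise PoolingError("variances must be nonnegative")
    qbar = float(q.mean())
    W = float(u.mean())
    B = float(q.var(ddof=1))
    T = W + (1.0 + 1.0 / M) * B
    if B > 0:
        r = (1.0 + 1.0 / M) * B
        with np.errstate(over="ignore"):  # W >> B legitimately gives df = inf
            df = float((M - 1.0) * np.square(1.0 + np.float64(W) / r))
        if complete_df is not None:
            # Barnard-Rubin: harmonic combination with the observed-data df
            lam = r / T
            df_obs = (complete_df + 1.0) / (complete_df + 3.0) * complete_df * (1.0 - lam)
            df = 1.0 / (1.0 / df + 1.0 / df_obs)
    else:
        df = float("inf")
    return PooledEstimate(qbar, W, B, T, M, df)
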