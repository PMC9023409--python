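"""Random-intercept linear mixed model via profiled (RE)ML.

With a single subject-level random intercept the marginal covariance of a
subject's rows is sigma_e^2 (I + theta * J), theta = sigma_b^2 / sigma_e^2.
For fixed theta the GLS coefficients and the residual scale have closed
forms (Woodbury on the rank-one J block), so estimation reduces to a
bounded one-dimensional search over log(theta).  This keeps thousands of
fits (imputations x replicates x scenarios) cheap while agreeing with
general-purpose mixed-model software to optimizer precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

LOG_RATIO_BOUNDS = (-12.0, 8.0)
OPT_TOL = 1e-8


class LMMError(ValueError):
    """Degenerate design or data."""


@dataclass
class LMMFit:
    beta: np.ndarray
    beta_covariance: np.ndarray
    sigma_b2: float
    sigma_e2: float
    loglik: float  # REML or ML log-likelihood at the optimum
    converged: bool
    n_subjects: int
    n_rows: int
    reml: bool
    columns: list = field(default_factory=list)
    design_info: dict = field(default_factory=dict)


def _group_sums(X: np.ndarray, y: np.ndarray, starts: np.ndarray):
    Sx = np.add.reduceat(X, starts, axis=0)  # (G, p) per-group row sums
    Sy = np.add.reduceat(y, starts)
    return Sx, Sy


def _profiled_quantities(theta: float, X, y, Sx, Sy, n_g, reml: bool):
    """GLS beta, profiled scale and -2*(profile log-lik) at a variance ratio."""
    n, p = X.shape
    c = theta / (1.0 + theta * n_g)  # (G,)
    XtWX = X.T @ X - (Sx * c[:, None]).T @ Sx
    XtWy = X.T @ y - (Sx * c[:, None]).T @ Sy
    yTWy = y @ y - c @ (Sy**2)
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError as exc:
        raise LMMError("singular weighted design") from exc
    rss = max(yTWy - beta @ XtWy, 1e-300)
    dof = n - p if reml else n
    sigma2 = rss / dof
    logdet_v = np.log1p(theta * n_g).sum()
    neg2 = dof * np.log(sigma2) + logdet_v + dof * (1.0 + np.log(2.0 * np.pi))
    if reml:
        sign, logdet_xwx = np.linalg.slogdet(XtWX)
        if sign <= 0:
            raise LMMError("singular weighted design")
        neg2 += logdet_xwx
    return beta, sigma2, XtWX, neg2


def fit_random_intercept(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    reml: bool = True,
    columns: list | None = None,
) -> LMMFit:
    """Fit y = X beta + b_group + e with b ~ N(0, sigma_b^2)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    if len(y) != len(X) or len(y) != len(groups):
        raise LMMError("y, X and groups must have equal length")
    if len(y) <= X.shape[1]:
        raise LMMError("not enough rows to fit the model")
    zero_var = [
        (columns[j] if columns else f"col{j}")
        for j in range(X.shape[1])
        if np.ptp(X[:, j]) == 0 and not np.allclose(X[:, j], 1.0)
    ]
    if zero_var:
        raise LMMError(f"constant (non-identifiable) design columns: {zero_var}")

    order = np.argsort(groups, kind="stable")
    Xs, ys, gs = X[order], y[order], groups[order]
    starts = np.flatnonzero(np.r_[True, gs[1:] != gs[:-1]])
    n_g = np.diff(np.r_[starts, len(gs)]).astype(float)
    Sx, Sy = _group_sums(Xs, ys, starts)

    def objective(log_theta: float) -> float:
        return _profiled_quantities(np.exp(log_theta), Xs, ys, Sx, Sy, n_g, reml)[3]

    res = minimize_scalar(
        objective, bounds=LOG_RATIO_BOUNDS, method="bounded", options={"xatol": OPT_TOL}
    )
    theta = float(np.exp(res.x))
    neg2_interior = res.fun
    # the theta -> 0 boundary (independence) can beat any interior point
    beta0, s0, XtWX0, neg2_zero = _profiled_quantities(0.0, Xs, ys, Sx, Sy, n_g, reml)
    if neg2_zero <= neg2_interior:
        theta, neg2 = 0.0, neg2_zero
        beta, sigma2, XtWX = beta0, s0, XtWX0
    else:
        beta, sigma2, XtWX, neg2 = _profiled_quantities(theta, Xs, ys, Sx, Sy, n_g, reml)

    cov_beta = sigma2 * np.linalg.inv(XtWX)
    return LMMFit(
        beta=beta,
        beta_covariance=0.5 * (cov_beta + cov_beta.T),
        sigma_b2=theta * sigma2,
        sigma_e2=sigma2,
        loglik=-0.5 * neg2,
        converged=bool(res.success),
        n_subjects=len(starts),
        n_rows=len(ys),
        reml=reml,
        columns=list(columns) if columns else [],
    )


def reml_objective(fit: LMMFit, y, X, groups, theta: float) -> float:
    """-2 profile (RE)ML at an arbitrary variance ratio, for diagnostics."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    order = np.argsort(groups, kind="stable")
    Xs, ys, gs = X[order], y[order], groups[order]
    starts = np.flatnonzero(np.r_[True, gs[1:] != gs[:-1]])
    n_g = np.diff(np.r_[starts, len(gs)]).astype(float)
    Sx, Sy = _group_sums(Xs, ys, starts)
    return _profiled_quantities(theta, Xs, ys, Sx, Sy, n_g, fit.reml)[3]
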