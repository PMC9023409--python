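"""Multiple imputation by EM on bootstrapped samples (EMB).

The working model treats the columns of an imputation frame — outcomes with
missing values plus complete predictors — as jointly multivariate normal.
For each of M imputations a bootstrap resample of the rows is drawn, the
normal mean/covariance is estimated on it by the EM algorithm for
incomplete data, and the *original* frame's missing entries are then drawn
from the conditional normal of missing given observed under those bootstrap
parameters.  Parameter uncertainty thus enters through the bootstrap,
sampling noise through the conditional draws.

Two frames are supported:

* item level — the five ordinal items are the outcomes; continuous
  imputations are rounded to the nearest integer (ties to even) and clipped
  to 1..5, then the index is recomputed with the value set.  Treating
  ordinal items as normal is a deliberate, documented approximation: it is
  the standard joint-normal strategy, and its small rounding errors are the
  suspected source of index distortion under preference-based scoring.
* score level — the index score is the outcome; the items accompany it in
  the frame (they carry information and have their own missingness handled
  jointly) but only the score is written back, left continuous.

Time trends are represented by orthogonal-polynomial basis columns of the
timepoint code; with two timepoints the basis degenerates to a single
linear column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .amputation import AmputedData
from .datasets import ITEMS, item_mask
from .scoring import ValueSet, score_dataset

EM_TOL = 1e-6
EM_MAX_ITER = 500
RIDGE = 1e-8


class ImputationError(ValueError):
    """Invalid frame or failed estimation."""


# ---------------------------------------------------------------------------
# time basis


def build_time_basis(timepoints, degree: int = 3) -> pd.DataFrame:
    """Orthogonal polynomial basis of the time code.

    Degree is capped at T-1 (T distinct timepoints support at most a
    polynomial of that degree).  Columns are mutually orthogonal with unit
    norm over the grid and deterministic for a given grid.
    """
    if degree < 1:
        raise ImputationError("degree must be >= 1")
    t = np.unique(np.asarray(timepoints, dtype=float))
    deg = min(degree, len(t) - 1)
    if deg < 1:
        raise ImputationError("need at least two distinct timepoints")
    V = np.vander(t, deg + 1, increasing=True)
    Q, R = np.linalg.qr(V)
    Q = Q * np.sign(np.diag(R))[None, :]  # fix signs so leading coefs > 0
    cols = {f"tb{k}": Q[:, k] for k in range(1, deg + 1)}
    return pd.DataFrame(cols, index=t.astype(int))


# ---------------------------------------------------------------------------
# frames


@dataclass
class ImputationFrame:
    """Numeric matrix ready for the joint-normal machinery."""

    X: np.ndarray  # (n_rows, n_cols), NaN = missing
    columns: list
    outcome_columns: list  # columns whose missing entries get imputed
    row_index: pd.DataFrame  # subject_id, time per row


def _predictor_block(data: pd.DataFrame, time_degree: int) -> pd.DataFrame:
    """Complete predictors: age, dummy-coded covariates, srh, time basis."""
    block = pd.DataFrame(index=data.index)
    block["age"] = data["age"].astype(float)
    block["gender_female"] = (data["gender"] == "female").astype(float)
    for name in ("marital", "academic"):
        ref = data[name].mode().iloc[0]  # most frequent level is the reference
        for lev in sorted(data[name].unique()):
            if lev != ref:
                block[f"{name}_{lev}"] = (data[name] == lev).astype(float)
    block["srh"] = data["srh"].astype(float)
    basis = build_time_basis(data["time"].unique(), degree=time_degree)
    for c in basis.columns:
        block[c] = data["time"].map(basis[c]).astype(float)
    return block


def build_item_frame(data: pd.DataFrame, time_degree: int = 3) -> ImputationFrame:
    pred = _predictor_block(data, time_degree)
    X = pd.concat([data[list(ITEMS)].astype(float), pred], axis=1)
    return ImputationFrame(
        X.to_numpy(dtype=float), list(X.columns), list(ITEMS), data[["subject_id", "time"]].copy()
    )


def build_score_frame(data: pd.DataFrame, time_degree: int = 3) -> ImputationFrame:
    pred = _predictor_block(data, time_degree)
    X = pd.concat([data[["index"]].astype(float), data[list(ITEMS)].astype(float), pred], axis=1)
    return ImputationFrame(
        X.to_numpy(dtype=float),
        list(X.columns),
        ["index", *ITEMS],
        data[["subject_id", "time"]].copy(),
    )


# ---------------------------------------------------------------------------
# EM for the incomplete multivariate normal


@dataclass
class MultivariateNormalFit:
    mean: np.ndarray
    cov: np.ndarray
    n_iterations: int
    converged: bool
    loglik_trace: list = field(default_factory=list)


def _solve_psd(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve A X = B for symmetric PSD A, with jitter fallback for
    near-singular blocks (e.g. a score column almost determined by items)."""
    try:
        c = np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        c = np.linalg.cholesky(A + (RIDGE + 1e-10 * np.trace(A)) * np.eye(len(A)))
    y = np.linalg.solve(c, B)
    return np.linalg.solve(c.T, y)


def _logdet_psd(A: np.ndarray) -> float:
    try:
        c = np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        c = np.linalg.cholesky(A + (RIDGE + 1e-10 * np.trace(A)) * np.eye(len(A)))
    return 2.0 * np.log(np.diag(c)).sum()


def _patterns(miss: np.ndarray):
    """Group row indices by missingness pattern."""
    keys, inverse = np.unique(miss, axis=0, return_inverse=True)
    return [(keys[k].astype(bool), np.flatnonzero(inverse == k)) for k in range(len(keys))]


def em_mvn(
    X: np.ndarray, tol: float = EM_TOL, max_iter: int = EM_MAX_ITER
) -> MultivariateNormalFit:
    """ML mean/covariance of an incomplete matrix under joint normality.

    E-step: per missingness pattern, conditional moments of the missing
    block given the observed block; M-step: moment update.  The observed-
    data log-likelihood is tracked and is nondecreasing (an EM guarantee,
    asserted in the test suite).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not np.all(np.isfinite(X) | np.isnan(X)):
        raise ImputationError("frame contains non-finite values")
    miss = np.isnan(X)
    if miss.all(axis=0).any():
        bad = [int(j) for j in np.flatnonzero(miss.all(axis=0))]
        raise ImputationError(f"columns {bad} have no observed values")
    if n <= p:
        warnings.warn(f"n rows ({n}) <= n columns ({p}); EM estimates may be unstable")

    if not miss.any():
        mean = X.mean(axis=0)
        cov = np.cov(X, rowvar=False, ddof=0)
        ll = _observed_loglik(X, [(np.zeros(p, bool), np.arange(n))], mean, np.atleast_2d(cov))
        return MultivariateNormalFit(mean, np.atleast_2d(cov), 1, True, [ll])

    # init from available-case moments
    mean = np.nanmean(X, axis=0)
    var = np.nanvar(X, axis=0)
    cov = np.diag(np.where(var > 0, var, 1.0))

    groups = _patterns(miss)
    trace = []
    converged = False
    for it in range(1, max_iter + 1):
        S1 = np.zeros(p)
        S2 = np.zeros((p, p))
        ll = 0.0
        for m_idx, rows in groups:
            o_idx = ~m_idx
            Xo = X[np.ix_(rows, np.flatnonzero(o_idx))]
            k = len(rows)
            if not m_idx.any():
                S1 += Xo.sum(axis=0)
                S2 += Xo.T @ Xo
                ll += _pattern_loglik(Xo, mean[o_idx], cov[np.ix_(o_idx, o_idx)])
                continue
            oo = cov[np.ix_(o_idx, o_idx)]
            om = cov[np.ix_(o_idx, m_idx)]
            mm = cov[np.ix_(m_idx, m_idx)]
            A = _solve_psd(oo, om).T  # regression of missing on observed
            resid = Xo - mean[o_idx]
            Em = mean[m_idx] + resid @ A.T  # (k, n_missing)
            C = mm - A @ om  # conditional covariance
            full_mean = np.zeros((k, p))
            full_mean[:, o_idx] = Xo
            full_mean[:, m_idx] = Em
            S1 += full_mean.sum(axis=0)
            S2 += full_mean.T @ full_mean
            S2[np.ix_(m_idx, m_idx)] += k * C
            ll += _pattern_loglik(Xo, mean[o_idx], oo)
        new_mean = S1 / n
        new_cov = S2 / n - np.outer(new_mean, new_mean)
        new_cov = 0.5 * (new_cov + new_cov.T)
        trace.append(ll)
        delta = max(np.abs(new_mean - mean).max(), np.abs(new_cov - cov).max())
        mean, cov = new_mean, new_cov
        if delta < tol:
            converged = True
            break
    return MultivariateNormalFit(mean, cov, it, converged, trace)


def _pattern_loglik(Xo: np.ndarray, mu_o: np.ndarray, cov_oo: np.ndarray) -> float:
    if Xo.shape[1] == 0:
        return 0.0
    k, q = Xo.shape
    resid = Xo - mu_o
    sol = _solve_psd(cov_oo, resid.T)
    quad = np.einsum("ij,ji->", resid, sol)
    return -0.5 * (k * (q * np.log(2 * np.pi) + _logdet_psd(cov_oo)) + quad)


def _observed_loglik(X, groups, mean, cov) -> float:
    ll = 0.0
    for m_idx, rows in groups:
        o_idx = ~m_idx
        ll += _pattern_loglik(X[np.ix_(rows, np.flatnonzero(o_idx))], mean[o_idx], cov[np.ix_(o_idx, o_idx)])
    return ll


def emb_draws(X: np.ndarray, M: int, seed: int = 0, max_retries: int = 10):
    """M (mean, covariance) draws: EM on M bootstrap resamples of the rows."""
    if M < 2:
        raise ImputationError("M must be >= 2")
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    fits = []
    for b in range(M):
        rng = substream(seed, b)
        fit = None
        for _ in range(max_retries):
            idx = rng.integers(0, n, size=n)
            Xb = X[idx]
            if np.isnan(Xb).all(axis=0).any():
                continue  # redraw: bootstrap lost every observation of a column
            fit = em_mvn(Xb)
            break
        if fit is None:
            raise ImputationError(f"bootstrap {b}: could not draw a sample with all columns observed")
        fits.append(fit)
    return fits


def impute_from_draw(
    X: np.ndarray, fit: MultivariateNormalFit, rng: np.random.Generator
) -> np.ndarray:
    """Fill missing entries with draws from the conditional normal under
    ``fit``; observed entries are returned unchanged."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(fit.mean):
        raise ImputationError("fit dimension does not match frame")
    out = X.copy()
    miss = np.isnan(X)
    mean, cov = fit.mean, fit.cov
    for m_idx, rows in _patterns(miss):
        if not m_idx.any():
            continue
        o_idx = ~m_idx
        oo = cov[np.ix_(o_idx, o_idx)]
        om = cov[np.ix_(o_idx, m_idx)]
        mm = cov[np.ix_(m_idx, m_idx)]
        if o_idx.any():
            A = _solve_psd(oo, om).T
            Em = mean[m_idx] + (X[np.ix_(rows, np.flatnonzero(o_idx))] - mean[o_idx]) @ A.T
            C = mm - A @ om
        else:
            Em = np.tile(mean[m_idx], (len(rows), 1))
            C = mm
        C = 0.5 * (C + C.T)
        try:
            L = np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            warnings.warn("singular conditional covariance; ridge-stabilized draw")
            L = np.linalg.cholesky(C + (RIDGE + 1e-10 * abs(np.trace(C))) * np.eye(len(C)))
        z = rng.standard_normal((len(rows), int(m_idx.sum())))
        out[np.ix_(rows, np.flatnonzero(m_idx))] = Em + z @ L.T
    return out


# ---------------------------------------------------------------------------
# item- and score-level MI


@dataclass
class ImputationSet:
    """M completed datasets plus bookkeeping."""

    datasets: list
    level: str  # "item" or "score"
    M: int
    seed: int
    converged: list = field(default_factory=list)


def _as_dataframe(data) -> pd.DataFrame:
    return data.data if isinstance(data, AmputedData) else data


def mi_items(data, M: int, seed: int, vs: ValueSet, time_degree: int = 3) -> ImputationSet:
    """Item-level MI: impute the five items jointly, round/clip, rescore."""
    df = _as_dataframe(data)
    if not item_mask(df).all(axis=None):
        frame = build_item_frame(df, time_degree)
        fits = emb_draws(frame.X, M, seed=seed)
        completed = []
        for b, fit in enumerate(fits):
            rng = substream(seed, b, 1)
            Xc = impute_from_draw(frame.X, fit, rng)
            items = Xc[:, : len(ITEMS)]
            items = np.clip(np.rint(items), 1, 5)  # nearest integer, ties to even
            out = df.copy()
            out[list(ITEMS)] = items
            completed.append(score_dataset(out, vs))
        return ImputationSet(completed, "item", M, seed, [f.converged for f in fits])
    # nothing to impute: all copies identical to the (scored) input
    scored = score_dataset(df, vs)
    return ImputationSet([scored.copy() for _ in range(M)], "item", M, seed, [True] * M)


def mi_scores(data, M: int, seed: int, vs: ValueSet, time_degree: int = 3) -> ImputationSet:
    """Score-level MI: impute the index (continuous), items ride along as
    jointly-modelled predictors but are not written back."""
    df = score_dataset(_as_dataframe(data), vs)
    if df["index"].isna().any():
        frame = build_score_frame(df, time_degree)
        fits = emb_draws(frame.X, M, seed=seed)
        completed = []
        for b, fit in enumerate(fits):
            rng = substream(seed, b, 1)
            Xc = impute_from_draw(frame.X, fit, rng)
            out = df.copy()
            out["index"] = Xc[:, 0]
            completed.append(out)
        return ImputationSet(completed, "score", M, seed, [f.converged for f in fits])
    return ImputationSet([df.copy() for _ in range(M)], "score", M, seed, [True] * M)
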