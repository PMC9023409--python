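"""The four analysis approaches and their shared mixed model.

All approaches fit the same random-intercept model of the index score —
fixed effects for time (categorical, baseline reference), age, gender,
academic status and the single self-rated health item, plus a subject
random intercept — and differ only in what data reach the model:

1. complete cases: only subjects with all items observed at every timepoint;
2. all available data: every scored row (mixed models tolerate unbalanced
   panels, so partially observed subjects contribute their observed rows);
3. MI of the index score, model fitted per imputation, Rubin-pooled;
4. MI of the items, scores recomputed, fitted per imputation, Rubin-pooled.

Marital status is deliberately absent from the model's fixed effects even
though it participates in the amputation mechanism and the imputation
models; the asymmetry mirrors the analysis design this framework recreates.

"Predicted mean" is a marginally standardized quantity: the fixed-effect
prediction averaged over a reference sample of covariates with time set to
each timepoint in turn.  By default each approach standardizes over its own
analysis sample (the subjects contributing scored rows to that fit) — this
is what lets health-selected dropout pass through to a complete-case
estimate, since the CC sample's covariate distribution is shifted toward
healthier subjects.  Pass ``reference=`` explicitly to standardize all
approaches over one common covariate distribution instead.  The SE is
x_bar' V(beta) x_bar on the averaged design row (Rubin total variance for
the MI approaches).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .amputation import AmputedData
from .datasets import item_mask
from .imputation import ImputationSet, mi_items, mi_scores
from .lmm import LMMError, LMMFit, fit_random_intercept
from .pooling import rubin_pool
from .scoring import ValueSet, score_dataset

MODEL_COVARIATES = ("age", "gender", "academic", "srh")


@dataclass
class ModelSpec:
    """Fixed-effect specification of the mixed model."""

    covariates: tuple = MODEL_COVARIATES
    reml: bool = True


@dataclass
class PredictedMeans:
    """Per-timepoint standardized predicted mean index and SE."""

    table: pd.DataFrame  # columns: time, mean, se
    reference_size: int

    def mean_at(self, t: int) -> float:
        return float(self.table.set_index("time").loc[t, "mean"])

    def se_at(self, t: int) -> float:
        return float(self.table.set_index("time").loc[t, "se"])


@dataclass
class ApproachResult:
    approach: str
    means: pd.DataFrame  # time, mean, se
    beta_time: float
    beta_time_se: float
    n_subjects: int
    n_rows: int
    m: int | None = None
    fits: list = field(default_factory=list, repr=False)


def build_design(
    data: pd.DataFrame, spec: ModelSpec, design_info: dict | None = None
) -> tuple[np.ndarray, list, dict]:
    """Fixed-effects design matrix; returns (X, column names, design info).

    ``design_info`` (levels and references recorded at fit time) makes the
    prediction design use exactly the fit's columns; a level unseen at fit
    time raises.
    """
    if design_info is None:
        design_info = {
            "times": sorted(int(t) for t in data["time"].unique()),
            "academic_levels": sorted(data["academic"].unique()),
            "academic_ref": data["academic"].mode().iloc[0],
        }
    else:
        new_ac = set(data["academic"].unique()) - set(design_info["academic_levels"])
        new_t = set(int(t) for t in data["time"].unique()) - set(design_info["times"])
        if new_ac or new_t:
            raise LMMError(f"levels absent from the fitted design: {sorted(new_ac) + sorted(new_t)}")
    cols = {"const": np.ones(len(data))}
    for t in design_info["times"][1:]:
        cols[f"time_{t}"] = (data["time"] == t).astype(float).to_numpy()
    if "age" in spec.covariates:
        cols["age"] = data["age"].to_numpy(dtype=float)
    if "gender" in spec.covariates:
        cols["gender_female"] = (data["gender"] == "female").astype(float).to_numpy()
    if "academic" in spec.covariates:
        for lev in design_info["academic_levels"]:
            if lev != design_info["academic_ref"]:
                cols[f"academic_{lev}"] = (data["academic"] == lev).astype(float).to_numpy()
    if "srh" in spec.covariates:
        cols["srh"] = data["srh"].to_numpy(dtype=float)
    X = np.column_stack(list(cols.values()))
    return X, list(cols.keys()), design_info


def fit_lmm(data: pd.DataFrame, spec: ModelSpec | None = None) -> LMMFit:
    """Fit the random-intercept model on all scored rows of ``data``.

    Rows with a missing index (non-scorable) or missing model covariates
    are dropped listwise within the model.
    """
    spec = spec or ModelSpec()
    needed = ["index", "time", "subject_id", *[c for c in spec.covariates]]
    rows = data.dropna(subset=[c for c in needed if c in data.columns])
    if rows["subject_id"].nunique() < 2:
        raise LMMError("need at least two subjects with scored rows")
    X, columns, design_info = build_design(rows, spec)
    fit = fit_random_intercept(
        rows["index"].to_numpy(dtype=float),
        X,
        rows["subject_id"].to_numpy(),
        reml=spec.reml,
        columns=columns,
    )
    fit.design_info = design_info
    return fit


def beta_time_of(fit: LMMFit) -> tuple[float, float]:
    """Per-unit-time slope: coefficient of the last time dummy divided by its
    time code (equals the time coefficient itself with two timepoints)."""
    times = fit.design_info["times"]
    last = times[-1]
    j = fit.columns.index(f"time_{last}")
    scale = float(last - times[0])
    return float(fit.beta[j]) / scale, float(np.sqrt(fit.beta_covariance[j, j])) / scale


def predict_means(
    fit: LMMFit, reference: pd.DataFrame, timepoints=None, spec: ModelSpec | None = None
) -> PredictedMeans:
    """Marginally standardized predicted means over the reference sample."""
    spec = spec or ModelSpec()
    timepoints = list(timepoints) if timepoints is not None else fit.design_info["times"]
    ref = reference.dropna(subset=[c for c in spec.covariates if c in reference.columns]).copy()
    if len(ref) == 0:
        raise LMMError("empty reference sample")
    rows = []
    for t in timepoints:
        at_t = ref.copy()
        at_t["time"] = t
        X, cols, _ = build_design(at_t, spec, design_info=fit.design_info)
        if cols != fit.columns:
            raise LMMError("prediction design does not match the fit")
        xbar = X.mean(axis=0)
        mean = float(xbar @ fit.beta)
        se = float(np.sqrt(xbar @ fit.beta_covariance @ xbar))
        rows.append({"time": t, "mean": mean, "se": se})
    return PredictedMeans(pd.DataFrame(rows), len(ref))


# ---------------------------------------------------------------------------
# approaches


def _as_df(amputed) -> pd.DataFrame:
    return amputed.data if isinstance(amputed, AmputedData) else amputed


def _single_fit_result(
    name: str, data: pd.DataFrame, vs: ValueSet, spec: ModelSpec,
    reference: pd.DataFrame | None,
) -> ApproachResult:
    scored = score_dataset(data, vs)
    fit = fit_lmm(scored, spec)
    if reference is None:
        # own analysis sample: subjects contributing at least one scored row
        used = scored.dropna(subset=["index"])["subject_id"].unique()
        reference = _baseline_reference(scored[scored["subject_id"].isin(used)])
    pm = predict_means(fit, reference, spec=spec)
    bt, bt_se = beta_time_of(fit)
    return ApproachResult(name, pm.table, bt, bt_se, fit.n_subjects, fit.n_rows, fits=[fit])


def run_approach_1_cc(
    amputed, vs: ValueSet, spec: ModelSpec | None = None, reference: pd.DataFrame | None = None
) -> ApproachResult:
    """Mixed model on subjects who completed every item at every timepoint."""
    spec = spec or ModelSpec()
    df = _as_df(amputed)
    ok = item_mask(df).all(axis=1).groupby(df["subject_id"]).transform("all")
    cc = df[ok.to_numpy()]
    if cc["subject_id"].nunique() == 0:
        raise LMMError("no complete cases")
    return _single_fit_result("cc", cc, vs, spec, reference)


def run_approach_2_available(
    amputed, vs: ValueSet, spec: ModelSpec | None = None, reference: pd.DataFrame | None = None
) -> ApproachResult:
    """Mixed model on every scorable row (no imputation)."""
    spec = spec or ModelSpec()
    df = _as_df(amputed)
    return _single_fit_result("available", df, vs, spec, reference)


def _pooled_result(
    name: str, imp: ImputationSet, spec: ModelSpec, reference: pd.DataFrame
) -> ApproachResult:
    per_time: dict = {}
    betas, beta_vars = [], []
    n_subj = n_rows = 0
    for completed in imp.datasets:
        fit = fit_lmm(completed, spec)
        pm = predict_means(fit, reference, spec=spec)
        for r in pm.table.itertuples():
            per_time.setdefault(int(r.time), ([], []))
            per_time[int(r.time)][0].append(r.mean)
            per_time[int(r.time)][1].append(r.se**2)
        bt, bt_se = beta_time_of(fit)
        betas.append(bt)
        beta_vars.append(bt_se**2)
        n_subj, n_rows = fit.n_subjects, fit.n_rows
    rows = []
    for t in sorted(per_time):
        pooled = rubin_pool(per_time[t][0], per_time[t][1])
        rows.append({"time": t, "mean": pooled.point, "se": np.sqrt(pooled.total)})
    bpool = rubin_pool(betas, beta_vars)
    return ApproachResult(
        name, pd.DataFrame(rows), bpool.point, float(np.sqrt(bpool.total)), n_subj, n_rows, m=imp.M
    )


def run_approach_3_mi_score(
    amputed, vs: ValueSet, spec: ModelSpec | None = None, M: int = 100,
    seed: int = 0, reference: pd.DataFrame | None = None,
) -> ApproachResult:
    """Mixed model after MI of the index scores, Rubin-pooled."""
    spec = spec or ModelSpec()
    df = _as_df(amputed)
    # MI restores every subject, so the analysis sample is the full cohort
    reference = reference if reference is not None else _baseline_reference(df)
    imp = mi_scores(amputed, M, seed, vs)
    return _pooled_result("mi_score", imp, spec, reference)


def run_approach_4_mi_item(
    amputed, vs: ValueSet, spec: ModelSpec | None = None, M: int = 100,
    seed: int = 0, reference: pd.DataFrame | None = None,
    return_imputations: bool = False,
):
    """Mixed model after MI of the items (rescored), Rubin-pooled."""
    spec = spec or ModelSpec()
    df = _as_df(amputed)
    reference = reference if reference is not None else _baseline_reference(df)
    imp = mi_items(amputed, M, seed, vs)
    result = _pooled_result("mi_item", imp, spec, reference)
    return (result, imp) if return_imputations else result


def _baseline_reference(df: pd.DataFrame) -> pd.DataFrame:
    from .datasets import covariate_table

    return covariate_table(df)
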