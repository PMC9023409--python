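"""Aggregation of approach results into simulation performance surfaces.

Truth is operationalized as the available-data mixed-model trajectory on
the pre-amputation (complete) dataset — estimator and estimand then live on
the same scale.  Per scenario the module produces: mean predicted-mean
trajectories per approach, mean model SEs, the empirical SD of estimates
across replicates, MSE against truth (headlined at the last timepoint), a
qualitative ordering check, and the item-misspecification table for MI by
items (difference true - imputed over originally amputed cells, as
percentages per item over all imputations and replicates).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datasets import ITEMS, item_mask
from .imputation import ImputationSet
from .modeling import ModelSpec, PredictedMeans, beta_time_of, fit_lmm, predict_means
from .scoring import ValueSet, score_dataset

DIFF_RANGE = tuple(range(-4, 5))


class EvaluationError(ValueError):
    """Inconsistent evaluation inputs."""


def truth_reference(
    complete_data: pd.DataFrame,
    vs: ValueSet,
    spec: ModelSpec | None = None,
    reference: pd.DataFrame | None = None,
) -> tuple[PredictedMeans, float]:
    """Truth trajectory and true time slope from the complete dataset."""
    spec = spec or ModelSpec()
    scored = score_dataset(complete_data, vs)
    fit = fit_lmm(scored, spec)
    if reference is None:
        from .datasets import covariate_table

        reference = covariate_table(scored)
    pm = predict_means(fit, reference, spec=spec)
    bt, _ = beta_time_of(fit)
    return pm, bt


def compute_mse(estimates_over_replicates, truth) -> np.ndarray:
    """Mean over replicates of (estimate - truth)^2, per timepoint.

    ``estimates_over_replicates`` is (n_replicates, n_timepoints); ``truth``
    is a length-n_timepoints vector (or per-replicate matrix of the same
    shape when the complete cohort is redrawn each replicate).
    """
    est = np.atleast_2d(np.asarray(estimates_over_replicates, dtype=float))
    tr = np.asarray(truth, dtype=float)
    if tr.ndim == 1 and est.shape[1] != len(tr):
        raise EvaluationError("estimates and truth have different numbers of timepoints")
    if tr.ndim == 2 and est.shape != tr.shape:
        raise EvaluationError("per-replicate truth must match the estimates' shape")
    return ((est - tr) ** 2).mean(axis=0)


def misspecification_table(
    true_data: pd.DataFrame, amputed_data: pd.DataFrame, imputation_set: ImputationSet
) -> pd.DataFrame:
    """Percentage of imputed item cells at each difference true - imputed.

    Counts only cells that were originally amputed (observed in
    ``true_data``, missing in ``amputed_data``), over all M imputations.
    Rows are items, columns the differences -4..4; each row sums to 100.
    """
    counts = misspecification_counts(true_data, amputed_data, imputation_set)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise EvaluationError("no amputed cells for some item; cannot tabulate")
    return 100.0 * counts.div(totals, axis=0)


def misspecification_counts(
    true_data: pd.DataFrame, amputed_data: pd.DataFrame, imputation_set: ImputationSet
) -> pd.DataFrame:
    """Raw difference counts behind :func:`misspecification_table` (summable
    across replicates)."""
    if imputation_set.level != "item":
        raise EvaluationError("misspecification table requires item-level imputations")
    true_items = true_data[list(ITEMS)].to_numpy(dtype=float)
    blanked = item_mask(true_data).to_numpy() & ~item_mask(amputed_data).to_numpy()
    counts = pd.DataFrame(0, index=list(ITEMS), columns=list(DIFF_RANGE))
    for completed in imputation_set.datasets:
        imp_items = completed[list(ITEMS)].to_numpy(dtype=float)
        for j, item in enumerate(ITEMS):
            sel = blanked[:, j]
            if not sel.any():
                continue
            diffs = (true_items[sel, j] - imp_items[sel, j]).astype(int)
            vals, cnt = np.unique(diffs, return_counts=True)
            for v, c in zip(vals, cnt):
                counts.loc[item, int(v)] += int(c)
    return counts


def ordering_check(summary: pd.DataFrame, tol: float = 0.005) -> dict:
    """Qualitative flags at the follow-up (last) timepoint.

    ``summary`` needs columns approach, time, mean with the four approaches
    present.  Returns flags: cc_highest, mi_item_lowest, mm_mi_score_close
    (approaches 2 and 3 within ``tol`` index points), and no_ordering when
    all four tie within ``tol``.
    """
    needed = {"cc", "available", "mi_score", "mi_item"}
    have = set(summary["approach"].unique())
    if not needed <= have:
        raise EvaluationError(f"missing approaches: {sorted(needed - have)}")
    t_last = summary["time"].max()
    at_last = summary[summary["time"] == t_last].set_index("approach")["mean"]
    spread = float(at_last.max() - at_last.min())
    return {
        "cc_highest": bool(at_last.idxmax() == "cc") and spread > tol,
        "mi_item_lowest": bool(at_last.idxmin() == "mi_item") and spread > tol,
        "mm_mi_score_close": bool(abs(at_last["available"] - at_last["mi_score"]) <= tol),
        "no_ordering": bool(spread <= tol),
    }
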