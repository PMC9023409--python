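"""Multivariate amputation: MAR missingness imposed on complete data.

The module deletes item responses from a complete longitudinal dataset so
that the probability of being amputed depends only on fully observed
auxiliary variables (age, gender, marital status, academic status, SRH) —
a missing-at-random mechanism.  The machinery follows the multivariate
amputation idea: each subject is assigned a candidate missingness pattern,
a weighted sum score of standardized auxiliaries is computed, and within
each pattern group subjects are amputed with a right-tailed (shifted)
logistic probability of their score, calibrated so the expected overall
amputed share equals the target.

The "GR schedule" reproduces the design of a rehabilitation-study
simulation: overall missingness levels 5-65% of subjects, decomposed into
at most 5 percentage points of unit non-response (UNR: all five items of a
timepoint blanked) at baseline, at most 7.5 points of item non-response
(INR: single items blanked), and the remainder UNR at follow-up, so the UNR
total peaks at 57.5 points under 65% overall missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from ._rng import substream
from .datasets import ITEMS, covariate_table, item_mask

GR_LEVELS = (5, 10, 15, 25, 35, 45, 55, 65)
UNR_T0_CAP_PP = 5.0
INR_CAP_PP = 7.5

#: Illustrative MAR weights: older subjects drop out less (negative age
#: weight), poorer self-rated health drops out more; category weights are
#: smaller nudges.  All configurable.
DEFAULT_MAR_WEIGHTS = {"age": -1.0, "gender": 0.5, "marital": 0.5, "academic": -0.5, "srh": 1.0}
MCAR_WEIGHTS = {k: 0.0 for k in DEFAULT_MAR_WEIGHTS}


class AmputationError(ValueError):
    """Invalid schedule or data for amputation."""


@dataclass(frozen=True)
class MissingnessPattern:
    """Cells ``(timepoint, item)`` blanked when the pattern fires."""

    cells: tuple
    relative_frequency: float

    def __post_init__(self) -> None:
        if not self.cells:
            raise AmputationError("pattern must blank at least one cell")
        if self.relative_frequency < 0:
            raise AmputationError("pattern frequency must be nonnegative")

    @property
    def kind(self) -> str:
        """UNR if all five items of some timepoint are blanked, else INR."""
        by_time: dict = {}
        for t, item in self.cells:
            by_time.setdefault(t, set()).add(item)
        return "UNR" if any(items >= set(ITEMS) for items in by_time.values()) else "INR"

    @property
    def timepoints(self) -> tuple:
        return tuple(sorted({t for t, _ in self.cells}))


@dataclass
class AmputationSchedule:
    """Target overall amputed share, patterns, and MAR weights.

    ``target_overall`` is a proportion of *subjects* (the pattern
    frequencies quoted in percentage points of subjects are additive under
    this denominator).
    """

    target_overall: float
    patterns: list = field(default_factory=list)
    weights: dict = field(default_factory=lambda: dict(DEFAULT_MAR_WEIGHTS))
    allocation: str = "right"

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_overall <= 1.0:
            raise AmputationError("target_overall must be in [0, 1]")
        if self.target_overall > 0 and not self.patterns:
            raise AmputationError("need at least one pattern when target_overall > 0")
        if self.patterns:
            total = sum(p.relative_frequency for p in self.patterns)
            if not np.isclose(total, 1.0):
                raise AmputationError(f"pattern frequencies must sum to 1, got {total}")
        if self.allocation != "right":
            raise AmputationError(f"allocation {self.allocation!r} not implemented (only 'right')")


@dataclass
class AmputedData:
    """Amputation output: data with updated mask plus provenance."""

    data: pd.DataFrame
    provenance: pd.DataFrame  # subject_id, pattern_id (or -1), kind
    schedule: AmputationSchedule
    realized: dict


def build_gr_schedule(
    level_pct: float,
    weights: dict | None = None,
    follow_up_time: int = 1,
) -> AmputationSchedule:
    """GR-design schedule for one of the eight configured levels.

    The overall level (percentage points of subjects) is decomposed as
    baseline UNR = min(5, level), INR = min(7.5, remainder) split uniformly
    over single-item patterns at follow-up, remainder UNR at follow-up.
    """
    if level_pct not in GR_LEVELS:
        raise AmputationError(f"level must be one of {GR_LEVELS}, got {level_pct}; use generic_schedule for others")
    return generic_schedule(level_pct, weights=weights, follow_up_time=follow_up_time)


def generic_schedule(
    level_pct: float,
    weights: dict | None = None,
    follow_up_time: int = 1,
    unr_t0_cap_pp: float = UNR_T0_CAP_PP,
    inr_cap_pp: float = INR_CAP_PP,
) -> AmputationSchedule:
    """Same decomposition as the GR schedule but for any level in [0, 100]."""
    if not 0.0 <= level_pct <= 100.0:
        raise AmputationError(f"level must be in [0, 100], got {level_pct}")
    weights = dict(DEFAULT_MAR_WEIGHTS) if weights is None else dict(weights)
    if level_pct == 0:
        return AmputationSchedule(0.0, [], weights)
    unr_t0 = min(unr_t0_cap_pp, level_pct)
    inr = min(inr_cap_pp, level_pct - unr_t0)
    unr_t1 = level_pct - unr_t0 - inr

    patterns = []
    if unr_t0 > 0:
        patterns.append(
            MissingnessPattern(tuple((0, item) for item in ITEMS), unr_t0 / level_pct)
        )
    if inr > 0:
        for item in ITEMS:
            patterns.append(
                MissingnessPattern(((follow_up_time, item),), inr / level_pct / len(ITEMS))
            )
    if unr_t1 > 0:
        patterns.append(
            MissingnessPattern(tuple((follow_up_time, item) for item in ITEMS), unr_t1 / level_pct)
        )
    return AmputationSchedule(level_pct / 100.0, patterns, weights)


_CATEGORY_CODES = {
    "gender": {"male": 0.0, "female": 1.0},
    "marital": {"never_married": 0.0, "married": 1.0, "separated": 2.0, "widowed": 3.0},
    "academic": {"no_schooling": 0.0, "grade_school": 1.0, "high_school": 2.0, "college": 3.0},
}


def weighted_sum_scores(covariates: pd.DataFrame, weights: dict) -> pd.Series:
    """Per-subject dot product of standardized auxiliary codes and weights.

    Categorical auxiliaries are numerically coded; every auxiliary is
    standardized to zero mean and unit variance (population SD) over the
    table before weighting.  Missing auxiliary values are an error: the
    mechanism assumes complete covariates.
    """
    cov = covariates.set_index("subject_id") if "subject_id" in covariates.columns else covariates
    if cov[["age", "gender", "marital", "academic", "srh"]].isna().any().any():
        raise AmputationError("auxiliary variables must be complete")
    score = pd.Series(0.0, index=cov.index)
    for name, w in weights.items():
        if w == 0:
            continue
        col = cov[name]
        if name in _CATEGORY_CODES:
            col = col.map(_CATEGORY_CODES[name])
        col = col.astype(float)
        sd = col.std(ddof=0)
        z = (col - col.mean()) / sd if sd > 0 else col * 0.0
        score = score + w * z
    return score


def allocate_missingness(
    scores,
    target_proportion: float,
    allocation: str = "right",
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Bernoulli amputation indicators with right-tailed logistic probabilities.

    Probabilities are ``expit(z_i + shift)`` of the standardized scores, the
    shift solved by bisection so the mean probability equals the target;
    higher scores therefore get higher missingness probability.  Ties
    (equal scores) receive identical probabilities.
    """
    if allocation != "right":
        raise AmputationError("only right-tailed allocation is implemented")
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise AmputationError("scores must be finite")
    if not 0.0 <= target_proportion <= 1.0:
        raise AmputationError("target proportion must be in [0, 1]")
    n = len(scores)
    if rng is None:
        rng = np.random.default_rng(seed)
    if target_proportion == 0.0 or n == 0:
        return np.zeros(n, dtype=bool)
    if target_proportion == 1.0:
        return np.ones(n, dtype=bool)
    probs = missingness_probabilities(scores, target_proportion)
    return rng.random(n) < probs


def missingness_probabilities(scores, target_proportion: float) -> np.ndarray:
    """The calibrated per-case probabilities behind :func:`allocate_missingness`."""
    scores = np.asarray(scores, dtype=float)
    sd = scores.std()
    if sd == 0:
        return np.full(len(scores), target_proportion)
    z = (scores - scores.mean()) / sd
    shift = brentq(lambda s: expit(z + s).mean() - target_proportion, -60.0, 60.0)
    return expit(z + shift)


def ampute(data: pd.DataFrame, schedule: AmputationSchedule, seed: int = 0) -> AmputedData:
    """Apply the schedule: assign patterns, draw amputation, blank cells.

    Only item cells named by the fired pattern are blanked (and the index of
    the affected rows, which becomes non-scorable); covariates and all other
    observed values are untouched.
    """
    times = set(data["time"].unique())
    for p in schedule.patterns:
        missing_t = set(p.timepoints) - times
        if missing_t:
            raise AmputationError(f"pattern references timepoints {sorted(missing_t)} absent from data")

    out = data.copy()
    cov = covariate_table(data)
    subjects = cov["subject_id"].to_numpy()
    n = len(subjects)
    prov = pd.DataFrame({"subject_id": subjects, "pattern_id": -1, "kind": "none"})

    if schedule.target_overall > 0 and schedule.patterns:
        rng = substream(seed, 0)
        freqs = np.array([p.relative_frequency for p in schedule.patterns])
        assignment = rng.choice(len(schedule.patterns), size=n, p=freqs / freqs.sum())
        scores = weighted_sum_scores(cov, schedule.weights).to_numpy()
        fired = np.zeros(n, dtype=bool)
        for k in range(len(schedule.patterns)):
            grp = np.flatnonzero(assignment == k)
            if len(grp) == 0:
                continue
            ind = allocate_missingness(
                scores[grp], schedule.target_overall, schedule.allocation, rng=rng
            )
            fired[grp[ind]] = True
        for k, pattern in enumerate(schedule.patterns):
            hit = subjects[fired & (assignment == k)]
            if len(hit) == 0:
                continue
            prov.loc[prov["subject_id"].isin(hit), ["pattern_id", "kind"]] = [k, pattern.kind]
            for t, item in pattern.cells:
                out.loc[out["subject_id"].isin(hit) & (out["time"] == t), item] = np.nan
        incomplete = ~item_mask(out).all(axis=1)
        out.loc[incomplete, "index"] = np.nan

    return AmputedData(out, prov, schedule, realized_proportions(out))


def realized_proportions(data: pd.DataFrame) -> dict:
    """Overall / UNR / INR / per-timepoint-UNR shares of subjects, recomputed
    from the missingness mask (in percent)."""
    mask = item_mask(data)
    any_missing_row = ~mask.all(axis=1)
    all_missing_row = ~mask.any(axis=1)
    by_subject_any = any_missing_row.groupby(data["subject_id"]).any()
    by_subject_unr = all_missing_row.groupby(data["subject_id"]).any()
    n = by_subject_any.index.size
    out = {
        "overall": 100.0 * by_subject_any.mean(),
        "unr": 100.0 * by_subject_unr.mean(),
        "inr": 100.0 * (by_subject_any & ~by_subject_unr).mean(),
    }
    for t in np.sort(data["time"].unique()):
        at_t = all_missing_row[data["time"] == t].groupby(data.loc[data["time"] == t, "subject_id"]).any()
        out[f"unr_t{t}"] = 100.0 * at_t.sum() / n
    return out
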