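"""Synthetic longitudinal EQ-5D-5L cohorts.

Real EQ-5D microdata (rehabilitation and diabetes cohorts of the kind this
framework targets) are not redistributable, so the generator produces
complete cohorts with the statistical structure the downstream analysis
assumes:

* baseline covariates age, gender, marital status (4 levels), academic
  status (4 levels) and a single self-rated health item (SRH, 1-5);
* five ordinal items on levels 1-5 at 2-3 timepoints, produced by a graded
  latent-Gaussian threshold model: a latent "health impairment" propensity
  per (subject, timepoint, item) is the sum of covariate effects, a
  per-timepoint shift (the time trend; negative = improvement), a shared
  subject random intercept and an item-level residual, cut at four ordered
  thresholds;
* covariates are always complete — missingness is introduced only later by
  the amputation module, mirroring a simulation design in which only the
  outcome is amputed.

Two presets are shipped: a "GR-like" inpatient-rehabilitation cohort
(n=450, 2 timepoints, improving) and an "ABCD-like" chronic-disease cohort
(n=2040, 3 timepoints, slowly deteriorating).  Their moments are matched
loosely to published baseline tables of such studies; the item-level joint
distribution is illustrative, not an estimate of any real dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from ._rng import substream
from .datasets import (
    ACADEMIC_LEVELS,
    COVARIATES,
    GENDER_LEVELS,
    ITEMS,
    MARITAL_LEVELS,
)


class CohortConfigError(ValueError):
    """Invalid cohort configuration."""


@dataclass
class CohortConfig:
    """Parameters of the latent-threshold cohort generator.

    ``latent_loadings`` are per-covariate coefficients on the standardized
    covariate codes; positive loadings push the latent impairment up (worse
    health).  ``time_effect`` is one latent shift per timepoint (first entry
    conventionally 0); negative shifts mean improvement.  ``thresholds`` are
    the four ordered cutpoints shared by all items.
    """

    n_subjects: int = 450
    n_timepoints: int = 2
    age_mean: float = 53.13
    age_sd: float = 10.43
    category_probabilities: dict = field(
        default_factory=lambda: {
            "gender": (0.333, 0.667),
            "marital": (0.131, 0.678, 0.142, 0.049),
            "academic": (0.151, 0.542, 0.249, 0.058),
            "srh": (0.0, 0.06, 0.416, 0.444, 0.08),
        }
    )
    latent_loadings: dict = field(
        default_factory=lambda: {
            "age": 0.10,
            "gender": 0.0,
            "marital": 0.0,
            "academic": -0.10,
            "srh": 0.55,
        }
    )
    time_effect: tuple = (0.0, -0.25)
    random_intercept_sd: float = 0.80
    residual_sd: float = 0.90
    thresholds: tuple = (-0.35, 0.65, 1.55, 2.40)
    seed: int = 0

    def validate(self) -> None:
        if self.n_timepoints not in (2, 3):
            raise CohortConfigError(f"n_timepoints must be 2 or 3, got {self.n_timepoints}")
        if len(self.time_effect) != self.n_timepoints:
            raise CohortConfigError("time_effect must have one entry per timepoint")
        th = np.asarray(self.thresholds, dtype=float)
        if len(th) != 4 or not np.all(np.diff(th) > 0):
            raise CohortConfigError("thresholds must be 4 strictly increasing cutpoints")
        if self.random_intercept_sd < 0 or self.residual_sd < 0 or self.age_sd < 0:
            raise CohortConfigError("standard deviations must be nonnegative")
        for name, probs in self.category_probabilities.items():
            p = np.asarray(probs, dtype=float)
            if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
                raise CohortConfigError(f"category probabilities for {name} must be a distribution")


def gr_like(seed: int = 0, n_subjects: int = 450) -> CohortConfig:
    """Inpatient-rehabilitation-like preset: 2 timepoints, improvement."""
    return CohortConfig(n_subjects=n_subjects, seed=seed)


def abcd_like(seed: int = 0, n_subjects: int = 2040) -> CohortConfig:
    """Chronic-disease-cohort-like preset: 3 timepoints, slow deterioration."""
    return CohortConfig(
        n_subjects=n_subjects,
        n_timepoints=3,
        age_mean=63.07,
        age_sd=13.41,
        category_probabilities={
            "gender": (0.548, 0.452),
            "marital": (0.725, 0.063, 0.114, 0.098),
            "academic": (0.005, 0.131, 0.401, 0.463),
            "srh": (0.035, 0.305, 0.462, 0.166, 0.032),
        },
        time_effect=(0.0, 0.03, 0.07),
        seed=seed,
    )


PRESETS = {"gr": gr_like, "abcd": abcd_like}

_CATEGORY_CODES = {
    "gender": np.arange(2, dtype=float),
    "marital": np.arange(4, dtype=float),
    "academic": np.arange(4, dtype=float),
    "srh": np.arange(1, 6, dtype=float),
}
_CATEGORY_LABELS = {
    "gender": GENDER_LEVELS,
    "marital": MARITAL_LEVELS,
    "academic": ACADEMIC_LEVELS,
    "srh": (1, 2, 3, 4, 5),
}


def _standardize(codes: np.ndarray, probs: np.ndarray, support: np.ndarray) -> np.ndarray:
    """Standardize category codes by their configured (theoretical) moments."""
    mu = float(probs @ support)
    var = float(probs @ (support - mu) ** 2)
    sd = np.sqrt(var) if var > 0 else 1.0
    return (codes - mu) / sd


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a complete cohort (no missing cells) under ``config``.

    Deterministic given ``config.seed``.  The index column is left NaN;
    apply :func:`eq5dsim.scoring.score_dataset` to fill it.
    """
    config.validate()
    rng = substream(config.seed, 0)
    n, T = config.n_subjects, config.n_timepoints

    age = rng.normal(config.age_mean, config.age_sd, size=n)
    cats = {}
    for name in ("gender", "marital", "academic", "srh"):
        probs = np.asarray(config.category_probabilities[name], dtype=float)
        cats[name] = rng.choice(len(probs), size=n, p=probs)

    # standardized covariate scores feeding the latent propensity
    z = {"age": (age - config.age_mean) / (config.age_sd if config.age_sd > 0 else 1.0)}
    for name in ("gender", "marital", "academic", "srh"):
        probs = np.asarray(config.category_probabilities[name], dtype=float)
        support = _CATEGORY_CODES[name]
        z[name] = _standardize(support[cats[name]], probs, support)

    covariate_effect = sum(config.latent_loadings.get(c, 0.0) * z[c] for c in COVARIATES)
    b = rng.normal(0.0, config.random_intercept_sd, size=n)
    eps = rng.normal(0.0, config.residual_sd, size=(n, T, len(ITEMS)))

    eta = covariate_effect[:, None, None] + np.asarray(config.time_effect)[None, :, None] + b[:, None, None] + eps
    thresholds = np.asarray(config.thresholds, dtype=float)
    levels = 1 + np.searchsorted(thresholds, eta.reshape(-1))  # 1..5
    levels = levels.reshape(n, T, len(ITEMS))

    subj = np.repeat(np.arange(n), T)
    time = np.tile(np.arange(T), n)
    df = pd.DataFrame({"subject_id": subj, "time": time})
    for j, item in enumerate(ITEMS):
        df[item] = levels[:, :, j].reshape(-1).astype(float)
    df["age"] = np.repeat(age, T)
    df["gender"] = np.asarray(GENDER_LEVELS)[np.repeat(cats["gender"], T)]
    df["marital"] = np.asarray(MARITAL_LEVELS)[np.repeat(cats["marital"], T)]
    df["academic"] = np.asarray(ACADEMIC_LEVELS)[np.repeat(cats["academic"], T)]
    df["srh"] = np.repeat(cats["srh"] + 1, T)
    df["index"] = np.nan
    return df


def summarize_cohort(data: pd.DataFrame) -> pd.DataFrame:
    """Baseline-table-style descriptives: means/SDs and category percentages,
    plus the per-timepoint index mean/SD.  Returns a tidy frame with columns
    variable, statistic, value."""
    if len(data) == 0:
        return pd.DataFrame(columns=["variable", "statistic", "value"])
    base = data[data["time"] == data["time"].min()]
    rows = [
        {"variable": "n_subjects", "statistic": "count", "value": data["subject_id"].nunique()},
        {"variable": "age", "statistic": "mean", "value": base["age"].mean()},
        {"variable": "age", "statistic": "sd", "value": base["age"].std()},
    ]
    for name in ("gender", "marital", "academic", "srh"):
        counts = base[name].value_counts(normalize=True)
        for label in _CATEGORY_LABELS[name]:
            rows.append(
                {"variable": name, "statistic": f"pct_{label}", "value": 100.0 * counts.get(label, 0.0)}
            )
    for t, grp in data.groupby("time"):
        rows.append({"variable": "index", "statistic": f"mean_t{t}", "value": grp["index"].mean()})
        rows.append({"variable": "index", "statistic": f"sd_t{t}", "value": grp["index"].std()})
    return pd.DataFrame(rows)


def config_to_dict(config: CohortConfig) -> dict:
    return asdict(config)


def config_from_dict(d: dict) -> CohortConfig:
    cfg = CohortConfig(**{**d})
    if isinstance(cfg.time_effect, list):
        cfg = replace(cfg, time_effect=tuple(cfg.time_effect))
    if isinstance(cfg.thresholds, list):
        cfg = replace(cfg, thresholds=tuple(cfg.thresholds))
    return cfg
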