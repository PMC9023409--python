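"""Long-format longitudinal EQ-5D-5L dataset container and I/O.

A dataset is a pandas DataFrame with one row per subject x timepoint and a
fixed column schema.  Missing item responses (and the index score, which is
not computable when any item is missing) are encoded as NaN; the missingness
mask is therefore simply ``item_mask(df)``.

Schema
------
subject_id : int
time       : int, 0-based timepoint code (0 = baseline)
mo, sc, ua, pd, ad : item levels 1-5 (nullable)
age        : float, years
gender     : {"male", "female"}
marital    : {"never_married", "married", "separated", "widowed"}
academic   : {"no_schooling", "grade_school", "high_school", "college"}
srh        : int 1-5, single self-rated health (1 = excellent ... 5 = poor)
index      : float, utility index score (nullable)
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

ITEMS = ("mo", "sc", "ua", "pd", "ad")
COVARIATES = ("age", "gender", "marital", "academic", "srh")
GENDER_LEVELS = ("male", "female")
MARITAL_LEVELS = ("never_married", "married", "separated", "widowed")
ACADEMIC_LEVELS = ("no_schooling", "grade_school", "high_school", "college")
SCHEMA = ("subject_id", "time", *ITEMS, *COVARIATES, "index")

CATEGORY_LEVELS = {
    "gender": GENDER_LEVELS,
    "marital": MARITAL_LEVELS,
    "academic": ACADEMIC_LEVELS,
    "srh": (1, 2, 3, 4, 5),
}


class DatasetError(ValueError):
    """Raised when a dataset violates the schema or its invariants."""


def item_mask(data: pd.DataFrame) -> pd.DataFrame:
    """Boolean observed-mask over the five item columns (True = observed)."""
    return data[list(ITEMS)].notna()


def validate_dataset(data: pd.DataFrame) -> None:
    """Check schema, level ranges and per-subject grid completeness."""
    missing_cols = [c for c in SCHEMA if c not in data.columns]
    if missing_cols:
        raise DatasetError(f"missing columns: {missing_cols}")
    items = data[list(ITEMS)]
    bad = items.stack().pipe(lambda s: s[(s < 1) | (s > 5) | (s != s.round())])
    if len(bad):
        raise DatasetError(f"item levels outside 1..5 at rows {sorted(set(bad.index.get_level_values(0)))[:5]}")
    # complete grid: every subject has a row for every timepoint
    times = np.sort(data["time"].unique())
    counts = data.groupby("subject_id")["time"].apply(lambda s: tuple(np.sort(s.values)))
    expected = tuple(times)
    off = counts[counts != expected]
    if len(off):
        raise DatasetError(f"incomplete timepoint grid for subjects {list(off.index[:5])}")


def covariate_table(data: pd.DataFrame) -> pd.DataFrame:
    """One row of covariates per subject (taken from the baseline row)."""
    base = data.sort_values("time").groupby("subject_id", sort=True).first()
    return base[list(COVARIATES)].reset_index()


def complete_subjects(data: pd.DataFrame) -> np.ndarray:
    """Subjects with all items observed at every timepoint."""
    ok = item_mask(data).all(axis=1)
    per_subject = ok.groupby(data["subject_id"]).all()
    return per_subject[per_subject].index.to_numpy()


def write_dataset(data: pd.DataFrame, path: str | Path) -> None:
    out = data.loc[:, list(SCHEMA)].copy()
    for c in ITEMS:
        out[c] = out[c].astype("Int64")
    out.to_csv(path, index=False)


def read_dataset(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"subject_id": int, "time": int, "gender": str, "marital": str, "academic": str},
    )
    missing_cols = [c for c in SCHEMA if c not in df.columns]
    if missing_cols:
        raise DatasetError(f"{path}: missing columns {missing_cols}")
    for c in ITEMS:
        df[c] = df[c].astype("Float64").astype(float)
    df["index"] = df["index"].astype(float)
    df["srh"] = df["srh"].astype(int)
    return df.loc[:, list(SCHEMA)]
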