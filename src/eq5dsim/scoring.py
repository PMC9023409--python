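"""Value-set scoring of EQ-5D-5L profiles.

An EQ-5D-5L health state is a profile of five items (mobility, self-care,
usual activities, pain/discomfort, anxiety/depression), each on severity
levels 1-5, giving 5**5 = 3125 distinct states.  A value set maps a profile
to a utility-like index score additively: the full-health value (profile
1,1,1,1,1) minus one decrement per dimension whose level exceeds 1.

Published tariffs are external publications and are not bundled; the module
ships two clearly synthetic value sets with the same additive shape and a
loader for user-supplied coefficient files (CSV or JSON).

A profile with any missing item cannot be scored: ``score_profile`` returns
NaN rather than raising, because downstream complete-case and available-data
analyses rely on non-scorability to drop exactly those rows.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import ITEMS

DIMENSIONS = ITEMS
LEVELS = (1, 2, 3, 4, 5)


class ValueSetError(ValueError):
    """Invalid value-set coefficients."""


@dataclass(frozen=True)
class ValueSet:
    """Additive value set: constant minus per-dimension per-level decrements.

    Parameters
    ----------
    name : str
        Label for manifests and file headers.
    full_health_value : float
        Index of the all-ones profile.
    decrements : dict
        ``(dimension, level)`` -> nonnegative decrement, for every dimension
        in :data:`DIMENSIONS` and every level 2..5.  Within a dimension the
        decrement must be nondecreasing in level (severity monotonicity).
    """

    name: str
    full_health_value: float
    decrements: dict = field(repr=False)

    def __post_init__(self) -> None:
        for dim in DIMENSIONS:
            prev = 0.0
            for lev in LEVELS[1:]:
                try:
                    d = float(self.decrements[(dim, lev)])
                except KeyError:
                    raise ValueSetError(f"missing decrement for ({dim}, {lev})") from None
                if d < 0:
                    raise ValueSetError(f"negative decrement for ({dim}, {lev})")
                if d < prev:
                    raise ValueSetError(f"decrement for {dim} not monotone at level {lev}")
                prev = d

    @property
    def worst_value(self) -> float:
        """Index of the 5,5,5,5,5 profile."""
        return self.full_health_value - sum(self.decrements[(d, 5)] for d in DIMENSIONS)

    def decrement_array(self) -> np.ndarray:
        """(5 dims, 5 levels) array of decrements; level-1 column is zero."""
        arr = np.zeros((len(DIMENSIONS), 5))
        for i, dim in enumerate(DIMENSIONS):
            for lev in LEVELS[1:]:
                arr[i, lev - 1] = self.decrements[(dim, lev)]
        return arr


def toy_linear_value_set() -> ValueSet:
    """Synthetic value set with a uniform linear decrement 0.05*(level-1)."""
    dec = {(d, lev): 0.05 * (lev - 1) for d in DIMENSIONS for lev in LEVELS[1:]}
    return ValueSet("toy-linear", 1.0, dec)


def synthetic_5l_value_set() -> ValueSet:
    """Synthetic tariff with convex decrements (severe levels cost much more).

    Published EQ-5D-5L tariffs penalise levels 4-5 far more than 2-3; this
    synthetic set mimics that shape (worst state 1 - 5*0.33 = -0.65, a range
    comparable to European tariffs) without reproducing any published
    coefficients.
    """
    steps = {2: 0.04, 3: 0.08, 4: 0.20, 5: 0.33}
    dec = {(d, lev): steps[lev] for d in DIMENSIONS for lev in LEVELS[1:]}
    return ValueSet("synthetic-5l", 1.0, dec)


BUILTIN_VALUE_SETS = {
    "toy-linear": toy_linear_value_set,
    "synthetic-5l": synthetic_5l_value_set,
}


def get_value_set(name_or_path: str) -> ValueSet:
    """Resolve a built-in value-set name or load from a CSV/JSON file."""
    if name_or_path in BUILTIN_VALUE_SETS:
        return BUILTIN_VALUE_SETS[name_or_path]()
    path = Path(name_or_path)
    if not path.exists():
        raise ValueSetError(
            f"unknown value set {name_or_path!r}; built-ins: {sorted(BUILTIN_VALUE_SETS)}"
        )
    if path.suffix.lower() == ".json":
        return read_value_set_json(path)
    return read_value_set_csv(path)


def score_profile(profile, vs: ValueSet) -> float:
    """Score one 5-item profile; NaN if any item is missing.

    Levels outside 1..5 raise; a missing item (None/NaN) makes the whole
    profile non-scorable, which is the instrument rule for multi-item
    preference-based scores.
    """
    levels = list(profile)
    if len(levels) != len(DIMENSIONS):
        raise ValueSetError(f"profile must have {len(DIMENSIONS)} items")
    total = vs.full_health_value
    for dim, lev in zip(DIMENSIONS, levels):
        if lev is None or (isinstance(lev, float) and math.isnan(lev)):
            return float("nan")
        lev = int(lev)
        if lev not in LEVELS:
            raise ValueSetError(f"level {lev} for {dim} outside 1..5")
        if lev > 1:
            total -= vs.decrements[(dim, lev)]
    return total


def enumerate_health_states(levels_per_dimension: int = 5):
    """Yield every complete profile; 5 levels per dimension gives 3125 states."""
    return itertools.product(range(1, levels_per_dimension + 1), repeat=len(DIMENSIONS))


def count_health_states(levels_per_dimension: int = 5) -> int:
    """Number of distinct complete health states (3125 for the 5L)."""
    return sum(1 for _ in enumerate_health_states(levels_per_dimension))


def score_dataset(data: pd.DataFrame, vs: ValueSet) -> pd.DataFrame:
    """Fill the index column: scored where all five items are present, NaN else.

    Items are untouched; the operation is idempotent.
    """
    out = data.copy()
    items = out[list(ITEMS)].to_numpy(dtype=float)
    complete = ~np.isnan(items).any(axis=1)
    dec = vs.decrement_array()
    scores = np.full(len(out), np.nan)
    if complete.any():
        lev = items[complete].astype(int) - 1  # 0-based levels
        scores[complete] = vs.full_health_value - dec[np.arange(5), lev].sum(axis=1)
    out["index"] = scores
    return out


# ---------------------------------------------------------------------------
# coefficient-file round trip


def write_value_set_csv(vs: ValueSet, path: str | Path) -> None:
    """CSV with columns dimension,level,decrement; one ``full_health`` record
    (blank level) carries the constant."""
    rows = [{"dimension": "full_health", "level": "", "decrement": vs.full_health_value}]
    for dim in DIMENSIONS:
        for lev in LEVELS[1:]:
            rows.append({"dimension": dim, "level": lev, "decrement": vs.decrements[(dim, lev)]})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_value_set_csv(path: str | Path) -> ValueSet:
    df = pd.read_csv(path)
    const = df[df["dimension"] == "full_health"]
    if len(const) != 1:
        raise ValueSetError(f"{path}: expected exactly one full_health record")
    dec = {
        (r.dimension, int(r.level)): float(r.decrement)
        for r in df[df["dimension"] != "full_health"].itertuples()
    }
    return ValueSet(Path(path).stem, float(const["decrement"].iloc[0]), dec)


def write_value_set_json(vs: ValueSet, path: str | Path) -> None:
    payload = {
        "name": vs.name,
        "full_health_value": vs.full_health_value,
        "decrements": {f"{d}.{lev}": vs.decrements[(d, lev)] for d in DIMENSIONS for lev in LEVELS[1:]},
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_value_set_json(path: str | Path) -> ValueSet:
    payload = json.loads(Path(path).read_text())
    dec = {}
    for key, val in payload["decrements"].items():
        dim, lev = key.split(".")
        dec[(dim, int(lev))] = float(val)
    return ValueSet(payload.get("name", Path(path).stem), float(payload["full_health_value"]), dec)
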