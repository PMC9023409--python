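"""End-to-end experiment orchestration.

One experiment = a factorial of missingness levels x simulation replicates.
Per replicate the pipeline (re)draws a complete synthetic cohort, computes
the truth trajectory on it, amputes it per the scenario schedule, runs the
enabled analysis approaches, and accumulates per-replicate estimates; per
scenario it aggregates trajectories, SEs, MSEs, the item-misspecification
table and ordering flags, writing everything as CSV plus a JSON manifest.

Seeding: a single master seed; every (scenario, replicate, stage) gets a
deterministic substream, so reruns are byte-identical and stages can be
reproduced in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import _rng
from .amputation import DEFAULT_MAR_WEIGHTS, MCAR_WEIGHTS, ampute, generic_schedule
from .cohort import CohortConfig, config_from_dict, config_to_dict, generate_cohort, PRESETS
from .datasets import covariate_table
from .evaluation import misspecification_counts, ordering_check, truth_reference
from .modeling import (
    ModelSpec,
    run_approach_1_cc,
    run_approach_2_available,
    run_approach_3_mi_score,
    run_approach_4_mi_item,
)
from .scoring import get_value_set, score_dataset

log = logging.getLogger("eq5dsim")

APPROACHES = ("cc", "available", "mi_score", "mi_item")
DEFAULT_LEVELS = (5, 10, 15, 25, 35, 45, 55, 65)


class ExperimentError(RuntimeError):
    """Experiment-level failure (e.g. too many failed replicates)."""


@dataclass
class ExperimentConfig:
    """Full description of one simulation experiment."""

    cohort_preset: str = "gr"
    n_subjects: int | None = None
    cohort: dict | None = None  # explicit CohortConfig fields override the preset
    value_set: str = "synthetic-5l"
    levels: tuple = DEFAULT_LEVELS
    mechanism: str = "mar"  # "mar" or "mcar"
    weights: dict | None = None
    n_replicates: int = 100
    m_imputations: int = 100
    approaches: tuple = APPROACHES
    seed: int = 0
    out_dir: str | None = None
    redraw_cohort: bool = True  # one fresh cohort per replicate
    max_failure_rate: float = 0.10

    def validate(self) -> None:
        if not all(0 < lv < 100 for lv in self.levels) and self.levels != (0,):
            if any(lv < 0 or lv >= 100 for lv in self.levels):
                raise ExperimentError(f"levels must lie in [0, 100): {self.levels}")
        if self.n_replicates < 1:
            raise ExperimentError("n_replicates must be >= 1")
        mi_wanted = {"mi_score", "mi_item"} & set(self.approaches)
        if mi_wanted and self.m_imputations < 2:
            raise ExperimentError("M must be >= 2 when MI approaches are enabled")
        if self.mechanism not in ("mar", "mcar"):
            raise ExperimentError(f"unknown mechanism {self.mechanism!r}")
        unknown = set(self.approaches) - set(APPROACHES)
        if unknown:
            raise ExperimentError(f"unknown approaches {sorted(unknown)}")

    def cohort_config(self, seed: int) -> CohortConfig:
        if self.cohort is not None:
            cfg = config_from_dict({**self.cohort, "seed": seed})
        else:
            kwargs = {"seed": seed}
            if self.n_subjects is not None:
                kwargs["n_subjects"] = self.n_subjects
            cfg = PRESETS[self.cohort_preset](**kwargs)
        return cfg

    def mar_weights(self) -> dict:
        if self.mechanism == "mcar":
            return dict(MCAR_WEIGHTS)
        return dict(self.weights) if self.weights else dict(DEFAULT_MAR_WEIGHTS)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["levels"] = list(self.levels)
        d["approaches"] = list(self.approaches)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "levels" in d:
            d["levels"] = tuple(d["levels"])
        if "approaches" in d:
            d["approaches"] = tuple(d["approaches"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def desk_scale(**overrides) -> ExperimentConfig:
    """Reduced-size profile for interactive runs: fewer replicates and
    imputations at the same cohort size."""
    base = dict(levels=(10, 35, 65), n_replicates=20, m_imputations=10)
    base.update(overrides)
    return ExperimentConfig(**base)


@dataclass
class ScenarioSummary:
    level: float
    summary: pd.DataFrame  # approach, time, mean_estimate, mean_se, sd_estimate, mse, ...
    orderings: dict
    misspecification: pd.DataFrame | None
    n_replicates: int


def _run_replicate(config: ExperimentConfig, level: float, level_idx: int, rep: int, vs, spec):
    """One (scenario, replicate) cell; returns raw rows + misspec counts."""
    cohort_rep = rep if config.redraw_cohort else 0
    cseed = _rng.subseed(config.seed, _rng.COHORT, cohort_rep)
    cohort = generate_cohort(config.cohort_config(cseed))
    scored = score_dataset(cohort, vs)
    reference = covariate_table(scored)
    truth_pm, truth_bt = truth_reference(scored, vs, spec, reference)

    schedule = generic_schedule(level, weights=config.mar_weights())
    amp = ampute(scored, schedule, seed=_rng.subseed(config.seed, _rng.AMPUTE, level_idx, rep))

    results = []
    misspec = None
    # each approach standardizes over its own analysis sample (reference=None)
    for name in config.approaches:
        if name == "cc":
            res = run_approach_1_cc(amp, vs, spec)
        elif name == "available":
            res = run_approach_2_available(amp, vs, spec)
        elif name == "mi_score":
            res = run_approach_3_mi_score(
                amp, vs, spec, M=config.m_imputations,
                seed=_rng.subseed(config.seed, _rng.MI_SCORE, level_idx, rep),
            )
        else:
            res, imp = run_approach_4_mi_item(
                amp, vs, spec, M=config.m_imputations,
                seed=_rng.subseed(config.seed, _rng.MI_ITEM, level_idx, rep),
                return_imputations=True,
            )
            if (amp.provenance["pattern_id"] >= 0).any():
                misspec = misspecification_counts(scored, amp.data, imp)
        results.append(res)

    rows = []
    truth_by_time = truth_pm.table.set_index("time")["mean"]
    for res in results:
        for r in res.means.itertuples():
            rows.append(
                {
                    "level": level, "replicate": rep, "approach": res.approach,
                    "time": int(r.time), "mean": r.mean, "se": r.se,
                    "beta_time": res.beta_time, "n_subjects": res.n_subjects,
                    "m": res.m if res.m else 1, "truth": float(truth_by_time.loc[int(r.time)]),
                    "truth_beta_time": truth_bt,
                }
            )
    return rows, misspec


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the factorial experiment; returns the aggregate tables and, when
    ``config.out_dir`` is set, writes CSV artifacts plus a manifest."""
    config.validate()
    vs = get_value_set(config.value_set)
    spec = ModelSpec()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    all_raw, summaries, ordering_rows, misspec_frames = [], [], [], []
    for level_idx, level in enumerate(config.levels):
        raw_rows = []
        counts = None
        failures = 0
        for rep in range(config.n_replicates):
            try:
                rows, misspec = _run_replicate(config, level, level_idx, rep, vs, spec)
            except Exception:
                failures += 1
                log.exception("replicate failed at level=%s rep=%s", level, rep)
                if failures > config.max_failure_rate * config.n_replicates:
                    raise ExperimentError(
                        f"more than {config.max_failure_rate:.0%} of replicates failed at level {level}"
                    )
                continue
            raw_rows.extend(rows)
            if misspec is not None:
                counts = misspec if counts is None else counts + misspec
        raw = pd.DataFrame(raw_rows)
        all_raw.append(raw)
        summary = _aggregate_scenario(raw)
        orderings = ordering_check(
            summary.rename(columns={"mean_estimate": "mean"})[["approach", "time", "mean"]]
        ) if set(summary["approach"]) >= set(APPROACHES) else {}
        summaries.append(ScenarioSummary(
            level, summary, orderings,
            None if counts is None else 100.0 * counts.div(counts.sum(axis=1), axis=0),
            raw["replicate"].nunique(),
        ))
        ordering_rows.append({"level": level, **orderings})
        if counts is not None:
            mf = (100.0 * counts.div(counts.sum(axis=1), axis=0)).reset_index(names="item")
            mf.insert(0, "level", level)
            misspec_frames.append(mf)

    summary_all = pd.concat(
        [s.summary.assign(level=s.level) for s in summaries], ignore_index=True
    )
    raw_all = pd.concat(all_raw, ignore_index=True)
    orderings_all = pd.DataFrame(ordering_rows)
    misspec_all = pd.concat(misspec_frames, ignore_index=True) if misspec_frames else None

    if out_dir:
        summary_all.to_csv(out_dir / "scenario_summary.csv", index=False)
        raw_all.to_csv(out_dir / "results_raw.csv", index=False)
        orderings_all.to_csv(out_dir / "orderings.csv", index=False)
        if misspec_all is not None:
            misspec_all.to_csv(out_dir / "misspecification.csv", index=False)
        manifest = {
            "config": config.to_dict(),
            "config_sha256": hashlib.sha256(
                json.dumps(config.to_dict(), sort_keys=True).encode()
            ).hexdigest(),
            "outputs": ["scenario_summary.csv", "results_raw.csv", "orderings.csv"]
            + (["misspecification.csv"] if misspec_all is not None else []),
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {
        "summary": summary_all,
        "raw": raw_all,
        "orderings": orderings_all,
        "misspecification": misspec_all,
        "scenarios": summaries,
    }


def _aggregate_scenario(raw: pd.DataFrame) -> pd.DataFrame:
    """Per approach x timepoint: mean estimate, mean model SE, empirical SD
    across replicates, MSE against truth, mean time slope."""
    rows = []
    for (approach, t), grp in raw.groupby(["approach", "time"]):
        est = grp["mean"].to_numpy()
        truth = grp["truth"].to_numpy()
        rows.append(
            {
                "approach": approach,
                "time": int(t),
                "mean_estimate": est.mean(),
                "mean_se": grp["se"].mean(),
                "sd_estimate": est.std(ddof=1) if len(est) > 1 else 0.0,
                "mse": float(((est - truth) ** 2).mean()),
                "mean_beta_time": grp["beta_time"].mean(),
                "truth_mean": truth.mean(),
                "mean_truth_beta_time": grp["truth_beta_time"].mean(),
                "n_replicates": len(est),
            }
        )
    return pd.DataFrame(rows).sort_values(["approach", "time"]).reset_index(drop=True)
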