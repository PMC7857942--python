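"""End-to-end pipeline: simulate -> window -> adhere -> score -> agree ->
compare -> trend, with input validation and a reproducible report bundle.

Every output table is written as plain CSV with a JSON metadata sidecar
carrying the run's config hash and seed; rerunning with the same config is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adherence import CompletionRule, adherence_table, completion_flags, timing_metrics
from .agreement import bland_altman, ccc, cohen_kappa, make_pairs
from .cohort_stats import (
    EDUCATION_LEVELS,
    collapse_sparse_levels,
    compare_groups,
    default_table1_specs,
    fit_returner_model,
)
from .errors import EfhsError, SampleSizeError
from .instruments import MEASURE_WAVES, SURVEY_ITEM_COUNTS, WAVES
from .longitudinal import fit_random_intercept, five_number_summaries, paired_t
from .scoring import score_measures
from .synthetic import CohortConfig, generate_cohort, read_cohort, write_cohort
from .windowing import apply_eligibility, assign_windows

logger = logging.getLogger(__name__)

ALL_ANALYSES = ("adherence", "agreement", "cohort_stats", "longitudinal")


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    out_dir: str
    cohort: CohortConfig = field(default_factory=CohortConfig)
    input_dir: Optional[str] = None  # load tables instead of simulating
    completion_threshold: float = 0.75
    min_followup_days: int = 365
    analyses: Tuple[str, ...] = ALL_ANALYSES

    @classmethod
    def from_yaml(cls, path, out_dir: Optional[str] = None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortConfig.from_dict(raw.pop("cohort", {}))
        if out_dir is not None:
            raw["out_dir"] = out_dir
        return cls(cohort=cohort, **raw)

    def to_dict(self) -> dict:
        return {
            "out_dir": self.out_dir,
            "cohort": self.cohort.to_dict(),
            "input_dir": self.input_dir,
            "completion_threshold": self.completion_threshold,
            "min_followup_days": self.min_followup_days,
            "analyses": list(self.analyses),
        }

    @property
    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir")  # hash the analysis, not where it lands
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class ReportBundle:
    tables: Dict[str, pd.DataFrame]
    metadata: dict


def validate_inputs(tables: Mapping[str, pd.DataFrame]) -> List[dict]:
    """Schema and consistency checks; returns a machine-readable issue list."""
    issues: List[dict] = []
    required = {
        "participants": ["id", "registration_ts", "enrolled", "followup_days"],
        "survey_returns": [
            "participant_id",
            "instance_id",
            "survey_type",
            "deployment_ts",
            "start_ts",
            "return_ts",
        ],
        "responses": ["participant_id", "instance_id", "item_index", "value"],
        "clinic": ["participant_id", "measure", "value"],
    }
    for table, cols in required.items():
        if table not in tables:
            issues.append({"table": table, "id": None, "issue": "missing table"})
            continue
        for col in cols:
            if col not in tables[table].columns:
                issues.append(
                    {"table": table, "id": None, "issue": f"missing column {col}"}
                )
    if issues:
        return issues

    parts = tables["participants"]
    dup = parts["id"][parts["id"].duplicated()]
    for pid in dup:
        issues.append({"table": "participants", "id": pid, "issue": "duplicate id"})
    neg = parts[parts["followup_days"] < 0]
    for pid in neg["id"]:
        issues.append(
            {"table": "participants", "id": pid, "issue": "negative followup_days"}
        )

    sr = tables["survey_returns"]
    for iid in sr["instance_id"][sr["instance_id"].duplicated()]:
        issues.append(
            {"table": "survey_returns", "id": iid, "issue": "duplicate instance_id"}
        )
    bad = sr[(sr["deployment_ts"] > sr["start_ts"]) | (sr["start_ts"] > sr["return_ts"])]
    for iid in bad["instance_id"]:
        issues.append(
            {"table": "survey_returns", "id": iid, "issue": "timestamp ordering violated"}
        )
    if "step_ts" in sr.columns:
        for iid, steps in zip(sr["instance_id"], sr["step_ts"]):
            if isinstance(steps, str) and steps:
                ts = [int(s) for s in steps.split(";")]
                if any(b < a for a, b in zip(ts, ts[1:])):
                    issues.append(
                        {
                            "table": "survey_returns",
                            "id": iid,
                            "issue": "step timestamps decrease",
                        }
                    )

    counts = tables["responses"].groupby("instance_id")["item_index"].count()
    stypes = sr.drop_duplicates("instance_id").set_index("instance_id")["survey_type"]
    for iid, n_rows in counts.items():
        expected = SURVEY_ITEM_COUNTS.get(stypes.get(iid))
        if expected is not None and n_rows != expected:
            issues.append(
                {
                    "table": "responses",
                    "id": iid,
                    "issue": f"item count {n_rows} != instrument size {expected}",
                }
            )
    return issues


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute all requested stages and write the report bundle."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables: Dict[str, pd.DataFrame] = {}
    meta: dict = {
        "config_hash": config.config_hash,
        "seed": config.cohort.seed,
        "version": __version__,
        "analyses": list(config.analyses),
        "stages": {},
        "skipped": [s for s in ALL_ANALYSES if s not in config.analyses],
    }

    # stage 1: simulate or load
    if config.input_dir:
        cohort = read_cohort(config.input_dir)
        logger.info("loaded cohort from %s", config.input_dir)
    else:
        cohort = generate_cohort(config.cohort)
        logger.info(
            "simulated cohort: %d participants, %d survey instances",
            len(cohort["participants"]),
            len(cohort["survey_returns"]),
        )
    write_cohort(cohort, out_dir)
    meta["stages"]["simulate"] = {
        "participants": int(len(cohort["participants"])),
        "survey_instances": int(len(cohort["survey_returns"])),
    }

    issues = validate_inputs(cohort)
    meta["stages"]["validate"] = {"n_issues": len(issues)}
    if issues:
        raise EfhsError(
            f"input validation failed with {len(issues)} issues; first: {issues[0]}"
        )

    participants = cohort["participants"]
    enrolled = participants[participants["enrolled"] == 1]

    # stage 2: windowing + eligibility
    assignments = assign_windows(cohort["survey_returns"], participants)
    eligible, exclusions = apply_eligibility(
        enrolled, assignments, config.min_followup_days
    )
    tables["assignments"] = assignments
    tables["exclusions"] = exclusions
    meta["stages"]["windowing"] = {
        "enrolled": int(len(enrolled)),
        "eligible": int(len(eligible)),
        "excluded": {
            rule: int(n)
            for rule, n in exclusions.groupby("rule").size().items()
        },
        "returns_per_wave": {
            w: int((assignments["wave"] == w).sum()) for w in list(WAVES) + ["excluded"]
        },
    }
    logger.info(
        "eligibility: %d enrolled -> %d eligible (%d excluded)",
        len(enrolled),
        len(eligible),
        len(exclusions),
    )
    eligible_ids = eligible["id"].tolist()

    rule = CompletionRule(config.completion_threshold)
    stypes = cohort["survey_returns"].set_index("instance_id")["survey_type"].to_dict()
    completed = completion_flags(cohort["responses"], stypes, rule)

    # stage 3: adherence + timing
    if "adherence" in config.analyses:
        tables["adherence"] = adherence_table(
            assignments, completed, config.cohort.schedule, eligible_ids
        )
        tables["timing"] = timing_metrics(cohort["survey_returns"], assignments)
        meta["stages"]["adherence"] = {
            "denominator": int(len(eligible_ids)),
        }

    # stage 4: scoring (needed by agreement and longitudinal)
    scores = pd.DataFrame()
    if {"agreement", "longitudinal"} & set(config.analyses):
        elig_assign = assignments[assignments["participant_id"].isin(set(eligible_ids))]
        scores = score_measures(elig_assign, cohort["survey_returns"], cohort["responses"])
        tables["scores"] = scores
        meta["stages"]["scoring"] = {"scored_rows": int(len(scores))}

    # stage 5: agreement at baseline
    if "agreement" in config.analyses:
        tables["agreement"], tables["blandaltman_points"] = _agreement_stage(
            cohort["clinic"], scores
        )

    # stage 6: cohort comparisons
    if "cohort_stats" in config.analyses:
        tables["table1"], tables["returner_model"] = _cohort_stats_stage(
            participants, cohort["survey_returns"]
        )

    # stage 7: longitudinal trends
    if "longitudinal" in config.analyses:
        tables["trend"] = _longitudinal_stage(scores)
        tables["boxplot_summaries"] = five_number_summaries(
            scores.dropna(subset=["value"])
        )

    _write_bundle(tables, meta, out_dir)
    return ReportBundle(tables, meta)


def _agreement_stage(clinic, scores):
    rows = []
    ba_points = []
    for measure in ("pai", "cesd_sum", "drinks_per_week"):
        try:
            x, y, n_dropped = make_pairs(clinic, scores, measure)
            res = ccc(x, y)
            ba = bland_altman(x, y)
        except EfhsError as exc:
            logger.warning("agreement for %s skipped: %s", measure, exc)
            continue
        rows.append(
            {
                "measure": measure,
                "statistic": "ccc",
                "estimate": res.estimate,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "n_pairs": res.n_pairs,
            }
        )
        for stat, val in (
            ("bias", ba["bias"]),
            ("loa_lower", ba["lower"]),
            ("loa_upper", ba["upper"]),
        ):
            rows.append(
                {
                    "measure": measure,
                    "statistic": stat,
                    "estimate": val,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "n_pairs": ba["n_pairs"],
                }
            )
        pts = ba["points"].copy()
        pts.insert(0, "measure", measure)
        ba_points.append(pts)
        logger.info("agreement %s: ccc=%.3f (n=%d, %d incomplete pairs dropped)",
                    measure, res.estimate, res.n_pairs, n_dropped)

    # depressive-symptoms binary flag: app vs clinic kappa
    try:
        clinic_cesd = clinic[clinic["measure"] == "cesd_sum"].set_index("participant_id")["value"]
        app = scores[(scores["measure"] == "cesd_sum") & (scores["wave"] == "baseline")]
        app_flag = app.set_index("participant_id")["flag"]
        joined = pd.concat(
            [(clinic_cesd >= 16).astype(float), app_flag], axis=1, keys=["x", "y"]
        ).dropna()
        res = cohen_kappa(joined["x"], joined["y"])
        rows.append(
            {
                "measure": "depression_flag",
                "statistic": "kappa",
                "estimate": res.estimate,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "n_pairs": res.n_pairs,
            }
        )
    except EfhsError as exc:
        logger.warning("kappa skipped: %s", exc)

    agreement = pd.DataFrame(
        rows, columns=["measure", "statistic", "estimate", "ci_low", "ci_high", "n_pairs"]
    )
    points = (
        pd.concat(ba_points, ignore_index=True)
        if ba_points
        else pd.DataFrame(columns=["measure", "mean", "diff"])
    )
    return agreement, points


def _cohort_stats_stage(participants, survey_returns):
    specs = default_table1_specs()
    if participants["enrolled"].nunique() == 2:
        table1 = compare_groups(participants, "enrolled", specs)
    else:
        logger.warning("table1 skipped: only one enrollment group present")
        table1 = pd.DataFrame(columns=["variable", "test", "statistic", "p"])

    enrolled = participants[participants["enrolled"] == 1].copy()
    returners = set(survey_returns["participant_id"])
    enrolled["returned"] = enrolled["id"].isin(returners).astype(int)
    # sparse education cells (all returners or all non-returners) would
    # quasi-separate the fit; merge them into the neighbouring level first
    enrolled["education"], levels = collapse_sparse_levels(
        enrolled["education"], EDUCATION_LEVELS
    )
    try:
        model = fit_returner_model(enrolled, categorical={"education": levels})
    except EfhsError as exc:
        logger.warning("returner model skipped: %s", exc)
        model = pd.DataFrame(columns=["term", "aor", "ci_low", "ci_high", "p"])
    return table1, model


def _longitudinal_stage(scores):
    rows = []
    present = scores.dropna(subset=["value"])
    for measure in ("pai", "cesd_sum"):
        waves = MEASURE_WAVES[measure]
        sub = present[(present["measure"] == measure) & present["wave"].isin(waves)]
        counts = sub.groupby("participant_id")["wave"].nunique()
        complete_ids = counts[counts == len(waves)].index
        panel = sub[sub["participant_id"].isin(complete_ids)][
            ["participant_id", "wave", "value"]
        ]
        try:
            fit = fit_random_intercept(panel)
        except EfhsError as exc:
            logger.warning("trend for %s skipped: %s", measure, exc)
            continue
        for rec in fit.effects.itertuples(index=False):
            rows.append(
                {
                    "measure": measure,
                    "wave": rec.wave,
                    "estimate": rec.estimate,
                    "se": rec.se,
                    "p": rec.p,
                    "tau2": fit.tau2,
                    "sigma2": fit.sigma2,
                    "n": fit.n_participants,
                }
            )

    # alcohol: paired t baseline vs 12 months
    alc = present[present["measure"] == "drinks_per_week"]
    wide = alc.pivot_table(index="participant_id", columns="wave", values="value")
    if {"baseline", "m12"} <= set(wide.columns):
        paired = wide[["baseline", "m12"]].dropna()
        try:
            res = paired_t(paired["baseline"], paired["m12"])
            rows.append(
                {
                    "measure": "drinks_per_week",
                    "wave": "m12",
                    "estimate": res["mean_diff"],
                    "se": np.nan,
                    "p": res["p"],
                    "tau2": np.nan,
                    "sigma2": np.nan,
                    "n": res["n"],
                }
            )
        except SampleSizeError as exc:
            logger.warning("paired t for alcohol skipped: %s", exc)
    return pd.DataFrame(
        rows, columns=["measure", "wave", "estimate", "se", "p", "tau2", "sigma2", "n"]
    )


def _write_bundle(tables, meta, out_dir: Path) -> None:
    for name, df in tables.items():
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        sidecar = {
            "table": name,
            "rows": int(len(df)),
            "config_hash": meta["config_hash"],
            "seed": meta["seed"],
            "version": meta["version"],
        }
        with open(out_dir / f"{name}.meta.json", "w") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True)
    with open(out_dir / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
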