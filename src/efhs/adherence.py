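"""Survey completion, the two adherence metrics, and timing summaries.

A survey instance counts as *complete* when the participant answered at
least 75% of its questions.  Adherence at a wave is reported two ways:

* ``p_any`` — proportion of eligible participants with at least one
  completed survey assigned to the wave;
* ``p_all`` — proportion who completed every survey type scheduled for the
  wave.

Both proportions share a single denominator: the full post-exclusion
participant count, non-returners included.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from ._util import percent
from .errors import ConfigError, DataError
from .instruments import SURVEY_ITEM_COUNTS, WAVES

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CompletionRule:
    """Fraction of questions that must be answered for a survey to count."""

    threshold: float = 0.75

    def __post_init__(self) -> None:
        if not (0 < self.threshold <= 1):
            raise ConfigError(f"completion threshold {self.threshold} not in (0, 1]")


def is_complete(responses: Sequence, rule: CompletionRule = CompletionRule()) -> bool:
    """True iff the answered fraction reaches the rule's threshold.

    ``responses`` is the full ordered item list for one instance; missing
    items are ``None`` or NaN.
    """
    arr = np.array([np.nan if v is None else v for v in responses], dtype=float)
    if arr.size == 0:
        raise DataError("zero-item instrument")
    answered = int(np.sum(~np.isnan(arr)))
    return answered / arr.size >= rule.threshold


def completion_flags(
    responses: pd.DataFrame,
    survey_types: Mapping[str, str],
    rule: CompletionRule = CompletionRule(),
    item_counts: Mapping[str, int] = SURVEY_ITEM_COUNTS,
) -> pd.Series:
    """Per-instance completion flag from the long response table.

    ``survey_types`` maps instance_id -> survey type; the item total comes
    from the instrument definition so unanswered trailing items cannot
    inflate the answered fraction.
    """
    answered = responses.groupby("instance_id")["value"].count()
    types = pd.Series(survey_types)
    totals = types.map(item_counts)
    if totals.isna().any():
        unknown = types[totals.isna()].unique()
        raise DataError(f"unknown survey types: {list(unknown)}")
    answered = answered.reindex(types.index, fill_value=0)
    return (answered / totals) >= rule.threshold


def adherence_any(
    assignments: pd.DataFrame,
    completed: pd.Series,
    eligible_participants: Iterable[str],
) -> pd.DataFrame:
    """Proportion with >=1 completed survey per wave (shared denominator)."""
    eligible = list(eligible_participants)
    denominator = len(eligible)
    comp = _completed_assignments(assignments, completed, eligible)
    rows = []
    for wave in WAVES:
        n_any = comp.loc[comp["wave"] == wave, "participant_id"].nunique()
        rows.append(
            {
                "wave": wave,
                "n_any": n_any,
                "denominator": denominator,
                "p_any": n_any / denominator if denominator else np.nan,
                "pct_any": percent(n_any, denominator) if denominator else np.nan,
            }
        )
    return pd.DataFrame(rows)


def adherence_all(
    assignments: pd.DataFrame,
    completed: pd.Series,
    schedule: Mapping[str, Sequence[str]],
    eligible_participants: Iterable[str],
) -> pd.DataFrame:
    """Proportion who completed every scheduled survey type per wave."""
    eligible = list(eligible_participants)
    denominator = len(eligible)
    comp = _completed_assignments(assignments, completed, eligible)
    rows = []
    for wave in WAVES:
        if wave not in schedule:
            raise ConfigError(f"wave {wave!r} absent from schedule")
        scheduled = set(schedule[wave])
        sub = comp[comp["wave"] == wave]
        per_participant = sub.groupby("participant_id")["survey_type"].agg(set)
        n_all = int((per_participant.apply(lambda s: scheduled <= s)).sum())
        rows.append(
            {
                "wave": wave,
                "n_all": n_all,
                "denominator": denominator,
                "p_all": n_all / denominator if denominator else np.nan,
                "pct_all": percent(n_all, denominator) if denominator else np.nan,
            }
        )
    return pd.DataFrame(rows)


def adherence_table(
    assignments: pd.DataFrame,
    completed: pd.Series,
    schedule: Mapping[str, Sequence[str]],
    eligible_participants: Iterable[str],
) -> pd.DataFrame:
    """Combined per-wave table with both metrics."""
    any_df = adherence_any(assignments, completed, eligible_participants)
    all_df = adherence_all(assignments, completed, schedule, eligible_participants)
    return any_df.merge(all_df.drop(columns="denominator"), on="wave")[
        ["wave", "n_any", "n_all", "denominator", "p_any", "p_all", "pct_any", "pct_all"]
    ]


def _completed_assignments(
    assignments: pd.DataFrame, completed: pd.Series, eligible: Sequence[str]
) -> pd.DataFrame:
    sub = assignments[assignments["participant_id"].isin(set(eligible))].copy()
    flags = sub["instance_id"].map(completed)
    return sub[flags.fillna(False).to_numpy(dtype=bool)]


def _quartiles(values: np.ndarray) -> Tuple[float, float, float]:
    """(q1, median, q3) by linear interpolation (type-7 quantiles)."""
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(q1), float(med), float(q3)


def timing_metrics(
    survey_returns: pd.DataFrame,
    assignments: pd.DataFrame,
    item_counts: Mapping[str, int] = SURVEY_ITEM_COUNTS,
) -> pd.DataFrame:
    """Median and IQR of timing metrics per survey type and wave.

    Metrics: return time (deployment to return, days), touch time (start to
    return, minutes), step time and per-question time (seconds).  Instances
    violating deployment <= start <= return are dropped with a log entry.
    """
    df = survey_returns.merge(
        assignments[["instance_id", "wave"]], on="instance_id", how="inner"
    )
    ok = (df["deployment_ts"] <= df["start_ts"]) & (df["start_ts"] <= df["return_ts"])
    for iid in df.loc[~ok, "instance_id"]:
        logger.warning("timing_metrics: dropping instance %s (timestamp ordering)", iid)
    df = df[ok]

    rows = []
    for (stype, wave), grp in df.groupby(["survey_type", "wave"], sort=True):
        return_days = (grp["return_ts"] - grp["deployment_ts"]).to_numpy() / 86400.0
        touch_min = (grp["return_ts"] - grp["start_ts"]).to_numpy() / 60.0
        step_secs: list = []
        for start, steps in zip(grp["start_ts"], grp["step_ts"]):
            ts = _parse_steps(steps)
            if len(ts):
                step_secs.extend(np.diff(np.concatenate([[start], ts])).tolist())
        step_secs_arr = np.asarray(step_secs, dtype=float)
        n_items = item_counts.get(stype, np.nan)
        metrics = {
            "return_time_days": return_days,
            "touch_time_minutes": touch_min,
            "step_time_seconds": step_secs_arr,
        }
        if step_secs_arr.size and n_items == n_items:
            # one timestamp per step; questions spread evenly across steps
            n_steps = np.median([len(_parse_steps(s)) for s in grp["step_ts"]])
            metrics["question_time_seconds"] = step_secs_arr * n_steps / n_items
        for metric, values in metrics.items():
            if values.size == 0:
                continue
            q1, med, q3 = _quartiles(values)
            rows.append(
                {
                    "survey_type": stype,
                    "wave": wave,
                    "metric": metric,
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                    "n": int(values.size if metric.startswith("return") or metric.startswith("touch") else len(grp)),
                }
            )
    return pd.DataFrame(rows, columns=["survey_type", "wave", "metric", "median", "q1", "q3", "n"])


def _parse_steps(steps) -> np.ndarray:
    if isinstance(steps, str):
        if not steps:
            return np.array([], dtype=np.int64)
        return np.array([int(s) for s in steps.split(";")], dtype=np.int64)
    return np.asarray(steps, dtype=np.int64)
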