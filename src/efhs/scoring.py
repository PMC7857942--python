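"""Scoring of the three analysed measures, with the study imputation rules.

* **Physical Activity Index (PAI).**  Weighted sum of daily hours spent in
  five intensity classes — sleep, sedentary, slight, moderate, heavy — with
  weights 1 / 1.1 / 1.5 / 2.4 / 5; the five hour inputs sum to 24, so the
  score ranges from 24 (all sleep) to 120 (all heavy).  A single missing
  hour entry is imputed as 24 minus the sum of the other four.
* **CES-D.**  Twenty items scored 0-3 (four standard items reverse-coded),
  summed to 0-60.  With 1-5 items missing the mean of the answered items is
  multiplied by 20; with more than 5 missing the score is missing.  The
  binary depressive-symptoms flag is 1 when the sum reaches 16.
* **Drinks per week.**  Average drinks per drinking day times the number of
  days per week with any alcohol.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DataError
from .instruments import MEASURE_SURVEY, SURVEY_ITEM_COUNTS

logger = logging.getLogger(__name__)

#: Hour weights for (sleep, sedentary, slight, moderate, heavy).
PAI_WEIGHTS: Mapping[str, float] = {
    "sleep": 1.0,
    "sedentary": 1.1,
    "slight": 1.5,
    "moderate": 2.4,
    "heavy": 5.0,
}
PAI_WEIGHT_ARRAY = np.array(list(PAI_WEIGHTS.values()))

#: 0-based positions of the CES-D items that are reverse-scored on the
#: standard form (items 4, 8, 12, 16 in 1-based numbering).
CESD_REVERSE_CODED: Tuple[int, ...] = (3, 7, 11, 15)

CESD_CUTOFF = 16

_HOURS_TOL = 1e-6


@dataclass(frozen=True)
class ScoredValue:
    """A scored measure with its missingness provenance."""

    value: Optional[float]
    imputed: bool
    n_items_missing: int

    @property
    def missing(self) -> bool:
        return self.value is None


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def score_pai(hours: Sequence) -> ScoredValue:
    """Score the Physical Activity Index from the 5 duration items.

    Exactly one missing item is imputed as ``max(0, 24 - sum(others))``;
    two or more missing items yield a missing score.  If the four present
    hours already exceed 24 (beyond tolerance) the imputation would be
    negative, which is a data error.
    """
    if len(hours) != len(PAI_WEIGHT_ARRAY):
        raise DataError(f"PAI expects 5 duration items, got {len(hours)}")
    vals = [None if _is_missing(v) else float(v) for v in hours]
    present = [v for v in vals if v is not None]
    if any(v < 0 for v in present):
        raise DataError("negative activity hours")
    n_missing = len(vals) - len(present)
    if n_missing >= 2:
        return ScoredValue(None, False, n_missing)
    if n_missing == 1:
        remainder = 24.0 - sum(present)
        if remainder < -_HOURS_TOL:
            raise DataError(
                f"present hours sum to {sum(present):.6f} > 24; cannot impute"
            )
        vals = [max(0.0, remainder) if v is None else v for v in vals]
    score = float(np.dot(np.array(vals, dtype=float), PAI_WEIGHT_ARRAY))
    return ScoredValue(score, n_missing == 1, n_missing)


def score_cesd(
    items: Sequence,
    reverse_coded_indices: Sequence[int] = CESD_REVERSE_CODED,
) -> Tuple[ScoredValue, Optional[int]]:
    """Score the CES-D sum and the binary depressive-symptoms flag.

    Returns ``(score, flag)`` where ``flag`` is 1 when the continuous score
    is >= 16, 0 when below, and None when the score is missing.
    """
    if len(items) != 20:
        raise DataError(f"CES-D expects 20 items, got {len(items)}")
    coded = []
    for i, v in enumerate(items):
        if _is_missing(v):
            coded.append(None)
            continue
        iv = float(v)
        if iv not in (0.0, 1.0, 2.0, 3.0):
            raise DataError(f"CES-D item {i} value {v!r} outside 0..3")
        coded.append(3.0 - iv if i in set(reverse_coded_indices) else iv)
    present = [v for v in coded if v is not None]
    n_missing = 20 - len(present)
    if n_missing > 5:
        return ScoredValue(None, False, n_missing), None
    if n_missing == 0:
        score = float(sum(present))
        imputed = False
    else:
        score = float(np.mean(present) * 20.0)
        imputed = True
    flag = 1 if score >= CESD_CUTOFF else 0
    return ScoredValue(score, imputed, n_missing), flag


def drinks_per_week(drinks_per_day: float, days_per_week: float) -> float:
    """Average weekly drinks: drinks per drinking day x drinking days/week."""
    if _is_missing(drinks_per_day) or _is_missing(days_per_week):
        raise DataError("missing alcohol item")
    days = float(days_per_week)
    if days < 0 or days > 7:
        raise DataError(f"days per week {days_per_week!r} outside 0..7")
    if float(drinks_per_day) < 0:
        raise DataError("negative drinks per day")
    if days == 0:
        return 0.0
    return float(drinks_per_day) * days


def score_measures(
    assignments: pd.DataFrame,
    survey_returns: pd.DataFrame,
    responses: pd.DataFrame,
    reverse_coded_indices: Sequence[int] = CESD_REVERSE_CODED,
) -> pd.DataFrame:
    """Score PAI, CES-D and drinks/week for every assigned survey instance.

    When a participant returned the same survey type more than once within a
    wave, the instance with the earliest return is scored.  Instances whose
    items violate the instrument contract are logged and left missing.

    Returns a long table: participant_id, measure, wave, value, imputed,
    n_items_missing (plus ``cesd_flag`` rows carried in the ``flag`` column
    for the depression binary).
    """
    merged = assignments.merge(
        survey_returns[["instance_id", "return_ts"]], on="instance_id"
    )
    merged = merged[merged["wave"] != "excluded"]
    scored_types = set(MEASURE_SURVEY.values())
    relevant = set(merged.loc[merged["survey_type"].isin(scored_types), "instance_id"])
    item_values = _items_by_instance(
        responses[responses["instance_id"].isin(relevant)]
    )

    rows = []
    for measure, stype in MEASURE_SURVEY.items():
        sub = merged[merged["survey_type"] == stype]
        if sub.empty:
            continue
        earliest = sub.sort_values("return_ts").groupby(
            ["participant_id", "wave"], as_index=False
        ).first()
        n_items = SURVEY_ITEM_COUNTS[stype]
        for rec in earliest.itertuples(index=False):
            items = item_values.get(rec.instance_id)
            vals = _dense_items(items, n_items)
            row = {
                "participant_id": rec.participant_id,
                "measure": measure,
                "wave": rec.wave,
                "value": np.nan,
                "imputed": False,
                "n_items_missing": int(sum(_is_missing(v) for v in vals)),
                "flag": np.nan,
            }
            try:
                if measure == "pai":
                    sv = score_pai(vals)
                elif measure == "cesd_sum":
                    sv, flag = score_cesd(vals, reverse_coded_indices)
                    row["flag"] = np.nan if flag is None else flag
                else:
                    if _is_missing(vals[0]) or _is_missing(vals[1]):
                        sv = ScoredValue(None, False, row["n_items_missing"])
                    else:
                        sv = ScoredValue(drinks_per_week(vals[0], vals[1]), False, 0)
                row["value"] = np.nan if sv.value is None else sv.value
                row["imputed"] = sv.imputed
                row["n_items_missing"] = sv.n_items_missing
            except DataError as exc:
                logger.warning("scoring %s %s: %s", measure, rec.instance_id, exc)
            rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "measure",
            "wave",
            "value",
            "imputed",
            "n_items_missing",
            "flag",
        ],
    )


def _items_by_instance(responses: pd.DataFrame) -> dict:
    grouped = {}
    for iid, grp in responses.groupby("instance_id"):
        grouped[iid] = dict(zip(grp["item_index"].astype(int), grp["value"]))
    return grouped


def _dense_items(items: Optional[dict], n_items: int) -> list:
    if items is None:
        return [None] * n_items
    return [items.get(i, None) for i in range(n_items)]
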