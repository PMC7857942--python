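"""Time-window assignment of returned surveys and eligibility exclusions.

Each returned survey instance is mapped to a protocol wave by the number of
whole days elapsed between the participant's registration and the return:
0-89 days is baseline, 90-179 is the 3-month wave, 180-269 the 6-month,
270-359 the 9-month, 360-449 the 12-month wave; later returns fall outside
the analysed windows and are marked excluded.

Eligibility mirrors the study design: participants need at least 12 months
of follow-up, and participants whose *first* return lands on day 90 or later
cannot be anchored to a baseline and are dropped; participants who never
returned anything are retained (they belong in adherence denominators).
"""

from __future__ import annotations

from typing import Iterable, Tuple

import numpy as np
import pandas as pd

from .errors import DataError
from .instruments import WAVES, WINDOWS

EXCLUDED = "excluded"

RULE_SHORT_FOLLOWUP = "followup_lt_min"
RULE_LATE_FIRST_RETURN = "first_return_on_or_after_day_90"

SECONDS_PER_DAY = 86400


def days_since_registration(registration_ts: int, return_ts: int) -> int:
    """Whole days elapsed between registration and survey return (floored)."""
    if return_ts < registration_ts:
        raise DataError(
            f"return timestamp {return_ts} precedes registration {registration_ts}"
        )
    return int((int(return_ts) - int(registration_ts)) // SECONDS_PER_DAY)


def assign_window(days: int) -> str:
    """Map a day index to its wave label, or ``"excluded"`` past day 449."""
    if days < 0:
        raise DataError(f"negative day index {days}")
    for wave in WAVES:
        lo, hi = WINDOWS[wave]
        if lo <= days <= hi:
            return wave
    return EXCLUDED


def assign_windows(
    survey_returns: pd.DataFrame, participants: pd.DataFrame
) -> pd.DataFrame:
    """Assign every survey instance to a wave.

    Parameters
    ----------
    survey_returns
        One row per instance with ``participant_id``, ``instance_id``,
        ``survey_type`` and ``return_ts``.
    participants
        Must carry ``id`` and ``registration_ts``.

    Returns
    -------
    DataFrame with columns participant_id, instance_id, survey_type, days,
    wave (one of the five wave labels or ``"excluded"``).
    """
    reg = participants.set_index("id")["registration_ts"]
    merged = survey_returns[
        ["participant_id", "instance_id", "survey_type", "return_ts"]
    ].copy()
    merged["registration_ts"] = merged["participant_id"].map(reg)
    if merged["registration_ts"].isna().any():
        missing = merged.loc[merged["registration_ts"].isna(), "instance_id"]
        raise DataError(
            f"returns without a registered participant: {list(missing.head())}"
        )
    bad = merged["return_ts"] < merged["registration_ts"]
    if bad.any():
        raise DataError(
            "return precedes registration for instances "
            f"{list(merged.loc[bad, 'instance_id'].head())}"
        )
    days = (
        (merged["return_ts"].astype(np.int64) - merged["registration_ts"].astype(np.int64))
        // SECONDS_PER_DAY
    ).astype(int)
    # vectorised equivalent of assign_window
    edges = [WINDOWS[w][0] for w in WAVES] + [WINDOWS[WAVES[-1]][1] + 1]
    labels = np.array(list(WAVES) + [EXCLUDED], dtype=object)
    idx = np.searchsorted(edges, days.to_numpy(), side="right") - 1
    idx = np.clip(idx, 0, len(WAVES))
    wave = labels[idx]
    out = merged[["participant_id", "instance_id", "survey_type"]].copy()
    out["days"] = days.to_numpy()
    out["wave"] = wave
    return out


def apply_eligibility(
    participants: pd.DataFrame,
    assignments: pd.DataFrame,
    min_followup_days: int = 365,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the two eligibility exclusions, in order.

    1. Participants with ``followup_days`` below ``min_followup_days`` are
       dropped (the study requires a full year of potential follow-up).
    2. Among participants who returned anything, those whose earliest return
       falls on day 90 or later are dropped: they have no baseline anchor.

    Non-returners survive both rules.  Returns ``(eligible, exclusions)``
    where ``eligible`` is the retained slice of ``participants`` and
    ``exclusions`` logs one row per dropped participant with its rule.
    """
    parts = participants
    exclusions = []

    short = parts["followup_days"].to_numpy() < min_followup_days
    for pid in parts.loc[short, "id"]:
        exclusions.append({"participant_id": pid, "rule": RULE_SHORT_FOLLOWUP})
    parts = parts.loc[~short]

    if len(assignments):
        first_return = assignments.groupby("participant_id")["days"].min()
        late = first_return[first_return >= 90].index
        late = [pid for pid in late if pid in set(parts["id"])]
    else:
        late = []
    for pid in late:
        exclusions.append({"participant_id": pid, "rule": RULE_LATE_FIRST_RETURN})
    parts = parts.loc[~parts["id"].isin(set(late))]

    exclusions_df = pd.DataFrame(exclusions, columns=["participant_id", "rule"])
    return parts.reset_index(drop=True), exclusions_df


def eligible_ids(
    participants: pd.DataFrame,
    assignments: pd.DataFrame,
    min_followup_days: int = 365,
) -> Iterable[str]:
    """Convenience: the eligible participant id set."""
    eligible, _ = apply_eligibility(participants, assignments, min_followup_days)
    return eligible["id"].tolist()
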