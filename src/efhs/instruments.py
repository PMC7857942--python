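"""Survey instruments, deployment schedule, and protocol time windows.

The eCohort protocol deploys health surveys on a smartphone app at
registration (baseline) and every three months for one year.  Nine surveys
are deployed at baseline; the physical-activity survey repeats at every
follow-up wave; medical-history update, depressive symptoms (CES-D) and the
health survey repeat at 6 and 12 months; medications/risk-factors, smoking
and alcohol repeat at 12 months — 22 deployed surveys in total.
"""

from __future__ import annotations

from typing import Dict, Mapping, Tuple

WAVES: Tuple[str, ...] = ("baseline", "m3", "m6", "m9", "m12")

#: Inclusive day-index windows from registration for each wave.
WINDOWS: Dict[str, Tuple[int, int]] = {
    "baseline": (0, 89),
    "m3": (90, 179),
    "m6": (180, 269),
    "m9": (270, 359),
    "m12": (360, 449),
}

#: Number of questions per survey instrument.  The physical activity (5
#: duration items), CES-D (20 items) and alcohol (2 items) counts are fixed
#: by the instruments themselves; the remaining counts are representative
#: lengths for surveys that are analysed only as completion counts.
SURVEY_ITEM_COUNTS: Dict[str, int] = {
    "sociodemographic": 12,
    "smoking": 8,
    "meds_risk_factors": 14,
    "cvd_history": 10,
    "noncvd_history": 16,
    "pai": 5,
    "alcohol": 2,
    "health": 12,
    "cesd": 20,
    "med_history_update": 32,
}

#: Survey types deployed at each wave (22 instances over the five waves).
DEFAULT_SCHEDULE: Dict[str, Tuple[str, ...]] = {
    "baseline": (
        "sociodemographic",
        "smoking",
        "meds_risk_factors",
        "cvd_history",
        "noncvd_history",
        "pai",
        "alcohol",
        "health",
        "cesd",
    ),
    "m3": ("pai",),
    "m6": ("pai", "med_history_update", "cesd", "health"),
    "m9": ("pai",),
    "m12": (
        "pai",
        "med_history_update",
        "cesd",
        "health",
        "meds_risk_factors",
        "smoking",
        "alcohol",
    ),
}

#: Analysed measure -> survey instrument that carries its items.
MEASURE_SURVEY: Dict[str, str] = {
    "pai": "pai",
    "cesd_sum": "cesd",
    "drinks_per_week": "alcohol",
}

#: Waves at which each analysed measure is collected under the default
#: schedule (derived, kept explicit for readability).
MEASURE_WAVES: Dict[str, Tuple[str, ...]] = {
    "pai": ("baseline", "m3", "m6", "m9", "m12"),
    "cesd_sum": ("baseline", "m6", "m12"),
    "drinks_per_week": ("baseline", "m12"),
}


def n_deployed(schedule: Mapping[str, Tuple[str, ...]]) -> int:
    """Total number of survey instances deployed per participant."""
    return sum(len(v) for v in schedule.values())
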