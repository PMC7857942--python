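"""Completion rule, adherence metrics, and timing summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from efhs.adherence import (
    CompletionRule,
    adherence_all,
    adherence_any,
    adherence_table,
    is_complete,
    timing_metrics,
)
from efhs.errors import ConfigError, DataError
from efhs.instruments import WAVES
from oracles import brute_force_adherence

DAY = 86400


@pytest.mark.parametrize(
    "n_answered, n_total, expected",
    [
        (15, 20, True),  # exactly 75%
        (14, 20, False),  # 70%
        (3, 4, True),  # exactly 75% on a short instrument
        (0, 5, False),
        (5, 5, True),
    ],
)
def test_is_complete_75_percent_rule(n_answered, n_total, expected):
    responses = [1.0] * n_answered + [None] * (n_total - n_answered)
    assert is_complete(responses) is expected


def test_zero_item_instrument_is_a_data_error():
    with pytest.raises(DataError):
        is_complete([])


def test_invalid_threshold_rejected():
    with pytest.raises(ConfigError):
        CompletionRule(0.0)
    with pytest.raises(ConfigError):
        CompletionRule(1.2)


@given(st.integers(1, 40), st.integers(0, 40))
def test_is_complete_matches_fraction_comparison(total, answered):
    answered = min(answered, total)
    responses = [0.0] * answered + [None] * (total - answered)
    assert is_complete(responses) == (answered / total >= 0.75)


def _scenario(records):
    """records: (pid, instance, stype, wave, completed)."""
    assignments = pd.DataFrame(
        [(p, i, s, 0, w) for p, i, s, w, _ in records],
        columns=["participant_id", "instance_id", "survey_type", "days", "wave"],
    )
    completed = pd.Series({i: c for _, i, _, _, c in records})
    return assignments, completed


TOY_SCHEDULE = {
    "baseline": ("pai", "cesd"),
    "m3": ("pai",),
    "m6": ("pai",),
    "m9": ("pai",),
    "m12": ("pai", "alcohol"),
}


def test_adherence_on_hand_listed_toy_cohort():
    eligible = [f"p{i}" for i in range(10)]
    records = [
        # p0 completes both baseline surveys; p1 completes one; p2 returns
        # an incomplete survey only; p3 returns nothing
        ("p0", "i1", "pai", "baseline", True),
        ("p0", "i2", "cesd", "baseline", True),
        ("p1", "i3", "pai", "baseline", True),
        ("p2", "i4", "pai", "baseline", False),
        ("p4", "i5", "pai", "baseline", True),
        ("p4", "i6", "cesd", "baseline", True),
        ("p4", "i7", "pai", "m3", True),
        ("p5", "i8", "pai", "m3", True),
        ("p6", "i9", "alcohol", "m12", True),
    ]
    assignments, completed = _scenario(records)
    table = adherence_table(assignments, completed, TOY_SCHEDULE, eligible)
    by_wave = table.set_index("wave")
    # hand counts
    assert by_wave.loc["baseline", "n_any"] == 3  # p0, p1, p4
    assert by_wave.loc["baseline", "n_all"] == 2  # p0, p4
    assert by_wave.loc["m3", "n_any"] == 2
    assert by_wave.loc["m3", "n_all"] == 2
    assert by_wave.loc["m12", "n_any"] == 1
    assert by_wave.loc["m12", "n_all"] == 0  # alcohol only, pai missing
    assert (by_wave["denominator"] == 10).all()
    assert by_wave.loc["baseline", "p_any"] == pytest.approx(0.3)


def test_adherence_matches_brute_force_on_random_small_cohorts():
    rng = np.random.default_rng(42)
    for trial in range(10):
        n = int(rng.integers(3, 21))
        eligible = [f"p{i}" for i in range(n)]
        records = []
        k = 0
        for pid in eligible:
            for wave in WAVES:
                for stype in TOY_SCHEDULE[wave]:
                    if rng.random() < 0.5:
                        records.append((pid, f"i{k}", stype, wave, bool(rng.random() < 0.8)))
                        k += 1
        if not records:
            continue
        assignments, completed = _scenario(records)
        table = adherence_table(assignments, completed, TOY_SCHEDULE, eligible)
        oracle = brute_force_adherence(
            [(p, w, s, c) for p, i, s, w, c in records], TOY_SCHEDULE, eligible, WAVES
        )
        for rec in table.itertuples(index=False):
            assert (rec.n_any, rec.n_all) == oracle[rec.wave], f"trial {trial}, {rec.wave}"


def test_p_all_never_exceeds_p_any():
    rng = np.random.default_rng(7)
    for _ in range(20):
        n = int(rng.integers(2, 15))
        eligible = [f"p{i}" for i in range(n)]
        records = []
        k = 0
        for pid in eligible:
            for wave in WAVES:
                for stype in TOY_SCHEDULE[wave]:
                    if rng.random() < 0.6:
                        records.append((pid, f"i{k}", stype, wave, bool(rng.random() < 0.7)))
                        k += 1
        assignments, completed = _scenario(records)
        table = adherence_table(assignments, completed, TOY_SCHEDULE, eligible)
        assert (table["n_all"] <= table["n_any"]).all()
        assert (table["n_any"] <= table["denominator"]).all()


def test_adding_a_completed_survey_is_monotone():
    eligible = ["a", "b", "c"]
    records = [("a", "i1", "pai", "baseline", True)]
    assignments, completed = _scenario(records)
    before = adherence_table(assignments, completed, TOY_SCHEDULE, eligible)
    records.append(("b", "i2", "cesd", "baseline", True))
    assignments2, completed2 = _scenario(records)
    after = adherence_table(assignments2, completed2, TOY_SCHEDULE, eligible)
    assert (after["n_any"] >= before["n_any"]).all()
    assert (after["n_all"] >= before["n_all"]).all()


def test_single_scheduled_survey_makes_metrics_agree():
    """Waves with one scheduled type have p_all == p_any."""
    eligible = ["a", "b", "c", "d"]
    records = [
        ("a", "i1", "pai", "m3", True),
        ("b", "i2", "pai", "m3", True),
        ("c", "i3", "pai", "m3", False),
    ]
    assignments, completed = _scenario(records)
    table = adherence_table(assignments, completed, TOY_SCHEDULE, eligible).set_index("wave")
    assert table.loc["m3", "p_any"] == table.loc["m3", "p_all"] == pytest.approx(0.5)


def test_missing_wave_in_schedule_is_a_config_error():
    assignments, completed = _scenario([("a", "i1", "pai", "baseline", True)])
    with pytest.raises(ConfigError):
        adherence_all(assignments, completed, {"baseline": ("pai",)}, ["a"])


def test_empty_eligible_set_reports_missing_proportions():
    assignments, completed = _scenario([("a", "i1", "pai", "baseline", True)])
    table = adherence_any(assignments, completed, [])
    assert table["p_any"].isna().all()


def _returns(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "instance_id",
            "survey_type",
            "deployment_ts",
            "start_ts",
            "return_ts",
            "step_ts",
        ],
    )


def _assign(rows):
    return pd.DataFrame(
        rows, columns=["participant_id", "instance_id", "survey_type", "days", "wave"]
    )


def test_timing_single_instance():
    ret = _returns([("a", "i1", "pai", 0, DAY, 2 * DAY, f"{DAY + 100};{2 * DAY}")])
    assigns = _assign([("a", "i1", "pai", 2, "baseline")])
    out = timing_metrics(ret, assigns)
    ret_row = out[out["metric"] == "return_time_days"].iloc[0]
    assert ret_row["median"] == pytest.approx(2.0)
    assert ret_row["q3"] - ret_row["q1"] == pytest.approx(0.0)
    touch_row = out[out["metric"] == "touch_time_minutes"].iloc[0]
    assert touch_row["median"] == pytest.approx(DAY / 60.0)


def test_timing_quartiles_match_hand_computation():
    """Return times 1,2,3,4,10 days -> median 3, quartiles 2 and 4."""
    rows = []
    assigns = []
    for j, d in enumerate([1, 2, 3, 4, 10]):
        rows.append(
            (f"p{j}", f"i{j}", "pai", 0, d * DAY - 600, d * DAY, str(d * DAY))
        )
        assigns.append((f"p{j}", f"i{j}", "pai", d, "baseline"))
    out = timing_metrics(_returns(rows), _assign(assigns))
    row = out[out["metric"] == "return_time_days"].iloc[0]
    assert (row["q1"], row["median"], row["q3"]) == pytest.approx((2.0, 3.0, 4.0))
    touch = out[out["metric"] == "touch_time_minutes"].iloc[0]
    assert touch["median"] == pytest.approx(10.0)


def test_timing_drops_misordered_instances():
    rows = [
        ("a", "ok", "pai", 0, 100, 200, "200"),
        ("a", "bad", "pai", 0, 300, 200, "200"),  # start after return
    ]
    assigns = _assign(
        [("a", "ok", "pai", 0, "baseline"), ("a", "bad", "pai", 0, "baseline")]
    )
    out = timing_metrics(_returns(rows), assigns)
    assert (out[out["metric"] == "return_time_days"]["n"] == 1).all()
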