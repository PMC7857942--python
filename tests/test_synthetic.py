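"""Statistical and structural properties of the synthetic cohort generator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from efhs.agreement import ccc, make_pairs
from efhs.errors import ConfigError
from efhs.instruments import SURVEY_ITEM_COUNTS, WINDOWS
from efhs.scoring import score_measures
from efhs.synthetic import (
    CohortConfig,
    expected_ccc,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from efhs.windowing import assign_windows

ALL_TYPES = list(SURVEY_ITEM_COUNTS)


def _full_return_config(**kw):
    """Everyone returns everything; no missing items."""
    base = dict(
        n_participants=50,
        n_nonenrolled=0,
        seed=5,
        wave_return_prob={w: 1.0 for w in WINDOWS},
        ever_return_prob=1.0,
        covariate_effects={},
        survey_return_prob={t: 1.0 for t in ALL_TYPES},
        item_missing_prob=0.0,
    )
    base.update(kw)
    return CohortConfig(**base)


class TestConfig:
    def test_default_schedule_deploys_22_surveys(self):
        assert CohortConfig().n_deployed_surveys == 22

    @pytest.mark.parametrize(
        "kw",
        [
            {"n_participants": -1},
            {"item_missing_prob": 1.5},
            {"wave_return_prob": {"baseline": -0.1}},
            {"ever_return_prob": 0.0},
            {"agreement_params": {"pai": {"delta": 0, "sigma_clinic": -1, "sigma_app": 1}}},
            {"schedule": {"baseline": ("unknown_survey",)}},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigError):
            CohortConfig.from_dict(kw)

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        cfg = CohortConfig(n_participants=10, seed=3)
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        assert CohortConfig.from_yaml(path).to_dict() == cfg.to_dict()


class TestDeterminism:
    def test_same_seed_gives_identical_tables(self):
        cfg = CohortConfig(n_participants=60, n_nonenrolled=20, seed=9)
        t1 = generate_cohort(cfg)
        t2 = generate_cohort(CohortConfig(n_participants=60, n_nonenrolled=20, seed=9))
        for name in t1:
            pd.testing.assert_frame_equal(t1[name], t2[name])

    def test_different_seed_differs(self):
        t1 = generate_cohort(CohortConfig(n_participants=60, seed=1))
        t2 = generate_cohort(CohortConfig(n_participants=60, seed=2))
        assert not t1["clinic"]["value"].equals(t2["clinic"]["value"])

    def test_write_read_round_trip(self, tmp_path, small_cohort):
        _, tables = small_cohort
        write_cohort(tables, tmp_path)
        back = read_cohort(tmp_path)
        for name in tables:
            pd.testing.assert_frame_equal(tables[name], back[name])

    def test_empty_cohort_writes_valid_header_only_files(self, tmp_path):
        tables = generate_cohort(CohortConfig(n_participants=0, n_nonenrolled=0))
        write_cohort(tables, tmp_path)
        back = read_cohort(tmp_path)
        for name in tables:
            assert len(back[name]) == 0
            assert list(back[name].columns) == list(tables[name].columns)


class TestStructure:
    def test_full_return_config_returns_every_scheduled_survey(self):
        cfg = _full_return_config()
        tables = generate_cohort(cfg)
        assert len(tables["survey_returns"]) == 50 * 22
        per_participant = tables["survey_returns"].groupby("participant_id").size()
        assert (per_participant == 22).all()

    def test_participant_ids_unique_and_default_size(self):
        tables = generate_cohort(CohortConfig(seed=0, n_nonenrolled=0))
        parts = tables["participants"]
        assert parts["id"].is_unique
        assert (parts["enrolled"] == 1).sum() == 1948

    def test_instrument_item_counts(self, small_cohort):
        _, tables = small_cohort
        counts = tables["responses"].groupby("instance_id")["item_index"].count()
        stypes = tables["survey_returns"].set_index("instance_id")["survey_type"]
        for stype, expected in SURVEY_ITEM_COUNTS.items():
            instances = stypes[stypes == stype].index
            if len(instances):
                assert (counts.loc[instances] == expected).all()

    def test_timestamp_ordering(self, small_cohort):
        _, tables = small_cohort
        sr = tables["survey_returns"]
        assert (sr["deployment_ts"] <= sr["start_ts"]).all()
        assert (sr["start_ts"] <= sr["return_ts"]).all()

    def test_returns_fall_inside_their_intended_wave(self, small_cohort):
        _, tables = small_cohort
        assigns = assign_windows(tables["survey_returns"], tables["participants"])
        # instance ids embed the intended wave
        intended = assigns["instance_id"].str.split("-").str[1]
        assert (assigns["wave"] == intended).all()

    def test_one_clinic_record_per_participant_and_measure(self, small_cohort):
        _, tables = small_cohort
        assert not tables["clinic"].duplicated(["participant_id", "measure"]).any()


class TestStatisticalProperties:
    def test_baseline_return_fraction_matches_configured_probability(self):
        """n=5000, baseline return probability 0.89 -> fraction within 0.02."""
        cfg = CohortConfig(
            n_participants=5000,
            n_nonenrolled=0,
            seed=21,
            schedule={"baseline": ("pai", "cesd", "alcohol")},
            wave_return_prob={"baseline": 0.89},
        )
        tables = generate_cohort(cfg)
        returners = tables["survey_returns"]["participant_id"].nunique()
        assert returners / 5000 == pytest.approx(0.89, abs=0.02)

    def test_returns_exchangeable_across_sex_without_covariate_effects(self):
        cfg = CohortConfig(
            n_participants=4000,
            n_nonenrolled=0,
            seed=13,
            covariate_effects={},
            schedule={"baseline": ("pai",)},
            wave_return_prob={"baseline": 0.6},
            ever_return_prob=0.9,
        )
        tables = generate_cohort(cfg)
        parts = tables["participants"]
        returned = parts["id"].isin(set(tables["survey_returns"]["participant_id"]))
        tab = pd.crosstab(parts["female"], returned)
        _, p, _, _ = stats.chi2_contingency(tab, correction=False)
        assert p > 0.01
        rates = returned.groupby(parts["female"]).mean()
        assert abs(rates.loc[0] - rates.loc[1]) < 0.05

    def test_covariate_effect_shifts_return_odds(self):
        cfg = CohortConfig(
            n_participants=8000,
            n_nonenrolled=0,
            seed=17,
            covariate_effects={"female": np.log(2.5)},
            schedule={"baseline": ("pai",)},
            wave_return_prob={"baseline": 0.5},
            ever_return_prob=0.6,
        )
        tables = generate_cohort(cfg)
        parts = tables["participants"]
        returned = parts["id"].isin(set(tables["survey_returns"]["participant_id"]))
        rates = returned.groupby(parts["female"]).mean()
        odds = rates / (1 - rates)
        assert odds.loc[1] / odds.loc[0] == pytest.approx(2.5, rel=0.25)

    def test_scored_app_values_recover_expected_ccc(self):
        """Empirical CCC against the closed form, n=5000, all measures.

        Uses trait settings well inside each instrument's range so boundary
        clipping is negligible; tau^2 is estimated from the clinic side
        (variance minus clinic noise), independent of the app pairing.
        """
        cfg = _full_return_config(
            n_participants=5000,
            seed=7,
            schedule={"baseline": ("pai", "cesd", "alcohol")},
            trait_params={
                "pai": {"alpha": (8, 10, 4, 1.5, 0.5), "concentration": 30},
                "cesd_sum": {"mean": 30, "sd": 6},
                "drinks_per_week": {"mean": 12, "sd": 3},
            },
            agreement_params={
                "pai": {"delta": 0.5, "sigma_clinic": 1.0, "sigma_app": 1.0},
                "cesd_sum": {"delta": 0.5, "sigma_clinic": 2.0, "sigma_app": 2.0},
                "drinks_per_week": {"delta": 0.5, "sigma_clinic": 1.0, "sigma_app": 1.0},
            },
        )
        tables = generate_cohort(cfg)
        assigns = assign_windows(tables["survey_returns"], tables["participants"])
        scores = score_measures(assigns, tables["survey_returns"], tables["responses"])
        for measure in ("pai", "cesd_sum", "drinks_per_week"):
            x, y, _ = make_pairs(tables["clinic"], scores, measure)
            prm = cfg.agreement_params[measure]
            tau2 = float(np.var(x)) - prm["sigma_clinic"] ** 2
            assert ccc(x, y).estimate == pytest.approx(
                expected_ccc(prm, tau2), abs=0.02
            ), measure


class TestExpectedCcc:
    def test_perfect_agreement(self):
        assert expected_ccc({"delta": 0, "sigma_clinic": 0, "sigma_app": 0}, 1.0) == 1.0

    def test_hand_arithmetic(self):
        prm = {"delta": 0.5, "sigma_clinic": np.sqrt(0.125), "sigma_app": np.sqrt(0.125)}
        assert expected_ccc(prm, 1.0) == pytest.approx(0.8)

    def test_large_bias_drives_ccc_to_zero(self):
        prm = {"delta": 1e6, "sigma_clinic": 1, "sigma_app": 1}
        assert expected_ccc(prm, 1.0) < 1e-9

    def test_nonpositive_trait_variance_rejected(self):
        with pytest.raises(ConfigError):
            expected_ccc({"delta": 0, "sigma_clinic": 1, "sigma_app": 1}, 0.0)
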