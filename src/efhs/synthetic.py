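"""Synthetic eCohort generator.

Emulates the data a smartphone-app survey study produces: a participant
table with exam covariates, a survey-event table with deployment / start /
return / per-step timestamps, a long item-response table, and a paired
clinic-measurement table.  The generator is the test bed for every
downstream stage, so its statistical structure matches what the analysis
assumes:

* each participant's wave-level return indicator is Bernoulli on the logit
  scale: ``logit(p_wave) + covariate effects`` (covariates are centred so
  ``p_wave`` stays the marginal return probability);
* a latent trait ``t`` per analysed measure is drawn once per participant;
  the clinic value is ``t + N(0, sigma_clinic^2)`` and the app item
  responses are constructed so the *scored* app value is
  ``t + delta + wave effect + N(0, sigma_app^2)`` — which makes the
  population concordance between app and clinic available in closed form
  (see :func:`expected_ccc`);
* item responses are independently missing with a configurable probability;
* survey timing (start lag after deployment, touch duration) is lognormal,
  with returns guaranteed to land inside the intended wave's day range.

One master seed drives independent named substreams, so adding a table does
not perturb existing draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .errors import ConfigError
from .instruments import (
    DEFAULT_SCHEDULE,
    SURVEY_ITEM_COUNTS,
    WAVES,
    WINDOWS,
    n_deployed,
)
from .scoring import CESD_REVERSE_CODED, PAI_WEIGHT_ARRAY

#: Epoch of 2017-01-01 00:00 UTC; registrations are scattered over the year.
REGISTRATION_EPOCH = 1483228800

MEASURES = ("pai", "cesd_sum", "drinks_per_week")

#: Covariate distributions for enrolled participants (eCohort column) and
#: for the comparison group that declined or was ineligible.
ENROLLED_COVARIATES = {
    "age_mean": 52.8,
    "age_sd": 8.7,
    "female": 0.5693,
    "current_smoker": 0.0555,
    "education": (0.0067, 0.0866, 0.2408, 0.3822, 0.2837),
    "married": 0.7473,
    "employed": 0.7019,
    "bmi_log_median": math.log(27.3),
    "bmi_log_sd": 0.1875,
}
NONENROLLED_COVARIATES = {
    "age_mean": 56.6,
    "age_sd": 9.8,
    "female": 0.4994,
    "current_smoker": 0.0799,
    "education": (0.0226, 0.1946, 0.2851, 0.3096, 0.1881),
    "married": 0.6515,
    "employed": 0.5932,
    "bmi_log_median": math.log(28.2),
    "bmi_log_sd": 0.2086,
}

EDUCATION_LEVELS = (
    "less_than_high_school",
    "high_school",
    "some_college",
    "bachelor",
    "graduate",
)


def _default_wave_return_prob() -> Dict[str, float]:
    return {"baseline": 0.89, "m3": 0.58, "m6": 0.52, "m9": 0.41, "m12": 0.40}


def _default_covariate_effects() -> Dict[str, float]:
    return {"female": math.log(1.58), "current_smoker": math.log(0.53)}


def _default_survey_return_prob() -> Dict[str, float]:
    probs = {stype: 0.97 for stype in SURVEY_ITEM_COUNTS}
    # the long, open-ended medical-history update is rarely completed
    probs["med_history_update"] = 0.04
    return probs


def _default_trait_params() -> Dict[str, dict]:
    # PAI trait SD ~4 points (concentration 14 on the activity-hour Dirichlet),
    # consistent with a cohort interquartile range of roughly 30-36.
    return {
        "pai": {"alpha": (8.0, 10.0, 4.0, 1.5, 0.5), "concentration": 14.0},
        "cesd_sum": {"mean": 7.0, "sd": 5.0},
        "drinks_per_week": {"mean": 3.5, "sd": 4.0},
    }


def _default_agreement_params() -> Dict[str, dict]:
    # deltas are the app-minus-clinic biases the study context suggests
    # (app reports slightly higher activity); noise SDs are set so the
    # population concordance is moderate for PAI and high for CES-D and
    # alcohol, as observed for these instruments.
    return {
        "pai": {"delta": 2.27, "sigma_clinic": 3.2, "sigma_app": 3.2},
        "cesd_sum": {"delta": 0.03, "sigma_clinic": 2.4, "sigma_app": 2.4},
        "drinks_per_week": {"delta": 0.54, "sigma_clinic": 1.5, "sigma_app": 1.5},
    }


def _default_wave_effects() -> Dict[str, Dict[str, float]]:
    return {"cesd_sum": {"m6": 1.01, "m12": 0.84}}


def _default_timing_params() -> Dict[str, float]:
    return {
        "start_lag_median_days": 1.7,
        "start_lag_log_sd": 1.0,
        "touch_median_minutes": 3.0,
        "touch_log_sd": 0.6,
    }


@dataclass
class CohortConfig:
    """Configuration for one synthetic cohort."""

    n_participants: int = 1948
    n_nonenrolled: int = 1566
    seed: int = 0
    wave_return_prob: Dict[str, float] = field(default_factory=_default_wave_return_prob)
    ever_return_prob: float = 0.906
    covariate_effects: Dict[str, float] = field(default_factory=_default_covariate_effects)
    survey_return_prob: Dict[str, float] = field(default_factory=_default_survey_return_prob)
    item_missing_prob: float = 0.02
    trait_params: Dict[str, dict] = field(default_factory=_default_trait_params)
    agreement_params: Dict[str, dict] = field(default_factory=_default_agreement_params)
    wave_effects: Dict[str, Dict[str, float]] = field(default_factory=_default_wave_effects)
    timing_params: Dict[str, float] = field(default_factory=_default_timing_params)
    schedule: Dict[str, Tuple[str, ...]] = field(
        default_factory=lambda: {w: tuple(v) for w, v in DEFAULT_SCHEDULE.items()}
    )
    short_followup_fraction: float = 0.0
    return_intercept_sd: float = 0.0

    def validate(self) -> None:
        if self.n_participants < 0 or self.n_nonenrolled < 0:
            raise ConfigError("participant counts must be nonnegative")
        for wave, p in self.wave_return_prob.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"wave_return_prob[{wave!r}]={p} outside [0,1]")
        if not (0.0 < self.ever_return_prob <= 1.0):
            raise ConfigError("ever_return_prob outside (0,1]")
        for stype, p in self.survey_return_prob.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"survey_return_prob[{stype!r}]={p} outside [0,1]")
        if not (0.0 <= self.item_missing_prob <= 1.0):
            raise ConfigError("item_missing_prob outside [0,1]")
        if not (0.0 <= self.short_followup_fraction <= 1.0):
            raise ConfigError("short_followup_fraction outside [0,1]")
        if self.return_intercept_sd < 0:
            raise ConfigError("return_intercept_sd must be >= 0")
        for measure, ap in self.agreement_params.items():
            if ap["sigma_clinic"] < 0 or ap["sigma_app"] < 0:
                raise ConfigError(f"negative noise SD for {measure}")
        for wave in self.schedule:
            if wave not in WAVES:
                raise ConfigError(f"unknown wave {wave!r} in schedule")
        unknown = {
            s for types in self.schedule.values() for s in types
        } - set(SURVEY_ITEM_COUNTS)
        if unknown:
            raise ConfigError(f"unknown survey types in schedule: {sorted(unknown)}")

    @property
    def n_deployed_surveys(self) -> int:
        return n_deployed(self.schedule)

    def to_dict(self) -> dict:
        return {
            "n_participants": self.n_participants,
            "n_nonenrolled": self.n_nonenrolled,
            "seed": self.seed,
            "wave_return_prob": dict(self.wave_return_prob),
            "ever_return_prob": self.ever_return_prob,
            "covariate_effects": dict(self.covariate_effects),
            "survey_return_prob": dict(self.survey_return_prob),
            "item_missing_prob": self.item_missing_prob,
            "trait_params": {
                k: {
                    kk: list(vv) if isinstance(vv, (tuple, list)) else vv
                    for kk, vv in v.items()
                }
                for k, v in self.trait_params.items()
            },
            "agreement_params": {k: dict(v) for k, v in self.agreement_params.items()},
            "wave_effects": {k: dict(v) for k, v in self.wave_effects.items()},
            "timing_params": dict(self.timing_params),
            "schedule": {w: list(v) for w, v in self.schedule.items()},
            "short_followup_fraction": self.short_followup_fraction,
            "return_intercept_sd": self.return_intercept_sd,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        cfg = cls()
        for key, value in d.items():
            if not hasattr(cfg, key):
                raise ConfigError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, dict) and isinstance(value, Mapping):
                merged = dict(current)
                merged.update(value)
                value = merged
            setattr(cfg, key, value)
        cfg.schedule = {w: tuple(v) for w, v in cfg.schedule.items()}
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def expected_ccc(agreement_params: Mapping[str, float], trait_variance: float) -> float:
    """Population concordance between clinic and app values.

    With clinic = t + e_c and app = t + delta + e_a for a latent trait with
    variance tau^2, the population CCC is
    ``2 tau^2 / (2 tau^2 + sigma_c^2 + sigma_a^2 + delta^2)``.
    """
    if trait_variance <= 0:
        raise ConfigError("trait variance must be positive")
    sc = agreement_params["sigma_clinic"]
    sa = agreement_params["sigma_app"]
    if sc < 0 or sa < 0:
        raise ConfigError("noise SDs must be >= 0")
    delta = agreement_params["delta"]
    tau2 = trait_variance
    return 2 * tau2 / (2 * tau2 + sc**2 + sa**2 + delta**2)


def generate_cohort(config: CohortConfig) -> Dict[str, pd.DataFrame]:
    """Generate all four tables. Deterministic given ``config.seed``."""
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_part, rng_trait, rng_return, rng_resp, rng_time, rng_clinic = (
        np.random.default_rng(s) for s in streams
    )

    participants = _generate_participants(config, rng_part)
    enrolled = participants[participants["enrolled"] == 1].reset_index(drop=True)
    traits, base_hours = _generate_traits(config, len(enrolled), rng_trait)

    instance_index = _generate_return_indicators(config, enrolled, rng_return)
    survey_returns, responses = _generate_instances(
        config, enrolled, traits, base_hours, instance_index, rng_resp, rng_time
    )
    clinic = _generate_clinic(config, enrolled, traits, rng_clinic)
    return {
        "participants": participants,
        "survey_returns": survey_returns,
        "responses": responses,
        "clinic": clinic,
    }


# ---------------------------------------------------------------------------
# participants


def _draw_covariates(params: Mapping, n: int, rng: np.random.Generator) -> dict:
    age = np.clip(rng.normal(params["age_mean"], params["age_sd"], n), 25, 90)
    edu = rng.choice(
        len(EDUCATION_LEVELS), size=n, p=np.asarray(params["education"]) / sum(params["education"])
    )
    return {
        "age": np.round(age, 1),
        "female": (rng.random(n) < params["female"]).astype(int),
        "current_smoker": (rng.random(n) < params["current_smoker"]).astype(int),
        "education": np.array(EDUCATION_LEVELS, dtype=object)[edu],
        "married": (rng.random(n) < params["married"]).astype(int),
        "employed": (rng.random(n) < params["employed"]).astype(int),
        "bmi": np.round(
            np.exp(rng.normal(params["bmi_log_median"], params["bmi_log_sd"], n)), 1
        ),
    }


def _generate_participants(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n, m = config.n_participants, config.n_nonenrolled
    frames = []

    cov = _draw_covariates(ENROLLED_COVARIATES, n, rng)
    reg = (
        REGISTRATION_EPOCH
        + rng.integers(0, 365, n) * 86400
        + rng.integers(0, 86400, n)
    )
    followup = 450 + rng.integers(0, 200, n)
    if config.short_followup_fraction > 0 and n > 0:
        short = rng.random(n) < config.short_followup_fraction
        followup = np.where(short, rng.integers(60, 365, n), followup)
    frames.append(
        pd.DataFrame(
            {
                "id": [f"P{i:06d}" for i in range(n)],
                "registration_ts": reg.astype("int64"),
                "enrolled": 1,
                "followup_days": followup.astype(int),
                **cov,
            }
        )
    )

    cov_ne = _draw_covariates(NONENROLLED_COVARIATES, m, rng)
    frames.append(
        pd.DataFrame(
            {
                "id": [f"N{i:06d}" for i in range(m)],
                "registration_ts": np.zeros(m, dtype="int64"),
                "enrolled": 0,
                "followup_days": np.zeros(m, dtype=int),
                **cov_ne,
            }
        )
    )
    cols = [
        "id",
        "registration_ts",
        "enrolled",
        "followup_days",
        "age",
        "female",
        "current_smoker",
        "education",
        "married",
        "employed",
        "bmi",
    ]
    return pd.concat(frames, ignore_index=True)[cols]


# ---------------------------------------------------------------------------
# latent traits


def _generate_traits(
    config: CohortConfig, n: int, rng: np.random.Generator
) -> Tuple[pd.DataFrame, np.ndarray]:
    tp = config.trait_params
    alpha = np.asarray(tp["pai"]["alpha"], dtype=float)
    conc = float(tp["pai"]["concentration"])
    if n > 0:
        hours = rng.dirichlet(alpha / alpha.sum() * conc, size=n) * 24.0
    else:
        hours = np.zeros((0, 5))
    t_pai = hours @ PAI_WEIGHT_ARRAY

    cm, cs = tp["cesd_sum"]["mean"], tp["cesd_sum"]["sd"]
    t_cesd = truncnorm.rvs(
        (0 - cm) / cs, (60 - cm) / cs, loc=cm, scale=cs, size=n, random_state=rng
    )
    dm, ds = tp["drinks_per_week"]["mean"], tp["drinks_per_week"]["sd"]
    t_drinks = np.clip(rng.normal(dm, ds, n), 0.0, None)

    traits = pd.DataFrame(
        {"pai": t_pai, "cesd_sum": t_cesd, "drinks_per_week": t_drinks}
    )
    return traits, hours


# ---------------------------------------------------------------------------
# survey returns


def _generate_return_indicators(
    config: CohortConfig, enrolled: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """One row per (participant index, wave, survey type) that gets returned.

    Returns follow a two-layer model.  A participant-level *ever-returner*
    indicator is Bernoulli on the logit scale — ``logit(ever_return_prob) +
    covariate effects`` with covariates centred, plus an optional random
    intercept — which is what the returner-characteristics logistic
    regression estimates.  Conditional on ever returning, each wave's return
    is an independent Bernoulli with probability ``wave_return_prob /
    ever_return_prob``, so the marginal wave return rate equals the
    configured ``wave_return_prob`` whenever ``ever_return_prob`` is at
    least the largest wave probability (when it is not, the conditional
    probability is capped at 1 and the marginal falls short).  Given a wave
    return, each scheduled survey type is returned with its own
    ``survey_return_prob``.
    """
    n = len(enrolled)
    shift = np.zeros(n)
    for cov, beta in config.covariate_effects.items():
        x = enrolled[cov].to_numpy(dtype=float)
        shift += beta * (x - x.mean() if n else x)
    if config.return_intercept_sd > 0:
        shift += rng.normal(0.0, config.return_intercept_sd, n)

    max_wave_p = max(
        (config.wave_return_prob.get(w, 0.0) for w in config.schedule), default=0.0
    )
    ever_p = max(config.ever_return_prob, max_wave_p)
    if ever_p >= 1.0:
        ever = np.ones(n, dtype=bool)
    else:
        ever = rng.random(n) < expit(logit(ever_p) + shift)

    rows = []
    for wave in WAVES:
        if wave not in config.schedule:
            continue
        p_cond = min(1.0, config.wave_return_prob.get(wave, 0.0) / ever_p)
        if p_cond <= 0.0:
            continue
        wave_ret = ever & (rng.random(n) < p_cond) if p_cond < 1.0 else ever.copy()
        for stype in config.schedule[wave]:
            tp = config.survey_return_prob.get(stype, 1.0)
            ret = wave_ret & (rng.random(n) < tp) if tp < 1.0 else wave_ret.copy()
            idx = np.nonzero(ret)[0]
            if idx.size:
                rows.append(
                    pd.DataFrame({"pidx": idx, "wave": wave, "survey_type": stype})
                )
    if not rows:
        return pd.DataFrame(columns=["pidx", "wave", "survey_type"])
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# instances, timing, responses


def _retarget_hours(hours: np.ndarray, target: float) -> np.ndarray:
    """Shift hours between intensity classes so the weighted sum hits target.

    Preserves the sum-to-24 constraint; any target in [24, 120] is reachable
    because moving an hour between classes changes the score by the weight
    difference.
    """
    h = hours.copy()
    w = PAI_WEIGHT_ARRAY
    score = float(h @ w)
    if target > score:
        for src in (0, 1, 2, 3):
            gain = w[4] - w[src]
            need = (target - score) / gain
            move = min(h[src], need)
            h[src] -= move
            h[4] += move
            score += move * gain
            if score >= target - 1e-9:
                break
    elif target < score:
        for src in (4, 3, 2, 1):
            drop = w[src] - w[0]
            need = (score - target) / drop
            move = min(h[src], need)
            h[src] -= move
            h[0] += move
            score -= move * drop
            if score <= target + 1e-9:
                break
    return h


def _wave_shift(config: CohortConfig, measure: str, wave: str) -> float:
    return float(config.wave_effects.get(measure, {}).get(wave, 0.0))


def _generate_instances(
    config: CohortConfig,
    enrolled: pd.DataFrame,
    traits: pd.DataFrame,
    base_hours: np.ndarray,
    index: pd.DataFrame,
    rng_resp: np.random.Generator,
    rng_time: np.random.Generator,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    ids = enrolled["id"].to_numpy()
    reg = enrolled["registration_ts"].to_numpy(dtype="int64")
    tparams = config.timing_params

    ret_frames = []
    resp_frames = []
    m_all = len(index)
    if m_all == 0:
        return _empty_returns(), _empty_responses()

    # timing draws for all instances at once
    lag_mu = math.log(tparams["start_lag_median_days"] * 86400.0)
    touch_mu = math.log(tparams["touch_median_minutes"] * 60.0)
    lag_all = rng_time.lognormal(lag_mu, tparams["start_lag_log_sd"], m_all)
    touch_all = rng_time.lognormal(touch_mu, tparams["touch_log_sd"], m_all)
    touch_all = np.clip(touch_all, 30.0, 7200.0)
    lag_all = np.minimum(lag_all, 85.0 * 86400.0)  # keep returns inside the window

    index = index.reset_index(drop=True)
    for (wave, stype), grp in index.groupby(["wave", "survey_type"], sort=True):
        m = len(grp)
        pidx = grp["pidx"].to_numpy()
        lag = lag_all[grp.index.to_numpy()]
        touch = touch_all[grp.index.to_numpy()]

        wave_start = WINDOWS[wave][0]
        deployment = reg[pidx] + wave_start * 86400
        start = deployment + lag.astype("int64")
        ret = start + np.maximum(1, touch.astype("int64"))

        n_items = SURVEY_ITEM_COUNTS[stype]
        frac = rng_time.dirichlet(np.ones(n_items), size=m)
        cum = np.cumsum(frac, axis=1) * touch[:, None]
        steps = start[:, None] + np.round(cum).astype("int64")
        steps = np.minimum(steps, ret[:, None])
        steps = np.maximum.accumulate(steps, axis=1)
        steps[:, -1] = ret

        instance_ids = np.array(
            [f"{ids[i]}-{wave}-{stype}" for i in pidx], dtype=object
        )
        ret_frames.append(
            pd.DataFrame(
                {
                    "participant_id": ids[pidx],
                    "instance_id": instance_ids,
                    "survey_type": stype,
                    "deployment_ts": deployment,
                    "start_ts": start,
                    "return_ts": ret,
                    "step_ts": [";".join(map(str, row)) for row in steps],
                }
            )
        )

        values = _generate_item_values(
            config, stype, wave, pidx, traits, base_hours, rng_resp
        )
        if config.item_missing_prob > 0:
            miss = rng_resp.random(values.shape) < config.item_missing_prob
            values = np.where(miss, np.nan, values)
        resp_frames.append(
            pd.DataFrame(
                {
                    "participant_id": np.repeat(ids[pidx], n_items),
                    "instance_id": np.repeat(instance_ids, n_items),
                    "item_index": np.tile(np.arange(n_items), m),
                    "value": values.ravel(),
                }
            )
        )

    survey_returns = pd.concat(ret_frames, ignore_index=True)
    responses = pd.concat(resp_frames, ignore_index=True)
    return survey_returns, responses


def _generate_item_values(
    config: CohortConfig,
    stype: str,
    wave: str,
    pidx: np.ndarray,
    traits: pd.DataFrame,
    base_hours: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    m = len(pidx)
    n_items = SURVEY_ITEM_COUNTS[stype]
    ap = config.agreement_params

    if stype == "pai":
        prm = ap["pai"]
        t = traits["pai"].to_numpy()[pidx]
        target = t + prm["delta"] + _wave_shift(config, "pai", wave)
        target = target + rng.normal(0.0, prm["sigma_app"], m)
        target = np.clip(target, 24.0, 120.0)
        out = np.empty((m, 5))
        for row, (i, tgt) in enumerate(zip(pidx, target)):
            out[row] = _retarget_hours(base_hours[i], float(tgt))
        return out

    if stype == "cesd":
        prm = ap["cesd_sum"]
        t = traits["cesd_sum"].to_numpy()[pidx]
        target = t + prm["delta"] + _wave_shift(config, "cesd_sum", wave)
        target = target + rng.normal(0.0, prm["sigma_app"], m)
        s = np.clip(np.round(target), 0, 60).astype(int)
        base, rem = s // 20, s % 20
        rank = rng.random((m, 20)).argsort(axis=1).argsort(axis=1)
        items = base[:, None] + (rank < rem[:, None]).astype(int)
        # store raw form: invert the standard reverse-coded items
        items = items.astype(float)
        for j in CESD_REVERSE_CODED:
            items[:, j] = 3.0 - items[:, j]
        return items

    if stype == "alcohol":
        prm = ap["drinks_per_week"]
        t = traits["drinks_per_week"].to_numpy()[pidx]
        target = t + prm["delta"] + _wave_shift(config, "drinks_per_week", wave)
        target = target + rng.normal(0.0, prm["sigma_app"], m)
        weekly = np.clip(target, 0.0, None)
        days = np.where(
            weekly <= 0.0,
            0,
            np.minimum(7, np.maximum(1, np.ceil(weekly / 3.0))).astype(int),
        )
        dpd = np.where(days > 0, weekly / np.maximum(days, 1), 0.0)
        return np.column_stack([dpd, days.astype(float)])

    # instruments analysed only as completion counts: generic 0..3 items
    return rng.integers(0, 4, size=(m, n_items)).astype(float)


def _generate_clinic(
    config: CohortConfig, enrolled: pd.DataFrame, traits: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    n = len(enrolled)
    frames = []
    for measure in MEASURES:
        prm = config.agreement_params[measure]
        value = traits[measure].to_numpy() + rng.normal(0.0, prm["sigma_clinic"], n)
        if measure == "pai":
            value = np.clip(value, 24.0, 120.0)
        elif measure == "cesd_sum":
            value = np.clip(np.round(value), 0, 60)
        else:
            value = np.clip(value, 0.0, None)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": enrolled["id"].to_numpy(),
                    "measure": measure,
                    "value": value,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["participant_id", "measure", "value"])
    return pd.concat(frames, ignore_index=True)


def _empty_returns() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "participant_id",
            "instance_id",
            "survey_type",
            "deployment_ts",
            "start_ts",
            "return_ts",
            "step_ts",
        ]
    )


def _empty_responses() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["participant_id", "instance_id", "item_index", "value"]
    )


# ---------------------------------------------------------------------------
# I/O

TABLE_FILES = {
    "participants": "participants.csv",
    "survey_returns": "survey_returns.csv",
    "responses": "responses.csv",
    "clinic": "clinic.csv",
}

_DTYPES = {
    "participants": {
        "id": str,
        "registration_ts": "int64",
        "enrolled": "int64",
        "followup_days": "int64",
        "age": float,
        "female": "int64",
        "current_smoker": "int64",
        "education": str,
        "married": "int64",
        "employed": "int64",
        "bmi": float,
    },
    "survey_returns": {
        "participant_id": str,
        "instance_id": str,
        "survey_type": str,
        "deployment_ts": "int64",
        "start_ts": "int64",
        "return_ts": "int64",
        "step_ts": str,
    },
    "responses": {
        "participant_id": str,
        "instance_id": str,
        "item_index": "int64",
        "value": float,
    },
    "clinic": {"participant_id": str, "measure": str, "value": float},
}


def write_cohort(tables: Mapping[str, pd.DataFrame], directory) -> Dict[str, Path]:
    """Write the four cohort tables as CSV; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, fname in TABLE_FILES.items():
        path = directory / fname
        tables[name].to_csv(path, index=False)
        paths[name] = path
    return paths


def read_cohort(directory) -> Dict[str, pd.DataFrame]:
    """Read tables written by :func:`write_cohort` (lossless round trip)."""
    directory = Path(directory)
    tables = {}
    for name, fname in TABLE_FILES.items():
        dtypes = {k: v for k, v in _DTYPES[name].items() if v != float}
        df = pd.read_csv(directory / fname, dtype=dtypes)
        for col, dt in _DTYPES[name].items():
            if col not in df.columns:
                raise ConfigError(f"{fname} missing column {col!r}")
            if dt is float:
                df[col] = df[col].astype(float)
        if name == "survey_returns" and len(df):
            df["step_ts"] = df["step_ts"].astype(str)
        tables[name] = df
    return tables
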