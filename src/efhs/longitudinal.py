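"""Longitudinal comparison of repeated measures across waves.

For measures observed at several waves the analysis subgroup is the set of
participants observed at *every* wave (complete-case balanced panel).  On a
balanced panel the random-intercept model

    value_it = mu + beta_wave + b_i + e_it,  b_i ~ N(0, tau^2), e ~ N(0, sigma^2)

has a closed form: the wave effects are the differences of wave sample means
from baseline, and the variance components follow from the within/between
mean squares of the two-way (participant x wave) ANOVA — identical to REML
on balanced data.  Alcohol use, observed at two waves only, is compared with
the classical paired t test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SampleSizeError, UnbalancedPanelError
from .instruments import WAVES


@dataclass
class TimeEffectFit:
    """Wave effects vs baseline plus variance components."""

    effects: pd.DataFrame  # wave, estimate, se, p
    tau2: float
    sigma2: float
    n_participants: int
    waves: tuple = field(default_factory=tuple)


def fit_random_intercept(long: pd.DataFrame) -> TimeEffectFit:
    """Fit the random-intercept wave-effect model on a balanced panel.

    ``long`` has columns participant_id, wave, value with at most one value
    per participant and wave.  Every participant must be observed at every
    wave present in the data; pre-filter to the complete-case subgroup
    before calling.  The first wave in protocol order is the reference.
    """
    waves = [w for w in WAVES if w in set(long["wave"])]
    if len(waves) < 2:
        raise SampleSizeError("need at least two waves")
    if long.duplicated(["participant_id", "wave"]).any():
        raise UnbalancedPanelError("duplicate participant x wave values")
    wide = long.pivot(index="participant_id", columns="wave", values="value")[waves]
    if wide.isna().any().any():
        raise UnbalancedPanelError(
            "panel is unbalanced; restrict to participants observed at all waves"
        )
    n, k = wide.shape
    if n < 2:
        raise SampleSizeError("need at least two participants")
    y = wide.to_numpy(dtype=float)
    grand = y.mean()
    wave_means = y.mean(axis=0)
    subj_means = y.mean(axis=1)

    resid = y - subj_means[:, None] - wave_means[None, :] + grand
    sigma2 = float((resid**2).sum() / ((n - 1) * (k - 1)))
    ms_subject = float(k * ((subj_means - grand) ** 2).sum() / (n - 1))
    tau2 = (ms_subject - sigma2) / k
    if tau2 < 0:
        tau2 = 0.0

    base = wave_means[0]
    se = np.sqrt(2.0 * sigma2 / n)
    rows = []
    for j, w in enumerate(waves[1:], start=1):
        beta = float(wave_means[j] - base)
        z = beta / se if se > 0 else np.inf * np.sign(beta) if beta else 0.0
        p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
        if se == 0 and beta == 0:
            p = 1.0
        rows.append({"wave": w, "estimate": beta, "se": float(se), "p": p})
    return TimeEffectFit(pd.DataFrame(rows), float(tau2), sigma2, n, tuple(waves))


def paired_t(x_baseline: Sequence, x_followup: Sequence) -> Dict[str, float]:
    """Classical paired t test on follow-up minus baseline differences."""
    a = np.asarray(x_baseline, dtype=float)
    b = np.asarray(x_followup, dtype=float)
    if a.shape != b.shape:
        raise SampleSizeError("paired vectors differ in length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    n = a.size
    if n < 2:
        raise SampleSizeError(f"paired t needs at least 2 pairs, got {n}")
    diff = b - a
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0:
        # all differences identical: t is 0/0 when the mean is 0, infinite otherwise
        t = 0.0 if mean_diff == 0 else float("inf") * np.sign(mean_diff)
        p = 1.0 if mean_diff == 0 else 0.0
    else:
        t, p = stats.ttest_rel(b, a)
        t, p = float(t), float(p)
    return {"mean_diff": mean_diff, "t": t, "p": p, "n": int(n)}


def five_number_summaries(long: pd.DataFrame) -> pd.DataFrame:
    """Boxplot summaries (min, q1, median, q3, max) per measure and wave."""
    rows = []
    for (measure, wave), grp in long.groupby(["measure", "wave"]):
        v = grp["value"].dropna().to_numpy(dtype=float)
        if v.size == 0:
            continue
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        rows.append(
            {
                "measure": measure,
                "wave": wave,
                "min": float(v.min()),
                "q1": float(q1),
                "median": float(med),
                "q3": float(q3),
                "max": float(v.max()),
                "n": int(v.size),
            }
        )
    return pd.DataFrame(rows)
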