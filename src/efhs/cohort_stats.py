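"""Baseline-characteristics comparison and the returner logistic model.

Two descriptive comparisons mirror the study design: enrolled vs
non-enrolled participants, and (among the enrolled) survey returners vs
non-returners.  Continuous variables are compared with a pooled-variance
two-sample t test, categorical variables with a Pearson chi-square test on
the full contingency table (no continuity correction).  Returner status is
additionally modelled with a multivariable logistic regression adjusting
for age, sex, current smoking, and highest education level; education is
entered as indicator terms against the lowest category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._util import percent, round_half_up
from .errors import DataError, SeparationError

#: Ordered education categories (lowest first; the reference level).
EDUCATION_LEVELS = (
    "less_than_high_school",
    "high_school",
    "some_college",
    "bachelor",
    "graduate",
)


@dataclass(frozen=True)
class VariableSpec:
    name: str
    kind: str  # continuous-normal | continuous-skewed | categorical
    decimals: int = 2

    def __post_init__(self) -> None:
        if self.kind not in ("continuous-normal", "continuous-skewed", "categorical"):
            raise DataError(f"unknown variable kind {self.kind!r}")


def summarize_variable(values: pd.Series, spec: VariableSpec) -> dict:
    """Summary of one variable in the printed-table style.

    Missing values are excluded and the non-missing count is the percentage
    denominator, matching per-variable footnote denominators.  Binary
    categorical variables summarise the count of 1s; multi-level categorical
    variables return one ``n (pct)`` entry per level.
    """
    v = pd.Series(values).dropna()
    n = len(v)
    if n == 0:
        return {"summary": None, "n": 0}
    d = spec.decimals
    if spec.kind == "continuous-normal":
        mean = round_half_up(float(v.mean()), d)
        sd = round_half_up(float(v.std(ddof=1)), d) if n > 1 else 0.0
        return {"summary": f"{mean} ({sd})", "n": n, "mean": mean, "sd": sd}
    if spec.kind == "continuous-skewed":
        q1, med, q3 = (round_half_up(float(q), d) for q in np.percentile(v, [25, 50, 75]))
        return {"summary": f"{med} ({q1}-{q3})", "n": n, "median": med, "q1": q1, "q3": q3}
    levels = sorted(v.unique().tolist())
    if set(levels) <= {0, 1}:
        count = int((v == 1).sum())
        return {
            "summary": f"{count} ({percent(count, n)})",
            "n": n,
            "count": count,
            "pct": percent(count, n),
        }
    parts = {}
    for lev in levels:
        count = int((v == lev).sum())
        parts[lev] = f"{count} ({percent(count, n)})"
    return {"summary": "; ".join(f"{k}: {s}" for k, s in parts.items()), "n": n, "levels": parts}


def compare_groups(
    data: pd.DataFrame,
    group_col: str,
    specs: Sequence[VariableSpec],
) -> pd.DataFrame:
    """Per-variable group summaries plus t / chi-square tests.

    ``data[group_col]`` must define exactly two groups.  Continuous
    variables (normal or skewed) use the pooled-variance Student t test;
    categorical variables use the Pearson chi-square on the full table.
    """
    groups = sorted(data[group_col].dropna().unique().tolist())
    if len(groups) != 2:
        raise DataError(f"expected 2 groups in {group_col!r}, found {groups}")
    g1, g2 = (data[data[group_col] == g] for g in groups)
    rows = []
    for spec in specs:
        row = {
            "variable": spec.name,
            f"summary_{groups[0]}": summarize_variable(g1[spec.name], spec)["summary"],
            f"summary_{groups[1]}": summarize_variable(g2[spec.name], spec)["summary"],
            "test": None,
            "statistic": np.nan,
            "p": np.nan,
            "error": None,
        }
        try:
            if spec.kind == "categorical":
                stat, p = chi_square_test(data[spec.name], data[group_col])
                row.update(test="chi-square", statistic=stat, p=p)
            else:
                a = g1[spec.name].dropna().to_numpy(dtype=float)
                b = g2[spec.name].dropna().to_numpy(dtype=float)
                if min(len(a), len(b)) < 2:
                    raise DataError("a group has fewer than 2 observations")
                stat, p = stats.ttest_ind(a, b, equal_var=True)
                row.update(test="t", statistic=float(stat), p=float(p))
        except DataError as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def chi_square_test(values: pd.Series, groups: pd.Series) -> tuple:
    """Pearson chi-square (no continuity correction) on the full table."""
    tab = pd.crosstab(pd.Series(values).dropna(), groups)
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        raise DataError("contingency table is degenerate")
    stat, p, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
    return float(stat), float(p)


def collapse_sparse_levels(
    values: pd.Series,
    ordered_levels: Sequence,
    min_count: int = 25,
) -> tuple:
    """Merge sparse ordinal levels into their neighbours.

    Levels with fewer than ``min_count`` observations are merged upward
    (the top level merges downward).  Guards logistic fits against
    quasi-separation from near-empty reference cells.  Returns the recoded
    series and the retained ordered level list.
    """
    levels = [lev for lev in ordered_levels]
    mapping = {lev: lev for lev in levels}
    while len(levels) > 1:
        counts = values.map(mapping).value_counts()
        sparse = [lev for lev in levels if counts.get(lev, 0) < min_count]
        if not sparse:
            break
        lev = sparse[0]
        i = levels.index(lev)
        target = levels[i + 1] if i + 1 < len(levels) else levels[i - 1]
        for k, v in mapping.items():
            if v == lev:
                mapping[k] = target
        levels.remove(lev)
    return values.map(mapping), tuple(levels)


def fit_returner_model(
    data: pd.DataFrame,
    outcome: str = "returned",
    continuous: Sequence[str] = ("age",),
    binary: Sequence[str] = ("female", "current_smoker"),
    categorical: Mapping[str, Sequence] = None,
) -> pd.DataFrame:
    """Adjusted logistic regression for returning any survey.

    Complete-case maximum-likelihood fit with Wald 95% confidence intervals
    reported on the odds-ratio scale.  ``categorical`` maps a column to its
    ordered level list; the first level is the reference.  Covariates with
    no variation in the analysis sample are dropped with a warning.
    """
    if categorical is None:
        categorical = {"education": EDUCATION_LEVELS}
    cols = [outcome, *continuous, *binary, *categorical]
    df = data[cols].dropna().copy()
    y = df[outcome].astype(float)
    if y.nunique() < 2:
        raise DataError("outcome has a single class")

    X = pd.DataFrame(index=df.index)
    for c in list(continuous) + list(binary):
        X[c] = df[c].astype(float)
    for c, levels in categorical.items():
        for lev in levels[1:]:
            X[f"{c}[{lev}]"] = (df[c] == lev).astype(float)

    dropped = [c for c in X.columns if X[c].nunique() <= 1]
    if dropped:
        warnings.warn(f"dropping zero-variance covariates: {dropped}", stacklevel=2)
        X = X.drop(columns=dropped)

    Xc = sm.add_constant(X, has_constant="add")
    try:
        fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
    except Exception as exc:  # PerfectSeparationError and numeric failures
        raise SeparationError(str(exc)) from exc
    if not fit.mle_retvals.get("converged", False) or np.max(np.abs(fit.params)) > 20:
        raise SeparationError("logistic fit did not converge (possible separation)")

    ci = fit.conf_int()
    rows = []
    for term in X.columns:
        rows.append(
            {
                "term": term,
                "aor": float(np.exp(fit.params[term])),
                "ci_low": float(np.exp(ci.loc[term, 0])),
                "ci_high": float(np.exp(ci.loc[term, 1])),
                "p": float(fit.pvalues[term]),
            }
        )
    return pd.DataFrame(rows)


def default_table1_specs() -> list:
    """Variable specs for the bundled synthetic cohort's characteristics."""
    return [
        VariableSpec("age", "continuous-normal", 1),
        VariableSpec("female", "categorical"),
        VariableSpec("current_smoker", "categorical"),
        VariableSpec("education", "categorical"),
        VariableSpec("married", "categorical"),
        VariableSpec("employed", "categorical"),
        VariableSpec("bmi", "continuous-skewed", 1),
    ]
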