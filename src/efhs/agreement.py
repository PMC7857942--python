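"""App-vs-clinic agreement statistics.

The research-center measurement is treated as the gold standard ``x`` and
the app-survey measurement as ``y``.  Agreement is quantified with:

* Lin's concordance correlation coefficient (CCC), which penalises both
  imprecision (low correlation) and inaccuracy (location/scale shift):
  ``ccc = 2 s_xy / (s_x^2 + s_y^2 + (x̄ - ȳ)^2)`` with 1/n moment
  estimators, and a confidence interval on the Fisher z scale using the
  corrected asymptotic variance;
* Cohen's unweighted kappa for categorical measures, with the standard
  asymptotic Wald interval;
* Bland-Altman bias and 95% limits of agreement on the differences
  ``y - x``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, SampleSizeError


@dataclass(frozen=True)
class AgreementResult:
    statistic: str
    estimate: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    n_pairs: int


def _clean_pairs(x, y) -> Tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise SampleSizeError("paired vectors differ in length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def make_pairs(
    clinic: pd.DataFrame,
    scores: pd.DataFrame,
    measure: str,
    wave: str = "baseline",
) -> Tuple[np.ndarray, np.ndarray, int]:
    """Complete-case pairing of clinic and baseline app values for a measure.

    Returns ``(x, y, n_dropped)`` where ``x`` is the clinic value.
    """
    c = clinic[clinic["measure"] == measure].set_index("participant_id")["value"]
    s = scores[(scores["measure"] == measure) & (scores["wave"] == wave)]
    s = s.set_index("participant_id")["value"]
    joined = pd.concat([c, s], axis=1, keys=["x", "y"], join="outer")
    complete = joined.dropna()
    return (
        complete["x"].to_numpy(),
        complete["y"].to_numpy(),
        len(joined) - len(complete),
    )


def ccc(x, y, alpha: float = 0.05) -> AgreementResult:
    """Lin's concordance correlation coefficient with a z-transform CI."""
    x, y = _clean_pairs(x, y)
    n = x.size
    if n < 3:
        raise SampleSizeError(f"CCC needs at least 3 pairs, got {n}")
    sx2 = float(np.var(x))  # 1/n moment estimators (Lin's definition)
    sy2 = float(np.var(y))
    if sx2 == 0 or sy2 == 0:
        raise DegenerateInputError("zero variance on one side of the pairing")
    xm, ym = float(np.mean(x)), float(np.mean(y))
    sxy = float(np.mean((x - xm) * (y - ym)))
    c = 2.0 * sxy / (sx2 + sy2 + (xm - ym) ** 2)

    r = sxy / math.sqrt(sx2 * sy2)
    u = (xm - ym) / (sx2 * sy2) ** 0.25

    ci_low = ci_high = None
    if abs(c) < 1 and r != 0:
        z = math.atanh(c)
        c2, r2 = c * c, r * r
        se2 = (
            (1 - r2) * c2 / ((1 - c2) * r2)
            + 2 * c ** 3 * (1 - c) * u * u / (r * (1 - c2) ** 2)
            - c ** 4 * u ** 4 / (2 * r2 * (1 - c2) ** 2)
        ) / (n - 2)
        se = math.sqrt(max(se2, 0.0))
        zcrit = stats.norm.ppf(1 - alpha / 2)
        ci_low = math.tanh(z - zcrit * se)
        ci_high = math.tanh(z + zcrit * se)
    elif abs(c) >= 1:
        ci_low = ci_high = c
    return AgreementResult("ccc", c, ci_low, ci_high, n)


def cohen_kappa(a: Sequence, b: Sequence, alpha: float = 0.05) -> AgreementResult:
    """Unweighted Cohen kappa with the asymptotic Wald interval.

    When both raters are constant and identical, chance agreement is 1 and
    kappa is undefined; a degenerate result with a missing estimate is
    returned rather than raising.
    """
    a = pd.Series(list(a))
    b = pd.Series(list(b))
    if len(a) != len(b):
        raise SampleSizeError("rating vectors differ in length")
    keep = a.notna() & b.notna()
    a, b = a[keep], b[keep]
    n = len(a)
    if n == 0:
        raise SampleSizeError("no complete rating pairs")
    table = pd.crosstab(a, b)
    cats = sorted(set(table.index) | set(table.columns))
    table = table.reindex(index=cats, columns=cats, fill_value=0)
    return kappa_from_table(table.to_numpy(), alpha=alpha)


def kappa_from_table(confusion: np.ndarray, alpha: float = 0.05) -> AgreementResult:
    """Kappa from a square confusion-count matrix."""
    m = np.asarray(confusion, dtype=float)
    n = m.sum()
    if n == 0:
        raise SampleSizeError("empty confusion table")
    p = m / n
    p_o = float(np.trace(p))
    p_e = float(np.sum(p.sum(axis=0) * p.sum(axis=1)))
    if p_e >= 1.0:
        return AgreementResult("kappa", None, None, None, int(n))
    kappa = (p_o - p_e) / (1 - p_e)
    se = math.sqrt(p_o * (1 - p_o) / (n * (1 - p_e) ** 2))
    zcrit = stats.norm.ppf(1 - alpha / 2)
    return AgreementResult("kappa", kappa, kappa - zcrit * se, kappa + zcrit * se, int(n))


def bland_altman(x, y, k: float = 1.96) -> Dict[str, object]:
    """Bland-Altman bias and limits of agreement for app (y) vs clinic (x).

    Returns bias = mean(y - x), sd of the differences (n-1 denominator),
    ``lower``/``upper`` limits ``bias ± k·sd``, and the per-pair scatter
    points (mean, diff) for plotting.
    """
    x, y = _clean_pairs(x, y)
    n = x.size
    if n < 2:
        raise SampleSizeError(f"Bland-Altman needs at least 2 pairs, got {n}")
    diff = y - x
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    points = pd.DataFrame({"mean": (x + y) / 2.0, "diff": diff})
    return {
        "bias": bias,
        "sd_diff": sd,
        "lower": bias - k * sd,
        "upper": bias + k * sd,
        "n_pairs": int(n),
        "points": points,
    }


def mean_difference(x, y) -> float:
    """Mean of app minus clinic differences (equals the Bland-Altman bias)."""
    x, y = _clean_pairs(x, y)
    if x.size < 1:
        raise SampleSizeError("no complete pairs")
    return float(np.mean(y - x))
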