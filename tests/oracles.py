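"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain loops over records, deliberately not
sharing code with the package.
"""

from __future__ import annotations

import math


def brute_force_adherence(records, schedule, eligible, waves):
    """Per-wave adherence by explicit enumeration.

    ``records`` is a list of (participant_id, wave, survey_type, completed)
    tuples.  Returns {wave: (n_any, n_all)} counting eligible participants
    with at least one completed survey, and with every scheduled type
    completed, at that wave.
    """
    out = {}
    for wave in waves:
        n_any = 0
        n_all = 0
        for pid in eligible:
            done_types = set()
            for rec_pid, rec_wave, stype, completed in records:
                if rec_pid == pid and rec_wave == wave and completed:
                    done_types.add(stype)
            if done_types:
                n_any += 1
            if all(s in done_types for s in schedule[wave]):
                n_all += 1
        out[wave] = (n_any, n_all)
    return out


def newton_logistic(x_rows, y, n_iter=200, tol=1e-12):
    """Maximum-likelihood logistic regression by plain Newton iteration.

    ``x_rows`` is a list of covariate lists WITHOUT intercept; an intercept
    column is prepended here.  Returns the coefficient list (intercept
    first).  Pure-python matrix algebra on purpose.
    """
    rows = [[1.0] + list(r) for r in x_rows]
    p = len(rows[0])
    beta = [0.0] * p
    for _ in range(n_iter):
        grad = [0.0] * p
        hess = [[0.0] * p for _ in range(p)]
        for r, yi in zip(rows, y):
            eta = sum(b * v for b, v in zip(beta, r))
            mu = 1.0 / (1.0 + math.exp(-eta))
            w = mu * (1.0 - mu)
            for j in range(p):
                grad[j] += (yi - mu) * r[j]
                for k in range(p):
                    hess[j][k] += w * r[j] * r[k]
        step = _solve(hess, grad)
        beta = [b + s for b, s in zip(beta, step)]
        if max(abs(s) for s in step) < tol:
            break
    return beta


def _solve(a, b):
    """Gaussian elimination with partial pivoting."""
    n = len(b)
    m = [row[:] + [bv] for row, bv in zip(a, b)]
    for col in range(n):
        piv = max(range(col, n), key=lambda r: abs(m[r][col]))
        m[col], m[piv] = m[piv], m[col]
        d = m[col][col]
        m[col] = [v / d for v in m[col]]
        for r in range(n):
            if r != col and m[r][col] != 0:
                f = m[r][col]
                m[r] = [v - f * w for v, w in zip(m[r], m[col])]
    return [m[r][n] for r in range(n)]
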