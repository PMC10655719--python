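"""Independent reference implementations used only to check the package.

These are deliberately written in the most literal way possible (explicit
loops, no shared helpers with the package) so that agreement with the
package is evidence of correctness rather than of shared code.
"""

from __future__ import annotations

import math

import numpy as np


def _median(values: list[float]) -> float:
    """Median with the even-count convention (mean of the two middle values)."""
    s = sorted(values)
    n = len(s)
    if n == 0:
        return float("nan")
    if n % 2 == 1:
        return s[n // 2]
    return 0.5 * (s[n // 2 - 1] + s[n // 2])


def reference_median_polish(y, tol=1e-4, max_iter=20):
    """Literal row-first/column-first sweep of Tukey's median polish.

    Returns (overall, row_effects, col_effects, residuals).  Medians skip
    missing cells; the median of the row/column effect vector is folded
    into the overall term after each half-sweep; iteration stops when the
    sum of absolute residuals changes by at most ``tol``.
    """
    y = [list(map(float, row)) for row in np.asarray(y, dtype=float)]
    nr, nc = len(y), len(y[0])
    resid = [row[:] for row in y]
    overall = 0.0
    row_eff = [0.0] * nr
    col_eff = [0.0] * nc

    def sum_abs():
        return sum(
            abs(resid[i][j])
            for i in range(nr)
            for j in range(nc)
            if not math.isnan(resid[i][j])
        )

    last = sum_abs()
    for _ in range(max_iter):
        for i in range(nr):
            m = _median([v for v in resid[i] if not math.isnan(v)])
            for j in range(nc):
                resid[i][j] -= m
            row_eff[i] += m
        d = _median(col_eff)
        col_eff = [c - d for c in col_eff]
        overall += d
        for j in range(nc):
            m = _median(
                [resid[i][j] for i in range(nr) if not math.isnan(resid[i][j])]
            )
            for i in range(nr):
                resid[i][j] -= m
            col_eff[j] += m
        d = _median(row_eff)
        row_eff = [r - d for r in row_eff]
        overall += d
        cur = sum_abs()
        if abs(last - cur) <= tol:
            break
        last = cur
    return overall, np.array(row_eff), np.array(col_eff), np.array(resid)


def bh_step_up(p_values):
    """Benjamini-Hochberg q-values computed literally from the definition:

    q_i = min over j with p_j >= p_i of (m * p_j / rank_j), clipped at 1.
    """
    p = list(map(float, p_values))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [1.0] * m
    running = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        rank = pos + 1
        running = min(running, m * p[i] / rank)
        q[i] = min(running, 1.0)
    return np.array(q)


def pooled_two_sample_t(a, b):
    """Classical pooled-variance two-sample t-test (difference b - a)."""
    from scipy import stats

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    s2 = (
        ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    ) / (na + nb - 2)
    diff = b.mean() - a.mean()
    se = math.sqrt(s2 * (1 / na + 1 / nb))
    t = diff / se
    p = 2 * stats.t.sf(abs(t), na + nb - 2)
    return diff, se, t, na + nb - 2, p
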