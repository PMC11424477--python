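"""Independent brute-force oracles, written from the definitions alone.

These deliberately avoid numpy/pandas and the package's own code paths:
pure-Python lists, statistics.median and math only, so agreement with the
implementation is a real cross-check rather than a tautology.
"""

import math
from statistics import median


def brute_median_polish(rows, tol=1e-6, max_iter=50):
    """Tukey median polish by hand; ``rows`` is a list of lists, None = missing.

    Sweeps row medians first, then column medians, each time re-centring the
    opposite effects, until no effect moves by more than ``tol``. Returns a
    list of per-column summaries (overall + column effect), None for columns
    with no observed value.
    """
    nrow, ncol = len(rows), len(rows[0])
    live_rows = [i for i in range(nrow) if any(rows[i][j] is not None for j in range(ncol))]
    live_cols = [j for j in range(ncol) if any(rows[i][j] is not None for i in range(nrow))]
    resid = {(i, j): rows[i][j] for i in live_rows for j in live_cols if rows[i][j] is not None}
    r = {i: 0.0 for i in live_rows}
    c = {j: 0.0 for j in live_cols}
    overall = 0.0

    def row_vals(i):
        return [resid[(i, j)] for j in live_cols if (i, j) in resid]

    def col_vals(j):
        return [resid[(i, j)] for i in live_rows if (i, j) in resid]

    for _ in range(max_iter):
        old = [overall] + [r[i] for i in live_rows] + [c[j] for j in live_cols]

        for i in live_rows:
            med = median(row_vals(i))
            for j in live_cols:
                if (i, j) in resid:
                    resid[(i, j)] -= med
            r[i] += med
        delta = median(c.values())
        for j in live_cols:
            c[j] -= delta
        overall += delta

        for j in live_cols:
            med = median(col_vals(j))
            for i in live_rows:
                if (i, j) in resid:
                    resid[(i, j)] -= med
            c[j] += med
        delta = median(r.values())
        for i in live_rows:
            r[i] -= delta
        overall += delta

        new = [overall] + [r[i] for i in live_rows] + [c[j] for j in live_cols]
        if max(abs(a - b) for a, b in zip(new, old)) <= tol:
            break

    return [overall + c[j] if j in c else None for j in range(ncol)]


def brute_bh(pvalues):
    """Benjamini-Hochberg step-up, straight from the definition.

    Sort ascending, scale p_(i) by m/i, take the running minimum from the
    largest rank down, cap at 1, and undo the sort.
    """
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        adjusted[i] = min(running, 1.0)
    return adjusted


def normal_sf(x):
    return 0.5 * math.erfc(x / math.sqrt(2.0))


def brute_kinase_score(all_fcs, substrate_fcs):
    """(m, M, mu, s, se, Z, P) from the z-score definition, by hand."""
    n = len(all_fcs)
    mu = sum(all_fcs) / n
    s = math.sqrt(sum((x - mu) ** 2 for x in all_fcs) / (n - 1))
    m = len(substrate_fcs)
    big_m = sum(substrate_fcs) / m
    se = s / math.sqrt(m)
    z = (big_m - mu) / se
    p = 2.0 * normal_sf(abs(z))
    return m, big_m, mu, s, se, z, p


def brute_two_sample_t(a, b):
    """Pooled-variance Student's t and df, from the textbook formula."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    ssa = sum((x - ma) ** 2 for x in a)
    ssb = sum((x - mb) ** 2 for x in b)
    df = na + nb - 2
    sp = math.sqrt((ssa + ssb) / df)
    t = (ma - mb) / (sp * math.sqrt(1 / na + 1 / nb))
    return t, df
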