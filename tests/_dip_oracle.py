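"""Brute-force dip oracle, independent of the package implementation.

Solves the defining minimization directly: the dip is the smallest d such
that some unimodal CDF G stays within sup-distance d of the empirical CDF.
For each possible mode placement (at a sample value, with a jump, or in
an open gap between values) the constraints -- band containment,
monotonicity, convexity left of the mode, concavity right of it -- are
linear in the node values of G and in d, so each placement is a linear
program; the dip is the minimum over placements.  Exact but slow:
intended for samples of a few dozen points.
"""

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import coo_matrix


def _solve(rows_cols_data, n_rows, nvars, b, d_index):
    rows, cols, data = rows_cols_data
    A = coo_matrix((data, (rows, cols)), shape=(n_rows, nvars))
    c = np.zeros(nvars)
    c[d_index] = 1.0
    res = linprog(
        c,
        A_ub=A,
        b_ub=np.asarray(b),
        bounds=[(0.0, 1.0)] * nvars,
        method="highs",
    )
    return res.fun if res.success else np.inf


def dip_bruteforce(sample) -> float:
    """min over unimodal CDFs G of sup |F_n - G|, via one LP per mode."""
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    v, counts = np.unique(x, return_counts=True)
    m = v.size
    if m == 1:
        return 0.0
    F = np.cumsum(counts) / n
    Fm1 = np.concatenate([[0.0], F[:-1]])
    best = np.inf

    def run(constraints, nvars, d_index):
        rows, cols, data, b = [], [], [], []
        for r, (coefs, rhs) in enumerate(constraints):
            for cvar, co in coefs.items():
                rows.append(r)
                cols.append(cvar)
                data.append(co)
            b.append(rhs)
        return _solve((rows, cols, data), len(constraints), nvars, b, d_index)

    # mode in the open gap after v_k (k = -1: mode below all values;
    # k = m-1: mode above all values)
    for k in range(-1, m):
        cons = []
        D = m
        for i in range(m):
            cons.append(({i: -1.0, D: -1.0}, -F[i]))      # g_i >= F_i - d
            cons.append(({i: 1.0, D: -1.0}, Fm1[i]))       # g_i <= F(v_i^-) + d
        for i in range(m - 1):
            cons.append(({i: 1.0, i + 1: -1.0}, 0.0))      # nondecreasing
        for i in range(1, k):                              # convex on 0..k
            h1, h2 = v[i] - v[i - 1], v[i + 1] - v[i]
            cons.append((
                {i - 1: -1.0 / h1, i: 1.0 / h1 + 1.0 / h2, i + 1: -1.0 / h2}, 0.0))
        for i in range(k + 2, m - 1):                      # concave on k+1..
            h1, h2 = v[i] - v[i - 1], v[i + 1] - v[i]
            cons.append((
                {i - 1: 1.0 / h1, i: -1.0 / h1 - 1.0 / h2, i + 1: 1.0 / h2}, 0.0))
        best = min(best, run(cons, m + 1, D))

    # mode at v_k with a jump: variable k holds the left limit, variable
    # m+1 the right value
    for k in range(m):
        cons = []
        D, B = m, m + 1
        for i in range(m):
            if i == k:
                continue
            cons.append(({i: -1.0, D: -1.0}, -F[i]))
            cons.append(({i: 1.0, D: -1.0}, Fm1[i]))
        cons.append(({k: 1.0, D: -1.0}, Fm1[k]))           # a_k <= F(v_k^-)+d
        cons.append(({B: -1.0, D: -1.0}, -F[k]))           # b >= F_k - d
        cons.append(({B: 1.0, D: -1.0}, F[k]))             # b <= F_k + d
        cons.append(({k: 1.0, B: -1.0}, 0.0))              # a_k <= b
        for i in range(m - 1):
            lo, hi = i, i + 1
            if hi == k:
                cons.append(({lo: 1.0, k: -1.0}, 0.0))
            elif lo == k:
                cons.append(({B: 1.0, hi: -1.0}, 0.0))
            else:
                cons.append(({lo: 1.0, hi: -1.0}, 0.0))
        for i in range(1, k):
            h1, h2 = v[i] - v[i - 1], v[i + 1] - v[i]
            cons.append((
                {i - 1: -1.0 / h1, i: 1.0 / h1 + 1.0 / h2, i + 1: -1.0 / h2}, 0.0))
        for i in range(k + 1, m - 1):
            h1, h2 = v[i] - v[i - 1], v[i + 1] - v[i]
            left = B if i - 1 == k else i - 1
            cons.append((
                {left: 1.0 / h1, i: -1.0 / h1 - 1.0 / h2, i + 1: 1.0 / h2}, 0.0))
        best = min(best, run(cons, m + 2, D))
    return best
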