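"""Numba core for the Hartigan-Hartigan dip statistic.

The dip of an empirical CDF F_n is min over unimodal CDFs G of
sup_x |F_n(x) - G(x)|.  Working on unique sample values v_0 < .. < v_{m-1}
with yhi_k = n F_n(v_k) (count at or below v_k) and ylo_k = count strictly
below, a unimodal G within band half-width c (count units) must satisfy
yhi_k - c <= n G(v_k) <= ylo_k + c at every value except the mode, where a
single jump is allowed; G is convex left of the mode, concave right of it.

Three ingredient families decide feasibility at a given c:

* convex-prefix certificates: a convex function exists in a band [l, u]
  iff the greatest convex minorant of u majorizes l; bands shift linearly
  in c, so the minimal 2c per prefix is the deviation of yhi above the
  lower convex hull of (v, ylo) (``bl`` arrays below); concave suffixes
  are handled by mirror symmetry (``br``);
* junction placement: the mode sits either at a value v_k (its band splits
  into a left-limit part from ylo_k and a right-value part from yhi_k) or
  in an open gap between values;
* coupling: the minimal terminal value of a feasible convex prefix
  function must not exceed the maximal initial value of a feasible concave
  suffix function; terminal bounds propagate along steepest tangent lines
  through (v_a, u_a) and (v_b, T_b).

The dip is found by bisection on c; the junction min-max over the ``bl``
and ``br`` certificates is a lower bound that is already exact whenever
the coupling constraint is slack (the common case).
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _prefix_devs(v, ylo, yhi):
    """blnode[k] = max over i<k of (yhi_i - hull fit at v_i), where the hull
    is the lower convex hull of (v_i, ylo_i) for i=0..k."""
    m = v.size
    blnode = np.empty(m)
    hull = np.empty(m, dtype=np.int64)
    nh = 0
    for k in range(m):
        while nh >= 2:
            a = hull[nh - 2]
            b = hull[nh - 1]
            cr = (v[b] - v[a]) * (ylo[k] - ylo[b]) - (v[k] - v[b]) * (ylo[b] - ylo[a])
            if cr <= 0.0:
                nh -= 1
            else:
                break
        hull[nh] = k
        nh += 1
        best = 0.0
        hi = 0
        for i in range(k):
            while hi + 1 < nh and v[hull[hi + 1]] <= v[i]:
                hi += 1
            a = hull[hi]
            if hi + 1 < nh:
                b = hull[hi + 1]
                fit = ylo[a] + (ylo[b] - ylo[a]) * (v[i] - v[a]) / (v[b] - v[a])
            else:
                fit = ylo[a]
            dev = yhi[i] - fit
            if dev > best:
                best = dev
        blnode[k] = best
    return blnode


@njit(cache=True)
def _tmin_pass(v, ylo, yhi, c):
    """Minimal value at v_k of a nondecreasing convex function within the
    band on nodes 0..k.  Tg: node-k band from yhi (mode beyond v_k);
    Tn: node-k band from ylo (mode at v_k, left limit)."""
    m = v.size
    Tg = np.empty(m)
    Tn = np.empty(m)
    slopes = np.full(m, -np.inf)
    for k in range(m):
        line = -np.inf
        for b in range(k):
            if slopes[b] > -np.inf:
                val = Tg[b] + slopes[b] * (v[k] - v[b])
                if val > line:
                    line = val
        lower = line
        if k > 0 and Tg[k - 1] > lower:
            lower = Tg[k - 1]
        if lower < 0.0:
            lower = 0.0
        Tg[k] = max(yhi[k] - c, lower)
        Tn[k] = max(ylo[k] - c, lower)
        s = -np.inf
        for a in range(k):
            cand = (Tg[k] - (ylo[a] + c)) / (v[k] - v[a])
            if cand > s:
                s = cand
        slopes[k] = s
    return Tg, Tn


@njit(cache=True)
def _feasible(c, v, ylo, yhi, n, blnode, blgap, brnode, brgap):
    m = v.size
    two_c = 2.0 * c
    if brgap[0] <= two_c or blgap[m - 1] <= two_c:
        return True
    Tg, Tn = _tmin_pass(v, ylo, yhi, c)
    vr = -v[::-1]
    ylor = np.empty(m)
    yhir = np.empty(m)
    for i in range(m):
        ylor[i] = n - yhi[m - 1 - i]
        yhir[i] = n - ylo[m - 1 - i]
    TgR, TnR = _tmin_pass(vr, ylor, yhir, c)
    eps = 1e-9 * n
    for k in range(m):
        if blnode[k] <= two_c and brnode[k] <= two_c:
            if Tn[k] <= (n - TnR[m - 1 - k]) + eps:
                return True
        if k < m - 1 and blgap[k] <= two_c and brgap[k + 1] <= two_c:
            if Tg[k] <= (n - TgR[m - 2 - k]) + eps:
                return True
    return False


@njit(cache=True)
def dip_sorted_unique(v, counts, n):
    """Dip statistic given unique sorted values and their counts."""
    m = v.size
    if m <= 1 or n < 2:
        return 0.0
    ylo = np.empty(m)
    yhi = np.empty(m)
    acc = 0.0
    for i in range(m):
        ylo[i] = acc
        acc += counts[i]
        yhi[i] = acc
    blnode = _prefix_devs(v, ylo, yhi)
    blgap = np.maximum(blnode, counts)
    vr = -v[::-1]
    ylor = np.empty(m)
    yhir = np.empty(m)
    for i in range(m):
        ylor[i] = n - yhi[m - 1 - i]
        yhir[i] = n - ylo[m - 1 - i]
    brnode_r = _prefix_devs(vr, ylor, yhir)
    brnode = brnode_r[::-1].copy()
    brgap = np.maximum(brnode, counts)

    # junction min-max ignoring coupling: lower bound on 2c, usually exact
    best = brgap[0]
    if blgap[m - 1] < best:
        best = blgap[m - 1]
    for k in range(m):
        cand = max(blnode[k], brnode[k])
        if cand < best:
            best = cand
        if k < m - 1:
            cand = max(blgap[k], brgap[k + 1])
            if cand < best:
                best = cand
    lo = best / 2.0
    if _feasible(lo, v, ylo, yhi, n, blnode, blgap, brnode, brgap):
        return lo / n
    hi = 0.5 * n
    tol = 1e-11 * n
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _feasible(mid, v, ylo, yhi, n, blnode, blgap, brnode, brgap):
            hi = mid
        else:
            lo = mid
    return hi / n
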