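"""Compiled inner loops for per-gene fitting.

The objective here mirrors the public one in `estimate.objective` but uses
fixed Gauss-Legendre nodes per inter-sample segment (no parameter-dependent
panel splits), so the quadrature approximation is a smooth function of the
transition centres — a requirement for finite-difference quasi-Newton
steps.  Transition centres are parameterized as (t1, dt) with dt = t2 - t1
>= 0 so the canonical ordering is maintained by a box bound.

Parameter layouts:
  per curve (6): h0, h1, h2, t1, dt, slope
  mode 0 (hard ties, 14): h0, h2 shared ->
      [h0, h2, h1a, t1a, dta, sa, h1g, t1g, dtg, sg, h1b, t1b, dtb, sb]
  mode 1 (free / soft, 18): three consecutive 6-blocks (alpha, gamma, beta)
"""

from __future__ import annotations

import numpy as np
from numba import njit

BIG = 1e30


@njit(cache=True)
def _pulse(h0, h1, h2, t1, dt, s, x):
    t2 = t1 + dt
    u1 = s * (x - t1)
    if u1 >= 0.0:
        s1 = 1.0 / (1.0 + np.exp(-u1))
    else:
        e = np.exp(u1)
        s1 = e / (1.0 + e)
    u2 = -s * (x - t2)
    if u2 >= 0.0:
        s2 = 1.0 / (1.0 + np.exp(-u2))
    else:
        e = np.exp(u2)
        s2 = e / (1.0 + e)
    return (h0 + (h1 - h0) * s1) * (h2 + (h1 - h2) * s2) / h1


@njit(cache=True)
def _expand(x, mode):
    p = np.empty(18)
    if mode == 0:
        h0 = x[0]
        h2 = x[1]
        for c in range(3):
            o = 2 + 4 * c
            b = 6 * c
            p[b + 0] = h0
            p[b + 1] = x[o + 0]
            p[b + 2] = h2
            p[b + 3] = x[o + 1]
            p[b + 4] = x[o + 2]
            p[b + 5] = x[o + 3]
    else:
        for i in range(18):
            p[i] = x[i]
    return p


@njit(cache=True)
def _objective18(p, segx, segw, winx, winw, obsP, obsT, obsTL, c1, c2, soft_w):
    m = obsP.shape[0]
    nseg = segx.shape[0]
    kseg = segx.shape[1]
    kwin = winx.shape[1]
    for i in range(18):
        if not np.isfinite(p[i]):
            return BIG
    for c in range(3):
        b = 6 * c
        if p[b] <= 0.0 or p[b + 1] <= 0.0 or p[b + 2] <= 0.0 or p[b + 5] <= 0.0:
            return BIG
        if p[b + 4] < 0.0:
            return BIG

    # per-segment integrals of the three curves
    Ia = np.empty(nseg)
    Ig = np.empty(nseg)
    Ib = np.empty(nseg)
    for j in range(nseg):
        sa = 0.0
        sg = 0.0
        sb = 0.0
        for k in range(kseg):
            x = segx[j, k]
            w = segw[j, k]
            sa += w * _pulse(p[0], p[1], p[2], p[3], p[4], p[5], x)
            sg += w * _pulse(p[6], p[7], p[8], p[9], p[10], p[11], x)
            sb += w * _pulse(p[12], p[13], p[14], p[15], p[16], p[17], x)
        Ia[j] = sa
        Ig[j] = sg
        Ib[j] = sb

    J = 0.0
    Pj = obsP[0]
    Tj = obsT[0]
    # j = 0 residuals: P and T are pinned to the observations; TL is not
    wa0 = 0.0
    for k in range(kwin):
        wa0 += winw[0, k] * _pulse(p[0], p[1], p[2], p[3], p[4], p[5], winx[0, k])
    r = c1 * Tj + c2 * wa0 - obsTL[0]
    J += r * r
    for j in range(1, m):
        Pj += Ia[j - 1] - Ig[j - 1]
        Tj += Ia[j - 1] - Ib[j - 1]
        wa = 0.0
        for k in range(kwin):
            wa += winw[j, k] * _pulse(p[0], p[1], p[2], p[3], p[4], p[5], winx[j, k])
        rP = Pj - obsP[j]
        rT = Tj - obsT[j]
        rL = c1 * Tj + c2 * wa - obsTL[j]
        J += rP * rP + rT * rT + rL * rL
    J *= 0.5
    if soft_w > 0.0:
        d1 = p[0] - p[12]
        d2 = p[0] - p[6]
        d3 = p[2] - p[14]
        d4 = p[2] - p[8]
        J += soft_w * (d1 * d1 + d2 * d2 + d3 * d3 + d4 * d4)
    if not np.isfinite(J):
        return BIG
    return J


@njit(cache=True)
def obj_value(x, mode, segx, segw, winx, winw, obsP, obsT, obsTL, c1, c2, soft_w):
    p = _expand(x, mode)
    return _objective18(p, segx, segw, winx, winw, obsP, obsT, obsTL, c1, c2, soft_w)


@njit(cache=True)
def obj_value_grad(x, mode, segx, segw, winx, winw, obsP, obsT, obsTL, c1, c2, soft_w):
    """Objective and forward-difference gradient in one compiled call."""
    n = x.shape[0]
    f0 = obj_value(x, mode, segx, segw, winx, winw, obsP, obsT, obsTL, c1, c2, soft_w)
    g = np.zeros(n)
    if f0 >= BIG:
        return f0, g
    xt = x.copy()
    for i in range(n):
        h = 1e-7 * max(1.0, abs(x[i]))
        xt[i] = x[i] + h
        fi = obj_value(xt, mode, segx, segw, winx, winw, obsP, obsT, obsTL, c1, c2, soft_w)
        g[i] = (fi - f0) / h
        xt[i] = x[i]
    return f0, g


@njit(cache=True)
def curve_value_grad(x, t, y):
    """Least squares of one pulse curve on (t, y) points, with
    forward-difference gradient; x = (h0, h1, h2, t1, dt, slope)."""
    n = t.shape[0]

    def _f(h0, h1, h2, t1, dt, s):
        if h0 <= 0.0 or h1 <= 0.0 or h2 <= 0.0 or s <= 0.0 or dt < 0.0:
            return BIG
        tot = 0.0
        for j in range(n):
            r = _pulse(h0, h1, h2, t1, dt, s, t[j]) - y[j]
            tot += r * r
        return 0.5 * tot

    f0 = _f(x[0], x[1], x[2], x[3], x[4], x[5])
    g = np.zeros(6)
    if f0 >= BIG:
        return f0, g
    xt = x.copy()
    for i in range(6):
        h = 1e-7 * max(1.0, abs(x[i]))
        xt[i] = x[i] + h
        fi = _f(xt[0], xt[1], xt[2], xt[3], xt[4], xt[5])
        g[i] = (fi - f0) / h
        xt[i] = x[i]
    return f0, g


@njit(cache=True)
def integral_curve_value_grad(x, nodes, wts, y):
    """Least squares of pulse-curve *integrals* on targets: for each row j,
    the quadrature sum over nodes[j] approximates one integral of the
    curve, matched against y[j].  x = (h0, h1, h2, t1, dt, slope)."""
    m = nodes.shape[0]
    k = nodes.shape[1]

    def _f(h0, h1, h2, t1, dt, s):
        if h0 <= 0.0 or h1 <= 0.0 or h2 <= 0.0 or s <= 0.0 or dt < 0.0:
            return BIG
        tot = 0.0
        for j in range(m):
            acc = 0.0
            for i in range(k):
                acc += wts[j, i] * _pulse(h0, h1, h2, t1, dt, s, nodes[j, i])
            r = acc - y[j]
            tot += r * r
        return 0.5 * tot

    f0 = _f(x[0], x[1], x[2], x[3], x[4], x[5])
    g = np.zeros(6)
    if f0 >= BIG:
        return f0, g
    xt = x.copy()
    for i in range(6):
        h = 1e-7 * max(1.0, abs(x[i]))
        xt[i] = x[i] + h
        fi = _f(xt[0], xt[1], xt[2], xt[3], xt[4], xt[5])
        g[i] = (fi - f0) / h
        xt[i] = x[i]
    return f0, g


def make_quadrature(times: np.ndarray, tL: float, kseg: int = 24, kwin: int = 12):
    """Fixed Gauss-Legendre nodes/weights for the fitting objective.

    Returns (segx, segw, winx, winw): nodes and weights for the m-1
    inter-sample segments and for the m labeling windows
    [max(0, t_j - tL), t_j].
    """
    times = np.asarray(times, dtype=float)
    xs, ws = np.polynomial.legendre.leggauss(kseg)
    xw, ww = np.polynomial.legendre.leggauss(kwin)
    m = times.size
    segx = np.empty((m - 1, kseg))
    segw = np.empty((m - 1, kseg))
    for j in range(m - 1):
        lo, hi = times[j], times[j + 1]
        half = 0.5 * (hi - lo)
        segx[j] = 0.5 * (hi + lo) + half * xs
        segw[j] = half * ws
    winx = np.empty((m, kwin))
    winw = np.empty((m, kwin))
    for j in range(m):
        lo = max(0.0, times[j] - tL)
        hi = times[j]
        half = 0.5 * (hi - lo)
        winx[j] = 0.5 * (hi + lo) + half * xw
        winw[j] = half * ww
    return segx, segw, winx, winw
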