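"""Numerical kernels for the two-region diversification likelihood.

The pruning pass integrates, along every branch, the coupled ODE system for
extinction probabilities E = (E_A, E_B, E_AB) and partial likelihoods
D = (D_A, D_B, D_AB) with a fixed-step classical Runge-Kutta scheme, combining
daughters at nodes and rescaling D to a per-node log accumulator to prevent
underflow. Rates may vary linearly with age t before present,
``r_j(t) = max(0, r0_j + m_j t)``; constant rates are the zero-slope case.

Kernels are JIT-compiled with numba when available and fall back to plain
Python otherwise (same code path, orders of magnitude slower).
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return wrap

# parameter vector layout: (sA, sB, sAB, xA, xB, dA, dB)
I_SA, I_SB, I_SAB, I_XA, I_XB, I_DA, I_DB = range(7)


@njit(cache=True)
def _deriv(t, y, r0, slope, out):
    """dy/dt for y = (E_A, E_B, E_AB, D_A, D_B, D_AB) at age t."""
    sA = max(0.0, r0[0] + slope[0] * t)
    sB = max(0.0, r0[1] + slope[1] * t)
    sAB = max(0.0, r0[2] + slope[2] * t)
    xA = max(0.0, r0[3] + slope[3] * t)
    xB = max(0.0, r0[4] + slope[4] * t)
    dA = max(0.0, r0[5] + slope[5] * t)
    dB = max(0.0, r0[6] + slope[6] * t)
    EA, EB, EAB, DA, DB, DAB = y[0], y[1], y[2], y[3], y[4], y[5]
    out[0] = xA - (sA + dA + xA) * EA + dA * EAB + sA * EA * EA
    out[1] = xB - (sB + dB + xB) * EB + dB * EAB + sB * EB * EB
    out[2] = (-(sA + sB + sAB + xA + xB) * EAB + xA * EB + xB * EA
              + sA * EA * EAB + sB * EB * EAB + sAB * EA * EB)
    out[3] = -(sA + dA + xA) * DA + dA * DAB + 2.0 * sA * EA * DA
    out[4] = -(sB + dB + xB) * DB + dB * DAB + 2.0 * sB * EB * DB
    out[5] = (-(sA + sB + sAB + xA + xB) * DAB + xA * DB + xB * DA
              + sA * (EAB * DA + EA * DAB) + sB * (EAB * DB + EB * DAB)
              + sAB * (EA * DB + EB * DA))


@njit(cache=True)
def _integrate_branch(t0, t1, y, r0, slope, h_target):
    """RK4 from age t0 up to t1 (t1 > t0), in place on y (length 6)."""
    dt = t1 - t0
    if dt <= 0.0:
        return
    nsteps = int(math.ceil(dt / h_target))
    if nsteps < 4:
        nsteps = 4
    h = dt / nsteps
    k1 = np.empty(6)
    k2 = np.empty(6)
    k3 = np.empty(6)
    k4 = np.empty(6)
    ytmp = np.empty(6)
    t = t0
    for _ in range(nsteps):
        _deriv(t, y, r0, slope, k1)
        for i in range(6):
            ytmp[i] = y[i] + 0.5 * h * k1[i]
        _deriv(t + 0.5 * h, ytmp, r0, slope, k2)
        for i in range(6):
            ytmp[i] = y[i] + 0.5 * h * k2[i]
        _deriv(t + 0.5 * h, ytmp, r0, slope, k3)
        for i in range(6):
            ytmp[i] = y[i] + h * k3[i]
        _deriv(t + h, ytmp, r0, slope, k4)
        for i in range(6):
            y[i] += h / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        t += h


@njit(cache=True)
def geosse_prune(post, left, right, is_tip, ages, d_tips, e_init,
                 r0, slope, h_target):
    """Postorder pruning pass.

    Returns (D_root(3), lognorm, E_root(3), err_node); err_node >= 0 flags the
    node where the D vector underflowed to zero (likelihood unusable).
    """
    n = post.shape[0]
    D = np.zeros((n, 3))
    E = np.zeros((n, 3))
    lognorm = np.zeros(n)
    root = post[n - 1]
    for ix in range(n):
        v = post[ix]
        if is_tip[v]:
            for i in range(3):
                D[v, i] = d_tips[v, i]
                E[v, i] = e_init[i]
            continue
        cl = left[v]
        cr = right[v]
        yl = np.empty(6)
        yr = np.empty(6)
        for i in range(3):
            yl[i] = E[cl, i]
            yl[3 + i] = D[cl, i]
            yr[i] = E[cr, i]
            yr[3 + i] = D[cr, i]
        # rates at age of speciation event v
        _integrate_branch(ages[cl], ages[v], yl, r0, slope, h_target)
        _integrate_branch(ages[cr], ages[v], yr, r0, slope, h_target)
        tv = ages[v]
        sA = max(0.0, r0[0] + slope[0] * tv)
        sB = max(0.0, r0[1] + slope[1] * tv)
        sAB = max(0.0, r0[2] + slope[2] * tv)
        dl_a, dl_b, dl_ab = yl[3], yl[4], yl[5]
        dr_a, dr_b, dr_ab = yr[3], yr[4], yr[5]
        da = sA * dl_a * dr_a
        db = sB * dl_b * dr_b
        dab = 0.5 * (sA * (dl_a * dr_ab + dl_ab * dr_a)
                     + sB * (dl_b * dr_ab + dl_ab * dr_b)
                     + sAB * (dl_a * dr_b + dl_b * dr_a))
        s = da + db + dab
        if not (s > 0.0) or not math.isfinite(s):
            return D[root], 0.0, E[root], v
        D[v, 0] = da / s
        D[v, 1] = db / s
        D[v, 2] = dab / s
        for i in range(3):
            E[v, i] = 0.5 * (yl[i] + yr[i])
        lognorm[v] = lognorm[cl] + lognorm[cr] + math.log(s)
    return D[root], lognorm[root], E[root], -1
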