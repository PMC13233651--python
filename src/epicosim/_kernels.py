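"""Compiled inner loop of the field integrator.

Plain-numpy reference semantics live in :mod:`epicosim.field` (heun_step);
this loop reproduces them over CSR connectivity with a ring history buffer.
"""

import numba
import numpy as np


@numba.njit(cache=True)
def _derivs(
    out,
    s,
    glob,
    lc11,
    lc12,
    lc22,
    x0,
    Iext,
    Iext2,
    m,
    g11,
    g12,
    g22,
    tau0,
    tau1,
    tau2,
    tt,
    zslope,
):  # pragma: no cover - exercised through run_field
    n = s.shape[1]
    for i in range(n):
        x1 = s[0, i]
        y1 = s[1, i]
        z = s[2, i]
        x2 = s[3, i]
        y2 = s[4, i]
        g = s[5, i]
        if x1 < 0.0:
            f1 = -(x1**3) + 3.0 * x1 * x1
        else:
            f1 = (m - x2 + 0.6 * (z - 4.0) ** 2) * x1
        out[0, i] = tt * (y1 - z + Iext + f1 + glob[i] + g11 * lc11[i])
        out[1, i] = tt * (1.0 - 5.0 * x1 * x1 - y1) / tau1
        out[2, i] = tt * (zslope * (x1 - x0[i]) - z) / tau0
        if x2 < -0.25:
            f2 = 0.0
        else:
            f2 = 6.0 * (x2 + 0.25)
        out[3, i] = tt * (
            -y2 + x2 - x2**3 + Iext2 + 2.0 * g - 0.3 * (z - 3.5) + g22 * lc22[i]
        )
        out[4, i] = tt * (-y2 + f2) / tau2
        out[5, i] = tt * (-0.01 * (g - 0.1 * x1) + g12 * lc12[i])


@numba.njit(cache=True)
def _local_sums(
    lc11, lc12, lc22, x1, x2, kdata, kind, kptr, th11, th12, th22
):  # pragma: no cover
    n = len(lc11)
    for i in range(n):
        a = 0.0
        b = 0.0
        c = 0.0
        for p in range(kptr[i], kptr[i + 1]):
            j = kind[p]
            k = kdata[p]
            if x1[j] > th11:
                a += k
            if x1[j] > th12:
                b += k
            if x2[j] > th22:
                c += k
        lc11[i] = a
        lc12[i] = b
        lc22[i] = c


@numba.njit(cache=True)
def _run_loop(
    state,
    x0,
    Iext,
    Iext2,
    m,
    kglob,
    g11,
    g12,
    g22,
    th11,
    th12,
    th22,
    tau0,
    tau1,
    tau2,
    tt,
    zslope,
    wdata,
    wind,
    wptr,
    dsteps,
    row_sum,
    kdata,
    kind,
    kptr,
    hist,
    dt,
    n_steps,
    stride,
    rec,
):  # pragma: no cover
    n = state.shape[1]
    depth = hist.shape[0]
    hidx = 0
    glob = np.zeros(n)
    lc11 = np.zeros(n)
    lc12 = np.zeros(n)
    lc22 = np.zeros(n)
    d1 = np.zeros((6, n))
    d2 = np.zeros((6, n))
    pred = np.zeros((6, n))
    rec[0] = state
    irec = 1
    for step in range(n_steps):
        # delayed difference coupling on x1, frozen within the step
        for i in range(n):
            acc = 0.0
            for p in range(wptr[i], wptr[i + 1]):
                j = wind[p]
                acc += wdata[p] * hist[(hidx - dsteps[p]) % depth, j]
            glob[i] = kglob * (acc - row_sum[i] * state[0, i])
        _local_sums(
            lc11, lc12, lc22, state[0], state[3], kdata, kind, kptr, th11, th12, th22
        )
        _derivs(
            d1, state, glob, lc11, lc12, lc22, x0, Iext, Iext2, m,
            g11, g12, g22, tau0, tau1, tau2, tt, zslope,
        )
        for v in range(6):
            for i in range(n):
                pred[v, i] = state[v, i] + dt * d1[v, i]
        _local_sums(
            lc11, lc12, lc22, pred[0], pred[3], kdata, kind, kptr, th11, th12, th22
        )
        _derivs(
            d2, pred, glob, lc11, lc12, lc22, x0, Iext, Iext2, m,
            g11, g12, g22, tau0, tau1, tau2, tt, zslope,
        )
        finite = True
        for v in range(6):
            for i in range(n):
                state[v, i] += 0.5 * dt * (d1[v, i] + d2[v, i])
                if not np.isfinite(state[v, i]):
                    finite = False
        if not finite:
            return False
        hidx = (hidx + 1) % depth
        hist[hidx] = state[0]
        if (step + 1) % stride == 0:
            rec[irec] = state
            irec += 1
    return True
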