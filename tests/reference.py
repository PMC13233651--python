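"""Independent dense reference implementations used as test oracles.

Everything here is deliberately naive: dense matrices, a full (non-ring)
history of every past state, plain numpy.  These implementations share no
code with the package's sparse/compiled integration path.
"""

import numpy as np


def dense_field_reference(
    init,  # (6, n)
    x0,  # (n,)
    weights,  # dense (n, n)
    delay_steps,  # dense int (n, n)
    kernel,  # dense (n, n) local kernel
    params,
    dt,
    n_steps,
):
    """Heun integration with dense coupling and a complete stored history.

    Global input: k * gamma_glob * sum_j w_ij (x1_j(t - d_ij) - x1_i(t)),
    frozen within a step.  Local Heaviside sums re-evaluated at the
    predictor.  Returns the (n_steps + 1, 6, n) trajectory.
    """
    p = params
    n = init.shape[1]
    full_hist = [init[0].copy()]  # x1 at steps ..., grows by one per step

    def derivs(s, glob, lc11, lc12, lc22):
        x1, y1, z, x2, y2, g = s
        f1 = np.where(
            x1 < 0,
            -(x1**3) + 3 * x1**2,
            (p.m - x2 + 0.6 * (z - 4.0) ** 2) * x1,
        )
        dx1 = p.tt * (y1 - z + p.Iext + f1 + glob + lc11)
        dy1 = p.tt * (1.0 - 5.0 * x1**2 - y1) / p.tau1
        dz = p.tt * (p.z_slope * (x1 - x0) - z) / p.tau0
        dx2 = p.tt * (
            -y2 + x2 - x2**3 + p.Iext2 + 2.0 * g - 0.3 * (z - 3.5) + lc22
        )
        f2 = np.where(x2 < -0.25, 0.0, 6.0 * (x2 + 0.25))
        dy2 = p.tt * (-y2 + f2) / p.tau2
        dg = p.tt * (-0.01 * (g - 0.1 * x1) + lc12)
        return np.stack([dx1, dy1, dz, dx2, dy2, dg])

    def local(x1, x2):
        lc11 = p.gamma11 * kernel @ (x1 > p.theta11).astype(float)
        lc12 = p.gamma12 * kernel @ (x1 > p.theta12).astype(float)
        lc22 = p.gamma22 * kernel @ (x2 > p.theta22).astype(float)
        return lc11, lc12, lc22

    state = init.copy()
    out = np.empty((n_steps + 1, 6, n))
    out[0] = state
    for step in range(n_steps):
        glob = np.zeros(n)
        now = len(full_hist) - 1
        for i in range(n):
            acc = 0.0
            for j in range(n):
                if weights[i, j] != 0.0:
                    past = max(now - delay_steps[i, j], 0)
                    acc += weights[i, j] * full_hist[past][j]
            glob[i] = p.k * p.gamma_glob * (acc - weights[i].sum() * state[0, i])
        lc = local(state[0], state[3])
        d1 = derivs(state, glob, *lc)
        pred = state + dt * d1
        d2 = derivs(pred, glob, *local(pred[0], pred[3]))
        state = state + 0.5 * dt * (d1 + d2)
        full_hist.append(state[0].copy())
        out[step + 1] = state
    return out


def tm_depression_amplitudes(U, tau_rec, weight, spike_times):
    """Closed-form Tsodyks-Markram recursion for a depressing synapse.

    With no facilitation, each presynaptic spike releases U * x of the
    resources; between spikes x recovers toward 1 with tau_rec.  Returns the
    sequence of PSC amplitudes weight * U * x_n.
    """
    x = 1.0
    amps = []
    last = None
    for t in spike_times:
        if last is not None:
            x = 1.0 - (1.0 - x) * np.exp(-(t - last) / tau_rec)
        amps.append(weight * U * x)
        x = x * (1.0 - U)
        last = t
    return np.array(amps)
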