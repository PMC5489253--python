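"""Hot integration loops, JIT-compiled when numba is available.

These kernels advance the two network models and the hemodynamic model in
chunks.  Noise increments are drawn *outside* (from one seeded generator, in
a fixed step-major/variable/region order) and passed in pre-scaled, so the
integration result is independent of the vectorization strategy and
identical with or without the JIT.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(fn):
            return fn

        return deco


@njit(cache=True)
def emfm_euler_chunk(
    S, C, wJn, GJn, I0, a, b, d, gamma_ms, tau_s, dt, noise, out, step0, rec_every
):
    """Euler-Maruyama steps for the reduced Wong-Wang gating variables.

    ``S``: (N,) state, updated in place.  ``noise``: (n_steps, N) pre-scaled
    increments.  States are recorded into ``out`` at every ``rec_every``-th
    global step (``step0`` = global index of the step before this chunk).
    """
    n_steps, n = noise.shape
    for i in range(n_steps):
        for j in range(n):
            acc = 0.0
            for k in range(n):
                acc += C[j, k] * S[k]
            x = wJn * S[j] + GJn * acc + I0
            u = a * x - b
            du = d * u
            if du > 1e-6 or du < -1e-6:
                if du < -500.0:
                    H = -u * np.exp(du)
                else:
                    H = u / (1.0 - np.exp(-du))
            else:
                H = 1.0 / d + u / 2.0
            s = S[j] + dt * (-S[j] / tau_s + (1.0 - S[j]) * gamma_ms * H) + noise[i, j]
            if s < 0.0:
                s = 0.0
            elif s > 1.0:
                s = 1.0
            S[j] = s
        g = step0 + i + 1
        if g % rec_every == 0:
            out[g // rec_every, 0, :] = S
    return 0


@njit(cache=True)
def _epi_drift(state, C, x0, I1, I2, tau, gamma_g, r, Ks, out):
    n = state.shape[1]
    for j in range(n):
        x1 = state[0, j]
        y1 = state[1, j]
        z = state[2, j]
        x2 = state[3, j]
        y2 = state[4, j]
        g = state[5, j]
        if x1 < 0.0:
            f1 = x1 * x1 * x1 - 3.0 * x1 * x1
        else:
            f1 = (x2 - 0.6 * (z - 4.0) * (z - 4.0)) * x1
        if x2 < -0.25:
            f2 = 0.0
        else:
            f2 = 6.0 * (x2 + 0.25)
        coup = 0.0
        for k in range(n):
            coup += C[j, k] * (state[0, k] - x1)
        zterm = 4.0 * (x1 - x0[j]) - z
        if z < 0.0:
            zterm -= 0.1 * z**7
        out[0, j] = y1 - f1 - z + I1
        out[1, j] = 1.0 - 5.0 * x1 * x1 - y1
        out[2, j] = r * zterm + Ks * coup
        out[3, j] = -y2 + x2 - x2 * x2 * x2 + I2 + 0.002 * g - 0.3 * (z - 3.5)
        out[4, j] = (-y2 + f2) / tau
        out[5, j] = x1 - gamma_g * g


@njit(cache=True)
def epileptor_heun_chunk(
    state, C, x0, I1, I2, tau, gamma_g, r, Ks, dt, noise, out, step0, rec_every
):
    """Stochastic Heun steps for the networked Epileptor.

    ``state``: (6, N), updated in place.  ``noise``: (n_steps, 2, N)
    pre-scaled increments for (x2, y2); the same increment enters predictor
    and corrector.
    """
    n_steps = noise.shape[0]
    n = state.shape[1]
    d0 = np.empty((6, n))
    d1 = np.empty((6, n))
    pred = np.empty((6, n))
    for i in range(n_steps):
        _epi_drift(state, C, x0, I1, I2, tau, gamma_g, r, Ks, d0)
        for v in range(6):
            for j in range(n):
                pred[v, j] = state[v, j] + dt * d0[v, j]
        for j in range(n):
            pred[3, j] += noise[i, 0, j]
            pred[4, j] += noise[i, 1, j]
        _epi_drift(pred, C, x0, I1, I2, tau, gamma_g, r, Ks, d1)
        for v in range(6):
            for j in range(n):
                state[v, j] += 0.5 * dt * (d0[v, j] + d1[v, j])
        for j in range(n):
            state[3, j] += noise[i, 0, j]
            state[4, j] += noise[i, 1, j]
        g = step0 + i + 1
        if g % rec_every == 0:
            out[g // rec_every, :, :] = state
    return 0


@njit(cache=True)
def balloon_chunk(u, dt_s, kappa, gamma_f, tau_h, alpha, rho, V0, k1, k2, k3, out):
    """Balloon-Windkessel forward model, explicit Euler at the input rate.

    ``u``: (N, T) neural drive; ``out``: (N, T) BOLD.  Integration starts
    from rest (s=0, f=v=q=1).  Returns (region, time-index) of the first
    nonpositive flow/volume, or (-1, -1) on success.
    """
    n, t_len = u.shape
    inv_alpha = 1.0 / alpha
    for j in range(n):
        s = 0.0
        f = 1.0
        v = 1.0
        q = 1.0
        for t in range(t_len):
            if f <= 0.0 or v <= 0.0:
                return j, t
            fv = v ** inv_alpha
            E = 1.0 - (1.0 - rho) ** (1.0 / f)
            ds = u[j, t] - kappa * s - gamma_f * (f - 1.0)
            df = s
            dv = (f - fv) / tau_h
            dq = (f * E / rho - fv * q / v) / tau_h
            s += dt_s * ds
            f += dt_s * df
            v += dt_s * dv
            q += dt_s * dq
            out[j, t] = V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))
    return -1, -1
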