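"""Compiled inner loops for the overdamped dynamics.

The settle loop runs an adaptive explicit Euler on ẋ = F/γ with a Lyapunov
guard: any trial step that would raise the potential is retried at half the
step size, so V is non-increasing along every accepted trajectory.  A
vanishing pair distance is clamped to 1e−9 with a fixed unit direction
(probability-zero geometry; documented in the methods note).
"""

import numpy as np
from numba import njit

_R_CLAMP = 1e-9


@njit(cache=True, fastmath=True)
def potential(pos, ei, ej, k, l):
    v = 0.0
    for s in range(ei.shape[0]):
        dx = pos[ei[s], 0] - pos[ej[s], 0]
        dy = pos[ei[s], 1] - pos[ej[s], 1]
        r = (dx * dx + dy * dy) ** 0.5
        d = r - l[s]
        v += 0.5 * k[s] * d * d
    return v


@njit(cache=True, fastmath=True)
def forces(pos, ei, ej, k, l, out):
    out[:, :] = 0.0
    for s in range(ei.shape[0]):
        i = ei[s]
        j = ej[s]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        r = (dx * dx + dy * dy) ** 0.5
        if r < _R_CLAMP:
            # coincident masses: arbitrary fixed direction, clamped distance
            dx, dy, r = _R_CLAMP, 0.0, _R_CLAMP
        c = -k[s] * (r - l[s]) / r
        fx = c * dx
        fy = c * dy
        out[i, 0] += fx
        out[i, 1] += fy
        out[j, 0] -= fx
        out[j, 1] -= fy


@njit(cache=True, fastmath=True)
def settle(pos, ei, ej, k, l, mobile, gamma, h_max, d_max, tol, max_steps, trace):
    """Relax ``pos`` in place to a local minimum of V.

    ``d_max`` caps the per-step displacement of any mass so the discrete
    path stays close to the continuous gradient flow even when forces are
    large (basin identity depends on the path, not just on descending).
    Returns (steps, converged, V_final, n_trace).  ``trace`` (len >= 1)
    receives V after each accepted step when its length allows.
    """
    n = pos.shape[0]
    f = np.empty((n, 2))
    trial = pos.copy()
    v = potential(pos, ei, ej, k, l)
    record = trace.shape[0] >= max_steps
    h = h_max
    steps = 0
    converged = False
    for _ in range(max_steps):
        forces(pos, ei, ej, k, l, f)
        fmax2 = 0.0
        for i in range(n):
            if mobile[i]:
                m2 = f[i, 0] * f[i, 0] + f[i, 1] * f[i, 1]
                if m2 > fmax2:
                    fmax2 = m2
        fmax = fmax2 ** 0.5
        if fmax < tol:
            converged = True
            break
        h_cap = h_max
        if fmax * h_max / gamma > d_max:
            h_cap = d_max * gamma / fmax
        if h > h_cap:
            h = h_cap
        accepted = False
        for _attempt in range(60):
            a = h / gamma
            for i in range(n):
                if mobile[i]:
                    trial[i, 0] = pos[i, 0] + a * f[i, 0]
                    trial[i, 1] = pos[i, 1] + a * f[i, 1]
            v_new = potential(trial, ei, ej, k, l)
            if v_new <= v + 1e-12 * (abs(v) + 1.0):
                for i in range(n):
                    if mobile[i]:
                        pos[i, 0] = trial[i, 0]
                        pos[i, 1] = trial[i, 1]
                v = v_new
                h = min(h * 1.02, h_cap)
                accepted = True
                break
            h *= 0.5
        if not accepted:
            # no downhill step found at any step size: numerically a minimum
            converged = True
            break
        if record:
            trace[steps] = v
        steps += 1
    return steps, converged, v, steps if record else 0
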