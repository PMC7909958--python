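"""Hot numerical kernels.

Plain-Python/numpy implementations that are JIT-compiled with numba when it
is importable.  ``HAVE_NUMBA`` tells callers whether the loop-based kernels
are fast; without numba the vectorized numpy fallbacks in ``tissue_pde`` are
used for smoothing instead of the loop versions here.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    import numba

    njit = numba.njit(cache=True, fastmath=False)
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    def njit(f):
        return f

    HAVE_NUMBA = False


@njit
def rbgs_sweep_2d(u, rhs, c, k2, phase):
    """One red-black Gauss-Seidel half-sweep for (c I - D/h^2 lap) u = rhs.

    ``k2 = D_alpha / h^2``; no-flux boundaries enter via mirrored neighbor
    indices.  Updates points with (i + j) % 2 == phase in place.
    """
    n0, n1 = u.shape
    for i in range(n0):
        im = i - 1 if i > 0 else 1
        ip = i + 1 if i < n0 - 1 else n0 - 2
        jstart = (phase + i) % 2
        for j in range(jstart, n1, 2):
            jm = j - 1 if j > 0 else 1
            jp = j + 1 if j < n1 - 1 else n1 - 2
            ns = u[im, j] + u[ip, j] + u[i, jm] + u[i, jp]
            u[i, j] = (rhs[i, j] + k2 * ns) / (c[i, j] + 4.0 * k2)


@njit
def rbgs_sweep_3d(u, rhs, c, k2, phase):
    n0, n1, n2 = u.shape
    for i in range(n0):
        im = i - 1 if i > 0 else 1
        ip = i + 1 if i < n0 - 1 else n0 - 2
        for j in range(n1):
            jm = j - 1 if j > 0 else 1
            jp = j + 1 if j < n1 - 1 else n1 - 2
            kstart = (phase + i + j) % 2
            for k in range(kstart, n2, 2):
                km = k - 1 if k > 0 else 1
                kp = k + 1 if k < n2 - 1 else n2 - 2
                ns = (u[im, j, k] + u[ip, j, k] + u[i, jm, k]
                      + u[i, jp, k] + u[i, j, km] + u[i, j, kp])
                u[i, j, k] = (rhs[i, j, k] + k2 * ns) / (c[i, j, k] + 6.0 * k2)


@njit
def _fprime(pv, Q, alpha_b, hc0, p50, n_hill, p50n):
    if pv < 0.0:
        pv = 0.0
    if pv > 0.0:
        pn = pv**n_hill
        sd = n_hill * p50n * pn / (pv * (pn + p50n) ** 2)
    elif n_hill == 1.0:
        sd = 1.0 / p50
    else:
        sd = 0.0
    return Q * (alpha_b + hc0 * sd)


@njit
def rk4_segment(P_b_in, Q, q, hs, alpha_b, hc0, p50, n_hill):
    """RK4 for dP_b/ds = -q(s)/f'(P_b) on a uniform grid (see blood_oxygen).

    ``hc0 = H_D * C0``.  Returns the P_b samples; the caller handles flux
    clamping and flow orientation.
    """
    m = q.shape[0] - 1
    out = np.empty(m + 1)
    p = P_b_in if P_b_in > 0.0 else 0.0
    out[0] = p
    p50n = p50**n_hill
    # midpoint flux by 4-point cubic interpolation: a chord average would
    # cut the classical RK4 to second order overall.  Where the samples are
    # locally non-smooth (clamp kinks, depletion fronts) the cubic lobes
    # oscillate and destabilize the outer coupling, so those intervals fall
    # back to the chord average (smoothness gauged by second differences).
    qmid = np.empty(m)
    for k in range(m):
        dq = abs(q[k + 1] - q[k])
        if 1 <= k <= m - 2:
            cub = (-q[k - 1] + 9.0 * q[k] + 9.0 * q[k + 1] - q[k + 2]) / 16.0
            curv = max(abs(q[k - 1] - 2.0 * q[k] + q[k + 1]),
                       abs(q[k] - 2.0 * q[k + 1] + q[k + 2]))
        elif m >= 3 and k == 0:
            cub = (5.0 * q[0] + 15.0 * q[1] - 5.0 * q[2] + q[3]) / 16.0
            curv = abs(q[0] - 2.0 * q[1] + q[2])
        elif m >= 3:
            cub = (5.0 * q[m] + 15.0 * q[m - 1] - 5.0 * q[m - 2] + q[m - 3]) / 16.0
            curv = abs(q[m] - 2.0 * q[m - 1] + q[m - 2])
        else:
            cub = 0.5 * (q[k] + q[k + 1])
            curv = 0.0
        if curv > 6.0 * dq + 1e-300:
            qmid[k] = 0.5 * (q[k] + q[k + 1])
        else:
            qmid[k] = cub
        if qmid[k] < 0.0 and q[k] >= 0.0 and q[k + 1] >= 0.0:
            qmid[k] = 0.0  # cubic overshoot at a clamped-flux kink
    for k in range(m):
        q0 = q[k]
        q1 = q[k + 1]
        qm = qmid[k]
        k1 = -q0 / _fprime(p, Q, alpha_b, hc0, p50, n_hill, p50n)
        k2 = -qm / _fprime(p + 0.5 * hs * k1, Q, alpha_b, hc0, p50, n_hill, p50n)
        k3 = -qm / _fprime(p + 0.5 * hs * k2, Q, alpha_b, hc0, p50, n_hill, p50n)
        k4 = -q1 / _fprime(p + hs * k3, Q, alpha_b, hc0, p50, n_hill, p50n)
        p = p + hs / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if p < 0.0:
            p = 0.0
        out[k + 1] = p
    return out
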