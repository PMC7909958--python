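"""Semi-implicit pseudo-time steps of the tissue reaction-diffusion equation.

One pseudo-time step solves the nonlinear elliptic system

    (P - P_prev)/dt = D_alpha lap_h P - M(P) + S

on a uniform node-centered grid with no-flux (mirrored ghost) boundaries,
where M(P) = M0 P/(P0 + P) is Michaelis-Menten consumption.  The solve uses
Newton linearization; each linear system (c I - D_alpha lap_h) e = r with
c = 1/dt + M'(P) is treated by geometric multigrid V-cycles (red-black
Gauss-Seidel 2+2 smoothing, full-weighting restriction, (bi/tri)linear
prolongation, dense coarsest solve at n = 4).  Full elliptic convergence per
step is deliberately not enforced — a few Newton steps suffice inside the
outer coupling loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .grid import Grid
from .parameters import PhysParams

__all__ = [
    "consumption",
    "consumption_deriv",
    "neighbor_sum",
    "laplacian_h",
    "pseudo_time_step",
    "v_cycle",
    "MultigridLevel",
    "build_hierarchy",
    "TissueField",
    "NewtonDivergenceError",
    "StepInfo",
]


class NewtonDivergenceError(RuntimeError):
    pass


def consumption(P_O, params: PhysParams):
    """Michaelis-Menten oxygen consumption M(P) = M0 P / (P0 + P)."""
    P_O = np.asarray(P_O, dtype=float)
    if np.any(P_O < 0):
        raise ValueError("tissue oxygen partial pressure must be >= 0")
    out = params.M0 * P_O / (params.P0 + P_O)
    return out if out.ndim else float(out)


def consumption_deriv(P_O, params: PhysParams):
    P_O = np.asarray(P_O, dtype=float)
    out = params.M0 * params.P0 / (params.P0 + P_O) ** 2
    return out if out.ndim else float(out)


def neighbor_sum(u: np.ndarray) -> np.ndarray:
    """Sum of the 2d axis neighbors with mirrored (no-flux) boundaries."""
    ns = np.zeros_like(u)
    for ax in range(u.ndim):
        um = np.moveaxis(u, ax, 0)
        nm = np.moveaxis(ns, ax, 0)
        nm[1:-1] += um[:-2] + um[2:]
        nm[0] += 2.0 * um[1]
        nm[-1] += 2.0 * um[-2]
    return ns


def laplacian_h(u: np.ndarray, h: float) -> np.ndarray:
    """Central-difference Laplacian with ghost-point reflection boundaries."""
    return (neighbor_sum(u) - 2.0 * u.ndim * u) / h**2


# ---------------------------------------------------------------------------
# multigrid machinery for (c I - D_alpha lap_h) e = r
# ---------------------------------------------------------------------------

_checker_cache: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _checker_masks(shape):
    key = shape
    if key not in _checker_cache:
        idx = sum(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"))
        _checker_cache[key] = (idx % 2 == 0, idx % 2 == 1)
    return _checker_cache[key]


def _smooth(u, rhs, c, k2, sweeps):
    """``sweeps`` red-black GS sweeps (each = red then black half-sweep)."""
    if _kernels.HAVE_NUMBA:
        f = _kernels.rbgs_sweep_2d if u.ndim == 2 else _kernels.rbgs_sweep_3d
        for _ in range(sweeps):
            f(u, rhs, c, k2, 0)
            f(u, rhs, c, k2, 1)
        return
    twod = 2.0 * u.ndim * k2
    for _ in range(sweeps):
        for mask in _checker_masks(u.shape):
            unew = (rhs + k2 * neighbor_sum(u)) / (c + twod)
            u[mask] = unew[mask]


def _linop_residual(u, rhs, c, k2):
    """r = rhs - (c u - D/h^2 (neighbor_sum - 2d u))."""
    return rhs - c * u + k2 * (neighbor_sum(u) - 2.0 * u.ndim * u)


def restrict_full_weighting(r: np.ndarray) -> np.ndarray:
    """Node-centered full weighting: (1/4, 1/2, 1/4) per axis, mirrored ends."""
    out = r
    for ax in range(r.ndim):
        m = np.moveaxis(out, ax, 0)
        even = m[::2]
        odd = m[1::2]
        res = 0.5 * even.copy()
        res[1:] += 0.25 * odd
        res[:-1] += 0.25 * odd
        res[0] += 0.25 * odd[0]
        res[-1] += 0.25 * odd[-1]
        out = np.moveaxis(res, 0, ax)
    return out


def prolong_linear(e: np.ndarray) -> np.ndarray:
    """(Bi/tri)linear interpolation from an (n/2+1)^d to an (n+1)^d grid."""
    out = e
    for ax in range(e.ndim):
        m = np.moveaxis(out, ax, 0)
        n_c = m.shape[0]
        fine = np.empty((2 * n_c - 1,) + m.shape[1:])
        fine[::2] = m
        fine[1::2] = 0.5 * (m[:-1] + m[1:])
        out = np.moveaxis(fine, 0, ax)
    return out


@dataclass
class MultigridLevel:
    grid: Grid
    c: np.ndarray          # diagonal field 1/dt + M'(u)
    k2: float              # D_alpha / h^2
    coarsest: bool = False


def build_hierarchy(grid: Grid, c_fine: np.ndarray, D_alpha: float) -> list[MultigridLevel]:
    levels = []
    g, c = grid, c_fine
    while True:
        levels.append(MultigridLevel(g, c, D_alpha / g.h**2, g.n == 4))
        if g.n == 4:
            return levels
        g = g.coarsen()
        c = restrict_full_weighting(c)


def _dense_matrix(level: MultigridLevel) -> np.ndarray:
    """Assemble the dense operator c I - D lap_h on a (small) level."""
    npts = level.grid.n + 1
    h2 = level.grid.h**2

    def lap1():
        L = np.zeros((npts, npts))
        for i in range(npts):
            L[i, i] = -2.0
            L[i, 1 if i == 0 else i - 1] += 1.0
            L[i, npts - 2 if i == npts - 1 else i + 1] += 1.0
        return L / h2

    L1 = lap1()
    eye = np.eye(npts)
    if level.grid.dim == 2:
        lap = np.kron(L1, eye) + np.kron(eye, L1)
    else:
        lap = (np.kron(np.kron(L1, eye), eye)
               + np.kron(np.kron(eye, L1), eye)
               + np.kron(np.kron(eye, eye), L1))
    return np.diag(level.c.reshape(-1)) - (level.k2 * h2) * lap


def v_cycle(u: np.ndarray, rhs: np.ndarray, levels: list[MultigridLevel],
            lev: int = 0, pre: int = 2, post: int = 2) -> np.ndarray:
    """One multigrid V-cycle for the Helmholtz-type system at ``levels[lev]``.

    Mutates and returns ``u``.
    """
    level = levels[lev]
    if level.coarsest:
        A = _dense_matrix(level)
        u[...] = np.linalg.solve(A, rhs.reshape(-1)).reshape(rhs.shape)
        return u
    _smooth(u, rhs, level.c, level.k2, pre)
    r = _linop_residual(u, rhs, level.c, level.k2)
    r_c = restrict_full_weighting(r)
    e_c = np.zeros_like(r_c)
    v_cycle(e_c, r_c, levels, lev + 1, pre, post)
    u += prolong_linear(e_c)
    _smooth(u, rhs, level.c, level.k2, post)
    return u


# ---------------------------------------------------------------------------
# the pseudo-time step
# ---------------------------------------------------------------------------

@dataclass
class StepInfo:
    newton_iters: int = 0
    v_cycles: int = 0
    residual_rms: float = 0.0


def pseudo_time_step(
    P_O_n: np.ndarray,
    S_field: np.ndarray,
    dt: float,
    params: PhysParams,
    grid: Grid,
    tol: float | None = None,
    max_newton: int = 10,
    max_vcycles_per_newton: int = 3,
    vcycle_contraction: float = 0.05,
) -> tuple[np.ndarray, StepInfo]:
    """Advance the tissue field by one semi-implicit pseudo-time step.

    Newton iterations stop once the RMS nonlinear residual drops below
    ``tol`` (default ``1e-3 * M0``); each Newton correction runs V-cycles
    until the linear residual has contracted by ``vcycle_contraction`` or
    ``max_vcycles_per_newton`` is reached.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if tol is None:
        tol = 1e-3 * params.M0
    u = np.array(P_O_n, dtype=float)
    rhs = P_O_n / dt + S_field
    info = StepInfo()

    def nonlinear_residual(v):
        return rhs - v / dt + params.D_alpha * laplacian_h(v, grid.h) \
            - consumption(np.maximum(v, 0.0), params)

    prev_rms = np.inf
    grow = 0
    for it in range(max_newton):
        r = nonlinear_residual(u)
        rms = float(np.sqrt(np.mean(r * r)))
        info.residual_rms = rms
        if rms < tol:
            break
        if rms > prev_rms * (1.0 + 1e-12):
            grow += 1
            if grow >= 3:
                raise NewtonDivergenceError(
                    f"Newton residual grew 3 consecutive iterations (rms={rms:.3e}); "
                    "try a smaller pseudo-time step dt"
                )
        else:
            grow = 0
        prev_rms = rms
        c = 1.0 / dt + consumption_deriv(np.maximum(u, 0.0), params)
        levels = build_hierarchy(grid, c, params.D_alpha)
        e = np.zeros_like(u)
        r0 = float(np.sqrt(np.mean(r * r)))
        for _ in range(max_vcycles_per_newton):
            v_cycle(e, r, levels)
            info.v_cycles += 1
            lin_r = _linop_residual(e, r, c, params.D_alpha / grid.h**2)
            if np.sqrt(np.mean(lin_r * lin_r)) < vcycle_contraction * r0:
                break
        u += e
        info.newton_iters += 1
    # converged steps keep the field physical; tiny negative round-off is cut
    np.clip(u, 0.0, None, out=u)
    return u, info


@dataclass
class TissueField:
    """Tissue oxygen partial pressure on a uniform grid.

    ``values`` is the reported field (post-processing correction applied
    near vessels when the solver ran with correction); ``raw`` is the
    uncorrected spread-source solution that the pseudo-time iteration
    propagates; ``source`` is the spread oxygen source density.
    """

    grid: Grid
    values: np.ndarray
    raw: np.ndarray | None = None
    source: np.ndarray | None = None
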