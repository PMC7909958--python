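"""Built-in quantitative studies: Krogh comparison, mesh refinement, error maps.

These drive the solver through the standard verification problems — the 2D
cobweb network and the 3D single-vessel cube — and compute the quantities a
convergence analysis reports: nested-mesh relative errors, fitted
convergence orders, and near-vessel error norms against a fine reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coupled import SolverConfig, solve_steady
from .grid import Grid
from .network import VesselNetwork, sample_polyline
from .parameters import PhysParams

__all__ = [
    "krogh_reference",
    "normalized_l2_diff",
    "restrict_injection",
    "vessel_region_mask",
    "mesh_refinement_study",
    "single_vessel_error_map",
    "RefinementResult",
    "pde_cost_scaling",
]


def krogh_reference(r, r0: float, Rt: float, Pb_wall: float, params: PhysParams):
    """Radial oxygen profile of the classical Krogh annulus.

    Zero-order consumption (P >> P0 so M ~ M0), wall value ``Pb_wall`` at
    the vessel radius ``r0``, no-flux at the tissue radius ``Rt``:

        P(r) = P_wall + (M0/(4 D_alpha)) (r^2 - r0^2)
                      - (M0 Rt^2 / (2 D_alpha)) ln(r / r0)
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < r0 * (1 - 1e-12)) or np.any(r > Rt * (1 + 1e-12)):
        raise ValueError("r must lie within the annulus [r0, Rt]")
    M0, D = params.M0, params.D_alpha
    out = Pb_wall + M0 / (4 * D) * (r * r - r0 * r0) - M0 * Rt**2 / (2 * D) * np.log(r / r0)
    return out if out.ndim else float(out)


def restrict_injection(fine: np.ndarray, factor: int) -> np.ndarray:
    """Nodal injection of a fine field onto a coarser nested grid."""
    sl = (slice(None, None, factor),) * fine.ndim
    return fine[sl]


def normalized_l2_diff(coarse: np.ndarray, fine: np.ndarray) -> float:
    """Normalized L2 difference at coincident nodes of nested meshes."""
    if fine.shape == coarse.shape:
        ref = fine
    else:
        factor = (fine.shape[0] - 1) // (coarse.shape[0] - 1)
        if (fine.shape[0] - 1) % (coarse.shape[0] - 1):
            raise ValueError("meshes are not nested")
        ref = restrict_injection(fine, factor)
    num = float(np.linalg.norm(coarse - ref))
    den = float(np.linalg.norm(ref))
    return num / den if den else 0.0


def vessel_region_mask(grid: Grid, net: VesselNetwork,
                       inflate: float = 0.0) -> np.ndarray:
    """Mesh nodes within the vessel radius (+ ``inflate``) of any centerline."""
    from .network import vessel_node_mask

    return vessel_node_mask(net, grid, inflate)


@dataclass
class RefinementResult:
    n_list: list[int]
    errors: list[float]       # E_n between the n and 2n solutions
    order: float              # least-squares slope of log2 E vs log2 h
    fields: dict              # n -> reported P_O field


def _fit_order(h_vals, errors) -> float:
    lh, le = np.log2(np.asarray(h_vals)), np.log2(np.asarray(errors))
    if len(lh) == 1:
        return float("nan")
    A = np.stack([lh, np.ones_like(lh)], axis=1)
    slope, _ = np.linalg.lstsq(A, le, rcond=None)[0]
    return float(slope)


def mesh_refinement_study(
    net: VesselNetwork,
    params: PhysParams,
    n_list: list[int],
    length: float,
    dim: int,
    config: SolverConfig | None = None,
    fields: dict | None = None,
) -> RefinementResult:
    """Solve at each mesh in ``n_list`` plus the next-finer mesh and fit the order.

    ``E_n`` is the normalized L2 difference between the n and 2n solutions at
    coincident nodes.  Pre-computed ``fields`` may be passed to reuse solves.
    """
    n_list = sorted(n_list)
    need = sorted(set(n_list) | {2 * max(n_list)} | {2 * n for n in n_list})
    fields = dict(fields or {})
    for n in need:
        if n not in fields:
            cfg = config or SolverConfig()
            tissue, *_ = solve_steady(net, params, cfg, Grid(dim, n, length))
            fields[n] = tissue.values
    errors = [normalized_l2_diff(fields[n], fields[2 * n]) for n in n_list]
    h_vals = [length / n for n in n_list]
    return RefinementResult(n_list, errors, _fit_order(h_vals, errors), fields)


def single_vessel_error_map(
    net: VesselNetwork,
    params: PhysParams,
    h_list: list[float],
    h_ref: float,
    length: float,
    config: SolverConfig | None = None,
    fields: dict | None = None,
) -> dict:
    """Relative error of P_O versus a fine-mesh reference run.

    Returns per-h global and vessel-region normalized L2 errors, the
    vessel-region being all mesh nodes within the vessel radius of the
    centerline.  Meshes must be nested with the reference.
    """
    if any(h < h_ref for h in h_list):
        raise ValueError("h_ref must be the smallest mesh size")
    fields = dict(fields or {})
    ns = {h: int(round(length / h)) for h in list(h_list) + [h_ref]}
    for h, n in ns.items():
        if n not in fields:
            cfg = config or SolverConfig()
            tissue, *_ = solve_steady(net, params, cfg, Grid(3, n, length))
            fields[n] = tissue.values
    n_ref = ns[h_ref]
    ref = fields[n_ref]
    out = {"h": [], "global_rel_err": [], "vessel_rel_err": [], "fields": fields}
    for h in h_list:
        n = ns[h]
        grid = Grid(3, n, length)
        mask = vessel_region_mask(grid, net)
        coarse = fields[n]
        ref_c = restrict_injection(ref, n_ref // n)
        out["h"].append(h)
        out["global_rel_err"].append(normalized_l2_diff(coarse, ref))
        num = float(np.linalg.norm((coarse - ref_c)[mask]))
        den = float(np.linalg.norm(ref_c[mask]))
        out["vessel_rel_err"].append(num / den if den else 0.0)
    return out


def pde_cost_scaling(n_list: list[int], dim: int = 2, repeats: int = 3) -> dict:
    """Wall time of a fixed-work pseudo-time step across mesh sizes.

    Measures one Newton iteration with one V-cycle on a smooth problem; at
    the multigrid's O(n^d log n) complexity the timing ratio across a 4x
    mesh range should track n^d log n.
    """
    import time

    from .parameters import default_params
    from .tissue_pde import pseudo_time_step

    params = default_params()
    out = {"n": list(n_list), "seconds": []}
    for n in n_list:
        grid = Grid(dim, n, 0.512)
        x = np.meshgrid(*[grid.axis_coords()] * dim, indexing="ij")
        S = 1e-4 * np.exp(-sum((xi - 0.256) ** 2 for xi in x) / 0.01)
        P0 = grid.zeros()
        pseudo_time_step(P0, S, 5000.0, params, grid, max_newton=1,
                         max_vcycles_per_newton=1)  # warm up caches/JIT
        best = np.inf
        for _ in range(repeats):
            t0 = time.perf_counter()
            pseudo_time_step(P0, S, 5000.0, params, grid, tol=0.0, max_newton=1,
                             max_vcycles_per_newton=1)
            best = min(best, time.perf_counter() - t0)
        out["seconds"].append(best)
    return out
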