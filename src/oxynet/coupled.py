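"""Outer fixed-point driver coupling blood and tissue oxygen.

Each outer iteration performs, in order:

1. evaluate the wall flux q* from the locally corrected tissue field with
   the blood oxygen pressure imposed on vessel walls;
2. relax the flux, ``q <- lam q + (1 - lam) q*`` (under-relaxation is
   required: a full update feeds the negative tissue-flux feedback loop);
3. sweep the network in flow order, integrating the blood oxygen ODE;
4. spread the centerline sources to the mesh and advance the tissue field
   by one semi-implicit multigrid-Newton pseudo-time step.

The iteration stops when the normalized L2 change of both q and P_O drops
below ``outer_tol``; at the fixed point the tissue field satisfies the
steady reaction-diffusion equation with the converged sources.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .blood_oxygen import BloodOxygenState, integrate_segment, invert_f, oxygen_flux_f, traverse_network
from .correction import CorrectionOperator
from .grid import Grid
from .hemodynamics import FlowSolution, solve_flow
from .network import VesselNetwork, vessel_node_mask
from .parameters import PhysParams
from .spreading import discretize_sources, spread
from .tissue_pde import TissueField, consumption, pseudo_time_step
from .wall_flux import evaluate_network_fluxes

__all__ = ["SolverConfig", "Diagnostics", "solve_steady", "residual_metrics",
           "default_dt", "SolverInstabilityError"]

log = logging.getLogger(__name__)


class SolverInstabilityError(RuntimeError):
    pass


def default_dt(grid: Grid) -> float:
    """Pseudo-time step schedule.

    Larger steps converge faster but destabilize the flux feedback loop; the
    stable window shrinks with mesh refinement.  Defaults: 5000 * (1024/n)
    in 2D and 5000 * (64/n) in 3D, overridable via :class:`SolverConfig`.
    """
    if grid.dim == 2:
        return 5000.0 * 1024.0 / grid.n
    return 5000.0 * 64.0 / grid.n


@dataclass
class SolverConfig:
    dt: float | None = None          # None -> default_dt(grid)
    lam: float = 0.5                 # flux relaxation weight
    outer_tol: float = 1e-3          # relative L2 change threshold (q and P_O)
    max_outer: int = 600
    clamp_negative_flux: bool = True
    use_correction: bool = True
    gauss_seidel_flux: bool = False
    newton_tol_factor: float = 1e-3  # Newton RMS tolerance = factor * M0
    max_newton: int = 10
    max_vcycles: int = 3
    correction_offsets: int = 4
    correction_patch: int = 8
    stall_action: str = "raise"      # or "accept": return the best state found
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.lam <= 1.0:
            raise ValueError("relaxation weight lam must lie in (0, 1]")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass
class Diagnostics:
    dt: float = 0.0
    iterations: int = 0
    converged: bool = False
    residual_q: list = field(default_factory=list)
    residual_P: list = field(default_factory=list)
    newton_iters: list = field(default_factory=list)
    v_cycles: list = field(default_factory=list)
    supply: float = 0.0        # total wall flux, cm^3 O2/s
    consumption: float = 0.0   # total tissue consumption, cm^3 O2/s


def residual_metrics(state_n, state_np1) -> tuple[float, float]:
    """Normalized L2 change of (q, P_O) between two outer iterates.

    Each state is a pair ``(q_vector, P_field)`` on identical discretizations.
    """
    q0, P0 = state_n
    q1, P1 = state_np1
    return _rel_l2(q0, q1), _rel_l2(P0.ravel(), P1.ravel())


def _rel_l2(a, b) -> float:
    nb = float(np.linalg.norm(b))
    d = float(np.linalg.norm(np.asarray(b) - np.asarray(a)))
    if nb == 0.0:
        return 0.0 if d == 0.0 else np.inf
    return d / nb


def _nearest_node_lookup(P: np.ndarray, grid: Grid):
    def lookup(pts):
        idx = np.clip(np.rint(np.atleast_2d(pts) / grid.h).astype(int), 0, grid.n)
        return P[tuple(idx.T)]
    return lookup


def solve_steady(
    net: VesselNetwork,
    params: PhysParams,
    config: SolverConfig,
    grid: Grid,
) -> tuple[TissueField, BloodOxygenState, FlowSolution, Diagnostics]:
    """Run the coupled solver to its steady state.

    Initialization: P_O = 0, q = 0, P_b = P_b0 everywhere.
    """
    params.validate()
    flow = solve_flow(net, params)
    h_k = grid.h / 3.0  # three centerline samples per mesh cell
    diag = Diagnostics(dt=config.dt if config.dt is not None else default_dt(grid))
    dt = diag.dt

    P = grid.zeros()
    q_list = None
    blood = traverse_network(net, flow, _zero_q(net, h_k), params, h_k,
                             clamp=config.clamp_negative_flux,
                             tissue_lookup=_nearest_node_lookup(P, grid))
    q_list = [np.zeros_like(p.q) for p in blood.profiles]
    corr_op = (CorrectionOperator(grid, None, params, config.correction_offsets,
                                  config.correction_patch)
               if config.use_correction else None)

    points = discretize_sources(net, blood, grid)
    # in-vessel mesh nodes are lumen, not tissue: never fit across them
    forbidden = vessel_node_mask(net, grid)
    from .wall_flux import foreign_lumen_masks

    wall_masks = foreign_lumen_masks(net, blood, grid) if grid.dim == 2 else None
    grow = 0
    prev_rq = np.inf
    # per-sample adaptive damping: the negative-flux clamp makes q* a
    # non-smooth map, and at fine meshes the depletion front of weak
    # vessels can flip a few samples on/off each sweep.  Samples whose
    # update direction alternates get their step shrunk (Aitken style),
    # which removes the limit cycle without touching smooth samples.
    damp = [np.ones_like(q) for q in q_list]
    prev_delta = [np.zeros_like(q) for q in q_list]
    for it in range(1, config.max_outer + 1):
        corr = corr_op.field(points) if corr_op is not None else 0.0
        field_eff = P + corr
        if config.gauss_seidel_flux:
            blood, q_new = _gauss_seidel_sweep(net, flow, blood, q_list, field_eff,
                                               grid, params, config, h_k, P, forbidden)
        else:
            q_star = evaluate_network_fluxes(net, blood, field_eff, grid, params,
                                             clamp=config.clamp_negative_flux,
                                             forbidden=forbidden,
                                             wall_masks=wall_masks)
            q_new = []
            for k, (qo, qs) in enumerate(zip(q_list, q_star)):
                delta = qs - qo
                flip = delta * prev_delta[k] < 0.0
                damp[k] = np.where(flip, np.maximum(0.002, 0.3 * damp[k]),
                                   np.minimum(1.0, 1.05 * damp[k]))
                prev_delta[k] = delta
                q_new.append(qo + damp[k] * (1.0 - config.lam) * delta)
            blood = traverse_network(net, flow, q_new, params, h_k,
                                     clamp=config.clamp_negative_flux,
                                     tissue_lookup=_nearest_node_lookup(P, grid))
        # the applied flux (after the depletion truncation of the sweep) is
        # the state the relaxation and the residual metric act on
        q_new = [prof.q for prof in blood.profiles]
        points = discretize_sources(net, blood, grid)
        S = spread(points, grid)
        P_new, info = pseudo_time_step(
            P, S, dt, params, grid,
            tol=config.newton_tol_factor * params.M0,
            max_newton=config.max_newton,
            max_vcycles_per_newton=config.max_vcycles,
        )
        rq, rp = residual_metrics(
            (np.concatenate(q_list) if q_list else np.empty(0), P),
            (np.concatenate(q_new) if q_new else np.empty(0), P_new),
        )
        diag.residual_q.append(rq)
        diag.residual_P.append(rp)
        diag.newton_iters.append(info.newton_iters)
        diag.v_cycles.append(info.v_cycles)
        q_list, P = q_new, P_new
        diag.iterations = it
        log.debug("outer %d: rq=%.3e rP=%.3e newton=%d vcycles=%d",
                  it, rq, rp, info.newton_iters, info.v_cycles)
        if rq < config.outer_tol and rp < config.outer_tol:
            diag.converged = True
            break
        if it > 5 and rq > 2.0 * prev_rq:
            grow += 1
            if grow >= 3:
                raise SolverInstabilityError(
                    f"outer residual doubling at iteration {it} "
                    f"(rq={rq:.3e}); reduce the pseudo-time step dt"
                )
        else:
            grow = 0
        prev_rq = rq
    else:
        if config.stall_action != "accept":
            raise SolverInstabilityError(
                f"no convergence within {config.max_outer} outer iterations; "
                f"residual history tail {diag.residual_q[-5:]}"
            )
        log.warning(
            "outer iteration stalled after %d steps (rq=%.2e, rP=%.2e): "
            "returning the final state; the flux residual is limited by "
            "clamp/depletion-front flicker at a few samples",
            config.max_outer, diag.residual_q[-1], diag.residual_P[-1],
        )

    corr = corr_op.field(points) if corr_op is not None else 0.0
    tissue = TissueField(grid=grid, values=P + corr, raw=P, source=S)
    diag.supply = blood.total_release()
    diag.consumption = float(np.sum(consumption(P, params)) * grid.h**grid.dim)
    return tissue, blood, flow, diag


def _zero_q(net: VesselNetwork, h_k: float) -> list[np.ndarray]:
    return [np.zeros(len(seg.sample_grid(h_k))) for seg in net.segments]


def _gauss_seidel_sweep(net, flow, blood, q_list, field_eff, grid, params, config,
                        h_k, P_raw, forbidden=None):
    """Flux update in flow order using freshly integrated upstream P_b."""
    from .wall_flux import (_fill_invalid, _normals_2d, flux_2d_batch, flux_3d,
                            junction_ball_mask, points_in_foreign_lumen)

    balls = junction_ball_mask(net, blood, grid)

    lam = config.lam
    clamp = config.clamp_negative_flux
    f_acc = np.zeros(net.n_nodes)
    Q_acc = np.zeros(net.n_nodes)
    pending = np.zeros(net.n_nodes, dtype=int)
    qmax = flow.max_flow()
    stag = np.abs(flow.Q) <= 1e-12 * qmax
    for k, seg in enumerate(net.segments):
        if not stag[k]:
            pending[seg.node_j if flow.Q[k] > 0 else seg.node_i] += 1
    for b in net.inlets:
        f_acc[b.node] += oxygen_flux_f(blood.inlet_Pb0, b.flow, params)
        Q_acc[b.node] += b.flow
    out_segs: dict[int, list[int]] = {}
    for k, seg in enumerate(net.segments):
        if not stag[k]:
            up = seg.node_i if flow.Q[k] > 0 else seg.node_j
            out_segs.setdefault(up, []).append(k)

    new_profiles = list(blood.profiles)
    q_new: list[np.ndarray] = [p.q for p in blood.profiles]
    lookup = _nearest_node_lookup(P_raw, grid)
    for k, prof in enumerate(blood.profiles):
        if prof.stagnant:
            q_new[k] = np.zeros(len(prof.s))
    ready = [n for n in range(net.n_nodes) if pending[n] == 0 and Q_acc[n] > 0]
    while ready:
        node = ready.pop()
        Pb_node = invert_f(f_acc[node], Q_acc[node], params)
        for k in out_segs.get(node, []):
            seg = net.segments[k]
            prof = blood.profiles[k]
            Qk = abs(flow.Q[k])
            forward = flow.Q[k] > 0
            oldq = q_list[k] if forward else q_list[k][::-1]
            prov = integrate_segment(Pb_node, Qk, oldq, seg.length, params, clamp)
            prov_poly = prov if forward else prov[::-1]
            if grid.dim == 2:
                normals = _normals_2d(prof.tangents)
                owner = np.full(len(prof.s), k)
                ok = ~balls[k]
                ok_p = ok & ~points_in_foreign_lumen(
                    prof.points + seg.radius * normals, net, owner)
                ok_m = ok & ~points_in_foreign_lumen(
                    prof.points - seg.radius * normals, net, owner)
                qs, valid = flux_2d_batch(field_eff, grid, prof.points, normals,
                                          seg.radius, prov_poly, params, clamp,
                                          forbidden, ok_p, ok_m)
                qs = _fill_invalid(qs, valid)
            else:
                qs = np.empty(len(prof.s))
                for m in range(len(prof.s)):
                    if balls[k][m]:
                        qs[m] = np.nan
                        continue
                    qs[m] = flux_3d(field_eff, grid, prof.points[m], prof.tangents[m],
                                    seg.radius, prov_poly[m], params, clamp,
                                    forbidden, on_degenerate="nan")
                qs = _fill_invalid(np.nan_to_num(qs), ~np.isnan(qs))
            qk = lam * q_list[k] + (1.0 - lam) * qs
            q_new[k] = qk
            q_flowdir = qk if forward else qk[::-1]
            pb_flowdir = integrate_segment(Pb_node, Qk, q_flowdir, seg.length, params, clamp)
            pb = pb_flowdir if forward else pb_flowdir[::-1]
            from .blood_oxygen import SegmentProfile
            new_profiles[k] = SegmentProfile(prof.s, prof.points, prof.tangents,
                                             pb, qk, float(flow.Q[k]), False)
            down = seg.node_j if forward else seg.node_i
            f_acc[down] += oxygen_flux_f(pb_flowdir[-1], Qk, params)
            Q_acc[down] += Qk
            pending[down] -= 1
            if pending[down] == 0:
                ready.append(down)
    return BloodOxygenState(new_profiles, blood.inlet_Pb0), q_new
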