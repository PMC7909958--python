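"""Intravascular oxygen transport.

The oxygen carried through a vessel cross-section is
``f(P_b) = Q (alpha_b P_b + H_D C0 S_a(P_b))`` with the Hill saturation
``S_a(P) = P^n / (P^n + P50^n)``.  Conservation along a vessel gives
``df/ds = -q(s)``; we integrate the equivalent pressure form
``dP_b/ds = -q(s) / f'(P_b)`` with classical RK4 on the per-segment
arclength grid.  A flow-ordered sweep propagates P_b through the network:
bifurcations inherit the parent value, collecting junctions mix by oxygen
conservation (invert f of the summed influx).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from ._kernels import rk4_segment
from .hemodynamics import FlowSolution
from .network import Segment, VesselNetwork, sample_polyline
from .parameters import PhysParams

__all__ = [
    "saturation",
    "saturation_deriv",
    "oxygen_flux_f",
    "flux_f_deriv",
    "invert_f",
    "integrate_segment",
    "traverse_network",
    "BloodOxygenState",
    "SegmentProfile",
]

log = logging.getLogger(__name__)

#: segments with |Q| below this fraction of the network maximum are stagnant
STAGNANT_REL = 1e-12


def saturation(P_b, params: PhysParams):
    """Hill oxygen-hemoglobin saturation S_a(P_b) in [0, 1]."""
    P_b = np.asarray(P_b, dtype=float)
    if np.any(P_b < 0):
        raise ValueError("blood oxygen partial pressure must be >= 0")
    pn = P_b**params.n_hill
    out = pn / (pn + params.P50**params.n_hill)
    return out if out.ndim else float(out)


def saturation_deriv(P_b, params: PhysParams):
    P_b = np.asarray(P_b, dtype=float)
    n, p50n = params.n_hill, params.P50**params.n_hill
    pn = P_b**n
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(P_b > 0, n * p50n * pn / (P_b * (pn + p50n) ** 2), 0.0)
    if params.n_hill == 1:
        out = np.where(P_b > 0, out, 1.0 / params.P50)
    return out if out.ndim else float(out)


def oxygen_flux_f(P_b, Q: float, params: PhysParams):
    """Cross-sectional oxygen flux f = Q (alpha_b P_b + H_D C0 S_a), cm^3 O2/s."""
    if Q < 0:
        raise ValueError("use the segment-local flow direction: Q must be >= 0")
    P_b = np.asarray(P_b, dtype=float)
    out = Q * (params.alpha_b * P_b + params.H_D * params.C0 * saturation(P_b, params))
    return out if out.ndim else float(out)


def flux_f_deriv(P_b, Q: float, params: PhysParams):
    P_b = np.asarray(P_b, dtype=float)
    out = Q * (params.alpha_b + params.H_D * params.C0 * saturation_deriv(P_b, params))
    return out if out.ndim else float(out)


def invert_f(f_target: float, Q: float, params: PhysParams) -> float:
    """Unique P_b with f(P_b) = f_target (f is strictly increasing for Q > 0)."""
    if Q <= 0:
        raise ValueError("invert_f requires Q > 0")
    if f_target < 0:
        raise ValueError("f_target must be >= 0")
    if f_target == 0.0:
        return 0.0
    # alpha_b * P <= f/Q at the root, so f/(Q alpha_b) bounds it above
    hi = f_target / (Q * params.alpha_b)
    lo = 0.0
    fun = lambda p: oxygen_flux_f(p, Q, params) - f_target
    if fun(hi) < 0:
        raise ValueError("f_target exceeds the physical range of f")
    p = brentq(fun, lo, hi, xtol=1e-14, rtol=8.881784197001252e-16, maxiter=200)
    return float(p)


def integrate_segment(
    P_b_in: float,
    Q: float,
    q_of_s: np.ndarray,
    L: float,
    params: PhysParams,
    clamp: bool = True,
) -> np.ndarray:
    """RK4 integration of dP_b/ds = -q(s)/f'(P_b) along one segment.

    ``q_of_s`` holds wall-flux samples on the uniform arclength grid
    ``s_k = k L/(len-1)``; midpoint values for RK4 stages are chord averages.
    With ``clamp`` (default) negative flux samples are treated as zero, so
    blood never gains oxygen from over-oxygenated tissue.  P_b is floored at
    zero (a depleted vessel cannot release more oxygen).
    """
    if Q <= 0:
        raise ValueError("integrate_segment requires Q > 0; handle stagnant segments upstream")
    q = np.maximum(q_of_s, 0.0) if clamp else np.asarray(q_of_s, dtype=float)
    m = len(q) - 1
    if m < 1:
        raise ValueError("need at least two flux samples")
    return rk4_segment(
        float(P_b_in), float(Q), np.ascontiguousarray(q, dtype=float), L / m,
        params.alpha_b, params.H_D * params.C0, params.P50, params.n_hill,
    )


@dataclass
class SegmentProfile:
    """Discretized blood state on one segment, in polyline orientation."""

    s: np.ndarray          # arclength samples, 0..L
    points: np.ndarray     # (m+1, dim) centerline coordinates
    tangents: np.ndarray   # (m+1, dim) unit tangents (polyline orientation)
    P_b: np.ndarray        # mmHg
    q: np.ndarray          # cm^3 O2 / cm / s
    Q: float               # signed flow in polyline orientation, cm^3/s
    stagnant: bool = False

    @property
    def h_k(self) -> float:
        return float(self.s[1] - self.s[0])

    def weights(self) -> np.ndarray:
        """Trapezoid arclength weights (endpoint halves)."""
        w = np.full(len(self.s), self.h_k)
        w[0] *= 0.5
        w[-1] *= 0.5
        return w


@dataclass
class BloodOxygenState:
    profiles: list[SegmentProfile]
    inlet_Pb0: float

    def total_release(self) -> float:
        """Total oxygen released to tissue, sum over segments of int q ds."""
        return float(sum(np.sum(p.q * p.weights()) for p in self.profiles))

    def q_vector(self) -> np.ndarray:
        return np.concatenate([p.q for p in self.profiles]) if self.profiles else np.empty(0)


def segment_sample_geometry(seg: Segment, h_k: float):
    s = seg.sample_grid(h_k)
    pts, tans = sample_polyline(seg.polyline, s)
    return s, pts, tans


def traverse_network(
    net: VesselNetwork,
    flow: FlowSolution,
    q_field: list[np.ndarray],
    params: PhysParams,
    h_k: float,
    inlet_Pb0: float | None = None,
    clamp: bool = True,
    tissue_lookup=None,
) -> BloodOxygenState:
    """Flow-ordered sweep computing P_b on every perfused segment.

    ``q_field[k]`` holds the wall flux on segment k's sample grid in polyline
    orientation.  Inlet boundary nodes carry blood at ``inlet_Pb0``
    (default ``params.P_b0``); bifurcations inherit the junction value and
    collecting junctions mix by conservation of oxygen.  Stagnant segments
    (|Q| ~ 0) release no oxygen and equilibrate with the surrounding tissue
    when a ``tissue_lookup(points) -> P_O`` callable is given.
    """
    if inlet_Pb0 is None:
        inlet_Pb0 = params.P_b0
    nseg = len(net.segments)
    qmax = flow.max_flow()
    stag = np.abs(flow.Q) <= STAGNANT_REL * qmax

    # per-node accumulators of arriving oxygen flux / flow
    f_acc = np.zeros(net.n_nodes)
    Q_acc = np.zeros(net.n_nodes)
    pending = np.zeros(net.n_nodes, dtype=int)  # unresolved upstream segments
    for k, seg in enumerate(net.segments):
        if stag[k]:
            continue
        down = seg.node_j if flow.Q[k] > 0 else seg.node_i
        pending[down] += 1
    for b in net.inlets:
        f_acc[b.node] += oxygen_flux_f(inlet_Pb0, b.flow, params)
        Q_acc[b.node] += b.flow

    profiles: list[SegmentProfile | None] = [None] * nseg
    # stagnant segments resolved immediately
    for k, seg in enumerate(net.segments):
        if not stag[k]:
            continue
        log.warning("segment %d is stagnant (Q ~ 0): q set to 0", k)
        s, pts, tans = segment_sample_geometry(seg, h_k)
        if tissue_lookup is not None:
            pb = np.asarray(tissue_lookup(pts), dtype=float)
        else:
            pb = np.zeros(len(s))
        profiles[k] = SegmentProfile(s, pts, tans, pb, np.zeros(len(s)), 0.0, True)

    out_segs: dict[int, list[int]] = {}
    for k, seg in enumerate(net.segments):
        if stag[k]:
            continue
        up = seg.node_i if flow.Q[k] > 0 else seg.node_j
        out_segs.setdefault(up, []).append(k)

    ready = [n for n in range(net.n_nodes) if pending[n] == 0 and Q_acc[n] > 0]
    done = np.zeros(nseg, dtype=bool)
    while ready:
        node = ready.pop()
        Pb_node = invert_f(f_acc[node], Q_acc[node], params) if Q_acc[node] > 0 else 0.0
        for k in out_segs.get(node, []):
            if done[k]:
                continue
            seg = net.segments[k]
            Qk = abs(flow.Q[k])
            s, pts, tans = segment_sample_geometry(seg, h_k)
            q = np.asarray(q_field[k], dtype=float)
            if len(q) != len(s):
                raise ValueError(f"q_field[{k}] has {len(q)} samples, expected {len(s)}")
            forward = flow.Q[k] > 0
            q_flowdir = q if forward else q[::-1]
            pb_flowdir = integrate_segment(Pb_node, Qk, q_flowdir, seg.length, params, clamp)
            # a depleted vessel (P_b = 0) has no oxygen left to release:
            # zero the flux beyond the depletion point and cap the cumulative
            # release at the oxygen flux actually entering the segment, so
            # the spread sources never exceed the blood's budget
            q_eff = q_flowdir.copy()
            q_eff[pb_flowdir <= 0.0] = 0.0
            w_tr = np.full(len(q_eff), seg.length / (len(q_eff) - 1))
            w_tr[0] *= 0.5
            w_tr[-1] *= 0.5
            f_in = oxygen_flux_f(Pb_node, Qk, params)
            cum = np.cumsum(q_eff * w_tr)
            if cum[-1] > f_in:
                over = np.searchsorted(cum, f_in)
                q_eff[over] -= (cum[over] - f_in) / w_tr[over]
                q_eff[over + 1:] = 0.0
                q_eff[over] = max(q_eff[over], 0.0)
            pb = pb_flowdir if forward else pb_flowdir[::-1]
            q_store = q_eff if forward else q_eff[::-1]
            profiles[k] = SegmentProfile(s, pts, tans, pb, q_store,
                                         float(flow.Q[k]), False)
            done[k] = True
            down = seg.node_j if forward else seg.node_i
            f_acc[down] += oxygen_flux_f(pb_flowdir[-1], Qk, params)
            Q_acc[down] += Qk
            pending[down] -= 1
            if pending[down] == 0:
                ready.append(down)
    if not all(done[k] or stag[k] for k in range(nseg)):
        raise RuntimeError("flow-directed cycle detected: traversal cannot order segments")
    return BloodOxygenState(profiles=profiles, inlet_Pb0=float(inlet_Pb0))
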