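"""Network hemodynamics: Poiseuille conductances and the Kirchhoff flow solve.

Each vessel is a Poiseuille resistor with conductance C = pi R^4 / (8 mu L);
node pressures solve the sparse symmetric Kirchhoff system sum_j Q_ij = s_i
with prescribed inflow/outflow s_i at boundary nodes and s_i = 0 at interior
nodes.  With pure-flow boundary conditions the pressures are determined only
up to a constant, so one boundary node is pinned to zero; flows are then
invariant to the absolute viscosity scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.linalg import spsolve

from .network import VesselNetwork
from .parameters import PhysParams

__all__ = ["conductance", "solve_flow", "FlowSolution"]


def conductance(R: float, L: float, mu: float) -> float:
    """Poiseuille conductance pi R^4 / (8 mu L)."""
    if R <= 0 or L <= 0 or mu <= 0:
        raise ValueError("R, L, mu must all be positive")
    return np.pi * R**4 / (8.0 * mu * L)


@dataclass
class FlowSolution:
    """Node pressures (internal units) and signed per-segment flows (cm^3/s).

    ``Q[k] > 0`` means flow runs from ``segments[k].node_i`` to ``node_j``.
    """

    pressure: np.ndarray
    Q: np.ndarray

    def max_flow(self) -> float:
        return float(np.max(np.abs(self.Q))) if len(self.Q) else 0.0


def solve_flow(net: VesselNetwork, params: PhysParams) -> FlowSolution:
    """Solve the Kirchhoff system for node pressures and segment flows."""
    net.validate()
    n = net.n_nodes
    cond = np.array(
        [conductance(s.radius, s.length, params.mu) for s in net.segments]
    )
    i = np.array([s.node_i for s in net.segments])
    j = np.array([s.node_j for s in net.segments])
    rows = np.concatenate([i, j, i, j])
    cols = np.concatenate([j, i, i, j])
    vals = np.concatenate([-cond, -cond, cond, cond])
    lap = csr_matrix(coo_matrix((vals, (rows, cols)), shape=(n, n)))

    s = net.source_vector()
    pin = net.boundary[0].node if net.boundary else 0
    lap = lap.tolil()
    lap[pin, :] = 0.0
    lap[:, pin] = 0.0
    lap[pin, pin] = 1.0
    rhs = s.copy()
    rhs -= 0.0  # pinned pressure is zero, nothing to move to the RHS
    rhs[pin] = 0.0
    p = spsolve(lap.tocsr(), rhs)
    if not np.all(np.isfinite(p)):
        raise RuntimeError("singular Kirchhoff system (disconnected component?)")

    Q = (p[i] - p[j]) * cond
    # interior mass-balance residual check
    res = s.copy()
    np.subtract.at(res, i, Q)
    np.add.at(res, j, Q)
    res[pin] = 0.0
    qscale = max(np.max(np.abs(Q)), 1e-300)
    if np.max(np.abs(res)) > 1e-10 * qscale:
        raise RuntimeError(
            f"flow solve failed conservation: residual {np.max(np.abs(res)):.3e}"
        )
    return FlowSolution(pressure=p, Q=Q)
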