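"""Vessel network representation, generators, and JSON input/output.

A :class:`VesselNetwork` is a graph of nodes with continuous coordinates (cm)
connected by cylindrical segments.  Each segment stores an ordered centerline
polyline so curved vessels (e.g. the cobweb ring arcs) are representable;
vessels need not align with any tissue mesh.  Boundary conditions prescribe
inflow/outflow rates (cm^3/s) at inlet/outlet nodes; all interior nodes are
flow-conserving.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .parameters import NL_PER_S

__all__ = [
    "Segment",
    "BoundaryNode",
    "VesselNetwork",
    "NetworkValidationError",
    "make_single_vessel_3d",
    "make_cobweb_2d",
    "make_random_web",
    "read_network",
    "write_network",
    "polyline_length",
    "sample_polyline",
    "vessel_node_mask",
]


class NetworkValidationError(ValueError):
    pass


def polyline_length(poly: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(poly, axis=0), axis=1)))


def sample_polyline(poly: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return points and unit tangents of a polyline at arclengths ``s``.

    Tangents are the chord directions of the hosting polyline piece, which is
    exact for straight segments and a consistent approximation for arcs.
    """
    chords = np.diff(poly, axis=0)
    clen = np.linalg.norm(chords, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(clen)])
    total = cum[-1]
    s = np.clip(np.asarray(s, dtype=float), 0.0, total)
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(clen) - 1)
    frac = (s - cum[idx]) / clen[idx]
    pts = poly[idx] + frac[:, None] * chords[idx]
    tans = chords[idx] / clen[idx, None]
    return pts, tans


@dataclass
class Segment:
    node_i: int
    node_j: int
    radius: float
    polyline: np.ndarray  # (m, dim); polyline[0] == nodes[node_i], [-1] == nodes[node_j]

    @property
    def length(self) -> float:
        return polyline_length(self.polyline)

    def sample_grid(self, h_k: float) -> np.ndarray:
        """Arclength sample grid 0 = s_0 < ... < s_m = L with spacing <= h_k."""
        L = self.length
        m = max(1, int(round(L / h_k)))
        return np.linspace(0.0, L, m + 1)


@dataclass
class BoundaryNode:
    node: int
    kind: str  # "inlet" | "outlet"
    flow: float  # cm^3/s, positive magnitude


@dataclass
class VesselNetwork:
    dim: int
    nodes: np.ndarray  # (N, dim) cm
    segments: list[Segment]
    boundary: list[BoundaryNode] = field(default_factory=list)

    # -- basic queries -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def inlets(self) -> list[BoundaryNode]:
        return [b for b in self.boundary if b.kind == "inlet"]

    @property
    def outlets(self) -> list[BoundaryNode]:
        return [b for b in self.boundary if b.kind == "outlet"]

    def source_vector(self) -> np.ndarray:
        """Kirchhoff node sources s_i: +flow at inlets, -flow at outlets."""
        s = np.zeros(self.n_nodes)
        for b in self.boundary:
            s[b.node] += b.flow if b.kind == "inlet" else -b.flow
        return s

    def total_length(self) -> float:
        return sum(seg.length for seg in self.segments)

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        if self.dim not in (2, 3) or self.nodes.shape[1] != self.dim:
            raise NetworkValidationError("node coordinates do not match dim")
        n = self.n_nodes
        for k, seg in enumerate(self.segments):
            if not (0 <= seg.node_i < n and 0 <= seg.node_j < n):
                raise NetworkValidationError(f"segment {k}: dangling node reference")
            if seg.radius <= 0:
                raise NetworkValidationError(f"segment {k}: nonpositive radius {seg.radius}")
            if len(seg.polyline) < 2:
                raise NetworkValidationError(f"segment {k}: polyline needs >= 2 points")
            for end, node in ((0, seg.node_i), (-1, seg.node_j)):
                if not np.allclose(seg.polyline[end], self.nodes[node], atol=1e-12):
                    raise NetworkValidationError(
                        f"segment {k}: polyline endpoint {end} detached from node {node}"
                    )
            L = seg.length
            if L <= 0:
                raise NetworkValidationError(f"segment {k}: zero length")
        for b in self.boundary:
            if b.kind not in ("inlet", "outlet"):
                raise NetworkValidationError(f"boundary node {b.node}: unknown kind {b.kind!r}")
            if not 0 <= b.node < n:
                raise NetworkValidationError(f"boundary: dangling node {b.node}")
            if b.flow < 0:
                raise NetworkValidationError(f"boundary node {b.node}: negative flow")
        s = self.source_vector()
        tot_in = sum(b.flow for b in self.inlets)
        if tot_in > 0 and abs(s.sum()) > 1e-10 * tot_in:
            raise NetworkValidationError(
                f"total inflow and outflow unbalanced: residual {s.sum():.3e} cm^3/s"
            )
        self._check_connected()

    def _check_connected(self) -> None:
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components

        if not self.segments:
            raise NetworkValidationError("network has no segments")
        i = np.array([s.node_i for s in self.segments])
        j = np.array([s.node_j for s in self.segments])
        a = coo_matrix((np.ones(len(i)), (i, j)), shape=(self.n_nodes, self.n_nodes))
        ncomp, labels = connected_components(a, directed=False)
        bnodes = {b.node for b in self.boundary}
        blabels = {labels[b] for b in bnodes}
        if len(blabels) > 1:
            raise NetworkValidationError("inlets and outlets lie in disconnected components")
        used = np.zeros(self.n_nodes, bool)
        used[i] = used[j] = True
        bad = set(labels[used]) - blabels
        if bad and bnodes:
            raise NetworkValidationError(
                f"connected component(s) {sorted(bad)} have no boundary node"
            )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def make_single_vessel_3d(
    edge_cm: float = 0.064,
    radius_cm: float = 0.001,
    inflow: float = 0.05 * NL_PER_S,
) -> VesselNetwork:
    """One straight axial vessel through the center of a tissue cube.

    Defaults reproduce the standard validation setup: 640 um cube, 10 um
    radius vessel spanning the full edge along z, 0.05 nl/s perfusion.
    """
    if edge_cm <= 0:
        raise ValueError("edge_cm must be positive")
    if radius_cm >= edge_cm / 4:
        raise ValueError("vessel radius must be < edge/4")
    c = edge_cm / 2
    nodes = np.array([[c, c, 0.0], [c, c, edge_cm]])
    seg = Segment(0, 1, radius_cm, nodes.copy())
    bc = [BoundaryNode(0, "inlet", inflow), BoundaryNode(1, "outlet", inflow)]
    net = VesselNetwork(3, nodes, [seg], bc)
    net.validate()
    return net


def make_cobweb_2d(
    n_spokes: int = 12,
    n_rings: int = 5,
    domain_cm: float = 0.512,
    radii_spec: tuple[float, float] = (28e-4, 12e-4),
    inflow_per_inlet: float = 0.6 * NL_PER_S,
    r_inner: float = 0.03,
    r_outer: float = 0.22,
    arc_chords: int = 12,
    inner_ring_radius: float = 5e-4,
    ring_radius: float = 10e-4,
) -> VesselNetwork:
    """Cobweb network: radial spokes plus concentric ring arcs.

    Mimics the main branches of a retinal network.  Blood enters and leaves
    at the innermost ring: the spoke-root nodes alternate inlet/outlet, so
    ``n_spokes`` must be even (12 spokes give the standard six inlets and six
    outlets at 0.6 nl/s each).  The spokes are the main branches and taper
    linearly from ``radii_spec[0]`` at the root to ``radii_spec[1]`` at the
    rim; ring arcs are thin cross-links (``ring_radius``) and the innermost
    loop is the thinnest of all (``inner_ring_radius``) — its large
    resistance keeps it from short-circuiting flow between the alternating
    inlets and outlets, so its blood flow is small and its oxygen pressure
    decays fast, while the bulk of the flow perfuses the spokes and the
    outer web.  Ring arcs are stored as fixed chordal polylines so the
    geometry is identical at every tissue-mesh resolution.
    """
    if n_spokes % 2 or n_spokes < 6:
        raise ValueError("n_spokes must be even and >= 6 to alternate inlets/outlets")
    if n_rings < 2:
        raise ValueError("need at least two rings")
    center = np.array([domain_cm / 2, domain_cm / 2])
    radii = np.linspace(r_inner, r_outer, n_rings)
    spoke_radius = np.linspace(radii_spec[0], radii_spec[1], n_rings)
    vradius = np.full(n_rings, ring_radius)
    vradius[0] = inner_ring_radius
    theta = 2 * np.pi * np.arange(n_spokes) / n_spokes

    nodes = np.empty((n_rings * n_spokes, 2))
    for k, r in enumerate(radii):
        nodes[k * n_spokes : (k + 1) * n_spokes] = (
            center + r * np.stack([np.cos(theta), np.sin(theta)], axis=1)
        )

    segments: list[Segment] = []
    # radial spokes between consecutive rings
    for k in range(n_rings - 1):
        for sp in range(n_spokes):
            i, j = k * n_spokes + sp, (k + 1) * n_spokes + sp
            poly = np.stack([nodes[i], nodes[j]])
            segments.append(Segment(i, j, 0.5 * (spoke_radius[k] + spoke_radius[k + 1]), poly))
    # ring arcs between adjacent spokes
    for k, r in enumerate(radii):
        for sp in range(n_spokes):
            i, j = k * n_spokes + sp, k * n_spokes + (sp + 1) % n_spokes
            t0, t1 = theta[sp], theta[sp] + 2 * np.pi / n_spokes
            ts = np.linspace(t0, t1, arc_chords + 1)
            poly = center + r * np.stack([np.cos(ts), np.sin(ts)], axis=1)
            poly[0], poly[-1] = nodes[i], nodes[j]  # exact endpoint attachment
            segments.append(Segment(i, j, vradius[k], poly))

    bc = [
        BoundaryNode(sp, "inlet" if sp % 2 == 0 else "outlet", inflow_per_inlet)
        for sp in range(n_spokes)
    ]
    net = VesselNetwork(2, nodes, segments, bc)
    net.validate()
    return net


def make_random_web(
    dim: int = 2,
    domain_cm: float = 0.512,
    target_density: float | None = None,
    seed: int = 0,
    prune: float = 0.25,
    capillary_radius: float = 3e-4,
) -> VesselNetwork:
    """Reproducible random capillary web on a jittered lattice.

    A synthetic stand-in for measured capillary plexus geometries: lattice
    nodes are jittered, lattice edges are randomly pruned, dead ends are
    trimmed, and four inlets plus four outlets are placed near the domain
    center (1 nl/s each in 2D, 2.5 nl/s in 3D).  ``target_density`` is the
    vessel length per tissue area (2D, cm/cm^2) or volume (3D, cm/cm^3); it
    sets the lattice spacing ``a`` via density ~ dim/a^(dim-1).
    """
    if dim not in (2, 3):
        raise ValueError("dim must be 2 or 3")
    rng = np.random.default_rng(seed)
    if target_density is None:
        target_density = 80.0 if dim == 2 else 2000.0
    a = (dim / target_density) ** (1.0 / (dim - 1))
    k = int(round(domain_cm / a)) - 1  # interior lattice nodes per axis
    if k < 4:
        raise NetworkValidationError("target_density too low: lattice degenerates")
    coords1 = np.linspace(a, domain_cm - a, k)
    mesh = np.meshgrid(*([coords1] * dim), indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    pts = pts + rng.uniform(-0.25 * a, 0.25 * a, pts.shape)

    def nid(idx):
        return int(np.ravel_multi_index(idx, (k,) * dim))

    edges = []
    for axis in range(dim):
        for idx in np.ndindex(*(k,) * dim):
            if idx[axis] + 1 < k:
                jdx = list(idx)
                jdx[axis] += 1
                edges.append((nid(idx), nid(tuple(jdx))))
    edges = [e for e in edges if rng.random() > prune]

    # inlets/outlets: the 8 lattice nodes nearest the center, alternating
    center = np.full(dim, domain_cm / 2)
    order = np.argsort(np.linalg.norm(pts - center, axis=1))
    special = order[:8]
    flow = (1.0 if dim == 2 else 2.5) * NL_PER_S

    # keep only the component containing the boundary nodes; trim dead ends
    adj = {i: set() for i in range(len(pts))}
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    seen, stack = set(), [int(special[0])]
    while stack:
        u = stack.pop()
        if u in seen:
            continue
        seen.add(u)
        stack.extend(adj[u] - seen)
    if not set(int(s) for s in special) <= seen:
        raise NetworkValidationError(
            "random web disconnected: raise target_density or lower prune"
        )
    keep = {i for i in seen}
    protected = {int(s) for s in special}
    changed = True
    while changed:  # iteratively trim degree-1 interior nodes
        changed = False
        deg = {i: 0 for i in keep}
        for i, j in edges:
            if i in keep and j in keep:
                deg[i] += 1
                deg[j] += 1
        drop = {i for i, d in deg.items() if d <= 1 and i not in protected}
        if drop:
            keep -= drop
            changed = True
    edges = [(i, j) for i, j in edges if i in keep and j in keep]

    remap = {old: new for new, old in enumerate(sorted(keep))}
    nodes = pts[sorted(keep)]
    segments = []
    for i, j in edges:
        ii, jj = remap[i], remap[j]
        r = capillary_radius * rng.uniform(0.8, 1.25)
        segments.append(Segment(ii, jj, r, np.stack([nodes[ii], nodes[jj]])))
    bc = [
        BoundaryNode(remap[int(s)], "inlet" if t % 2 == 0 else "outlet", flow)
        for t, s in enumerate(special)
    ]
    net = VesselNetwork(dim, nodes, segments, bc)
    net.validate()
    return net


def vessel_node_mask(net: VesselNetwork, grid, inflate: float = 0.0) -> np.ndarray:
    """Mesh nodes within the vessel radius (+ ``inflate``) of any centerline.

    Works chord-by-chord on local bounding boxes, so it stays cheap on fine
    meshes; used both as the "vessel region" of error metrics and to keep
    wall-flux fits from sampling the lumen of neighboring vessels.
    """
    h, n, d = grid.h, grid.n, grid.dim
    mask = np.zeros(grid.shape, dtype=bool)
    for seg in net.segments:
        reach = seg.radius * (1 + 1e-12) + inflate
        poly = seg.polyline
        for a, b in zip(poly[:-1], poly[1:]):
            lo = np.maximum(np.floor((np.minimum(a, b) - reach) / h).astype(int), 0)
            hi = np.minimum(np.ceil((np.maximum(a, b) + reach) / h).astype(int), n)
            if np.any(lo > hi):
                continue
            axes = [np.arange(lo[k], hi[k] + 1) for k in range(d)]
            mesh = np.meshgrid(*axes, indexing="ij")
            pts = np.stack([m.ravel() for m in mesh], axis=1) * h
            ab = b - a
            L2 = float(ab @ ab)
            t = np.clip((pts - a) @ ab / L2, 0.0, 1.0)
            dist = np.linalg.norm(pts - (a + t[:, None] * ab), axis=1)
            sub = (dist <= reach).reshape([len(ax) for ax in axes])
            sl = tuple(slice(lo[k], hi[k] + 1) for k in range(d))
            mask[sl] |= sub
    return mask


# ---------------------------------------------------------------------------
# JSON input/output
# ---------------------------------------------------------------------------

def write_network(net: VesselNetwork, path: str | Path) -> None:
    doc = {
        "dim": net.dim,
        "nodes": [list(map(float, p)) for p in net.nodes],
        "segments": [
            {
                "node_i": s.node_i,
                "node_j": s.node_j,
                "radius": float(s.radius),
                "polyline": [list(map(float, p)) for p in s.polyline],
            }
            for s in net.segments
        ],
        "boundary": [
            {"node": b.node, "type": b.kind, "flow_nl_per_s": float(b.flow / NL_PER_S)}
            for b in net.boundary
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_network(path: str | Path) -> VesselNetwork:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise NetworkValidationError(f"not valid network JSON: {e}") from e
    for key in ("dim", "nodes", "segments", "boundary"):
        if key not in doc:
            raise NetworkValidationError(f"missing field {key!r}")
    nodes = np.asarray(doc["nodes"], dtype=float)
    segments = []
    for k, s in enumerate(doc["segments"]):
        for key in ("node_i", "node_j", "radius", "polyline"):
            if key not in s:
                raise NetworkValidationError(f"segment {k}: missing field {key!r}")
        segments.append(
            Segment(int(s["node_i"]), int(s["node_j"]), float(s["radius"]),
                    np.asarray(s["polyline"], dtype=float))
        )
    bc = []
    for b in doc["boundary"]:
        for key in ("node", "type", "flow_nl_per_s"):
            if key not in b:
                raise NetworkValidationError(f"boundary record missing field {key!r}")
        bc.append(BoundaryNode(int(b["node"]), str(b["type"]),
                               float(b["flow_nl_per_s"]) * NL_PER_S))
    net = VesselNetwork(int(doc["dim"]), nodes, segments, bc)
    net.validate()
    return net
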