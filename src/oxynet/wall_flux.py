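"""Wall-flux evaluation from the tissue field by local least-squares fits.

The blood oxygen partial pressure is imposed on the vessel wall
(P_O = P_b at distance r0 from the centerline), and the near-wall tissue
field is fitted with a fixed intercept:

* 2D: on each side of the vessel, the four mesh points nearest to
  ``x +- r0 n`` that lie outside the vessel (ties included) fit a linear
  function ``P ~ P_b + G.(x - x+-)``; the side flux is ``-D_alpha G.n_out``
  and the two sides add.
* 3D: mesh points in the cylindrical shell ``r0 < r_perp <= r0 + h`` within
  an axial window ``|z - z0| <= h`` fit
  ``P ~ P_b + c1 log(r/r0) + c2 (z-z0) + c3 (z-z0) log(r/r0)``;
  the flux per unit length is ``-2 pi D_alpha c1``.

The fitting bases are solutions of the near-wall *Laplace* equation, but at
tissue-typical consumption the reaction term curves the field measurably
across the fit shell (the Krogh r^2 term, order M0 h^2 / D_alpha): left in,
it biases the fitted gradient at first order in h.  Both fits therefore
subtract the known zero-order-consumption particular solution —
``(M/4D)(r^2 - r0^2)`` around a 3D vessel, ``(M/2D)(d - r0)^2`` beyond a 2D
wall — scaled by the local saturation ``M(P_b)/M0``, before fitting the
harmonic basis.

Mesh nodes inside *any* vessel lumen never represent tissue, so a network
evaluation passes an in-vessel node mask and those nodes are excluded from
every fit.  Samples that lose their fit this way (it happens right at
junctions, where several lumina overlap) inherit the flux of the nearest
resolvable sample on the same segment — consistent with the observation
that the flux dips at cross-links where vessels share the local supply.

Fluxes are positive when oxygen leaves the blood; negative values are
clamped to zero by default (over-oxygenated tissue cannot push oxygen back
into the vessel).
"""

from __future__ import annotations

import numpy as np

from .grid import Grid
from .parameters import PhysParams

__all__ = ["flux_2d", "flux_3d", "flux_2d_batch", "evaluate_network_fluxes",
           "DegenerateFitError"]


class DegenerateFitError(RuntimeError):
    pass


def _mirror_idx(idx: np.ndarray, n: int) -> np.ndarray:
    """Reflect node indices across the no-flux faces (field is even there)."""
    idx = np.abs(idx)
    return np.where(idx > n, 2 * n - idx, idx)


# ---------------------------------------------------------------------------
# 2D: vectorized over centerline samples
# ---------------------------------------------------------------------------

_OFFS_2D = np.array([(di, dj) for di in range(-1, 3) for dj in range(-1, 3)])


def points_in_foreign_lumen(points: np.ndarray, net, owner: np.ndarray) -> np.ndarray:
    """True where a point lies inside the lumen of a segment it does not own."""
    out = np.zeros(len(points), dtype=bool)
    for k, seg in enumerate(net.segments):
        reach = seg.radius * (1.0 + 1e-12)
        poly = seg.polyline
        lo = poly.min(axis=0) - reach
        hi = poly.max(axis=0) + reach
        cand = np.all((points >= lo) & (points <= hi), axis=1) & (owner != k) & ~out
        if not np.any(cand):
            continue
        pts = points[cand]
        inside = np.zeros(len(pts), dtype=bool)
        for a, b in zip(poly[:-1], poly[1:]):
            ab = b - a
            t = np.clip((pts - a) @ ab / float(ab @ ab), 0.0, 1.0)
            dist = np.linalg.norm(pts - (a + t[:, None] * ab), axis=1)
            inside |= dist <= reach
        out[np.flatnonzero(cand)[inside]] = True
    return out


def _side_flux_2d_batch(field, grid, centers, normals, r0, P_b, params,
                        n_out_sign, forbidden, wall_ok=None):
    """Fitted outward-gradient flux on one side for all samples at once.

    Returns ``(q_side, valid)``; rows without at least 3 usable fit points
    or with a collinear point set are flagged invalid.
    """
    h, n = grid.h, grid.n
    n_out = n_out_sign * normals
    xp = centers + r0[:, None] * n_out
    base = np.floor(xp / h).astype(np.int64)
    idx = base[:, None, :] + _OFFS_2D[None, :, :]          # (K, 16, 2)
    y = idx * h  # geometric positions; indices mirrored across no-flux faces
    idx = _mirror_idx(idx, n)
    rel = y - centers[:, None, :]
    dperp = np.abs(np.einsum("kmi,ki->km", rel, n_out))
    usable = dperp > r0[:, None] * (1.0 + 1e-12)
    if forbidden is not None:
        usable &= ~forbidden[idx[..., 0], idx[..., 1]]
    counts = np.count_nonzero(usable, axis=1)
    valid = counts >= 3
    if wall_ok is not None:
        valid &= wall_ok  # x_side buried in a neighboring lumen: no wall there
    d = y - xp[:, None, :]
    dist = np.linalg.norm(d, axis=2)
    dist_m = np.where(usable, dist, np.inf)
    part = np.partition(dist_m, 3, axis=1)[:, 3]
    fallback = np.max(np.where(usable, dist, -np.inf), axis=1)  # < 4 usable points
    thresh = np.where(np.isfinite(part), part, fallback)
    keep = usable & (dist <= thresh[:, None] * (1.0 + 1e-12))
    w = keep.astype(float)
    vals = field[idx[..., 0], idx[..., 1]] - P_b[:, None]
    # remove the zero-order consumption curvature beyond the wall
    sat = P_b / (params.P0 + P_b)
    vals = vals - (sat * params.M0 / (2.0 * params.D_alpha))[:, None] \
        * np.maximum(dperp - r0[:, None], 0.0) ** 2
    a11 = np.sum(w * d[..., 0] ** 2, axis=1)
    a12 = np.sum(w * d[..., 0] * d[..., 1], axis=1)
    a22 = np.sum(w * d[..., 1] ** 2, axis=1)
    b1 = np.sum(w * d[..., 0] * vals, axis=1)
    b2 = np.sum(w * d[..., 1] * vals, axis=1)
    det = a11 * a22 - a12 * a12
    scale = np.maximum(a11 * a22, 1e-300)
    valid &= np.abs(det) > 1e-12 * scale
    det = np.where(valid, det, 1.0)
    g1 = (a22 * b1 - a12 * b2) / det
    g2 = (a11 * b2 - a12 * b1) / det
    q = -params.D_alpha * (g1 * n_out[:, 0] + g2 * n_out[:, 1])
    return q, valid


def flux_2d_batch(field, grid, centers, normals, r0, P_b, params, clamp=True,
                  forbidden=None, wall_ok_plus=None, wall_ok_minus=None):
    """Two-sided wall flux for a batch of 2D samples -> (q, valid)."""
    centers = np.atleast_2d(centers)
    normals = np.atleast_2d(normals)
    r0 = np.broadcast_to(np.asarray(r0, float), (len(centers),))
    P_b = np.broadcast_to(np.asarray(P_b, float), (len(centers),))
    qp, vp = _side_flux_2d_batch(field, grid, centers, normals, r0, P_b,
                                 params, +1.0, forbidden, wall_ok_plus)
    qm, vm = _side_flux_2d_batch(field, grid, centers, normals, r0, P_b,
                                 params, -1.0, forbidden, wall_ok_minus)
    q = qp + qm
    if clamp:
        q = np.maximum(q, 0.0)
    return q, vp & vm


def flux_2d(field, grid, x_center, normal, r0, P_b, params, clamp=True,
            forbidden=None) -> float:
    """Wall flux per unit length at one 2D centerline point."""
    q, valid = flux_2d_batch(field, grid, x_center[None, :], normal[None, :],
                             r0, P_b, params, clamp, forbidden)
    if not valid[0]:
        raise DegenerateFitError(
            "fewer than 3 usable fit points outside the vessel (or collinear)"
        )
    return float(q[0])


# ---------------------------------------------------------------------------
# 3D
# ---------------------------------------------------------------------------

def flux_3d(
    field: np.ndarray,
    grid: Grid,
    x_center: np.ndarray,
    tangent: np.ndarray,
    r0: float,
    P_b: float,
    params: PhysParams,
    clamp: bool = True,
    forbidden: np.ndarray | None = None,
    on_degenerate: str = "raise",
) -> float:
    """Wall flux per unit length at one 3D centerline point."""
    h, n = grid.h, grid.n
    reach = r0 + h
    lo = np.floor((x_center - reach) / h).astype(int)
    hi = np.ceil((x_center + reach) / h).astype(int)
    axes = [np.arange(lo[a], hi[a] + 1) for a in range(3)]
    II, JJ, KK = np.meshgrid(*axes, indexing="ij")
    idx = np.stack([II.ravel(), JJ.ravel(), KK.ravel()], axis=1)
    y = idx * h  # geometric positions; indices mirrored across no-flux faces
    idx = _mirror_idx(idx, n)
    dvec = y - x_center
    dz = dvec @ tangent
    rperp = np.linalg.norm(dvec - dz[:, None] * tangent, axis=1)
    sel = (rperp > r0 * (1.0 + 1e-12)) & (rperp <= reach * (1.0 + 1e-12)) \
        & (np.abs(dz) <= h * (1.0 + 1e-12))
    if forbidden is not None:
        sel &= ~forbidden[idx[:, 0], idx[:, 1], idx[:, 2]]
    if np.count_nonzero(sel) < 4:
        if on_degenerate == "raise":
            raise DegenerateFitError("fewer than 4 usable fit points in the 3D shell")
        return np.nan
    idx, dz, rperp = idx[sel], dz[sel], rperp[sel]
    ell = np.log(rperp / r0)
    A = np.stack([ell, dz, dz * ell], axis=1)
    vals = field[idx[:, 0], idx[:, 1], idx[:, 2]] - P_b
    # remove the zero-order consumption curvature (Krogh r^2 term)
    sat = P_b / (params.P0 + P_b)
    vals = vals - sat * params.M0 / (4.0 * params.D_alpha) * (rperp**2 - r0**2)
    # min-norm least squares: at coarse h the shell can hold a single radius,
    # which ties the dz and dz*log(r) columns; c1 stays well determined
    coef, *_ = np.linalg.lstsq(A, vals, rcond=None)
    q = -2.0 * np.pi * params.D_alpha * float(coef[0])
    return max(q, 0.0) if clamp else q


def _normals_2d(tangents: np.ndarray) -> np.ndarray:
    return np.stack([-tangents[:, 1], tangents[:, 0]], axis=1)


def junction_ball_mask(net, blood, grid) -> np.ndarray:
    """Per-segment masks flagging samples too close to a vessel end.

    The fitted flux at a segment end measures the constant-pressure edge
    singularity of the line-source model (and, at junctions, a region
    crowded by other lumina): its value grows under mesh refinement and
    dumps the blood's oxygen budget into a vanishing neighborhood.  Samples
    within twice the node's largest vessel radius of an end node are
    therefore flagged and inherit the nearest resolvable interior flux
    instead — matching the physical observation that the flux dips where
    vessels share the local supply.  The exclusion radius is purely
    geometric (mesh independent), so successive meshes regularize the same
    physical neighborhood and nested-mesh comparisons remain meaningful.
    End nodes lying on a no-flux domain face are exempt: the mirror
    symmetry continues the vessel there and the local fit is regular.
    """
    node_r = np.zeros(net.n_nodes)
    for seg in net.segments:
        node_r[seg.node_i] = max(node_r[seg.node_i], seg.radius)
        node_r[seg.node_j] = max(node_r[seg.node_j], seg.radius)
    h, L = grid.h, grid.length

    def on_face(node):
        x = net.nodes[node]
        return bool(np.any(np.abs(x) < h * 1e-6) or np.any(np.abs(x - L) < h * 1e-6))

    masks = []
    for k, prof in enumerate(blood.profiles):
        seg = net.segments[k]
        bad = np.zeros(len(prof.s), dtype=bool)
        if not on_face(seg.node_i):
            bad |= prof.s < 2.0 * node_r[seg.node_i]
        if not on_face(seg.node_j):
            bad |= prof.s > seg.length - 2.0 * node_r[seg.node_j]
        masks.append(bad)
    return masks


def foreign_lumen_masks(net, blood, grid=None):
    """Per-sample wall validity for both 2D fit sides, in evaluation order.

    Combines the foreign-lumen test for each side's wall point with the
    junction-ball exclusion.  Depends only on the sample geometry, so
    callers compute it once per (network, mesh) and reuse it across outer
    iterations.
    """
    cen, nor, rr, owner = [], [], [], []
    for k, prof in enumerate(blood.profiles):
        if prof.stagnant:
            continue
        cen.append(prof.points)
        nor.append(_normals_2d(prof.tangents))
        rr.append(np.full(len(prof.s), net.segments[k].radius))
        owner.append(np.full(len(prof.s), k))
    if not cen:
        return None
    cen = np.concatenate(cen)
    nor = np.concatenate(nor)
    rr = np.concatenate(rr)
    owner = np.concatenate(owner)
    ok_p = ~points_in_foreign_lumen(cen + rr[:, None] * nor, net, owner)
    ok_m = ~points_in_foreign_lumen(cen - rr[:, None] * nor, net, owner)
    if grid is not None:
        balls = junction_ball_mask(net, blood, grid)
        ball = np.concatenate([balls[k] for k in range(len(blood.profiles))
                               if not blood.profiles[k].stagnant])
        ok_p &= ~ball
        ok_m &= ~ball
    return ok_p, ok_m


def _fill_invalid(q: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Replace invalid samples by the nearest valid one along the segment."""
    if valid.all():
        return q
    if not valid.any():
        return np.zeros_like(q)
    s = np.arange(len(q), dtype=float)
    out = q.copy()
    out[~valid] = np.interp(s[~valid], s[valid], q[valid])
    return out


def evaluate_network_fluxes(
    net,
    blood,
    field: np.ndarray,
    grid: Grid,
    params: PhysParams,
    clamp: bool = True,
    forbidden: np.ndarray | None = None,
    wall_masks=None,
) -> list[np.ndarray]:
    """Evaluate q*(s) on every segment's sample grid from the tissue field.

    This is the flux-evaluation operator of the outer iteration: given the
    current blood profiles (for wall values) and the locally corrected
    tissue field, return fitted flux samples per segment.  ``forbidden``
    marks in-vessel mesh nodes to exclude from the fits; ``wall_masks``
    (from :func:`foreign_lumen_masks`) flags samples whose wall evaluation
    point is buried in a neighboring lumen.
    """
    out: list[np.ndarray | None] = [None] * len(blood.profiles)
    if grid.dim == 2:
        cen, nor, rr, pb, owner = [], [], [], [], []
        for k, prof in enumerate(blood.profiles):
            if prof.stagnant:
                out[k] = np.zeros(len(prof.s))
                continue
            cen.append(prof.points)
            nor.append(_normals_2d(prof.tangents))
            rr.append(np.full(len(prof.s), net.segments[k].radius))
            pb.append(prof.P_b)
            owner.append(np.full(len(prof.s), k))
        if cen:
            cen = np.concatenate(cen)
            nor = np.concatenate(nor)
            rr = np.concatenate(rr)
            owner = np.concatenate(owner)
            if wall_masks is None:
                ok_p = ~points_in_foreign_lumen(cen + rr[:, None] * nor, net, owner)
                ok_m = ~points_in_foreign_lumen(cen - rr[:, None] * nor, net, owner)
            else:
                ok_p, ok_m = wall_masks
            q, valid = flux_2d_batch(field, grid, cen, nor, rr,
                                     np.concatenate(pb), params, clamp, forbidden,
                                     wall_ok_plus=ok_p, wall_ok_minus=ok_m)
            for k in range(len(blood.profiles)):
                if out[k] is None:
                    sel = owner == k
                    out[k] = _fill_invalid(q[sel], valid[sel])
    else:
        balls = junction_ball_mask(net, blood, grid)
        for k, prof in enumerate(blood.profiles):
            if prof.stagnant:
                out[k] = np.zeros(len(prof.s))
                continue
            seg = net.segments[k]
            qs = np.empty(len(prof.s))
            for m in range(len(prof.s)):
                if balls[k][m]:
                    qs[m] = np.nan
                    continue
                qs[m] = flux_3d(field, grid, prof.points[m], prof.tangents[m],
                                seg.radius, prof.P_b[m], params, clamp,
                                forbidden, on_degenerate="nan")
            ok = ~np.isnan(qs)
            out[k] = _fill_invalid(np.nan_to_num(qs), ok)
    return out
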