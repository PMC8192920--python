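"""Roll the planar wireframe back onto the 3D lumen and sweep strut volumes.

The rollback map is the exact inverse of the planar unrolling: the axial
coordinate selects a pullback station (with linear blending of
equal-arclength-resampled stent contours between frames), the circumferential
coordinate is walked as arc length along that contour, and any stored
malapposition gap is re-applied radially.  Crown apexes are rounded with
circular-arc fillets and the strut cross-section profile is swept along each
edge with rotation-minimizing orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .core import Contour2D, FrameField, rotation_minimizing_frames, Centerline
from .errors import InvalidParameterError, OutOfRangeError
from .unroll import PlanarPointSet, StraightenedStack, rollup_strut
from .wireframe import WireframeGraph


def _poly_centroid(v: np.ndarray) -> np.ndarray:
    v2 = np.roll(v, -1, axis=0)
    cross = v[:, 0] * v2[:, 1] - v2[:, 0] * v[:, 1]
    a = cross.sum() / 2.0
    if abs(a) < 1e-12:
        return v.mean(axis=0)
    cx = ((v[:, 0] + v2[:, 0]) * cross).sum() / (6.0 * a)
    cy = ((v[:, 1] + v2[:, 1]) * cross).sum() / (6.0 * a)
    return np.array([cx, cy])


class RollbackMap:
    """Planar (x, y) -> 3D map anchored on the straightened stack.

    At a frame station the inverse walks the frame's own measured contour
    polygon (bit-exact inverse of unrolling); between frames the two
    neighbouring contours are resampled to a common arc-length
    parameterization anchored at the reference direction and blended
    linearly.
    """

    def __init__(
        self,
        stack: StraightenedStack,
        frame_field: FrameField,
        y_mode: str = "arclength",
        y_ref_period: Optional[float] = None,
        blend_samples: int = 512,
        station_tolerance: Optional[float] = None,
        smooth_window: int = 3,
    ):
        self.stack = stack
        self.field = frame_field
        self.y_mode = y_mode
        self.stations = stack.stations
        self.s0 = stack.distal_station
        spacing = np.diff(self.stations)
        if station_tolerance is None:
            # apex refinement may place crowns up to a frame spacing (plus the
            # fillet trim) beyond the outermost sampled frame; such points are
            # clamped to the boundary frame rather than rejected
            self.station_tolerance = (
                max(2.0 * float(spacing.max()), 0.3) if len(spacing) else 0.0
            )
        else:
            self.station_tolerance = station_tolerance
        # resampled contours, anchored at the reference direction
        raw = np.asarray([sf.contour.resample(blend_samples) for sf in stack.frames])
        if smooth_window > 0 and len(raw) > 2:
            # triangular moving average across frames: damps per-frame
            # segmentation noise while preserving slow axial variation
            # (linear trends are unchanged by the symmetric window)
            w = np.concatenate(
                [np.arange(1, smooth_window + 2), np.arange(smooth_window, 0, -1)]
            ).astype(float)
            sm = np.empty_like(raw)
            K = len(raw)
            for k in range(K):
                i0 = max(0, k - smooth_window)
                i1 = min(K, k + smooth_window + 1)
                ww = w[i0 - k + smooth_window : i1 - k + smooth_window]
                sm[k] = (raw[i0:i1] * ww[:, None, None]).sum(axis=0) / ww.sum()
            self._rs = list(sm)
        else:
            self._rs = list(raw)
        self._cen = [_poly_centroid(v) for v in self._rs]
        self._per = [sf.perimeter for sf in stack.frames]
        self.y_ref_period = y_ref_period or float(np.mean(self._per))

    def _local_y(self, y: float, perimeter: float) -> float:
        if self.y_mode == "normalized":
            return y * perimeter / self.y_ref_period
        return y

    def map_point(self, x: float, y: float, gap: float = 0.0, flagged: bool = False):
        """Map a planar point (stored gap re-applied radially) to 3D."""
        s = self.s0 + x
        lo, hi = self.stations[0], self.stations[-1]
        if s < lo - self.station_tolerance - 1e-9 or s > hi + self.station_tolerance + 1e-9:
            raise OutOfRangeError(
                f"x = {x} maps to station {s} outside stack range [{lo}, {hi}]"
            )
        s = min(max(s, lo), hi)
        k = int(np.clip(np.searchsorted(self.stations, s) - 1, 0, len(self.stations) - 2))
        w = (s - self.stations[k]) / (self.stations[k + 1] - self.stations[k])
        if w < 1e-9 or w > 1 - 1e-9:
            kk = k if w < 0.5 else k + 1
            sf = self.stack.frames[kk]
            y_loc = self._local_y(y, self._per[kk])
            uv = rollup_strut(sf.contour, float(np.mod(y_loc, self._per[kk])), gap, flagged)
            s_exact = self.stations[kk]
        else:
            verts = (1 - w) * self._rs[k] + w * self._rs[k + 1]
            cen = (1 - w) * self._cen[k] + w * self._cen[k + 1]
            per = (1 - w) * self._per[k] + w * self._per[k + 1]
            y_loc = float(np.mod(self._local_y(y, per), per))
            uv = _walk_polygon(verts, cen, y_loc, gap, flagged)
            s_exact = s
        aligned = np.asarray(uv) + self.stack.offset
        fr = self.field.frame_at(s_exact)
        return fr.from_plane(aligned[0], aligned[1])


def _walk_polygon(verts: np.ndarray, cen: np.ndarray, y: float, gap: float, flagged: bool):
    loop = np.vstack([verts, verts[:1]])
    cum = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(loop, axis=0), axis=1))])
    P = cum[-1]
    if flagged:
        c2d = Contour2D(verts, validate=False)
        return rollup_strut(c2d, float(np.mod(y, P)), gap, True)
    yy = float(np.mod(y * P / P, P))
    i = int(np.clip(np.searchsorted(cum, yy) - 1, 0, len(cum) - 2))
    t = (yy - cum[i]) / (cum[i + 1] - cum[i])
    q = loop[i] + t * (loop[i + 1] - loop[i])
    d = q - cen
    r = np.linalg.norm(d)
    if r == 0:
        return q
    return cen + d * (r - gap) / r


def make_gap_field(
    xs: np.ndarray,
    ys: np.ndarray,
    gaps: np.ndarray,
    wrap_period: float,
    radius: float = 0.3,
    min_gap: float = 0.1,
    k: int = 9,
    min_neighbors: int = 4,
):
    """Malapposition field over the planar domain from observed strut gaps.

    Returns a callable ``(x, y) -> gap``: the median gap of up to ``k``
    observed struts within ``radius``; gaps below ``min_gap``, or estimates
    supported by fewer than ``min_neighbors`` struts, are treated as apposed
    (zero) so segmentation jitter and isolated outliers are not re-applied
    to the wireframe.  The y axis is treated circularly by augmenting with
    +-period copies.
    """
    if len(xs) == 0:
        return lambda x, y: 0.0
    pts = np.column_stack(
        [np.tile(xs, 3), np.concatenate([ys - wrap_period, ys, ys + wrap_period])]
    )
    g3 = np.tile(gaps, 3)
    tree = cKDTree(pts)

    def field_fn(x, y):
        d, idx = tree.query([x, np.mod(y, wrap_period)], k=min(k, len(pts)))
        d, idx = np.atleast_1d(d), np.atleast_1d(idx)
        sel = idx[d <= radius]
        if sel.size < min_neighbors:
            return 0.0
        med = float(np.median(g3[sel]))
        return med if abs(med) >= min_gap else 0.0

    return field_fn


def roll_back_points(planar: PlanarPointSet, stack: StraightenedStack,
                     frame_field: FrameField) -> np.ndarray:
    """Map unrolled strut points back to 3D (exact inverse of unrolling).

    Strut rows sit exactly at frame stations, so each point is inverted
    against its own frame's measured contour polygon — the map is the
    bit-exact inverse of :func:`stentrec.unroll.unroll_strut`.
    """
    rmap = RollbackMap(stack, frame_field)
    df = planar.struts()
    out = [
        rmap.map_point(r.x_mm, r.y_mm, r.malapposition_mm, bool(r.flagged))
        for r in df.itertuples()
    ]
    return np.asarray(out)


# ---------------------------------------------------------------------------
# 3D wireframe


@dataclass
class Wire3D:
    """3D embedding of the wireframe: node positions and edge polylines."""

    g: nx.Graph  # nodes: pos (3,), role, provenance; edges: polyline (M,3), apex_idx

    def segments(self) -> np.ndarray:
        """All polyline segments as an (S, 2, 3) array."""
        segs = []
        for _, _, dd in self.g.edges(data=True):
            p = dd["polyline"]
            segs.append(np.stack([p[:-1], p[1:]], axis=1))
        return np.concatenate(segs, axis=0) if segs else np.zeros((0, 2, 3))

    def samples(self) -> np.ndarray:
        pts = [dd["polyline"] for _, _, dd in self.g.edges(data=True)]
        return np.vstack(pts) if pts else np.zeros((0, 3))

    def total_length(self) -> float:
        return float(
            sum(
                np.linalg.norm(np.diff(dd["polyline"], axis=0), axis=1).sum()
                for _, _, dd in self.g.edges(data=True)
            )
        )


@dataclass
class StentMesh:
    """Final stent: 3D wireframe plus swept volume surface."""

    wireframe3d: Wire3D
    volume_mesh: trimesh.Trimesh
    segment_meshes: list = field(default_factory=list)


def _densify_polyline(poly: np.ndarray, marked: list, step: float):
    """Insert points so segments are <= step; return new polyline and the
    indices of the originally marked vertices."""
    out = [poly[0]]
    new_marked = {0: 0}
    for i in range(len(poly) - 1):
        a, b = poly[i], poly[i + 1]
        L = np.linalg.norm(b - a)
        n = max(1, int(np.ceil(L / step)))
        for j in range(1, n + 1):
            out.append(a + (b - a) * j / n)
        new_marked[i + 1] = len(out) - 1
    idx = [new_marked[m] for m in marked if m in new_marked]
    return np.asarray(out), idx


def roll_back_wireframe(
    graph: WireframeGraph,
    stack: StraightenedStack,
    frame_field: FrameField,
    densify_step: float = 0.05,
    gap_field=None,
) -> Wire3D:
    """Map the planar wireframe onto the lumen-anchored stent surface.

    Edge polylines are densified (default 0.05 mm) before mapping so they
    follow the surface curvature; ``gap_field`` supplies per-sample
    malapposition offsets re-applied radially.
    """
    rmap = RollbackMap(stack, frame_field, graph.y_mode)
    if gap_field is None:
        gap_field = lambda x, y: 0.0
    g3 = nx.Graph()
    for nid, dd in graph.g.nodes(data=True):
        p = rmap.map_point(dd["x"], dd["y"], gap_field(dd["x"], dd["y"]))
        g3.add_node(nid, pos=np.asarray(p), role=dd["role"], ring=dd["ring"],
                    provenance=dd["provenance"])
    for a, b, dd in graph.g.edges(data=True):
        poly, apex_idx = _densify_polyline(
            np.asarray(dd["polyline"], dtype=float), dd.get("apex_idx", []), densify_step
        )
        pts = np.array([
            rmap.map_point(px, py, gap_field(px, py)) for px, py in poly
        ])
        g3.add_edge(a, b, polyline=pts, apex_idx=apex_idx,
                    provenance="bridged" if (
                        graph.g.nodes[a]["provenance"] == "bridged"
                        or graph.g.nodes[b]["provenance"] == "bridged") else "observed")
    return Wire3D(g3)


# ---------------------------------------------------------------------------
# Crown rounding


def _corner_fillet(branch_a: np.ndarray, branch_b: np.ndarray, radius: float,
                   n_arc: int = 9):
    """Fillet the corner where two polyline branches meet.

    ``branch_a``/``branch_b`` are ordered *outward from the corner* (first
    point = corner).  Returns ``(arc_points, trim_a, trim_b)`` — arc samples
    from the tangent point on branch a to the tangent point on branch b, and
    the arc-length trims applied to each branch — or None for a straight or
    degenerate corner.
    """
    P = branch_a[0]
    la = np.linalg.norm(np.diff(branch_a, axis=0), axis=1)
    lb = np.linalg.norm(np.diff(branch_b, axis=0), axis=1)
    if la.sum() == 0 or lb.sum() == 0 or radius <= 0:
        return None
    da = branch_a[1] - P
    db = branch_b[1] - P
    da = da / np.linalg.norm(da)
    db = db / np.linalg.norm(db)
    cosang = float(np.clip(da @ db, -1.0, 1.0))
    psi = np.arccos(cosang)  # angle between outgoing legs
    if psi > np.pi - 1e-6:  # collinear pass-through: no corner
        return None
    if psi < 0.35:  # near-parallel spike: artifact, not a crown; leave sharp
        return None
    t = radius / np.tan(psi / 2.0)
    t_max = 0.5 * min(la.sum(), lb.sum())
    if t > t_max:
        warnings.warn("fillet radius infeasible at a crown; using maximum feasible")
        t = t_max
        radius = t * np.tan(psi / 2.0)
    # arc center: along the bisector
    bis = da + db
    bis = bis / np.linalg.norm(bis)
    center = P + bis * radius / np.sin(psi / 2.0)
    pa = P + da * t
    pb = P + db * t
    va = pa - center
    vb = pb - center
    # rotate va toward vb in their common plane
    axis = np.cross(va, vb)
    na = np.linalg.norm(axis)
    if na < 1e-12:
        return None
    axis /= na
    total = np.arccos(np.clip((va @ vb) / (np.linalg.norm(va) * np.linalg.norm(vb)), -1, 1))
    arc = []
    for u in np.linspace(0.0, 1.0, n_arc):
        ang = u * total
        v = (
            va * np.cos(ang)
            + np.cross(axis, va) * np.sin(ang)
            + axis * (axis @ va) * (1 - np.cos(ang))
        )
        arc.append(center + v)
    return np.asarray(arc), t, t


def _trim_from_start(poly: np.ndarray, t: float) -> np.ndarray:
    """Drop the first ``t`` mm of a polyline (measured along it)."""
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if t >= cum[-1]:
        return poly[-1:].copy()
    i = int(np.searchsorted(cum, t, side="right") - 1)
    w = (t - cum[i]) / seg[i] if seg[i] > 0 else 0.0
    first = poly[i] + w * (poly[i + 1] - poly[i])
    return np.vstack([first, poly[i + 2:]]) if w > 1 - 1e-12 else np.vstack([first, poly[i + 1:]])


def round_crowns(wire: Wire3D, fillet_radius: float,
                 wrap_period: Optional[float] = None) -> Wire3D:
    """Replace each crown apex corner by a tangent circular-arc blend.

    Degree-2 apex nodes are filleted across the node (half the arc goes to
    each incident edge); crown corners absorbed inside edge polylines
    (linked crowns) are filleted in place.  Endpoints and link junctions are
    untouched.  Infeasible radii fall back per-apex to the maximum feasible
    radius with a warning.

    ``wrap_period`` handles planar wireframes whose second coordinate is
    circumferential: seam-crossing polylines are shifted to the node's
    period representative before filleting (3D wireframes have no seam and
    do not need this).
    """
    if fillet_radius < 0:
        raise InvalidParameterError("fillet_radius must be >= 0")
    out = Wire3D(wire.g.copy())
    if fillet_radius == 0:
        return out
    g = out.g
    # 1. interior corners (linked crown apexes) within each edge polyline
    for a, b, dd in g.edges(data=True):
        poly = np.asarray(dd["polyline"], dtype=float).copy()
        for ai in sorted(dd.get("apex_idx", []), reverse=True):
            if ai <= 0 or ai >= len(poly) - 1:
                continue
            branch_a = poly[ai::-1]
            branch_b = poly[ai:]
            res = _corner_fillet(branch_a, branch_b, fillet_radius)
            if res is None:
                continue
            arc, ta, tb = res
            left = _trim_from_start(branch_a, ta)[::-1]
            right = _trim_from_start(branch_b, tb)
            poly = _dedup(np.vstack([left, arc, right]))
        dd["polyline"] = poly
        dd["apex_idx"] = []
    # 2. degree-2 apex nodes: half the arc goes to each incident edge
    for nid in list(g.nodes):
        nd = g.nodes[nid]
        if nd["role"] not in ("peak", "valley") or g.degree[nid] != 2:
            continue
        (e1, e2) = list(g.edges(nid, data=True))
        d1, d2 = e1[2], e2[2]
        p1 = np.asarray(d1["polyline"], dtype=float)
        p2 = np.asarray(d2["polyline"], dtype=float)
        if wrap_period is not None:
            p1 = _to_node_period(p1, nd["pos"], wrap_period)
            p2 = _to_node_period(p2, nd["pos"], wrap_period)
        # orient both polylines outward from the node, remembering orientation
        flip1 = np.linalg.norm(p1[0] - nd["pos"]) > np.linalg.norm(p1[-1] - nd["pos"])
        flip2 = np.linalg.norm(p2[0] - nd["pos"]) > np.linalg.norm(p2[-1] - nd["pos"])
        if flip1:
            p1 = p1[::-1]
        if flip2:
            p2 = p2[::-1]
        res = _corner_fillet(p1, p2, fillet_radius)
        if res is None:
            continue
        arc, ta, tb = res
        mid = len(arc) // 2
        nd["pos"] = arc[mid]
        # outward-from-node polylines: arc half first, then the trimmed leg
        new_p1 = _dedup(np.vstack([arc[mid::-1], _trim_from_start(p1, ta)]))
        new_p2 = _dedup(np.vstack([arc[mid:], _trim_from_start(p2, tb)]))
        d1["polyline"] = new_p1[::-1] if flip1 else new_p1
        d2["polyline"] = new_p2[::-1] if flip2 else new_p2
    return out


def _to_node_period(poly: np.ndarray, pos: np.ndarray, period: float) -> np.ndarray:
    """Shift a planar polyline along the circumferential axis (index 1) so
    its node-side endpoint lands in the same period as the node position."""
    poly = poly.copy()
    # choose the endpoint whose shifted distance to the node is smallest
    best_shift = 0.0
    best = np.inf
    for endpoint in (poly[0], poly[-1]):
        for k in (-1.0, 0.0, 1.0):
            dist = np.linalg.norm(endpoint[:2] + np.array([0, k * period]) - pos[:2])
            if dist < best:
                best, best_shift = dist, k * period
    poly[:, 1] += best_shift
    return poly


def _dedup(poly: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Remove consecutive duplicate vertices (within tol)."""
    keep = np.concatenate(
        [[True], np.linalg.norm(np.diff(poly, axis=0), axis=1) > tol]
    )
    return poly[keep]


# ---------------------------------------------------------------------------
# Volume sweep


def _profile_polygon(profile: dict, n_circle: int = 24) -> np.ndarray:
    """2D cross-section polygon; circular profiles are area-corrected n-gons.

    The n-gon radius is inflated by sqrt(2*pi / (n*sin(2*pi/n))) so the
    polygon area equals the circle area and swept volumes match closed forms.
    """
    shape = profile.get("shape")
    if shape == "circular":
        d = float(profile["diameter"])
        if d <= 0:
            raise InvalidParameterError("profile diameter must be > 0")
        r = d / 2.0
        r_poly = r * np.sqrt(2 * np.pi / (n_circle * np.sin(2 * np.pi / n_circle)))
        ang = 2 * np.pi * np.arange(n_circle) / n_circle
        return np.column_stack([r_poly * np.cos(ang), r_poly * np.sin(ang)])
    if shape == "rectangular":
        w, t = float(profile["width"]), float(profile["thickness"])
        if w <= 0 or t <= 0:
            raise InvalidParameterError("profile dimensions must be > 0")
        return np.array(
            [[-w / 2, -t / 2], [w / 2, -t / 2], [w / 2, t / 2], [-w / 2, t / 2]]
        )
    raise InvalidParameterError(f"unknown profile shape {shape!r}")


def _sweep_polyline(
    poly: np.ndarray,
    profile2d: np.ndarray,
    radial_dirs: Optional[np.ndarray] = None,
) -> trimesh.Trimesh:
    """Sweep a profile along a 3D polyline; flat caps at both ends.

    Profile x spans the first in-plane axis, y the second.  With
    ``radial_dirs`` given (unit vectors, one per sample), the second axis is
    aligned with the radial direction so a rectangle's wide face lies
    tangent to the local lumen surface; otherwise orientation is
    rotation-minimizing along the polyline.
    """
    poly = _dedup(np.asarray(poly, dtype=float))
    if len(poly) < 2:
        raise InvalidParameterError("polyline too short to sweep")
    frames = rotation_minimizing_frames(Centerline(poly))
    rings = []
    for i, fr in enumerate(frames):
        e2 = fr.normal
        e1 = fr.binormal
        if radial_dirs is not None:
            r = radial_dirs[i] - (radial_dirs[i] @ fr.tangent) * fr.tangent
            nr = np.linalg.norm(r)
            if nr > 1e-6:
                e1 = r / nr  # thickness axis along the radial direction
                e2 = np.cross(e1, fr.tangent)
        ring = (
            fr.origin
            + np.outer(profile2d[:, 0], e2)
            + np.outer(profile2d[:, 1], e1)
        )
        rings.append(ring)
    rings = np.asarray(rings)
    K, N = rings.shape[:2]
    verts = rings.reshape(-1, 3)
    faces = []
    for k in range(K - 1):
        a = k * N + np.arange(N)
        b = k * N + (np.arange(N) + 1) % N
        c = (k + 1) * N + np.arange(N)
        d = (k + 1) * N + (np.arange(N) + 1) % N
        faces.append(np.stack([a, b, d], axis=1))
        faces.append(np.stack([a, d, c], axis=1))
    faces = np.vstack(faces)
    # caps: triangle fans about the end centroids
    c0 = len(verts)
    c1 = len(verts) + 1
    verts = np.vstack([verts, rings[0].mean(axis=0), rings[-1].mean(axis=0)])
    cap0 = np.stack(
        [np.full(N, c0), (np.arange(N) + 1) % N, np.arange(N)], axis=1
    )
    base = (K - 1) * N
    cap1 = np.stack(
        [np.full(N, c1), base + np.arange(N), base + (np.arange(N) + 1) % N], axis=1
    )
    mesh = trimesh.Trimesh(
        vertices=verts, faces=np.vstack([faces, cap0, cap1]), process=False
    )
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def sweep_volume(
    wire: Wire3D,
    profile: dict,
    frame_field: Optional[FrameField] = None,
    attempt_union: bool = False,
) -> StentMesh:
    """Sweep the strut profile along every wireframe edge into a volume mesh.

    Rectangular profiles are oriented with their wide face tangent to the
    lumen surface, approximated by the radial direction from the centerline
    (falls back to rotation-minimizing orientation where no centerline is
    given or the strut is on-axis).  Per-segment meshes are watertight; the
    combined surface is their union when a boolean engine is available, and
    their concatenation otherwise (end caps of adjacent segments abut after
    crown rounding, which makes tangents continuous across degree-2 nodes).
    """
    profile2d = _profile_polygon(profile)
    use_radial = profile.get("shape") == "rectangular" and frame_field is not None
    meshes = []
    for a, b, dd in wire.g.edges(data=True):
        poly = _dedup(np.asarray(dd["polyline"], dtype=float))
        if len(poly) < 2 or np.linalg.norm(np.diff(poly, axis=0), axis=1).sum() < 1e-9:
            warnings.warn(f"zero-length edge {a}-{b} skipped in sweep")
            continue
        radial = None
        if use_radial:
            s = frame_field.nearest_station(poly)
            origins = frame_field.resampled.point_at(s)
            radial = poly - origins
            norms = np.linalg.norm(radial, axis=1, keepdims=True)
            radial = np.divide(radial, np.where(norms > 1e-9, norms, 1.0))
        meshes.append(_sweep_polyline(poly, profile2d, radial))
    if not meshes:
        raise InvalidParameterError("wireframe has no sweepable edges")
    combined = None
    if attempt_union:
        try:
            combined = trimesh.boolean.union(meshes)
        except BaseException:
            combined = None
    if combined is None:
        combined = trimesh.util.concatenate(meshes)
    return StentMesh(wireframe3d=wire, volume_mesh=combined, segment_meshes=meshes)
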