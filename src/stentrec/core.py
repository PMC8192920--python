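"""Centerline geometry, rotation-minimizing frames, and in-plane coordinates.

Everything downstream of segmentation is expressed relative to a 3D vessel
centerline: OCT cross-sections are planes perpendicular to it, and absolute
roll about it is transported by rotation-minimizing frames (RMF).  The RMF is
computed with the double-reflection construction, which is stable at
inflection points where Frenet frames flip.

Units are millimetres throughout; coordinate systems are right-handed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import (
    InvalidContourError,
    InvalidInputError,
    InvalidParameterError,
    OutOfRangeError,
)

_ORTHO_TOL = 1e-9

# ---------------------------------------------------------------------------
# Centerline


class Centerline:
    """Ordered 3D polyline with cumulative arc length.

    Parameters
    ----------
    points : (N, 3) array_like
        Ordered vertices in mm.  At least two distinct points are required;
        exactly coincident consecutive points are merged.
    """

    def __init__(self, points) -> None:
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
            raise InvalidInputError("centerline needs >= 2 points of shape (N, 3)")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        keep = np.concatenate([[True], seg > 0.0])
        pts = pts[keep]
        if len(pts) < 2:
            raise InvalidInputError("centerline has < 2 distinct points")
        self.points = pts
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        self.cumulative_arclength = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def total_length(self) -> float:
        return float(self.cumulative_arclength[-1])

    def point_at(self, s):
        """Linear interpolation of position at arc length ``s`` (scalar or array)."""
        s = np.asarray(s, dtype=float)
        out = np.stack(
            [np.interp(s, self.cumulative_arclength, self.points[:, k]) for k in range(3)],
            axis=-1,
        )
        return out

    @classmethod
    def from_csv(cls, path) -> "Centerline":
        import pandas as pd

        df = pd.read_csv(path)
        cols = [c.strip().lower() for c in df.columns]
        df.columns = cols
        if not {"x", "y", "z"}.issubset(cols):
            raise InvalidInputError(f"centerline CSV must have x,y,z columns, got {cols}")
        return cls(df[["x", "y", "z"]].to_numpy())

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.points, columns=["x", "y", "z"]).to_csv(path, index=False)

    @classmethod
    def from_vtk(cls, path) -> "Centerline":
        """Read the first polyline from a legacy ASCII VTK PolyData file."""
        with open(path) as fh:
            tokens = fh.read().split()
        up = [t.upper() for t in tokens]
        if "POINTS" not in up:
            raise InvalidInputError("no POINTS section in VTK file")
        i = up.index("POINTS")
        n = int(tokens[i + 1])
        coords = np.array(tokens[i + 3 : i + 3 + 3 * n], dtype=float).reshape(n, 3)
        if "LINES" in up:
            j = up.index("LINES")
            count = int(tokens[j + 3])
            ids = np.array(tokens[j + 4 : j + 4 + count], dtype=int)
            coords = coords[ids]
        return cls(coords)


def resample_by_arclength(centerline: Centerline, spacing: float) -> Centerline:
    """Resample a centerline at (near-)equal arc-length spacing.

    The requested spacing is rounded to the nearest exact divisor of the total
    length so both endpoints are preserved and samples are exactly equally
    spaced.  Sparse inputs (median vertex spacing > 1 mm) are first smoothed
    with a cubic spline through the vertices.
    """
    if not np.isfinite(spacing) or spacing <= 0:
        raise InvalidParameterError(f"spacing must be > 0, got {spacing}")
    L = centerline.total_length
    if spacing >= L:
        raise InvalidParameterError(f"spacing {spacing} exceeds total length {L}")

    src = centerline
    seg = np.diff(src.cumulative_arclength)
    if np.median(seg) > 1.0:
        # sparse polyline: cubic spline through vertices, then arc-length resample
        cs = CubicSpline(src.cumulative_arclength, src.points, axis=0)
        fine_s = np.linspace(0.0, L, max(len(src.points) * 50, 200))
        src = Centerline(cs(fine_s))
        L = src.total_length

    n = max(1, int(round(L / spacing)))
    s_grid = np.linspace(0.0, L, n + 1)
    return Centerline(src.point_at(s_grid))


# ---------------------------------------------------------------------------
# Frames


@dataclass(frozen=True)
class LocalFrame:
    """Right-handed orthonormal frame at a point of the centerline.

    ``normal``/``binormal`` span the cross-section plane; ``tangent`` points
    along increasing arc length.
    """

    origin: np.ndarray
    tangent: np.ndarray
    normal: np.ndarray
    binormal: np.ndarray

    def __post_init__(self):
        for v in (self.tangent, self.normal, self.binormal):
            if abs(np.linalg.norm(v) - 1.0) > 1e-6:
                raise InvalidInputError("frame axes must be unit vectors")
        if (
            abs(self.tangent @ self.normal) > 1e-6
            or abs(self.tangent @ self.binormal) > 1e-6
            or abs(self.normal @ self.binormal) > 1e-6
        ):
            raise InvalidInputError("frame axes must be orthogonal")
        if np.linalg.norm(np.cross(self.tangent, self.normal) - self.binormal) > 1e-6:
            raise InvalidInputError("frame must be right-handed (t x n = b)")

    def to_plane(self, point3d):
        """Project to in-plane coordinates ``(u, v)`` plus out-of-plane offset."""
        d = np.asarray(point3d, dtype=float) - self.origin
        return float(d @ self.normal), float(d @ self.binormal), float(d @ self.tangent)

    def from_plane(self, u, v, offset=0.0):
        return self.origin + u * self.normal + v * self.binormal + offset * self.tangent

    def from_plane_many(self, uv):
        uv = np.asarray(uv, dtype=float)
        return self.origin + np.outer(uv[:, 0], self.normal) + np.outer(uv[:, 1], self.binormal)


def frame_plane_coordinates(frame: LocalFrame, point3d):
    """In-plane ``(u, v)`` coordinates and signed out-of-plane offset of a point."""
    return frame.to_plane(point3d)


def default_initial_normal(tangent: np.ndarray) -> np.ndarray:
    """Deterministic normal perpendicular to ``tangent``.

    Chooses the world axis least aligned with the tangent and orthogonalizes.
    Both the phantom generator and the reconstruction use this convention, so
    absolute roll calibrated via the marker is shared.
    """
    t = np.asarray(tangent, dtype=float)
    t = t / np.linalg.norm(t)
    axis = np.zeros(3)
    axis[int(np.argmin(np.abs(t)))] = 1.0
    n = axis - (axis @ t) * t
    return n / np.linalg.norm(n)


def _double_reflection_step(p0, t0, n0, p1, t1):
    """Transport normal n0 from (p0, t0) to (p1, t1) with minimal twist."""
    r1 = p1 - p0
    c1 = r1 @ r1
    if c1 == 0.0:
        nL, tL = n0, t0
    else:
        nL = n0 - (2.0 / c1) * (r1 @ n0) * r1
        tL = t0 - (2.0 / c1) * (r1 @ t0) * r1
    r2 = t1 - tL
    c2 = r2 @ r2
    if c2 == 0.0:
        n1 = nL
    else:
        n1 = nL - (2.0 / c2) * (r2 @ nL) * r2
    # re-orthogonalize against accumulated rounding
    n1 = n1 - (n1 @ t1) * t1
    return n1 / np.linalg.norm(n1)


def _polyline_tangents(points: np.ndarray) -> np.ndarray:
    t = np.gradient(points, axis=0)
    return t / np.linalg.norm(t, axis=1, keepdims=True)


def rotation_minimizing_frames(centerline: Centerline, initial_normal=None):
    """One twist-free frame per centerline point (double-reflection method).

    Parameters
    ----------
    initial_normal : array_like, optional
        Unit vector not parallel to the first tangent.  Defaults to
        :func:`default_initial_normal` of the first tangent.
    """
    pts = centerline.points
    tangents = _polyline_tangents(pts)
    if initial_normal is None:
        n = default_initial_normal(tangents[0])
    else:
        n = np.asarray(initial_normal, dtype=float)
        nn = np.linalg.norm(n)
        if nn == 0 or np.linalg.norm(np.cross(n / nn, tangents[0])) < 1e-9:
            raise InvalidParameterError("initial_normal parallel to first tangent")
        n = n - (n @ tangents[0]) * tangents[0]
        n = n / np.linalg.norm(n)

    frames = [LocalFrame(pts[0], tangents[0], n, np.cross(tangents[0], n))]
    for i in range(len(pts) - 1):
        n = _double_reflection_step(pts[i], tangents[i], n, pts[i + 1], tangents[i + 1])
        frames.append(LocalFrame(pts[i + 1], tangents[i + 1], n, np.cross(tangents[i + 1], n)))
    return frames


class FrameField:
    """Queryable rotation-minimizing frame field along a centerline.

    The centerline is resampled at ``spacing`` (default 0.05 mm) and an RMF
    chain is built once; :meth:`frame_at` interpolates position/tangent
    linearly within a segment and transports the nearest chain normal by one
    double-reflection step, so queries are continuous in arc length and
    reproducible across runs.
    """

    def __init__(self, centerline: Centerline, spacing: float = 0.05, initial_normal=None):
        self.centerline = centerline
        if centerline.total_length <= spacing:
            spacing = centerline.total_length / 4.0
        self.resampled = resample_by_arclength(centerline, spacing)
        self.frames = rotation_minimizing_frames(self.resampled, initial_normal)
        self.s_grid = self.resampled.cumulative_arclength

    @property
    def total_length(self) -> float:
        return float(self.s_grid[-1])

    def frame_at(self, s: float) -> LocalFrame:
        if s < -1e-9 or s > self.total_length + 1e-9:
            raise OutOfRangeError(
                f"station {s} outside centerline range [0, {self.total_length}]"
            )
        s = min(max(s, 0.0), self.total_length)
        i = int(np.clip(np.searchsorted(self.s_grid, s) - 1, 0, len(self.s_grid) - 2))
        w = (s - self.s_grid[i]) / (self.s_grid[i + 1] - self.s_grid[i])
        if w < 1e-12:
            return self.frames[i]
        if w > 1 - 1e-12:
            return self.frames[i + 1]
        f0, f1 = self.frames[i], self.frames[i + 1]
        origin = (1 - w) * f0.origin + w * f1.origin
        t = (1 - w) * f0.tangent + w * f1.tangent
        t = t / np.linalg.norm(t)
        n = _double_reflection_step(f0.origin, f0.tangent, f0.normal, origin, t)
        return LocalFrame(origin, t, n, np.cross(t, n))

    def nearest_station(self, points) -> np.ndarray:
        """Arc length of the nearest resampled centerline vertex per query point."""
        from scipy.spatial import cKDTree

        tree = cKDTree(self.resampled.points)
        _, idx = tree.query(np.atleast_2d(points))
        return self.s_grid[idx]


# ---------------------------------------------------------------------------
# Contours


def _signed_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


class Contour2D:
    """Closed (or open) polyline in a frame's normal/binormal plane.

    Closed contours are validated simple (non-self-intersecting) and stored
    counterclockwise; the last vertex must not repeat the first.
    """

    def __init__(self, vertices, closed: bool = True, validate: bool = True) -> None:
        v = np.asarray(vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise InvalidContourError("contour vertices must be (N, 2)")
        if closed and len(v) >= 2 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        if closed:
            if len(v) < 3:
                raise InvalidContourError("closed contour needs >= 3 vertices")
            if validate:
                from shapely.geometry import LinearRing

                if not LinearRing(v).is_simple:
                    raise InvalidContourError("contour is self-intersecting")
            if _signed_area(v) < 0:
                v = v[::-1].copy()
        self.vertices = v
        self.closed = closed
        self._cum = None
        self._ref = None
        self._cen = None

    @property
    def perimeter(self) -> float:
        v = self.vertices
        d = np.diff(np.vstack([v, v[:1]]) if self.closed else v, axis=0)
        return float(np.linalg.norm(d, axis=1).sum())

    @property
    def centroid(self) -> np.ndarray:
        """Area centroid for closed contours, vertex mean otherwise."""
        if self._cen is not None:
            return self._cen
        self._cen = self._centroid_impl()
        return self._cen

    def _centroid_impl(self) -> np.ndarray:
        if not self.closed:
            return self.vertices.mean(axis=0)
        v = self.vertices
        v2 = np.roll(v, -1, axis=0)
        cross = v[:, 0] * v2[:, 1] - v2[:, 0] * v[:, 1]
        a = cross.sum() / 2.0
        if abs(a) < 1e-12:
            return v.mean(axis=0)
        cx = ((v[:, 0] + v2[:, 0]) * cross).sum() / (6.0 * a)
        cy = ((v[:, 1] + v2[:, 1]) * cross).sum() / (6.0 * a)
        return np.array([cx, cy])

    @property
    def area(self) -> float:
        return abs(_signed_area(self.vertices)) if self.closed else 0.0

    # -- arc-length parameterization anchored at the reference direction -----

    def _loop(self) -> np.ndarray:
        return np.vstack([self.vertices, self.vertices[:1]])

    def _cumlen(self) -> np.ndarray:
        if self._cum is None:
            loop = self._loop()
            self._cum = np.concatenate(
                [[0.0], np.cumsum(np.linalg.norm(np.diff(loop, axis=0), axis=1))]
            )
        return self._cum

    def reference_start(self):
        """Intersection of the contour with the +u ray from its centroid.

        Returns ``(point, s0)`` where ``s0`` is the vertex-chain arc length of
        the intersection; it anchors the contour's arc-length coordinate so
        that unrolled frames share a common circumferential origin.
        """
        if self._ref is None:
            self._ref = self.ray_intersection(0.0)
        return self._ref

    def ray_intersection(self, angle: float):
        """First crossing of the ray from the centroid at ``angle`` (CCW from +u).

        Returns ``(point, s_along_contour)``.
        """
        c = self.centroid
        d = np.array([np.cos(angle), np.sin(angle)])
        loop = self._loop()
        a = loop[:-1] - c
        b = loop[1:] - c
        # solve a + t*(b-a) = r*d, t in [0,1), r > 0
        e = b - a
        denom = e[:, 0] * d[1] - e[:, 1] * d[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (a[:, 1] * d[0] - a[:, 0] * d[1]) / denom
            r = np.where(
                np.abs(d[0]) > np.abs(d[1]),
                (a[:, 0] + t * e[:, 0]) / d[0],
                (a[:, 1] + t * e[:, 1]) / d[1],
            )
        ok = np.isfinite(t) & (t >= -1e-12) & (t < 1.0 + 1e-12) & (r > 0)
        if not ok.any():
            raise InvalidContourError("ray from centroid does not cross contour")
        idx = np.flatnonzero(ok)
        best = idx[np.argmin(r[idx])]
        tt = float(np.clip(t[best], 0.0, 1.0))
        pt = loop[best] + tt * (loop[best + 1] - loop[best])
        cum = self._cumlen()
        s = cum[best] + tt * (cum[best + 1] - cum[best])
        return pt, float(s)

    def point_at_arclength(self, s: float, from_reference: bool = True):
        """Point at arc length ``s`` along the contour (CCW, modulo perimeter)."""
        cum = self._cumlen()
        P = cum[-1]
        if from_reference:
            _, s0 = self.reference_start()
            s = s + s0
        s = float(np.mod(s, P))
        loop = self._loop()
        i = int(np.clip(np.searchsorted(cum, s) - 1, 0, len(cum) - 2))
        w = (s - cum[i]) / (cum[i + 1] - cum[i])
        return loop[i] + w * (loop[i + 1] - loop[i])

    def resample(self, n: int, anchor_reference: bool = True) -> np.ndarray:
        """``n`` points equally spaced in arc length, starting at the reference
        direction (or at vertex 0 when ``anchor_reference`` is False)."""
        cum = self._cumlen()
        P = cum[-1]
        s0 = self.reference_start()[1] if anchor_reference else 0.0
        targets = np.mod(s0 + np.arange(n) * P / n, P)
        loop = self._loop()
        idx = np.clip(np.searchsorted(cum, targets, side="right") - 1, 0, len(cum) - 2)
        w = (targets - cum[idx]) / (cum[idx + 1] - cum[idx])
        return loop[idx] + w[:, None] * (loop[idx + 1] - loop[idx])

    def radial_project(self, point):
        """Project ``point`` radially (through the centroid) onto the contour.

        Returns ``(contour_point, s_from_reference, gap)`` where ``gap`` is the
        radial distance from the contour inwards to the point (positive when
        the point lies between centroid and contour, i.e. malapposed toward
        the lumen center).
        """
        c = self.centroid
        p = np.asarray(point, dtype=float)
        d = p - c
        theta = float(np.arctan2(d[1], d[0]))
        q, s_abs = self.ray_intersection(theta)
        _, s0 = self.reference_start()
        P = self.perimeter
        s_rel = float(np.mod(s_abs - s0, P))
        gap = float(np.linalg.norm(q - c) - np.linalg.norm(d))
        return q, s_rel, gap

    def rotated(self, angle: float) -> "Contour2D":
        ca, sa = np.cos(angle), np.sin(angle)
        R = np.array([[ca, -sa], [sa, ca]])
        return Contour2D(self.vertices @ R.T, closed=self.closed)

    def translated(self, offset) -> "Contour2D":
        return Contour2D(self.vertices + np.asarray(offset, dtype=float), closed=self.closed)


@dataclass(frozen=True)
class StrutPoint2D:
    """Segmented strut point in a frame plane."""

    position: tuple
    frame_index: int


def rotate2(points, angle):
    """Rotate 2D points CCW by ``angle`` about the origin."""
    pts = np.asarray(points, dtype=float)
    ca, sa = np.cos(angle), np.sin(angle)
    R = np.array([[ca, -sa], [sa, ca]])
    return pts @ R.T
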