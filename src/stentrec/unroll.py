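"""Packaging, rotation, straightening, and planar unrolling of stent struts.

After applying the per-frame lumen rotations, the stent contours and strut
points are stacked on a straight axis at their pullback stations, translated
so the distal stent contour centroid is the axis origin, and unrolled: the
axial coordinate is the station offset from the distal frame, the
circumferential coordinate is the arc length along the frame's stent contour
from the transported reference direction to the strut's radial projection.

Unrolling walks the measured contour polygon itself (no smoothing), so the
planar map and its inverse (rollback) are exact mutual inverses per frame.
Struts found further than a threshold from the stent contour are flagged
malapposed and unrolled on the arc at their own radius; the radial gap is
stored and re-applied at rollback so malapposition survives the round trip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from .core import Contour2D, rotate2
from .errors import InsufficientInputError, InvalidInputError
from .lumen import OCTFrame

MALAPPOSITION_FLAG_MM = 1.0  # radial gap beyond which a strut is flagged


@dataclass
class StackFrame:
    """One frame of the straightened stack (aligned + translated coordinates)."""

    index: int
    station: float
    contour: Contour2D
    struts: np.ndarray  # (K, 2)
    contour_fitted: bool = False

    @property
    def perimeter(self) -> float:
        return self.contour.perimeter


@dataclass
class StraightenedStack:
    frames: list  # of StackFrame, stations strictly increasing
    offset: np.ndarray  # translation applied (distal stent centroid, aligned coords)

    @property
    def stations(self) -> np.ndarray:
        return np.array([f.station for f in self.frames])

    @property
    def distal_station(self) -> float:
        return float(self.frames[0].station)


@dataclass
class PlanarPointSet:
    """Unrolled planar strut points and contour rows.

    ``points`` columns: x_mm, y_mm, role (strut|contour), frame_index,
    malapposition_mm, flagged, wrap_copy.  ``wrap_period`` maps frame index to
    that frame's stent-contour perimeter (the local wrap period).
    """

    points: pd.DataFrame
    wrap_period: dict

    def struts(self, include_wrap: bool = False) -> pd.DataFrame:
        df = self.points[self.points.role == "strut"]
        if not include_wrap:
            df = df[~df.wrap_copy]
        return df

    def to_csv(self, path) -> None:
        self.points.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PlanarPointSet":
        df = pd.read_csv(path)
        per = {}
        for fi, grp in df[df.role == "contour"].groupby("frame_index"):
            per[int(fi)] = float(grp.y_mm.max())
        return cls(points=df, wrap_period=per)


def fit_stent_contour(struts: np.ndarray) -> Contour2D:
    """Convex closed contour through a frame's strut points.

    Used when the segmentation provides strut points but no stent contour;
    the convex hull polygon is densified by arc length so downstream
    projections behave like a segmented contour.
    """
    struts = np.asarray(struts, dtype=float)
    if len(struts) < 3:
        raise InsufficientInputError("need >= 3 strut points to fit a stent contour")
    hull = ConvexHull(struts)
    poly = Contour2D(struts[hull.vertices])
    return Contour2D(poly.resample(max(60, 4 * len(struts)), anchor_reference=False))


def package_and_rotate(
    frames: Sequence[OCTFrame], lumen_rotations: np.ndarray
) -> StraightenedStack:
    """Rotate stent contours/struts by the lumen rotations and straighten.

    Frames without any stent information (no contour and fewer than 3 strut
    points) are omitted from the stack.  The whole stack is translated by the
    centroid of the distal (lowest-station) stent contour.
    """
    if len(lumen_rotations) != len(frames):
        raise InvalidInputError(
            f"rotation list length {len(lumen_rotations)} != frame count {len(frames)}"
        )
    stack_frames = []
    for f, rot in zip(frames, lumen_rotations):
        has_struts = len(f.strut_points) > 0
        contour = f.stent_contour
        fitted = False
        if contour is None:
            if len(f.strut_points) >= 3:
                contour = fit_stent_contour(f.strut_points)
                fitted = True
            elif has_struts:
                warnings.warn(
                    f"frame {f.index}: strut points but no stent contour and too few "
                    "points to fit one; frame skipped"
                )
                continue
            else:
                continue
        struts = rotate2(f.strut_points, rot) if has_struts else np.zeros((0, 2))
        stack_frames.append(
            StackFrame(
                index=f.index,
                station=f.station,
                contour=contour.rotated(rot),
                struts=struts,
                contour_fitted=fitted,
            )
        )
    if not stack_frames:
        raise InsufficientInputError("no frame carries stent information")
    stack_frames.sort(key=lambda sf: sf.station)
    offset = stack_frames[0].contour.centroid.copy()
    for sf in stack_frames:
        sf.contour = sf.contour.translated(-offset)
        sf.struts = sf.struts - offset
    return StraightenedStack(frames=stack_frames, offset=offset)


def unroll_strut(contour: Contour2D, point: np.ndarray):
    """Unroll one strut point against its frame's stent contour.

    Returns ``(y, gap, flagged)``: circumferential arc-length coordinate,
    stored radial gap, and the malapposition flag.  Flagged struts use the
    arc length at their own radius (azimuth preserved).
    """
    q, s_rel, gap = contour.radial_project(point)
    if abs(gap) <= MALAPPOSITION_FLAG_MM:
        return float(s_rel), float(gap), False
    c = contour.centroid
    d = np.asarray(point, dtype=float) - c
    theta = float(np.mod(np.arctan2(d[1], d[0]), 2 * np.pi))
    r = float(np.linalg.norm(d))
    return r * theta, float(gap), True


def rollup_strut(contour: Contour2D, y: float, gap: float, flagged: bool) -> np.ndarray:
    """Inverse of :func:`unroll_strut` on the same contour polygon."""
    c = contour.centroid
    if not flagged:
        q = contour.point_at_arclength(y)
        d = q - c
        r = np.linalg.norm(d)
        if r == 0:
            return q
        return c + d * (r - gap) / r
    # own-radius arc: y = r * theta with r = r_contour(theta) - gap
    theta = 2 * np.pi * np.mod(y, contour.perimeter) / contour.perimeter
    for _ in range(50):
        q, _ = contour.ray_intersection(theta)
        r = np.linalg.norm(q - c) - gap
        new_theta = y / r
        if abs(new_theta - theta) < 1e-12:
            theta = new_theta
            break
        theta = new_theta
    q, _ = contour.ray_intersection(np.mod(theta, 2 * np.pi))
    rc = np.linalg.norm(q - c)
    return c + (q - c) * (rc - gap) / rc


def unroll_to_plane(
    stack: StraightenedStack,
    wrap_band: float = 2.0,
    contour_samples: int = 100,
) -> PlanarPointSet:
    """Unroll the straightened stack onto the (axial, circumferential) plane.

    ``x`` is the station offset from the distal frame; ``y`` the contour
    arc-length coordinate.  A duplicate wrap band of width ``wrap_band`` is
    appended beyond ``y = perimeter`` to expose cross-seam continuity.
    """
    if not stack.frames:
        raise InsufficientInputError("empty stack")
    s0 = stack.distal_station
    rows = []
    wrap = {}
    for sf in stack.frames:
        x = sf.station - s0
        P = sf.perimeter
        wrap[sf.index] = P
        ys = np.arange(contour_samples) * P / contour_samples
        for y in ys:
            rows.append((x, y, "contour", sf.index, 0.0, False, False))
        for y in ys[ys < wrap_band]:
            rows.append((x, y + P, "contour", sf.index, 0.0, False, True))
        for p in sf.struts:
            y, gap, flagged = unroll_strut(sf.contour, p)
            rows.append((x, y, "strut", sf.index, gap, flagged, False))
            if y < wrap_band:
                rows.append((x, y + P, "strut", sf.index, gap, flagged, True))
    df = pd.DataFrame(
        rows,
        columns=["x_mm", "y_mm", "role", "frame_index", "malapposition_mm", "flagged", "wrap_copy"],
    )
    return PlanarPointSet(points=df, wrap_period=wrap)
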