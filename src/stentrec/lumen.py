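"""Lumen reconstruction: package, orient, and loft OCT lumen contours.

The segmented per-frame lumen contours are placed on rotation-minimizing
frames at their pullback stations (station = frame index x frame distance),
rotated in-plane so the per-frame marker direction maps onto the transported
reference direction, and lofted into a triangulated tube.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import trimesh

from .core import Contour2D, FrameField, LocalFrame
from .errors import (
    InsufficientInputError,
    InvalidContourError,
    InvalidInputError,
    MissingReferenceError,
    OutOfRangeError,
)


@dataclass
class OCTFrame:
    """One segmented OCT pullback cross-section.

    Coordinates are mm in the OCT image plane with the catheter center at the
    origin.  ``marker_angle`` is the CCW angle (radians) at which the
    orientation marker appears in image coordinates; aligned frames map this
    direction to the transported reference direction (angle 0).
    """

    index: int
    station: float
    lumen_contour: Contour2D
    stent_contour: Optional[Contour2D] = None
    strut_points: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    marker_angle: Optional[float] = None

    def __post_init__(self):
        self.strut_points = np.asarray(self.strut_points, dtype=float).reshape(-1, 2)
        if self.station < 0:
            raise InvalidInputError(f"frame {self.index}: negative station {self.station}")


@dataclass
class LumenSurface:
    """Lofted lumen tube plus the aligned rings it interpolates."""

    mesh: trimesh.Trimesh
    rings: np.ndarray  # (K, N, 3) aligned, resampled ring vertices
    stations: np.ndarray  # (K,)


def _check_frames(frames: Sequence[OCTFrame]):
    st = np.array([f.station for f in frames], dtype=float)
    if len(st) and not np.all(np.diff(st) > 0):
        raise InvalidInputError("frame stations must be strictly increasing")


def package_contours(frames: Sequence[OCTFrame], field: FrameField):
    """Assign each frame's lumen contour the RMF frame at its station.

    Returns a list of ``(LocalFrame, Contour2D)`` pairs; the contour plane is
    perpendicular to the local centerline tangent by construction.
    """
    _check_frames(frames)
    placed = []
    for f in frames:
        if f.station > field.total_length + 1e-9:
            raise OutOfRangeError(
                f"frame {f.index} station {f.station} beyond centerline "
                f"length {field.total_length}"
            )
        placed.append((field.frame_at(f.station), f.lumen_contour))
    return placed


def interpolate_rotations(frames: Sequence[OCTFrame]) -> np.ndarray:
    """Per-frame in-plane rotation aligning the marker to the reference.

    The rotation for frame k is ``-marker_angle_k``; frames without a marker
    get linear angular interpolation between the nearest marked frames
    (boundary values held).  Marker angles are unwrapped before interpolating
    so slow catheter rotation drift is followed continuously.
    """
    idx = np.arange(len(frames))
    marked = np.array([i for i, f in enumerate(frames) if f.marker_angle is not None])
    if marked.size == 0:
        raise MissingReferenceError("no frame carries a marker angle")
    angles = np.unwrap(np.array([frames[i].marker_angle for i in marked], dtype=float))
    rot = -np.interp(idx, marked, angles)
    return rot


def orient_contours(placed, rotations: np.ndarray):
    """Rotate each placed contour in its plane by the given rotation."""
    if len(rotations) != len(placed):
        raise InvalidInputError("rotation list length mismatch")
    return [(fr, c.rotated(a)) for (fr, c), a in zip(placed, rotations)]


def loft_surface(oriented, samples_per_contour: int = 64) -> LumenSurface:
    """Loft aligned contours into a triangulated tube (open at both ends).

    Each contour is resampled to ``samples_per_contour`` points by arc length
    starting at the transported reference direction, giving a twist-free ring
    correspondence; consecutive rings are stitched with triangles.
    """
    if len(oriented) < 2:
        raise InsufficientInputError("lofting needs >= 2 contours")
    if samples_per_contour < 8:
        raise InsufficientInputError("samples_per_contour must be >= 8")
    rings = []
    stations = []
    for fr, c in oriented:
        if not c.closed:
            raise InvalidContourError("loft requires closed contours")
        uv = c.resample(samples_per_contour)
        rings.append(fr.from_plane_many(uv))
        stations.append(0.0)
    rings = np.asarray(rings)
    K, N = rings.shape[:2]
    vertices = rings.reshape(-1, 3)
    faces = []
    for k in range(K - 1):
        a = k * N + np.arange(N)
        b = k * N + (np.arange(N) + 1) % N
        c_ = (k + 1) * N + np.arange(N)
        d = (k + 1) * N + (np.arange(N) + 1) % N
        faces.append(np.stack([a, b, d], axis=1))
        faces.append(np.stack([a, d, c_], axis=1))
    faces = np.vstack(faces)
    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    if not mesh.is_winding_consistent:
        warnings.warn("lofted mesh winding inconsistent")
    return LumenSurface(mesh=mesh, rings=rings, stations=np.asarray(stations))


def reconstruct_lumen(
    frames: Sequence[OCTFrame], field: FrameField, samples_per_contour: int = 64
):
    """Full lumen stage: package, orient (marker), loft.

    Returns ``(LumenSurface, rotations)``; the rotations are reused verbatim
    by the stent unrolling stage.
    """
    placed = package_contours(frames, field)
    rotations = interpolate_rotations(frames)
    oriented = orient_contours(placed, rotations)
    surface = loft_surface(oriented, samples_per_contour)
    surface.stations = np.array([f.station for f in frames], dtype=float)
    return surface, rotations
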