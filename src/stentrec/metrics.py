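"""Morphometric comparison metrics and agreement statistics.

Implements the validation quantities used to compare reconstructed stents:
stent length along the centerline, mean stent diameter (MSD) from serial
cross-sections, cross-sectional ellipse ratio, strut-to-lumen malapposition,
Bland-Altman agreement, and the time-averaged wall shear stress (TAWSS)
post-processing formula TAWSS = (1/T) * integral of |tau_w| dt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .core import FrameField
from .errors import InsufficientInputError, InvalidInputError, InvalidParameterError
from .lumen import LumenSurface
from .rollback import StentMesh, Wire3D


# ---------------------------------------------------------------------------
# Cross-sections


@dataclass
class CrossSectionSeries:
    """Planar stent slices at uniform arc-length stations along the centerline."""

    stations: np.ndarray  # (K,)
    slices: list  # (M_k, 2) in-plane point sets (strut intersections)


def cross_sections(
    wire: Wire3D,
    field: FrameField,
    section_spacing: float = 0.1,
    stations=None,
) -> CrossSectionSeries:
    """Cut the stent wireframe perpendicular to the centerline every
    ``section_spacing`` (default 0.1 mm) over the stent's axial extent.

    Pass an explicit ``stations`` array to cut two stents (e.g. a
    reconstruction and its ground truth) on a common grid for paired
    comparison.
    """
    if section_spacing <= 0:
        raise InvalidParameterError("section_spacing must be > 0")
    segs = wire.segments()
    if len(segs) == 0:
        raise InvalidInputError("empty wireframe")
    if stations is None:
        samples = segs.reshape(-1, 3)
        s_all = field.nearest_station(samples)
        s_min, s_max = float(s_all.min()), float(s_all.max())
        stations = np.arange(s_min, s_max + 1e-9, section_spacing)
    else:
        stations = np.asarray(stations, dtype=float)
    a, b = segs[:, 0], segs[:, 1]
    slices = []
    for s in stations:
        fr = field.frame_at(min(s, field.total_length))
        da = (a - fr.origin) @ fr.tangent
        db = (b - fr.origin) @ fr.tangent
        mask = (da * db <= 0) & (np.abs(da - db) > 1e-15)
        if not mask.any():
            slices.append(np.zeros((0, 2)))
            continue
        t = da[mask] / (da[mask] - db[mask])
        p = a[mask] + t[:, None] * (b[mask] - a[mask])
        d = p - fr.origin
        uv = np.column_stack([d @ fr.normal, d @ fr.binormal])
        slices.append(uv)
    return CrossSectionSeries(stations=stations, slices=slices)


def paired_cross_sections(
    wire_a: Wire3D,
    field_a: FrameField,
    wire_b: Wire3D,
    field_b: FrameField,
    section_spacing: float = 0.1,
):
    """Slice two stents on a common station grid for paired comparison.

    The grid spans the overlap of the two axial extents; returns
    ``(series_a, series_b)`` with identical ``stations``.
    """
    sa = field_a.nearest_station(wire_a.samples())
    sb = field_b.nearest_station(wire_b.samples())
    lo = max(float(sa.min()), float(sb.min()))
    hi = min(float(sa.max()), float(sb.max()))
    stations = np.arange(lo, hi + 1e-9, section_spacing)
    return (
        cross_sections(wire_a, field_a, section_spacing, stations),
        cross_sections(wire_b, field_b, section_spacing, stations),
    )


# ---------------------------------------------------------------------------
# Stent length and diameter


def stent_length(wire: Wire3D, field: FrameField) -> float:
    """Arc-length distance along the centerline between the most distal and
    most proximal strut material."""
    pts = wire.samples()
    if len(pts) == 0:
        raise InvalidInputError("empty stent wireframe")
    s = field.nearest_station(pts)
    return float(s.max() - s.min())


def slice_diameter(points: np.ndarray, method: str = "area") -> float:
    """Stent diameter of one cross-sectional slice.

    ``method='area'`` (default): area-equivalent diameter 2*sqrt(A/pi) of
    the polygon through the slice strut points ordered by azimuth about
    their centroid.  ``'max_feret'``/``'min_feret'``: extremal caliper
    widths of the point set, exposed as alternative definitions.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        raise InsufficientInputError("slice needs >= 3 strut intersections")
    if method in ("max_feret", "min_feret"):
        ang = np.linspace(0, np.pi, 180, endpoint=False)
        dirs = np.column_stack([np.cos(ang), np.sin(ang)])
        proj = points @ dirs.T
        widths = proj.max(axis=0) - proj.min(axis=0)
        return float(widths.max() if method == "max_feret" else widths.min())
    if method != "area":
        raise InvalidParameterError(f"unknown diameter method {method!r}")
    c = points.mean(axis=0)
    d = points - c
    order = np.argsort(np.arctan2(d[:, 1], d[:, 0]))
    v = points[order]
    x, y = v[:, 0], v[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return float(2.0 * np.sqrt(area / np.pi))


def mean_stent_diameter(series: CrossSectionSeries):
    """Per-station area-equivalent diameters and their unweighted mean (MSD).

    Stations with fewer than 3 strut intersections are skipped with a warning.
    Returns ``(msd, stations, diameters)``.
    """
    if len(series.slices) == 0:
        raise InsufficientInputError("no cross-sections")
    st, dia = [], []
    skipped = 0
    for s, pts in zip(series.stations, series.slices):
        if len(pts) < 3:
            skipped += 1
            continue
        st.append(s)
        dia.append(slice_diameter(pts))
    if skipped:
        warnings.warn(f"{skipped} stations skipped (< 3 strut intersections)")
    if not dia:
        raise InsufficientInputError("no usable cross-sections")
    return float(np.mean(dia)), np.asarray(st), np.asarray(dia)


# ---------------------------------------------------------------------------
# Ellipse ratio


def ellipse_ratio(points: np.ndarray) -> float:
    """Cross-sectional circularity: X / Y.

    X is the distance between the two furthest points of the slice; Y is the
    maximum point-pair separation measured perpendicular to X's direction.
    Degenerate (collinear) slices raise.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise InsufficientInputError("ellipse ratio needs >= 3 points")
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    X = float(np.sqrt(d2[i, j]))
    if X == 0:
        raise InvalidInputError("all points coincide")
    axis = (pts[j] - pts[i]) / X
    perp = np.array([-axis[1], axis[0]])
    proj = pts @ perp
    Y = float(proj.max() - proj.min())
    if Y < 1e-12:
        raise InvalidInputError("collinear point set: ellipse ratio undefined")
    return X / Y


def _covers_circumference(pts: np.ndarray, max_gap_deg: float = 90.0) -> bool:
    """True when the slice samples the whole cross-sectional circumference:
    no azimuthal gap about the slice centroid wider than ``max_gap_deg``.
    Slices cutting only inter-ring links, or only two opposite crown arcs,
    do not define a stent shape."""
    d = pts - pts.mean(axis=0)
    ang = np.sort(np.arctan2(d[:, 1], d[:, 0]))
    gaps = np.diff(np.concatenate([ang, [ang[0] + 2 * np.pi]]))
    return float(np.degrees(gaps.max())) <= max_gap_deg


def ellipse_ratio_series(series: CrossSectionSeries, min_points: int = 6):
    """Ellipse ratio per usable cross-section; returns (stations, ratios).

    Slices with fewer than ``min_points`` strut intersections, or without
    full azimuthal coverage, are skipped: the ratio is a shape measure of
    the cross-sectional circumference and is undefined where the cut only
    grazes a few link struts.
    """
    st, rr = [], []
    for s, pts in zip(series.stations, series.slices):
        if len(pts) < min_points or not _covers_circumference(pts):
            continue
        try:
            rr.append(ellipse_ratio(pts))
        except (InsufficientInputError, InvalidInputError):
            continue
        st.append(s)
    return np.asarray(st), np.asarray(rr)


# ---------------------------------------------------------------------------
# Malapposition


def _distance_to_mesh(points: np.ndarray, mesh, k: int = 12) -> np.ndarray:
    """Unsigned distance to a triangulated surface.

    Exact point-to-triangle distance against the ``k`` nearest triangles (by
    centroid), which is exact whenever the true nearest triangle is among the
    candidates — ample for tubes with locally uniform triangle size.
    """
    import trimesh

    tris = mesh.triangles
    cent = tris.mean(axis=1)
    tree = cKDTree(cent)
    _, idx = tree.query(points, k=min(k, len(cent)))
    idx = np.atleast_2d(idx)
    best = np.full(len(points), np.inf)
    for col in range(idx.shape[1]):
        q = trimesh.triangles.closest_point(tris[idx[:, col]], points)
        best = np.minimum(best, np.linalg.norm(points - q, axis=1))
    return best


def malapposition(
    stent: StentMesh | Wire3D,
    lumen: LumenSurface,
    field: Optional[FrameField] = None,
    max_samples: int = 2000,
):
    """Signed strut-to-lumen distance per wireframe sample, and the maximum.

    Positive values point toward the lumen center (strut standing off the
    wall).  Returns ``(per_sample, max_value, sample_points)``.
    """
    wire = stent.wireframe3d if isinstance(stent, StentMesh) else stent
    pts = wire.samples()
    if len(pts) == 0:
        raise InvalidInputError("empty stent wireframe")
    if len(pts) > max_samples:
        sel = np.linspace(0, len(pts) - 1, max_samples).astype(int)
        pts = pts[sel]
    d = _distance_to_mesh(pts, lumen.mesh)
    if field is not None:
        s = field.nearest_station(pts)
        axis_pts = field.resampled.point_at(s)
        r_pt = np.linalg.norm(pts - axis_pts, axis=1)
        # surface radius at the same station/azimuth via the lumen rings
        tree = cKDTree(lumen.mesh.vertices)
        _, vid = tree.query(pts)
        v = lumen.mesh.vertices[vid]
        sv = field.nearest_station(v)
        r_sf = np.linalg.norm(v - field.resampled.point_at(sv), axis=1)
        sign = np.where(r_pt <= r_sf + 1e-12, 1.0, -1.0)
        d = d * sign
    return d, float(d.max()), pts


# ---------------------------------------------------------------------------
# Agreement statistics


@dataclass
class AgreementResult:
    """Bland-Altman agreement: mean difference and 95% limits."""

    mean_difference: float
    loa_low: float
    loa_high: float
    sd: float
    n: int


def bland_altman(a, b) -> AgreementResult:
    """Bland-Altman analysis of paired series ``a`` and ``b``.

    Differences d = a - b; limits of agreement are mean(d) +- 1.96 * SD(d)
    with the sample (n-1) standard deviation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidInputError("paired series must be 1-D and equal length")
    if len(a) < 2:
        raise InvalidInputError("need >= 2 pairs")
    d = a - b
    m = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(
        mean_difference=m,
        loa_low=m - 1.96 * sd,
        loa_high=m + 1.96 * sd,
        sd=sd,
        n=len(d),
    )


# ---------------------------------------------------------------------------
# TAWSS


@dataclass
class WSSHistory:
    """Wall-shear-stress magnitude per surface element over one cardiac cycle."""

    times: np.ndarray  # (T,) strictly increasing, spanning [0, period]
    tau_w: np.ndarray  # (T, E) or (T,) Pa, >= 0 after magnitude

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.tau_w = np.asarray(self.tau_w, dtype=float)
        if self.times.ndim != 1 or not np.all(np.diff(self.times) > 0):
            raise InvalidInputError("times must be 1-D strictly increasing")
        if self.tau_w.shape[0] != len(self.times):
            raise InvalidInputError("tau_w first axis must match times")


def tawss(history: WSSHistory) -> np.ndarray | float:
    """Time-averaged wall shear stress per element.

    TAWSS = (1/T) * trapezoidal integral of |tau_w| over one cycle of
    duration T = times[-1] - times[0].
    """
    if len(history.times) < 3:
        raise InvalidInputError("need >= 3 time points spanning a full cycle")
    T = history.times[-1] - history.times[0]
    integral = np.trapezoid(np.abs(history.tau_w), history.times, axis=0)
    out = integral / T
    return float(out) if np.ndim(out) == 0 else out
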