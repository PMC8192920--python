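"""Synthetic stented-vessel phantoms with known ground truth.

Replaces physical silicone models imaged by micro-CT: a parametric vessel
(straight, arc, or helix centerline; constant, tapered, or elliptic lumen)
receives a template stent wrapped geometrically at its deployment diameter,
and a virtual OCT pullback samples cross-sections at the frame distance —
strut points from wireframe/plane intersections with Gaussian segmentation
jitter, a guidewire-shadow sector with missing struts, per-frame catheter
rotation (drift) encoded by the orientation marker, and analytic lumen/stent
contours.

Deployment is purely geometric (struts lie on the local lumen wall, offset
inward by the configured gap inside malapposition zones); no mechanics are
modelled, which matches what the reconstruction itself assumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from typing import Optional

import networkx as nx
import numpy as np

from .core import Centerline, Contour2D, FrameField, rotate2
from .errors import InvalidSpecError
from .lumen import LumenSurface, OCTFrame
from .rollback import Wire3D, _densify_polyline, round_crowns
from .wireframe import StentTemplate, WireframeGraph, make_generic_template, template_graph


@dataclass
class PhantomSpec:
    """Complete description of a synthetic stented vessel and its pullback."""

    template: StentTemplate
    deploy_diameter: float = 3.0
    centerline_kind: str = "straight"  # straight | arc | helix
    arc_radius: float = 20.0
    helix_radius: float = 10.0
    helix_pitch: float = 20.0
    lumen_kind: str = "constant"  # constant | taper | elliptic
    lumen_radius: float = 1.5
    taper_ratio: float = 1.0  # end radius / start radius across the vessel
    ellipse_ratio: float = 1.0  # major/minor axis ratio (area-preserving)
    malapposition_zones: list = dc_field(default_factory=list)
    # each zone: {"x_range": [x0, x1], "azimuth_deg": [a0, a1], "gap_mm": g}
    frame_distance: float = 0.2
    margin: float = 2.0  # centerline extension beyond the stent, each side
    shadow_width_deg: float = 30.0
    shadow_start_deg: float = 120.0
    shadow_drift_deg_per_frame: float = 0.0
    marker_start_deg: float = 0.0
    marker_drift_deg_per_frame: float = 0.0
    jitter_sd: float = 0.03
    contour_samples: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.shadow_width_deg >= 180:
            raise InvalidSpecError("shadow sector must be < 180 deg")
        if self.jitter_sd < 0:
            raise InvalidSpecError("jitter sd must be >= 0")
        for z in self.malapposition_zones:
            if z["gap_mm"] < 0:
                raise InvalidSpecError("malapposition gap must be >= 0")

    def to_json(self, path=None):
        d = {k: v for k, v in self.__dict__.items() if k != "template"}
        d["template"] = self.template.to_json()
        if path is None:
            return d
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, source) -> "PhantomSpec":
        if not isinstance(source, dict):
            with open(source) as fh:
                source = json.load(fh)
        source = dict(source)
        source["template"] = StentTemplate.from_json(source["template"])
        return cls(**source)


@dataclass
class GroundTruth:
    """Everything the reconstruction is later compared against."""

    spec: PhantomSpec
    centerline: Centerline
    field: FrameField
    planar_graph: WireframeGraph  # sharp template pattern (topology reference)
    planar_rounded: Wire3D  # crown-rounded planar pattern actually deployed
    wire3d: Wire3D
    lumen: LumenSurface
    marker_angles: np.ndarray  # per frame, radians
    n_frames: int

    @property
    def stent_start(self) -> float:
        return self.spec.margin


# ---------------------------------------------------------------------------
# Geometry helpers


def _make_centerline(spec: PhantomSpec) -> Centerline:
    L = spec.template.nominal_length + 2 * spec.margin
    s = np.arange(0.0, L + 1e-9, 0.05)
    if spec.centerline_kind == "straight":
        pts = np.column_stack([np.zeros_like(s), np.zeros_like(s), s])
    elif spec.centerline_kind == "arc":
        R = spec.arc_radius
        ang = s / R
        pts = np.column_stack([R - R * np.cos(ang), np.zeros_like(s), R * np.sin(ang)])
    elif spec.centerline_kind == "helix":
        r, p = spec.helix_radius, spec.helix_pitch
        c = np.sqrt(r**2 + (p / (2 * np.pi)) ** 2)
        ang = s / c
        pts = np.column_stack(
            [r * np.cos(ang) - r, r * np.sin(ang), p * ang / (2 * np.pi)]
        )
    else:
        raise InvalidSpecError(f"unknown centerline kind {spec.centerline_kind!r}")
    return Centerline(pts)


def _base_radius(spec: PhantomSpec, s: float, total_length: float) -> float:
    r0 = spec.lumen_radius
    if spec.lumen_kind == "taper":
        w = s / total_length
        return r0 * (1 + (spec.taper_ratio - 1) * w)
    return r0


def lumen_radius(spec: PhantomSpec, s, theta, total_length: float):
    """Analytic lumen radius at station ``s`` and azimuth ``theta``."""
    r = _base_radius(spec, float(s), total_length)
    if spec.lumen_kind == "elliptic" and spec.ellipse_ratio != 1.0:
        q = np.sqrt(spec.ellipse_ratio)
        a, b = r * q, r / q
        theta = np.asarray(theta, dtype=float)
        return a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    return r if np.isscalar(theta) else np.full(np.shape(theta), r)


def _contour_param(spec: PhantomSpec, s: float, L_total: float, n: int = 2048):
    """Arc-length parameterization of the analytic lumen contour at ``s``.

    Returns ``(perimeter, theta_grid, cum_arclength)``; arc length is
    measured CCW from theta = 0 (the rotation-minimizing reference
    direction), matching the circumferential origin used by the unrolling.
    """
    th = np.linspace(0.0, 2 * np.pi, n + 1)
    r = lumen_radius(spec, s, th, L_total)
    pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
    cum = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    return float(cum[-1]), th, cum


def _zone_gap(spec: PhantomSpec, x: float, theta: float) -> float:
    th = np.mod(np.degrees(theta), 360.0)
    for z in spec.malapposition_zones:
        x0, x1 = z["x_range"]
        a0, a1 = np.mod(z["azimuth_deg"][0], 360.0), np.mod(z["azimuth_deg"][1], 360.0)
        in_sector = (a0 <= th <= a1) if a0 <= a1 else (th >= a0 or th <= a1)
        if x0 <= x <= x1 and in_sector:
            return float(z["gap_mm"])
    return 0.0


# ---------------------------------------------------------------------------
# Deployment


def deploy_stent(spec: PhantomSpec) -> GroundTruth:
    """Wrap the template wireframe onto the vessel at the deployment diameter.

    The planar pattern is mapped onto the wall preserving circumferential arc
    length (scaled uniformly to the local lumen perimeter), as a metal
    scaffold conforms to a non-circular lumen; struts sit on the wall, offset
    radially inward by the configured gap inside malapposition zones.
    """
    centerline = _make_centerline(spec)
    field = FrameField(centerline)
    L_total = centerline.total_length

    # feasibility: deployment within 0.8-1.2x the local lumen diameter
    for s_chk in (spec.margin, spec.margin + spec.template.nominal_length):
        d_local = 2 * _base_radius(spec, s_chk, L_total)
        ratio = spec.deploy_diameter / d_local
        if not (0.8 - 1e-9 <= ratio <= 1.2 + 1e-9):
            raise InvalidSpecError(
                f"deployment diameter {spec.deploy_diameter} is {ratio:.2f}x the "
                f"local lumen diameter {d_local:.2f} at s={s_chk}"
            )

    W = np.pi * spec.deploy_diameter
    planar = template_graph(spec.template, W, x0=0.0)

    # physical stents have rounded crowns: fillet the planar pattern (same
    # default radius the reconstruction uses, 1.5x the strut half-width)
    prof = spec.template.strut_profile
    half = prof["diameter"] / 2 if prof["shape"] == "circular" else prof["width"] / 2
    gflat = nx.Graph()
    for nid, dd in planar.g.nodes(data=True):
        gflat.add_node(nid, pos=np.array([dd["x"], dd["y"], 0.0]), role=dd["role"],
                       ring=dd["ring"], provenance="observed")
    for a, b, dd in planar.g.edges(data=True):
        p = np.asarray(dd["polyline"], dtype=float)
        gflat.add_edge(a, b, polyline=np.column_stack([p, np.zeros(len(p))]),
                       apex_idx=list(dd.get("apex_idx", [])), provenance="observed")
    rounded_flat = round_crowns(Wire3D(gflat), 1.5 * half, wrap_period=W)

    param_cache = {}

    def theta_of(s, y):
        key = round(s, 9)
        if key not in param_cache:
            param_cache[key] = _contour_param(spec, s, L_total)
        P, th, cum = param_cache[key]
        ell = np.mod(y, W) * P / W
        return float(np.interp(ell, cum, th))

    def to3d(x, y):
        s = spec.margin + x
        theta = theta_of(s, y)
        r = float(lumen_radius(spec, s, theta, L_total)) - _zone_gap(spec, x, theta)
        fr = field.frame_at(s)
        return fr.from_plane(r * np.cos(theta), r * np.sin(theta))

    g3 = nx.Graph()
    for nid, dd in rounded_flat.g.nodes(data=True):
        x, y = dd["pos"][0], dd["pos"][1]
        g3.add_node(nid, pos=np.asarray(to3d(x, y)), role=dd["role"],
                    ring=dd["ring"], provenance="observed")
    for a, b, dd in rounded_flat.g.edges(data=True):
        poly, apex_idx = _densify_polyline(
            np.asarray(dd["polyline"], dtype=float)[:, :2], dd.get("apex_idx", []), 0.05
        )
        pts = np.array([to3d(px, py) for px, py in poly])
        g3.add_edge(a, b, polyline=pts, apex_idx=apex_idx, provenance="observed")
    wire3d = Wire3D(g3)

    lumen = _analytic_lumen_surface(spec, field, L_total)

    n_frames = int(np.floor(L_total / spec.frame_distance)) + 1
    marker = np.radians(
        spec.marker_start_deg + spec.marker_drift_deg_per_frame * np.arange(n_frames)
    )
    return GroundTruth(
        spec=spec,
        centerline=centerline,
        field=field,
        planar_graph=planar,
        planar_rounded=rounded_flat,
        wire3d=wire3d,
        lumen=lumen,
        marker_angles=marker,
        n_frames=n_frames,
    )


def _analytic_lumen_surface(spec, field, L_total, ds=0.2, m=100) -> LumenSurface:
    import trimesh

    stations = np.arange(0.0, L_total + 1e-9, ds)
    theta = 2 * np.pi * np.arange(m) / m
    rings = []
    for s in stations:
        r = lumen_radius(spec, s, theta, L_total)
        fr = field.frame_at(float(s))
        uv = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        rings.append(fr.from_plane_many(uv))
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
    mesh = trimesh.Trimesh(vertices=verts, faces=np.vstack(faces), process=False)
    return LumenSurface(mesh=mesh, rings=rings, stations=stations)


# ---------------------------------------------------------------------------
# Virtual pullback


def _planar_plane_hits(planar, xc: float):
    """Intersections of the planar truth wireframe with the line x = xc.

    Returns arrays (y, ) of crossing circumferential coordinates.
    """
    ys = []
    for _, _, dd in planar.g.edges(data=True):
        poly = np.asarray(dd["polyline"], dtype=float)[:, :2]
        x0, x1 = poly[:-1, 0], poly[1:, 0]
        y0, y1 = poly[:-1, 1], poly[1:, 1]
        mask = ((x0 - xc) * (x1 - xc) <= 0) & (np.abs(x0 - x1) > 1e-12)
        if mask.any():
            t = (xc - x0[mask]) / (x1[mask] - x0[mask])
            ys.extend((y0[mask] + t * (y1[mask] - y0[mask])).tolist())
        # axial segments lying exactly on the cutting plane: take midpoints
        on = (np.abs(x0 - xc) <= 1e-12) & (np.abs(x1 - xc) <= 1e-12)
        if on.any():
            ys.extend((0.5 * (y0[on] + y1[on])).tolist())
    if not ys:
        return np.zeros(0)
    ys = np.sort(np.asarray(ys, dtype=float))
    # merge near-duplicate crossings (apex exactly on the plane)
    keep = np.concatenate([[True], np.diff(ys) > 1e-6])
    return ys[keep]


def _smooth_radial_noise(rng, theta, sd, n_harmonics: int = 6):
    """Smooth periodic radial perturbation with pointwise standard deviation
    ``sd`` — low-order Fourier noise emulating operator tracing error, which
    is correlated along the contour (i.i.d. vertex noise would produce
    self-intersecting polygons)."""
    if sd == 0:
        return np.zeros_like(theta)
    sc = sd / np.sqrt(n_harmonics + 1)
    out = rng.normal(0, sc) * np.ones_like(theta)
    for k in range(1, n_harmonics + 1):
        out = out + rng.normal(0, sc) * np.cos(k * theta) + rng.normal(0, sc) * np.sin(
            k * theta
        )
    return out


def simulate_pullback(truth: GroundTruth, spec: Optional[PhantomSpec] = None):
    """Sample the phantom as an OCT pullback; returns a list of frames.

    Frames are cut every ``frame_distance`` along the centerline.  Strut
    points are wireframe/plane intersections projected into catheter (image)
    coordinates — rotated by the per-frame marker angle, jittered
    (i.i.d. Gaussian), and censored inside the guidewire-shadow sector.
    Lumen and stent contours are sampled analytically with smooth correlated
    radial noise of the same amplitude.
    """
    spec = spec or truth.spec
    rng = np.random.default_rng(spec.seed)
    L_total = truth.centerline.total_length
    W = np.pi * spec.deploy_diameter
    theta_c = 2 * np.pi * np.arange(spec.contour_samples) / spec.contour_samples
    frames = []
    x_lo, x_hi = 0.0, spec.template.nominal_length
    for k in range(truth.n_frames):
        s_k = k * spec.frame_distance
        if s_k > L_total + 1e-9:
            break
        m_k = float(truth.marker_angles[k])
        r_c = lumen_radius(spec, s_k, theta_c, L_total)
        r_noisy = r_c + _smooth_radial_noise(rng, theta_c, spec.jitter_sd)
        lumen_img = rotate2(
            np.column_stack([r_noisy * np.cos(theta_c), r_noisy * np.sin(theta_c)]), m_k
        )
        xc = s_k - spec.margin
        stent_contour = None
        struts = np.zeros((0, 2))
        if x_lo - 1e-9 <= xc <= x_hi + 1e-9:
            r_s = r_c + _smooth_radial_noise(rng, theta_c, spec.jitter_sd)
            stent_img = rotate2(
                np.column_stack([r_s * np.cos(theta_c), r_s * np.sin(theta_c)]), m_k
            )
            stent_contour = Contour2D(stent_img)
            ys = _planar_plane_hits(truth.planar_rounded, xc)
            P, th_grid, cum = _contour_param(spec, s_k, L_total)
            pts = []
            for y in ys:
                theta = float(np.interp(np.mod(y, W) * P / W, cum, th_grid))
                r = float(lumen_radius(spec, s_k, theta, L_total)) - _zone_gap(
                    spec, xc, theta
                )
                pts.append([r * np.cos(theta), r * np.sin(theta)])
            if pts:
                img = rotate2(np.asarray(pts), m_k) + rng.normal(
                    0, spec.jitter_sd, (len(pts), 2)
                )
                # guidewire shadow: censored sector in image coordinates
                ang = np.mod(
                    np.degrees(np.arctan2(img[:, 1], img[:, 0])), 360.0
                )
                a0 = np.mod(
                    spec.shadow_start_deg + spec.shadow_drift_deg_per_frame * k, 360.0
                )
                a1 = np.mod(a0 + spec.shadow_width_deg, 360.0)
                in_shadow = (
                    (ang >= a0) & (ang <= a1) if a0 <= a1 else (ang >= a0) | (ang <= a1)
                )
                struts = img[~in_shadow]
        frames.append(
            OCTFrame(
                index=k,
                station=s_k,
                lumen_contour=Contour2D(lumen_img),
                stent_contour=stent_contour,
                strut_points=struts,
                marker_angle=m_k,
            )
        )
    return frames


def validation_suite(seed: int = 0) -> list:
    """The six-phantom validation suite used for accuracy studies.

    Deployment diameters span 2.5-4.0 mm with 16/18 mm templates and the
    two pullback frame distances (0.1 and 0.2 mm); lumens include elliptic
    cross-sections up to ratio 1.5.  All phantoms use 0.03 mm segmentation
    jitter and a 30 deg guidewire shadow.  Each phantom gets a distinct
    sub-seed derived from ``seed``.
    """
    base = dict(jitter_sd=0.03, shadow_width_deg=30.0)
    defs = [
        dict(deploy_diameter=3.5, rings=10, crowns=8, length=18.0, fd=0.1,
             ell=1.0, marker_drift=0.2, shadow_start=90.0),
        dict(deploy_diameter=3.0, rings=9, crowns=8, length=16.0, fd=0.1,
             ell=1.2, marker_drift=0.0, shadow_start=200.0),
        dict(deploy_diameter=2.5, rings=9, crowns=6, length=16.0, fd=0.2,
             ell=1.0, marker_drift=0.5, shadow_start=45.0),
        dict(deploy_diameter=4.0, rings=10, crowns=10, length=18.0, fd=0.1,
             ell=1.0, marker_drift=0.0, shadow_start=300.0),
        dict(deploy_diameter=3.0, rings=9, crowns=8, length=16.0, fd=0.1,
             ell=1.5, marker_drift=0.1, shadow_start=10.0),
        dict(deploy_diameter=3.25, rings=9, crowns=8, length=16.0, fd=0.2,
             ell=1.3, marker_drift=0.3, shadow_start=150.0),
    ]
    specs = []
    for i, d in enumerate(defs):
        tpl = make_generic_template(
            rings=d["rings"], crowns_per_ring=d["crowns"],
            nominal_diameter=d["deploy_diameter"], nominal_length=d["length"],
        )
        specs.append(
            PhantomSpec(
                template=tpl,
                deploy_diameter=d["deploy_diameter"],
                lumen_radius=d["deploy_diameter"] / 2.0,
                lumen_kind="elliptic" if d["ell"] > 1.0 else "constant",
                ellipse_ratio=d["ell"],
                frame_distance=d["fd"],
                marker_drift_deg_per_frame=d["marker_drift"],
                shadow_start_deg=d["shadow_start"],
                shadow_drift_deg_per_frame=0.2,
                seed=(seed * 1000 + i) % (2**31 - 1),
                **base,
            )
        )
    return specs


def default_phantom_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """A representative phantom: 3.0 mm stent, 9 rings x 8 crowns, 30 deg
    shadow, 0.03 mm segmentation jitter."""
    kwargs = dict(
        template=make_generic_template(nominal_diameter=3.0),
        deploy_diameter=3.0,
        lumen_radius=1.5,
        seed=seed,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)
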