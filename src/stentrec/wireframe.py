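"""Planar stent wireframe reconstruction from unrolled strut points.

The unrolled strut cloud is turned into a node/edge graph following the four
connection rules of the method: (1) straight line fragments connect
consecutive peaks and valleys within each zig-zag ring; (2) link locations
between rings follow the stent's planar CAD template numbering; (3) gaps left
by the guidewire shadow are bridged at the template's expected crown phase;
(4) the pattern is continued across the circumferential seam.

A linked crown pair (peak of one ring joined to the facing valley of the
next) is represented by a single degree-4 junction node at the link midpoint;
the two crown apexes become interior vertices of the incident edge polylines.
Unlinked crown apexes are degree-2 nodes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np

from .errors import (
    CannotBridgeError,
    EditError,
    InsufficientInputError,
    InvalidInputError,
    TemplateMismatchWarning,
)
from .unroll import PlanarPointSet

DEFAULT_CONFIG = {
    "clustering_radius": 0.15,  # mm; observed-node-to-point match radius
    "prominence_frac": 0.25,  # min apex prominence as fraction of crown height
    "level_tol_frac": 0.35,  # max apex deviation from ring peak/valley level
    "perimeter_norm_threshold": 0.10,  # switch to normalized azimuth above this
    "fit_inner_frac": 0.1,  # leg-fit window, inner bound (fraction of dy)
    "fit_outer_frac": 0.85,  # leg-fit window, outer bound (fraction of dy)
    "arc_band_frac": 0.12,  # crown-arc exclusion band (fraction of crown height)
}


# ---------------------------------------------------------------------------
# Template


@dataclass
class StentTemplate:
    """Planar CAD pattern of a zig-zag-and-link stent.

    ``rings`` zig-zag hoops of ``crowns_per_ring`` peaks (and as many
    valleys) are joined by ``links_per_ring_pair`` short axial connectors;
    ``link_phase`` rotates the linked crown slots by that many crowns per
    successive ring pair.  ``ring_gap_mm`` is the axial link length between
    facing crowns.
    """

    name: str
    rings: int
    crowns_per_ring: int
    links_per_ring_pair: int
    link_phase: int
    strut_profile: dict
    nominal_diameter: float
    nominal_length: float
    ring_gap_mm: float = 0.3

    def __post_init__(self):
        if self.rings < 1:
            raise InvalidInputError("template needs >= 1 ring")
        if self.crowns_per_ring < 3:
            raise InvalidInputError("crowns_per_ring must be >= 3")
        if not (1 <= self.links_per_ring_pair <= self.crowns_per_ring):
            raise InvalidInputError("links_per_ring_pair must be in [1, crowns_per_ring]")
        shape = self.strut_profile.get("shape")
        if shape not in ("circular", "rectangular"):
            raise InvalidInputError(f"unknown strut profile shape {shape!r}")

    @property
    def crown_height(self) -> float:
        """Axial height of one ring."""
        return (self.nominal_length - (self.rings - 1) * self.ring_gap_mm) / self.rings

    @property
    def ring_pitch(self) -> float:
        return self.crown_height + self.ring_gap_mm

    def link_slots(self, pair: int) -> list:
        """Crown numbers (0-based, ascending from the seam) carrying links
        between rings ``pair`` and ``pair + 1``."""
        C, L = self.crowns_per_ring, self.links_per_ring_pair
        return sorted(
            {(pair * self.link_phase + int(round(k * C / L))) % C for k in range(L)}
        )

    def to_json(self, path=None):
        d = {
            "name": self.name,
            "rings": self.rings,
            "crowns_per_ring": self.crowns_per_ring,
            "links_per_ring_pair": self.links_per_ring_pair,
            "link_phase": self.link_phase,
            "strut_profile": self.strut_profile,
            "nominal_diameter": self.nominal_diameter,
            "nominal_length": self.nominal_length,
            "ring_gap_mm": self.ring_gap_mm,
        }
        if path is None:
            return d
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, source) -> "StentTemplate":
        if isinstance(source, dict):
            return cls(**source)
        with open(source) as fh:
            return cls(**json.load(fh))


def make_generic_template(
    rings: int = 9,
    crowns_per_ring: int = 8,
    links_per_ring_pair: int = 3,
    link_phase: int = 1,
    nominal_diameter: float = 3.0,
    nominal_length: float = 16.0,
    profile_shape: str = "circular",
    profile_dims=(0.081,),
    ring_gap_mm: float = 0.3,
    name: Optional[str] = None,
) -> StentTemplate:
    """Generic open-cell zig-zag-and-link template (2..10 rings)."""
    if profile_shape == "circular":
        profile = {"shape": "circular", "diameter": float(profile_dims[0])}
    else:
        profile = {
            "shape": "rectangular",
            "width": float(profile_dims[0]),
            "thickness": float(profile_dims[1]),
        }
    return StentTemplate(
        name=name or f"generic-{rings}x{crowns_per_ring}",
        rings=rings,
        crowns_per_ring=crowns_per_ring,
        links_per_ring_pair=links_per_ring_pair,
        link_phase=link_phase,
        strut_profile=profile,
        nominal_diameter=nominal_diameter,
        nominal_length=nominal_length,
        ring_gap_mm=ring_gap_mm,
    )


# ---------------------------------------------------------------------------
# Graph


class WireframeGraph:
    """Planar stent wireframe: nodes with roles, edges with polyline geometry.

    Node attributes: ``x``, ``y`` (mm, y canonical in [0, wrap_period)),
    ``role`` (peak | valley | link-junction), ``ring``, ``provenance``
    (observed | bridged).  Edge attribute ``polyline`` is an (M, 2) array;
    ``apex_idx`` lists interior polyline vertices that are crown corners
    (used for crown rounding after rollback).  Edge polylines may leave the
    canonical y band to stay continuous across the seam.
    """

    def __init__(self, wrap_period: float, y_mode: str = "arclength"):
        self.g = nx.Graph()
        self.wrap_period = float(wrap_period)
        self.y_mode = y_mode  # arclength | normalized (y scaled to mean perimeter)

    # -- construction -------------------------------------------------------

    def add_node(self, nid, x, y, role, ring, provenance="observed"):
        self.g.add_node(
            nid,
            x=float(x),
            y=float(np.mod(y, self.wrap_period)),
            role=role,
            ring=int(ring),
            provenance=provenance,
        )

    def add_edge(self, a, b, polyline, apex_idx=()):
        self.g.add_edge(a, b, polyline=np.asarray(polyline, dtype=float), apex_idx=list(apex_idx))

    def node_pos(self, nid):
        d = self.g.nodes[nid]
        return np.array([d["x"], d["y"]])

    # -- queries -------------------------------------------------------------

    def crown_count(self, ring: int) -> int:
        """Crown apexes of a ring, counting apexes absorbed into junctions."""
        n_apex = sum(
            1
            for _, d in self.g.nodes(data=True)
            if d["ring"] == ring and d["role"] in ("peak", "valley")
        )
        n_junc = sum(
            1
            for _, d in self.g.nodes(data=True)
            if d["role"] == "link-junction" and d["ring"] in (ring, ring - 1) and
            self._junction_touches(d, ring)
        )
        return n_apex + n_junc

    @staticmethod
    def _junction_touches(d, ring):
        # a junction between rings (r, r+1) carries one absorbed apex of each
        return d["ring"] == ring or d["ring"] == ring - 1

    def link_count(self, pair: int) -> int:
        return sum(
            1 for _, d in self.g.nodes(data=True) if d["role"] == "link-junction" and d["ring"] == pair
        )

    def validate(self, strict: bool = True):
        problems = []
        for n, d in self.g.nodes(data=True):
            deg = self.g.degree[n]
            if d["role"] == "link-junction" and deg != 4:
                problems.append(f"junction {n} has degree {deg} != 4")
            if d["role"] in ("peak", "valley") and deg != 2:
                problems.append(f"apex {n} has degree {deg} != 2")
        if self.g.number_of_nodes() and not nx.is_connected(self.g):
            problems.append("graph is not connected")
        if strict and problems:
            raise EditError("; ".join(problems))
        return problems

    def is_isomorphic_to(self, other: "WireframeGraph") -> bool:
        return nx.is_isomorphic(self.g, other.g)

    # -- serialization -------------------------------------------------------

    def to_json(self, path=None):
        d = {
            "wrap_period": self.wrap_period,
            "y_mode": self.y_mode,
            "nodes": [
                {"id": str(n), **{k: (float(v) if isinstance(v, (int, float, np.floating)) and k in ("x", "y") else v) for k, v in dd.items()}}
                for n, dd in self.g.nodes(data=True)
            ],
            "edges": [
                {
                    "a": str(a),
                    "b": str(b),
                    "polyline": np.asarray(dd["polyline"]).tolist(),
                    "apex_idx": list(dd.get("apex_idx", [])),
                }
                for a, b, dd in self.g.edges(data=True)
            ],
        }
        if path is None:
            return d
        with open(path, "w") as fh:
            json.dump(d, fh)

    @classmethod
    def from_json(cls, source) -> "WireframeGraph":
        if not isinstance(source, dict):
            with open(source) as fh:
                source = json.load(fh)
        wf = cls(source["wrap_period"], source.get("y_mode", "arclength"))
        for nd in source["nodes"]:
            nd = dict(nd)
            nid = nd.pop("id")
            wf.g.add_node(nid, **nd)
        for ed in source["edges"]:
            wf.add_edge(ed["a"], ed["b"], np.asarray(ed["polyline"]), ed.get("apex_idx", []))
        return wf


def template_graph(template: StentTemplate, wrap_period: float, x0: float = 0.0) -> WireframeGraph:
    """Exact planar wireframe of a template at a given circumference."""
    C, R = template.crowns_per_ring, template.rings
    h, g = template.crown_height, template.ring_gap_mm
    W = float(wrap_period)
    dy = W / (2 * C)

    wf = WireframeGraph(W)
    apex_pos = {}  # (ring, j) -> (x, y)
    linked = {}  # (ring, j) -> junction id
    for i in range(R):
        for j in range(2 * C):
            apex_pos[(i, j)] = (x0 + i * (h + g) + h * ((i + j) % 2), j * dy)

    junctions = {}
    for pair in range(R - 1):
        p_parity = (pair + 1) % 2
        for m in template.link_slots(pair):
            j1 = 2 * m + p_parity
            jid = f"J_{pair}_{m}"
            xj = x0 + pair * (h + g) + h + g / 2.0
            yj = j1 * dy
            wf.add_node(jid, xj, yj, "link-junction", pair)
            junctions[jid] = (xj, yj)
            linked[(pair, j1)] = jid
            linked[(pair + 1, j1)] = jid

    def node_for(i, j):
        if (i, j) in linked:
            return linked[(i, j)], True
        return f"a_{i}_{j}", False

    for i in range(R):
        for j in range(2 * C):
            nid, is_j = node_for(i, j)
            if not is_j:
                x, y = apex_pos[(i, j)]
                role = "peak" if ((i + j) % 2 == 1) else "valley"
                # "peak" = distal-facing crown (higher x within the ring)
                if nid not in wf.g:
                    wf.add_node(nid, x, y, role, i)

    for i in range(R):
        for j in range(2 * C):
            j2 = (j + 1) % (2 * C)
            a_id, a_link = node_for(i, j)
            b_id, b_link = node_for(i, j2)
            xa, ya = apex_pos[(i, j)]
            xb, yb = apex_pos[(i, j2)]
            if j2 == 0:  # seam-crossing leg: continue past the period
                yb = 2 * C * dy
            poly = [[xa, ya]]
            apex_idx = []
            if a_link:
                jid = a_id
                xj, yj = junctions[jid]
                yj_cont = ya  # same y slot as apex a
                poly = [[xj, yj_cont], [xa, ya]]
                apex_idx = [1]
            poly.append([xb, yb])
            if b_link:
                jid = b_id
                xj, _ = junctions[jid]
                poly.append([xj, yb])
                apex_idx = apex_idx + [len(poly) - 2]
            wf.add_edge(a_id, b_id, np.asarray(poly, dtype=float), apex_idx)
    return wf


# ---------------------------------------------------------------------------
# Builder


def _circ_mean(values: np.ndarray, period: float) -> float:
    ang = 2 * np.pi * np.asarray(values) / period
    m = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
    return float(np.mod(m * period / (2 * np.pi), period))


def _circ_dist(a, b, period):
    d = np.mod(a - b, period)
    return np.minimum(d, period - d)


def _signed_circ_diff_vec(b, a, period):
    """Vectorized signed circular difference b - a in (-period/2, period/2]."""
    d = np.mod(np.asarray(b) - a, period)
    return np.where(d > period / 2, d - period, d)


def cluster_rows(planar: PlanarPointSet, template: StentTemplate):
    """Partition strut points into rings by 1-D clustering on x.

    Ring centers follow the template pitch scaled to the observed axial
    extent; each point joins the nearest center.  Returns ``(assignments,
    struts_df)`` where ``assignments`` is a list of index arrays (ring order,
    distal first) into ``struts_df``.
    """
    df = planar.struts(include_wrap=False).reset_index(drop=True)
    if len(df) == 0:
        raise InsufficientInputError("no strut points to cluster")
    if len(df) < 2 * template.crowns_per_ring:
        raise InsufficientInputError(
            f"{len(df)} strut points < 2x crowns_per_ring = {2 * template.crowns_per_ring}"
        )
    x = df.x_mm.to_numpy()
    R = template.rings
    span = x.max() - x.min()
    scale = span / template.nominal_length if template.nominal_length > 0 else 1.0
    if scale == 0:
        scale = 1.0
    centers = x.min() + (
        np.arange(R) * template.ring_pitch + template.crown_height / 2.0
    ) * scale
    lab = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
    groups = [np.flatnonzero(lab == i) for i in range(R)]
    detected = sum(1 for g in groups if len(g) > 0)
    if abs(detected - R) > 1:
        warnings.warn(
            f"detected {detected} rings, template has {R}", TemplateMismatchWarning
        )
    return groups, df


def _detect_ring_apexes(xs, ys, W, C, config):
    """Detect and bridge the 2C apex slots of one ring.

    The zig-zag phase is estimated by a grid search fitting a triangle wave
    (robust to link points sitting in the inter-ring gaps and to the x
    quantization at frame stations); each crown corner is then solved from
    its two adjacent legs with the ring's common leg slope held fixed.
    Unobserved slots (wire shadow) are synthesized at the template phase and
    marked bridged.  Returns ``(apexes, delta)`` where 'peak' is the
    higher-x crown level of the ring.
    """
    dy = W / (2 * C)
    order = np.argsort(ys)
    xs, ys = xs[order], ys[order]
    lo, hi = np.percentile(xs, 5), np.percentile(xs, 95)
    height = max(hi - lo, 1e-9)

    # 1. phase: triangle wave with a peak at rel-y = 0 (mod 2*dy)
    deltas = np.arange(0.0, 2 * dy, 2 * dy / 160)
    rel = np.mod(ys[None, :] - deltas[:, None], 2 * dy)
    frac = rel / dy
    model = hi - height * np.minimum(frac, 2.0 - frac)
    cost = np.abs(xs[None, :] - model).sum(axis=1)
    delta = float(deltas[int(np.argmin(cost))])

    level_tol = config["level_tol_frac"] * height

    f_in = config.get("fit_inner_frac", 0.1)
    f_out = config.get("fit_outer_frac", 0.85)
    arc_band = config.get("arc_band_frac", 0.12) * height

    # common |leg slope| of the ring: every leg of the template zig-zag has
    # the same |dy/dx|, so the median over per-leg fits is a low-noise shared
    # estimate.  Regressions are y-on-x throughout: x (the pullback station)
    # is exact while y carries the segmentation jitter, so x-on-y fits would
    # attenuate the slope and bias every corner inward.
    mid_band = (xs > lo + 0.2 * height) & (xs < hi - 0.2 * height)
    rel_all = np.mod(ys - delta, 2 * C * dy)
    leg_id = np.floor(rel_all / dy).astype(int) % (2 * C)
    slopes = []
    for leg in range(2 * C):
        m = mid_band & (leg_id == leg)
        if m.sum() >= 3 and xs[m].max() - xs[m].min() > 1e-9:
            A = np.vstack([xs[m], np.ones(m.sum())]).T
            coef, *_ = np.linalg.lstsq(A, rel_all[m], rcond=None)
            if abs(coef[0]) > 1e-6:
                slopes.append(abs(coef[0]))
    c_leg = float(np.median(slopes)) if slopes else dy / height

    def _refine_corner(dloc, kk):
        """Corner (x, y-offset) with the ring slope held fixed.

        Model: dloc_i = s_i * c * (x_i - xc) + eta with flank sign s_i = +-1;
        solving for (xc, eta) pools both flanks; a one-sided solution (wire
        shadow over one flank) assumes eta = 0.
        """
        m = (
            (np.abs(dloc) > f_in * dy)
            & (np.abs(dloc) < f_out * dy)
            & (xs > lo + arc_band)
            & (xs < hi - arc_band)
        )
        if m.sum() < 3:
            return None
        d, xv = dloc[m], xs[m]
        sgn = -np.sign(d) if kk == "peak" else np.sign(d)
        xc = eta = None
        for _ in range(2):  # one robust re-fit pass
            if (sgn > 0).any() and (sgn < 0).any():
                A = np.column_stack([-sgn * c_leg, np.ones(len(d))])
                b = d - sgn * c_leg * xv
                (xc, eta), *_ = np.linalg.lstsq(A, b, rcond=None)
            else:
                xc = float(np.mean(xv - d / (sgn * c_leg)))
                eta = 0.0
            res = np.abs(d - (sgn * c_leg * (xv - xc) + eta))
            keep = res <= max(0.08, 3 * np.median(res) + 1e-9)
            if keep.all() or keep.sum() < 3:
                break
            d, xv, sgn = d[keep], xv[keep], sgn[keep]
        return float(xc), float(eta)

    apexes = []
    n_observed = 0
    for j in range(2 * C):
        kk = "peak" if j % 2 == 0 else "valley"
        level = hi if kk == "peak" else lo
        slot_y = np.mod(delta + j * dy, W)
        dloc = _signed_circ_diff_vec(ys, slot_y, W)
        near = (np.abs(dloc) <= 0.45 * dy) & (np.abs(xs - level) <= level_tol)
        if near.any():
            # observed: best point near the apex, refined from the leg fits
            cand = np.flatnonzero(near)
            best = cand[np.argmax(xs[cand]) if kk == "peak" else np.argmin(xs[cand])]
            yy, xx = ys[best], xs[best]
            res = _refine_corner(dloc, kk)
            if res is not None:
                x_ref, eta = res
                # accept only plausible corners: near the slot and not
                # extrapolated far beyond the ring's crown levels
                if abs(eta) < 0.5 * dy and (lo - 0.3 * height) <= x_ref <= (
                    hi + 0.3 * height
                ):
                    yy = np.mod(slot_y + eta, W)
                    xx = x_ref
            apexes.append(
                {"slot": j, "x": float(xx), "y": float(np.mod(yy, W)), "kind": kk,
                 "provenance": "observed"}
            )
            n_observed += 1
        else:
            apexes.append(
                {"slot": j, "x": float(level), "y": float(slot_y),
                 "kind": kk, "provenance": "bridged"}
            )
    if n_observed == 0:
        raise InsufficientInputError("no apex observed in ring")
    # bridged crowns sit at the ring's consensus crown level (median of the
    # observed refined apexes of the same kind), per the template pattern
    for kk in ("peak", "valley"):
        obs = [a["x"] for a in apexes if a["kind"] == kk and a["provenance"] == "observed"]
        if obs:
            level = float(np.median(obs))
            for a in apexes:
                if a["kind"] == kk and a["provenance"] == "bridged":
                    a["x"] = level
    return apexes, delta


def build_wireframe(
    planar: PlanarPointSet,
    template: Optional[StentTemplate],
    config: Optional[dict] = None,
) -> WireframeGraph:
    """Reconstruct the planar wireframe graph from unrolled strut points."""
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    if template is None:
        _check_bridgeable_without_template(planar)
        raise CannotBridgeError("wireframe reconstruction requires a template")

    groups, df = cluster_rows(planar, template)
    perims = np.array([planar.wrap_period[int(fi)] for fi in df.frame_index])
    Wm = float(np.mean(list(planar.wrap_period.values())))
    variation = (max(planar.wrap_period.values()) - min(planar.wrap_period.values())) / Wm
    if variation > cfg["perimeter_norm_threshold"]:
        y_work = (df.y_mm.to_numpy() / perims) * Wm
        y_mode = "normalized"
    else:
        y_work = df.y_mm.to_numpy()
        y_mode = "arclength"
    x_all = df.x_mm.to_numpy()

    C, R = template.crowns_per_ring, template.rings
    ring_apexes = []
    for i, grp in enumerate(groups):
        if len(grp) < 4:
            warnings.warn(f"ring {i}: only {len(grp)} points; ring bridged from template",
                          TemplateMismatchWarning)
            ring_apexes.append(None)
            continue
        apexes, _ = _detect_ring_apexes(x_all[grp], np.mod(y_work[grp], Wm), Wm, C, cfg)
        ring_apexes.append(apexes)

    # rings with no data: synthesize from neighbours / template spacing
    for i, ap in enumerate(ring_apexes):
        if ap is None:
            ref = next((a for a in ring_apexes if a is not None), None)
            if ref is None:
                raise InsufficientInputError("no ring has enough points")
            shift = (i - ring_apexes.index(ref)) * template.ring_pitch
            ring_apexes[i] = [
                {**a, "x": a["x"] + shift, "provenance": "bridged"} for a in ref
            ]

    # struts are only observable at frame stations: clamp apex positions to
    # the sampled axial extent plus a margin covering the crown-arc depth
    # and one frame spacing (the rollback map clamps the same overhang)
    x_lo_c, x_hi_c = x_all.min() - 0.3, x_all.max() + 0.3
    for apx in ring_apexes:
        for a in apx:
            a["x"] = float(np.clip(a["x"], x_lo_c, x_hi_c))

    # crown numbering on a common circumferential anchor: ring i's peaks sit
    # at (2m + (i+1) mod 2) * dy from the pattern origin, i.e. peak phases
    # alternate by one slot between consecutive rings.  Pooling a parity-
    # corrected anchor across rings and rounding each peak onto the 2*dy
    # grid keeps crown numbers consistent between rings — a per-ring
    # "sort by y" would rotate the numbering whenever an apex sits within
    # noise of the y = 0 seam, mispairing the links
    dy = Wm / (2 * C)
    phis = []
    for i, apx in enumerate(ring_apexes):
        pys = [a["y"] for a in apx if a["kind"] == "peak" and a["provenance"] == "observed"]
        if not pys:
            pys = [a["y"] for a in apx if a["kind"] == "peak"]
        phi = _circ_mean(np.mod(np.asarray(pys), 2 * dy), 2 * dy)
        phis.append(np.mod(phi - ((i + 1) % 2) * dy, 2 * dy))
    anchor = _circ_mean(np.asarray(phis), 2 * dy)
    for i, apx in enumerate(ring_apexes):
        off = anchor + ((i + 1) % 2) * dy
        for a in apx:
            if a["kind"] == "peak":
                a["pnum"] = int(np.round(np.mod(a["y"] - off, Wm) / (2 * dy))) % C

    # the global rotation of the crown numbering relative to the template's
    # link chart is unobservable from the zig-zag rows alone; the observed
    # strut points inside the inter-ring gaps (link crossings) fix it
    rotation = _link_rotation_from_gaps(ring_apexes, template, x_all, y_work, Wm)

    wf = WireframeGraph(Wm, y_mode)

    # ring i's peak (high-x) crowns face ring i+1's valley (low-x) crowns
    linked = {}
    junctions = {}
    for pair in range(R - 1):
        apx_a = ring_apexes[pair]
        apx_b = ring_apexes[pair + 1]
        peaks_by_num = {a["pnum"]: a for a in apx_a if a["kind"] == "peak"}
        valleys_b = [a for a in apx_b if a["kind"] == "valley"]
        for m in template.link_slots(pair):
            pk = peaks_by_num.get((m + rotation) % template.crowns_per_ring)
            if pk is None:
                warnings.warn(f"pair {pair}: no peak numbered {m} detected",
                              TemplateMismatchWarning)
                continue
            # facing valley of the next ring: nearest in circular y
            dists = [_circ_dist(v["y"], pk["y"], Wm) for v in valleys_b]
            vi = int(np.argmin(dists))
            vl = valleys_b[vi]
            if dists[vi] > Wm / (2 * C):
                warnings.warn(
                    f"pair {pair} link {m}: facing valley {dists[vi]:.2f} mm off",
                    TemplateMismatchWarning,
                )
            jid = f"J_{pair}_{m}"
            xj = 0.5 * (pk["x"] + vl["x"])
            yj = np.mod(pk["y"] + 0.5 * _signed_circ_diff(vl["y"], pk["y"], Wm), Wm)
            prov = "observed" if (pk["provenance"] == "observed" and vl["provenance"] == "observed") else "bridged"
            wf.add_node(jid, xj, yj, "link-junction", pair, prov)
            junctions[jid] = (xj, yj)
            linked[(pair, pk["slot"])] = jid
            linked[(pair + 1, vl["slot"])] = jid

    def node_for(i, j):
        if (i, j) in linked:
            return linked[(i, j)], True
        return f"a_{i}_{j}", False

    for i in range(R):
        for a in ring_apexes[i]:
            nid, is_j = node_for(i, a["slot"])
            if not is_j and nid not in wf.g:
                wf.add_node(nid, a["x"], a["y"], a["kind"], i, a["provenance"])

    for i in range(R):
        apx = sorted(ring_apexes[i], key=lambda a: a["slot"])
        n_ap = len(apx)
        for k in range(n_ap):
            a, b = apx[k], apx[(k + 1) % n_ap]
            a_id, a_link = node_for(i, a["slot"])
            b_id, b_link = node_for(i, b["slot"])
            ya = a["y"]
            yb = ya + _signed_circ_diff(b["y"], ya, Wm)
            poly = []
            apex_idx = []
            if a_link:
                xj, yj = junctions[a_id]
                poly.append([xj, ya + _signed_circ_diff(yj, ya, Wm)])
                poly.append([a["x"], ya])
                apex_idx.append(1)
            else:
                poly.append([a["x"], ya])
            poly.append([b["x"], yb])
            if b_link:
                xj, yj = junctions[b_id]
                apex_idx.append(len(poly) - 1)
                poly.append([xj, yb + _signed_circ_diff(yj, yb, Wm)])
            wf.add_edge(a_id, b_id, np.asarray(poly), apex_idx)
    return wf


def _link_rotation_from_gaps(ring_apexes, template, x_all, y_all, W):
    """Crown-numbering rotation that best explains the observed link points.

    Strut points falling between a ring's peak level and the next ring's
    valley level can only belong to links; the rotation (0..C-1) whose
    predicted link positions are circularly closest to those points aligns
    the template's link chart with the data.
    """
    C, R = template.crowns_per_ring, template.rings
    pair_pts = []
    for pair in range(R - 1):
        pk_lvl = np.median([a["x"] for a in ring_apexes[pair] if a["kind"] == "peak"])
        vl_lvl = np.median(
            [a["x"] for a in ring_apexes[pair + 1] if a["kind"] == "valley"]
        )
        if vl_lvl - pk_lvl < 0.08:
            pair_pts.append(None)
            continue
        m = (x_all > pk_lvl + 0.02) & (x_all < vl_lvl - 0.02)
        pair_pts.append(np.mod(y_all[m], W))
    if all(p is None or len(p) == 0 for p in pair_pts):
        return 0
    best_r, best_cost = 0, np.inf
    for r in range(C):
        cost, n = 0.0, 0
        for pair in range(R - 1):
            pts = pair_pts[pair]
            if pts is None or len(pts) == 0:
                continue
            peaks_by_num = {
                a["pnum"]: a for a in ring_apexes[pair] if a["kind"] == "peak"
            }
            ys = [
                peaks_by_num[(m + r) % C]["y"]
                for m in template.link_slots(pair)
                if (m + r) % C in peaks_by_num
            ]
            if not ys:
                continue
            d = np.min(_circ_dist(pts[:, None], np.asarray(ys)[None, :], W), axis=1)
            cost += float(d.sum())
            n += len(d)
        if n and cost < best_cost:
            best_cost, best_r = cost, r
    return best_r


def _signed_circ_diff(b, a, period):
    """Signed circular difference b - a wrapped to (-period/2, period/2]."""
    d = np.mod(b - a, period)
    if d > period / 2:
        d -= period
    return d


def _check_bridgeable_without_template(planar: PlanarPointSet):
    df = planar.struts(include_wrap=False)
    if len(df) == 0:
        raise InsufficientInputError("no strut points")


# ---------------------------------------------------------------------------
# Manual edits


def apply_manual_edits(graph: WireframeGraph, edits: list) -> WireframeGraph:
    """Apply a declarative edit list (the operator-in-the-loop escape hatch).

    Supported ops: ``add_node`` (id, x, y, role, ring), ``move_node`` (id, x,
    y), ``delete_node`` (id, removes incident edges), ``add_edge`` (a, b),
    ``delete_edge`` (a, b).  Graph invariants are re-validated after the full
    list; violations reject the edit with a diagnostic.
    """
    out = WireframeGraph(graph.wrap_period, graph.y_mode)
    out.g = graph.g.copy()
    for e in edits:
        op = e.get("op")
        if op == "add_node":
            out.add_node(
                e["id"], e["x"], e["y"], e.get("role", "peak"), e.get("ring", 0),
                e.get("provenance", "observed"),
            )
        elif op == "move_node":
            if e["id"] not in out.g:
                raise EditError(f"move_node: unknown id {e['id']}")
            out.g.nodes[e["id"]]["x"] = float(e["x"])
            out.g.nodes[e["id"]]["y"] = float(np.mod(e["y"], out.wrap_period))
        elif op == "delete_node":
            if e["id"] not in out.g:
                raise EditError(f"delete_node: unknown id {e['id']}")
            out.g.remove_node(e["id"])
        elif op == "add_edge":
            for nid in (e["a"], e["b"]):
                if nid not in out.g:
                    raise EditError(f"add_edge: unknown id {nid}")
            pa, pb = out.node_pos(e["a"]), out.node_pos(e["b"])
            yb = pa[1] + _signed_circ_diff(pb[1], pa[1], out.wrap_period)
            out.add_edge(e["a"], e["b"], np.array([[pa[0], pa[1]], [pb[0], yb]]), [])
        elif op == "delete_edge":
            if not out.g.has_edge(e["a"], e["b"]):
                raise EditError(f"delete_edge: no edge {e['a']}-{e['b']}")
            out.g.remove_edge(e["a"], e["b"])
        else:
            raise EditError(f"unknown edit op {op!r}")
    # re-anchor polyline endpoints at (possibly moved) node positions,
    # keeping seam-continued y coordinates continuous
    for a, b, dd in out.g.edges(data=True):
        poly = np.asarray(dd["polyline"], dtype=float)
        pa, pb = out.node_pos(a), out.node_pos(b)
        poly[0, 0], poly[-1, 0] = pa[0], pb[0]
        poly[0, 1] = pa[1]
        poly[-1, 1] = poly[0, 1] + _signed_circ_diff(pb[1], poly[0, 1], out.wrap_period)
        dd["polyline"] = poly
    out.validate(strict=True)
    return out
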