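"""File formats: segmented-frame JSON, centerline CSV/VTK, mesh export.

The frame file is one JSON object per pullback::

    {"frame_distance_mm": 0.2,
     "frames": [{"index": 0, "marker_angle_deg": 12.0,
                 "lumen": [[u, v], ...], "stent": [[u, v], ...],
                 "struts": [[u, v], ...]}, ...]}

Coordinates are mm in the OCT image plane with the catheter center at (0, 0).
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np

from .core import Centerline, Contour2D
from .errors import InvalidInputError
from .lumen import OCTFrame


def write_frames(frames: Sequence[OCTFrame], frame_distance: float, path) -> None:
    out = {"frame_distance_mm": float(frame_distance), "frames": []}
    for f in frames:
        d = {"index": int(f.index), "lumen": f.lumen_contour.vertices.tolist()}
        if f.marker_angle is not None:
            d["marker_angle_deg"] = float(np.degrees(f.marker_angle))
        if f.stent_contour is not None:
            d["stent"] = f.stent_contour.vertices.tolist()
        if len(f.strut_points):
            d["struts"] = np.asarray(f.strut_points).tolist()
        out["frames"].append(d)
    with open(path, "w") as fh:
        json.dump(out, fh)


def read_frames(path):
    """Load a frame file; returns ``(frames, frame_distance_mm)``."""
    with open(path) as fh:
        data = json.load(fh)
    try:
        fd = float(data["frame_distance_mm"])
    except (KeyError, TypeError, ValueError) as e:
        raise InvalidInputError(f"frame file {path}: missing frame_distance_mm") from e
    frames = []
    for rec in data.get("frames", []):
        idx = rec.get("index")
        try:
            frames.append(
                OCTFrame(
                    index=int(idx),
                    station=int(idx) * fd,
                    lumen_contour=Contour2D(np.asarray(rec["lumen"], dtype=float)),
                    stent_contour=(
                        Contour2D(np.asarray(rec["stent"], dtype=float))
                        if "stent" in rec
                        else None
                    ),
                    strut_points=np.asarray(rec.get("struts", []), dtype=float).reshape(-1, 2),
                    marker_angle=(
                        np.radians(float(rec["marker_angle_deg"]))
                        if "marker_angle_deg" in rec
                        else None
                    ),
                )
            )
        except (KeyError, TypeError, ValueError) as e:
            raise InvalidInputError(f"frame file {path}: bad frame index {idx!r}: {e}") from e
    frames.sort(key=lambda f: f.index)
    return frames, fd


def read_centerline(path) -> Centerline:
    """Centerline from CSV (columns x,y,z) or legacy ASCII VTK polyline."""
    path = str(path)
    if path.lower().endswith((".vtk",)):
        return Centerline.from_vtk(path)
    return Centerline.from_csv(path)


def export_mesh(mesh, path) -> None:
    """STL/PLY (binary, mm) or legacy ASCII VTK export of a trimesh."""
    path = str(path)
    if path.lower().endswith(".vtk"):
        write_vtk_polydata(path, mesh.vertices, faces=mesh.faces)
    else:
        mesh.export(path)


def write_vtk_polydata(path, points, faces=None, lines=None) -> None:
    """Minimal legacy ASCII VTK PolyData writer (triangles and/or polylines)."""
    points = np.asarray(points, dtype=float)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nstentrec scene\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(points)} float\n")
        for p in points:
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        if faces is not None and len(faces):
            faces = np.asarray(faces, dtype=int)
            fh.write(f"POLYGONS {len(faces)} {4 * len(faces)}\n")
            for f in faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        if lines is not None and len(lines):
            total = sum(len(l) + 1 for l in lines)
            fh.write(f"LINES {len(lines)} {total}\n")
            for l in lines:
                fh.write(" ".join([str(len(l))] + [str(i) for i in l]) + "\n")


def export_wire_vtk(wire, path) -> None:
    """3D wireframe as VTK polylines."""
    pts = []
    lines = []
    for _, _, dd in wire.g.edges(data=True):
        poly = np.asarray(dd["polyline"], dtype=float)
        start = len(pts)
        pts.extend(poly.tolist())
        lines.append(list(range(start, start + len(poly))))
    write_vtk_polydata(path, np.asarray(pts), lines=lines)


def read_wss_history(path):
    """WSS time series from CSV columns element_id, time, tau_w."""
    import pandas as pd

    from .metrics import WSSHistory

    df = pd.read_csv(path)
    need = {"element_id", "time", "tau_w"}
    if not need.issubset(df.columns):
        raise InvalidInputError(f"WSS CSV needs columns {sorted(need)}")
    pivot = df.pivot_table(index="time", columns="element_id", values="tau_w")
    if pivot.isna().any().any():
        raise InvalidInputError("WSS history incomplete: missing (element, time) samples")
    return WSSHistory(times=pivot.index.to_numpy(), tau_w=pivot.to_numpy())
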