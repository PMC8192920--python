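"""End-to-end reconstruction pipeline and its configuration."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import io as sio
from .core import Centerline, FrameField
from .errors import StentRecError
from .lumen import reconstruct_lumen
from .metrics import (
    cross_sections,
    ellipse_ratio_series,
    malapposition,
    mean_stent_diameter,
    stent_length,
)
from .rollback import make_gap_field, roll_back_wireframe, round_crowns, sweep_volume
from .unroll import package_and_rotate, unroll_to_plane
from .wireframe import StentTemplate, build_wireframe


@dataclass
class PipelineConfig:
    """All pipeline tunables, with per-value provenance for the manifest."""

    samples_per_contour: int = 64
    clustering_radius: float = 0.15  # mm, point-to-wireframe match radius
    prominence_frac: float = 0.25  # apex prominence as a fraction of crown height
    fillet_radius: Optional[float] = None  # mm; default 1.5x strut half-width
    section_spacing: float = 0.1  # mm between measurement cross-sections
    wrap_band: float = 2.0  # mm duplicate band beyond the seam
    densify_step: float = 0.05  # mm polyline densification before rollback
    gap_radius: float = 0.3  # mm neighbourhood for the malapposition field
    gap_min: float = 0.1  # mm below which struts are treated as apposed
    field_spacing: float = 0.05  # mm centerline resampling for the frame field
    seed: int = 0
    provenance: dict = field(default_factory=dict)

    def resolved_fillet(self, template: StentTemplate) -> float:
        if self.fillet_radius is not None:
            return self.fillet_radius
        prof = template.strut_profile
        half = (
            prof["diameter"] / 2 if prof["shape"] == "circular" else prof["width"] / 2
        )
        return 1.5 * half

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("provenance")
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path, **flag_overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        prov = {k: "file" for k in data}
        data.update(flag_overrides)
        prov.update({k: "flag" for k in flag_overrides})
        cfg = cls(**data)
        cfg.provenance = {
            f.name: prov.get(f.name, "default")
            for f in cfg.__dataclass_fields__.values()
            if f.name != "provenance"
        }
        return cfg


@dataclass
class PipelineResult:
    field: FrameField
    lumen: object
    rotations: np.ndarray
    stack: object
    planar: object
    graph: object
    wire3d: object
    stent: object
    metrics: dict
    per_station: dict


def reconstruct(frames, centerline: Centerline, template: StentTemplate,
                config: Optional[PipelineConfig] = None,
                timings: Optional[dict] = None) -> PipelineResult:
    """Run the full reconstruction on in-memory inputs."""
    cfg = config or PipelineConfig()
    tm = timings if timings is not None else {}

    def stage(name):
        tm[name] = time.perf_counter()

    def done(name):
        tm[name] = time.perf_counter() - tm[name]

    stage("lumen")
    field = FrameField(centerline, spacing=cfg.field_spacing)
    lumen_surface, rotations = reconstruct_lumen(frames, field, cfg.samples_per_contour)
    done("lumen")

    stage("unroll")
    stack = package_and_rotate(frames, rotations)
    planar = unroll_to_plane(stack, wrap_band=cfg.wrap_band)
    done("unroll")

    stage("wireframe")
    graph = build_wireframe(
        planar,
        template,
        {"clustering_radius": cfg.clustering_radius, "prominence_frac": cfg.prominence_frac},
    )
    done("wireframe")

    stage("rollback")
    struts = planar.struts()
    Wm = graph.wrap_period
    if graph.y_mode == "normalized":
        per = np.array([planar.wrap_period[int(i)] for i in struts.frame_index])
        ys = struts.y_mm.to_numpy() / per * Wm
    else:
        ys = struts.y_mm.to_numpy()
    gap_field = make_gap_field(
        struts.x_mm.to_numpy(), ys, struts.malapposition_mm.to_numpy(), Wm,
        radius=cfg.gap_radius, min_gap=cfg.gap_min,
    )
    wire3d = roll_back_wireframe(graph, stack, field, cfg.densify_step, gap_field)
    wire3d = round_crowns(wire3d, cfg.resolved_fillet(template))
    stent = sweep_volume(wire3d, template.strut_profile, field)
    done("rollback")

    stage("metrics")
    series = cross_sections(wire3d, field, cfg.section_spacing)
    msd, st, dia = mean_stent_diameter(series)
    est, ers = ellipse_ratio_series(series)
    _, mal_max, _ = malapposition(stent, lumen_surface, field)
    length = stent_length(wire3d, field)
    metrics = {
        "stent_length_mm": length,
        "mean_stent_diameter_mm": msd,
        "mean_ellipse_ratio": float(np.mean(ers)) if len(ers) else float("nan"),
        "max_malapposition_mm": mal_max,
        "n_cross_sections": int(len(st)),
    }
    per_station = {
        "station_mm": st.tolist(),
        "diameter_mm": dia.tolist(),
        "ellipse_station_mm": est.tolist(),
        "ellipse_ratio": ers.tolist(),
    }
    done("metrics")

    return PipelineResult(
        field=field, lumen=lumen_surface, rotations=rotations, stack=stack,
        planar=planar, graph=graph, wire3d=wire3d, stent=stent,
        metrics=metrics, per_station=per_station,
    )


def run_pipeline(frames_path, centerline_path, template_path, outdir,
                 config: Optional[PipelineConfig] = None) -> dict:
    """File-based pipeline: read inputs, reconstruct, write artifacts.

    Writes lumen/stent meshes, the planar point set, the wireframe graph, a
    metrics report (JSON + per-station CSV) and a manifest with the config
    hash and per-stage timings.  On a stage failure, partial artifacts are
    kept and the failing stage is named.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config or PipelineConfig()
    timings = {}
    t0 = time.perf_counter()
    timings["load"] = time.perf_counter()
    frames, fd = sio.read_frames(frames_path)
    centerline = sio.read_centerline(centerline_path)
    template = StentTemplate.from_json(template_path)
    timings["load"] = time.perf_counter() - timings["load"]

    try:
        res = reconstruct(frames, centerline, template, cfg, timings)
    except StentRecError as e:
        manifest = {
            "status": "failed", "error": str(e),
            "stages_completed": [k for k, v in timings.items() if v < 1e6],
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        raise

    timings["export"] = time.perf_counter()
    sio.export_mesh(res.lumen.mesh, outdir / "lumen.stl")
    sio.export_mesh(res.stent.volume_mesh, outdir / "stent.stl")
    sio.export_wire_vtk(res.wire3d, outdir / "stent_wireframe.vtk")
    res.planar.to_csv(outdir / "planar_points.csv")
    res.graph.to_json(outdir / "wireframe.json")
    with open(outdir / "metrics.json", "w") as fh:
        json.dump(res.metrics, fh, indent=1, sort_keys=True)
    import pandas as pd

    pd.DataFrame(
        {
            "station_mm": res.per_station["station_mm"],
            "diameter_mm": res.per_station["diameter_mm"],
        }
    ).to_csv(outdir / "per_station.csv", index=False)
    timings["export"] = time.perf_counter() - timings["export"]

    manifest = {
        "status": "ok",
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "frame_distance_mm": fd,
        "stages": [
            {"name": k, "seconds": round(v, 4)} for k, v in timings.items()
        ],
        "total_seconds": round(time.perf_counter() - t0, 4),
        "artifacts": [
            "lumen.stl", "stent.stl", "stent_wireframe.vtk", "planar_points.csv",
            "wireframe.json", "metrics.json", "per_station.csv",
        ],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
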