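"""End-to-end pipeline: images (real or simulated) to exported 3D model.

Stages run in the fixed order stack (macro only) -> silhouettes -> poses
-> carve -> mesh -> texture -> optional pin removal -> export, each
reading and writing plain files so any stage can be re-run or inspected
in isolation.  A manifest records parameters, the seed and per-stage
counts; runs are deterministic given (config, seed).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

import insecthull
from insecthull.camera import CameraIntrinsics, CameraView, pose_from_turntable
from insecthull.errors import InsectHullError
from insecthull.hull import carve, mesh_from_grid
from insecthull.plan import generate_plan, ingest_captures, DEFAULT_TILTS_DEG
from insecthull.render import (
    Primitive,
    SyntheticScene,
    render_focus_stack,
    render_view,
    synthetic_weevil,
)
from insecthull.silhouette import extract_silhouette
from insecthull.stacking import stack_view
from insecthull.texturing import bake_atlas, export_mesh, remove_pin, select_best_view

__all__ = ["PipelineConfig", "run_pipeline", "scene_from_config"]


@dataclass
class PipelineConfig:
    """Parameters for one digitization run.  All lengths mm, angles deg."""

    mode: str = "normal"
    pan_steps: int = 24
    tilt_angles_deg: tuple = DEFAULT_TILTS_DEG
    focus_count: int = 1
    focus_step_mm: float = 0.25
    # ~100 px/mm at the specimen: a desk-scale stand-in for the macro
    # rig's 18-megapixel frames, fine enough that the 1 px conservative
    # silhouette dilation stays a small fraction of the specimen
    camera_distance_mm: float = 150.0
    image_size: tuple = (600, 600)
    focal_length_px: float = 15000.0
    # input: synthetic scene name/spec, or a directory of captures
    scene: object = "weevil"
    input_dir: str | None = None
    blur_gain: float = 4.0
    # stage parameter blocks
    # keep_components="all": specimen parts (head, legs, pin) may project
    # as disjoint 2D blobs; dropping them from any one view's mask would
    # carve them out of the hull
    silhouette: dict = field(default_factory=lambda: {
        "threshold": 0.12, "min_blob_px": 16, "close_px": 3, "dilate_px": 1,
        "keep_components": "all"})
    carving: dict = field(default_factory=lambda: {
        "bbox_mm": 3.2, "resolution": 96, "samples_per_voxel": 1})
    texturing: dict = field(default_factory=lambda: {"atlas_size": 1024})
    pin_removal: dict | None = None        # e.g. {"method": "component"}
    export_formats: tuple = ("obj",)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for k, v in d.items():
            if not hasattr(cfg, k):
                raise InsectHullError(f"unknown config key {k!r}")
            if isinstance(getattr(cfg, k), dict) and isinstance(v, dict):
                getattr(cfg, k).update(v)
            else:
                setattr(cfg, k, v)
        return cfg


def scene_from_config(spec) -> SyntheticScene:
    """Resolve a config scene entry: stock name or list of primitive dicts."""
    if isinstance(spec, SyntheticScene):
        return spec
    if spec == "weevil":
        return synthetic_weevil()
    if spec == "weevil-attached":
        return synthetic_weevil(pin_attached=True)
    if spec == "weevil-nopin":
        return synthetic_weevil(with_pin=False)
    if isinstance(spec, (list, tuple)):
        prims = [Primitive(p["shape"], tuple(p["size"]),
                           centre=tuple(p.get("centre", (0, 0, 0))),
                           colour=tuple(p.get("colour", (200, 60, 40))))
                 for p in spec]
        return SyntheticScene(tuple(prims))
    raise InsectHullError(f"unknown scene {spec!r}")


def _build_views(cfg: PipelineConfig, plan) -> list[CameraView]:
    w, h = cfg.image_size
    intr = CameraIntrinsics(cfg.focal_length_px, (w / 2.0, h / 2.0), (w, h))
    return [CameraView(i, intr, pose_from_turntable(state))
            for i, state in enumerate(plan.views)]


def _acquire_images(cfg: PipelineConfig, plan, views, manifest):
    """Per-view all-in-focus images, simulated or ingested from disk."""
    images = []
    if cfg.input_dir is not None:
        groups = ingest_captures(plan, cfg.input_dir)
        for group in groups:
            frames = [np.asarray(Image.open(p).convert("RGB"))
                      for p in group]
            focus = plan.focus_positions_mm or (0.0,)
            img, _ = stack_view(frames, focus)
            images.append(img)
        manifest["stages"]["acquire"] = {"source": "disk",
                                         "views": len(images)}
        return images, None
    scene = scene_from_config(cfg.scene)
    if cfg.mode == "macro":
        offsets = np.asarray(plan.focus_positions_mm)
        planes = cfg.camera_distance_mm + offsets - offsets.mean()
        for view in views:
            frames, _, _ = render_focus_stack(
                scene, view, planes, blur_gain=cfg.blur_gain)
            img, _ = stack_view(frames, plan.focus_positions_mm)
            images.append(img)
    else:
        for view in views:
            img, _, _ = render_view(scene, view)
            images.append(img)
    manifest["stages"]["acquire"] = {"source": "synthetic",
                                     "views": len(images),
                                     "captures": plan.total_captures}
    return images, scene


def run_pipeline(cfg: PipelineConfig, out_dir):
    """Run the whole digitization pipeline; returns (TexturedMesh, manifest).

    Stage errors propagate with the failing stage named in the message.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"package": "insecthull", "version": insecthull.__version__,
                "seed": cfg.seed, "config": _cfg_dict(cfg), "stages": {}}
    rng = np.random.default_rng(cfg.seed)  # reserved for noise models
    del rng

    stage = "plan"
    try:
        plan = generate_plan(cfg.mode, cfg.pan_steps, cfg.tilt_angles_deg,
                             cfg.focus_count, cfg.focus_step_mm,
                             camera_distance_mm=cfg.camera_distance_mm)
        manifest["stages"]["plan"] = {"views": len(plan.views),
                                      "total_captures": plan.total_captures}
        views = _build_views(cfg, plan)

        stage = "acquire/stack"
        images, scene = _acquire_images(cfg, plan, views, manifest)

        stage = "silhouettes"
        bg = (scene.background if scene is not None else
              tuple(cfg.silhouette.get("background", (0, 140, 0))))
        sil_kw = {k: v for k, v in cfg.silhouette.items()
                  if k != "background"}
        masks = [extract_silhouette(img, background=bg, view_id=i, **sil_kw)
                 for i, img in enumerate(images)]
        manifest["stages"]["silhouettes"] = {
            "views": len(masks),
            "mean_area_px": float(np.mean([m.area_px for m in masks]))}

        stage = "carve"
        half = float(cfg.carving["bbox_mm"])
        res = int(cfg.carving["resolution"])
        grid = carve(masks, views, (-half, -half, -half), (half, half, half),
                     resolution=(res, res, res),
                     samples_per_voxel=int(
                         cfg.carving.get("samples_per_voxel", 1)))
        manifest["stages"]["carve"] = {
            "resolution": res, "occupied_voxels": int(grid.occupancy.sum()),
            "volume_mm3": grid.volume_mm3}

        stage = "mesh"
        mesh = mesh_from_grid(grid)
        manifest["stages"]["mesh"] = {"vertices": len(mesh.vertices),
                                      "faces": len(mesh.faces)}

        stage = "texture"
        assignments = select_best_view(mesh, views)
        tm = bake_atlas(mesh, assignments, images, views,
                        atlas_size=int(cfg.texturing["atlas_size"]))
        manifest["stages"]["texture"] = {
            "faces_textured": int((assignments >= 0).sum()),
            "faces_unseen": int((assignments < 0).sum())}

        if cfg.pin_removal:
            stage = "editpin"
            kw = dict(cfg.pin_removal)
            method = kw.pop("method", "component")
            tm, info = remove_pin(tm, method=method, **kw)
            manifest["stages"]["editpin"] = {"method": method, **info}

        stage = "export"
        written = []
        for fmt in cfg.export_formats:
            written += [str(p) for p in
                        export_mesh(tm, out / f"model.{fmt}", fmt)]
        manifest["stages"]["export"] = {"files": written}
    except InsectHullError as exc:
        raise InsectHullError(f"stage {stage!r}: {exc}") from exc

    manifest["finished_utc"] = time.strftime("%Y-%m-%dT%H:%M:%SZ",
                                             time.gmtime())
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return tm, manifest


def _cfg_dict(cfg: PipelineConfig) -> dict:
    d = {k: getattr(cfg, k) for k in cfg.__dataclass_fields__}
    if not isinstance(d["scene"], (str, list, type(None))):
        d["scene"] = "<scene object>"
    for k in ("tilt_angles_deg", "export_formats", "image_size"):
        d[k] = list(d[k])
    return d
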