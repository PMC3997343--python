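"""Capture schedules for normal-mode and macro-mode acquisition.

A plan enumerates turntable settings (pan-major within each tilt) and, in
macro mode, the focus-rail positions visited at every setting.  The stock
normal-mode schedule is 24 pan steps x 6 tilts = 144 views; macro mode
adds 31 focus positions 0.25 mm apart at each view, 4,464 captures total.
The same plan drives the synthetic renderer and ingestion of a directory
of real captures named ``view{i:04d}_focus{j:03d}.png``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from insecthull.camera import TurntableState
from insecthull.errors import (
    InvalidScheduleError,
    MissingCaptureError,
    OrphanFileError,
)

__all__ = ["AcquisitionPlan", "generate_plan", "ingest_captures",
           "DEFAULT_TILTS_DEG"]

DEFAULT_TILTS_DEG = (-45.0, -27.0, -9.0, 9.0, 27.0, 45.0)

_CAPTURE_RE = re.compile(r"^view(\d{4})_focus(\d{3})\.(png|jpg|jpeg)$",
                         re.IGNORECASE)


@dataclass(frozen=True)
class AcquisitionPlan:
    """Ordered capture schedule.

    ``views`` are TurntableStates in pan-major order within each tilt;
    ``focus_positions_mm`` is empty for normal mode.  ``total_captures``
    always equals ``len(views) * max(1, len(focus_positions_mm))``.
    """

    mode: str
    views: tuple
    focus_positions_mm: tuple
    camera_distance_mm: float

    def __post_init__(self):
        if self.mode not in ("normal", "macro"):
            raise InvalidScheduleError(f"unknown mode {self.mode!r}")
        fp = tuple(float(x) for x in self.focus_positions_mm)
        if self.mode == "normal" and fp:
            raise InvalidScheduleError("normal mode takes no focus positions")
        if fp:
            steps = np.diff(fp)
            if not (steps > 0).all():
                raise InvalidScheduleError("focus positions must increase")
            if len(steps) > 1 and not np.allclose(steps, steps[0], rtol=1e-6):
                raise InvalidScheduleError("focus positions must be uniform")
        object.__setattr__(self, "views", tuple(self.views))
        object.__setattr__(self, "focus_positions_mm", fp)

    @property
    def total_captures(self) -> int:
        return len(self.views) * max(1, len(self.focus_positions_mm))

    def capture_name(self, view_idx: int, focus_idx: int = 0,
                     ext: str = "png") -> str:
        return f"view{view_idx:04d}_focus{focus_idx:03d}.{ext}"

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "camera_distance_mm": float(self.camera_distance_mm),
            "views": [{"pan_deg": v.pan_deg, "tilt_deg": v.tilt_deg}
                      for v in self.views],
            "focus_positions_mm": list(self.focus_positions_mm),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionPlan":
        dist = float(d["camera_distance_mm"])
        views = tuple(TurntableState(v["pan_deg"], v["tilt_deg"], dist)
                      for v in d["views"])
        return cls(d["mode"], views, tuple(d.get("focus_positions_mm", ())),
                   dist)

    def save(self, path):
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "AcquisitionPlan":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def generate_plan(mode: str, pan_steps: int = 24,
                  tilt_angles_deg=DEFAULT_TILTS_DEG,
                  focus_count: int = 1, focus_step_mm: float = 0.25,
                  focus_start_mm: float = 0.0,
                  camera_distance_mm: float = 150.0) -> AcquisitionPlan:
    """Build a capture schedule.

    Normal mode visits ``pan_steps`` uniform pan angles at each tilt; macro
    mode additionally sweeps ``focus_count`` rail positions spaced
    ``focus_step_mm`` starting at ``focus_start_mm`` (focus depths are
    relative offsets added to the camera distance at render/ingest time).
    """
    if pan_steps < 1 or len(tuple(tilt_angles_deg)) < 1:
        raise InvalidScheduleError("need >= 1 pan step and >= 1 tilt angle")
    if mode == "macro" and focus_count < 2:
        raise InvalidScheduleError("macro mode requires focus_count >= 2")
    if focus_count < 1 or focus_step_mm <= 0:
        raise InvalidScheduleError("invalid focus schedule")
    pans = [360.0 * i / pan_steps for i in range(pan_steps)]
    views = tuple(TurntableState(p, float(t), camera_distance_mm)
                  for t in tilt_angles_deg for p in pans)
    focus = ()
    if mode == "macro":
        focus = tuple(focus_start_mm + focus_step_mm * j
                      for j in range(focus_count))
    return AcquisitionPlan(mode, views, focus, camera_distance_mm)


def ingest_captures(plan: AcquisitionPlan, directory) -> list[list[Path]]:
    """Map every plan slot to an image file in ``directory``.

    Returns one list of file paths per view (length 1 in normal mode,
    ``len(focus_positions_mm)`` in macro mode, ordered by focus index).
    Raises ``MissingCaptureError`` naming absent (view, focus) slots and
    ``OrphanFileError`` for image files matching no slot.
    """
    directory = Path(directory)
    n_focus = max(1, len(plan.focus_positions_mm))
    found: dict[tuple[int, int], Path] = {}
    orphans = []
    for p in sorted(directory.iterdir()):
        m = _CAPTURE_RE.match(p.name)
        if not m:
            continue
        i, j = int(m.group(1)), int(m.group(2))
        if i >= len(plan.views) or j >= n_focus:
            orphans.append(p.name)
        else:
            found[(i, j)] = p
    missing = [(i, j) for i in range(len(plan.views))
               for j in range(n_focus) if (i, j) not in found]
    if missing:
        raise MissingCaptureError(missing)
    if orphans:
        raise OrphanFileError(orphans)
    return [[found[(i, j)] for j in range(n_focus)]
            for i in range(len(plan.views))]
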