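"""Readers and writers for blood tables, frame schedules, TACs, images and
study configuration.

File-boundary time unit defaults to seconds (acquisition protocols are
written in seconds); everything internal is minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .kinetics import FrameSchedule, InputFunctionSet, TissueTAC

__all__ = [
    "read_blood_table",
    "write_blood_table",
    "read_frame_schedule",
    "write_frame_schedule",
    "read_tac_table",
    "write_tac_table",
    "load_image",
    "save_image",
    "StudyConfig",
]


def _resample_to_fine_grid(time_min, curves, dt_s: float = 1.0):
    """Linear interpolation of tabulated curves onto the internal fine grid,
    anchored at zero activity at t=0."""
    t = np.asarray(time_min, float)
    if t[0] > 0:
        t = np.concatenate([[0.0], t])
        curves = [np.concatenate([[0.0], np.asarray(c, float)]) for c in curves]
    fine = np.arange(0.0, t[-1] + 1e-12, dt_s / 60.0)
    return fine, [np.interp(fine, t, np.asarray(c, float)) for c in curves]


def read_blood_table(
    path, cp_unlabeled: float, time_unit: str = "s", sep=None, dt_s: float = 1.0
) -> InputFunctionSet:
    """Read arterial blood data from delimited text.

    Expected columns: ``time_s`` (or ``time_min`` with ``time_unit='min'``),
    ``cp_star``, ``cb_star`` and optionally ``cc_star`` (assumed zero when
    absent).  Curves are linearly interpolated onto the internal 1-s grid.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    tcol = "time_s" if "time_s" in df.columns else "time_min" if "time_min" in df.columns else "time"
    if tcol not in df.columns:
        raise ValueError(f"{path}: no time column (expected time_s/time_min/time)")
    for col in ("cp_star", "cb_star"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    t = df[tcol].to_numpy(float)
    if time_unit == "s" and tcol != "time_min":
        t = t / 60.0
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    cp = df["cp_star"].to_numpy(float)
    cb = df["cb_star"].to_numpy(float)
    cc = df["cc_star"].to_numpy(float) if "cc_star" in df.columns else np.zeros_like(cp)
    for name, c in (("cp_star", cp), ("cb_star", cb), ("cc_star", cc)):
        if np.any(c < 0):
            raise ValueError(f"{path}: negative activities in column {name!r}")
    fine, (cp_f, cb_f, cc_f) = _resample_to_fine_grid(t, [cp, cb, cc], dt_s=dt_s)
    return InputFunctionSet(fine, cp_f, cb_f, cc_f, cp_unlabeled)


def write_blood_table(path, inputs: InputFunctionSet, stride: int = 1) -> None:
    df = pd.DataFrame(
        {
            "time_s": inputs.time[::stride] * 60.0,
            "cp_star": inputs.cp_star[::stride],
            "cb_star": inputs.cb_star[::stride],
            "cc_star": inputs.cc_star[::stride],
        }
    )
    df.to_csv(path, index=False)


def read_frame_schedule(path, sep=None) -> FrameSchedule:
    """Read a frame schedule with columns ``start_s`` and ``dur_s``."""
    df = pd.read_csv(path, sep=sep, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    if "start_s" not in df.columns or "dur_s" not in df.columns:
        raise ValueError(f"{path}: expected columns start_s, dur_s")
    return FrameSchedule.from_seconds(df["start_s"].to_numpy(float), df["dur_s"].to_numpy(float))


def write_frame_schedule(path, schedule: FrameSchedule) -> None:
    pd.DataFrame(
        {"start_s": schedule.start_times * 60.0, "dur_s": schedule.durations * 60.0}
    ).to_csv(path, index=False)


def read_tac_table(path, schedule: FrameSchedule, sep=None) -> TissueTAC:
    df = pd.read_csv(path, sep=sep, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    if "value" not in df.columns:
        raise ValueError(f"{path}: expected a 'value' column")
    return TissueTAC(schedule, df["value"].to_numpy(float))


def write_tac_table(path, tac: TissueTAC) -> None:
    pd.DataFrame(
        {"mid_time_s": tac.schedule.mid_times * 60.0, "value": tac.values}
    ).to_csv(path, index=False)


def load_image(path):
    """Load a NIfTI volume; returns ``(data, affine, voxel_size_mm)``."""
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: missing or invalid voxel-size metadata")
    return np.asarray(img.dataobj), img.affine, tuple(float(z) for z in zooms)


def save_image(path, data: np.ndarray, affine: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(data, affine), str(path))


@dataclass
class StudyConfig:
    """Paths and settings of one analysis run, loadable from YAML."""

    blood_table: str | None = None
    schedule_table: str | None = None
    dynamic_image: str | None = None
    roi_labels: str | None = None
    cp_unlabeled: float = 120.0
    vd: float = 0.41
    grid_size: int = 100
    band: tuple[float, float] = (0.02, 0.3)
    noise_level: str = "voxel"
    delay_range_s: tuple[float, float] = (0.0, 20.0)
    fwhm_mm: float = 7.1
    seed: int = 0
    extras: dict = field(default_factory=dict)

    @classmethod
    def load(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extras"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        for key in ("band", "delay_range_s"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        extras = {k: v for k, v in raw.items() if k not in known}
        cfg = cls(**kwargs, extras=extras)
        for attr in ("blood_table", "schedule_table", "dynamic_image", "roi_labels"):
            p = getattr(cfg, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config references missing file: {p}")
        return cfg

    def dump(self, path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
            if k != "extras" and v is not None
        }
        data.update(self.extras)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
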