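"""Readers, writers and run configuration.

File conventions (fixed for byte-stable outputs):

* Contour CSV — header ``x_mm,y_mm``, one vertex per row, 6 significant
  digits, ``\n`` newlines, UTF-8.
* Clinical CSV — ``patient_id,os_days,os_event[,pfs_days,pfs_event,recist_6m]``.
* Mask input — single-slice PNG (any nonzero pixel = foreground) with the
  spacing supplied by the caller/config, or a NIfTI slice whose spacing is
  taken from the header.
* Results — JSON with stable key order; KM curves additionally as CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields as _dc_fields
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .geometry import BinaryMask, Contour

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "read_contour_csv",
    "write_contour_csv",
    "read_mask_png",
    "write_mask_png",
    "read_mask_nifti",
    "read_clinical_csv",
    "write_cohort_csv",
    "write_json",
    "km_curve_frame",
]

_FLOAT_FMT = "%.6g"


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass(frozen=True)
class RunConfig:
    """Validated run settings; unknown keys are rejected on load."""

    spacing_row_mm: float = 1.0
    spacing_col_mm: float = 1.0
    timepoint_tolerance_weeks: float = 6.0
    min_prop: float = 0.1
    n_perm: int = 2000
    seed: int = 0
    pr_threshold: float = -0.30
    pd_threshold: float = 0.20
    pd_min_increase_mm: float = 5.0

    def __post_init__(self):
        if self.spacing_row_mm <= 0 or self.spacing_col_mm <= 0:
            raise ConfigError("pixel spacings must be positive")
        if not 0 < self.min_prop < 0.5:
            raise ConfigError("min_prop must lie in (0, 0.5)")
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        if self.timepoint_tolerance_weeks <= 0:
            raise ConfigError("timepoint tolerance must be positive")


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a flat key-value YAML config, apply overrides, validate."""
    data: dict = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must contain a flat key-value mapping")
        data.update(loaded)
    data.update(overrides)
    known = {f.name for f in _dc_fields(RunConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown config keys: {unknown}")
    return RunConfig(**data)


# ---------------------------------------------------------------------------
# Contours and masks


def read_contour_csv(path: str | Path) -> Contour:
    df = pd.read_csv(path)
    missing = [c for c in ("x_mm", "y_mm") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: contour CSV must have header x_mm,y_mm "
                         f"(missing {missing})")
    return Contour(df[["x_mm", "y_mm"]].to_numpy(dtype=float))


def write_contour_csv(contour: Contour, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("x_mm,y_mm\n")
        for x, y in contour.vertices:
            fh.write(f"{x:.6g},{y:.6g}\n")


def read_mask_png(path: str | Path, spacing: tuple[float, float] = (1.0, 1.0)) -> BinaryMask:
    arr = np.asarray(Image.open(path).convert("L"))
    return BinaryMask(arr > 0, spacing)


def write_mask_png(mask: BinaryMask, path: str | Path) -> None:
    Image.fromarray((mask.grid.astype(np.uint8)) * 255, mode="L").save(path)


def read_mask_nifti(path: str | Path) -> BinaryMask:
    """Load a single-slice NIfTI mask; pixel spacing from the header zooms."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()
    keep = [i for i, s in enumerate(data.shape) if s > 1]
    if len(keep) != 2:
        raise ValueError(f"{path}: expected a single 2D slice, got shape {data.shape}")
    sl = [0] * data.ndim
    for i in keep:
        sl[i] = slice(None)
    grid = data[tuple(sl)] > 0
    spacing = (float(zooms[keep[0]]), float(zooms[keep[1]]))
    return BinaryMask(grid, spacing)


# ---------------------------------------------------------------------------
# Tables and results


def read_clinical_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"patient_id", "os_days", "os_event"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise ValueError(f"{path}: clinical CSV missing columns {missing}")
    df["patient_id"] = df["patient_id"].astype(str)
    if (df["os_days"] <= 0).any() or not np.isfinite(df["os_days"]).all():
        raise ValueError(f"{path}: os_days must be finite and positive")
    return df


def write_cohort_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Cohort table CSV with stable column order and 6-significant-digit floats."""
    out = df.sort_values("patient_id", kind="stable") if "patient_id" in df else df
    out.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(_jsonable(obj), fh, indent=2)
        fh.write("\n")


def km_curve_frame(curve) -> pd.DataFrame:
    """Tidy per-time KM table (time, at-risk, events, survival, CI band)."""
    return pd.DataFrame({
        "time_days": curve.times,
        "at_risk": curve.at_risk,
        "n_events": curve.n_events,
        "n_censored": curve.n_censored,
        "survival": curve.survival,
        "ci_lower": curve.ci_lower,
        "ci_upper": curve.ci_upper,
    })
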