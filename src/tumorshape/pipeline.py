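"""End-to-end helpers tying files to the analysis stages.

These functions are the programmatic equivalents of the command-line
subcommands: contour/mask files in, feature tables, cohort tables and
analysis results out.  The CLI is a thin wrapper around them.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import io as tio
from .geometry import ShapeFeatures, shape_features, mask_to_contour
from .response import LesionTimepoint, Timepoint, build_cohort_table

__all__ = ["features_for_file", "features_table", "cohort_from_files"]

_MASK_SUFFIXES = {".png", ".nii", ".gz"}


def features_for_file(path: str | Path,
                      spacing: tuple[float, float] = (1.0, 1.0)) -> ShapeFeatures:
    """Shape features of one lesion file (contour CSV, PNG or NIfTI mask)."""
    p = Path(path)
    suffix = p.suffix.lower()
    if suffix == ".csv":
        contour = tio.read_contour_csv(p)
    elif suffix == ".png":
        contour = mask_to_contour(tio.read_mask_png(p, spacing))
    elif suffix == ".nii" or p.name.lower().endswith(".nii.gz"):
        contour = mask_to_contour(tio.read_mask_nifti(p))
    else:
        raise ValueError(f"{p}: unsupported lesion file type {suffix!r}")
    return shape_features(contour)


def features_table(paths, spacing=(1.0, 1.0), strict: bool = False) -> pd.DataFrame:
    """One row of shape features per input file; failures become rows with an
    ``error`` column unless ``strict`` (then the first failure raises)."""
    rows = []
    for path in paths:
        row: dict = {"path": str(path)}
        try:
            f = features_for_file(path, spacing)
            row.update(area_mm2=f.area, perimeter_mm=f.perimeter,
                       hull_area_mm2=f.hull_area, solidity=f.solidity,
                       circularity=f.circularity, circularity_raw=f.circularity_raw,
                       max_diameter_mm=f.max_diameter)
        except Exception as exc:  # per-file error reporting
            if strict:
                raise
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_from_files(manifest: str | Path | pd.DataFrame,
                      clinical: str | Path | pd.DataFrame,
                      spacing=(1.0, 1.0)) -> pd.DataFrame:
    """Build the analysis-ready cohort table from a lesion manifest.

    ``manifest`` is a CSV/DataFrame with columns ``patient_id, timepoint,
    path`` (paths relative to the manifest file when one is given).
    """
    if isinstance(manifest, (str, Path)):
        mpath = Path(manifest)
        mdf = pd.read_csv(mpath)
        root = mpath.parent
    else:
        mdf = manifest.copy()
        root = Path(".")
    for col in ("patient_id", "timepoint", "path"):
        if col not in mdf.columns:
            raise ValueError(f"lesion manifest is missing column {col!r}")
    clin = tio.read_clinical_csv(clinical) if isinstance(clinical, (str, Path)) else clinical

    lesions = []
    for rec in mdf.itertuples(index=False):
        p = Path(rec.path)
        if not p.is_absolute():
            p = root / p
        lesions.append(LesionTimepoint(
            patient_id=str(rec.patient_id),
            timepoint=Timepoint(rec.timepoint),
            features=features_for_file(p, spacing),
            source=str(p),
        ))
    return build_cohort_table(lesions, clin)
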