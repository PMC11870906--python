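"""Longitudinal assembly: shape trajectories, simplified RECIST 1.1 labels,
cohort exclusion accounting and the analysis-ready cohort table.

Timepoints are baseline, 3-month ("m3") and 6-month ("m6") follow-up.  Shape
variation follows the convention *baseline minus follow-up*: a positive
variation means the index decreased under treatment, i.e. the tumor became
more irregular (solidity) or less circular (circularity).

RECIST 1.1 is simplified to a single target lesion (the largest target):
response is classified from the lesion's longest diameter relative to
baseline and nadir.  Sum-of-diameters bookkeeping, non-target assessment and
new-lesion detection are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .geometry import ShapeFeatures

__all__ = [
    "Timepoint",
    "ResponseStatus",
    "LesionTimepoint",
    "ShapeTrajectory",
    "CohortError",
    "shape_variation",
    "recist_classify",
    "running_nadir",
    "exclusion_filter",
    "build_cohort_table",
]

TIMEPOINTS = ("baseline", "m3", "m6")


class Timepoint(str, Enum):
    BASELINE = "baseline"
    M3 = "m3"
    M6 = "m6"


class ResponseStatus(str, Enum):
    """RECIST 1.1 response category for a single target lesion."""

    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"

    @property
    def controlled(self) -> bool:
        """Disease control = partial response or stable disease."""
        return self in (ResponseStatus.PR, ResponseStatus.SD)

    @property
    def ordinal(self) -> int:
        """Severity ordering CR < PR < SD < PD, for rank correlations."""
        return ("CR", "PR", "SD", "PD").index(self.value)


class CohortError(ValueError):
    """Inconsistent cohort inputs (duplicate records, unresolvable ids, ...)."""


@dataclass(frozen=True)
class LesionTimepoint:
    """Shape features of one patient's target lesion at one timepoint."""

    patient_id: str
    timepoint: Timepoint
    features: ShapeFeatures
    source: str | None = None


@dataclass(frozen=True)
class ShapeTrajectory:
    """Per-patient features over time plus the derived variation values."""

    patient_id: str
    baseline: ShapeFeatures
    m3: ShapeFeatures | None = None
    m6: ShapeFeatures | None = None

    @property
    def solidity_variation(self) -> float | None:
        if self.m6 is None:
            return None
        return shape_variation(self.baseline.solidity, self.m6.solidity)

    @property
    def circularity_variation(self) -> float | None:
        if self.m6 is None:
            return None
        return shape_variation(self.baseline.circularity, self.m6.circularity)

    @property
    def size_variation_mm(self) -> float | None:
        """Baseline minus 6-month maximum diameter (mm); positive = shrinkage."""
        if self.m6 is None:
            return None
        return self.baseline.max_diameter - self.m6.max_diameter

    @property
    def area_variation_mm2(self) -> float | None:
        if self.m6 is None:
            return None
        return self.baseline.area - self.m6.area


def shape_variation(baseline_value: float | None, followup_value: float | None) -> float | None:
    """Shape variation = index at baseline minus index at follow-up.

    Positive values mean the index decreased (the tumor became more irregular
    or less circular).  A missing endpoint yields ``None``, never 0.
    """
    if baseline_value is None or followup_value is None:
        return None
    b, f = float(baseline_value), float(followup_value)
    if math.isnan(b) or math.isnan(f):
        return None
    for name, v in (("baseline", b), ("follow-up", f)):
        if not (0.0 < v <= 1.0):
            raise ValueError(f"{name} shape index must lie in (0, 1], got {v}")
    return b - f


def recist_classify(
    baseline_mm: float,
    nadir_mm: float,
    current_mm: float,
    *,
    pr_threshold: float = -0.30,
    pd_threshold: float = 0.20,
    pd_min_increase_mm: float = 5.0,
) -> ResponseStatus:
    """Simplified single-lesion RECIST 1.1 classification.

    CR: current diameter 0; PR: >= 30% decrease from baseline; PD: >= 20%
    increase from nadir *and* an absolute increase of at least 5 mm; SD
    otherwise.  Precedence on the (theoretical) boundary is PD > PR > SD.
    ``pd_min_increase_mm=0`` disables the absolute rule.
    """
    dia = (baseline_mm, nadir_mm, current_mm)
    if any(not math.isfinite(v) or v < 0 for v in dia):
        raise ValueError(f"diameters must be finite and non-negative, got {dia}")
    if baseline_mm <= 0:
        raise ValueError("baseline diameter must be positive")
    if nadir_mm > baseline_mm + 1e-9:
        raise ValueError("nadir cannot exceed the baseline diameter")
    if current_mm == 0:
        return ResponseStatus.CR
    if nadir_mm == 0:
        return ResponseStatus.PD  # reappearance after complete response
    rel_nadir = (current_mm - nadir_mm) / nadir_mm
    if rel_nadir >= pd_threshold and current_mm - nadir_mm >= pd_min_increase_mm:
        return ResponseStatus.PD
    if (current_mm - baseline_mm) / baseline_mm <= pr_threshold:
        return ResponseStatus.PR
    return ResponseStatus.SD


def running_nadir(diameters_mm) -> float:
    """Nadir = running minimum of the observed diameters, baseline included."""
    ds = [float(d) for d in diameters_mm if d is not None and not math.isnan(float(d))]
    if not ds:
        raise ValueError("no diameters available to compute the nadir")
    return min(ds)


def exclusion_filter(patients) -> tuple[list, dict[str, int]]:
    """Apply the study exclusion cascade and account for every patient.

    Each record must expose ``has_separate_target`` and
    ``has_followup_imaging`` (attributes or mapping keys).  Exclusions are
    applied in that order, so a patient lacking both counts only under
    ``no_separate_target``.  Returns (included records, counts) with
    ``included + sum(excluded) == len(patients)``.
    """

    def flag(rec, name):
        if isinstance(rec, dict):
            return bool(rec[name])
        return bool(getattr(rec, name))

    counts = {"screened": len(patients), "no_separate_target": 0,
              "no_followup_imaging": 0, "included": 0}
    included = []
    for rec in patients:
        if not flag(rec, "has_separate_target"):
            counts["no_separate_target"] += 1
        elif not flag(rec, "has_followup_imaging"):
            counts["no_followup_imaging"] += 1
        else:
            included.append(rec)
    counts["included"] = len(included)
    return included, counts


_FEATURE_COLS = ("area", "perimeter", "hull_area", "solidity", "circularity",
                 "max_diameter")


def _trajectories(lesions) -> dict[str, ShapeTrajectory]:
    seen: dict[tuple[str, str], ShapeFeatures] = {}
    for les in lesions:
        tp = Timepoint(les.timepoint).value
        key = (str(les.patient_id), tp)
        if key in seen:
            raise CohortError(f"duplicate lesion record for patient "
                              f"{key[0]!r} at timepoint {key[1]!r}")
        seen[key] = les.features
    out: dict[str, ShapeTrajectory] = {}
    for pid in sorted({k[0] for k in seen}):
        base = seen.get((pid, "baseline"))
        if base is None:
            raise CohortError(f"patient {pid!r} has follow-up lesions but no baseline")
        out[pid] = ShapeTrajectory(pid, base, seen.get((pid, "m3")), seen.get((pid, "m6")))
    return out


def build_cohort_table(
    lesions,
    clinical: pd.DataFrame,
    responses: dict | None = None,
) -> pd.DataFrame:
    """Join shape trajectories with clinical outcomes into one row per patient.

    ``clinical`` must contain ``patient_id``, ``os_days`` and ``os_event``
    (``pfs_days``/``pfs_event``/``recist_6m`` optional).  ``responses``
    optionally maps patient id -> :class:`ResponseStatus` and overrides both
    a ``recist_6m`` column and the diameter-derived classification.  When no
    label is supplied, RECIST at 6 months is computed from the lesion maximum
    diameters (nadir = running minimum over available timepoints).

    Patients missing the 6-month lesion keep their row; the 6-month feature
    and all variation columns stay null.  Lesions whose patient id is absent
    from the clinical table raise :class:`CohortError` listing the offenders.
    Exclusion/missingness bookkeeping for the study flowchart is attached as
    ``df.attrs["flowchart"]``.
    """
    if "patient_id" not in clinical.columns:
        raise CohortError("clinical table must have a patient_id column")
    for col in ("os_days", "os_event"):
        if col not in clinical.columns:
            raise CohortError(f"clinical table is missing required column {col!r}")
    clin = clinical.copy()
    clin["patient_id"] = clin["patient_id"].astype(str)
    if clin["patient_id"].duplicated().any():
        dups = sorted(clin.loc[clin["patient_id"].duplicated(), "patient_id"])
        raise CohortError(f"duplicate patient ids in clinical table: {dups}")

    traj = _trajectories(lesions)
    unknown = sorted(set(traj) - set(clin["patient_id"]))
    if unknown:
        raise CohortError(f"lesion records reference unknown patient ids: {unknown}")

    rows = []
    for pid in sorted(traj):
        tr = traj[pid]
        row: dict = {"patient_id": pid}
        for tp in TIMEPOINTS:
            feats = {"baseline": tr.baseline, "m3": tr.m3, "m6": tr.m6}[tp]
            for col in _FEATURE_COLS:
                row[f"{col}_{tp}"] = getattr(feats, col) if feats is not None else np.nan
        row["solidity_variation"] = _nan(tr.solidity_variation)
        row["circularity_variation"] = _nan(tr.circularity_variation)
        row["size_variation_mm"] = _nan(tr.size_variation_mm)
        row["area_variation_mm2"] = _nan(tr.area_variation_mm2)

        status: ResponseStatus | None = None
        if responses and pid in responses:
            status = ResponseStatus(responses[pid])
        elif "recist_6m" in clin.columns:
            lab = clin.set_index("patient_id").at[pid, "recist_6m"]
            if isinstance(lab, str) and lab:
                status = ResponseStatus(lab)
        if status is None and tr.m6 is not None:
            dias = [tr.baseline.max_diameter]
            if tr.m3 is not None:
                dias.append(tr.m3.max_diameter)
            status = recist_classify(
                tr.baseline.max_diameter, running_nadir(dias), tr.m6.max_diameter
            )
        row["recist_6m"] = status.value if status is not None else None
        row["controlled"] = status.controlled if status is not None else None
        rows.append(row)

    df = pd.DataFrame(rows)
    clin_cols = [c for c in ("os_days", "os_event", "pfs_days", "pfs_event")
                 if c in clin.columns]
    df = df.merge(clin[["patient_id"] + clin_cols], on="patient_id", how="left")
    df = df.sort_values("patient_id", kind="stable").reset_index(drop=True)
    df.attrs["flowchart"] = {
        "clinical_rows": int(len(clin)),
        "with_baseline_lesion": int(len(df)),
        "clinical_without_lesions": int(len(clin) - len(df)),
        "missing_m3": int(df["solidity_m3"].isna().sum()),
        "missing_m6": int(df["solidity_m6"].isna().sum()),
    }
    return df


def _nan(v):
    return np.nan if v is None else v
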