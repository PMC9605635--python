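"""Volumetric image and cohort-table I/O.

Establishes the coordinate and unit conventions used by every downstream
module: all physical quantities are internal millimeters (mm, mm^2, mm^3);
voxel index ``(i, j, k)`` maps to world position ``origin + index * spacing``
(voxel-center convention, 0-based). Reporting layers convert to the clinical
units (cm, cm^2, mL) only at output time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd

log = logging.getLogger("gliomics")

KI67_HIGH_CUT_PCT = 20.0  # percent positively stained cells

COHORT_COLUMNS = [
    "patient_id", "age", "ecog", "resection", "stupp_complete", "ki67_pct",
    "who_grade", "os_months", "os_event", "pfs_months", "pfs_event",
]
_MANDATORY_COLUMNS = [c for c in COHORT_COLUMNS if c != "ki67_pct"]


class Modality(str, Enum):
    PET = "PET"
    MRI = "MRI"


@dataclass
class VoxelGrid:
    """A 3D scalar field with physical voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel intensities: SUV for PET, arbitrary units for MRI.
    spacing : tuple of float
        Physical voxel size along each axis, millimeters.
    origin : tuple of float
        World coordinate of the center of voxel (0, 0, 0), millimeters.
    modality : Modality
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: Modality = Modality.PET

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive on all axes, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values (NaN/Inf)")
        self.modality = Modality(self.modality)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel, mm^3."""
        return float(np.prod(self.spacing))

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel centers for an (n, 3) index array."""
        idx = np.atleast_2d(np.asarray(indices, dtype=np.float64))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)


def load_volume(path: str | Path, modality: Modality | str) -> VoxelGrid:
    """Read a NIfTI volume into a :class:`VoxelGrid`.

    Spacing is taken from the file header (mm); the affine translation gives
    the origin. 4D or otherwise non-3D files and non-positive header spacings
    are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim}D shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise ValueError(f"{path}: non-positive voxel spacing {spacing}")
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return VoxelGrid(values=np.asarray(data, dtype=np.float64), spacing=spacing,
                     origin=origin, modality=Modality(modality))


def save_volume(grid: VoxelGrid, path: str | Path) -> None:
    """Write a :class:`VoxelGrid` as NIfTI with a diagonal affine."""
    affine = np.diag(list(grid.spacing) + [1.0])
    affine[:3, 3] = grid.origin
    nib.save(nib.Nifti1Image(grid.values.astype(np.float64), affine), str(path))


@dataclass
class CohortRecord:
    """One patient's clinical covariates and survival outcomes."""

    patient_id: str
    age: float
    ecog: int
    resection: str               # complete | partial | biopsy
    stupp_complete: bool
    who_grade: str               # III | IV
    os_months: float
    os_event: bool
    pfs_months: float
    pfs_event: bool
    ki67_high: Optional[bool] = None
    extras: dict = field(default_factory=dict)


_RESECTIONS = {"complete", "partial", "biopsy"}
_GRADES = {"III", "IV"}


def _validate_row(row: pd.Series) -> list[str]:
    problems = []
    if not (0 <= row["ecog"] <= 3):
        problems.append(f"ecog {row['ecog']} outside 0-3")
    if str(row["resection"]) not in _RESECTIONS:
        problems.append(f"unknown resection {row['resection']!r}")
    if str(row["who_grade"]) not in _GRADES:
        problems.append(f"unknown who_grade {row['who_grade']!r}")
    for col in ("os_months", "pfs_months"):
        if row[col] < 0:
            problems.append(f"negative survival time {col}={row[col]}")
    if bool(row["os_event"]) and bool(row["pfs_event"]) and row["pfs_months"] > row["os_months"]:
        problems.append(f"pfs_months {row['pfs_months']} > os_months {row['os_months']} with both events observed")
    return problems


def load_cohort(path: str | Path) -> list[CohortRecord]:
    """Read and validate a cohort CSV.

    Rows violating the record invariants are dropped with a row-level
    diagnostic logged at WARNING. ``ki67_high`` is derived from a ``ki67_pct``
    column (percent positive cells) at the 20% cut when present; missing
    percentages leave it ``None``.
    """
    df = pd.read_csv(path)
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    records: list[CohortRecord] = []
    for i, row in df.iterrows():
        problems = _validate_row(row)
        if problems:
            log.warning("cohort row %d (patient %s) rejected: %s", i, row["patient_id"], "; ".join(problems))
            continue
        ki67_high = None
        if "ki67_pct" in df.columns and pd.notna(row.get("ki67_pct")):
            ki67_high = bool(float(row["ki67_pct"]) >= KI67_HIGH_CUT_PCT)
        records.append(CohortRecord(
            patient_id=str(row["patient_id"]),
            age=float(row["age"]),
            ecog=int(row["ecog"]),
            resection=str(row["resection"]),
            stupp_complete=bool(row["stupp_complete"]),
            who_grade=str(row["who_grade"]),
            os_months=float(row["os_months"]),
            os_event=bool(row["os_event"]),
            pfs_months=float(row["pfs_months"]),
            pfs_event=bool(row["pfs_event"]),
            ki67_high=ki67_high,
        ))
    return records


def cohort_to_frame(records: list[CohortRecord]) -> pd.DataFrame:
    """Flatten records (plus any extras) into a DataFrame, one row per patient."""
    rows = []
    for r in records:
        d = {k: v for k, v in r.__dict__.items() if k != "extras"}
        d.update(r.extras)
        rows.append(d)
    return pd.DataFrame(rows)
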