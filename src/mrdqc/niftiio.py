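"""Loading, orienting, and measuring NIfTI volumes and label maps.

All geometric conventions used by the rest of the toolkit live here:

* Volumes are held as :class:`VoxelGrid` — a 3D scalar array plus a 4x4
  voxel-index-to-world-mm affine (NIfTI convention, 0-based indices).
* Internal processing assumes the canonical RAS+ orientation produced by
  :func:`reorient_canonical`: axis 0 increases to the patient's Right,
  axis 1 to Anterior, axis 2 to Superior.  "Axial" slices are taken along
  axis 2, "sagittal" along axis 0, "coronal" along axis 1.
* Label maps store small non-negative integers; the mapping from label
  value to anatomical role (enhancing tumor, edema, ...) travels with the
  map in :class:`LabelMap.label_names`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "AbsentInputError",
    "FormatError",
    "GeometryError",
    "OrientationError",
    "VoxelGrid",
    "LabelMap",
    "StudyRecord",
    "read_volume",
    "read_label_map",
    "write_volume",
    "reorient_canonical",
    "voxel_volume_mm3",
    "label_volume_cm3",
    "read_manifest",
    "write_manifest",
]

ANATOMICAL_MODALITIES = ("T1", "T1C", "T2", "FLAIR")
ANNOTATION_ROLES = ("brain_mask", "tumor_seg", "csf_roi")

#: default label roles for the three-label tumor segmentation
TUMOR_LABEL_NAMES = {1: "enhancing", 2: "necrosis", 3: "edema"}
BINARY_LABEL_NAMES = {1: "foreground"}


class AbsentInputError(FileNotFoundError):
    """An expected input file is missing (feeds the "No PNGs" review flag)."""


class FormatError(ValueError):
    """A file exists but is not a readable NIfTI-1 volume."""


class GeometryError(ValueError):
    """Arrays that must share a voxel grid do not."""


class OrientationError(ValueError):
    """The affine is too oblique to assign anatomical axes."""


@dataclass(frozen=True)
class VoxelGrid:
    """A 3D scalar image with a voxel-to-world affine.

    Parameters
    ----------
    data
        3D array; anatomical images are float, label maps integer.
    affine
        4x4 voxel-index (0-based) to world-mm transform; the upper-left
        3x3 must be invertible.
    path
        Optional source file identifier, kept for reporting.
    """

    data: np.ndarray
    affine: np.ndarray
    path: str | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        affine = np.asarray(self.affine, dtype=float)
        if data.ndim != 3 or min(data.shape) < 1:
            raise GeometryError(f"expected a 3D volume, got shape {data.shape}")
        if affine.shape != (4, 4):
            raise GeometryError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise GeometryError("affine upper-left 3x3 is singular")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]


@dataclass(frozen=True)
class LabelMap:
    """An integer-labeled :class:`VoxelGrid` for masks and segmentations."""

    grid: VoxelGrid
    label_names: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.issubdtype(self.grid.data.dtype, np.integer):
            raise FormatError("LabelMap requires integer voxel values")
        if (self.grid.data < 0).any():
            raise FormatError("LabelMap voxel values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def labels_present(self) -> list[int]:
        vals = np.unique(self.grid.data)
        return [int(v) for v in vals if v != 0]

    def mask(self, labels=None) -> np.ndarray:
        """Boolean foreground mask for ``labels`` (default: any nonzero)."""
        if labels is None:
            return self.grid.data != 0
        return np.isin(self.grid.data, list(labels))


@dataclass
class StudyRecord:
    """One case's modality and annotation file set plus reference volumes."""

    study_id: str
    anatomical: dict[str, str] = field(default_factory=dict)
    functional: dict[str, str] = field(default_factory=dict)
    annotations: dict[str, str] = field(default_factory=dict)
    reference_volumes: tuple[float, float] | None = None  # (total, enhancing) cm3
    extras: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.study_id:
            raise ValueError("study_id must be nonempty")
        self.anatomical = {k: v for k, v in self.anatomical.items() if v}
        self.functional = {k: v for k, v in self.functional.items() if v}
        self.annotations = {k: v for k, v in self.annotations.items() if v}
        if not self.anatomical:
            raise ValueError(f"study {self.study_id!r}: at least one anatomical image required")

    def reference_anatomical(self) -> str:
        """Modality used as the grayscale background for overlay panels."""
        for m in ANATOMICAL_MODALITIES:
            if m in self.anatomical:
                return m
        return next(iter(self.anatomical))


def read_volume(path: str | Path) -> VoxelGrid:
    """Load a NIfTI-1 volume (optionally .gz) with header scaling applied.

    NaN voxels are replaced by the image minimum with a warning: the
    toolkit's job is to render degraded data, not crash on it.
    """
    path = Path(path)
    if not path.exists():
        raise AbsentInputError(f"input volume not found: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(dtype=np.float64))
    except AbsentInputError:
        raise
    except Exception as exc:  # nibabel raises a mix of its own error types
        raise FormatError(f"not a readable NIfTI file: {path}: {exc}") from exc
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    if np.isnan(data).any():
        fill = np.nanmin(data) if np.isfinite(np.nanmin(data)) else 0.0
        warnings.warn(f"{path}: NaN voxels replaced by image minimum {fill:g}")
        data = np.nan_to_num(data, nan=fill)
    return VoxelGrid(data=data, affine=np.asarray(img.affine, float), path=str(path))


def read_label_map(path: str | Path, label_names: Mapping[int, str] | None = None) -> LabelMap:
    """Load a NIfTI label map, rounding any non-integer stored values."""
    grid = read_volume(path)
    data = grid.data
    rounded = np.rint(data)
    if not np.array_equal(rounded, data):
        warnings.warn(f"{path}: non-integer label values rounded to nearest integer")
    ints = rounded.astype(np.int32)
    if (ints < 0).any():
        warnings.warn(f"{path}: negative label values clipped to 0")
        ints = np.clip(ints, 0, None)
    out = VoxelGrid(data=ints, affine=grid.affine, path=grid.path)
    if label_names is None:
        present = [int(v) for v in np.unique(ints) if v != 0]
        label_names = {v: f"label_{v}" for v in present}
    return LabelMap(grid=out, label_names=dict(label_names))


def write_volume(grid: VoxelGrid, path: str | Path, dtype=None) -> Path:
    """Write a grid as NIfTI-1; returns the path written."""
    path = Path(path)
    data = grid.data if dtype is None else grid.data.astype(dtype)
    img = nib.Nifti1Image(data, grid.affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))
    return path


def _io_orientation(affine: np.ndarray) -> np.ndarray:
    # reject truly oblique affines: every voxel axis must lie within 45
    # degrees of some cardinal world axis
    cols = affine[:3, :3]
    norms = np.linalg.norm(cols, axis=0)
    cosines = np.abs(cols) / norms
    if (cosines.max(axis=0) < np.cos(np.deg2rad(45.0)) - 1e-9).any():
        raise OrientationError("affine too oblique: no cardinal axis within 45 degrees")
    return nib.orientations.io_orientation(affine)


def reorient_canonical(grid: VoxelGrid) -> VoxelGrid:
    """Reorder/flip axes to RAS+ without changing any voxel's world position."""
    ornt = _io_orientation(grid.affine)
    target = nib.orientations.axcodes2ornt(("R", "A", "S"))
    transform = nib.orientations.ornt_transform(ornt, target)
    if np.array_equal(transform, np.array([[0, 1], [1, 1], [2, 1]], float)):
        return grid
    data = nib.orientations.apply_orientation(grid.data, transform)
    inv = nib.orientations.inv_ornt_aff(transform, grid.data.shape)
    affine = grid.affine @ inv
    return VoxelGrid(data=data, affine=affine, path=grid.path)


def reorient_label_map(m: LabelMap) -> LabelMap:
    return LabelMap(grid=reorient_canonical(m.grid), label_names=dict(m.label_names))


def voxel_volume_mm3(grid: VoxelGrid) -> float:
    """Volume of one voxel in mm^3: |det| of the affine's upper-left 3x3."""
    return float(abs(np.linalg.det(grid.affine[:3, :3])))


def label_volume_cm3(m: LabelMap, labels) -> float:
    """Total volume in cm^3 of voxels whose value is in ``labels``."""
    labels = set(labels)
    if not labels:
        raise ValueError("labels must be nonempty")
    count = int(np.isin(m.grid.data, list(labels)).sum())
    return count * voxel_volume_mm3(m.grid) / 1000.0


# ---------------------------------------------------------------------------
# Study manifest (CSV)

_MANIFEST_PATH_COLS = {
    "path_T1": ("anatomical", "T1"),
    "path_T1C": ("anatomical", "T1C"),
    "path_T2": ("anatomical", "T2"),
    "path_FLAIR": ("anatomical", "FLAIR"),
    "path_brain_mask": ("annotations", "brain_mask"),
    "path_tumor_seg": ("annotations", "tumor_seg"),
    "path_csf_roi": ("annotations", "csf_roi"),
}
_REF_COLS = ("ref_total_cm3", "ref_enhancing_cm3")


def read_manifest(path: str | Path) -> list[StudyRecord]:
    """Parse a study manifest CSV into :class:`StudyRecord` rows.

    Recognized columns: ``study_id``, the seven ``path_*`` columns, the two
    optional ``ref_*_cm3`` columns, ``path_func_<name>`` for functional or
    derived maps, and anything else lands in ``extras``.  Relative paths are
    resolved against the manifest's directory.
    """
    path = Path(path)
    if not path.exists():
        raise AbsentInputError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "study_id" not in df.columns:
        raise FormatError("manifest missing required column 'study_id'")
    base = path.parent
    records: list[StudyRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = row["study_id"].strip()
        if sid in seen:
            raise FormatError(f"duplicate study_id in manifest: {sid!r}")
        seen.add(sid)
        anatomical: dict[str, str] = {}
        annotations: dict[str, str] = {}
        functional: dict[str, str] = {}
        extras: dict[str, object] = {}
        refs: dict[str, float] = {}
        for col, raw in row.items():
            if col == "study_id":
                continue
            val = str(raw).strip()
            if col in _MANIFEST_PATH_COLS:
                if val:
                    group, key = _MANIFEST_PATH_COLS[col]
                    target = anatomical if group == "anatomical" else annotations
                    target[key] = str((base / val) if not Path(val).is_absolute() else Path(val))
            elif col.startswith("path_func_"):
                if val:
                    name = col[len("path_func_"):]
                    functional[name] = str((base / val) if not Path(val).is_absolute() else Path(val))
            elif col in _REF_COLS:
                if val:
                    refs[col] = float(val)
            else:
                extras[col] = val
        reference = None
        if refs:
            reference = (refs.get("ref_total_cm3", float("nan")),
                         refs.get("ref_enhancing_cm3", float("nan")))
        records.append(StudyRecord(study_id=sid, anatomical=anatomical,
                                   functional=functional, annotations=annotations,
                                   reference_volumes=reference, extras=extras))
    return records


def write_manifest(records: list[StudyRecord], path: str | Path) -> Path:
    """Write records as a manifest CSV; paths are stored relative to the
    manifest's directory so the cohort folder stays relocatable."""
    import os

    path = Path(path)
    base = path.parent.resolve()

    def rel(p: str) -> str:
        return os.path.relpath(Path(p).resolve(), base)

    rows = []
    for s in records:
        row: dict[str, object] = {"study_id": s.study_id}
        for col, (group, key) in _MANIFEST_PATH_COLS.items():
            src = s.anatomical if group == "anatomical" else s.annotations
            row[col] = rel(src[key]) if key in src else ""
        for name, p in s.functional.items():
            row[f"path_func_{name}"] = rel(p)
        if s.reference_volumes is not None:
            row["ref_total_cm3"] = s.reference_volumes[0]
            row["ref_enhancing_cm3"] = s.reference_volumes[1]
        row.update(s.extras)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return path
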