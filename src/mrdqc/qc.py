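"""Automatic screening quantities surfaced next to the snapshot panels.

These are advisory pre-flags only: the quality calls in the review log are
human.  Three signals are computed per study:

* a normalization check — robust (0.5th/99.5th percentile) within-brain
  intensity range against the expected normalized range such as [-5, 5];
  isolated hot voxels are tolerated, a wholesale scale break is not;
* the fraction of tumor-segmentation foreground lying outside the brain
  mask (the cropped-field-of-view signature);
* segmented tumor volumes in cm^3: total over all nonzero labels and the
  T1-enhancing label alone.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from .niftiio import (
    GeometryError,
    LabelMap,
    StudyRecord,
    VoxelGrid,
    label_volume_cm3,
    read_label_map,
    read_volume,
    reorient_canonical,
    reorient_label_map,
    AbsentInputError,
    FormatError,
    TUMOR_LABEL_NAMES,
)
from .snapshots import RenderConfig, SnapshotSet, expected_panels, panel_filename

__all__ = ["StudyQC", "normalization_check", "seg_outside_mask", "tumor_volumes",
           "compute_study_qc", "qc_table"]


@dataclass
class StudyQC:
    """Per-study automatic screening results."""

    study_id: str
    intensity_stats: dict[str, tuple[float, float]] = field(default_factory=dict)
    normalization_flag: dict[str, bool | None] = field(default_factory=dict)
    tumor_total_cm3: float | None = None
    tumor_enhancing_cm3: float | None = None
    seg_outside_brain_fraction: float | None = None
    missing_panels: list[str] = field(default_factory=list)

    def any_normalization_flag(self) -> bool:
        return any(v is True for v in self.normalization_flag.values())

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=1))
        return path


def normalization_check(image: VoxelGrid, brain: LabelMap,
                        expected: tuple[float, float] = (-5.0, 5.0),
                        robust_pct: tuple[float, float] = (0.5, 99.5)
                        ) -> tuple[bool | None, tuple[float, float]]:
    """Flag an image whose robust in-brain intensity range escapes ``expected``.

    Returns ``(flag, (robust_low, robust_high))``.  An empty brain mask
    yields an indeterminate flag (``None``) with a warning.
    """
    if image.shape != brain.shape:
        raise GeometryError(f"image {image.shape} and brain mask {brain.shape} differ")
    lo_e, hi_e = expected
    if not lo_e < hi_e:
        raise ValueError("expected interval must have low < high")
    fg = brain.grid.data != 0
    if not fg.any():
        warnings.warn(f"{image.path or 'image'}: empty brain mask, normalization check indeterminate")
        return None, (float("nan"), float("nan"))
    lo, hi = np.percentile(image.data[fg], robust_pct)
    flag = bool(lo < lo_e or hi > hi_e)
    return flag, (float(lo), float(hi))


def seg_outside_mask(seg: LabelMap, brain: LabelMap) -> float:
    """Fraction of segmentation foreground falling on brain-mask background."""
    if seg.shape != brain.shape:
        raise GeometryError(f"seg {seg.shape} and brain mask {brain.shape} differ")
    fg = seg.grid.data != 0
    n = int(fg.sum())
    if n == 0:
        return 0.0
    outside = int((fg & (brain.grid.data == 0)).sum())
    return outside / n


def tumor_volumes(seg: LabelMap, label_roles: Mapping[int, str] | None = None
                  ) -> tuple[float, float | None]:
    """(total cm^3 over all nonzero labels, enhancing cm^3 or None).

    "Total" covers every nonzero label — the T2-FLAIR hyperintensity
    footprint of enhancing tumor, necrosis, and edema together.  The
    enhancing volume uses the label mapped to role ``"enhancing"``; if no
    label carries that role the enhancing volume is reported absent
    (``None``), not zero.
    """
    roles = dict(label_roles) if label_roles is not None else dict(seg.label_names)
    present = seg.labels_present()
    total = label_volume_cm3(seg, present) if present else 0.0
    enh_labels = [lab for lab, role in roles.items() if role == "enhancing"]
    if not enh_labels:
        return total, None
    return total, label_volume_cm3(seg, enh_labels)


def compute_study_qc(s: StudyRecord, snapshots: SnapshotSet | None = None,
                     expected: tuple[float, float] = (-5.0, 5.0),
                     robust_pct: tuple[float, float] = (0.5, 99.5),
                     snapshot_dir: str | Path | None = None,
                     render_config: RenderConfig | None = None) -> StudyQC:
    """Run all automatic checks for one study; missing inputs yield absent fields.

    ``missing_panels`` (the "No PNGs" feed) lists expected-but-unrendered
    panel files: from the snapshot statuses when a :class:`SnapshotSet` is
    given, else by checking the configured layout's expected inventory
    against ``snapshot_dir`` on disk; with neither, the list stays empty.
    """
    qc = StudyQC(study_id=s.study_id)

    brain: LabelMap | None = None
    if "brain_mask" in s.annotations:
        try:
            brain = reorient_label_map(read_label_map(s.annotations["brain_mask"]))
        except (AbsentInputError, FormatError):
            pass

    for mod, path in s.anatomical.items():
        try:
            img = reorient_canonical(read_volume(path))
        except (AbsentInputError, FormatError):
            continue
        if brain is None or brain.shape != img.shape:
            continue
        flag, stats = normalization_check(img, brain, expected, robust_pct)
        qc.normalization_flag[mod] = flag
        qc.intensity_stats[mod] = stats

    seg: LabelMap | None = None
    if "tumor_seg" in s.annotations:
        try:
            seg = reorient_label_map(read_label_map(s.annotations["tumor_seg"], TUMOR_LABEL_NAMES))
        except (AbsentInputError, FormatError):
            pass
    if seg is not None:
        total, enhancing = tumor_volumes(seg)
        qc.tumor_total_cm3 = total
        qc.tumor_enhancing_cm3 = enhancing
        if brain is not None and brain.shape == seg.shape:
            qc.seg_outside_brain_fraction = seg_outside_mask(seg, brain)

    if snapshots is not None:
        qc.missing_panels = snapshots.missing()
    elif snapshot_dir is not None:
        base = Path(snapshot_dir)
        qc.missing_panels = [
            fname for k, m, p in expected_panels(s, render_config or RenderConfig())
            if not (base / (fname := panel_filename(s.study_id, k, m, p))).exists()
        ]
    return qc


def qc_table(results: list[StudyQC]):
    """Flatten StudyQC results into one row per study for the report index."""
    import pandas as pd

    rows = []
    for qc in results:
        rows.append({
            "study_id": qc.study_id,
            "norm_flag_any": qc.any_normalization_flag(),
            "norm_flag_modalities": ",".join(m for m, v in qc.normalization_flag.items() if v),
            "tumor_total_cm3": qc.tumor_total_cm3,
            "tumor_enhancing_cm3": qc.tumor_enhancing_cm3,
            "seg_outside_brain_fraction": qc.seg_outside_brain_fraction,
            "n_missing_panels": len(qc.missing_panels),
        })
    return pd.DataFrame(rows)
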