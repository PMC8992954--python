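"""Synthetic multi-study phantom cohorts with injectable failure modes.

Every other module is testable without downloading any imaging data: this
module writes fully synthetic studies that have the statistical structure a
processed brain-tumor study presents to the reviewer — four co-registered
anatomical modalities with tissue-dependent contrast (enhancing tumor
bright on T1C, edema bright on T2/FLAIR, CSF bright on T2 and dark on
FLAIR), Gaussian noise, intensities z-score-normalized within the brain
mask, plus a binary brain mask, a three-label tumor segmentation
(1 = enhancing, 2 = necrosis, 3 = edema), and a small CSF ROI.

Anatomy is geometric (an ellipsoidal brain, spherical tumor compartments):
the toolkit tests rendering and accounting, not segmentation accuracy.
Six failure modes can be injected, each degrading exactly one artifact and
each mapping to exactly one review category:

==================  =======================================  ==================
mode                degradation                              review category
==================  =======================================  ==================
misregistration     one modality rotated about the axial     registration
                    axis and resampled on the same grid
bias_field          smooth multiplicative intensity ramp     bias field
normalization_break intensities scaled by a large factor     normalization
cropped_fov         top axial slices of all images and the   image quality
                    brain mask zeroed; tumor map untouched,
                    so the segmentation exits the brain
corrupt_seg         tumor map dilated and shifted            tumor segmentation
missing_file        one modality dropped from the manifest   no PNGs
==================  =======================================  ==================
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .niftiio import (
    StudyRecord,
    VoxelGrid,
    write_volume,
    write_manifest,
    TUMOR_LABEL_NAMES,
)
from .review import ReviewEntry

__all__ = ["PhantomParams", "FailureMode", "MODE_TO_REVIEW",
           "make_phantom_study", "inject_failure", "make_cohort", "truth_to_review"]


#: per-modality raw mean intensity per tissue class (arbitrary units,
#: z-normalized within brain afterwards)
TISSUE_MEANS = {
    "T1":    {"brain": 1.0, "csf": 0.3, "edema": 0.8, "enhancing": 0.9, "necrosis": 0.5},
    "T1C":   {"brain": 1.0, "csf": 0.3, "edema": 0.8, "enhancing": 1.8, "necrosis": 0.5},
    "T2":    {"brain": 1.0, "csf": 1.8, "edema": 1.6, "enhancing": 1.2, "necrosis": 1.4},
    "FLAIR": {"brain": 1.0, "csf": 0.2, "edema": 1.7, "enhancing": 1.2, "necrosis": 1.3},
}

FAILURE_MODES = ("misregistration", "bias_field", "normalization_break",
                 "cropped_fov", "corrupt_seg", "missing_file")

#: injected mode -> (review category or flag, see review.ReviewEntry)
MODE_TO_REVIEW = {
    "misregistration": ("quality", "registration"),
    "bias_field": ("flag", "bias_field"),
    "normalization_break": ("flag", "normalization_failure"),
    "cropped_fov": ("flag", "image_unusable"),
    "corrupt_seg": ("quality", "tumor_seg"),
    "missing_file": ("flag", "no_pngs"),
}


@dataclass
class PhantomParams:
    """Geometry, contrast, and noise of one synthetic study.

    Lengths are mm; the default grid is 64^3 at 3 mm isotropic spacing
    (192 mm field of view).  ``seed`` fixes every stochastic draw, so a
    study regenerates byte-identically.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    brain_semiaxes_mm: tuple[float, float, float] = (78.0, 90.0, 66.0)
    tumor_center_mm: tuple[float, float, float] = (18.0, 9.0, 21.0)  # offset from grid center
    edema_radius_mm: float = 27.0
    enhancing_radius_mm: float = 18.0
    necrosis_radius_mm: float = 9.0
    csf_radius_mm: float = 7.5
    csf_center_mm: tuple[float, float, float] = (-21.0, -15.0, 0.0)
    tissue_means: dict = field(default_factory=lambda: copy.deepcopy(TISSUE_MEANS))
    noise_sd: float = 0.2
    seed: int = 0


@dataclass
class FailureMode:
    """One failure mode with its magnitude parameters."""

    mode: str
    rotation_deg: float = 10.0
    bias_amplitude: float = 0.4
    scale_factor: float = 100.0
    crop_fraction: float = 0.3
    seg_dilate_voxels: int = 2
    seg_shift_voxels: int = 3
    target_modality: str = "FLAIR"

    def __post_init__(self) -> None:
        if self.mode not in FAILURE_MODES:
            raise ValueError(f"unknown failure mode {self.mode!r}; "
                             f"expected one of {FAILURE_MODES}")
        if not (0.0 < self.crop_fraction < 1.0):
            raise ValueError("crop_fraction must be in (0, 1)")


def _mm_grids(shape, spacing):
    center = [(n - 1) / 2.0 * s for n, s in zip(shape, spacing)]
    axes = [np.arange(n) * s - c for n, s, c in zip(shape, spacing, center)]
    return np.meshgrid(*axes, indexing="ij")


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def make_phantom_study(p: PhantomParams, out_dir: str | Path,
                       study_id: str = "phantom") -> tuple[StudyRecord, dict]:
    """Write one clean synthetic study; returns (record, truth).

    The truth dict records the applied parameters, per-label voxel counts,
    true volumes in cm^3, and ``injected_mode`` ("clean"); it is also
    written to ``{study_id}_truth.json`` next to the volumes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(p.seed)
    X, Y, Z = _mm_grids(p.shape, p.spacing)
    a, b, c = p.brain_semiaxes_mm
    brain = (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1.0

    tx, ty, tz = p.tumor_center_mm
    r2 = (X - tx) ** 2 + (Y - ty) ** 2 + (Z - tz) ** 2
    edema = (r2 <= p.edema_radius_mm ** 2) & brain
    enhancing = (r2 <= p.enhancing_radius_mm ** 2) & brain
    necrosis = (r2 <= p.necrosis_radius_mm ** 2) & brain
    tumor = np.zeros(p.shape, dtype=np.int16)
    tumor[edema] = 3
    tumor[enhancing & ~necrosis] = 1
    tumor[necrosis] = 2

    cx, cy, cz = p.csf_center_mm
    csf = ((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= p.csf_radius_mm ** 2) & brain
    csf = csf & (tumor == 0)

    aff = _affine(p.spacing)
    vox_mm3 = float(np.prod(p.spacing))
    anatomical: dict[str, str] = {}
    annotations: dict[str, str] = {}

    tissue_of = {"csf": csf, "edema": tumor == 3, "enhancing": tumor == 1,
                 "necrosis": tumor == 2}
    for mod in ("T1", "T1C", "T2", "FLAIR"):
        means = p.tissue_means[mod]
        img = np.zeros(p.shape, dtype=np.float64)
        img[brain] = means["brain"]
        for tissue, mask in tissue_of.items():
            img[mask] = means[tissue]
        img += rng.normal(0.0, p.noise_sd, size=p.shape)
        img[~brain] *= 0.05  # faint background, mostly air
        inb = img[brain]
        img = (img - inb.mean()) / inb.std()   # z-score within brain mask
        path = out_dir / f"{study_id}_{mod}.nii"
        write_volume(VoxelGrid(img.astype(np.float32), aff), path)
        anatomical[mod] = str(path)

    for role, arr in (("brain_mask", brain.astype(np.int16)),
                      ("tumor_seg", tumor),
                      ("csf_roi", csf.astype(np.int16))):
        path = out_dir / f"{study_id}_{role}.nii"
        write_volume(VoxelGrid(arr, aff), path)
        annotations[role] = str(path)

    record = StudyRecord(study_id=study_id, anatomical=anatomical,
                         annotations=annotations)

    label_counts = {str(lab): int((tumor == lab).sum()) for lab in (1, 2, 3)}
    total_vox = int((tumor != 0).sum())
    enh_vox = label_counts["1"]
    truth = {
        "study_id": study_id,
        "injected_mode": "clean",
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(p).items() if k != "tissue_means"},
        "voxel_volume_mm3": vox_mm3,
        "label_voxel_counts": label_counts,
        "brain_voxels": int(brain.sum()),
        "csf_voxels": int(csf.sum()),
        "true_total_cm3": total_vox * vox_mm3 / 1000.0,
        "true_enhancing_cm3": enh_vox * vox_mm3 / 1000.0,
    }
    (out_dir / f"{study_id}_truth.json").write_text(json.dumps(truth, indent=1))
    record.extras["truth_json"] = str(out_dir / f"{study_id}_truth.json")
    return record, truth


def _read_raw(path: str) -> tuple[np.ndarray, np.ndarray]:
    import nibabel as nib
    img = nib.load(path)
    return np.asarray(img.get_fdata()), np.asarray(img.affine)


def _write_raw(data: np.ndarray, affine: np.ndarray, path: str, dtype) -> None:
    write_volume(VoxelGrid(data.astype(dtype), affine), path)


def inject_failure(s: StudyRecord, f: FailureMode, seed: int = 0,
                   truth: dict | None = None) -> tuple[StudyRecord, dict]:
    """Degrade exactly one artifact of a written study, in place on disk.

    Returns a (modified record, updated truth) pair; the truth JSON next to
    the study is rewritten with the injected mode.  ``missing_file`` only
    edits the record (manifest view) — the file itself stays on disk, the
    study simply no longer references it.
    """
    s = copy.deepcopy(s)
    truth = dict(truth) if truth is not None else _load_truth(s)
    rng = np.random.default_rng(seed)

    if f.mode == "misregistration":
        path = s.anatomical[f.target_modality]
        data, aff = _read_raw(path)
        rot = ndimage.rotate(data, f.rotation_deg, axes=(0, 1), reshape=False,
                             order=1, mode="constant", cval=float(data.min()))
        _write_raw(rot, aff, path, np.float32)
    elif f.mode == "bias_field":
        path = s.anatomical[f.target_modality]
        data, aff = _read_raw(path)
        u = np.linspace(-1.0, 1.0, data.shape[0])[:, None, None]
        v = np.linspace(-1.0, 1.0, data.shape[1])[None, :, None]
        field = 1.0 + f.bias_amplitude * 0.5 * (u + v)  # smooth diagonal ramp
        _write_raw(data * field, aff, path, np.float32)
    elif f.mode == "normalization_break":
        path = s.anatomical[f.target_modality]
        data, aff = _read_raw(path)
        _write_raw(data * f.scale_factor, aff, path, np.float32)
    elif f.mode == "cropped_fov":
        n_keep = None
        for path in list(s.anatomical.values()) + [s.annotations["brain_mask"]]:
            data, aff = _read_raw(path)
            nk = data.shape[2]
            n_crop = max(1, int(round(nk * f.crop_fraction)))
            n_keep = nk - n_crop
            data[:, :, n_keep:] = 0
            dtype = np.int16 if path == s.annotations["brain_mask"] else np.float32
            _write_raw(data, aff, path, dtype)
        truth["cropped_from_slice"] = n_keep
    elif f.mode == "corrupt_seg":
        path = s.annotations["tumor_seg"]
        data, aff = _read_raw(path)
        lab = np.rint(data).astype(np.int16)
        size = 2 * f.seg_dilate_voxels + 1
        lab = ndimage.grey_dilation(lab, size=(size, size, size))
        lab = np.roll(lab, f.seg_shift_voxels, axis=0)
        _write_raw(lab, aff, path, np.int16)
        vox_mm3 = truth.get("voxel_volume_mm3", float(abs(np.linalg.det(aff[:3, :3]))))
        truth["corrupt_total_cm3"] = int((lab != 0).sum()) * vox_mm3 / 1000.0
    elif f.mode == "missing_file":
        s.anatomical.pop(f.target_modality, None)

    truth["injected_mode"] = f.mode
    truth["failure_params"] = asdict(f)
    tj = s.extras.get("truth_json")
    if tj:
        Path(tj).write_text(json.dumps(truth, indent=1))
    return s, truth


def _load_truth(s: StudyRecord) -> dict:
    tj = s.extras.get("truth_json")
    if tj and Path(tj).exists():
        return json.loads(Path(tj).read_text())
    return {"study_id": s.study_id, "injected_mode": "clean"}


def make_cohort(n: int, mode_rates: dict[str, float], seed: int,
                out_dir: str | Path,
                params: PhantomParams | None = None,
                reference_error_sd_cm3: float = 5.0,
                failure_overrides: dict[str, FailureMode] | None = None
                ) -> tuple[Path, Path]:
    """Generate ``n`` independent studies, each clean or given one failure mode.

    Each study is drawn clean with probability ``1 - sum(mode_rates)`` or
    assigned a single mode with its stated probability.  Reference tumor
    volumes for the scatter/RMSE machinery are the true volumes plus
    Gaussian error of sd ``reference_error_sd_cm3``.  Writes
    ``manifest.csv`` and ``truth.csv`` under ``out_dir`` and returns their
    paths.
    """
    rates = dict(mode_rates)
    bad = set(rates) - set(FAILURE_MODES)
    if bad:
        raise ValueError(f"unknown failure modes: {sorted(bad)}")
    if any(not 0.0 <= r <= 1.0 for r in rates.values()) or sum(rates.values()) > 1.0 + 1e-12:
        raise ValueError("mode rates must be probabilities summing to <= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    template = params or PhantomParams()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n)
    assign_rng = np.random.default_rng(ss.spawn(1)[0])
    modes = list(rates)
    cum = np.cumsum([rates[m] for m in modes])

    records: list[StudyRecord] = []
    truth_rows: list[dict] = []
    for i, child in enumerate(children):
        sid = f"study_{i:03d}"
        child_ints = child.generate_state(2)
        p = replace(template, seed=int(child_ints[0] % (2 ** 31)))
        rec, truth = make_phantom_study(p, out_dir / sid, study_id=sid)
        u = assign_rng.uniform()
        mode = "clean"
        for m, edge in zip(modes, cum):
            if u < edge:
                mode = m
                break
        if mode != "clean":
            fm = (failure_overrides or {}).get(mode, FailureMode(mode=mode))
            rec, truth = inject_failure(rec, fm, seed=int(child_ints[1] % (2 ** 31)),
                                        truth=truth)
        ref_total = truth["true_total_cm3"] + assign_rng.normal(0, reference_error_sd_cm3)
        ref_enh = truth["true_enhancing_cm3"] + assign_rng.normal(0, reference_error_sd_cm3)
        rec.reference_volumes = (round(float(ref_total), 4), round(float(ref_enh), 4))
        records.append(rec)
        truth_rows.append({
            "study_id": sid,
            "injected_mode": truth["injected_mode"],
            "true_total_cm3": truth["true_total_cm3"],
            "true_enhancing_cm3": truth["true_enhancing_cm3"],
            "ref_total_cm3": rec.reference_volumes[0],
            "ref_enhancing_cm3": rec.reference_volumes[1],
        })

    import pandas as pd
    manifest_path = write_manifest(records, out_dir / "manifest.csv")
    truth_path = out_dir / "truth.csv"
    pd.DataFrame(truth_rows).to_csv(truth_path, index=False)
    return manifest_path, truth_path


def truth_to_review(truth_rows, reviewer: str = "oracle",
                    timestamp: str = "2020-01-01T00:00:00+00:00") -> list[ReviewEntry]:
    """Oracle reviewer: convert injected truth labels into review entries.

    Each injected failure mode marks exactly its corresponding review
    category as failed (or sets its flag); clean studies review as fully
    acceptable.  Used to close the loop between the generator and the
    review aggregation.
    """
    entries = []
    for row in truth_rows:
        mode = row["injected_mode"]
        quality: dict[str, str] = {}
        flags: dict[str, bool] = {}
        if mode != "clean":
            kind, name = MODE_TO_REVIEW[mode]
            if kind == "quality":
                quality[name] = "fail"
            else:
                flags[name] = True
        entries.append(ReviewEntry(study_id=row["study_id"], reviewer=reviewer,
                                   timestamp=timestamp, quality=quality, flags=flags))
    return entries
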