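"""Pre-rendered static snapshot panels for each study.

The review workflow trades free slice scrolling for speed: a handful of
key slices per study are rendered once, up front, and the reviewer only
ever looks at those rasters.  The slice shown for a segmentation overlay
is the one with the largest in-plane segmentation area; registration
panels reuse the *brain mask's* slice indices on every co-registered
modality so a misregistered volume is visually obvious.

Display convention (fixed, documented, changeable via the functions in
this module): volumes are rendered in canonical RAS+ order; axial panels
put anterior at the top with the patient's left on the viewer's right
(radiological style); sagittal and coronal panels put superior at the top.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from scipy import ndimage

from .niftiio import (
    ANATOMICAL_MODALITIES,
    GeometryError,
    LabelMap,
    StudyRecord,
    VoxelGrid,
    read_label_map,
    read_volume,
    reorient_canonical,
    reorient_label_map,
    AbsentInputError,
    FormatError,
    TUMOR_LABEL_NAMES,
)

__all__ = [
    "PLANE_AXES",
    "PanelSpec",
    "SnapshotSet",
    "RenderConfig",
    "max_area_slice",
    "window_for_display",
    "composite_overlay",
    "crosshair_target",
    "render_density_panel",
    "render_study",
    "expected_panels",
]

#: anatomical plane -> array axis in RAS+ order
PLANE_AXES = {"sagittal": 0, "coronal": 1, "axial": 2}
PLANES = ("axial", "sagittal", "coronal")

# fixed color-blind-aware palette, RGB in [0, 1]
PALETTE = {
    "brain_mask": (1.0, 0.9, 0.0),   # yellow, drawn as contour
    "tumor_1": (0.9, 0.1, 0.1),      # enhancing: red
    "tumor_2": (0.1, 0.8, 0.1),      # necrosis: green
    "tumor_3": (0.2, 0.4, 1.0),      # edema: blue
    "csf_roi": (0.0, 0.9, 0.9),      # cyan
    "crosshair": (1.0, 0.5, 0.0),
}


@dataclass
class RenderConfig:
    """Tunable rendering parameters.

    window_pct
        Percentile pair for grayscale display windowing, applied per slice
        to within-brain voxels when a brain mask is available (robust to
        hot artifact voxels — the very thing the panels exist to reveal).
    alpha
        Overlay opacity for filled label overlays.
    expected_range
        Normalized-intensity endpoints annotated on density panels.
    scale
        Integer nearest-neighbour upscale factor for panel PNGs.
    """

    window_pct: tuple[float, float] = (1.0, 99.0)
    alpha: float = 0.4
    expected_range: tuple[float, float] = (-5.0, 5.0)
    density_bins: int = 100
    scale: int = 3
    modalities: tuple[str, ...] = ANATOMICAL_MODALITIES
    registration_planes: tuple[str, ...] = ("axial", "sagittal")


@dataclass
class PanelSpec:
    """One rendered (or skipped) snapshot panel."""

    kind: str        # three_plane_overlay | registration_check | csf_confirm | density | crosshair
    modality: str    # modality name, annotation role, or functional-map name
    plane: str       # axial | sagittal | coronal | all
    path: str
    status: str = "rendered"   # rendered | skipped_missing_input | failed
    slice_index: int | None = None


@dataclass
class SnapshotSet:
    """All panels rendered (or attempted) for one study."""

    study_id: str
    panels: list[PanelSpec] = field(default_factory=list)

    def by_kind(self, kind: str) -> list[PanelSpec]:
        return [p for p in self.panels if p.kind == kind]

    def missing(self) -> list[str]:
        return [p.path for p in self.panels if p.status != "rendered"]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {"study_id": self.study_id, "panels": [asdict(p) for p in self.panels]}
        path.write_text(json.dumps(payload, indent=1))
        return path


# ---------------------------------------------------------------------------
# slice selection and 2D primitives

def max_area_slice(m: LabelMap, plane: str) -> int:
    """Index along ``plane`` of the slice with the most foreground voxels.

    Ties break to the lowest index; an empty map falls back to the middle
    slice (floor of the dimension / 2) so a panel is always produced.
    """
    axis = PLANE_AXES[plane]
    fg = m.grid.data != 0
    other = tuple(a for a in range(3) if a != axis)
    areas = fg.sum(axis=other)
    if areas.max() == 0:
        return m.shape[axis] // 2
    return int(np.argmax(areas))


def window_for_display(slice2d: np.ndarray, lo_pct: float = 1.0, hi_pct: float = 99.0,
                       within: np.ndarray | None = None) -> np.ndarray:
    """Percentile-windowed grayscale in [0, 1]; constant input maps to zeros.

    ``within`` optionally restricts the percentile computation (not the
    output) to a boolean mask, e.g. within-brain voxels.
    """
    if not (0 <= lo_pct < hi_pct <= 100):
        raise ValueError("require 0 <= lo_pct < hi_pct <= 100")
    slice2d = np.asarray(slice2d, dtype=float)
    sample = slice2d[within] if within is not None and within.any() else slice2d
    lo, hi = np.percentile(sample, [lo_pct, hi_pct])
    if hi <= lo:
        return np.zeros_like(slice2d)
    return np.clip((slice2d - lo) / (hi - lo), 0.0, 1.0)


def composite_overlay(gray: np.ndarray, labels: Sequence[tuple[np.ndarray, tuple]],
                      alpha: float = 0.4) -> np.ndarray:
    """Blend colored masks over a grayscale slice; later masks win overlaps."""
    gray = np.asarray(gray, dtype=float)
    rgb = np.repeat(gray[..., None], 3, axis=2)
    for mask, color in labels:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != gray.shape:
            raise GeometryError(f"mask shape {mask.shape} != image shape {gray.shape}")
        color = np.asarray(color, dtype=float)
        rgb[mask] = (1.0 - alpha) * rgb[mask] + alpha * color
    return rgb


def mask_contour(mask: np.ndarray) -> np.ndarray:
    """1-pixel inner contour of a 2D boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask
    return mask & ~ndimage.binary_erosion(mask)


def crosshair_target(image: VoxelGrid, roi: LabelMap) -> tuple[int, int, int]:
    """Voxel index of the maximum image intensity inside the ROI.

    Ties break to the lexicographically smallest index; an empty ROI falls
    back to the image center.
    """
    if image.shape != roi.shape:
        raise GeometryError(f"image {image.shape} and roi {roi.shape} differ")
    fg = roi.grid.data != 0
    if not fg.any():
        return tuple(s // 2 for s in image.shape)  # type: ignore[return-value]
    vals = np.where(fg, image.data, -np.inf)
    flat = int(np.argmax(vals))  # first occurrence in C order = lexicographic min
    return tuple(int(i) for i in np.unravel_index(flat, image.shape))  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# 2D display extraction

def display_slice(data: np.ndarray, plane: str, index: int) -> np.ndarray:
    """Extract one slice from RAS-ordered data in display orientation.

    axial: rows anterior->posterior top-down, patient left on viewer right;
    coronal: rows superior->inferior, patient left on viewer right;
    sagittal: rows superior->inferior, anterior on viewer right.
    """
    axis = PLANE_AXES[plane]
    sl = np.take(data, index, axis=axis)
    if plane == "axial":      # remaining axes (R, A)
        return np.flipud(np.fliplr(sl.T))
    if plane == "coronal":    # remaining axes (R, S)
        return np.fliplr(np.flipud(sl.T))
    return np.flipud(sl.T)    # sagittal: remaining axes (A, S)


def _save_png(rgb: np.ndarray, path: Path, scale: int) -> None:
    arr = np.clip(rgb * 255.0, 0, 255).astype(np.uint8)
    if scale > 1:
        arr = np.repeat(np.repeat(arr, scale, axis=0), scale, axis=1)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(arr).save(path)


# ---------------------------------------------------------------------------
# density panel (matplotlib, Agg, deterministic metadata)

def render_density_panel(image: VoxelGrid, regions: Sequence[tuple[LabelMap, str, tuple]],
                         path: str | Path, expected_range: tuple[float, float] = (-5.0, 5.0),
                         bins: int = 100) -> PanelSpec:
    """Unit-peak intensity histograms of each segmented region.

    Each region's histogram is rescaled so its own maximum is 1: curve
    shapes are comparable, not masses.  Vertical lines mark the expected
    normalized-intensity endpoints, e.g. [-5, 5]; in-brain intensities
    straying past them are the normalization-failure signature.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    path = Path(path)
    nonempty = [(m, name, color) for m, name, color in regions if (m.grid.data != 0).any()]
    if not nonempty:
        return PanelSpec(kind="density", modality=path.stem, plane="all",
                         path=str(path), status="skipped_missing_input")
    pooled = np.concatenate([image.data[m.grid.data != 0] for m, _, _ in nonempty])
    lo, hi = float(pooled.min()), float(pooled.max())
    if hi <= lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, bins + 1)
    fig, ax = plt.subplots(figsize=(4, 2.5), dpi=100)
    for m, name, color in nonempty:
        vals = image.data[m.grid.data != 0]
        counts, _ = np.histogram(vals, bins=edges)
        peak = counts.max()
        centers = 0.5 * (edges[:-1] + edges[1:])
        ax.plot(centers, counts / peak if peak else counts, color=color, label=name, lw=1.2)
    for x in expected_range:
        ax.axvline(x, color="0.4", ls="--", lw=0.8)
    ax.set_ylim(0, 1.08)
    ax.set_xlabel("normalized intensity")
    ax.set_ylabel("scaled density")
    ax.legend(fontsize=6, loc="upper right")
    fig.tight_layout()
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, metadata={"Date": None, "Software": None})
    plt.close(fig)
    return PanelSpec(kind="density", modality=path.stem, plane="all", path=str(path))


# ---------------------------------------------------------------------------
# study-level orchestration

def panel_filename(study_id: str, kind: str, modality: str, plane: str) -> str:
    return f"{study_id}_{kind}_{modality}_{plane}.png"


def expected_panels(s: StudyRecord, config: RenderConfig | None = None) -> list[tuple[str, str, str]]:
    """(kind, modality, plane) inventory the configured layout implies."""
    cfg = config or RenderConfig()
    out: list[tuple[str, str, str]] = []
    for role in ("brain_mask", "tumor_seg", "csf_roi"):
        for plane in PLANES:
            out.append(("three_plane_overlay", role, plane))
    for mod in cfg.modalities:
        for plane in cfg.registration_planes:
            out.append(("registration_check", mod, plane))
    for mod in cfg.modalities:
        out.append(("csf_confirm", mod, "axial"))
    for mod in cfg.modalities:
        out.append(("density", mod, "all"))
    for name in s.functional:
        for plane in PLANES:
            out.append(("crosshair", name, plane))
    return out


def _load_gray(path: str) -> VoxelGrid:
    return reorient_canonical(read_volume(path))


def _tumor_overlays(tumor: LabelMap, sl_fn) -> list[tuple[np.ndarray, tuple]]:
    out = []
    for lab in sorted(tumor.labels_present()):
        color = PALETTE.get(f"tumor_{lab}", PALETTE["tumor_3"])
        out.append((sl_fn(tumor.grid.data == lab), color))
    return out


def render_study(s: StudyRecord, out_dir: str | Path,
                 config: RenderConfig | None = None) -> SnapshotSet:
    """Render every configured panel for one study; never abort the study.

    Missing input files produce panels with status ``skipped_missing_input``;
    unexpected per-panel errors are recorded as ``failed``.  A JSON sidecar
    ``{study_id}_snapshots.json`` listing all panels is written alongside
    the PNGs.
    """
    cfg = config or RenderConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    snaps = SnapshotSet(study_id=s.study_id)

    # load what exists once; record what does not
    images: dict[str, VoxelGrid] = {}
    for mod, p in {**s.anatomical, **s.functional}.items():
        try:
            images[mod] = _load_gray(p)
        except (AbsentInputError, FormatError):
            pass
    annots: dict[str, LabelMap] = {}
    for role, p in s.annotations.items():
        try:
            names = TUMOR_LABEL_NAMES if role == "tumor_seg" else None
            annots[role] = reorient_label_map(read_label_map(p, names))
        except (AbsentInputError, FormatError):
            pass

    ref_mod = s.reference_anatomical()
    ref_img = images.get(ref_mod)
    brain = annots.get("brain_mask")
    brain_fg = brain.grid.data != 0 if brain is not None else None

    def window(img: VoxelGrid, plane: str, idx: int) -> np.ndarray:
        sl = display_slice(img.data, plane, idx)
        within = None
        if brain_fg is not None and brain_fg.shape == img.data.shape:
            within = display_slice(brain_fg, plane, idx).astype(bool)
        return window_for_display(sl, *cfg.window_pct, within=within)

    def emit(kind: str, modality: str, plane: str, render_fn, idx: int | None = None) -> None:
        fname = panel_filename(s.study_id, kind, modality, plane)
        spec = PanelSpec(kind=kind, modality=modality, plane=plane,
                         path=str(out_dir / fname), slice_index=idx)
        if render_fn is None:
            spec.status = "skipped_missing_input"
        else:
            try:
                render_fn(out_dir / fname)
            except AbsentInputError:
                spec.status = "skipped_missing_input"
            except Exception:
                spec.status = "failed"
        snaps.panels.append(spec)

    # (a) three-plane overlay of each annotation over the reference image,
    # at that annotation's own max-area slices
    for role in ("brain_mask", "tumor_seg", "csf_roi"):
        ann = annots.get(role)
        for plane in PLANES:
            if ann is None or ref_img is None or ann.shape != ref_img.shape:
                emit("three_plane_overlay", role, plane, None)
                continue
            idx = max_area_slice(ann, plane)

            def draw(path, ann=ann, role=role, plane=plane, idx=idx):
                gray = window(ref_img, plane, idx)
                sl = lambda a: display_slice(a, plane, idx).astype(bool)
                if role == "brain_mask":
                    overlays = [(mask_contour(sl(ann.grid.data != 0)), PALETTE["brain_mask"])]
                    rgb = composite_overlay(gray, overlays, alpha=1.0)
                elif role == "tumor_seg":
                    rgb = composite_overlay(gray, _tumor_overlays(ann, sl), alpha=cfg.alpha)
                else:
                    rgb = composite_overlay(gray, [(sl(ann.grid.data != 0), PALETTE["csf_roi"])],
                                            alpha=cfg.alpha)
                _save_png(rgb, path, cfg.scale)

            emit("three_plane_overlay", role, plane, draw, idx)

    # (b) per-modality registration check: brain-mask contour at the brain
    # mask's max-area slices — identical indices across co-registered
    # modalities, so a rotated volume visibly disagrees with the contour
    reg_idx = {plane: (max_area_slice(brain, plane) if brain is not None
                       else None) for plane in cfg.registration_planes}
    for mod in cfg.modalities:
        img = images.get(mod)
        for plane in cfg.registration_planes:
            idx = reg_idx[plane]
            if img is None or brain is None or idx is None or img.shape != brain.shape:
                emit("registration_check", mod, plane, None)
                continue

            def draw(path, img=img, plane=plane, idx=idx):
                gray = window(img, plane, idx)
                contour = mask_contour(display_slice(brain.grid.data != 0, plane, idx).astype(bool))
                _save_png(composite_overlay(gray, [(contour, PALETTE["brain_mask"])], alpha=1.0),
                          path, cfg.scale)

            emit("registration_check", mod, plane, draw, idx)

    # (c) CSF-ROI confirmation on every modality, at the CSF max-area slice
    csf = annots.get("csf_roi")
    csf_idx = max_area_slice(csf, "axial") if csf is not None else None
    for mod in cfg.modalities:
        img = images.get(mod)
        if img is None or csf is None or img.shape != csf.shape:
            emit("csf_confirm", mod, "axial", None)
            continue

        def draw(path, img=img, idx=csf_idx):
            gray = window(img, "axial", idx)
            fg = display_slice(csf.grid.data != 0, "axial", idx).astype(bool)
            _save_png(composite_overlay(gray, [(fg, PALETTE["csf_roi"])], alpha=cfg.alpha),
                      path, cfg.scale)

        emit("csf_confirm", mod, "axial", draw, csf_idx)

    # (d) density panel per modality over the segmented regions
    for mod in cfg.modalities:
        img = images.get(mod)
        regions: list[tuple[LabelMap, str, tuple]] = []
        if brain is not None:
            regions.append((brain, "brain", (0.3, 0.3, 0.3)))
        tumor = annots.get("tumor_seg")
        if tumor is not None:
            for lab in sorted(tumor.labels_present()):
                sub = LabelMap(grid=VoxelGrid((tumor.grid.data == lab).astype(np.int16),
                                              tumor.grid.affine),
                               label_names={1: "foreground"})
                regions.append((sub, tumor.label_names.get(lab, f"label {lab}"),
                                PALETTE.get(f"tumor_{lab}", PALETTE["tumor_3"])))
        if csf is not None:
            regions.append((csf, "csf", PALETTE["csf_roi"]))
        if img is None or not regions or any(r.shape != img.shape for r, _, _ in regions):
            emit("density", mod, "all", None)
            continue

        def draw(path, img=img, regions=regions):
            spec = render_density_panel(img, regions, path,
                                        expected_range=cfg.expected_range,
                                        bins=cfg.density_bins)
            if spec.status != "rendered":
                raise AbsentInputError("all regions empty")

        emit("density", mod, "all", draw)

    # (e) crosshair three-plane panels for each functional map, centered on
    # the maximum-intensity voxel inside the tumor ROI
    tumor = annots.get("tumor_seg")
    for name in s.functional:
        img = images.get(name)
        target = None
        if img is not None and tumor is not None and img.shape == tumor.shape:
            target = crosshair_target(img, tumor)
        for plane in PLANES:
            if target is None or img is None:
                emit("crosshair", name, plane, None)
                continue
            idx = target[PLANE_AXES[plane]]

            def draw(path, img=img, plane=plane, target=target, idx=idx):
                gray = window(img, plane, idx)
                rgb = np.repeat(gray[..., None], 3, axis=2)
                r, c = _display_rowcol(img.data.shape, plane, target)
                rgb[r, :, :] = PALETTE["crosshair"]
                rgb[:, c, :] = PALETTE["crosshair"]
                _save_png(rgb, path, cfg.scale)

            emit("crosshair", name, plane, draw, idx)

    snaps.to_json(out_dir / f"{s.study_id}_snapshots.json")
    return snaps


def _display_rowcol(shape: tuple[int, int, int], plane: str,
                    voxel: tuple[int, int, int]) -> tuple[int, int]:
    """Display-space (row, col) of a voxel within a plane's slice image."""
    i, j, k = voxel
    ni, nj, nk = shape
    if plane == "axial":      # rows: flipped A, cols: flipped R
        return nj - 1 - j, ni - 1 - i
    if plane == "coronal":    # rows: flipped S, cols: flipped R
        return nk - 1 - k, ni - 1 - i
    return nk - 1 - k, j      # sagittal: rows flipped S, cols A
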