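"""Static HTML review gallery assembled from pre-rendered panels.

The output is a fully serverless directory tree: an index page with a
client-side searchable/sortable table of studies and one page per case
laying out the snapshot panels, the automatic QC values, and the current
review state, with previous/next navigation.  Review entry happens by
editing the review CSV (or via the CLI), never in the browser — the CSV is
the source of truth.
"""

from __future__ import annotations

import html
import json
import shutil
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .niftiio import StudyRecord
from .qc import StudyQC
from .review import ReviewEntry, classify_combined
from .snapshots import SnapshotSet, PanelSpec

__all__ = ["ReportConfig", "build_case_page", "build_index", "build_scatter", "build_site"]

#: panel kinds in default page order
DEFAULT_LAYOUT = ("three_plane_overlay", "registration_check", "csf_confirm",
                  "density", "crosshair")

_CSS = """
body { font-family: sans-serif; margin: 1em; background: #fafafa; }
table { border-collapse: collapse; } th, td { border: 1px solid #ccc; padding: 4px 8px; }
th { cursor: pointer; background: #eee; }
.panel-row img { margin: 2px; border: 1px solid #999; max-height: 220px; }
.placeholder { display: inline-block; width: 192px; height: 192px; background: #ddd;
  color: #a00; text-align: center; line-height: 192px; border: 1px dashed #a00;
  margin: 2px; font-size: 0.8em; }
.qc { background: #fff; border: 1px solid #ccc; padding: 0.5em; margin: 0.5em 0; }
.flag { color: #a00; font-weight: bold; }
nav a { margin-right: 1.5em; }
"""

_TABLE_JS = """
function filterRows() {
  var q = document.getElementById('search').value.toLowerCase();
  var rows = document.querySelectorAll('#idx tbody tr');
  rows.forEach(function(r) {
    r.style.display = r.textContent.toLowerCase().indexOf(q) >= 0 ? '' : 'none';
  });
}
function sortBy(col) {
  var tb = document.querySelector('#idx tbody');
  var rows = Array.from(tb.querySelectorAll('tr'));
  var asc = tb.dataset.sortCol == col && tb.dataset.sortAsc != '1';
  rows.sort(function(a, b) {
    var x = a.cells[col].textContent, y = b.cells[col].textContent;
    var nx = parseFloat(x), ny = parseFloat(y);
    var c = (!isNaN(nx) && !isNaN(ny)) ? nx - ny : x.localeCompare(y);
    return asc ? c : -c;
  });
  rows.forEach(function(r) { tb.appendChild(r); });
  tb.dataset.sortCol = col; tb.dataset.sortAsc = asc ? '1' : '0';
}
"""


@dataclass
class ReportConfig:
    """Layout options for the static site."""

    layout: tuple[str, ...] = DEFAULT_LAYOUT
    include_scatter: bool = True
    table_columns: tuple[str, ...] = ()   # () = all manifest extras + QC columns


def _page(title: str, body: str, extra_head: str = "") -> str:
    return (f"<!DOCTYPE html><html><head><meta charset='utf-8'>"
            f"<title>{html.escape(title)}</title><style>{_CSS}</style>{extra_head}"
            f"</head><body>{body}</body></html>")


def _panel_img(p: PanelSpec, rel: str) -> str:
    label = html.escape(f"{p.kind} {p.modality} {p.plane}")
    if p.status != "rendered":
        return f"<span class='placeholder' title='{label}'>missing<br>{label}</span>"
    return (f"<img src='{html.escape(rel)}' alt='{label}' title='{label}'>")


def build_case_page(s: StudyRecord, snaps: SnapshotSet, qc: StudyQC | None,
                    entry: ReviewEntry | None, out_path: str | Path,
                    panel_rel_dir: str = "panels",
                    prev_id: str | None = None, next_id: str | None = None,
                    config: ReportConfig | None = None) -> Path:
    """Write one self-contained case page; missing panels become placeholders."""
    cfg = config or ReportConfig()
    out_path = Path(out_path)
    parts = [f"<h1>{html.escape(s.study_id)}</h1>", "<nav>"]
    parts.append("<a href='index.html'>index</a>")
    if prev_id:
        parts.append(f"<a href='{html.escape(prev_id)}.html'>&laquo; prev</a>")
    if next_id:
        parts.append(f"<a href='{html.escape(next_id)}.html'>next &raquo;</a>")
    parts.append("</nav>")

    if qc is not None:
        flagged = [m for m, v in qc.normalization_flag.items() if v]
        rows = [
            ("tumor total (cm&sup3;)", f"{qc.tumor_total_cm3:.2f}" if qc.tumor_total_cm3 is not None else "&mdash;"),
            ("tumor enhancing (cm&sup3;)", f"{qc.tumor_enhancing_cm3:.2f}" if qc.tumor_enhancing_cm3 is not None else "&mdash;"),
            ("seg outside brain", f"{qc.seg_outside_brain_fraction:.1%}" if qc.seg_outside_brain_fraction is not None else "&mdash;"),
            ("normalization flags", ("<span class='flag'>" + ", ".join(flagged) + "</span>") if flagged else "none"),
            ("missing panels", f"<span class='flag'>{len(qc.missing_panels)}</span>" if qc.missing_panels else "0"),
        ]
        parts.append("<div class='qc'><b>automatic QC</b><table>")
        parts.extend(f"<tr><td>{k}</td><td>{v}</td></tr>" for k, v in rows)
        parts.append("</table></div>")

    parts.append("<div class='qc'><b>review</b> ")
    if entry is None:
        parts.append("<i>unreviewed</i></div>")
    else:
        cls = classify_combined(entry)
        qual = ", ".join(f"{c}: {v}" for c, v in entry.quality.items())
        set_flags = [f for f, v in entry.flags.items() if v]
        parts.append(f"combined: <b>{cls}</b><br>{html.escape(qual)}<br>"
                     f"flags: {html.escape(', '.join(set_flags) or 'none')}<br>"
                     f"comment: {html.escape(entry.comment or '')}</div>")

    for kind in cfg.layout:
        panels = snaps.by_kind(kind)
        if not panels:
            continue
        parts.append(f"<h2>{html.escape(kind.replace('_', ' '))}</h2><div class='panel-row'>")
        for p in panels:
            rel = f"{panel_rel_dir}/{Path(p.path).name}"
            parts.append(_panel_img(p, rel))
        parts.append("</div>")

    out_path.write_text(_page(s.study_id, "".join(parts)))
    return out_path


def build_index(records: list[StudyRecord], qc_rows: dict[str, StudyQC],
                log: dict[str, ReviewEntry], out_path: str | Path,
                scatter_rel: str | None = None,
                config: ReportConfig | None = None) -> Path:
    """Write the index page: one searchable/sortable row per study."""
    out_path = Path(out_path)
    extra_cols: list[str] = []
    for s in records:
        for k in s.extras:
            if k != "truth_json" and k not in extra_cols:
                extra_cols.append(k)
    cols = ["study_id"] + extra_cols + ["tumor_total_cm3", "seg_outside", "norm_flag", "review"]
    head = "".join(f"<th onclick='sortBy({i})'>{html.escape(c)}</th>" for i, c in enumerate(cols))
    body_rows = []
    for s in records:
        qc = qc_rows.get(s.study_id)
        e = log.get(s.study_id)
        cells = [f"<a href='{html.escape(s.study_id)}.html'>{html.escape(s.study_id)}</a>"]
        cells += [html.escape(str(s.extras.get(k, ""))) for k in extra_cols]
        cells.append(f"{qc.tumor_total_cm3:.2f}" if qc and qc.tumor_total_cm3 is not None else "")
        cells.append(f"{qc.seg_outside_brain_fraction:.2%}" if qc and qc.seg_outside_brain_fraction is not None else "")
        cells.append("yes" if qc and qc.any_normalization_flag() else "")
        cells.append(classify_combined(e) if e is not None else "unreviewed")
        body_rows.append("<tr>" + "".join(f"<td>{c}</td>" for c in cells) + "</tr>")
    body = [f"<h1>Review gallery ({len(records)} studies)</h1>"]
    if scatter_rel:
        body.append(f"<img src='{html.escape(scatter_rel)}' alt='volume agreement scatter' style='max-width:480px'>")
    body.append("<p><input id='search' onkeyup='filterRows()' placeholder='search...'></p>")
    body.append(f"<table id='idx'><thead><tr>{head}</tr></thead><tbody>"
                + "".join(body_rows) + "</tbody></table>")
    out_path.write_text(_page("Review gallery", "".join(body),
                              extra_head=f"<script>{_TABLE_JS}</script>"))
    return out_path


def build_scatter(measured: dict[str, float], reference: dict[str, float],
                  out_path: str | Path, highlight: str | None = None,
                  title: str = "segmented vs reference tumor volume") -> Path | None:
    """Scatter of measured vs reference volumes with an identity line.

    The dashed identity line marks perfect agreement; an optionally
    highlighted study is drawn as a distinct marker.  Returns None (skipped,
    with a warning) when no study has both values.
    """
    import warnings
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    ids = sorted(set(measured) & set(reference))
    if not ids:
        warnings.warn("no paired volumes; scatter skipped")
        return None
    x = np.array([reference[i] for i in ids])
    y = np.array([measured[i] for i in ids])
    fig, ax = plt.subplots(figsize=(4, 4), dpi=100)
    ax.scatter(x, y, s=14, c="#336699", alpha=0.7, label="studies")
    lim = (min(0.0, x.min(), y.min()), max(x.max(), y.max()) * 1.05 + 1e-9)
    ax.plot(lim, lim, "k--", lw=1, label="agreement")
    if highlight in ids:
        ax.scatter([reference[highlight]], [measured[highlight]], s=80,
                   facecolors="none", edgecolors="#cc2200", lw=2, label=highlight)
    ax.set_xlabel("reference volume (cm$^3$)")
    ax.set_ylabel("segmented volume (cm$^3$)")
    ax.set_title(title, fontsize=9)
    ax.legend(fontsize=7)
    fig.tight_layout()
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, metadata={"Date": None, "Software": None})
    plt.close(fig)
    return out_path


def build_site(records: list[StudyRecord], snapshot_dir: str | Path,
               qc_results: list[StudyQC], log: list[ReviewEntry],
               out_dir: str | Path, config: ReportConfig | None = None) -> Path:
    """Assemble the full static site: index, case pages, copied panels, scatter."""
    cfg = config or ReportConfig()
    out_dir = Path(out_dir)
    panels_dir = out_dir / "panels"
    panels_dir.mkdir(parents=True, exist_ok=True)
    snapshot_dir = Path(snapshot_dir)

    qc_by_id = {q.study_id: q for q in qc_results}
    log_by_id = {e.study_id: e for e in log}

    snaps_by_id: dict[str, SnapshotSet] = {}
    for s in records:
        sidecar = snapshot_dir / f"{s.study_id}_snapshots.json"
        snaps = SnapshotSet(study_id=s.study_id)
        if sidecar.exists():
            payload = json.loads(sidecar.read_text())
            snaps.panels = [PanelSpec(**p) for p in payload["panels"]]
        snaps_by_id[s.study_id] = snaps
        for p in snaps.panels:
            src = Path(p.path)
            if p.status == "rendered" and src.exists():
                shutil.copy2(src, panels_dir / src.name)

    scatter_rel = None
    if cfg.include_scatter:
        measured = {q.study_id: q.tumor_total_cm3 for q in qc_results
                    if q.tumor_total_cm3 is not None}
        reference = {s.study_id: s.reference_volumes[0] for s in records
                     if s.reference_volumes is not None}
        if build_scatter(measured, reference, out_dir / "scatter.png") is not None:
            scatter_rel = "scatter.png"

    ids = [s.study_id for s in records]
    for i, s in enumerate(records):
        build_case_page(s, snaps_by_id[s.study_id], qc_by_id.get(s.study_id),
                        log_by_id.get(s.study_id), out_dir / f"{s.study_id}.html",
                        prev_id=ids[i - 1] if i > 0 else None,
                        next_id=ids[i + 1] if i + 1 < len(ids) else None,
                        config=cfg)
    index = build_index(records, qc_by_id, log_by_id, out_dir / "index.html",
                        scatter_rel=scatter_rel, config=cfg)
    return index
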