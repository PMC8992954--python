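"""Structured human review log: entry, CSV persistence, merging, and aggregation.

The review of one study records a three-level quality call (acceptable /
poor / fail) for each annotation category — brain mask, tumor segmentation,
CSF ROI, registration — plus six boolean study-level flags (study artifact,
image unusable, bias field, normalization failure, no PNGs, needs review),
a free-form CSF-location string, and a free-text comment.  "Poor" marks
minor errors unlikely to affect downstream processing; "fail" marks an
unusable annotation.

A CSV file is the single source of truth: reviews are exported, merged, and
re-imported rather than held in server state.  Aggregation reproduces the
standard review-result table: per-category acceptable/minor/failure counts,
a combined per-study classification (max severity across categories), and
derived failure rates and acceptable fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping

import math

import numpy as np
import pandas as pd

__all__ = [
    "QUALITY_LEVELS", "CATEGORIES", "FLAGS", "CSV_COLUMNS",
    "ReviewEntry", "ReviewSummary", "SchemaError",
    "classify_combined", "merge_logs", "summarize", "rmse_by_quality",
    "export_csv", "import_csv", "percent_reduction",
]

QUALITY_LEVELS = ("acceptable", "poor", "fail")
#: combined classes in increasing severity
COMBINED_LEVELS = ("acceptable", "minor_errors", "failure")
CATEGORIES = ("brain_mask", "tumor_seg", "csf_roi", "registration")
FLAGS = ("study_artifact", "image_unusable", "bias_field",
         "normalization_failure", "no_pngs", "needs_review")

CSV_COLUMNS = (
    "study_id", "reviewer", "timestamp",
    "q_brain_mask", "q_tumor_seg", "q_csf_roi", "q_registration",
    "f_study_artifact", "f_image_unusable", "f_bias_field",
    "f_normalization_failure", "f_no_pngs", "f_needs_review",
    "csf_location", "comment",
)


class SchemaError(ValueError):
    """A review-log file or row violates the review schema."""


@dataclass(frozen=True)
class ReviewEntry:
    """One structured human review of one study."""

    study_id: str
    reviewer: str = ""
    timestamp: str = "1970-01-01T00:00:00+00:00"
    quality: Mapping[str, str] = field(default_factory=dict)   # category -> level
    flags: Mapping[str, bool] = field(default_factory=dict)    # flag -> bool
    csf_location: str = ""
    comment: str = ""
    extras: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.study_id:
            raise SchemaError("study_id must be nonempty")
        q = {c: "acceptable" for c in CATEGORIES}
        for c, v in self.quality.items():
            if c not in CATEGORIES:
                raise SchemaError(f"unknown review category {c!r}")
            if v not in QUALITY_LEVELS:
                raise SchemaError(f"invalid quality level {v!r} for {c}")
            q[c] = v
        f = {name: False for name in FLAGS}
        for name, v in self.flags.items():
            if name not in FLAGS:
                raise SchemaError(f"unknown review flag {name!r}")
            f[name] = bool(v)
        try:
            parsed = pd.Timestamp(self.timestamp)
            if pd.isna(parsed):
                raise ValueError
        except ValueError as exc:
            raise SchemaError(f"unparseable timestamp {self.timestamp!r}") from exc
        object.__setattr__(self, "quality", q)
        object.__setattr__(self, "flags", f)
        object.__setattr__(self, "extras", dict(self.extras))

    def parsed_timestamp(self) -> pd.Timestamp:
        ts = pd.Timestamp(self.timestamp)
        if ts.tzinfo is None:
            ts = ts.tz_localize("UTC")
        return ts


def classify_combined(e: ReviewEntry, bias_field_severity: str = "minor_errors") -> str:
    """Combined study quality: the maximum severity across categories and flags.

    failure      — any category failed, or the study-artifact, image-unusable
                   or normalization-failure flag is set;
    minor_errors — otherwise, any category poor or (by default) the
                   bias-field flag set;
    acceptable   — otherwise.

    ``no_pngs`` and ``needs_review`` gate completeness, not quality, and are
    ignored here.  ``bias_field_severity`` may be "minor_errors" or "failure".
    """
    if bias_field_severity not in ("minor_errors", "failure"):
        raise ValueError("bias_field_severity must be 'minor_errors' or 'failure'")
    fail = (any(e.quality[c] == "fail" for c in CATEGORIES)
            or e.flags["study_artifact"] or e.flags["image_unusable"]
            or e.flags["normalization_failure"]
            or (e.flags["bias_field"] and bias_field_severity == "failure"))
    if fail:
        return "failure"
    minor = (any(e.quality[c] == "poor" for c in CATEGORIES)
             or (e.flags["bias_field"] and bias_field_severity == "minor_errors"))
    return "minor_errors" if minor else "acceptable"


def merge_logs(a: Iterable[ReviewEntry], b: Iterable[ReviewEntry]) -> list[ReviewEntry]:
    """Union of two logs by study_id; the later review of a study wins.

    Conflicts resolve by timestamp, then reviewer name, then the full
    serialized row — the merge is deterministic and idempotent.  Output is
    sorted by study_id.
    """
    def sort_key(e: ReviewEntry):
        return (e.parsed_timestamp(), e.reviewer, tuple(_entry_row(e).items()))

    chosen: dict[str, ReviewEntry] = {}
    for e in list(a) + list(b):
        cur = chosen.get(e.study_id)
        if cur is None or sort_key(e) >= sort_key(cur):
            chosen[e.study_id] = e
    return [chosen[sid] for sid in sorted(chosen)]


# ---------------------------------------------------------------------------
# CSV persistence

def _entry_row(e: ReviewEntry) -> dict[str, str]:
    row = {"study_id": e.study_id, "reviewer": e.reviewer, "timestamp": e.timestamp}
    for c in CATEGORIES:
        row[f"q_{c}"] = e.quality[c]
    for name in FLAGS:
        row[f"f_{name}"] = "1" if e.flags[name] else "0"
    row["csf_location"] = e.csf_location
    row["comment"] = e.comment
    row.update(e.extras)
    return row


def export_csv(log: Iterable[ReviewEntry], path: str | Path) -> Path:
    """Write a review log as CSV (RFC 4180, UTF-8, booleans as 0/1)."""
    rows = [_entry_row(e) for e in log]
    extra_cols = sorted({k for r in rows for k in r} - set(CSV_COLUMNS))
    df = pd.DataFrame(rows, columns=list(CSV_COLUMNS) + extra_cols)
    path = Path(path)
    df.to_csv(path, index=False, encoding="utf-8")
    return path


def import_csv(path: str | Path) -> list[ReviewEntry]:
    """Read a review-log CSV; unknown columns are preserved as extras.

    Missing mandatory columns raise :class:`SchemaError` naming them;
    schema-invalid rows raise with a row-level report rather than being
    silently dropped.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"review log {path} missing columns: {', '.join(missing)}")
    extra_cols = [c for c in df.columns if c not in CSV_COLUMNS]
    entries: list[ReviewEntry] = []
    bad: list[str] = []
    for i, row in df.iterrows():
        try:
            entries.append(ReviewEntry(
                study_id=row["study_id"],
                reviewer=row["reviewer"],
                timestamp=row["timestamp"],
                quality={c: row[f"q_{c}"] for c in CATEGORIES},
                flags={n: row[f"f_{n}"] in ("1", "true", "True") for n in FLAGS},
                csf_location=row["csf_location"],
                comment=row["comment"],
                extras={c: row[c] for c in extra_cols},
            ))
        except SchemaError as exc:
            bad.append(f"row {i + 2}: {exc}")  # +2: header + 1-based
    if bad:
        raise SchemaError(f"invalid rows in {path}:\n" + "\n".join(bad))
    return entries


# ---------------------------------------------------------------------------
# aggregation

#: Table rows: (display name, how counts are derived)
_TWO_LEVEL_ROWS = {
    "image_quality": ("study_artifact", "image_unusable"),
    "normalization": ("normalization_failure",),
}
_THREE_LEVEL_ROWS = {
    "brain_mask": "brain_mask",
    "registration": "registration",
    "tumor_segmentation": "tumor_seg",
    "csf_localization": "csf_roi",
}


@dataclass
class ReviewSummary:
    """Review-result table: per-category and combined counts with percentages."""

    n: int
    counts: pd.DataFrame          # rows = categories + "review_result"; cols acceptable/minor_errors/failure
    failure_rate_pct: pd.Series   # failures / n * 100, one decimal
    acceptable_fraction_pct: float        # (acceptable + minor) / n * 100, one decimal
    acceptable_fraction_pct_int: int      # same, nearest integer

    def failure_rate(self, category: str, decimals: int = 1) -> float:
        return round(float(self.counts.loc[category, "failure"]) / self.n * 100, decimals)


def summarize(log: Iterable[ReviewEntry],
              bias_field_severity: str = "minor_errors") -> ReviewSummary:
    """Tally a review log into the standard review-result table.

    Three-level categories count acceptable/poor/fail per annotation;
    image quality and normalization are two-level (no minor tier, reported
    NaN); the combined row applies :func:`classify_combined` per study.
    Every row's counts sum to the log size.
    """
    entries = list(log)
    if not entries:
        raise SchemaError("cannot summarize an empty review log")
    n = len(entries)
    rows: dict[str, dict[str, float]] = {}
    for name, flags in _TWO_LEVEL_ROWS.items():
        failures = sum(1 for e in entries if any(e.flags[f] for f in flags))
        rows[name] = {"acceptable": n - failures, "minor_errors": math.nan,
                      "failure": failures}
    for name, cat in _THREE_LEVEL_ROWS.items():
        levels = [e.quality[cat] for e in entries]
        rows[name] = {"acceptable": levels.count("acceptable"),
                      "minor_errors": levels.count("poor"),
                      "failure": levels.count("fail")}
    combined = [classify_combined(e, bias_field_severity) for e in entries]
    rows["review_result"] = {lvl: combined.count(lvl) for lvl in COMBINED_LEVELS}
    counts = pd.DataFrame(rows).T[list(COMBINED_LEVELS)]

    failure_rate = (counts["failure"] / n * 100).round(1)
    acc = rows["review_result"]["acceptable"] + rows["review_result"]["minor_errors"]
    return ReviewSummary(
        n=n,
        counts=counts,
        failure_rate_pct=failure_rate,
        acceptable_fraction_pct=round(acc / n * 100, 1),
        acceptable_fraction_pct_int=int(round(acc / n * 100)),
    )


def default_rmse_eligibility(e: ReviewEntry) -> bool:
    """Restrict the volume-error comparison to studies where the tumor
    segmentation is the deciding quality factor: image quality, registration
    and brain mask must all be clean (no flags, category 'acceptable')."""
    return (not e.flags["study_artifact"] and not e.flags["image_unusable"]
            and e.quality["registration"] == "acceptable"
            and e.quality["brain_mask"] == "acceptable")


def rmse_by_quality(log: Iterable[ReviewEntry],
                    measured: Mapping[str, float],
                    reference: Mapping[str, float],
                    eligibility: Callable[[ReviewEntry], bool] | None = None
                    ) -> pd.DataFrame:
    """RMSE between measured and reference volumes, stratified by the
    tumor-segmentation quality call (not the combined class).

    Returns a DataFrame indexed by quality level with columns ``n`` and
    ``rmse_cm3``; an empty stratum reports n=0 with RMSE absent (NaN).
    """
    if eligibility is None:
        eligibility = default_rmse_eligibility
    strata: dict[str, list[float]] = {lvl: [] for lvl in QUALITY_LEVELS}
    for e in log:
        if e.study_id not in measured or e.study_id not in reference:
            continue
        if not eligibility(e):
            continue
        err = float(measured[e.study_id]) - float(reference[e.study_id])
        strata[e.quality["tumor_seg"]].append(err)
    rows = []
    for lvl in QUALITY_LEVELS:
        errs = strata[lvl]
        rmse = float(np.sqrt(np.mean(np.square(errs)))) if errs else math.nan
        rows.append({"quality": lvl, "n": len(errs), "rmse_cm3": rmse})
    return pd.DataFrame(rows).set_index("quality")


def percent_reduction(smaller: float, larger: float) -> int:
    """How much smaller (percent, nearest integer) ``smaller`` is than ``larger``."""
    if larger == 0:
        raise ValueError("reference value must be nonzero")
    return int(round((larger - smaller) / larger * 100))
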