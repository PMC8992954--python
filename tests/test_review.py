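"""Review-log schema, persistence, classification, and aggregation."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrdqc.review import (
    CATEGORIES,
    FLAGS,
    QUALITY_LEVELS,
    ReviewEntry,
    SchemaError,
    classify_combined,
    export_csv,
    import_csv,
    merge_logs,
    percent_reduction,
    rmse_by_quality,
    summarize,
)


def entry(sid="s", ts="2021-06-01T10:00:00+00:00", **kw):
    return ReviewEntry(study_id=sid, reviewer=kw.pop("reviewer", "r1"),
                       timestamp=ts, **kw)


class TestClassifyCombined:
    def test_all_acceptable(self):
        assert classify_combined(entry()) == "acceptable"

    def test_single_poor_category_is_minor(self):
        assert classify_combined(entry(quality={"tumor_seg": "poor"})) == "minor_errors"

    def test_max_severity_wins(self):
        e = entry(quality={"registration": "fail", "brain_mask": "poor"})
        assert classify_combined(e) == "failure"

    @pytest.mark.parametrize("flag,expected", [
        ("study_artifact", "failure"), ("image_unusable", "failure"),
        ("normalization_failure", "failure"), ("bias_field", "minor_errors"),
        ("no_pngs", "acceptable"), ("needs_review", "acceptable"),
    ])
    def test_flag_severity(self, flag, expected):
        assert classify_combined(entry(flags={flag: True})) == expected

    def test_bias_field_severity_configurable(self):
        e = entry(flags={"bias_field": True})
        assert classify_combined(e, bias_field_severity="failure") == "failure"

    def test_monotone_in_every_category(self):
        """Worsening any single category never improves the combined class."""
        order = {"acceptable": 0, "minor_errors": 1, "failure": 2}
        base_grids = itertools.product(QUALITY_LEVELS, repeat=len(CATEGORIES))
        for levels in base_grids:
            e = entry(quality=dict(zip(CATEGORIES, levels)))
            base = order[classify_combined(e)]
            for cat, lvl in zip(CATEGORIES, levels):
                worse = {"acceptable": "poor", "poor": "fail", "fail": "fail"}[lvl]
                e2 = entry(quality={**dict(zip(CATEGORIES, levels)), cat: worse})
                assert order[classify_combined(e2)] >= base


class TestSchema:
    def test_invalid_level_rejected(self):
        with pytest.raises(SchemaError):
            entry(quality={"tumor_seg": "meh"})

    def test_unknown_flag_rejected(self):
        with pytest.raises(SchemaError):
            entry(flags={"sharpness": True})

    def test_unparseable_timestamp_rejected(self):
        with pytest.raises(SchemaError):
            entry(ts="not-a-time")


class TestMerge:
    def test_disjoint_union(self):
        a = [entry(f"a{i}") for i in range(3)]
        b = [entry(f"b{i}") for i in range(4)]
        assert len(merge_logs(a, b)) == 7

    def test_later_timestamp_wins(self):
        old = entry("x", ts="2021-01-01T00:00:00+00:00", comment="old")
        new = entry("x", ts="2021-02-01T00:00:00+00:00", comment="new")
        [kept] = merge_logs([old], [new])
        assert kept.comment == "new"
        [kept] = merge_logs([new], [old])
        assert kept.comment == "new"

    def test_idempotence(self):
        a = [entry("x", comment="c"), entry("y", quality={"csf_roi": "poor"})]
        assert merge_logs(a, a) == sorted(a, key=lambda e: e.study_id)

    def test_tie_breaks_deterministic(self):
        e1 = entry("x", reviewer="alice")
        e2 = entry("x", reviewer="bob")
        assert merge_logs([e1], [e2]) == merge_logs([e2], [e1])


class TestCsvRoundTrip:
    def test_simple_round_trip(self, tmp_path):
        log = [entry("a", quality={"brain_mask": "poor"}, flags={"bias_field": True},
                     csf_location="left frontal", comment="ok"),
               entry("b", quality={"tumor_seg": "fail"})]
        export_csv(log, tmp_path / "log.csv")
        assert import_csv(tmp_path / "log.csv") == log

    def test_quoting_of_commas_and_quotes(self, tmp_path):
        log = [entry("a", comment='tricky, "quoted" comment, with commas')]
        export_csv(log, tmp_path / "log.csv")
        [back] = import_csv(tmp_path / "log.csv")
        assert back.comment == 'tricky, "quoted" comment, with commas'

    def test_missing_mandatory_column_named(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("reviewer,timestamp\nr,2021-01-01\n")
        with pytest.raises(SchemaError, match="study_id"):
            import_csv(p)

    def test_invalid_row_reported_not_dropped(self, tmp_path):
        log = [entry("a"), entry("b")]
        export_csv(log, tmp_path / "log.csv")
        text = (tmp_path / "log.csv").read_text().replace("acceptable", "wat", 1)
        (tmp_path / "bad.csv").write_text(text)
        with pytest.raises(SchemaError, match="row 2"):
            import_csv(tmp_path / "bad.csv")

    def test_unknown_columns_preserved(self, tmp_path):
        export_csv([entry("a", extras={"site": "B"})], tmp_path / "log.csv")
        [back] = import_csv(tmp_path / "log.csv")
        assert back.extras["site"] == "B"

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(comments=st.lists(
        st.text(alphabet=st.characters(blacklist_categories=("Cs", "Cc")), max_size=40),
        min_size=1, max_size=5))
    def test_round_trip_arbitrary_comments(self, comments, tmp_path_factory):
        tmp = tmp_path_factory.mktemp("rt")
        log = [entry(f"s{i}", comment=c) for i, c in enumerate(comments)]
        export_csv(log, tmp / "log.csv")
        assert import_csv(tmp / "log.csv") == log


def make_log(n, fail_counts=None, poor_counts=None, flag_counts=None):
    """Build a log of n entries with the requested per-category marginals.

    Failing entries for a category occupy the first rows, then poor entries —
    marginals are independent per category, as in a review-result table.
    """
    fail_counts = fail_counts or {}
    poor_counts = poor_counts or {}
    flag_counts = flag_counts or {}
    entries = []
    for i in range(n):
        quality = {}
        for cat in CATEGORIES:
            nf, np_ = fail_counts.get(cat, 0), poor_counts.get(cat, 0)
            if i < nf:
                quality[cat] = "fail"
            elif i < nf + np_:
                quality[cat] = "poor"
        flags = {f: i < c for f, c in flag_counts.items()}
        entries.append(entry(f"s{i:04d}", quality=quality, flags=flags))
    return entries


class TestSummarize:
    def test_counts_sum_to_log_size(self):
        log = make_log(50, fail_counts={"tumor_seg": 5}, poor_counts={"brain_mask": 7},
                       flag_counts={"image_unusable": 3})
        summary = summarize(log)
        for row in summary.counts.index:
            vals = summary.counts.loc[row]
            assert np.nansum(vals) == 50

    def test_failure_rates_from_published_clinical_marginals(self):
        # 1380 studies: 133 failed tumor segmentations and 64 failed
        # registrations give 9.6% and 4.6% failure rates
        log = make_log(1380,
                       fail_counts={"tumor_seg": 133, "registration": 64,
                                    "brain_mask": 30, "csf_roi": 24},
                       poor_counts={"tumor_seg": 54, "registration": 55,
                                    "brain_mask": 184, "csf_roi": 128})
        summary = summarize(log)
        assert summary.failure_rate("tumor_segmentation") == 9.6
        assert summary.failure_rate("registration") == 4.6
        assert summary.counts.loc["tumor_segmentation", "acceptable"] == 1193
        assert summary.counts.loc["brain_mask", "minor_errors"] == 184

    def test_combined_acceptable_fraction(self):
        # combined counts 888 / 293 / 199 -> 85.6% -> 86% of studies usable
        log = make_log(1380, fail_counts={"tumor_seg": 199},
                       poor_counts={"tumor_seg": 293})
        summary = summarize(log)
        assert tuple(summary.counts.loc["review_result"]) == (888, 293, 199)
        assert summary.acceptable_fraction_pct == 85.6
        assert summary.acceptable_fraction_pct_int == 86

    def test_single_acceptable_entry_is_100pct(self):
        summary = summarize([entry("only")])
        assert summary.acceptable_fraction_pct == 100.0

    def test_empty_log_rejected(self):
        with pytest.raises(SchemaError, match="empty"):
            summarize([])

    def test_two_level_rows_have_no_minor_tier(self):
        summary = summarize(make_log(10, flag_counts={"study_artifact": 2}))
        assert math.isnan(summary.counts.loc["image_quality", "minor_errors"])
        assert summary.counts.loc["image_quality", "failure"] == 2
        assert math.isnan(summary.counts.loc["normalization", "minor_errors"])


class TestRmseByQuality:
    def test_closed_form_example(self):
        # errors [1, 2] -> RMSE sqrt((1+4)/2) = sqrt(2.5)
        log = [entry("a"), entry("b")]
        table = rmse_by_quality(log, {"a": 1.0, "b": 2.0}, {"a": 0.0, "b": 0.0})
        assert table.loc["acceptable", "n"] == 2
        assert table.loc["acceptable", "rmse_cm3"] == pytest.approx(math.sqrt(2.5))

    def test_perfect_agreement_is_zero(self):
        log = [entry("a", quality={"tumor_seg": "poor"})]
        table = rmse_by_quality(log, {"a": 7.0}, {"a": 7.0})
        assert table.loc["poor", "rmse_cm3"] == 0.0

    def test_ineligible_study_excluded_from_all_strata(self):
        log = [entry("a"), entry("b", quality={"registration": "fail"})]
        vols = {"a": 1.0, "b": 1.0}
        table = rmse_by_quality(log, vols, {"a": 0.0, "b": 0.0})
        assert table["n"].sum() == 1

    def test_empty_stratum_reports_nan(self):
        table = rmse_by_quality([entry("a")], {"a": 1.0}, {"a": 0.0})
        assert table.loc["fail", "n"] == 0
        assert math.isnan(table.loc["fail", "rmse_cm3"])

    def test_stratified_by_tumor_seg_not_combined(self):
        # bias-field flag worsens the combined class but not the stratum
        log = [entry("a", flags={"bias_field": True})]
        table = rmse_by_quality(log, {"a": 3.0}, {"a": 0.0})
        assert table.loc["acceptable", "n"] == 1


def test_percent_reduction_examples():
    assert percent_reduction(12.2, 27.4) == 55
    assert percent_reduction(12.2, 20.5) == 40
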