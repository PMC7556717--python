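import math

import numpy as np
import pandas as pd
import pytest

from ctcdte.cohort_analysis import (
    build_cohort_report,
    longitudinal_contrasts,
    reconstruct_scores,
    reference_cohort,
    reference_summaries,
    summarize_counts,
    summarize_timepoint,
    total_confirmed_ctcs,
)
from ctcdte.exceptions import ValidationError
from ctcdte.mt_dte_scoring import MtDteScore, ThresholdBounds


def score_obj(value, cell_id="c"):
    return MtDteScore(cell_id=cell_id, bounds=ThresholdBounds(0.75, 1.0),
                      roi_area_px=1, roi_mean_intensity=value,
                      integrated_density=value)


class TestSummarizeTimepoint:
    def test_two_cell_mean_and_sample_sd(self):
        s = summarize_timepoint([0.1, 0.3], "P1", "C1D1")
        assert s.n_ctc == 2
        assert s.mean_dte == pytest.approx(0.2)
        assert s.sd_dte == pytest.approx(math.sqrt(((0.1 - 0.2) ** 2 + (0.3 - 0.2) ** 2) / 1))
        assert s.sd_dte == pytest.approx(0.14142135623730953)

    def test_single_cell_has_no_sd(self):
        s = summarize_timepoint([0.004], "P1", "C1D1+4h")
        assert s.mean_dte == pytest.approx(0.004)
        assert math.isnan(s.sd_dte)

    def test_empty_analyzed_timepoint(self):
        s = summarize_timepoint([], "P1", "C1D1")
        assert s.n_ctc == 0
        assert math.isnan(s.mean_dte) and math.isnan(s.sd_dte)

    def test_not_received_ignores_scores(self):
        s = summarize_timepoint([1.0], "P1", "C1D1", status="sample_not_received")
        assert s.n_ctc == 0 and math.isnan(s.mean_dte)

    def test_accepts_score_objects(self):
        s = summarize_timepoint([score_obj(2.0), score_obj(4.0)], "P1", "C1D8")
        assert s.mean_dte == pytest.approx(3.0)

    def test_unknown_timepoint_label_rejected(self):
        with pytest.raises(ValidationError, match="C1D1"):
            summarize_timepoint([1.0], "P1", "C9D9")


class TestCounts:
    @pytest.mark.parametrize(
        "counts,mean,lo,hi,total",
        [
            ((3, 1, 2, 6, 2, 17, 11), 6.0, 1, 17, 42),
            ((3, 20, 5, 2, 10, 17), 9.5, 2, 20, 57),
            ((5,), 5.0, 5, 5, 5),
        ],
    )
    def test_count_statistics(self, counts, mean, lo, hi, total):
        tps = ["C1D1", "C1D1+4h", "C1D2", "C1D8", "C2D1", "C2D1+4h", "C2D8"]
        summaries = [
            summarize_timepoint([1.0] * c, "P", tp) for c, tp in zip(counts, tps)
        ]
        cs = summarize_counts(summaries)
        assert cs.mean_count == pytest.approx(mean)
        assert (cs.min_count, cs.max_count, cs.total_count) == (lo, hi, total)

    def test_not_received_rows_excluded(self):
        summaries = [
            summarize_timepoint([1.0, 2.0], "P", "C1D1"),
            summarize_timepoint([], "P", "C2D8", status="sample_not_received"),
        ]
        cs = summarize_counts(summaries)
        assert (cs.mean_count, cs.total_count) == (2.0, 2)

    def test_reference_totals(self):
        summaries = reference_summaries()
        assert total_confirmed_ctcs(summaries) == 149
        p1 = [s for s in summaries if s.patient_id == "Patient 1"]
        assert total_confirmed_ctcs(p1) == 42

    def test_empty_cohort_total(self):
        assert total_confirmed_ctcs([]) == 0


class TestContrasts:
    def test_responder_both_cycles_increase(self):
        summaries = [s for s in reference_summaries() if s.patient_id == "Patient 1"]
        contrasts = longitudinal_contrasts(summaries)
        assert [c.cycle for c in contrasts] == [1, 2]
        assert all(c.increased for c in contrasts)
        assert contrasts[0].delta == pytest.approx(1.0 - 0.19)
        assert contrasts[1].delta == pytest.approx(0.45 - 0.17)

    def test_stable_patient_cycle2_decrease(self):
        summaries = [s for s in reference_summaries() if s.patient_id == "Patient 3"]
        c2 = [c for c in longitudinal_contrasts(summaries) if c.cycle == 2][0]
        assert c2.increased is False
        assert c2.baseline_mean == pytest.approx(46.64)
        assert c2.week1_mean == pytest.approx(0.1185)

    def test_missing_side_gives_missing_flag(self):
        summaries = [s for s in reference_summaries() if s.patient_id == "Patient 2"]
        c2 = [c for c in longitudinal_contrasts(summaries) if c.cycle == 2][0]
        assert c2.increased is None
        assert math.isnan(c2.ratio)

    def test_early_timepoints_never_enter_contrasts(self):
        summaries = reference_summaries()
        for pid in ("Patient 1", "Patient 2", "Patient 3"):
            for c in longitudinal_contrasts([s for s in summaries if s.patient_id == pid]):
                assert "+4h" not in c.baseline_timepoint
                assert c.baseline_timepoint in ("C1D1", "C2D1")
                assert c.week1_timepoint in ("C1D8", "C2D8")


class TestAggregationLinearity:
    def test_scaling_scores_scales_stats_and_keeps_flags(self, rng):
        vals = rng.gamma(2.0, 3.0, size=12)
        base = summarize_timepoint(list(vals), "P", "C1D1")
        week = summarize_timepoint(list(vals * 1.5 + 2), "P", "C1D8")
        c = 7.0
        base_s = summarize_timepoint(list(vals * c), "P", "C1D1")
        week_s = summarize_timepoint(list((vals * 1.5 + 2) * c), "P", "C1D8")
        assert base_s.mean_dte == pytest.approx(c * base.mean_dte)
        assert base_s.sd_dte == pytest.approx(c * base.sd_dte)
        orig = longitudinal_contrasts([base, week])[0]
        scaled = longitudinal_contrasts([base_s, week_s])[0]
        assert orig.increased == scaled.increased


class TestReport:
    def test_row_conservation(self, tmp_path):
        summaries = reference_summaries()
        contrasts = []
        for pid in ("Patient 1", "Patient 2", "Patient 3"):
            contrasts += longitudinal_contrasts([s for s in summaries if s.patient_id == pid])
        paths = build_cohort_report(summaries, contrasts, tmp_path)
        table = pd.read_csv(paths["cohort_table"])
        assert len(table) == 21  # 3 patients x 7 timepoints

    def test_empty_inputs_yield_header_only_files(self, tmp_path):
        paths = build_cohort_report([], [], tmp_path, plot=False)
        table = pd.read_csv(paths["cohort_table"])
        assert table.empty
        assert list(table.columns) == ["patient_id", "timepoint", "n_ctc",
                                       "mean_dte", "sd_dte", "status"]

    def test_clinical_metadata_merged_as_text(self, tmp_path):
        summaries = [summarize_timepoint([1.0], "P1", "C1D1")]
        clinical = pd.DataFrame(
            [{"patient_id": "P1", "best_psa_response_pct": -44,
              "recist_label": "Partial response (-50%)"}]
        )
        paths = build_cohort_report(summaries, [], tmp_path, clinical=clinical,
                                    plot=False)
        table = pd.read_csv(paths["cohort_table"])
        assert table.loc[0, "recist_label"] == "Partial response (-50%)"


class TestReconstruction:
    def test_exact_mean_recovery(self, rng):
        for n, mean, sd in [(3, 0.19, 0.16), (6, 1.0, 0.85), (17, 8.3, 7.8),
                            (2, 0.34, 0.26), (1, 0.004, None)]:
            vals = reconstruct_scores(n, mean, sd, rng=rng)
            assert len(vals) == n
            s = summarize_timepoint(list(vals), "P", "C1D1")
            assert s.mean_dte == mean

    def test_two_cell_reconstruction_recovers_sd(self):
        vals = reconstruct_scores(2, 0.34, 0.26)
        s = summarize_timepoint(list(vals), "P", "C1D2")
        assert s.sd_dte == pytest.approx(0.26, rel=1e-12)

    def test_reference_table_reproduced_through_pipeline(self, tmp_path, rng):
        ref = reference_cohort()
        summaries = []
        for row in ref.itertuples(index=False):
            if row.status != "analyzed":
                summaries.append(summarize_timepoint([], row.patient_id,
                                                     row.timepoint, status=row.status))
                continue
            vals = reconstruct_scores(int(row.n_ctc), float(row.mean_dte),
                                      None if np.isnan(row.sd_dte) else float(row.sd_dte),
                                      rng=rng)
            summaries.append(summarize_timepoint(list(vals), row.patient_id, row.timepoint))
        paths = build_cohort_report(summaries, [], tmp_path, plot=False)
        table = pd.read_csv(paths["cohort_table"])
        merged = table.merge(ref, on=["patient_id", "timepoint"], suffixes=("", "_ref"))
        analyzed = merged[merged["status_ref"] == "analyzed"]
        assert (analyzed["n_ctc"] == analyzed["n_ctc_ref"]).all()
        assert (analyzed["mean_dte"] == analyzed["mean_dte_ref"]).all()
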