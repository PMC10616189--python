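import math

import numpy as np
import pytest

from xicalign.model import (
    AnnotationTable,
    Feature,
    IntensityMatrix,
    ValidationError,
    Xic,
    XicGroup,
)
from xicalign.quant import (
    QuantResult,
    SelectionParams,
    assemble_matrix,
    cv_metrics,
    integrate_signal,
    pick_aligned_peak,
    quantitation_error_rate,
    summarize_proteins,
    transpose_across_charges,
)


def _feat(prec="P/2", run="r1", apex=100.0, q=0.01, p=None, d=3.0, width=12.5,
          intensity=1000.0):
    return Feature(prec, run, apex, apex - width, apex + width, intensity,
                   d_score=d, p_value=p if p is not None else q / 2, q_value=q)


class TestPickAlignedPeak:
    params = SelectionParams()

    def test_lowest_p_in_window_wins(self):
        cands = [_feat(apex=100.0, p=0.001, q=0.004),
                 _feat(apex=104.0, p=0.01, q=0.004)]
        chosen = pick_aligned_peak(cands, t_ref=102.0, params=self.params,
                                   window_seconds=10.0)
        assert chosen.rt_apex == 100.0

    def test_alignment_overturns_score_order(self):
        # the d-score-best peak sits off the aligned time; the in-window
        # peak must win even though its classifier score is worse
        best_scored = _feat(apex=140.0, q=0.002, p=0.0005, d=5.0)
        in_window = _feat(apex=101.0, q=0.01, p=0.004, d=2.0)
        chosen = pick_aligned_peak([best_scored, in_window], t_ref=100.0,
                                   params=self.params, window_seconds=12.0)
        assert chosen.rt_apex == 101.0
        assert chosen.flag is None

    def test_out_of_window_needs_direct_ceiling_and_is_flagged(self):
        params = SelectionParams(aligned_fdr1=0.01, aligned_fdr2=0.05)
        far = _feat(apex=150.0, q=0.2)
        assert pick_aligned_peak([far], 100.0, params, 10.0) is None
        far_good = _feat(apex=150.0, q=0.005)
        chosen = pick_aligned_peak([far_good], 100.0, params, 10.0)
        assert chosen.flag == "outside-window"
        assert chosen.provenance == "aligned-reassigned"

    def test_in_window_candidate_above_fdr2_not_selected(self):
        params = SelectionParams(aligned_fdr1=0.01, aligned_fdr2=0.02)
        cand = _feat(apex=100.0, q=0.04)
        assert pick_aligned_peak([cand], 100.0, params, 10.0) is None


class TestIntegrateSignal:
    def test_gaussian_area_within_one_percent(self):
        sigma = 2.0
        t = np.arange(-10.0, 10.0 + 0.25, 0.5)
        group = XicGroup("P/2", "r", ["y1"],
                         [Xic(t, np.exp(-(t**2) / (2 * sigma**2)))])
        f = integrate_signal(group, -4 * sigma, 4 * sigma)
        expected = math.sqrt(2 * math.pi) * sigma
        assert abs(f.intensity - expected) / expected < 0.01
        assert f.q_value is None and f.p_value is None
        assert f.provenance == "integrated"

    def test_all_zero_trace_yields_zero_flagged(self):
        t = np.arange(0.0, 20.0, 1.0)
        group = XicGroup("P/2", "r", ["y1"], [Xic(t, np.zeros_like(t))])
        f = integrate_signal(group, 5.0, 15.0)
        assert f.intensity == 0.0 and f.flag == "low-signal"

    def test_fragment_areas_are_additive(self):
        t = np.arange(0.0, 30.0, 1.0)
        rect = np.where((t >= 10) & (t <= 20), 1.0, 0.0)
        group = XicGroup("P/2", "r", ["y1", "y2"], [Xic(t, rect), Xic(t, rect)])
        f = integrate_signal(group, 10.0, 20.0)
        assert f.intensity == pytest.approx(20.0, rel=0.01)

    def test_window_outside_grid_raises(self):
        t = np.arange(0.0, 10.0, 1.0)
        group = XicGroup("P/2", "r", ["y1"], [Xic(t, np.ones_like(t))])
        with pytest.raises(ValidationError):
            integrate_signal(group, 50.0, 60.0)


class TestTransposeAcrossCharges:
    def _xic(self, prec, run="r1"):
        t = np.arange(80.0, 121.0, 1.0)
        peak = 100.0 * np.exp(-((t - 100.0) ** 2) / 18.0)
        return XicGroup(prec, run, ["y1"], [Xic(t, peak)])

    def test_boundaries_copied_to_scoreless_charge(self):
        feats = {("PEPA/2", "r1"): [_feat("PEPA/2", apex=100.0, width=10.0)]}
        xics = {("PEPA/2", "r1"): self._xic("PEPA/2"),
                ("PEPA/3", "r1"): self._xic("PEPA/3")}
        out = transpose_across_charges(feats, xics, SelectionParams())
        assert len(out) == 1
        f = out[0]
        assert f.precursor_id == "PEPA/3" and f.provenance == "integrated"
        assert (f.left_boundary, f.right_boundary) == (90.0, 110.0)
        assert f.intensity > 0

    def test_no_transposition_when_both_charges_qualify(self):
        feats = {("PEPA/2", "r1"): [_feat("PEPA/2")],
                 ("PEPA/3", "r1"): [_feat("PEPA/3")]}
        xics = {("PEPA/2", "r1"): self._xic("PEPA/2"),
                ("PEPA/3", "r1"): self._xic("PEPA/3")}
        assert transpose_across_charges(feats, xics, SelectionParams()) == []

    def test_zero_signal_window_retained_and_flagged(self):
        t = np.arange(80.0, 121.0, 1.0)
        feats = {("PEPA/2", "r1"): [_feat("PEPA/2", apex=100.0, width=10.0)]}
        xics = {("PEPA/2", "r1"): self._xic("PEPA/2"),
                ("PEPA/3", "r1"): XicGroup("PEPA/3", "r1", ["y1"],
                                           [Xic(t, np.zeros_like(t))])}
        out = transpose_across_charges(feats, xics, SelectionParams())
        assert len(out) == 1 and out[0].intensity == 0.0
        assert out[0].flag == "low-signal"


class TestAssembleMatrix:
    def test_identical_selection_is_all_unchanged(self):
        picks = {("P1/2", "r1"): _feat("P1/2", q=0.01),
                 ("P2/2", "r1"): _feat("P2/2", q=0.02)}
        result = assemble_matrix(["P1/2", "P2/2"], ["r1"], picks, picks,
                                 SelectionParams())
        assert result.report == {"unchanged": 2, "reassigned": 0,
                                 "removed": 0, "integrated": 0}

    def test_switched_peak_counts_as_reassigned(self):
        original = {("P1/2", "r1"): _feat("P1/2", apex=100.0, q=0.01)}
        switched = {("P1/2", "r1"): _feat("P1/2", apex=140.0, q=0.02)}
        result = assemble_matrix(["P1/2"], ["r1"], switched, original,
                                 SelectionParams())
        assert result.report["reassigned"] == 1

    def test_final_score_filter_has_no_leakage(self):
        picks = {("P1/2", "r1"): _feat("P1/2", q=0.01),
                 ("P2/2", "r1"): _feat("P2/2", q=0.2)}
        params = SelectionParams(final_mscore=0.025, final_qvalue=0.025,
                                 max_fdr_query=0.5, aligned_fdr1=0.5,
                                 aligned_fdr2=0.5)
        result = assemble_matrix(["P1/2", "P2/2"], ["r1"], picks, picks, params)
        for feature in result.matrix.features.values():
            assert feature.q_value <= 0.025
        assert result.matrix.cell("P2/2", "r1") is None

    def test_completeness_monotone_in_aligned_fdr2(self):
        # sweep the alignment-assisted ceiling on one fixed candidate set
        rng = np.random.default_rng(0)
        precursors = [f"P{k}/2" for k in range(150)]
        candidates = {
            (p, "r1"): [_feat(p, q=float(10 ** rng.uniform(-4, -0.5)))]
            for p in precursors
        }
        completenesses = []
        for fdr2 in (0.005, 0.01, 0.05, 0.1):
            params = SelectionParams(max_fdr_query=0.5, aligned_fdr1=0.005,
                                     aligned_fdr2=fdr2, final_mscore=1.0,
                                     final_qvalue=1.0)
            selections = {
                cell: pick_aligned_peak(cands, cands[0].rt_apex, params, 10.0)
                for cell, cands in candidates.items()
            }
            result = assemble_matrix(precursors, ["r1"], selections, selections,
                                     params)
            completenesses.append(result.matrix.completeness())
        assert completenesses == sorted(completenesses)


class TestErrorRate:
    def _result(self, features):
        precs = sorted({f.precursor_id for f in features})
        runs = sorted({f.run_id for f in features})
        m = IntensityMatrix(precs, runs)
        for f in features:
            m.set_cell(f)
        return QuantResult(matrix=m)

    def test_perfect_overlap_gives_zero_incorrect(self):
        feats = [_feat(f"P{k}/2", apex=100.0, q=0.005) for k in range(5)]
        ann = AnnotationTable()
        for k in range(5):
            ann.set(f"P{k}/2", "r1", (95.0, 105.0))
        rates = quantitation_error_rate(self._result(feats), ann, [0.01])
        assert rates.loc[0, "incorrect_fraction"] == 0.0
        assert rates.loc[0, "correct_fraction"] == 1.0

    def test_one_bad_cell_in_ten(self):
        feats = [_feat(f"P{k}/2", apex=100.0, q=0.005) for k in range(10)]
        ann = AnnotationTable()
        for k in range(9):
            ann.set(f"P{k}/2", "r1", (95.0, 105.0))
        ann.set("P9/2", "r1", (300.0, 320.0))  # no overlap: incorrect
        rates = quantitation_error_rate(self._result(feats), ann, [0.01])
        assert rates.loc[0, "incorrect_fraction"] == pytest.approx(0.1)

    def test_selection_where_annotation_absent_is_incorrect(self):
        feats = [_feat("P0/2", q=0.005)]
        ann = AnnotationTable()
        ann.set("P0/2", "r1", None)
        rates = quantitation_error_rate(self._result(feats), ann, [0.01])
        assert rates.loc[0, "incorrect_fraction"] == 1.0

    def test_integrated_cells_are_excluded(self):
        feats = [_feat(f"P{k}/2", apex=100.0, q=0.005) for k in range(4)]
        integrated = Feature("P9/2", "r1", 500.0, 490.0, 510.0, 10.0,
                             provenance="integrated")
        ann = AnnotationTable()
        for k in range(4):
            ann.set(f"P{k}/2", "r1", (95.0, 105.0))
        ann.set("P9/2", "r1", None)  # would count incorrect if included
        rates = quantitation_error_rate(self._result(feats + [integrated]),
                                        ann, [0.01])
        assert rates.loc[0, "total_peaks"] == 4
        assert rates.loc[0, "incorrect_fraction"] == 0.0

    def test_empty_annotation_overlap_raises(self):
        feats = [_feat("P0/2", q=0.005)]
        ann = AnnotationTable()
        ann.set("OTHER/2", "r9", (0.0, 1.0))
        with pytest.raises(ValidationError):
            quantitation_error_rate(self._result(feats), ann, [0.01])


class TestCvMetrics:
    def _matrix(self, rows):
        runs = [f"r{k}" for k in range(len(next(iter(rows.values()))))]
        m = IntensityMatrix(sorted(rows), runs)
        for prec, values in rows.items():
            for run, v in zip(runs, values):
                if v is not None:
                    m.set_cell(Feature(prec, run, 100.0, 90.0, 110.0, v,
                                       q_value=0.01))
        return m

    def test_constant_intensities_give_zero_cv(self):
        m = self._matrix({"P/2": [50.0, 50.0, 50.0]})
        assert cv_metrics(m)["cross_site_mean_cv"] == pytest.approx(0.0)

    def test_hand_computed_cv(self):
        m = self._matrix({"P/2": [90.0, 100.0, 110.0]})
        assert cv_metrics(m)["cross_site_mean_cv"] == pytest.approx(0.1)

    def test_site_specific_leq_cross_site_with_site_offsets(self):
        rng = np.random.default_rng(3)
        rows = {}
        for k in range(40):
            base = rng.uniform(500, 1500)
            site1 = base * rng.normal(1.0, 0.05, 3)
            site2 = base * 1.6 * rng.normal(1.0, 0.05, 3)
            rows[f"P{k}/2"] = list(site1) + list(site2)
        m = self._matrix(rows)
        labels = {f"r{k}": ("s1" if k < 3 else "s2") for k in range(6)}
        out = cv_metrics(m, labels)
        assert out["site_specific_mean_cv"] <= out["cross_site_mean_cv"]

    def test_zero_mean_analyte_flagged_and_excluded(self):
        m = self._matrix({"P/2": [0.0, 0.0], "Q/2": [10.0, 12.0]})
        out = cv_metrics(m)
        assert "P/2" in out["flagged_analytes"]
        assert np.isfinite(out["cross_site_mean_cv"])


def test_protein_rollup_sums_top_peptides():
    m = IntensityMatrix(["A/2", "B/2", "C/2"], ["r1"])
    for prec, v in (("A/2", 100.0), ("B/2", 50.0), ("C/2", 10.0)):
        m.set_cell(Feature(prec, "r1", 100.0, 90.0, 110.0, v, q_value=0.01))
    prot = summarize_proteins(m, {"A/2": "PROT1", "B/2": "PROT1", "C/2": "PROT1"},
                              top_peptides=2)
    assert prot.loc["PROT1", "r1"] == pytest.approx(150.0)
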