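"""Consensus, ROC, quartiles, relative intensity, expression fits,
matching report."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import plmatch as pm
from plmatch.benchmark import (
    abundance_quartiles,
    auroc_rank,
    expression_response_fit,
    matching_report,
    occurrence_frequency,
    relative_intensity,
    roc_analysis,
)
from plmatch.errors import DesignError
from plmatch.types import DIFF_COLUMNS


def diff_result(calls: dict, pi: dict | None = None, bait="B", control="C"):
    proteins = list(calls)
    tab = pd.DataFrame({
        "log2_fc": [2.0 if calls[p] == "enriched" else 0.0 for p in proteins],
        "t_mod": 0.0,
        "df_total": 4.0,
        "p_raw": 0.5,
        "p_adj": 0.5,
        "pi_value": [pi.get(p, 0.0) if pi else 0.0 for p in proteins],
        "call": [calls[p] for p in proteins],
    }, index=pd.Index(proteins, name="protein"))
    return pm.DiffResult(tab, bait_group=bait, control_group=control)


class TestOccurrenceFrequency:
    def test_counts_and_threshold(self):
        results = []
        for i in range(6):
            call = "enriched" if i < 4 else "not_significant"
            results.append(diff_result({"A": call, "B": "not_significant"}))
        cons = occurrence_frequency(results, threshold=3)
        assert cons.table.loc["A", "occurrence_frequency"] == 4
        assert bool(cons.table.loc["A", "high_confidence"])
        assert cons.table.loc["B", "occurrence_frequency"] == 0
        assert not cons.table.loc["B", "high_confidence"]

    def test_absent_protein_contributes_zero(self):
        r1 = diff_result({"A": "enriched", "B": "enriched"})
        r2 = diff_result({"A": "enriched"})  # B absent here
        cons = occurrence_frequency([r1, r2], threshold=2)
        assert cons.table.loc["B", "occurrence_frequency"] == 1

    def test_threshold_above_n_results_rejected(self):
        results = [diff_result({"A": "enriched"}) for _ in range(6)]
        with pytest.raises(ValueError):
            occurrence_frequency(results, threshold=7)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 1000))
    def test_permutation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        results = [
            diff_result({f"P{j}": ("enriched" if rng.random() < 0.4 else "not_significant")
                         for j in range(10)})
            for _ in range(5)
        ]
        a = occurrence_frequency(results, 2).table
        perm = [results[i] for i in rng.permutation(5)]
        b = occurrence_frequency(perm, 2).table
        pd.testing.assert_frame_equal(a, b)


class TestROC:
    def test_perfect_separation(self):
        pi = {f"P{i}": 10.0 - i for i in range(10)}
        result = diff_result({p: "not_significant" for p in pi}, pi=pi)
        auc, curve = roc_analysis(result, {"P0", "P1", "P2"})
        assert auc == 1.0

    def test_single_positive_at_median_rank(self):
        pi = {f"P{i}": float(i) for i in range(11)}
        result = diff_result({p: "not_significant" for p in pi}, pi=pi)
        auc, _ = roc_analysis(result, {"P5"})
        assert auc == 0.5

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        aucs = []
        for _ in range(5):
            scores = rng.normal(size=2000)
            labels = rng.random(2000) < 0.1
            aucs.append(auroc_rank(scores, labels))
        assert abs(np.mean(aucs) - 0.5) < 0.03

    def test_rank_formula_equals_trapezoidal_curve_area(self):
        rng = np.random.default_rng(1)
        scores = np.round(rng.normal(size=500), 1)  # force ties
        labels = rng.random(500) < 0.2
        pi = {f"P{i}": scores[i] for i in range(500)}
        result = diff_result({p: "not_significant" for p in pi}, pi=pi)
        positives = {f"P{i}" for i in range(500) if labels[i]}
        auc, curve = roc_analysis(result, positives)
        area = np.trapezoid(curve["tpr"], curve["fpr"])
        assert auc == pytest.approx(area, abs=1e-12)

    def test_no_positives_rejected(self):
        result = diff_result({"A": "enriched"})
        with pytest.raises(ValueError):
            roc_analysis(result, {"ZZZ"})


class TestAbundanceQuartiles:
    def test_top_values_assigned_q1(self):
        ab = pd.Series(np.arange(1.0, 101.0), index=[f"P{i:03d}" for i in range(100)])
        qmap = abundance_quartiles(ab)
        top = qmap.proteins_in("Q1_top")
        assert sorted(top) == [f"P{i:03d}" for i in range(75, 100)]

    def test_eight_proteins_quartiles_of_two(self):
        ab = pd.Series([8.0, 7, 6, 5, 4, 3, 2, 1], index=list("abcdefgh"))
        qmap = abundance_quartiles(ab)
        counts = qmap.table["abundance_quartile"].value_counts()
        assert (counts == 2).all()

    def test_ties_broken_by_stable_id_order(self):
        ab = pd.Series([5.0, 5.0, 5.0, 5.0], index=["d", "b", "a", "c"])
        qmap = abundance_quartiles(ab)
        # after sort on (-abundance, id): a, b, c, d
        assert qmap.table.loc["a", "abundance_quartile"] == "Q1_top"
        assert qmap.table.loc["d", "abundance_quartile"] == "Q4_bottom"

    def test_top1pct_flag(self):
        ab = pd.Series(np.arange(1.0, 201.0), index=[f"P{i:03d}" for i in range(200)])
        qmap = abundance_quartiles(ab)
        assert qmap.table["top1pct"].sum() == 2
        assert bool(qmap.table.loc["P199", "top1pct"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            abundance_quartiles(pd.Series(dtype=float))


def make_matrix(values, samples, **flags):
    frame = pd.DataFrame(values, columns=samples,
                         index=pd.Index([f"P{i}" for i in range(len(values))], name="protein"))
    return pm.ProteinMatrix(frame, **flags)


@pytest.fixture
def series_design():
    rows = []
    for gi, (g, e) in enumerate([("g1", 1.0), ("g2", 2.0), ("g3", 4.0)]):
        for r in (1, 2):
            rows.append(dict(sample_id=f"{g}_r{r}", group=g, role="control",
                             replicate=r, turboid_expression=e))
    return pm.StudyDesign(pd.DataFrame(rows))


class TestRelativeIntensity:
    def test_ratio_against_baseline(self, series_design):
        vals = [[10.0, 10.0, 200.0, 200.0, 50.0, 50.0]]
        matrix = make_matrix(vals, series_design.sample_ids)
        ratios, _ = relative_intensity(matrix, series_design, "g1")
        assert ratios.loc["P0", "g2"] == pytest.approx(20.0)
        assert ratios.loc["P0", "g3"] == pytest.approx(5.0)

    def test_baseline_vs_itself_is_one(self, series_design):
        rng = np.random.default_rng(2)
        matrix = make_matrix(rng.lognormal(3, 1, (5, 6)), series_design.sample_ids)
        ratios, _ = relative_intensity(matrix, series_design, "g1")
        np.testing.assert_allclose(ratios["g1"].to_numpy(), 1.0, rtol=1e-12)

    def test_protein_missing_in_baseline_excluded(self, series_design):
        vals = np.array([
            [np.nan, np.nan, 4.0, 4.0, 8.0, 8.0],
            [1.0, 1.0, 2.0, 2.0, 3.0, 3.0],
        ])
        matrix = make_matrix(vals, series_design.sample_ids)
        qmap = pm.QuartileMap(pd.DataFrame(
            {"abundance_quartile": ["Q1_top", "Q1_top"], "top1pct": False},
            index=pd.Index(["P0", "P1"], name="protein")))
        ratios, perq = relative_intensity(matrix, series_design, "g1", quartiles=qmap)
        assert np.isnan(ratios.loc["P0", "g2"])
        assert perq.loc["Q1_top", "g2"] == pytest.approx(2.0)  # P1 only

    def test_unknown_baseline_rejected(self, series_design):
        matrix = make_matrix([[1.0] * 6], series_design.sample_ids)
        with pytest.raises(DesignError):
            relative_intensity(matrix, series_design, "nope")


class TestExpressionResponseFit:
    def test_protein_in_two_groups_excluded(self, series_design):
        vals = np.array([
            [1.0, 1.0, 2.0, 2.0, np.nan, np.nan],
            [1.0, 1.0, 2.0, 2.0, 4.0, 4.0],
        ])
        matrix = make_matrix(vals, series_design.sample_ids)
        fit = expression_response_fit(matrix, series_design)
        assert list(fit.fits.index) == ["P1"]
        assert fit.fits.loc["P1", "n_groups_used"] == 3

    def test_constant_response_r2_zero(self, series_design):
        matrix = make_matrix([[7.0] * 6], series_design.sample_ids)
        fit = expression_response_fit(matrix, series_design)
        assert fit.fits.loc["P0", "r_squared"] == 0.0

    def test_exact_line_r2_one(self, series_design):
        # intensity = 3*E exactly
        vals = [[3.0, 3.0, 6.0, 6.0, 12.0, 12.0]]
        matrix = make_matrix(vals, series_design.sample_ids)
        fit = expression_response_fit(matrix, series_design)
        assert fit.fits.loc["P0", "r_squared"] == pytest.approx(1.0)
        assert fit.fits.loc["P0", "slope"] == pytest.approx(3.0)
        assert fit.fraction_above_threshold == 1.0

    def test_fewer_than_three_groups_rejected(self):
        rows = [dict(sample_id=f"g{g}_r{r}", group=f"g{g}", role="control",
                     replicate=r, turboid_expression=float(g))
                for g in (1, 2) for r in (1, 2)]
        design = pm.StudyDesign(pd.DataFrame(rows))
        matrix = make_matrix([[1.0, 1.0, 2.0, 2.0]], design.sample_ids)
        with pytest.raises(DesignError):
            expression_response_fit(matrix, design)


class TestMatchingReport:
    @pytest.fixture
    def titration_design(self):
        rows = [dict(sample_id="b_r1", group="bait", role="bait", replicate=1,
                     turboid_expression=1.0)]
        for g, e in (("c_low", 0.25), ("c_eq", 1.0), ("c_hi", 4.0)):
            rows.append(dict(sample_id=f"{g}_r1", group=g, role="control",
                             replicate=1, turboid_expression=e))
        return pm.StudyDesign(pd.DataFrame(rows))

    def test_recommends_expression_matched_control(self, titration_design):
        results = {g: diff_result({"A": "enriched"}, bait="bait", control=g)
                   for g in ("c_low", "c_eq", "c_hi")}
        report = matching_report(results, titration_design, "bait")
        assert report.recommended_control == "c_eq"
        np.testing.assert_allclose(
            report.controls["expression_mismatch"].to_numpy(), [-2.0, 0.0, 2.0]
        )

    def test_truth_with_no_interactors(self, titration_design, default_sim):
        truth = pm.GroundTruth(
            proteins=default_sim.truth.proteins.assign(is_interactor=False),
            proximity=default_sim.truth.proximity,
        )
        results = {g: diff_result({"PROT00000": "enriched"}, bait="bait", control=g)
                   for g in ("c_low", "c_eq")}
        report = matching_report(results, titration_design, "bait", truth=truth)
        assert (report.controls["true_positives"] == 0).all()
        assert (report.controls["false_negatives"] == 0).all()
        assert (report.controls["false_positives"] == 1).all()

    def test_zero_bait_expression_rejected(self):
        rows = [
            dict(sample_id="p_r1", group="p", role="no_turbo", replicate=1,
                 turboid_expression=0.0),
            dict(sample_id="c_r1", group="c", role="control", replicate=1,
                 turboid_expression=1.0),
        ]
        design = pm.StudyDesign(pd.DataFrame(rows))
        with pytest.raises(ValueError):
            matching_report({"c": diff_result({"A": "enriched"}, bait="p", control="c")},
                            design, "p")

    def test_mismatched_bait_rejected(self, titration_design):
        res = diff_result({"A": "enriched"}, bait="other", control="c_eq")
        with pytest.raises(DesignError):
            matching_report({"c_eq": res}, titration_design, "bait")


class TestNormalizationDistortion:
    def test_high_expression_control_plus_normalization_flags_endogenous_biotin(self):
        """The ACACA phenomenon: expression-independent biotinylated
        background looks bait-enriched when a high-expression control is
        normalized, but not with a matched control."""
        norm_hi = matched = 0
        for seed in range(5):
            sim = pm.simulate_experiment(pm.SimConfig(seed=seed))
            truth = sim.truth.proteins
            endog = set(truth.index[truth["is_endogenous_biotin"] & ~truth["is_interactor"]])
            m_raw = pm.quantify_pipeline(sim.precursors, normalize=False)
            m_norm = pm.quantify_pipeline(sim.precursors, normalize=True)
            res_matched, _ = pm.fit_moderated(m_raw, sim.design, "bait", "ctrl_matched")
            res_norm_hi, _ = pm.fit_moderated(m_norm, sim.design, "bait", "ctrl_high")
            norm_hi += len(set(res_norm_hi.enriched()) & endog)
            matched += len(set(res_matched.enriched()) & endog)
        assert norm_hi > matched
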