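import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from caseseries import (
    CohortValidationError,
    collapse_test_measures,
    composite_scores,
    deficit_flags,
    deficit_tests,
    dissociation_tests,
    generate_cohort,
    GeneratorConfig,
    orient_measures,
    pattern_label,
    pattern_table,
    pooled_t_from_summary,
)
from caseseries.composites import overlay_report


@pytest.fixture(scope="module")
def analysed():
    """Complete default cohort taken through composites + deficits once."""
    cohort, truth = generate_cohort(GeneratorConfig(missing_rate=0.0), seed=21)
    cohort = orient_measures(cohort)
    sm = collapse_test_measures(cohort)
    comps = composite_scores(sm, cohort)
    defs = deficit_tests(comps, cohort, n_mc=4000, seed=13)
    return cohort, truth, sm, comps, defs


class TestCompositeScores:
    def test_pca_weighted_standardized(self, analysed):
        _, _, _, comps, _ = analysed
        for d in ("word", "object", "face"):
            v = comps.values[d]
            assert v.mean() == pytest.approx(0.0, abs=1e-8)
            assert v.std(ddof=1) == pytest.approx(1.0, abs=1e-8)

    def test_single_test_domain_is_zscore(self):
        from caseseries.cohort import (CohortTable, Direction, Group, Measure,
                                       ParticipantRecord, TestSpec)
        from caseseries.preprocess import ScoreMatrix
        rng = np.random.default_rng(0)
        tests = [
            TestSpec("w1", "word", (Measure("acc", "higher_is_better"),), True),
            TestSpec("o1", "object", (Measure("acc", "higher_is_better"),), True),
            TestSpec("f1", "face", (Measure("acc", "higher_is_better"),), True),
        ]
        parts = [ParticipantRecord(f"s{i}", Group.CONTROL, age=60.0)
                 for i in range(12)]
        vals = rng.normal(size=(12, 3))
        cohort = CohortTable(parts, tests, vals)
        sm = collapse_test_measures(cohort)
        comps = composite_scores(sm, cohort)
        z = (vals[:, 0] - vals[:, 0].mean()) / vals[:, 0].std(ddof=1)
        np.testing.assert_allclose(comps.values["word"].to_numpy(), z, atol=1e-10)

    def test_matches_eigen_oracle(self):
        # 20 subjects x 4 perfectly known tests: composite must equal the
        # leading-eigenvector-weighted z-scores from a direct decomposition
        from caseseries.cohort import (CohortTable, Direction, Group, Measure,
                                       ParticipantRecord, TestSpec)
        rng = np.random.default_rng(1)
        base = rng.standard_normal(20)
        vals = np.column_stack([base + 0.5 * rng.standard_normal(20)
                                for _ in range(4)])
        tests = ([TestSpec(f"w{j}", "word", (Measure("acc", "higher_is_better"),), True)
                  for j in range(4)]
                 + [TestSpec("o1", "object", (Measure("acc", "higher_is_better"),), True),
                    TestSpec("f1", "face", (Measure("acc", "higher_is_better"),), True)])
        parts = [ParticipantRecord(f"s{i}", Group.CONTROL, age=60.0) for i in range(20)]
        allvals = np.column_stack([vals, rng.standard_normal((20, 2))])
        cohort = CohortTable(parts, tests, allvals)
        sm = collapse_test_measures(cohort)
        comps = composite_scores(sm, cohort)
        Z = sm.values[:, :4]
        R = np.corrcoef(Z, rowvar=False)
        lam, vec = np.linalg.eigh(R)
        lead = vec[:, -1] if vec[:, -1].mean() > 0 else -vec[:, -1]
        oracle = (Z @ lead) / np.sqrt(lam[-1])
        np.testing.assert_allclose(comps.values["word"].to_numpy(), oracle,
                                   atol=1e-10)

    def test_rank_sum_order_isomorphic(self, analysed):
        cohort, _, sm, comps, _ = analysed
        rcomps = composite_scores(sm, cohort, method="rank_sum")
        # rank composite must be a monotone function of mean per-test ranks
        from scipy import stats
        for d in ("word", "object", "face"):
            rho = stats.spearmanr(comps.values[d], rcomps.values[d]).statistic
            assert rho > 0.9

    def test_methods_agree_on_flags(self, analysed):
        cohort, _, sm, comps, defs = analysed
        rcomps = composite_scores(sm, cohort, method="rank_sum")
        rdefs = deficit_tests(rcomps, cohort, n_mc=4000, seed=13)
        a = deficit_flags(defs).set_index("participant_id")
        b = deficit_flags(rdefs).set_index("participant_id")
        agree = (a["label"] == b["label"]).mean()
        assert agree >= 0.8


class TestDeficitPatterns:
    def test_pattern_label_mapping(self):
        assert pattern_label(False, False, False) == "NONE"
        assert pattern_label(True, True, True) == "WOF"
        assert pattern_label(True, False, True) == "WF"
        labels = {pattern_label(w, o, f)
                  for w in (0, 1) for o in (0, 1) for f in (0, 1)}
        assert len(labels) == 8

    def test_counts_partition_patients(self, analysed):
        cohort, _, _, _, defs = analysed
        flags = deficit_flags(defs)
        table = pattern_table(flags, cohort)
        assert table["total"].sum() == int(cohort.is_patient.sum())
        # by-laterality columns sum to the totals
        lat = table[["bilateral", "left", "right"]].to_numpy().sum()
        assert lat == table["total"].sum()

    def test_planted_word_cases_flagged(self, analysed):
        cohort, truth, _, _, defs = analysed
        flags = deficit_flags(defs).set_index("participant_id")
        for pid in truth.planted_ids["word"]:
            assert bool(flags.loc[pid, "word"])


class TestDissociations:
    def test_gating_excludes_unimpaired(self, analysed):
        cohort, _, _, comps, defs = analysed
        diss = dissociation_tests(comps, cohort, defs, n_mc=2000, seed=3)
        flags = deficit_flags(defs)
        unimpaired = set(flags.loc[flags.label == "NONE", "participant_id"])
        assert unimpaired.isdisjoint(set(diss.participant_id))

    def test_classical_requires_all_criteria(self, analysed):
        cohort, _, _, comps, defs = analysed
        diss = dissociation_tests(comps, cohort, defs, n_mc=2000, seed=3)
        classical = diss[diss.label == "classical"]
        assert (classical.criterion1_x_deficit
                & classical.criterion2_y_in_range
                & classical.criterion3_diff_significant).all()
        none_rows = diss[~(diss.criterion1_x_deficit
                           & diss.criterion2_y_in_range
                           & diss.criterion3_diff_significant)]
        assert not (none_rows.label == "classical").any()

    def test_planted_selective_case_dissociates(self):
        # a deep, purely word-selective case must yield a classical
        # word/face dissociation most of the time
        hits = total = 0
        for seed in range(5):
            cfg = GeneratorConfig(missing_rate=0.0,
                                  planted_cases=(("word", 4.0, 4),))
            cohort, truth = generate_cohort(cfg, seed=300 + seed)
            cohort = orient_measures(cohort)
            sm = collapse_test_measures(cohort)
            comps = composite_scores(sm, cohort)
            defs = deficit_tests(comps, cohort, n_mc=3000, seed=seed)
            diss = dissociation_tests(comps, cohort, defs, n_mc=3000, seed=seed)
            for pid in truth.planted_ids["word"]:
                sub = diss[(diss.participant_id == pid)
                           & (diss.pair == "word-face")]
                if len(sub):
                    total += 1
                    hits += (sub.label == "classical").any()
        assert total >= 15
        assert hits / total >= 0.9


class TestOverlay:
    def test_rows_and_flags(self, analysed):
        from caseseries import (extract_components, factor_scores,
                                project_controls, rotate_solution,
                                zscore_to_reference)
        cohort, _, _, comps, defs = analysed
        pat = cohort.is_patient
        sm = collapse_test_measures(cohort, fit_mask=pat)
        z = zscore_to_reference(sm, pat)
        sol = rotate_solution(extract_components(z.rows(pat)))
        fs = factor_scores(sol, z.rows(pat))
        ctrl = project_controls(sol, z.rows(~pat))
        fs.control_mean, fs.control_sd, fs.cutoff = (
            ctrl.control_mean, ctrl.control_sd, ctrl.cutoff)
        flags = deficit_flags(defs)
        overlay = overlay_report(fs, flags, cohort)
        assert len(overlay) == int(pat.sum())
        below = overlay["factor1"] < fs.cutoff[0]
        assert (overlay["factor1_below_cutoff"] == below).all()

    def test_id_mismatch_rejected(self, analysed):
        from caseseries import (extract_components, factor_scores,
                                rotate_solution, zscore_to_reference)
        cohort, _, _, _, defs = analysed
        pat = cohort.is_patient
        sm = collapse_test_measures(cohort, fit_mask=pat)
        z = zscore_to_reference(sm, pat)
        sol = rotate_solution(extract_components(z.rows(pat)))
        fs = factor_scores(sol, z.rows(pat))
        fs.cutoff = np.zeros(sol.n_retained)
        flags = deficit_flags(defs).iloc[:-1]
        with pytest.raises(ValueError, match="mismatch"):
            overlay_report(fs, flags, cohort)


class TestPooledT:
    def test_equal_means_zero(self):
        t, df, p = pooled_t_from_summary(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_lesion_volume_right_vs_bilateral(self):
        t, df, _ = pooled_t_from_summary(61.4, 37.9, 9, 34.7, 39.2, 23)
        assert df == 30
        assert round(abs(t), 2) == 1.75

    def test_time_since_stroke_comparisons(self):
        t1, df1, _ = pooled_t_from_summary(42.3, 48.0, 32, 42.0, 59.4, 23)
        assert (df1, round(abs(t1), 2)) == (53, 0.02)
        t2, df2, _ = pooled_t_from_summary(42.3, 48.0, 32, 40.0, 28.5, 9)
        assert (df2, round(abs(t2), 2)) == (39, 0.14)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            pooled_t_from_summary(1.0, 1.0, 1, 2.0, 1.0, 5)
        with pytest.raises(ValueError):
            pooled_t_from_summary(1.0, 0.0, 5, 2.0, 0.0, 5)
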