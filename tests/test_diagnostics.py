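import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from growthdx.diagnostics import (
    ContingencyTable,
    build_table,
    clopper_pearson,
    compare_proportions,
    compare_rr,
    diagnostic_summary,
    mcnemar_from_discordant,
    mcnemar_test,
    operating_point_metrics,
    relative_risk,
)
from growthdx.errors import DomainError, EmptyAnalysisError

cell = st.integers(min_value=1, max_value=200)


class TestContingencyTable:
    def test_counts_conserved(self):
        table = ContingencyTable(tp=2, fp=3, fn=4, tn=5, excluded_lga=1, excluded_overnourished=2)
        assert table.n_eligible == 14
        assert table.n_total == 17

    def test_negative_counts_rejected(self):
        with pytest.raises(DomainError):
            ContingencyTable(tp=-1, fp=0, fn=0, tn=1)

    def test_empty_table_rejected(self):
        with pytest.raises(EmptyAnalysisError):
            ContingencyTable(tp=0, fp=0, fn=0, tn=0)


class TestBuildTable:
    def test_one_of_each(self, toy_classifications):
        table = build_table(toy_classifications)
        assert (table.tp, table.fp, table.fn, table.tn) == (1, 1, 1, 1)

    def test_lga_excluded(self, toy_classifications):
        extra = pd.concat(
            [
                toy_classifications,
                pd.DataFrame({"size_class": ["LGA"], "nutrition": ["normal"]}),
            ]
        )
        table = build_table(extra)
        assert (table.tp, table.fp, table.fn, table.tn) == (1, 1, 1, 1)
        assert table.excluded_lga == 1
        assert table.n_total == 5

    def test_overnourished_and_out_of_coverage_excluded(self, toy_classifications):
        extra = pd.concat(
            [
                toy_classifications,
                pd.DataFrame(
                    {
                        "size_class": ["SGA", "AGA"],
                        "nutrition": ["overnourished", "out_of_coverage"],
                    }
                ),
            ]
        )
        table = build_table(extra)
        assert table.excluded_overnourished == 1
        assert table.excluded_out_of_coverage == 1
        assert table.n_eligible == 4

    def test_empty_eligible_set_raises(self):
        frame = pd.DataFrame({"size_class": ["LGA"], "nutrition": ["normal"]})
        with pytest.raises(EmptyAnalysisError):
            build_table(frame)

    def test_matches_brute_force_enumeration(self, rng):
        """Oracle: independent filter-and-count loop over random cohorts."""
        sizes = np.array(["SGA", "AGA", "LGA"])
        statuses = np.array(["undernourished", "normal", "overnourished", "out_of_coverage"])
        for _ in range(50):
            n = int(rng.integers(5, 80))
            frame = pd.DataFrame(
                {
                    "size_class": rng.choice(sizes, n, p=[0.25, 0.6, 0.15]),
                    "nutrition": rng.choice(statuses, n, p=[0.2, 0.6, 0.1, 0.1]),
                }
            )
            tp = fp = fn = tn = 0
            for _, row in frame.iterrows():
                if row["size_class"] == "LGA" or row["nutrition"] in (
                    "overnourished",
                    "out_of_coverage",
                ):
                    continue
                if row["size_class"] == "SGA" and row["nutrition"] == "undernourished":
                    tp += 1
                elif row["size_class"] == "SGA":
                    fp += 1
                elif row["nutrition"] == "undernourished":
                    fn += 1
                else:
                    tn += 1
            if tp + fp + fn + tn == 0:
                with pytest.raises(EmptyAnalysisError):
                    build_table(frame)
                continue
            table = build_table(frame)
            assert (table.tp, table.fp, table.fn, table.tn) == (tp, fp, fn, tn)
            assert table.n_total == n


class TestDiagnosticSummary:
    def test_uninformative_table(self):
        summary = diagnostic_summary(ContingencyTable(tp=7, fp=7, fn=7, tn=7))
        assert summary.sensitivity.estimate == pytest.approx(0.5)
        assert summary.specificity.estimate == pytest.approx(0.5)
        assert summary.ppv.estimate == pytest.approx(0.5)
        assert summary.npv.estimate == pytest.approx(0.5)
        assert summary.lr_pos.estimate == pytest.approx(1.0)
        assert summary.lr_neg.estimate == pytest.approx(1.0)
        assert summary.dor.estimate == pytest.approx(1.0)
        assert summary.youden.estimate == pytest.approx(0.0)

    def test_published_operating_point_bmi_customized(self):
        metrics = operating_point_metrics(0.60, 0.7874)
        assert round(metrics["lr_pos"], 2) == 2.82
        assert round(metrics["lr_neg"], 2) == 0.51
        assert round(metrics["dor"], 2) == pytest.approx(5.56, abs=0.02)
        assert round(metrics["youden"], 2) == 0.39

    def test_published_operating_point_bmi_population(self):
        metrics = operating_point_metrics(0.40, 0.879)
        assert round(metrics["lr_pos"], 2) == 3.31
        assert round(metrics["lr_neg"], 2) == 0.68
        assert round(metrics["dor"], 2) == pytest.approx(4.84, abs=0.02)
        assert round(metrics["youden"], 2) == 0.28

    def test_operating_point_rejects_degenerate_inputs(self):
        with pytest.raises(DomainError):
            operating_point_metrics(0.0, 0.5)

    def test_zero_cell_flags_ratio_metrics_undefined(self):
        summary = diagnostic_summary(ContingencyTable(tp=5, fp=0, fn=3, tn=10))
        assert not summary.lr_pos.defined
        assert summary.sensitivity.defined

    def test_continuity_correction_is_logged_not_silent(self):
        summary = diagnostic_summary(ContingencyTable(tp=5, fp=0, fn=3, tn=10), continuity=True)
        assert summary.lr_pos.defined
        assert "continuity" in summary.lr_pos.note

    def test_youden_delta_and_bootstrap_both_bracket_point(self):
        table = ContingencyTable(tp=9, fp=36, fn=6, tn=155)
        for method in ("bootstrap", "delta"):
            summary = diagnostic_summary(table, youden_ci=method, seed=3)
            youden = summary.youden
            assert youden.ci_low <= youden.estimate <= youden.ci_high

    def test_youden_bootstrap_is_seeded(self):
        table = ContingencyTable(tp=9, fp=36, fn=6, tn=155)
        a = diagnostic_summary(table, seed=5).youden
        b = diagnostic_summary(table, seed=5).youden
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    @given(tp=cell, fp=cell, fn=cell, tn=cell)
    @settings(max_examples=100, deadline=None)
    def test_dor_identity(self, tp, fp, fn, tn):
        table = ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)
        summary = diagnostic_summary(table, youden_ci="delta")
        direct = (tp * tn) / (fp * fn)
        assert summary.dor.estimate == pytest.approx(direct, rel=1e-9)
        assert summary.dor.estimate == pytest.approx(
            summary.lr_pos.estimate / summary.lr_neg.estimate, rel=1e-9
        )

    @given(tp=cell, fp=cell, fn=cell, tn=cell)
    @settings(max_examples=100, deadline=None)
    def test_youden_identity(self, tp, fp, fn, tn):
        summary = diagnostic_summary(
            ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn), youden_ci="delta"
        )
        assert summary.youden.estimate == pytest.approx(
            summary.sensitivity.estimate + summary.specificity.estimate - 1.0, abs=1e-12
        )

    @given(tp=cell, fp=cell, fn=cell, tn=cell)
    @settings(max_examples=50, deadline=None)
    def test_label_swap_duality(self, tp, fp, fn, tn):
        table = ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)
        swapped = table.swapped()
        s = diagnostic_summary(table, youden_ci="delta")
        t = diagnostic_summary(swapped, youden_ci="delta")
        assert t.sensitivity.estimate == pytest.approx(s.specificity.estimate)
        assert t.specificity.estimate == pytest.approx(s.sensitivity.estimate)
        assert t.ppv.estimate == pytest.approx(s.npv.estimate)
        assert t.npv.estimate == pytest.approx(s.ppv.estimate)
        assert t.lr_pos.estimate == pytest.approx(1.0 / s.lr_neg.estimate, rel=1e-9)
        # DOR is invariant under the joint exposure+outcome relabelling
        assert t.dor.estimate == pytest.approx(s.dor.estimate, rel=1e-9)

    @given(tp=cell, fp=cell, fn=cell, tn=cell)
    @settings(max_examples=50, deadline=None)
    def test_cis_bracket_point_estimates(self, tp, fp, fn, tn):
        summary = diagnostic_summary(
            ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn), youden_ci="delta"
        )
        for metric in summary.metrics().values():
            if metric.defined:
                assert metric.ci_low <= metric.estimate + 1e-12
                assert metric.estimate <= metric.ci_high + 1e-12

    def test_clopper_pearson_covers_printed_style_interval(self):
        # exact interval at a small count has the familiar wide shape
        low, high = clopper_pearson(6, 15)
        assert low < 6 / 15 < high
        assert high - low > 0.3


class TestRelativeRisk:
    def test_toy_table(self):
        result = relative_risk(ContingencyTable(tp=9, fp=36, fn=6, tn=155))
        assert result.rr == pytest.approx(5.366666666666667, rel=1e-12)
        assert result.ci_low <= result.rr <= result.ci_high

    def test_equal_risks_give_unity_and_ci_contains_one(self):
        result = relative_risk(ContingencyTable(tp=10, fp=90, fn=10, tn=90))
        assert result.rr == pytest.approx(1.0)
        assert result.ci_low < 1.0 < result.ci_high

    @given(tp=cell, fp=cell, fn=cell, tn=cell)
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_ratio(self, tp, fp, fn, tn):
        result = relative_risk(ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn))
        brute = (tp / (tp + fp)) / (fn / (fn + tn))
        assert result.rr == pytest.approx(brute, rel=1e-12)

    def test_zero_events_require_explicit_continuity(self):
        table = ContingencyTable(tp=0, fp=20, fn=5, tn=75)
        with pytest.raises(DomainError):
            relative_risk(table)
        corrected = relative_risk(table, continuity=True)
        assert corrected.continuity_corrected
        assert corrected.rr > 0

    def test_katz_se_formula(self):
        table = ContingencyTable(tp=9, fp=36, fn=6, tn=155)
        result = relative_risk(table)
        expected_se = math.sqrt(1 / 9 - 1 / 45 + 1 / 6 - 1 / 161)
        assert result.log_se == pytest.approx(expected_se, rel=1e-12)


class TestCompareRR:
    def test_identical_rrs(self):
        rr = relative_risk(ContingencyTable(tp=9, fp=36, fn=6, tn=155))
        comp = compare_rr(rr, rr)
        assert comp.ratio == pytest.approx(1.0)
        assert comp.p_value == pytest.approx(1.0)

    def test_three_four_five_se(self):
        from growthdx.diagnostics import RiskRatioResult

        rr1 = RiskRatioResult(rr=2.0, ci_low=1.0, ci_high=4.0, log_se=0.3)
        rr2 = RiskRatioResult(rr=2.0, ci_low=1.0, ci_high=4.0, log_se=0.4)
        comp = compare_rr(rr1, rr2)
        # SE_diff = 0.5 exactly; CI half-width on the log scale is 1.96 * 0.5
        assert math.log(comp.ci_high / comp.ratio) == pytest.approx(1.959964 * 0.5, abs=1e-5)

    def test_p_matches_direct_normal_formula(self):
        from scipy.stats import norm

        rr1 = relative_risk(ContingencyTable(tp=9, fp=36, fn=6, tn=155))
        rr2 = relative_risk(ContingencyTable(tp=5, fp=45, fn=9, tn=141))
        comp = compare_rr(rr1, rr2)
        z = (math.log(rr1.rr) - math.log(rr2.rr)) / math.sqrt(
            rr1.log_se**2 + rr2.log_se**2
        )
        assert comp.p_value == pytest.approx(2 * norm.sf(abs(z)), rel=1e-9)


class TestMcNemar:
    def test_symmetric_discordance(self):
        assert mcnemar_from_discordant(5, 5).p_value == pytest.approx(1.0)

    def test_one_sided_doubling(self):
        result = mcnemar_from_discordant(9, 0)
        assert result.method == "exact"
        assert result.p_value == pytest.approx(2 * 0.5**9, rel=1e-12)

    def test_zero_discordant_warns_p_one(self):
        with pytest.warns(UserWarning):
            result = mcnemar_from_discordant(0, 0)
        assert result.p_value == 1.0

    def test_asymptotic_switch_at_25(self):
        assert mcnemar_from_discordant(20, 4).method == "exact"
        assert mcnemar_from_discordant(20, 5).method == "chi2-cc"

    def test_exact_matches_tail_sum_oracle(self, rng):
        from scipy.special import comb

        for _ in range(25):
            b = int(rng.integers(0, 12))
            c = int(rng.integers(0, 12))
            if b + c == 0:
                continue
            n = b + c
            k = min(b, c)
            tail = sum(comb(n, i, exact=True) for i in range(k + 1)) * 0.5**n
            expected = min(1.0, 2.0 * tail)
            assert mcnemar_from_discordant(b, c).p_value == pytest.approx(expected, rel=1e-9)

    def test_paired_interface_counts_discordants(self):
        m1 = [True, True, False, False, True]
        m2 = [True, False, True, False, False]
        result = mcnemar_test(m1, m2)
        assert (result.b, result.c) == (2, 1)

    def test_matches_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.stats.contingency_tables")
        for b, c in ((3, 8), (15, 30), (0, 7)):
            ours = mcnemar_from_discordant(b, c)
            theirs = statsmodels.mcnemar(
                [[1, b], [c, 1]], exact=(b + c < 25), correction=True
            )
            assert ours.p_value == pytest.approx(float(theirs.pvalue), rel=1e-6)


class TestCompareProportions:
    def test_equal_proportions(self):
        result = compare_proportions(20, 100, 40, 200)
        assert result.chi2 == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0)

    def test_printed_sga_frequencies(self):
        # frozen textbook chi-square arithmetic for 45/226 vs 27/226
        result = compare_proportions(45, 226, 27, 226)
        assert result.chi2 == pytest.approx(5.352631578947, rel=1e-9)
        assert result.p_value == pytest.approx(0.0206910, abs=1e-6)

    def test_doubling_counts_doubles_chi2(self):
        base = compare_proportions(30, 100, 20, 100)
        doubled = compare_proportions(60, 200, 40, 200)
        assert doubled.chi2 == pytest.approx(2 * base.chi2, rel=1e-12)

    def test_sparse_table_falls_back_to_exact(self):
        with pytest.warns(UserWarning):
            result = compare_proportions(0, 300, 1, 3)
        assert result.method == "fisher-exact"

    def test_paired_alternative(self):
        result = compare_proportions(45, 226, 27, 226, paired_discordant=(20, 2))
        assert result.method == "mcnemar"
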