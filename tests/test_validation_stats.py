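"""Agreement metrics, ISO 81060-2 criteria, hypothesis tests and BP grading."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rppg_vitals import validation_stats as vs


def _pairs(pred, ref, ids=None):
    pred = np.asarray(pred, dtype=float)
    if ids is None:
        ids = np.arange(len(pred))
    return vs.PairedReadings(subject_id=np.asarray(ids), predicted=pred,
                             reference=np.asarray(ref, dtype=float))


class TestMape:
    def test_perfect_agreement_is_zero(self):
        assert vs.mape(_pairs([120, 80], [120, 80])) == 0.0

    def test_single_ratio(self):
        assert vs.mape(_pairs([110], [100])) == pytest.approx(10.0)

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(0)
        pred, ref = rng.uniform(90, 150, 200), rng.uniform(90, 150, 200)
        acc = 0.0
        for p, r in zip(pred, ref):
            acc += abs(p - r) / abs(r)
        assert vs.mape(_pairs(pred, ref)) == pytest.approx(100 * acc / 200, rel=1e-12)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            vs.mape(_pairs([1.0], [0.0]))


class TestPairedDifferenceSummary:
    def test_identical_arrays(self):
        assert vs.paired_difference_summary(_pairs([1, 2, 3], [1, 2, 3])) == (0, 0, 0)

    def test_hand_arithmetic(self):
        mean, sd, ci = vs.paired_difference_summary(_pairs([1, -1], [0, 0]))
        assert mean == 0.0
        assert sd == pytest.approx(np.sqrt(2))
        assert ci == pytest.approx(1.96 * np.sqrt(2) / np.sqrt(2))

    def test_published_sbp_aggregate_means(self):
        # mean predicted 131.46 vs mean reference 128.77 => mean difference 2.69
        mean, _, _ = vs.paired_difference_summary(
            _pairs([131.46, 131.46], [128.77, 128.77]))
        assert round(mean, 2) == 2.69

    def test_absolute_convention_for_dbp(self):
        mean, _, _ = vs.paired_difference_summary(
            _pairs([75.38, 75.38], [75.54, 75.54]), signed=False)
        assert round(mean, 2) == 0.16

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            vs.paired_difference_summary(_pairs([1.0], [0.0]))


class TestBlandAltman:
    def test_constant_difference_collapses_limits(self):
        bias, lo, hi = vs.bland_altman(_pairs([103, 105, 107], [100, 102, 104]))
        assert bias == pytest.approx(3.0)
        assert lo == pytest.approx(3.0) and hi == pytest.approx(3.0)

    def test_limits_symmetric_about_bias(self):
        rng = np.random.default_rng(1)
        ref = rng.uniform(90, 150, 100)
        bias, lo, hi = vs.bland_altman(_pairs(ref + rng.normal(2, 5, 100), ref))
        assert hi - bias == pytest.approx(bias - lo)

    def test_normal_coverage_near_95_percent(self):
        rng = np.random.default_rng(2026)
        ref = np.full(10000, 100.0)
        d = rng.normal(0.0, 1.0, 10000)
        pairs = _pairs(ref + d, ref)
        bias, lo, hi = vs.bland_altman(pairs)
        frac = np.mean((pairs.differences > lo) & (pairs.differences < hi))
        assert abs(frac - 0.95) < 0.01

    def test_plot_artifact_written(self, tmp_path):
        out = tmp_path / "ba.png"
        vs.bland_altman(_pairs([101, 99, 104], [100, 100, 100]), plot_path=out)
        assert out.exists() and out.stat().st_size > 0


class TestISOCriterion1:
    def test_published_sbp_values_pass(self):
        assert vs.criterion1_verdict(2.68, 7.86) == (True, True, True)

    def test_sd_bound_violation_fails(self):
        assert vs.criterion1_verdict(0.0, 8.5)[2] is False

    def test_mean_bound_violation_fails(self):
        mean_ok, sd_ok, overall = vs.criterion1_verdict(6.0, 3.0)
        assert (mean_ok, sd_ok, overall) == (False, True, False)

    def test_from_pairs(self):
        rng = np.random.default_rng(3)
        ref = rng.uniform(100, 160, 300)
        pairs = _pairs(ref + rng.normal(1.0, 4.0, 300), ref)
        mean, sd, ok = vs.iso_criterion1(pairs)
        assert ok
        assert mean == pytest.approx(pairs.differences.mean())
        assert sd == pytest.approx(pairs.differences.std(ddof=1))


class TestPerSubjectErrors:
    def test_one_reading_per_subject_is_identity(self):
        pairs = _pairs([101, 102], [100, 100], ids=["a", "b"])
        np.testing.assert_allclose(vs.per_subject_errors(pairs), [1.0, 2.0])

    def test_subject_average(self):
        pairs = _pairs([102, 104], [100, 100], ids=["s", "s"])
        np.testing.assert_allclose(vs.per_subject_errors(pairs), [3.0])

    def test_matches_naive_per_subject_loop(self):
        rng = np.random.default_rng(4)
        ids = rng.choice(["a", "b", "c", "d"], 50)
        ref = rng.uniform(100, 150, 50)
        pairs = _pairs(ref + rng.normal(0, 3, 50), ref, ids=ids)
        got = vs.per_subject_errors(pairs)
        seen, expected = [], []
        for i, sid in enumerate(ids):
            if sid not in seen:
                seen.append(sid)
        for sid in seen:
            expected.append(pairs.differences[ids == sid].mean())
        np.testing.assert_allclose(got, expected, rtol=1e-12)


class TestISOCriterion2Threshold:
    def test_zero_mean_threshold(self):
        assert round(vs.iso_criterion2_threshold(0.0), 2) == 6.95

    def test_sbp_mean_threshold(self):
        assert round(vs.iso_criterion2_threshold(2.9), 2) == 6.30

    def test_zero_mean_closed_form(self):
        # at m=0 the condition reduces to 2*Phi(10/s) - 1 = 0.85
        z = stats.norm.ppf(0.925)
        assert vs.iso_criterion2_threshold(0.0) == pytest.approx(10.0 / z, abs=1e-4)

    def test_symmetric_and_decreasing_in_abs_mean(self):
        ms = [0.0, 1.0, 3.0, 6.0, 9.0, 9.9]
        ts = [vs.iso_criterion2_threshold(m) for m in ms]
        assert all(a > b for a, b in zip(ts, ts[1:]))
        for m in ms[1:]:
            assert vs.iso_criterion2_threshold(-m) == pytest.approx(
                vs.iso_criterion2_threshold(m), abs=1e-3)
        assert ts[-1] < 0.5  # threshold collapses toward 0 as |m| -> 10

    def test_bisection_agrees_with_scipy_root(self):
        from scipy.optimize import brentq
        for m in (0.0, 2.9, 5.0):
            f = lambda s: (stats.norm.cdf((10 - m) / s)
                           - stats.norm.cdf((-10 - m) / s) - 0.85)
            assert vs.iso_criterion2_threshold(m) == pytest.approx(
                brentq(f, 1e-6, 50.0), abs=2e-4)

    def test_infeasible_mean_rejected(self):
        with pytest.raises(ValueError):
            vs.iso_criterion2_threshold(10.0)


class TestISOCriterion2:
    def test_published_sbp_fails(self):
        sd_max, ok = vs.criterion2_verdict(2.92, 8.02)
        assert round(sd_max, 2) == 6.30 and not ok

    def test_published_dbp_passes(self):
        sd_max, ok = vs.criterion2_verdict(0.27, 3.43)
        assert ok and sd_max > 6.9

    def test_all_zero_errors_pass(self):
        pairs = _pairs([100, 120, 130], [100, 120, 130], ids=["a", "b", "c"])
        mean, sd, sd_max, ok = vs.iso_criterion2(pairs)
        assert (mean, sd) == (0.0, 0.0) and ok

    def test_per_subject_averaging_changes_result(self):
        # two discordant readings per subject cancel under per-subject averaging
        ids = ["a", "a", "b", "b"]
        pairs = _pairs([110, 90, 125, 115], [100, 100, 120, 120], ids=ids)
        _, sd_subj, _, _ = vs.iso_criterion2(pairs, per_subject=True)
        _, sd_meas, _, _ = vs.iso_criterion2(pairs, per_subject=False)
        assert sd_subj < sd_meas


class TestNormalityTest:
    def test_null_retention_rate(self):
        rng = np.random.default_rng(0)
        retained = sum(vs.normality_test(rng.normal(size=500))[1] > 0.05
                       for _ in range(100))
        assert retained >= 90

    def test_power_against_heavy_tails(self):
        rng = np.random.default_rng(1)
        _, p = vs.normality_test(rng.standard_t(df=2, size=500))
        assert p < 0.001

    def test_constant_input_degenerate(self):
        with pytest.raises(ValueError):
            vs.normality_test(np.full(10, 3.0))

    def test_out_of_range_n(self):
        with pytest.raises(ValueError):
            vs.normality_test([1.0, 2.0])


class TestWilcoxon:
    def test_all_positive_exact_p(self):
        pairs = _pairs([1, 2, 3, 4, 5, 6], [0, 0, 0, 0, 0, 0])
        stat, p = vs.wilcoxon_signed_rank(pairs)
        assert p == pytest.approx(2 / 64)
        assert stat == 0.0

    def test_identical_pairs_degenerate(self):
        assert vs.wilcoxon_signed_rank(_pairs([1, 2, 3], [1, 2, 3])) == (0.0, 1.0)

    def test_antisymmetric_differences_central(self):
        pairs = _pairs([3, -3, 2, -2, 1, -1], [0, 0, 0, 0, 0, 0])
        stat, p = vs.wilcoxon_signed_rank(pairs)
        assert p > 0.9

    def test_enumeration_agrees_with_scipy_exact(self):
        # 100 random tie-free instances across n = 5..12
        rng = np.random.default_rng(6)
        for _ in range(100):
            n = int(rng.integers(5, 13))
            d = rng.normal(0.7, 1.0, n)
            while (d == 0).any() or len(np.unique(np.abs(d))) < n:
                d = rng.normal(0.7, 1.0, n)
            pairs = _pairs(d, np.zeros(n))
            _, p_enum = vs.wilcoxon_signed_rank(pairs)
            p_scipy = stats.wilcoxon(d, method="exact",
                                     alternative="two-sided").pvalue
            assert p_enum == pytest.approx(min(1.0, p_scipy), abs=1e-12)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(7)
        d = rng.normal(2.0, 1.0, 200)
        _, p = vs.wilcoxon_signed_rank(_pairs(d, np.zeros(200)))
        assert p < 1e-10


class TestClassifyBP:
    @pytest.mark.parametrize("sbp,dbp,expected", [
        (119, 79, vs.BPCategory.optimal),
        (100, 75, vs.BPCategory.hypotension),
        (135, 95, vs.BPCategory.grade1),
        (110, 60, vs.BPCategory.hypotension),
        (125, 75, vs.BPCategory.normal),
        (119, 85, vs.BPCategory.normal),
        (150, 85, vs.BPCategory.grade1),
        (165, 75, vs.BPCategory.grade2_3),
        (130, 105, vs.BPCategory.grade2_3),
        (185, 110, vs.BPCategory.grade2_3),
    ])
    def test_grading_examples(self, sbp, dbp, expected):
        assert vs.classify_bp(sbp, dbp) == expected

    @given(sbp=st.floats(101, 240), dbp=st.floats(61, 140), bump=st.floats(0, 30))
    @settings(max_examples=100, derandomize=True)
    def test_raising_bp_never_lowers_category(self, sbp, dbp, bump):
        order = [vs.BPCategory.optimal, vs.BPCategory.normal,
                 vs.BPCategory.grade1, vs.BPCategory.grade2_3]
        base = vs.classify_bp(sbp, dbp)
        higher = vs.classify_bp(sbp + bump, dbp)
        assert order.index(higher) >= order.index(base)


class TestCohortComposition:
    @staticmethod
    def _table3_cohort():
        # 200 patients realizing the sampling counts: SBP 16 hypotensive,
        # 36 in 140-159, 16 at >=160; DBP 8 hypotensive, 27 at >=85, 0 at >=100
        import pandas as pd
        sbp = np.concatenate([np.full(16, 95.0), np.full(36, 145.0),
                              np.full(16, 165.0), np.full(132, 125.0)])
        dbp = np.concatenate([np.full(8, 55.0), np.full(27, 90.0),
                              np.full(165, 75.0)])
        return pd.DataFrame({"sbp": sbp, "dbp": dbp})

    def test_reproduces_iso_comparison_table(self):
        comp = self._table3_cohort().pipe(vs.cohort_composition)
        by = comp.set_index("range")
        assert by.loc["sbp_le_100", "percent"] == pytest.approx(8.0)
        assert by.loc["sbp_ge_140", "percent"] == pytest.approx(26.0)
        assert by.loc["sbp_ge_160", "percent"] == pytest.approx(8.0)
        assert by.loc["dbp_le_60", "percent"] == pytest.approx(4.0)
        assert by.loc["dbp_ge_85", "percent"] == pytest.approx(13.5)
        assert by.loc["dbp_ge_100", "percent"] == pytest.approx(0.0)
        assert list(by["meets_minimum"]) == [True, True, True, False, False, False]

    def test_empty_category_fails_positive_minimum(self):
        import pandas as pd
        labels = pd.DataFrame({"sbp": [125.0] * 10, "dbp": [75.0] * 10})
        comp = vs.cohort_composition(labels).set_index("range")
        assert comp.loc["sbp_ge_160", "percent"] == 0.0
        assert not comp.loc["sbp_ge_160", "meets_minimum"]


class TestAgreementReport:
    def test_internal_consistency(self):
        rng = np.random.default_rng(8)
        ref = rng.uniform(100, 160, 500)
        rep = vs.agreement_report(_pairs(ref + rng.normal(1, 5, 500), ref))
        assert rep.ba_loa_low == pytest.approx(rep.ba_bias - 1.96 * rep.sd_diff)
        assert rep.ba_loa_high == pytest.approx(rep.ba_bias + 1.96 * rep.sd_diff)
        assert rep.mape >= 0
        assert rep.n == 500
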