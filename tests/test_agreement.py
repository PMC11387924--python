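"""Agreement statistics against independent oracles and closed forms."""

import numpy as np
import pytest
from scipy import stats

from nightvitals import (
    ConfusionMatrix2x2,
    InputError,
    InsufficientDataError,
    PairedAgreement,
    UndefinedResultError,
    abs_error_quantiles,
    bland_altman,
    icc_two_way_random,
    mae_mape,
    mcc,
    mdc_from_sd,
    r_squared,
    sad,
)


def brute_force_icc21(y):
    """ICC(2,1) from explicit ANOVA sums of squares, written out longhand
    as an independent oracle."""
    y = np.asarray(y, dtype=float)
    n, k = y.shape
    grand = y.mean()
    ss_rows = sum(k * (y[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (y[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((y[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestBlandAltman:
    def test_zero_differences(self):
        ba = bland_altman(np.full(10, 60.0), np.full(10, 60.0))
        assert ba.bias == 0.0 and ba.sd_diff == 0.0
        assert ba.loa_lower == ba.loa_upper == 0.0 and ba.mdc == 0.0

    def test_mdc_from_printed_sd(self):
        # SD of nightly differences 1.66 bpm -> MDC 3.25 bpm
        assert round(mdc_from_sd(1.66), 2) == 3.25

    def test_matches_direct_formula_evaluation(self):
        rng = np.random.default_rng(0)
        d = rng.normal(0.5, 2.0, 40)
        ba = bland_altman(d)
        n = d.size
        bias = d.mean()
        sd = d.std(ddof=1)
        tq = stats.t.ppf(0.975, n - 1)
        assert ba.bias == pytest.approx(bias)
        assert ba.sd_diff == pytest.approx(sd)
        assert ba.loa_lower == pytest.approx(bias - 1.96 * sd)
        assert ba.loa_upper == pytest.approx(bias + 1.96 * sd)
        assert ba.bias_ci[0] == pytest.approx(bias - tq * sd / np.sqrt(n))
        assert ba.loa_upper_ci[1] == pytest.approx(
            bias + 1.96 * sd + tq * sd * np.sqrt(3 / n))
        assert ba.mdc == pytest.approx((ba.loa_upper - ba.loa_lower) / 2)

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            bland_altman(np.array([1.0, 2.0]))


class TestMaeMape:
    def test_identical_series(self):
        mae, _, mape, _ = mae_mape(np.full(5, 60.0), np.full(5, 60.0))
        assert mae == 0.0 and mape == 0.0

    def test_ten_percent_scaling(self):
        ref = np.linspace(50, 80, 20)
        _, _, mape, _ = mae_mape(ref * 1.10, ref)
        assert mape == pytest.approx(10.0)

    def test_per_participant_t_interval_closed_form(self):
        # three participants with per-participant MAPE 2, 4, 6 %
        ref = np.full(30, 100.0)
        dev = ref.copy()
        ids = np.repeat(["a", "b", "c"], 10)
        for pid, pct in zip("abc", (2.0, 4.0, 6.0)):
            dev[ids == pid] *= 1 + pct / 100
        _, _, mape, ci = mae_mape(dev, ref, participant_ids=ids,
                                  aggregate="per_participant")
        assert mape == pytest.approx(4.0)
        half = stats.t.ppf(0.975, 2) * 2.0 / np.sqrt(3)  # sd({2,4,6}) = 2
        assert ci == pytest.approx((4.0 - half, 4.0 + half))

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(InputError):
            mae_mape(np.ones(3), np.array([1.0, 0.0, 2.0]))


class TestSad:
    def test_equal_means(self):
        x = np.array([59.0, 61.0, 63.0])
        assert sad(x, x.copy()) == 0.0

    def test_half_when_means_one_apart_pooled_sd_two(self):
        dev = np.array([60.0, 62.0, 64.0])   # mean 62, sd 2
        ref = np.array([59.0, 61.0, 63.0])   # mean 61, sd 2
        assert sad(dev, ref) == pytest.approx(0.5)

    def test_matches_textbook_cohens_d(self):
        rng = np.random.default_rng(5)
        a = rng.normal(62, 3, 50)
        b = rng.normal(60, 4, 50)
        s2 = ((49 * a.var(ddof=1) + 49 * b.var(ddof=1)) / 98)
        expected = abs(a.mean() - b.mean()) / np.sqrt(s2)
        assert sad(a, b) == pytest.approx(expected)

    def test_diff_denominator(self):
        dev = np.array([61.0, 63.0, 66.0])
        ref = np.array([60.0, 61.0, 63.0])
        d = dev - ref
        assert sad(dev, ref, denominator="diff") == pytest.approx(
            abs(d.mean()) / d.std(ddof=1))

    def test_zero_sd_nonzero_difference_undefined(self):
        with pytest.raises(UndefinedResultError):
            sad(np.full(3, 61.0), np.full(3, 60.0))


class TestIcc:
    def test_perfect_agreement(self):
        x = np.linspace(50, 80, 8)
        res = icc_two_way_random(np.column_stack([x, x]))
        assert res.icc == 1.0

    def test_dominant_noise_drives_icc_to_zero(self):
        rng = np.random.default_rng(1)
        subj = rng.normal(60, 0.5, 400)
        noisy = subj + rng.normal(0, 25, 400)
        res = icc_two_way_random(np.column_stack([noisy, subj]))
        assert res.icc < 0.1

    def test_matches_brute_force_anova(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            y = rng.normal(60, 5, (6, 2)) + rng.normal(0, 2, (6, 1))
            res = icc_two_way_random(y)
            assert res.icc_raw == pytest.approx(brute_force_icc21(y), abs=1e-12)

    def test_matches_pingouin(self):
        """Cross-check estimate and CI against the reference implementation."""
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(3)
        y = rng.normal(60, 8, (12, 1)) + rng.normal(0, 2, (12, 2))
        res = icc_two_way_random(y)
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(12), 2),
            "raters": np.tile(["dev", "ref"], 12),
            "score": y.ravel()})
        table = pg.intraclass_corr(df, targets="targets", raters="raters",
                                   ratings="score")
        # single-measure absolute agreement row (ICC(2,1) in the two-way
        # random-effects convention)
        row = table[table.Type.str.contains(r"A,1|ICC2", regex=True)].iloc[0]
        assert res.icc_raw == pytest.approx(row.ICC, abs=1e-9)
        ci_col = "CI95" if "CI95" in table.columns else "CI95%"
        assert res.ci[0] == pytest.approx(row[ci_col][0], abs=0.015)
        assert res.ci[1] == pytest.approx(row[ci_col][1], abs=0.015)

    def test_degenerate_between_subject_variance(self):
        with pytest.warns(UserWarning):
            res = icc_two_way_random(np.full((6, 2), 60.0))
        assert res.icc == 0.0

    def test_equals_pearson_in_no_bias_equal_variance_limit(self):
        rng = np.random.default_rng(7)
        subj = rng.normal(60, 8, 1000)
        a = subj + rng.normal(0, 2, 1000)
        b = subj + rng.normal(0, 2, 1000)
        res = icc_two_way_random(np.column_stack([a, b]))
        pearson = stats.pearsonr(a, b).statistic
        assert res.icc == pytest.approx(pearson, abs=0.02)


class TestRegression:
    def test_exact_line(self):
        x = np.linspace(0, 10, 20)
        res = r_squared(x, 2 * x + 1)
        assert res.r2 == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(0)
        res = r_squared(rng.normal(size=5000), rng.normal(size=5000))
        assert res.r2 < 0.01

    def test_matches_normal_equations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 6.0])
        y = np.array([2.1, 3.9, 6.2, 8.1, 11.8])
        # hand solution of the normal equations
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        intercept = y.mean() - slope * x.mean()
        resid = y - (slope * x + intercept)
        r2 = 1 - (resid ** 2).sum() / ((y - y.mean()) ** 2).sum()
        res = r_squared(x, y)
        assert (res.slope, res.intercept, res.r2) == pytest.approx(
            (slope, intercept, r2))

    def test_constant_x_rejected(self):
        with pytest.raises(InputError):
            r_squared(np.full(5, 3.0), np.arange(5.0))


class TestMcc:
    def test_perfect_classifier(self):
        assert mcc(ConfusionMatrix2x2(tp=10, fp=0, fn=0, tn=10)) == 1.0

    def test_snorer_counts(self):
        assert round(mcc(ConfusionMatrix2x2(tp=17, fp=0, fn=5, tn=8)), 2) == 0.69

    def test_all_positive_predictions_zero_by_convention(self):
        assert mcc(ConfusionMatrix2x2(tp=10, fp=10, fn=0, tn=0)) == 0.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(InputError):
            mcc(ConfusionMatrix2x2(0, 0, 0, 0))

    def test_matches_sklearn(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(0)
        for _ in range(10):
            truth = rng.integers(0, 2, 60)
            pred = np.where(rng.random(60) < 0.75, truth,
                            rng.integers(0, 2, 60))
            cm = ConfusionMatrix2x2(
                tp=int(((truth == 1) & (pred == 1)).sum()),
                fp=int(((truth == 0) & (pred == 1)).sum()),
                fn=int(((truth == 1) & (pred == 0)).sum()),
                tn=int(((truth == 0) & (pred == 0)).sum()))
            assert mcc(cm) == pytest.approx(
                sk.matthews_corrcoef(truth, pred), abs=1e-12)


class TestQuantiles:
    def test_constant_errors(self):
        qs, _, _ = abs_error_quantiles(np.array([61.0] * 3), np.array([60.0] * 3))
        assert qs[0.5] == 1.0 and qs[0.9] == 1.0

    def test_order_statistic_interpolation(self):
        dev = np.arange(1.0, 101.0) + 100.0
        ref = np.full(100, 100.0)
        qs, _, _ = abs_error_quantiles(dev, ref)
        assert qs[0.5] == pytest.approx(50.5)
        assert qs[0.9] == pytest.approx(90.1)

    def test_cdf_nondecreasing_to_one(self):
        rng = np.random.default_rng(1)
        _, x, cdf = abs_error_quantiles(rng.normal(60, 2, 50),
                                        rng.normal(60, 2, 50))
        assert np.all(np.diff(x) >= 0)
        assert np.all(np.diff(cdf) >= 0)
        assert cdf[-1] == 1.0


class TestPairedAgreementModel:
    def test_fit_report_invariants(self):
        rng = np.random.default_rng(4)
        ref = rng.normal(62, 6, 80)
        dev = ref + rng.normal(0.5, 2, 80)
        res = PairedAgreement(dev, ref, variable="hr").fit()
        rep = res.report
        assert rep.loa_lower < rep.loa_upper
        assert rep.mdc == pytest.approx(1.96 * rep.sd_diff)
        assert rep.mae >= abs(rep.bias) - 1e-9
        assert 0.0 <= rep.icc <= 1.0
        assert 0.0 <= rep.r2 <= 1.0

    def test_summary_and_table_formatting(self):
        rng = np.random.default_rng(6)
        ref = rng.normal(14, 2, 40).clip(8, None)
        dev = ref + rng.normal(-0.5, 1, 40)
        res = PairedAgreement(dev, ref, variable="br").fit()
        text = res.summary()
        assert "MDC" in text and "ICC(2,1)" in text
        from nightvitals.agreement import TABLE1_COLUMNS, reports_to_table

        table = reports_to_table({"dev_br": res.report})
        assert list(table.columns) == TABLE1_COLUMNS
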