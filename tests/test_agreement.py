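"""Agreement statistics: Bland-Altman, percentage error, Pearson CI, ICC, KS."""

import numpy as np
import pytest

from modioloc import (
    ElectrodeArrayMeasurement,
    InsufficientDataError,
    IncompleteMatrixError,
    InvalidReferenceError,
    PairingError,
    UndefinedCorrelationError,
    bland_altman,
    group_bias_tests,
    icc_two_way_mixed_absolute,
    ks_normality,
    paired_differences,
    pearson_with_ci,
    percentage_error,
)


def _sets(values_a, values_b):
    def build(vals, label):
        out = []
        for i, arr in enumerate(vals):
            arr = np.asarray(arr, dtype=float)
            out.append(ElectrodeArrayMeasurement(
                f"a{i}", label, tuple(range(1, len(arr) + 1)),
                emd=arr, adoi=np.linspace(10, 300, len(arr))))
        return out
    return build(values_a, "A"), build(values_b, "B")


class TestPairedDifferences:
    def test_identical_sets(self):
        a, b = _sets([[1.0, 2.0, 3.0]], [[1.0, 2.0, 3.0]])
        pairs = paired_differences(a, b, "EMD")
        np.testing.assert_allclose(pairs["diff"], 0.0)
        assert len(pairs) == 3

    def test_constant_offset(self):
        base = np.array([1.0, 2.0, 3.0])
        a, b = _sets([base + 0.5], [base])
        pairs = paired_differences(a, b, "EMD")
        np.testing.assert_allclose(pairs["diff"], 0.5)
        np.testing.assert_allclose(pairs["mean"], base + 0.25)

    def test_pooling_across_arrays(self):
        a, b = _sets([[1.0] * 12] * 50, [[1.0] * 12] * 50)
        assert len(paired_differences(a, b, "EMD")) == 600

    def test_unmatched_pairs_listed(self):
        a, b = _sets([[1.0, 2.0, 3.0]], [[1.0, 2.0]])
        with pytest.raises(PairingError, match=r"\('a0', 3\)"):
            paired_differences(a, b, "EMD")


class TestBlandAltman:
    def test_constant_differences(self):
        ba = bland_altman([0.3] * 10)
        assert ba.bias == pytest.approx(0.3)
        assert ba.loa_high - ba.loa_low == pytest.approx(0.0)

    def test_two_point_hand_computation(self):
        # sample SD of [-1, 1] is sqrt(2); limits = 0 +/- 1.96*sqrt(2)
        ba = bland_altman([-1.0, 1.0])
        assert ba.bias == pytest.approx(0.0, abs=1e-12)
        assert ba.loa_high == pytest.approx(2.7719, abs=1e-4)
        assert ba.loa_low == pytest.approx(-2.7719, abs=1e-4)

    def test_interrater_noise_closed_form(self):
        """Differences of two independent N(0, sigma) errors have SD
        sqrt(2)*sigma, so LoA converge to 1.96*sqrt(2)*sigma (= 10 deg for
        sigma = 3.61 deg)."""
        rng = np.random.default_rng(2024)
        sigma = 3.61
        d = rng.normal(0, sigma, 20000) - rng.normal(0, sigma, 20000)
        ba = bland_altman(d)
        assert ba.half_width == pytest.approx(1.96 * np.sqrt(2) * sigma,
                                              rel=0.03)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            bland_altman([1.0])

    def test_self_comparison_is_exactly_zero(self):
        rng = np.random.default_rng(7)
        x = rng.normal(2.0, 0.5, 100)
        ba = bland_altman(x - x)
        assert ba.bias == 0.0 and ba.loa_low == 0.0 and ba.loa_high == 0.0


class TestPercentageError:
    @pytest.mark.parametrize("lo, hi, mean, expected", [
        (-0.7, 0.7, 2.0, 70.0),
        (-0.8, 0.6, 2.5, 56.0),
        (-1.0, 1.0, 4.0, 50.0),
    ])
    def test_direct_formula(self, lo, hi, mean, expected):
        assert percentage_error(lo, hi, mean) == pytest.approx(expected)

    def test_scale_invariance(self, rng):
        d = rng.normal(0.1, 0.3, 200)
        mean = 2.5
        ba = bland_altman(d)
        pe = percentage_error(ba.loa_low, ba.loa_high, mean)
        c = 3.7
        ba_c = bland_altman(d * c)
        pe_c = percentage_error(ba_c.loa_low, ba_c.loa_high, mean * c)
        assert pe_c == pytest.approx(pe, rel=1e-12)

    def test_invalid_reference(self):
        with pytest.raises(InvalidReferenceError):
            percentage_error(-1.0, 1.0, 0.0)


class TestPearsonWithCI:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, lo, hi = pearson_with_ci(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        r, _, _ = pearson_with_ci(x, -x)
        assert r == pytest.approx(-1.0)

    def test_ci_brackets_r(self, rng):
        x = rng.normal(size=100)
        y = 0.7 * x + rng.normal(size=100)
        r, lo, hi = pearson_with_ci(x, y)
        assert lo <= r <= hi

    def test_constant_input(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_with_ci([1.0] * 10, list(range(10)))

    def test_ci_matches_bootstrap(self):
        """Fisher-z interval vs a 10,000-resample percentile bootstrap."""
        rng = np.random.default_rng(99)
        n = 300
        x = rng.normal(size=n)
        y = 0.7 * x + rng.normal(size=n) * 0.7
        r, lo, hi = pearson_with_ci(x, y)
        idx = rng.integers(0, n, size=(10000, n))
        xs, ys = x[idx], y[idx]
        xc = xs - xs.mean(axis=1, keepdims=True)
        yc = ys - ys.mean(axis=1, keepdims=True)
        boot = (xc * yc).sum(axis=1) / np.sqrt(
            (xc ** 2).sum(axis=1) * (yc ** 2).sum(axis=1))
        blo, bhi = np.percentile(boot, [2.5, 97.5])
        assert lo == pytest.approx(blo, abs=0.02)
        assert hi == pytest.approx(bhi, abs=0.02)


class TestICC:
    def test_identical_raters(self):
        rng = np.random.default_rng(1)
        col = rng.normal(2.0, 0.5, 20)
        assert icc_two_way_mixed_absolute(
            np.column_stack([col, col])) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(2)
        m = rng.normal(size=(1000, 2))
        assert abs(icc_two_way_mixed_absolute(m)) < 0.1

    def test_hand_built_table_against_mean_squares_oracle(self):
        """6x2 table: the implementation must match an explicitly summed
        two-way ANOVA variance decomposition to 1e-9."""
        table = np.array([[9.0, 2.0], [1.0, 10.0], [8.0, 9.0],
                          [2.0, 6.0], [7.0, 8.0], [2.0, 2.0]])
        n, k = table.shape
        grand = table.sum() / table.size
        msr = sum(k * (row.mean() - grand) ** 2 for row in table) / (n - 1)
        msc = sum(n * (table[:, j].mean() - grand) ** 2
                  for j in range(k)) / (k - 1)
        sse = sum((table[i, j] - table[i].mean() - table[:, j].mean()
                   + grand) ** 2 for i in range(n) for j in range(k))
        mse = sse / ((n - 1) * (k - 1))
        expected_k = (msr - mse) / (msr + (msc - mse) / n)
        expected_1 = (msr - mse) / (msr + (k - 1) * mse
                                    + k * (msc - mse) / n)
        assert icc_two_way_mixed_absolute(table) == pytest.approx(
            expected_k, abs=1e-9)
        assert icc_two_way_mixed_absolute(table, average=False) == \
            pytest.approx(expected_1, abs=1e-9)

    def test_cross_check_against_pingouin(self):
        import pandas as pd
        import pingouin as pg
        rng = np.random.default_rng(3)
        subj = rng.normal(2.0, 0.6, 30)
        table = np.column_stack([subj + rng.normal(0, 0.1, 30),
                                 subj + 0.05 + rng.normal(0, 0.1, 30)])
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(30), 2),
            "rater": np.tile(["r1", "r2"], 30),
            "score": table.reshape(-1),
        })
        icc = pg.intraclass_corr(long, targets="subject", raters="rater",
                                 ratings="score")
        by_type = icc.set_index("Type")["ICC"]
        # label differs across pingouin versions: ICC(A,k) vs ICC2k
        ref_k = float(by_type.get("ICC(A,k)", by_type.get("ICC2k")))
        ref_1 = float(by_type.get("ICC(A,1)", by_type.get("ICC2")))
        assert icc_two_way_mixed_absolute(table) == pytest.approx(ref_k,
                                                                  abs=1e-8)
        assert icc_two_way_mixed_absolute(table, average=False) == \
            pytest.approx(ref_1, abs=1e-8)

    def test_noise_strictly_decreases_icc(self):
        rng = np.random.default_rng(4)
        subj = rng.normal(2.0, 0.6, 200)
        clean = np.column_stack([subj, subj])
        for seed in range(5):
            noisy = clean + np.random.default_rng(seed).normal(
                0, 0.2, clean.shape)
            assert icc_two_way_mixed_absolute(noisy) < 1.0

    def test_incomplete_matrix(self):
        m = np.ones((6, 2))
        m[0, 0] = np.nan
        with pytest.raises(IncompleteMatrixError):
            icc_two_way_mixed_absolute(m)


class TestKSNormality:
    def test_normal_sample_accepted(self):
        rng = np.random.default_rng(600)
        res = ks_normality(rng.normal(size=600))
        assert res.normal and not res.degenerate

    def test_uniform_sample_rejected(self):
        rng = np.random.default_rng(601)
        res = ks_normality(rng.uniform(0, 1, size=600))
        assert not res.normal

    def test_constant_data_flagged(self):
        res = ks_normality([1.0] * 10)
        assert res.degenerate and not res.normal

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            ks_normality([1.0, 2.0])


class TestGroupBiasTests:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(5)
        values = rng.normal(0, 0.1, 60)
        groups = np.repeat(["a", "b"], 30)
        rep = group_bias_tests(values, groups)
        assert rep.test == "wilcoxon-rank-sum"
        assert rep.p_value > 0.05

    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(6)
        values = np.concatenate([rng.normal(0, 0.1, 30),
                                 rng.normal(0.5, 0.1, 30)])
        groups = np.repeat(["a", "b"], 30)
        rep = group_bias_tests(values, groups, criterion=0.2)
        assert rep.p_value < 0.001
        assert rep.exceeds_criterion

    def test_five_groups_anova(self):
        """Image-quality-score style grouping (scores 4-8, frequencies
        10/28/26/24/12% of 50 arrays) with a shared bias: no group effect."""
        rng = np.random.default_rng(7)
        sizes = {4: 5, 5: 14, 6: 13, 7: 12, 8: 6}
        values = np.concatenate(
            [rng.normal(-0.1, 0.1, n) for n in sizes.values()])
        groups = np.concatenate(
            [np.full(n, g) for g, n in sizes.items()])
        rep = group_bias_tests(values, groups, criterion=0.2)
        assert rep.test == "one-way-anova"
        assert rep.p_value > 0.05
        assert rep.exceeds_criterion is False

    def test_small_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            group_bias_tests([1.0, 2.0, 3.0, 4.0], ["a", "a", "a", "b"])
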