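import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from ki67eval.errors import DegenerateDataError, ValidationError
from ki67eval.stats import (
    ABSOLUTE_AGREEMENT,
    CONSISTENCY,
    agreement_report,
    bland_altman_nonparametric,
    icc_two_way_mixed_single,
    wilcoxon_signed_rank,
)


def anova_oracle_icc(a, b, variant):
    """Independent ICC oracle computed directly from the ANOVA definitions
    with explicit loops (no shared code with the implementation)."""
    table = [[float(x), float(y)] for x, y in zip(a, b)]
    n = len(table)
    k = 2
    grand = sum(sum(row) for row in table) / (n * k)
    row_means = [sum(row) / k for row in table]
    col_means = [sum(table[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = sum(k * (rm - grand) ** 2 for rm in row_means)
    ss_cols = sum(n * (cm - grand) ** 2 for cm in col_means)
    ss_tot = sum((table[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    if variant == "consistency":
        return (msr - mse) / (msr + (k - 1) * mse)
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


SMALL_TABLES = [
    ([9, 6, 8, 7, 10, 6], [2, 1, 4, 1, 5, 2]),
    ([10.1, 9.9, 10.0, 10.4, 9.8, 10.2], [10.3, 9.7, 10.1, 10.5, 9.6, 10.4]),
    ([1, 2, 3, 4, 5, 6], [1.5, 2.2, 2.9, 4.4, 5.1, 5.9]),
    ([180, 205, 190, 240, 160, 210], [195, 220, 180, 260, 170, 230]),
]


class TestICC:
    def test_identical_series_give_exactly_one(self):
        a = np.array([1.0, 5.0, 3.0, 7.0])
        r = icc_two_way_mixed_single(a, a.copy())
        assert r.icc == 1.0
        assert (r.ci_low, r.ci_high) == (1.0, 1.0)

    @pytest.mark.parametrize("a,b", SMALL_TABLES)
    @pytest.mark.parametrize("variant", [CONSISTENCY, ABSOLUTE_AGREEMENT])
    def test_matches_hand_computed_anova_oracle(self, a, b, variant):
        r = icc_two_way_mixed_single(a, b, variant=variant)
        assert r.icc == pytest.approx(anova_oracle_icc(a, b, variant), abs=1e-10)

    @pytest.mark.parametrize("a,b", SMALL_TABLES)
    def test_matches_pingouin_point_estimates_and_ci(self, a, b):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        n = len(a)
        df = pd.DataFrame({
            "targets": list(range(n)) * 2,
            "raters": ["a"] * n + ["b"] * n,
            "ratings": list(a) + list(b),
        })
        icc_table = pingouin.intraclass_corr(
            df, targets="targets", raters="raters", ratings="ratings"
        ).set_index("Type")
        ours_c = icc_two_way_mixed_single(a, b, CONSISTENCY)
        ours_a = icc_two_way_mixed_single(a, b, ABSOLUTE_AGREEMENT)
        assert ours_c.icc == pytest.approx(icc_table.loc["ICC(C,1)", "ICC"], abs=1e-8)
        assert ours_a.icc == pytest.approx(icc_table.loc["ICC(A,1)", "ICC"], abs=1e-8)
        ci_col = "CI95%" if "CI95%" in icc_table.columns else "CI95"
        lo, hi = icc_table.loc["ICC(C,1)", ci_col]  # reported rounded to 2 d.p.
        assert ours_c.ci_low == pytest.approx(lo, abs=0.01)
        assert ours_c.ci_high == pytest.approx(hi, abs=0.01)
        lo2, hi2 = icc_table.loc["ICC(A,1)", ci_col]
        assert ours_a.ci_low == pytest.approx(lo2, abs=0.01)
        assert ours_a.ci_high == pytest.approx(hi2, abs=0.01)

    def test_white_noise_icc_near_zero(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=10_000)
        b = rng.normal(size=10_000)
        r = icc_two_way_mixed_single(a, b)
        assert abs(r.icc) <= 0.05
        assert r.ci_low <= r.icc <= r.ci_high

    def test_recovers_known_intraclass_correlation(self):
        rho = 0.7
        rng = np.random.default_rng(11)
        n = 5_000
        shared = rng.normal(0, math.sqrt(rho), size=n)
        a = shared + rng.normal(0, math.sqrt(1 - rho), size=n)
        b = shared + rng.normal(0, math.sqrt(1 - rho), size=n)
        r = icc_two_way_mixed_single(a, b)
        assert r.icc == pytest.approx(rho, abs=0.03)
        assert r.ci_low <= rho <= r.ci_high

    def test_consistency_invariant_to_constant_offset_absolute_not(self):
        a = np.array([3.0, 8.0, 5.0, 9.0, 4.0, 7.0])
        b = a + 5.0
        cons = icc_two_way_mixed_single(a, b, CONSISTENCY)
        absol = icc_two_way_mixed_single(a, b, ABSOLUTE_AGREEMENT)
        assert cons.icc == pytest.approx(1.0)
        assert absol.icc < 0.9

    def test_degenerate_and_short_inputs_rejected(self):
        with pytest.raises(DegenerateDataError):
            icc_two_way_mixed_single([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        with pytest.raises(ValidationError):
            icc_two_way_mixed_single([1.0, 2.0], [1.0, 2.0])

    def test_p_value_is_f_test(self):
        a, b = SMALL_TABLES[0]
        r = icc_two_way_mixed_single(a, b)
        assert r.p_value == pytest.approx(sps.f.sf(r.f_value, r.df1, r.df2))


class TestBlandAltman:
    def test_identical_series(self):
        a = np.array([1.0, 2.0, 3.0])
        r = bland_altman_nonparametric(a, a)
        assert r.bias == 0.0 and r.loa_low == 0.0 and r.loa_high == 0.0

    def test_percentiles_of_1_to_100(self):
        b = np.zeros(100)
        a = np.arange(1.0, 101.0)
        r = bland_altman_nonparametric(a, b)
        assert r.bias == pytest.approx(50.5)
        assert r.loa_low == pytest.approx(3.475)
        assert r.loa_high == pytest.approx(97.525)

    def test_constant_offset(self):
        rng = np.random.default_rng(12)
        b = rng.uniform(0, 10, size=20)
        r = bland_altman_nonparametric(b + 5.0, b)
        assert r.bias == pytest.approx(5.0)
        assert r.loa_low == pytest.approx(5.0)
        assert r.loa_high == pytest.approx(5.0)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(13)
        a = rng.normal(size=50)
        b = rng.normal(size=50)
        r0 = bland_altman_nonparametric(a, b)
        r1 = bland_altman_nonparametric(a + 3.0, b)
        assert r1.bias == pytest.approx(r0.bias + 3.0)
        assert r1.loa_low == pytest.approx(r0.loa_low + 3.0)
        assert r1.loa_high == pytest.approx(r0.loa_high + 3.0)

    def test_limits_bracket_95pct_of_differences(self):
        rng = np.random.default_rng(14)
        a = rng.exponential(5.0, size=400)
        b = rng.exponential(4.0, size=400)
        r = bland_altman_nonparametric(a, b)
        inside = np.mean((r.diffs >= r.loa_low) & (r.diffs <= r.loa_high))
        assert inside >= 0.94
        assert r.loa_low <= r.bias <= r.loa_high


def exact_signed_rank_p(diffs):
    """Two-sided p by brute-force enumeration of all 2^n sign patterns."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    count = 0
    for signs in itertools.product([1, -1], repeat=n):
        s = np.array(signs)
        w = min(ranks[s > 0].sum(), ranks[s < 0].sum())
        if w <= w_obs + 1e-12:
            count += 1
    return count / 2**n


class TestWilcoxon:
    def test_all_positive_n6_exact(self):
        a = np.array([5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
        b = np.array([1.0, 1.5, 2.0, 2.5, 3.0, 3.5])
        r = wilcoxon_signed_rank(a, b)
        assert r.method == "exact"
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(2 / 64)
        assert r.p_value == pytest.approx(exact_signed_rank_p(a - b))

    def test_exact_matches_enumeration_on_mixed_signs(self):
        rng = np.random.default_rng(15)
        for _ in range(5):
            d = rng.normal(0.3, 1.0, size=8)
            d = d[d != 0]
            r = wilcoxon_signed_rank(d, np.zeros_like(d))
            if r.method == "exact":
                assert r.p_value == pytest.approx(exact_signed_rank_p(d))

    def test_antisymmetric_differences_p_one(self):
        a = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        r = wilcoxon_signed_rank(a, np.zeros_like(a))
        # tied |d| values force the normal approximation; symmetric W -> p = 1
        assert r.method == "normal_approx"
        assert r.p_value == pytest.approx(1.0)

    def test_large_sample_shift_detected(self):
        rng = np.random.default_rng(16)
        b = rng.normal(size=200)
        a = b + 0.5 + rng.normal(0, 0.5, size=200)
        r = wilcoxon_signed_rank(a, b)
        assert r.p_value < 0.001

    def test_zero_differences_dropped(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([1.0, 2.0, 1.0, 2.0])
        r = wilcoxon_signed_rank(a, b)
        assert r.n_effective == 2

    def test_all_zero_differences_degenerate(self):
        a = np.array([1.0, 2.0, 3.0])
        r = wilcoxon_signed_rank(a, a.copy())
        assert r.method == "degenerate"
        assert r.p_value == 1.0

    def test_exact_close_to_normal_at_n25(self):
        # the normal approximation tracks the exact null closely at n = 25:
        # within 0.01 in the decision-relevant range (p < 0.25) and within
        # 0.02 even for central statistics
        for seed in range(10):
            rng = np.random.default_rng(seed)
            d = rng.normal(0.3, 1.0, size=25)
            assert np.unique(np.abs(d)).size == 25
            exact = wilcoxon_signed_rank(d, np.zeros_like(d))
            assert exact.method == "exact"
            approx = sps.wilcoxon(d, correction=False, method="approx").pvalue
            tol = 0.01 if exact.p_value < 0.25 else 0.02
            assert exact.p_value == pytest.approx(approx, abs=tol)


class TestAgreementReport:
    def test_report_bundles_all_statistics(self):
        rng = np.random.default_rng(18)
        a = rng.uniform(0, 10, size=30)
        b = a + rng.normal(0.5, 0.5, size=30)
        rep = agreement_report(a, b)
        d = rep.to_dict()
        assert d["icc_consistency"]["variant"] == CONSISTENCY
        assert d["icc_absolute_agreement"]["variant"] == ABSOLUTE_AGREEMENT
        assert d["bland_altman"]["bias"] == pytest.approx(np.median(a - b))
        assert 0 <= d["wilcoxon"]["p_value"] <= 1
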