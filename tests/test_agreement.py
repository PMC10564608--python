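"""Agreement statistics: ICC, paired means, quintiles/PABAK, sample size."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from novarecall import (
    ContractError,
    DegenerateDataError,
    compare_means,
    icc_band,
    icc_sample_size,
    icc_two_way,
    pabak_band,
    pabak_from_table,
    quintile_agreement,
    stratified_icc,
)


def icc_consistency_oracle(y):
    """Independent mean-squares oracle: explicit summation loops over the
    two-way ANOVA decomposition, no vectorized shortcuts."""
    n, k = len(y), len(y[0])
    grand = sum(sum(row) for row in y) / (n * k)
    row_means = [sum(row) / k for row in y]
    col_means = [sum(y[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_total = sum((y[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    mse = (ss_total - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse)


class TestICC:
    def test_matches_mean_squares_oracle_on_random_tables(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = int(rng.integers(3, 21))
            k = int(rng.integers(2, 4))
            y = rng.normal(50, 10, (n, k)) + rng.normal(0, 8, (n, 1))
            mine = icc_two_way(y).icc
            oracle = icc_consistency_oracle(y.tolist())
            assert mine == pytest.approx(oracle, abs=1e-10)

    def test_matches_pingouin_both_forms(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(5)
        n = 40
        lat = rng.normal(50, 10, n)
        y = np.column_stack([lat + rng.normal(0, 5, n),
                             lat + 2 + rng.normal(0, 5, n)])
        df = pd.DataFrame({"targets": np.repeat(np.arange(n), 2),
                           "raters": np.tile(["a", "b"], n),
                           "ratings": y.ravel()})
        table = pg.intraclass_corr(df, "targets", "raters", "ratings")
        ref = {row.Type: row.ICC for row in table.itertuples()}
        assert icc_two_way(y, "consistency").icc == pytest.approx(
            ref["ICC(C,1)"], abs=1e-12)
        assert icc_two_way(y, "absolute_agreement").icc == pytest.approx(
            ref["ICC(A,1)"], abs=1e-12)

    def test_identical_pairs_give_icc_one_excellent(self):
        x = np.arange(10.0)
        res = icc_two_way(np.column_stack([x, x]))
        assert res.icc == pytest.approx(1.0)
        assert res.band == "excellent"
        assert res.ci_low <= res.icc <= res.ci_high

    def test_degenerate_constant_table_rejected(self):
        with pytest.raises(DegenerateDataError):
            icc_two_way(np.full((5, 2), 3.0))

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ContractError):
            icc_two_way([[1, 2], [3, 4]])

    def test_parameter_recovery_and_ci_coverage(self):
        """Data simulated from a two-way model with known ICC is recovered
        within +-0.05 and the 95% CI covers the truth 92-98% of the time
        (n=500, k=2, 1000 replicates per true value)."""
        rng = np.random.default_rng(2024)
        n, reps = 500, 1000
        for rho in (0.3, 0.55, 0.75, 0.9):
            sigma_b = math.sqrt(rho)
            sigma_e = math.sqrt(1 - rho)
            estimates = np.empty(reps)
            covered = 0
            for r in range(reps):
                subject = sigma_b * rng.standard_normal((n, 1))
                y = subject + sigma_e * rng.standard_normal((n, 2))
                res = icc_two_way(y)
                estimates[r] = res.icc
                covered += res.ci_low <= rho <= res.ci_high
            assert abs(estimates.mean() - rho) < 0.05, rho
            assert 0.92 <= covered / reps <= 0.98, (rho, covered / reps)


class TestBands:
    @pytest.mark.parametrize("value,band", [
        (0.30, "poor"), (0.4999, "poor"),
        (0.50, "moderate"), (0.54, "moderate"), (0.72, "moderate"),
        (0.75, "good"), (0.78, "good"), (0.90, "good"),
        (0.91, "excellent"), (1.0, "excellent"),
    ])
    def test_icc_bands(self, value, band):
        assert icc_band(value) == band

    @pytest.mark.parametrize("value,band", [
        (-0.2, "none"), (0.0, "none"),
        (0.1, "none_to_slight"), (0.20, "none_to_slight"),
        (0.30, "fair"), (0.40, "fair"),
        (0.50, "moderate"), (0.60, "moderate"),
        (0.61, "substantial"), (0.69, "substantial"),
        (0.77, "substantial"), (0.78, "substantial"), (0.80, "substantial"),
        (0.81, "almost_perfect"), (1.0, "almost_perfect"),
    ])
    def test_pabak_bands(self, value, band):
        assert pabak_band(value) == band

    @given(st.floats(-1, 1), st.floats(-1, 1))
    @settings(deadline=None, derandomize=True)
    def test_bands_total_and_monotone(self, x, y):
        order = {"none": 0, "none_to_slight": 1, "fair": 2, "moderate": 3,
                 "substantial": 4, "almost_perfect": 5}
        icc_order = {"poor": 0, "moderate": 1, "good": 2, "excellent": 3}
        lo, hi = sorted([x, y])
        assert order[pabak_band(lo)] <= order[pabak_band(hi)]
        assert icc_order[icc_band(lo)] <= icc_order[icc_band(hi)]


class TestCompareMeans:
    def test_identical_tools_no_difference(self):
        x = np.linspace(10, 60, 20)
        res = compare_means({1: (x, x)})
        assert res[1].diff == 0.0
        assert res[1].degenerate and res[1].significant is None

    def test_constant_shift_flagged_degenerate(self):
        x = np.linspace(10, 60, 20)
        res = compare_means({4: (x + 5, x)})
        assert res[4].diff == pytest.approx(5.0)
        assert res[4].degenerate
        assert res[4].diff_ci == (pytest.approx(5.0), pytest.approx(5.0))

    def test_detects_real_shift(self):
        rng = np.random.default_rng(8)
        x = rng.normal(50, 10, 186)
        res = compare_means({1: (x + 3 + rng.normal(0, 4, 186),
                                 x + rng.normal(0, 4, 186))})
        assert res[1].significant
        assert res[1].mean_a - res[1].mean_b == pytest.approx(res[1].diff)

    def test_ci_matches_scipy_t_interval(self):
        rng = np.random.default_rng(9)
        x = rng.normal(50, 10, 30)
        res = compare_means({1: (x, x + rng.normal(0, 1, 30))})
        lo, hi = stats.t.interval(0.95, 29, loc=x.mean(),
                                  scale=x.std(ddof=1) / math.sqrt(30))
        assert res[1].ci_a == (pytest.approx(lo), pytest.approx(hi))

    def test_wilcoxon_method_available(self):
        rng = np.random.default_rng(10)
        x = rng.normal(50, 10, 50)
        res = compare_means({1: (x, x + rng.normal(1, 2, 50))},
                            method="wilcoxon")
        assert res[1].method == "wilcoxon"
        assert 0 <= res[1].p_value <= 1


class TestQuintiles:
    def test_identical_rankings(self):
        rng = np.random.default_rng(3)
        x = rng.normal(50, 10, 200)
        res = quintile_agreement(x, x)
        assert res.p_same == 1.0 and res.pabak == 1.0
        assert res.band == "almost_perfect"
        assert res.p_same_or_adjacent == 1.0

    def test_chance_agreement_gives_pabak_zero(self):
        # p_same = 0.2 for 5 balanced categories -> PABAK = (5*0.2-1)/4 = 0
        table = np.full((5, 5), 4)
        assert pabak_from_table(table) == pytest.approx(0.0)

    def test_independent_rankings_pabak_near_zero(self):
        rng = np.random.default_rng(4)
        res = quintile_agreement(rng.normal(size=5000), rng.normal(size=5000))
        assert abs(res.pabak) < 0.02

    def test_cross_table_sums_to_n_and_adjacent_geq_same(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=186)
        y = x + rng.normal(0, 0.5, 186)
        res = quintile_agreement(x, y)
        assert res.cross_table.sum() == 186
        assert 0 <= res.p_same <= res.p_same_or_adjacent <= 1

    @given(st.lists(st.integers(0, 20), min_size=25, max_size=25))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_pabak_closed_form_equals_brute_force(self, cells):
        table = np.array(cells, dtype=float).reshape(5, 5)
        if table.sum() == 0:
            table[0, 0] = 1
        c = 5
        po = np.trace(table) / table.sum()
        assert pabak_from_table(table) == pytest.approx((c * po - 1) / (c - 1))

    def test_heavy_ties_fall_back_to_rank_split_with_warning(self):
        values = np.zeros(50)
        values[-1] = 1.0
        with pytest.warns(UserWarning, match="empty quintile"):
            res = quintile_agreement(values, values, mode="quantile")
        assert res.mode == "rank"
        assert res.cross_table.sum() == 50


class TestSampleSize:
    def test_weak_agreement_design_needs_152_subjects(self):
        assert icc_sample_size(0, 0.2, k=2, alpha=0.05, power=0.80) == 152

    def test_monotone_decreasing_in_alternative(self):
        sizes = [icc_sample_size(0, rho1) for rho1 in (0.05, 0.1, 0.2, 0.5, 0.9)]
        assert sizes == sorted(sizes, reverse=True)
        assert sizes[0] > 2000  # rho1 -> rho0+ blows up

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ContractError):
            icc_sample_size(0.3, 0.2)

    def test_power_at_returned_n_confirmed_by_simulation(self):
        """Monte-Carlo oracle: at the returned n for rho1=0.5, simulate the
        reliability study and test rho=0 one-sided with the exact F test.
        The approximation is accurate but not conservative, so the realized
        power must land within 5 points of the nominal 80%."""
        n = icc_sample_size(0, 0.5, k=2, alpha=0.05, power=0.80)
        rng = np.random.default_rng(77)
        reps, hits = 2000, 0
        crit = stats.f.ppf(0.95, n - 1, n - 1)  # H0: rho=0 => F = MSR/MSE ~ F
        for _ in range(reps):
            subject = math.sqrt(0.5) * rng.standard_normal((n, 1))
            y = subject + math.sqrt(0.5) * rng.standard_normal((n, 2))
            res = icc_two_way(y)
            hits += (res.ms_rows / res.ms_error) > crit
        assert abs(hits / reps - 0.80) <= 0.05


class TestStratifiedICC:
    def test_identical_strata_identical_iccs(self):
        rng = np.random.default_rng(11)
        lat = rng.normal(50, 10, 30)
        y = np.column_stack([lat + rng.normal(0, 5, 30),
                             lat + rng.normal(0, 5, 30)])
        pairs = np.vstack([y, y])
        strata = ["a"] * 30 + ["b"] * 30
        res = stratified_icc(pairs, strata)
        assert res["a"].icc == pytest.approx(res["b"].icc)

    def test_random_split_tracks_pooled(self):
        rng = np.random.default_rng(12)
        lat = rng.normal(50, 10, 600)
        y = np.column_stack([lat + rng.normal(0, 5, 600),
                             lat + rng.normal(0, 5, 600)])
        pooled = icc_two_way(y).icc
        strata = rng.choice(["a", "b"], 600)
        res = stratified_icc(y, strata)
        for r in res.values():
            assert abs(r.icc - pooled) < 0.1

    def test_undersized_stratum_skipped_with_warning(self):
        y = np.column_stack([np.arange(10.0), np.arange(10.0) + 1])
        strata = ["big"] * 8 + ["tiny"] * 2
        with pytest.warns(UserWarning, match="tiny"):
            res = stratified_icc(y, strata)
        assert "tiny" not in res and "big" in res
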