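import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ki67quant import (
    SlideSummary,
    agreement_stats,
    bonferroni_adjust,
    kruskal_wallis,
    summarize_by_group,
)
from ki67quant.stats import boxplot_table, icc_2_1


def _summary(slide_id, group, n_pos, n_neg, area=1.0):
    return SlideSummary(slide_id=slide_id, group=group, n_pos=n_pos,
                        n_neg=n_neg, area_mm2=area)


def icc21_anova_oracle(x, y):
    """Hand-built two-way ANOVA decomposition for ICC(2,1).

    Mean squares computed from explicit per-cell residuals rather than
    sums-of-squares shortcuts, as one would on paper.
    """
    data = np.stack([x, y], axis=1).astype(float)
    n, k = data.shape
    grand = data.mean()
    rows = data.mean(axis=1)
    cols = data.mean(axis=0)
    msr = k * sum((r - grand) ** 2 for r in rows) / (n - 1)
    msc = n * sum((c - grand) ** 2 for c in cols) / (k - 1)
    resid = [
        (data[i, j] - rows[i] - cols[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    ]
    mse = sum(resid) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestSummarizeByGroup:
    def test_hand_arithmetic(self):
        # LIs {10, 20, 30}%: median 20, mean 20, sample sd 10
        summaries = [
            _summary("a", "g", 10, 90),
            _summary("b", "g", 20, 80),
            _summary("c", "g", 30, 70),
        ]
        table = summarize_by_group(summaries)
        row = table.iloc[0]
        assert row["li_percent_median"] == pytest.approx(20.0)
        assert row["li_percent_mean"] == pytest.approx(20.0)
        assert row["li_percent_sd"] == pytest.approx(10.0)
        assert (row["li_percent_min"], row["li_percent_max"]) == (10.0, 30.0)

    def test_single_slide_group_sd_is_na(self):
        table = summarize_by_group([_summary("a", "solo", 5, 95)])
        assert math.isnan(table.iloc[0]["li_percent_sd"])

    def test_groups_ordered_by_descending_median_li(self):
        summaries = [
            _summary("a", "low", 5, 95),
            _summary("b", "high", 25, 75),
            _summary("c", "low", 5, 95),
            _summary("d", "high", 25, 75),
        ]
        table = summarize_by_group(summaries)
        assert list(table["group"]) == ["high", "low"]

    def test_na_li_rows_excluded_per_metric(self):
        summaries = [_summary("a", "g", 10, 90), _summary("b", "g", 0, 0)]
        table = summarize_by_group(summaries)
        assert table.iloc[0]["li_percent_median"] == pytest.approx(10.0)
        assert table.iloc[0]["n_slides"] == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_by_group([])

    def test_invariant_to_slide_order(self, rng):
        summaries = [
            _summary(f"s{i}", f"g{i % 3}", int(rng.integers(0, 50)), 100)
            for i in range(12)
        ]
        t1 = summarize_by_group(summaries)
        t2 = summarize_by_group(list(reversed(summaries)))
        assert list(t1["group"]) == list(t2["group"])
        num = t1.select_dtypes("number")
        np.testing.assert_allclose(num.to_numpy(), t2[num.columns].to_numpy(),
                                   rtol=1e-12)


class TestKruskalWallis:
    def test_identical_groups(self):
        h, p = kruskal_wallis([np.array([1.0, 2, 3]), np.array([1.0, 2, 3])])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_complete_separation_hand_formula(self):
        # ranks 1..3 vs 4..6: H = 12/(6·7)·(6²/3 + 15²/3) − 3·7 = 3.857142…
        h, p = kruskal_wallis([np.array([1.0, 2, 3]), np.array([10.0, 11, 12])])
        assert h == pytest.approx(12 / 42 * (36 / 3 + 225 / 3) - 21, abs=1e-12)

    def test_all_identical_observations(self):
        h, p = kruskal_wallis([np.array([5.0, 5]), np.array([5.0, 5, 5])])
        assert (h, p) == (0.0, 1.0)

    def test_matches_scipy_on_random_data(self, rng):
        from scipy import stats as sps

        for _ in range(100):
            k = rng.integers(2, 5)
            groups = [
                rng.normal(rng.uniform(-1, 1), 1, size=rng.integers(3, 12))
                for _ in range(k)
            ]
            if rng.random() < 0.5:    # inject ties
                groups = [np.round(g) for g in groups]
            h, p = kruskal_wallis(groups)
            h_ref, p_ref = sps.kruskal(*groups)
            assert h == pytest.approx(h_ref, abs=1e-10)
            assert p == pytest.approx(p_ref, abs=1e-10)

    def test_permutation_invariance(self, rng):
        groups = [rng.normal(0, 1, 8), rng.normal(1, 1, 5), rng.normal(2, 1, 7)]
        h1, _ = kruskal_wallis(groups)
        shuffled = [g[rng.permutation(len(g))] for g in groups]
        h2, _ = kruskal_wallis(list(reversed(shuffled)))
        assert h1 == pytest.approx(h2, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([np.array([1.0]), np.array([])])


class TestBonferroni:
    def test_basic_adjustment(self):
        adj, flags = bonferroni_adjust([0.01, 0.4])
        assert adj == [0.02, 0.8]
        assert flags == [True, False]

    def test_capped_at_one(self):
        adj, _ = bonferroni_adjust([0.9, 0.5, 0.5, 0.5, 0.5])
        assert adj[0] == 1.0

    def test_single_test_identity(self):
        adj, _ = bonferroni_adjust([0.03])
        assert adj == [0.03]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_adjusted_never_below_raw(self, ps):
        adj, _ = bonferroni_adjust(ps)
        assert all(a >= p for a, p in zip(adj, ps))
        assert all(0 <= a <= 1 for a in adj)


class TestAgreementStats:
    def test_identity(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        res = agreement_stats(x, x)
        assert res["spearman_rho"] == pytest.approx(1.0)
        assert res["icc"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(1.0)
        assert res["intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_reversed_ranks(self):
        x = np.array([1.0, 2, 3, 4, 5])
        res = agreement_stats(x, x[::-1])
        assert res["spearman_rho"] == pytest.approx(-1.0)

    def test_constant_shift_breaks_absolute_agreement(self):
        x = np.array([3.0, 7, 1, 9, 4, 6])
        res = agreement_stats(x, x + 2.0)
        assert res["spearman_rho"] == pytest.approx(1.0)
        assert res["icc"] < 1.0

    def test_icc_matches_anova_oracle_on_ratings_table(self):
        # classic 6-target, 2-rater reliability layout
        x = np.array([9.0, 6, 8, 7, 10, 6])
        y = np.array([2.0, 1, 4, 1, 5, 2])
        assert icc_2_1(x, y) == pytest.approx(icc21_anova_oracle(x, y), abs=1e-8)

    def test_icc_matches_anova_oracle_random(self, rng):
        for _ in range(50):
            x = rng.normal(0, 1, size=rng.integers(4, 20))
            y = x + rng.normal(0, 0.5, size=len(x))
            assert icc_2_1(x, y) == pytest.approx(icc21_anova_oracle(x, y),
                                                  abs=1e-8)

    def test_icc_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        x = rng.normal(10, 3, 12)
        y = x + rng.normal(1, 1, 12)
        df = pd.DataFrame(
            {
                "target": list(range(12)) * 2,
                "rater": ["a"] * 12 + ["b"] * 12,
                "score": np.concatenate([x, y]),
            }
        )
        ref = pg.intraclass_corr(df, targets="target", raters="rater",
                                 ratings="score")
        # two-way random, absolute agreement, single measurement
        ref_icc2 = ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].item()
        assert icc_2_1(x, y) == pytest.approx(ref_icc2, abs=1e-8)

    def test_spearman_matches_scipy_with_ties(self, rng):
        from scipy import stats as sps

        for _ in range(100):
            n = rng.integers(4, 30)
            x = np.round(rng.normal(0, 2, n))
            y = np.round(x + rng.normal(0, 2, n))
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            res = agreement_stats(x, y)
            ref = sps.spearmanr(x, y).statistic
            assert res["spearman_rho"] == pytest.approx(ref, abs=1e-10)

    def test_zero_variance_reports_na(self):
        res = agreement_stats(np.ones(5), np.array([1.0, 2, 3, 4, 5]))
        assert math.isnan(res["spearman_rho"]) and math.isnan(res["icc"])

    def test_negative_icc_not_clamped(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([6.0, 1, 5, 2, 4, 3])
        icc = icc_2_1(x, y)
        assert icc == pytest.approx(icc21_anova_oracle(x, y), abs=1e-10)
        assert icc < 0

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            agreement_stats([1, 2], [1, 2])
        with pytest.raises(ValueError):
            agreement_stats([1, 2, np.nan, 4], [1, 2, 3, 4])


def test_boxplot_table_quartiles():
    summaries = [_summary(f"s{i}", "g", li, 100 - li) for i, li in
                 enumerate([10, 20, 30, 40, 50])]
    table = boxplot_table(summaries, "li_percent")
    row = table.iloc[0]
    assert row["median"] == pytest.approx(30.0)
    assert row["q1"] == pytest.approx(20.0)
    assert row["q3"] == pytest.approx(40.0)
    assert row["whisker_low"] == 10.0 and row["whisker_high"] == 50.0
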