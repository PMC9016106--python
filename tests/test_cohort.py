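"""Group summaries and the statistical tests behind the cohort tables."""

import itertools
import math

import numpy as np
import pytest

from petconcord.cohort import (
    GROUP_CIRCUMSCRIBED,
    GROUP_DIFFUSE,
    PatientRecord,
    build_cohort_tables,
    fisher_exact,
    records_to_frame,
    summarize,
    t_test_independent,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)
from petconcord.concordance import LesionMetrics


def ranksum_enumeration_p(x, y):
    """Exact two-sided p by enumerating all rank assignments (no ties)."""
    pooled = np.concatenate([x, y])
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    n = len(pooled)
    w_obs = sum(ranks[v] for v in x)
    ws = [sum(c) for c in itertools.combinations(range(1, n + 1), len(x))]
    mean_w = len(x) * (n + 1) / 2
    dev = abs(w_obs - mean_w)
    extreme = sum(1 for w in ws if abs(w - mean_w) >= dev - 1e-12)
    return extreme / len(ws)


def signedrank_enumeration_p(x, y):
    """Exact two-sided p by enumerating all 2^n sign patterns."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product((False, True), repeat=n)
    ]
    p_low = sum(1 for w in ws if w <= w_obs + 1e-12) / len(ws)
    p_high = sum(1 for w in ws if w >= w_obs - 1e-12) / len(ws)
    return min(1.0, 2 * min(p_low, p_high))


class TestSummarize:
    def test_constant(self):
        assert summarize([1, 1, 1]) == (1.0, 0.0)

    def test_two_values(self):
        mean, sd = summarize([1, 3])
        assert mean == 2.0
        assert sd == pytest.approx(math.sqrt(2), abs=1e-4)  # 1.4142

    def test_textbook_sample(self):
        mean, sd = summarize([2, 4, 4, 4, 5, 5, 7, 9])
        assert mean == 5.0
        assert sd == pytest.approx(2.1381, abs=1e-4)  # n-1 denominator

    def test_needs_two(self):
        with pytest.raises(ValueError):
            summarize([1.0])


class TestRankSum:
    def test_fully_separated_small_sample(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)  # 2/C(6,3)=2/20
        assert res.statistic == 6.0  # rank sum of x

    def test_identical_samples_no_shift(self):
        res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert res.p_value >= 0.99

    @pytest.mark.parametrize("nx,ny", [(2, 3), (3, 3), (4, 4), (3, 5)])
    def test_matches_enumeration(self, nx, ny):
        rng = np.random.default_rng(nx * 10 + ny)
        x = rng.permutation(np.arange(1.0, nx + ny + 1))[:nx]
        y = np.setdiff1d(np.arange(1.0, nx + ny + 1), x)
        assert wilcoxon_rank_sum(x, y).p_value == pytest.approx(
            ranksum_enumeration_p(x, y)
        )

    def test_symmetry(self):
        x, y = [1.0, 4.0, 7.0], [2.0, 3.0, 9.0, 11.0]
        assert wilcoxon_rank_sum(x, y).p_value == pytest.approx(
            wilcoxon_rank_sum(y, x).p_value
        )

    def test_asymptotic_close_to_exact_at_8_plus_8(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 8)
        y = rng.normal(1.0, 1, 8)
        exact = wilcoxon_rank_sum(x, y).p_value  # n=16, tie-free: exact path
        assert exact == pytest.approx(ranksum_enumeration_p(x, y))
        approx = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert abs(approx - exact) < 0.02

    def test_monotone_in_separation(self):
        base = np.array([0.1, 0.5, 0.9, 1.3, 1.7])
        ps = [
            wilcoxon_rank_sum(base, base + shift).p_value for shift in (0.05, 1.0, 2.0)
        ]
        assert ps[0] >= ps[1] >= ps[2]

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestSignedRank:
    def test_constant_shift_n6(self):
        x = np.arange(6.0)
        res = wilcoxon_signed_rank(x + 1, x)
        assert res.p_value == pytest.approx(0.03125)  # 2/2^6
        assert res.statistic == pytest.approx(21.0)  # all ranks positive

    def test_symmetric_differences_near_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])  # differences -1,+1,-1,+1
        assert wilcoxon_signed_rank(x, y).p_value >= 0.99

    def test_matches_enumeration_n10(self):
        rng = np.random.default_rng(17)
        x = rng.normal(0.3, 1.0, 10)
        y = rng.normal(0.0, 1.0, 10)
        assert wilcoxon_signed_rank(x, y).p_value == pytest.approx(
            signedrank_enumeration_p(x, y)
        )

    def test_matches_enumeration_with_tied_magnitudes(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = x - np.array([0.5, 0.5, 0.5, -0.5, 0.5])
        assert wilcoxon_signed_rank(x, y).p_value == pytest.approx(
            signedrank_enumeration_p(x, y)
        )

    def test_zero_differences_dropped(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 2.0, 3.0])  # two zeros dropped -> n=2
        res = wilcoxon_signed_rank(x, y)
        assert 0 < res.p_value <= 1

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0], [1.0, 2.0])


class TestWelch:
    def test_identical_groups(self):
        assert t_test_independent([1, 2, 3], [1, 2, 3]).p_value == pytest.approx(1.0)

    def test_extreme_separation(self):
        assert t_test_independent([1, 2, 3], [101, 102, 103]).p_value < 1e-3

    def test_hand_computed_welch(self):
        # closed-form oracle: t = (mx-my)/sqrt(sx2/nx+sy2/ny),
        # Welch-Satterthwaite df, two-sided p from the t distribution
        from scipy.stats import t as tdist

        x = np.array([27.5, 21.0, 19.0, 23.6, 17.0, 17.9, 16.9, 20.1, 21.9, 22.6, 23.1, 19.6])
        y = np.array([27.1, 22.0, 20.8, 23.4, 23.4, 23.5, 25.8, 22.0, 24.8, 20.2, 21.9, 22.1])
        nx, ny = len(x), len(y)
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        se2 = vx / nx + vy / ny
        t_stat = (x.mean() - y.mean()) / math.sqrt(se2)
        df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
        p = 2 * tdist.sf(abs(t_stat), df)
        res = t_test_independent(x, y)
        assert res.statistic == pytest.approx(t_stat)
        assert res.p_value == pytest.approx(p)

    def test_degenerate_variance(self):
        with pytest.raises(ValueError, match="degenerate"):
            t_test_independent([1.0, 1.0], [2.0, 2.0])


class TestFisher:
    def test_sex_table(self):
        # 10/6 males vs 4/3: no association at all
        assert fisher_exact([[10, 4], [6, 3]]).p_value == pytest.approx(1.0, abs=5e-4)

    def test_perfect_association(self):
        # only the two extreme tables are as unlikely: 2/C(10,5) = 0.00794
        assert fisher_exact([[5, 0], [0, 5]]).p_value == pytest.approx(2 / 252)

    def test_zero_margin(self):
        assert fisher_exact([[0, 0], [3, 4]]).p_value == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [2, 3]])


def make_record(i, group, dice, overlap=1.0, suv_mean_mri=1.2, suv_mean_fby=1.0):
    metrics = LesionMetrics(
        volume_mri_ml=10.0 + i,
        volume_fby_ml=15.0 + i,
        overlap_volume=overlap,
        dice=dice,
        suv_max=2.5,
        tn_ratio=21.0,
        suv_mean_mri=suv_mean_mri,
        suv_mean_fby=suv_mean_fby,
        suv_mean_margin=0.6,
        margin_over_nmax=5.2,
        margin_volume_ml=5.0,
        n_max=0.116,
        n_mean=0.037,
    )
    return PatientRecord(
        id=f"P{i}",
        group=group,
        age=40.0 + i,
        sex="male" if i % 2 else "female",
        metrics=metrics,
    )


class TestCohortTables:
    def test_identical_groups_are_not_significant(self):
        rng = np.random.default_rng(2)
        dices = rng.uniform(0.5, 0.9, 6)
        records = [make_record(i, GROUP_DIFFUSE, dices[i]) for i in range(6)] + [
            make_record(i + 10, GROUP_CIRCUMSCRIBED, dices[i]) for i in range(6)
        ]
        result = build_cohort_tables(records)
        assert result.variables.loc["dice", "p"] >= 0.95
        assert result.variables.loc["overlap_volume", "p"] >= 0.95

    def test_fby_equals_mri_everywhere_surfaces_precondition(self):
        records = [
            make_record(i, GROUP_DIFFUSE, 1.0, suv_mean_mri=1.0, suv_mean_fby=1.0)
            for i in range(4)
        ] + [
            make_record(i + 10, GROUP_CIRCUMSCRIBED, 1.0, suv_mean_mri=1.0, suv_mean_fby=1.0)
            for i in range(4)
        ]
        with pytest.raises(ValueError, match="zero"):
            build_cohort_tables(records)

    def test_missing_group_rejected(self):
        records = [make_record(i, GROUP_DIFFUSE, 0.7) for i in range(4)]
        with pytest.raises(ValueError, match="both groups"):
            build_cohort_tables(records)

    def test_table_matches_recomputation_from_frame(self):
        rng = np.random.default_rng(3)
        records = [
            make_record(i, GROUP_DIFFUSE, float(rng.uniform(0.4, 0.8)),
                        suv_mean_fby=float(rng.uniform(0.8, 1.1)))
            for i in range(8)
        ] + [
            make_record(i + 20, GROUP_CIRCUMSCRIBED, float(rng.uniform(0.8, 0.95)),
                        suv_mean_fby=float(rng.uniform(0.9, 1.15)))
            for i in range(5)
        ]
        result = build_cohort_tables(records)
        frame = records_to_frame(records)
        diff = frame[frame.group == GROUP_DIFFUSE]["dice"].to_numpy()
        circ = frame[frame.group == GROUP_CIRCUMSCRIBED]["dice"].to_numpy()
        assert result.variables.loc["dice", "diffuse_mean"] == pytest.approx(diff.mean())
        assert result.variables.loc["dice", "p"] == pytest.approx(
            wilcoxon_rank_sum(diff, circ).p_value
        )
        age_p = t_test_independent(
            frame[frame.group == GROUP_DIFFUSE]["age"],
            frame[frame.group == GROUP_CIRCUMSCRIBED]["age"],
        ).p_value
        assert result.variables.loc["age", "p"] == pytest.approx(age_p)
        assert result.sex_table.sum() == 13

    def test_invalid_record_labels(self):
        with pytest.raises(ValueError):
            make_record(1, "other", 0.5)
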