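from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from pairtcr.errors import ConfigError, InvariantError
from pairtcr.stats import (
    chi_squared_composition,
    holm_adjust,
    regulon_specificity_score,
    stars,
    t_test_unpaired,
    tumor_volume,
    wilcoxon_rank_sum,
)


class TestChiSquared:
    def test_homogeneous_table(self):
        res = chi_squared_composition([[10, 10], [10, 10]])
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0)
        assert res.stars == "ns"

    def test_hand_arithmetic_oracle(self):
        # margins of [[30,10],[20,40]]: E=[[20,20],[30,30]],
        # stat = 100/20 + 100/20 + 100/30 + 100/30 = 50/3
        res = chi_squared_composition([[30, 10], [20, 40]])
        assert res.statistic == pytest.approx(50.0 / 3.0, abs=1e-12)
        assert res.df == 1
        assert res.p == pytest.approx(float(sps.chi2.sf(50.0 / 3.0, 1)))

    def test_percentages_refused(self):
        with pytest.raises(ConfigError, match="percentages"):
            chi_squared_composition([[40.5, 59.5], [30.2, 69.8]])

    def test_zero_expected_rejected(self):
        with pytest.raises(ConfigError):
            chi_squared_composition([[5, 0], [3, 0]])

    def test_low_expected_warns_in_result(self):
        res = chi_squared_composition([[2, 3], [4, 1]])
        assert any("expected" in w for w in res.warnings)

    def test_invariant_to_row_and_column_permutation(self):
        rng = np.random.default_rng(8)
        tab = rng.integers(5, 40, size=(3, 4))
        base = chi_squared_composition(tab).statistic
        assert chi_squared_composition(tab[::-1]).statistic == pytest.approx(base)
        assert chi_squared_composition(tab[:, ::-1]).statistic == pytest.approx(base)

    def test_type_one_rate(self):
        rng = np.random.default_rng(1)
        n_sim, rejections = 2000, 0
        p = np.array([0.4, 0.6])
        for _ in range(n_sim):
            tab = np.vstack([rng.multinomial(120, p), rng.multinomial(120, p)])
            if tab.min() == 0:
                continue
            rejections += chi_squared_composition(tab).p < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07


def enumeration_oracle(x, y):
    """Exact two-sided rank-sum p by brute force over value assignments."""
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    ranks = sps.rankdata(pooled)
    mu = nx * (n + 1) / 2.0
    obs = abs(ranks[:nx].sum() - mu)
    hits = total = 0
    for subset in combinations(range(n), nx):
        w = ranks[list(subset)].sum()
        hits += abs(w - mu) >= obs - 1e-12
        total += 1
    return hits / total


class TestWilcoxon:
    def test_small_example_third(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.p == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_identical_multisets_p_one(self):
        with pytest.warns(UserWarning):
            res = wilcoxon_rank_sum([2, 2, 2], [2, 2, 2])
        assert res.p == 1.0

    def test_exact_matches_enumeration_n6(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            assert wilcoxon_rank_sum(x, y).p == pytest.approx(
                enumeration_oracle(x, y), abs=1e-12)

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        y = rng.normal(0.8, size=40)
        res = wilcoxon_rank_sum(x, y)
        assert res.test == "wilcoxon_rank_sum"
        assert res.p < 0.01

    def test_empty_arm_rejected(self):
        with pytest.raises(ConfigError):
            wilcoxon_rank_sum([], [1.0])


class TestTTest:
    def test_identical_arms(self):
        res = t_test_unpaired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_pooled_statistic(self):
        # means 2 and 5, pooled s2 = 1, se = sqrt(2/3), t = -3/se
        res = t_test_unpaired([1, 2, 3], [4, 5, 6])
        assert res.statistic == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), abs=1e-12)
        assert res.df == 4

    def test_zero_variance_equal_means(self):
        res = t_test_unpaired([2.0, 2.0], [2.0, 2.0])
        assert res.p == 1.0

    def test_type_one_rate(self):
        rng = np.random.default_rng(4)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            rejections += t_test_unpaired(rng.normal(size=15),
                                          rng.normal(size=15)).p < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07


class TestHolm:
    def test_two_values(self):
        assert holm_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_single_value_identity(self):
        assert holm_adjust([0.2]) == pytest.approx([0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            holm_adjust([0.5, 1.2])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_sandwiched_between_raw_and_bonferroni(self, pvals):
        adj = np.array(holm_adjust(pvals))
        raw = np.array(pvals)
        bonf = np.minimum(raw * len(raw), 1.0)
        assert np.all(adj >= raw - 1e-15)
        assert np.all(adj <= bonf + 1e-15)

    def test_monotone_in_inputs(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=6)
        bigger = np.minimum(p + rng.uniform(0, 0.2, size=6), 1.0)
        assert np.all(np.array(holm_adjust(bigger)) >=
                      np.array(holm_adjust(p)) - 1e-12)


class TestStars:
    @pytest.mark.parametrize("p,label", [
        (0.03, "*"), (0.05, "ns"), (5e-5, "****"), (0.009, "**"),
        (5e-4, "***"), (0.9, "ns"), (0.0, "****"),
    ])
    def test_threshold_map(self, p, label):
        assert stars(p) == label

    def test_out_of_range(self):
        with pytest.raises(InvariantError):
            stars(1.5)


def jsd_oracle(p, q):
    """Term-by-term base-2 Jensen-Shannon divergence."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    m = (p + q) / 2.0
    kl_pm = sum(pi * np.log2(pi / mi) for pi, mi in zip(p, m) if pi > 0)
    kl_qm = sum(qi * np.log2(qi / mi) for qi, mi in zip(q, m) if qi > 0)
    return 0.5 * kl_pm + 0.5 * kl_qm


class TestRSS:
    def test_perfectly_specific_regulon(self):
        labels = ["A"] * 4 + ["B"] * 4
        act = pd.DataFrame([[1, 1, 1, 1, 0, 0, 0, 0]], index=["reg1"],
                           columns=[f"c{i}" for i in range(8)])
        rss = regulon_specificity_score(act, labels)
        assert rss.loc["reg1", "A"] == pytest.approx(1.0)

    def test_uniform_regulon_against_half_label_oracle(self):
        n = 10
        labels = ["A"] * 5 + ["B"] * 5
        act = pd.DataFrame([np.ones(n)], index=["r"],
                           columns=[f"c{i}" for i in range(n)])
        rss = regulon_specificity_score(act, labels)
        p = np.full(n, 1.0 / n)
        q = np.array([0.2] * 5 + [0.0] * 5)
        expect = 1.0 - np.sqrt(jsd_oracle(p, q))
        assert rss.loc["r", "A"] == pytest.approx(expect, abs=1e-10)

    def test_mixing_toward_uniform_decreases_rss(self):
        n = 20
        labels = ["A"] * 5 + ["B"] * 15
        specific = np.array([1.0] * 5 + [0.0] * 15)
        uniform = np.ones(n)
        last = np.inf
        for step in range(21):
            alpha = step / 20.0
            act = pd.DataFrame([(1 - alpha) * specific + alpha * uniform],
                               index=["r"], columns=[f"c{i}" for i in range(n)])
            val = regulon_specificity_score(act, labels).loc["r", "A"]
            assert val < last
            last = val

    def test_all_zero_regulon_missing(self):
        act = pd.DataFrame([[0.0, 0.0]], index=["r"], columns=["a", "b"])
        rss = regulon_specificity_score(act, ["A", "B"])
        assert rss.loc["r"].isna().all()

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(6)
        act = pd.DataFrame(rng.gamma(1.0, size=(5, 30)))
        labels = list(rng.choice(["A", "B", "C"], size=30))
        rss = regulon_specificity_score(act, labels)
        assert ((rss >= 0) & (rss <= 1)).all().all()


class TestTumorVolume:
    def test_formula(self):
        assert tumor_volume(2, 4) == pytest.approx(8.0)
        assert tumor_volume(1, 1) == pytest.approx(0.5)

    def test_swapped_diameters_rejected(self):
        with pytest.raises(ConfigError):
            tumor_volume(5, 3)

    def test_non_positive_rejected(self):
        with pytest.raises(ConfigError):
            tumor_volume(0, 3)
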