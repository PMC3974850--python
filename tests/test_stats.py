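"""Exact rank tests vs brute-force and scipy oracles; Spearman permutation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from sparklet import (
    mann_whitney,
    paired_table,
    spearman_dependence,
    summarize_mean_sem,
    unpaired_t,
    wilcoxon_signed_rank,
)
from sparklet.stats import compare_conditions
from sparklet.validation import (
    brute_force_mann_whitney_p,
    brute_force_wilcoxon_p,
)


class TestWilcoxon:
    def test_all_positive_differences_exact(self):
        # W = 0 (smaller rank sum), p = 2/2^5
        r = wilcoxon_signed_rank([1, 2, 3, 4, 5], [0, 0, 0, 0, 0])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(0.0625, abs=1e-12)
        assert r.method == "exact"

    def test_antisymmetric_pair_p_one(self):
        r = wilcoxon_signed_rank([1, -1], [0, 0])
        assert r.p_value == 1.0

    def test_all_zero_differences_degenerate(self):
        r = wilcoxon_signed_rank([1, 2], [1, 2])
        assert r.method == "degenerate"
        assert r.p_value == 1.0

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            m = int(rng.integers(4, 11))
            x, y = rng.normal(size=m), rng.normal(size=m)
            ours = wilcoxon_signed_rank(x, y, method="exact").p_value
            ref = sps.wilcoxon(x, y, mode="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    @given(st.integers(0, 200))
    def test_exact_equals_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(3, 9))
        x = np.round(rng.normal(size=m) * 2) / 2
        y = np.round(rng.normal(size=m) * 2) / 2
        ours = wilcoxon_signed_rank(x, y, method="exact").p_value
        assert ours == pytest.approx(brute_force_wilcoxon_p(x, y), abs=1e-12)

    def test_exact_vs_normal_approx_agree(self):
        rng = np.random.default_rng(7)
        for m in range(5, 13):
            x, y = rng.normal(size=m), rng.normal(size=m)
            pe = wilcoxon_signed_rank(x, y, method="exact").p_value
            pa = wilcoxon_signed_rank(x, y, method="approx").p_value
            assert abs(pe - pa) < 0.03


class TestMannWhitney:
    def test_identical_groups_p_one(self):
        assert mann_whitney([1, 2, 3], [1, 2, 3]).p_value == 1.0

    def test_fully_separated_groups_exact(self):
        # U = 0, p = 2 / C(6,3)
        r = mann_whitney([1, 2, 3], [10, 11, 12])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(0.1, abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n_a, n_b = int(rng.integers(3, 7)), int(rng.integers(3, 8))
            a, b = rng.normal(size=n_a), rng.normal(size=n_b)
            ours = mann_whitney(a, b, method="exact").p_value
            ref = sps.mannwhitneyu(a, b, method="exact",
                                   alternative="two-sided").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    @given(st.integers(0, 200))
    def test_exact_equals_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_a = int(rng.integers(2, 6))
        n_b = int(rng.integers(2, 11 - n_a))
        a = np.round(rng.normal(size=n_a) * 2) / 2
        b = np.round(rng.normal(size=n_b) * 2) / 2
        ours = mann_whitney(a, b, method="exact").p_value
        assert ours == pytest.approx(brute_force_mann_whitney_p(a, b), abs=1e-12)

    def test_exact_vs_normal_approx_agree(self):
        rng = np.random.default_rng(9)
        for n in range(5, 13):
            a, b = rng.normal(size=n // 2 + 2), rng.normal(size=n - n // 2 + 2)
            pe = mann_whitney(a, b, method="exact").p_value
            pa = mann_whitney(a, b, method="approx").p_value
            assert abs(pe - pa) < 0.03

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestUnpairedT:
    def test_identical_groups(self):
        r = unpaired_t([1, 2, 3], [1, 2, 3])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_matches_hand_computed_pooled_t(self):
        a = np.array([4.0, 5.0, 6.0, 7.0])
        b = np.array([1.0, 2.0, 3.0])
        sp2 = (a.var(ddof=1) * 3 + b.var(ddof=1) * 2) / 5
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 4 + 1 / 3))
        p = 2 * sps.t.sf(abs(t), df=5)
        r = unpaired_t(a, b)
        assert r.statistic == pytest.approx(t, abs=1e-10)
        assert r.p_value == pytest.approx(p, abs=1e-10)

    def test_p_monotone_in_shift(self):
        base = np.array([0.0, 1.0])
        ps = [unpaired_t(base, base + delta).p_value
              for delta in (0.5, 1.0, 2.0, 4.0)]
        assert ps == sorted(ps, reverse=True)

    def test_too_small_group_raises(self):
        with pytest.raises(ValueError):
            unpaired_t([1.0], [1.0, 2.0])


class TestSpearman:
    def test_identity_and_reversal(self):
        assert spearman_dependence([1, 2, 3, 4, 5],
                                   [2, 4, 6, 8, 10]).statistic == pytest.approx(1.0)
        assert spearman_dependence([1, 2, 3, 4, 5],
                                   [9, 7, 5, 3, 1]).statistic == pytest.approx(-1.0)

    def test_textbook_rs_and_full_permutation_p(self):
        # d^2 sums to 6: rs = 1 - 36/120 = 0.7; p from the 5! enumeration
        x, y = [1, 2, 3, 4, 5], [2, 3, 1, 4, 5]
        r = spearman_dependence(x, y)
        assert r.statistic == pytest.approx(0.7)
        assert r.method == "exact"
        rs_all = [sps.spearmanr(x, np.array(y)[list(p)]).statistic
                  for p in itertools.permutations(range(5))]
        p_oracle = np.mean(np.abs(rs_all) >= 0.7 - 1e-12)
        assert r.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_permutation_p_reproducible_and_calibrated(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r1 = spearman_dependence(x, y, seed=5)
        r2 = spearman_dependence(x, y, seed=5)
        assert r1.p_value == r2.p_value
        assert r1.method == "permutation"
        assert "mc_se" in r1.extras
        # strongly monotone data must be declared dependent
        strong = spearman_dependence(np.arange(20.0), np.arange(20.0) ** 2,
                                     seed=1)
        assert strong.extras["dependent"]

    def test_constant_column_degenerate(self):
        r = spearman_dependence([1, 1, 1, 1], [1, 2, 3, 4])
        assert r.method == "degenerate"

    def test_too_few_pairs_raises(self):
        with pytest.raises(ValueError):
            spearman_dependence([1, 2, 3], [1, 2, 3])


class TestRowOrderInvariance:
    @given(st.integers(0, 30))
    def test_tests_invariant_to_row_order(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        x, y = rng.normal(size=n), rng.normal(size=n)
        perm = rng.permutation(n)
        assert (wilcoxon_signed_rank(x, y).p_value
                == wilcoxon_signed_rank(x[perm], y[perm]).p_value)
        assert (spearman_dependence(x, y).p_value
                == spearman_dependence(x[perm], y[perm]).p_value)
        assert (mann_whitney(x, y).p_value
                == mann_whitney(rng.permutation(x), rng.permutation(y)).p_value)


def test_summarize_mean_sem():
    assert summarize_mean_sem([1, 1, 1])[:2] == (1.0, 0.0)
    assert summarize_mean_sem([0, 2])[:2] == (1.0, 1.0)
    m, s, flags = summarize_mean_sem([3.5])
    assert (m, s) == (3.5, 0.0)
    assert flags["sem_undefined"]


def _cells(freqs, amps, condition="a"):
    return pd.DataFrame({
        "cell_id": range(1, len(freqs) + 1),
        "condition": condition,
        "n_events": [0 if np.isnan(a) else 2 for a in amps],
        "membrane_area_mm2": 0.001,
        "recording_duration_s": 13.333,
        "frequency_hz_per_mm2": freqs,
        "mean_amplitude_ff0": amps,
    })


class TestCompareConditions:
    def test_identical_tables_give_null_frequency_result(self):
        cells = _cells([1.0, 2.0, 3.0, 4.0, 5.0], [0.1, 0.2, 0.1, 0.3, 0.2])
        rep = compare_conditions(cells, cells.copy(), paired=True)
        assert rep["tests"]["frequency"]["p_value"] == 1.0
        assert rep["tests"]["frequency_dependence"]["statistic"] == pytest.approx(1.0)
        assert rep["tests"]["amplitude"]["p_value"] == pytest.approx(1.0)

    def test_unpaired_selects_mann_whitney(self):
        a = _cells([1.0, 2.0, 3.0, 4.0], [0.1, 0.2, 0.15, 0.12])
        b = _cells([5.0, 6.0, 7.0], [0.1, 0.2, 0.14], condition="b")
        rep = compare_conditions(a, b, paired=False)
        assert rep["tests"]["frequency"]["test_name"] == "mann_whitney"

    def test_paired_mismatched_cells_raise(self):
        a = _cells([1.0, 2.0, 3.0, 4.0], [0.1] * 4)
        b = a.copy()
        b.cell_id = [1, 2, 3, 99]
        with pytest.raises(ValueError):
            compare_conditions(a, b, paired=True)

    def test_paired_table_rejects_duplicates(self):
        a = _cells([1.0, 2.0], [0.1, 0.1])
        dup = pd.concat([a, a])
        with pytest.raises(ValueError):
            paired_table(dup, dup)
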