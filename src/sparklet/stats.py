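"""Nonparametric comparison and rank-dependence tests.

The statistical layer of the pipeline: Wilcoxon matched-pairs signed-rank for
paired frequencies, Mann-Whitney for unpaired designs, a pooled-variance
Student t-test for amplitudes (zero-sparklet cells removed upstream), and a
Spearman rank-correlation test of whether paired per-cell frequencies are
statistically dependent.  All p-values are two-sided; significance is read
at alpha = 0.05.

Small samples use exact null distributions: full enumeration of the 2^m sign
assignments (Wilcoxon, m <= 12), of the C(n, n_a) group labelings
(Mann-Whitney, n_a + n_b <= 14) and of the n! rank permutations (Spearman,
n <= 8); midranks handle ties throughout.  Above those cutoffs the standard
tie-corrected normal approximations (with continuity correction) or a seeded
Monte-Carlo permutation null (Spearman, 10^4 draws, Monte-Carlo SE reported)
take over.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "wilcoxon_signed_rank",
    "mann_whitney",
    "unpaired_t",
    "spearman_dependence",
    "summarize_mean_sem",
    "paired_table",
    "compare_conditions",
]

WILCOXON_EXACT_MAX = 12
MANN_WHITNEY_EXACT_MAX = 14
SPEARMAN_EXACT_MAX = 8
SPEARMAN_N_PERMUTATIONS = 10_000


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test (two-sided p-value)."""

    test_name: str
    statistic: float
    p_value: float
    n: object  # pair count or (n_a, n_b)
    method: str  # exact | approx | permutation | degenerate
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")

    @property
    def significant_at_0_05(self) -> bool:
        return self.p_value < 0.05

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n": self.n,
            "method": self.method,
            "significant_at_0.05": bool(self.significant_at_0_05),
            **self.extras,
        }


def _two_sided_from_distribution(weights: np.ndarray, observed_idx: float,
                                 total: float) -> float:
    """2 * min(lower, upper) tail probability from a discrete pmf on indices."""
    idx = np.arange(len(weights))
    lower = weights[idx <= observed_idx + 1e-9].sum()
    upper = weights[idx >= observed_idx - 1e-9].sum()
    return min(1.0, 2.0 * min(lower, upper) / total)


# ---------------------------------------------------------------------------
# Wilcoxon matched-pairs signed rank


def wilcoxon_signed_rank(x, y, method: str = "auto") -> TestResult:
    """Wilcoxon matched-pairs signed-rank test on paired samples.

    Zero differences are dropped; tied absolute differences receive midranks.
    ``method``: "exact" (enumeration of sign assignments), "approx"
    (tie-corrected normal with continuity correction) or "auto" (exact when
    the number of nonzero differences is <= 12).
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0.0]
    m = d.size
    if m == 0:
        return TestResult("wilcoxon_signed_rank", math.nan, 1.0, 0, "degenerate",
                          {"note": "all differences zero"})
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if method == "auto":
        method = "exact" if m <= WILCOXON_EXACT_MAX else "approx"
    if method == "exact":
        # distribution of W+ over all 2^m sign assignments by convolution
        # over doubled ranks (midranks are multiples of 1/2)
        r2 = np.rint(2 * ranks).astype(int)
        pmf = np.zeros(r2.sum() + 1)
        pmf[0] = 1.0
        for r in r2:
            pmf[r:] += pmf[:-r].copy() if r else pmf.copy()
        p = _two_sided_from_distribution(pmf, 2 * w_plus, 2.0**m)
    else:
        mean = ranks.sum() / 2.0
        var = float((ranks**2).sum()) / 4.0
        z = (w_plus - mean - math.copysign(0.5, w_plus - mean)) / math.sqrt(var)
        if w_plus == mean:
            z = 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        p = min(1.0, p)
    w_minus = float(ranks.sum()) - w_plus
    # report the conventional W: the smaller of the two signed rank sums
    return TestResult("wilcoxon_signed_rank", min(w_plus, w_minus), p, m,
                      method, {"w_plus": w_plus, "w_minus": w_minus})


# ---------------------------------------------------------------------------
# Mann-Whitney


def _mw_exact_p(ranks2: np.ndarray, n_a: int, u2_obs: float) -> float:
    """Exact two-sided p for U via DP over subsets of size n_a (doubled ranks)."""
    total = ranks2.sum()
    # dp[k][s]: number of k-subsets of the doubled ranks with sum s
    dp = np.zeros((n_a + 1, int(total) + 1))
    dp[0, 0] = 1.0
    for r in ranks2:
        for k in range(min(n_a, 1_000), 0, -1):
            dp[k, r:] += dp[k - 1, :int(total) + 1 - r]
    pmf = dp[n_a]
    # U = R_a - n_a(n_a+1)/2; doubled: U2 = S2 - n_a(n_a+1)
    offset = n_a * (n_a + 1)
    u_pmf = pmf[offset:]
    return _two_sided_from_distribution(u_pmf, u2_obs, u_pmf.sum())


def mann_whitney(group_a, group_b, method: str = "auto") -> TestResult:
    """Mann-Whitney U test (two-sided) for two independent samples.

    Exact by enumeration of group labelings when n_a + n_b <= 14; otherwise a
    tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n_a, n_b = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    r_a = float(ranks[:n_a].sum())
    u_a = r_a - n_a * (n_a + 1) / 2.0
    if method == "auto":
        method = "exact" if n_a + n_b <= MANN_WHITNEY_EXACT_MAX else "approx"
    if method == "exact":
        ranks2 = np.rint(2 * ranks).astype(int)
        p = _mw_exact_p(ranks2, n_a, 2 * u_a)
    else:
        n = n_a + n_b
        mean = n_a * n_b / 2.0
        _, counts = np.unique(combined, return_counts=True)
        tie_term = float((counts**3 - counts).sum())
        var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            return TestResult("mann_whitney", u_a, 1.0, (n_a, n_b), "degenerate",
                              {"note": "all values tied"})
        z = (u_a - mean - math.copysign(0.5, u_a - mean)) / math.sqrt(var)
        if u_a == mean:
            z = 0.0
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return TestResult("mann_whitney", u_a, p, (n_a, n_b), method)


# ---------------------------------------------------------------------------
# Student t (pooled variance)


def unpaired_t(group_a, group_b) -> TestResult:
    """Classic pooled-variance two-sided Student t-test."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        # scipy returns NaN for zero pooled variance with equal means
        return TestResult("unpaired_t", 0.0, 1.0, (a.size, b.size), "degenerate",
                          {"note": "zero pooled variance"})
    res = sps.ttest_ind(a, b, equal_var=True)
    if not math.isfinite(res.pvalue):
        raise ValueError("zero pooled variance with unequal means")
    return TestResult("unpaired_t", float(res.statistic), float(res.pvalue),
                      (a.size, b.size), "exact",
                      {"df": a.size + b.size - 2})


# ---------------------------------------------------------------------------
# Spearman rank dependence


def _spearman_rs(rx: np.ndarray, ry: np.ndarray) -> float:
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float((rxc**2).sum() * (ryc**2).sum()))
    if denom == 0.0:
        return math.nan
    return float((rxc * ryc).sum() / denom)


def spearman_dependence(x, y, seed: int = 0,
                        n_permutations: int = SPEARMAN_N_PERMUTATIONS,
                        method: str = "auto") -> TestResult:
    """Spearman rank correlation with a permutation test of independence.

    ``rs`` uses midranks (with no ties it equals 1 - 6 sum d^2 / (n(n^2-1))).
    The two-sided p enumerates all n! rank permutations when n <= 8 and
    otherwise uses ``n_permutations`` seeded random permutations (the
    Monte-Carlo standard error is reported in ``extras``).  Dependence is
    declared when p < 0.05.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult("spearman_dependence", math.nan, math.nan, n,
                          "degenerate", {"note": "constant column"})
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rs = _spearman_rs(rx, ry)
    if method == "auto":
        method = "exact" if n <= SPEARMAN_EXACT_MAX else "permutation"
    extras: dict = {}
    if method == "exact":
        perms = np.array(list(itertools.permutations(range(n))))
        rs_all = _rs_against(rx, ry[perms])
        p = float(np.mean(np.abs(rs_all) >= abs(rs) - 1e-12))
    else:
        rng = np.random.default_rng(seed)
        perm_y = rng.permuted(np.tile(ry, (n_permutations, 1)), axis=1)
        rs_perm = _rs_against(rx, perm_y)
        hits = int(np.sum(np.abs(rs_perm) >= abs(rs) - 1e-12))
        p = (1.0 + hits) / (1.0 + n_permutations)
        extras["mc_se"] = math.sqrt(p * (1 - p) / n_permutations)
    extras["dependent"] = bool(p < 0.05)
    return TestResult("spearman_dependence", rs, p, n, method, extras)


def _rs_against(rx: np.ndarray, ry_matrix: np.ndarray) -> np.ndarray:
    """Vectorized Spearman rs of one rank vector against many."""
    rxc = rx - rx.mean()
    ryc = ry_matrix - ry_matrix.mean(axis=1, keepdims=True)
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum(axis=1))
    return (ryc @ rxc) / denom


# ---------------------------------------------------------------------------
# summaries and report assembly


def summarize_mean_sem(values) -> tuple[float, float, dict]:
    """Mean and standard error of the mean; SEM is 0 (flagged) at n = 1."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 1:
        raise ValueError("need at least one value")
    if v.size == 1:
        return float(v[0]), 0.0, {"n": 1, "sem_undefined": True}
    return float(v.mean()), float(v.std(ddof=1) / math.sqrt(v.size)), {"n": int(v.size)}


def paired_table(cells_a: pd.DataFrame, cells_b: pd.DataFrame,
                 value: str = "frequency_hz_per_mm2") -> pd.DataFrame:
    """Join two per-cell summaries into (cell_id, value_control, value_treatment).

    Requires identical, unique cell_id sets (no missing halves).
    """
    ids_a, ids_b = set(cells_a.cell_id), set(cells_b.cell_id)
    if len(ids_a) != len(cells_a) or len(ids_b) != len(cells_b):
        raise ValueError("duplicate cell_ids in a summary table")
    if ids_a != ids_b:
        raise ValueError("paired tables must cover the same cells")
    merged = cells_a[["cell_id", value]].merge(
        cells_b[["cell_id", value]], on="cell_id", suffixes=("_control", "_treatment")
    )
    merged.columns = ["cell_id", "value_control", "value_treatment"]
    return merged.sort_values("cell_id").reset_index(drop=True)


def compare_conditions(
    cells_a: pd.DataFrame,
    cells_b: pd.DataFrame,
    paired: bool = True,
    seed: int = 0,
) -> dict:
    """Run the full comparison battery on two per-cell summary tables.

    Paired designs use the Wilcoxon matched-pairs signed-rank test on
    frequencies plus the Spearman dependence test; unpaired designs (e.g. the
    EGTA-AM case, where paired controls are impossible) use Mann-Whitney.
    Amplitudes are always compared with the unpaired pooled t-test after
    removing zero-sparklet cells.
    """
    report: dict = {"paired": paired, "tests": {}}
    if paired:
        pt = paired_table(cells_a, cells_b)
        report["tests"]["frequency"] = wilcoxon_signed_rank(
            pt.value_control, pt.value_treatment).to_dict()
        if len(pt) >= 4:
            report["tests"]["frequency_dependence"] = spearman_dependence(
                pt.value_control, pt.value_treatment, seed=seed).to_dict()
        else:
            report["tests"]["frequency_dependence"] = {
                "test_name": "spearman_dependence", "skipped": True,
                "note": "fewer than 4 pairs",
            }
    else:
        report["tests"]["frequency"] = mann_whitney(
            cells_a.frequency_hz_per_mm2, cells_b.frequency_hz_per_mm2).to_dict()
    amp_a = cells_a.loc[cells_a.n_events >= 1, "mean_amplitude_ff0"]
    amp_b = cells_b.loc[cells_b.n_events >= 1, "mean_amplitude_ff0"]
    if len(amp_a) >= 2 and len(amp_b) >= 2:
        report["tests"]["amplitude"] = unpaired_t(amp_a, amp_b).to_dict()
    else:
        report["tests"]["amplitude"] = {
            "test_name": "unpaired_t", "skipped": True,
            "note": "fewer than 2 sparklet-positive cells in a group",
        }
    for label, amp, cells in (("a", amp_a, cells_a), ("b", amp_b, cells_b)):
        mean_f, sem_f, _ = summarize_mean_sem(cells["frequency_hz_per_mm2"])
        report.setdefault("summary", {})[label] = {
            "n_cells": int(len(cells)),
            "frequency_mean_hz_per_mm2": mean_f,
            "frequency_sem_hz_per_mm2": sem_f,
            "n_sparklet_positive_cells": int(len(amp)),
            "amplitude_mean_ff0": float(np.mean(amp)) if len(amp) else None,
        }
    return report
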