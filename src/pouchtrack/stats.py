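"""Group-comparison statistics for migration metrics and phenotype scores.

The battery mirrors what is conventional for this kind of experiment:

* one-tailed Welch t-test (unequal variances, Welch–Satterthwaite df) for
  cell velocity and persistence;
* Pearson chi-square test of independence for deviation-angle
  distributions (two groups × angle bins);
* Fisher's exact test for 2×2 contribution tables, computed with exact
  integer arithmetic and the probability-mass two-tailed convention;
* Tukey–Kramer all-pairs multiple comparison of group means for pouch and
  ceratobranchial scores, using the studentized-range distribution and
  valid for unequal group sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import InputValidationError
from .tracks import AngleHistogram

__all__ = [
    "TestResult",
    "PairwiseComparison",
    "welch_t_one_tailed",
    "chi_square_independence",
    "fisher_exact",
    "tukey_kramer",
    "compare_angle_distributions",
]

TAILS = ("one_tailed_greater", "one_tailed_less", "two_tailed")


@dataclass
class TestResult:
    test_name: str
    statistic: float
    df: float | None
    p_value: float
    tail: str
    degenerate: bool = False


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_diff: float       # mean_a - mean_b
    q_statistic: float
    p_adjusted: float
    degenerate: bool = False


def _check_tail(tail: str) -> None:
    if tail not in TAILS:
        raise InputValidationError(f"tail must be one of {TAILS}, got {tail!r}")


# ---------------------------------------------------------------------------
# Welch t-test


def welch_t_one_tailed(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    tail: str = "one_tailed_less",
) -> TestResult:
    """Welch unequal-variance t-test of mean(a) against mean(b).

    ``one_tailed_greater`` tests the alternative mean(a) > mean(b),
    ``one_tailed_less`` the alternative mean(a) < mean(b).  When both
    samples have zero variance the test is degenerate: equal means give
    p = 0.5 (one-tailed) or 1.0 (two-tailed); unequal means give p = 0 or
    1 according to the tail.
    """
    _check_tail(tail)
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    for name, s in (("sample_a", a), ("sample_b", b)):
        if s.size < 2:
            raise InputValidationError(f"{name} needs n >= 2, got {s.size}")
        if not np.all(np.isfinite(s)):
            raise InputValidationError(f"{name} contains non-finite values")

    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        diff = a.mean() - b.mean()
        if diff == 0.0:
            p = 1.0 if tail == "two_tailed" else 0.5
            return TestResult("welch_t", 0.0, math.nan, p, tail, degenerate=True)
        t = math.inf if diff > 0 else -math.inf
        if tail == "two_tailed":
            p = 0.0
        elif tail == "one_tailed_greater":
            p = 0.0 if diff > 0 else 1.0
        else:
            p = 0.0 if diff < 0 else 1.0
        return TestResult("welch_t", t, math.nan, p, tail, degenerate=True)

    alternative = {
        "one_tailed_greater": "greater",
        "one_tailed_less": "less",
        "two_tailed": "two-sided",
    }[tail]
    res = sps.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return TestResult(
        "welch_t",
        float(res.statistic),
        float(res.df),
        float(res.pvalue),
        tail,
    )


# ---------------------------------------------------------------------------
# chi-square


def chi_square_independence(table: Sequence[Sequence[float]]) -> TestResult:
    """Pearson chi-square test of independence on an R×C count table.

    Expected counts come from the margins; df = (R-1)(C-1); upper-tail p.
    No continuity correction is applied.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise InputValidationError("table must be at least 2x2")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise InputValidationError("table counts must be finite and >= 0")
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    for i, s in enumerate(row_sums):
        if s == 0:
            raise InputValidationError(f"row {i} has zero margin")
    for j, s in enumerate(col_sums):
        if s == 0:
            raise InputValidationError(f"column {j} has zero margin")
    stat, p, df, _ = sps.chi2_contingency(t, correction=False)
    return TestResult("chi_square_independence", float(stat), int(df), float(p),
                      "two_tailed")


# ---------------------------------------------------------------------------
# Fisher's exact test (exact integer arithmetic)


@lru_cache(maxsize=4096)
def _fisher_family(r1: int, r2: int, c1: int) -> dict[int, tuple[float, float, float]]:
    """p-values for every table with row margins (r1, r2) and first-column
    margin c1, keyed by the top-left cell count.

    Returns ``{a: (p_two, p_greater, p_less)}``.  Weights are exact
    integers (binomial coefficients), so probability-mass ties are resolved
    exactly and two tables with equal hypergeometric probability are always
    grouped together.
    """
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = range(lo, hi + 1)
    w = {a: math.comb(r1, a) * math.comb(r2, c1 - a) for a in support}
    denom = math.comb(r1 + r2, c1)
    order = sorted(support, key=w.__getitem__)
    # prefix sums of weights in increasing probability order
    prefix: list[int] = [0]
    for a in order:
        prefix.append(prefix[-1] + w[a])
    rank_end: dict[int, int] = {}
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and w[order[j + 1]] == w[order[i]]:
            j += 1
        for k_ in range(i, j + 1):   # ties share the inclusive prefix sum
            rank_end[order[k_]] = j + 1
        i = j + 1
    out: dict[int, tuple[float, float, float]] = {}
    cum_ge = 0  # running sum of weights for a' >= a, built from the top
    ge: dict[int, int] = {}
    for a in range(hi, lo - 1, -1):
        cum_ge += w[a]
        ge[a] = cum_ge
    total = prefix[-1]
    for a in support:
        p_two = float(Fraction(prefix[rank_end[a]], denom))
        p_greater = float(Fraction(ge[a], denom))
        p_less = float(Fraction(total - ge[a] + w[a], denom))
        out[a] = (min(p_two, 1.0), min(p_greater, 1.0), min(p_less, 1.0))
    return out


def fisher_exact(
    table: Sequence[Sequence[int]], tail: str = "two_tailed"
) -> TestResult:
    """Fisher's exact test on a 2×2 count table.

    The two-tailed p sums the probabilities of all tables (with the same
    margins) whose hypergeometric probability does not exceed that of the
    observed table — the probability-mass convention — with ties resolved
    by exact integer arithmetic.  ``one_tailed_greater`` is the upper tail
    on the top-left cell (enrichment of row 1 in column 1).  The reported
    statistic is the sample odds ratio.
    """
    _check_tail(tail)
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise InputValidationError(f"table must be 2x2, got shape {t.shape}")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise InputValidationError("table must hold non-negative integers")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    if a + b + c + d < 1:
        raise InputValidationError("grand total must be >= 1")
    p_two, p_greater, p_less = _fisher_family(a + b, c + d, a + c)[a]
    p = {"two_tailed": p_two,
         "one_tailed_greater": p_greater,
         "one_tailed_less": p_less}[tail]
    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a * d > 0:
        odds = math.inf
    else:
        odds = math.nan
    return TestResult("fisher_exact", odds, None, p, tail)


# ---------------------------------------------------------------------------
# Tukey–Kramer


def tukey_kramer(
    groups: Mapping[str, Sequence[float]],
) -> list[PairwiseComparison]:
    """All-pairs Tukey–Kramer comparison of group means.

    Uses the pooled within-group variance (MSE on N-k df) and, for each
    pair, q = \\|mean_a - mean_b\\| / sqrt(MSE/2 * (1/n_a + 1/n_b)); the
    adjusted p comes from the studentized-range distribution with k groups
    and N-k error df.  The Kramer form is valid for unequal group sizes.
    """
    if len(groups) < 2:
        raise InputValidationError("need at least 2 groups")
    arrs: dict[str, np.ndarray] = {}
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 2:
            raise InputValidationError(f"group {name!r} needs n >= 2, got {v.size}")
        if not np.all(np.isfinite(v)):
            raise InputValidationError(f"group {name!r} contains non-finite values")
        arrs[name] = v
    k = len(arrs)
    n_total = sum(v.size for v in arrs.values())
    df_error = n_total - k
    sse = sum(float(((v - v.mean()) ** 2).sum()) for v in arrs.values())
    mse = sse / df_error

    out: list[PairwiseComparison] = []
    for name_a, name_b in combinations(sorted(arrs), 2):
        va, vb = arrs[name_a], arrs[name_b]
        diff = float(va.mean() - vb.mean())
        se = math.sqrt(mse / 2.0 * (1.0 / va.size + 1.0 / vb.size))
        if mse == 0.0:
            if diff == 0.0:
                out.append(PairwiseComparison(name_a, name_b, 0.0, 0.0, 1.0))
            else:
                out.append(
                    PairwiseComparison(
                        name_a, name_b, diff, math.inf, 0.0, degenerate=True
                    )
                )
            continue
        q = abs(diff) / se
        p = float(sps.studentized_range.sf(q, k, df_error))
        out.append(PairwiseComparison(name_a, name_b, diff, q, min(max(p, 0.0), 1.0)))
    return out


# ---------------------------------------------------------------------------
# angle-distribution comparison


def compare_angle_distributions(
    hist_a: AngleHistogram, hist_b: AngleHistogram
) -> TestResult:
    """Chi-square comparison of two binned deviation-angle distributions.

    The two count vectors are stacked into a 2×n_bins table; bins empty in
    both groups are dropped (reducing df) to avoid zero expected counts.
    """
    if hist_a.bin_edges_deg.shape != hist_b.bin_edges_deg.shape or not np.allclose(
        hist_a.bin_edges_deg, hist_b.bin_edges_deg, atol=1e-9
    ):
        raise InputValidationError("histograms have mismatched bin edges")
    table = np.vstack([hist_a.counts, hist_b.counts])
    nonempty = table.sum(axis=0) > 0
    table = table[:, nonempty]
    if table.shape[1] < 2:
        raise InputValidationError(
            "fewer than 2 non-empty bins; angle distributions cannot be compared"
        )
    res = chi_square_independence(table)
    res.test_name = "angle_distribution_chi_square"
    return res
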