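"""Normality-gated inference: paired comparisons and correlations with exact
small-sample rank p-values.

The gate applies the Shapiro-Wilk test: a sample is routed to non-parametric
statistics when W's p-value falls below 0.05.  Correlations between two
variables use Spearman's rank coefficient with a two-sided p from the exact
permutation null whenever either variable fails the gate, and Pearson's
product-moment coefficient with the t reference distribution otherwise.
Paired comparisons gate on the differences and use the paired t-test or the
Wilcoxon signed-rank test.  All p-values are two-sided.

Exact Spearman null
-------------------
The permutation null holds one variable fixed and considers all n! orderings
of the other.  Three routes, recorded in ``p_method``:

* ``exact`` via full enumeration for n <= 9 (average ranks, so ties are
  handled);
* ``exact`` via the exact distribution of the rank statistic
  S = sum_i (R_i - i)^2 for tie-free data and larger n: the number of
  permutations attaining each S value is counted by a dynamic programme over
  subsets of assigned ranks (2^n states, each carrying a vector of counts over
  S), which reproduces full enumeration without materialising n! permutations;
* ``monte_carlo`` with >= 1e6 seeded permutations and the add-one estimator
  (count+1)/(m+1) as the fallback for tied data above n = 9.

A permutation statistic counts as at least as extreme as the observed one when
|r_perm| >= |r_obs| - 1e-12.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from math import factorial

import numpy as np
from scipy import stats

from .exceptions import (
    DegenerateInputError,
    InsufficientDataError,
    ParameterError,
)

PERM_TOL = 1e-12
ENUM_MAX_N = 9  # full n! enumeration up to here
DP_MAX_N = 13  # exact rank-statistic distribution up to here (tie-free)


@dataclass(frozen=True)
class GateResult:
    decision: str  # "parametric" | "nonparametric"
    shapiro_p: float
    degenerate: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    measure_x: str
    measure_y: str
    method: str  # "spearman" | "pearson"
    r: float
    p: float
    p_method: str  # "exact" | "approximate" | "monte_carlo"
    n: int


@dataclass(frozen=True)
class PairedComparisonResult:
    method: str  # "paired_t" | "wilcoxon_signed_rank"
    statistic: float
    p: float
    n: int
    degenerate: bool = False


def normality_gate(sample, alpha: float = 0.05) -> GateResult:
    """Shapiro-Wilk gate: non-parametric iff the test rejects at ``alpha``.

    A constant (zero-variance) sample is degenerate for the test and is routed
    to the non-parametric branch with a warning.
    """
    arr = np.asarray(sample, dtype=float)
    if arr.size < 3:
        raise InsufficientDataError(
            f"normality gate needs n >= 3, got n={arr.size}"
        )
    if np.ptp(arr) == 0:
        warnings.warn(
            "constant sample: normality test degenerate, using non-parametric branch",
            stacklevel=2,
        )
        return GateResult("nonparametric", float("nan"), degenerate=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns for n>5000; harmless here
        p = float(stats.shapiro(arr).pvalue)
    return GateResult("nonparametric" if p < alpha else "parametric", p)


# ---------------------------------------------------------------------------
# exact Spearman machinery


@lru_cache(maxsize=4)
def _all_permutations(n: int) -> np.ndarray:
    return np.array(list(permutations(range(n))), dtype=np.int64)


@lru_cache(maxsize=8)
def spearman_s_null_counts(n: int) -> np.ndarray:
    """Exact permutation counts of S = sum_i (R_i - i)^2 over all n! rank
    permutations, indexed by S in 0..n(n^2-1)/3.

    Computed by a subset dynamic programme: ranks are assigned to positions
    1..n in order; the state is the set of ranks already used, carrying the
    count vector over partial S.  Counts fit in int64 for n <= 13.
    """
    s_max = n * (n * n - 1) // 3
    size = s_max + 1
    full = 1 << n
    dp: list[np.ndarray | None] = [None] * full
    start = np.zeros(size, dtype=np.int64)
    start[0] = 1
    dp[0] = start
    for mask in range(full - 1):
        cur = dp[mask]
        if cur is None:
            continue
        pos = bin(mask).count("1")  # next 0-based position
        for r in range(n):
            bit = 1 << r
            if mask & bit:
                continue
            d2 = (r - pos) * (r - pos)
            tgt = mask | bit
            if dp[tgt] is None:
                dp[tgt] = np.zeros(size, dtype=np.int64)
            if d2 == 0:
                dp[tgt] += cur
            else:
                dp[tgt][d2:] += cur[: size - d2]
        dp[mask] = None  # free as we go
    counts = dp[full - 1]
    assert counts is not None and counts.sum() == factorial(n)
    return counts


def _rank_r(rx: np.ndarray, ry: np.ndarray) -> float:
    """Pearson correlation of two rank vectors."""
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    if denom == 0:
        raise DegenerateInputError("zero variance in ranks")
    return float((rxc * ryc).sum() / denom)


def _exact_p_from_s(n: int, r_obs: float) -> float:
    counts = spearman_s_null_counts(n)
    s_vals = np.arange(counts.size, dtype=float)
    denom = n * (n * n - 1.0)
    r_null = 1.0 - 6.0 * s_vals / denom
    mask = np.abs(r_null) >= abs(r_obs) - PERM_TOL
    return float(counts[mask].sum()) / factorial(n)


def _enum_p(rx: np.ndarray, ry: np.ndarray, r_obs: float) -> float:
    n = rx.size
    perms = _all_permutations(n)
    ry_perm = ry[perms]  # (n!, n)
    rxc = rx - rx.mean()
    ryc = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum(axis=1))
    r_all = (ryc @ rxc) / denom
    return float(np.mean(np.abs(r_all) >= abs(r_obs) - PERM_TOL))


def _mc_p(
    rx: np.ndarray, ry: np.ndarray, r_obs: float, seed: int, n_mc: int
) -> float:
    rng = np.random.default_rng(seed)
    n = rx.size
    rxc = rx - rx.mean()
    sx = np.sqrt((rxc**2).sum())
    hits = 0
    done = 0
    chunk = 200_000
    while done < n_mc:
        m = min(chunk, n_mc - done)
        block = np.tile(ry, (m, 1))
        block = rng.permuted(block, axis=1)
        bc = block - block.mean(axis=1, keepdims=True)
        r_all = (bc @ rxc) / (sx * np.sqrt((bc**2).sum(axis=1)))
        hits += int(np.sum(np.abs(r_all) >= abs(r_obs) - PERM_TOL))
        done += m
    return (hits + 1) / (n_mc + 1)


def spearman_exact(
    x,
    y,
    name_x: str = "x",
    name_y: str = "y",
    seed: int | None = None,
    n_mc: int = 1_000_000,
) -> CorrelationResult:
    """Spearman rank correlation with a two-sided exact-distribution p.

    Ties receive average ranks.  See the module docstring for how the
    permutation null is evaluated; the Monte-Carlo fallback (tied data with
    n > 9) requires an explicit ``seed``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ParameterError("x and y must be paired samples of equal length")
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"correlation needs n >= 3, got n={n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance in a correlation variable")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r_obs = _rank_r(rx, ry)

    tie_free = np.unique(x).size == n and np.unique(y).size == n
    if n <= ENUM_MAX_N:
        p = _enum_p(rx, ry, r_obs)
        p_method = "exact"
    elif tie_free and n <= DP_MAX_N:
        p = _exact_p_from_s(n, r_obs)
        p_method = "exact"
    else:
        if seed is None:
            raise ParameterError(
                "Monte-Carlo Spearman p requires an explicit seed "
                f"(ties={not tie_free}, n={n})"
            )
        p = _mc_p(rx, ry, r_obs, seed, n_mc)
        p_method = "monte_carlo"
    return CorrelationResult(name_x, name_y, "spearman", r_obs, p, p_method, n)


def pearson_corr(x, y, name_x: str = "x", name_y: str = "y") -> CorrelationResult:
    """Pearson product-moment correlation, two-sided p from the t reference
    distribution."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ParameterError("x and y must be paired samples of equal length")
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"correlation needs n >= 3, got n={n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance in a correlation variable")
    res = stats.pearsonr(x, y)
    return CorrelationResult(
        name_x, name_y, "pearson", float(res.statistic), float(res.pvalue),
        "approximate", n,
    )


def paired_compare(a, b, gate_alpha: float = 0.05) -> PairedComparisonResult:
    """Paired two-sample comparison, gated on the normality of the differences.

    Parametric branch: two-tailed paired t-test.  Non-parametric branch:
    Wilcoxon signed-rank test (exact where scipy supports it).  All-zero
    differences yield the degenerate result p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ParameterError("paired samples must have equal length")
    n = a.size
    d = a - b
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return PairedComparisonResult(
            "wilcoxon_signed_rank", 0.0, 1.0, n, degenerate=True
        )
    gate = normality_gate(d, alpha=gate_alpha)
    if gate.decision == "parametric":
        res = stats.ttest_rel(a, b)
        return PairedComparisonResult(
            "paired_t", float(res.statistic), float(res.pvalue), n
        )
    res = stats.wilcoxon(a, b)
    return PairedComparisonResult(
        "wilcoxon_signed_rank", float(res.statistic), float(res.pvalue), n
    )
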