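"""From-scratch statistical primitives shared by every pipeline stage.

Each routine here is small enough to verify against a closed form or an
exhaustive enumeration, which the test suite does.  Distribution functions
(normal, t, F CDFs) come from :mod:`scipy.stats`; the test statistics,
rankings, tie corrections and multiple-testing adjustments are implemented
directly.  All tests are two-sided.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

__all__ = [
    "TestResult",
    "bh_adjust",
    "holm_sidak_adjust",
    "wilcoxon_ranksum",
    "kendall_tau_b",
    "t_test_unpaired",
    "hypergeom_upper_tail",
    "two_way_anova",
]


@dataclass
class TestResult:
    """Outcome of a hypothesis test.

    ``extra`` carries method-specific values (medians, tau, degrees of
    freedom, ...).  ``p`` is two-sided unless the method label says otherwise.
    """

    method: str
    statistic: float
    p: float
    n: tuple[int, ...]
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or math.isnan(self.p)):
            raise ValueError(f"p-value {self.p} outside [0, 1]")
        if any(k < 1 for k in self.n):
            raise ValueError("sample sizes must be >= 1")


def _check_pvalues(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment.

    Returns adjusted values in the input order, monotone over the sorted
    raw p-values and capped at 1.
    """
    p = _check_pvalues(p_values)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def holm_sidak_adjust(p_values) -> np.ndarray:
    """Holm–Šidák step-down adjustment, returned in input order.

    For sorted p-values p_(1) <= ... <= p_(m), the j-th adjusted value is
    ``max_{i<=j} 1 - (1 - p_(i))^(m - i + 1)``, capped at 1.
    """
    p = _check_pvalues(p_values)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    exponents = m - np.arange(m)  # m, m-1, ..., 1
    sidak = 1.0 - np.power(1.0 - p[order], exponents)
    adjusted = np.minimum(np.maximum.accumulate(sidak), 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def _midranks(values: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties replaced by the mean rank of the tied block."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(values.size, dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < values.size:
        j = i
        while j + 1 < values.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


_EXACT_WILCOXON_MAX_N = 12


def wilcoxon_ranksum(a, b) -> TestResult:
    """Two-sample Wilcoxon rank-sum test (two-sided).

    Midranks handle ties.  For combined sample size <= 12 the permutation
    distribution of the rank sum is enumerated exactly; otherwise a normal
    approximation with tie-corrected variance and continuity correction is
    used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na == 0 or nb == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    n = na + nb
    ranks = _midranks(combined)
    w = float(ranks[:na].sum())
    mean_w = na * (n + 1) / 2.0

    if n <= _EXACT_WILCOXON_MAX_N:
        # exhaustively enumerate rank assignments to group A; the permutation
        # distribution is symmetric about mean_w even under ties
        sums = np.fromiter(
            (sum(c) for c in itertools.combinations(ranks, na)),
            dtype=float,
            count=math.comb(n, na),
        )
        dev = abs(w - mean_w)
        p = float(np.mean(np.abs(sums - mean_w) >= dev - 1e-9))
        method = "wilcoxon_ranksum_exact"
        stat = w
    else:
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        var_w = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
        if var_w <= 0:  # every observation tied
            return TestResult(
                "wilcoxon_ranksum_normal",
                w,
                1.0,
                (na, nb),
                extra={"median_a": float(np.median(a)), "median_b": float(np.median(b))},
            )
        z = (abs(w - mean_w) - 0.5) / math.sqrt(var_w)
        z = max(z, 0.0)
        p = float(min(1.0, 2.0 * _sps.norm.sf(z)))
        method = "wilcoxon_ranksum_normal"
        stat = w
    return TestResult(
        method,
        stat,
        p,
        (na, nb),
        extra={"median_a": float(np.median(a)), "median_b": float(np.median(b))},
    )


def _pair_counts(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Concordant minus discordant counts over all pairs, chunked O(n^2)."""
    n = x.size
    cd = 0.0
    chunk = 512
    for i0 in range(0, n, chunk):
        xs = x[i0 : i0 + chunk, None]
        ys = y[i0 : i0 + chunk, None]
        dx = np.sign(xs - x[None, :])
        dy = np.sign(ys - y[None, :])
        prod = dx * dy
        # each unordered pair appears twice across the full loop except the
        # diagonal (zero contribution); halve at the end
        cd += float(prod.sum())
    return cd / 2.0, float(n)


def kendall_tau_b(x, y) -> TestResult:
    """Kendall's tau-b with tie correction; p by normal approximation.

    tau_b = (C - D) / sqrt((n0 - n1)(n0 - n2)) where n0 = n(n-1)/2 and
    n1, n2 are the tie terms of x and y.  The variance of C - D under the
    null uses the standard tie-corrected expression.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least two observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("tau undefined: a variable is constant")

    c_minus_d, _ = _pair_counts(x, y)
    n0 = n * (n - 1) / 2.0
    _, tx = np.unique(x, return_counts=True)
    _, ty = np.unique(y, return_counts=True)
    n1 = float(np.sum(tx * (tx - 1)) / 2.0)
    n2 = float(np.sum(ty * (ty - 1)) / 2.0)
    tau = c_minus_d / math.sqrt((n0 - n1) * (n0 - n2))

    # tie-corrected null variance of C - D
    v0 = n * (n - 1) * (2 * n + 5)
    vt = float(np.sum(tx * (tx - 1) * (2 * tx + 5)))
    vu = float(np.sum(ty * (ty - 1) * (2 * ty + 5)))
    v1 = float(np.sum(tx * (tx - 1)) * np.sum(ty * (ty - 1))) / (2.0 * n * (n - 1))
    v2 = 0.0
    if n > 2:
        v2 = (
            float(np.sum(tx * (tx - 1) * (tx - 2)) * np.sum(ty * (ty - 1) * (ty - 2)))
            / (9.0 * n * (n - 1) * (n - 2))
        )
    var = (v0 - vt - vu) / 18.0 + v1 + v2
    if var <= 0:
        p = 1.0
        z = 0.0
    else:
        z = c_minus_d / math.sqrt(var)
        p = float(min(1.0, 2.0 * _sps.norm.sf(abs(z))))
    return TestResult(
        "kendall_tau_b",
        tau,
        p,
        (n,),
        extra={"z": z, "concordant_minus_discordant": c_minus_d},
    )


def t_test_unpaired(a, b, *, welch: bool = False) -> TestResult:
    """Unpaired two-sided Student's t-test (pooled variance by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("need at least two observations per group")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if welch:
        se2 = va / na + vb / nb
        if se2 == 0:
            if ma == mb:
                return TestResult("t_welch", 0.0, 1.0, (na, nb), extra={"df": na + nb - 2})
            raise ZeroDivisionError("zero variance with unequal means: t is infinite")
        t = (ma - mb) / math.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        method = "t_welch"
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        if sp2 == 0:
            if ma == mb:
                return TestResult("t_pooled", 0.0, 1.0, (na, nb), extra={"df": na + nb - 2})
            raise ZeroDivisionError("zero variance with unequal means: t is infinite")
        t = (ma - mb) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df = na + nb - 2
        method = "t_pooled"
    p = float(min(1.0, 2.0 * _sps.t.sf(abs(t), df)))
    return TestResult(method, float(t), p, (na, nb), extra={"df": float(df), "mean_a": ma, "mean_b": mb})


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws).

    Summed in log space for numerical stability with genome-scale N.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("require 0 <= K, n <= N")
    if not (0 <= k <= min(K, n)):
        raise ValueError("require 0 <= k <= min(K, n)")
    if k == 0:
        return 1.0

    def log_comb(a: int, b: int) -> float:
        return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)

    denom = log_comb(N, n)
    terms = []
    for j in range(k, min(K, n) + 1):
        if n - j > N - K:
            continue
        terms.append(log_comb(K, j) + log_comb(N - K, n - j) - denom)
    if not terms:
        return 0.0
    mx = max(terms)
    total = mx + math.log(sum(math.exp(t - mx) for t in terms))
    return float(min(1.0, math.exp(total)))


def two_way_anova(values, factor_a, factor_b) -> dict[str, TestResult]:
    """Balanced two-way fixed-effects ANOVA with interaction.

    Returns TestResults keyed ``"A"``, ``"B"`` and ``"A:B"``.  Only balanced
    designs (every cell with the same replicate count r >= 2) are accepted;
    anything else is a hard error rather than a silently different model.
    """
    y = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (y.size == fa.size == fb.size):
        raise ValueError("values and factors must have equal length")
    levels_a = np.unique(fa)
    levels_b = np.unique(fb)
    a, b = levels_a.size, levels_b.size
    if a < 2 or b < 2:
        raise ValueError("each factor needs at least two levels")
    cells = np.empty((a, b), dtype=object)
    r = None
    for i, la in enumerate(levels_a):
        for j, lb in enumerate(levels_b):
            cell = y[(fa == la) & (fb == lb)]
            if r is None:
                r = cell.size
            elif cell.size != r:
                raise ValueError("unbalanced design: cell sizes differ")
            cells[i, j] = cell
    if r is None or r < 2:
        raise ValueError("need >= 2 replicates per cell")

    grand = y.mean()
    cell_means = np.array([[cells[i, j].mean() for j in range(b)] for i in range(a)])
    mean_a = cell_means.mean(axis=1)
    mean_b = cell_means.mean(axis=0)

    ss_a = b * r * float(np.sum((mean_a - grand) ** 2))
    ss_b = a * r * float(np.sum((mean_b - grand) ** 2))
    ss_ab = r * float(
        np.sum((cell_means - mean_a[:, None] - mean_b[None, :] + grand) ** 2)
    )
    ss_e = float(sum(np.sum((cells[i, j] - cell_means[i, j]) ** 2) for i in range(a) for j in range(b)))

    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_e = a * b * (r - 1)
    ms_e = ss_e / df_e
    if ms_e == 0:
        raise ZeroDivisionError("zero residual variance: F undefined")

    out = {}
    for name, ss, df in (("A", ss_a, df_a), ("B", ss_b, df_b), ("A:B", ss_ab, df_ab)):
        f = (ss / df) / ms_e
        p = float(_sps.f.sf(f, df, df_e))
        out[name] = TestResult(
            "two_way_anova",
            float(f),
            p,
            (y.size,),
            extra={"ss": ss, "df": df, "df_error": df_e, "ms_error": ms_e},
        )
    return out
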