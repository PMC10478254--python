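"""Exact and asymptotic tests used across the pipeline.

Mann–Whitney U (exact by enumeration for small untied samples, otherwise a
tie- and continuity-corrected normal approximation) with the rank-biserial
style effect size r = |Z|/√N; Fisher's exact test for 2×2 and small R×C
tables under the minimum-likelihood two-sided rule; the pooled-variance
two-sample Student t; and Benjamini–Hochberg adjustment.

The exact paths are deliberately enumeration-based so they can be checked
against independent brute-force oracles on small instances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class TestResult:
    statistic: float
    p_two_sided: float
    effect_size_r: float | None
    method: str


@dataclass(frozen=True)
class ContingencyTable:
    """Non-negative integer R×C table (R, C ≥ 2, total > 0)."""

    counts: tuple[tuple[int, ...], ...]

    def __post_init__(self):
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("contingency table needs at least 2 rows and 2 columns")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("contingency table entries must be integers")
        if (arr < 0).any():
            raise ValueError("contingency table entries must be non-negative")
        if arr.sum() == 0:
            raise ValueError("contingency table total must be > 0")

    @classmethod
    def from_array(cls, arr) -> "ContingencyTable":
        a = np.asarray(arr)
        if a.ndim != 2:
            raise ValueError("contingency table must be 2-D")
        if not np.all(a == np.floor(a)):
            raise ValueError("contingency table entries must be integers")
        return cls(tuple(tuple(int(x) for x in row) for row in a))

    def to_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=int)


# --------------------------------------------------------------------------
# Mann–Whitney U

#: Largest combined sample size for which the exact null distribution of U
#: is enumerated (untied data only); beyond it, the corrected normal
#: approximation is used.
MWU_EXACT_LIMIT = 12


def _u_null_counts(nx: int, ny: int) -> list[int]:
    """counts[u] = number of equally likely rank assignments with U = u.

    Full enumeration of the C(nx+ny, nx) ways to place the x sample among
    the ranks 1..nx+ny (feasible because the exact path is restricted to
    nx+ny ≤ 12).
    """
    from itertools import combinations

    n = nx + ny
    offset = nx * (nx + 1) // 2
    counts = [0] * (nx * ny + 1)
    for positions in combinations(range(1, n + 1), nx):
        counts[sum(positions) - offset] += 1
    return counts


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann–Whitney U test with effect size r = |Z|/√N.

    U is computed with midranks. The p-value is exact (full enumeration of
    the U null distribution) when n_x + n_y ≤ 12 and there are no ties;
    otherwise a normal approximation with tie correction and a 0.5
    continuity correction is used. The effect size always derives from the
    corrected normal deviate, matching the convention of standard
    statistical packages that report Z alongside exact p-values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    n = nx + ny
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    rx = ranks[:nx].sum()
    u_x = rx - nx * (nx + 1) / 2.0

    # normal approximation machinery (also supplies the effect size)
    mu = nx * ny / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        z = 0.0
    else:
        diff = u_x - mu
        cc = 0.5 if diff != 0 else 0.0
        z = (diff - math.copysign(cc, diff)) / math.sqrt(sigma2)
    r = abs(z) / math.sqrt(n)

    has_ties = np.any(tie_counts > 1)
    if n <= MWU_EXACT_LIMIT and not has_ties:
        counts = _u_null_counts(nx, ny)
        total = math.comb(n, nx)
        u_obs = int(round(u_x))
        p_le = sum(counts[: u_obs + 1]) / total
        p_ge = sum(counts[u_obs:]) / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "mann-whitney-u exact enumeration"
    else:
        p = min(1.0, 2.0 * sps.norm.sf(abs(z))) if sigma2 > 0 else 1.0
        method = "mann-whitney-u normal approximation (tie/continuity corrected)"
    return TestResult(statistic=float(u_x), p_two_sided=float(p),
                      effect_size_r=float(r), method=method)


# --------------------------------------------------------------------------
# Fisher exact tests


def fisher_exact_2x2(table: ContingencyTable) -> TestResult:
    """Two-sided Fisher's exact test on a 2×2 table.

    p = sum of hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed that of the observed table
    (minimum-likelihood rule, the convention of common statistical software).
    """
    arr = table.to_array()
    if arr.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 needs a 2x2 table")
    a, b = arr[0]
    c, d = arr[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    ntot = r1 + r2
    kmin = max(0, c1 - r2)
    kmax = min(c1, r1)
    support = np.arange(kmin, kmax + 1)
    pmf = sps.hypergeom.pmf(support, ntot, r1, c1)
    p_obs = sps.hypergeom.pmf(a, ntot, r1, c1)
    p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    odds = (a * d) / (b * c) if b * c > 0 else math.inf if a * d > 0 else math.nan
    return TestResult(statistic=float(odds), p_two_sided=min(1.0, p),
                      effect_size_r=None, method="fisher exact 2x2 (minimum likelihood)")


def _log_table_prob(arr: np.ndarray, row_sums, col_sums, lg_total: float) -> float:
    """log multivariate hypergeometric probability of a fixed-margin table."""
    lp = (
        sum(math.lgamma(r + 1) for r in row_sums)
        + sum(math.lgamma(c + 1) for c in col_sums)
        - lg_total
        - sum(math.lgamma(int(v) + 1) for v in arr.ravel())
    )
    return lp


def _enumerate_tables(row_sums, col_sums):
    """Yield all non-negative integer tables with the given margins."""
    n_rows = len(row_sums)
    n_cols = len(col_sums)

    def fill(row_idx: int, remaining_cols: tuple[int, ...], rows_acc: list):
        if row_idx == n_rows - 1:
            yield rows_acc + [list(remaining_cols)]
            return
        target = row_sums[row_idx]

        def compositions(j: int, left: int, rem: tuple[int, ...], acc: list):
            if j == n_cols - 1:
                if left <= rem[j]:
                    yield acc + [left]
                return
            hi = min(left, rem[j])
            for v in range(hi + 1):
                yield from compositions(j + 1, left - v, rem, acc + [v])

        for row in compositions(0, target, remaining_cols, []):
            new_rem = tuple(r - v for r, v in zip(remaining_cols, row))
            # feasibility: remaining row sums must be able to absorb columns
            if sum(new_rem) == sum(row_sums[row_idx + 1:]):
                yield from fill(row_idx + 1, new_rem, rows_acc + [row])

    yield from fill(0, tuple(col_sums), [])


def fisher_exact_rxc(table: ContingencyTable, max_total: int = 60) -> TestResult:
    """Exact conditional test on an R×C table by full enumeration.

    Enumerates every table with the observed margins and sums the
    multivariate hypergeometric probabilities of tables no more probable
    than the observed one. Totals above ``max_total`` are refused (the
    enumeration would be too large; use a Monte-Carlo approach instead).
    """
    arr = table.to_array()
    ntot = int(arr.sum())
    if ntot > max_total:
        raise ValueError(
            f"table total {ntot} exceeds exact enumeration bound {max_total}; "
            "increase max_total or use a Monte-Carlo approximation"
        )
    row_sums = arr.sum(axis=1)
    col_sums = arr.sum(axis=0)
    lg_total = math.lgamma(ntot + 1)
    lp_obs = _log_table_prob(arr, row_sums, col_sums, lg_total)
    p = 0.0
    for tab in _enumerate_tables(list(row_sums), list(col_sums)):
        lp = _log_table_prob(np.asarray(tab), row_sums, col_sums, lg_total)
        if lp <= lp_obs + 1e-9:
            p += math.exp(lp)
    return TestResult(statistic=float(math.exp(lp_obs)), p_two_sided=min(1.0, p),
                      effect_size_r=None, method="fisher exact RxC enumeration")


# --------------------------------------------------------------------------
# Student t


def student_t(x, y) -> TestResult:
    """Two-sided pooled-variance two-sample Student t test.

    Degenerate pooled variance: equal means → p = 1 by convention; unequal
    means → p = 0 (the samples separate perfectly).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    nx, ny = x.size, y.size
    df = nx + ny - 2
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
    diff = x.mean() - y.mean()
    if sp2 == 0:
        if diff == 0:
            return TestResult(0.0, 1.0, None, "student-t pooled (zero variance)")
        import warnings

        warnings.warn("zero pooled variance with unequal means: p = 0")
        t = math.inf if diff > 0 else -math.inf
        return TestResult(t, 0.0, None, "student-t pooled (zero variance)")
    t = diff / math.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(min(1.0, p)), None, "student-t pooled")


# --------------------------------------------------------------------------
# multiple testing


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if ((arr < 0) | (arr > 1)).any() or not np.isfinite(arr).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]
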