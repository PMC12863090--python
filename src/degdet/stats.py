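"""Group-comparison statistics for determinant profiles.

Continuous determinants are compared with Wilcoxon rank-sum (unpaired) or
signed-rank (paired original-vs-shuffled) tests; binary determinants with
Fisher's exact test (unpaired) or McNemar's test (paired).  Effect sizes
follow the conventions used in sequence-feature enrichment work:
rank-biserial correlation for rank tests, odds ratios for 2×2 tables,
Cohen's d for mean shifts, and risk ratios for prevalences.  P values are
Benjamini–Hochberg adjusted within each report family.

Rank-biserial convention: the primary estimate is r = 1 − 2U/(n1·n2) where
U is the Mann–Whitney statistic of the first sample, so r = +1 when every
value of ``x`` ranks below every value of ``y``.  A z-based variant
(z/√N, the convention of some R effect-size packages, which differs under
ties) is reported alongside in ``extra``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from scipy.stats.contingency import odds_ratio as _conditional_odds_ratio
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar
from statsmodels.stats.multitest import multipletests

EXACT_SWITCH_RANK_SUM = 50   # total n at or below which the rank-sum test is exact
EXACT_SWITCH_SIGNED_RANK = 25
EXACT_SWITCH_MCNEMAR = 25
EXACT_SWITCH_SPEARMAN = 7


class DegenerateDataError(ValueError):
    """Raised when a test's inputs carry no usable signal (e.g. all ties)."""


@dataclass(frozen=True)
class GroupComparison:
    test: str
    statistic: float
    p_raw: float
    effect_name: str
    effect_value: float
    n1: int
    n2: int = 0
    p_adjusted: Optional[float] = None
    ci: Optional[tuple[float, float, float]] = None  # (low, high, level)
    extra: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows = groups, columns = feature present/absent."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("table must have at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    @classmethod
    def from_flags(cls, x_present: Sequence[bool], y_present: Sequence[bool]
                   ) -> "ContingencyTable2x2":
        xp = int(np.sum(x_present))
        yp = int(np.sum(y_present))
        return cls(xp, len(x_present) - xp, yp, len(y_present) - yp)


def rank_biserial(x: Sequence[float], y: Sequence[float]) -> float:
    """r = 1 − 2U/(n1·n2) with U the Mann–Whitney statistic of ``x``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    u1 = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").statistic
    return float(1.0 - 2.0 * u1 / (len(x) * len(y)))


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) with rank-biserial effect.

    Exact enumeration for small tie-free samples (total n ≤ 50);
    tie-corrected normal approximation with continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("each group needs at least one observation")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        raise DegenerateDataError("all values identical across both groups")
    n1, n2 = len(x), len(y)
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (n1 + n2 <= EXACT_SWITCH_RANK_SUM and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    r = 1.0 - 2.0 * u1 / (n1 * n2)
    # z-based variant (differs under ties); sign matches r
    mu = n1 * n2 / 2.0
    t = np.unique(pooled, return_counts=True)[1]
    tie_term = (t ** 3 - t).sum() / ((n1 + n2) * (n1 + n2 - 1))
    sigma = math.sqrt(n1 * n2 / 12.0 * ((n1 + n2 + 1) - tie_term))
    z = (u1 - mu) / sigma if sigma > 0 else 0.0
    return GroupComparison(
        test="rank_sum", statistic=u1, p_raw=float(res.pvalue),
        effect_name="rank_biserial", effect_value=float(r), n1=n1, n2=n2,
        extra={"method": method, "rank_biserial_z": float(-z / math.sqrt(n1 + n2))},
    )


def _exact_signed_rank_p(abs_ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided sign-flip p: P(|W+ − μ| ≥ |w − μ|), ties allowed.

    Average ranks are doubled to integers and the W+ null distribution is
    built by dynamic programming over the 2^n equally likely sign patterns.
    """
    r2 = np.round(2 * abs_ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    mu = total / 2.0
    dev = abs(round(2 * w_plus) - mu)
    mask = np.abs(np.arange(total + 1) - mu) >= dev - 1e-9
    return float(counts[mask].sum() / counts.sum())


def signed_rank_test(deltas: Sequence[float], pratt: bool = False) -> GroupComparison:
    """Two-sided Wilcoxon signed-rank on paired deltas.

    Zeros are dropped (Pratt handling via ``pratt=True``); exact sign-flip
    enumeration (tie-aware, via dynamic programming) for ≤ 25 nonzero
    deltas, normal approximation with continuity correction otherwise.
    Effect size is the matched-pairs rank-biserial correlation
    (positive-rank share minus negative-rank share).
    """
    d = np.asarray(deltas, dtype=float)
    nonzero = d[d != 0]
    if nonzero.size == 0:
        raise DegenerateDataError("all paired deltas are zero")
    n = nonzero.size
    ranks = sps.rankdata(np.abs(nonzero))
    w_plus = float(ranks[nonzero > 0].sum())
    w_minus = float(ranks[nonzero < 0].sum())
    r = (w_plus - w_minus) / ranks.sum()
    if pratt:
        res = sps.wilcoxon(d, zero_method="pratt", alternative="two-sided",
                           mode="approx", correction=True)
        p, mode = float(res.pvalue), "pratt_approx"
    elif n <= EXACT_SWITCH_SIGNED_RANK:
        p, mode = _exact_signed_rank_p(ranks, w_plus), "exact"
    else:
        res = sps.wilcoxon(nonzero, zero_method="wilcox", alternative="two-sided",
                           mode="approx", correction=True)
        p, mode = float(res.pvalue), "approx"
    return GroupComparison(
        test="signed_rank", statistic=min(w_plus, w_minus), p_raw=p,
        effect_name="matched_rank_biserial", effect_value=float(r),
        n1=int(n), n2=int(n), extra={"mode": mode, "n_zero": int(d.size - n)},
    )


def fisher_exact(table: ContingencyTable2x2) -> GroupComparison:
    """Two-sided Fisher exact test with conditional-MLE and sample odds ratios.

    The conditional MLE odds ratio (with 95% CI) is the primary effect; the
    sample odds ratio ad/bc — Haldane–Anscombe 0.5-corrected when any cell
    is zero — is reported in ``extra``.
    """
    arr = table.as_array()
    _, p = sps.fisher_exact(arr, alternative="two-sided")
    orr = _conditional_odds_ratio(arr)
    ci = orr.confidence_interval(confidence_level=0.95)
    a, b, c, d = (float(v) for v in (table.a, table.b, table.c, table.d))
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    else:
        corrected = False
    sample_or = (a * d) / (b * c)
    return GroupComparison(
        test="fisher_exact", statistic=float(orr.statistic), p_raw=float(p),
        effect_name="odds_ratio", effect_value=float(orr.statistic),
        n1=table.a + table.b, n2=table.c + table.d,
        ci=(float(ci.low), float(ci.high), 0.95),
        extra={"sample_odds_ratio": float(sample_or),
               "haldane_corrected": corrected},
    )


def mcnemar_test(b: int, c: int) -> GroupComparison:
    """McNemar's test on the discordant-pair counts of a paired binary design.

    Exact binomial for b + c ≤ 25, chi-square with continuity correction
    otherwise.  Effect size is the discordant odds ratio b/c
    (0.5-corrected when either count is zero).
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    if b + c == 0:
        raise DegenerateDataError("no discordant pairs")
    exact = (b + c) <= EXACT_SWITCH_MCNEMAR
    res = _sm_mcnemar(np.array([[0, b], [c, 0]]), exact=exact, correction=True)
    bb, cc = (b + 0.5, c + 0.5) if min(b, c) == 0 else (float(b), float(c))
    return GroupComparison(
        test="mcnemar", statistic=float(res.statistic), p_raw=float(res.pvalue),
        effect_name="discordant_odds_ratio", effect_value=float(bb / cc),
        n1=b, n2=c, extra={"exact": exact},
    )


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def proportion_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval with continuity correction for a binomial proportion.

    Matches the behavior of R's ``prop.test`` confidence interval.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    z = sps.norm.ppf(1 - (1 - level) / 2)
    p_hat = successes / n
    z22n = z * z / (2 * n)
    # the correction shrinks to zero as x approaches n/2 (prop.test behavior)
    yates = min(0.5, abs(successes - n * 0.5))

    def _bound(p_c: float, sign: int) -> float:
        rad = math.sqrt(p_c * (1 - p_c) / n + z22n / (2 * n))
        return (p_c + z22n + sign * z * rad) / (1 + 2 * z22n)

    p_c = p_hat + yates / n
    upper = 1.0 if p_c >= 1 else _bound(p_c, +1)
    p_c = p_hat - yates / n
    lower = 0.0 if p_c <= 0 else _bound(p_c, -1)
    return max(0.0, lower), min(1.0, upper)


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> GroupComparison:
    """Spearman rank correlation; exact permutation p for n ≤ 7."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise DegenerateDataError("constant input")
    rho, p = sps.spearmanr(x, y)
    n = len(x)
    if n <= EXACT_SWITCH_SPEARMAN:
        ry = sps.rankdata(y)
        obs = abs(rho)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r_perm = sps.spearmanr(x, ry[list(perm)]).statistic
            if abs(r_perm) >= obs - 1e-12:
                count += 1
            total += 1
        p = count / total
    return GroupComparison(
        test="spearman", statistic=float(rho), p_raw=float(p),
        effect_name="rho", effect_value=float(rho), n1=n, n2=n,
        extra={"exact": n <= EXACT_SWITCH_SPEARMAN},
    )


def poisson_rate_test(count1: int, exposure1: float,
                      count2: int, exposure2: float) -> GroupComparison:
    """Exact conditional comparison of two Poisson rates.

    Conditional on the total count, ``count1`` is binomial with success
    probability exposure1/(exposure1+exposure2) under equal rates; the
    two-sided exact binomial test of that hypothesis is reported with the
    rate ratio and a CI transformed from the binomial proportion CI.
    """
    if exposure1 <= 0 or exposure2 <= 0:
        raise ValueError("exposures must be positive")
    if count1 < 0 or count2 < 0:
        raise ValueError("counts must be non-negative")
    total = count1 + count2
    if total == 0:
        raise DegenerateDataError("both counts are zero")
    p0 = exposure1 / (exposure1 + exposure2)
    res = sps.binomtest(count1, total, p0, alternative="two-sided")
    rate1 = count1 / exposure1
    rate2 = count2 / exposure2
    rr = rate1 / rate2 if rate2 > 0 else math.inf
    ci_pi = res.proportion_ci(confidence_level=0.95, method="exact")

    def pi_to_rr(pi: float) -> float:
        if pi >= 1.0:
            return math.inf
        return (pi / (1 - pi)) * (exposure2 / exposure1)

    return GroupComparison(
        test="poisson_rate", statistic=float(count1), p_raw=float(res.pvalue),
        effect_name="rate_ratio", effect_value=float(rr),
        n1=count1, n2=count2,
        ci=(pi_to_rr(ci_pi.low), pi_to_rr(ci_pi.high), 0.95),
        extra={"rate1": rate1, "rate2": rate2},
    )


def cohens_d(x: Sequence[float], y: Sequence[float]) -> float:
    """Cohen's d with the pooled (n−1-weighted) standard deviation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two observations for d")
    s2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if s2 == 0:
        raise DegenerateDataError("zero pooled standard deviation")
    return float((x.mean() - y.mean()) / math.sqrt(s2))


def ratio_effects(table: ContingencyTable2x2) -> dict[str, float]:
    """Risk ratio and sample odds ratio from a 2×2 prevalence table."""
    n1 = table.a + table.b
    n2 = table.c + table.d
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups need observations")
    risk1 = table.a / n1
    risk2 = table.c / n2
    a, b, c, d = (float(v) for v in (table.a, table.b, table.c, table.d))
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return {
        "risk_ratio": risk1 / risk2 if risk2 > 0 else math.inf,
        "odds_ratio": (a * d) / (b * c),
    }


def effect_sizes(x: Optional[Sequence[float]] = None,
                 y: Optional[Sequence[float]] = None,
                 table: Optional[ContingencyTable2x2] = None) -> dict[str, float]:
    """Bundle of effect sizes for whichever inputs are supplied."""
    out: dict[str, float] = {}
    if x is not None and y is not None:
        out["cohens_d"] = cohens_d(x, y)
        out["rank_biserial"] = rank_biserial(x, y)
    if table is not None:
        out.update(ratio_effects(table))
    if not out:
        raise ValueError("supply (x, y) samples and/or a 2x2 table")
    return out
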