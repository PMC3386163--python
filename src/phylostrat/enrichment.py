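"""Age-enrichment comparisons between two protein sets.

The overall question — is one set of proteins older or younger than
another? — is answered with a two-sided Mann-Whitney U test on the numeric
ages (mya).  Stratum-level questions — is the fraction of proteins
originating at a particular taxon different between the sets? — are
answered with Fisher's exact test on a 2x2 table per age stratum, strata
being the named taxa on the species' leaf-to-root path ordered root ->
leaf.

When one input list is a proper subset of the other (a set versus a more
specific background), the background is first disjointified (background
minus set) so that the 2x2 margins remain valid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .age_assignment import AgeDatabase, ProteinAge, lookup_ages
from .errors import ArgumentError, DegenerateInputError, EmptyInputError
from .family_db import ProteinList

__all__ = [
    "mann_whitney_u",
    "fisher_exact_2x2",
    "StratumResult",
    "EnrichmentResult",
    "compare_age_sets",
    "significance_stars",
]

#: Largest combined sample size for which the exact (enumerative) U-test
#: null distribution is used when there are no ties.
EXACT_U_LIMIT = 12


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns (U, p) where U counts pairs (xi, yj) with xi > yj plus half the
    ties — the U statistic of the first sample, so
    ``U(x, y) + U(y, x) = n1 * n2``.  The p value is exact (full
    enumeration of the rank-assignment null) when n1 + n2 <= 12 and there
    are no ties, otherwise a normal approximation with midrank tie
    correction and a 0.5 continuity correction is used.  With zero
    tie-corrected variance (all observations equal) p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ArgumentError("mann_whitney_u requires two nonempty samples")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0  # pairs with x > y (+ half ties)

    no_ties = np.unique(pooled).size == pooled.size
    if n1 + n2 <= EXACT_U_LIMIT and no_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(u), float(res.pvalue)

    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return float(u), 1.0
    mu = n1 * n2 / 2.0
    diff = u - mu
    # continuity correction shrinks |diff| by 0.5
    z = (diff - math.copysign(min(0.5, abs(diff)), diff)) / math.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return float(u), float(p)


def fisher_exact_2x2(
    table: Sequence[Sequence[float]],
) -> tuple[float, float]:
    """Fisher's exact test for a 2x2 table of nonnegative integer counts.

    Returns (odds ratio, two-sided p).  The odds ratio is the sample value
    a*d / (b*c), with inf when only the denominator is zero and nan when
    both are.  The two-sided p sums the hypergeometric probabilities of all
    tables with the same margins whose probability does not exceed the
    observed one — computed with exact integer arithmetic for totals up to
    500, and in log space with a 1e-12 relative slack on the probability
    comparison above that.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ArgumentError("fisher_exact_2x2 expects a 2x2 table")
    if (t < 0).any():
        raise ArgumentError("fisher_exact_2x2: negative counts")
    if not np.allclose(t, np.round(t)):
        raise ArgumentError("fisher_exact_2x2: counts must be integers")
    a, b, c, d = (int(v) for v in np.round(t).ravel())
    n = a + b + c + d
    if n == 0:
        raise ArgumentError("fisher_exact_2x2: empty table")
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)

    r1, c1 = a + b, a + c
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    if lo == hi:  # a degenerate margin admits only one table
        return odds, 1.0
    support = range(lo, hi + 1)
    if n <= 500:
        # unnormalized weights C(r1, k) * C(n - r1, c1 - k), exact integers
        w = {k: math.comb(r1, k) * math.comb(n - r1, c1 - k) for k in support}
        total = sum(w.values())
        p = sum(v for v in w.values() if v <= w[a]) / total
    else:
        lg = [
            math.lgamma(r1 + 1)
            - math.lgamma(k + 1)
            - math.lgamma(r1 - k + 1)
            + math.lgamma(n - r1 + 1)
            - math.lgamma(c1 - k + 1)
            - math.lgamma(n - r1 - c1 + k + 1)
            for k in support
        ]
        lw = np.array(lg)
        lw -= lw.max()
        weights = np.exp(lw)
        obs = weights[a - lo]
        p = float(weights[weights <= obs * (1.0 + 1e-12)].sum() / weights.sum())
    return odds, min(1.0, float(p))


def significance_stars(p: float) -> str:
    """Reporting convention: *, **, *** at 0.05, 0.01, 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class StratumResult:
    """Per-age-stratum 2x2 comparison."""

    taxon: str
    age_mya: float
    count1: int
    count2: int
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    q_value: Optional[float] = None


@dataclass
class EnrichmentResult:
    """Result of comparing two protein sets' age distributions."""

    species: str
    n1: int
    n2: int
    u_statistic: float
    u_p_value: float
    mean_age1: float
    mean_age2: float
    strata: list[StratumResult] = field(default_factory=list)
    missing1: list[str] = field(default_factory=list)
    missing2: list[str] = field(default_factory=list)
    disjointified: bool = False


def _stratum_order(db: AgeDatabase, ages: list[ProteinAge]) -> list[tuple[str, float]]:
    """Observed origin taxa ordered oldest (root) to youngest (leaf)."""
    seen: dict[str, float] = {}
    for a in ages:
        seen.setdefault(a.origin_taxon, a.age_mya)
    return sorted(seen.items(), key=lambda kv: (-kv[1], kv[0]))


def compare_age_sets(
    set1: ProteinList,
    set2: Optional[ProteinList],
    db: AgeDatabase,
    bh: bool = False,
) -> EnrichmentResult:
    """Compare the age distributions of two protein sets.

    ``set2 = None`` means "the whole proteome" (every protein in the age
    database).  If set1 is a subset of set2 after ID resolution, set2 is
    replaced by set2 minus set1 so the two samples are disjoint; identical
    sets therefore raise :class:`DegenerateInputError` (empty background).
    ``bh`` adds Benjamini-Hochberg adjusted q values across strata.
    """
    ages1, missing1 = lookup_ages(db, set1)
    if set2 is None:
        ages2 = sorted(db.ages.values(), key=lambda a: a.protein)
        missing2: list[str] = []
    else:
        ages2, missing2 = lookup_ages(db, set2)
    if not ages1 or not ages2:
        raise EmptyInputError("a protein set resolved to zero aged proteins")

    ids1 = {a.protein for a in ages1}
    ids2 = {a.protein for a in ages2}
    disjointified = False
    if ids1 <= ids2:
        ages2 = [a for a in ages2 if a.protein not in ids1]
        disjointified = True
        if not ages2:
            raise DegenerateInputError(
                "background is empty after removing the query set"
            )

    mya1 = [a.age_mya for a in ages1]
    mya2 = [a.age_mya for a in ages2]
    u, p = mann_whitney_u(mya1, mya2)

    result = EnrichmentResult(
        species=db.species,
        n1=len(ages1),
        n2=len(ages2),
        u_statistic=u,
        u_p_value=p,
        mean_age1=float(np.mean(mya1)),
        mean_age2=float(np.mean(mya2)),
        missing1=missing1,
        missing2=missing2,
        disjointified=disjointified,
    )

    counts1: dict[str, int] = {}
    counts2: dict[str, int] = {}
    for a in ages1:
        counts1[a.origin_taxon] = counts1.get(a.origin_taxon, 0) + 1
    for a in ages2:
        counts2[a.origin_taxon] = counts2.get(a.origin_taxon, 0) + 1

    for taxon, age in _stratum_order(db, ages1 + ages2):
        a_ = counts1.get(taxon, 0)
        b_ = len(ages1) - a_
        c_ = counts2.get(taxon, 0)
        d_ = len(ages2) - c_
        odds, fp = fisher_exact_2x2([[a_, b_], [c_, d_]])
        result.strata.append(
            StratumResult(
                taxon=taxon,
                age_mya=age,
                count1=a_,
                count2=c_,
                table=((a_, b_), (c_, d_)),
                odds_ratio=odds,
                p_value=fp,
            )
        )

    if bh and result.strata:
        pvals = np.array([s.p_value for s in result.strata])
        qvals = stats.false_discovery_control(pvals, method="bh")
        for s, q in zip(result.strata, qvals):
            s.q_value = float(q)
    return result
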