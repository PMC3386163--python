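"""Correlating protein age with quantitative protein features.

Given per-protein ages (mya) and a single numeric feature (length,
expression, evolutionary rate, ...), this module computes Spearman's rank
correlation between age and feature, per-age-stratum box-plot summaries,
and an ordinary least-squares trend of feature against age (in feature
units per million years), optionally excluding the most ancient strata
where age resolution is poorest.
"""

from __future__ import annotations

import io
import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import ArgumentError, DegenerateInputError, EmptyInputError, FormatError

__all__ = [
    "FeatureTable",
    "read_feature_table",
    "spearman_correlation",
    "tukey_hinges",
    "per_age_summary",
    "StratumSummary",
    "linear_trend",
]

#: Largest n for which the exact permutation null of Spearman's rho is
#: enumerated; above this the t approximation is used.
EXACT_SPEARMAN_LIMIT = 10


@dataclass
class FeatureTable:
    """One numeric feature per protein."""

    values: dict[str, float]
    name: str = "feature"
    units: str = ""

    def __len__(self) -> int:
        return len(self.values)


def read_feature_table(
    source: str | io.TextIOBase, name: str = "feature", units: str = ""
) -> FeatureTable:
    """Read a 2-column (protein ID, value) tab-delimited table.

    An optional single header row (non-numeric second field) is skipped;
    '#' comments ignored; duplicate IDs and non-finite values rejected.
    """
    if isinstance(source, str):
        lines = open(source).readlines()
    else:
        lines = list(source)
    values: dict[str, float] = {}
    first_data = True
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(
                f"feature table line {lineno}: expected 2 tab-separated columns"
            )
        pid, val_s = parts[0].strip(), parts[1].strip()
        try:
            val = float(val_s)
        except ValueError:
            if first_data:  # header row
                first_data = False
                continue
            raise FormatError(
                f"feature table line {lineno}: non-numeric value {val_s!r}"
            ) from None
        first_data = False
        if not math.isfinite(val):
            raise FormatError(f"feature table line {lineno}: non-finite value")
        if pid in values:
            raise FormatError(f"feature table: duplicate protein ID {pid!r}")
        values[pid] = val
    if not values:
        raise EmptyInputError("feature table is empty")
    return FeatureTable(values=values, name=name, units=units)


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided permutation p for Spearman's rho at small n.

    Enumerates all n! orderings of one rank vector; ties are handled
    because midranks are permuted as values.
    """
    n = rx.size
    cx = rx - rx.mean()
    denom = math.sqrt(float((cx**2).sum()) * float(((ry - ry.mean()) ** 2).sum()))
    # |rho| comparisons reduce to |dot(cx, perm(ry))| comparisons
    obs = abs(rho_obs) * denom
    count = 0
    total = 0
    chunk: list[tuple[float, ...]] = []
    perms = itertools.permutations(ry.tolist())
    while True:
        chunk = list(itertools.islice(perms, 40320))
        if not chunk:
            break
        arr = np.array(chunk)
        dots = np.abs((arr - ry.mean()) @ cx)
        count += int((dots >= obs - 1e-9).sum())
        total += arr.shape[0]
    return count / total


def spearman_correlation(
    pairs: Sequence[tuple[float, float]],
) -> tuple[float, float]:
    """Spearman's rank correlation between ages and feature values.

    rho is the Pearson correlation of midranks.  The two-sided p value is
    an exact permutation enumeration for n <= 10 and the usual
    t-distribution approximation (df = n - 2) otherwise.  Constant input in
    either variable raises :class:`DegenerateInputError`.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ArgumentError("spearman_correlation expects (age, feature) pairs")
    n = arr.shape[0]
    if n < 3:
        raise ArgumentError("spearman_correlation requires at least 3 pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateInputError("constant ages or features; rho undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n <= EXACT_SPEARMAN_LIMIT:
        p = _exact_spearman_p(rx, ry, rho)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


def tukey_hinges(values: Sequence[float]) -> tuple[float, float, float]:
    """(Q1, median, Q3) by the median-of-halves convention.

    With an odd number of observations the median is included in both
    halves (classic Tukey hinges, as drawn by traditional box plots).
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        raise ArgumentError("tukey_hinges on empty data")
    med = float(np.median(v))
    if n == 1:
        return med, med, med
    half = (n + 1) // 2  # include median in both halves when n is odd
    lower = v[:half]
    upper = v[n - half:]
    return float(np.median(lower)), med, float(np.median(upper))


@dataclass
class StratumSummary:
    """Box-plot style numeric summary of a feature within one age stratum."""

    taxon: str
    age_mya: float
    n: int
    mean: float
    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float


def per_age_summary(
    groups: Mapping[str, Sequence[float]],
    stratum_ages: Mapping[str, float],
) -> list[StratumSummary]:
    """Summarize a feature within each age stratum (origin taxon).

    Quartiles follow :func:`tukey_hinges`; whiskers are the extreme
    observed values within [Q1 - 1.5 IQR, Q3 + 1.5 IQR].  Strata are
    returned ordered oldest -> youngest.
    """
    out = []
    for taxon, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if v.size == 0:
            continue
        q1, med, q3 = tukey_hinges(v)
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = v[(v >= lo_fence) & (v <= hi_fence)]
        out.append(
            StratumSummary(
                taxon=taxon,
                age_mya=float(stratum_ages[taxon]),
                n=int(v.size),
                mean=float(v.mean()),
                q1=q1,
                median=med,
                q3=q3,
                whisker_low=float(inside.min()),
                whisker_high=float(inside.max()),
            )
        )
    out.sort(key=lambda s: (-s.age_mya, s.taxon))
    return out


def linear_trend(
    records: Iterable[tuple[str, float, float]],
    exclude_strata: Optional[Iterable[str]] = None,
) -> tuple[float, float]:
    """OLS fit of feature against age: returns (slope per mya, intercept).

    ``records`` are (origin taxon, age_mya, feature value) triples;
    ``exclude_strata`` names taxa to drop before fitting — typically the
    most ancient groups, whose age resolution is poorest.
    """
    excl = set(exclude_strata or ())
    kept = [(age, val) for taxon, age, val in records if taxon not in excl]
    if len(kept) < 2:
        raise DegenerateInputError("fewer than 2 points after stratum exclusion")
    ages = np.array([a for a, _ in kept])
    vals = np.array([v for _, v in kept])
    if np.all(ages == ages[0]):
        raise DegenerateInputError("all ages identical after stratum exclusion")
    res = stats.linregress(ages, vals)
    return float(res.slope), float(res.intercept)
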