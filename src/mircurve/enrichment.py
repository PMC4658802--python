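"""Seed-match pattern enrichment.

Every positive interaction contributes one alignment pattern **a** (codes
1 match / 2 mismatch / 3 gap / 4 G:U over guide nt 1-8, bulges included).
For a pattern seen k times among n positives, the chance probability of a
specific length-|a| target sequence is 0.25^|a|, so

    alpha      = Binomial(k | n, 0.25^|a|)        (probability mass at k)
    enrichment = 1 - alpha

computed in log space so large n is exact to machine precision.  A config
switch replaces the probability mass with the upper tail P(X >= k), the
statistically conventional reading; the mass form is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import exp, expm1, fsum, lgamma, log, log1p

import numpy as np


def _log_binom_coef(n: int, k: int) -> float:
    """log C(n, k); exact log summation up to n ~ 10^5, lgamma beyond."""
    m = min(k, n - k)
    if n <= 100_000:
        return fsum(log(n - m + j) - log(j) for j in range(1, m + 1))
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def log_binom_pmf(k: int, n: int, p: float) -> float:
    """log Binomial(k | n, p), exact in log space."""
    if not 0 <= k <= n:
        return -np.inf
    if p <= 0.0:
        return 0.0 if k == 0 else -np.inf
    if p >= 1.0:
        return 0.0 if k == n else -np.inf
    return _log_binom_coef(n, k) + k * log(p) + (n - k) * log1p(-p)


def binom_pmf(k: int, n: int, p: float) -> float:
    return exp(log_binom_pmf(k, n, p))


def binom_sf_inclusive(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), summed in log space."""
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    logs = [log_binom_pmf(j, n, p) for j in range(k, n + 1)]
    m = max(logs)
    return exp(m) * sum(exp(v - m) for v in logs)


def pattern_chance_probability(pattern) -> float:
    """Chance probability 0.25^|a| of one specific length-|a| target word."""
    return 0.25 ** len(pattern)


@dataclass
class PatternTable:
    """Occurrence counts and enrichment scores of seed-match patterns."""

    counts: dict[tuple, int] = field(default_factory=dict)
    n: int = 0
    scores: dict[tuple, float] = field(default_factory=dict)
    tail: bool = False

    def relative_frequencies(self, universe=None) -> dict[tuple, float]:
        keys = universe if universe is not None else self.counts.keys()
        if self.n == 0:
            return {k: 0.0 for k in keys}
        return {k: self.counts.get(k, 0) / self.n for k in keys}


def pattern_enrichment(k: int, n: int, pattern, tail: bool = False) -> float:
    """Enrichment score 1 - alpha for a pattern with k of n occurrences."""
    p = pattern_chance_probability(pattern)
    if tail:
        alpha = binom_sf_inclusive(k, n, p)
    else:
        if k == 0:
            # 1 - (1-p)^n, computed without cancellation
            return -expm1(n * log1p(-p))
        alpha = binom_pmf(k, n, p)
    return min(1.0, max(0.0, 1.0 - alpha))


def build_pattern_table(positive_sites, tail: bool = False) -> PatternTable:
    """Count patterns over positive sites and score each one.

    ``positive_sites`` is an iterable of sites carrying ``.pattern`` (or of
    raw pattern tuples).  Each positive contributes exactly one pattern, so
    counts sum to n.  The build is order-invariant.
    """
    counts: dict[tuple, int] = {}
    for item in positive_sites:
        pat = tuple(item.pattern if hasattr(item, "pattern") else item)
        counts[pat] = counts.get(pat, 0) + 1
    n = sum(counts.values())
    scores = {pat: pattern_enrichment(k, n, pat, tail=tail)
              for pat, k in counts.items()}
    return PatternTable(counts=counts, n=n, scores=scores, tail=tail)


def enrichment_of(site_or_pattern, table: PatternTable) -> float:
    """Exact-pattern lookup; unseen patterns score 0."""
    pat = tuple(site_or_pattern.pattern if hasattr(site_or_pattern, "pattern")
                else site_or_pattern)
    return table.scores.get(pat, 0.0)


def cross_species_pattern_correlation(table_a: PatternTable,
                                      table_b: PatternTable) -> float:
    """Pearson correlation of pattern relative frequencies across two tables.

    The pattern universe is the union of both tables (missing -> frequency
    0).  Returns NaN when fewer than two shared universe patterns exist or a
    table is degenerate (zero variance).
    """
    universe = sorted(set(table_a.counts) | set(table_b.counts))
    if len(universe) < 2:
        return float("nan")
    fa = np.array([table_a.relative_frequencies(universe)[p] for p in universe])
    fb = np.array([table_b.relative_frequencies(universe)[p] for p in universe])
    if fa.std() == 0.0 or fb.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(fa, fb)[0, 1])


# TSV round-trip -------------------------------------------------------------

def write_pattern_table(table: PatternTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("pattern\tk\tn\tenrichment\n")
        for pat in sorted(table.counts):
            fh.write("-".join(map(str, pat)) + f"\t{table.counts[pat]}\t"
                     f"{table.n}\t{table.scores[pat]:.12g}\n")


def read_pattern_table(path) -> PatternTable:
    counts, scores, n = {}, {}, 0
    with open(path) as fh:
        next(fh)
        for line in fh:
            pat_s, k, n_s, score = line.rstrip("\n").split("\t")
            pat = tuple(int(x) for x in pat_s.split("-"))
            counts[pat] = int(k)
            scores[pat] = float(score)
            n = int(n_s)
    return PatternTable(counts=counts, n=n, scores=scores)
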