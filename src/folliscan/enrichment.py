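"""Hypergeometric gene-set enrichment and target/DE-mRNA overlap reports.

The enrichment statistic is the upper-tail hypergeometric probability

    P = 1 - sum_{i=0}^{m-1} C(M, i) * C(N - M, n - i) / C(N, n)

with N the annotated universe size, n the query genes in the universe,
M the genes annotated to the term, and m the query genes annotated to the
term.  Terms are flagged significant at raw P < 0.05 (the study's printed
rule); BH-adjusted values are reported alongside as standard practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Set

import numpy as np
from scipy.special import gammaln

from .core import FolliscanError
from .expression import benjamini_hochberg

#: printed significance rule for enrichment (raw P)
ENRICH_P = 0.05


def _log_comb(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_upper(N: int, M: int, n: int, m: int) -> float:
    """P(X >= m) for X ~ Hypergeometric(N, M, n), computed in log space.

    Evaluates 1 - sum_{i < m} pmf(i); out-of-support i contribute nothing.
    Bounds are validated: 0 <= M <= N, 0 <= n <= N, 0 <= m <= min(n, M).
    """
    if not (0 <= M <= N and 0 <= n <= N and 0 <= m <= min(n, M)):
        raise FolliscanError(
            f"hypergeometric bounds violated: N={N}, M={M}, n={n}, m={m}"
        )
    if m == 0:
        return 1.0
    i = np.arange(0, m)
    # support: 0 <= i <= M and 0 <= n - i <= N - M
    ok = (i <= M) & (n - i >= 0) & (n - i <= N - M)
    i = i[ok]
    if i.size == 0:
        return 1.0
    log_pmf = (
        _log_comb(np.full_like(i, M, dtype=float), i.astype(float))
        + _log_comb(np.full_like(i, N - M, dtype=float), (n - i).astype(float))
        - _log_comb(float(N), float(n))
    )
    lower = np.exp(log_pmf).sum()
    return float(min(1.0, max(0.0, 1.0 - lower)))


@dataclass
class EnrichmentResult:
    """One term's enrichment statistics."""

    term: str
    N: int  # annotated universe size
    n: int  # query genes in the universe
    M: int  # genes annotated to the term (within the universe)
    m: int  # query genes annotated to the term
    P: float
    padj: float = float("nan")

    def __post_init__(self) -> None:
        if not (0 <= self.m <= min(self.n, self.M)):
            raise FolliscanError(f"{self.term}: m out of bounds")
        if not (0.0 <= self.P <= 1.0):
            raise FolliscanError(f"{self.term}: P out of [0, 1]")

    @property
    def significant(self) -> bool:
        return self.P < ENRICH_P


def enrich(
    query: Iterable[str],
    terms: Mapping[str, Set[str]],
    universe: Iterable[str],
) -> List[EnrichmentResult]:
    """Hypergeometric enrichment of a query gene set against a term map.

    Gene symbols are uppercased before matching.  The universe defaults to
    whatever annotated gene list the caller supplies; the query is
    intersected with it.  Results are sorted by (P, term id); BH adjustment
    runs across all terms.
    """
    universe_set = {g.upper() for g in universe}
    if not universe_set:
        raise FolliscanError("empty universe")
    query_set = {g.upper() for g in query} & universe_set

    N = len(universe_set)
    n = len(query_set)
    results: List[EnrichmentResult] = []
    for term in sorted(terms):
        term_genes = {g.upper() for g in terms[term]} & universe_set
        M = len(term_genes)
        m = len(query_set & term_genes)
        P = hypergeom_upper(N, M, n, m)
        results.append(EnrichmentResult(term=term, N=N, n=n, M=M, m=m, P=P))
    if results:
        padj = benjamini_hochberg([r.P for r in results])
        for r, q in zip(results, padj):
            r.padj = float(q)
    results.sort(key=lambda r: (r.P, r.term))
    return results


@dataclass
class OverlapReport:
    """Intersection of a lncRNA-target gene set with a DE-mRNA gene set."""

    category: str
    lnc_targets: FrozenSet[str]
    de_mrnas: FrozenSet[str]
    intersection: FrozenSet[str]

    @property
    def size(self) -> int:
        return len(self.intersection)


def overlap_analysis(
    lnc_target_sets: Mapping[str, Iterable[str]],
    de_mrna_sets: Mapping[str, Iterable[str]],
) -> List[OverlapReport]:
    """Per-category intersection of predicted lncRNA targets with DE mRNAs.

    Category keys must match between the two maps; gene symbols are
    uppercased (hyphens preserved) before intersecting.
    """
    unknown = set(lnc_target_sets) ^ set(de_mrna_sets)
    if unknown:
        raise FolliscanError(f"category keys do not match: {sorted(unknown)}")
    reports = []
    for category in lnc_target_sets:
        targets = frozenset(g.upper() for g in lnc_target_sets[category])
        mrnas = frozenset(g.upper() for g in de_mrna_sets[category])
        reports.append(
            OverlapReport(
                category=category,
                lnc_targets=targets,
                de_mrnas=mrnas,
                intersection=targets & mrnas,
            )
        )
    return reports
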