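"""Independent brute-force oracles used to validate the implementation.

Everything here is written deliberately naively (per-base sets, exhaustive
pair enumeration, quadratic dynamic programming, full probability sums) and
shares no code path with the package internals it checks.
"""

from __future__ import annotations

from itertools import combinations
from math import comb
from typing import Dict, List, Optional, Sequence, Set, Tuple

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
STOPS = {"TAA", "TAG", "TGA"}


def naive_extract(exons: Sequence[Tuple[int, int]], strand: str, chrom_seq: str) -> str:
    """Per-base transcript construction."""
    bases: List[str] = []
    for s, e in sorted(exons):
        for p in range(s, e):
            bases.append(chrom_seq[p])
    if strand == "-":
        bases = [COMPLEMENT[b] for b in reversed(bases)]
    return "".join(bases)


def orf_bruteforce(seq: str) -> int:
    """Longest complete ORF length by enumerating all (start, stop) pairs."""
    seq = seq.upper()
    best = 0
    n = len(seq)
    for i in range(n - 2):
        if seq[i : i + 3] != "ATG":
            continue
        for j in range(i + 3, n - 2, 3):
            codon = seq[j : j + 3]
            if codon in STOPS:
                best = max(best, j + 3 - i)
                break
    return best


# ---------------------------------------------------------------------------
# per-base genomic classification oracles
# ---------------------------------------------------------------------------

Tx = Tuple[str, str, List[Tuple[int, int]]]  # (id_or_gene, strand, exons)


def _exon_bases(exons: Sequence[Tuple[int, int]]) -> Set[int]:
    out: Set[int] = set()
    for s, e in exons:
        out.update(range(s, e))
    return out


def _intron_intervals(exons: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    exons = sorted(exons)
    return [(a[1], b[0]) for a, b in zip(exons, exons[1:]) if b[0] > a[1]]


def classcode_per_base(
    t_strand: str, t_exons: List[Tuple[int, int]], refs: List[Tx]
) -> str:
    """Class code via per-base sets, applying = > x > i > o > u."""
    t_bases = _exon_bases(t_exons)
    t_span = set(range(min(s for s, _ in t_exons), max(e for _, e in t_exons)))
    t_introns = tuple(sorted(_intron_intervals(t_exons)))

    same = [r for r in refs if r[1] == t_strand]
    anti = [r for r in refs if r[1] != t_strand]

    for _, _, r_exons in same:
        r_introns = tuple(sorted(_intron_intervals(r_exons)))
        if len(t_exons) > 1 and len(r_exons) > 1 and t_introns == r_introns:
            return "="
        if (
            len(t_exons) == 1
            and len(r_exons) == 1
            and sorted(t_exons) == sorted(r_exons)
        ):
            return "="
    for _, _, r_exons in anti:
        if t_bases & _exon_bases(r_exons):
            return "x"
    for _, _, r_exons in same:
        for s, e in _intron_intervals(r_exons):
            if t_span <= set(range(s, e)):
                return "i"
    for _, _, r_exons in same:
        if t_bases & _exon_bases(r_exons):
            return "o"
    return "u"


def context_per_base(
    t_strand: str,
    t_exons: List[Tuple[int, int]],
    coding: List[Tx],
    max_bidirectional: int = 1000,
) -> str:
    """Six-way genomic context via per-base sets, exonic > intronic >
    bidirectional > intergenic, sense before antisense."""
    t_bases = _exon_bases(t_exons)
    t_start = min(s for s, _ in t_exons)
    t_end = max(e for _, e in t_exons)
    t_span = set(range(t_start, t_end))

    for want_same, name in ((True, "exonic_sense"), (False, "exonic_antisense")):
        for _, strand, exons in coding:
            if (strand == t_strand) == want_same and t_bases & _exon_bases(exons):
                return name
    for want_same, name in ((True, "intronic_sense"), (False, "intronic_antisense")):
        for _, strand, exons in coding:
            if (strand == t_strand) != want_same:
                continue
            for s, e in _intron_intervals(exons):
                if t_span <= set(range(s, e)):
                    return name
    for _, strand, exons in coding:
        if strand == t_strand:
            continue
        g_start = min(s for s, _ in exons)
        g_end = max(e for _, e in exons)
        if t_strand == "+" and strand == "-" and g_end <= t_start:
            d = t_start - (g_end - 1)
        elif t_strand == "-" and strand == "+" and t_end <= g_start:
            d = g_start - (t_end - 1)
        else:
            continue
        if d < max_bidirectional:
            return "bidirectional"
    return "intergenic"


def cis_bruteforce(
    lncs: Dict[str, Tuple[str, int, int]],
    genes: Dict[str, Tuple[str, int, int]],
    window: int = 10_000,
) -> Set[Tuple[str, str, int]]:
    """All-pairs distance scan over (chrom, start, end) spans."""
    out = set()
    for lid, (lc, ls, le) in lncs.items():
        for gid, (gc, gs, ge) in genes.items():
            if lc != gc:
                continue
            gap = max(0, max(ls, gs) - min(le, ge))
            if gap <= window:
                out.add((lid, gid, gap))
    return out


# ---------------------------------------------------------------------------
# alignment and statistics oracles
# ---------------------------------------------------------------------------

def sw_gotoh(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -2.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> float:
    """Textbook Smith–Waterman with affine gaps (Gotoh three-matrix DP).

    A gap of length L scores gap_open + gap_extend * (L - 1).  N matches
    nothing.
    """
    NEG = float("-inf")
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def hypergeom_enum(N: int, M: int, n: int, m: int) -> float:
    """P(X >= m) by exact combinatorial counting."""
    total = comb(N, n)
    count = 0
    for i in range(m, min(n, M) + 1):
        count += comb(M, i) * comb(N - M, n - i)
    return count / total


def hypergeom_draws(N: int, M: int, n: int, m: int) -> float:
    """P(X >= m) by literally enumerating every draw of size n (tiny N)."""
    marked = set(range(M))
    hits = 0
    total = 0
    for draw in combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= m:
            hits += 1
    return hits / total if total else 1.0


def fpkm_two_loops(counts, lengths) -> List[List[float]]:
    """Two-loop FPKM: counts is a list of rows, lengths per row."""
    n_samples = len(counts[0])
    totals = [sum(row[j] for row in counts) for j in range(n_samples)]
    out = []
    for row, length in zip(counts, lengths):
        out.append(
            [row[j] / ((length / 1e3) * (totals[j] / 1e6)) for j in range(n_samples)]
        )
    return out


def bh_formula(p: Sequence[float]) -> List[float]:
    """BH by the printed step-up formula on the sorted vector."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, min(1.0, p[i] * m / rank))
        adj[i] = running
    return adj


def venn_powerset(sets: List[Set[str]]) -> Dict[Tuple[bool, ...], int]:
    """Region cardinalities by brute-force membership of each element."""
    regions: Dict[Tuple[bool, ...], int] = {}
    universe = set().union(*sets) if sets else set()
    for x in sorted(universe):
        key = tuple(x in s for s in sets)
        regions[key] = regions.get(key, 0) + 1
    return regions
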