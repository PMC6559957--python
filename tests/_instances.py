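"""Random small problem instances for oracle-equivalence checks."""

from __future__ import annotations

from typing import List, Tuple

import numpy as np

from folliscan.core import (
    BIOTYPE_PROTEIN_CODING,
    AnnotationSet,
    GenomicInterval,
    TranscriptModel,
)

GENOME_LEN = 3000


def random_exons(
    rng: np.random.Generator, max_exons: int = 4, genome_len: int = GENOME_LEN
) -> List[Tuple[int, int]]:
    n = int(rng.integers(1, max_exons + 1))
    cut = max(1, genome_len - 1)
    pos = sorted(int(p) for p in rng.integers(0, cut, size=2 * n))
    exons = []
    for i in range(n):
        s, e = pos[2 * i], pos[2 * i + 1]
        if e <= s:
            e = s + 1
        if exons and s <= exons[-1][1]:
            s = exons[-1][1] + 1
            e = max(e, s + 1)
        if e > genome_len:
            break
        exons.append((s, e))
    if not exons:
        exons = [(0, int(rng.integers(1, 50)))]
    return exons


def random_transcript(
    rng: np.random.Generator, tid: str, biotype: str = "unknown"
) -> TranscriptModel:
    strand = "+" if rng.random() < 0.5 else "-"
    exons = random_exons(rng)
    return TranscriptModel(
        transcript_id=tid,
        gene_id=f"gene_{tid}",
        exons=[GenomicInterval("chr1", s, e, strand) for s, e in exons],
        biotype=biotype,
    )


def random_reference(rng: np.random.Generator, n: int = 5) -> AnnotationSet:
    return AnnotationSet(
        random_transcript(rng, f"ref{i}", biotype=BIOTYPE_PROTEIN_CODING)
        for i in range(n)
    )


def as_tuples(ann: AnnotationSet):
    """(id, strand, exon pairs) view consumed by the per-base oracles."""
    return [
        (t.transcript_id, t.strand, [(e.start, e.end) for e in t.exons])
        for t in ann
    ]
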