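"""Core domain types shared by every stage of the pipeline.

Coordinates are 0-based half-open internally; GTF/GFF on disk is 1-based
inclusive (conversion happens in :mod:`folliscan.io`).  Strand is always one
of ``+``/``-``: unstranded transcript models are rejected at parse time
because every downstream classification rule is strand-aware.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

STRANDS = ("+", "-")

#: transcript biotype buckets used by the identification cascade
BIOTYPE_PROTEIN_CODING = "protein_coding"
BIOTYPE_KNOWN_LNCRNA = "known_lncRNA_db_class"
BIOTYPE_OTHER_NCRNA = "other_ncRNA"
BIOTYPE_UNKNOWN = "unknown"

#: raw annotation biotype strings folded into the other_ncRNA exclusion bucket
OTHER_NCRNA_BIOTYPES = frozenset(
    {"rRNA", "tRNA", "snRNA", "snoRNA", "pre_miRNA", "pre-miRNA", "miRNA",
     "pseudogene", "processed_pseudogene"}
)


class FolliscanError(Exception):
    """Base class for all package errors."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FolliscanError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise FolliscanError(
                f"invalid strand {self.strand!r} on {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> Optional[int]:
        """Distance in bp between two spans on the same chromosome.

        0 when they overlap or abut; ``None`` on different chromosomes.
        """
        if self.chrom != other.chrom:
            return None
        return max(0, max(self.start, other.start) - min(self.end, other.end))


@dataclass
class TranscriptModel:
    """An exon chain plus identity and biotype.

    Exons are kept sorted by start, non-overlapping, and all on one
    chromosome/strand (enforced at construction).
    """

    transcript_id: str
    gene_id: str
    exons: List[GenomicInterval]
    biotype: str = BIOTYPE_UNKNOWN

    def __post_init__(self) -> None:
        if not self.exons:
            raise FolliscanError(f"{self.transcript_id}: transcript has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise FolliscanError(
                f"{self.transcript_id}: exons on mixed chromosomes/strands"
            )
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise FolliscanError(f"{self.transcript_id}: overlapping exons")

    # -- geometry ---------------------------------------------------------
    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def tss(self) -> int:
        """Transcription start site position (0-based)."""
        return self.start if self.strand == "+" else self.end - 1

    def introns(self) -> List[GenomicInterval]:
        return [
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
            if b.start > a.end
        ]

    def intron_chain(self) -> Tuple[Tuple[int, int], ...]:
        return tuple((i.start, i.end) for i in self.introns())


class AnnotationSet:
    """A collection of transcripts with per-chromosome lookup.

    Transcript ids are unique; each transcript belongs to exactly one gene.
    """

    def __init__(self, transcripts: Iterable[TranscriptModel] = ()) -> None:
        self._transcripts: Dict[str, TranscriptModel] = {}
        self._by_chrom: Dict[str, List[TranscriptModel]] = {}
        self._sorted = True
        for t in transcripts:
            self.add(t)

    def add(self, t: TranscriptModel) -> None:
        if t.transcript_id in self._transcripts:
            raise FolliscanError(f"duplicate transcript_id {t.transcript_id}")
        self._transcripts[t.transcript_id] = t
        self._by_chrom.setdefault(t.chrom, []).append(t)
        self._sorted = False

    def _ensure_sorted(self) -> None:
        if not self._sorted:
            for lst in self._by_chrom.values():
                lst.sort(key=lambda t: (t.start, t.end, t.transcript_id))
            self._sorted = True

    def __len__(self) -> int:
        return len(self._transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        self._ensure_sorted()
        for chrom in sorted(self._by_chrom):
            yield from self._by_chrom[chrom]

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._transcripts

    def get(self, transcript_id: str) -> TranscriptModel:
        return self._transcripts[transcript_id]

    @property
    def transcript_ids(self) -> List[str]:
        return [t.transcript_id for t in self]

    def genes(self) -> Dict[str, List[TranscriptModel]]:
        out: Dict[str, List[TranscriptModel]] = {}
        for t in self:
            out.setdefault(t.gene_id, []).append(t)
        return out

    def on_chrom(self, chrom: str) -> Sequence[TranscriptModel]:
        self._ensure_sorted()
        return self._by_chrom.get(chrom, [])

    def overlapping(self, iv: GenomicInterval) -> List[TranscriptModel]:
        """Transcripts whose span overlaps ``iv`` (strand-agnostic)."""
        out = []
        for t in self.on_chrom(iv.chrom):
            if t.start < iv.end and iv.start < t.end:
                out.append(t)
        return out

    def nearest_gap(self, iv: GenomicInterval) -> Optional[int]:
        """Smallest span gap from ``iv`` to any transcript on its chromosome."""
        gaps = [t.span.gap_to(iv) for t in self.on_chrom(iv.chrom)]
        gaps = [g for g in gaps if g is not None]
        return min(gaps) if gaps else None

    def subset(self, ids: Iterable[str]) -> "AnnotationSet":
        return AnnotationSet(self._transcripts[i] for i in ids)

    def of_biotype(self, biotype: str) -> "AnnotationSet":
        return AnnotationSet(t for t in self if t.biotype == biotype)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return {k: (v.gene_id, tuple(v.exons), v.biotype)
                for k, v in self._transcripts.items()} == \
               {k: (v.gene_id, tuple(v.exons), v.biotype)
                for k, v in other._transcripts.items()}


class SequenceStore:
    """Named nucleotide sequences over {A,C,G,T,N}."""

    _ALPHABET = frozenset("ACGTN")

    def __init__(self, sequences: Optional[Dict[str, str]] = None) -> None:
        self._seqs: Dict[str, str] = {}
        for name, seq in (sequences or {}).items():
            self[name] = seq

    def __setitem__(self, name: str, seq: str) -> None:
        seq = seq.upper()
        if set(seq) - self._ALPHABET:
            bad = sorted(set(seq) - self._ALPHABET)
            raise FolliscanError(f"sequence {name}: illegal characters {bad}")
        self._seqs[name] = seq

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __len__(self) -> int:
        return len(self._seqs)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self._seqs))

    def items(self) -> Iterator[Tuple[str, str]]:
        for name in self:
            yield name, self._seqs[name]

    def fetch(self, iv: GenomicInterval) -> str:
        """Forward-strand slice of the stored sequence for ``iv``."""
        if iv.chrom not in self._seqs:
            raise FolliscanError(f"unknown sequence {iv.chrom}")
        seq = self._seqs[iv.chrom]
        if iv.end > len(seq):
            raise FolliscanError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} outside sequence "
                f"bounds (length {len(seq)})"
            )
        return seq[iv.start:iv.end]

    def paint(self, chrom: str, start: int, segment: str) -> None:
        """Overwrite ``segment`` into a stored sequence at ``start``."""
        if chrom not in self._seqs:
            raise FolliscanError(f"unknown sequence {chrom}")
        segment = segment.upper()
        if set(segment) - self._ALPHABET:
            raise FolliscanError(f"illegal characters painted into {chrom}")
        seq = self._seqs[chrom]
        if start < 0 or start + len(segment) > len(seq):
            raise FolliscanError(
                f"paint outside bounds of {chrom}: {start}+{len(segment)}"
            )
        self._seqs[chrom] = seq[:start] + segment + seq[start + len(segment):]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SequenceStore):
            return NotImplemented
        return self._seqs == other._seqs


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_transcript_sequence(t: TranscriptModel, genome: SequenceStore) -> str:
    """Spliced transcript sequence, 5'→3'.

    Exon substrings are concatenated in genomic order; on the minus strand
    the reverse complement of the concatenation is returned.
    """
    try:
        cat = "".join(genome.fetch(e) for e in t.exons)
    except FolliscanError as exc:
        raise FolliscanError(f"{t.transcript_id}: {exc}") from exc
    return cat if t.strand == "+" else reverse_complement(cat)


DEFAULT_STAGES = ("E65", "E85", "E105", "E135", "D7", "D30")
DEFAULT_COMPARISONS = (
    ("E85", "E65"),
    ("E105", "E85"),
    ("E135", "E105"),
    ("D7", "E135"),
    ("D30", "E65"),
    ("D30", "D7"),
)


@dataclass(frozen=True)
class SampleDesign:
    """Six developmental stages x three replicates and the six stage contrasts.

    Stages cover four fetal time points (embryonic days 65/85/105/135) and two
    postnatal ones (days 7 and 30); each contrast is (treatment, control).
    """

    stages: Tuple[str, ...] = DEFAULT_STAGES
    replicates_per_stage: int = 3
    comparisons: Tuple[Tuple[str, str], ...] = DEFAULT_COMPARISONS

    def __post_init__(self) -> None:
        if self.replicates_per_stage < 1:
            raise FolliscanError("replicates_per_stage must be >= 1")
        for trt, ctl in self.comparisons:
            if trt not in self.stages or ctl not in self.stages:
                raise FolliscanError(f"comparison ({trt},{ctl}) uses unknown stage")

    @property
    def samples(self) -> List[str]:
        return [
            f"{stage}-{rep}"
            for stage in self.stages
            for rep in range(1, self.replicates_per_stage + 1)
        ]

    def stage_samples(self, stage: str) -> List[str]:
        if stage not in self.stages:
            raise FolliscanError(f"unknown stage {stage}")
        return [f"{stage}-{r}" for r in range(1, self.replicates_per_stage + 1)]

    def comparison_label(self, comparison: Tuple[str, str]) -> str:
        return f"{comparison[0]}-VS-{comparison[1]}"
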