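"""lncRNA identification cascade and genomic-context classification.

The cascade applies six criteria in fixed order to assembled transcripts:

1. drop single-exon transcripts and transcripts shorter than 200 nt;
2. drop transcripts whose longest *complete* ORF (ATG through an in-frame
   stop, length counted including the stop codon) exceeds 300 nt;
3. drop housekeeping/structural ncRNA biotypes (rRNA, tRNA, snRNA, snoRNA,
   pre-miRNA, pseudogene);
4. keep only cuffcompare-style class codes ``u`` (intergenic), ``i``
   (intronic, same strand) and ``x`` (exonic antisense);
5. split survivors into *known* (exact, zero-mismatch match against a known
   lncRNA database) and *novel*;
6. keep only transcripts called noncoding by every coding-potential
   predictor supplied (a single "coding" call removes the transcript).

Accepted lncRNAs (or any transcript set a caller supplies) can then be
placed into one of six genomic contexts relative to protein-coding genes:
exonic sense/antisense, intronic sense/antisense, bidirectional
(divergent promoters < 1000 bp apart) and intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

from .core import (
    BIOTYPE_OTHER_NCRNA,
    BIOTYPE_PROTEIN_CODING,
    AnnotationSet,
    FolliscanError,
    SequenceStore,
    TranscriptModel,
    extract_transcript_sequence,
)

# ---------------------------------------------------------------------------
# ORF finding
# ---------------------------------------------------------------------------

START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class OrfResult:
    """Longest complete open reading frame of a transcript sequence.

    ``start``/``end`` are offsets in transcript coordinates (0-based,
    half-open); ``length`` counts nucleotides including the stop codon.
    """

    start: int = 0
    end: int = 0
    length: int = 0
    complete: bool = False

    def __post_init__(self) -> None:
        if self.complete and self.length % 3 != 0:
            raise FolliscanError("complete ORF length must be a multiple of 3")


def find_longest_complete_orf(seq: str) -> OrfResult:
    """Longest ATG..stop span on the given strand, scanning all three frames.

    Codons containing ``N`` count as neither start nor stop.  Ties on length
    are broken by the leftmost start.  Returns a zero-length, incomplete
    result when no complete ORF exists.
    """
    seq = seq.upper()
    best = OrfResult()
    n = len(seq)
    for frame in range(3):
        open_starts: List[int] = []
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                if open_starts:
                    start = open_starts[0]  # earliest start gives longest ORF
                    length = pos + 3 - start
                    if length > best.length or (
                        length == best.length and best.complete and start < best.start
                    ):
                        best = OrfResult(start=start, end=pos + 3, length=length, complete=True)
                    open_starts.clear()
            elif codon == START_CODON:
                open_starts.append(pos)
    return best


# ---------------------------------------------------------------------------
# Coding-potential verdicts
# ---------------------------------------------------------------------------

RULE_SCORE = "score<0"
RULE_EVALUE = "E<0.001"


@dataclass(frozen=True)
class PredictorVerdict:
    """One coding-potential predictor's call for one transcript.

    ``rule`` states how the score maps to a call: ``score<0`` means a
    negative score is noncoding (CNCI/CPC convention); ``E<0.001`` means a
    *small* E-value is evidence of a protein domain, hence coding
    (Pfam-scan convention).
    """

    tool: str
    score: float
    rule: str = RULE_SCORE

    def __post_init__(self) -> None:
        if self.rule not in (RULE_SCORE, RULE_EVALUE):
            raise FolliscanError(f"unknown verdict rule {self.rule!r}")

    @property
    def call(self) -> str:
        if self.rule == RULE_SCORE:
            return "noncoding" if self.score < 0 else "coding"
        return "coding" if self.score < 0.001 else "noncoding"


#: minimum ORF fraction of transcript length for the builtin heuristic to
#: call a transcript coding
BUILTIN_ORF_FRACTION = 0.35


def builtin_coding_potential(seq: str) -> PredictorVerdict:
    """ORF-fraction heuristic so the cascade can run without external tools.

    score = (longest complete ORF length / transcript length) - 0.35; the
    transcript is called coding iff score >= 0 (negative score = noncoding,
    the same sign convention the score-based external tools use).
    """
    if not seq:
        raise FolliscanError("empty sequence")
    orf = find_longest_complete_orf(seq)
    score = orf.length / len(seq) - BUILTIN_ORF_FRACTION
    return PredictorVerdict(tool="builtin_orf_fraction", score=score, rule=RULE_SCORE)


# ---------------------------------------------------------------------------
# Class codes
# ---------------------------------------------------------------------------

CLASS_CODES = ("=", "x", "i", "o", "u")
RETAINED_CLASS_CODES = frozenset({"u", "i", "x"})


def _exon_overlap(t: TranscriptModel, r: TranscriptModel) -> bool:
    """Any base-level exon overlap between two transcripts (same chrom)."""
    for e in t.exons:
        for f in r.exons:
            if e.start < f.end and f.start < e.end:
                return True
    return False


def _within_one_intron(t: TranscriptModel, r: TranscriptModel) -> bool:
    """Whole span of ``t`` inside a single intron of ``r``."""
    for intron in r.introns():
        if intron.start <= t.start and t.end <= intron.end:
            return True
    return False


def assign_class_code(t: TranscriptModel, ref: AnnotationSet) -> str:
    """Relate an assembled transcript to the reference annotation.

    ``=``: identical intron chain to a same-strand reference transcript
    (single-exon transcripts match on the exact exon span);
    ``x``: exonic overlap with an opposite-strand reference exon;
    ``i``: fully contained within one intron of a same-strand reference
    transcript;
    ``o``: any other same-strand exonic overlap;
    ``u``: none of the above (includes truly intergenic transcripts and
    opposite-strand intronic containment, for which cuffcompare-style codes
    have no retained category).  Precedence: ``=`` > ``x`` > ``i`` > ``o``.
    """
    same = [r for r in ref.on_chrom(t.chrom) if r.strand == t.strand]
    anti = [r for r in ref.on_chrom(t.chrom) if r.strand != t.strand]

    for r in same:
        if t.n_exons > 1:
            if t.intron_chain() == r.intron_chain() and r.n_exons > 1:
                return "="
        elif r.n_exons == 1 and (t.start, t.end) == (r.start, r.end):
            return "="
    if any(_exon_overlap(t, r) for r in anti):
        return "x"
    if any(_within_one_intron(t, r) for r in same):
        return "i"
    if any(_exon_overlap(t, r) for r in same):
        return "o"
    return "u"


# ---------------------------------------------------------------------------
# Genomic context
# ---------------------------------------------------------------------------

CONTEXT_CATEGORIES = (
    "exonic_sense",
    "intronic_sense",
    "exonic_antisense",
    "intronic_antisense",
    "bidirectional",
    "intergenic",
)

#: maximum promoter-to-promoter distance for a divergent pair to count as
#: bidirectional (strict inequality)
BIDIRECTIONAL_DISTANCE = 1000


@dataclass(frozen=True)
class ContextCategory:
    """Genomic context of a lncRNA relative to protein-coding genes."""

    category: str
    partner_gene: Optional[str] = None
    distance: Optional[int] = None  # bp; 0 for overlap categories

    def __post_init__(self) -> None:
        if self.category not in CONTEXT_CATEGORIES:
            raise FolliscanError(f"unknown context category {self.category!r}")


def _divergent_tss_distance(lnc: TranscriptModel, gene: TranscriptModel) -> Optional[int]:
    """TSS-to-TSS distance of a head-to-head (divergent) pair, else None.

    The pair must be on opposite strands and transcribed away from each
    other: the minus-strand partner lies 5' (leftward) of the plus-strand
    partner's start.
    """
    if lnc.strand == gene.strand:
        return None
    plus, minus = (lnc, gene) if lnc.strand == "+" else (gene, lnc)
    if minus.end <= plus.start:
        return plus.start - (minus.end - 1)
    return None


def classify_genomic_context(
    lnc: TranscriptModel,
    ref: AnnotationSet,
    max_bidirectional: int = BIDIRECTIONAL_DISTANCE,
) -> ContextCategory:
    """Place a transcript into one of the six genomic-context categories.

    Classification is relative to protein-coding reference transcripts
    only.  Precedence: exonic > intronic > bidirectional > intergenic;
    within the exonic and intronic tiers a same-strand (sense) relation
    wins over an antisense one.
    """
    coding = [
        r for r in ref.on_chrom(lnc.chrom) if r.biotype == BIOTYPE_PROTEIN_CODING
    ]

    sense_exonic = [r for r in coding if r.strand == lnc.strand and _exon_overlap(lnc, r)]
    if sense_exonic:
        return ContextCategory("exonic_sense", sense_exonic[0].gene_id, 0)
    anti_exonic = [r for r in coding if r.strand != lnc.strand and _exon_overlap(lnc, r)]
    if anti_exonic:
        return ContextCategory("exonic_antisense", anti_exonic[0].gene_id, 0)

    sense_intronic = [
        r for r in coding if r.strand == lnc.strand and _within_one_intron(lnc, r)
    ]
    if sense_intronic:
        return ContextCategory("intronic_sense", sense_intronic[0].gene_id, 0)
    anti_intronic = [
        r for r in coding if r.strand != lnc.strand and _within_one_intron(lnc, r)
    ]
    if anti_intronic:
        return ContextCategory("intronic_antisense", anti_intronic[0].gene_id, 0)

    best: Optional[Tuple[int, str]] = None
    for r in coding:
        d = _divergent_tss_distance(lnc, r)
        if d is not None and d < max_bidirectional:
            if best is None or (d, r.gene_id) < best:
                best = (d, r.gene_id)
    if best is not None:
        return ContextCategory("bidirectional", best[1], best[0])
    return ContextCategory("intergenic")


# ---------------------------------------------------------------------------
# Known-lncRNA matching
# ---------------------------------------------------------------------------

def match_known_lncrnas(candidate_seq: str, known: SequenceStore) -> str:
    """``known`` iff the candidate is identical to, or an exact substring
    of, a database sequence (identity 100%, zero mismatches); else
    ``novel``."""
    for _, db_seq in known.items():
        if candidate_seq in db_seq:
            return "known"
    return "novel"


# ---------------------------------------------------------------------------
# The cascade
# ---------------------------------------------------------------------------

MIN_LENGTH = 200
MAX_ORF = 300

CRITERIA = (
    "length_exon",        # (1) single exon or < 200 nt
    "orf",                # (2) complete ORF > 300 nt
    "biotype_exclusion",  # (3) rRNA/tRNA/snRNA/snoRNA/pre-miRNA/pseudogene
    "class_code",         # (4) only u/i/x retained
    "known_match",        # (5) known vs novel split (never rejects)
    "coding_potential",   # (6) any predictor calls coding -> removed
)


@dataclass
class FilterTrail:
    """Per-criterion audit trail for one transcript.

    Verdicts are recorded in cascade order; the first failure short-circuits
    the cascade but is itself recorded.
    """

    transcript_id: str
    verdicts: List[Tuple[str, bool, str]] = field(default_factory=list)
    class_code: Optional[str] = None
    novelty: Optional[str] = None  # known | novel

    def record(self, criterion: str, passed: bool, reason: str = "") -> None:
        if criterion not in CRITERIA:
            raise FolliscanError(f"unknown criterion {criterion!r}")
        self.verdicts.append((criterion, passed, reason))

    @property
    def accepted(self) -> bool:
        return all(passed for _, passed, _ in self.verdicts) and len(self.verdicts) > 0

    @property
    def rejected_at(self) -> Optional[str]:
        for criterion, passed, _ in self.verdicts:
            if not passed:
                return criterion
        return None


@dataclass
class CascadeResult:
    """Outcome of the identification cascade."""

    lncrnas: AnnotationSet
    mrnas: AnnotationSet
    trails: Dict[str, FilterTrail]

    @property
    def known_ids(self) -> List[str]:
        return [t for t, tr in sorted(self.trails.items()) if tr.novelty == "known" and tr.accepted]

    @property
    def novel_ids(self) -> List[str]:
        return [t for t, tr in sorted(self.trails.items()) if tr.novelty == "novel" and tr.accepted]


def filter_candidates(
    assembled: AnnotationSet,
    ref: AnnotationSet,
    seqs: SequenceStore,
    known: Optional[SequenceStore] = None,
    verdicts: Optional[Mapping[str, Mapping[str, PredictorVerdict]]] = None,
    min_length: int = MIN_LENGTH,
    max_orf: int = MAX_ORF,
    use_builtin_predictor: bool = True,
) -> CascadeResult:
    """Run the six-criterion cascade over assembled transcripts.

    ``seqs`` maps transcript_id to spliced sequence (use
    :func:`folliscan.core.extract_transcript_sequence` to build it from a
    genome).  ``verdicts`` supplies external coding-potential calls as
    tool -> transcript_id -> :class:`PredictorVerdict`; the builtin
    ORF-fraction heuristic is added unless disabled.  The mRNA set contains
    assembled transcripts whose class code is ``=`` against a
    protein-coding reference transcript.
    """
    if known is None or len(known) == 0:
        import logging

        logging.getLogger(__name__).warning(
            "known-lncRNA database empty: all accepted lncRNAs will be novel"
        )
        known = SequenceStore()
    verdicts = dict(verdicts or {})
    coding_ref = ref.of_biotype(BIOTYPE_PROTEIN_CODING)

    lnc = AnnotationSet()
    mrna = AnnotationSet()
    trails: Dict[str, FilterTrail] = {}

    for t in assembled:
        trail = FilterTrail(transcript_id=t.transcript_id)
        trails[t.transcript_id] = trail

        if t.transcript_id not in seqs:
            trail.record("length_exon", False, "no sequence available")
            continue
        seq = seqs[t.transcript_id]

        # class code is needed both for criterion 4 and for the mRNA set
        code = assign_class_code(t, ref)
        trail.class_code = code
        if code == "=" and assign_class_code(t, coding_ref) == "=":
            mrna.add(t)

        # (1) single exon OR < 200 nt
        ok = t.n_exons >= 2 and t.spliced_length >= min_length
        trail.record(
            "length_exon",
            ok,
            f"exons={t.n_exons}, length={t.spliced_length}",
        )
        if not ok:
            continue

        # (2) complete ORF > 300 nt
        orf = find_longest_complete_orf(seq)
        ok = not (orf.complete and orf.length > max_orf)
        trail.record("orf", ok, f"longest_complete_orf={orf.length}")
        if not ok:
            continue

        # (3) other ncRNA biotypes
        ok = t.biotype != BIOTYPE_OTHER_NCRNA
        trail.record("biotype_exclusion", ok, f"biotype={t.biotype}")
        if not ok:
            continue

        # (4) class code u/i/x only
        ok = code in RETAINED_CLASS_CODES
        trail.record("class_code", ok, f"class_code={code}")
        if not ok:
            continue

        # (5) known vs novel (never rejects)
        trail.novelty = match_known_lncrnas(seq, known)
        trail.record("known_match", True, trail.novelty)

        # (6) consensus noncoding
        calls = []
        if use_builtin_predictor:
            calls.append(builtin_coding_potential(seq))
        for tool in sorted(verdicts):
            v = verdicts[tool].get(t.transcript_id)
            if v is not None:
                calls.append(v)
        coding_tools = [v.tool for v in calls if v.call == "coding"]
        ok = not coding_tools
        trail.record(
            "coding_potential",
            ok,
            "all noncoding" if ok else f"coding call by {','.join(coding_tools)}",
        )
        if not ok:
            continue

        lnc.add(t)

    return CascadeResult(lncrnas=lnc, mrnas=mrna, trails=trails)


def context_counts(
    lncrnas: AnnotationSet, ref: AnnotationSet
) -> Tuple[Dict[str, ContextCategory], Dict[str, int]]:
    """Classify every lncRNA and tally the six categories.

    The tally always partitions the input: every transcript receives
    exactly one category, so counts sum to ``len(lncrnas)``.
    """
    assignments = {
        t.transcript_id: classify_genomic_context(t, ref) for t in lncrnas
    }
    counts = {c: 0 for c in CONTEXT_CATEGORIES}
    for ctx in assignments.values():
        counts[ctx.category] += 1
    return assignments, counts
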