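"""Synthetic fixture-bundle generator with planted ground truth.

Builds a toy genome carrying protein-coding genes with genuine complete
ORFs, lncRNAs planted in each of the six genomic contexts, reject-class
transcripts for every identification filter, a known-lncRNA database, a
six-stage x three-replicate FPKM table with planted fold changes and
temporal archetypes, lncRNA–neighbour co-expression pairs within 10 kb,
and a term-to-gene annotation with one genuinely enriched term.  Every
planted geometry is re-verified before a bundle is accepted, and the
whole bundle is byte-deterministic for a fixed (seed, config).

The default configuration is the study design the package analyses: six
stages (E65..D30), three replicates, planted fold change 8 (log2 = 3, so
threshold recovery at |log2FC| >= 2 is robust with n = 3), log-normal
replicate noise at CV = 0.1.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import io as fio
from .core import (
    BIOTYPE_PROTEIN_CODING,
    BIOTYPE_UNKNOWN,
    AnnotationSet,
    FolliscanError,
    GenomicInterval,
    SampleDesign,
    SequenceStore,
    TranscriptModel,
    extract_transcript_sequence,
    reverse_complement,
)
from .expression import ExpressionTable
from .identify import (
    BUILTIN_ORF_FRACTION,
    MAX_ORF,
    classify_genomic_context,
    find_longest_complete_orf,
)

# genomic layout of one gene slot (offsets from the slot base, bp)
_SLOT = 6400
_EXONS = ((1800, 2000), (3500, 4100), (4900, 5200))  # 200 + 600 + 300 nt
_GENE_SPAN = (1800, 5200)
_MRNA_LEN = 1100
_ORF_SPLICED = (260, 740)  # 480 nt, inside coding exons on either strand
_FAR_GAP = 10_001  # bp between the last gene and the gene-free far region
_FAR_STRIDE = 1500

ROLES = (
    "protein_coding",
    "lncRNA",
    "known_lncRNA",
    "short_reject",
    "single_exon_reject",
    "coding_orf_reject",
)

CONTEXT_ORDER = (
    "exonic_sense",
    "intronic_sense",
    "exonic_antisense",
    "intronic_antisense",
    "bidirectional",
    "intergenic",
)

#: contexts whose planted lncRNA shares its expression series with the
#: neighbouring gene (the planted cis pairs)
CIS_CONTEXTS = ("intronic_sense", "intronic_antisense", "bidirectional")

PATTERNS = ("increasing", "decreasing", "transient", "stable")


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic study; defaults are the emulated conditions."""

    seed: int = 1
    n_coding_genes: int = 40
    n_lncrna_per_context: int = 5
    n_rejects_per_class: int = 4
    fold_change_planted: float = 8.0
    replicate_cv: float = 0.1
    genome_length: int = 300_000
    n_chroms: int = 1
    fpkm_baseline_range: Tuple[float, float] = (5.0, 50.0)

    def __post_init__(self) -> None:
        if self.fold_change_planted < 4:
            raise FolliscanError("fold_change_planted must be >= 4")
        if min(self.n_coding_genes, self.n_lncrna_per_context,
               self.n_rejects_per_class, self.n_chroms) < 1:
            raise FolliscanError("all counts must be >= 1")
        if self.genome_length < 50_000:
            raise FolliscanError("genome_length must be >= 50 kb per chromosome")
        if self.n_coding_genes < 5 * self.n_lncrna_per_context + 2:
            raise FolliscanError(
                "need n_coding_genes >= 5 * n_lncrna_per_context + 2 "
                "(five contexts need partner genes, plus two free genes "
                "hosting near-intergenic lncRNAs)"
            )

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class FixtureBundle:
    """All artifacts of one synthetic study plus the planted truth."""

    config: GeneratorConfig
    design: SampleDesign
    genome: SequenceStore
    reference: AnnotationSet
    assembled: AnnotationSet
    transcript_seqs: SequenceStore
    known: SequenceStore
    expression: ExpressionTable
    truth: pd.DataFrame
    terms: Dict[str, Set[str]]

    @property
    def de_comparison_columns(self) -> List[str]:
        return [f"de_{self.design.comparison_label(c)}" for c in self.design.comparisons]


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def generate_genome(cfg: GeneratorConfig) -> SequenceStore:
    """Uniform-composition random genome; deterministic for a fixed seed."""
    rng = np.random.default_rng(cfg.seed)
    store = SequenceStore()
    bases = np.frombuffer(b"ACGT", dtype="S1")
    for i in range(cfg.n_chroms):
        draw = rng.integers(0, 4, size=cfg.genome_length)
        store[f"chr{i + 1}"] = b"".join(bases[draw]).decode()
    return store


def _random_seq(rng: np.random.Generator, n: int) -> str:
    bases = np.frombuffer(b"ACGT", dtype="S1")
    return b"".join(bases[rng.integers(0, 4, size=n)]).decode()


# ---------------------------------------------------------------------------
# sequence design helpers
# ---------------------------------------------------------------------------

_NONSTOP_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)


def design_orf(rng: np.random.Generator, length: int) -> str:
    """ATG + random non-stop codons + TAA; ``length`` must be 3k >= 9."""
    if length % 3 or length < 9:
        raise FolliscanError("ORF length must be a multiple of 3, >= 9")
    n_mid = length // 3 - 2
    mid = "".join(
        _NONSTOP_CODONS[i] for i in rng.integers(0, len(_NONSTOP_CODONS), size=n_mid)
    )
    return "ATG" + mid + "TAA"


def break_long_orfs(
    seq: str,
    max_len: int,
    protected: frozenset = frozenset(),
    max_iter: int = 60,
) -> str:
    """Mutate codons to TAA until no complete ORF exceeds ``max_len``.

    ``protected`` is a set of transcript positions that must not change
    (e.g. bases shared with a coding exon).  The mutated codon is chosen
    near the middle of the offending ORF so each pass roughly halves it.
    """
    s = list(seq.upper())
    for _ in range(max_iter):
        orf = find_longest_complete_orf("".join(s))
        if not orf.complete or orf.length <= max_len:
            return "".join(s)
        n_codons = orf.length // 3
        order = sorted(range(1, n_codons - 1), key=lambda k: abs(k - n_codons // 2))
        for k in order:
            p = orf.start + 3 * k
            if {p, p + 1, p + 2} & protected:
                continue
            s[p : p + 3] = "TAA"
            break
        else:
            raise FolliscanError("cannot break ORF: all codons protected")
    raise FolliscanError("ORF breaking did not converge")


def paint_transcript(
    genome: SequenceStore, exons: Sequence[GenomicInterval], strand: str, seq: str
) -> None:
    """Write a spliced transcript sequence into the genome across its exons
    (inverse of :func:`folliscan.core.extract_transcript_sequence`)."""
    total = sum(len(e) for e in exons)
    if len(seq) != total:
        raise FolliscanError("sequence length does not match exon chain")
    genomic = seq if strand == "+" else reverse_complement(seq)
    off = 0
    for e in sorted(exons, key=lambda e: e.start):
        genome.paint(e.chrom, e.start, genomic[off : off + len(e)])
        off += len(e)


def _transcript_genomic_positions(t: TranscriptModel) -> List[int]:
    """Genomic position of each transcript base, 5'->3'."""
    pos = [p for e in t.exons for p in range(e.start, e.end)]
    return pos if t.strand == "+" else pos[::-1]


# ---------------------------------------------------------------------------
# annotation + truth
# ---------------------------------------------------------------------------

def _intervals(chrom: str, strand: str, pairs: Sequence[Tuple[int, int]]) -> List[GenomicInterval]:
    return [GenomicInterval(chrom, s, e, strand) for s, e in pairs]


def generate_annotation(
    cfg: GeneratorConfig, genome: SequenceStore
) -> Tuple[AnnotationSet, AnnotationSet, pd.DataFrame]:
    """Plant genes, lncRNAs and reject transcripts; paint their sequences.

    Returns (reference annotation, assembled transcripts, truth table) and
    mutates ``genome`` in place.  Raises before writing anything if the
    genome cannot host the requested features.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    K = cfg.n_lncrna_per_context

    # --- capacity planning -------------------------------------------------
    per_chrom_slots = cfg.genome_length // _SLOT
    slots: List[Tuple[str, int]] = []  # (chrom, base)
    for chrom in chroms:
        for s in range(per_chrom_slots):
            slots.append((chrom, s * _SLOT))
    if len(slots) < cfg.n_coding_genes + 1:  # keep >= 1 slot of headroom
        raise FolliscanError(
            f"genome too small: {len(slots)} gene slots available, "
            f"{cfg.n_coding_genes} genes requested"
        )
    slots = slots[: cfg.n_coding_genes]
    # far, gene-free region sits on the last chromosome past a 10-kb gap
    last_on_last_chrom = max((b for c, b in slots if c == chroms[-1]), default=None)
    if last_on_last_chrom is None:
        far_cursor = _FAR_GAP
    else:
        far_cursor = last_on_last_chrom + _GENE_SPAN[1] + _FAR_GAP
    n_far = max(0, K - 2) + 3 * cfg.n_rejects_per_class
    if far_cursor + n_far * _FAR_STRIDE > cfg.genome_length:
        raise FolliscanError(
            "genome too small for the far intergenic region "
            f"({n_far} features need {n_far * _FAR_STRIDE} bp after {far_cursor})"
        )
    far_chrom = chroms[-1]

    # --- context -> partner-gene indices ------------------------------------
    ctx_gene_range = {
        "intronic_sense": range(0, K),
        "intronic_antisense": range(K, 2 * K),
        "exonic_sense": range(2 * K, 3 * K),
        "exonic_antisense": range(3 * K, 4 * K),
        "bidirectional": range(4 * K, 5 * K),
    }
    bidir_genes = set(ctx_gene_range["bidirectional"])
    free_genes = list(range(5 * K, cfg.n_coding_genes))

    # --- reference genes ----------------------------------------------------
    reference = AnnotationSet()
    gene_meta: Dict[int, Tuple[str, int, str]] = {}  # idx -> (chrom, base, strand)
    for gi, (chrom, base) in enumerate(slots):
        strand = "+" if (gi % 2 == 0 or gi in bidir_genes) else "-"
        gene_meta[gi] = (chrom, base, strand)
        exons = _intervals(chrom, strand, [(base + s, base + e) for s, e in _EXONS])
        gid = f"G{gi + 1:04d}"
        reference.add(
            TranscriptModel(
                transcript_id=f"{gid}.t1",
                gene_id=gid,
                exons=exons,
                biotype=BIOTYPE_PROTEIN_CODING,
            )
        )
        # paint a real mRNA with a complete 480-nt ORF into the exons
        mrna = list(_random_seq(rng, _MRNA_LEN))
        s0, s1 = _ORF_SPLICED
        mrna[s0:s1] = design_orf(rng, s1 - s0)
        paint_transcript(genome, exons, strand, "".join(mrna))

    coding_exon_pos: Dict[str, Set[int]] = {c: set() for c in chroms}
    for t in reference:
        for e in t.exons:
            coding_exon_pos[e.chrom].update(range(e.start, e.end))

    # --- assembled transcripts ----------------------------------------------
    assembled = AnnotationSet()
    rows: List[dict] = []

    def add_row(tid: str, gid: str, role: str, context: str, pattern: str,
                cis_partner: str, baseline: float) -> None:
        rows.append(
            {
                "transcript_id": tid,
                "gene_id": gid,
                "planted_role": role,
                "planted_context": context,
                "planted_pattern": pattern,
                "planted_cis_partner": cis_partner,
                "planted_trans_partner": "",
                "baseline_fpkm": round(float(baseline), 4),
            }
        )

    def draw_baseline() -> float:
        lo, hi = cfg.fpkm_baseline_range
        return float(rng.uniform(lo, hi))

    # assembled copies of every reference gene (identical intron chain -> "=")
    gene_pattern: Dict[int, str] = {}
    gene_baseline: Dict[int, float] = {}
    free_cycle = ("stable", "increasing", "decreasing", "stable")
    for gi in range(cfg.n_coding_genes):
        if gi in free_genes:
            gene_pattern[gi] = free_cycle[free_genes.index(gi) % 4]
        else:
            gene_pattern[gi] = "stable"  # cis partners overridden below
        gene_baseline[gi] = draw_baseline()

    # --- planted lncRNAs ----------------------------------------------------
    lnc_defs: List[Tuple[str, str, List[GenomicInterval], Optional[int]]] = []
    # (lnc_id, strand, exons, partner gene idx or None)
    for ctx in CONTEXT_ORDER:
        for j in range(K):
            lid = f"LNC_{ctx.upper()}_{j + 1:02d}"
            if ctx in ("intronic_sense", "intronic_antisense"):
                gi = ctx_gene_range[ctx][j]
                chrom, base, gs = gene_meta[gi]
                strand = gs if ctx == "intronic_sense" else ("-" if gs == "+" else "+")
                exons = _intervals(
                    chrom, strand,
                    [(base + 2050, base + 2350), (base + 2450, base + 2750)],
                )
                lnc_defs.append((lid, ctx, exons, gi))
            elif ctx in ("exonic_sense", "exonic_antisense"):
                gi = ctx_gene_range[ctx][j]
                chrom, base, gs = gene_meta[gi]
                strand = gs if ctx == "exonic_sense" else ("-" if gs == "+" else "+")
                if gs == "+":  # pure-UTR exon is the rightmost one
                    pairs = [(base + 5100, base + 5400), (base + 5500, base + 5800)]
                else:          # for minus genes it is the leftmost one
                    pairs = [(base + 1200, base + 1500), (base + 1600, base + 1900)]
                lnc_defs.append((lid, ctx, _intervals(chrom, strand, pairs), gi))
            elif ctx == "bidirectional":
                gi = ctx_gene_range[ctx][j]
                chrom, base, gs = gene_meta[gi]  # gs is "+" by construction
                d = int(rng.integers(100, 1000))  # head-to-head TSS distance
                e = base + _GENE_SPAN[0] + 1 - d
                pairs = [(e - 700, e - 400), (e - 300, e)]
                lnc_defs.append((lid, ctx, _intervals(chrom, "-", pairs), gi))
            else:  # intergenic
                if j < 2:  # near a free gene, tandem orientation, within 10 kb
                    gi = free_genes[j]
                    chrom, base, gs = gene_meta[gi]
                    pairs = [(base + 5400, base + 5700), (base + 5800, base + 6100)]
                    lnc_defs.append((lid, ctx, _intervals(chrom, gs, pairs), None))
                else:  # > 10 kb from every gene
                    pairs = [(far_cursor, far_cursor + 300),
                             (far_cursor + 400, far_cursor + 700)]
                    strand = "+" if j % 2 else "-"
                    lnc_defs.append((lid, ctx, _intervals(far_chrom, strand, pairs), None))
                    far_cursor += _FAR_STRIDE

    # one far intergenic lncRNA doubles as the planted trans pair: it shares
    # a 60-nt exact block and the expression series of a distant free gene
    trans_lnc_id = f"LNC_INTERGENIC_{min(3, K):02d}" if K >= 3 else None
    trans_gene_idx = free_genes[1]

    cis_cycle = ("increasing", "decreasing", "transient")
    other_cycle = ("stable", "increasing", "decreasing", "transient")
    for lid, ctx, exons, gi in lnc_defs:
        j = int(lid.rsplit("_", 1)[1]) - 1
        t = TranscriptModel(
            transcript_id=lid, gene_id=f"XLOC_{lid}", exons=exons,
            biotype=BIOTYPE_UNKNOWN,
        )
        assembled.add(t)
        # make the planted lncRNA confidently noncoding: no complete ORF
        # above the cascade threshold nor above the ORF-fraction heuristic
        seq = extract_transcript_sequence(t, genome)
        limit = min(MAX_ORF, int(BUILTIN_ORF_FRACTION * len(seq)) - 3)
        protected = frozenset(
            i
            for i, gp in enumerate(_transcript_genomic_positions(t))
            if gp in coding_exon_pos[t.chrom]
        )
        if lid == trans_lnc_id:
            # splice a 3'-UTR block of the partner mRNA into the lncRNA
            partner_t = reference.get(f"G{trans_gene_idx + 1:04d}.t1")
            block = extract_transcript_sequence(partner_t, genome)[800:860]
            seq = seq[:100] + block + seq[160:]
            protected = protected | frozenset(range(100, 160))
        fixed = break_long_orfs(seq, limit, protected=protected)
        paint_transcript(genome, t.exons, t.strand, fixed)

        role = "known_lncRNA" if j == 0 else "lncRNA"
        trans_partner = ""
        if ctx in CIS_CONTEXTS:
            pattern = cis_cycle[j % 3]
            baseline = draw_baseline()
            gene_pattern[gi] = pattern  # planted cis pair shares the series
            gene_baseline[gi] = baseline
            partner = f"G{gi + 1:04d}"
        elif lid == trans_lnc_id:
            # the trans pair shares the partner gene's series (an
            # "increasing" free gene by construction of the free cycle)
            pattern = gene_pattern[trans_gene_idx]
            baseline = gene_baseline[trans_gene_idx]
            partner = ""
            trans_partner = f"G{trans_gene_idx + 1:04d}"
        else:
            pattern = other_cycle[j % 4]
            baseline = draw_baseline()
            partner = ""
        add_row(lid, t.gene_id, role, ctx, pattern, partner, baseline)
        rows[-1]["planted_trans_partner"] = trans_partner

    # truth rows for the assembled gene copies (after cis overrides)
    for gi in range(cfg.n_coding_genes):
        gid = f"G{gi + 1:04d}"
        tid = f"TCONS_{gid}"
        ref_t = reference.get(f"{gid}.t1")
        assembled.add(
            TranscriptModel(
                transcript_id=tid, gene_id=f"XLOC_{gid}",
                exons=list(ref_t.exons), biotype=BIOTYPE_UNKNOWN,
            )
        )
        add_row(tid, gid, "protein_coding", "n/a", gene_pattern[gi], "",
                gene_baseline[gi])

    # --- reject-class transcripts (far region) ------------------------------
    for r in range(cfg.n_rejects_per_class):
        c = far_cursor
        tid = f"REJ_SHORT_{r + 1:02d}"  # two exons but only 160 nt
        t = TranscriptModel(
            tid, f"XLOC_{tid}",
            _intervals(far_chrom, "+", [(c, c + 80), (c + 130, c + 210)]),
        )
        assembled.add(t)
        seq = extract_transcript_sequence(t, genome)
        paint_transcript(genome, t.exons, t.strand, break_long_orfs(seq, 50))
        add_row(tid, t.gene_id, "short_reject", "n/a", "stable", "", draw_baseline())
        far_cursor += _FAR_STRIDE

        c = far_cursor
        tid = f"REJ_SINGLE_{r + 1:02d}"  # 600 nt but a single exon
        t = TranscriptModel(tid, f"XLOC_{tid}", _intervals(far_chrom, "-", [(c, c + 600)]))
        assembled.add(t)
        seq = extract_transcript_sequence(t, genome)
        paint_transcript(genome, t.exons, t.strand, break_long_orfs(seq, 180))
        add_row(tid, t.gene_id, "single_exon_reject", "n/a", "stable", "", draw_baseline())
        far_cursor += _FAR_STRIDE

        c = far_cursor
        tid = f"REJ_ORF_{r + 1:02d}"  # two exons, 660 nt, complete 480-nt ORF
        t = TranscriptModel(
            tid, f"XLOC_{tid}",
            _intervals(far_chrom, "+", [(c, c + 330), (c + 430, c + 760)]),
        )
        assembled.add(t)
        seq = list(extract_transcript_sequence(t, genome))
        seq[60:540] = design_orf(rng, 480)
        paint_transcript(genome, t.exons, t.strand, "".join(seq))
        add_row(tid, t.gene_id, "coding_orf_reject", "n/a", "stable", "", draw_baseline())
        far_cursor += _FAR_STRIDE

    truth = pd.DataFrame(rows).set_index("transcript_id", drop=False)
    _verify_annotation(cfg, genome, reference, assembled, truth)
    return reference, assembled, truth


def _verify_annotation(
    cfg: GeneratorConfig,
    genome: SequenceStore,
    reference: AnnotationSet,
    assembled: AnnotationSet,
    truth: pd.DataFrame,
) -> None:
    """Re-verify every planted geometry before the bundle is accepted."""
    for t in reference:
        orf = find_longest_complete_orf(extract_transcript_sequence(t, genome))
        if not (orf.complete and orf.length > MAX_ORF):
            raise FolliscanError(f"planted gene {t.transcript_id} lost its ORF")
    for row in truth.itertuples():
        t = assembled.get(row.transcript_id)
        seq = extract_transcript_sequence(t, genome)
        orf = find_longest_complete_orf(seq)
        role = row.planted_role
        if role in ("lncRNA", "known_lncRNA"):
            if t.spliced_length < 200 or t.n_exons < 2:
                raise FolliscanError(f"{row.transcript_id}: bad lncRNA geometry")
            if orf.complete and orf.length > min(
                MAX_ORF, BUILTIN_ORF_FRACTION * len(seq)
            ):
                raise FolliscanError(f"{row.transcript_id}: residual long ORF")
            ctx = classify_genomic_context(t, reference)
            if ctx.category != row.planted_context:
                raise FolliscanError(
                    f"{row.transcript_id}: planted {row.planted_context}, "
                    f"classified {ctx.category}"
                )
            if row.planted_context == "bidirectional" and not (
                ctx.distance is not None and 100 <= ctx.distance < 1000
            ):
                raise FolliscanError(f"{row.transcript_id}: bad divergent distance")
        elif role == "short_reject" and t.spliced_length >= 200:
            raise FolliscanError(f"{row.transcript_id}: short reject too long")
        elif role == "single_exon_reject" and t.n_exons != 1:
            raise FolliscanError(f"{row.transcript_id}: not single exon")
        elif role == "coding_orf_reject" and not (orf.complete and orf.length > MAX_ORF):
            raise FolliscanError(f"{row.transcript_id}: missing planted ORF")


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def pattern_stage_means(pattern: str, baseline: float, fold_change: float) -> np.ndarray:
    """Noiseless six-stage means for one temporal archetype.

    increasing/decreasing are geometric ramps spanning the planted fold
    change (every stage has a distinct mean, so replicates of different
    stages stay distinguishable); transient peaks at E85/E105; stable is
    flat at the baseline.
    """
    F = float(fold_change)
    if pattern == "increasing":
        mult = F ** (np.arange(6) / 5.0)
    elif pattern == "decreasing":
        mult = F ** (np.arange(5, -1, -1) / 5.0)
    elif pattern == "transient":
        mult = np.array([1.0, F, F, 1.0, 1.0, 1.0])
    elif pattern == "stable":
        mult = np.ones(6)
    else:
        raise FolliscanError(f"unknown pattern {pattern!r}")
    return baseline * mult


def _de_truth_from_means(
    means: np.ndarray, design: SampleDesign, pseudocount: float = 1.0
) -> Dict[str, str]:
    by_stage = dict(zip(design.stages, means))
    out = {}
    for trt, ctl in design.comparisons:
        lfc = np.log2((by_stage[trt] + pseudocount) / (by_stage[ctl] + pseudocount))
        label = f"de_{trt}-VS-{ctl}"
        out[label] = "up" if lfc >= 2 else ("down" if lfc <= -2 else "null")
    return out


def generate_expression(
    cfg: GeneratorConfig,
    truth: pd.DataFrame,
    design: Optional[SampleDesign] = None,
) -> Tuple[ExpressionTable, pd.DataFrame]:
    """Realize FPKM values for every truth feature.

    Stage means follow each feature's planted pattern (baseline x stage
    multipliers; the planted fold change separates high from low stages);
    replicates get multiplicative log-normal noise with CV =
    ``replicate_cv`` (mean-corrected so E[FPKM] equals the stage mean).
    Gene-level features (``G####``) reuse the pattern/baseline stored on
    their assembled copy, so planted cis pairs share an identical
    noiseless series (Pearson r = 1).

    Returns the table plus a truth copy extended with per-comparison
    ``de_*`` columns derived from the noiseless means.
    """
    design = design or SampleDesign()
    rng = np.random.default_rng(cfg.seed + 2)
    sigma = float(np.sqrt(np.log(1.0 + cfg.replicate_cv**2)))

    feature_ids: List[str] = []
    profiles: List[np.ndarray] = []
    truth = truth.copy()
    for row in truth.itertuples():
        means = pattern_stage_means(
            row.planted_pattern, row.baseline_fpkm, cfg.fold_change_planted
        )
        if row.planted_role == "protein_coding":
            fid = row.gene_id  # gene-level feature for target correlation
        else:
            fid = row.transcript_id
        feature_ids.append(fid)
        profiles.append(means)
        for label, verdict in _de_truth_from_means(means, design).items():
            truth.loc[row.transcript_id, label] = verdict

    mat = np.zeros((len(feature_ids), len(design.samples)))
    for i, means in enumerate(profiles):
        for j, stage in enumerate(design.stages):
            z = rng.standard_normal(design.replicates_per_stage)
            noise = np.exp(sigma * z - 0.5 * sigma**2)
            cols = slice(
                j * design.replicates_per_stage, (j + 1) * design.replicates_per_stage
            )
            mat[i, cols] = means[j] * noise

    df = pd.DataFrame(mat, index=feature_ids, columns=design.samples)
    truth["expression_feature"] = feature_ids
    return ExpressionTable(df, design, kind="mixed"), truth


def generate_de_benchmark(
    seed: int,
    n_de: int = 200,
    n_null: int = 200,
    fold_change: float = 8.0,
    cv: float = 0.1,
    baseline_range: Tuple[float, float] = (5.0, 50.0),
    design: Optional[SampleDesign] = None,
) -> Tuple[ExpressionTable, pd.DataFrame]:
    """Flat features plus single-contrast fold-change bumps.

    Each DE feature is flat at its baseline except in one stage of one
    designated comparison: the treatment stage is multiplied by the fold
    change for "up" plantings, the control stage for "down" plantings (so
    the low side stays at baseline and the planted |log2FC| is attained
    despite the pseudo-count).  Truth lists the per-comparison
    expectation derived from the noiseless means.
    """
    design = design or SampleDesign()
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log(1.0 + cv**2)))

    rows = []
    ids, profiles = [], []
    for i in range(n_de + n_null):
        b = float(rng.uniform(*baseline_range))
        means = np.full(len(design.stages), b)
        if i < n_de:
            comp = design.comparisons[i % len(design.comparisons)]
            direction = "up" if (i // len(design.comparisons)) % 2 == 0 else "down"
            stage = comp[0] if direction == "up" else comp[1]
            means[design.stages.index(stage)] = b * fold_change
            fid = f"DE_{i + 1:04d}"
        else:
            comp, direction = None, "null"
            fid = f"NULL_{i - n_de + 1:04d}"
        ids.append(fid)
        profiles.append(means)
        row = {"feature_id": fid, "planted_comparison":
               f"{comp[0]}-VS-{comp[1]}" if comp else "", "planted_direction": direction}
        row.update(_de_truth_from_means(means, design))
        rows.append(row)

    mat = np.zeros((len(ids), len(design.samples)))
    for i, means in enumerate(profiles):
        for j in range(len(design.stages)):
            z = rng.standard_normal(design.replicates_per_stage)
            noise = np.exp(sigma * z - 0.5 * sigma**2)
            cols = slice(
                j * design.replicates_per_stage, (j + 1) * design.replicates_per_stage
            )
            mat[i, cols] = means[j] * noise
    table = ExpressionTable(
        pd.DataFrame(mat, index=ids, columns=design.samples), design, kind="mixed"
    )
    return table, pd.DataFrame(rows).set_index("feature_id")


# ---------------------------------------------------------------------------
# terms, known database, full bundle
# ---------------------------------------------------------------------------

def _generate_terms(
    cfg: GeneratorConfig, truth: pd.DataFrame, n_background_terms: int = 7
) -> Dict[str, Set[str]]:
    """Term map over reference genes with one genuinely enriched term.

    The planted term draws almost all of its genes from the planted DE
    genes, so a query of DE/target genes ranks it first.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    genes = sorted(truth.loc[truth.planted_role == "protein_coding", "gene_id"])
    # planted cis-partner genes are certain lncRNA targets (close + shared
    # series), so a term drawn mostly from them is genuinely enriched in
    # the pipeline's target-gene query
    partner_genes = sorted(set(truth.planted_cis_partner) - {""})
    other = [g for g in genes if g not in partner_genes]
    terms: Dict[str, Set[str]] = {}
    planted = [str(g) for g in rng.choice(
        partner_genes, size=min(11, len(partner_genes)), replace=False)]
    if other:
        planted += [str(rng.choice(other))]
    terms["T0001_planted"] = set(planted)
    for i in range(n_background_terms):
        size = min(8, len(genes))
        terms[f"T{i + 2:04d}"] = {
            str(g) for g in rng.choice(genes, size=size, replace=False)
        }
    return terms


def generate_bundle(cfg: Optional[GeneratorConfig] = None) -> FixtureBundle:
    """Generate the full synthetic study for one (seed, config)."""
    cfg = cfg or GeneratorConfig()
    design = SampleDesign()
    genome = generate_genome(cfg)
    reference, assembled, truth = generate_annotation(cfg, genome)

    seqs = SequenceStore()
    for t in assembled:
        seqs[t.transcript_id] = extract_transcript_sequence(t, genome)

    known = SequenceStore()
    for row in truth.itertuples():
        if row.planted_role == "known_lncRNA":
            known[f"KNOWN_{row.transcript_id}"] = seqs[row.transcript_id]
    rng = np.random.default_rng(cfg.seed + 4)
    for i in range(2):  # decoy database entries matching nothing planted
        known[f"KNOWN_DECOY_{i + 1}"] = break_long_orfs(_random_seq(rng, 500), 170)

    expression, truth = generate_expression(cfg, truth, design)
    terms = _generate_terms(cfg, truth)
    return FixtureBundle(
        config=cfg,
        design=design,
        genome=genome,
        reference=reference,
        assembled=assembled,
        transcript_seqs=seqs,
        known=known,
        expression=expression,
        truth=truth,
        terms=terms,
    )


# ---------------------------------------------------------------------------
# bundle round trip
# ---------------------------------------------------------------------------

BUNDLE_FILES = {
    "genome": "genome.fasta",
    "reference": "reference.gtf",
    "assembled": "assembled.gtf",
    "known": "known_lncrnas.fasta",
    "expression": "fpkm.tsv",
    "truth": "truth.tsv",
    "terms": "terms.tsv",
}


def write_fixture_bundle(bundle: FixtureBundle, outdir) -> Dict[str, object]:
    """Write all artifacts in the package's standard formats + a manifest."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise FolliscanError(f"cannot create bundle directory {outdir}: {exc}") from exc
    fio.write_fasta(bundle.genome, outdir / BUNDLE_FILES["genome"])
    fio.write_gtf(bundle.reference, outdir / BUNDLE_FILES["reference"])
    fio.write_gtf(bundle.assembled, outdir / BUNDLE_FILES["assembled"])
    fio.write_fasta(bundle.known, outdir / BUNDLE_FILES["known"])
    fio.write_expression_table(bundle.expression, outdir / BUNDLE_FILES["expression"])
    bundle.truth.to_csv(outdir / BUNDLE_FILES["truth"], sep="\t", index=False)
    fio.write_term_annotation(bundle.terms, outdir / BUNDLE_FILES["terms"])
    manifest = {
        "seed": bundle.config.seed,
        "config_hash": bundle.config.hash(),
        "config": asdict(bundle.config),
        "files": dict(BUNDLE_FILES),  # relative to the bundle directory
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def load_fixture_bundle(outdir) -> FixtureBundle:
    """Reload a written bundle (inverse of :func:`write_fixture_bundle`)."""
    outdir = Path(outdir)
    with open(outdir / "manifest.json") as fh:
        manifest = json.load(fh)
    cfg = GeneratorConfig(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in manifest["config"].items()
    })
    design = SampleDesign()
    genome = fio.read_fasta(outdir / BUNDLE_FILES["genome"])
    reference = fio.read_gtf(outdir / BUNDLE_FILES["reference"])
    assembled = fio.read_gtf(outdir / BUNDLE_FILES["assembled"])
    known = fio.read_fasta(outdir / BUNDLE_FILES["known"])
    expression = fio.read_expression_table(
        outdir / BUNDLE_FILES["expression"], design, kind="mixed"
    )
    truth = pd.read_csv(outdir / BUNDLE_FILES["truth"], sep="\t").set_index(
        "transcript_id", drop=False
    )
    truth = truth.fillna("")
    terms = fio.read_term_annotation(outdir / BUNDLE_FILES["terms"])
    seqs = SequenceStore()
    for t in assembled:
        seqs[t.transcript_id] = extract_transcript_sequence(t, genome)
    return FixtureBundle(
        config=cfg,
        design=design,
        genome=genome,
        reference=reference,
        assembled=assembled,
        transcript_seqs=seqs,
        known=known,
        expression=expression,
        truth=truth,
        terms=terms,
    )
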