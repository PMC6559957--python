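"""Readers/writers for the standard formats the pipeline touches.

GTF/GFF3 annotation (1-based inclusive on disk, 0-based half-open in
memory), FASTA sequences, and TSV tables for expression, coding-potential
verdicts and term-to-gene annotation.  All writers emit deterministic
record and column order so that fixture bundles are byte-reproducible.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Set, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

from .core import (
    BIOTYPE_KNOWN_LNCRNA,
    BIOTYPE_OTHER_NCRNA,
    BIOTYPE_PROTEIN_CODING,
    BIOTYPE_UNKNOWN,
    OTHER_NCRNA_BIOTYPES,
    AnnotationSet,
    FolliscanError,
    GenomicInterval,
    SampleDesign,
    SequenceStore,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

_INTERNAL_BIOTYPES = {
    BIOTYPE_PROTEIN_CODING,
    BIOTYPE_KNOWN_LNCRNA,
    BIOTYPE_OTHER_NCRNA,
    BIOTYPE_UNKNOWN,
}


def map_biotype(raw: Optional[str]) -> str:
    """Fold a raw annotation biotype string into the internal buckets."""
    if raw is None or raw == "":
        return BIOTYPE_UNKNOWN
    if raw in _INTERNAL_BIOTYPES:
        return raw
    if raw in OTHER_NCRNA_BIOTYPES:
        return BIOTYPE_OTHER_NCRNA
    if raw in {"lncRNA", "lincRNA", "antisense", "known_lncRNA"}:
        return BIOTYPE_KNOWN_LNCRNA
    return BIOTYPE_UNKNOWN


# ---------------------------------------------------------------------------
# GTF / GFF3
# ---------------------------------------------------------------------------

def _attr(feature, *names: str) -> Optional[str]:
    for name in names:
        if name in feature.attributes:
            vals = feature.attributes[name]
            if vals:
                return vals[0]
    return None


def read_gtf(
    path,
    dialect: str = "gtf",
    rejects: Optional[List[Tuple[str, str]]] = None,
) -> AnnotationSet:
    """Read an annotation file into an :class:`AnnotationSet`.

    ``dialect`` is ``"gtf"`` (attributes ``transcript_id``/``gene_id`` on
    exon records) or ``"gff3"`` (exons carry ``Parent``; transcript records
    carry ``ID`` and ``Parent`` pointing at the gene).  File coordinates are
    1-based inclusive and converted to the internal 0-based half-open
    convention.  Malformed lines raise with the line number; transcripts
    with exons on mixed strands/chromosomes, or without a usable strand,
    are rejected and logged (optionally collected into ``rejects``).
    """
    if dialect not in ("gtf", "gff3"):
        raise FolliscanError(f"unknown dialect {dialect!r}")
    path = Path(path)
    if not path.is_file():
        raise FolliscanError(f"no such file: {path}")

    exon_rows: Dict[str, List[Tuple[str, int, int, str]]] = {}
    tx_gene: Dict[str, str] = {}
    tx_biotype: Dict[str, str] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise FolliscanError(
                    f"{path}:{lineno}: malformed line: expected 9 tab-separated fields"
                )
            try:
                feat = feature_from_line(line, dialect=None)
            except Exception as exc:  # gffutils raises various types
                raise FolliscanError(f"{path}:{lineno}: malformed line: {exc}") from exc
            ftype = feat.featuretype
            if dialect == "gtf":
                tid = _attr(feat, "transcript_id")
                gid = _attr(feat, "gene_id")
                if ftype == "exon":
                    if tid is None or gid is None:
                        raise FolliscanError(
                            f"{path}:{lineno}: exon without transcript_id/gene_id"
                        )
                    exon_rows.setdefault(tid, []).append(
                        (feat.seqid, feat.start - 1, feat.end, feat.strand)
                    )
                    tx_gene.setdefault(tid, gid)
                if tid is not None:
                    bio = _attr(feat, "biotype", "transcript_biotype", "gene_biotype")
                    if bio is not None:
                        tx_biotype.setdefault(tid, bio)
            else:  # gff3
                if ftype in ("transcript", "mRNA"):
                    tid = _attr(feat, "ID")
                    gid = _attr(feat, "Parent", "gene_id")
                    if tid is None:
                        raise FolliscanError(f"{path}:{lineno}: transcript without ID")
                    tx_gene[tid] = gid if gid is not None else tid
                    bio = _attr(feat, "biotype")
                    if bio is not None:
                        tx_biotype[tid] = bio
                elif ftype == "exon":
                    tid = _attr(feat, "Parent")
                    if tid is None:
                        raise FolliscanError(f"{path}:{lineno}: exon without Parent")
                    exon_rows.setdefault(tid, []).append(
                        (feat.seqid, feat.start - 1, feat.end, feat.strand)
                    )

    ann = AnnotationSet()
    for tid in exon_rows:
        rows = exon_rows[tid]
        strands = {r[3] for r in rows}
        chroms = {r[0] for r in rows}
        reason = None
        if strands - {"+", "-"}:
            reason = "unstranded record ('.' strand)"
        elif len(strands) > 1 or len(chroms) > 1:
            reason = "exons on mixed strands/chromosomes"
        if reason is None:
            try:
                exons = [GenomicInterval(c, s, e, st) for c, s, e, st in rows]
                ann.add(
                    TranscriptModel(
                        transcript_id=tid,
                        gene_id=tx_gene.get(tid, tid),
                        exons=exons,
                        biotype=map_biotype(tx_biotype.get(tid)),
                    )
                )
                continue
            except FolliscanError as exc:
                reason = str(exc)
        logger.warning("rejected transcript %s: %s", tid, reason)
        if rejects is not None:
            rejects.append((tid, reason))
    return ann


def write_gtf(ann: AnnotationSet, path, dialect: str = "gtf") -> None:
    """Write an annotation set as GTF (default) or GFF3, 1-based inclusive."""
    if dialect not in ("gtf", "gff3"):
        raise FolliscanError(f"unknown dialect {dialect!r}")
    path = Path(path)
    with open(path, "w") as fh:
        if dialect == "gff3":
            fh.write("##gff-version 3\n")
        for t in ann:
            if dialect == "gtf":
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'biotype "{t.biotype}";'
                )
                fh.write(
                    f"{t.chrom}\tfolliscan\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )
                for e in t.exons:
                    fh.write(
                        f"{e.chrom}\tfolliscan\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{e.strand}\t.\t{attrs}\n"
                    )
            else:
                fh.write(
                    f"{t.chrom}\tfolliscan\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                    f"{t.strand}\t.\tID={t.transcript_id};Parent={t.gene_id};"
                    f"biotype={t.biotype}\n"
                )
                for i, e in enumerate(t.exons, start=1):
                    fh.write(
                        f"{e.chrom}\tfolliscan\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{e.strand}\t.\tID={t.transcript_id}.exon{i};"
                        f"Parent={t.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> SequenceStore:
    path = Path(path)
    if not path.is_file():
        raise FolliscanError(f"no such file: {path}")
    store = SequenceStore()
    for rec in SeqIO.parse(str(path), "fasta"):
        store[rec.id] = str(rec.seq)
    return store


def write_fasta(store: SequenceStore, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in store.items()
    ]
    SeqIO.write(records, str(Path(path)), "fasta")


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

def read_expression_table(path, design: SampleDesign, kind: str = "lncRNA"):
    """Read a features x samples FPKM TSV into an :class:`ExpressionTable`.

    The header must name samples as ``<stage>-<replicate>``; every sample in
    ``design`` must be present (extra columns are ignored), and all values
    must be non-negative numbers.
    """
    from .expression import ExpressionTable

    path = Path(path)
    if not path.is_file():
        raise FolliscanError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [s for s in design.samples if s not in df.columns]
    if missing:
        raise FolliscanError(f"expression table missing samples: {', '.join(missing)}")
    df = df[design.samples]
    if not all(pd.api.types.is_numeric_dtype(dt) for dt in df.dtypes):
        raise FolliscanError("expression table contains non-numeric values")
    if (df.values < 0).any():
        bad = df.index[(df.values < 0).any(axis=1)][0]
        raise FolliscanError(f"negative expression value for feature {bad}")
    return ExpressionTable(df, design, kind=kind)


def write_expression_table(table, path) -> None:
    df = table.values
    df.to_csv(Path(path), sep="\t", index_label="feature_id", float_format="%.6g")


# ---------------------------------------------------------------------------
# Term annotation and verdict tables
# ---------------------------------------------------------------------------

def read_term_annotation(path) -> Dict[str, Set[str]]:
    """Read a two-column (term_id, gene_id) TSV into term -> gene-set.

    Gene symbols are uppercased (matching is case-insensitive throughout the
    package) and deduplicated.  An optional header line is tolerated.  An
    empty file yields an empty map with a warning.
    """
    path = Path(path)
    if not path.is_file():
        raise FolliscanError(f"no such file: {path}")
    terms: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FolliscanError(f"{path}:{lineno}: expected two tab-separated columns")
            term, gene = fields[0].strip(), fields[1].strip()
            if lineno == 1 and term.lower() in ("term", "term_id"):
                continue
            terms.setdefault(term, set()).add(gene.upper())
    if not terms:
        logger.warning("term annotation %s is empty", path)
    return terms


def write_term_annotation(terms: Dict[str, Set[str]], path) -> None:
    with open(Path(path), "w") as fh:
        fh.write("term_id\tgene_id\n")
        for term in sorted(terms):
            for gene in sorted(terms[term]):
                fh.write(f"{term}\t{gene}\n")


def read_verdict_table(path) -> Dict[str, Dict[str, "object"]]:
    """Read external coding-potential verdicts.

    TSV columns: ``transcript_id``, ``tool``, ``score``, ``rule``
    (``score<0`` or ``E<0.001``).  Returns tool -> transcript_id -> verdict.
    """
    from .identify import PredictorVerdict

    df = pd.read_csv(Path(path), sep="\t")
    required = {"transcript_id", "tool", "score", "rule"}
    if not required.issubset(df.columns):
        raise FolliscanError(f"verdict table needs columns {sorted(required)}")
    out: Dict[str, Dict[str, PredictorVerdict]] = {}
    for row in df.itertuples(index=False):
        v = PredictorVerdict(tool=row.tool, score=float(row.score), rule=row.rule)
        out.setdefault(row.tool, {})[row.transcript_id] = v
    return out
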