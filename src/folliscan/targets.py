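"""cis/trans lncRNA target prediction.

cis: protein-coding genes within 10 kb of a lncRNA (span-to-span gap,
strand-agnostic; overlap counts as distance 0), gated by significant
Pearson correlation of log2(FPKM + 1) profiles (BH-adjusted p < 0.05
across all candidate pairs of the mode).

trans: distant genes screened by a local-alignment complementarity score
(Smith–Waterman, match +1 / mismatch -2 / gap open -5 / gap extend -2,
computed against both the gene transcript and its reverse complement),
then the same correlation gate.  Pairs in cis range are never reported as
trans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats

from .core import (
    AnnotationSet,
    FolliscanError,
    SequenceStore,
    TranscriptModel,
    reverse_complement,
)
from .expression import ExpressionTable, benjamini_hochberg

logger = logging.getLogger(__name__)

#: cis search window, bp, inclusive
CIS_WINDOW = 10_000
#: minimum local-alignment score for the trans sequence screen
TRANS_SCORE_MIN = 40.0
#: correlation-gate significance threshold (BH-adjusted)
CORR_PADJ = 0.05


@dataclass
class TargetPair:
    """One lncRNA–gene link, cis or trans."""

    lncrna_id: str
    gene_id: str
    mode: str  # cis | trans
    distance: Optional[int] = None  # bp, cis only; 0 if overlapping
    r: Optional[float] = None
    p: Optional[float] = None
    padj: Optional[float] = None
    similarity_score: Optional[float] = None  # trans only

    def __post_init__(self) -> None:
        if self.mode not in ("cis", "trans"):
            raise FolliscanError(f"unknown target mode {self.mode!r}")
        if self.mode == "cis" and self.distance is not None and self.distance > CIS_WINDOW:
            raise FolliscanError("cis pair beyond the 10-kb window")
        if self.r is not None and not -1.0 <= self.r <= 1.0 + 1e-12:
            raise FolliscanError("correlation out of [-1, 1]")


# ---------------------------------------------------------------------------
# cis candidates
# ---------------------------------------------------------------------------

def _gene_spans(ref: AnnotationSet) -> List[Tuple[str, str, int, int]]:
    """(gene_id, chrom, start, end) spans, one per gene (union of transcripts)."""
    spans: Dict[str, Tuple[str, int, int]] = {}
    for t in ref:
        if t.gene_id in spans:
            c, s, e = spans[t.gene_id]
            spans[t.gene_id] = (c, min(s, t.start), max(e, t.end))
        else:
            spans[t.gene_id] = (t.chrom, t.start, t.end)
    return [(g, c, s, e) for g, (c, s, e) in sorted(spans.items())]


def cis_candidates(
    lncrnas: AnnotationSet,
    coding_genes: AnnotationSet,
    window: int = CIS_WINDOW,
) -> List[TargetPair]:
    """All (lncRNA, gene) pairs with span gap <= ``window`` bp.

    Strand-agnostic; the gene span is the union of its transcripts.
    Distance is the gap between closest span ends (0 for overlap).
    """
    spans = _gene_spans(coding_genes)
    by_chrom: Dict[str, List[Tuple[str, int, int]]] = {}
    for g, c, s, e in spans:
        by_chrom.setdefault(c, []).append((g, s, e))

    pairs: List[TargetPair] = []
    for lnc in lncrnas:
        genes = by_chrom.get(lnc.chrom, [])
        if not genes:
            continue
        starts = np.array([g[1] for g in genes])
        ends = np.array([g[2] for g in genes])
        gaps = np.maximum(
            0, np.maximum(starts, lnc.start) - np.minimum(ends, lnc.end)
        )
        for idx in np.nonzero(gaps <= window)[0]:
            pairs.append(
                TargetPair(
                    lncrna_id=lnc.transcript_id,
                    gene_id=genes[idx][0],
                    mode="cis",
                    distance=int(gaps[idx]),
                )
            )
    pairs.sort(key=lambda p: (p.lncrna_id, p.gene_id))
    return pairs


# ---------------------------------------------------------------------------
# Correlation gate
# ---------------------------------------------------------------------------

def correlate(
    pairs: Sequence[TargetPair],
    lnc_expr: ExpressionTable,
    gene_expr: ExpressionTable,
    padj_threshold: float = CORR_PADJ,
    keep_all: bool = False,
) -> List[TargetPair]:
    """Pearson correlation + BH across a candidate-pair list.

    r is computed on log2(FPKM + 1) across the paired samples; the
    two-sided p comes from the t-transform with n - 2 degrees of freedom;
    BH runs over all supplied pairs.  Pairs with a zero-variance side are
    dropped with a logged reason.  Only pairs with padj < threshold are
    returned unless ``keep_all``.
    """
    lmat = lnc_expr.log2p1()
    gmat = gene_expr.log2p1()
    n = len(lnc_expr.design.samples)

    scored: List[TargetPair] = []
    pvals: List[float] = []
    for pair in pairs:
        if pair.lncrna_id not in lmat.index or pair.gene_id not in gmat.index:
            raise FolliscanError(
                f"pair ({pair.lncrna_id}, {pair.gene_id}) missing from expression"
            )
        x = lmat.loc[pair.lncrna_id].values
        y = gmat.loc[pair.gene_id].values
        if x.std() == 0 or y.std() == 0:
            logger.info(
                "dropping pair (%s, %s): zero-variance profile",
                pair.lncrna_id,
                pair.gene_id,
            )
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        r = min(1.0, max(-1.0, r))
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
        scored.append(
            TargetPair(
                lncrna_id=pair.lncrna_id,
                gene_id=pair.gene_id,
                mode=pair.mode,
                distance=pair.distance,
                r=r,
                p=p,
                similarity_score=pair.similarity_score,
            )
        )
        pvals.append(p)

    if not scored:
        return []
    padj = benjamini_hochberg(pvals)
    for pair, q in zip(scored, padj):
        pair.padj = float(q)
    if keep_all:
        return scored
    return [p for p in scored if p.padj < padj_threshold]


# ---------------------------------------------------------------------------
# trans similarity screen
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    # match +1, mismatch -2; N matches nothing (so all-N sequences score 0)
    mat = substitution_matrices.Array("ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            if a == b and a != "N":
                mat[a, b] = 1.0
            else:
                mat[a, b] = -2.0
    aligner.substitution_matrix = mat
    # a gap of length L scores -5 - 2*(L - 1)
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    return aligner


_ALIGNER = _make_aligner()


def trans_similarity(lnc_seq: str, gene_seq: str) -> float:
    """Best local-alignment score of the lncRNA against the gene transcript
    or its reverse complement (complementarity proxy).

    Smith–Waterman with match +1, mismatch -2, gap open -5, gap extend -2.
    """
    if not lnc_seq or not gene_seq:
        raise FolliscanError("empty sequence in trans similarity screen")
    fwd = _ALIGNER.score(lnc_seq.upper(), gene_seq.upper())
    rev = _ALIGNER.score(lnc_seq.upper(), reverse_complement(gene_seq.upper()))
    return float(max(0.0, fwd, rev))


def trans_targets(
    lncrnas: AnnotationSet,
    coding_genes: AnnotationSet,
    lnc_seqs: SequenceStore,
    gene_seqs: Mapping[str, str],
    lnc_expr: ExpressionTable,
    gene_expr: ExpressionTable,
    s_min: float = TRANS_SCORE_MIN,
    padj_threshold: float = CORR_PADJ,
    cis_pairs: Optional[Sequence[TargetPair]] = None,
) -> List[TargetPair]:
    """Sequence-similarity screen followed by the correlation gate.

    ``gene_seqs`` maps gene_id to a representative transcript sequence.
    Pairs that are cis candidates for the same gene are excluded (they are
    reported under cis, never trans).
    """
    if cis_pairs is None:
        cis_pairs = cis_candidates(lncrnas, coding_genes)
    cis_keys: Set[Tuple[str, str]] = {(p.lncrna_id, p.gene_id) for p in cis_pairs}

    screened: List[TargetPair] = []
    for lnc in lncrnas:
        if lnc.transcript_id not in lnc_seqs:
            continue
        lseq = lnc_seqs[lnc.transcript_id]
        for gene_id in sorted({t.gene_id for t in coding_genes}):
            if (lnc.transcript_id, gene_id) in cis_keys:
                continue
            gseq = gene_seqs.get(gene_id)
            if not gseq:
                continue
            score = trans_similarity(lseq, gseq)
            if score >= s_min:
                screened.append(
                    TargetPair(
                        lncrna_id=lnc.transcript_id,
                        gene_id=gene_id,
                        mode="trans",
                        similarity_score=score,
                    )
                )
    return correlate(screened, lnc_expr, gene_expr, padj_threshold=padj_threshold)


def target_pairs_frame(pairs: Sequence[TargetPair]) -> pd.DataFrame:
    """Flatten target pairs into a deterministic DataFrame for writing."""
    rows = [
        {
            "lncrna_id": p.lncrna_id,
            "gene_id": p.gene_id,
            "mode": p.mode,
            "distance": p.distance,
            "r": p.r,
            "p": p.p,
            "padj": p.padj,
            "similarity_score": p.similarity_score,
        }
        for p in pairs
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "lncrna_id", "gene_id", "mode", "distance",
            "r", "p", "padj", "similarity_score",
        ],
    )
    return df.sort_values(["mode", "lncrna_id", "gene_id"]).reset_index(drop=True)
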