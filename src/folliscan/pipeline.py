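"""End-to-end orchestration: identify -> express -> targets -> cluster ->
enrich -> overlap, with a machine-readable run report.

Every printed threshold of the analysis is surfaced on
:class:`PipelineConfig` rather than hard-coded; the report re-checks the
structural invariants (context categories partition the accepted lncRNA
set; up + down = DE total per comparison) before a run is declared good.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from . import io as fio
from .core import (
    BIOTYPE_PROTEIN_CODING,
    AnnotationSet,
    FolliscanError,
    SampleDesign,
    SequenceStore,
    extract_transcript_sequence,
)
from .enrichment import EnrichmentResult, OverlapReport, enrich, overlap_analysis
from .expression import (
    ClusterAssignment,
    ComparisonResult,
    ExpressionTable,
    SampleDendrogram,
    VennResult,
    hierarchical_cluster_samples,
    kmeans_patterns,
    run_all_comparisons,
    venn_stage_specific,
)
from .identify import (
    CascadeResult,
    ContextCategory,
    context_counts,
    filter_candidates,
)
from .targets import (
    TargetPair,
    cis_candidates,
    correlate,
    target_pairs_frame,
    trans_targets,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one pipeline run."""

    assembled_gtf: str = ""
    reference_gtf: str = ""
    genome_fasta: str = ""
    known_fasta: str = ""
    expression_tsv: str = ""
    counts_tsv: str = ""
    lengths_tsv: str = ""
    terms_tsv: str = ""
    verdicts_tsv: str = ""

    min_length: int = 200
    max_orf: int = 300
    bidirectional_dist: int = 1000
    cis_window: int = 10_000
    padj_de: float = 0.05
    lfc_min: float = 2.0
    corr_padj: float = 0.05
    enrich_p: float = 0.05
    k: int = 10
    s_min: float = 40.0
    pseudocount: float = 1.0
    tau_fraction: float = 0.1
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("min_length", "max_orf", "bidirectional_dist", "cis_window",
                     "padj_de", "lfc_min", "corr_padj", "enrich_p", "k", "s_min",
                     "pseudocount", "tau_fraction"):
            if getattr(self, name) <= 0:
                raise FolliscanError(f"threshold {name} must be positive")

    def apply_overrides(self, overrides: Mapping[str, str]) -> "PipelineConfig":
        data = dataclasses.asdict(self)
        for key, raw in overrides.items():
            if key not in data:
                raise FolliscanError(f"unknown config key {key!r}")
            cur = data[key]
            data[key] = type(cur)(raw) if not isinstance(cur, str) else raw
        return PipelineConfig(**data)


@dataclass
class RunReport:
    """Per-stage counts of one pipeline run."""

    thresholds: Dict[str, float]
    n_assembled: int = 0
    rejected_per_criterion: Dict[str, int] = field(default_factory=dict)
    n_lncrna_known: int = 0
    n_lncrna_novel: int = 0
    n_mrna: int = 0
    context_category_counts: Dict[str, int] = field(default_factory=dict)
    de_counts: Dict[str, Dict[str, int]] = field(default_factory=dict)  # kind -> label -> n
    de_up_down: Dict[str, Dict[str, Tuple[int, int]]] = field(default_factory=dict)
    venn_stage_specific: Dict[str, int] = field(default_factory=dict)
    cluster_sizes: Dict[int, int] = field(default_factory=dict)
    cluster_pattern_groups: Dict[int, str] = field(default_factory=dict)
    n_cis_targets: int = 0
    n_trans_targets: int = 0
    n_enriched_terms: int = 0
    overlap_sizes: Dict[str, int] = field(default_factory=dict)

    @property
    def n_lncrna(self) -> int:
        return self.n_lncrna_known + self.n_lncrna_novel

    def check_invariants(self) -> None:
        if sum(self.context_category_counts.values()) != self.n_lncrna:
            raise FolliscanError("context category counts do not partition lncRNAs")
        for kind, labels in self.de_up_down.items():
            for label, (up, down) in labels.items():
                if up + down != self.de_counts[kind][label]:
                    raise FolliscanError(f"{kind} {label}: up+down != DE total")

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (set, frozenset)):
                return sorted(o)
            raise TypeError(type(o))

        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True,
                          default=default)


@dataclass
class PipelineResult:
    report: RunReport
    cascade: CascadeResult
    contexts: Dict[str, ContextCategory]
    lnc_de: List[ComparisonResult]
    mrna_de: List[ComparisonResult]
    venn: VennResult
    dendrogram: Optional[SampleDendrogram]
    clusters: Optional[ClusterAssignment]
    cis: List[TargetPair]
    trans: List[TargetPair]
    enrichment: List[EnrichmentResult]
    overlaps: List[OverlapReport]


def summarize_qc(raw_reads: int, clean_reads: int) -> float:
    """Clean-read retention percentage, half-even rounded to 2 decimals."""
    if raw_reads <= 0:
        raise FolliscanError("raw_reads must be positive")
    if not 0 < clean_reads <= raw_reads:
        raise FolliscanError("need 0 < clean_reads <= raw_reads")
    pct = Decimal(100 * clean_reads) / Decimal(raw_reads)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))


def reference_gene_of(t, ref: AnnotationSet) -> Optional[str]:
    """Gene id of the same-strand reference transcript with the identical
    intron chain (the ``=`` partner), if any."""
    for r in ref.on_chrom(t.chrom):
        if r.strand != t.strand:
            continue
        if t.n_exons > 1 and r.n_exons > 1:
            if t.intron_chain() == r.intron_chain():
                return r.gene_id
        elif t.n_exons == 1 and r.n_exons == 1 and (t.start, t.end) == (r.start, r.end):
            return r.gene_id
    return None


def _gene_level_expression(
    expression: ExpressionTable,
    mrnas: AnnotationSet,
    ref: AnnotationSet,
) -> Tuple[ExpressionTable, Dict[str, str]]:
    """Gene-level table for accepted mRNAs.

    If a gene id already names an expression row it is used directly
    (gene-level quantification); otherwise the gene's transcript rows are
    summed.  Returns the table and the transcript -> gene map.
    """
    tx2gene: Dict[str, str] = {}
    for t in mrnas:
        gid = reference_gene_of(t, ref)
        if gid is not None:
            tx2gene[t.transcript_id] = gid
    rows = {}
    for tid, gid in sorted(tx2gene.items()):
        if gid in rows:
            continue
        if gid in expression.values.index:
            rows[gid] = expression.values.loc[gid]
        elif tid in expression.values.index:
            rows[gid] = expression.values.loc[tid]
    if not rows:
        raise FolliscanError("no expression rows found for accepted mRNA genes")
    df = pd.DataFrame(rows).T
    df.index.name = "feature_id"
    return ExpressionTable(df, expression.design, kind="mRNA"), tx2gene


def run_pipeline(
    cfg: PipelineConfig,
    outdir=None,
    bundle=None,
) -> PipelineResult:
    """Execute every stage in order and return all results.

    Inputs come either from the paths in ``cfg`` or, for programmatic
    runs, from a pre-generated synthetic ``bundle``.  When ``outdir`` is
    given every artifact is written there along with ``report.json``.  Any
    stage error aborts with the stage name attached; the run is
    deterministic for a fixed seed.
    """
    stage = "load"
    try:
        if bundle is not None:
            reference, assembled = bundle.reference, bundle.assembled
            seqs, known = bundle.transcript_seqs, bundle.known
            expression, terms = bundle.expression, bundle.terms
            genome = bundle.genome
        else:
            reference = fio.read_gtf(cfg.reference_gtf)
            assembled = fio.read_gtf(cfg.assembled_gtf)
            genome = fio.read_fasta(cfg.genome_fasta)
            known = fio.read_fasta(cfg.known_fasta) if cfg.known_fasta else SequenceStore()
            seqs = SequenceStore()
            for t in assembled:
                seqs[t.transcript_id] = extract_transcript_sequence(t, genome)
            design = SampleDesign()
            if cfg.expression_tsv:
                expression = fio.read_expression_table(cfg.expression_tsv, design)
            elif cfg.counts_tsv:
                from .expression import compute_fpkm

                counts = pd.read_csv(cfg.counts_tsv, sep="\t", index_col=0)
                lengths = pd.read_csv(
                    cfg.lengths_tsv, sep="\t", index_col=0
                ).iloc[:, 0].to_dict()
                expression = ExpressionTable(
                    compute_fpkm(counts, lengths), design, kind="mixed"
                )
            else:
                raise FolliscanError("no expression input configured")
            terms = fio.read_term_annotation(cfg.terms_tsv) if cfg.terms_tsv else {}
        verdicts = (
            fio.read_verdict_table(cfg.verdicts_tsv) if cfg.verdicts_tsv else None
        )

        stage = "identify"
        cascade = filter_candidates(
            assembled, reference, seqs, known, verdicts,
            min_length=cfg.min_length, max_orf=cfg.max_orf,
        )
        contexts, ctx_counts = context_counts(cascade.lncrnas, reference)

        stage = "express"
        lnc_ids = [i for i in cascade.lncrnas.transcript_ids
                   if i in expression.values.index]
        lnc_expr = ExpressionTable(
            expression.values.loc[lnc_ids], expression.design, kind="lncRNA"
        )
        gene_expr, tx2gene = _gene_level_expression(expression, cascade.mrnas, reference)
        de_kw = dict(padj_threshold=cfg.padj_de, lfc_threshold=cfg.lfc_min,
                     pseudocount=cfg.pseudocount)
        lnc_de = run_all_comparisons(lnc_expr, **de_kw)
        mrna_de = run_all_comparisons(gene_expr, **de_kw)
        venn = venn_stage_specific(lnc_de)

        de_lnc_ids = sorted(set().union(*(r.de_features for r in lnc_de)))
        dendrogram = clusters = None
        if len(de_lnc_ids) >= 2:
            de_tab = lnc_expr.subset(de_lnc_ids)
            dendrogram = hierarchical_cluster_samples(de_tab)
            k = cfg.k
            if len(de_lnc_ids) < k:
                k = max(2, len(de_lnc_ids) // 2)
                logger.warning(
                    "only %d DE lncRNAs; clustering with k=%d instead of %d",
                    len(de_lnc_ids), k, cfg.k,
                )
            if len(de_lnc_ids) >= 2:
                clusters = kmeans_patterns(
                    de_tab, k=k, seed=cfg.seed, tau_fraction=cfg.tau_fraction
                )

        stage = "targets"
        coding_ref = reference.of_biotype(BIOTYPE_PROTEIN_CODING)
        cis_cand = cis_candidates(cascade.lncrnas, coding_ref, window=cfg.cis_window)
        cis_cand = [
            p for p in cis_cand
            if p.lncrna_id in lnc_expr.values.index
            and p.gene_id in gene_expr.values.index
        ]
        cis = correlate(cis_cand, lnc_expr, gene_expr, padj_threshold=cfg.corr_padj)
        gene_seqs = {}
        for t in coding_ref:
            if t.gene_id not in gene_seqs:
                gene_seqs[t.gene_id] = extract_transcript_sequence(t, genome)
        lnc_for_trans = cascade.lncrnas.subset(lnc_ids)
        trans = trans_targets(
            lnc_for_trans, coding_ref, seqs, gene_seqs, lnc_expr, gene_expr,
            s_min=cfg.s_min, padj_threshold=cfg.corr_padj, cis_pairs=cis_cand,
        )

        stage = "enrich"
        target_genes = sorted({p.gene_id for p in cis} | {p.gene_id for p in trans})
        enrichment = []
        overlaps = []
        if terms:
            universe = sorted(set().union(*terms.values()))
            enrichment = enrich(target_genes, terms, universe)
        de_mrna_genes = sorted(set().union(*(r.de_features for r in mrna_de)))
        overlaps = overlap_analysis(
            {"targets_vs_de_mrnas": target_genes},
            {"targets_vs_de_mrnas": de_mrna_genes},
        )
    except FolliscanError as exc:
        raise FolliscanError(f"pipeline stage '{stage}' failed: {exc}") from exc

    # --- report -------------------------------------------------------------
    rejected: Dict[str, int] = {}
    for trail in cascade.trails.values():
        crit = trail.rejected_at
        if crit is not None:
            rejected[crit] = rejected.get(crit, 0) + 1
    report = RunReport(
        thresholds={
            "min_length": cfg.min_length, "max_orf": cfg.max_orf,
            "bidirectional_dist": cfg.bidirectional_dist,
            "cis_window": cfg.cis_window, "padj_de": cfg.padj_de,
            "lfc_min": cfg.lfc_min, "corr_padj": cfg.corr_padj,
            "enrich_p": cfg.enrich_p, "k": cfg.k, "s_min": cfg.s_min,
            "pseudocount": cfg.pseudocount, "tau_fraction": cfg.tau_fraction,
        },
        n_assembled=len(assembled),
        rejected_per_criterion=rejected,
        n_lncrna_known=len(cascade.known_ids),
        n_lncrna_novel=len(cascade.novel_ids),
        n_mrna=len(cascade.mrnas),
        context_category_counts=ctx_counts,
    )
    for kind, results in (("lncRNA", lnc_de), ("mRNA", mrna_de)):
        report.de_counts[kind] = {r.label: len(r.de_features) for r in results}
        report.de_up_down[kind] = {r.label: (r.n_up, r.n_down) for r in results}
    report.venn_stage_specific = {k: len(v) for k, v in venn.stage_specific.items()}
    if clusters is not None:
        report.cluster_sizes = clusters.cluster_sizes()
        report.cluster_pattern_groups = clusters.pattern_groups
    report.n_cis_targets = len(cis)
    report.n_trans_targets = len(trans)
    report.n_enriched_terms = sum(1 for r in enrichment if r.P < cfg.enrich_p)
    report.overlap_sizes = {o.category: o.size for o in overlaps}
    report.check_invariants()

    result = PipelineResult(
        report=report, cascade=cascade, contexts=contexts, lnc_de=lnc_de,
        mrna_de=mrna_de, venn=venn, dendrogram=dendrogram, clusters=clusters,
        cis=cis, trans=trans, enrichment=enrichment, overlaps=overlaps,
    )
    if outdir is not None:
        write_artifacts(result, outdir)
    return result


def write_artifacts(result: PipelineResult, outdir) -> None:
    """Write every stage artifact as deterministic text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fio.write_gtf(result.cascade.lncrnas, outdir / "lncrna.gtf")
    fio.write_gtf(result.cascade.mrnas, outdir / "mrna.gtf")

    trail_rows = []
    for tid in sorted(result.cascade.trails):
        trail = result.cascade.trails[tid]
        for criterion, passed, reason in trail.verdicts:
            trail_rows.append(
                {"transcript_id": tid, "criterion": criterion,
                 "passed": passed, "reason": reason}
            )
    pd.DataFrame(trail_rows).to_csv(outdir / "filter_trails.tsv", sep="\t", index=False)

    ctx_rows = [
        {"transcript_id": tid, "category": c.category,
         "partner_gene": c.partner_gene or "", "distance": c.distance}
        for tid, c in sorted(result.contexts.items())
    ]
    pd.DataFrame(ctx_rows).to_csv(outdir / "context.tsv", sep="\t", index=False)

    for kind, results in (("lncrna", result.lnc_de), ("mrna", result.mrna_de)):
        for r in results:
            r.table.to_csv(
                outdir / f"de_{kind}_{r.label}.tsv", sep="\t",
                index_label="feature_id", float_format="%.6g",
            )

    venn_rows = [
        {"membership": "".join("1" if b else "0" for b in key), "count": n}
        for key, n in sorted(result.venn.regions.items())
    ]
    pd.DataFrame(venn_rows).to_csv(outdir / "venn_regions.tsv", sep="\t", index=False)

    if result.clusters is not None:
        cl = result.clusters
        df = cl.assignments.to_frame()
        df["pattern_group"] = [
            cl.pattern_groups[int(c)] for c in cl.assignments
        ]
        df.to_csv(outdir / "clusters.tsv", sep="\t", index_label="feature_id")

    target_pairs_frame(result.cis + result.trans).to_csv(
        outdir / "targets.tsv", sep="\t", index=False, float_format="%.6g"
    )

    enr_rows = [
        {"term": r.term, "N": r.N, "n": r.n, "M": r.M, "m": r.m,
         "P": r.P, "padj": r.padj, "significant": r.significant}
        for r in result.enrichment
    ]
    pd.DataFrame(enr_rows).to_csv(
        outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g"
    )

    ov_rows = [
        {"category": o.category, "n_targets": len(o.lnc_targets),
         "n_de_mrnas": len(o.de_mrnas), "n_overlap": o.size,
         "overlap_genes": ",".join(sorted(o.intersection))}
        for o in result.overlaps
    ]
    pd.DataFrame(ov_rows).to_csv(outdir / "overlap.tsv", sep="\t", index=False)

    with open(outdir / "report.json", "w") as fh:
        fh.write(result.report.to_json())
        fh.write("\n")


def plot_heatmap(dendrogram: SampleDendrogram, path) -> None:
    """Sample-clustered log2(FPKM+1) heat map with the dendrogram on top."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster import hierarchy

    fig, (ax_d, ax_h) = plt.subplots(
        2, 1, figsize=(8, 8), height_ratios=[1, 3], constrained_layout=True
    )
    hierarchy.dendrogram(
        dendrogram.linkage, labels=dendrogram.labels, ax=ax_d, color_threshold=0
    )
    ax_d.set_ylabel("distance")
    mat = dendrogram.matrix
    im = ax_h.imshow(mat.values, aspect="auto", cmap="RdYlGn_r")
    ax_h.set_xticks(range(len(mat.columns)), mat.columns, rotation=90, fontsize=6)
    ax_h.set_yticks([])
    fig.colorbar(im, ax=ax_h, label="log2(FPKM+1)")
    fig.savefig(path, dpi=120)
    plt.close(fig)
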