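"""ORF finding, class codes, context classification and the cascade."""

import numpy as np
import pytest

from folliscan.core import (
    AnnotationSet,
    BIOTYPE_OTHER_NCRNA,
    BIOTYPE_PROTEIN_CODING,
    GenomicInterval,
    SequenceStore,
    TranscriptModel,
)
from folliscan.identify import (
    PredictorVerdict,
    assign_class_code,
    builtin_coding_potential,
    classify_genomic_context,
    filter_candidates,
    find_longest_complete_orf,
    match_known_lncrnas,
)

from _instances import as_tuples, random_reference, random_transcript
from _oracles import classcode_per_base, context_per_base, orf_bruteforce


def _iv(start, end, strand="+"):
    return GenomicInterval("chr1", start, end, strand)


def _tx(tid, pairs, strand="+", biotype="unknown", gene=None):
    return TranscriptModel(
        tid, gene or f"g_{tid}", [_iv(s, e, strand) for s, e in pairs], biotype
    )


class TestOrfFinder:
    def test_minimal_complete_orf(self):
        orf = find_longest_complete_orf("ATGAAATAG")
        assert orf.complete and orf.length == 9 and orf.start == 0

    def test_no_start_codon(self):
        orf = find_longest_complete_orf("CCCCCC")
        assert not orf.complete and orf.length == 0

    def test_start_without_stop_is_incomplete(self):
        assert not find_longest_complete_orf("ATGAAAAAA").complete

    def test_codons_with_n_are_neither_start_nor_stop(self):
        # ATN cannot open an ORF; TNA cannot close one
        assert not find_longest_complete_orf("ATNAAATAG").complete
        assert not find_longest_complete_orf("ATGAAATNA").complete

    def test_matches_exhaustive_pair_enumeration(self):
        rng = np.random.default_rng(42)
        alphabet = np.array(list("ACGTN"))
        for _ in range(500):
            n = int(rng.integers(5, 150))
            seq = "".join(rng.choice(alphabet, size=n, p=[0.24] * 4 + [0.04]))
            assert find_longest_complete_orf(seq).length == orf_bruteforce(seq)


class TestBuiltinCodingPotential:
    def test_orf_fraction_score(self):
        seq = "ATG" + "GCT" * 98 + "TAA" + "C" * 100  # 300-nt ORF in 400 nt
        v = builtin_coding_potential(seq)
        assert v.score == pytest.approx(300 / 400 - 0.35)
        assert v.call == "coding"

    def test_no_orf_is_noncoding(self):
        v = builtin_coding_potential("CCCCCCCCCC")
        assert v.score == pytest.approx(-0.35) and v.call == "noncoding"

    def test_agrees_with_planted_roles(self, bundle):
        """>= 95% agreement with planted coding/noncoding ground truth."""
        hits = total = 0
        for row in bundle.truth.itertuples():
            if row.planted_role not in ("protein_coding", "lncRNA", "known_lncRNA"):
                continue
            call = builtin_coding_potential(
                bundle.transcript_seqs[row.transcript_id]
            ).call
            want = "coding" if row.planted_role == "protein_coding" else "noncoding"
            hits += call == want
            total += 1
        assert hits / total >= 0.95


class TestPredictorVerdict:
    def test_score_rule_sign_convention(self):
        assert PredictorVerdict("cnci", -0.5).call == "noncoding"
        assert PredictorVerdict("cnci", 0.0).call == "coding"

    def test_evalue_rule_small_is_coding(self):
        assert PredictorVerdict("pfam", 1e-6, rule="E<0.001").call == "coding"
        assert PredictorVerdict("pfam", 0.5, rule="E<0.001").call == "noncoding"


class TestClassCode:
    def test_intergenic_is_u(self):
        ref = AnnotationSet([_tx("r", [(0, 100), (200, 300)], biotype="protein_coding")])
        assert assign_class_code(_tx("t", [(20000, 20100), (20200, 20300)]), ref) == "u"

    def test_identical_intron_chain_is_equals(self):
        ref = AnnotationSet([_tx("r", [(0, 100), (200, 300)])])
        assert assign_class_code(_tx("t", [(10, 100), (200, 290)]), ref) == "="

    def test_antisense_exon_overlap_is_x(self):
        ref = AnnotationSet([_tx("r", [(0, 100), (200, 300)], strand="+")])
        assert assign_class_code(_tx("t", [(50, 120), (150, 180)], strand="-"), ref) == "x"

    def test_same_strand_intron_containment_is_i(self):
        ref = AnnotationSet([_tx("r", [(0, 100), (500, 600)])])
        assert assign_class_code(_tx("t", [(150, 250), (300, 400)]), ref) == "i"

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(500):
            ref = random_reference(rng, n=int(rng.integers(1, 6)))
            t = random_transcript(rng, "query")
            got = assign_class_code(t, ref)
            want = classcode_per_base(
                t.strand, [(e.start, e.end) for e in t.exons], as_tuples(ref)
            )
            assert got == want


class TestGenomicContext:
    def _gene(self, pairs, strand="+"):
        return _tx("r", pairs, strand=strand, biotype="protein_coding", gene="G1")

    def test_divergent_pair_within_1kb_is_bidirectional(self):
        # gene on + starting at 5000; lncRNA on - ending at 4201 -> TSS gap 800
        ref = AnnotationSet([self._gene([(5000, 6000), (7000, 8000)])])
        lnc = _tx("l", [(3500, 3800), (3900, 4201)], strand="-")
        ctx = classify_genomic_context(lnc, ref)
        assert ctx.category == "bidirectional" and ctx.distance == 800

    def test_distance_exactly_1000_is_not_bidirectional(self):
        ref = AnnotationSet([self._gene([(5000, 6000), (7000, 8000)])])
        lnc = _tx("l", [(3500, 3800), (3900, 4001)], strand="-")
        assert classify_genomic_context(lnc, ref).category == "intergenic"

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(500):
            ref = random_reference(rng, n=int(rng.integers(1, 6)))
            t = random_transcript(rng, "query")
            got = classify_genomic_context(t, ref).category
            want = context_per_base(
                t.strand, [(e.start, e.end) for e in t.exons], as_tuples(ref)
            )
            assert got == want


class TestKnownMatching:
    def test_exact_match_is_known(self):
        known = SequenceStore({"k1": "ACGTACGTAA"})
        assert match_known_lncrnas("ACGTACGTAA", known) == "known"

    def test_single_mismatch_is_novel(self):
        known = SequenceStore({"k1": "ACGTACGTAA"})
        assert match_known_lncrnas("ACGTACGTAC", known) == "novel"

    def test_exact_substring_is_known(self):
        rng = np.random.default_rng(3)
        db = "".join(np.random.default_rng(4).choice(list("ACGT"), size=300))
        for _ in range(50):
            i = int(rng.integers(0, 200))
            j = int(rng.integers(i + 20, 300))
            assert match_known_lncrnas(db[i:j], SequenceStore({"k": db})) == "known"


class TestCascade:
    def _setup(self):
        ref = AnnotationSet(
            [_tx("r1", [(50_000, 50_100), (50_200, 50_300)], biotype="protein_coding")]
        )
        return ref

    def test_short_two_exon_rejected_at_criterion_one(self):
        ref = self._setup()
        t = _tx("t", [(0, 80), (120, 190)])  # 150 nt, two exons
        seqs = SequenceStore({"t": "A" * 150})
        res = filter_candidates(AnnotationSet([t]), ref, seqs)
        assert res.trails["t"].rejected_at == "length_exon"

    def test_passing_candidate_accepted_novel(self):
        ref = self._setup()
        t = _tx("t", [(0, 125), (175, 300)])  # 250 nt, far from genes -> "u"
        seq = "C" * 250
        res = filter_candidates(AnnotationSet([t]), ref, SequenceStore({"t": seq}))
        trail = res.trails["t"]
        assert trail.accepted and trail.novelty == "novel"
        assert "t" in res.lncrnas

    def test_any_coding_verdict_rejects_at_criterion_six(self):
        ref = self._setup()
        t = _tx("t", [(0, 125), (175, 300)])
        seqs = SequenceStore({"t": "C" * 250})
        verdicts = {
            "cnci_like": {"t": PredictorVerdict("cnci_like", score=1.5)},
            "cpc_like": {"t": PredictorVerdict("cpc_like", score=-1.0)},
        }
        res = filter_candidates(AnnotationSet([t]), ref, seqs, verdicts=verdicts)
        trail = res.trails["t"]
        assert trail.rejected_at == "coding_potential"
        assert "cnci_like" in trail.verdicts[-1][2]

    def test_other_ncrna_biotype_rejected(self):
        ref = self._setup()
        t = _tx("t", [(0, 125), (175, 300)], biotype=BIOTYPE_OTHER_NCRNA)
        res = filter_candidates(AnnotationSet([t]), ref, SequenceStore({"t": "C" * 250}))
        assert res.trails["t"].rejected_at == "biotype_exclusion"

    def test_missing_sequence_rejected_with_reason(self):
        ref = self._setup()
        t = _tx("t", [(0, 125), (175, 300)])
        res = filter_candidates(AnnotationSet([t]), ref, SequenceStore())
        assert res.trails["t"].rejected_at == "length_exon"
        assert "no sequence" in res.trails["t"].verdicts[0][2]

    def test_cascade_monotonicity(self, bundle):
        """Relaxing any criterion never shrinks the accepted set."""
        base = filter_candidates(
            bundle.assembled, bundle.reference, bundle.transcript_seqs, bundle.known
        )
        accepted = set(base.lncrnas.transcript_ids)
        relaxed = [
            dict(min_length=1),
            dict(max_orf=10**9),
            dict(use_builtin_predictor=False),
        ]
        for kw in relaxed:
            res = filter_candidates(
                bundle.assembled, bundle.reference, bundle.transcript_seqs,
                bundle.known, **kw,
            )
            assert accepted <= set(res.lncrnas.transcript_ids)

    def test_mrna_set_is_reference_identical_transcripts(self, bundle, cascade):
        assert len(cascade.mrnas) == bundle.config.n_coding_genes
        assert all(t.transcript_id.startswith("TCONS_") for t in cascade.mrnas)


class TestContextPartition:
    def test_every_accepted_lncrna_gets_one_category(self, bundle, cascade):
        from folliscan.identify import context_counts

        assignments, counts = context_counts(cascade.lncrnas, bundle.reference)
        assert len(assignments) == len(cascade.lncrnas)
        assert sum(counts.values()) == len(cascade.lncrnas)
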