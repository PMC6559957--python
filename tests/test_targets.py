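"""cis proximity scan, correlation gate and trans similarity screen."""

import numpy as np
import pandas as pd
import pytest

from folliscan.core import (
    AnnotationSet,
    FolliscanError,
    GenomicInterval,
    SampleDesign,
    SequenceStore,
    TranscriptModel,
)
from folliscan.expression import ExpressionTable
from folliscan.targets import (
    TargetPair,
    cis_candidates,
    correlate,
    trans_similarity,
    trans_targets,
)

from _oracles import cis_bruteforce, sw_gotoh

DESIGN = SampleDesign()


def _tx(tid, start, end, strand="+", gene=None, chrom="chr1", biotype="protein_coding"):
    return TranscriptModel(
        tid, gene or f"g_{tid}",
        [GenomicInterval(chrom, start, end, strand)], biotype,
    )


def _expr(rows: dict) -> ExpressionTable:
    return ExpressionTable(
        pd.DataFrame(rows, index=DESIGN.samples).T, DESIGN
    )


class TestCisCandidates:
    def test_gap_9999_included_10001_excluded(self):
        lnc = AnnotationSet([_tx("l", 0, 1000, biotype="unknown")])
        genes = AnnotationSet([
            _tx("near.t", 10_999, 12_000, gene="NEAR"),
            _tx("far.t", 11_001, 12_000, gene="FAR"),
        ])
        pairs = cis_candidates(lnc, AnnotationSet([genes.get("near.t")]))
        assert [(p.gene_id, p.distance) for p in pairs] == [("NEAR", 9999)]
        assert cis_candidates(lnc, AnnotationSet([genes.get("far.t")])) == []

    def test_overlap_is_distance_zero(self):
        lnc = AnnotationSet([_tx("l", 500, 1500, biotype="unknown")])
        genes = AnnotationSet([_tx("g.t", 1000, 3000, gene="G")])
        (pair,) = cis_candidates(lnc, genes)
        assert pair.distance == 0

    def test_matches_all_pairs_bruteforce(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            lncs, genes = {}, {}
            lnc_models, gene_models = [], []
            for i in range(int(rng.integers(1, 8))):
                chrom = f"chr{int(rng.integers(1, 3))}"
                s = int(rng.integers(0, 60_000))
                e = s + int(rng.integers(100, 2000))
                lncs[f"l{i}"] = (chrom, s, e)
                lnc_models.append(_tx(f"l{i}", s, e, chrom=chrom, biotype="unknown",
                                      gene=f"xl{i}"))
            for i in range(int(rng.integers(1, 8))):
                chrom = f"chr{int(rng.integers(1, 3))}"
                s = int(rng.integers(0, 60_000))
                e = s + int(rng.integers(100, 4000))
                genes[f"G{i}"] = (chrom, s, e)
                gene_models.append(_tx(f"G{i}.t", s, e, chrom=chrom, gene=f"G{i}"))
            got = {
                (p.lncrna_id, p.gene_id, p.distance)
                for p in cis_candidates(AnnotationSet(lnc_models),
                                        AnnotationSet(gene_models))
            }
            assert got == cis_bruteforce(lncs, genes)


class TestCorrelationGate:
    def test_identical_profiles_r_one(self):
        x = np.linspace(1, 100, 18)
        le = _expr({"l": x})
        ge = _expr({"G": x})
        (pair,) = correlate([TargetPair("l", "G", "cis", distance=0)], le, ge,
                            keep_all=True)
        assert pair.r == pytest.approx(1.0, abs=1e-9)
        assert pair.p < 1e-50

    def test_negated_profile_r_minus_one(self):
        x = np.linspace(1, 9, 18)
        y = x.mean() * 2 - x  # reflection about the mean, still positive
        le = _expr({"l": 2**x - 1})
        ge = _expr({"G": 2**y - 1})
        (pair,) = correlate([TargetPair("l", "G", "cis", distance=0)], le, ge,
                            keep_all=True)
        assert pair.r == pytest.approx(-1.0)

    def test_padj_at_least_p(self):
        rng = np.random.default_rng(0)
        le = _expr({f"l{i}": rng.uniform(1, 50, 18) for i in range(10)})
        ge = _expr({f"G{i}": rng.uniform(1, 50, 18) for i in range(10)})
        pairs = [TargetPair(f"l{i}", f"G{i}", "cis", distance=0) for i in range(10)]
        for p in correlate(pairs, le, ge, keep_all=True):
            assert p.padj >= p.p - 1e-15

    def test_zero_variance_pair_dropped(self):
        le = _expr({"l": np.full(18, 7.0)})
        ge = _expr({"G": np.linspace(1, 50, 18)})
        assert correlate([TargetPair("l", "G", "cis", distance=0)], le, ge,
                         keep_all=True) == []

    def test_planted_cis_pairs_recovered(self, bundle, cascade):
        """>= 90% of planted lncRNA-neighbour pairs pass the gate."""
        from folliscan.core import BIOTYPE_PROTEIN_CODING

        coding = bundle.reference.of_biotype(BIOTYPE_PROTEIN_CODING)
        cand = cis_candidates(cascade.lncrnas, coding)
        expr = bundle.expression
        lnc_tab = ExpressionTable(
            expr.values.loc[[p for p in cascade.lncrnas.transcript_ids]],
            bundle.design,
        )
        gene_ids = sorted({p.gene_id for p in cand})
        gene_tab = ExpressionTable(expr.values.loc[gene_ids], bundle.design)
        kept = {(p.lncrna_id, p.gene_id) for p in correlate(cand, lnc_tab, gene_tab)}
        planted = bundle.truth[bundle.truth.planted_cis_partner != ""]
        recovered = sum(
            (r.transcript_id, r.planted_cis_partner) in kept
            for r in planted.itertuples()
        )
        assert recovered / len(planted) >= 0.90

    def test_label_permutation_destroys_recovery(self, bundle, cascade):
        """Permuting one side's samples kills >= 95% of planted recoveries."""
        from folliscan.core import BIOTYPE_PROTEIN_CODING

        coding = bundle.reference.of_biotype(BIOTYPE_PROTEIN_CODING)
        cand = cis_candidates(cascade.lncrnas, coding)
        expr = bundle.expression
        lnc_tab = ExpressionTable(
            expr.values.loc[[p for p in cascade.lncrnas.transcript_ids]],
            bundle.design,
        )
        gene_ids = sorted({p.gene_id for p in cand})
        rng = np.random.default_rng(13)
        shuffled = expr.values.loc[gene_ids].copy()
        for gid in gene_ids:  # standard permutation null: per-feature shuffle
            shuffled.loc[gid] = shuffled.loc[gid].values[rng.permutation(18)]
        gene_tab = ExpressionTable(shuffled, bundle.design)
        kept = {(p.lncrna_id, p.gene_id) for p in correlate(cand, lnc_tab, gene_tab)}
        planted = bundle.truth[bundle.truth.planted_cis_partner != ""]
        surviving = sum(
            (r.transcript_id, r.planted_cis_partner) in kept
            for r in planted.itertuples()
        )
        assert surviving / len(planted) <= 0.05


class TestTransSimilarity:
    def test_identical_hundred_mers_score_100(self):
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), size=100))
        assert trans_similarity(seq, seq) == 100.0

    def test_disjoint_homopolymers_score_below_threshold(self):
        assert trans_similarity("A" * 80, "C" * 80) < 40.0

    def test_reverse_complement_detected(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), size=60))
        from folliscan.core import reverse_complement

        assert trans_similarity(seq, reverse_complement(seq)) == 60.0

    def test_all_n_sequence_scores_zero(self):
        assert trans_similarity("N" * 50, "ACGT" * 20) == 0.0

    def test_matches_gotoh_dp_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(200):
            n1 = int(rng.integers(10, 70))
            n2 = int(rng.integers(10, 70))
            a = "".join(rng.choice(list("ACGTN"), size=n1, p=[0.24] * 4 + [0.04]))
            b = "".join(rng.choice(list("ACGTN"), size=n2, p=[0.24] * 4 + [0.04]))
            from folliscan.core import reverse_complement

            want = max(0.0, sw_gotoh(a, b), sw_gotoh(a, reverse_complement(b)))
            assert trans_similarity(a, b) == pytest.approx(want)


class TestTransTargets:
    def test_planted_trans_pair_recovered(self, bundle, cascade):
        from folliscan.core import BIOTYPE_PROTEIN_CODING, extract_transcript_sequence

        coding = bundle.reference.of_biotype(BIOTYPE_PROTEIN_CODING)
        expr = bundle.expression
        lnc_ids = cascade.lncrnas.transcript_ids
        lnc_tab = ExpressionTable(expr.values.loc[lnc_ids], bundle.design)
        gene_ids = sorted({t.gene_id for t in coding})
        gene_tab = ExpressionTable(expr.values.loc[gene_ids], bundle.design)
        gene_seqs = {
            t.gene_id: extract_transcript_sequence(t, bundle.genome) for t in coding
        }
        pairs = trans_targets(
            cascade.lncrnas, coding, bundle.transcript_seqs, gene_seqs,
            lnc_tab, gene_tab,
        )
        planted = bundle.truth[bundle.truth.planted_trans_partner != ""]
        got = {(p.lncrna_id, p.gene_id) for p in pairs}
        for r in planted.itertuples():
            assert (r.transcript_id, r.planted_trans_partner) in got
        # precedence: no trans pair may also be a cis candidate
        cis_keys = {
            (p.lncrna_id, p.gene_id) for p in cis_candidates(cascade.lncrnas, coding)
        }
        assert not (got & cis_keys)

    def test_similar_sequence_without_correlation_excluded(self):
        rng = np.random.default_rng(12)
        shared = "".join(rng.choice(list("ACGT"), size=60))
        lnc_seq = "".join(rng.choice(list("ACGT"), size=100)) + shared
        gene_seq = shared + "".join(rng.choice(list("ACGT"), size=200))
        lnc = AnnotationSet([_tx("l", 0, 160, biotype="unknown", gene="xl")])
        gene_model = _tx("G1.t", 50_000, 50_260, gene="G1")
        genes = AnnotationSet([gene_model])
        le = _expr({"l": rng.uniform(1, 50, 18)})
        ge = _expr({"G1": rng.uniform(1, 50, 18)})
        pairs = trans_targets(
            lnc, genes, SequenceStore({"l": lnc_seq}), {"G1": gene_seq}, le, ge,
        )
        assert pairs == []
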