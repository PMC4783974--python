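"""Tests for gene models, transcript placement and region classification."""

import numpy as np
import pytest
from Bio.Seq import Seq

from qtlsnp.annotation import (
    GeneModel,
    classify_snp_region,
    place_gene,
    scan_orthologs,
)


def _toy_gene_plus():
    """Plus-strand gene: 5'UTR 10 bp, CDS ATG GTT TAA in one exon plus a
    second exon, intron between, 3'UTR 8 bp.

    Layout (1-based):  exon1 = 11..32 (UTR5 11..20, CDS 21..29 = ATGGTTTAA
    starts mid-exon... simplified: CDS entirely in exon1), intron 33..52,
    exon2 = 53..60 (3'UTR).
    """
    utr5 = "TTTTTTTTTT"
    cds = "ATG" + "GTT" + "TAA"
    utr3_1, utr3_2 = "CCC", "CCCCCCCC"
    intron = "G" * 20
    seq = "A" * 10 + utr5 + cds + utr3_1 + intron + utr3_2 + "A" * 10
    genome = {"s": seq}
    gene = GeneModel(
        "g+",
        "s",
        "+",
        exons=[(11, 32), (53, 60)],
        cds=[(21, 29)],
    )
    return genome, gene


def _mirror_minus(genome, gene):
    """Reverse-complement the scaffold; the same gene on the minus strand."""
    seq = genome[gene.scaffold]
    L = len(seq)
    rc = str(Seq(seq).reverse_complement())
    flip = lambda iv: (L - iv[1] + 1, L - iv[0] + 1)
    mirrored = GeneModel(
        gene.gene_id + "_rc",
        gene.scaffold,
        "-",
        exons=[flip(iv) for iv in gene.exons],
        cds=[flip(iv) for iv in gene.cds],
    )
    return {gene.scaffold: rc}, mirrored, lambda pos: L - pos + 1


class TestClassifySnpRegion:
    def test_nonsynonymous_hand_translated(self):
        """GTT (Val) -> GCT (Ala) at the codon's middle base: 'V-A'."""
        genome, gene = _toy_gene_plus()
        # CDS offsets 3..5 hold GTT at genomic 24..26; middle base at 25.
        assert genome["s"][23:26] == "GTT"
        rc = classify_snp_region(25, "T", "C", gene, genome)
        assert rc.region == "exon_nonsynonymous"
        assert rc.aa_change == "V-A"
        assert rc.label == "Exon V-A"

    def test_synonymous_third_position(self):
        """GTT -> GTC keeps Val: synonymous."""
        genome, gene = _toy_gene_plus()
        rc = classify_snp_region(26, "T", "C", gene, genome)
        assert rc.region == "exon_synonymous"
        assert rc.aa_change is None

    def test_utr_and_intron(self):
        genome, gene = _toy_gene_plus()
        assert classify_snp_region(15, "T", "A", gene, genome).region == "five_prime_utr"
        assert classify_snp_region(30, "C", "A", gene, genome).region == "three_prime_utr"
        assert classify_snp_region(55, "C", "A", gene, genome).region == "three_prime_utr"
        assert classify_snp_region(40, "G", "A", gene, genome).region == "intron"

    def test_outside_gene_raises(self):
        genome, gene = _toy_gene_plus()
        with pytest.raises(ValueError):
            classify_snp_region(5, "A", "G", gene, genome)

    def test_strand_symmetry(self):
        """Classifying the reverse-complemented mirror gene gives identical
        region and amino-acid results at mirrored positions."""
        genome, gene = _toy_gene_plus()
        rc_genome, rc_gene, flip_pos = _mirror_minus(genome, gene)
        lo, hi = gene.span
        for pos in range(lo, hi + 1):
            ref = genome["s"][pos - 1]
            alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
            fwd = classify_snp_region(pos, ref, alt, gene, genome)
            m_pos = flip_pos(pos)
            m_ref = rc_genome["s"][m_pos - 1]
            m_alt = str(Seq(alt).complement())
            rev = classify_snp_region(m_pos, m_ref, m_alt, rc_gene, rc_genome)
            assert fwd == rev, pos

    def test_minus_strand_utr_orientation(self):
        """On the minus strand the 5'UTR is the higher-coordinate UTR."""
        genome, gene = _toy_gene_plus()
        _, rc_gene, _ = _mirror_minus(genome, gene)
        assert min(s for s, _ in rc_gene.utr5) > max(e for _, e in rc_gene.utr3)

    def test_region_partition_over_generated_genes(self, toy_world):
        """Every in-gene position of every generated gene maps to exactly
        one region; UTR/CDS/intron interval sets tile the gene span."""
        genome, genes, _ = toy_world
        for g in genes:
            lo, hi = g.span
            for pos in range(lo, hi + 1):
                ref = genome[g.scaffold][pos - 1]
                alt = "A" if ref != "A" else "G"
                rc = classify_snp_region(pos, ref, alt, g, genome)
                regions = {
                    "five_prime_utr": g.utr5,
                    "three_prime_utr": g.utr3,
                    "intron": g.introns,
                    "cds": g.cds,
                }
                memberships = [
                    name
                    for name, ivs in regions.items()
                    for s, e in ivs
                    if s <= pos <= e
                ]
                assert len(memberships) == 1, (g.gene_id, pos, memberships)
                expected = memberships[0]
                if expected == "cds":
                    assert rc.region in ("exon_synonymous", "exon_nonsynonymous")
                else:
                    assert rc.region == expected


class TestGeneModelInvariants:
    def test_cds_frame_enforced(self):
        with pytest.raises(ValueError):
            GeneModel("bad", "s", "+", exons=[(1, 100)], cds=[(10, 20)])

    def test_bad_strand(self):
        with pytest.raises(ValueError):
            GeneModel("bad", "s", ".", exons=[(1, 10)], cds=[])


class TestScanOrthologs:
    def test_self_match(self, toy_world):
        genome, _, _ = toy_world
        q = genome["Sm_1"][100:400]
        hits = scan_orthologs({"q": q}, genome, min_identity=0.9, min_aligned_len=50)
        best = [h for h in hits if h.best][0]
        assert best.ref_id == "Sm_1"
        assert best.identity == 1.0
        assert best.strand == "+"
        assert (best.r_start, best.r_end) == (101, 400)

    def test_reverse_complement_found(self, toy_world):
        genome, _, _ = toy_world
        q = str(Seq(genome["Sm_2"][200:500]).reverse_complement())
        hits = scan_orthologs({"q": q}, genome, min_identity=0.9, min_aligned_len=50)
        best = [h for h in hits if h.best][0]
        assert best.ref_id == "Sm_2"
        assert best.strand == "-"
        assert best.identity == 1.0
        assert (best.r_start, best.r_end) == (201, 500)

    def test_random_queries_find_nothing(self, toy_world):
        """A 90%-identical 100 bp match to random sequence is vanishingly
        unlikely; 20 random queries all come back empty."""
        genome, _, _ = toy_world
        rng = np.random.default_rng(123)
        for _ in range(20):
            q = "".join(rng.choice(list("ACGT"), size=150))
            hits = scan_orthologs(
                {"q": q}, genome, min_identity=0.9, min_aligned_len=100
            )
            assert hits == []

    def test_kmer_longer_than_sequence_rejected(self):
        with pytest.raises(ValueError):
            scan_orthologs({"q": "ACGT"}, {"r": "ACGTACGTACGT"}, k=11)


class TestPlaceGene:
    def test_planted_transcript_placed(self, toy_world):
        genome, _, _ = toy_world
        q = genome["Sm_3"][500:900]
        placement, reason = place_gene("t1", q, genome)
        assert reason == "ok"
        assert placement.scaffold == "Sm_3"
        assert (placement.start, placement.end) == (501, 900)

    def test_duplicated_transcript_non_unique(self, toy_world):
        genome, _, _ = toy_world
        seg = genome["Sm_1"][100:300]
        doctored = dict(genome)
        doctored["Sm_4"] = genome["Sm_4"][:1000] + seg + genome["Sm_4"][1000 + len(seg):]
        placement, reason = place_gene("t1", seg, doctored)
        assert placement is None
        assert reason == "non-unique"

    def test_absent_transcript_no_hit(self, toy_world):
        genome, _, _ = toy_world
        rng = np.random.default_rng(7)
        q = "".join(rng.choice(list("ACGT"), size=200))
        placement, reason = place_gene("t1", q, genome)
        assert placement is None
        assert reason == "no hit"

    def test_precomputed_hit_table_accepted(self, toy_world):
        from qtlsnp.annotation import OrthologHit

        genome, _, _ = toy_world
        hits = [
            OrthologHit("t1", "Sm_2", 300, 0.99, 300, "+", 1, 300, 11, 310)
        ]
        placement, reason = place_gene("t1", "N/A", genome, hits=hits)
        assert reason == "ok"
        assert placement.scaffold == "Sm_2"
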