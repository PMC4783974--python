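"""Tests for the synthetic-data generator."""

import json
from pathlib import Path

import numpy as np
import pytest

from qtlsnp.calling import call_sites, tally_site
from qtlsnp.sim import (
    SimConfig,
    SizingError,
    emit_fixtures,
    gen_genome,
    make_truth,
    sim_genotypes,
    sim_pileup,
)


class TestGenGenome:
    def test_no_genes(self):
        genome, genes = gen_genome(SimConfig(seed=3, n_genes=0))
        assert genes == []
        assert len(genome) == 4

    def test_deterministic_bytes(self, tmp_path):
        from qtlsnp import formats

        for sub in ("a", "b"):
            genome, genes = gen_genome(SimConfig(seed=1))
            formats.write_fasta(genome, tmp_path / f"{sub}.fasta")
            formats.write_gff3(genes, tmp_path / f"{sub}.gff3")
        assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()
        assert (tmp_path / "a.gff3").read_bytes() == (tmp_path / "b.gff3").read_bytes()

    def test_intron_count_via_independent_gff_reparse(self, tmp_path):
        """Every 3-exon gene re-read by gffutils has exactly 2 introns."""
        import gffutils

        from qtlsnp import formats

        cfg = SimConfig(seed=5, exons_per_gene=(3, 3))
        genome, genes = gen_genome(cfg)
        path = tmp_path / "genes.gff3"
        formats.write_gff3(genes, path)
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique"
        )
        n_genes = 0
        for gene in db.features_of_type("gene"):
            exons = sorted(
                db.children(gene, featuretype="exon"), key=lambda f: f.start
            )
            assert len(exons) == 3
            introns = [
                (a.end + 1, b.start - 1) for a, b in zip(exons, exons[1:])
            ]
            assert len(introns) == 2
            assert all(s <= e for s, e in introns)
            n_genes += 1
        assert n_genes == cfg.n_genes

    def test_cds_structure(self, toy_world):
        genome, genes, _ = toy_world
        stops = {"TAA", "TAG", "TGA"}
        strands = set()
        for g in genes:
            cds = g.cds_sequence(genome)
            assert cds.startswith("ATG")
            assert len(cds) % 3 == 0
            internal = [cds[i : i + 3] for i in range(0, len(cds) - 3, 3)]
            assert not (set(internal) & stops)
            assert cds[-3:] in stops
            strands.add(g.strand)
        assert strands == {"+", "-"}  # genes land on both strands

    def test_sizing_error(self):
        with pytest.raises(SizingError):
            gen_genome(SimConfig(seed=1, scaffold_length_bp=300, n_genes=8))


class TestSimPileup:
    def test_noise_free_full_alt(self, toy_world):
        genome, genes, _ = toy_world
        cfg = SimConfig(seed=11, pooled_allele_freq_range=(0.999999, 0.999999))
        truth = make_truth(genome, genes, cfg)
        planted = {(v.scaffold, v.pos): v for v in truth.variants}
        for site in sim_pileup(genome, truth, cfg, error_rate=0.0):
            v = planted.get((site.scaffold, site.pos))
            if v is not None and site.observations:
                assert all(tok == v.alt for tok, _ in site.observations)

    def test_planted_free_scaffold_noise_free(self):
        cfg = SimConfig(seed=2, n_genes=0, snp_density=0.0, n_scaffolds=1,
                        scaffold_length_bp=500)
        genome, genes = gen_genome(cfg)
        truth = make_truth(genome, genes, cfg)
        assert truth.variants == []
        for site in sim_pileup(genome, truth, cfg, error_rate=0.0):
            assert all(tok == site.ref for tok, _ in site.observations)

    def test_mean_alt_fraction_matches_planted_frequency(self):
        """At depth 50 and alt frequency 0.5 the mean alt fraction over many
        planted sites stays within the binomial sampling bound."""
        cfg = SimConfig(
            seed=4,
            n_scaffolds=1,
            scaffold_length_bp=20000,
            n_genes=0,
            snp_density=50.0,  # 1000 planted sites
            pooled_allele_freq_range=(0.5, 0.5),
            indel_fraction=0.0,
        )
        genome, genes = gen_genome(cfg)
        truth = make_truth(genome, genes, cfg)
        assert len(truth.variants) == 1000
        planted = {(v.scaffold, v.pos): v for v in truth.variants}
        fracs = []
        for site in sim_pileup(genome, truth, cfg, error_rate=0.0):
            v = planted.get((site.scaffold, site.pos))
            if v is None or not site.observations:
                continue
            n_alt = sum(1 for tok, _ in site.observations if tok == v.alt)
            fracs.append(n_alt / len(site.observations))
        assert abs(np.mean(fracs) - 0.5) < 0.05

    def test_depth_zero_sites_emitted(self):
        cfg = SimConfig(seed=6, n_scaffolds=1, scaffold_length_bp=200,
                        n_genes=0, snp_density=0.0, mean_depth=0.5)
        genome, genes = gen_genome(cfg)
        truth = make_truth(genome, genes, cfg)
        sites = list(sim_pileup(genome, truth, cfg))
        assert len(sites) == 200
        assert any(len(s.observations) == 0 for s in sites)


class TestSimGenotypes:
    def test_full_inbreeding_no_heterozygotes(self):
        for p in (0.2, 0.5, 0.8):
            g = sim_genotypes(p, f=1.0, n=500, seed=1)
            assert (g != 1).all()

    def test_p_zero_all_alternate_homozygotes(self):
        g = sim_genotypes(0.0, f=0.0, n=100, seed=2)
        assert (g == 2).all()

    def test_p_one_all_reference_homozygotes(self):
        g = sim_genotypes(1.0, f=0.0, n=100, seed=2)
        assert (g == 0).all()

    def test_fractions_match_closed_form(self):
        p, f, n = 0.3, 0.1, 100_000
        g = sim_genotypes(p, f, n, seed=7)
        expected = [
            p * p + f * p * (1 - p),
            2 * p * (1 - p) * (1 - f),
            (1 - p) ** 2 + f * p * (1 - p),
        ]
        for code, e in zip((0, 1, 2), expected):
            assert abs((g == code).mean() - e) < 0.01

    def test_heterozygote_excess_feasible(self):
        """Negative f down to the feasibility bound is accepted."""
        p = 0.5
        g = sim_genotypes(p, f=-1.0, n=2000, seed=3)  # bound: f >= -1 at p=0.5
        ho = (g == 1).mean()
        expected = 2 * p * (1 - p) * 2  # (1-f) = 2
        assert abs(ho - min(expected, 1.0)) < 0.05

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(ValueError):
            sim_genotypes(0.9, f=-0.5, n=10, seed=0)  # P(aa) < 0

    def test_missing_rate(self):
        g = sim_genotypes(0.5, 0.0, 50_000, missing_rate=0.1, seed=9)
        assert abs((g == -1).mean() - 0.1) < 0.01


@pytest.fixture(scope="module")
def bundle(tmp_path_factory):
    cfg = SimConfig(seed=21)
    out = tmp_path_factory.mktemp("fixtures")
    return cfg, emit_fixtures(cfg, out)


class TestEmitFixtures:
    def test_round_trip(self, bundle):
        from qtlsnp import formats

        cfg, b = bundle
        genome = formats.read_fasta(b["paths"]["genome"])
        assert genome == b["genome"]
        genes = formats.read_gff3(b["paths"]["gff3"])
        by_id = {g.gene_id: g for g in genes}
        for g in b["genes"]:
            r = by_id[g.gene_id]
            assert (r.scaffold, r.strand, r.exons, r.cds) == (
                g.scaffold,
                g.strand,
                g.exons,
                g.cds,
            )
        anchors = formats.read_anchor_tsv(b["paths"]["anchors"])
        assert anchors == b["anchors"]
        qtls = formats.read_qtl_tsv(b["paths"]["qtl"])
        assert qtls == b["qtls"]
        matrix = formats.read_genepop(b["paths"]["genepop"])
        assert matrix.loci == b["matrix"].loci
        assert (matrix.codes == b["matrix"].codes).all()

    def test_truth_conservation(self, bundle):
        cfg, b = bundle
        doc = json.loads(Path(b["paths"]["truth"]).read_text())
        assert len(doc["variants"]) == len(b["truth"].variants)
        n_snps = sum(1 for v in b["truth"].variants if v.is_snp)
        assert len(doc["pop_params"]) == n_snps
        assert len(b["matrix"].loci) == n_snps  # GENEPOP loci = pop_params

    def test_emit_deterministic(self, tmp_path):
        for sub in ("x", "y"):
            emit_fixtures(SimConfig(seed=8), tmp_path / sub)
        for name in ("genome.fasta", "genes.gff3", "pileup.tsv", "anchors.tsv",
                     "qtl.tsv", "genotypes.gen", "truth.json"):
            assert (tmp_path / "x" / name).read_bytes() == (
                tmp_path / "y" / name
            ).read_bytes(), name


def test_planted_variants_recoverable_noise_free(toy_world):
    """With zero error and ample depth, the caller recovers every planted
    variant whose pooled frequency clears the minor-allele-count filter."""
    genome, genes, _ = toy_world
    cfg = SimConfig(seed=11, pooled_allele_freq_range=(0.3, 0.5))
    truth = make_truth(genome, genes, cfg)
    calls = call_sites(sim_pileup(genome, truth, cfg, error_rate=0.0))
    called = {(c.scaffold, c.pos) for c in calls}
    planted = {(v.scaffold, v.pos) for v in truth.variants}
    assert planted <= called
    assert called <= planted  # and nothing else is called
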