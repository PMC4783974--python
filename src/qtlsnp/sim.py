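"""Synthetic fixtures with known ground truth for every pipeline stage.

Generates a toy draft genome (scaffolds with strand-aware multi-exon gene
models), plants biallelic variants with known pooled allele frequencies,
simulates noisy pileups over them (Poisson depth, Phred-scored bases with
quality-dependent error), simulates validation-population genotypes under
Wright's inbreeding model, and emits the whole bundle in the pipeline's
file dialects.  Everything is a pure function of the configuration seed.

The defaults emulate the study design this package targets: a pooled
discovery sample observed as site-level allele frequencies through an
RNA-seq pileup (the pool's individual structure is invisible to the
caller, so it is not modelled), ~1 SNP per 100 bp as typical for fish
transcriptomes, mean read depth 50, and a validation population of 34
diploids genotyped per selected locus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
from Bio.Seq import Seq

from .annotation import GeneModel, classify_snp_region
from .calling import PileupSite

__all__ = [
    "SimConfig",
    "PlantedVariant",
    "TruthSet",
    "gen_genome",
    "make_truth",
    "sim_pileup",
    "sim_genotypes",
    "emit_fixtures",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS and a + b + c != "ATG"
]
INDEL_TOKEN = "*"


class SizingError(ValueError):
    """Scaffolds too short to host the requested gene complement."""


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic-data generator."""

    seed: int = 0
    n_scaffolds: int = 4
    scaffold_length_bp: int = 2500
    n_genes: int = 8
    exons_per_gene: tuple[int, int] = (2, 4)
    utr_lengths_bp: tuple[int, int] = (60, 90)  # (5'UTR, 3'UTR)
    snp_density: float = 10.0  # SNPs per kb, ~1/100 bp as typical in fish
    pooled_allele_freq_range: tuple[float, float] = (0.1, 0.5)
    mean_depth: float = 50.0
    qual_profile: dict = field(
        default_factory=lambda: {40: 0.9, 12: 0.1}
    )  # Phred value -> mixture weight
    indel_fraction: float = 0.05  # planted non-SNP polymorphisms
    ts_fraction: float = 1.346 / 2.346  # transition fraction among planted SNPs
    pop_n: int = 34  # validation population size
    pop_f: float = 0.0  # inbreeding coefficient of the validation population
    missing_rate: float = 0.02

    def __post_init__(self) -> None:
        if min(self.n_scaffolds, self.scaffold_length_bp) <= 0:
            raise ValueError("scaffold counts/lengths must be positive")
        if self.n_genes < 0 or self.pop_n <= 0:
            raise ValueError("n_genes must be >= 0 and pop_n > 0")
        if not (1 <= self.exons_per_gene[0] <= self.exons_per_gene[1]):
            raise ValueError("exons_per_gene must be an increasing positive range")
        lo, hi = self.pooled_allele_freq_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("pooled_allele_freq_range must lie in [0, 1]")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if not -1 <= self.pop_f <= 1:
            raise ValueError("pop_f must be in [-1, 1]")
        if self.mean_depth < 0 or self.snp_density < 0:
            raise ValueError("mean_depth and snp_density must be non-negative")
        if not self.qual_profile or any(w < 0 for w in self.qual_profile.values()):
            raise ValueError("qual_profile must be non-empty with weights >= 0")
        if not (0 <= self.indel_fraction <= 1 and 0 <= self.ts_fraction <= 1):
            raise ValueError("indel_fraction and ts_fraction must be in [0, 1]")


@dataclass(frozen=True)
class PlantedVariant:
    scaffold: str
    pos: int  # 1-based
    ref: str
    alt: str  # single base, or the indel token for non-SNP polymorphisms
    alt_freq: float
    gene_id: Optional[str]
    region: Optional[str]  # region key when inside a gene and a SNP

    @property
    def is_snp(self) -> bool:
        return self.alt != INDEL_TOKEN


@dataclass
class TruthSet:
    """Planted variants plus per-locus validation-population parameters."""

    variants: list[PlantedVariant]
    pop_params: dict  # locus name -> (p_ref, f)

    def __post_init__(self) -> None:
        seen = set()
        for v in self.variants:
            key = (v.scaffold, v.pos)
            if key in seen:
                raise ValueError(f"duplicate planted position {key}")
            seen.add(key)
            if v.ref == v.alt:
                raise ValueError(f"ref == alt at {key}")
            if not 0 < v.alt_freq < 1:
                raise ValueError(f"alt_freq must be in (0, 1) at {key}")

    def locus_name(self, v: PlantedVariant) -> str:
        return f"{v.scaffold}:{v.pos}"


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _random_dna(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.choice(np.array(list("ACGT")), size=n)


def _build_gene(
    rng: np.random.Generator, cfg: SimConfig, gene_id: str
) -> tuple[str, list[tuple[int, int]], int, int]:
    """Pre-mRNA segment (transcription order) with exon layout.

    Returns (segment, exon segment-offset intervals 0-based half-open,
    5'UTR length, CDS length).
    """
    u5, u3 = cfg.utr_lengths_bp
    n_codons = int(rng.integers(30, 61))
    cds = "ATG" + "".join(rng.choice(SENSE_CODONS, size=n_codons)) + "TAA"
    mrna = (
        "".join(_random_dna(rng, u5)) + cds + "".join(_random_dna(rng, u3))
    )
    k = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    if k > 1:
        cuts = sorted(rng.choice(np.arange(1, len(mrna)), size=k - 1, replace=False))
    else:
        cuts = []
    bounds = [0] + [int(c) for c in cuts] + [len(mrna)]
    chunks = [(bounds[i], bounds[i + 1]) for i in range(k)]
    segment_parts = []
    exon_offsets = []
    off = 0
    for i, (a, b) in enumerate(chunks):
        exon_offsets.append((off, off + (b - a)))
        segment_parts.append(mrna[a:b])
        off += b - a
        if i < k - 1:
            ilen = int(rng.integers(40, 121))
            segment_parts.append("".join(_random_dna(rng, ilen)))
            off += ilen
    return "".join(segment_parts), exon_offsets, u5, len(cds)


def gen_genome(cfg: SimConfig) -> tuple[dict[str, str], list[GeneModel]]:
    """Random scaffolds hosting non-overlapping strand-aware gene models.

    Each gene has a 5'UTR, a CDS spread over >= 1 exon (starting ATG, no
    internal stop, length divisible by 3), a 3'UTR and introns between
    exons; genes land on both strands.  Raises ``SizingError`` when the
    configured scaffolds cannot host the requested genes.
    """
    rng = _rng(cfg, 0)
    scaffolds = {
        f"Sm_{i + 1}": "".join(_random_dna(rng, cfg.scaffold_length_bp))
        for i in range(cfg.n_scaffolds)
    }
    seqs = {name: list(seq) for name, seq in scaffolds.items()}
    cursors = {name: 50 for name in scaffolds}  # leading margin
    genes: list[GeneModel] = []
    names = list(scaffolds)
    for gi in range(cfg.n_genes):
        gene_id = f"gene_{gi + 1}"
        segment, exon_offs, u5, cds_len = _build_gene(rng, cfg, gene_id)
        strand = "+" if rng.random() < 0.5 else "-"
        scaf = names[gi % len(names)]
        start0 = cursors[scaf]  # 0-based genomic start of the segment
        L = len(segment)
        if start0 + L + 50 > cfg.scaffold_length_bp:
            raise SizingError(
                f"scaffold {scaf} (length {cfg.scaffold_length_bp}) too short "
                f"for gene {gene_id} of {L} bp at offset {start0}; increase "
                f"scaffold_length_bp or reduce n_genes"
            )
        cursors[scaf] = start0 + L + int(rng.integers(50, 150))

        placed = segment if strand == "+" else str(Seq(segment).reverse_complement())
        seqs[scaf][start0 : start0 + L] = list(placed)

        def to_genomic(t0: int, t1: int) -> tuple[int, int]:
            """Segment offsets [t0, t1) -> genomic 1-based inclusive."""
            if strand == "+":
                return (start0 + t0 + 1, start0 + t1)
            return (start0 + L - t1 + 1, start0 + L - t0)

        exons = [to_genomic(a, b) for a, b in exon_offs]
        # CDS occupies mRNA offsets [u5, u5 + cds_len); intersect per exon.
        cds_ivs = []
        moff = 0
        for (a, b), (t0, t1) in zip(
            [(0, b - a) for a, b in exon_offs], exon_offs
        ):
            chunk_len = t1 - t0
            m0, m1 = moff, moff + chunk_len
            lo, hi = max(m0, u5), min(m1, u5 + cds_len)
            if lo < hi:
                s0 = t0 + (lo - m0)
                cds_ivs.append(to_genomic(s0, s0 + (hi - lo)))
            moff = m1
        genes.append(
            GeneModel(
                gene_id=gene_id,
                scaffold=scaf,
                strand=strand,
                exons=exons,
                cds=cds_ivs,
                transcript_id=f"{gene_id}.t1",
            )
        )
    genome = {name: "".join(seqs[name]) for name in scaffolds}
    return genome, genes


def make_truth(
    genome: dict[str, str], genes: list[GeneModel], cfg: SimConfig
) -> TruthSet:
    """Plant biallelic variants at the configured density with known truth.

    A configurable fraction are non-SNP polymorphisms (indel-token alleles);
    in-gene SNPs carry their true region classification.  Per-locus
    validation-population parameters (reference-allele frequency, f) are
    attached for every planted SNP.
    """
    rng = _rng(cfg, 1)
    total_bp = sum(len(s) for s in genome.values())
    n_var = int(round(cfg.snp_density * total_bp / 1000.0))
    names = sorted(genome)
    lengths = np.array([len(genome[n]) for n in names])
    variants: list[PlantedVariant] = []
    used: set[tuple[str, int]] = set()
    lo, hi = cfg.pooled_allele_freq_range
    lo = max(lo, 1e-6)
    hi = min(hi, 1 - 1e-6)
    by_scaffold = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold, []).append(g)
    while len(variants) < n_var:
        si = int(rng.choice(len(names), p=lengths / lengths.sum()))
        scaf = names[si]
        pos = int(rng.integers(1, lengths[si] + 1))
        if (scaf, pos) in used:
            continue
        used.add((scaf, pos))
        ref = genome[scaf][pos - 1]
        is_indel = rng.random() < cfg.indel_fraction
        if is_indel:
            alt = INDEL_TOKEN
        elif rng.random() < cfg.ts_fraction:
            alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
        else:
            tvs = [b for b in "ACGT" if b != ref and frozenset((b, ref)) not in
                   ({frozenset("AG"), frozenset("CT")})]
            alt = str(rng.choice(tvs))
        af = float(rng.uniform(lo, hi))
        gene_id = region = None
        for g in by_scaffold.get(scaf, ()):
            if g.contains(pos):
                gene_id = g.gene_id
                if not is_indel:
                    region = classify_snp_region(pos, ref, alt, g, genome).region
                break
        variants.append(
            PlantedVariant(scaf, pos, ref, alt, af, gene_id, region)
        )
    variants.sort(key=lambda v: (v.scaffold, v.pos))
    pop_params = {
        f"{v.scaffold}:{v.pos}": (round(1.0 - v.alt_freq, 6), cfg.pop_f)
        for v in variants
        if v.is_snp
    }
    return TruthSet(variants=variants, pop_params=pop_params)


def sim_pileup(
    genome: dict[str, str],
    truth: TruthSet,
    cfg: SimConfig,
    error_rate: Optional[float] = None,
) -> Iterator[PileupSite]:
    """Simulate a pooled pileup over every genome position.

    Depth is Poisson(mean_depth) per site.  Each read base equals the
    planted alternate allele with probability equal to the pooled alternate
    frequency (reference otherwise), then is flipped to a random other base
    with probability 10^(-Q/10) for its drawn Phred quality Q (override the
    quality-derived error with ``error_rate``, e.g. 0 for noise-free
    pileups).  Depth-0 sites are emitted with empty observation lists.
    """
    for v in truth.variants:
        if v.scaffold not in genome or not 1 <= v.pos <= len(genome[v.scaffold]):
            raise ValueError(f"planted variant off genome: {v.scaffold}:{v.pos}")
    rng = _rng(cfg, 2)
    quals = np.array(sorted(cfg.qual_profile), dtype=int)
    weights = np.array([cfg.qual_profile[q] for q in quals], dtype=float)
    weights = weights / weights.sum()
    planted = {(v.scaffold, v.pos): v for v in truth.variants}
    other = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}
    other[INDEL_TOKEN] = list("ACGT")

    for scaf in sorted(genome):
        seq = genome[scaf]
        depths = rng.poisson(cfg.mean_depth, size=len(seq))
        for i, d in enumerate(depths):
            pos = i + 1
            ref = seq[i]
            if d == 0:
                yield PileupSite(scaf, pos, ref, ())
                continue
            q = rng.choice(quals, size=d, p=weights)
            v = planted.get((scaf, pos))
            if v is not None:
                is_alt = rng.random(d) < v.alt_freq
                bases = np.where(is_alt, v.alt, ref)
            else:
                bases = np.full(d, ref)
            err = (
                np.full(d, error_rate)
                if error_rate is not None
                else 10.0 ** (-q / 10.0)
            )
            flip = rng.random(d) < err
            obs = []
            for b, qq, fl in zip(bases, q, flip):
                b = str(b)
                if fl and b != INDEL_TOKEN:
                    b = other[b][int(rng.integers(3))]
                obs.append((b, int(qq)))
            yield PileupSite(scaf, pos, ref, tuple(obs))


def sim_genotypes(
    p: float,
    f: float,
    n: int,
    missing_rate: float = 0.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Diploid genotypes under Wright's inbreeding equilibrium.

    Draws n genotypes with P(AA) = p^2 + f p(1-p), P(Aa) = 2p(1-p)(1-f),
    P(aa) = (1-p)^2 + f p(1-p), where p is the frequency of allele A;
    returns codes 0 (AA), 1 (Aa), 2 (aa) with -1 for missing entries
    inserted at ``missing_rate``.  Negative f is allowed down to the
    feasibility bound (all three probabilities non-negative), modelling
    heterozygote excess.
    """
    if not 0 <= p <= 1:
        raise ValueError(f"allele frequency p={p} outside [0, 1]")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    probs = np.array(
        [
            p * p + f * p * (1 - p),
            2 * p * (1 - p) * (1 - f),
            (1 - p) ** 2 + f * p * (1 - p),
        ]
    )
    if (probs < -1e-12).any() or f > 1:
        raise ValueError(
            f"(p={p}, f={f}) gives negative genotype probabilities; "
            f"f must satisfy f >= -p/(1-p), f >= -(1-p)/p and f <= 1"
        )
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum()
    if rng is None:
        rng = np.random.default_rng(seed)
    g = rng.choice(np.array([0, 1, 2], dtype=np.int8), size=n, p=probs)
    if missing_rate > 0:
        g[rng.random(n) < missing_rate] = -1
    return g


def emit_fixtures(cfg: SimConfig, outdir) -> dict:
    """Generate and write the full cross-consistent fixture bundle.

    Writes genome FASTA, gene-model GFF3, pileup TSV, map-anchor TSV, QTL
    TSV, a GENEPOP genotype file for the validation population, and a truth
    JSON; returns the paths together with the in-memory objects.
    """
    import json
    from pathlib import Path

    from . import formats
    from .mapping import MapAnchor, QTLRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes = gen_genome(cfg)
    truth = make_truth(genome, genes, cfg)

    paths = {
        "genome": outdir / "genome.fasta",
        "gff3": outdir / "genes.gff3",
        "pileup": outdir / "pileup.tsv",
        "anchors": outdir / "anchors.tsv",
        "qtl": outdir / "qtl.tsv",
        "genepop": outdir / "genotypes.gen",
        "truth": outdir / "truth.json",
    }
    try:
        formats.write_fasta(genome, paths["genome"])
        formats.write_gff3(genes, paths["gff3"])
        formats.write_pileup_tsv(sim_pileup(genome, truth, cfg), paths["pileup"])

        # Map anchors: every scaffold but the last is anchored to its own LG
        # with two markers; the last stays unanchored to exercise the
        # synteny-inference path.
        rng = _rng(cfg, 4)
        anchors: list[MapAnchor] = []
        names = sorted(genome)
        anchored = names[:-1] if len(names) > 1 else names
        for li, scaf in enumerate(anchored):
            L = len(genome[scaf])
            for j, frac in enumerate((0.25, 0.75)):
                bp = max(1, int(L * frac))
                anchors.append(
                    MapAnchor(
                        marker=f"M_{scaf}_{j + 1}",
                        lg=li + 1,
                        cm=round(bp / 0.5e6, 4),
                        scaffold=scaf,
                        bp=bp,
                    )
                )
        qtls = []
        traits = ["BW", "L", "K"]
        for t, a in zip(traits, anchors[:3]):
            qtls.append(
                QTLRecord(
                    trait=t,
                    lg=a.lg,
                    marker=a.marker,
                    vpe=round(float(rng.uniform(5, 25)), 1),
                    ci_markers=(),
                )
            )
        if len(anchors) >= 2:  # one marker-less QTL resolved via CI markers
            qtls.append(
                QTLRecord(
                    trait="L",
                    lg=anchors[0].lg,
                    marker="nd",
                    vpe=None,
                    ci_markers=(anchors[0].marker, anchors[1].marker),
                )
            )
        formats.write_anchor_tsv(anchors, paths["anchors"])
        formats.write_qtl_tsv(qtls, paths["qtl"])

        # Validation-population genotypes for every planted SNP.
        grng = _rng(cfg, 3)
        loci = list(truth.pop_params)
        codes = np.full((cfg.pop_n, len(loci)), -1, dtype=np.int8)
        for j, locus in enumerate(loci):
            p_ref, f = truth.pop_params[locus]
            codes[:, j] = sim_genotypes(
                p_ref, f, cfg.pop_n, missing_rate=cfg.missing_rate, rng=grng
            )
        from .popgen import GenotypeMatrix

        matrix = GenotypeMatrix(
            loci,
            [f"ind_{i + 1}" for i in range(cfg.pop_n)],
            codes,
            alleles={
                f"{v.scaffold}:{v.pos}": (v.ref, v.alt)
                for v in truth.variants
                if v.is_snp
            },
        )
        formats.write_genepop(matrix, paths["genepop"], title="synthetic panel")

        truth_doc = {
            "config": {
                **{
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in vars(cfg).items()
                    if k != "qual_profile"
                },
                "qual_profile": {str(k): v for k, v in cfg.qual_profile.items()},
            },
            "variants": [
                {
                    "scaffold": v.scaffold,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "alt_freq": v.alt_freq,
                    "gene_id": v.gene_id,
                    "region": v.region,
                }
                for v in truth.variants
            ],
            "pop_params": {k: list(v) for k, v in truth.pop_params.items()},
        }
        paths["truth"].write_text(json.dumps(truth_doc, indent=1) + "\n")
    except OSError as exc:
        raise OSError(f"failed writing fixture under {outdir}: {exc}") from exc

    return {
        "paths": {k: str(v) for k, v in paths.items()},
        "genome": genome,
        "genes": genes,
        "truth": truth,
        "anchors": anchors,
        "qtls": qtls,
        "matrix": matrix,
    }
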