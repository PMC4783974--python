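"""End-to-end orchestration: simulate → call → annotate → colocalize →
select → popgen, with stage logging and machine-readable reports.

The pipeline is a pure function of (input files, configuration, seed):
re-running with the same configuration produces byte-identical outputs.
Each stage is also exposed as a standalone function over files so the CLI
subcommands can compose them through the TSV dialects in
:mod:`qtlsnp.formats`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import formats
from .annotation import GeneModel, GenePlacement, classify_snp_region
from .calling import call_sites, snps_per_gene, spectrum
from .mapping import anchor_scaffold, colocalize
from .popgen import summarize
from .selection import CandidateSNP, SelectionConfig, panel_region_breakdown, select_panel
from .sim import SimConfig, emit_fixtures

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "STAGE_EXIT_CODES"]

log = logging.getLogger("qtlsnp")

STAGE_EXIT_CODES = {
    "simulate": 10,
    "call": 11,
    "annotate": 12,
    "colocalize": 13,
    "select": 14,
    "popgen": 15,
    "report": 16,
}


class StageError(RuntimeError):
    def __init__(self, stage: str, msg: str) -> None:
        super().__init__(f"stage {stage!r} failed: {msg}")
        self.stage = stage
        self.exit_code = STAGE_EXIT_CODES.get(stage, 1)


@dataclass
class PipelineConfig:
    """All knobs of the stage chain, with the calling/selection defaults.

    ``simulate=True`` generates the inputs from :class:`SimConfig`;
    otherwise the input paths must point at existing files.
    """

    outdir: str = "qtlsnp_out"
    simulate: bool = True
    seed: int = 0
    # input paths (filled by the simulate stage when simulate=True)
    genome: Optional[str] = None
    gff3: Optional[str] = None
    pileup: Optional[str] = None
    anchors: Optional[str] = None
    qtl: Optional[str] = None
    genepop: Optional[str] = None
    # caller thresholds
    min_qual: int = 20
    min_depth: int = 10
    min_mac: int = 3
    # co-localization preference distance (bp)
    max_pref: int = 1_000_000
    # selection
    min_discovery_maf: float = 0.1
    min_flank_bp: int = 30
    # popgen
    alpha: float = 0.05
    ld_permutations: int = 1000
    # report rounding
    decimals: int = 3
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        if min(self.min_qual, self.min_depth, self.min_mac) < 0:
            raise ValueError("caller thresholds must be non-negative")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        sim_doc = doc.pop("sim", {})
        doc.update({k: v for k, v in overrides.items() if v is not None})
        if "seed" in doc and "seed" not in sim_doc:
            sim_doc["seed"] = doc["seed"]
        for key in ("exons_per_gene", "utr_lengths_bp", "pooled_allele_freq_range"):
            if key in sim_doc:
                sim_doc[key] = tuple(sim_doc[key])
        return cls(sim=SimConfig(**sim_doc), **doc)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["qual_profile"] = {
            str(k): v for k, v in d["sim"]["qual_profile"].items()
        }
        return d


def _require(stage: str, path, what: str) -> Path:
    if path is None:
        raise StageError(stage, f"no {what} file configured")
    p = Path(path)
    if not p.exists():
        raise StageError(stage, f"{what} file not found: {p}")
    return p


def _flank(call, positions_on_scaffold, scaffold_len: int, cap: int = 1000) -> int:
    """Clean flank: bases to the nearest other variant or scaffold edge."""
    up = call.pos - 1
    down = scaffold_len - call.pos
    for p in positions_on_scaffold:
        if p == call.pos:
            continue
        if p < call.pos:
            up = min(up, call.pos - p - 1)
        else:
            down = min(down, p - call.pos - 1)
    return min(up, down, cap)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full stage chain; returns the machine-readable summary.

    Writes into ``cfg.outdir``: VCF, spectrum TSV, region-call TSV, gene–QTL
    co-localization TSV, panel TSV, per-locus validation TSV, LD TSV and
    ``summary.json`` (which echoes the effective configuration).  A stage
    failure raises :class:`StageError` naming the stage.
    """
    t0 = time.time()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": cfg.to_dict(), "stages": {}}

    def stage_log(stage: str, **counts) -> None:
        summary["stages"][stage] = counts
        log.info("stage %-11s %s  (%.2fs)", stage, counts, time.time() - t0)

    # ---- simulate -------------------------------------------------------
    if cfg.simulate:
        try:
            bundle = emit_fixtures(cfg.sim, outdir / "fixtures")
        except Exception as exc:  # sizing or I/O problems
            raise StageError("simulate", str(exc)) from exc
        for key in ("genome", "gff3", "pileup", "anchors", "qtl", "genepop"):
            setattr(cfg, key, bundle["paths"][key])
        stage_log(
            "simulate",
            scaffolds=len(bundle["genome"]),
            genes=len(bundle["genes"]),
            planted_variants=len(bundle["truth"].variants),
        )

    # ---- call -----------------------------------------------------------
    pileup_path = _require("call", cfg.pileup, "pileup")
    try:
        calls = call_sites(
            formats.read_pileup_tsv(pileup_path),
            min_base_qual=cfg.min_qual,
            min_depth=cfg.min_depth,
            min_mac=cfg.min_mac,
        )
    except formats.ParseError as exc:
        raise StageError("call", str(exc)) from exc
    genome = formats.read_fasta(_require("call", cfg.genome, "genome"))
    formats.write_vcf(
        calls, outdir / "calls.vcf", contigs={k: len(v) for k, v in genome.items()}
    )
    spec = spectrum(calls)
    formats.write_spectrum_tsv(spec, outdir / "spectrum.tsv")
    stage_log(
        "call",
        calls=len(calls),
        snps=spec.snp_count,
        nonsnp=spec.nonsnp_count,
        ts_tv=None if spec.ts_tv_ratio is None else round(spec.ts_tv_ratio, 3),
    )

    # ---- annotate -------------------------------------------------------
    genes = formats.read_gff3(_require("annotate", cfg.gff3, "gene models"))
    by_scaffold: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold, []).append(g)
    region_rows = []
    for c in calls:
        if c.variant_class != "SNP" or c.note:
            continue
        alt = c.minor if c.major == c.ref else c.major
        if alt == c.ref:
            continue
        for g in by_scaffold.get(c.scaffold, ()):
            if g.contains(c.pos):
                try:
                    rc = classify_snp_region(c.pos, c.ref, alt, g, genome)
                except ValueError as exc:
                    raise StageError("annotate", str(exc)) from exc
                region_rows.append((g.gene_id, c.scaffold, c.pos, c.ref, alt, rc))
                break
    formats.write_region_tsv(region_rows, outdir / "regions.tsv")
    per_gene = snps_per_gene(calls, genes)
    stage_log(
        "annotate",
        in_gene_snps=len(region_rows),
        genes_with_snps=len(per_gene["per_gene"]),
        snps_per_gene_mean=per_gene["mean"] and round(per_gene["mean"], 2),
    )

    # ---- colocalize -----------------------------------------------------
    anchors = formats.read_anchor_tsv(_require("colocalize", cfg.anchors, "anchors"))
    qtls = formats.read_qtl_tsv(_require("colocalize", cfg.qtl, "QTL table"))
    colocs_by_gene: dict[str, list] = {}
    coloc_rows = []
    all_warnings: list[str] = []
    for g in genes:
        lg, _ = anchor_scaffold(g.scaffold, anchors)
        placement = GenePlacement(
            gene_id=g.gene_id,
            scaffold=g.scaffold,
            start=g.span[0],
            end=g.span[1],
            strand=g.strand,
            identity=1.0,
        )
        colocs, warnings = colocalize(placement, qtls, anchors, max_pref=cfg.max_pref)
        all_warnings.extend(warnings)
        colocs_by_gene[g.gene_id] = colocs
        coloc_rows.append((g.gene_id, lg, colocs))
    formats.write_coloc_tsv(coloc_rows, outdir / "colocalization.tsv")
    stage_log(
        "colocalize",
        genes=len(genes),
        genes_with_qtl=sum(1 for _, _, cl in coloc_rows if cl),
        unresolved_markers=len(set(all_warnings)),
    )

    # ---- select ---------------------------------------------------------
    call_positions: dict[str, list[int]] = {}
    for c in calls:
        call_positions.setdefault(c.scaffold, []).append(c.pos)
    calls_by_key = {(c.scaffold, c.pos): c for c in calls}
    candidates: dict[str, list[CandidateSNP]] = {}
    for gene_id, scaf, pos, ref, alt, rc in region_rows:
        c = calls_by_key[(scaf, pos)]
        candidates.setdefault(gene_id, []).append(
            CandidateSNP(
                gene_id=gene_id,
                call=c,
                region=rc,
                discovery_maf=c.minor_fraction,
                flank=_flank(c, call_positions[scaf], len(genome[scaf])),
            )
        )
    sel_cfg = SelectionConfig(
        min_discovery_maf=cfg.min_discovery_maf, min_flank_bp=cfg.min_flank_bp
    )
    panel, unselectable = select_panel(candidates, colocs_by_gene, sel_cfg)
    formats.write_panel_tsv(panel, outdir / "panel.tsv")
    breakdown = panel_region_breakdown(panel) if panel else None
    stage_log(
        "select",
        panel=len(panel),
        unselectable=len(unselectable),
        utr_fraction=breakdown and round(breakdown["utr_fraction"], 3),
    )

    # ---- popgen ---------------------------------------------------------
    matrix = formats.read_genepop(_require("popgen", cfg.genepop, "GENEPOP"))
    pg = summarize(
        matrix,
        alpha=cfg.alpha,
        ld_permutations=cfg.ld_permutations,
        seed=cfg.seed,
    )
    formats.write_locus_stats_tsv(
        pg["locus_stats"], outdir / "locus_stats.tsv", decimals=cfg.decimals
    )
    formats.write_ld_tsv(pg["ld_pairs"], outdir / "ld.tsv")
    stage_log(
        "popgen",
        loci=pg["n_loci"],
        polymorphic=pg["n_polymorphic"],
        ld_pairs=pg["n_ld_pairs"],
        mean_he=pg["means"]["he"]["mean"] and round(pg["means"]["he"]["mean"], 3),
    )

    # ---- report ---------------------------------------------------------
    summary["results"] = {
        "n_calls": len(calls),
        "n_snps": spec.snp_count,
        "n_nonsnp": spec.nonsnp_count,
        "snp_fraction": spec.snp_fraction,
        "ts_tv_ratio": spec.ts_tv_ratio,
        "snps_per_gene": {
            "mean": per_gene["mean"],
            "sd": per_gene["sd"],
            "range": per_gene["range"],
        },
        "panel_size": len(panel),
        "panel_breakdown": breakdown and {
            "utr_fraction": breakdown["utr_fraction"],
            "coding_fraction": breakdown["coding_fraction"],
            "intron_fraction": breakdown["intron_fraction"],
        },
        "popgen": {
            "n_polymorphic": pg["n_polymorphic"],
            "n_monomorphic": pg["n_monomorphic"],
            "n_failed": pg["n_failed"],
            "n_ld_pairs": pg["n_ld_pairs"],
            "bonferroni_threshold": pg["bonferroni_threshold"],
            "means": pg["means"],
        },
    }
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True, default=str) + "\n"
    )
    stage_log("report", outputs=8)
    return summary


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(levelname)s] %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.INFO if verbose else logging.WARNING)
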