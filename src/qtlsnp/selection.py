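"""Assay-panel selection: one SNP per candidate gene.

Candidates surviving the calling filters are scored deterministically from
three signals: the gene-region class (non-synonymous exonic change first,
then 5'UTR, 3'UTR, synonymous, intron by default), a bonus for
co-localization with a growth QTL within the preference distance, and a
clean-flank adequacy term (assay primers need variant-free flanking
sequence).  A minimum discovery minor-allele fraction excludes SNPs whose
minor allele was barely observed in the pooled discovery sample — a codified
form of the manual read-inspection step such panels typically undergo.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .annotation import RegionCall
from .calling import VariantCall
from .mapping import Colocalization

__all__ = [
    "CandidateSNP",
    "SelectionConfig",
    "PanelEntry",
    "score_snp",
    "select_panel",
    "panel_region_breakdown",
]

DEFAULT_PRIORITY = (
    "exon_nonsynonymous",
    "five_prime_utr",
    "three_prime_utr",
    "exon_synonymous",
    "intron",
)


@dataclass(frozen=True)
class CandidateSNP:
    """A called SNP in a candidate gene, with assay-design context."""

    gene_id: str
    call: VariantCall
    region: RegionCall
    discovery_maf: float  # minor-allele fraction in the pooled discovery data
    flank: int  # clean bases (no other variant, no N) on the tighter side

    def __post_init__(self) -> None:
        if self.flank < 0:
            raise ValueError("flank must be >= 0")
        if not 0 < self.discovery_maf <= 0.5:
            raise ValueError("discovery MAF must be in (0, 0.5]")


@dataclass(frozen=True)
class SelectionConfig:
    min_discovery_maf: float = 0.1
    min_flank_bp: int = 30
    region_priority: tuple[str, ...] = DEFAULT_PRIORITY
    qtl_bonus: float = 5.0

    def __post_init__(self) -> None:
        if len(set(self.region_priority)) != len(self.region_priority):
            raise ValueError("region_priority must be a strict ordering")


@dataclass(frozen=True)
class PanelEntry:
    gene_id: str
    snp: CandidateSNP
    score: float
    rationale: str
    colocalizations: tuple[Colocalization, ...] = ()


def score_snp(
    candidate: CandidateSNP,
    colocs: Sequence[Colocalization],
    cfg: SelectionConfig = SelectionConfig(),
) -> float:
    """Deterministic selection score; -inf excludes the candidate.

    score = 10·(region rank, best first) + qtl_bonus (any within-preference
    co-localization) + flank adequacy in [0, 1].  Candidates below the
    minimum discovery minor-allele fraction are excluded outright.
    """
    if candidate.discovery_maf < cfg.min_discovery_maf:
        return float("-inf")
    try:
        rank = cfg.region_priority.index(candidate.region.region)
    except ValueError:
        rank = len(cfg.region_priority)  # unknown regions rank last
    region_points = 10.0 * (len(cfg.region_priority) - rank)
    qtl_points = (
        cfg.qtl_bonus if any(c.within_preference for c in colocs) else 0.0
    )
    flank_points = min(candidate.flank, cfg.min_flank_bp) / cfg.min_flank_bp
    return region_points + qtl_points + flank_points


def select_panel(
    candidates_by_gene: dict[str, Sequence[CandidateSNP]],
    colocs_by_gene: Optional[dict[str, Sequence[Colocalization]]] = None,
    cfg: SelectionConfig = SelectionConfig(),
) -> tuple[list[PanelEntry], list[str]]:
    """Pick the max-score candidate per gene.

    Ties are broken by larger flank, then by smaller genome coordinate.
    Returns (panel, unselectable genes) — a gene is unselectable when all
    of its candidates are excluded.
    """
    colocs_by_gene = colocs_by_gene or {}
    panel: list[PanelEntry] = []
    unselectable: list[str] = []
    for gene in sorted(candidates_by_gene):
        colocs = tuple(colocs_by_gene.get(gene, ()))
        scored = [
            (score_snp(c, colocs, cfg), c) for c in candidates_by_gene[gene]
        ]
        scored = [(s, c) for s, c in scored if s != float("-inf")]
        if not scored:
            unselectable.append(gene)
            continue
        scored.sort(key=lambda sc: (-sc[0], -sc[1].flank) + _coord_key(sc[1]))
        best_score, best = scored[0]
        reasons = [f"region={best.region.label}"]
        if any(c.within_preference for c in colocs):
            reasons.append("QTL co-localized within preference")
        reasons.append(f"flank={best.flank}bp, discovery MAF={best.discovery_maf:.2f}")
        panel.append(
            PanelEntry(
                gene_id=gene,
                snp=best,
                score=best_score,
                rationale="; ".join(reasons),
                colocalizations=colocs,
            )
        )
    return panel, unselectable


def _coord_key(c: CandidateSNP) -> tuple:
    # Smaller coordinate wins the final tie-break; scaffold names compare
    # lexicographically, positions numerically.
    return (_scaffold_sort_key(c.call.scaffold), c.call.pos)


def _scaffold_sort_key(name: str):
    return tuple(
        int(p) if p.isdigit() else p
        for p in name.replace("_", " ").split()
    )


def panel_region_breakdown(panel: Sequence[PanelEntry]) -> dict:
    """Fractions of the panel per region class, plus UTR and coding totals."""
    if not panel:
        raise ValueError("panel is empty")
    n = len(panel)
    counts: dict[str, int] = {}
    for e in panel:
        counts[e.snp.region.region] = counts.get(e.snp.region.region, 0) + 1
    fractions = {r: c / n for r, c in counts.items()}
    utr = counts.get("five_prime_utr", 0) + counts.get("three_prime_utr", 0)
    coding = counts.get("exon_synonymous", 0) + counts.get("exon_nonsynonymous", 0)
    return {
        "n": n,
        "counts": counts,
        "fractions": fractions,
        "utr_fraction": utr / n,
        "coding_fraction": coding / n,
        "intron_fraction": counts.get("intron", 0) / n,
    }
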