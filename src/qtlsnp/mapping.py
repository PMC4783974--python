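"""Genetic-map integration: scaffold anchoring, synteny inference,
gene–QTL co-localization and genetic↔physical distance conversion.

Scaffolds carry anchor markers that have both a linkage-group (LG, cM)
position on the genetic map and a (scaffold, bp) position on the assembly.
A gene placed on a scaffold co-localizes with a QTL when the QTL's
associated marker (or, for marker-less QTLs, its confidence-interval
reference markers) resolves to the same scaffold; the gene–marker distance
is measured from the nearest gene-span boundary, zero when the marker falls
inside the span.  Scaffolds without anchors can be assigned an LG by
majority vote of model-species ortholog positions (comparative synteny).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .annotation import GenePlacement

__all__ = [
    "MapAnchor",
    "QTLRecord",
    "Colocalization",
    "MapConstants",
    "anchor_scaffold",
    "infer_lg_synteny",
    "colocalize",
    "mb_to_cm",
    "cm_to_mb",
]


@dataclass(frozen=True)
class MapAnchor:
    """Marker present on both the genetic map and the assembly."""

    marker: str
    lg: int
    cm: float
    scaffold: str
    bp: int  # 1-based

    def __post_init__(self) -> None:
        if self.bp < 1:
            raise ValueError("anchor bp position must be >= 1")


@dataclass(frozen=True)
class QTLRecord:
    """A growth QTL: trait, linkage group and marker evidence.

    ``marker`` is "nd" when no associated marker was reported, in which
    case ``ci_markers`` (markers bounding the QTL confidence interval) must
    be non-empty and are used for co-localization instead.
    """

    trait: str  # BW (body weight) | L (length) | K (Fulton factor)
    lg: int
    marker: str  # marker id or "nd"
    vpe: Optional[float] = None  # % phenotypic variance explained
    ci_markers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.marker == "nd" and not self.ci_markers:
            raise ValueError("marker-less QTL requires CI reference markers")


@dataclass(frozen=True)
class Colocalization:
    gene_id: str
    qtl_trait: str
    marker: str
    distance_bp: int
    within_preference: bool
    evidence: str  # direct-marker | closest-marker | synteny-inferred

    def __post_init__(self) -> None:
        if self.distance_bp < 0:
            raise ValueError("distance must be >= 0")


@dataclass(frozen=True)
class MapConstants:
    """Genetic↔physical conversion factor (Mb of sequence per cM of map)."""

    mb_per_cm: float = 0.5

    def __post_init__(self) -> None:
        if self.mb_per_cm <= 0:
            raise ValueError("mb_per_cm must be positive")


def anchor_scaffold(
    scaffold: str, anchors: Iterable[MapAnchor]
) -> tuple[Optional[int], str]:
    """Linkage group of a scaffold from its anchor markers.

    Returns (LG, "ok"), (None, "no anchors") or (None, "conflict") when the
    scaffold's markers disagree about the LG.
    """
    lgs = {a.lg for a in anchors if a.scaffold == scaffold}
    if not lgs:
        return None, "no anchors"
    if len(lgs) > 1:
        return None, "conflict"
    return lgs.pop(), "ok"


def infer_lg_synteny(
    ortholog_chromosomes: Sequence[str],
    chrom_to_lg: dict[str, int],
) -> tuple[Optional[int], str]:
    """Infer a scaffold's LG from model-species ortholog positions.

    Majority vote over the LGs paired with the chromosomes carrying the
    scaffold's orthologs; a tie or no mappable ortholog yields None.  The
    result is marked "inferred" so reports can flag it (asterisk
    convention).
    """
    votes = Counter(
        chrom_to_lg[c] for c in ortholog_chromosomes if c in chrom_to_lg
    )
    if not votes:
        return None, "no data"
    top = votes.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        return None, "tie"
    return top[0][0], "inferred"


def _gene_marker_distance(span: tuple[int, int], marker_bp: int) -> int:
    lo, hi = span
    if lo <= marker_bp <= hi:
        return 0
    return lo - marker_bp if marker_bp < lo else marker_bp - hi


def colocalize(
    gene: GenePlacement,
    qtls: Iterable[QTLRecord],
    anchors: Iterable[MapAnchor],
    max_pref: int = 1_000_000,
) -> tuple[list[Colocalization], list[str]]:
    """Co-localize a placed gene with QTL markers on its scaffold.

    For each QTL whose associated marker (or any CI reference marker, for
    marker-less QTLs) resolves to the gene's scaffold, reports the physical
    gene–marker distance measured from the nearest gene-span boundary
    (0 when the marker lies inside the span) and whether it falls within
    the preference distance (default 1 Mbp — a ranking preference, not a
    hard filter).  Unresolvable marker ids are reported as warnings, never
    fatally.  QTLs with no marker on the scaffold yield no record.
    """
    by_marker = {a.marker: a for a in anchors}
    out: list[Colocalization] = []
    warnings: list[str] = []
    span = (gene.start, gene.end)
    for q in qtls:
        if q.marker != "nd":
            candidates = [(q.marker, "direct-marker")]
        else:
            candidates = [(m, "closest-marker") for m in q.ci_markers]
        best: Optional[Colocalization] = None
        for marker, evidence in candidates:
            a = by_marker.get(marker)
            if a is None:
                warnings.append(
                    f"QTL {q.trait}@LG{q.lg}: marker {marker} not in anchor table"
                )
                continue
            if a.scaffold != gene.scaffold:
                continue
            d = _gene_marker_distance(span, a.bp)
            c = Colocalization(
                gene_id=gene.gene_id,
                qtl_trait=q.trait,
                marker=marker,
                distance_bp=d,
                within_preference=d < max_pref,
                evidence=evidence,
            )
            if best is None or c.distance_bp < best.distance_bp:
                best = c
        if best is not None:
            out.append(best)
    return out, warnings


def mb_to_cm(d_mb: float, constants: MapConstants = MapConstants()) -> float:
    """Physical distance (Mb) to genetic distance (cM): cM = Mb / (Mb/cM)."""
    if d_mb < 0:
        raise ValueError("distance must be non-negative")
    return d_mb / constants.mb_per_cm


def cm_to_mb(d_cm: float, constants: MapConstants = MapConstants()) -> float:
    """Genetic distance (cM) to physical distance (Mb)."""
    if d_cm < 0:
        raise ValueError("distance must be non-negative")
    return d_cm * constants.mb_per_cm
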