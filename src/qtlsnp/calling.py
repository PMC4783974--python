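"""Pileup-based SNP calling and variant-spectrum summaries.

The caller operates on per-site base tallies: observations below a Phred
base-quality floor are discarded first, then a variant is emitted at a site
when the quality-filtered depth and the minor allele count both clear their
thresholds (defaults: quality >= 20, depth >= 10, minor allele count >= 3).
A call whose top two alleles are single bases is a SNP; an indel token in
the top two makes it a non-SNP polymorphism.  SNPs are classified into the
six substitution types, with A<->G and C<->T as transitions and the rest
transversions.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "PileupSite",
    "AlleleTally",
    "VariantCall",
    "SpectrumSummary",
    "tally_site",
    "call_variant",
    "call_sites",
    "combine_tallies",
    "classify_substitution",
    "spectrum",
    "snps_per_gene",
    "SUBSTITUTION_TYPES",
]

BASES = frozenset("ACGT")
# Canonical six-type partition of biallelic SNPs.
SUBSTITUTION_TYPES = ("A/G", "C/T", "A/C", "A/T", "C/G", "G/T")
TRANSITIONS = {frozenset("AG"), frozenset("CT")}


@dataclass(frozen=True)
class PileupSite:
    """Per-position tally of observed bases (or indel tokens) with qualities."""

    scaffold: str
    pos: int  # 1-based
    ref: str
    observations: tuple[tuple[str, int], ...]  # (base or indel token, phred)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("position must be >= 1 (1-based)")
        if any(q < 0 for _, q in self.observations):
            raise ValueError("Phred qualities must be >= 0")


@dataclass
class AlleleTally:
    """Quality-filtered allele counts at one site."""

    scaffold: str
    pos: int
    ref: str
    counts: Counter

    @property
    def filtered_depth(self) -> int:
        return sum(self.counts.values())

    def ranked_alleles(self) -> list[tuple[str, int]]:
        """Alleles by descending count, ties broken lexicographically."""
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))


@dataclass
class VariantCall:
    scaffold: str
    pos: int
    ref: str
    major: str
    minor: str
    major_count: int
    minor_count: int
    depth: int
    variant_class: str  # "SNP" | "non-SNP polymorphism"
    subst_type: Optional[str] = None  # e.g. "A/G", SNPs only
    ts_tv: Optional[str] = None  # "transition" | "transversion"
    note: Optional[str] = None  # extra alleles passing MAC, if any

    @property
    def minor_fraction(self) -> float:
        return self.minor_count / self.depth if self.depth else 0.0


@dataclass
class SpectrumSummary:
    type_counts: dict
    ts_count: int
    tv_count: int
    ts_tv_ratio: Optional[float]  # None when tv_count == 0
    snp_count: int
    nonsnp_count: int
    multiallelic_count: int

    @property
    def snp_fraction(self) -> Optional[float]:
        total = self.snp_count + self.nonsnp_count
        return self.snp_count / total if total else None


def tally_site(site: PileupSite, min_base_qual: int = 20) -> AlleleTally:
    """Count alleles at a site after discarding low-quality observations."""
    counts = Counter(
        tok for tok, q in site.observations if q >= min_base_qual
    )
    return AlleleTally(site.scaffold, site.pos, site.ref, counts)


def combine_tallies(a: AlleleTally, b: AlleleTally) -> AlleleTally:
    """Add per-allele counts of the same site from two libraries."""
    if (a.scaffold, a.pos) != (b.scaffold, b.pos) or a.ref != b.ref:
        raise ValueError("tallies describe different sites")
    return AlleleTally(a.scaffold, a.pos, a.ref, a.counts + b.counts)


def call_variant(
    tally: AlleleTally, min_depth: int = 10, min_mac: int = 3
) -> Optional[VariantCall]:
    """Emit a variant call, or None when the site fails the filters.

    A call requires quality-filtered depth >= ``min_depth``, at least two
    observed alleles, and a second-most-frequent allele count >= ``min_mac``.
    With three or more alleles passing the minor-allele-count threshold the
    top two are called and the remainder recorded in ``note`` (such calls
    are excluded from the substitution spectrum).
    """
    if tally.filtered_depth < min_depth:
        return None
    ranked = tally.ranked_alleles()
    if len(ranked) < 2 or ranked[1][1] < min_mac:
        return None
    (major, n_major), (minor, n_minor) = ranked[0], ranked[1]
    extra = [a for a, c in ranked[2:] if c >= min_mac]
    is_snp = major in BASES and minor in BASES
    subst = ts_tv = None
    if is_snp:
        subst = "/".join(sorted((major, minor)))
        ts_tv = classify_substitution(major, minor)
    return VariantCall(
        scaffold=tally.scaffold,
        pos=tally.pos,
        ref=tally.ref,
        major=major,
        minor=minor,
        major_count=n_major,
        minor_count=n_minor,
        depth=tally.filtered_depth,
        variant_class="SNP" if is_snp else "non-SNP polymorphism",
        subst_type=subst,
        ts_tv=ts_tv,
        note=f"extra alleles passing MAC: {','.join(extra)}" if extra else None,
    )


def call_sites(
    sites: Iterable[PileupSite],
    min_base_qual: int = 20,
    min_depth: int = 10,
    min_mac: int = 3,
) -> list[VariantCall]:
    """Tally and call a stream of pileup sites with the given thresholds."""
    calls = []
    for site in sites:
        call = call_variant(
            tally_site(site, min_base_qual), min_depth=min_depth, min_mac=min_mac
        )
        if call is not None:
            calls.append(call)
    return calls


def classify_substitution(a: str, b: str) -> str:
    """Transition (A<->G, C<->T) or transversion (all other base pairs)."""
    if a == b:
        raise ValueError("alleles are identical")
    if a not in BASES or b not in BASES:
        raise ValueError(f"not single bases: {a!r}, {b!r}")
    return "transition" if frozenset((a, b)) in TRANSITIONS else "transversion"


def spectrum(calls: Iterable[VariantCall]) -> SpectrumSummary:
    """Substitution-type spectrum over biallelic SNP calls.

    Non-SNP polymorphisms and SNPs with extra alleles passing the MAC
    threshold are counted separately and excluded from the six-type
    partition.  The ts/tv ratio is None when no transversions are present.
    """
    type_counts = {t: 0 for t in SUBSTITUTION_TYPES}
    ts = tv = n_snp = n_nonsnp = n_multi = 0
    for c in calls:
        if c.variant_class != "SNP":
            n_nonsnp += 1
            continue
        n_snp += 1
        if c.note:
            n_multi += 1
            continue
        type_counts[c.subst_type] += 1
        if c.ts_tv == "transition":
            ts += 1
        else:
            tv += 1
    return SpectrumSummary(
        type_counts=type_counts,
        ts_count=ts,
        tv_count=tv,
        ts_tv_ratio=(ts / tv) if tv else None,
        snp_count=n_snp,
        nonsnp_count=n_nonsnp,
        multiallelic_count=n_multi,
    )


def snps_per_gene(calls: Iterable[VariantCall], gene_models) -> dict:
    """Per-gene SNP counts with mean, SD and range over genes holding >= 1 SNP.

    A SNP is assigned to every gene whose genomic span contains it; genes
    with no SNP do not enter the mean or range (a gene only appears in the
    discovery data through its variants).
    """
    snps = [c for c in calls if c.variant_class == "SNP"]
    counts: dict[str, int] = {}
    for g in gene_models:
        lo, hi = g.span
        n = sum(1 for c in snps if c.scaffold == g.scaffold and lo <= c.pos <= hi)
        if n:
            counts[g.gene_id] = n
    vals = list(counts.values())
    if not vals:
        return {"per_gene": {}, "mean": None, "sd": None, "range": None}
    mean = sum(vals) / len(vals)
    sd = (
        math.sqrt(sum((v - mean) ** 2 for v in vals) / (len(vals) - 1))
        if len(vals) > 1
        else 0.0
    )
    return {
        "per_gene": counts,
        "mean": mean,
        "sd": sd,
        "range": (min(vals), max(vals)),
    }
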