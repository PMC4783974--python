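"""Gene models, transcript placement, and SNP region/codon-effect classification.

A ``GeneModel`` is a strand-aware exon/CDS structure on a genome scaffold
from which 5'UTR, 3'UTR and intron intervals are derived.  SNPs falling in
a gene are classified into one of five regions (5' UTR, 3' UTR, synonymous
exon, non-synonymous exon, intron); for coding positions the reference
codon is read strand-aware, the alternate allele substituted, and both are
translated with the standard genetic code.

Transcript placement on the genome uses an ungapped seed-and-extend
matcher (exact k-mer seeds, match +1 / mismatch −2): a deliberately simple
local aligner adequate for the scales this package targets.  Precomputed
hit tables from an external aligner can be supplied instead wherever an
``OrthologHit`` list is accepted.

All interval fields are 1-based inclusive, matching GFF3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio.Seq import Seq

__all__ = [
    "GeneModel",
    "RegionCall",
    "OrthologHit",
    "GenePlacement",
    "scan_orthologs",
    "place_gene",
    "classify_snp_region",
    "REGION_LABELS",
]

Interval = tuple[int, int]  # 1-based inclusive

REGION_LABELS = {
    "five_prime_utr": "5' UTR",
    "three_prime_utr": "3' UTR",
    "exon_synonymous": "Exon syn",
    "exon_nonsynonymous": "Exon {aa}",  # aa like "V-A"
    "intron": "Intron",
}


def _merge_sorted(intervals: Iterable[Interval]) -> list[Interval]:
    ivs = sorted(intervals)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _subtract(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Interval-set difference a \\ b, both sorted non-overlapping."""
    out: list[Interval] = []
    for s, e in a:
        cur = s
        for bs, be in b:
            if be < cur or bs > e:
                continue
            if bs > cur:
                out.append((cur, bs - 1))
            cur = max(cur, be + 1)
            if cur > e:
                break
        if cur <= e:
            out.append((cur, e))
    return out


@dataclass
class GeneModel:
    """Strand-aware gene structure: ordered exons with embedded CDS.

    Invariants: exons sorted, non-overlapping; CDS intervals contained in
    exons; total CDS length divisible by 3.  UTR and intron intervals are
    derived, not stored.
    """

    gene_id: str
    scaffold: str
    strand: str  # "+" or "-"
    exons: list[Interval]
    cds: list[Interval]
    transcript_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.exons = _merge_sorted(self.exons)
        self.cds = sorted(self.cds)
        for s, e in self.exons + self.cds:
            if s > e or s < 1:
                raise ValueError(f"bad interval ({s}, {e}) in {self.gene_id}")
        if self.cds:
            cds_len = sum(e - s + 1 for s, e in self.cds)
            if cds_len % 3:
                raise ValueError(
                    f"{self.gene_id}: CDS length {cds_len} not divisible by 3"
                )

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def introns(self) -> list[Interval]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out

    def _utrs(self) -> tuple[list[Interval], list[Interval]]:
        """(5'UTR, 3'UTR) genomic intervals, strand-aware."""
        if not self.cds:
            return [], []
        non_cds = _subtract(self.exons, self.cds)
        cds_lo, cds_hi = self.cds[0][0], self.cds[-1][1]
        left = [iv for iv in non_cds if iv[1] < cds_lo]
        right = [iv for iv in non_cds if iv[0] > cds_hi]
        # On the minus strand transcription runs high->low, so the 5'UTR is
        # the higher-coordinate side.
        return (left, right) if self.strand == "+" else (right, left)

    @property
    def utr5(self) -> list[Interval]:
        return self._utrs()[0]

    @property
    def utr3(self) -> list[Interval]:
        return self._utrs()[1]

    def contains(self, pos: int) -> bool:
        lo, hi = self.span
        return lo <= pos <= hi

    def cds_offset(self, pos: int) -> Optional[int]:
        """0-based offset of a genomic position within the spliced CDS."""
        ivs = self.cds if self.strand == "+" else list(reversed(self.cds))
        off = 0
        for s, e in ivs:
            if s <= pos <= e:
                return off + (pos - s if self.strand == "+" else e - pos)
            off += e - s + 1
        return None

    def cds_sequence(self, genome: dict[str, str]) -> str:
        """Spliced CDS in reading orientation (starts with the start codon)."""
        seq = "".join(genome[self.scaffold][s - 1 : e] for s, e in self.cds)
        return str(Seq(seq).reverse_complement()) if self.strand == "-" else seq


@dataclass(frozen=True)
class RegionCall:
    """Gene-region classification of one SNP.

    ``region`` is one of five_prime_utr / three_prime_utr / exon_synonymous /
    exon_nonsynonymous / intron; ``aa_change`` (e.g. "V-A", reference amino
    acid first) is present exactly when the region is exon_nonsynonymous.
    """

    region: str
    aa_change: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.aa_change is not None) != (self.region == "exon_nonsynonymous"):
            raise ValueError("aa_change present iff region is exon_nonsynonymous")

    @property
    def label(self) -> str:
        tpl = REGION_LABELS[self.region]
        return tpl.format(aa=self.aa_change) if "{aa}" in tpl else tpl


@dataclass
class OrthologHit:
    """One local ungapped alignment between a query and a reference sequence."""

    query_id: str
    ref_id: str
    score: int
    identity: float
    aligned_len: int
    strand: str  # strand of the query relative to the reference
    q_start: int  # 1-based inclusive, on the forward query
    q_end: int
    r_start: int
    r_end: int
    best: bool = False


@dataclass(frozen=True)
class GenePlacement:
    gene_id: str
    scaffold: str
    start: int  # 1-based inclusive genomic span of the best hit
    end: int
    strand: str
    identity: float


def _extend(q: str, r: str, qi: int, ri: int, k: int, xdrop: int = 20) -> tuple:
    """Ungapped extension of a k-mer seed; returns (score, qs, qe, matches, length).

    Match +1, mismatch −2; extension stops when the running score falls
    ``xdrop`` below the best seen.  Coordinates are 0-based half-open on q.
    """
    score = best = k
    matches = k
    # right extension
    bi, bj = qi + k, ri + k
    i, j, cur, m = bi, ri + k, k, k
    while i < len(q) and j < len(r):
        cur += 1 if q[i] == r[j] else -2
        m += 1 if q[i] == r[j] else 0
        i += 1
        j += 1
        if cur > best:
            best, bi, bj, matches = cur, i, j, m
        elif cur < best - xdrop:
            break
    qe, re_ = bi, bj
    score = best
    # left extension
    bi, bj = qi, ri
    i, j, cur, m = qi, ri, best, matches
    while i > 0 and j > 0:
        i -= 1
        j -= 1
        cur += 1 if q[i] == r[j] else -2
        m += 1 if q[i] == r[j] else 0
        if cur > score:
            score, bi, bj, matches = cur, i, j, m
        elif cur < score - xdrop:
            break
    return score, bi, qe, bj, re_, matches


def scan_orthologs(
    queries: dict[str, str],
    references: dict[str, str],
    min_identity: float = 0.9,
    min_aligned_len: int = 50,
    k: int = 11,
) -> list[OrthologHit]:
    """Seed-and-extend scan of query sequences against reference sequences.

    Exact k-mer seeds indexed over the references, extended ungapped in both
    directions with match +1 / mismatch −2.  Both query strands are scanned.
    Hits passing ``min_identity`` and ``min_aligned_len`` are returned, the
    single best hit per query flagged ``best``.
    """
    for name, seq in {**queries, **references}.items():
        if not seq:
            raise ValueError(f"empty sequence: {name}")
        if k > len(seq):
            raise ValueError(f"k-mer size {k} exceeds length of {name}")

    index: dict[str, list[tuple[str, int]]] = {}
    for rid, rseq in references.items():
        for i in range(len(rseq) - k + 1):
            index.setdefault(rseq[i : i + k], []).append((rid, i))

    hits: list[OrthologHit] = []
    for qid, qseq_fwd in queries.items():
        per_query: dict[tuple, OrthologHit] = {}
        for strand in "+-":
            qseq = (
                qseq_fwd
                if strand == "+"
                else str(Seq(qseq_fwd).reverse_complement())
            )
            seen: set[tuple] = set()
            for qi in range(len(qseq) - k + 1):
                for rid, ri in index.get(qseq[qi : qi + k], ()):
                    if (rid, ri - qi) in seen:  # one extension per diagonal
                        continue
                    seen.add((rid, ri - qi))
                    rseq = references[rid]
                    score, qs, qe, rs, re_, matches = _extend(qseq, rseq, qi, ri, k)
                    alen = qe - qs
                    ident = matches / alen if alen else 0.0
                    if alen < min_aligned_len or ident < min_identity:
                        continue
                    if strand == "-":  # report on the forward query
                        qs, qe = len(qseq) - qe, len(qseq) - qs
                    key = (rid, strand, rs)
                    hit = OrthologHit(
                        query_id=qid,
                        ref_id=rid,
                        score=score,
                        identity=ident,
                        aligned_len=alen,
                        strand=strand,
                        q_start=qs + 1,
                        q_end=qe,
                        r_start=rs + 1,
                        r_end=re_,
                    )
                    prev = per_query.get(key)
                    if prev is None or hit.score > prev.score:
                        per_query[key] = hit
        qhits = sorted(
            per_query.values(), key=lambda h: (-h.score, h.ref_id, h.r_start)
        )
        if qhits:
            qhits[0].best = True
        hits.extend(qhits)
    return hits


def place_gene(
    transcript_id: str,
    transcript_seq: str,
    genome: dict[str, str],
    min_identity: float = 0.9,
    min_aligned_len: int = 50,
    k: int = 11,
    hits: Optional[list[OrthologHit]] = None,
) -> tuple[Optional[GenePlacement], str]:
    """Place a transcript on the genome; unique-scaffold hits only.

    Returns (placement, reason).  The placement is None with reason
    "no hit" when nothing passes the thresholds and "non-unique" when
    passing hits fall on more than one scaffold.  A precomputed hit table
    (e.g. from an external aligner) can be passed via ``hits``.
    """
    if hits is None:
        hits = scan_orthologs(
            {transcript_id: transcript_seq},
            genome,
            min_identity=min_identity,
            min_aligned_len=min_aligned_len,
            k=k,
        )
    passing = [
        h
        for h in hits
        if h.query_id == transcript_id
        and h.identity >= min_identity
        and h.aligned_len >= min_aligned_len
    ]
    if not passing:
        return None, "no hit"
    scaffolds = {h.ref_id for h in passing}
    if len(scaffolds) > 1:
        return None, "non-unique"
    best = max(passing, key=lambda h: h.score)
    span = (
        min(h.r_start for h in passing if h.strand == best.strand),
        max(h.r_end for h in passing if h.strand == best.strand),
    )
    return (
        GenePlacement(
            gene_id=transcript_id,
            scaffold=best.ref_id,
            start=span[0],
            end=span[1],
            strand=best.strand,
            identity=best.identity,
        ),
        "ok",
    )


def classify_snp_region(
    pos: int,
    ref: str,
    alt: str,
    model: GeneModel,
    genome: dict[str, str],
) -> RegionCall:
    """Classify a SNP inside a gene into one of five regions.

    Coding positions: the containing codon is read from the spliced CDS in
    reading orientation, the alternate allele substituted (reverse-
    complemented for minus-strand genes), and both codons translated.
    """
    if not model.contains(pos):
        raise ValueError(
            f"position {pos} outside gene {model.gene_id} span {model.span}"
        )
    genome_ref = genome[model.scaffold][pos - 1]
    if genome_ref != ref:
        raise ValueError(
            f"reference mismatch at {model.scaffold}:{pos}: "
            f"genome has {genome_ref}, call says {ref}"
        )

    off = model.cds_offset(pos)
    if off is not None:
        cds = model.cds_sequence(genome)
        codon_i = off // 3
        codon = cds[3 * codon_i : 3 * codon_i + 3]
        if len(codon) < 3:
            raise ValueError(f"{model.gene_id}: CDS frame inconsistency at {pos}")
        alt_base = alt if model.strand == "+" else str(Seq(alt).complement())
        within = off % 3
        alt_codon = codon[:within] + alt_base + codon[within + 1 :]
        aa_ref = str(Seq(codon).translate())
        aa_alt = str(Seq(alt_codon).translate())
        if aa_ref == aa_alt:
            return RegionCall("exon_synonymous")
        return RegionCall("exon_nonsynonymous", aa_change=f"{aa_ref}-{aa_alt}")

    for s, e in model.utr5:
        if s <= pos <= e:
            return RegionCall("five_prime_utr")
    for s, e in model.utr3:
        if s <= pos <= e:
            return RegionCall("three_prime_utr")
    for s, e in model.introns:
        if s <= pos <= e:
            return RegionCall("intron")
    # Exonic but outside CDS and UTRs only happens for CDS-less models.
    raise ValueError(
        f"position {pos} in {model.gene_id} could not be assigned a region"
    )
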