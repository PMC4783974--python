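"""File codecs for every format the pipeline reads or writes.

All on-disk coordinates are 1-based inclusive (FASTA/GFF3/pileup/VCF
convention); conversion to internal representations happens here and only
here.  Dialects:

- pileup TSV: scaffold, pos, ref, bases string, quals string (Phred+33);
  column 4/5 empty at depth-0 sites.
- map-anchor TSV: marker, LG, cM, scaffold, bp.
- QTL TSV: trait, LG, marker|nd, VPE% (empty allowed), CI markers
  (comma-separated list, empty allowed).
- GENEPOP: title line, one locus name per line, "Pop", then
  "id ,  g1 g2 ..." rows with 2-digit allele codes (00 = missing).
- VCF: minimal v4.2 writer (DP/AC plus a TS_TV tag in INFO).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import GeneModel, RegionCall
from .calling import PileupSite, VariantCall
from .mapping import Colocalization, MapAnchor, QTLRecord
from .popgen import GenotypeMatrix, LDPair

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_pileup_tsv",
    "write_pileup_tsv",
    "read_anchor_tsv",
    "write_anchor_tsv",
    "read_qtl_tsv",
    "write_qtl_tsv",
    "read_genepop",
    "write_genepop",
    "write_vcf",
    "write_spectrum_tsv",
    "write_region_tsv",
    "read_region_tsv",
    "write_coloc_tsv",
    "write_panel_tsv",
    "write_locus_stats_tsv",
    "write_ld_tsv",
]


class ParseError(ValueError):
    def __init__(self, path, line_no: int, msg: str) -> None:
        super().__init__(f"{path}:{line_no}: {msg}")
        self.path, self.line_no = str(path), line_no


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(genome: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------- GFF3

def write_gff3(genes: Iterable[GeneModel], path) -> None:
    """GFF3 with gene/mRNA/exon/CDS/five_prime_UTR/three_prime_UTR features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            lo, hi = g.span
            tid = g.transcript_id or f"{g.gene_id}.t1"

            def row(ftype, s, e, parent=None, fid=None):
                attrs = []
                if fid:
                    attrs.append(f"ID={fid}")
                if parent:
                    attrs.append(f"Parent={parent}")
                fh.write(
                    "\t".join(
                        [
                            g.scaffold,
                            "qtlsnp_sim",
                            ftype,
                            str(s),
                            str(e),
                            ".",
                            g.strand,
                            ".",
                            ";".join(attrs) or ".",
                        ]
                    )
                    + "\n"
                )

            row("gene", lo, hi, fid=g.gene_id)
            row("mRNA", lo, hi, parent=g.gene_id, fid=tid)
            for s, e in g.exons:
                row("exon", s, e, parent=tid)
            for s, e in g.cds:
                row("CDS", s, e, parent=tid)
            for s, e in g.utr5:
                row("five_prime_UTR", s, e, parent=tid)
            for s, e in g.utr3:
                row("three_prime_UTR", s, e, parent=tid)


def read_gff3(path) -> list[GeneModel]:
    """Rebuild gene models from gene/mRNA/exon/CDS rows (UTRs re-derived)."""
    genes: dict[str, dict] = {}
    tid_to_gene: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(path, ln, f"expected 9 columns, got {len(parts)}")
            scaf, _, ftype, s, e, _, strand, _, attrs = parts
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            try:
                s, e = int(s), int(e)
            except ValueError:
                raise ParseError(path, ln, "non-integer coordinates") from None
            if ftype == "gene":
                genes[attr["ID"]] = {
                    "scaffold": scaf,
                    "strand": strand,
                    "exons": [],
                    "cds": [],
                    "tid": None,
                }
            elif ftype == "mRNA":
                tid_to_gene[attr["ID"]] = attr["Parent"]
                genes[attr["Parent"]]["tid"] = attr["ID"]
            elif ftype in ("exon", "CDS"):
                gene_id = tid_to_gene.get(attr.get("Parent", ""), attr.get("Parent"))
                if gene_id not in genes:
                    raise ParseError(path, ln, f"unknown parent {attr.get('Parent')}")
                key = "exons" if ftype == "exon" else "cds"
                genes[gene_id][key].append((s, e))
    return [
        GeneModel(
            gene_id=gid,
            scaffold=d["scaffold"],
            strand=d["strand"],
            exons=d["exons"],
            cds=d["cds"],
            transcript_id=d["tid"],
        )
        for gid, d in genes.items()
    ]


# ---------------------------------------------------------------- pileup TSV

def write_pileup_tsv(sites: Iterable[PileupSite], path) -> None:
    with open(path, "w") as fh:
        fh.write("scaffold\tpos\tref\tbases\tquals\n")
        for s in sites:
            bases = "".join(tok for tok, _ in s.observations)
            quals = "".join(chr(q + 33) for _, q in s.observations)
            fh.write(f"{s.scaffold}\t{s.pos}\t{s.ref}\t{bases}\t{quals}\n")


def read_pileup_tsv(path) -> Iterable[PileupSite]:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("scaffold\t"):
            raise ParseError(path, 1, "missing pileup header")
        for ln, line in enumerate(fh, 2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise ParseError(path, ln, f"expected 5 columns, got {len(parts)}")
            scaf, pos, ref, bases, quals = parts
            if len(bases) != len(quals):
                raise ParseError(path, ln, "bases/quals length mismatch")
            try:
                pos_i = int(pos)
            except ValueError:
                raise ParseError(path, ln, f"bad position {pos!r}") from None
            yield PileupSite(
                scaf,
                pos_i,
                ref,
                tuple((b, ord(q) - 33) for b, q in zip(bases, quals)),
            )


# ---------------------------------------------------------------- map tables

def write_anchor_tsv(anchors: Iterable[MapAnchor], path) -> None:
    with open(path, "w") as fh:
        fh.write("marker\tLG\tcM\tscaffold\tbp\n")
        for a in anchors:
            fh.write(f"{a.marker}\t{a.lg}\t{a.cm}\t{a.scaffold}\t{a.bp}\n")


def read_anchor_tsv(path) -> list[MapAnchor]:
    out = []
    with open(path) as fh:
        next(fh)
        for ln, line in enumerate(fh, 2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise ParseError(path, ln, f"expected 5 columns, got {len(parts)}")
            try:
                out.append(
                    MapAnchor(
                        marker=parts[0],
                        lg=int(parts[1]),
                        cm=float(parts[2]),
                        scaffold=parts[3],
                        bp=int(parts[4]),
                    )
                )
            except ValueError as exc:
                raise ParseError(path, ln, str(exc)) from None
    return out


def write_qtl_tsv(qtls: Iterable[QTLRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("trait\tLG\tmarker\tVPE\tci_markers\n")
        for q in qtls:
            vpe = "" if q.vpe is None else str(q.vpe)
            fh.write(
                f"{q.trait}\t{q.lg}\t{q.marker}\t{vpe}\t{','.join(q.ci_markers)}\n"
            )


def read_qtl_tsv(path) -> list[QTLRecord]:
    out = []
    with open(path) as fh:
        next(fh)
        for ln, line in enumerate(fh, 2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise ParseError(path, ln, f"expected 5 columns, got {len(parts)}")
            try:
                out.append(
                    QTLRecord(
                        trait=parts[0],
                        lg=int(parts[1]),
                        marker=parts[2],
                        vpe=float(parts[3]) if parts[3] else None,
                        ci_markers=tuple(m for m in parts[4].split(",") if m),
                    )
                )
            except ValueError as exc:
                raise ParseError(path, ln, str(exc)) from None
    return out


# ---------------------------------------------------------------- GENEPOP

def write_genepop(matrix: GenotypeMatrix, path, title: str = "panel") -> None:
    """GENEPOP with 2-digit allele codes: 01 = major/reference allele of the
    stored orientation, 02 = the alternate; 0000 = missing genotype."""
    code_map = {0: "0101", 1: "0102", 2: "0202", -1: "0000"}
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in matrix.loci:
            fh.write(locus + "\n")
        fh.write("Pop\n")
        for i, ind in enumerate(matrix.individuals):
            row = " ".join(code_map[int(c)] for c in matrix.codes[i])
            fh.write(f"{ind} ,  {row}\n")


def read_genepop(path) -> GenotypeMatrix:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise ParseError(path, 1, "empty GENEPOP file")
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        # locus names may also come comma-separated on one line
        loci.extend(x.strip() for x in lines[i].split(",") if x.strip())
        i += 1
    if i == len(lines):
        raise ParseError(path, i, 'no "Pop" line found')
    individuals: list[str] = []
    rows: list[list[int]] = []
    decode = {"0101": 0, "0102": 1, "0201": 1, "0202": 2, "0000": -1}
    for ln in range(i + 1, len(lines)):
        line = lines[ln].strip()
        if not line:
            continue
        if line.lower() == "pop":
            raise ParseError(path, ln + 1, "multiple Pop blocks not supported")
        if "," not in line:
            raise ParseError(path, ln + 1, "expected 'id , genotypes' row")
        ind, geno = line.split(",", 1)
        toks = geno.split()
        if len(toks) != len(loci):
            raise ParseError(
                path, ln + 1, f"expected {len(loci)} genotypes, got {len(toks)}"
            )
        try:
            rows.append([decode[t] for t in toks])
        except KeyError as exc:
            raise ParseError(path, ln + 1, f"bad genotype code {exc}") from None
        individuals.append(ind.strip())
    codes = np.array(rows, dtype=np.int8).reshape(len(individuals), len(loci))
    return GenotypeMatrix(loci, individuals, codes)


# ---------------------------------------------------------------- VCF

def write_vcf(calls: Iterable[VariantCall], path, contigs=None) -> None:
    """Minimal VCF v4.2: DP, AC and a TS_TV tag in INFO; FILTER=PASS.

    REF is the pileup reference base; ALT the called allele differing from
    it (both called alleles when neither matches the reference).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Filtered depth">\n')
        fh.write(
            '##INFO=<ID=AC,Number=A,Type=Integer,Description="Allele count">\n'
        )
        fh.write(
            '##INFO=<ID=TS_TV,Number=1,Type=String,Description='
            '"transition or transversion">\n'
        )
        fh.write(
            '##INFO=<ID=VC,Number=1,Type=String,Description="Variant class">\n'
        )
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: (c.scaffold, c.pos)):
            alts, acs = [], []
            for allele, count in ((c.major, c.major_count), (c.minor, c.minor_count)):
                if allele != c.ref:
                    alts.append(allele if allele != "*" else "<NON_SNP>")
                    acs.append(str(count))
            if not alts:
                continue
            info = [f"DP={c.depth}", f"AC={','.join(acs)}"]
            if c.ts_tv:
                info.append(f"TS_TV={c.ts_tv}")
            info.append(f"VC={'SNP' if c.variant_class == 'SNP' else 'NON_SNP'}")
            fh.write(
                f"{c.scaffold}\t{c.pos}\t.\t{c.ref}\t{','.join(alts)}\t.\tPASS\t"
                + ";".join(info)
                + "\n"
            )


# ---------------------------------------------------------------- reports

def write_spectrum_tsv(summary, path) -> None:
    with open(path, "w") as fh:
        fh.write("type\tcount\n")
        for t, n in summary.type_counts.items():
            fh.write(f"{t}\t{n}\n")
        fh.write(f"transitions\t{summary.ts_count}\n")
        fh.write(f"transversions\t{summary.tv_count}\n")
        ratio = "NA" if summary.ts_tv_ratio is None else f"{summary.ts_tv_ratio:.3f}"
        fh.write(f"ts_tv_ratio\t{ratio}\n")
        fh.write(f"snp_count\t{summary.snp_count}\n")
        fh.write(f"nonsnp_count\t{summary.nonsnp_count}\n")


def write_region_tsv(rows: Iterable[tuple], path) -> None:
    """Rows: (gene, scaffold, pos, ref, alt, RegionCall)."""
    with open(path, "w") as fh:
        fh.write("gene\tscaffold\tpos\tref\talt\tregion\taa_change\n")
        for gene, scaf, pos, ref, alt, rc in rows:
            fh.write(
                f"{gene}\t{scaf}\t{pos}\t{ref}\t{alt}\t{rc.region}\t"
                f"{rc.aa_change or ''}\n"
            )


def read_region_tsv(path) -> list[tuple]:
    out = []
    with open(path) as fh:
        next(fh)
        for ln, line in enumerate(fh, 2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 7:
                raise ParseError(path, ln, f"expected 7 columns, got {len(parts)}")
            gene, scaf, pos, ref, alt, region, aa = parts
            out.append(
                (gene, scaf, int(pos), ref, alt, RegionCall(region, aa or None))
            )
    return out


def write_coloc_tsv(
    rows: Iterable[tuple[str, Optional[int], list[Colocalization]]], path
) -> None:
    """Gene–QTL report (one row per gene): LG, closest QTL marker, distance
    in kbp, evidence; "nd" when no QTL marker shares the gene's scaffold."""
    with open(path, "w") as fh:
        fh.write("gene\tLG\tqtl_marker\tdistance_kbp\ttrait\tevidence\n")
        for gene, lg, colocs in rows:
            lg_s = "nd" if lg is None else str(lg)
            if not colocs:
                fh.write(f"{gene}\t{lg_s}\tnd\tnd\tnd\tnd\n")
                continue
            best = min(colocs, key=lambda c: c.distance_bp)
            fh.write(
                f"{gene}\t{lg_s}\t{best.marker}\t{best.distance_bp / 1000:.0f}\t"
                f"{best.qtl_trait}\t{best.evidence}\n"
            )


def write_panel_tsv(panel, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tscaffold\tpos\talleles\tregion\trationale\n")
        for e in panel:
            c = e.snp.call
            fh.write(
                f"{e.gene_id}\t{c.scaffold}\t{c.pos}\t{c.major}/{c.minor}\t"
                f"{e.snp.region.label}\t{e.rationale}\n"
            )


def write_locus_stats_tsv(table, path, decimals: int = 3) -> None:
    """Per-locus validation report (panel-table shape): MAF, p(HW), He, Fis."""
    with open(path, "w") as fh:
        fh.write("locus\tstatus\tn\tMAF\tp_HW\tHe\tFis\n")
        for _, r in table.iterrows():
            def fmt(x, d=decimals):
                return "-" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.{d}f}"

            fh.write(
                f"{r.locus}\t{r.status}\t{r.n_typed}\t{fmt(r.maf)}\t"
                f"{fmt(r.hw_p, 4)}\t{fmt(r.he)}\t{fmt(r.fis)}\n"
            )


def write_ld_tsv(pairs: Iterable[LDPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("locus_a\tlocus_b\tG\tp\tm\tsignificant\tbonferroni\n")
        for p in pairs:
            fh.write(
                f"{p.locus_a}\t{p.locus_b}\t{p.g:.4f}\t{p.p:.6f}\t{p.m}\t"
                f"{int(p.significant_nominal)}\t{int(p.significant_bonferroni)}\n"
            )
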