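"""Select one assay-worthy SNP per candidate gene.

Two candidates in one gene: an intronic SNP with a long clean flank and a
3'UTR SNP co-localized with a growth QTL.  Region priority and the QTL
bonus decide; the discovery minor-allele-fraction floor (default 0.1)
excludes SNPs whose minor allele was barely seen in the pooled reads.
"""

from collections import Counter

from qtlsnp.annotation import RegionCall
from qtlsnp.calling import AlleleTally, call_variant
from qtlsnp.mapping import Colocalization
from qtlsnp.selection import CandidateSNP, select_panel

def cand(pos, region, maf, flank, aa=None):
    call = call_variant(AlleleTally("s1", pos, "A", Counter({"A": 30, "G": 15})))
    return CandidateSNP("lepr", call, RegionCall(region, aa), maf, flank)

candidates = {
    "lepr": [
        cand(1200, "intron", maf=0.33, flank=80),
        cand(3400, "three_prime_utr", maf=0.25, flank=45),
        cand(5100, "exon_synonymous", maf=0.05, flank=90),  # below MAF floor
    ]
}
colocs = {
    "lepr": [Colocalization("lepr", "BW", "Sma-USC65", 488_000, True,
                            "direct-marker")]
}

panel, unselectable = select_panel(candidates, colocs)
for e in panel:
    print(f"{e.gene_id}: SNP at {e.snp.call.scaffold}:{e.snp.call.pos} "
          f"[{e.snp.region.label}] score={e.score:.1f}")
    print(f"  rationale: {e.rationale}")
print("The 3'UTR SNP wins on region priority; the low-MAF candidate was")
print("excluded before scoring, mimicking manual read inspection.")
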