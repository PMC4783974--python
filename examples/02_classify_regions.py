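"""Classify a SNP's gene region and codon effect on a toy gene.

A plus-strand gene with a 5'UTR, a one-exon CDS (ATG GTT TAA) and a split
3'UTR is built by hand; three SNPs are classified.  A coding change is
called synonymous or non-synonymous by translating the reference and
alternate codons (strand-aware for minus-strand genes).
"""

from qtlsnp.annotation import GeneModel, classify_snp_region

genome = {"s": "A" * 10 + "TTTTTTTTTT" + "ATGGTTTAA" + "CCC" + "G" * 20
               + "CCCCCCCC" + "A" * 10}
gene = GeneModel("toy", "s", "+", exons=[(11, 32), (53, 60)], cds=[(21, 29)])

for pos, ref, alt in [(25, "T", "C"), (26, "T", "C"), (40, "G", "A")]:
    rc = classify_snp_region(pos, ref, alt, gene, genome)
    print(f"SNP {ref}>{alt} at {pos}: {rc.label}")

print("GTT->GCT swaps valine for alanine (non-synonymous, 'Exon V-A');")
print("GTT->GTC keeps valine (synonymous); position 40 falls in the intron.")
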