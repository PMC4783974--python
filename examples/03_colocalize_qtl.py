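"""Co-localize a placed candidate gene with growth-QTL markers.

A gene on scaffold s1 is compared with QTL markers resolved through the
map-anchor table.  Distance is measured from the nearest gene-span
boundary; markers within 1 Mbp are flagged as preferred candidates.  The
0.5 Mb/cM factor converts physical to genetic distance.
"""

from qtlsnp.annotation import GenePlacement
from qtlsnp.mapping import MapAnchor, QTLRecord, colocalize, mb_to_cm

gene = GenePlacement("fgf6b", "s1", 1_034_001, 1_040_000, "+", 1.0)
anchors = [
    MapAnchor("SmaUSC-E11", 16, 2.0, "s1", 1_000_001),
    MapAnchor("Sma-USC223", 16, 4.5, "s1", 2_600_000),
]
qtls = [
    QTLRecord("K", 16, "SmaUSC-E11", vpe=25.0),
    QTLRecord("BW", 16, "Sma-USC223", vpe=13.0),
]

colocs, warnings = colocalize(gene, qtls, anchors, max_pref=1_000_000)
for c in colocs:
    d_mb = c.distance_bp / 1e6
    print(
        f"{c.gene_id} ~ {c.marker} ({c.qtl_trait}-QTL): "
        f"{c.distance_bp / 1000:.0f} kbp (~{mb_to_cm(d_mb):.2f} cM), "
        f"within 1 Mbp preference: {c.within_preference}"
    )
print("The closer marker lies 34 kbp from the gene boundary - a strong")
print("co-localization; the second is outside the 1 Mbp preference window.")
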