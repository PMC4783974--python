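"""Simulate a toy transcriptome pileup and call SNPs from it.

Builds a small draft genome with planted variants of known pooled
frequency, simulates a Poisson-depth pileup with Phred-scored bases, and
runs the quality/depth/minor-allele-count caller over it.  Prints the call
counts, the substitution spectrum and the transition/transversion ratio:
transitions (A<->G, C<->T) typically outnumber any single transversion
type in fish transcriptomes.
"""

from qtlsnp.calling import call_sites, spectrum
from qtlsnp.sim import SimConfig, gen_genome, make_truth, sim_pileup

cfg = SimConfig(seed=1)
genome, genes = gen_genome(cfg)
truth = make_truth(genome, genes, cfg)
calls = call_sites(sim_pileup(genome, truth, cfg), min_base_qual=20,
                   min_depth=10, min_mac=3)
s = spectrum(calls)

print(f"planted variants : {len(truth.variants)}")
print(f"calls            : {len(calls)} "
      f"({s.snp_count} SNPs, {s.nonsnp_count} non-SNP polymorphisms)")
print(f"SNP fraction     : {s.snp_fraction:.3f}")
for t, n in s.type_counts.items():
    print(f"  {t}: {n}")
print(f"ts/tv ratio      : {s.ts_tv_ratio:.3f}")
print("A ratio above 1 means transitions dominate, as expected from the")
print("mutational bias the generator plants.")
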