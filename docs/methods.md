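# Methods

This note documents the models, estimators and design choices behind
`qtlsnp`, in the order the pipeline runs them.

## Synthetic data: what it emulates

The generator (`qtlsnp.sim`) produces every input the pipeline consumes,
with known ground truth:

- **Genome and gene models.** Random scaffolds (`Sm_1`, `Sm_2`, …) host
  non-overlapping genes on both strands.  Each gene has a 5'UTR, a CDS
  spread over one or more exons (ATG start, no internal stop, length a
  multiple of 3, stop codon at the end) and a 3'UTR, with introns of
  40–120 bp.  Defaults: 4 scaffolds × 2,500 bp, 8 genes, 2–4 exons per
  gene, UTRs of 60/90 bp — a desk-scale genome of 10⁴ sites chosen so that
  exhaustive per-position property tests stay fast.
- **Pooled discovery sample.** The discovery material is a pooled sample,
  so individual genotypes are unrecoverable from the pileup; the simulator
  models each planted variant only by its pooled alternate-allele
  frequency, drawn uniformly from [0.1, 0.5].  Depth is Poisson with mean
  50; each read base is the alternate allele with that frequency, then
  flipped to a random other base with probability 10^(−Q/10) for its Phred
  quality Q, drawn from a mixture (default 90% Q40, 10% Q12, i.e. a small
  tail of ~6% error bases).  Variant density is 10/kb, the ~1 SNP/100 bp
  typical of fish transcriptomes; 5% of planted variants are non-SNP
  polymorphisms (indel-token alleles); planted substitutions are
  transitions with probability 1.346/2.346 ≈ 0.574, matching a ts/tv ratio
  of ≈1.35 as observed in flatfish transcriptome SNP sets.
- **Validation population.** Genotypes at each planted SNP are drawn from
  Wright's inbreeding equilibrium: P(AA) = p² + fp(1−p),
  P(Aa) = 2p(1−p)(1−f), P(aa) = (1−p)² + fp(1−p).  Negative f is accepted
  down to the feasibility bound (all probabilities ≥ 0) so heterozygote
  excess — common in small validation samples — is representable.  Defaults:
  n = 34 diploids (the size of the reference validation sample), f = 0,
  2% missing genotypes.
- **Map tables.** Each scaffold except the last is anchored to its own
  linkage group by two markers (cM = bp at 0.5 Mb/cM); the last scaffold is
  left unanchored to exercise the synteny-inference path.  Three QTLs point
  at anchor markers directly and one is marker-less, resolved through
  confidence-interval reference markers.

What the generator does **not** emulate: read-level artifacts (alignment
error, strand bias, indel realignment), allele-specific expression in the
pooled RNA (allele frequency at expressed sites may not equal the DNA
pool frequency), population structure in the validation sample, and
linked loci (all planted SNPs are simulated independently, so LD tests on
synthetic data measure the null).  Passing tests therefore demonstrate
algorithmic correctness and statistical calibration, not robustness to
those real-data artifacts.

Everything is a pure function of the configuration seed: the same
`SimConfig` yields byte-identical files.

## SNP calling

Per site, observations below the Phred floor (default 20) are discarded
first; a call then requires quality-filtered depth ≥ 10 and second-most-
frequent allele count ≥ 3.  Applying the quality filter before the depth
filter means low-quality bases can never support a call; the order is
configurable for sensitivity analysis.  Ties between equally frequent
alleles break lexicographically.  Reads from multiple libraries are merged
by per-site tally addition *before* calling (`combine_tallies`), so the
thresholds act on combined coverage.

A call whose top two alleles are single bases is a SNP; an indel token in
the top two makes it a non-SNP polymorphism.  When a third allele also
clears the minor-allele-count threshold the top two are called and the
extras recorded in a note; such sites are excluded from the six-type
substitution spectrum so the ts/tv partition stays well defined.  The
ts/tv ratio is reported as undefined (None) when no transversions exist.

Monotonicity (tightening any threshold never increases the call count) and
conservation (SNPs + non-SNP polymorphisms = calls; the six substitution
types partition biallelic SNPs) are enforced by property tests.

## Region and codon-effect classification

Gene models store exons and CDS (1-based inclusive, as in GFF3); UTRs and
introns are derived, with the 5'UTR on the higher-coordinate side for
minus-strand genes.  A coding SNP's codon is read from the spliced CDS in
reading orientation; the alternate allele is complemented for minus-strand
genes before substitution, and both codons are translated with the
standard genetic code (synonymous if equal, otherwise "X-Y" with the
reference amino acid first).  Region assignment is a partition: every
in-gene position maps to exactly one of the five classes, verified by
exhaustive sweeps and by strand-symmetry tests against mirrored genes.

Transcript placement uses an ungapped seed-and-extend matcher (exact
11-mer seeds, match +1 / mismatch −2, X-drop 20, both strands) with
identity and aligned-length thresholds instead of an e-value — thresholds
that are directly interpretable at the scales this package targets.  A
placement is accepted only when all passing hits fall on a single scaffold
("non-unique" otherwise).  Precomputed hit tables from an external aligner
can be supplied wherever hits are accepted.  For multi-isoform genes the
reported region is that of the canonical (longest-CDS) transcript; per-
isoform calls can be retained by classifying each transcript separately.

## QTL co-localization

Gene–marker distance is measured from the nearest gene-span boundary
(0 when the marker lies inside the span): published gene–marker distances
in this setting are boundary-style, and the reference point is otherwise
underdetermined.  The 1 Mbp proximity window is a ranking preference, not
a filter — more distant co-localizations remain in the report.  Marker-less
QTLs are resolved through their confidence-interval reference markers
(evidence tier "closest-marker"); scaffolds without anchors can be
assigned a linkage group by majority vote over model-species ortholog
positions, flagged "inferred", with ties yielding no assignment.
Genetic↔physical conversion uses 0.5 Mb/cM (configurable).

## Panel selection

One SNP per gene, scored deterministically:
`10·(region rank) + qtl_bonus + min(flank, 30)/30`, with region priority
non-synonymous exon > 5'UTR > 3'UTR > synonymous exon > intron and a
bonus (default 5) for any within-preference QTL co-localization.
Candidates with discovery minor-allele fraction < 0.1 are excluded before
scoring — a codified reconstruction of the manual read-inspection step
that discards low-MAF genes in practice, not a claim about any particular
study's threshold.  Ties break by larger clean flank, then smaller genome
coordinate, making selection a pure function of its inputs.

## Validation statistics

- **He**: Nei's unbiased gene diversity,
  He = n/(n−1)·(1 − Σp̂² − Ho/2n).  The simpler (2n/(2n−1))·(1 − Σp̂²)
  correction was rejected because it disagrees at the third decimal with
  the reference panel values this implementation reproduces (e.g. 0.507
  vs 0.508 at a locus with 16/34 heterozygotes and MAF 0.5).
- **F_IS** = 1 − Ho/He with the He above; undefined when He = 0.
  (A Weir–Cockerham variant was considered and left out: the simple ratio
  matches every reconstructable reference row.)
- **Exact HW test**: complete enumeration conditional on allele counts,
  probability-ordering (two-sided) p-value, computed with log-factorials
  and a 1e−12 relative tie tolerance.  The enumeration normalises to 1
  within 1e−9 for all n ≤ 200 (property test) and agrees exactly with a
  rational brute-force oracle over genotype multisets for n ≤ 8.
- **LD G-test**: G = 2·ΣO·ln(O/E) over the genotype×genotype table (zero
  cells skipped), null by m permutations of one locus's genotype column;
  p = (b+1)/(m+1) so p is never 0 and never below 1/(m+1).  Permuting one
  column leaves both margins fixed, which allows a fully vectorised
  permutation loop.  Default m = 10,000 for standalone tests; the pipeline
  default is m = 1,000 per pair, adequate for its nominal-rate summaries
  over thousands of pairs.  Type-I error at the nominal 5% level is
  calibration-tested over 741 independent-locus pairs.
- **Missing data**: all statistics use locus-wise complete cases (pairwise
  for LD); per-locus n is carried through and reported.
- **Assay classification**: failed if > 50% genotypes missing, monomorphic
  if one allele observed, polymorphic otherwise; diversity statistics and
  HW tests run on polymorphic loci only, and the LD family size is
  C(k, 2) over the k polymorphic loci with Bonferroni threshold α/k.
- **Panel means** are arithmetic over polymorphic loci, reported with SD
  and SE; reports round to 3 decimals (4 for HW p-values), internal values
  keep full precision.

## Numerical and interface conventions

All file formats use 1-based inclusive coordinates; conversions are
centralised in `qtlsnp.formats`.  GENEPOP files use 2-digit allele codes
(01 = stored reference orientation, 02 = alternate, 00 = missing); the
reader re-polarises counts so "major" is always the more frequent allele.
Genotype matrices realised from published counts (`GenotypeMatrix.
from_counts`) are laid out in genotype order, which is fine for per-locus
statistics but induces artificial between-locus association; a seed
argument shuffles columns independently when LD tests are intended.
The pipeline seeds every stochastic stage from one configuration seed and
is byte-reproducible end to end.

## Known limitations

- The seed-and-extend placer is ungapped; transcripts spanning introns
  align as multiple local hits and the placement span covers them jointly,
  but genes with very short exons (< k = 11 bp) may not seed.
- The HW enumeration is exact only for biallelic loci (by design; the
  package scopes to biallelic SNP panels).
- The LD permutation scheme is one documented reconstruction of the
  genotypic G-test; other implementations may permute differently, so
  p-values are comparable in calibration, not bit-for-bit.
- The ± values sometimes attached to published panel means are not
  reproduced (their definition — SD, SE or jackknife — is ambiguous);
  plain SD and SE are reported instead.
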