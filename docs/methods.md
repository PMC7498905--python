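# Methods

## Tag prediction (in-silico FspEI digestion)

FspEI recognizes fully methylated CCGG and CCWGG and cleaves both strands a
fixed distance 3′ of the modified cytosine (N12/N16). Potential sites are
enumerated as every motif occurrence on either strand; a minus-strand
occurrence is recorded at the forward-strand coordinates of its footprint
with the motif text as read on the minus strand. CCGG is its own reverse
complement and CCAGG/CCTGG imply each other across strands, so each locus
produces a strand pair; `collapse_palindromes` merges the pair into one
record. The default is per-strand records, because methylation of the two
strands is biologically distinct; the synthetic pipeline collapses, so one
planted locus is one tag. Candidate windows containing N are skipped — a
motif call needs unambiguous bases — while flanks may contain N (a flank
mismatch is absorbed by the matcher's mismatch allowance).

Tag geometry is not dictated by the enzyme alone; the default flanks are 12
bp upstream and 16 bp downstream of the motif on its strand (≈32-33 bp
tags), mirroring the cleavage offsets, and both are configurable. Tags
truncated by a contig edge are flagged `clipped`. Coordinates are 0-based
half-open internally and 1-based only at FASTA-header/GFF3 boundaries.

## Read-to-tag matching

A read matches a tag if the shorter sequence aligns ungapped within the
longer at some offset with Hamming distance ≤ 2 over the overlap, in either
orientation; reads with more than one N are discarded first. A read is
counted only when a single site attains the minimum distance and every
other hit exceeds it — the "uniquely mapped" criterion. An 8-mer seed index
is purely an acceleration: for overlaps of at least three seed lengths, a
≤2-mismatch alignment must contain an exact aligned 8-mer (pigeonhole over
three blocks), so seed lookup plus verification cannot miss a hit; shorter
overlaps fall back to exhaustive scanning. Tests assert exact equality with
a brute-force all-pairs oracle.

The library total used for reads-per-million is the number of reads
surviving the N filter (before matching) — the closest reading of
"total reads per library" — and is the denominator even for unmatched
reads.

## Methylation calls and false-positive calibration

A site is methylated in a sample iff its raw count ≥ `min_cov` (default 2).
Because the plant chloroplast genome is essentially unmethylated, any
chloroplast site passing the threshold estimates the protocol's false-
positive rate: FP% = 100 × (chloroplast sites called) / (chloroplast
sites), per CG/CHG class, per sample and pooled. Under the generator's
emission model (below) the pooled estimate converges on the Poisson tail
P(Poisson(depth × leak) ≥ min_cov), which the tests verify against a
closed form over a grid of depths and leak rates.

## Context annotation

A site's anchor is the second cytosine of its motif — the base the enzyme
reads — in forward-strand coordinates. The site is genic iff the anchor
overlaps any `gene` feature and TE iff it overlaps any feature whose
source/type/attributes match the RepeatModeler round-family pattern
`rnd-[1-5]` (configurable); the two axes are independent because TEs occur
inside genes and between them. GFF3 intervals (1-based inclusive) convert
to 0-based half-open on parse; overlap queries use an interval tree that
tests verify against a naive scan. Context summaries are computed over
sites methylated in at least one sample, with partition fractions that sum
to one by construction.

## Genetic variation

The filter cascade follows the standard hard-filtering order: site-level
INFO thresholds (drop when QD < 15, FS > 12, MQ < 38, MQRankSum < −1.5,
ReadPosRankSum < −4, or DP > 4000 — the DP ceiling removes variants in
collapsed duplications), then genotype masking (GQ < 30 or DP < 20 set
missing), then selection of biallelic SNPs with minor-allele frequency
≥ 0.01 and zero missingness. A missing INFO annotation does not trigger
its criterion (rank-sum statistics are undefined at sites without the
required genotype classes); a strict mode is available. SNPs at which all
samples share one genotype are then excluded: they measure distance to the
reference genome, not among clonal ramets. Genotypes are encoded as
alternate-allele dosage (0/1/2) — the simplest convention, adopted as
normative since distance tools differ — and genetic distance is Euclidean
over dosage vectors. Multilocus microsatellite genotypes group samples
into genets by exact matching with order-insensitive allele pairs; samples
with a missing locus remain unassigned rather than fuzzily matched.

## Epigenetic distance

Per sequence context, the RPM matrix (sites × samples) is transposed,
zero-variance sites are dropped (scaling them is undefined; the count is
reported), columns are centered and by default scaled to unit variance, and
samples are projected on the top two principal components (full SVD; sign
fixed by making the first sample's score nonnegative). Distance is
Euclidean in that plane, which is invariant to component sign flips, and
`relative_distances` divides by the maximum for cross-context comparison.
Unit-variance scaling defaults on, matching the common PCA-tool default;
the flag exists because either choice is defensible. On data of rank ≤ 2
the plane is lossless and 2-D distances equal full-space distances, which
is tested.

## Phenotype (JIP test)

From each OJIP measurement: VJ = (FJ−F0)/(FM−F0), M0 = 4(F300µs−F0)/(FM−F0),
and PiABS = ((1−F0/FM)/(M0/VJ)) · ((FM−F0)/F0) · ((1−VJ)/VJ). PiABS is a
ratio of fluorescence values, hence invariant to the instrument's absolute
scale (property-tested). Records with VJ ∉ (0,1) or M0 ≤ 0 (saturated or
inverted kinetics) are flagged non-finite and excluded from shoot means
rather than propagated — one bad measurement should not void a shoot. A
shoot's value is the mean of its ≤ 4 finite measurements (two replicates on
each of two inner leaves). The performance-difference matrix is
|PiABS_i − PiABS_j| of shoot means: the minimal choice that is a valid
distance matrix.

## Mantel inference

The Mantel statistic is the Pearson correlation over the n(n−1)/2 distance
pairs; the null is built by simultaneously permuting rows and columns of
one matrix. The partial statistic is the first-order partial correlation
r_xy·z recomputed for every permutation of the first matrix (r_yz is
permutation-invariant). The alternative is one-tailed greater — the
question is whether distances covary positively — and
p = (1 + #{r_perm ≥ r_obs}) / (1 + N), so p ≥ 1/(N+1) and is never zero.
For n ≤ 6 an exact mode enumerates all n! relabelings, which anchors the
sampled estimator in tests. Conditioning matrices perfectly correlated with
either argument (|r| = 1) raise a degenerate-conditioning error. Family
p-values are Benjamini-Hochberg adjusted (Bonferroni available), and an
association is "biologically linked" when r > 0.65 and adjusted p < 0.05.
Calibration tests show ~5% type-I error under independent random matrices
(200 replicates, n = 10, 1,000 permutations) and ≥95% detection of a
perfectly planted coupling.

## Differential methylation

TMM normalization follows the published definition: the reference is the
sample whose 75th-percentile count fraction is nearest the mean; M (log2
relative abundance vs reference) and A (mean log abundance) are computed
over sites nonzero in both libraries; M is trimmed 30% and A 5% per tail;
the factor is 2 to the inverse-asymptotic-variance weighted mean of the
surviving M, and factors are rescaled to geometric mean 1. This is a
from-scratch implementation anchored by a brute-force oracle (1e-9
agreement), not a bit-compatible clone of any release of the established
count-analysis packages; tag-wise dispersion and GLM pipelines are out of
scope because a two-group design with all samples as replicates is served
by the classic exact-test path.

Counts are equalized to the geometric-mean effective library by scaling
and rounding (a simplification of quantile adjustment, documented as a
deviation). A single common NB dispersion φ maximizes the profile
likelihood — group means profiled at their MLE — over a log grid with
bounded refinement; φ = 0 (Poisson) is admissible and parameter recovery
is simulation-tested. The exact test conditions on each site's total: the
two group sums are NB with size n_g/φ and shared success probability
1/(1+φμ₀), and the two-sided "doubletail" p sums the probabilities of all
splits as or less likely than observed; at φ = 0 and equal effective
libraries this reduces exactly to the two-sided binomial test (verified to
1e-9). log2 fold changes use a 0.5 prior count per group; sites all-zero
across samples are dropped; direction is hyper (higher in the second
group) or hypo at BH-adjusted p < 0.05.

## Synthetic-data generator

The generator emulates the study design the package targets: clonal shoots
split into two performance groups, methylomes with group structure, and a
phenotype coupled to methylome distance.

* **Genome** — uniform-random bases with the requested number of CCGG and
  CCWGG loci planted non-overlapping (flank-padded so no tag is clipped);
  with `exclusive_motifs` accidental occurrences on either strand are
  edited away by rejection, so digest counts are exactly verifiable. One
  contig is the chloroplast; it carries recognition sites but its
  methylome rows are forced to zero.
* **Methylomes** — each group draws one site pattern from class-specific
  probabilities (defaults 0.5 for CG, 0.4 for CHG, reflecting the CG-rich
  methylation typical of plant genomes); each sample inherits its group
  pattern with independent per-site flips at `epimutation_rate`
  (default 0.02, standing in for accumulated ramet-level epimutation
  divergence — the per-generation rate would be orders smaller, but
  ramets of a centuries-old genet are many mitotic generations apart).
  Sites where the two group patterns differ are the planted differential-
  methylation truth.
* **Reads** — methylated sites emit Poisson(`mean_depth`, default 10)
  copies of the tag; unmethylated sites leak Poisson(depth ×
  `fp_emission_rate`) reads. The default leak 0.007 makes the 2×-coverage
  chloroplast call rate ≈ 0.24%, a sub-percent rate of the magnitude real
  MethylRAD calibrations report. Optional per-base substitution errors
  (default 0) exercise the mismatch tolerance. The Poisson emission model
  is an assumption: no noise model for MethylRAD counts is established,
  and real libraries add PCR duplication and coverage biases this
  generator does not represent — passing tests certify the estimators
  under this model, not under every real-data pathology.
* **Genotypes** — one shared ancestral zygote: most SNPs heterozygous and
  identical in all samples; a `somatic_diff_rate` fraction (default 0.07,
  the order observed between clonal ramets) differ in a random sample
  subset. Fractions of records violate one hard filter each, or carry a
  low-GQ genotype, so every filter stage is exercised; the clean differing
  SNPs are the ground-truth dosage matrix.
* **Phenotype** — per-sample PiABS targets combine the first classical-MDS
  coordinate of the true methylome distance matrix (weight
  `mantel_effect`) with independent Gaussian noise (weight
  √(1−effect²)), mapped to a plausible PiABS range (mean 3, SD 0.8,
  floor 0.5). Quadruples are back-solved with F0 = 100 and FM = 500
  (arbitrary units) and VJ = 0.5, so M0 = 1.6/PiABS and the forward
  computation reproduces each target exactly; targets below 0.4 would
  demand M0 ≥ 4 and raise a construction error. A 1-D embedding is only
  lossless for 1-D distance structure, so perfect r = 1 is expected only
  there; for group-structured methylomes the embedding captures the
  dominant separation and detection remains near-certain at effect 1.
* **Annotation** — genes placed non-overlapping in per-contig slots; TE
  intervals (~300 bp) placed alternately inside genes and anywhere, until
  `te_fraction` of each contig is covered.

All generators derive their streams from a single seed; identical seeds
give byte-identical output files.

## Problem sizes and numerical choices

The acceptance run and end-to-end tests use 20 samples, 5,000 tag loci on
264 kb of genome, and 800 SNPs — a scale chosen so a full run takes about a
minute while every estimator operates far from small-sample regimes.
Statistical calibration tests use 150-200 replicates with binomial
(≈99%) acceptance envelopes around nominal rates. Numerical conventions:
PCA via full SVD with first-sample-positive sign; distance matrices
symmetrized and diagonal-zeroed to kill float asymmetry before condensed
extraction; permutation p-value comparisons use a 1e-12 slack so the
identity relabeling ties with the observed statistic; doubletail
probability comparison uses a (1+1e-10) relative slack as is conventional
for discrete two-sided tests.

## Known limitations

The matcher is ungapped and quality-blind (no indels, no BAM); enzyme
efficiency, hemimethylation, and CCGG/CCWGG affinity differences are not
modeled; dispersion is common rather than tag-wise; the generator draws
independent sites (no LD, no methylation autocorrelation along the
genome); inter-genet comparisons and clonal-richness statistics beyond
exact multilocus grouping are out of scope.
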