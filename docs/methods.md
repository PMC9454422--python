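# Methods

## Genotype model and conventions

The canonical object is a samples x sites matrix of alternate-allele
dosages (0/1/2, with -1 for a missing call) over biallelic SNPs only.
Coordinates are 1-based inclusive everywhere inside the package, matching
VCF; BED input/output converts at the boundary (internal `[s, e]` maps to
BED `s-1, e`). GT phase separators are ignored: every statistic is
genotype-based. Multiallelic and indel records are skipped at read time.

QC thresholds are inclusive on both sides: a site at exactly minor-allele
frequency 0.05, or at exactly missing rate 0.20, is kept. The published
filter expression this mirrors does not state boundary behaviour, so the
inclusive convention is a package decision and boundary hits are logged.
Non-autosomal contigs are retained at read time; the F_ROH denominator can
be restricted through an explicit autosome list (by default every contig
counts, which matches the synthetic cohorts).

## ROH detection

The ROH definition is five explicit criteria (minimum SNP count 100,
density at least one SNP per 100 kb computed as `length / n_snps <= 1e5`,
minimum length 1 Mb, at most 1 heterozygous and 2 missing calls per run,
maximum inter-SNP gap 1 Mb). Two conventions the criteria leave open are
fixed as follows:

* **Boundary homozygosity.** The first and last SNP of a run must be
  homozygous. Allowing a het/missing terminus would extend a run with a
  SNP that carries no evidence of autozygosity.
* **Selection among overlapping windows.** Scanning left to right, the
  earliest start with any qualifying window is extended to its largest
  qualifying end; the run is emitted and the scan resumes after it. Ties
  at equal start resolve to the longest window. This recursive greedy rule
  is deterministic and independent of input permutations.

The production scanner uses prefix sums (het/missing budgets), gap-break
blocks and a downward end-scan per candidate start; the test suite proves
it equal to an exhaustive all-windows enumerator on hundreds of random
instances with randomised criteria. Because detection is exact on the
criteria rather than a sliding-window heuristic, segment margins may
differ from heuristic tools run on the same data.

F_ROH divides an individual's summed ROH length by the SNP-covered
autosomal length (sum over chromosomes of last-minus-first SNP position
plus one). ROH incidence at a SNP is the fraction of **all** individuals,
pooled across populations, whose ROH cover its position; islands are
maximal runs of consecutive SNPs with incidence >= 0.30 (inclusive
comparison, chosen where "above 30%" and "0.3 as the threshold" conflict),
never merged across a below-threshold SNP. Note that raising the island
threshold shrinks the set of member SNPs monotonically but can *split* an
island in two, so the island count itself is not monotone.

## LD decay

r² is the squared Pearson correlation of dosage vectors over samples
non-missing at both sites — the genotype-correlation convention for
unphased data; EM haplotype-frequency r² is out of scope. Pairs are
same-chromosome, distance in (0, `max_dist`] with `max_dist` defaulting to
5 Mb (only the 200 kb bin width is prescribed by the source analysis; the
pair-distance ceiling is a package default). Binning is half-open
(`[0, 200k), [200k, 400k), ...`). "Linear fitting" is reproduced as OLS of
per-bin mean r² against bin midpoint, with a Spearman rank statistic
alongside; no parametric decay family is asserted because none is given.
LD is computed within-breed, matching per-population decay curves.

## Distances, NJ, bootstrap, PCA

The tree-building distance is allele-sharing (IBS) by default —
`d = mean(|d_i - d_j|) / 2` over co-typed sites — because the source
analysis never names its distance matrix metric. A K2P distance on
consensus pseudo-sequences (dosage 0 -> ref, 2 -> alt, heterozygote -> a
seeded random allele; transitions A<->G, C<->T) is provided behind a flag
to mirror the stated substitution model; the genotype-to-sequence step is
a documented invention since K2P is defined on sequences. Saturated pairs
(log argument <= 0) are reported as +inf with a warning.

Neighbor joining is the standard Saitou–Nei agglomeration on the
Q-criterion, implemented in-package so that the tie-break (first minimum
in row-major order of the current node ordering) and branch-length
arithmetic are fully deterministic; it is exact on additive matrices
(topology and branch lengths), which the tests verify against randomly
generated additive trees and cross-check against scikit-bio's NJ.
Negative branch lengths are clamped to zero for presentation by default;
the raw value is retained on each node (`raw_length`).

Bootstrap support resamples site columns with replacement (multinomial
site weights), rebuilds the tree per replicate, and reports the fraction
of replicates containing each internal bipartition of the full-data tree.

PCA normalises each dosage as `(d - 2p) / sqrt(p(1-p))` with p the
observed alternate-allele frequency, zero-fills missing cells after
centring, skips monomorphic sites, and eigendecomposes the sample
covariance `ZZ'/m`; coordinates are the projections `U * sqrt(m*lambda)`.

## Synthetic cohorts

The generator emulates the cohort structure the analyses assume: several
differentiated populations of diploid individuals genotyped at SNPs placed
uniformly along chromosomes (default 4 populations x 30 individuals,
2 x 50 Mb chromosomes, 2e4 sites — one SNP per ~5 kb, desk-scale in
seconds). Population allele frequencies follow the Balding–Nichols model:
Beta(p(1-c)/c, (1-p)(1-c)/c) around an ancestral frequency p drawn
Uniform(0.1, 0.9), with c the F_ST-like drift parameter. This is the
simplest standard drift model reproducing a several-breed cohort; no
coalescent or recombination-map realism is attempted.

Inbreeding has two mechanisms:

* **site-wise** (`f_inbreed`): each genotype is independently autozygous
  with probability F. Exact for Hardy–Weinberg arithmetic
  (het = 2q(1-q)(1-F)) but leaves sites independent, so it creates
  neither ROH nor LD.
* **segmental** (`f_autozygous`): each individual receives non-overlapping
  autozygous segments (~2.5 Mb each, placed uniformly, padded by 1.5 Mb so
  neighbouring runs cannot fuse) covering the requested fraction of the
  SNP-covered genome, each copied homozygously from one of a small pool
  (default 4) of per-population founder haplotypes. Sharing founders is
  what real autozygosity does, and it is the mechanism that generates
  both run-length structure and block LD: with segmental F in
  {0, 0.1, 0.2}, within-population mean r² increases with F and decays
  with distance. At F = 0 the generator has *no* distance-dependent LD by
  construction, so a decay slope is only asserted for inbred populations.

Shared planted segments (`planted_segments`) homozygose a chosen fraction
of one population's individuals over one interval, producing the pooled
incidence needed for island calling (e.g. carrier fraction 0.7 in two of
four populations of 30 gives pooled incidence 42/120 = 0.35). Admixed
individuals draw each allele copy from population A with probability alpha,
else population B.

Truth files record realized autozygous intervals as the first/last SNP
positions inside each planted stretch — the same convention the detector
reports — so recovery is asserted to within one inter-SNP spacing at each
boundary (a carrier's run extends past the planted edge while flanking
sites happen to be homozygous; with typical heterozygosity this extension
is about one site).

What passing tests do **not** show about real data: the generator has no
linkage-map heterogeneity, no genotyping-error model, site-independent
missingness only, and drift without migration or selection; island
boundary behaviour on real data will be noisier than the one-spacing
recovery achieved here.

## Problem sizes and numerical choices

The test and acceptance runs use 2e4 sites x 30 individuals for F_ROH
recovery (three planted fractions, several seeds; mean absolute recovery
error < 0.005), 2e4 sites x 120 individuals for island calling, 1e4 sites
x 120 for PCA/k-means (agreement 100%) and 100-replicate bootstrap
(between-breed supports 1.0), and 1e4 sites x 90 for LD direction —
each chosen as the smallest cohort at which the statistic under test is
stable across seeds. Zero-variance LD pairs are skipped; all-missing
sites carry NaN frequencies and fail QC; empty QC results and empty
genotype matrices raise explicit errors rather than propagating empty
arrays. Percent shares are rounded to two decimals at the reporting
boundary only.
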