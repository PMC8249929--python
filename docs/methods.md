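# Methods

## The scan

`poolscan` detects candidate selective sweeps from pooled whole-genome
sequencing (Pool-Seq) of phenotype-contrasted populations. Each pool is one
sequencing library made from equimolar DNA of many individuals; allele
frequencies are estimated from read depths, never from genotypes. Two window
statistics drive the scan, both computed on fixed non-overlapping windows
(default 10 kb) tiled from position 1 of each scaffold:

**Pooled heterozygosity.** For each SNP in a pool, let n_MAJ and n_MIN be the
read counts of its most and least abundant allele. The window statistic is

    Hp = 2 Σn_MAJ Σn_MIN / (Σn_MAJ + Σn_MIN)²

with sums over the SNPs of the window. Hp ∈ [0, 0.5]; a sweep drags it toward
0. Per pool, window values are standardised as −ZHp = −(Hp − μHp)/σHp with
moments over that pool's retained windows, so large positive −ZHp marks
heterozygosity deficits. The standard deviation uses the sample convention
(ddof = 1, exposed as an argument); with thousands of windows the choice is
numerically irrelevant but it is fixed for determinism. Windows with fewer
than 10 SNPs are discarded *before* the moments are computed.

**F_ST.** Between-pool differentiation uses the Weir–Cockerham two-population
estimator in its allele-frequency (haploid-sampling) form. Per site, with
allele frequency p_i estimated by the read fraction and effective sample size
n_i = min(read depth, haploid pool size) — reads cannot represent more
independent chromosomes than were pooled — the between-population component a
and within-population component b are formed from the ANOVA mean squares
(MSP, MSG with n_c the usual sample-size correction), and the window estimate
is the ratio of sums Σa / Σ(a+b), the standard multi-locus Weir–Cockerham
combination. Negative estimates are reported as computed; truncating at zero
would bias the upper-tail quantiles the scan thresholds on. The tests check
this implementation to 1e−10 against an independent oracle that builds
explicit 0/1 allele arrays and runs the ANOVA literally.

**Three-step sweep calling.** Each scan's retained windows are thresholded at
the empirical top 3% ("higher" quantile interpolation so the cutoff is an
observed value; ties at the cutoff are all selected). Candidate regions are:
(1) windows in the top 3% of the F_ST scans of *both* (reference, target)
pairs; (2) windows in the top 3% of the −ZHp scans of *both* target pools;
(3) the intersection of (1) and (2). Adjacent surviving windows are merged
into regions, and genes whose span extended by a 10-kb flank on each side
intersects a region are reported.

## Site filters

A SNP enters the scan iff: per-pool A/C/G/T read depth within [10, 100],
phred site quality ≥ 20 when the input provides one (sync files do not;
such sites are counted but not rejected), minor allele frequency ≥ 0.05, and
no indel within 15 bp (boundary inclusive). In the pipeline the MAF
criterion is evaluated on read counts summed across the pools
(`joint_site_filter`): SNP sets for multi-pool scans come from joint variant
calling, and a site monomorphic in a swept population but polymorphic in the
reference must be retained — those are precisely the sites a heterozygosity
scan needs. Applying the MAF filter per pool instead silently deletes the
sweep signal: inside a swept region the target pool's MAF falls below 0.05,
the sites are dropped, and the windows fail the 10-SNP minimum. The per-pool
variant remains available (`filter_sites`) for single-pool workflows; both
attribute each rejection to the first failing reason (depth, quality, MAF,
indel).

## Validation statistics

The statistics used to validate pooled allele-frequency estimates against
individual genotyping:

- **χ² association** (`chi_square_association`): Pearson χ² without
  continuity correction on a genotype × group count table after dropping
  all-zero rows/columns; df = (rows−1)(cols−1). Expected cells below 5 are
  counted but not blocking — small genotype classes are routine in strongly
  associated tables. The bundled published tables for the KITLG, MITF, TYRO3
  and KIT SNPs reproduce their printed statistics (102.89, 80.44, 106.57,
  93.80) to two decimals under exactly this convention.
- **Fisher's exact allele-depth test** (`fisher_allele_depth`): two-sided
  exact p on the 2×2 table of (major, minor) read counts in two pools, used
  to rank SNPs for validation. Verified against exhaustive hypergeometric
  enumeration for all margins ≤ 30.
- **Allele frequency from genotypes** (`af_from_genotypes`):
  (2·hom + het) / (2n).
- **Kendall's W** (`kendall_w`): concordance of the pooled-read and
  genotype-based frequency estimates across loci, with mid-ranks for ties and
  the tie-corrected denominator W = 12S / (m²(n³−n) − mT), plus the χ² = 
  m(n−1)W approximation on n−1 df. With m = 2, identical orderings give
  W = 1 and reversed orderings give W = 0.
- **Loss-of-function classes** (`lof_categorize`): consequence terms map to
  1 stop gain/loss, 2 frameshift, 3 essential splice site, 4 initiator codon.

## The synthetic-data generator

`simulate_pool_counts` emulates the structure of a three-pool scan: a gray
reference pool of 117 diploids and two white target pools of 25 and 87, each
sequenced to a mean depth of 44×. Per site, a baseline minor-allele frequency
is drawn uniformly on [0.05, 0.5] (so sites pass the MAF filter by
construction; a configurable contamination fraction below 0.05 exercises the
filter), randomly oriented onto a derived allele, and perturbed per pool by
Gaussian drift noise (sd 0.03, clipped to [0, 1]). Inside a planted sweep the
target pools' derived-allele frequency is set to `derived_freq` (default
0.98), which depresses Hp in the targets and raises F_ST against the
reference. Depths are Poisson around the pool mean, truncated to
[1, 3·mean] so both depth-filter bounds are exercised; reads are binomial at
the pool frequency with a symmetric error flip (rate 0.002) between the
site's two alleles. Identical configuration and seed give byte-identical
output.

SNP density defaults to 0.002/bp (~20 SNPs per 10-kb window), enough that
the 10-SNP window filter passes typical windows. Planted sweeps default to
40 kb on distinct scaffolds: across the default 5 × 1 Mb genome the three
sweeps occupy 12 windows, deliberately inside the ~15-window capacity of the
3% tail — a sweep occupying more windows than the tail holds cannot fully
survive the intersection of independently thresholded scans, which is a
property of top-quantile calling, not of the data.

What the generator does *not* model: linkage and recombination (sweep edges
are step functions, not diversity valleys), demography, allele-frequency
spectra of real populations, mapping artefacts, or indels (indel positions
are supplied to the filter separately). Passing tests therefore demonstrate
that the statistics and the calling procedure behave as designed under their
own assumptions — they do not certify performance on real resequencing data.

## Numerical and design choices

- Internal coordinates are 1-based inclusive (sync/GFF3 convention); BED is
  converted at the I/O boundary. Window index of position p is ⌈p/size⌉.
- Major-allele ties break by fixed order A < C < G < T (Hp is symmetric under
  the choice; determinism only).
- For F_ST, the two pools' frequencies are expressed on the first pool's
  major allele; an allele absent from a pool's top-two counts has frequency
  0 there. Sites present in only one pool contribute to that pool's Hp but
  never to F_ST. Windows with no shared site, and empty windows for Hp,
  return an undefined sentinel (`None`), never 0.
- Haploid pool sizes are required parameters (234/50/174 for the default
  three-pool design, i.e. twice the diploid counts).
- A scan whose window values are all identical has no upper tail and is an
  error; a single-window scan degenerates with a warning.
- The χ² association p-value uses the asymptotic distribution; only the
  statistic is checked against printed values.

## Scale and limitations

The test and acceptance runs use a 5-scaffold × 1-Mb synthetic genome
(~10,000 SNPs, three pools) and 20 seeded replicates for the recovery
benchmark; these sizes were chosen so the whole suite runs comfortably on a
laptop. Published genome-scale outcomes of real scans of this design — SNP
totals in the millions, the counts of top-3% regions (hundreds) and of final
intersected regions (tens), gene lists and genome-wide F_ST summaries —
depend on the full resequencing data and a complete genome annotation and
are **not reproduced and not within reach** of the synthetic benchmark; the
property suite (closed-form identities, independent oracles, planted-sweep
recovery, null calibration) covers the machinery instead. Kendall's W on
real paired frequency tables is likewise only a hook: the package computes
it from any supplied AF table, but no such table is bundled.
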