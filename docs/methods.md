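# Methods

## Data model

The package operates on four aligned loci × samples matrices — blood and
tumour BAF in [0, 1], blood and tumour LRR in log2 units — plus a locus
annotation (chromosome, 1-based position, design alleles, optional gene and
cytoband). BAF is the normalised proportion of the array's B design allele;
LRR is log2 of total probe intensity against a reference and proxies total
copy number. Missing cells are NaN throughout and every operation skips them
cell-wise. Loci are kept in a total order (chromosome 1–22, X, Y; then
position; then locus id) so all outputs are deterministic.

## Pre-processing

Blood BAF is cut into genotype regions at fixed thresholds, default
(0.2, 0.8]: AA for BAF ≤ 0.2, AB for 0.2 < BAF ≤ 0.8, BB above. The boundary
inclusivity follows the region definitions as printed on the array-analysis
side; it matters only for values exactly at a threshold, which have measure
zero for continuous signals. Chromosome-Y loci are removed, then any locus
whose non-missing blood calls do not contain all three genotype groups —
monomorphic loci being the extreme case — is dropped as non-informative:
with no heterozygous reference cluster and no observed homozygote on each
side, a directional shift is undefined. Missing calls are ignored when
counting groups, so an all-missing locus is non-informative. The filter is
idempotent and its counts partition the input exactly.

## Directional disparity

Per locus, the blood-heterozygous samples give the reference cluster mean μ
and sample SD σ (n−1 denominator) of blood BAF. Loci with fewer than two
usable heterozygotes are skipped: σ is undefined and no 2-SD band exists.
A blood-AB sample counts as shifted toward AA when its tumour BAF < μ − kσ
and toward BB when > μ + kσ, with k = 2 by default (configurable as
`sd_multiplier`). We treat the *outside* of the band as the disparity event;
the band itself is the null region. μ and σ are estimated from heterozygous
samples only — a band around the all-sample mean would sit near the cohort
allele frequency and say nothing about departure from the heterozygous
cluster.

The per-locus score S = (1 − min/max of the two shift counts)·100 measures
direction asymmetry; equal counts (including zero) give S = 0 and no
direction label, and such symmetric loci are excluded from the
direction-labelled outputs. The rates r(tAA), r(tBB) (shares of the shifted
samples per direction), r(tAB) (share of heterozygotes that shifted at all)
and Δ = r(tBB) − r(tAA) are all reported per locus, together with blood
genotype counts, percent heterozygosity, minor-allele frequency, and a
Hardy–Weinberg χ² computed from the blood genotype counts with expected
counts Np², 2Npq, Nq². The HWE flag (χ² ≤ 3.841, the 0.95 quantile of χ²₁)
is annotation only; out-of-HWE loci stay in the analysis. Selection keeps
loci with S ≥ 75 (boundary inclusive); the strict subset additionally
requires that at least half of the heterozygotes shifted. Both cut-offs are
parameters.

Direction labels are reported in B-allele space (toward-A / toward-B). At
any locus the cohort minor allele may be either design allele; the reported
MAF lets users re-express directions in minor/major terms when needed.

## Copy-number calling

Tumour LRR is smoothed per sample and chromosome by an exact
piecewise-constant fit: minimise total within-segment SSE plus γ per
breakpoint, each segment at least `kmin` loci long, solved by an O(n²)
dynamic program whose optimality is tested against exhaustive breakpoint
enumeration on short inputs. An exact solver was preferred over the usual
fast heuristics because array-scale chromosomes (a few hundred to a few
thousand loci) make O(n²) cheap and the optimum is testable.

γ is expressed on the standardised signal: the effective penalty is
γ·σ̂² with σ̂ a per-sample robust noise estimate from first differences
(MAD/0.6745/√2). The default γ = 15 is on the BIC scale (2·log n ≈ 10–12
for chromosome-length signals) and was chosen so that the documented
recovery contract holds: segments of |mean shift| ≥ 0.2 over ≥ 20–30 loci
at noise SD 0.15 (about 1.3 SD per point) are detected with average
boundary error ≤ 2 loci, while a null cohort draws essentially no
false-positive calls. Larger penalties in common use for noisier data
(γ ≈ 40) fail that contract at these sizes because the SSE saving of such
a segment is below the two-breakpoint cost; γ and `kmin` (default 5)
remain configurable. Missing LRR values are dropped before fitting and
inherit the smoothed value of the segment enclosing their position.

Calls threshold the per-sample smoothed LRR at ±0.07: amplification above,
deletion below, the closed interval normal. On the non-logarithmic scale
(2^x) these are copy ratios ≈ 1.05 and 0.95. The de-logged per-locus mean
histogram (with local-maxima detection) is provided as a diagnostic for
choosing the threshold; it plays no part in calling. The ±0.07 band is kept
symmetric in log2 units. Joint classes label each blood-heterozygous cell
by shift direction × CNA state (e.g. AA-amplification); unshifted cells are
"unshifted" regardless of CNA state.

## Association tests

The global test pools every locus × sample cell into one 2 × k table
(disparity vs not, by covariate level). Cells within a sample are
correlated, so this pooled χ² is descriptive — a cohort-level effect size
summary — not a calibrated inference; the per-locus scan, which uses
samples as units, is the inferential tool. Nominal covariates get the
uncorrected Pearson χ² (a Yates flag exists for 2 × 2 but defaults off,
matching the convention of the reference results); ordered covariates
(grade 1 < 2 < 3; tumour size T1 < T2 < T3+4, with T3 and T4 merged) get
the Cochran–Armitage trend test in the score-test form used by R's
`prop.trend.test`, with equally spaced integer scores by default. The
statistic is invariant to affine score changes and never exceeds the
Pearson 2 × 3 statistic on the same table. Per-locus scans report raw and
Benjamini–Hochberg-adjusted p-values across the scanned loci; degenerate
tables are reported as untestable rather than dropped.

## Aggregation

Cytoband summaries take the full scored-locus table plus the S ≥ 75 flag:
per band, the number of studied loci, the number and percentage flagged,
and the mean score over flagged loci (empty when none); bands at ≥ 30%
disparity are highlighted, and loci that map to no band are grouped as
"unassigned". Band assignment accepts UCSC cytoBand.txt (0-based half-open;
1-based locus positions are converted by subtracting one) or the annotation's
own cytoband column. Gene collapsing calls a gene "disparity" when more than
half of its loci are flagged, excludes exact 50/50 splits as ties, and
counts comma-separated multi-gene annotations toward each listed gene;
intergenic loci are excluded. Gene-level CNA classes use the same majority
rule on amplified vs deleted locus × sample cells. Gene-set comparisons put
set membership against the collapsed outcome in a 2 × 2 table and use the
uncorrected Pearson χ².

## Synthetic cohorts

The generator emulates a paired tumour–normal array experiment: per-locus
minor-allele frequency uniform on (0.05, 0.5) with the B allele minor half
the time; blood genotypes drawn under Hardy–Weinberg equilibrium; BAF as
cluster centre (0 / 0.5 / 1) plus Gaussian noise SD 0.03 clipped to [0, 1];
1% missing cells per matrix; tumour BAF equal to blood BAF except at
planted loci. Copying blood to tumour is deliberate: with no somatic event
the two assays measure the same genotype, and the ≈ 4.6% nominal 2-SD tail
rate still emerges because each value is compared against the cohort
heterozygote band. Defaults plant directional shifts at 2% of loci in 80%
of their heterozygotes, shifted values drawn uniformly between the 2-SD
boundary and the homozygous cluster edge (the real magnitude law is
unknown; uniform is the least-informative choice over the detectable
range). Planted loci are drawn only among loci whose realised genotypes
contain all three groups with ≥ 2 heterozygotes — an event planted on a
locus the pipeline must discard by definition is not a recoverable event.
Tumour LRR is built from planted constant segments (default: four segments
of 40–50 loci at ±0.3) plus Gaussian noise SD 0.15; blood LRR is pure
noise around 0. Clinical covariates are drawn from realistic marginal
frequencies and can be coupled to shifted-sample selection through an odds
parameter (default 1 = independent). Everything derives from one seed and
identical configs reproduce bit-identical outputs.

What the generator does not emulate: tumour purity and subclonality,
GC waves and other spatial intensity artefacts, linkage between loci,
genotyping-error structure, and BAF asymmetries of real Illumina clusters.
Passing recovery tests therefore demonstrate the correctness and
calibration of the algorithms under their stated model, not performance on
real arrays, where noise is heavier-tailed and events are subclonal.

## Problem sizes and test budget

The recovery acceptance runs on a 5,000-locus × 100-sample cohort (the
whole pipeline takes a few seconds), chosen as the smallest size at which
per-chromosome segments of realistic length (≈ 50 loci on 22 chromosomes)
coexist with stable per-locus heterozygote counts. The exhaustive
segmentation oracle is run on inputs up to length 12 (2¹¹ breakpoint
subsets), where enumeration is still instant.

## Known limitations

- The 2-SD band uses a normal-theory cut-off on an empirical cluster; with
  very few heterozygotes the band estimate is noisy and loci with < 2
  heterozygotes are skipped outright.
- CNA calls are per-cell threshold calls on smoothed LRR; no tumour-purity
  or allele-specific copy-number decomposition is attempted, so a 50%-pure
  tumour's single-copy loss (expected LRR ≈ −0.22 at full purity) can fall
  inside the normal band.
- The pooled global association treats correlated cells as independent (see
  above) and should be read descriptively.
- Gene and cytoband aggregation inherit whatever annotation the user
  supplies; no liftover or symbol normalisation is performed.
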