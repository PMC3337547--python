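# snpdisparity

Detection of **directional allele-specific disparity** (asymmetric loss of
heterozygosity) and **copy-number alteration** in paired blood–tumour SNP-array
data, from B-allele frequency (BAF) and log R ratio (LRR) matrices.

## The problem

On a genotyping array, the BAF of a diploid normal sample clusters near 0 (AA),
0.5 (AB) and 1 (BB), while the LRR tracks total copy number. When a tumour
loses or amplifies one allele at a locus that is heterozygous in the patient's
blood, the tumour BAF of that sample drifts out of the heterozygous cluster
toward one of the homozygous clusters. If, across many patients, the drift at
one locus is consistently toward the *same* homozygote, the locus shows
*directional* LOH — a candidate target of selection rather than random
mitotic error. This package scores that asymmetry per locus, calls
amplification/deletion from segmented tumour LRR, tests association of
disparity with clinical covariates, and aggregates the calls by cytoband and
gene. It is aimed at cancer-genomics analysts working with paired
tumour–normal array data (or any BAF/LRR-like paired signal).

## The statistics

For each locus *j*, blood-heterozygous samples define a reference cluster with
mean μ and sample standard deviation σ of their blood BAF. A blood-AB sample
is *shifted* toward AA if its tumour BAF < μ − 2σ, toward BB if > μ + 2σ.
With n(tAA), n(tBB) the shifted counts and n(tAB) the heterozygote count:

- score S = (1 − min/max(n(tAA), n(tBB))) · 100 ∈ [0, 100]; S = 0 for
  symmetric shifts, 100 when all shifts go one way;
- r(tAA) = n(tAA)/(n(tAA)+n(tBB)) · 100 and r(tBB) analogously;
- r(tAB) = (n(tAA)+n(tBB))/n(tAB) · 100, the percentage of heterozygotes
  showing disparity;
- Δ = r(tBB) − r(tAA).

High-disparity loci are selected at S ≥ 75; a strict subset additionally
requires that ≥ 50% of heterozygotes shifted. Each locus is tested for
Hardy–Weinberg equilibrium (χ² against 3.841, the 0.95 quantile at 1 df) and
flagged, not removed. Tumour LRR is smoothed per sample and chromosome by an
exact piecewise-constant fit (penalised least squares solved by dynamic
programming) and calls are made at ±0.07 in log2 units (≈ copy ratios
0.95/1.05): above is amplification, below is deletion. Associations use the
uncorrected Pearson χ² for nominal covariates and the Cochran–Armitage trend
test for ordered ones, with Benjamini–Hochberg adjustment across per-locus
scans.

## Worked example

Every stage runs on synthetic cohorts with known planted events:

```python
from snpdisparity.simulate import SimulationConfig, simulate, truth_recovery_report
from snpdisparity.preprocess import filter_informative
from snpdisparity.disparity import compute_disparity, select_loci
from snpdisparity.cna import smooth_lrr, call_cna_matrix

data, clinical, truth = simulate(SimulationConfig(n_loci=2000, n_samples=112, seed=7))
retained, summary, calls = filter_informative(data)
records = compute_disparity(retained, calls)
selected, strict = select_loci(records)
smoothed, segments = smooth_lrr(retained.tumour_lrr, retained.loci)
report = truth_recovery_report(truth, records, strict.index, call_cna_matrix(smoothed))
print(summary)
print(report.round(3))
```

prints

```
FilterSummary(n_input_loci=2000, n_removed_chrY=0, n_removed_noninformative=171, n_retained=1829)
                   n_true  sensitivity  specificity  direction_accuracy
event
directional_shift      40        1.000        1.000                 1.0
amplification        8736        0.990        0.997                 NaN
deletion             3136        0.984        0.997                 NaN
```

171 of 2,000 simulated loci lack all three blood genotype groups and are
dropped as non-informative; all 40 loci planted with one-directional shifts
are recovered in the strict subset with the correct direction, and planted
amplified/deleted locus×sample cells are called with ≥ 98% sensitivity at
≤ 0.3% false calls on unaltered cells.

The same pipeline is available from the shell:

```sh
snpdisparity simulate --out-dir cohort --seed 7
snpdisparity disparity --blood-baf cohort/blood_baf.tsv --tumour-baf cohort/tumour_baf.tsv \
    --blood-lrr cohort/blood_lrr.tsv --tumour-lrr cohort/tumour_lrr.tsv \
    --annotation cohort/annotation.tsv --out-dir results
snpdisparity run-all --config run.yaml --out-dir results
```

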