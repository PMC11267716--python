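# Methods

This note records the models implemented in `sweepcnv`, their assumptions,
the parameters that matter, and the design choices made where the design
was genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Windowed H12 selection scan (`sweepcnv.sweep`)

H12 is computed on phased biallelic haplotypes. A window's haplotype
frequency spectrum counts *whole-window* identical haplotypes; with sorted
frequencies `p1 >= p2 >= ...`,

    H1  = sum_i p_i^2
    H12 = (p1 + p2)^2 + sum_{i>=3} p_i^2

H12 >= H1 always, H12 = 1 exactly when the two most frequent classes hold
every haplotype, and H12 >= 1/n for n haplotypes. Pooling the top two
classes keeps power when selection has driven two distinct haplotypes up
(soft sweep).

Scan conventions:

* **SNP-count windows, non-overlapping.** Windows hold a fixed number of
  SNPs (default 1,500) rather than a fixed physical span, so window
  variance is constant in the number of sampled haplotypes; "stepping" is
  read as contiguous non-overlapping blocks, the simplest interpretation. A
  trailing remainder shorter than one window is dropped.
* **Cohort downsampling.** Each cohort is downsampled once, without
  replacement, to `n_haplotypes_sampled` (default 100) haplotypes before
  scanning, so H12 is comparable across cohorts of different sizes. The
  draw is seeded; tracks are reproducible.
* **Window coordinates.** `midpoint` is the midpoint of the window's first
  and last SNP. `start`/`end` delimit the genomic interval the window
  represents: boundaries are placed midway between adjacent windows' edge
  SNPs, so consecutive windows partition the scanned range with no gaps.
  This matters when asking "which window contains position x" — with raw
  first/last-SNP spans, a position can fall between windows.
* **Maximal windows come in plateaus.** When a sweep spans more than one
  window, adjacent fully swept windows can attain identical H12 (including
  bit-identical values on synthetic data). Detection is therefore assessed
  against the *set* of windows within 1e-12 of the maximum, not a single
  argmax, mirroring how broad empirical sweep signals are read.
* Multiallelic sites are rejected at load; haplotype input is biallelic 0/1
  with no missing calls (upstream filtering is assumed).

## Diplotype clustering (`sweepcnv.diplotypes`)

Unphased genotypes over a locus are represented as a sites × samples × 4
allele-count tensor (counts sum to 2 per site). The distance between two
individuals is

    d(a, b) = (1/S) * sum_sites sum_{4 alleles} |count_a - count_b|

i.e. city-block distance divided by the number of sites S. **The division
by S is a design choice**: a per-site scale makes the default cut height
(0.04) independent of locus length; users with raw-scale cuts should
multiply by S. Identical diplotypes have distance 0; a single-site
homozygote/heterozygote pair has per-site distance 2; the maximum per-site
distance is 4.

Complete-linkage hierarchical clustering (scipy) is cut at `cut_height`
(default 0.04); flat groups smaller than `min_cluster_size` (default 40)
are left unassigned (label 0). Surviving clusters are numbered 1..k by
descending size — the numbering scheme is a convention chosen for
reproducibility (ties broken by smallest member index), since no canonical
ordering exists. Per-individual observed heterozygosity is the fraction of
sites at which the two alleles differ, averaged over all sites of the
locus; a cluster of individuals homozygous for one swept haplotype has
heterozygosity ~0, while carriers of two distinct swept haplotypes show
elevated heterozygosity at the sites where the cores differ. Missing
genotypes are an error rather than silently imputed.

## Copy-number calling (`sweepcnv.cnv`)

**Normalization.** Raw depth in fixed 300 bp windows is normalized per
sample: each window's depth is divided by the sample's median depth among
all windows in the same 2%-wide GC bin, times 2, giving a diploid
expectation of 2 regardless of sequencing effort (the transform is exactly
scale-free). Windows in GC bins with fewer than 10 members are flagged and
excluded from HMM input rather than interpolated — with so few windows the
bin median is unstable.

**QC.** A sample is excluded when the variance of its normalized coverage
on the coverage/2 scale exceeds 0.2 *strictly* (a variance of exactly 0.2
is retained). The variance is computed post-normalization with ddof = 0.
High-variance samples produce erratic state paths; excluding them is
cheaper and safer than modelling their noise.

**HMM.** 13 hidden states represent copy numbers 0–12 (up to a 6-fold
amplification, 10 extra copies). Emissions are Gaussian with mean equal to
the state copy number and one shared variance; by default the variance is
estimated per sample from presumed-diploid windows as a 10%-trimmed
variance rescaled by the truncated-normal variance ratio (so it is
consistent under Gaussian diploid noise and robust to a minority of
amplified windows). The transition matrix has stay probability `1 - rho`
and splits `rho` equally among the other 12 states; the default
`rho = 1e-4` per 300 bp step strongly favours long constant segments, which
is what tandem duplications look like. Viterbi decoding is exact dynamic
programming; ties break deterministically toward the lower copy number
(argmax-first over states ordered 0..12). The Gaussian-emission variance is
shared across states although counting noise actually grows with copy
number; with the strong self-transition prior this misspecification does
not affect segment-level calls in practice (measured by the recovery tests).

**Gene summaries.** Gene copy number is the modal state over the windows
overlapping the gene span, ties broken toward the diploid state 2 and then
toward the lower copy number (prefer the conservative call). The genomic
span of an amplification is the maximal run of contiguous windows with
state > 2 containing the gene. Cohort frequency of "at least one extra
copy" carries a Wilson 95% binomial interval.

Coordinates are 0-based half-open internally (bedGraph/BED convention) and
1-based inclusive in region strings (`2L:28,545,396-28,550,748`).

## Association (`sweepcnv.association`)

A binomial GLM with logit link models bioassay survival (alive = 1, so an
odds ratio above 1 for copy number means resistance-associated). Copy
number enters as a linear integer dose — one coefficient per extra copy —
with carrier-status coding left to the caller (pass a thresholded column).
A covariate locus (e.g. *Ace1* copy number, the established
organophosphate-resistance locus) is always in the per-location and pooled
designs to control confounding.

The fitter is iteratively reweighted least squares with **step-halving**,
which makes the log-likelihood provably non-decreasing across iterations
(the trace is stored on the result and asserted in tests). Convergence is
a maximum absolute coefficient change below 1e-8. Perfect or quasi-perfect
separation is detected as any |coefficient| > 15; the fit is flagged
non-converged with a warning but estimates are still reported. Wald
standard errors from the inverse Fisher information give 95% CIs
(`exp(beta ± 1.96 se)`) and p-values. statsmodels' GLM serves as an
independent cross-check in the test suite, never as the implementation.

**Pooling across sites uses fixed location indicators**, not a random
intercept: with two locations a random-intercept variance is weakly
identified, and the fixed-effect model answers the same confounding
question; this is an intentional approximation and the package's own
choice. Pooling requires the CNV to segregate in at least two locations; a
location where the CNV is monomorphic is skipped with an explicit reason
rather than fitted.

Calibration, measured by the suite and `scripts/acceptance.py`: simulated
copy-number effects of OR 1.62 per extra copy at n = 400 are recovered
without practical bias; Wald CI coverage sits near 95%; the null rejection
rate of the Wald test at n = 300 is within Monte-Carlo error of 5%.

## Expression summaries (`sweepcnv.expression`)

Per-experiment fold changes with adjusted p-values are aggregated per
species: counts of significantly up- and down-regulated experiments
(adjusted p <= 0.05, inclusive, with the sign of the log2 fold change) and
mean/median fold change. Because "mean fold change" is ambiguous between
the linear and log2 scales, **both are always reported, labelled**; the
input declares its scale explicitly. Up, down and non-significant counts
partition the experiments exactly.

## Synthetic data (`sweepcnv.simulate`)

The generator produces the statistical structure the analyses consume, not
a demographically realistic population:

* **Haplotypes: founder mosaic, not a coalescent.** Each background
  haplotype is stitched from segments of a small founder pool (default 20
  founders, Poisson(5) switch points per haplotype; founder allele
  frequencies drawn log-uniform, a 1/f-like spectrum) and then receives
  private mutations as allele flips at a default 0.2 per kb. The default
  density is chosen so background haplotypes are effectively unique within
  a 500-SNP scan window — as in the hyperdiverse study system — which is
  the property H12's background level depends on. Linkage decay, gene
  conversion and demography are not modelled; positions are uniform with no
  recombination map.
* **Sweeps.** A fraction `sweep_frequency` of haplotypes carries one of
  `n_sweep_haplotypes` distinct cores (1 = hard, >1 = soft), identical
  within `sweep_width` (default 150 kb, deliberately wider than one
  500-SNP scan window at the default SNP density) of `sweep_center` and
  retained with linearly decreasing probability over one further
  `sweep_width` beyond the core edge — a crude stand-in for recombination
  eroding an aging sweep. Sweep age dynamics are not modelled.
* **Coverage.** Window depth is negative-binomial with mean
  `base_depth * gc_bias(gc) * CN/2` and variance `mean * overdispersion`
  (Poisson at overdispersion = 1); GC per window is uniform on a
  configurable range and the bias curve is user-supplied. Mappability,
  repeats and breakpoint-spanning reads are not emulated, so passing
  recovery tests shows the HMM chain is correct under its own noise model,
  not that it is robust to real-data artefacts.
* **Phenotypes.** Survival is Bernoulli with
  `logit p = intercept + beta_cnv (CN - 2) + beta_cov * cov + location offset`;
  the default `beta_cnv = ln 1.62` is a realistic effect size for this kind
  of locus. This is exactly the inverse of the association model, so
  recovery tests measure estimator calibration, not model misspecification.

All randomness flows through explicitly passed seeds
(`numpy.random.default_rng`); identical configs give byte-identical
outputs. In the end-to-end scenario every swept haplotype carries a tandem
duplication adding 2 extra copies (sample CN = 2, 4 or 6 — the empirically
plausible ceiling), planted over a ~3.6 kb interval in a 180 kb coverage
frame so the duplication occupies ~2% of windows and does not trip the
coverage-variance QC, as in genome-wide data where CNVs are a tiny fraction
of the genome.

## Problem sizes

Defaults used by the test suite and acceptance script: 5,000-SNP regions of
500 kb with 200 haplotypes (scan windows of 500 SNPs, 100 sampled
haplotypes); 600-window (180 kb) coverage frames at 30× depth; association
simulations at n = 300–400 with 200–1,000 replicates; the end-to-end cohort
is 200 diploid samples across two collection sites. These sizes were chosen
so every property is measured with useful Monte-Carlo resolution while the
whole suite stays fast.

## Known limitations

* The founder-mosaic background has no genealogy; statistics that depend on
  tree shape (e.g. haplotype sharing decay with distance) are only
  qualitatively realistic.
* The HMM's shared emission variance underweights high-copy noise; per-state
  variances would be better for CN > 6.
* The random-intercept pooled model is approximated by fixed location
  effects; with many locations a mixed model would be preferable.
* Deletion alleles (CN < 2) are representable but unexercised by the
  synthetic scenarios and untested against truth.
* The scan loops over one contig at a time; multi-contig orchestration is a
  thin loop left to the caller or CLI.
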