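# sweepcnv

Selective-sweep detection, coverage-based copy-number calling and
genotype–phenotype association for population-genomic cohorts of malaria
mosquitoes (and structurally similar diploid resequencing data).

Insecticide-resistance loci in *Anopheles* evolve by positive selection on
haplotypes that often carry tandem gene duplications of detoxification
genes (carboxylesterases, P450s). Surveillance cohorts of whole-genome
sequenced mosquitoes — with collection metadata and WHO tube-bioassay
phenotypes — make it possible to (i) find loci under recent selection,
(ii) resolve the distinct swept haplotypes segregating there, (iii) call
gene copy number from sequencing depth, and (iv) test whether extra gene
copies predict surviving insecticide exposure. `sweepcnv` implements this
chain as a reusable, tested library and CLI, together with a synthetic-data
generator that produces all inputs with known ground truth.

## The statistics at the core

**H12 haplotype homozygosity.** For a window of phased haplotypes with
haplotype class frequencies $p_1 \ge p_2 \ge \dots$, plain haplotype
homozygosity is $H1 = \sum_i p_i^2$; H12 pools the top two classes,

$$H12 = (p_1 + p_2)^2 + \sum_{i \ge 3} p_i^2,$$

making it sensitive to soft sweeps (several sweeping haplotypes) as well as
hard ones. The scan computes H12 in non-overlapping windows of a fixed SNP
count (default 1,500) after downsampling each cohort once to a fixed number
of haplotypes (default 100).

**Diplotype clustering.** Unphased genotypes over a locus are encoded as
per-site allele-count vectors of length 4 (summing to 2); individuals are
clustered by per-site city-block (Manhattan) distance with complete
linkage; the dendrogram is cut at distance 0.04 with a minimum cluster size
of 40. Per-individual observed heterozygosity and gene copy number are
overlaid to tell homozygous sweep clusters from mixed ones.

**Copy-number HMM.** Window depth (300 bp windows) is normalized within 2%
GC bins to a diploid expectation of 2, samples with coverage/2 variance
above 0.2 are excluded, and a 13-state HMM (copy numbers 0–12, Gaussian
emissions centred on the state, strong self-transition) is decoded by
Viterbi. Gene copy number is the modal state over the gene's windows.

**Association.** Survival (alive = 1) after insecticide exposure is
modelled by a binomial GLM with logit link on gene copy number plus a
covariate locus (e.g. *Ace1*), pooling collection sites with fixed location
effects; odds ratios carry Wald 95% intervals.

## Worked example

Simulate a 200-sample cohort carrying a 50% hard sweep whose haplotype
bears a tandem duplication of a focal gene, analyse it end to end, and
compare the estimates to the planted truth:

```python
import json
import sweepcnv as sc

results = sc.run_synthetic_pipeline("demo_out", seed=1)
print(json.dumps(results["truth_report"], indent=2, sort_keys=True))
```

```json
{
  "fitted_or": 1.7506240703839688,
  "fitted_or_ci": [1.3346537992224186, 2.2962393975076147],
  "gene_cn_accuracy_vs_truth": 1.0,
  "h12_max_value": 0.24519999999999997,
  "h12_max_window_midpoint": 219805,
  "n_clusters_found": 1,
  "n_qc_pass": 200,
  "sweep_center": 250000,
  "sweep_center_in_max_window": true,
  "sweep_cluster": 1,
  "sweep_cluster_fraction_amplified": 1.0,
  "true_or": 1.62,
  "true_or_within_ci": true
}
```

Reading the report: the maximal-H12 window set contains the planted sweep
center (H12 ≈ 0.245, close to the 0.26 expected when half the sampled
haplotypes are identical); the one diplotype cluster found is the sweep
cluster and every member carries the planted duplication; the HMM recovers
every sample's gene copy number; and the fitted copy-number odds ratio
(1.75, CI 1.33–2.30) covers the planted effect of 1.62 per extra copy. The
fitted model itself:

```text
                       estimate      se  odds_ratio  ci_low  ci_high  p_value
term
intercept               -1.1028  0.9318      0.3319  0.0534   2.0619   0.2366
cnv_copy_number          0.5600  0.1384      1.7506  1.3347   2.2962   0.0001
covariate_copy_number   -0.0613  0.2535      0.9406  0.5723   1.5459   0.8091
location[siteB]          0.3703  0.3527      1.4482  0.7255   2.8908   0.2937
```

The same stages are available on files from the shell:

```bash
sweepcnv simulate --n-samples 100 --seed 5 --out-dir sim/
sweepcnv scan sim/haplotypes.vcf --window-snps 500 --out track.tsv
sweepcnv cluster sim/genotypes.vcf --region "sim1:200,000-300,000" --out clusters.tsv
sweepcnv cnv coverage.tsv --genes genes.bed --out gene_cn.tsv
sweepcnv assoc samples.tsv --out assoc.json
sweepcnv run --synthetic --seed 1 --out-dir demo/
```

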