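# imprintscreen

A genome-wide screen for imprinting defects in hydatidiform moles, built on
methylation-array β values.

Complete hydatidiform moles come in two flavours with the same placental
phenotype: sporadic androgenetic moles (two paternal genome copies, no
maternal genome) and familial biparental recurrent moles caused by
maternal-effect *NLRP7* mutations, in which the oocyte fails to establish
maternal methylation imprints. Comparing the two against normal placenta,
somatic tissues and sperm on Infinium-style methylation arrays separates
germline differentially methylated regions (DMRs) by parental origin and
exposes loci that are imprinted only in placenta. This package implements
that screen end to end for epigenomics researchers: probe-level quality
filtering, empirical-Bayes moderated differential methylation, run-based
candidate-DMR detection, classification of each region's germline
epigenotype, interpreters for the orthogonal validation assays (bisulfite
clone panels, methylation-sensitive HpaII genotyping, pyrosequencing
summaries, allelic expression calls), and a seeded synthetic-data generator
so everything runs with no downloads.

## The statistics at the core

For each probe *g*, with case group (NLRP7-mutated moles, n₁ samples) and
control group (pooled normal placenta, n₂ samples):

- effect: Δβ_g = mean(case β) − mean(control β), with pooled residual
  variance s²_g on d = n₁ + n₂ − 2 degrees of freedom;
- empirical-Bayes moderation: a scaled inverse-chi-square prior
  s²_g ~ s₀² · d₀ / χ²_{d₀} is fitted across probes by moment matching on
  log s²_g (digamma/trigamma relations, trigamma inverted by Newton
  iteration), giving the posterior variance
  s̃²_g = (d₀ s₀² + d s²_g) / (d₀ + d);
- moderated t: t_g = Δβ_g / √(s̃²_g (1/n₁ + 1/n₂)), two-sided p from a
  t distribution with d₀ + d degrees of freedom (standard normal when d₀
  is infinite).

Candidate regions are maximal runs of ≥ 3 probes on a chromosome in which
every probe has p < 0.01, all effects share a sign, consecutive probes lie
< 500 bp apart, and the *average* |Δβ| over the run exceeds 0.2. Each
region's epigenotype is then read from its mean β per sample group: a
maternal germline DMR is partially methylated (β ≈ 0.5) in biparental
placenta, unmethylated in both mole types and in sperm, and
placenta-specific exactly when somatic tissue is also unmethylated;
paternal germline DMRs (*H19*-type) are fully methylated in androgenetic
moles but keep partial methylation in *NLRP7* moles; secondary DMRs
(*ZDBF2*/*ZNF597*-type) are fully methylated in both mole types.

## Worked example

```python
from imprintscreen import ImprintingScreen, SimulationConfig, simulate_dataset
from imprintscreen.simulate import known_dmrs_from_truth, evaluate_screen

config = SimulationConfig(seed=1, n_islands=200)        # study-default groups
dataset, truth = simulate_dataset(config)
model = ImprintingScreen(dataset, known_dmrs=known_dmrs_from_truth(truth))
results = model.fit()
print(results.summary())
```

prints

```
Imprinting-defect methylation screen
==========================================
probes in / retained:     1112 / 1081
case group:               NLRP7_RHM (n=5)
control groups:           PLACENTA_FIRST+PLACENTA_TERM (n=7)
eBayes prior:             d0=7.21, s0^2=0.00163
candidate regions:        70 (gain 20, loss 50)
CpG-island regions:       70 (100.0%)
promoter regions:         81.4%
epigenotype labels:
  MATERNAL_GDMR_PLACENTA_SPECIFIC  30
  MATERNAL_GDMR_UBIQUITOUS         20
  SECONDARY_DMR                    20
known-DMR probe tallies:
  placenta_specific                148
  ubiquitous                       163
```

The 1112 simulated probes sit in 200 CpG islands; 31 are discarded by the
detection-p / missing-value / chrX rules. The 70 candidate regions are the
islands planted as differential in the mole-vs-placenta contrast: maternal
DMRs lose methylation in the moles ("loss"), secondary DMRs appear fully
methylated ("gain"). Checking against the generator's ground truth:

```python
print(evaluate_screen(results.regions, truth))
# {'n_differential': 70, 'n_recovered': 70, 'sensitivity': 1.0,
#  'n_regions': 70, 'n_false': 0, 'fdp': 0.0}
```

`results.save(outdir)` writes the probe statistics (TSV), regions (BED +
TSV), epigenotype calls, a heatmap-ready region × sample matrix, and a
JSON summary. The same pipeline runs from the shell:

```sh
imprintscreen simulate --seed 1 --outdir ws
imprintscreen screen --manifest ws/manifest.tsv --beta ws/beta.tsv \
    --samplesheet ws/samples.csv --detection ws/detection_p.tsv \
    --known-dmrs ws/known_dmrs.tsv --outdir out
imprintscreen profile-known --manifest ws/manifest.tsv --beta ws/beta.tsv \
    --samplesheet ws/samples.csv --known-dmrs ws/known_dmrs.tsv --outdir prof
```

Real array data is consumed the same way: a TSV probe manifest
(`probe_id chrom pos cgi feature`), a β matrix (GEO series-matrix bodies
work after their `!` comment lines, which the reader skips), an optional
aligned detection-p matrix, a `sample_id,group` CSV and a known-DMR TSV.

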