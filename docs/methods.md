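# Methods

## The screening model

The screen treats each array probe as an independent two-group comparison
on the β scale (fraction methylated, ∈ [0, 1]). The case group is the
*NLRP7*-mutated mole set; the control group pools first-trimester and term
placenta, since both show the same partial methylation at imprinted DMRs
and pooling buys residual degrees of freedom. Tests are run on β directly
rather than logit-transformed M-values because the effect threshold that
defines a candidate region (|Δβ| > 0.2) is a β-scale quantity; the
variance heteroscedasticity this leaves in the tails is absorbed by the
empirical-Bayes prior rather than removed by transformation.

Variance moderation assumes the per-probe true variances σ²_g are
exchangeable draws from a scaled inverse-chi-square prior with parameters
(d₀, s₀²). The prior is estimated by the closed-form log-variance moment
method: with z_g = log s²_g and residual df d,

    E[z] = log s₀² + ψ(d/2) − log(d/2) − ψ(d₀/2) + log(d₀/2)
    Var[z] = ψ′(d/2) + ψ′(d₀/2)

so the excess of the observed spread of z over ψ′(d/2) identifies d₀
through the trigamma inverse (Newton iteration from y = 0.5 + 1/x, which
converges quadratically because ψ′ is monotone), and the mean then
identifies s₀². A non-positive excess means the sample variances carry no
spread beyond chi-square sampling noise; the estimator returns d₀ = ∞ and
every posterior variance collapses to s₀² (moderated t referred to a
standard normal). This estimator was chosen over REML-style alternatives
because it is deterministic, dependency-free and is the standard estimator
behind moderated-t analyses; the test suite cross-checks it — prior
parameters, t statistics and p-values — against Bioconductor limma's
`lmFit`/`eBayes` on a shared matrix via `Rscript`.

Balanced-design assumption: all probes must share the same residual df
(guaranteed here because every probe uses the same sample columns). The
moment fit refuses to run on fewer than 50 probes, since the prior is a
cross-probe quantity.

## Region calling

Candidate regions are maximal runs over positionally sorted, QC-retained
probes. A probe qualifies iff p < 0.01 and Δβ ≠ 0; a run extends while the
next probe qualifies, matches the run's sign, and lies strictly less than
500 bp from the previous member; any violation ends the run (a qualifying
probe of opposite sign immediately seeds a new run — no probe skipping).
A run is emitted iff it has ≥ 3 probes and |mean Δβ| > 0.2. Three
interpretive choices deserve note:

- "consecutive" means adjacent among retained probes, because filtering
  precedes testing; a dropped probe does not break a run's adjacency but
  does contribute its genomic distance to the gap check;
- the gap rule is pairwise and strict (< 500 bp), not a bound on total
  region span, and not a fixed tiling of the genome into 500 bp windows;
- the 20% effect threshold applies to the run *average*, so individual
  probes below 0.2 may sit inside a region.

Equal probe positions are ordered lexically by probe id — a deterministic
tie-break that is logged when it fires. The scanner is property-tested for
exact equality against a brute-force enumeration of all contiguous probe
windows reduced to maximal valid ones.

## Epigenotype classification

A region's profile is the unweighted mean β over (region probes × group
samples). The decision table uses four thresholds — lo = 0.15,
part_lo = 0.30, part_hi = 0.70, hi = 0.85 — that bound the three idealised
states (unmethylated ≈ 0, allelic/partial ≈ 0.5, full ≈ 1) with wide
margins. These are interpretive dials, not measurements; they are exposed
in configuration. First match wins:

1. every available group < lo → NOT_IMPRINTED_UNMETH; every group > hi →
   NOT_IMPRINTED_METH. These extremes are checked first: a promoter
   methylated everywhere would otherwise satisfy the secondary-DMR
   pattern, which is defined by *contrast* between mole types and
   placenta, not by uniform methylation.
2. placenta (pooled first + term) partial, both mole groups unmethylated,
   sperm unmethylated if present → maternal germline DMR;
   placenta-specific iff somatic < lo, ubiquitous iff somatic partial.
3. placenta partial, androgenetic mole > hi, *NLRP7* mole partial →
   paternal germline DMR (*H19*-type; the paternal imprint survives the
   maternal-effect defect).
4. both mole groups > hi with placenta partial or methylated → secondary
   DMR (*ZDBF2*/*ZNF597*-type, methylation acquired post-fertilisation on
   the paternal allele).
5. otherwise AMBIGUOUS, with a reason when a required group is missing.

Mosaic imprint retention. Individual moles can retain the partial state at
a bona fide maternal DMR (the *FAM50B* pattern: retained in two of four
androgenetic moles; single *NLRP7* moles retaining *PLAGL1*, *PEG10*,
*SNURF*). A strict group mean would mislabel such regions — with a
4-sample androgenetic group, one retained sample puts the expected group
mean at 0.1475, indistinguishable from the 0.15 threshold. The maternal
test therefore excludes mole samples whose per-sample mean lies in the
partial band, provided they are a minority (at most half their group), and
reports them in `retained_in`. If more than half a group is partial, the
group mean stands — that is the group's real state, not mosaicism.
Loci known to retain methylation in moles (*IGF1R*, *RB1*, *SNURF*)
legitimately classify as AMBIGUOUS or SECONDARY; the classifier makes no
attempt to force them into the maternal class.

## Quality control

Three per-probe exclusion rules, applied before testing and commuting by
construction: detection failure (p > 0.01 in any sample; a leniency
parameter allowing a tolerated failing fraction exists but defaults to 0,
matching the companion rule that a probe missing a value in one sample is
excluded), missing signal in any sample, and sex chromosomes (chrX always
for the genome-wide screen; chrY optional and off by default since X is
the confounded chromosome in a placental comparison). Known-DMR profiling
skips the sex-chromosome rule: the reference list is trusted and some
imprinted loci would otherwise vanish from the report. An optional
user-supplied probe blocklist (e.g. cross-reactive probes) is applied
last.

## Validation-assay interpreters

- Bisulfite clone panels: each clone is classed by its CpG methylation
  fraction as hi (> 0.7), lo (< 0.3) or mixed. A panel is *allelic* when
  hi and lo classes each hold ≥ 25% of clones and SNP labels anchor them
  (≥ 80% of hi clones on one allele, differing from the lo majority);
  bimodal without anchoring is *strand_mixture*; ≥ 75% of clones in one
  extreme class is *methylated*/*unmethylated*; panels under 4 clones are
  inconclusive. The 0.7/0.3/0.25/0.8 defaults reproduce the qualitative
  reading of published clone diagrams and are exposed in configuration.
- HpaII genotyping: a heterozygous SNP reduced to homozygosity after
  digestion proves allelic methylation, the surviving allele naming the
  methylated chromosome; parental origin is assigned only when exactly one
  parent could have transmitted that allele. A heterozygous digested call
  is reported as both-methylated with an incomplete-digestion flag — the
  two are indistinguishable at the genotype level.
- Pyrosequencing summaries: case value against the control panel's median
  and empirical 5th–95th percentile band (linear interpolation, ≥ 5
  controls required).
- Allelic expression: numeric allele fractions stand in for
  electropherogram peak reading; ≥ 90% of total signal on one allele is
  monoallelic, ≥ 25% on each is biallelic, anything else inconclusive.

## The synthetic-data generator

The generator emulates the features the screen's statistics rely on:
island-clustered probe spacing (3–8 probes per island, 20–200 bp apart,
islands ≥ 600 bp apart so no region can span two islands and ground-truth
matching is unambiguous), group-specific β targets per island class
(partial 0.50, unmethylated 0.03, full 0.97), per-sample imprint-retention
mosaicism at maternal islands (probability 0.05 per mole sample × island),
rare detection failures (rate 0.001 per cell), and bisulfite clone panels
with 2% conversion error. Group sizes default to the study design — 4
androgenetic moles, 5 *NLRP7* moles, 3 first-trimester + 4 term placentas,
4 somatic tissues, 1 sperm. Island classes default to 10% maternal
ubiquitous, 15% maternal placenta-specific, 5% paternal, 10% secondary,
60% not imprinted; the LOM-vs-partial targets give the differential
classes an expected |Δβ| of 0.47.

Noise is truncated-normal on the β scale (draw N(target, 0.05), clamp to
[0, 1]) — variance is then directly the square of the sd parameter, which
makes power calculations transparent; a moment-matched beta-distribution
alternative sits behind `noise_model="beta"`. All draws come from a
single integer-seeded PCG64 generator (child streams via `SeedSequence`),
so equal seeds give bit-identical datasets across platforms.

What the generator does *not* emulate — and what passing tests therefore
do not show about real arrays: probe-type (Infinium I/II) chemistry bias,
spatial/batch effects, cell-composition heterogeneity, correlated noise
along an island, SNP-overlapping or cross-reactive probes, and the
vendor's normalisation. Results on real series additionally depend on
normalisation parity with whatever produced the β matrix.

## Numerical choices and degenerate inputs

- Sample variances are floored at 1e−8 before log-moment estimation so
  zero-variance (degenerate synthetic) probes cannot poison the prior.
- A zero posterior standard error with zero effect yields t = 0, p = 1;
  with non-zero effect, t = ±∞, p = 0.
- β values outside [0, 1] are rejected at read time naming the offending
  probe — never clipped, since they indicate a corrupted input.
- Probes lacking coordinates are dropped at read time with a logged
  count; the screen is positional.
- Coordinates are 1-based inclusive internally (manifest convention); BED
  export converts to 0-based half-open. Strand is ignored throughout: β
  is strand-symmetric at CpGs.
- Percentile computation uses numpy's linear interpolation; region BED
  scores are round(1000·|mean Δβ|) capped at 1000.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data:
200-island datasets (~1100 probes × 21 samples) for recovery measurements,
20 000-probe null simulations across 20 seeds for calibration, 500 random
instances of ≤ 25 probes per chromosome for oracle equivalence, 10 000
probes for prior-parameter recovery, and 500 twelve-clone panels for the
clone caller. These sizes give the binomial/recovery tolerances quoted in
the tests while keeping a full run in the tens of seconds.

## Known limitations

- The moderated test assumes within-group homoscedastic normal noise per
  probe; β values near 0 and 1 violate this, and the partial-band
  thresholds compensate only interpretively.
- No multiple-testing correction is applied across regions: the screen
  reports raw-threshold candidates for orthogonal validation, which is
  how the assay interpreters are meant to be used.
- Parent-of-origin cannot be proven from array data alone; the epigenotype
  labels are hypotheses that the HpaII and clone assays confirm or refute.
- GEO series-matrix support is limited to comment-line stripping of the
  matrix body; IDAT parsing and normalisation from raw intensities are
  out of scope (the pipeline consumes β).
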