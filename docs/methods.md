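# Methods

## Scope and data model

`ncpanel` analyzes targeted hybridization-counting panels: each sample is a
vector of integer molecule counts over probes of four classes — Endogenous
targets, Positive and Negative spike-in controls, and Housekeeping
(candidate reference) genes. A cohort is a probes × samples matrix with a
control/patient label per sample; columns are ordered controls first so that
control-derived statistics are always computed on a contiguous block. Counts
are integers by construction (the platform counts molecules); everything
downstream of normalization is real-valued.

## Normalization chain

**Background.** Per sample, the detection threshold is
`T_s = mean(neg) + k·SD(neg)` with `k = 2` by default and the SD the sample
SD (n−1). The threshold is used two ways, both deliberate design choices:

* *Detectability*: an endogenous gene is kept iff its **raw** count strictly
  exceeds `T_s` in at least `min_fraction = 0.5` of all samples. The strict
  inequality makes the all-at-threshold case undetectable; the 50 % rule is
  exposed in config because no single convention dominates in practice.
* *Flooring*: endogenous and housekeeping counts below `T_s` are raised to
  `T_s` before any geometric mean or log-ratio is formed. Counts are never
  background-*subtracted* — subtraction can produce zeros/negatives that
  destroy the log-scale machinery, while a floor only compresses values that
  are statistically indistinguishable from background anyway. If negatives
  are all zero (threshold 0) the floor falls back to 1 count.

Zero variance among negatives is tolerated (threshold = mean) with a logged
warning rather than an error: it occurs legitimately in low-background runs.

**Positive controls.** The factor convention is
`f_s = mean_s(G)/G_s`, `G_s` = geometric mean of the positive titration
counts of sample *s* — the arithmetic-mean-of-geometric-means convention
used by the platform vendor's analysis software. Factors are therefore
dimensionless, strictly positive, average ≈ 1 across samples, and recover
planted lane efficiencies up to a global constant (`log f_s ≈ −log e_s`).
A zero positive count is an error (the geometric mean would be 0).

**geNorm.** For housekeeping candidates *j, k* the pairwise variation is
`V_jk = SD_samples(log2 x_j/x_k)` and the stability `M_j = mean_{k≠j} V_jk`
(lower = more stable). The least stable gene is removed and M recomputed
until two remain; ties in M break lexicographically so runs are
deterministic. The pairwise-variation curve `V(n, n+1)` is the SD over
samples of `log2(NF_n/NF_{n+1})`, `NF_n` being the per-sample geometric
mean of the *n* most stable genes; the number of reference genes is the
smallest `n ≥ 2` with `V < 0.15` (the algorithm's canonical cutoff, exposed
in config), falling back to all candidates when the curve never dips below
it. The two final genes share one M value; their relative order is
alphabetical and does not affect any downstream quantity (both are always
included together).

**Content factor.** Identical in form to the positive-control factor, but
computed on the geometric mean of the selected reference genes after
positive normalization. An algebraic consequence tested explicitly: after
applying the factors, the per-sample reference-gene geometric means are
equal across samples.

## Outlier calling

`z = (x − µ)/σ` on normalized counts directly, where `µ` and `σ` are the
mean and sample SD (n−1) of the control samples. Calls are inclusive at the
conventional limits: `z ≥ 2` → high, `z ≤ −2` → low. A log2-scale variant
exists behind `zscore.log2` but defaults off: the plain-count formula is the
field's reporting convention for this assay class, despite the right-skew
of count data. A gene whose controls have zero variance is a hard error —
z would be undefined — rather than a silent skip.

Sparse published call lists can be summarized through
`zscore_table_from_entries`, which builds the dense patients × genes table
and drops entries naming a patient outside the enrolled cohort (logged).
The bundled worked-example list contains one such un-attributable entry;
dropping it is the only reading under which the list's own printed
summaries (11 of 19 patients flagged; 3 multi-gene patients) are
self-consistent.

**Statistical limitation (known, by design).** With only 8 controls, `µ`
and `σ` are noisy estimates; under a normal (or CV ≤ 20 % log-normal) null,
`(x − µ̂)/σ̂` has t-like tails and `P(|z| ≥ 2) ≈ 0.09–0.10` per cell, not
the ≈ 0.046 of known parameters. The acceptance script measures this
per-cell null call rate on synthetic cohorts; users should read isolated
single-gene calls accordingly. Sensitivity for genuinely extreme cells
(|log2 FC| ≥ 1.5 at 20 % biological CV) is high (≥ 0.9 measured).

## Cohort statistics

* Two-group contrasts: Shapiro–Wilk per group at α = 0.05 gates between an
  unpaired two-sided Student t-test (equal variances; Welch behind config)
  and a two-sided Mann–Whitney U (scipy's `method="auto"`: exact for small
  tie-free samples, tie-corrected normal approximation otherwise).
  Constant-valued groups fail the gate by definition. Groups below n = 3
  are an error; strata below 3 in stratified contrasts are skipped with a
  logged reason. No multiplicity adjustment is applied, matching reporting
  practice for panels of ~7 genes; a Benjamini–Hochberg pass can be applied
  downstream by the user if wanted.
* Correlations: Pearson when both variables pass the same gate, Spearman
  otherwise; pairwise-complete over patients with a non-missing clinical
  value, minimum 4 pairs.
* Stratifiers: onset age ≤ 25 vs > 25 years (the inclusive boundary follows
  the clinical definition of young-onset diabetes; patients aged exactly 25
  at onset fall in the young stratum), and WHO BMI class contrasting obese
  (≥ 30) against normal weight (18.5–24.99), leaving overweight out of the
  contrast.

## Clinical module conventions

BMI classes use the WHO boundaries with half-open intervals
([18.5, 25) normal, [25, 30) overweight, ≥ 30 obese). Glycemic control is
*poor* iff HbA1c ≥ 7.0 % — the complement of the "< 7 %" treatment target,
so the boundary value itself counts as poor. Reference intervals (glucose
74–105 mg/dL closed, HbA1c < 5.7 % upper-only, C-peptide 0.81–2.85 ng/mL
closed) are routine laboratory ranges and are configurable. Missing values
are first-class: excluded from means/SDs, counted as `unknown` in flags,
with fractions reported over the full cohort denominator and the
non-missing n always available. SDs are sample SDs (n−1) throughout, the
convention of the clinical statistics packages this module mirrors.

## Synthetic-data generator

The generator emulates the study conditions the pipeline is built for:
8 controls + 19 patients; 19 endogenous genes of which 12 are planted below
background (mirroring how few MODY genes are expressed in whole blood);
8 housekeeping candidates of which 3 receive extra per-sample jitter
(SD 0.5 log2) making them unstable; 6 positive probes in a 4-fold titration
from 20 000 counts with 5 % technical CV; 8 negative probes at a
Poisson(10) floor. Per-sample lane efficiency is `2^N(0, 0.3²)` (applied to
everything except negatives) and RNA content `2^N(0, 0.2²)` (applied to
endogenous + housekeeping only, which is exactly the component content
normalization must remove). Biological noise is multiplicative log-normal
with CV 20 %; baselines are log-uniform over 2⁸–2¹² counts (2⁹–2¹³ for
housekeeping), the platform's comfortable high-count regime. Planted
signals (outlier cells, patient-group shifts, stratum shifts) multiply the
affected cell means by `2^FC` *before* the noise draw; all randomness comes
from one seeded generator in a fixed order, so two configs differing only
in planted signals share every unaffected count, and a fixed seed
reproduces a cohort byte-for-byte.

What the generator does **not** emulate — and hence what passing recovery
tests do not show about real data: probe-specific hybridization biases,
cartridge/batch structure, count overdispersion beyond log-normal,
RNA-quality (RIN) effects, and any true biological covariance between genes
or with the clinical variables (clinical records are drawn independently of
expression except through explicitly planted stratum shifts).

## Problem sizes and numerical choices

The recovery experiments run at: 100 seeds for detectability recovery,
5 cohorts for lane-efficiency correlation, 30 cohorts × 5 planted cells for
outlier sensitivity/false-positive rate, and 2000 replicates for the
gated-test type-I error at n = 8 vs 19 — sizes chosen so each Monte-Carlo
standard error is well below the margin being checked while the whole suite
runs in seconds. Floating-point comparisons in tests use relative
tolerances of 1e−12 for algebraic identities (self-standardization, oracle
equivalence) and looser stochastic bands where sampling noise is the
dominant term. Degenerate inputs are decided explicitly rather than left to
propagate: all-zero negatives → threshold 0 with floor 1; constant groups →
nonparametric branch; constant controls → error at z-scoring; fewer than 3
housekeeping candidates → error at geNorm.
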