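# Methods

## The problem

Peptide quantification by data-independent acquisition (DIA / SWATH) mass
spectrometry drifts: instrument sensitivity decays with time since the
last clean, differs between instruments, and recovers after maintenance.
In a study that acquires replicates of the same samples on several
instruments over months, this unwanted variation can exceed the biological
differences of interest, and the accompanying loss of sensitivity turns
low-abundance peptides into missing values. `pronorm` implements a
normalization and missing-value strategy built for exactly this setting,
together with a synthetic-cohort generator that makes the whole stack
testable against known ground truth.

## Model

For `m` runs of `n` peptides on the log2-intensity scale,

    Y = M X beta + W alpha + eps

where `M` (m × m1) assigns runs to technical-replicate groups, `X beta`
is the biological signal (constant within replicate groups), `W alpha`
is unwanted variation of unknown dimension `k`, and `eps` is noise. The
goal of normalization is to estimate `W alpha` and subtract it without
touching `X beta`. Two ingredients identify `W alpha`:

* **technical replicates** — runs of the same sample differ only through
  unwanted variation, so the residual of `Y` against `M` is pure nuisance
  (plus noise);
* **negative-control peptides** — features assumed unaffected by the
  biological contrast. In mixture designs with no natural controls,
  yeast-derived peptides are rescaled so that each control's mean log2
  intensity is identical across sample types (the unweighted grand mean
  of the per-sample-type means, so sample types with more replicates do
  not dominate); what remains in them is unwanted variation.

### The complete-data estimator (`RUV3`)

1. residualize against the replicate structure:
   `Y0 = Y − M (MᵀM)⁻¹ Mᵀ Y`;
2. take the top-`k` left singular directions `U` of `Y0`;
3. `alpha = Uᵀ Y`;
4. restrict to control columns: `alpha_c`;
5. regress the **column-mean-centered** control sub-matrix on `alpha_c`:
   `W = Ỹ_c alpha_cᵀ (alpha_c alpha_cᵀ)⁻¹`;
6. `normalized = Y − W alpha`.

The centering in step 5 is a deliberate part of this package's estimator
contract. Without it, any run-constant unwanted factor (an intensity
offset common to all peptides — exactly what drift produces) lets the
controls' absolute intensity levels leak into the regression, and the
normalized matrix loses its location (columns end up centered near zero
rather than near their raw intensities). With centering, every column of
`W alpha` has zero mean over runs, so normalization preserves each
peptide's mean observed intensity. The product `W·alpha` is invariant to
sign flips and rotations of the singular directions, so ties among
singular values are harmless; this is covered by a permutation-
equivariance test.

`k` must satisfy `1 ≤ k ≤ m − m1`; requesting more factors than the
residual has dimensions is an error, as is a replicate structure with no
within-group variation (`Y0 = 0`) or a control Gram matrix
`alpha_c alpha_cᵀ` whose condition number exceeds 1e12.

### The complete-cases variant (`RUVIIIC`)

Real matrices have missing values of three kinds: truly absent peptides,
detection-limit censoring (MNAR), and random dropout (MCAR). Averaging
replicates across such holes is not meaningful, so the estimator is run
per peptide on complete sub-matrices. For each target peptide `p`:

1. rows ← assigned, control-bearing runs where `p` is observed (a run is
   control-bearing when at least one control is observed in it; runs of
   sample types without control material get missing output);
2. shared controls ← controls observed in **all** those rows;
3. eligibility: with `R_p` rows spanning `G_p` replicate groups, `p` is
   normalizable iff `|R_p| − G_p ≥ k` (the residual degrees of freedom
   must cover the factor dimension) and the shared-control count exceeds
   `k` (see below);
4. run the six-step estimator on the sub-matrix of those rows, and write
   back the normalized column for `p` only. Missing entries stay missing.

The factor subspace of each sub-problem is estimated from **every**
column fully observed on the selected rows, not just the target and the
controls. This matters: the top-`k` singular subspace of a column subset
generally differs from that of the full matrix, and with this policy the
per-peptide algorithm coincides exactly (to numerical precision) with
the whole-matrix estimator whenever nothing is missing — a reduction
property the test suite asserts at 1e-8 on a 60 × 50 instance.

**Minimum controls.** A sub-problem with `k` or fewer shared controls
leaves the control regression with no residual degrees of freedom, and
the output is numerically wild (per-peptide residuals an order of
magnitude above noise were observed on the benchmark). `RUVIIIC`
therefore requires `n_controls ≥ k + 1` by default (`min_controls=1`
restores the permissive rule) and reports offending peptides as
ineligible with reason `too_few_controls`.

**Identifiability of the location.** Replicates and within-study controls
cannot distinguish "all runs drifted down by c" from "all true abundances
are lower by c": the cohort-average sensitivity is a single unidentifiable
global constant. `pronorm`'s convention is that normalized intensities
are reported relative to the cohort-average sensitivity (each peptide
keeps its mean observed intensity). Comparisons against simulated ground
truth therefore align that one scalar before computing residuals.

**Choosing `k`.** `k` is a required parameter, not auto-selected. For
cohort-scale data with many nuisance sources a value around 20 is the
field's common operating point; on the small benchmark cohort the true
nuisance rank is 3 (one run-level sensitivity shift plus rank-2
contamination) and `k = 3` is used — larger `k` overfits the per-peptide
control regressions and inflates residuals. The `sweep-k` utility
reports the median dilution correlation over a grid of `k` so users can
pick a value where the known positive-control signal is high and stable.

### Replicate-design construction

Runs of each sample type are randomly partitioned into groups of
`group_size` (default 3). With `cross_instrument=True` each group's runs
come from distinct instruments, chosen by a feasibility-greedy rule (one
run from each of the best-stocked instruments per group), so groups span
maintenance states and the estimator sees drift as within-replicate
variation. Leftover runs stay unassigned. Deterministic given the seed.

## Technical replacement of missing values

Within each replicate group `g`, the log-CV of each peptide observed at
least twice is `sd / mean` of its log2 values (this quantity is a
convention of the approach, computed on the log scale, not
back-transformed), and `meanLogCV(g)` averages these. A peptide observed
in at least `min_observed` runs of `g` but missing in others has each
missing slot replaced by an independent draw from

    Normal(mu_pg, sd_fraction × meanLogCV(g) × mu_pg),

with `mu_pg` its mean observed log2 intensity in `g` and
`sd_fraction = 0.25`. Draws are not truncated (the log2 scale admits any
real value); the scale parameter is taken in absolute value, which only
matters when normalized intensities are centered near zero (e.g. after
median normalization — on raw-scale log2 intensities the issue never
arises). Supported observation rules: ≥1 of 2, ≥2 of 3–6, or a majority
of 4–6 (`majority_rule`). Each missing slot is drawn independently
rather than once per (peptide, group). Replacement runs **after**
normalization, on normalized intensities, and every synthesized cell is
recorded in a boolean audit mask written next to the filled matrix.

Relaxing the rule monotonically increases both the true-positive and the
false-positive observation rates; the ≥2-of-3 rule is the default
because it raises TP fill while barely moving FP fill.

## Missingness classification

Per sample type: peptides missing in ≥ 90 % of replicates are called
true missing. The rest are assessed on random groups of six replicates:
a mean missing count per group ≥ 5 → MNAR, ≤ 1 → MCAR, otherwise
intermediate. On detection-limit-censored data MNAR-labelled peptides
have systematically lower observed intensities than MCAR-labelled ones;
`mnar_mcar_intensity_test` quantifies this with a two-sided unpaired
t-test on per-peptide median observed intensities (equal-variance by
default, Welch by flag).

## Evaluation metrics

* **CV%** — always on the natural scale: log2 values are exponentiated
  before `100 × sd / mean` (sample sd, n−1). Undefined below two
  observations. Reported per peptide within groups (sample type by
  default) and summarized by the median.
* **Dilution correlation** — per-peptide Pearson correlation of log2
  intensity against log2 tissue proportion; zero-proportion samples are
  excluded on the log scale (a linear-proportion option includes them).
* **Cohort power** — the analysis unit is the technical-replicate-group
  mean. For each cohort size, units are drawn without replacement, each
  peptide is tested with a two-sided unpaired t-test, and the fraction
  significant at alpha = 0.05 is averaged over iterations with a
  t-based 95 % CI. No multiple-testing correction is applied (the metric
  is the raw fraction below alpha).

## The synthetic cohort generator

The generator emulates an eight-sample benchmarking design: a dilution
series of ovarian tumour tissue (0–50 %) against a fixed 50 % prostate
background with yeast as filler (Samples 1–6), a 50:50 ovary:yeast mix
(Sample 7), and a HEK293T control (Sample 8); four samples per block in
triplicate and four in duplicate (20 runs per instrument per block), on
a configurable number of instruments and acquisition blocks. The full
default design is 6 instruments × 13 blocks × 20 = 1560 runs.

Latent log2 intensity: `base + log2(tissue proportion) + instrument
offset − drift_rate × days_since_clean + (W_true A_true) + noise`. A
peptide whose source tissue is absent from a sample is true missing;
otherwise observation fails with probability
`sigmoid((threshold − latent)/width)` (MNAR; threshold at a quantile of
the latent distribution) and additionally at `mcar_rate` (MCAR). Drift
is linear in days since the last clean by default (the decay shape in
real instruments is monotone but otherwise unknown); seeds are split
hierarchically (abundance / nuisance / noise / missingness) so
missingness can be re-rolled on fixed intensities.

### The benchmark parameter set (`BENCHMARK_A`)

Two instruments with offsets ±0.5 log2 units; four blocks on days 1, 40,
80 and 119 (a realistic four-month span, cleaning at day 0 only); drift
rates 0.035 and 0.025 log2/day (instruments degrade at different rates;
mean 0.03); rank-2 contamination of entry sd 0.4; noise sd 0.15;
detection threshold at the 15th latent percentile with logistic width
0.3; 2 % random dropout; 500 peptides — 175 ovary-responsive, 125
prostate-constant, 150 yeast controls, 50 HEK-only — with base
abundances N(15, 1). Under these conditions the raw matrix has a median
dilution correlation of the responsive peptides below 0.6 and a median
natural-scale CV of the constant peptides above 30 %; after RUV-III-C
with `k = 3` the correlation exceeds 0.9, the CV falls below 15 %, and
the residual against the generating signal (after aligning the global
sensitivity constant) is within 3× the noise sd.

### What the generator does and does not emulate

It reproduces the failure modes the method targets — multi-instrument
offsets, monotone sensitivity drift with cleaning recovery, low-rank
contamination, composition-driven absence, LOD censoring and random
dropout — with known ground truth. It does not simulate peak picking,
FDR filtering, interference, retention-time drift, sample-preparation
variability, or correlated peptide structure within proteins. Passing
tests therefore demonstrate that the estimators remove the modelled
nuisance structure and preserve the modelled signal; they do not certify
performance on any particular real instrument fleet.

## Numerical choices and degenerate inputs

* SVD via LAPACK (`numpy.linalg.svd`, economy mode); ties broken by
  decomposition order (harmless — see rotation invariance above).
* Control Gram condition threshold 1e12; `Y0` treated as zero below
  1e-12 relative to the data scale.
* Pairwise run correlations in QC use pairwise-complete observations and
  skip pairs sharing fewer than 50 peptides (correlation on a tiny
  overlap is noise); sample types with one run skip the correlation
  criterion with a warning.
* Observation-fraction denominators count post-QC runs of the relevant
  sample type; all selection thresholds are strict inequalities.
* The <1200-protein QC rule counts proteins with ≥ 1 supporting peptide.
* Control scaling is applied after run-level QC.
* Replicate-group replacement skips groups with no multiply-observed
  peptide (no meanLogCV is estimable) with a warning.
* Runs with zero observations are left unchanged by median
  normalization, with a warning.
* iRT calibration peptides are carried in the matrix but excluded from
  selections via the origin filter; they are instrument diagnostics, not
  biology.

## Problem sizes

The test suite and the acceptance script run the benchmark cohort at
160 runs × 500 peptides, the estimator-vs-oracle comparison on one
hundred 12 × 8 instances, the classifier check on 36 runs × 1500
peptides, and the power calibration on 500 peptides × 40 replicate
groups per arm — sizes at which every property above is measurable in
seconds while leaving the algorithms identical to what a full-scale run
would execute.

## Known limitations

* The per-peptide estimator refits the factor subspace for every target;
  peptides observed in nearly identical run sets could share a fit, and
  no such caching is attempted.
* The absolute location of normalized intensities is a convention (see
  identifiability above); downstream consumers comparing cohorts should
  anchor on shared reference samples.
* Cross-instrument grouping requires at least `group_size` instruments
  per sample type; the benchmark cohort (2 instruments) uses random
  within-sample triplicates instead.
* `eq`-style equality of filled matrices across platforms is only
  guaranteed with identical BLAS/LAPACK builds; within one environment
  all outputs are byte-reproducible from the config seeds.
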