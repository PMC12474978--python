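# Methods

This note documents the statistical models behind `vepbench`, the design
choices that were genuinely open, what the synthetic cohort does and does
not emulate, and the package's numerical conventions.

## Calibration of raw scores

Methods differ in how scores become classes, and the package keeps the
four modes distinct (`MethodSpec.calibration_mode`):

- **builtin_classes** — the method's own three-way labels are used
  verbatim; "uncertain" labels are excluded from both reclassified sets
  downstream (reclassification is two-sided; uncertain is neither).
- **qvalue_threshold** — per-variant p-values are BH-adjusted and
  `q ≤ 0.05` (boundary inclusive) is pathogenic.
- **class_selection** — for tiered classifiers that trade coverage for
  confidence, the tier with the highest AUROC on the driver-vs-negative
  task is selected; ties prefer the tier retaining more variants.
- **learned_cutoff** — the threshold maximizing sensitivity +
  specificity over the *observed* scores (a Youden-type cutpoint).
  Candidate thresholds are the unique observed values, not midpoints:
  the classification rule is stated on observed scores (≥ t pathogenic
  for higher-is-pathogenic methods, ≤ t for the reverse), so midpoints
  would create thresholds no observation can exercise. When several
  thresholds tie, the final threshold is their median. Cutoffs are
  re-learned per dataset.

The cutpoint scan weights instances at mutation level (each unique
variant once) by default; population-level weighting is an option.

## Driver-rediscovery ROC

AUROC is the Mann–Whitney estimator with ties counted ½; variance and
CIs come from DeLong's structural components
(`V10_i = P̂(S_i > S_neg)`, `V01_j = P̂(S_pos > S_j)` with midranks),
normal approximation, clipped to [0, 1]. Paired comparisons use the
DeLong covariance of the two methods' components on the identical
instance multiset. Degenerate variance (identical scorers, perfect
separation) is reported as a flagged point CI; a self-comparison's p is
defined as 1 rather than 0/0. Negatives are upsampled with replacement
to match the positive count; because duplicated negatives understate the
DeLong variance slightly, the upsampled CI mirrors the study design and
the unique-negative fit is available as a diagnostic. The comparison
plan when method classes are given is best-within-class vs class
members, then class bests vs the overall best, BH-corrected as one
family.

## Binding enrichment

The 2×2 pools all genes with structural data: rows = reclassified
pathogenic / benign, columns = binding / non-binding residue. Genes
without binding data and variants whose protein change does not parse
are an explicit `unmapped` category excluded from denominators. The
exact two-sided p sums hypergeometric outcomes with probability ≤ the
observed table's; the odds ratio is the cross-product estimate with a
Haldane–Anscombe 0.5 added to every cell only when some cell is zero,
and the Woolf log-normal CI uses the same corrected cells. The exact p
is never continuity-corrected. OR_binding is computed at mutation level
(unique variants) — an assumption, recorded here, since either level is
defensible.

## Survival

**Timescale and truncation.** Time zero is diagnosis; patients enter
the risk set at first tumor sequencing (`t_entry`) and exit at death or
last contact. Left truncation removes the immortal-time bias of
conditioning on surviving to sequencing. With multiple sequencing
events, the earliest defines entry.

**Strata.** Per gene: oncogenic > reclassified pathogenic >
reclassified benign > no mutation, by strength of evidence — the
precedence for mixed carriers is an assumption and is emitted with
results. VUS carriers whose classification is uncertain or missing stay
in `no_mutation` (a sensitivity option excludes them). Patients whose
panel does not cover the gene are excluded.

**IPTW.** The propensity model is main-effects logistic on baseline
covariates (age, sex, stage, smoking, TMB, MSI, …; categorical
covariates are dummy-coded). Weights are stabilized so their mean is
near 1, which makes the mean-weight invariant testable; raw weights and
percentile truncation are options, off by default. Fitted propensities
within 1e-6 of 0/1 raise a positivity error naming the offending
covariate pattern. Balance is reported as standardized mean differences
before/after weighting.

**Cox fit.** The weighted partial likelihood uses Breslow tie handling
and counting-process risk sets (`entry < t ≤ exit`), maximized by
Newton–Raphson with step-halving; a parameter escaping ±20 raises
(monotone likelihood, no finite MLE). Variance is the robust sandwich
`A⁻¹(Σ (w_i U_i)(w_i U_i)ᵀ)A⁻¹` with Lin–Wei score residuals — case
weights invalidate the inverse-information variance. The implementation
is validated against `lifelines` (point estimates) and against R
`survival::coxph` (robust SEs with weights and truncation agree to
seven digits; the frozen oracle value lives in the test suite).

**RR.** `RR = HR(pathogenic vs none)/HR(benign vs none)`. Its CI is a
patient-level nonparametric bootstrap that re-runs *both* weighted fits
(weight re-estimation included) per replicate; replicates with an empty
arm or no events are dropped and counted, with > 20% drops an error. A
bootstrap was chosen over a delta method because the two fitted HRs
share the reference arm and the weighting step, and no variance formula
for that dependence is assumed.

**KM.** The weighted product-limit estimator shares the Cox risk-set
convention; strata under 10 patients are dropped. Curves are invariant
to rescaling all weights.

**Two-stage FDR.** Discovery contrasts are BH-corrected at FDR 0.1 as
one family; only discovery-significant contrasts are re-fit in the
confirmation cohort, and confirmation q-values are BH over that reduced
family alone.

## Mutual exclusivity

The one-vs-all table includes the focal gene in the oncogenic column (a
patient carrying only an oncogenic mutation in the focal gene counts in
the column but not the row), while OR_mutex excludes the focal gene
from its column ("other pathway genes") — the two statistics answer
different questions and each follows its own definition. Significance
is `logOR < 0` and BH `q ≤ 0.1`, with the BH family being all
(gene, pathway, method) tests of one invocation. The pathway rate's
denominator is *all* pathway genes, so untestable genes dilute the
rate by design. Per-gene panel filtering is applied before counting
(an assumption; the alternative — one fixed cohort for all genes — is
a one-line change). The TMB-adjusted logistic regression is a
maximum-likelihood fit of the pathway-oncogenic indicator on the
reclassified-mutation and TMB-high indicators; perfect separation is
detected and flagged (NaN estimates) rather than reported as a huge
finite coefficient. TMB-high is `TMB ≥ 10` mut/Mb (boundary included);
MSI-high is `MSIsensor score > 10` (strict).

## Neutral-variant simulation (SBS96)

Substitutions are keyed by the pyrimidine-strand trinucleotide context
and alternate base (96 categories, COSMIC convention); purine-reference
records are reverse-complemented. The empirical profile of observed
SNVs is the sampling distribution for simulated neutral variants;
genomic "opportunities" act only as a feasibility check (a category
with profile mass but zero available sites is an error) and default to
uniform, since no opportunity correction is applied to the sampling
itself. Simulated variants carry no gene assignment by default; a
mapping hook can place them on synthetic genes. Whether simulated SNPs
should be constrained to panel regions or missense consequences is
exposed as options; the default applies neither constraint.

## Ensemble

Features are per-method scores, z-scored with the *sample* (n−1)
standard deviation, fitted on training rows only; constant features are
dropped. Instances with any missing feature are dropped before
splitting (median imputation is behind a flag). The 75:25 split is
stratified by class with largest-remainder allocation and grouped by
variant, so population-level duplicates of one variant never straddle
the split — stricter than strictly necessary, to exclude leakage.
`mtry` (features per split) is tuned over {1, 2, 3, √p} by CV AUROC
under 5-fold or gene-holdout CV; gene-holdout folds partition genes so
validation measures generalization to unseen genes. 500 trees by
default (200 in the bundled pipeline for speed). Test metrics use the
0.5 probability threshold; the ensemble-vs-baseline comparison is a
paired DeLong test on identical test instances.

## The synthetic cohort generator

The generator is the package's ground-truth instrument, emulating the
statistical structure the benchmarks assume:

- **Mutations.** Per gene: a per-patient mutation probability split
  into known-oncogenic variants, latent-driver VUSs and passenger VUSs.
  Default prevalences follow a lung-adenocarcinoma-like ranking (TP53
  45%, KRAS 25%, KEAP1 17%, …) with driver hazard ratios near 2 for
  KEAP1 and ~1.6 for STK11/SMARCA4, and none for passengers.
- **Scores.** Class-conditional Beta distributions per method on
  [0, 1]; lower-is-pathogenic methods are reflected (1 − s), so one
  sampler serves both orientations. Scores attach to unique variants,
  so every occurrence of a variant scores identically.
- **Confounding.** Named covariates (smoking, age, TMB) shift both the
  mutation log-odds and the log hazard, per standardized unit.
- **Survival.** Exponential baseline hazard (closed-form truth;
  Weibull was considered and rejected for testability), administrative
  censoring at a horizon, and entry uniform on [0, 6] months; survival
  is drawn conditional on surviving to entry via exponential
  memorylessness, so the left-truncated likelihood is exactly correct.
- **Binding.** 10% of residues per gene are binding sites; driver
  variants land on them with a configured odds ratio (default 5)
  against the passenger rate.
- **Exclusivity.** Within each pathway the focal (first-listed) gene's
  driver indicator is coupled to "any driver in the other pathway
  genes" through the Plackett 2×2 construction, which attains the
  configured odds ratio exactly, per patient, conditional on
  covariates. Only the focal pair is coupled; other gene pairs remain
  conditionally independent.
- **Panel censoring.** A second panel missing configured genes covers
  ~20% of patients; their mutations in uncovered genes are absent.
- **Reproducibility.** One seed feeds named `SeedSequence` substreams
  per component (and per covariate / gene / method), so components are
  independent and enlarging the cohort leaves earlier patients' draws
  unchanged.

**The confounded-recovery scenario** (`iptw_benchmark_config`) fixes
one gene of interest at true HR 2.0 with ~30% prevalence, confounders
on, and a 24-month horizon. Two design constraints matter here. First,
IPTW targets the *marginal* hazard ratio, which is attenuated below the
conditional one when hazard-side heterogeneity is large and follow-up
near-complete (non-collapsibility — a property of the estimand, not a
weighting failure); hazard-side covariate effects are therefore kept
moderate and follow-up partial (~55% events), so the marginal and
conditional HRs agree to within ~0.08 on the log scale. Second,
covariate balance diagnostics on a small treated arm are noise-limited
(max |SMD| over five covariates has sampling scale
`≈ √(1/n₁ + 1/n₀)` even under perfect balance), so the scenario uses a
prevalence yielding ~600 treated patients at n = 2000.

**What the generator does not emulate** — and hence what passing tests
do not establish about real cohorts: genomic sequence context beyond
the SBS96 label, copy-number and structural variants, clonal
hematopoiesis and other artifacts, informative censoring, non-
proportional hazards, inter-gene mutation correlation beyond the focal
pathway coupling, unmeasured confounding (the propensity model sees
every true confounder, which is exactly what real data cannot
guarantee), and real VEP score distributions, whose class overlap need
not be Beta-shaped.

## Numerical conventions and problem sizes

- Exact Fisher p via `scipy.stats.fisher_exact` (validated exhaustively
  against hypergeometric enumeration for all tables with N ≤ 12); BH
  via `statsmodels` (validated against a reference step-up to 1e-12).
- Cox Newton iterations stop when the log-likelihood change < 1e-10 and
  the step < 1e-12; ties are Breslow (event times in the generator are
  continuous, so Breslow and Efron coincide on synthetic data).
- Boundary rules are inclusive wherever a rule is stated on a
  threshold: score = cutoff is pathogenic, q = 0.05 is pathogenic,
  TMB = 10 is TMB-high; MSI > 10 is strict.
- Simulation-based test sizes were chosen to hold the full suite to a
  few minutes on one core: 100 replicates at n = 2000 for the IPTW
  recovery check, 100 seeds × 60 bootstrap replicates at n = 1000 for
  RR coverage, 200 tables at n = 1000 for mutual-exclusivity error
  rates, n = 2000 with 10 noise features for the ensemble checks, and
  1e5 draws for neutral-profile fidelity. The bundled pipeline defaults
  (n = 1500–2000 patients, 40–60 bootstrap replicates, 200 trees)
  follow the same reasoning.

## Known limitations

- The DeLong CI on upsampled negatives inherits the duplication
  optimism noted above.
- The RR bootstrap percentile CI is slightly anti-conservative at small
  replicate counts; 60 replicates give ~95% empirical coverage of the
  designed ratio in the bundled scenario.
- `or_mutex` is underpowered at gene level for low-prevalence genes —
  the result is then flagged rather than estimated, matching how such
  analyses behave on real cohorts.
- The CLI exposes the synthetic pipeline; wiring external MAF/clinical
  tables end-to-end through the CLI is limited to the formats in
  `vepbench.io`.
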