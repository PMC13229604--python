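# Methods

## Scope and data model

`sleepdex` operationalizes a cross-sectional multidimensional-sleep analysis
for an EHR-linked biobank. It consumes eight tables: participants
(demographics, lifestyle covariates, ancestry principal components, a
comorbidity score, survey date), a sleep survey (weekday/weekend bed and
wake clock times in half-hour increments), ICD and medication event streams,
an ICD→phecode map, a sleep-relevant code classification, a variant weight
table with a dosage matrix, and kinship pairs. Genotyping, imputation,
ancestry inference, and the Bayesian shrinkage that produces the variant
weights are upstream of this package: the weight table is an input contract.

## Survey cleaning and derived traits

Self-reported clock times are prone to AM/PM misreporting. Bedtimes in the
closed window [08:00, 14:00] and wake times in [18:00, 24:00) are set to
missing; midnight (00:00) is a legitimate wake time and is retained. Time in
bed is the forward arc from bedtime to wake time on the 24-hour circle, so
bed 23:00 / wake 07:00 gives 8 h; values below 3 h or above 18 h are set to
missing. Derived traits: weighted weekly time in bed (5/7 weekday + 2/7
weekend), time-in-bed irregularity |TIB_wd − TIB_we| (a plain difference of
durations, not circular), sleep midpoint (halfway along the bed→wake arc),
and social jetlag.

Social jetlag is the absolute difference of weekend and weekday midpoints.
Near midnight a linear difference is ambiguous (23:00 vs 01:00 could read as
22 h); we take the circular shorter-arc distance, capped at 12 h by
construction. This is a deliberate design choice and is pinned by an
enumeration oracle in the tests. The weekday midpoint, needed only for
jetlag, is computed by the same midpoint formula applied to weekday times.

## Index scoring

Eight components score one point each when favorable: weighted TIB in the
closed interval [7, 9] h; irregularity strictly below 1 h; weekend midpoint
in the closed window [02:00, 04:00]; social jetlag strictly below 2 h; and
absence of sleep medication, insomnia disorder, breathing disorder, and any
other sleep disorder. Boundary conventions follow the printed symbols of the
component definitions (closed where "≥/≤", strict where "<"). Aggregation is
complete-case: any missing component (a cleaned survey value, or a
one-code disorder flag) makes the whole index missing. Prorating partial
indices was rejected as it changes the estimand of per-unit odds ratios.

## Phenotyping

Events are deduplicated per (participant, ICD version, code, date) and
non-ICD-9/10 rows dropped. The analysis window is ±`window_years` (default
5) *calendar* years around the participant's survey date, closed at both
ends — an event exactly five years out is in-window, with Feb 29 references
resolved by calendar arithmetic. Participants lacking a survey date fall
back to their enrollment date as reference; participants with events but no
reference date are reported as unusable, never silently dropped.

Phecode status: case with ≥2 qualifying in-window codes, control with 0,
excluded with exactly 1. The case rule counts post-dedup codes without
requiring distinct dates (dedup already removes same-day copies of one
code). The sleep-disorder flags feeding the index are stricter: *present*
requires ≥2 codes on ≥2 distinct dates; *absent* requires zero codes;
anything between (one code, or several codes on a single day) is *missing*,
a conservative extension of the one-code-missing rule to the same-day edge
case. Control exclusion ranges of full phecode maps are intentionally not
implemented; phenotyping is exactly the two-code/zero-code rule. Phecodes
with fewer than `min_cases` (default 100) cases are dropped from the scan's
retained list, though their calls are still emitted.

## Genetics

Dosage columns are named `variant:counted_allele`. Per variant, the dosage
is used as-is when the counted allele equals the weight table's effect
allele, flipped to `2 − d` when it equals the other allele, and the variant
is dropped (with a logged count) otherwise; zero overlap is an error and
>50% loss a warning. The raw score is the weighted sum over retained
variants. Relatedness pruning removes, greedily by descending degree in the
kinship graph (coefficient strictly above 0.0625), the lexicographically
greatest id among ties, until no related pair survives — deterministic, and
never worse than the minimum vertex cover plus one per connected component.
Standardization (mean 0, SD 1 with the n−1 denominator) happens after
pruning, over exactly the analytic sample; the order is configurable but
pruning-first is the default.

## Association models

All inference is Wald: estimate ± 1.96·SE, exponentiated for logistic
models, with two-sided normal p-values — the standard PheWAS reporting
convention. Covariate sets: the *primary* model for genetic exposures is
{age, sex, genotyping array, batch, 4 ancestry PCs}; *fully adjusted* adds
{employment, education, exercise, smoking, alcohol, BMI, comorbidity
index}; index-exposure scans use {age, sex} plus the lifestyle set.
Categorical covariates are dummy-coded against the lexicographically first
level, which makes designs deterministic. Logistic fits use Newton
iterations (≤100, log-likelihood tolerance 1e-8); non-convergence,
separation (any |coefficient| > 15 on the logit scale), fewer cases than
parameters, or a degenerate interaction column flag the result unfit
(`converged=False`, NaN statistics) rather than aborting a scan. Unfit
outcomes still count toward `n_tests`, so the Bonferroni threshold
α/n_tests is conservative. Interaction outcomes default to the five
smallest-p mental-disorder phecodes significant for both exposures; a fixed
list can be supplied in the config.

## Synthetic cohort generator

The generator defines the study conditions the tests run under. Defaults:
n = 15,884 participants (the scale of a survey-complete biobank analytic
sample), 100 variants with allele frequencies U(0.05, 0.5), a planted
PRS→index slope of 0.05 per SD, four planted outcomes with prevalences
0.12–0.25 and per-SD polygenic ORs 0.85–1.0 / per-index-unit ORs 0.70–1.0
(magnitudes typical of published biobank scans, including one fully null
outcome), 1% AM/PM bedtime misreports (survey cleaning removes well under
1% of fields in real questionnaires; 1% is deliberately on the heavy side),
5% one-code exclusions and 5% window violations among cases, background
code noise at 0.8 codes/participant, and 5% of participants in a
kinship-0.25 pair (plus an equal number of sub-threshold 0.05 pairs).

Two design choices make recovery *exact* rather than approximate:

1. **Linear-probability component allocation.** Each of the eight components
   is favorable with probability `base_k + (β/8)·z` (clipped to
   [0.005, 0.995]), so the marginal regression slope of the 0–8 index on the
   standardized score equals the planted β by construction. A Gaussian
   liability link was considered and rejected because it calibrates the
   marginal slope only approximately. Base rates mirror a survey cohort
   (rare coded sleep disorders at 1.9–3.5%, common favorable behaviors at
   55–90%). Mild age confounding (−0.10 SD⁻¹ spread over the four
   behavioral components) is planted; the rare EHR components are left
   unconfounded so their probabilities stay clear of the clipping bounds.
2. **Inverse-scored survey times.** Component states are drawn first; bed
   and wake times on the 30-minute grid are then constructed to reproduce
   those states exactly through the cleaning and scoring rules (grid-parity
   bookkeeping keeps midpoints consistent with half-hour bed/wake times,
   and all constructed times avoid the cleaning windows). Misreported
   bedtimes are shifted +12 h and clamped into [08:00, 14:00], so the
   cleaned fraction equals the planted rate exactly.

Disease status follows `logit p = α + log(OR_prs)·z + log(OR_idx)·index +
λ·z·index + γ'C` with mild covariate effects (age 0.01/yr, male +0.15, BMI
0.02, comorbidity 0.10 on the logit scale) and α solved by root-finding to
hit the target prevalence; a required intercept outside ±20 raises an error
naming the outcome. Cases emit 2 + Poisson(0.7) codes uniformly dated
inside the window (minus the engineered one-code and out-of-window
fractions); code dates are a modeling convenience, as only the window
membership matters downstream.

What the generator does **not** emulate: linkage disequilibrium or
haplotype structure (dosages are independent binomials, kinship pairs are
labels without genotype correlation), realistic ICD vocabularies (a
~30-code toy map), care-seeking and coding-intensity biases, longitudinal
behavior change, and correlated component structure beyond the shared PRS
and age terms. Passing recovery tests therefore demonstrates correctness of
the pipeline's arithmetic and inference under its stated model, not
robustness to real-world EHR pathologies.

## Recovery experiments and problem sizes

CI-coverage experiments plant a single outcome (prevalence 0.2, OR 0.85 per
SD or per index unit) at n = 20,000 and run the full pipeline per
replicate; 300 replicates are used in the test suite and 200 in the
acceptance script, with 30 variants per cohort — sizes chosen to keep a
full suite run in minutes on one CPU while leaving the Monte-Carlo band
(93–97% for nominal 95% coverage) informative. These configurations set the
engineered defect rates (misreports, one-code, window violations, junk,
unmapped, background) to zero: each defect has its own dedicated audit, and
the coverage experiments measure estimator calibration alone. The
interaction type-I experiment keeps both main effects planted (OR 0.90 and
0.85) with a null product term, n = 4,000 × 600 replicates; the family-wise
audit scans 100 independent null outcomes (prevalence 0.3, n = 500, scan
covariates {age, sex}) and checks the mean Bonferroni-significant count.
Replicate seeds derive from a `SeedSequence` spawn of the experiment seed.

## Numerical notes

Clock arithmetic is exact: all grid times are multiples of 15 minutes,
which are exactly representable, and boundary comparisons (7 and 9 h, 02:00
and 04:00) resolve without float hazard because boundary-hitting weighted
averages are exact binary fractions. Standardized scores reproduce mean 0 /
SD 1 to 1e-9; the logistic fitter matches closed-form 2×2 odds ratios to
1e-8 and OLS matches normal-equation solutions to 1e-10. Ties in
relatedness pruning and categorical level ordering are broken
lexicographically, making every pipeline output byte-reproducible for a
given seed.

## Known limitations

The published cohort's headline estimates (specific β's, significant-hit
counts, Table-style interaction ORs) depend on access-restricted patient
data and are not reproducible here; the package instead demonstrates, on
synthetic cohorts with known truth, that its estimators would recover such
quantities correctly. The toy phecode map is for testing; real analyses
should supply a full map in the same layout. Standardization currently
assumes a single ancestry-homogeneous analytic sample. Nonparametric
interaction models, FDR procedures, mixed models, and figure rendering are
out of scope (plot-ready Manhattan/Miami tables are emitted instead).
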