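# Methods

## Study design implemented

`clopnsaid` implements a new-user, active-comparator cohort analysis of
concomitant clopidogrel + NSAID exposure in administrative claims. Ten oral
NSAIDs define the exposure groups (ibuprofen, celecoxib, naproxen,
rofecoxib, meloxicam, diclofenac, indomethacin, valdecoxib, nabumetone,
etodolac), with ibuprofen the referent. Three endpoints are analyzed:
all-cause mortality (death-file linkage), the thrombotic composite
AMI/ischemic stroke, and the bleeding composite GIB/ICH, each ascertained
with validated ICD-9 claims algorithms.

### Drug eras and cohort entry

Dispensings are converted to *drug eras* per person and ingredient.
A dispensing on day *d* with *s* days' supply covers the closed interval
*d … d+s−1*; overlapping refills stockpile (coverage extends, never
truncates). Successive coverage runs merge when separated by at most
`grace_days` uncovered days (default 15, the conventional allowance for
imperfect adherence); the stored era end is the last covered supply day,
and the grace tail is applied by overlap and follow-up logic rather than
stored.

Cohort entry is the earliest calendar day on which a clopidogrel era and a
study-NSAID era overlap, both extended by the grace tail. The design is
"apparently new": the first such overlap in all observed history defines
the entry candidate, and a person failing eligibility there (age outside
18–100 years; the 365 days before entry through the entry day not
continuously covered by enrollment; more than one study NSAID covering the
entry day) never enters later. A configurable washout
(`washout_days`) relaxes "all observed history" to a fixed clean window;
the default is full-history because no washout length is standard for this
design. Entry-day multi-NSAID exposure drops the person entirely, so each
patient contributes person-time to exactly one NSAID group.

Concomitancy is classified by its *trigger*: NSAID-triggered when the
clopidogrel era containing entry started strictly earlier, clopidogrel-
triggered when the NSAID era did, combination-triggered when both started
on the entry day.

### Follow-up

Follow-up begins at entry (the entry day contributes one day) and ends at
the earliest of: (1) the outcome; (2) the last covered day of clopidogrel
or the exposure NSAID plus the grace period; (3) the day before a
dispensing of a non-exposure study NSAID (switching); (4) disenrollment;
(5) the end of the dataset; and optionally (6) a fixed day-count censor
(180 days in the sensitivity variant). The outcome wins ties — standard
practice that maximizes event capture; remaining ties resolve in the order
listed, which is documented in `END_REASONS`. Follow-up is computed
independently per outcome, so per-outcome person-years differ.

### Outcome ascertainment

Outcome definitions are data, not code: a JSON file of ICD-9 wildcard
patterns with setting and diagnosis-position restrictions and optional
intracranial-injury exclusions. Wildcard semantics mirror ICD-9-CM
structure: a pattern without `*` is an exact full-length match; terminal
`*` matches any suffix including the empty one; interior `*` matches
exactly one character (so `434.*0` is a five-digit family). The injury
exclusion (codes 800\*–804\*, 850\*–854\*) applies to the *same admission*,
defined as the same claim record (a flag widens this to overlapping
inpatient date ranges); for ischemic stroke its scope is secondary-position
diagnoses, for ICH any position — following the respective algorithm
definitions, which differ in exactly this way. The event date is the
admission date (discharge may postdate censoring). Composite endpoints take
the earliest component event; a same-day pair counts once and is flagged so
the overlap can be tallied.

### Covariates

Prespecified covariates are declared in a spec file: demographics (age
continuous at entry; sex, race/ethnicity, state as indicators),
utilization-intensity counts thresholded to binary, diagnosis flags, drug
flags, and prior-outcome flags — all binary covariates measured strictly
within the baseline window entry−365 … entry−1 (a claim dated on the entry
day does not count). The shipped spec has 31 covariates matched to the
synthetic dictionary; at full claims scale the same schema expresses the
usual hundred-plus list.

The hdPS procedure: nine data dimensions (inpatient / outpatient / other
setting × ICD-9 diagnoses and procedures, plus inpatient and outpatient
CPT/HCPCS and outpatient medication ingredients, with study-exposure drugs
excluded from the medication dimension). Per dimension, the `top_k` codes
by number of distinct baseline persons become candidates (ties at the
boundary break lexicographically). Per comparator-vs-referent pair, each
candidate is scored by its confounding potential — the absolute log Bross
multiplicative bias

    BiasM = (PC1·(RR−1) + 1) / (PC0·(RR−1) + 1)

with PC1/PC0 the candidate prevalences in the comparator/referent arm and
RR the outcome risk ratio in covariate-positive vs covariate-negative pair
subjects, continuity-corrected (0.5 added to events, 1 to denominators)
when a cell is empty, and folded to max(RR, 1/RR) so protective covariates
rank as well. The `top_n` highest scores are selected per pair (ties break
by higher pooled prevalence, then column name); the nine selections are
pooled, de-duplicated, filtered for a minimum count of covariate-positive
subjects (`min_exposed`, default 10) and for codes identical to a
prespecified definition. The bookkeeping identity
`retained = pooled − duplicates − under_threshold − prespecified_overlap`
holds by construction and is asserted in tests. Candidate recurrence coding
(once/sporadic/frequent) is deliberately off: one covariate per code, which
is what makes 9 dimensions × 200 candidates pool to at most 1,800. hdPS
selection uses the outcome under analysis, so selections (and the
propensity model built on them) are cached per outcome by default; a shared
selection is a flag away.

### Propensity and balance

A multinomial logistic regression of the ten-level exposure on the combined
covariate matrix yields each subject's probability vector over the groups.
The fit is unpenalized maximum likelihood on internally standardized
covariates; if it fails to converge or any coefficient exceeds 8 per SD
(an implausible odds ratio, taken as quasi-separation), an l2-penalized
refit takes over and the fallback is logged.

Balance per covariate and comparator pair:

* standardized difference — binary `|p_a−p_b| / sqrt((p_a(1−p_a)+p_b(1−p_b))/2)`,
  continuous `|m_a−m_b| / sqrt((v_a+v_b)/2)`; reported as absolute values;
  zero pooled variance with unequal means reports infinity and is flagged.
* WCSD (weighted conditional standardized difference) — pair subjects are
  stratified on the comparator-group propensity into `n_strata` quantile
  strata (default 10; when the score takes few distinct values, one stratum
  per value, since quantile cuts would collapse); within-stratum
  standardized differences are averaged with weights proportional to
  stratum pair-total size; strata with an empty arm are skipped and weights
  renormalized. With one stratum the WCSD equals the unconditional
  standardized difference exactly. The construction is stratification-based
  because only the conditional-balance concept, not a formula, is standard.

Covariates with WCSD > 0.1 (the conventional imbalance flag) enter the
outcome models directly.

### Hazard models

Crude incidence rates are `1000 · events / person-years` with exact Poisson
(chi-square) confidence intervals; the CI method is a package choice since
rate tables conventionally leave it unstated. Cox proportional-hazards
models use days since entry as the time scale. The unadjusted model has
exposure indicators only. The adjusted model — one model per outcome with
the full ten-level exposure — adds the propensity probability vector as
continuous covariates (the referent-group probability omitted to avoid the
sum-to-one redundancy) and the WCSD-flagged covariates; zero-variance and
linearly dependent columns are pruned automatically and logged. Pairwise
two-arm models are available behind a flag. Fitting uses lifelines
(Efron ties); statsmodels PHReg serves as an independent cross-check in the
test suite.

The proportional-hazards assumption is tested per exposure term with the
scaled Schoenfeld-residual test (log-time transform). If any exposure term
rejects at α = 0.05, the model is refit with exposure × log(time)
interactions via episode splitting at event-time quantiles. Two numerical
points matter here. First, the log-time covariate is a step function
evaluated at the episode midpoint — constant within an episode and thus
identical for every subject in a risk set; evaluating it at each subject's
own interval end would leak individual event/censoring times into the
covariate and bias the interaction severely (this failure mode is guarded
by a regression test). Second, log(time) is centered at the median
follow-up among events, so the exposure main effect *is* the hazard ratio
at median follow-up (the reported summary under non-proportionality) and
the main/interaction collinearity that otherwise destabilizes the fit at
modest event counts disappears.

Subgroups (age 18–<65 vs 65–100; male vs female; NSAID-triggered vs
clopidogrel-or-combination-triggered) and the two sensitivity analyses
(180-day censoring; exclusion of subjects with any managed-care enrollment,
the potentially-incomplete-capture proxy) rerun the same machinery on the
stratum. No multiplicity adjustment is applied across the nine comparisons;
per-comparison 95% CIs are reported.

At synthetic event counts the WCSD flag is noisy in small comparator arms,
so the number of flagged covariates admitted to an outcome model is capped
by an events-per-variable floor (default 5 events per parameter after the
structural exposure and propensity terms), taking the largest-WCSD
covariates first; the cap and any truncation are logged. This guards the
partial likelihood against overfitting and is a no-op at full claims scale.

## The synthetic-claims generator

The generator is first-class code, not a fixture: it emulates the data
structure the analysis assumes so that every stage is testable against
planted truth.

* **Population.** Ages ~ Normal(66, 13) truncated to 25–97 (median entry age
  in the high-60s/low-70s), 61% female, race/ethnicity and five state labels
  with fixed frequencies; a small fraction (2%) of ages fall outside 18–100
  and 3% of baselines are too short, to exercise the exclusion cascade.
* **Assignment.** A multinomial logit on the design matrix (standardized
  age, sex, race, 14 clinical flags) with intercepts reproducing the
  empirical market shares of the ten NSAIDs and channeling coefficients
  that push older, female, GI-fragile patients toward COX-2-selective
  agents — the confounding structure the propensity machinery must remove.
  Every clinical flag is observable downstream as a baseline diagnosis
  claim or dispensing, so prespecified covariates and hdPS proxies have
  signal.
* **Exposure.** First fills at the latent index date with a trigger mix of
  45% NSAID-triggered / 40% clopidogrel-triggered / 15% combination;
  days' supply ∈ {15, 30, 60, 90} with probabilities {.10, .60, .20, .10};
  refill chains continue with probability 0.70 per fill with small random
  gaps (10% of gaps exceed the grace period and break the era). The refill
  probability is calibrated so the median per-outcome follow-up is ≈46
  days, matching the published cohort. 8% of subjects later receive a
  different study NSAID (exercising switch censoring) and 2% receive a
  second NSAID on the index day (exercising the multi-NSAID exclusion).
* **Events.** Per outcome, subject hazards are exponential:
  baseline × planted HR(assigned NSAID) × exp(covariate log-hazards), with
  the baseline normalized so the referent-arm marginal rate equals the
  configured rate (defaults 50.8 / 58.6 / 54.3 events per 1,000
  person-years for mortality / AMI-stroke / GIB-ICH). Proportional hazards
  therefore holds exactly and crude rate ratios are closed-form checkable.
  Death competes with the nonfatal outcomes by first-event-wins, and no
  dispensing or claim is generated after death (so supply exhaustion ends
  follow-up for the deceased, as in real claims). Event claims carry the
  exact setting and diagnosis position their algorithms require; a
  configurable fraction of persons (default 25%) additionally carry decoy
  admissions — wrong setting, wrong position, or intracranial-injury-coded —
  that ascertainment must reject.
* **Not emulated.** Calendar availability windows (rofecoxib/valdecoxib
  withdrawals), seasonal prescribing, dose/strength, OTC exposure,
  informative disenrollment, miscoded diagnoses beyond the decoy classes,
  and within-person hazard heterogeneity beyond the modeled covariates.
  Passing tests therefore demonstrate correctness of the pipeline's logic
  and estimators under the stated generative assumptions, not robustness to
  every real-claims pathology.

## Validation design and problem sizes

* Era merging, enrollment coverage and follow-up censoring are checked
  against brute-force day-scan oracles on 1,000+ random instances each.
* Ascertainment must recover planted events *exactly* (set equality) on
  decoy-rich bundles.
* Parameter recovery: with default (confounded) channeling and planted
  bleeding hazard ratios of 2.0, 0.7 and 1.0, the propensity-adjusted fits'
  95% CIs cover the planted values in ≥90% of comparator × replicate checks
  (20 seeds at n = 20,000 subjects — about 170 bleeding events per
  replicate, chosen to keep a full recovery study inside a few minutes).
* The proportionality test's per-term type-I error is checked against its
  nominal 5% level under homogeneous exponential truth (30 replicate
  cohorts of n = 6,000, 9 exposure terms each, three-binomial-SE band); the
  test runs mildly conservative (~0.04) at these event counts, consistent
  with its asymptotics.
* Published-table arithmetic (incidence rates, standardized differences,
  hdPS bookkeeping) is recomputed from the printed inputs; agreement is to
  the printed precision — person-years and proportions are published
  rounded, which bounds achievable agreement at one unit in the last
  printed digit for a handful of cells.

## Known limitations

* The WCSD is upward-noisy in small comparator arms (tens of subjects per
  stratum); the events-per-variable cap mitigates the consequence but the
  diagnostic itself remains noisy at synthetic scale.
* The exposure × log(time) refit approximates log(t) by a step function over
  event-time quantile episodes; with very few events the interaction is
  weakly identified and the penalized fallback may engage.
* Real claims pathologies outside the generator's scope (above) are
  untested by construction.
* Adjusted hazard ratios from the original licensed claims data are not
  reproducible without those data; the package's claims are about the
  pipeline's correctness under known truth, not about replicating the
  original effect estimates.
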