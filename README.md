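# clopnsaid

Comparative safety of individual NSAIDs used concomitantly with clopidogrel,
as a reusable, tested claims-analysis pipeline.

Patients on clopidogrel often need an NSAID for pain or inflammation, and the
choice among NSAIDs matters: NSAIDs modulate platelet function and gastric
mucosa in drug-specific ways, so both thrombotic risk (acute myocardial
infarction / ischemic stroke) and bleeding risk (gastrointestinal bleeding /
intracranial hemorrhage) can differ across agents, and may differ again in
the presence of clopidogrel's P2Y12 inhibition. The natural design is a
new-user, active-comparator cohort built from administrative claims: subjects
enter at their first day of overlapping clopidogrel and NSAID supply, each of
ten study NSAIDs defines an exposure group with ibuprofen as referent, and
outcomes are ascertained with validated ICD-9 claims algorithms.

Because such claims data are licensed and cannot be redistributed, the
package ships a synthetic-claims generator whose output has the statistical
structure the analysis must confront — covariate-driven channeling into NSAID
groups (confounding) and exponential event processes with *known* hazard
ratios — so every stage is testable against planted truth.

## What the pipeline does

1. **Claims data model** (`clopnsaid.data_model`) — five delimited-text
   tables (persons, enrollment, dispensings, long-format claims, deaths),
   validated and round-trippable; ICD-9 codes stored dot-free.
2. **Synthetic claims** (`clopnsaid.simulate`) — multinomial-logit treatment
   assignment on baseline covariates, refill chains with days' supply,
   outcome claims written with the exact setting/diagnosis-position the
   algorithms require, plus decoy admissions that must never be captured.
3. **Cohort construction** (`clopnsaid.cohort`) — drug eras bridging ≤15-day
   gaps, first-concomitancy entry with one-year baseline enrollment,
   age 18–100, trigger classification (NSAID- / clopidogrel- /
   combination-triggered), and per-outcome follow-up with five censoring
   rules (plus an optional 180-day censor).
4. **Outcome ascertainment** (`clopnsaid.outcomes`) — declarative ICD-9
   definitions for AMI, ischemic stroke, GIB and ICH (wildcard patterns,
   position and setting restrictions, intracranial-injury exclusions),
   death-file linkage, and composite first-event logic.
5. **Covariates** (`clopnsaid.covariates`) — prespecified baseline
   covariates from a spec file, and hdPS empirical covariate selection:
   top-k prevalent codes per claims dimension, ranked per comparator pair by
   the Bross multiplicative bias
   `BiasM = (PC1(RR−1)+1) / (PC0(RR−1)+1)`, pooled with a transparent
   accounting (`retained = pooled − duplicates − under-threshold −
   prespecified-overlap`).
6. **Propensity & balance** (`clopnsaid.balance`) — multinomial logistic
   propensity over all ten groups; standardized differences and the weighted
   conditional standardized difference (WCSD) with the 0.1 flag rule.
7. **Hazard models** (`clopnsaid.hazards`) — exact-Poisson incidence rates
   per 1,000 person-years; unadjusted and propensity-adjusted Cox models
   (propensity probabilities as continuous covariates + WCSD-flagged
   covariates); scaled Schoenfeld proportionality check with an
   exposure×log(time) refit when it rejects; age/sex/trigger subgroups and
   the two sensitivity analyses.

A thin CLI (`clopnsaid simulate|build-cohort|ascertain|covariates|analyze|run-all`)
wraps `clopnsaid.pipeline.run_all`, which writes every artifact as delimited
text plus a manifest keyed by config hash and seed.

## Worked example

```bash
python examples/05_hazard_models.py
```

prints (abridged):

```
worked example: 108 events / 829 person-years -> 130.3 per 1,000 p-y (95% CI 106.9-157.3)

adjusted GIB/ICH hazard ratios vs ibuprofen (planted truth shown):
             hr    lo    hi  truth  covered
nsaid
celecoxib  1.76  1.16  2.67    2.0     True
naproxen   0.54  0.26  1.14    0.7     True
meloxicam  0.59  0.28  1.24    1.0     True
rofecoxib  0.90  0.49  1.62    1.0     True
```

The first line is the incidence-rate arithmetic every rate table uses
(events / person-years, scaled to 1,000 person-years, exact Poisson CI).
The table shows the propensity-adjusted Cox estimates recovering the
planted bleeding hazard ratios on a confounded synthetic cohort of 20,000
subjects — channeling pushes older, GI-fragile patients toward the
COX-2-selective arms, and the adjustment removes that bias.

Other example scripts cover simulation (`01`), cohort construction (`02`),
outcome ascertainment with decoys (`03`) and hdPS/balance diagnostics (`04`).

## Scope

The package estimates comparative hazards *between* NSAIDs in concomitant
use with clopidogrel; it does not address NSAID-vs-non-use contrasts,
dose–response, or real identified-claims linkage mechanics. Real adjusted
hazard ratios from licensed claims data are not reproducible here by
construction; the acceptance surface is worked-example arithmetic plus
planted-truth recovery, as documented in `docs/methods.md`.
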