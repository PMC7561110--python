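# Methods notes

This note records the modelling conventions, defaults, and numerical
choices the package makes, what the synthetic generator does and does not
emulate, and the known limitations.

## Exposure construction

**Conversion factors.** The shipped table
(`src/opioidtraj/data/conversion_factors.csv`) carries CDC-derived oral
equianalgesic factors (codeine 0.15, dihydrocodeine 0.25, tramadol 0.1,
tapentadol 0.4, morphine 1.0, oxycodone 1.5, hydromorphone 4.0, pethidine
0.1, oral buprenorphine 10.0) and transdermal factors per µg/hour with the
24-hour delivery rate folded in (fentanyl 2.4, buprenorphine 12.6), so
patch records never need a daily count. Diamorphine (1.5) and meptazinol
(0.1) have no CDC entry; the shipped values are stand-ins from UK practice
and can be replaced by pointing `prepare --conversion-table` at a
substitute file. Transdermal rows also carry `patch_wear_days` (fentanyl 3,
buprenorphine 7): supply duration of a patch prescription is
`quantity × wear days`.

**Cleaning rules.** A missing daily count is imputed from the patient's
modal daily count for the same ingredient, else the population median for
that ingredient. Oral supply duration is `ceil(quantity / daily count)`,
floored at 1 day and capped at 183 days (the cap protects timelines from
implausible bulk entries; the long-term "single prescription ≥ 90 days"
rule is evaluated on the cleaned duration, which the cap does not reach).
Records that cannot be repaired are dropped with a reason code
(`bad_date`, `unknown_ingredient`, `zero_quantity`, `no_daily_count`) and
logged — never silently. Cleaning can only drop records or fill a missing
daily count, so it never increases total dispensed milligrams.

**Timelines.** Dates are handled internally as day offsets from the index
date (day 0 = index), with half-open supply intervals
`[start, start + duration)`. A same-ingredient prescription issued while a
previous supply of that ingredient is still running is stockpiled: it
starts when the running supply ends. (The obvious alternative — doubling
the dose — would make duplicate same-day scripts look like dose
escalation.) Different ingredients always contribute additively, matching
the summing convention for combination regimens.

**Window averages.** The average MME/day over a 6-month band divides by
covered (exposure > 0) days only; a band with no covered day is the
off-treatment state. This keeps a patient's category independent of their
coverage fraction — a steady 18 MME/day codeine user is "low" whether they
collected 4 or 6 scripts in the band. Whether the divisor should instead be
all 182 calendar days is genuinely ambiguous; both conventions are
implemented (`convention="covered" | "calendar"`), covered-days is the
default.

## Cohort rules

Candidate index = first opioid prescription inside the study window; a
failed eligibility rule excludes the patient rather than re-indexing to a
later script. Exclusions are evaluated and logged in a fixed precedence
(age → cancer → methadone → not-incident → no-follow-up), one reason per
patient, so attrition flowcharts are reproducible. Cancer flags on or
before the index date within the 10-year lookback exclude; non-melanoma
skin cancer is exempt. Patients censored before day 365 are retained and
analysed on available time (`short_follow_up` flag) rather than dropped.

Covariate windows: diagnosis flags use `[index − 365 d, index)` and
baseline drug flags (benzodiazepine, gabapentinoid, psychotropic) use
`[index − 365 d, index]` — drug use on the day of the first opioid script
counts as baseline co-prescribing, a same-day diagnosis does not. The
Charlson score is a configurable weighted sum over condition flags
(categories 0 / 1–3 / ≥ 4 → low/medium/high); weights are config because
code-list curation is out of scope. Missing deprivation/ethnicity values
are explicit `missing` categories, never dropped rows.

## Long-term phenotype

The 90-day criterion is a sliding half-open interval `[t, t + 90)` over
issue dates, not calendar quarters: three issues spanning exactly 90 days
(days x … x+89) qualify, x+90 does not. Days 0–30 are blanked for both
rules — a prescription issued in that window neither counts toward the
3-in-90 rule nor seeds the single-≥90-day rule. The window rule is checked
before the single-script rule when both hold. The classifier is verified
against an exhaustive all-start-points oracle in the tests.

## Transitions

Six-month bands are 182-day blocks from index (days 0–181, 182–363,
364–545, 546–727). Each cohort member occupies exactly one state per band;
a band with no covered day — including all time after censoring — is the
off state. This makes the conservation identity exact (per band, state
counts sum to the stratum size) at the cost of counting early-censored
members as off rather than excluding them; members fully observed are
unaffected, and the choice is flagged for sensitivity analyses.

## The nested logistic model

**Estimation.** Laplace-approximate maximum likelihood in two stages.
Stage 1 profiles the fixed effects at the joint penalised mode: for
candidate standard deviations σ = (σ_region, σ_practice, σ_prescriber) a
damped Newton iteration maximises the joint penalised log-likelihood over
(β, b) with spherical effects u = σ·b, and L-BFGS-B with non-negativity
bounds maximises the Laplace criterion
`ℓ_joint − ½ log det(Λ'Z'WZΛ + I)`. Stage 2 then moves β into the outer
optimisation (the log-determinant depends on β through the working weights
W), starting from the stage-1 optimum — this is the same estimator as
lme4's `glmer` at its default Laplace setting, and the test suite checks
agreement with `glmer` on a simulated dataset. Linear predictors are
clipped at ±30; a fixed effect exceeding 15 on the log-odds scale raises a
separation warning rather than failing silently. Variance parameters may
sit exactly on the zero boundary, in which case the model degenerates to
single-level logistic regression (tested to ≤ 10⁻³ per coefficient; note
the boundary ML estimate has sampling noise of order `√(2/J)` across J
units, so exact agreement needs many observations per unit).

**Explained variation.** Latent-variable decomposition with logistic
residual variance fixed at π²/3: a level's share is
`σ²_level / (Σ σ² + π²/3) × 100`, and the residual share is defined as the
complement so the four shares sum to 100 exactly in floating point.

**Unit profiles.** Each unit's random effect is summarised by simulating
from its empirical-Bayes conditional distribution
`N(û_j, conditional sd_j²)`, where û is the conditional mode and the
conditional variance comes from the inverse of the random-effects block of
the joint Hessian (fixed effects held at their estimates). Default 1,000
draws; fewer than 100 warns. Point estimates and 95% intervals are
percentile summaries of the draws; ranks are by point estimate with ties
broken by unit id; a unit with no information keeps its prior (draws
centred at 0 with the level's σ²). Whether such intervals should instead
be fully Bayesian credible intervals is left open; percentile intervals of
conditional draws are the convention here.

**Flagging.** High-risk iff the whole OR interval exceeds 1; low-risk iff
wholly below 1. Under a true null (all σ² = 0) empirical-Bayes shrinkage
pulls every interval toward zero width around 0, so the realised false-flag
rate is well *below* the nominal 2.5% one-sided level — the calibration
test asserts the conservative direction, not equality.

**Proportion scale.** Adjusted unit effects are reported as proportions via
the anchored transform `expit(logit(p̄) + u)`, where p̄ is the cohort's
observed long-term proportion, so u = 0 maps to the population average
exactly and the transform is strictly increasing. An alternative
(averaging over the covariate distribution) would give marginal rather
than anchored proportions; the anchored form was chosen because the
population-average reference is the quantity the flags compare against.

**Trends.** Annual rate = prescriptions / registered patients × 10,000 per
ingredient-year, with raw mid-year registration counts as denominators (no
person-time adjustment).

## Synthetic generator

The generator draws the hierarchy (regions → practices → prescribers →
patients), mean-zero normal random intercepts per unit with configured
variances, independent Bernoulli covariate flags at configured prevalences,
and a latent long-term indicator from exactly the logistic model the
inference stage assumes — by design, so that recovery tests are
well-posed. Refill patterns are then emitted conditional on that
indicator: long-term patients receive ~10–14 monthly 28-day scripts (40%
continue into year 2), short-term patients one or two scripts inside the
first 30 days plus occasionally up to two sparse later scripts that cannot
satisfy either long-term rule. Defaults: intercept `logit(0.146)`
(population long-term average at reference covariates), effects
gabapentinoid ln 2.52, fibromyalgia ln 1.81, substance use ln 1.72,
depression ln 1.30, codeine-dominated drug mix, 2006–2017 calendar span,
5% messy records (blanked daily counts, zero quantities), and small rates
of methadone use (1%), washout-violating prior use (5%), beyond-washout
remote use (5%), under-18 patients (2%), and early censoring (5%) to
exercise every exclusion and censoring path. Special prior-use scripts are
placed before the study start by construction so the candidate index date
is never re-anchored onto them.

What it does **not** emulate: realistic UK market shares or seasonality,
policy shocks (e.g. the 2014 tramadol rescheduling), dose tapering or
escalation within a patient, correlated covariates (a shared-latent-factor
switch exists but is off by default), informative censoring, or
prescribing behaviour as a clinical process. Age, sex, ethnicity and
deprivation are generated for table realism but carry no effect in the
default latent model, which keeps parameter-recovery tests interpretable.
Passing tests therefore demonstrate that the pipeline's rules and estimator
are correct under the stated data-generating process — not that the model
is adequate for any particular real population.

## Problem sizes used in the checks

Recovery runs use 5 regions × 8 practices × 5 prescribers × 50 patients
(10,000 patients, 200 prescribers) averaged over 20 generator seeds;
the zero-variance reduction check uses 24 prescribers × 1,000 patients so
the boundary variance estimate is tight; the phenotype oracle comparison
uses 1,000 randomised prescription histories plus dense boundary sweeps.
These sizes were chosen so each check is statistically informative while
the whole suite stays quick to run.

## Known limitations

- Fixed-effect standard errors condition on the estimated variance
  components (no propagation of σ² uncertainty), as is standard for
  Laplace GLMM fits.
- The Laplace approximation is least accurate for binary outcomes with few
  observations per unit and large σ²; the recovery tests quantify the
  residual bias at the sizes above (a few percent on σ²_prescriber).
- Cross-classified (non-nested) structures, random slopes, and survival
  extensions are out of scope; non-nested ids raise a structural error.
- The transdermal wear-day convention and the two no-CDC-entry factors are
  pragmatic defaults; sensitivity analyses should swap the conversion
  table.
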