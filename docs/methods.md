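# Methods

## Model structure

`cvdmicrosim` simulates individual adults in annual cycles from 1 January
2013 through 31 December 2022. The population is stratified into 24 cohorts:
age bands 20–29 … 70–79 × {male, female} × {urban, rural}. Age is continuous
(uniform within the band at baseline; a design choice — the within-band
distribution of the source populations is not specified anywhere we rely
on). Each cohort is simulated with `n_per_cohort` individuals and results
are scaled to the projected census, with weights recomputed every year as
`census(cohort, year) / n_alive_simulated(cohort, year)` so population
growth is honoured. Cohort membership for mortality lookup is recomputed
from attained age; individuals ageing past 79 keep the 70–79 rates but are
excluded from all reported 20–79 tallies. New 20-year-olds enter each year
(one tenth of the cohort size, scaled by the census growth trend); entry is
on by default and toggleable (`add_entrants=False`).

## Risk profiles (Gaussian copula)

Six risk factors per person: systolic blood pressure (SBP, mmHg), total
cholesterol (mmol/l), diabetes, CHD history, cerebrovascular history, and a
single 7-level tobacco variable {never, passive-only, former, cigarette,
bidi, chewing, dual}. "Dual" means chewing plus one smoked product; the
smoked product is assigned from the cohort's cigarette:bidi ratio.

The joint distribution is induced by a latent multivariate normal with the
configured 6×6 correlation matrix: continuous factors are linear transforms
of their latent coordinate (clamped to physiologic ranges, SBP 60–300 mmHg,
cholesterol 1–15 mmol/l; a warning fires if more than 0.1% of draws clamp);
binaries threshold their coordinate at the prevalence quantile; tobacco maps
one coordinate's CDF through inverse-CDF assignment over the fixed category
order. The copula is a modelling choice: the inputs specify marginals and
pairwise correlations but no joint mechanism. Correlation matrices that
fail positive semidefiniteness (e.g. from printed rounding) are repaired by
eigenvalue clipping with a renormalized unit diagonal; repairs moving the
matrix more than Frobenius distance 0.05 are errors.

Baseline former users draw quit durations uniform on [0, 120] months so
their residual excess risk spans the whole lag curve; the true distribution
of time-since-quit at baseline is unknown.

## Hazard and competing risks

Per cause c ∈ {MI, stroke}, an individual's relative risk is the product of
per-unit multipliers for continuous factors (`RR^((x − ref)/unit)`),
per-state multipliers for binaries and tobacco category, with former users
contributing the lag-decayed multiplier (below). Annual probabilities are
mean-RR normalized:

    p_i = m_cohort,c(year) · RR_i / mean_alive(RR)

which makes the cohort mean equal the input mortality rate exactly (tested
to 1e-12) — the input rates are population rates, so individual variation
must average out to them. Under an intervention scenario the normalizing
mean is evaluated on the *counterfactual* tobacco state (what each person's
tobacco RR would have been without the intervention), otherwise
normalization would cancel the intervention's effect. Other-cause mortality
carries no individual RR. Annual rates are used directly as probabilities
(they are ≤ a few percent; the rate→probability conversion is taken as the
identity and documented as an approximation). Each person-year draws one
uniform and selects from {MI death, stroke death, other death, survive};
individual probabilities are clamped at 0.999 with a logged warning if
normalization ever pushes them past certainty.

## Interventions

Four fixed-effect measures (fractional reductions in use probability, with
95% CIs): smoke-free laws (passive channel 64% [39–89], active channels 1%
[0–2]), brief cessation advice (1% [0–3]), mass media (5% [1–11]),
advertising ban (6% [5–7]). Tax increases act mechanistically per product
and location: `reduction = |elasticity| × tax_share × increase%/100`,
assuming full pass-through (tax shares 38% cigarette / 9% bidi; elasticities
−0.34/−0.19 cigarette rural/urban, −0.92/−0.85 bidi). The mechanistic form
reproduces all six published 50/300/500% anchors within 3 percentage points
and extrapolates to the 800% sensitivity range. Chewing-only tobacco is not
targeted by any measure and its risk contribution persists.

Combination modes: `max_only` (largest effect only), `cumulative`
(1 − Π(1 − eⱼ)), `synergy25` (cumulative with each effect inflated 25%,
capped at 1).

Implementation schedules. Baseline: legislation is immediate and national,
but its effect on smoking phases in linearly over 10 years
(`effective = (t+1)/10`). Delayed: legislative coverage ramps 0→80% over 5
years; each newly covered tranche starts its own 10-year response, so the
effective fraction is the convolution of coverage increments with the
response ramp (reaching 0.64 of full effect in year 10). Taking the raw
coverage schedule as the effect multiplier would make the delayed scenario
*stronger* in early years and stronger on average — contradicting both
intuition and the attenuation the model is meant to exhibit — so the
convolution is the deliberate design choice; `coverage_ramp` exposes the raw
schedules and `effective_ramp` the convolved ones.

Each year, per channel (active cigarette, active bidi, passive) and
location, the target cumulative fraction of ever-users to convert is
`combine_effects(channel effects) × effective_ramp(year)`. Quitters are
drawn without replacement among current users from a dedicated intervention
random stream, so the trajectory is monotone (a target below the achieved
level is a no-op) and all other randomness is shared with the baseline run.
Quitters become former users with a fresh quit clock; dual users lose the
smoked component and keep chewing (risk decays from the dual to the chewing
level); passive-exposed individuals lose passive excess risk under the same
lag (the lag sources do not distinguish channels).

Quit-benefit lag: residual RR after quitting is
`1 + (RR − 1)·exp(−months/τ)` with τ = 19.1 months, floored at full recovery
after 120 months. A single exponential with this τ cannot simultaneously
yield a 15% excess-risk decline at 1 year and 36% at 3 years (it gives ~47%
and ~85%); the exponential-on-excess-risk form with the stated τ is
implemented and the discrepant anchors are left unreconciled.

## Medications

Eligibility: aspirin for CHD/cerebrovascular history; statins for total
cholesterol ≥ 5.2 mmol/l or history; antihypertensives (ACE inhibitor +
thiazide without history, beta-blocker regimen with history, one shared
effect size) for SBP ≥ 140 mmHg or history. Thresholds are configurable
defaults. Class benefits are annual relative risk reductions assumed
additive across classes, floored at a hazard multiplier of 0.1 because
additivity can go non-physical at extreme configurations. The RRR values
shipped by the generator are literature-plausible placeholders (synthetic),
with 95% CIs used by the Monte Carlo layer.

Coverage expands linearly from 15% to 45% over 10 years (80% in the
sensitivity preset). Coverage and adherence (40% [20–60] without history,
60% [40–80] with history) are person-level Bernoulli gates fixed at
assignment from the medication stream — re-drawing annually would overstate
turnover; a person is covered in year t iff their fixed uniform is below
coverage(t), making individual coverage monotone.

## Monte Carlo uncertainty

Each replicate draws intervention effects, medication RRRs and adherence
from normals defined by their 95% CIs (sd = width/3.92), truncated to [0,1];
optionally elasticities (±10% relative sd) and the census growth trend
(±0.3 percentage points sd) — spreads are package defaults since the source
tables carry no CIs for them. Per-unit relative risks carry no CI fields in
the schema and are not drawn. Each replicate re-samples the population, so
both parameter and sampling uncertainty propagate. Baseline and every
scenario share the replicate's streams (common random numbers); intervals
are 2.5/97.5 percentiles across replicates because averted-death
distributions are skewed. Failed replicates are recorded and excluded; more
than 1% failures aborts.

## Synthetic parameter generator

`SyntheticSpec` defaults define the study conditions: 750 million adults
20–79 (32% urban, 52% male, age weights 0.30/0.25/0.19/0.13/0.08/0.05),
census growth +1.3%/yr; SBP 118 mmHg + 3.5 per decade of age (+2 male,
+2 urban, sd 14); cholesterol 4.3 + 0.15 per decade (+0.25 urban, sd 0.9);
diabetes 2% × 1.5 per decade (×1.8 urban); CHD/cerebrovascular history
growing ×1.8 per decade from 0.4%/0.3%; tobacco tables with urban men
heaviest users, women mostly chewing/passive, passive exposure skewed
younger; MI mortality 0.0002→0.016 and stroke 0.00012→0.012 across bands
(×1.3 male, ×1.1 urban) so the 60–69 band carries the largest absolute CVD
death counts; secular trends SBP +0.3%/yr, cholesterol +0.2%/yr, diabetes
+3%/yr, MI/stroke mortality +1%/yr, other-cause −0.5%/yr (risk factors
drifting upward). A small per-(gender, location) multiplicative jitter
(2% relative) makes seeds differ while preserving every monotone gradient
exactly. Magnitudes are demographically plausible emulations chosen once;
they are not survey values, so absolute death counts are not comparable to
India's. What passing tests show is that the *mechanisms* (conservation,
dose-response, CRN, lag, combination algebra) behave correctly, not that the
synthetic population matches the real one.

## Problem sizes and numerical choices

Tests run at 300–10,000 individuals per cohort and up to 16 Monte Carlo
replicates; the acceptance script uses 30 replicates × 6,000 per cohort —
sizes chosen so the checked quantities' Monte Carlo error is small relative
to their tolerances while a full run stays in the minutes range on one CPU.
Tie-breaks and degenerate inputs: empty effect lists combine to 0;
zero-prevalence categories are never sampled; a u = 0 uniform maps to the
first tobacco category with positive mass; cohort extinction (no alive
simulants while the census is positive) raises an error naming the cohort
and year; quitter counts are rounded to the nearest integer against the
cumulative target, so trajectories are exact up to ±1 person per channel.

## Known limitations

Deaths only: no non-fatal events, case fatality or hospitalisation. No
product substitution (cigarette→bidi switching under asymmetric taxes). No
socioeconomic stratification, body-mass index, or migration between strata.
No longitudinal autocorrelation of risk factors beyond secular trends.
Whether the combined 1% smoke-free active effect overlaps the cessation
advice effect is unknown; they are treated as independent under the chosen
combination mode. The quit-lag anchor discrepancy above is unresolved by
construction.
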