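# Methods

## Model and estimands

The unit of analysis is a follow-up interval on the **age** timescale:
(entry age, exit age, event), with event one of censored, death from
natural causes, death from unnatural causes. Entry age encodes delayed
entry: a person diagnosed before a 3-year analysis window enters at their
age on 1 January of the window's index year (prevalent case); a person
first diagnosed inside the window enters at their age at diagnosis
(incident case). Exit is at death within the window or at the age on
31 December of the final year (administrative censoring). Deaths on the
window's closing date belong to the window. Ages are continuous,
(date − birth date)/365.25 days.

Survival S(t) is the product-limit estimator with left truncation; the
risk set at age t counts intervals with entry < t ≤ exit, tied deaths are
aggregated, and deaths precede censorings at the same age. Cause-specific
cumulative incidence CIFₖ(t) is the Aalen–Johansen estimator
Σ_{u ≤ t} S(u−) dₖ(u)/n(u). With only death as a decrement,
S + CIF_nat + CIF_unnat = 1 holds identically, so the decomposition of
life-years lost is conserved to floating precision at every level
(per-age, weighted, per bootstrap replicate); the suite asserts 1e-9.

For onset age a and horizon τ = 95 (few people survive beyond that age,
so LYL(a) reads as the reduction in remaining life expectancy),

    LYL(a)   = (τ − a) − ∫ₐ^τ S(t|a) dt,
    LYLₖ(a)  = ∫ₐ^τ CIFₖ(t|a) dt.

Conditioning on survival to a uses the ratio form of one overall fit,
S(t|a) = S(t)/S(a), CIFₖ(t|a) = (CIFₖ(t) − CIFₖ(a))/S(a). Under the
entry < t ≤ exit convention this is algebraically identical to refitting
the estimators from age a (the products and sums telescope), which a
property test verifies; the ratio form lets one O(n log n) fit serve all
77 onset ages. Integrals of step functions are computed exactly
(value × segment length), with no quadrature error.

Cohort-level LYL weights the per-age values by the empirical distribution
of age at first SMI diagnosis (integer ages 18–94, floor of continuous
age, clamped to the grid) over the **entire** cohort, not the period
subcohort. The same fixed weights are reused in every period and every
bootstrap replicate, so period-to-period movement isolates survival
change. Onset ages at which no one is at risk just after a
(n(a) = #{entry ≤ a < exit} = 0) or at which S(a) = 0 are inestimable;
their weight is dropped and the remainder renormalised, with a logged
count.

## Cohort derivation

SMI categories come from prefix matching of normalised codes (dots
stripped, upper-cased): ICD-10 F20/F25 → schizophrenia, F30–F31 →
bipolar, F32–F33 → depression; ICD-9 four-digit prefixes 2950–2953 and
2956–2959 → schizophrenia, 2960 and 2962–2966 → bipolar, 2961, 2980,
3004 and prefix 311 → depression. A person with several SMIs takes the
most severe (schizophrenia > bipolar > depression). Two diagnosis-date
rules are provided: the date of the first admission with any SMI code
(primary — severe conditions often present first as less severe ones) and
the date of the first admission carrying the most severe SMI
(sensitivity). Only the date differs between modes; category, sex and
vital-status fields are identical, and the depression stratum is
unaffected by construction.

Underlying causes of death are classified from ICD-10 ranges on the first
three characters (with the Y87.x sequelae handled at four characters):
suicide/self-harm/undetermined intent X60–X84, Y10–Y34, Y87.0, Y87.2;
accidents V01–X59, Y85–Y86; other external Y40–Y84, X85–Y09, Y87.1,
Y88–Y89; everything else — including a missing code — is natural. A
present but malformed code (no leading letter + two digits) raises rather
than silently classifying.

Cohort membership requires at least one qualifying admission at age ≥ 18
and being alive on the study start (1 January 2000 by default); deaths
before study start are excluded, deaths with no matching admission are an
error, death records for unknown persons are ignored with a warning.
Entry ages at or above 95 drop the person from the period; exits past 95
are truncated to 95 and forced to censored.

## Uncertainty

Percentile bootstrap over individuals (whole follow-up intervals) within
the stratum-period subcohort, default B = 500, 2.5/97.5 percentile
bounds. The onset distribution and the national life table are held fixed
across replicates: the weights are a cohort-level constant by design, and
national tables are population-level quantities without sampling error to
propagate. Both choices are the package's defaults rather than options
because varying them changes the estimand. Sub-seeds are spawned
deterministically per stratum and period from the run seed
(`numpy.random.SeedSequence`; PCG64 — identical streams on every
platform), so full trend tables are byte-reproducible.

## Life tables and excess LYL

Life tables are ingested as survivorship l_x (or death probability q_x,
converted by l_{x+1} = l_x(1 − q_x) from l_0 = 100 000) on consecutive
integer ages covering at least 18–95, validated for monotonicity.
Within-year interpolation assumes a piecewise-constant hazard
(l(x+f) = l_x · (l_{x+1}/l_x)^f, the standard demographic choice; linear
interpolation is available). The interpolated curve is discretised to a
left-endpoint step function at 64 steps/year so the population side flows
through the same exact step integrator as the disease side; the resulting
bias on an integral is below 1/(2·64) ≈ 0.008 years, comfortably inside
the 0.05-year tolerance the property tests allow. Excess LYL is
Σₐ wₐ(LYL_disease(a) − LYL_pop(a)); the population side is all-cause only,
so the natural/unnatural split is reported for the disease side alone.

## Synthetic registry generator

The generator draws, per person: sex and SMI from configured mixtures
(defaults 50/50 and 24.4% schizophrenia / 14.1% bipolar / 61.5%
depression, a realistic national-register mix), onset age from a
truncated log-normal on [18, 94] (default median 38, σ = 0.45) or an
empirical weight table, and a diagnosis calendar date uniform over
1981–2019 — so a year-2000 study start sees both prevalent and incident
cases. Birth dates are back-computed from onset age and diagnosis date.
Death ages come from inverse-transform sampling of piecewise-constant
competing hazards (natural/unnatural by age band), optionally scaled by
multiplicative calendar-period factors; the same factors can generate the
matching reference life table via q_x = 1 − exp(−∫ hazard). Admissions
before April 1996 carry ICD-9 codes and later ones ICD-10, exercising
both code lists; optional earlier less-severe admissions exercise the
severity hierarchy; optional never-qualifying persons exercise the
exclusion path; deaths before the study start are emitted and must be
filtered by the cohort builder. Not emulated: coding noise, readmission
dynamics, emigration/loss to follow-up, deprivation gradients — so
passing tests demonstrate estimator correctness under the stated model,
not robustness to real-registry messiness.

`analytic_lyl` integrates the same piecewise model in closed form
(per-piece exponential survival; cause split proportional to λₖ/λ),
giving the independent oracle for recovery tests, e.g.
LYL = (τ−a) − (1 − e^{−λ(τ−a)})/λ = 40.996 at λ = 0.05, a = 35.

## Problem sizes and numerical choices

Closed-form recovery and null-excess checks use n = 20 000 simulated
individuals (Monte-Carlo error ≈ 0.13 years on an LYL of ~41). The
bootstrap-coverage experiment uses 200 simulation repetitions of n = 500
individuals with B = 200 replicates each, judged against the binomial 95%
band around nominal 0.95 coverage. Trend scenarios use 10 000–15 000
individuals in a single stratum. Rolling-window trend diagnostics use
sign tests on differences at lag 3 (successive **non-overlapping**
windows): adjacent rolling windows share two of their three years, so
lag-1 differences are strongly dependent and a sign test on them would be
invalid. Degenerate inputs: an empty risk window raises; a window with
deaths but no later entrants carries the last value forward; zero-death
data yield LYL = 0; conditioning at an age where S = 0 raises a
degenerate-conditioning error.

## Known limitations

Only death and administrative censoring end follow-up (no emigration);
the estimators assume censoring independent of survival within stratum;
the excess comparison inherits whatever period/sex granularity the
supplied life tables have; calendar effects in the generator are step
functions at year boundaries, approximating a calendar year as 365.25
days when mapped onto each person's age axis.
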