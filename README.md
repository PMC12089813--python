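# lifeyears

Life Years Lost (LYL) estimation for psychiatric cohorts followed in
routinely collected hospital and death-registration data.

People with a severe mental illness (SMI — schizophrenia, bipolar disorder
or major depression, ascertained from psychiatric hospital discharge
diagnoses) die far earlier than the general population, mostly of natural
causes. Quantifying that gap, how it splits between natural and unnatural
(suicide/self-harm, accidents, other external) causes, and whether it is
closing over calendar time requires survival methodology that handles
variable age at onset, delayed entry of prevalent cases, and competing
causes of death. This package implements that pipeline for epidemiologists
working with registry-shaped inputs: ICD-9/ICD-10–coded admission records,
cause-coded death records, and national life tables.

## Method

For onset age *a* and horizon τ = 95, life-years lost is the gap between
the full span and the restricted mean residual lifetime,

    LYL(a) = (τ − a) − ∫ₐ^τ S(t | a) dt = Σₖ ∫ₐ^τ CIFₖ(t | a) dt,

where S is the Kaplan–Meier survival on the age timescale with left
truncation (individuals enter the risk set at their entry age) and CIFₖ
the Aalen–Johansen cumulative incidence of cause *k* ∈ {natural,
unnatural}. Because S + CIF_nat + CIF_unnat = 1 pointwise, the cause
decomposition of LYL is exact. Cohort-level LYL is the weighted average
Σₐ wₐ · LYL(a) over the empirical distribution wₐ of age at first SMI
diagnosis in the **entire** cohort; holding wₐ fixed across rolling 3-year
periods (and across bootstrap replicates) makes trends reflect survival
change only. Excess LYL subtracts, under the same weights, the LYL a
same-age, same-sex reference population would experience according to a
national life table. Confidence intervals are percentile bootstrap over
individuals (default 500 replicates).

A synthetic registry generator with piecewise-exponential competing-risks
hazards (and multiplicative calendar-period factors) provides ground truth
for every stage; its closed-form oracle `analytic_lyl` is what the test
suite checks the estimators against.

## Worked example

`examples/03_lyl_closed_form.py` simulates 20 000 lifetimes with constant
hazard λ = 0.05 from onset age 35 and recovers the closed form
(τ − a) − (1 − e^{−λ(τ−a)})/λ:

```
estimated LYL(35) = 41.032 years
closed form        = 40.996 years
difference         = +0.037 (Monte-Carlo noise)
```

A person diagnosed at 35 under this mortality loses about 41 of the 60
years remaining to the age-95 horizon. `examples/05_rolling_trend.py`
runs the full pipeline on a scenario whose natural-cause hazard declines
over calendar time while the unnatural hazard stays flat:

```
natural-cause LYL: 25.1 -> 18.3 years; unnatural: 7.4 -> 7.2 years
```

The other examples cover cohort derivation with the severity hierarchy
(`01`), survival/incidence curves from age 35 (`02`), and excess LYL
against a generated life table with a bootstrap CI (`04`).

A thin CLI wraps the same functions:

```bash
lifeyears simulate --config scenarios/default.yaml --out-dir data/
lifeyears build-cohort --admissions data/admissions.csv --deaths data/deaths.csv --out cohort.csv
lifeyears lyl --cohort cohort.csv --periods 2000:2017 --reps 500 --seed 42 --out lyl_trend.csv
lifeyears excess --cohort cohort.csv --lifetables lt.csv --periods 2000:2017 --reps 500 --seed 42 --out excess.csv
```

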