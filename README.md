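# nof1sim

Simulation-based comparison of **aggregated N-of-1 trials** with **parallel
RCT** and **crossover** designs.

N-of-1 trials randomize a single patient back and forth between a new
therapy and placebo over several cycles; aggregating many such trials pools
the within-patient contrasts across a cohort. This package answers the
design questions a trialist planning such a study faces: how much power does
the aggregated design buy at a given number of patients, how well is the
type-I error controlled, how badly do unmodeled carryover effects and
non-representative sampling distort the answer, and what can patient-level
random effects reveal about hidden sub-populations. It is written for
biostatisticians and methodologists who want these operating characteristics
by Monte Carlo under a transparent generative model.

## Model

Outcomes are generated from a random-intercept linear model

```
Y_ick = mu_i + tau * Z_ick + eps_ick
mu_i  ~ N(mu, sigma_mu^2)        patient random intercept
eps_ick ~ N(0, sigma_eps^2)      residual error
```

for patient `i`, cycle `c = 1..3` and period ("look") `k = 1, 2`, where
`Z_ick` indicates the new therapy and each cycle contains one treated and
one placebo period in randomized order. Four variance scenarios
`(sigma_mu, sigma_eps)` are built in: (0.1, 0.5), (0, 0.5), (0.5, 0.5),
(0.5, 1).

Each simulated cohort supplies all three designs, so comparisons share the
same outcome draws: the full cohort is the aggregated N-of-1 trial, cycle 1
alone is the crossover, and one randomly chosen cycle-1 period per patient
is the parallel RCT.

Analysis follows the deviance recipe: the random-intercept model is fitted
by full maximum likelihood with and without the treatment term (the fit
profiles the fixed effects and error variance analytically and optimizes
only the variance ratio `lambda = sigma_mu^2 / sigma_eps^2`), and the
deviance difference `D_0 - D_1` is referred to chi-squared(1) at
`alpha = 0.05`. The single-observation RCT is tested by OLS. Carryover adds
a fixed increment `gamma` to any period immediately following a treated
period, within the chronology of each design; selection bias draws each
patient from the target population with probability `p` and from a
sub-population with a different effect otherwise.

## Worked example

```
$ python examples/02_design_power_comparison.py
power to detect tau = 0.25 at n = 30 (scenario 1):
  nof1       89.8%  (MC se 0.015)
  crossover  48.0%  (MC se 0.025)
  rct        20.2%  (MC se 0.020)
```

Thirty patients, 400 simulated trials per design, identical outcome draws:
the aggregated N-of-1 design detects the moderate effect (`tau = 0.25`,
about half an error SD) in ~90% of trials, the crossover in about half, the
parallel RCT in a fifth. `examples/` contains one script per capability
(single-cohort fitting, power comparison, carryover inflation, selection
bias, random-effect separation), each printing a few numbers and what they
mean.

The same machinery is available from the shell:

```
nof1sim simulate --scenario 1 --n 30 --seed 7 --out cohort.csv
nof1sim fit cohort.csv --design nof1
nof1sim run --experiment power_vs_n --scenario 1 --reps 2000 --out results/
nof1sim plot results/results.csv --out power.png
```

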