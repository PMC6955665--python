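# Methods

## Generative model

One simulated cohort consists of `n` patients, each observed over `c = 3`
treatment cycles with two observation periods ("looks") per cycle — one
under the new therapy (`Z = 1`), one under placebo (`Z = 0`), in randomized
order. Outcomes follow

    Y_ick = mu_i + tau_i * Z_ick + eps_ick,
    mu_i ~ N(mu, sigma_mu^2),   eps_ick ~ N(0, sigma_eps^2),

with `tau_i = tau` for patients drawn from the target population
(probability `p_representative`) and `tau_i = tau_sub` for sub-population
patients. Draws are consumed in a fixed stream order (population labels,
intercepts, cycle orders, residuals), which is what makes common random
numbers across designs work (below).

Parameters, units and defaults (`SimulationModel`):

| parameter | meaning | default |
|---|---|---|
| `mu` | grand outcome mean | 0 (the intercept is always estimated, so rejection rates are invariant to it) |
| `tau` | treatment effect, outcome units | 0.25 — a moderate effect, half the residual SD in the moderate-error scenarios |
| `sigma_mu` | between-patient SD | scenario value |
| `sigma_eps` | residual SD | scenario value |
| `n_cycles` | cycles per patient | 3 |
| `looks_per_cycle` | periods per cycle | fixed at 2; the design is defined by one period per condition per cycle |
| `carryover` | additive carryover increment `gamma` | 0 |
| `p_representative` | target-population sampling probability | 1 |
| `tau_sub` | sub-population treatment effect | 0 |

The four built-in variance scenarios `(sigma_mu, sigma_eps)` = (0.1, 0.5),
(0, 0.5), (0.5, 0.5), (0.5, 1) span weak-to-strong patient heterogeneity
and moderate-to-large error.

Within-cycle condition order is re-randomized independently each cycle with
probability 1/2. Whether the order should instead be fixed per patient is a
genuinely open design choice; re-randomization is the default because the
alternating designs are meant to be free of sequence-allocation bias, and
`reorder_each_cycle=False` exposes the alternative. The two settings give
identical operating characteristics without carryover; with carryover they
differ (a fixed order makes between-cycle carryover systematically hit the
same condition).

## The three designs from shared draws

Every replicate simulates one full N-of-1 cohort and derives the other two
designs from it, never re-sampling outcomes: the crossover keeps both
cycle-1 periods per patient; the parallel RCT keeps exactly one cycle-1
period per patient, chosen uniformly, with outcome and treatment assignment
kept together. This is a common-random-numbers construction: design
comparisons at a given grid point are differences in analysis, not in data.

## Carryover

`apply_carryover` adds `gamma` to every period whose chronological
predecessor, **within the design's own period sequence**, was treated. In
the N-of-1 design this acts both within cycles (treated first period
inflates the following placebo period) and across cycle boundaries; in the
crossover it acts only when placebo follows treatment; the RCT has single
periods and is unaffected. Carryover does not compound: a period after two
consecutive treated periods still gains a single `gamma`. No washout
periods are modeled — the increment abstracts away cycle length entirely.
Under the null this biases the within-patient contrast by `-gamma/2` in
expectation, which is the mechanism behind the inflated type-I error the
carryover experiments measure.

## Estimation and testing

For N-of-1 and crossover data the working model is the random-intercept
LMM. Both the null (intercept-only) and alternative (intercept + treatment)
models are fitted by **full maximum likelihood, never REML** — the test
statistic is a deviance difference between models differing in fixed
effects, which is only meaningful under ML. The statistic
`max(D_0 - D_1, 0)` is referred to chi-squared with 1 df at `alpha = 0.05`
two-sided. No boundary correction (e.g. a 50:50 chi-squared mixture) is
applied: the tested parameter is a fixed effect, not a variance component.
When adjusting for carryover, the previous-period-treated indicator enters
**both** models as a fixed effect so the test keeps one degree of freedom;
because the carryover mechanism adds exactly `gamma` times that indicator
to the outcome, the covariate absorbs it algebraically and the adjusted
test's decisions are identical for any `gamma` on the same draws (the small
power cost of adjustment comes from estimating the extra coefficient, not
from the carryover itself).
The RCT is tested by OLS of outcome on intercept + treatment (Wald t,
`n - 2` df), computed in closed form for the two-group design.

### Profiled likelihood

Given the variance ratio `lambda = sigma_mu^2 / sigma_eps^2`, both the GLS
fixed effects and the ML error variance have closed forms, so the fit is a
bounded one-dimensional minimization of the profiled deviance over
`log lambda` with `lambda in [1e-10, 1e10]` and relative tolerance `1e-9`.
All per-candidate quantities reduce to sufficient statistics (`X'X`, `X'y`,
`y'y` and per-patient column sums), making one fit a few dozen
O(patients x p^2) evaluations — roughly a millisecond — which is what makes
the Monte-Carlo grids tractable on one CPU. After the bounded search the
`lambda = 1e-10` endpoint is taken instead whenever it is at least as good,
so homogeneous cohorts land exactly on the boundary (there the profiled
deviance equals the OLS deviance). Degenerate inputs with zero residual
variance are floored at `1e-24` rather than erroring. BLUPs are the
conditional means `E[b_i | y]`, i.e. the per-patient mean residual shrunk by
`lambda * m_i / (1 + lambda * m_i)` for `m_i` observations; they always
shrink toward zero relative to the raw mean residuals.

Replicates whose fit fails (rank deficiency, non-convergence, or an RCT
randomization that leaves an arm empty at small `n`) are excluded from the
rejection-rate denominator and counted in `n_excluded`; in practice
exclusions are essentially zero except for empty arms at `n = 10`.

## Monte-Carlo experiments

`run_oc` estimates a rejection rate over `B` replicates; the default is
`B = 5000`, and the validation suites use `B = 2000`, which resolves a rate
near 0.5 to about +/-0.011 (one MC standard error, `sqrt(p(1-p)/B)`). A
root seed spawns one child stream per replicate (and per grid point for
curves), so every cell is bit-reproducible and replicates are independent;
passing the same root seed to different designs reuses the same cohorts.
`min_n_for_power` walks the sample-size grid
(10, 20, 30, 40, 50, 100, 150, 200 by default) in order with the same
per-point seeds as `power_curve` and stops at the first qualifying point.

Selection-bias experiments fix the mixture by mode: `type1` sets
`(tau, tau_sub) = (0, 0.25)` so every rejection is a false conclusion about
the target population; `power` sets `(0.25, 0)`. The random-effect
comparison uses the `type1` mixture and reports, per replicate, the mean
BLUP of sub-population patients minus that of representative patients under
both N-of-1 and crossover analyses of the shared cohort; only sign and
ordering summaries of these differences are treated as conclusions, not the
density shape itself.

## What the generator does and does not emulate

It emulates the core structure of an aggregated N-of-1 study: within-patient
randomized crossings, patient heterogeneity as a random intercept, a fixed
additive carryover, and contaminated sampling. It does **not** model
autocorrelated or non-Gaussian errors, time trends, missing data, washout
periods of varying length, treatment-effect heterogeneity beyond the
two-point mixture, or adaptive stopping. Passing tests therefore show that
the analysis pipeline has the stated operating characteristics *under this
generative model*; they do not certify behavior under serial correlation or
informative missingness, the two deviations most likely in real N-of-1
data.

## Numerical choices

- Optimizer: scipy bounded Brent on `log lambda`, `xatol = 1e-9`; one extra
  endpoint evaluation decides boundary fits.
- LRT statistic clipped below at 0 (numerically tiny negative differences
  occur when both fits sit at the same boundary).
- Deviances serialized to 6 decimal places; BLUP sums are zero to machine
  precision for balanced designs.
- Ties in `min_n_for_power` cannot occur (grids are strictly increasing);
  equality with the target power counts as qualifying.
- `p_value = chi2.sf(statistic, 1)`, so a zero statistic gives p = 1.

## Known limitations

- The deviance test's chi-squared reference is asymptotic; with only two
  periods per patient (crossover) at small `n` it is mildly
  anti-conservative (empirical size up to ~0.07 at `n = 30`), which the
  calibration checks treat as expected behavior rather than a defect.
- The profiled fitter covers exactly one random intercept per patient —
  no crossed or nested random effects, no heteroscedastic residuals.
- Power estimates near a decision boundary (e.g. a grid point whose true
  power is ~0.79) can flip the minimum-n answer between adjacent grid
  values; the replicate counts above keep this probability small but not
  zero.
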