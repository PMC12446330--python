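# Methods

## The decision problem and model structure

`osteocea` implements an individual-level state-transition (Markov
microsimulation) model of postmenopausal osteoporosis in Chinese women,
comparing three strategies: a 6-month course of Xianling Gubao capsules, a
6-month course of Jintiange capsules, and no drug treatment. Women enter
fracture-free at 55, 60, 65 or 70 years with a femoral-neck bone mineral
density (BMD) drawn from their age band's Normal(mean, SD), truncated below
at zero. Annual cycles run to death (the horizon is bounded by `max_age`,
default 100, where the life table forces death). Health states are: no
fracture; acute and post-fracture states per site (hip, clinical vertebral,
other); bedridden (entered only from a hip fracture, absorbing except to
death); and dead. A second fracture event of any site marks the individual
as being in the "complex fracture" state (`complex_fracture_flag`); no one
returns to the fracture-free state.

Outcomes are lifetime discounted costs (2022 USD) and quality-adjusted
life-years (QALYs), both discounted at 3%/year with the end-of-cycle
convention `1/(1+r)^(t+1)`. Strategies are compared by the incremental
cost-effectiveness ratio (ICER) against no treatment, with a
willingness-to-pay threshold of $38,223/QALY (three times GDP per capita).

## Cycle mechanics

Within each annual cycle, in this fixed order:

1. **Death draw.** Annual probability `q(age)` from the life table,
   multiplied by the excess post-hip-fracture ratio when the individual is
   bedridden (lifelong) or within `excess_duration` (default 1 year) of a
   hip fracture, clamped to [0, 1]. Decedents accrue nothing in their death
   cycle — event costs are never paid by individuals who die first.
2. **Fracture draw** (skipped while bedridden). Per-site annual
   probabilities come from the incidence model (below), multiplied by the
   site's prior-fracture relative risk (1.97 hip / 1.91 vertebral / 1.91
   other) if any fracture has occurred, clamped last. At most one fracture
   event per cycle: the overall event probability is
   `1 − Π(1 − p_site)`; the site is drawn proportionally to the `p_site`.
3. **Bedridden draw.** A hip event leads to the bedridden state with
   probability 0.136.
4. **Accrual.** Costs: annual medical cost ($439.78) for every alive cycle
   (switchable to post-fracture-only); one-off fracture treatment cost in
   the event cycle ($7,379.82 / $1,361.12 / $1,758.30); annual bedridden
   care ($4,948.90) while bedridden (including the transition cycle); drug
   cost in cycle 0 as annual price × treatment time (i.e. half the annual
   price for the 6-month courses; switchable to full annual price).
   Utility: flat 0.192 while bedridden; otherwise the age-band baseline
   (0.88 / 0.869 / 0.827 / 0.808, the last band persisting beyond 74)
   multiplied per fractured site by the first-year multiplier in the event
   cycle and the later-years multiplier afterwards; multipliers for
   distinct sites stack multiplicatively (the source table presents them as
   multipliers but never shows a multi-site example — an assumption).

Treatment raises BMD by the full increment (0.05 g/cm² Xianling Gubao,
0.11 g/cm² Jintiange) at the start of cycle 0 — the 6-month course
completes within the first annual cycle — and the attained BMD persists for
life. An optional `annual_bmd_decline` setting (default 0) lets users model
untreated age-related BMD loss instead; lifetime persistence of the
treatment gain is the model's single strongest assumption and is the main
reason absolute (not incremental-arithmetic) outputs should be read as
scenario results.

## Fracture incidence and calibration

The per-site annual fracture rate follows the standard epidemiological
decomposition

    rate(age, bmd) = exp(b0 + b1·(age − 55)) · g^((bmd_ref − bmd)/bmd_sd),

converted to a probability by `1 − exp(−rate)` and clamped. `g ≥ 1` is the
risk ratio per SD of femoral-neck BMD below the reference.

The age coefficients `(b0, b1)` are calibrated by OLS on the log-rate scale
against age-specific incidence target points (the package's
`IncidenceCalibration` model/results pair reports coefficients, standard
errors and R² on the log scale). Because BMD enters log-linearly, the
population-average rate over a Normal BMD distribution has the closed form
`E[rate] = rate(ref) · exp(µ_W ln g + (σ_W ln g)²/2)`, so targets that
describe an average woman of the band are matched exactly and noise-free
targets recover the generator to machine precision (tested).

### Synthetic baseline scenario

The fitted incidence equations, the census life table and the excess
post-hip-fracture mortality ratios behind the original analysis are not
publicly printed, so the package generates structural stand-ins and treats
them as its baseline scenario (users substitute real data through the same
CSV formats):

* **Life table** — Gompertz form `q(a) = min(1, 0.004 · 2^((a−55)/8))`,
  terminal probability forced to 1 at age 100. Mortality doubling every
  ~8 years is the classic adult pattern; the resulting life expectancy at
  55 (~28 years) is in the range of contemporary Chinese women.
* **Excess post-hip-fracture mortality** — ratio 2.5 for one year after a
  hip event and lifelong while bedridden, the order of magnitude of
  published first-year relative mortality in elderly women.
* **Incidence targets** — exponential in age at the entry band's reference
  BMD: hip 5×10⁻⁴/y at 55 doubling every 9 years; vertebral 4.5×10⁻³/y
  doubling every 25 years; other 3×10⁻³/y doubling every 20 years. Levels
  were chosen so a no-treatment cohort entering at 55 accumulates lifetime
  fracture probabilities of the magnitude the published base case reports
  (~7% hip, ~21% vertebral).
* **BMD gradients** — `g` = 1.27 (hip), 1.42 (vertebral), 1.35 (other).
  These are the effective gradients implied by the published base-case
  outputs themselves: lifetime hip reductions of 8.20%/18.33% for BMD gains
  of 0.38/0.85 band-SD both give ≈1.27 per SD, and the vertebral reductions
  give ≈1.42. They are deliberately flatter than the classic
  cross-sectional meta-analytic hip gradient (~2.6/SD): the steep gradient
  describes between-women risk differences, while a treatment-effect
  pathway through BMD appears to act much more weakly in the source model,
  and adopting the cross-sectional value would roughly triple every
  treatment effect. The gradient is a per-site argument to the calibration
  for users with better information.

What the synthetic baseline does *not* emulate: the exact shape of the
original fitted incidence equations, regional/secular incidence variation,
non-fracture comorbidity, and any correlation between BMD and mortality.
Consequently the package's *simulated absolute* costs, QALYs and
acceptability probabilities are scenario outputs, not reproductions; the
published worked-example arithmetic (incrementals, ICERs, percent
reductions from the printed table) is reproduced exactly from the printed
inputs, and the engine itself is verified against independent oracles
(below).

## Uncertainty analysis

Every scalar input carries a deterministic sensitivity range and a
probabilistic distribution, which differ where the source table says so
(the bedridden probability has a printed range but is fixed in PSA).

* **Distributions.** Triangular(low, mode=base, high) for costs (±20%).
  Log-normal for relative risks: median = point estimate, (low, high)
  matched to the 95% CI on the log scale. Beta for utilities, multipliers
  and BMD increments by method of moments: mean = base, SD = (high −
  low)/(2·1.96), i.e. the printed range is a central 95% interval; BMD
  increments are rescaled to a [0, 0.3] g/cm² support. A beta fit whose
  variance exceeds m(1−m) raises an error instructing a range shrink.
* **One-way DSA** reruns both cohorts of the target comparison at each
  parameter's low and high bound with one shared uniform block (common
  random numbers), so a tornado bar reflects only the swept parameter;
  zero-width ranges reproduce the base ICER exactly.
* **PSA** redraws all non-fixed parameters each iteration (independent
  draws, manifest order under a seeded generator) and re-simulates every
  strategy. One inner uniform block is shared across strategies *and*
  iterations: within an iteration this pairs strategies, across iterations
  it freezes first-order noise so the (cost, QALY) cloud isolates parameter
  uncertainty. Draws violating a model invariant (first-year disutility
  multiplier above the later-years one, ~3%; relative risk below 1, ~1%)
  are skipped, logged and counted — the effective distributions are
  truncated to the invariant region. Default 1,000 iterations at an inner
  cohort of 10,000 (the Monte-Carlo SE is reported so users can trade
  precision for time; the acceptance script uses 200 × 2,000).
* **CEAC** probabilities are the fraction of iterations in which a strategy
  has the strictly maximal net monetary benefit λ·QALY − cost; exact ties
  split their weight equally, so curves partition to 1 at every λ. The
  default grid is $0–60,000/QALY in $500 steps.

ICER tables are computed against the no-treatment reference (the published
table's convention, verified arithmetically: 956.38/0.08 = 11,954.75 ≈
11,955); a sequential frontier view with standard and extended dominance is
also provided. The published "30.05%" vertebral reduction for Jintiange at
55–59 is inconsistent with the same table's probabilities (21.03% → 15.47%
gives 26.44%); the package reports computed values.

## Numerical and engineering choices

* **Two engines, one randomness contract.** All randomness is pre-drawn as
  one block (one BMD uniform per individual; four uniforms — death,
  fracture, site, bedridden — per individual-cycle, consumed positionally
  whether or not a draw is reached). A vectorized numpy engine is the
  production path; a per-individual reference engine records full
  trajectories. Both consume the block identically and are tested for exact
  agreement, which also guards the economics rules encoded in each. Sharing
  a block across strategies yields common random numbers: the same woman
  has the same baseline BMD and event uniforms under every strategy.
* **BMD sampling** uses the inverse-CDF of the zero-truncated normal so
  each individual consumes exactly one uniform.
* **Clamping, not renormalization,** when relative risks push a probability
  past 1; clamping is applied after all multiplications.
* **No half-cycle correction** (the source analysis mentions none); death
  before fracture within a cycle; discounting at end of cycle. These
  conventions are fixed and tested so results reproduce bit-for-bit.
* **Problem sizes.** Defaults follow the source analysis (100,000
  individuals; 1,000 PSA iterations). The test suite and acceptance script
  run scaled-down cohorts (300–50,000 individuals; 200 PSA iterations of
  2,000) — the package's own choice of desk-scale study sizes; Monte-Carlo
  standard errors accompany all simulated means so the precision of any
  run is explicit.

## Validation and verification

* ICER/reduction arithmetic reproduces the published 55–59 worked example
  exactly from printed inputs.
* The microsimulation mean cost and QALYs agree with an independent
  deterministic cohort-Markov (state-distribution) oracle within 3
  Monte-Carlo SE on a simplified model (history RRs 1, bedridden
  probability 0, degenerate BMD, hip only).
* Fracture-free cohort survival matches the closed-form life-table
  expectancy within 3 SE.
* Calibration recovers known generator coefficients from noise-free targets
  to machine precision and from 10%-noise targets within 3 fitted SE in
  ≥97/100 replicates.
* Simulated no-treatment incidence (events per person-year at risk, Wilson
  95% bands) brackets every calibration target when history effects are
  off; doubling all hazards flags every age — the misfit detector works.
* A state-machine fuzz (extreme hazards) finds no forbidden transition:
  dead is absorbing, bedridden never reverts, fracture history never
  clears.

## Known limitations

* The synthetic baseline is structural, not empirical: absolute simulated
  costs/QALYs and CEAC probabilities depend on it and should not be quoted
  as reproductions of the original analysis.
* Lifetime persistence of a 6-month treatment's BMD gain is optimistic;
  the `annual_bmd_decline` switch only partially addresses it.
* No sub-cycle event timing, no competing non-fracture morbidity, no
  adverse events, no societal costs (healthcare-provider perspective only).
* The bedridden state admits no further fractures and no recovery.
* PSA invariant-rejection truncates the tails of the hip disutility and
  relative-risk distributions (~4% of draws in total).
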