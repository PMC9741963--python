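# Methods

## Model structure

`markovcea` implements a deterministic three-state Markov cohort model for
cost-utility analysis of adjuvant osimertinib versus placebo after complete
resection of EGFR-mutated NSCLC. The states are disease-free survival (DFS),
progressed survival (PS) and Death (absorbing). The whole cohort starts in
DFS; each monthly cycle a DFS occupant may progress, die of background causes,
or remain, and a PS occupant may die or remain. The default horizon is 240
monthly cycles (20 years), after which any residual alive fraction is censored
with no terminal payoff — the model's working assumption is that a cohort
starting at age 60 is extinct by then. Setting
`force_all_dead_at_horizon=False` instead runs the cohort to extinction
(capped at ten times the horizon).

Transition probabilities come from survival analysis, not from a transition
matrix supplied directly:

- **DFS → PS**: the per-cycle interval transition probability
  `p_k = 1 − S(t_{k+1})/S(t_k)` of the strategy's DFS law — Weibull
  (λ = 0.000112076, γ = 2.162643) for osimertinib, Gompertz (λ = 0.0131044,
  γ = 0.425736) for placebo — multiplied by the probability of *not* dying of
  background causes that cycle. This multiplicative competing-risk layout
  keeps every row a probability vector even when the progression hazard
  drives `p_k` to 1; additive layouts cannot run the shipped placebo
  parameterization (see "Time units" below). Probabilities outside [0, 1]
  still raise a model-specification error; nothing is silently renormalized.
- **DFS → Death**: background mortality only, from an age-indexed life table
  converted to monthly probabilities via `1 − (1 − q)^{1/12}`, with age
  advancing along model time from the starting age (default 60). All
  disease-specific death is routed through PS, since DFS is by definition
  pre-progression.
- **PS → Death**: an exponential post-progression survival law calibrated so
  that `S(median) = 1/2` (default median 38.6 months — a configuration
  default standing in for trial OS data that is not publicly printed),
  blended with background mortality under independence:
  `1 − (1 − p_disease)(1 − p_background)`. Any parametric law may be
  substituted through the configuration.

## Parameterizations and time units

Weibull `S(t) = exp(−λt^γ)`, Gompertz `S(t) = exp(−(λ/γ)(e^{γt} − 1))`
(the common hazard-`λe^{γt}` convention; the γ → 0 limit is the exponential,
handled with `expm1` so tiny shapes are numerically exact), exponential
`S(t) = exp(−λt)`.

Published parameter tables for digitized-curve fits often omit the time
scale. The shipped placebo Gompertz pair implies a median DFS of 7.4 *units*:
under a monthly reading that is implausibly fast progression
(S(12 months) ≈ 0.006), while a quarterly reading implies ≈ 22 months, close
to the source trial's placebo arm. Rather than guessing, every law carries an
explicit `time_unit` field (month/quarter/year, default month) and
`select_time_unit` picks the unit whose implied median best matches a
user-supplied trial median. The shipped default remains the monthly reading;
its consequences for reproducing the published absolute results are discussed
under "Limitations".

## Economic accrual

Costs (2021 USD) and utilities are accrued per cycle on state occupancy,
costed at cycle start (no half-cycle correction by default, matching the
behaviour of the point-and-click tool this class of analysis is usually built
in; a flag enables start/end averaging):

- DFS: follow-up cost $60.3/cycle (both arms), plus drug cost $858.46/cycle
  on the treated arm for cycles 0–35 (the 3-year treatment cap).
- PS: supportive care $359/cycle. No post-progression drug cost by default
  (`drug_cost_in_ps` enables the alternative scenario of continuing the drug
  after progression).
- Severe adverse events (grade ≥ 3): a one-time expected-value adjustment at
  treatment start on the treated arm only — probability 0.23 × cost $362, and
  probability-weighted disutility −0.0731 applied for one cycle. The duration
  of the disutility is an assumption; one cycle is the conservative minimal
  reading.
- QALYs: occupancy-weighted utilities (DFS 0.82, PS 0.70) × 1/12 per monthly
  cycle.
- Discounting: both costs and outcomes at 5%/year, compounded per cycle as
  `(1.05)^(−k/12)`. Outcomes are discounted because the one-way sensitivity
  analysis explicitly varies an outcome discount rate.

Incremental results use ΔC = cost(intervention) − cost(comparator), likewise
ΔQ; ICER = ΔC/ΔQ when ΔQ ≠ 0. Dominance (cheaper and more effective, or
costlier and less effective) and equal-effectiveness are reported as tags,
never as signed ICERs. Decisions at a willingness-to-pay (WTP) threshold
(default $31,451.64/QALY, 3× 2020 Chinese GDP per capita) follow the strict
net-monetary-benefit rule `WTP·ΔQ − ΔC > 0`, which coincides with
`ICER < WTP` whenever ΔQ > 0.

## Sensitivity analysis

**One-way DSA**: each parameter is set to its low and high value in turn (all
else at base), the full model re-run twice, and parameters ordered by the
width of the ICER swing (tornado). Sorting is stable with ties broken by
parameter path; a range that makes the model invalid is flagged in place, not
dropped. In dominance quadrants the signed ratio ΔC/ΔQ is used for the span
computation only.

**PSA**: 1000 joint redraws of all uncertain parameters, both arms re-run per
draw. Distribution families follow standard practice — beta for utilities,
probabilities and the negated SAE disutility; gamma for costs; uniform
(0–8%/year) for the two discount rates — with the published (low, high)
ranges read as approximate 95% intervals, `sd = (high − low)/3.92`, and
hyperparameters moment-matched so the sampling mean equals the base value.
Failed iterations are recorded with their draw and the run continues. The
CEAC reports, at each WTP on a grid covering [0, 3×GDP], the fraction of
draws with strictly higher intervention NMB; ties count as not
cost-effective.

## Synthetic data

The generators stand in for inputs the pipeline would otherwise need from
external sources:

- `gen_km_points` emulates digitizer output: exact evaluations of a known
  law, optional additive Gaussian read-off noise on the survival scale,
  clipped to (0, 1] and re-monotonized by a running minimum. Noiseless output
  satisfies the generating law exactly, so fit-recovery tests have a ground
  truth.
- `gen_life_table` is a synthetic geometric-growth mortality schedule
  `q(age) = base·(1+g)^(age−start)` (defaults 0.008 and 8%/year from age 60),
  chosen so a 60-year-old's 20-year all-cause survival is ≈ 66% —
  demographically plausible, but not any real census table.
- `base_case()` assembles the full published parameterization.

What passing tests on synthetic inputs do **not** show: agreement with real
digitized trial curves (which carry correlated, step-shaped digitization
error rather than i.i.d. jitter), real census mortality, or real
post-progression survival.

## Numerical choices

- Weibull curve fitting uses the closed-form linearization (regress
  `log(−log S)` on `log t`), weighted by `(S ln S)²` — the delta-method
  inverse variance of the transform under survival-scale noise — so points
  near S = 1, where the transform amplifies noise enormously, do not dominate.
  Gompertz and exponential fits use bounded nonlinear least squares on the
  survival scale (`scipy.optimize.least_squares`), initialized from a
  closed-form exponential rate. Points with S ≥ 1 or S ≤ 0 are dropped before
  fitting; time ties keep the lower survival value; fewer than 3 usable
  points is an error.
- Interval transition probabilities are clamped to [0, 1]; a survival
  function that has already reached zero at cycle start yields probability 1
  (cohort exhausted), logged once.
- Occupancy conservation (1e−12) and Death-monotonicity are asserted on every
  cohort run.
- Cycle-probability arrays depend only on the survival side of the
  specification and are memoized, so the PSA re-runs the economic
  accumulation rather than the survival algebra; results are identical to
  recomputation.
- PSA draws use one `numpy` Generator seeded once, with columns drawn in
  ranges order, making runs bit-reproducible for a given (seed, n, order).

## Limitations

- The published absolute per-arm totals (8.45/6.99 QALYs, $39,962.99 /
  $25,864.48) are not reproducible from printed inputs alone: the
  post-progression mortality source, the Gompertz time scale and the PSA
  distributions are not stated. Under the shipped defaults the base case
  gives an ICER of ≈ $10,800/QALY against the published $9,661.97 — the same
  decision at any plausible threshold, but not the same number. The
  structural property suite (trace vs matrix-power oracle, chained-interval
  telescoping, discount geometric sums, NMB/ICER equivalence, fit recovery)
  substitutes for exact reproduction.
- Downstream of that gap, the CEAC under the shipped defaults reaches 100%
  at ≈ $18,000–22,000/QALY rather than at the published $15,000, with every
  PSA draw in the more-effective-and-costlier quadrant; and the tornado ranks
  the drug cost first with the outcome discount rate a close second, rather
  than the outcome discount rate first. Both are sensitive to the time-unit
  decision above.
- Single cohort, single starting age; no tunnel states, no individual-level
  simulation, no stage subgroups, no currency conversion (costs are used as
  printed 2021 USD).
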