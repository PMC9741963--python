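# markovcea

Markov cohort cost-utility analysis of adjuvant osimertinib versus placebo in
completely resected EGFR-mutated non-small-cell lung cancer, built as a
reusable, tested Python pipeline for three-state state-transition models.

It is aimed at health-economics and outcomes-research analysts who want the
whole chain — parametric survival extrapolation, cohort simulation, discounted
cost/QALY accrual, ICER arithmetic, and deterministic/probabilistic
sensitivity analysis — as inspectable library code rather than a spreadsheet
or point-and-click decision tree.

## The model

Three health states: disease-free survival (DFS), progressed survival (PS),
and Death. All patients start in DFS at age 60 and are followed in monthly
cycles over a 20-year horizon. Transitions are driven by survival functions:

- DFS → PS: per-cycle interval probability `p_k = 1 − S(t_{k+1})/S(t_k)` from
  the arm's fitted DFS law — Weibull `S(t) = exp(−λt^γ)` with
  λ = 0.000112076, γ = 2.162643 for osimertinib; Gompertz
  `S(t) = exp(−(λ/γ)(e^{γt} − 1))` with λ = 0.0131044, γ = 0.425736 for
  placebo — net of background mortality;
- DFS → Death: age-indexed background (all-cause) mortality from a life
  table;
- PS → Death: an exponential post-progression law (default median 38.6
  months) blended with background mortality assuming independent competing
  risks.

Costs (drug $858.46/cycle capped at 3 years, follow-up $60.3, supportive care
$359, one-time expected SAE cost 0.23 × $362) and utilities (DFS 0.82,
PS 0.70, SAE disutility −0.0731 for one cycle) accrue on state occupancy and
are discounted at 5%/year. The headline statistic is the incremental
cost-effectiveness ratio ICER = ΔCost/ΔQALY, judged against a
willingness-to-pay threshold of $31,451.64/QALY (3× 2020 Chinese GDP per
capita) via net monetary benefit NMB = WTP·QALY − cost. Probabilistic
sensitivity analysis (1000 Monte-Carlo redraws; beta for utilities and
probabilities, gamma for costs, uniform for discount rates) yields the
cost-effectiveness acceptability curve (CEAC). See `docs/methods.md` for the
full account, including the explicit treatment of the undocumented time scale
of the placebo survival parameters.

## Worked example

```python
from markovcea import compute_icer, run_cohort
from markovcea.synthetic import base_case

spec, econ, ranges = base_case()
osi = run_cohort(spec, econ, "osimertinib")
plc = run_cohort(spec, econ, "placebo")
res = compute_icer(osi.total_cost, osi.total_qaly, plc.total_cost, plc.total_qaly)
print(f"osimertinib: ${osi.total_cost:,.2f}, {osi.total_qaly:.2f} QALYs")
print(f"placebo:     ${plc.total_cost:,.2f}, {plc.total_qaly:.2f} QALYs")
print(f"ICER: ${res.icer:,.2f}/QALY -> {res.decision}")
```

prints

```
osimertinib: $41,192.07, 5.34 QALYs
placebo:     $15,654.79, 2.98 QALYs
ICER: $10,823.15/QALY -> cost_effective
```

Osimertinib costs $25,537 more but yields 2.36 more quality-adjusted life
years per patient, so each extra QALY costs about $10.8k — well below the
$31.5k/QALY threshold, hence `cost_effective`. (The absolute totals differ
from the published analysis because several of its inputs — post-progression
mortality, the placebo-curve time scale — are not printed; `docs/methods.md`
discusses the gap. The decision is unchanged.)

The same analyses are available from the shell:

```sh
markovcea run --out results            # traces + results.json
markovcea dsa --out results            # tornado.csv
markovcea psa --out results --seed 7 --n 1000   # psa_samples.csv, ceac.csv
markovcea fit-km --points km.csv --family weibull --out fit.json
```

All subcommands accept `--config cfg.yaml` to override any model, economics
or sensitivity parameter; the effective configuration is echoed next to the
results. `--plots` adds CE-plane, CEAC and tornado figures.

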