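# tmscea — cost-utility modelling of TMS therapies for treatment-resistant depression

`tmscea` implements a health-economic evaluation of two transcranial
magnetic stimulation therapies — repetitive TMS (rTMS) and intermittent
theta-burst stimulation (iTBS), each delivered as an adjunct to
treatment-as-usual (TAU) — against TAU alone for adults with moderate to
severe treatment-resistant depression in UK specialist mental health
services. It is written for health economists and methodologists who
want a fully tested, reproducible implementation of the whole pipeline:
transition estimation from interval-censored trial panels, expert
elicitation pooling, cohort simulation, probabilistic sensitivity
analysis and operational ("service delivery") sensitivity analysis.

## The model

A Markov cohort model tracks the distribution of a cohort over five
states — Remission, Mild, Moderate and Severe depression (HDRS-17 bands
0–7 / 8–13 / 14–22 / 23+) plus absorbing Death — in 2-week cycles over
an 18-month horizon (39 cycles), with a half-cycle correction and 3.5%
p.a. discounting of costs and outcomes. Outputs per arm are discounted
costs *C* and quality-adjusted life-years *Q*; alternatives are compared
by the incremental cost-effectiveness ratio

ICER = ΔC / ΔQ  (£ per QALY gained),

appraised against the NICE £20 000–£30 000/QALY range, with dominance
and extended dominance handled in the fully incremental comparison.
Decision uncertainty is summarised by cost-effectiveness acceptability
curves: at each willingness-to-pay λ, the probability that an arm
maximises net monetary benefit λ·Q − C across 5000 Monte Carlo
parameter draws.

Arm-specific transition structure:

* **TMS arms** — a continuous-time Markov chain over the four alive
  states fitted to interval-censored panel data (states observed at
  0/8/16/26 weeks) by maximising the matrix-exponential likelihood
  ∏ [exp(QΔt)]. The 2-week cycle matrix is exp(2Q).
* **TAU** — transitions observed at biannual assessments, assumed
  uniform within each interval: the cycle matrix is the regularised
  principal 13th matrix root of the 6-month matrix.
* **Maintenance** — beyond 26 weeks no further gain over TAU is
  assumed; the TMS cohort's alive composition is blended toward TAU's by
  a Weibull retained-effect curve w(t) = exp(−(((t−26)/λ_w))^k) fitted
  to expert-elicited retained fractions at 12 and 18 months (linear
  opinion pool of per-expert piecewise-linear CDFs).

Economic inputs: per-course intervention costs (annuitised equipment
capital ÷ annual machine throughput + session staff time + training
+ MRI targeting for iTBS), health-state costs from a GEE panel
regression, utilities from an OLS panel regression of cross-walked
EQ-5D-3L scores, human-capital productivity costs and informal-care
hours from state-stratified means. The societal perspective adds
productivity costs; informal care is reported in hours.

No participant-level data are deposited, so the package ships a
synthetic-data module that generates trial-like panels from a known
ground-truth process at the source studies' sizes (TMS arms n=127/128,
specialist-care arms n=94/93); every estimator is validated by recovery
against that truth. The packaged parameter table is a calibrated
placeholder standing in for the study's unpublished supplementary
values.

## Worked example

```python
from tmscea.bundle import make_base_case_bundle
from tmscea.psa import run_psa, incremental_analysis

bundle = make_base_case_bundle()
result = run_psa(bundle.spec, n_sims=5000, seed=1)
m = result.means()
print(incremental_analysis(
    {a: (m.loc[a, "cost"], m.loc[a, "qalys"]) for a in result.arms}
))
```

With seed 1 this prints (health-service perspective, GBP and QALYs per
person over 18 months):

```
      block  arm comparator      cost  qalys   d_cost  d_qalys       icer               status
   pairwise rtms        tau 6510.2580 0.9741 576.0230   0.0482 11950.4304                 icer
   pairwise itbs        tau 6620.9855 0.9854 686.7505   0.0595 11535.2994                 icer
incremental  tau       None 5934.2350 0.9259      NaN      NaN        NaN          on_frontier
incremental rtms        tau 6510.2580 0.9741      NaN      NaN        NaN extendedly_dominated
incremental itbs        tau 6620.9855 0.9854 686.7505   0.0595 11535.2994          on_frontier
```

Read: TAU costs £5934 and yields 0.9259 QALYs per person; rTMS adds
£576 for 0.048 extra QALYs (pairwise ICER ≈ £11 950/QALY) and iTBS £687
for 0.060 (≈ £11 535/QALY) — both well inside the NICE range. In the
fully incremental comparison iTBS's ICER is here slightly below rTMS's,
so rTMS is flagged extendedly dominated and the frontier runs from TAU
straight to iTBS. The same
result object gives informal-care reductions of ~30 h (rTMS) and ~37 h
(iTBS) versus TAU, and under the societal perspective
(`tmscea.psa.societal_totals`) both therapies become cost-saving.

The numbered scripts under `analysis/` run the full narrative —
simulate trials, fit transitions, estimate economic inputs, pool the
elicitation, base case, scenarios, operational sensitivity — writing
tables under `results/`.

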