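# Methods

This note documents the model, its parameterisation, the synthetic-data
design and the numerical choices made where the design was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Cohort model

The engine (`tmscea.engine`) propagates a closed cohort over five
states — Remission, Mild, Moderate, Severe (HDRS-17 bands 0–7, 8–13,
14–22, 23+) and absorbing Death — through a per-cycle schedule of 5×5
row-stochastic matrices. Settings and defaults:

| parameter | default | rationale |
|---|---|---|
| cycle length | 2 weeks | short enough to resolve early TMS response |
| horizon | 39 cycles (≈18 months) | duration over which experts judged benefits plausible; 26 cycles/year convention |
| discount rate | 3.5 % p.a. | UK health-technology-assessment convention, applied to costs and QALYs |
| half-cycle correction | on | trapezoidal variant: each cycle's reward weight is the mean of start- and end-of-cycle occupancy |
| discount timing | cycle midpoint, exponent (c+0.5)/26 on (1+r)⁻¹ | consistent with mid-cycle rewards |

Mortality is a uniform per-cycle probability in every alive state:
the annual general-population probability *q* is converted to a rate
−ln(1−q), multiplied by the all-cause relative risk of severe unipolar
depression, divided by 26 and converted back. Defaults (flat life table
q = 0.0025 at cohort age 45, RR = 1.58) are placeholders; the published
life table and RR are in unpublished supplementary material. Mortality
is applied before severity transitions within a cycle (competing-risk
rate scaling); the cohort is not re-aged over the 18-month horizon.
QALYs accumulate as utility × 2/52 per cycle; utilities are admitted
down to the EQ-5D-3L floor (−0.594) without truncation of totals.

The engine is validated against an independent individual-level
microsimulation (200 000 paths per schedule) and by property tests
(probability conservation, Dead-column monotonicity, half-cycle bounds,
discounting order).

## Transition estimation

**TMS arms.** "Multistate model" is operationalised as a
time-homogeneous continuous-time Markov chain on the four alive states
over the 0–26-week window, estimated from interval-censored panels by
maximising Σ n(Δt, i, j) · log [exp(QΔt)]₍ᵢⱼ₎. All 12 off-diagonal
intensities are free by default (a tridiagonal adjacent-severity
restriction is available as a flag). Optimisation runs on
log-intensities (positivity by construction) with L-BFGS-B, three
jittered starts (seeded), relative tolerance 1e-8, bounds
e⁻²⁰–e³ per week. A row with no observed exits is driven to ~0 rates
by the likelihood itself. A time-homogeneous chain was chosen over a
piecewise (0–8/8–16/16–26) variant because three observation gaps
cannot identify three separate generators without strong pooling; the
homogeneous fit recovers the generating 2-week matrix with element-wise
bias < 0.02 at n = 500.

**TAU.** Transitions are observed at 26-week intervals and assumed
uniform within the interval: the per-cycle matrix is exp(logm(P₆)/13)
with any negative off-diagonal intensities zeroed and absorbed into the
diagonal (the standard regularisation for non-embeddable matrices); the
reconstruction error ‖P_c¹³ − P₆‖_max is recorded. Raw interval counts
are retained as Dirichlet effective counts for the probabilistic
analysis.

**Maintenance beyond 26 weeks.** The arm's alive composition is blended
toward TAU's contemporaneous composition:
comp(t) = w(t)·comp_TMS(26wk) + (1−w(t))·comp_TAU(t), renormalised,
with w(t) = exp(−(((t−26)/λ_w))^k), w(26) = 1. Anchoring the blend on
*composition* (not intensities) matches the assumption that the effect,
not the mechanism, converges to TAU. In the schedule this is encoded by
setting every alive row of the cycle matrix to the target composition;
for a cohort model only occupancy matters, so this is exact. The
(k, λ_w) point estimate is the two-point closed-form solution through
the pooled medians of the elicited retained fractions at 12 and 18
months.

## Expert elicitation

Each expert's judgment (quartiles within stated plausible bounds) is
reconstructed as a monotone piecewise-linear CDF through (low, 0), the
quantile pairs, and (high, 1) — the least-assumption reconstruction —
and experts are combined by an equal-weight linear opinion pool. The
packaged panel is synthetic: 7 experts on operational quantities, 5 on
time-to-improvement with TAU, 4 on maintenance, matching the reported
participation, with quantiles encoding the reported consensus (a
drop-off between 6 and 12 months, gradual decline to 18 months). In the
probabilistic analysis, maintenance is sampled expert-consistently: one
expert and one quantile level are drawn and applied to both the 12- and
18-month fractions, so every draw is a coherent, monotone judgment pair
with marginals equal to the pools.

## Economic inputs

Per-course intervention cost = annuitised equipment capital ÷ annual
throughput + sessions × (minutes/60) × staff rate + training
+ imaging (iTBS only). Annuitisation uses the standard annuity factor
at 3.5 % over a 10-year machine lifetime. The base-case operational
profile (27 × 30-minute sessions, 43 patients/year/machine) follows the
elicited averages; the component unit costs are placeholders back-solved
so the per-course totals equal the published £1184 (rTMS) and £1440
(iTBS).

Health-state costs: GEE regression of per-cycle-scaled period costs on
state membership with age, sex, period (factor) and site (factor)
adjustment, exchangeable working correlation, robust SEs; with an
independence working correlation the coefficients equal pooled least
squares (asserted in tests). Utilities: OLS with the same adjustment
plus baseline utility (and ethnicity when present). Adjusted state
means are predictions at the mean covariate profile. Period values are
converted to per-cycle rates by proportional scaling before regression.
Productivity: human-capital approach — state-stratified mean workdays
lost over the 0–16-week window (16–26 weeks in a scenario) × gross
daily earnings (£120, placeholder) × employed fraction (0.55, reflecting
the lower full-time employment reported in the specialist-care trial).
Informal care: the analogous hours quantity, uncosted.

## Probabilistic analysis

5000 Monte Carlo draws per analysis. Families follow health-economics
convention: Dirichlet per transition-matrix row (effective counts sized
by each trial's expected state exposures), gamma for cost-like state
means (method of moments on mean/SE), beta for utilities, lognormal
(σ_log = 0.10) for the mortality RR, and the elicitation pools for
maintenance. All arms share each draw's common parameters (common
random numbers), reflecting the identical baseline population; the CRN
design demonstrably reduces incremental variance. Draws with
non-finite outcomes would be excluded and counted (none occur in the
packaged base case). With every input at point mass the PSA reproduces
the deterministic run exactly. Because the model is nonlinear in its
inputs (matrix roots, 13-fold compounding, the Weibull blend),
probabilistic means differ from the deterministic run; headline results
are therefore reported as probabilistic means, and the packaged
parameter table was calibrated at that level.

CEACs use the three-way net-monetary-benefit comparison on a
£0–£100 000 grid in £1000 steps (ties split equally); the pairwise
probability versus TAU is also available. The fully incremental
comparison sorts by cost (ties broken by higher effect), removes
dominated then extendedly dominated options, and reports frontier
ICERs; the frontier equals brute-force NMB maximisation over a dense λ
grid (oracle test).

## Scenarios and operational sensitivity

Ten named scenarios override exactly one aspect of the base case:
maintenance best case (w ≡ 1), worst case (w ≈ 0 beyond 26 weeks),
single most-optimistic/most-pessimistic expert, no mortality,
alternative trial sources for utilities and costs (re-estimated from
the simulated trials), the enhanced-care (SDS) TAU trajectory,
trial-observed delivery costs (20 × 60-minute sessions), and the
16–26-week productivity/care window.

The operational sensitivity analysis varies throughput, sessions per
course and minutes per session over the elicited plausible ranges
(packaged defaults 5–60 patients/year, 20–30 sessions, 15–60 minutes).
Efficacy is held fixed, so cells differ only through the per-course
cost; every cell reuses the base run's draws with the per-cell course
cost added — numerically identical to rerunning the PSA with common
seeds, and it makes the ICER and probability surfaces exactly monotone
in cost. The reported throughput threshold is the linear interpolation
of the ICER-vs-TAU curve across £30 000/QALY.

## Synthetic data and what the tests show

The generator simulates continuous-time severity paths (Gillespie) for
the TMS designs and direct interval draws for the specialist-care
designs, at the source trials' sizes (127/128 and 94/93), baseline
restricted to Moderate/Severe. Period economic totals accumulate
per-cycle noise (gamma costs and care hours with cv 0.9 and 1.0 per
cycle, so a 13-cycle period total has cv/√13; truncated-normal
utilities, sd 0.10; Poisson workdays), matching the PSA's families so
recovery tests and the PSA are coherent.

The packaged parameter table (`make_base_case_bundle`) is built directly
from this ground truth with trial-scale uncertainty hyperparameters; it
stands in for the study's unpublished supplementary parameter table and
is flagged as a placeholder throughout. Ground-truth values were
calibrated once, at probabilistic-mean level, to the published
incremental anchors, and frozen. The estimation pipeline
(`estimate_inputs`) — simulate, fit, pool — is exercised separately by
recovery tests and the estimation-source scenarios; at the real trials'
sizes its sampling noise on the increments is substantial (±30 % on
ΔC), which is precisely the parameter uncertainty the PSA propagates.

What passing tests do *not* show about real data: the generator has no
dropout or missingness, no measurement error on HDRS (states are
observed exactly), no covariate effects on transitions, and independent
periods given states; real trial estimates would carry additional bias
and variance from all four.

## Known limitations

* Unit costs, the life table, the mortality RR, elicited quantiles and
  the SDS transition matrix are placeholders for unpublished values;
  quantities that depend on their levels (scenario magnitudes, CEAC
  probabilities at delivery extremes) are indicative only.
* Time-homogeneous TMS intensities over 0–26 weeks; a piecewise chain
  is not identified from three observation gaps without pooling.
* One mortality RR irrespective of severity state, per the model's
  stated structure.
* The interval matrix root is regularised, not exact, for
  non-embeddable sampled matrices; the reconstruction error is recorded
  per draw and is < 0.01 for diagonally dominant matrices.
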