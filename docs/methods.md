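# Methods

This note documents the modelling choices behind `mhspc_cea` the way one
would document any decision-analytic model: the state-transition structure
and its assumptions, the estimation steps, the numerical conventions, what
the synthetic-data generator does and does not emulate, and the places where
the design was genuinely open and a choice had to be made.

## State-transition model

Three states: progression-free (PF, on first-line therapy), progression
(castration-resistant prostate cancer, CRPC) and death (absorbing).  The
whole cohort starts PF.  Defaults: start age 60 years, cycle length 1 month,
horizon 480 cycles (age 100, with the life table's closing row absorbing
older ages), annual discount rate 3%, willingness-to-pay US$100,000/QALY.
The cohort weight (70 kg) is carried for documentation only; drug costs are
per-month config inputs, never derived from dose internally, because no
body-surface-area assumption is published and inventing one would be false
precision.

Within-cycle ordering is death-first: PF patients die of background
mortality with `p_bg(age) = 1 − (1 − q_annual)^(1/12)`, survivors progress
with the schedule probability `p_prog(t)`.  In CRPC, background mortality
and the disease-specific monthly death probability combine multiplicatively
as independent competing risks, `1 − (1 − p_bg)(1 − p_crpc)`, which keeps
both probabilities interpretable and the total ≤ 1 by construction.  The
ordering is a stated convention; at monthly cycles its effect is
second-order.  No half-cycle correction is applied by default — occupancy is
valued at cycle starts — but `ModelConfig(half_cycle_correction=True)`
averages start/end occupancy for valuation, documenting the choice rather
than hiding it.

## Survival estimation from digitized curves

Published PFS curves enter as digitized (time, survival) points.  Because a
proper likelihood (and hence AIC) needs patient-level data, the package
reconstructs pseudo individual-patient data first:

* events are allocated from the survival drops with cumulative rounding, so
  the empirical survivor function tracks the digitized curve within
  1/(2·target_n) at every digitized time;
* event times are placed at the midpoint of the digitized interval in which
  the drop occurred.  Midpoint placement removes most of the discretisation
  bias in fitted location parameters (interval-end placement biases medians
  upward by about half a grid step) while leaving the Kaplan-Meier match at
  digitized times intact, since all events of an interval have happened by
  its right endpoint;
* without reported numbers at risk, censoring is assumed to occur only at
  maximum follow-up; with numbers at risk, censoring is spread uniformly
  (deterministically) within inter-anchor intervals and event counts chosen
  so the running product-limit estimate tracks the curve, in the spirit of
  the Guyot reconstruction.  Censor times are snapped to the right endpoint
  of their subinterval so the recomputed estimator sees exactly the risk
  sets the allocation assumed.  Note that with interior censoring the
  product-limit increments are `km/n_risk`, so once the at-risk count decays
  the reconstruction cannot match the curve more finely than that — an
  intrinsic granularity of integer patient counts, not an implementation
  limit.

Default `target_n` is 1000, making reconstruction error ≤ 0.001 survival
units in the censoring-free case.

Exponential, Weibull and log-normal families are then fitted by
right-censored maximum likelihood: the exponential rate in closed form
(λ = events / total follow-up), the two-parameter families by Nelder-Mead
over log-parametrised coordinates (log-likelihood tolerance 1e-8) started
from exponential/empirical moments.  Model choice is by AIC
(`2k − 2·loglik`), ties broken by fewer parameters then the fixed order
exponential, Weibull, log-normal.  A caveat worth knowing: when the true law
is exponential, the nesting Weibull fit wins the AIC contest in roughly 16%
of large samples (2·Δloglik is asymptotically χ²₁ and the AIC penalty is 2),
so near-exponential data can legitimately select Weibull; the two-parameter
families are mutually identifiable and selected essentially always at large
n.  Since both families converge to the same fitted curve in that regime,
the downstream schedule is barely affected.

The fitted survival converts to per-cycle progression probabilities with the
interval-conditional formula `p(t) = [S(tc) − S((t+1)c)] / S(tc)` (and
`p = 1` where `S = 0`), which is exact for any S — no constant-hazard
approximation — so `∏(1 − p)` reproduces S at cycle boundaries to machine
precision.  Time convention throughout: cycle `t` covers months
`[tc, (t+1)c)`, survival evaluated at cycle starts.

## Calibration of the CRPC→death probability

One time-independent monthly probability, shared across strategies, is
estimated by minimising the sum of squared differences between model OS
(fraction alive at cycle starts) and the target OS curve at the target's
digitized times.  The objective is scanned on a 1e-3-step grid over [0, 1]
(the cohort recursion is vectorised across the grid, so this is cheap) and
the best cell refined by bounded scalar minimisation to 1e-6; the grid scan
guards against the refinement landing in a local dip.  If the optimum sits
at 0 or 1 a `CalibrationBoundaryWarning` is issued and the boundary value
returned.  Sensitivity analyses that redo calibration per draw use a
1e-2 grid (the basin is smooth; recovered values agree to ~1e-4).

The choice of objective (SSE at digitized times, calibrated against the
referent strategy's OS curve) is a documented design decision — the
calibration target and fit statistic were genuinely open.  Squared error at
the digitized times is conventional, transparent and reproducible; the
target strategy is configurable.

## Costs and utilities

Per cycle: PF occupancy pays ADT plus drug and administration cost while
the drug is given — a fixed number of cycles for docetaxel-type regimens,
until progression otherwise; CRPC occupancy pays a monthly cost composed of
baseline CRPC care plus the subsequent-line proportion times the
second-line therapy mix (the mix prices cabazitaxel separately because its
share differs by first-line arm); new entrants to death pay a one-time
terminal-care cost, which avoids paying death costs every cycle.  Grade ≥3
adverse events enter as expected one-time amounts, `Σ rate × cost` and
`Σ rate × disutility`, at treatment start; for fixed-duration regimens they
are spread evenly over the treated cycles.  Utilities: the on-treatment
utility applies while the drug is given (so a docetaxel-type strategy
reverts to the metastatic-on-ADT utility after its six cycles), the
progression utility in CRPC.  Docetaxel's "six cycles" are modelled as six
model (monthly) cycles; all published costs are already converted to
one-month cycles, and the treated-window semantics of the economics
contracts are defined in model cycles.  Inflation adjustment of input costs
is data preparation, done by the parameter-file author (a helper multiplies
by a supplied index ratio); the engine never consults a price index.

Incremental analysis sorts strategies by discounted total cost, removes
strongly dominated entries (no cheaper-or-equal alternative with at least
as many QALYs and one strict inequality), then iteratively removes extended
dominance until frontier ICERs strictly increase.  Each non-referent row
reports incremental cost/QALYs against the previous non-dominated strategy;
only frontier rows carry an ICER.  Identical (cost, QALY) pairs are kept
and flagged, their mutual ICER undefined.

## Sensitivity analyses

*One-way:* each parameter moved to low/high with the rest at base, the
pairwise ICER of a configurable comparison recorded, entries sorted by
swing.  "±20% variance" is read as a ±20% range around base — the most
common convention in CEA practice — used directly as the one-way endpoints.

*Two-way threshold:* with median PFS held at a chosen value, bisection on
monthly drug cost until the pairwise ICER equals WTP, bracket narrowed
below $1; monotonicity of the ICER over the bracket is verified numerically
first, and a no-crossing bracket returns an explicit no-threshold result.

*PSA:* independent draws per iteration — beta for utilities/probabilities,
gamma for costs, log-normal for median PFS (standard domain-respecting
conventions; the families are per-parameter configurable).  Distributions
are moment-matched: mean equals base, and [low, high] maps to a central 95%
interval via `sd = (high − low)/3.92` (for log-normal, σ from the log-range
and μ set so the arithmetic mean equals base).  Efficacy draws rebuild the
transition schedule — by rescaling the selected fit's time scale to the
drawn median, shape preserved, so a draw at the base median exactly
reproduces the base case — and recalibrate when the calibration strategy is
touched; draws are bit-reproducible given the seed.  The CEAC reports, per
WTP value, the fraction of iterations in which each strategy has the
strictly highest net monetary benefit (`wtp·QALYs − cost`), exact ties
shared equally.

## Synthetic data: what it does and does not emulate

The generator produces the complete input set: log-normal PFS truths per
strategy (σ = 0.8; medians 14, 17, 41.7, 55, 48 months for the ADT,
docetaxel, abiraterone, enzalutamide and apalutamide arms — the abiraterone
median and the drug prices $1,440, $7,400, ~$12,000 cabazitaxel anchor the
regime to printed magnitudes), digitization on a monthly grid to 60 months
with truncated Gaussian noise (sd 0.005 by default) forced monotone, a
Gompertz-like life table (`q = 0.011 · 1.09^(age−60)`, closed at 100), a
true CRPC→death probability of 0.028/month (≈ 2.5-year median CRPC
survival), and full cost/utility/adverse-event parameter sets with
subsequent-line proportions of 0.80 (ADT, docetaxel) and 0.65 (the rest)
and cabazitaxel shares of 14% vs 5%.

The OS calibration target is generated by the *forward model itself* (true
schedule, true death probability), which makes calibration exactly
identifiable — deliberately, so recovery failures indicate implementation
errors rather than target misspecification.  Consequences to keep in mind
when interpreting green tests: real published OS curves are *not* generated
by the model (the fit compromise visible in real calibrations is absent
here), digitization error in practice is not Gaussian or independent across
points, trial-arm sampling noise and patient-level heterogeneity are not
emulated, and the synthetic cost regime — while realistic in magnitude —
is not the study's actual (unavailable) parameter table.  Passing tests
demonstrate that the machinery recovers known truths under its stated
assumptions, not that the published numbers are reproduced; the published
incremental arithmetic is checked separately from the printed totals.

In the default synthetic regime the apalutamide-like arm ends up
*extended*-dominated (its earlier progression shortens time on an expensive
drug, lowering lifetime cost below enzalutamide's), whereas the published
base case reports strong dominance; the strong-dominance logic is exercised
against the printed totals and in randomized oracle tests.

## Numerical conventions and degenerate inputs

Occupancy conservation is enforced at 1e-12 per cycle.  Curves must be
non-increasing within 1e-12 and are validated on ingestion with row-numbered
errors.  Zero-event pseudo-data refuse to fit (there is no likelihood);
schedules shorter than the horizon, ages outside the life table, negative
costs and out-of-range utilities all raise named errors.  Monetary values
are carried in full double precision and rendered to two decimals only at
the I/O boundary.  All randomness flows through `numpy.random.default_rng`
with explicit seeds; synthetic curves derive per-curve seeds from
(scenario seed, strategy index, endpoint) so curves are independent but
reproducible.

## Problem sizes used in the shipped checks

Reconstruction and fitting checks use target_n = 1000–2000 pseudo-patients;
AIC family-selection consistency uses 100 replicates of n = 5000; parameter
recovery uses n = 2000 with 20% censoring; calibration recovery uses the
full 480-cycle horizon against 60-month targets; the dominance oracle runs
200 random strategy sets; PSA summaries use 1,000 Monte Carlo iterations.
These sizes make every check a few seconds to a few tens of seconds on one
CPU while keeping Monte Carlo error well inside the asserted tolerances.

## Known limitations

No microsimulation or tunnel states (history beyond the three states is
ignored); a single shared CRPC→death probability across strategies; no
strategy-specific post-progression survival; no disease-volume or risk
stratification; no radiotherapy comparator; no EVPI or correlated PSA
draws; societal costs out of scope.  These mirror the boundaries of the
modelled decision problem rather than engineering shortcuts.
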