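# mhspc-cea

A Markov cohort cost-effectiveness model for first-line therapy of
metastatic hormone-sensitive prostate cancer (mHSPC), written for health
economists and methodologists who want a tested, scriptable implementation
of the full decision-model pipeline: survival-curve fitting, overall-survival
calibration, lifetime cohort simulation, incremental cost-effectiveness
analysis, and deterministic + probabilistic sensitivity analyses.

## The model

Five strategies are compared from the US payer perspective: androgen
deprivation therapy (ADT) alone, and ADT combined with docetaxel,
abiraterone, enzalutamide or apalutamide.  A cohort of 60-year-old men moves
through three states — progression-free (PF), progression
(castration-resistant disease, CRPC) and death — in monthly cycles over a
lifetime horizon (480 cycles), with costs and quality-adjusted life-years
(QALYs) discounted at 3%/year.

The pieces, in the order the pipeline runs them:

1. **Survival fitting.** Published progression-free survival (PFS) curves
   arrive as digitized points.  Pseudo individual-patient data are
   reconstructed so their Kaplan-Meier estimate reproduces the digitized
   curve, then exponential, Weibull and log-normal models are fitted by
   right-censored maximum likelihood and the family with the lowest AIC is
   selected.  The fitted S(t) becomes the per-cycle progression probability
   `p(t) = [S(t) − S(t+1)] / S(t)`.
2. **Calibration.** A single time-independent monthly CRPC→death
   probability, shared by all strategies, is chosen so model-predicted
   overall survival matches a published OS curve in least squares (grid scan
   plus bounded refinement to 1e-6).  Background all-cause mortality comes
   from a life table via `1 − (1 − q_annual)^(1/12)`.
3. **Economics.** PF occupancy pays ADT plus drug/administration cost while
   the drug is given (six cycles for docetaxel, until progression
   otherwise); the CRPC state pays a monthly cost that folds in the
   subsequent-line therapy mix; new deaths pay a one-time terminal-care
   cost; grade ≥3 adverse events enter as expected one-time costs and QALY
   decrements.  Strategies are then sorted by cost, dominated ones removed
   (strong and extended dominance) and incremental cost-effectiveness
   ratios (ICERs, Δcost/ΔQALY) computed along the frontier.
4. **Sensitivity.** One-way tornado analysis on the ICER of a chosen pair,
   two-way drug-price threshold search (bisection until the ICER equals the
   willingness-to-pay, default US$100,000/QALY), and probabilistic
   sensitivity analysis (beta/gamma/log-normal parameter draws, default
   1,000 Monte Carlo iterations) summarised as cost-effectiveness
   acceptability curves (CEACs).

Because published unit-cost, utility and adverse-event tables are rarely
available in machine-readable form, the package ships a first-class
synthetic-data generator (`mhspc_cea.synthetic`) that produces a complete,
internally consistent study — digitized curves from known parametric truths,
a Gompertz-like life table, and full parameter sets anchored to printed
magnitudes — so every stage is testable against known ground truth.

## Worked example

```python
from mhspc_cea import MarkovCEModel, default_scenario

model = MarkovCEModel.from_scenario(default_scenario(seed=1))
results = model.fit()
print(results.summary())
```

prints

```
Markov cohort cost-effectiveness model (mHSPC first-line therapy)
====================================================================
Cohort: start age 60, 480 cycles of 1 month(s), discount 3.0%/year, WTP $100,000/QALY
Calibrated p(CRPC->death) = 0.02805 per cycle (target: ADT OS)

Survival fits (AIC-selected):
  ADT        lognormal   median PFS   14.0 mo   (mu=2.637, sigma=0.797; AIC 7,390.7)
  DCX+ADT    lognormal   median PFS   17.0 mo   (mu=2.832, sigma=0.79; AIC 7,627.0)
  AA+ADT     lognormal   median PFS   41.8 mo   (mu=3.733, sigma=0.8038; AIC 6,633.6)
  ENZ+ADT    weibull     median PFS   55.2 mo   (shape=1.785, scale=67.78; AIC 5,756.6)
  APA+ADT    weibull     median PFS   49.3 mo   (shape=1.672, scale=61.39; AIC 6,258.2)

Cost-effectiveness table (cost-ordered):
strategy  total_cost  total_qalys  total_lys  incremental_cost  incremental_qalys         icer             status
     ADT  164,026.38         2.76       4.01                 —                  —            —           referent
 DCX+ADT  169,309.81         2.94       4.26          5,283.43               0.18            — extended-dominated
  AA+ADT  191,308.81         4.63       6.18         27,282.43               1.87    14,567.82        on-frontier
 APA+ADT  491,756.72         4.65       6.20        300,447.92               0.02            — extended-dominated
 ENZ+ADT  512,559.36         4.92       6.51        321,250.55               0.29 1,121,019.38        on-frontier

Highest net monetary benefit at WTP $100,000/QALY: AA+ADT
```

Reading it: the generator's abiraterone-like arm (true median PFS 41.7
months, drug cost $1,440/month) is fitted at 41.8 months; the CRPC→death
probability calibrated against the ADT overall-survival target recovers the
generating value 0.028 to 5e-5.  In this synthetic regime abiraterone + ADT
sits on the frontier at an ICER of ≈$14.6k/QALY against ADT and is the
preferred strategy at the $100,000/QALY threshold, while enzalutamide's
extra 0.29 QALYs cost over $1.1M each.  Sensitivity analyses hang off the
same object:

```python
from mhspc_cea import default_sensitivity_params

params = default_sensitivity_params(results)            # ±20% ranges
tornado = results.tornado(params, ("AA+ADT", "DCX+ADT"))
psa     = results.psa(params, n_iter=1000, seed=1)
ceac    = results.ceac(psa)
thr     = results.threshold("strategies.AA+ADT.drug_cost_pf_monthly",
                            ("AA+ADT", "DCX+ADT"))
```

The same pipeline is scriptable from the shell:

```bash
mhspc-cea synth --seed 11 --out-dir study     # write a synthetic study
mhspc-cea run   --in-dir study --out-dir out  # fit/calibrate/simulate/rank
mhspc-cea psa   --in-dir study --n-iter 1000 --seed 7
```

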