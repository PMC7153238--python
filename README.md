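# lawbend

Piecewise change-point trend models for injury surveillance rates around
staggered policy dates.

## The problem

Between 2009 and 2014 every US state (and DC) passed a youth
traumatic-brain-injury law regulating when a concussed high-school athlete
may return to play (RTP) and who must receive concussion education.  Did
concussion *rates* — events per athlete-exposure (AE), one athlete in one
practice or competition — bend around those laws, and does the bend depend
on the law's language (whether it names the clearing healthcare provider,
whether it restricts clearance to physicians, whether it requires education
for both coaches and parents)?

Because passage dates are staggered, calendar time is replaced by a
**standardized month (STDM)**: the whole-month offset of an event from its
state's passage month (0 = passage month, negative = before).  `lawbend`
implements the full analysis chain for this design:

1. **ingest** — surveillance and law CSVs, exclusion filters with full
   bookkeeping, law-language grouping, the 14-model analysis plan
   (overall + three dichotomies, each for incident and recurrent events);
2. **temporal alignment** — exposure weeks 1–52 summed into thirteen
   four-week blocks per academic year, blocks mapped onto the STDM axis,
   state × STDM analysis cells;
3. **model** — a piecewise log-linear negative-binomial (NB2) mixed model
   with log-AE offset and a state random intercept integrated out by
   adaptive Gauss–Hermite quadrature:

       y_sm | b_s ~ NB2(mu_sm, alpha),   Var = mu + alpha mu^2
       log mu_sm = log AE_sm + beta0 + b_s + beta1 m
                   + gamma1 (m - tau1)+ + gamma2 (m - tau2)+
       b_s ~ N(0, sigma_b^2)

   so the log-rate trend is continuous with slope `beta1` before `tau1`,
   `beta1+gamma1` between the change points and `beta1+gamma1+gamma2`
   after `tau2`;
4. **profile-likelihood scan** — the change points `(tau1, tau2)` are
   estimated by refitting the model at every ordered pair on a six-month
   grid (all other parameters re-maximized each time) and keeping the pair
   with the largest log likelihood;
5. **inference** — slopes reported as percent change per STDM,
   `100(exp(gamma)-1)`, with Wald CIs; between-group slope differences via
   the large-sample two-sample z statistic; an optional cluster bootstrap
   (states resampled with replacement) with skewness diagnostics that flag
   unreliable bootstrap distributions;
6. **synthetic data** — the real surveillance data is restricted-access,
   so a first-class generator simulates the whole world (raw event and
   exposure-week records included) from known parameters, and a recovery
   harness measures bias, RMSE, CI coverage and change-point hit rates.

## Worked example

The numbered scripts under `analysis/` run the whole chain on the
synthetic world (24→40 states, true change points at −12 and +12 months,
−4%/month bend at `tau1`, +3%/month rebound at `tau2`):

```bash
python analysis/01_simulate_data.py
python analysis/02_ingest_and_align.py
python analysis/03_scan_change_points.py
python analysis/04_fit_model_plan.py
python analysis/05_bootstrap_diagnostics.py
python analysis/06_recovery_study.py
```

Step 02 prints the exclusion bookkeeping and conservation check:

```
events read: 7500; kept 7097, excluded 403 (5.4%)
  missing_date: 154
  ...
events conserved into cells: 7067 == 7067
```

(7097 kept records minus 30 whose dates fall outside the emitted exposure
weeks of the boundary academic years.)  Step 03 scans the 21 candidate
knot pairs and recovers the truth for the well-powered incident stream:

```
incident: best (tau1, tau2) = (-12, 12), loglik = -4801.82
recurrent: best (tau1, tau2) = (0, 6), loglik = -1322.86
```

The recurrent stream is ~9% of events, so its scan lands off-truth — a
deliberate illustration that change-point placement is data-limited.
Step 06 quantifies recovery over 40 replicates (the acceptance suite runs
200):

```
parameter   truth    bias    rmse  coverage_95  within_2se
    beta1  0.0200  0.0003  0.0078       0.9250      0.9250
   gamma1 -0.0400  0.0000  0.0091       0.9250      0.9250
   gamma2  0.0300 -0.0003  0.0084       0.9750      0.9750
  tau1 within one grid step of -12: 100% of replicates
  tau2 within one grid step of 12: 88% of replicates
```

All reported intervals are Wald intervals **unadjusted for knot
selection**: the change points are themselves chosen by maximizing the
likelihood, so these intervals are narrower than honest post-selection
intervals would be.  Every table and serialized fit carries that caveat.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline end to end from a fresh seeded simulation — raw
records through CSV round-trip, exclusions, four-week aggregation, the
profile-likelihood scan and the final percent-scale inference — printing
the selected change points and slope changes, and writes the JSON summary
to `--out`.

## Layout

```
src/lawbend/        library: config, simulate, ingest, alignment, model,
                    scan, inference, recovery
analysis/           numbered narrative drivers writing under results/
tests/              pytest suite; test_acceptance.py holds the heavy
                    statistical validation (recovery, coverage, type-I)
docs/methods.md     modelling assumptions, numerical choices, limitations
```
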