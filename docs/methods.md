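# Methods

## Model

For state `s` and standardized month `m` (months since the state's
law-passage month), the event count `y_sm` with athlete-exposure
denominator `AE_sm` follows

    y_sm | b_s ~ NB2(mu_sm, alpha)
    log mu_sm = log AE_sm + beta0 + b_s + beta1 m
                + gamma1 (m - tau1)+ + gamma2 (m - tau2)+
    b_s ~ Normal(0, sigma_b^2)

* **NB2 parameterization.** Variance `mu + alpha mu^2`, `alpha >= 0`;
  `alpha = 0` degenerates to Poisson.  The generator and the fitter share
  this parameterization so recovery experiments are exact by
  construction.
* **Truncated-line knots.** `(x)+ = max(x, 0)`; the trend is continuous
  with slope breaks only.  `tau1 < tau2` strictly — coincident knots
  would make `gamma1` and `gamma2` unidentifiable.
* **Random intercept.** One per state, capturing stable differences in
  baseline reporting/rate levels.  No random slopes, no serial residual
  structure, no zero-inflation.

## Estimation

* **Marginal likelihood.** The intercept is integrated out per state by
  *adaptive* Gauss–Hermite quadrature: Newton's method finds the mode of
  the integrand (strictly concave in `b`), the curvature sets the scale,
  and a 15-node Hermite rule is applied on the recentred axis.  On
  realistic fixtures 15 vs 30 nodes changes the log likelihood by far
  less than 1e-4; `quadrature_nodes` is configurable.  With
  `sigma_b < 1e-6` the code switches to the exact fixed-effects sum.
* **Optimization.** All six parameters `(beta0, beta1, gamma1, gamma2,
  log alpha, log sigma_b)` are maximized jointly by L-BFGS-B with an
  analytic gradient (the posterior-weighted score, using the same
  quadrature nodes as the objective).  Starting values: Poisson
  fixed-effects GLM for the slopes, method-of-moments for `alpha`.
  A Nelder–Mead polish (off during grid scans for speed) tightens the
  optimum so refits from perturbed starts agree to ~1e-6 in log
  likelihood.  Non-convergence after the configured restarts is returned
  as `converged=False`, never a silent estimate.
* **Covariance.** Central-difference Hessian of the negative log
  likelihood over all six parameters; the fixed-effects block of its
  inverse (so slope SEs reflect dispersion and variance-component
  estimation), eigenvalue-clipped to be positive semidefinite.  Wald
  intervals only — the original analysis reports symmetric intervals and
  profile intervals for slopes would not change the knot-selection
  caveat below.
* **Determinism.** Cells are canonically sorted and per-state likelihood
  contributions are summed in value order, so the log likelihood is
  bit-identical under row permutations and state relabelling.

## Change-point search

The profile likelihood over `(tau1, tau2)` is evaluated by exhaustive
refit on a six-month grid anchored at STDM 0 (the full −96..+108
surveillance range gives 35 points and C(35,2) = 595 pairs).  Dispersion
and the random-intercept SD are re-estimated at every pair — a full
profile, not a plug-in.  Pairs leaving no data strictly on one side of a
knot are recorded as ineligible rather than fitted.  The winner is the
largest converged log likelihood; ties (within 1e-9) break to the
smallest `(tau1, tau2)`.  Scan fits reuse the nearest converged
solution as a warm start; the winner is refit at full precision.

In the bundled analyses and recovery studies the candidate grid is
restricted to (−18, +18) within a ±24-month observation window so every
candidate segment contains at least six months of data; edge knots are
otherwise weakly identified.

## Inference

* **Percent scale.** A log slope `g` is reported as `100(exp(g) - 1)` %
  per standardized month (for |g| ≤ 0.02 this is within a few percent of
  `100 g`, so the choice is immaterial at realistic effect sizes).  CIs
  are transformed endpoint-wise, hence correctly asymmetric for large
  slopes.
* **Group comparisons.** `(g_a - g_b)/sqrt(se_a^2 + se_b^2)` referred to
  the standard normal — a two-sample t with effectively infinite degrees
  of freedom, appropriate because the inputs are ML coefficients, not
  sample means with a natural df.  The difference is reported as
  `100(exp(g_a - g_b) - 1)` relative to the declared reference group.
  Incident-vs-recurrent comparisons treat the two fits as independent;
  they share AE denominators but not events, so this is an approximation
  (slightly conservative if the estimates are positively correlated).
* **Knot-selection caveat.** Because the knots maximize the likelihood,
  Wald intervals at the selected knots are anti-conservative.  Every
  output object and table carries the label *unadjusted for
  knot-selection*; no adjustment is attempted.
* **Cluster bootstrap.** States resampled with replacement (resampled
  copies get distinct labels), refit at fixed knots; reports bootstrap
  SEs, 2.5/97.5 percentile intervals and bias-corrected sample skewness.
  |skewness| > 1 (default) flags a coefficient's distribution as
  unreliable — the documented failure mode when a few dominant clusters
  drive the fit.  A parametric mode (counts re-simulated from the fitted
  model, intercepts redrawn) is provided as the better-behaved
  alternative.  Non-convergent replicates are counted and excluded,
  never silently dropped.

## Synthetic data

The generator *is* the model plus the surrounding bookkeeping:

* per state, a passage date drawn from the observed 2009–2014
  distribution (2:8:27:7:6:1 across 51 jurisdictions) and law-language
  labels drawn from the observed shares (27/51 specify the RTP provider;
  7/27 of those physicians-only; 40/51 both-party education);
* a log-normal AE denominator per state-month (defaults
  `ae_log_mean=10`, `ae_log_sd=0.5`, median ≈ 22k AE/state-month — a
  plausible statewide high-school figure chosen once, not tuned);
* NB2 counts around the continuous piecewise trend, split
  incident:recurrent at 0.091;
* the raw-record generator emits weekly exposure streams (week 1 =
  first Monday-starting week of August, configurable) and event-level
  records dated inside the contributing exposure weeks, with per-field
  missingness injected independently and ground-truth flags retained so
  filter tests have an exact oracle.

What it does **not** emulate: sport/sex/school structure, seasonality
within the academic year, reporting drift, media-coverage covariates, or
correlation between law language and baseline rates.  A green recovery
test therefore establishes internal statistical correctness of the
pipeline, not robustness to those real-world features.

Default effect sizes in the bundled studies (`beta1=0.02`,
`gamma1=-0.04`, `gamma2=0.03` per month, knots at ±12) were chosen to
make recovery experiments informative — clear bends, realistic noise —
not to mimic any published estimate; the restricted real data would be
required for that.

## Numerical and data-handling choices

* **STDM** is a pure calendar-month difference (day-of-month ignored);
  antisymmetric and invariant to whole-month shifts.
* **Four-week blocks → months.** Exposure weeks 1–52 sum into 13 blocks
  per academic year; a block is assigned the STDM of the calendar month
  containing its central day (day 14 of the 28-day span).  The true
  week-to-month correspondence is irrecoverable after 4-week
  aggregation; this deterministic rule is documented configuration, as
  is the week-1 anchor.
* **Exclusions.** A record is removed once no matter how many rules it
  trips; every applicable reason is tallied, so reason counts may sum to
  more than the number excluded.  Kept + excluded = input always, and
  filtering is idempotent.
* **Zero-exposure cells.** Dropped (log-offset undefined) with a logged
  count when they carry no events; a zero-AE cell *with* events is a
  hard error.
* **Degenerate knots** (no data strictly on both sides) make a fit
  ineligible during scans and flagged, not an exception.

## Known limitations

* Wald inference at scan-selected knots overstates precision (see
  caveat); only the bootstrap diagnostics speak to this, and the
  nonparametric bootstrap itself is unreliable under dominant clusters.
* The grid search is O(pairs × fit); no continuous knot optimization and
  no more than two knots.
* The two-group comparison ignores cross-fit correlation for shared-
  denominator comparisons.
* With few states (< ~5) in a stratum the variance components are
  weakly identified; fits are returned but their SEs should be read
  skeptically.
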