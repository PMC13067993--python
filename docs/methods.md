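# Methods

`arselect` is a Monte-Carlo laboratory for a single question: when a
univariate psychological time series may be nonstationary, how reliably do
the standard model-selection criteria identify the process that generated
it?  The package simulates series from nine AR(1)-based processes, fits all
nine as candidate models to every simulated series, scores the candidates
with in-sample information criteria and out-of-sample prediction criteria,
and summarizes how often (and how highly) each criterion ranks the true
process.

## The model family

All nine processes are built on the lag-1 recursion

    y_t = intercept(t) + phi(t) * y_{t-1} + eps_t,    t = 2..T,

with unit-variance normal innovations unless stated otherwise:

| model            | structure                                                      |
|------------------|----------------------------------------------------------------|
| `white_noise`    | phi = 0, intercept 0 (i.i.d. draws)                            |
| `ar1`            | constant intercept alpha and phi, \|phi\| < 1                  |
| `random_walk`    | phi = 1, no intercept (unit root)                              |
| `ar1_trend`      | intercept alpha + beta*t (linear deterministic trend)          |
| `tvar_intercept` | intercept alpha + A*sin(2*pi*t/T), constant phi                |
| `tvar_phi`       | constant alpha, phi(t) = phi + A*sin(2*pi*t/T)                 |
| `setar`          | two (alpha, phi) regimes switching on y_{t-1} <= tau           |
| `hmm`            | two white-noise regimes with different means                   |
| `rs_ar1`         | two AR(1) regimes                                              |

The sinusoid completes exactly one period over the observed window, so the
time-varying conditions are genuinely nonstationary at every sample size.
The regime conditions switch *deterministically* at fixed time points
(T/2, or T/4, T/2, 3T/4), starting in regime 1; a switch scheduled at
fraction f takes effect from t = ceil(f*T).  Stochastic (Markov-driven)
switching is deliberately not generated — the candidate fitters assume it,
which is part of what the study probes — and the generators inject no
missing data.

Initial values: stationary processes start at intercept(1)/(1 - phi(1))
plus one innovation; the random walk and the regime models start from a
single innovation.  No burn-in is used, so a requested length T is exact.
This convention is a documented choice; its main visible effect is a
one-observation transient in the regime conditions.

The skew-normal innovation family (location 0, scale 2, slant 40) emulates
the strongly right-skewed distributions typical of negative-affect
measurements.  Its mean, omega*delta*sqrt(2/pi) with
delta = slant/sqrt(1+slant^2), is about 1.595, so skewed conditions are
shifted as well as asymmetric — both features stress the Gaussian
likelihood that the information criteria rely on.

## Estimation

Every candidate is fitted by regressing the *predictable* observations
(t = 2..T, i.e. those with an observed lag) on their predictors, and every
candidate reports a Gaussian conditional log-likelihood over that same set
of T-1 points, conditioning on y_1.  This keeps the nine likelihoods
comparable: no candidate is credited or charged for the first observation.

* **OLS candidates.** White noise (mean + variance, p = 2), AR(1)
  (p = 3), random walk (variance of first differences about zero, p = 1 —
  no drift term), AR(1)+trend (regression on {1, t, y_{t-1}}, raw integer
  time, p = 4).  Residual variances are maximum-likelihood (SSE/n).
* **Time-varying AR(1).** Penalized cubic B-spline regression over scaled
  time t/T: 10 basis functions, the integrated-squared-second-derivative
  (O'Sullivan) curvature penalty, and the penalty weight chosen by
  generalized cross-validation over a log-spaced grid *plus the exact
  infinite-penalty limit*, with near-tied GCV scores resolved toward the
  stiffer fit.  The penalty's null space is exactly the affine functions
  of time, so a fully collapsed `tvar_intercept` fit coincides — bit for
  bit, because the limit is computed from the same design matrix — with
  the AR(1)+trend OLS fit, and a collapsed `tvar_phi` fit is a linear-in-
  time AR coefficient.  This exactness matters: information criteria
  compare the two models at equal fit, and a collapse that differed by
  numerical dust would decide those comparisons arbitrarily.  The
  parameter count is the effective degrees of freedom (trace of the hat
  matrix, minimum 3) plus one for the variance, so p is non-integer in
  general and never below 4.
* **SETAR(2,1,1).** Exhaustive search of the threshold over observed lag
  values between their 15th and 85th percentiles, requiring at least 5
  rows per regime; per-regime OLS with per-regime variances; the threshold
  minimizing total SSE wins, ties going to the smallest threshold.  A
  regime with constant lag values (slope unidentified) is projected on its
  mean.  Following the convention common for threshold models, the
  threshold is *not* counted as a free parameter: p = 6.  If no admissible
  threshold exists the fit falls back to AR(1) and is flagged
  non-converged.
* **HMM and RS-AR(1).** A shared 2-state EM engine (numba-accelerated
  forward-backward recursion) fits state-specific regressions — a constant
  mean for the HMM, {1, y_{t-1}} for the switching AR — with state
  variances and a 2x2 transition matrix.  10 restarts (one deterministic,
  nine randomized), at most 500 iterations, relative log-likelihood
  tolerance 1e-6, variance floor 1e-6.  The initial state distribution is
  fixed at (1/2, 1/2) rather than tied to the stationary distribution of
  the transition matrix: a coupled initial distribution breaks the EM
  ascent guarantee (observed decreases of several nats between
  iterations), while a fixed one keeps every iteration monotone and costs
  at most a bounded first-observation term.  States are canonicalized by
  ascending mean (HMM) or ascending AR coefficient (RS-AR), so labels are
  a function of the estimates, never of the initialization.  p = 6 (HMM)
  and p = 8 (RS-AR): state means/coefficients, state variances, and two
  free transition probabilities.  A fit counts as converged only if the
  best restart met the tolerance *and* beats the corresponding
  single-regime fit (white noise or AR(1)).

Degenerate inputs (zero-variance series, constant lag regressors, zero
residual variance in the white-noise or random-walk fit) raise a
`DegenerateSeriesError`; noiseless but informative series are legal and
produce exact fits with infinite log-likelihood, which the criteria order
correctly ( -inf beats everything).

## Selection criteria

Four information criteria share the likelihood and the parameter count:
AIC = -2 logL + 2p, AICc = AIC + 2p(p+1)/(T-p-1),
BIC = -2 logL + log(T) p, HQ = -2 logL + 2 log(log T) p, where T is the
number of predictable points (series length minus one) — the observation
count the likelihood is actually computed over.  Non-integer p (the
TV-AR effective degrees of freedom) enters all four formulas unchanged.

Three prediction criteria need no likelihood:

* **LOO-CV** removes each predictable observation once *as a regression
  target only* — its observed value still serves as the lag regressor of
  its successor — refits the candidate, and predicts the held-out value
  from the training fit and the observed lag.
* **Blocked CV** (K = 10 in the study) partitions the time axis into K
  contiguous blocks (earlier blocks take any remainder) and holds out all
  predictable targets in one block per fold; rows are assigned to the fold
  of their *target*, so a training row just after a held-out block may use
  an observed held-out value as its lag.  With K = T-1 the scheme reduces
  exactly to LOO (the first block is {1, 2}, whose only predictable
  target is t = 2).  Both schemes refit fully on every fold; for the
  switching models the fold refit masks the held-out rows out of the
  likelihood, and held-out predictions come from the forward filter run
  over the full observed past with frozen parameters — the only coherent
  one-step forecast for a latent-state model.
* **Population MSPE** evaluates a fitted model's one-step predictions on
  an independently simulated 100,000-point series from the true process.
  One population per condition is shared across replicates (a per-replicate
  population is available as a config switch).  Time-varying candidates
  evaluate their smooth at the scaled time t/T of the series being
  predicted, i.e. the fitted trajectory is stretched over the population's
  window.

All seven criteria are "smaller is better".  Rankings sort ascending;
exact ties break by smaller p, then candidate name; candidates whose fit
failed or did not converge rank after all others (the `rank_last` policy;
`drop` excludes them instead).

## The Monte-Carlo harness

The registry holds 33 conditions: 31 normal-innovation rows spanning the
nine processes and the two skew-normal rows (AR(1) with phi=.3;
AR(1)+trend with beta=.1, phi=.3).  The full study crosses them with
T in {50, 100, 200, 1000} at 100 replicates per cell.  Cross-validation is
computed only for T <= 200 (and reported as missing above), matching the
study design; the full grid with CV and OOS at every cell is intentionally
not a single-command run — per-cell execution via `run_cell` or the CLI
keeps any one quantity reproducible in minutes.

Seeding is hierarchical: every replicate's generation and fitting streams
derive from (master seed, condition label, T, replicate index) through
`numpy.random.SeedSequence`, and each condition's population series from
(master seed, condition label, "population").  Any cell is therefore
reproducible in isolation, and a rerun of `run_study` writes byte-identical
CSVs.

Aggregation per cell and criterion reports the mean rank of the true model
(Monte-Carlo SE = sd/sqrt(n)), the proportion of replicates ranking it
first (binomial SE = sqrt(p(1-p)/n); missing at n = 1), the candidate with
the smallest mean rank ("optimal"), and per-candidate non-convergence
counts.

## What the generators do and do not emulate

Passing tests show that the selection machinery behaves correctly under
the study's idealized conditions: known parametric generators, complete
equally spaced series, fixed-time regime switches, and a candidate set
that contains the truth.  Real experience-sampling data violate all four —
missing observations, day/night spacing, stochastic regime dynamics, and
generating processes outside the candidate set — so the reported
proportions say nothing about selection accuracy on empirical data; they
measure the criteria relative to each other under controlled conditions.

## Numerical choices and limitations

* Problem sizes: the shipped acceptance run uses 100 replicates per cell
  (50 for the blocked-CV cell, whose 10 refits x 9 candidates per
  replicate dominate cost), the study's own replicate count.
* GCV, not REML, selects the TV-AR smoothness; with GCV's known
  undersmoothing the time-varying candidates occasionally retain a few
  spurious effective degrees of freedom on truly linear data and then
  out-score the trend model on BIC — visible as a few percent of
  "overspecified" selections in trend conditions.
* The EM criterion compares penalized likelihoods at the *converged*
  parameters; like all EM fits these are local optima, mitigated but not
  eliminated by the restart schedule.
* LOO-CV for the switching models refits EM T-1 times per candidate and
  is the slowest path (about 1.5 s per candidate at T = 100); blocked CV
  is about ten times cheaper.
* The SETAR trimming (15%/85%) and minimum regime size (5) are standard
  but not canonical; looser settings admit near-degenerate splits whose
  tiny-variance regimes inflate the likelihood, which mostly affects how
  often SETAR overtakes simpler true models.
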