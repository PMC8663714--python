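# Methods

## Problem and model

Cohort studies recruit through overlapping campaigns — mailed letters, paid
and unpaid social-media posts, news coverage, partner newsletters, snowball
referral, in-person events — and a campaign's yield is not instantaneous: a
letter keeps producing sign-ups for days, a news article for a day or two.
`recruitlag` models the number of recruits on study day *d* as a finite
distributed-lag linear regression

    y_d = α + Σ_k β_k · z_k(d) + ε_d

where `z_k` is channel *k*'s daily intensity spread over an `s_k`-day window
with nonnegative weights `w_0..w_{s_k−1}` summing to one, and the paid-reach
channel enters as `ln(lagged reach / 1000)` so its coefficient scales with
*proportional* reach changes.  Because each kernel sums to one, β_k on an
identity channel is directly the total number of recruits attributable to
one unit campaign event; its per-day profile is `β_k · w_j`.

Assumptions: effects are additive across channels and linear in intensity;
the lag window starts on the event day (same-day recruitment is possible);
errors are homoskedastic and serially uncorrelated.  Day-of-week
seasonality, autocorrelation-robust errors and count-likelihood (Poisson)
estimation are deliberately out of scope; OLS is the estimator because the
model is linear in the lag-distributed regressors and the reported
uncertainty intervals are symmetric.

## Numerical and design choices

* **Kernel shape.** Only the sum-to-one constraint is inherent to the
  model; the default kernel is uniform (`1/s` per day), with `linear_decay`
  (weights ∝ `s, s−1, …, 1`) available.  All results here use uniform.
* **Zero exposure under the log.** Days with zero lagged paid reach
  contribute 0 to the linear predictor rather than `log(ε)`; a `log1p`
  alternative is available via `zero_mode`.
* **Transform order.** The log is applied *after* lag-weighting (log of the
  lagged variable).
* **Information criteria.** AIC = −2ℓ + 2k and BIC = −2ℓ + k·ln n with the
  full Gaussian log-likelihood and k = p + 1 (the error variance counts as
  a parameter).  Only differences matter for selection; the convention is
  stated for reproducibility.  Confidence intervals use the t distribution
  with n − p degrees of freedom.
* **Lag selection.** A full factorial search over nine channels and lags
  1–15 (15⁹ ≈ 3.8 × 10¹⁰ fits) is infeasible; the default
  `profile_then_descend` strategy starts every channel at lag 2 and cycles
  channel-by-channel, profiling each over 1–15 with the others fixed,
  until a pass changes nothing (max 5 passes, then best-so-far with a
  warning).  Ties break by AIC, then BIC, then the smaller lag — fully
  deterministic.  Statistical significance of individual terms is reported
  but not used as an automatic selection rule (no principled threshold
  exists for it).  An `exhaustive_capped` strategy takes explicit
  per-channel candidate sets for small grids.
* **Degenerate fits.** A perfect fit (SSR/n below 1e−12) maps to
  AIC = BIC = −∞ so ties resolve to the smallest lag; a constant outcome
  reports R² = 0.  Negative fitted values are reported unclipped.
* **Rank deficiency** raises an error naming the collinear columns (via
  rank-revealing QR).  Channels with all-zero intensity are excluded from
  the lag search's design and keep the smallest candidate lag.
* The search uses a direct least-squares criteria path for speed; a unit
  test pins its AIC/BIC/R² to the full fitting routine, which is
  statsmodels OLS behind the module surface.

## Effectiveness metrics

* **Completion rate** = completers ÷ eligible recruits per group, as a
  percentage; empty groups report an absent rate, never 0.
* **Completion delay** = whole days between eligibility- and
  health-questionnaire completion (same-day = 0); sample SD (n−1); absent
  for groups with fewer than two completers.
* **Cost per completer** = (material + transmission + staff hours × hourly
  rate) ÷ completers.  Staff hours come from counted activities at fixed
  rates (0.5 h per Facebook post, 4 h per in-person event, 2 h per media
  publication, 2 h per partner post, 50 h per letter campaign, 35 h per
  snowball campaign), overridable.  The hourly wage is a **required**
  config input with no default: published cost cells are matched by
  calibrating the ledger, never by a hidden wage constant.  Pooled rows are
  completer-weighted means of their cells, so pooled value × total
  completers ≡ Σ cell value × cell completers; zero-completer cells with
  nonzero cost are flagged infinite and excluded from pooling.
  Participant compensation and prizes are excluded from cost.  CAD→USD
  conversion uses a configurable factor (default 0.7692).
* **Demographic cross-tab** percentages use the method's completer count as
  denominator, with missing responses shown as their own row — matching
  the convention of the published tables this suite mirrors (an alternative
  non-missing denominator was considered and rejected for that reason).
* Dates are calendar dates; the method taxonomy is fixed to six categories
  (city-specific sub-options must be mapped to `other` upstream); each
  participant reports a single recruitment source (the source questionnaire
  was single-select as far as can be determined).

## Synthetic data

The stochastic generator emulates the Montreal arm of a three-city Canadian
cohort study (Montreal, Saskatoon, Vancouver) over a 199-day recruitment
period, since that is the arm with a daily campaign log:

* 151 paid-reach days drawn as a contiguous block with 10% of days swapped
  to random positions (paid campaigns ran near-continuously); reach values
  are lognormal, moment-matched to mean 2770 / SD 3558 and rejected outside
  [144, 20 156].  Moment matching precedes truncation, so the truncated
  mean sits slightly (~3%) below target; this is accepted and documented
  because only the mean/SD/min/max are known.
* 44 unpaid posts over 34 distinct days; 18 partner communications, 2
  wide-reach and 6 smaller-reach media events, 1 snowball campaign and 16
  other events on uniform random days; one letter campaign on a uniform day
  early enough for its 15-day window, with the reminder mailed 14 days
  later (the mailing protocol used a two-week reminder).
* Daily counts come from the model used generatively at the published
  coefficient estimates (intercept 4.3; letters 106.5; reminders 16.9; log
  paid reach/1000 1.4; unpaid posts 3.2; partner 3.5; snowball 2.5; wide
  media 163.6; small media 10.4; other −1.3) with the published lags
  (letters 15, reminders 5, snowball and other 4, the rest 2).  Noise is
  `round(max(N(η, σ), 0))` (default, σ = 2 — a realistic day-level
  dispersion for a series averaging ~8 recruits/day) or Poisson(max(η,
  0.01)); the Gaussian default mirrors the OLS estimator since the noise
  family of the real counts is unknown.
* Participant records draw method (multinomial over published recruited
  shares), completion (Bernoulli at the method's published rate), delay
  (lognormal moment-matched to the method's published mean/SD, rounded to
  whole days) and demographics (per-method multinomials from the published
  completer distributions, with missingness at the published overall rates
  applied uniformly across methods, per-method missingness being
  unpublished).

**What the simulator does not emulate:** day-of-week and holiday structure,
correlation between channels' timing (beyond the letter→reminder link),
demographic dependence between dimensions (age × income etc. are drawn
independently), attrition after baseline, and participants hearing about
the study from several sources.  Passing recovery tests therefore shows the
estimator is correct *under the stated generative model*, not that the
published coefficient table would be recovered from the real (unpublished)
daily data.

## Deterministic fixture

`build_fixture` enumerates 2318 recruits / 1791 completers whose city,
method, demographic, participation-option and mail-group margins equal the
published tables cell by cell, so the metric suite is testable offline.
Two source-table reconciliations were needed:

* The within-city split of non-completers across methods is unpublished;
  cells were allocated once, proportionally to completers, and frozen.
  The three mailed-letter arm sizes (75 + 88 + 8 = 171) exceed Montreal's
  148 letter *completers*, so they are interpreted as Montreal letter
  *recruits*, implying 10 letter-reporting recruits in Saskatoon with no
  completions.
* The published per-city average costs per completer are not the
  completer-weighted means of that city's method cells; both are carried
  separately (`COST_PER_COMPLETER_CAD` cells vs
  `CITY_COST_PER_COMPLETER_CAD`), and pooled method values are computed
  from the cells.

Fixture delays are per-method constants (the rounded published means) —
valid, but only the *counts* in the fixture are meaningful.  The ledger
back-solves material cost as printed cell value × completers with zero
staff activities, so printed cells are reproduced without inventing a wage.

## Problem sizes used by the checks

The test suite and the acceptance script use: 100 random small OLS
instances (T ≤ 50, ≤ 4 channels) against a normal-equations oracle;
200 replicates (tests) / 100 replicates (script) of the T = 199, σ = 2
coverage experiment; 20 seeds of the σ = 1 lag-recovery experiment; and
10⁴-sample checks of the truncated-lognormal and delay samplers.  Slope-
coefficient CI coverage is required to fall in [90%, 98%]; letters and
wide-media lag recovery in ≥ 15/20 seeds.  The published adjusted R² (0.78)
is *not* a reproduction target: it depends on the unpublished daily series,
and the simulator's signal-to-noise (adjusted R² ≈ 0.97 at σ = 2) is set by
the published effect sizes, not tuned to match it.

## Known limitations

* The semilog channel's per-event effect has no additive reading;
  `proportional_effect` reports β·ln(1+δ) and is approximate as a
  statement about multi-day totals.
* Coordinate-wise lag selection can in principle settle in a local optimum
  of the AIC surface; the per-candidate criteria table is emitted so the
  profile curves can be inspected, and a capped exhaustive grid is
  available.
* Weakly identified channels (single events with small coefficients, e.g.
  one snowball campaign at β = 2.5) have essentially flat criterion
  profiles; their selected lags are not trustworthy at realistic noise
  levels, and the recovery experiments accordingly only constrain the
  strongly identified channels.
* OLS treats counts as Gaussian; for very low daily rates the Poisson
  option of the simulator will expose mild heteroskedasticity that the
  reported standard errors ignore.
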