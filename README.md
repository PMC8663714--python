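# recruitlag

Tools for evaluating how a cohort study's recruitment campaigns perform:
a finite **distributed-lag regression** of daily recruit counts on campaign
events, AIC/BIC lag-length selection, and the standard effectiveness
metric suite (completion rates, completion delays, cost per completer with
staff-time accounting, demographic composition by recruitment method).
Built for the three-city Canadian cohort setting (Montreal, Saskatoon,
Vancouver) in which recruits report one of six methods — mailed letters,
social media, news media, partner communications, snowball referral, other
— and Montreal's 199-day campaign log supports daily modeling.

## The model

Recruits on study day *d*:

    y_d = α + β₁·[x₁(d−s)] + β₂·[log x₂(d−s)/1000] + … + β₉·[x₉(d−s)] + ε_d

Each channel's daily intensity is spread over a finite lag window of
*s* ∈ 1..15 days with nonnegative weights summing to 1 (uniform by
default), so **β_k is the total number of recruits per unit campaign
event**, distributed over the window.  Paid Facebook reach enters as the
log of the lagged reach per 1000, so its coefficient scales with
proportional reach changes.  Estimation is OLS; lag lengths are chosen per
channel by AIC (ties: BIC, then the smaller lag) via coordinate-wise
profiling.  See `docs/methods.md` for conventions and assumptions.

Because the participant-level study data are not public, the package ships
two synthetic substitutes (`recruitlag.synthetic_data`): seeded stochastic
simulators of the Montreal campaign structure, and a deterministic fixture
whose margins equal the study's printed tables cell by cell.

## Worked example

Simulate a Montreal-like campaign and fit the model
(`python analysis/03_simulate_recruitment.py && python analysis/04_fit_distributed_lag.py`):

```
seed 11: 1679 recruits over 199 days (mean 8.44/day)

                  term  estimate    se  ci_low  ci_high     p
             intercept     4.401 0.217   3.972    4.830 0.000
         letters_lag15    93.009 7.909  77.408  108.611 0.000
paid_fb_reach_log_lag2     1.436 0.177   1.087    1.785 0.000
  unpaid_fb_posts_lag2     3.327 0.353   2.629    4.024 0.000
        reminders_lag5    19.098 4.406  10.406   27.790 0.000
    partner_comms_lag2     3.351 0.635   2.098    4.604 0.000
         snowball_lag4     0.712 4.042  -7.261    8.686 0.860
       wide_media_lag2   167.070 2.069 162.989  171.151 0.000
      small_media_lag2     9.730 1.205   7.354   12.106 0.000
            other_lag4    -2.050 1.049  -4.120    0.019 0.052
R2 = 0.978, adjusted R2 = 0.977
letter campaign: 93.0 recruits over 15 days (6.2/day)
```

Read: one mailed-letter campaign yields ≈93 recruits spread over 15 days
(≈6/day) in this realization (generating value 106.5); each wide-reach news
article yields ≈167 recruits over 2 days; the baseline organic rate is
≈4.4 recruits/day.  Weakly identified channels (the single snowball
campaign) have wide intervals.  `analysis/05_select_lags.py` then recovers
the generating lag lengths for the strongly identified channels by AIC
profiling, and `analysis/06_parameter_recovery.py` shows ≈94–95% CI
coverage across replicates.

The effectiveness side (`python analysis/01_build_fixture.py &&
python analysis/02_effectiveness_metrics.py`) prints, from the fixture:

```
completion rate, mailed letters: 88.4%
completion rate, snowball:       72.5%
cost/completer, social media:    CAD 15.04
cost/completer, partner comms:   CAD 5.16
```

i.e. letter recruits complete most reliably, while partner newsletters are
the cheapest method per completed participant and social media the largest
source of completers (687 of 1791).

There is also a thin CLI: `recruitlag validate|fit|metrics|simulate|fixture`
(see `recruitlag --help`).

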