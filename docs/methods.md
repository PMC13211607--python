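# Methods

This note records the modeling assumptions, parameter defaults, and
numerical choices behind `digasim`, and what the synthetic data generator
does and does not emulate.

## 1. Data model

The unit of analysis is a *fund-year record*: one accident-insurance fund
(Berufsgenossenschaft), one calendar year, with expenditure (EUR) and case
counts for two therapy classes — conventional physiotherapy and extended
outpatient physiotherapy (EAP). Missing cells are explicit (`None`), never
silently zero. Validation checks nonnegativity, plausibility windows
(years 2000–2100; spend per case €10–€50,000), reconciliation of class
sums against an optional stated total, and cross-year consistency;
violations are emitted as structured JSONL, one object per finding.

Derived indicators are spend per case by class, year-over-year cost and
volume growth, and the daily EAP arrival rate (annual cases / 250 business
days).

## 2. Cost-consequence model

For each fund and therapy class, with `n` annual cases and spend per case
`spc`, two mutually exclusive mechanisms act on disjoint partitions of the
*engaged* cohort:

- **Substitution** — a share `R_Sub` of cases is fully replaced by a
  digital application, saving `spc` per substituted case:
  `S_sub = n_eff · R_Sub · spc`.
- **Complementary efficiency** — among the remaining `1 − R_Sub` cases, a
  share `R_Comp` adds the application on top of standard care and reduces
  its cost by a fraction `E_Gain`:
  `S_comp = n_eff · (1 − R_Sub) · R_Comp · E_Gain · spc`.

### Adherence funnel

The effective cohort `n_eff` comes from a three-stage funnel applied
upstream of both mechanisms:

1. **Eligibility / willingness:** 70% of annual cases are prescribed.
2. **Engagement split:** 15% of prescribed cases become engaged users;
   the other 85% are short-term users.
3. **Benefit attribution:** engaged users realize the full substitution
   and complementary effects (`n_eff = n · 0.70 · 0.15`); short-term
   users are credited only a *partial benefit* worth 3 avoided
   physiotherapy sessions each. The session price defaults to the fund's
   physiotherapy spend per case divided by an assumed 6 sessions per
   case, and can be overridden per class.

### Cost accounting

The prescription price `C_DiGA` is charged once per *prescribed* case —
engaged or not — reflecting the German reimbursement rule that payment is
triggered by prescription, not by sustained use. Net savings per fund are
therefore

```
net = S_sub + S_comp + partial_benefit − n · 0.70 · C_DiGA
```

summed over both therapy classes. A consequence worth stating plainly:
because 85% of prescriptions incur the full price but return only the
small partial benefit, realistic adherence dominates the economics, and
the model can be (and under the default synthetic cost split *is*)
net-negative.

### Thresholds and sensitivity

With all parameters fixed at their modes, bisection solves two threshold
problems:

- **Break-even price:** the largest `C_DiGA` at which net savings are
  zero. Bisection brackets from the distribution minimum with doubling;
  if net savings are negative even at the minimum price the result is
  flagged infeasible.
- **Break-even adherence:** the smallest engaged share at which net
  savings are zero, solved on the extended domain [0, 5] so that a root
  above 1.0 is *reported* (status `infeasible`) rather than clipped —
  an adherence requirement above 100% is itself the finding.

One-way sensitivity curves sweep a single parameter (price or engaged
share) over a grid while holding the rest at modes.

### Demand-reduction coupling

The economic model feeds the queuing model through the fraction of EAP
demand removed. Two policies exist: `funnel` derives it mechanically as
eligibility × engaged share × R_Sub(EAP) (≈ 0.3% at modes — honest but
tiny), and `fixed` uses a preset scenario value (default 15%) representing
the *realistic* policy scenario; scenario multipliers 0.5/1.0/1.5 give
conservative/realistic/ambitious variants.

## 3. Probabilistic sensitivity analysis

All uncertain parameters carry independent triangular distributions
(min / mode / max):

| Parameter | Physiotherapy | EAP |
|---|---|---|
| `C_DiGA` (EUR/prescription) | 250 / 450 / 600 | (shared) |
| `R_Sub` | 0.05 / 0.10 / 0.25 | 0.01 / 0.03 / 0.08 |
| `R_Comp` | 0.20 / 0.35 / 0.50 | 0.15 / 0.25 / 0.40 |
| `E_Gain` | 0.10 / 0.20 / 0.30 | (shared) |

Sampling is by inverse CDF of the triangular distribution applied to
uniform variates; the default run is 10,000 iterations (~1 s). Summaries
report mean, median, the 2.5th/97.5th percentiles (numpy's default linear
interpolation), and the exact fraction of iterations with positive net
savings. Stratified runs reuse one shared parameter draw per iteration
across funds (so fund results are comparable and sum to the pooled total)
unless independent draws are requested.

Randomness is organized as named substreams: a master seed plus a label
(e.g. `"psa"`, `"psa:fund_03"`) hashed via BLAKE2s into a
`numpy.random.SeedSequence`, so adding or removing one analysis stage
never shifts another stage's draws.

## 4. Queuing model

The EAP rehabilitation pathway is modeled as a single-server M/M/1 queue
in units of business days. Defaults: λ = 27 annual starts / 250 days =
0.108/day; mean time in queue `Wq = λ / (μ(μ − λ))`; waiting-time tail
`P(Wq > t) = ρ·exp(−(μ − λ)t)` with ρ = λ/μ.

Two service-rate calibrations are provided:

- **Mean-wait** (default): invert the `Wq` formula given an observed mean
  wait (17.28 days from a 31-patient sample), giving μ ≈ 0.1497 ≈ 0.150
  per day, ρ ≈ 0.72.
- **Exceedance**: given an observed share waiting longer than a threshold
  (96.8% beyond 3 days), either read ρ directly from the share
  (`rho-direct`, μ = λ/share ≈ 0.1116) or solve the full tail formula by
  bisection (`tail-consistent`, μ ≈ 0.1107).

The two calibrations are *mutually inconsistent* at the observed inputs —
the mean-wait fit implies a 3-day exceedance of ~63%, not 96.8%. This is a
property of the data against the M/M/1 form (the small sample's mean and
tail cannot both hold), and the package deliberately exposes both fits
rather than reconciling them.

Demand scenarios scale λ by (1 − reduction). Because the baseline queue
runs near saturation, waiting times respond hyper-linearly: a 15%
reduction cuts the mean wait by ~39%. Waiting-day savings are
(baseline − scenario mean wait) × annual EAP population (26,705), and an
optional productivity valuation multiplies by a €180/day gross wage with a
68–80% replacement-cost band.

## 5. Discrete event simulation

The DES is an exact single-server FCFS simulation used to validate the
analytic M/M/1 results: exponential interarrival and service times via
inverse CDF, waiting times by the Lindley recurrence
`W_{n+1} = max(0, W_n + S_n − A_{n+1})`, computed vectorized as a running
minimum of a cumulative sum. Protocol: 2,000 warm-up patients discarded,
20,000 post-warm-up patients per replication, 200 independent
replications (~4 million simulated patients, a few seconds). Reported:
grand mean of replication means, the 2.5th/97.5th percentiles across
replications, and the standard error of the grand mean. Scenario
comparisons use common random numbers (the same substream per replication
index across scenarios) to sharpen contrasts. Each replication draws from
`SeedSequence([seed, label_key, replication])`, keeping replications
independent and every derived seed well below 2³¹.

At ρ = 0.72 with 20,000 post-warm-up patients, residual initialization
bias is under 1% of the analytic mean (verified by doubling the warm-up),
and DES grand means at ρ ∈ {0.3, 0.5, 0.72, 0.9} agree with the analytic
`Wq` within three standard errors.

## 6. Synthetic data generator

The real fund-level ledger is not public. The generator produces a
two-year, ten-fund panel that reproduces these **system-level marginals
exactly** (to allocation precision):

- combined therapy expenditure in the latest year: €404.0 M;
- year-over-year aggregate cost growth: +10.1%;
- year-over-year aggregate volume growth: +1.2%;
- total insured population: 25.9 M;
- annual EAP patient count: 26,705.

Exactness is achieved by largest-remainder allocation: integer case
counts and cent-level expenditures are distributed across funds so column
sums hit the targets without rounding drift; first-year expenditures are
allocated proportionally to second-year shares so aggregate growth is
exact, and first-year case counts are real-valued (second-year / 1.012)
so volume growth is exact. Fund shares follow a configurable decreasing
profile with optional seeded lognormal jitter on spend per case
(`jitter_sigma`, default on; set to 0 for a strictly proportional case
mix).

**What the generator does *not* emulate.** The split of the €404 M
between physiotherapy and EAP, the fund-size profile, and per-fund cost
heterogeneity are unpublished; they are free parameters of
`SyntheticConfig`, set to round defaults. Fund-level economic outputs on
synthetic data are therefore *structurally* faithful (correct formulas,
correct marginals) but not *numerically* faithful to the real system —
in particular, with the default cost split the base-case net savings are
negative. These defaults were chosen once, a priori, and not adjusted to
make any downstream number come out favorably.

A companion routine generates a 31-observation waiting-time sample with
an exact target mean (17.3 days) and an exact share above a threshold
(96.8% above 3 days), built as threshold offsets plus slack-scaled
exponential tails; it is a reproduction device for the queuing inputs,
not a model of the empirical waiting-time distribution's shape.

## 7. Numerical choices

- Bisection for break-even price runs to an internal tolerance of 1e-7 so
  that the plugged-back net at the reported root is within €1 even at
  large case volumes; reported precision is one cent.
- Break-even adherence uses bisection on [0, 5]; no sign change over the
  domain yields status `no_root`.
- Triangular draws use the closed-form inverse CDF (no rejection).
- Percentiles use `numpy.percentile` defaults.
- All Monte Carlo components accept a single master seed; derived
  substream seeds are deterministic functions of (seed, label[,
  replication]) and remain below 2³¹.

## 8. Limitations

- The queue is a single aggregate M/M/1 server; real EAP capacity is many
  providers with heterogeneous, non-exponential service times. The model
  captures the congestion *mechanism* (hyper-linear relief near
  saturation), not center-level detail.
- The 17.28-day mean wait comes from a 31-patient convenience sample; the
  mean-wait and exceedance calibrations disagree (Section 4) and both are
  carried rather than resolved.
- Adherence funnel shares (70% / 15% / 85%) and the 3-session partial
  benefit are assumptions, not estimates; the break-even adherence solver
  exists precisely because they dominate the result.
- PSA parameters are drawn independently; plausible correlations (e.g.
  price vs. efficacy) are not modeled.
- Savings are gross payer-perspective therapy-cost offsets within one
  year; implementation, prescriber-time, and long-run outcome effects are
  out of scope.
- Synthetic fund-level detail is illustrative only (Section 6).
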