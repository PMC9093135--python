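# Methods

## Model structure

The analysis is a deterministic (expected-value) cohort model over three
health states — progression-free (PFS), progressed disease (PD) and
death — with monthly cycles and a 10-year horizon (120 cycles).  The
whole cohort starts in PFS.  Death is absorbing and there is no PD→PFS
backflow.  Per-cycle transition probabilities are time-varying:

* **PFS → death**: background mortality from a life table at the
  cohort's current age.  Annual qx converts to a monthly probability
  under a constant within-year hazard, p_m = 1 − (1 − qx)^(1/12); the
  cohort ages by 1/12 year per cycle from a configurable starting age
  (default 68 — an assumption, the source cohort's age is not used
  directly).
* **PFS → PD**: the PFS Weibull's conditional per-cycle probability
  minus background mortality, floored at zero ("subtraction" rule), so
  total PFS exit equals the fitted PFS curve's conditional probability
  and PFS occupancy telescopes exactly to the fitted survivor function.
  A "multiplicative" variant (progression and background death as
  independent competing risks) is available via
  `ModelSpec.competing_risk`; under it PFS occupancy equals the survivor
  function times the cumulative background-survival product.  Both
  identities are asserted in the test suite under their respective
  configurations.
* **PD → death**: the OS Weibull's conditional per-cycle probability,
  floored at background mortality.  The evidence base never states which
  fitted curve feeds this transition; this choice is the model's largest
  structural judgment call and is deliberately config-swappable.  Note
  its consequence: everyone in PD dies at the *marginal* OS rate, which
  understates early post-progression mortality and therefore lets
  incremental survival accrue mostly in PD (see "Known limitations").

No half-cycle correction is applied in the base case (a flag enables
it); occupancy at cycle start is used for both accrual and transitions.

## Survival inputs

Weibull models are parameterized by the cumulative hazard H(t) = λt^γ
(λ > 0 per month^γ, γ > 0), so S(t) = exp(−λt^γ) and the conditional
cycle transition probability is 1 − exp[λt^γ − λ(t+1)^γ] — the exact
printed formula, not the location-scale form some survival packages use
(conversion helpers `to_aft_params`/`from_aft_params` are provided and
the fit is cross-checked against lifelines in the tests).  Fitting
maximizes the right-censored log-likelihood on (log λ, log γ) with
analytic gradients, multi-started from the exponential closed form and
polished by damped Newton steps until the absolute gradient norm is
≤ 1e−6; the fit must also beat the γ=1 submodel.  λ and γ are strongly
anti-correlated, so individual parameter estimates are noisy even at
large n (λ̂ has ≈4.5% sampling SD at n=5000 under 20% censoring) while
the implied median survival is stable; accuracy checks therefore use
medians over replicates.

## Pseudo-IPD reconstruction

Digitized coordinates are preprocessed (sorted, clamped to [0,1],
running-minimum monotone, duplicates collapsed to the lower value,
(0,1) prepended) and combined with a numbers-at-risk table.  Within
each inter-risk-table interval the algorithm iterates: place the
current censoring count on a uniform grid over the interval, imply
event counts at each curve-drop time from the product-limit relation
d = n_r (1 − S_target/S_run), round them by largest remainder within
the interval, and update the censoring count to the drop in numbers at
risk not explained by events.  The procedure is fully deterministic.
Small event excesses relative to the risk table (digitization noise)
are pushed past the interval boundary; gross excesses (>10% of the
interval's risk set) raise a reconstruction-infeasible error naming the
interval.  Without a risk table, no censoring is assumed before the
last coordinate and all survivors are censored there — the conservative
default of the reconstruction literature.  Time is months everywhere;
curves digitized in weeks are converted at 12 months = 52.18 weeks.

## Economics

QALYs accrue as Σ_t [occ_PFS(t)·u_PFS + occ_PD(t)·u_PD]·(Δt/12)·df(t)
with df(t) = (1+r)^(−t/12), r = 3% (US) or 5% (China) annually,
applied at cycle start.  Utilities derive from QLQ-C30 scores divided
by 126 (1 = perfect health, 0 = death): u_PFS = 0.84, u_PD = 0.80.

The published parameter table does not state cost timing, so the
schedule is explicit and configurable; the defaults are:

| item | timing | state | arm | notes |
|---|---|---|---|---|
| PD-L1 test | one-time at entry | — | both | |
| pretreatment | one-time at entry | — | both | |
| AE management | one-time at entry | — | arm-specific | |
| drug acquisition | per cycle | PFS | AVE | stops at the median treatment duration, 24.9 weeks = 5.73 months |
| BSC | per cycle | PFS | arm-specific | monthly rates as published |
| imaging | per cycle | PFS | both | one scan per 8 weeks = 1.84 months, accrued at its monthly equivalent |
| post-progression care | per cycle | PD | both | published as cost per patient-month |

China prices are stored in USD as published (converted at the fixed
1 USD = 6.36 CNY rate; `cny_to_usd` exists for ingesting new prices).
ICER = ΔC/ΔE when both increments are positive; dominance, "southwest"
(cheaper but less effective) and undefined (ΔE = 0) cases carry explicit
flags instead of silent NaNs.  NMB = WTP·E − C with WTP $150,000/QALY
(US) and $30,447.09/QALY (China).

## Sensitivity analysis

Published ranges (≈ ±20% of base) are read as 95% intervals, so
SE = (high − low)/3.92; a uniform-range interpretation is available
behind a config switch.  Utilities get beta distributions and costs
gamma distributions, moment-matched to (base, SE) exactly — matching is
analytic and verified both algebraically and by Monte Carlo in the
tests.  One-way DSA evaluates the ICER at each parameter's bounds with
the rest at base and sorts bars by width; endpoints that hit dominance
fall back to the incremental-NMB scale and are flagged.  The PSA draws
1,000 independent parameter vectors (second-order uncertainty only —
parameter draws over the deterministic cohort model, no patient-level
resampling), evaluates the scenario per draw, and reports CEACs as the
fraction of draws with positive incremental NMB over a WTP grid
(0–300,000 in 5,000 steps, always containing both thresholds).  Cohort
traces do not depend on the economic parameters, so they are computed
once per arm and reused across all DSA/PSA evaluations; parameter
correlations are not modelled (none are published).

## Synthetic data

The generator emulates: (i) two-arm Weibull event times by inversion
with independent exponential censoring whose rate is solved numerically
so the expected censored fraction equals the requested 20%, plus
administrative censoring at 42 months of follow-up; (ii) figure
digitization — the exact product-limit curve sampled at 60 of its step
corners with ±0.005 uniform survival jitter, plus a 6-point
numbers-at-risk table (corner sampling reflects how digitizers click
visible steps; uniform-time sampling provably shifts reconstructed
events later and biases the fitted shape up by ≈5%); (iii) a
Gompertz-shaped life table qx(age) = min(1, 5e−5·e^{0.09·age}) over
ages 40–110.

The base case uses γ = 1.2 (a mild increasing hazard; no shape is
published) with λ = ln 2 / median^γ solved per arm × endpoint so the
four printed medians (OS 21.4/14.3, PFS 3.7/2.0 months) hold exactly by
construction, and n = 350 per arm.  What passing tests show: the
pipeline recovers its own ground truth through digitization and
reconstruction, and the incremental arithmetic is exact.  What they do
not show: agreement with the published absolute per-arm costs and
QALYs, which depend on unpublished fit parameters and timing
conventions — the published QALY scale (≈0.21 over 10 years) is not
reconcilable with a 21.4-month median OS under any conventional
accrual, so only the published table's internal arithmetic identities
are asserted.  The two populations share survival curves in the fixture
and differ only in their cost blocks.

## Numerical choices

* Probability tolerances: transition-matrix rows and trace rows must
  sum to 1 within 1e−12; occupancy identities hold to 1e−9.
* Largest-remainder rounding breaks ties toward earlier times,
  deterministically.
* Degenerate inputs raise typed errors: zero events
  (non-identifiable fit), reversed intervals, ages below the life
  table, infeasible beta variances, inconsistent risk tables.
* All randomness flows through `numpy.random.default_rng` seeded per
  invocation; PSA results are bitwise reproducible given a seed.
* Problem sizes in the routine checks (350 subjects/arm, 5–10 seeds,
  1,000 PSA draws, n=5000 for recovery studies) keep the full suite
  fast while leaving the estimators well inside their asymptotic
  regimes.

## Known limitations

* With PD→death driven by the marginal OS hazard, incremental
  life-years accrue predominantly in the PD state under this
  calibration (≈0.85 of ≈1.0 undiscounted incremental life-years in
  the US overall scenario).  The PD utility therefore carries more
  one-way leverage than the PFS utility, whereas the source analysis
  reported the PFS utility among the two most influential parameters;
  on this synthetic calibration that ordering does not emerge, and the
  corresponding check is expected to fail rather than being relaxed.
* Single cohort starting age; no treatment-waning, tunnel states or
  subsequent-line treatment switching; biomarker subgroups differ only
  through their cost blocks.
* PSA covers parameter (second-order) uncertainty only.
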