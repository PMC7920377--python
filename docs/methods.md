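# Methods

## Model structure

The model is a three-state Markov cohort simulation of first-line treatment
for advanced (stage IIIB/IV) NSCLC: progression-free survival (PFS),
progressed disease (PD) and death (absorbing). Cycles are monthly; the
horizon is 120 cycles (10 years), long enough that under the base-case
overall-survival curve less than 0.3% of the cohort is alive at the end.
Four strategies are compared: empirical cisplatin-pemetrexed chemotherapy
for everyone, and EGFR mutation-guided use of afatinib, erlotinib or
gefitinib, in which mutation-positive patients (prevalence 50.1%) receive
the TKI until progression and mutation-negative or non-compliant patients
receive chemotherapy. Guided strategies add a one-time EGFR test cost
(USD 324) at entry. By linearity of the cohort model, a guided strategy is
evaluated exactly as the mixture
`w · TKI-arm + (1−w) · chemo-arm`, `w = prevalence × compliance`.

### Transition probabilities

The chemotherapy arm's PFS and OS are Weibull, `S(t) = exp(−λ t^γ)` with
(λ, γ) = (0.0572, 1.2883) for PFS and (0.0057, 1.4499) for OS (both fitted
upstream to digitized trial Kaplan-Meier curves; both shapes > 1, so
hazards increase with time). The monthly event probability is the
discrete-time hazard `P(t) = 1 − S(t)/S(t−1) = 1 − exp(λ(t−1)^γ − λ t^γ)`.
TKI arms rescale the monthly odds of remaining event-free by the
treatment's odds ratio (PFS and OS separately), i.e.
`p' = p / (p + OR·(1−p))`; OR > 1 therefore lengthens survival, matching
the direction of the source meta-analysis. The same formula is its own
inverse under OR → 1/OR and is applied on the natural OR scale (the
published anchors are declared Triangular on that scale; log-scale sampling
would be a one-line change in `sample_parameter`).

### Within-cycle competing risks

The published model description does not say how PFS exits split between
progression and death. We treat the monthly death probability (from the OS
curve) and the monthly PFS-event probability as independent within-cycle
risks, applied death-first:

    PFS → DEATH : p_death(t)
    PFS → PD    : (1 − p_death(t)) · p_pfs(t)
    PD  → DEATH : p_death(t)

Because death applies at the same rate to PFS and PD occupants, the
marginal alive fraction tracks the fitted OS Weibull exactly. This slightly
double-counts death inside the PFS-event probability (trial PFS events
include deaths), shortening PFS occupancy by a few percent relative to the
pure PFS curve; the alternative split (death subtracted from the PFS-event
probability, `PFS→PD = max(0, p_pfs − p_death)`) keeps PFS occupancy equal
to the PFS curve but overstates the published TKI-strategy PFS months by
22–34%. The independent-risks split reproduces every published base-case
cell within ±7%, and is the structure a TreeAge tree with separate
death/progression chance nodes produces, so it is the default; the split is
isolated in one place (`markov._arm_outcome` / `transition_matrix_at`)
should anyone want the alternative.

### Counting, discounting, rewards

State membership is counted at the *beginning* of each cycle (cycle 0
included, no half-cycle correction) — the counting TreeAge applies by
default and the convention that best matches the published undiscounted
survival totals. Cycle i (0-based) contributes discount factor
`(1.03)^(−i/12)` to costs and QALYs; PFS/OS months are undiscounted sums of
occupancy. QALYs weight PFS months by u = 0.80 and PD months by u = 0.56
(÷12 to convert months to years).

Costs per cycle: the chemotherapy arm pays the cisplatin-pemetrexed monthly
cost (USD 2,374) for the first 4.2 months of PFS occupancy — "up to six
21-day cycles" = 126 days, prorated inside the fifth monthly cycle — then
off-chemotherapy follow-up (USD 152/month) while still progression-free;
the six-month literal reading would overstate drug exposure by ~45% and is
one config edit away (`settings.chemo_duration_months`). TKI arms pay the
TKI monthly cost for every PFS month (treatment until progression; the
published cost already includes non-drug resource use). PD occupancy pays
palliative care (USD 493/month).

Serious adverse events (grade ≥ 3: nausea/vomiting, diarrhea, rash, anemia,
neutropenic fever) are applied once at treatment initiation as an expected
episode cost `Σ incidence × episode cost` and an expected QALY decrement
`Σ incidence × |disutility| × duration/12`, because the trial incidences
are per treatment course, not per cycle. The episode duration is unstated
in the source; one month is the minimal consistent choice and is a config
knob (`settings.sae_duration_months`).

## Cost-effectiveness analysis

Strict dominance only (fewer QALYs at higher cost) eliminates strategies,
matching the published analysis; extended dominance is computed as a
diagnostic but never used for elimination. ICERs are reported against the
common chemotherapy comparator and sequentially along the cost-sorted
frontier. The operational decision rule is net monetary benefit
(`NMB = WTP·QALY − cost`, WTP = 143,436 USD/QALY = 3× Hong Kong GDP per
capita), which the test suite verifies to be equivalent to the published
two-clause rule (cost-saving, or ICER below WTP) walked along the frontier;
NMB is total-order and numerically robust when ΔQALY is of order 0.03.

## Sensitivity analyses

**One-way:** every input with a published range is set to each extreme with
all others at base; the preferred strategy is recomputed. The bisection
threshold search (`threshold_scan`, tolerance USD 1, with a 50-point
monotonicity pre-scan) reproduces the extended analysis on the afatinib
monthly cost: the frontier ICER of guided afatinib falls below WTP near
USD 830/month (published: below USD 818). One caveat this implementation
surfaces: at the upper 95% CI of the TKI overall-survival odds ratios
(e.g. afatinib OS OR = 1.96) the afatinib-vs-erlotinib ICER sits almost
exactly on the WTP threshold — in our model it dips just below, flipping
the NMB winner; on the published numbers it is ~140k vs 143,436, a knife
edge in either direction. All 44 other varied inputs leave guided
erlotinib preferred at both extremes.

**Probabilistic:** 10,000 Monte-Carlo draws; each non-fixed input is drawn
once per draw and all four strategies are evaluated on the same draw
(common random parameters, required for meaningful incremental scatter).
Probabilities and prevalences draw from Beta distributions moment-matched
to mean = base and sd = (high − low)/(2·1.96), i.e. the printed range read
as a 95% interval (if moment matching is ever infeasible the range is
refit as 1st/99th percentiles; with the packaged inputs this never
triggers). Incidences printed as 0% collapse to a point mass at zero.
Odds ratios, utilities, disutilities and costs draw from Triangular(low,
mode = base, high); for costs the anchors are median/IQR, so using them as
hard bounds understates tail uncertainty — a deliberate mirror of the
published input table. Weibull parameters and compliance stay fixed. The
right-skew of the Triangular OR anchors is why the PSA mean QALY gain of
guided erlotinib over chemotherapy (~0.21) exceeds the base-case difference
(0.159) — the same pattern the published PSA shows (0.2217 vs 0.1714).
The engine is vectorized over draws (a 10,000-draw PSA takes under a
second); the default seed is 20210301 and every run records seed, n and
the sampled draws in its manifest.

## Synthetic data generator

`simulate_ipd` draws continuous Weibull event times by inverse transform
with administrative censoring at a single cutoff (default 36 months —
trial-like follow-up); `simulate_ipd_discrete` generates a TKI-like arm in
discrete monthly time using exactly the engine's odds-rescaled monthly
probabilities, so the recovery test validates the same code path the
Markov model uses. `km_estimate` is the product-limit estimator (lifelines)
and `fit_weibull_to_km` the log-log linearization fitted by OLS (points at
s ∈ {0, 1} dropped). `end_to_end_recovery` chains
simulate → KM → Weibull fit and recovers the odds ratio from the two arms'
life-table monthly probabilities by inverse-variance-weighted averaging of
monthly log-ORs. At 5,000 patients/arm it recovers λ and γ within 5% and
the OR within a few percent.

What the generator does *not* emulate: staggered accrual and dropout
censoring, digitization error of published curves, correlation between PFS
and OS within patients, or non-proportional treatment effects. Passing
recovery tests therefore show the estimation pipeline is correct under the
model's own assumptions, not that those assumptions hold in any real trial.

## Numerical choices and degenerate inputs

- Probabilities are clipped nowhere: the odds transform and the
  discrete-time hazard are closed in [0, 1] by construction; transition
  rows sum to 1 to 1e−12 and traces conserve mass to 1e−9 over 120 cycles.
- `threshold_scan` returns None when the criterion never flips and raises
  on a non-monotone pre-scan rather than silently bisecting.
- Degenerate sampling anchors (low = high, Beta mean of exactly 0 or 1)
  collapse to point masses.
- Ties in the NMB rule are broken by lower cost, then name, and the CEAC
  uses the same tie-break; ties have measure zero under continuous draws.

## Known limitations

- Reproduction accuracy is bounded by structural choices the source leaves
  open (competing-risk split, cycle counting, SAE timing, chemotherapy
  proration). Base-case cells agree within ±7%; ratio quantities over thin
  QALY margins amplify this — the gefitinib-vs-chemotherapy ICER divides a
  ~0.006–0.011 QALY margin and lands ~1.5× the published value despite all
  underlying cells agreeing within tolerance.
- No second-line/maintenance therapy, no treatment discontinuation for
  toxicity, no parameter correlation in the PSA, no EVPI — all outside the
  reproduced analysis.
- Costs are 2020 USD for Hong Kong's public system; no currency or
  inflation adjustment is provided.
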