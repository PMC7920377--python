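# nsclc-cea

A decision-analytic cost-effectiveness model comparing **EGFR mutation-guided
first-line TKI therapy** (afatinib, erlotinib or gefitinib for
mutation-positive patients, cisplatin-pemetrexed otherwise) against
**empirical cisplatin-pemetrexed chemotherapy** for advanced (stage IIIB/IV)
non-small-cell lung cancer, from the perspective of the Hong Kong public
healthcare provider.

The package is aimed at health-economics and HTA analysts who want a fully
scriptable, testable version of this class of model: every input, structural
choice and analysis step that usually lives inside a TreeAge worksheet is an
inspectable Python object here.

## The model

A three-state Markov cohort model — progression-free survival (PFS),
progressed disease (PD), death — with monthly cycles over a 10-year horizon.
The whole cohort enters in PFS. For the chemotherapy reference arm, monthly
transition probabilities come from Weibull curves fitted to trial
Kaplan-Meier data, S(t) = exp(−λt^γ), via the discrete-time hazard

    P(t) = 1 − S(t)/S(t−1) = 1 − exp(λ(t−1)^γ − λt^γ).

TKI arms rescale the monthly odds of *remaining* event-free by the
treatment's odds ratio from a network meta-analysis (OR > 1 lengthens
survival). Death draws on the overall-survival curve and applies to PFS and
PD occupants alike; progression applies to PFS occupants surviving the
cycle. Costs (EGFR test, monthly therapy, follow-up, palliative care,
serious-adverse-event episodes) and utility-weighted life-time (QALYs,
u_PFS = 0.80, u_PD = 0.56, SAE disutilities) are accumulated per cycle and
discounted at 3% per annum. A mutation-guided strategy is the
prevalence-weighted (50.1%) mixture of the TKI and chemotherapy arms plus
the one-time test cost.

Analyses on top of the engine: strict-dominance frontier, ICERs versus the
common comparator and along the frontier, net-monetary-benefit decision rule
at the WTP threshold of 143,436 USD/QALY (3× Hong Kong GDP per capita),
one-way sensitivity analysis with bisection threshold search, and a
10,000-draw probabilistic sensitivity analysis (Beta/Triangular input
distributions, common random draws across arms) with cost-effectiveness
acceptability curves. A synthetic individual-patient-data module emulates
the upstream survival-input pipeline (Weibull sampling → Kaplan-Meier →
Weibull re-fit → odds-ratio recovery) so the whole chain is testable.

## Worked example

```python
import nsclc_cea as nc

params = nc.default_parameters()          # packaged base-case inputs
outcomes = {s: nc.evaluate_strategy(s, params) for s in nc.STRATEGIES}
print(nc.outcomes_frame(outcomes).round(4))
print(nc.dominance_frontier(outcomes).frontier)
print(nc.preferred_strategy(outcomes, nc.WTP_3X_GDP))
```

prints

```
                        cost    qaly  pfs_months  os_months
strategy
empirical         21425.2184  1.5916      8.1757    32.4696
guided_afatinib   34418.8690  1.7816     15.6484    33.6276
guided_erlotinib  18500.7894  1.7507     14.6631    33.3164
guided_gefitinib  25236.0504  1.5973     13.3571    30.2354
['guided_erlotinib', 'guided_afatinib']
guided_erlotinib
```

Guided erlotinib yields more QALYs at lower cost than empirical
chemotherapy (which it therefore dominates, along with guided gefitinib);
guided afatinib adds 0.031 QALYs over erlotinib at an ICER of about 517,000
USD/QALY — far above the willingness-to-pay threshold — so guided erlotinib
is the preferred strategy. A probabilistic run:

```python
psa = nc.run_psa(params, n_sims=10_000, seed=nc.DEFAULT_SEED)
print(nc.pairwise_acceptance(psa, "guided_erlotinib", "empirical", nc.WTP_3X_GDP))
print(nc.acceptability_curves(psa, [nc.WTP_1X_GDP, nc.WTP_3X_GDP]).round(3))
```

```
0.9689
          empirical  guided_afatinib  guided_erlotinib  guided_gefitinib
wtp
47812.0       0.012            0.005             0.981             0.002
143436.0      0.001            0.305             0.670             0.023
```

i.e. guided erlotinib is cost-effective versus empirical chemotherapy in
~97% of draws and carries the highest acceptability over the whole 1×–3×
GDP WTP range.

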