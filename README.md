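# mucea

Cost-effectiveness analysis of maintenance immunotherapy (avelumab +
best supportive care vs best supportive care alone) for advanced or
metastatic urothelial carcinoma, rebuilt as a tested, reusable Python
pipeline.  It is aimed at health-economics researchers who want each
stage of a published Markov cohort analysis — curve reconstruction,
survival extrapolation, state-transition modelling, incremental
cost-effectiveness statistics and sensitivity analysis — as an
inspectable, swappable component rather than a spreadsheet or TreeAge
model.

## What it computes

1. **Pseudo individual patient data (IPD)** from digitized Kaplan-Meier
   coordinates and numbers-at-risk tables, by deterministic Guyot-style
   interval balancing; a product-limit estimator validates every
   reconstruction by round-trip (`mucea.km_ipd`).
2. **Weibull survival fits** in the cumulative-hazard form H(t) = λt^γ,
   by right-censored maximum likelihood with analytic gradients.  The
   per-cycle transition probability is the published formula
   P(t → t+1) = 1 − exp[λt^γ − λ(t+1)^γ] (`mucea.parametric_survival`).
3. **A three-state Markov cohort model** over {progression-free (PFS),
   progressed disease (PD), death} with monthly cycles over a 10-year
   horizon.  PFS→death uses age-dependent background mortality from a
   life table; PFS→PD is the Weibull PFS exit net of background death;
   PD→death follows the OS fit's conditional probability
   (`mucea.markov_engine`, `mucea.lifetable`).
4. **Discounted costs and QALYs** per arm under an explicit cost-timing
   schedule, then ΔC, ΔE, ICER = ΔC/ΔE and net monetary benefit
   NMB = WTP·E − C (`mucea.economics`).
5. **Sensitivity analysis**: one-way DSA with tornado ordering, and a
   probabilistic SA with beta-distributed utilities and
   gamma-distributed costs moment-matched to the published ranges,
   summarized as cost-effectiveness acceptability curves
   (`mucea.sensitivity`).

Because no patient-level data are public, `mucea.synthetic_data`
generates every input from known ground truth — Weibull event times
calibrated to the trial's printed median survival (OS 21.4/14.3 months,
PFS 3.7/2.0 months; 350 patients per arm), an emulated digitization of
the resulting curves, and a Gompertz-shaped life table — so the entire
pipeline runs and is tested with no downloads.

## Worked example

```bash
mucea fixture --seed 1 --out demo/inputs      # synthetic trial bundle
mucea run --inputs demo/inputs --out demo/results
```

prints (one line per country × population scenario):

```
China/PD-L1-positive: ICER 616,198.31 USD/QALY (not cost-effective at WTP 30,447.09)
China/overall: ICER 950,807.57 USD/QALY (not cost-effective at WTP 30,447.09)
US/PD-L1-positive: ICER 106,815.11 USD/QALY (cost-effective at WTP 150,000.00)
US/overall: ICER 156,333.83 USD/QALY (not cost-effective at WTP 150,000.00)
```

Each ICER is the incremental cost per QALY gained by the maintenance
arm over best supportive care, on this synthetic calibration; the
verdict compares it with the country's willingness-to-pay threshold
($150,000/QALY US, $30,447.09/QALY China).  The qualitative pattern of
the source analysis — far more favourable in the US and in the
PD-L1-positive population (cheaper drug price basis), far from
cost-effective in China at the Hong-Kong drug price — emerges directly.
Absolute totals depend on the synthetic survival calibration and on the
cost-timing conventions (see `docs/methods.md`), so they are model-scale
quantities, not reproductions of the published table.

```bash
mucea dsa --inputs demo/inputs --out demo/dsa          # tornado CSVs
mucea psa --inputs demo/inputs --out demo/psa --n-draws 1000 --seed 1
```

The PSA line for the US PD-L1-positive scenario, for example, reports
`P(cost-effective at WTP 150,000.00) = 0.994` — the CEAC height at the
threshold over 1,000 moment-matched parameter draws.

The same stages are available as library calls
(`mucea.pipeline.ScenarioModel` et al.) for use in notebooks.

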