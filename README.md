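# enclavoc

Joint social–environmental exposure analysis for pregnancy cohorts:
**ethnic-enclave residence × ambient volatile organic compound (VOC)
exposure and gestational diabetes mellitus (GDM) risk**.

The package is aimed at perinatal / environmental epidemiologists who want
to run — or stress-test on fully synthetic data — an analysis in which a
social exposure (residence in an ethnic enclave) and an environmental
exposure (high ambient VOC concentration) are crossed into joint categories
and related to a binary pregnancy outcome with hierarchical logistic
regression.

## What it computes

**Enclave classification.** Small-area (ZCTA-like) race/ethnicity counts
are aggregated to regions (HRR-like catchment areas) through a crosswalk,
and three region-level measures are computed per census period:

- API population density: (A_T / P_T) × 100
- API–White dissimilarity: ½ Σᵢ |wᵢ/W_T − aᵢ/A_T|
- API isolation: Σᵢ (aᵢ/A_T)(aᵢ/Pᵢ)

where aᵢ, wᵢ, Pᵢ are a unit's Asian/Pacific-Islander, White and total
counts and A_T, W_T, P_T the region totals.  A region is an **ethnic
enclave** when it sits at or above the 66.7th percentile of all three
measures simultaneously.

**Exposure windows.** Per-region VOC concentration series (ppb, 14
species) are averaged over the 91-day preconception window and the 91-day
first trimester, then dichotomised at the analytic sample's 75th
percentile per VOC per window (≥ cutoff = "high").

**Joint categories and inference.** VOC level × enclave residence gives
four categories (Low VOC/Enclave is the reference).  For each VOC and
window, GDM is modelled by a region-level random-intercept logistic
regression

  logit P(GDM᷈ᵢⱼ = 1 | bⱼ) = xᵢⱼ′β + bⱼ,  bⱼ ~ N(0, σ²)

adjusted for maternal age, marital status, insurance, BMI category,
parity, season of conception, hospital type and area-level poverty, fitted
by adaptive Gauss–Hermite quadrature.  BMI (42% missing) is multiply
imputed (m = 10) and pooled by Rubin's rules; standard errors are
cluster-robust on the mother (repeat births); Benjamini–Hochberg step-up
control at FDR q = 0.10 is applied per exposure window.  Sensitivity
analyses re-fit the enclave flag and each component tertile alone, and a
PCA-based "high multiple VOC" flag (high on *every* VOC in the first
principal component's high-loading block).

**Synthetic cohort.** `enclavoc.synthetic` generates the whole study shape
with known ground truth — nested geography with designated enclave-like
regions, ~9 000 births to ~8 350 mothers (7.9% repeat births), 14
log-normal VOC series with a correlated traffic/fuel block (ρ = 0.9), and
GDM drawn from the logistic model above with configurable true odds
ratios — so every stage is testable without any restricted data.

## Worked example

```sh
enclavoc simulate --seed 7 --out sim          # writes the 4 input CSVs + truth.json
enclavoc all --inputs sim --seed 7 --out run  # full pipeline, all reports
```

or, in Python:

```python
from enclavoc import GeneratorConfig, simulate, impute_bmi, fit_joint_model
from enclavoc.exposure import window_average_table, dichotomize_high

study = simulate(GeneratorConfig(vocs=("benzene",)), seed=3)
avg = window_average_table(study.exposure, study.cohort, "preconception",
                           vocs=["benzene"])
levels = dichotomize_high(avg, "benzene", "preconception")
datasets = impute_bmi(study.cohort, m=10, seed=3)
result = fit_joint_model(datasets, "benzene", "preconception", levels)
print(result.odds_ratios.round(3))
```

prints

```
                term     n     OR  ci_low  ci_high      p
0   LowVOC_NoEnclave  5523  1.150   0.716    1.849  0.563
1    HighVOC_Enclave   576  1.103   0.675    1.803  0.694
2  HighVOC_NoEnclave  1691  1.391   0.820    2.357  0.221
```

— the three adjusted odds ratios (with 95% CIs, MI-pooled, mother-clustered
robust SEs) for the non-reference joint categories versus Low VOC/Enclave.
With only 15 regions a single draw is noisy; the generating odds ratios
here were 1.5, 1.2 and 2.0, and the simulation suite shows the estimator
recovers them without bias over replicates.

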