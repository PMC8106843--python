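# Methods

## Segregation measures and enclave classification

Counts are two-group: Asian/Pacific-Islander (API) and White residents
enter the dissimilarity and isolation indices; residents of other groups
count toward unit and region populations only.  The isolation index uses
the *unit* population in its second factor, Σ (aᵢ/A_T)(aᵢ/Pᵢ): this is the
standard interaction-probability form and is the only form whose range is
[A_T/P_T, 1].  A variant using the region total (sometimes seen in printed
formula tables, unreachable at 1 for multi-unit regions) is available as
`isolation_index(..., region_denominator=True)` for comparability.

Tertile cutpoints are the 33.333rd/66.667th linear-interpolation sample
quantiles over the regions of one census period, each region counting
once.  A value equal to a cutpoint falls upward ("≥ 66th percentile" ⇒
high), so a degenerate distribution classifies everything high.
Population-weighted quantiles are available (`weights=` in
`classify_enclaves`) because "population-based percentiles" is ambiguous
in the literature this design follows; unweighted is the default.
Cutpoints are computed separately per census period (decennial census for
deliveries through 2004, 5-year ACS for 2005 onward), and each pregnancy
takes the enclave label of its region in the period of its delivery year.

## Exposure windows

Both windows are fixed at 91 days: preconception = [conception − 91 d,
conception − 1 d], first trimester = [conception, conception + 90 d]
("through 13 weeks").  When only delivery date and LMP-based gestational
length are known, conception = delivery − gestation + 14 d.  Window
averages weight every series point equally, so daily and hourly series
with the same step function give identical means; series must cover at
least one point per window or the operation errors rather than silently
extrapolating.

The high/low cutoff is the 75th linear-interpolation percentile of the
window averages pooled over the whole analytic sample, per VOC per window
(≥ cutoff = high).  Pooled — rather than per-region or per-period — because
the stratum sizes this convention produces (~25% high) match the reference
tabulations; the percentile and windows are configurable.

## Hierarchical model

Per VOC and window: logit P(GDM | b_region) = x′β + b, b ~ N(0, σ²), with
fixed effects for the three non-reference joint categories (reference Low
VOC/Enclave, the anticipated lowest-risk cell) and the shared adjustment
set (maternal age in years, marital status, insurance, BMI category,
parity, season of conception, hospital type, area-level poverty
proportion).

The marginal likelihood is maximised with adaptive Gauss–Hermite
quadrature (9 nodes by default; nodes centred and scaled at each region's
conditional posterior mode/curvature).  The fixed-node objective is
optimised by a damped Newton iteration: the fixed-effect Hessian block is
analytic (conditional information minus posterior score variance), the
log-σ row is finite-differenced, and negative-curvature directions are
flipped (saddle-free modification) because the frozen-node objective can
be locally concave in log σ away from the adaptation point.  Adaptation is
refreshed until the log-likelihood changes by < 1e-8 (relative).  log σ is
bounded in [log 1e-8, log 10]; a boundary solution is a legitimate
zero-variance fit and reproduces plain logistic ML to ~1e-12.  Coefficients
larger than 20 in absolute value raise a separation error naming the
covariate.  The implementation agrees with lme4::glmer (nAGQ = 9) to ~1e-5
on coefficients and ~2e-5 on σ on a frozen reference fit.

**Variances.** Model-based covariance: inverse observed information of the
marginal likelihood (fixed-effect block).  Robust covariance: cluster
sandwich on the mother, conditional on the fitted σ — per-mother scores are
the posterior-expected conditional scores Σⱼ xⱼ(yⱼ − p̄ⱼ), which sum
exactly to the region-level marginal scores; the bread is the model-based
covariance.  With σ → 0 and singleton mothers this is exactly HC0.  In a
60-replicate pilot at the recovery design the mean robust SE matched the
empirical SD of the estimates and 95% CI coverage was 0.93–0.98.

## Multiple imputation

BMI enters as four clinical categories (<18.5, 18.5–24.9, 25–29.9, ≥30).
Missing categories (≈42%, treated as MCAR in the generator) are imputed
m = 10 times from a multinomial logistic model on age, parity, insurance
and marital status.  Each imputation refits the model on a bootstrap
resample of the complete cases before drawing, so parameter uncertainty
propagates into the between-imputation variance (approximately proper MI).
If a bootstrap sample is quasi-separated the fit falls back from Newton to
BFGS and, failing that, to the bootstrap marginal frequencies for the
affected rows.  Pooling is Rubin's rules with the classic
(m−1)(1 + ūm/((m+1)B))² degrees of freedom and t-based CIs; with zero
between-imputation variance the pooled result equals the single fit.

## FDR and sensitivity analyses

Benjamini–Hochberg step-up at q = 0.10, applied per exposure window to the
family of all contrast p-values (3 per VOC × all VOCs; 42 p-values per
window at the full species list).  The family definition is configurable
(`fdr_q`, window families) since reasonable alternatives exist.

Component models: binary enclave (non-enclave reference) and each measure's
tertiles (low reference), adjusted for the shared covariates plus
dichotomised preconception and first-trimester benzene, fitted separately
(the alternative — one model with all component terms jointly — is noted
but not the default, matching the separate-models description of the
procedure this mirrors).

High-multiple-VOC: PCA on the standardised pregnancies × VOC window-average
matrix; loadings are reported on the variable–component correlation scale
(eigenvector × singular value / √(n−1)), so the default threshold 0.4 is
meaningful regardless of block size — a 7-variable equal block's raw
eigenvector entries cap at 1/√7 ≈ 0.378, which would make any raw-loading
threshold ≥ 0.38 unusable.  A pregnancy is flagged only if high on *every*
selected VOC; categories are rebuilt against a Not-High/Enclave reference.

## Synthetic-data generator

Defaults emulate the study shape: 15 regions (5 designated enclave-like),
40 area units per region, 8 350 mothers with 7.9% of births being repeat
births (≈9 066 births), deliveries 2002–2008 linked to two census periods,
14 VOC series, GDM prevalence calibrated to 9.9%.

- **Geography.** Unit populations are log-normal (median ≈ 11 000).
  Region API share is drawn from (0.25, 0.40) for enclave-like regions and
  (0.02, 0.12) otherwise; unit-level API shares follow a Beta distribution
  whose concentration is low (0.8) in enclave-like regions — clustering
  API residents into few units, which raises dissimilarity and isolation —
  and high (50) elsewhere.  ACS-period counts are the census counts with
  5% log-normal drift.  Designated regions land in the classifier's top
  tertile of all three measures in >90% of seeds; the *classifier's*
  labels, not the designation, feed the outcome model.
- **Exposure.** Daily log-normal series: per-VOC log-means at typical
  urban ppb levels, day-to-day log-SD 0.5, between-region log-SD 0.3, a
  shared winter-peaking seasonal cycle (amplitude 0.2 in log) for the
  seven traffic/fuel VOCs (benzene, ethylbenzene, toluene, the xylenes,
  n-hexane) and spread-out phases for the rest; cross-VOC correlation 0.9
  within the block and 0.1 outside, applied to both the daily noise and
  the region offsets.  Window-average Spearman correlations reproduce this
  block structure within ±0.1.
- **Covariates.** Categorical distributions follow the reference cohort's
  marginals (marital status 84/14/2, insurance 70/14/2/14, parity 49/51,
  BMI 12/66/14/8 with 42% MCAR missingness, hospital type 41/55/5 drawn per
  mother — multiple hospitals can share a region, so type varies within
  region and every stratum stays populated).
  Effects enter centred (age at 29.5 y, poverty at its region mean,
  reference categories at zero), so with all effects zero the prevalence
  equals expit(baseline).
- **Outcome.** logit p = baseline + covariate effects + joint-category
  log-OR + region intercept.  True joint-category ORs default to 1.5 (Low
  VOC/No Enclave), 1.2 (High VOC/Enclave), 2.0 (High VOC/No Enclave) with
  region SD 0.3.  The joint category is computed by running the *pipeline's
  own* classifier and dichotomiser on the generated data before the outcome
  draw, so label reconstruction is exact and recovery tests isolate the
  inference machinery.  baseline = −3.01 was calibrated by simulation to
  give 9.9% prevalence under the default effects.

**What the generator does not emulate:** real spatial autocorrelation of
pollution fields, exposure measurement error (the analysis sees the same
series the outcome was generated from), residential mobility, ancestry
heterogeneity within the API group, outcome misclassification, and
informative (non-MCAR) BMI missingness.  Passing recovery tests therefore
demonstrate the correctness of the estimation machinery under the stated
model, not robustness to these real-data features.

## Problem sizes

Tests and the acceptance script use: the full default cohort (~9 066
births, 14 VOCs, 28 MI(10) models) for the end-to-end run; 40 regions ×
~5 400 births × 200 replicates for odds-ratio recovery (single VOC — the
generating category depends on one VOC, so the other 13 add cost without
information); and reduced 9-region/2-VOC configurations for smoke and
determinism checks, where scientific content is not at stake.

## Known limitations

- The mother-level cluster sandwich is conditional on the fitted σ and the
  region posterior; with very few regions (≪ 40) between-region
  uncertainty in region-level contrasts is the dominant error term and CI
  calibration degrades (as it would for any of the standard choices).
- The BH family is per window across VOCs; because the same pregnancies
  appear in every VOC's model the tests are strongly dependent — BH remains
  valid under PRDS but can be conservative.
- Imputation treats BMI as MCAR given the model covariates; MNAR
  missingness would bias the BMI coefficients (though typically not the
  exposure contrasts).
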