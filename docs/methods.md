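# Methods

## Cross-study harmonization

Each study enters as a probe × sample matrix of log-scale intensities (the
package never re-logs; linear-scale input is a contract violation).  Genes
measured by several probes are collapsed to the probe with the **maximum
mean intensity** across the study's samples; ties are broken by the
lexicographically smallest probe id and logged.  Each gene row is then
standardized **within its study** to mean 0 and sample SD 1 (n−1
denominator throughout, so the two standardization rounds and the z-score
definition agree); zero-variance rows carry no ranking information and are
dropped with a warning.  Studies are pooled by gene symbol as a **union**:
a gene absent from one platform is missing (NaN) for that study's samples
and excluded from that gene's pooled mean/SD and from downstream signature
averages.  The union-with-mask choice (rather than intersecting gene
universes) keeps platform-restricted isoforms analyzable on the platforms
that carry them; it is a documented divergence risk for exact reproduction
of analyses that may have restricted to common genes.  The pooled matrix is
re-standardized per gene, yielding z-scores comparable across genes and
patients.

Two consequences are used as invariants: any per-study gene-wise affine
transform x → a·x + b (a > 0) of the raw values leaves the harmonized
matrix unchanged (batch-effect immunity by construction, not correction),
and re-running the harmonization on its own output reproduces it, because
both standardization rounds are themselves affine.

## Signatures and stratification

A signature score is the arithmetic mean of a sample's z-scores over a
fixed gene set; genes missing for a sample are left out of its mean (with
`n_genes_used` recorded).  Built-ins: the three CA localization groups and
a chronic-inflammation panel (IL1A, IL1B, IL4, IL6, NFKB1, STAT3, CXCL2).
CD45 is looked up under its HGNC symbol PTPRC with the CD45 alias accepted.

Stratification uses strict inequalities, so boundary values need a
decision: `binary0` assigns z = 0 to `excluded` and `tertile025` assigns
z = ±0.25 to `moderate` (both logged).  With continuous scores these are
measure-zero events; the choices only matter for degenerate inputs.
`classify_extremes` selects discordant infiltration/inflammation corners by
marginal quantiles with configurable q (default 0.25).  The published
analysis reports extreme-group sizes but not its cut rule, so q is
explicitly a tunable, not a reproduction of that rule.

## Survival statistics

All estimators are implemented from first principles; lifelines appears
only as an independent oracle in the test suite.

* **Kaplan–Meier**: S(t) = Π_{t_i ≤ t} (1 − d_i/n_i).  Subjects censored at
  an event time remain at risk for that time (censoring after events at
  ties).
* **Weighted log-rank**: at each pooled event time the observed per-group
  events are compared with the hypergeometric expectation; weights w_j = 1
  (Mantel–Cox) or w_j = n_j (Gehan–Breslow–Wilcoxon).  The two-group
  statistic is (Σ w_j(d_Aj − E_Aj))²/Σ w_j²V_j; k > 2 groups use the
  multivariate hypergeometric covariance with df = k−1 (the k-group form
  exists so the trend test can be compared against the heterogeneity test).
* **Trend test**: score-weighted observed-minus-expected sum over ordered
  groups (default centered equally spaced scores, −1/0/+1 for three), χ²
  with 1 df.
* **Hazard ratio**: default is the one-parameter Cox partial likelihood
  with **Efron** tie handling, maximized by Newton–Raphson to |Δβ| <
  1e−10 (risk-set sums via suffix sums, O(n) per step); the
  Mantel–Haenszel (O_A/E_A)/(O_B/E_B) estimator with se = √(1/E_A + 1/E_B)
  is retained for cross-checks.  The Cox default matches the convention of
  the public Kaplan–Meier plotting services the cohorts come from; the
  source analysis does not state its estimator.  CIs are 95%
  normal-approximation intervals on log HR; p-values are two-sided from χ².
  Where three strata exist the reported HR compares high vs low; no
  multiplicity adjustment is applied in this module.

Out of scope by design: multivariable Cox, time-varying covariates,
competing risks.

## pH physiology

Ratio→pH calibration is linear least squares (sigmoidal calibration is out
of scope); the round trip ratio→pH→ratio is exact.  Intrinsic buffering
uses the NH₄Cl washout in CO₂-free solution, assuming transmembrane NH₃
equilibrium: [NH₄⁺]ₒ = NH₄Cl/(1+10^(pHₒ−pKa)) with pKa 8.9 at 37 °C
(configurable; the source omits it), [NH₄⁺]ᵢ = [NH₄⁺]ₒ·10^(pHₒ−pHᵢ), and
β_i = [NH₄⁺]ᵢ(plateau)/ΔpHᵢ.  The plateau is the mean of the final 10 s of
the NH₄ epoch; the nadir is the minimum of a 5-s rolling-mean-smoothed
washout segment — smoothing prevents photometric noise from biasing the
minimum downward.  A single β_i value is the default; a callable β_i(pHᵢ)
is accepted for piecewise estimates.  Bicarbonate buffering is the
open-system β = 2.3·[HCO₃⁻]ᵢ with [HCO₃⁻]ᵢ = [HCO₃⁻]ₒ·10^(pHᵢ−pHₒ)
(transmembrane CO₂ equilibration; the source states the β formula but not
the [HCO₃⁻]ᵢ estimate).

Net acid extrusion divides the recovery segment into fixed pHᵢ bins
(default 0.05) and multiplies the within-bin least-squares recovery slope
by β_total(pHᵢ) at the bin center.  Bin membership is decided on a smoothed
copy of the trace while slopes are fit on raw values; selecting on noisy pH
would otherwise attenuate the slope (regression dilution).  Bins with fewer
than 3 samples are skipped.  Edge bins are only partially traversed and
systematically under-sampled on one side; quantitative comparisons should
use interior bins, which is what the tests and the acceptance script do.
The Na⁺-dependent component is the per-bin difference of fluxes measured
with and without bath Na⁺ on common bins.  The CO₂-hydration rate is the
steepest negative sliding-window slope (default 5 s) after CO₂ addition,
reported positive.

## Tumor growth

V = π/6·W²·L in µL after subtracting the 2-mm skin thickness from each
caliper dimension; dimensions at or below skin thickness clamp the volume
to zero with a warning (a palpable but sub-threshold tumor), rather than
erroring.  Growth curves are second-order polynomials fit to all pooled
measurements of an arm (a per-animal option exists; the source does not
state which was used) and compared by the extra sum-of-squares F-test of
the pooled single-curve fit against separate fits: F = ((SS_p −
SS_s)/3)/(SS_s/df_s), p from F(3, df_s).  The pooled model shares all three
coefficients; per-coefficient tests are not implemented.

## Synthetic data

The generators define the package's study conditions; all randomness flows
through one PCG64 generator so a config and seed reproduce outputs
bit-for-bit.

* **Expression**: 3 studies × 200 samples over ~30 genes (all signature
  genes, PTPRC, housekeeping fillers).  Gene-level latent values are
  subtype mean shifts plus correlated noise (within-signature correlation ρ
  = 0.5, mirroring the co-regulation that makes signature averaging
  denoise); probes add an offset and noise; per-study gene-wise affine
  batch effects (scale 0.5–2, shift ±2) are applied to the complete
  observed value.  Subtype proportions 45/20/15/20% (Luminal A/Luminal
  B/HER2-enriched/Basal-like) approximate clinical prevalence.  The random
  stream is consumed identically with batch effects on or off, which is
  what makes the invariance check exact.
* **Survival**: exponential baseline hazard 0.02/month (median ~35 months
  at score 0, a plausible recurrence scale), log-hazard linear in the true
  signature score (default 0: null), censoring min(U(0, 160), 120) months —
  roughly 30% censoring in the two-arm recovery setting.  Exponential
  rather than Weibull keeps closed-form checks; proportional hazards holds
  by construction.
* **pH traces**: 10 Hz sampling, pH noise SD 0.005.  The washout step is
  computed from the same buffering algebra the estimator inverts (β_i = 95
  mM/pH, 20 mM NH₄Cl, plateau pH 7.1 → nadir ≈ 6.69), and the recovery
  integrates dpH/dt = J(pH)/β with J linear in (pH_eq − pH) (Na-dependent
  slope 10, Na-independent 1.5 mM·min⁻¹·pH⁻¹, pH_eq 7.35).  These values
  put the per-bin slope standard error near 2% against the 5% round-trip
  tolerance.  The CO₂ assay is a saturating exponential (amplitude 0.6 pH,
  rate 0.005 s⁻¹) with SD 0.0005 noise, as appropriate for a cuvette
  electrode trace.
* **Growth**: 17 animals/arm, twice-weekly caliper days over 4 weeks,
  quadratic volume curves (treated arm with larger curvature), noise SD 30
  µL; volumes are inverted to W = L caliper pairs with the skin re-added so
  the volume formula round-trips exactly at zero noise.

What the generators deliberately do **not** emulate: platform-specific
probe chemistry, real GEO intensity distributions, non-proportional
hazards, informative censoring, and intra-tumor measurement correlation.
Passing tests therefore demonstrate correctness of the estimators under
the stated model, not robustness to those real-data features.

## Problem sizes

The simulation studies use 200 cohorts of 2000/arm for log-HR recovery,
2000 replicates for each type-I-error estimate, and 100 pipeline runs
(600 patients each) for null CI coverage — sizes at which the binomial
margins quoted in the tests are meaningful while the whole suite stays
fast.

## Known limitations

* The external full-cohort hazard ratios cannot be recomputed here; they
  are registered in `casurv.validation` for a rerun with patient-level
  data, and the synthetic cohorts make no attempt to match their values.
* The flux estimator's edge bins are biased by partial traversal (see
  above); they are reported but flagged by position.
* The Mantel–Haenszel HR is slightly biased toward the null for strong
  effects; the Cox estimator is the default for that reason.
* PAM50 subtype labels are inputs; the classifier itself is out of scope.
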