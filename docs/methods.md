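# Methods

This note documents the models, conventions, defaults and known limitations
of `mrpd`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Harmonisation (`mrpd.summary_io`)

Exposure and outcome summary statistics are matched by rsID (proxies are
substituted by the caller via an explicit `proxy_map`; no LD-reference lookup
is performed). Allele handling:

- Alleles are normalised to uppercase single bases; indels are rejected —
  the instrument panels this package targets are SNP-only.
- If the outcome's allele pair equals the exposure's (directly or as a
  strand complement), betas are taken as-is; if it is the swapped pair, the
  outcome beta's sign is flipped and its allele frequency complemented.
  Any other pair is excluded with reason `allele mismatch`.
- **Palindromic variants** (A/T, C/G) are strand-ambiguous: allele identity
  cannot distinguish "same allele" from "opposite allele on the other
  strand". Policy `drop` removes them; the default `frequency_check` keeps
  them when both studies' frequencies are informative, i.e. outside the
  window **[0.42, 0.58]** around 0.5. Within the window the variant is
  excluded. When both frequencies are informative but disagree about which
  allele is the minor one, the orientation is flipped — that is precisely
  what comparing allele frequencies between datasets is for. The window
  bounds are a design choice (no standard exists); 0.42–0.58 is tight enough
  to keep the packaged panel's palindromes (frequencies 0.409, 0.154, 0.638,
  0.403) and wide enough to catch genuinely ambiguous variants.
- `harmonise` returns a result object carrying the harmonised variants plus
  per-variant exclusion reasons and the unmatched list, so that
  matched + excluded + unmatched always equals the input count.

The packaged fixture (`data/table1.tsv`, loaded by `load_fixture_table1`) is
a 77-variant BMI instrument panel already expressed on the BMI-raising
study's effect alleles: per-allele BMI effects on a 5-kg/m² scale with their
SEs and allele frequencies, and per-allele PD log-ORs with SEs. rs887912 is
recorded as standing proxy for rs1016287. Coordinates are 1-based.

## Clumping (`mrpd.clumping`)

Greedy p-value-ranked clumping with defaults p < 5×10⁻⁸, r² ≥ 0.001,
window 10,000 kb. A candidate is absorbed into an existing index SNP's clump
only if it is **both** within the window on the same chromosome **and** at
r² at or above the threshold; variants merely nearby but in linkage
equilibrium stay candidates, and cross-chromosome LD entries are ignored.
Ties in p are broken lexicographically by rsID so the output is independent
of input row order. LD is an input (3-column table; absent pairs are r² = 0):
computing LD from a reference panel is out of scope, though a test helper
computes dosage-correlation r² from a small genotype matrix.

## Estimators (`mrpd.estimators`)

`IVWRegression` and `EggerRegression` are scikit-learn-style estimators
(`fit(X, y, sample_weight)` with X the exposure betas and weights 1/σ²);
`ivw`, `mr_egger`, `leave_one_out`, `funnel_data` wrap them for lists of
harmonised variants. Numerical conventions, all surfaced as parameters:

- **Wald SEs are first-order** (σ_Y/|β_ZX|): exposure-side uncertainty is
  ignored, consistent with the weighting used in the pooled fits.
- **SE model.** `fixed` reports the fixed-effect (known-variance) SE.
  The default `multiplicative` inflates it by max(1, √(Q/df)) (IVW) or
  max(1, σ̂) with σ̂² the weighted residual mean square on k−2 df (Egger).
  The floor at 1 is the conventional choice that never reports an SE below
  the fixed-effect one; the published intervals this package reproduces are
  consistent with the floored multiplicative convention.
- **Egger orientation.** Variants are re-oriented so every exposure beta is
  positive (flipping both betas leaves the Wald ratio unchanged); without a
  consistent orientation the intercept has no meaning. A design with no
  variation in β_ZX after orientation is rejected as collinear.
- **Reference distributions.** CIs and p-values use normal quantiles by
  default; Egger optionally uses t with k−2 df (`p_reference="t"`). The Q
  p-value uses χ² with k−1 df. I² is reported as max(0, (Q−df)/Q).
- Degenerate inputs fail loudly: k < 2 (IVW), k < 3 (Egger, leave-one-out),
  any β_ZX = 0, non-positive weights.

## Instrument strength and power (`mrpd.instrument_metrics`)

R² assumes exposure betas on an (approximately) unit-variance scale and
independent variants; no rescaling by an assumed BMI SD is applied. The
F statistic is the closed form above. Power uses Brion's binary-outcome
non-centrality approximation exactly as stated in the README; the
second-order variance correction (subtracting b²) is omitted as negligible
at these designs. Note the approximation's literal limit at OR = 1 is α/2,
not α.

## Synthetic data (`mrpd.synthetic`)

`generate_two_sample` draws β_ZX,j ~ U(0.015, 0.081) (the magnitude range of
the packaged panel), frequencies U(0.05, 0.95), and exposure SEs from a
nominal sample size of 339,224, then sets

    β_ZY,j = θ β_ZX,j + α_j + e_j,  e_j ~ N(0, se_zy_level²)

with `se_zy_level` defaulting to 0.018 (the packaged panel's median outcome
SE) and reported outcome SEs equal to it — so with no pleiotropy Q/df is
calibrated to mean ≈ 1 by construction. Pleiotropy α_j is 0 (`none`),
N(0, s) (`balanced`) or N(s, s/2) (`directional`, s = `pleiotropy_scale`),
always drawn independently of β_ZX so InSIDE holds. What this generator does
*not* emulate: LD between variants, winner's curse in instrument selection,
allele-frequency-dependent outcome SEs, or exposure-side estimation error
feeding the estimator (the estimator ignores it by design). Recovery tests
therefore validate estimator algebra and calibration, not robustness to
those real-data features.

## Frailty simulation (`mrpd.frailty`)

Per replicate: genotypes at the panel frequencies (Hardy–Weinberg, two
binomial allele draws); BMI in SD units as genotype score plus Gaussian
noise with total variance 1 and mean 0; ages from a binned distribution;
a single cross-sectional alive/dead draw with probability
1 − exp(−H(a)·exp(γ·BMI)) where H is the Gompertz–Makeham cumulative hazard
H(a) = λa + (α/β)(e^{βa} − 1) (analytic limit λa + αa at β = 0); PD status
drawn from an age-binned rate table, independent of BMI given age; surviving
cases and controls sampled (simple random, or stratified to target age
distributions with largest-remainder apportionment); per-SNP PD log-ORs by
single-variant logistic regression on dosage (vectorised Newton on the 2×3
case-status × dosage tables, cross-checked against statsmodels in tests);
IVW and Egger on those with the panel betas as β_ZX; observational estimate
by logistic regression of PD on BMI. Estimates are converted from per-SD to
per-5-kg/m² using `bmi_sd_kgm2` (default 4.77 kg/m² per SD).

Defaults (all user-visible config, since the mortality/rate calibrations are
not published with the analysis this package re-implements): cohort 500,000;
ages uniform over 5-year bins 40–90; Makeham λ = 0.001/yr, Gompertz slope
β = 0.09/yr, Gompertz scale α solved in closed form so cumulative mortality
by age 70 is 0.2 at average BMI; mortality hazard ratio e^γ = 1.15 per SD of
BMI; PD diagnosis probability 0.006 below age 50 rising log-linearly
ten-fold from 0.012 at 50 to ≈0.12 at 85; 13,708 cases and 95,282 controls;
1,000 replicates. With these, the induced (purely selection-driven) MR
effect is a modest protective bias — a plausibility statement, not a
calibrated reproduction, because the original mortality and age inputs are
not available.

Two numerical choices deserve note. Replicate summaries report **geometric
means** of the odds ratios (means on the log-odds scale, exponentiated):
with noisy per-replicate estimates the arithmetic mean of exp(β̂) is
Jensen-inflated and would masquerade as upward bias in a null study.
Replicate seeds are spawned from a single `SeedSequence`, so runs are
deterministic end-to-end given the config seed.

The simulation-based checks in the test suite run at scaled sizes chosen to
keep the whole study to minutes on one CPU: 50,000 individuals per cohort,
600 cases / 6,000 controls per replicate with age-stratified targets (cases
65–90, weighted towards older bins; controls 40–65), 100 null replicates,
and 50 replicates per hazard level in the monotonicity sweep over mortality
hazard ratios 1.2, 1.7 and 2.4 per SD of BMI. The sweep reuses one seed
across hazard levels (common random numbers), a standard variance-reduction
device for paired monotonicity comparisons. The stratified age gap makes the
selection mechanism strong enough to measure at these sizes; at the
full-scale defaults the same mechanism produces a smaller bias.

## Known limitations

- No weighted-median/mode estimators, multivariable MR or Steiger filtering.
- No liftover, strand inference from a reference genome, or remote proxy
  search; LD is always an input.
- The frailty model is cross-sectional (one mortality draw at current age):
  no longitudinal follow-up, competing risks or time-varying BMI.
- Power and R² formulas assume independent variants and unit-variance
  exposure scaling; both are approximations for real panels.
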