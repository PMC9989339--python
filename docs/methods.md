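# Methods

## Measurement model and data reduction

A multi-collector ICP-MS session is an ordered run of acquisition blocks,
each recording per-cycle Faraday-cup intensities (volts) at masses 42, 43,
43.5 and 44 (40 cycles per block by default). Mass 43.5 carries no calcium
isotope; it monitors ⁸⁷Sr²⁺ and hence the presence of ⁸⁶Sr²⁺/⁸⁸Sr²⁺
isobaric interference on ⁴³Ca and ⁴⁴Ca. Session structure is invariant:
an instrument blank precedes every standard and sample block, and every
sample is bracketed by a standard before and after it in run order.

Reduction proceeds per sample:

1. **Blank subtraction.** The nearest preceding blank block's per-mass mean
   intensity is subtracted from every cycle of the sample and of its
   bracketing standards. Negative corrected intensities are retained and
   flagged, never clamped, so the reduction stays linear in the input.
2. **Ratio summaries.** Per-cycle 44/42, 43/42 and 43.5/44 ratios are
   averaged per block; cycle scatter is reported as 2× the population
   standard deviation of the per-cycle per-mille deviations from the block
   mean.
3. **Bracketed deltas.** δ = (R_sample / R_std − 1) × 1000 ‰, where R_std is
   the arithmetic mean of the before/after standard ratios. The mean is the
   minimal bracketing convention and cancels drift that is symmetric about
   the sample; a linear-in-run-index interpolation is available behind the
   `bracketing: linear` configuration switch. Because any constant
   exponential-law mass bias multiplies sample and standard ratios by the
   same factor, bracketing removes it exactly — the noise-free round trip is
   exact to floating-point precision for any constant β and blank level.
4. **Internal precision.** 2·sd/√n of the per-cycle bracketed 44/42 deltas.

### Quality control

Four filters, each with its threshold in configuration (defaults in
parentheses); an analysis is accepted only if all four pass, and rejected
analyses are emitted flagged, never dropped:

* **Interference** (1e-5): fail if the blank-corrected 43.5/44 ratio
  strictly exceeds the threshold. No interference correction is ever
  applied; the screen only rejects.
* **Intensity match** (10%): fail if the sample's mean ⁴⁴Ca intensity
  deviates from the mean of the two bracketing standards' ⁴⁴Ca intensities
  by more than the threshold. The bracket mean (rather than the preceding
  standard alone) is used because the delta itself is computed against the
  bracket mean.
* **Mass-bias-factor spread** (0.1): the exponential (kinetic) law
  R_measured = R_true · (m_num/m_den)^(−β) is inverted for the 43/42, 44/42
  and 44/43 ratios against natural-abundance reference ratios
  (⁴⁴Ca/⁴²Ca = 3.224, ⁴³Ca/⁴²Ca = 0.2087; configurable) with atomic masses
  41.9586, 42.9588, 43.9555 u. Fail if 2× the sample standard deviation of
  the three factors exceeds the threshold. β is invariant under inverting a
  ratio pair, so the pair orientation is immaterial.
* **Mass dependence** (0.1‰): fail if |0.50667·δ⁴⁴/⁴² − δ⁴³/⁴²| exceeds the
  threshold. 0.50667 is (to the quoted precision) the exponential-law slope
  ln(m₄₃/m₄₂)/ln(m₄₄/m₄₂) = 0.506687 linking the two delta scales, so any
  purely mass-dependently fractionated analysis passes for any β, while a
  non-mass-dependent ⁴³Ca excess (interference, spike) fails. The statistic
  is the analysis-level absolute difference; a cycle-level variant (2·sd of
  the per-cycle paired values) sits behind `massdep_mode: cycle`.

Two deliberate asymmetries in the spread statistics: the cycle-scatter
summaries use the population standard deviation (they describe a fixed set
of cycles), while the mass-bias-factor spread uses the sample standard
deviation of the three factors. Both conventions are frozen by unit tests
against hand-computed values.

Optional per-block cycle trimming (2.5 sd on the 44/42 ratio) exists behind
a flag and is off by default: the reduction applies no outlier rejection
unless asked.

### Reference scales and concentrations

Delta values are measured against the in-house bracketing standard (the
"WIGL" scale) and converted to community scales by fixed additive offsets:
ICP Ca Lyon +0.009‰, ICP1 +0.277‰, NIST SRM 915a +0.527‰. Conversion
between any two scales is the offset difference — exact, associative and
invertible. Cohort-level serum/urine deltas are reported on the SRM 915a
scale.

Quadrupole ICP-MS calcium concentrations are obtained from an ordinary
least-squares calibration line (0.5–250 ng/g envelope) after dividing all
analyte counts by each measurement's internal-standard (⁴⁵Sc) counts
relative to the calibration-set mean, which removes slow instrument drift.
Values mapping outside the envelope are flagged, not clamped.

## Clinical reference standard

Intimal calcification is proxied by peripheral artery disease: ABI ≤ 0.9 or
ABI ≥ 1.3 (both bounds inclusive). The two-sided rule is the default; a
one-sided mode (ABI ≤ 0.9 only) reproduces summary tables that tabulate
"no PAD" as ABI > 0.9. Medial calcification (arteriosclerosis) is present
if ba-PWV ≥ 1800 cm/s (inclusive, age/sex-independent) or if ba-PWV strictly
exceeds 0.16·age² − 4.40·age + 977.52 cm/s (female) or
0.20·age² − 12.13·age + 1341.34 cm/s (male). Both classifiers are pure
functions; missing inputs propagate to missing calls, never imputed.

## Statistics

All test statistics are computed from their defining formulas; only the
reference distributions (F, χ², t) are taken from scipy. Group contrasts
use one-way ANOVA for variables flagged normal in configuration,
Kruskal–Wallis (with tie correction) otherwise, and Pearson χ² for
categorical variables — mirroring the mean±SD versus median[IQR] reporting
convention. Correlations are product-moment r with a t(n−2) p-value,
pairwise-complete; creatinine and FGF23 are log₁₀-transformed before
correlating. No multiple-testing correction is applied; α = 0.05.

Backward stepwise regression: candidates are screened univariably at
p < 0.2; the full model on the kept set is fitted by QR orthogonalisation;
then the single term whose removal yields the largest adjusted R² is removed
repeatedly, accepting a removal only when adjusted R² does not decrease (so
ties favour the smaller model). Rank-deficient candidate designs raise a
collinearity error naming the dependent terms. Listwise deletion over the
response and all candidates; the CKD group indicator is not a default
candidate because it is collinear with creatinine.

ROC analysis uses the strictly-greater decision rule (score > threshold →
positive), thresholds at −∞ plus every distinct score, and a trapezoidal
AUC computed from integer true/false-positive counts, which makes it exactly
equal to the Mann–Whitney pair-counting statistic (concordant + ½ ties over
n₊·n₋) — an equality the test suite verifies by exhaustive enumeration. The
operating cutoff maximises Youden's J = sensitivity + specificity − 1, with
ties broken toward higher specificity and then the higher threshold (the
conventional default of standard ROC software). AUC quality bands: ≥0.9
excellent, ≥0.8 very good, ≥0.7 good, ≥0.6 sufficient, ≥0.5 poor, below 0.5
not useful; boundaries go to the higher band.

## Synthetic data

**Sessions.** The generator emits the blank–standard–blank–sample–…–standard
layout with known ground truth echoed only into block metadata. Sample true
ratios are the reference ratios shifted by the requested δ⁴⁴/⁴², with
δ⁴³/⁴² = 0.506687·δ⁴⁴/⁴² (the exact exponential-law slope) plus any
non-mass-dependent ⁴³Ca spike; measured ratios add the exponential-law bias
(constant or drifting linearly over run index), independent per-cycle
relative ratio noise on each ratio, additive blank, and optional Sr signal
at mass 43.5 scaled to a target 43.5/44 ratio. Two knobs exist purely to
plant QC violations: a sample/standard beam-intensity mismatch factor, and a
pair-specific mass-bias offset on the 43/42 ratio applied to *all* blocks —
the latter perturbs the three mass-bias factors without touching the
bracketed deltas (bracketing cancels it), so the factor-spread rule can be
violated in isolation from the mass-dependence rule.

**Mass balance.** A steady-state box model: dietary calcium at δ_in leaves
the exchangeable (serum) pool through urine, net bone mineralisation and
vascular accretion with flux fractions summing to 1 and fixed per-route
offsets relative to serum (urine +1.2‰, bone −0.30‰, vessel mineral
defaulting to the bone value, since no vessel-specific fractionation has
been measured). Closed form: serum δ = δ_in − Σ fᵢΔᵢ; urine δ = serum δ +
Δ_urine. Flux-weighted outputs equal the input exactly (isotope mass
conservation, property-tested). The classic renal feedback emerges as the
special case f_urine = ½ with remodeling-neutral bone: serum δ = −0.6‰.

**Cohort.** Four groups (controls n = 28, mild–moderate CKD n = 9, dialysis
n = 22, transplant n = 19) with per-group parameters defaulting to the
published summary statistics: serum δ⁴⁴/⁴²Ca means/SDs of −0.70 ± 0.16,
−0.60 ± 0.14, 0.14 ± 0.24 and −0.47 ± 0.16‰; urine Ca 119 ± 86, 30 ± 38,
29 ± 20 and 31 ± 22 µg/g; ba-PWV 1227 ± 229, 1694 ± 264, 2050 ± 713 and
1585 ± 318 cm/s; arteriosclerosis prevalences 0.068/0.429/0.75/0.692.
Serum δ and ba-PWV are drawn jointly from a bivariate normal with a
configurable within-group correlation ρ (default 0.3 — the within-group
association is unknown, and no default claims to reproduce any real-data
AUC); urine Ca from a lognormal moment-matched to the stated mean and SD;
ages from normals truncated at 18. Variables published as median[IQR] are
approximated by normals with spread half-IQR/0.6745. Arteriosclerosis
labels are assigned either mechanistically (applying the ba-PWV classifier
to the drawn values) or marginally (Bernoulli at the stated prevalence,
the default, because the joint availability of PWV and serum δ per subject
is not published). One master seed expands into one child stream per group
via numpy SeedSequence spawning, making cohorts bit-reproducible.

What the generator does **not** emulate: within-subject repeat measurements,
diet- or medication-driven delta shifts, joint correlation structure among
the chemistry covariates beyond group membership, and real missingness
mechanisms (an optional mode blanks columns at the published per-variable
availability, independently at random). Passing calibration tests therefore
demonstrates that the pipeline recovers what it simulates — not that the
synthetic cohort reproduces real-cohort regression coefficients or
diagnostic accuracy.

## Problem sizes and numerical choices

The test suite uses 40-cycle blocks, 100-seed Monte-Carlo repeats for the
noisy reduction round trip (0.05‰ per-cycle noise → mean bias < 0.01‰),
1000-instance ROC oracle sweeps, 200-seed stepwise-recovery simulations, and
n = 10,000 per group for generator-calibration means; these sizes put the
Monte-Carlo error well inside each asserted tolerance while keeping the full
suite in seconds. Degenerate inputs are handled explicitly: identical value
multisets give ANOVA F = 0/p = 1; an all-tie Kruskal–Wallis returns H = 0;
zero-variance correlation inputs raise rather than return NaN; zero-sd
cohort groups are exactly degenerate.

## Known limitations

* The mass-bias QC factors are computed against natural-abundance reference
  ratios; a standard whose true composition differs from them shifts all
  three factors coherently (harmless for the spread statistic, but the
  absolute β values are nominal).
* Linear mass-bias drift is cancelled only to first order by mean
  bracketing; the residual curvature bias is second-order and covered by
  the Monte-Carlo tolerance, not eliminated.
* The stepwise procedure's exact-support recovery under the documented
  screen-then-adjusted-R² rule plateaus near 87% in the two-null benchmark
  (a null surviving both the p < 0.2 screen and the |t| > 1 removal
  criterion is retained ≈7% of the time), a property of the selection rule
  itself rather than of this implementation.
* No survival or longitudinal modelling, no imputation, no
  covariate-adjusted ROC, no double-spike or ⁴⁰Ca-based reduction schemes,
  and no vendor-format parsing (sessions must be pre-converted to the
  documented CSV schema).
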