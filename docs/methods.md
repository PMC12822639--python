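# Methods

## The problem and the data model

Chert-hosted fossils preserve organic matter as kerogenous residues whose
infrared absorption bands retain lineage-level information: chitin-bearing
organisms (fungi, arthropods, and convergently oomycetes and amoebae)
fossilize into sugar–protein products rich in amide I (~1655 cm⁻¹),
amide II (~1545 cm⁻¹), heteroatom N-products and carboxylate; bacterial
mats are comparatively rich in aliphatic CHₓ stretches (~2925/2960 cm⁻¹);
vascular plants and *Prototaxites* are depleted in both, the latter with a
distinct carbonyl/aromatic contribution. The package treats a spectrum as
a pair (ν, A) on a strictly ascending wavenumber grid with an append-only
preprocessing history, and a dataset as spectra on a shared grid with a
closed seven-class label vocabulary and a one-hot encoding.

## Synthetic-spectrum generator

Each spectrum is a sum of Gaussian bands (FWHM 20–40 cm⁻¹ by band), a
silica-overtone band at 1615 cm⁻¹ common to every class (all fossils are
chert-hosted), a random degree-2 baseline, and i.i.d. Gaussian noise.
Band heights are per-class means multiplied by a unit-mean lognormal
factor (coefficient of variation 0.10); band centers jitter by a normal
displacement (sd 0.5 cm⁻¹, realistic at 4 cm⁻¹ instrumental resolution);
noise sd is 0.02 absorbance units against a silica peak of ~1.2. Sample
`i` under master seed `s` uses the RNG stream `default_rng([s, i])`, so
any sample regenerates independently; everything is deterministic under
(design, profiles, seed).

The per-class mean levels are **artifact parameters, not measured
values**: they encode only the ordinal contrasts described above
(chitinous > others in the four protein bands; bacteria highest in CHₓ;
*Prototaxites* lowest in combined amide + aliphatic signal with nonzero
carbonyl) and were calibrated so that the full pipeline exercises its
acceptance behavior — class contrasts recoverable, screening power
against injected artifacts, coverage calibration. The generator emulates
the study *design* (per-class counts 37/24/12/10/4/3/12, total 102;
650–4000 cm⁻¹ at step 4), not the physics: no Mie/ATR optical artifacts,
no atmospheric lines, no diagenetic gradients, no spatial correlation
between acquisition spots. Passing tests therefore demonstrate that the
statistical machinery behaves correctly under the assumed data model —
they say nothing about how well real chert spectra satisfy it.

## Preprocessing choices

* Baseline: asymmetric least squares (λ = 1e5, p = 0.01, 10 iterations)
  by default — robust for broad chert backgrounds; rubberband (lower
  convex hull) as the alternative.
* "Light Gaussian smoothing" is quantified as sigma = 2 grid points.
* Truncation windows are closed intervals; with the 650–4000 step-4 grid
  the ATR windows retain 137 points (77 + 60).
* Silica normalization divides by the maximum within a [1585, 1645] cm⁻¹
  search window rather than the point value at 1615 cm⁻¹, since jitter
  moves the apex; the nominal peak is retained in the recipe metadata.
  The 1615 cm⁻¹ reference sits in the amide-I region; the procedure
  follows the established protocol without adjudicating the assignment.
* Savitzky–Golay derivatives require a uniform grid and are scaled by
  spacing^(−deriv); endpoint values rest on one-sided fits and are not
  used for derivative-based band picking.

## Multivariate exploration

PCA is mean-centered, never autoscaled (standard for spectra; band
features are standardized separately only for CCA). Component signs are
fixed by making the largest-magnitude loading entry positive, which makes
scores, loadings and bootstrap cosines reproducible. Bootstrap stability
resamples rows with replacement (default 100), refits, and reports
|l·l_boot| per component; degenerate zero-variance resamples are skipped
and counted rather than retried.

Outlier screening uses Hotelling's T² over the retained components
(threshold a(n−1)/(n−a)·F₁₋α(a, n−a)) and the Q residual with the
Jackson–Mudholkar limit from the discarded eigenvalue spectrum. A sample
is flagged when either exceeds its limit (the OR rule; AND available).
The screening dimension (default 5 components) trades two failure modes:
too few components leave structured variance (band-height covariation,
jitter) in the residual and inflate the Q limit; too many absorb a
single contaminated sample into the model and mask it.

CCA follows ter Braak: the chi-square standardized response matrix is
projected, with row-total weights, onto the span of the standardized
explanatory variables, and the fitted matrix is decomposed by SVD.
Scaling 1 (site-focused) is the default; the implementation was
cross-checked against an independent constrained-ordination
implementation on a small fixture (eigenvalues agree to seven digits)
and that fixture is frozen as a regression test. For a one-hot response
the total inertia equals (number of classes − 1), which the tests use as
a closed-form check.

## Supervised discrimination

The split is stratified by largest-remainder allocation toward the
global 30 % test count, which guarantees the overall fraction within
rounding while keeping per-class proportions. PCA projection (2
components for the nearly balanced bacteria task, 4 otherwise) and SMOTE
are fitted on training rows only; SMOTE synthesizes minority points as
x + u·(x_nn − x) with u ~ U(0,1) among the k = 5 nearest minority
neighbors, and is applied only when the class ratio exceeds 1.25 (the
bacteria task, 12 vs 10, is left unbalanced). Following a parsimony
principle, LDA is fitted first and the model escalates to an RBF SVM
(grid C ∈ {0.01…100}, γ ∈ {0.001…1}, leave-one-out accuracy, ties to the
smallest C then γ) only when LDA's LOO accuracy falls below 0.95. LOO
validation runs on the SMOTE-balanced training set. MCC uses the
zero-denominator → 0 convention, with a warning.

On the shipped generator the class contrasts are strong enough that LDA
reaches perfect LOO accuracy on every task and never escalates; the SVM
path is exercised directly in tests. This is a property of the synthetic
conditions, not a claim about real spectra.

## One-class DD-SIMCA

The target-class PCA defines SD (Mahalanobis distance within the model
plane) and OD (squared residual norm). Each distance is treated as
scaled chi-square; degrees of freedom and scale are estimated by moments
(N = round(2·mean²/var), floor 1) or robustly (median/IQR quantile
matching). Estimation uses **leave-one-out distances** by default:
in-sample training distances systematically understate fresh-sample
distances (the model optimism bias), which at nominal α = 0.05 produced
~7 % type-I error in simulation; LOO estimation restores coverage to
0.95 ± 0.02. The full decision distance c = N_SD·SD/SD₀ + N_OD·OD/OD₀ is
compared to χ²(1−α, N_SD+N_OD) — the full-distance formulation rather
than a rectangular SD/OD box. Training outliers are flagged at an
extreme level (α_out = 0.01) and reported, never silently removed.

Component count is selected by leave-one-out sensitivity (acceptance
fraction of held-out target samples), ties to the smallest dimension.
A known limitation: because the DoF estimation self-calibrates at any
candidate dimension, LOO sensitivity is close to 1−α across candidates
and the selection is only weakly identifying; it guards against gross
over-fitting rather than recovering a "true" dimension.

## Chain-length calibration

For an unbranched alkane with two terminal CH₃ groups and n−2 CH₂
units, the intensity ratio is R₃/₂ = 2k/(n−2), hence n = 2k/R₃/₂ + 2,
strictly decreasing in the ratio with n → 2 as R₃/₂ → ∞. The
absorptivity ratio k = 2.625 is fixed by anchoring R₃/₂ = 0.75 at nine
carbons; it is exposed as a parameter. Heights are the default intensity
measure; integrated areas above a local linear baseline are available
for sensitivity analysis.

## Problem sizes and numerical conventions

The test suite and the acceptance script run the full 102-sample design
end to end; coverage calibration uses 500 training and 10 000 fresh
target-class draws (chosen so that the scale-estimation noise, ~sd/√n of
the LOO distance mean, is small against the ±0.02 coverage band);
screening power uses 100 trials of 41 spectra. Tolerances follow the
quantity: exact identities at 1e-10 (PCA vs dense eigendecomposition,
CCA inertia fraction), discretization-aware bounds for peak measures on
a 1–4 cm⁻¹ grid, and simulation bands for stochastic rates. All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; no global RNG state is used.

## Known limitations

* The six-band table reconstructs the informative moieties from their
  standard literature centers; real band lists for specific fossil
  assemblages may differ, and all centers/windows are overridable.
* The generator's Gaussian lineshapes and additive noise ignore ATR
  penetration-depth dispersion, water vapor, and CO₂.
* CCA significance is assessed only by the permutation check in the
  tests; no detrended or partial variants.
* Binary tasks only; multiclass discrimination and probability
  calibration are out of scope.
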