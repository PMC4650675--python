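# Methods

This note documents the models, numerical choices and limitations of
`soilspec`; the README gives the user-facing overview.

## PLS2 discriminant model

PLSDA is PLS2 regression of a 0/1 class-indicator matrix **Y** (one column
per class, row sums 1) on the spectra **X**, followed by assignment to the
class with the largest predicted indicator value.  Assumptions: classes are
linearly separable in a low-dimensional latent subspace of the centered
spectra; the indicator coding treats all misclassifications symmetrically.

Both blocks are mean-centered and never variance-scaled.  Absorbance
channels share a common physical scale, so scaling would only amplify noise
channels; centering is treated as part of the regression, not as spectral
pretreatment (no derivatives, SNV or scatter correction are applied
anywhere).

Latent variables are extracted sequentially with X-block deflation only.
The weight vector of each component is computed directly as the dominant
eigenvector of **EᵀY YᵀE** via the K × K eigenproblem on (**YᵀE**)(**EᵀY**)
— the exact fixed point of the classical NIPALS inner iteration — rather
than by iterating.  This is algebraically identical to converged NIPALS up
to the (irrelevant) sign of the weight vector and removes the iteration
tolerance as a numerical parameter; equivalence with a literal textbook
NIPALS implementation (double deflation, inner iteration) is asserted in
the test suite at 1e-8 after sign alignment.  Y-deflation is omitted
because successive X-residuals are orthogonal to earlier scores, making it
a no-op for the extracted sequence.

Coefficients at a truncated component count a use the rotation
**R** = **W**(**PᵀW**)⁻¹; **PᵀW** is unit upper triangular, so truncation
equals taking leading columns of **R** and the solve is a stable triangular
solve.  Degenerate inputs fail loudly: a zero-variance response, a request
for more components than `min(n-1, p)`, or an X-residual exhausted before
the requested component count all raise with the offending quantity named.

Tie-breaking in the argmax assignment goes to the earliest class in the
declared class order (the conventional reporting order of the five FAO
classes); `numpy.argmax` provides exactly this rule.  Classification is
invariant to adding a constant to all responses of a sample.

## VIP

Multi-response VIP is computed per class with per-class SSY weighting
(SSYₐₖ = qₐₖ²·tₐᵀtₐ) so each soil class gets its own importance profile;
the normalization Σⱼ VIPⱼₖ² = p holds per class and is asserted on every
fit in the tests.  The component count at which VIP is evaluated is an
explicit argument (the final 26-component model is the natural choice, but
nothing in the formulation fixes it), defaulting to the fitted count.

## Cross-validation

LOO refits the model from scratch on the n−1 retained samples — means are
recomputed inside each fold, so no information from the held-out spectrum
leaks into the centering.  Accuracy-vs-components curves fit each fold once
at the maximum component count and truncate, which is exact and reduces the
cost from O(n·A) fits to O(n).

The GA fitness uses exact LOO by default.  A deterministic stratified
k-fold accelerator (`cv_folds`) exists for large grids and desk-scale
experiments; folds are assigned round-robin within each class with no
randomness so repeated evaluations of the same subset are identical and can
be cached.

## Stratified 2:1 split

Per class, the training allocation is the nearest integer to 2n/3 (thirds
never produce .5 ties).  This reproduces the study-style allocation for
class sizes (36, 72, 29, 45, 48) → (24, 48, 19, 30, 32) training and
(12, 24, 10, 15, 16) testing samples.

## Genetic algorithm

A chromosome is an explicit sorted index set (not a fixed-length bitmask),
which makes the size bounds — at least `n_components + 1` features so the
regression is determined, at most 75 — first-class and checkable every
generation (a hard assertion in the loop).

The fitness of a subset is the equal-weight combination
½·r_calibration + ½·r_LOO with both accuracies as fractions; the weights
are exposed in `GAConfig` because the combination rule admits variants, and
equal weighting keeps the natural stopping value of 1.0 meaningful.
Operators: tournament selection of size 2 (rank-robust and standard);
union crossover (child drawn from the parents' union, sized like a randomly
chosen parent); mutation toggles every grid channel independently with
probability 0.05 per generation — the behaviour of a binary-mask GA — and
repairs the result back into the size bounds by random removal/addition;
elitism of 1 makes the best fitness non-decreasing.  One master seed drives
a single generator; per-replicate streams elsewhere are spawned via
`SeedSequence`.  A run is fully deterministic given its configuration.

Single-run semantics: the selected subset of one GA run is reported as-is,
with the full (best, mean) fitness trajectory.

## Resampling comparison

Each replicate re-draws the stratified 2:1 split (both sets re-drawn) and
fits up to three variants at 26 latent variables: all features, a fixed
pre-selected subset (scheme 1), and a per-replicate GA selection
(scheme 2).  Summaries are medians with 95% percentile-bootstrap CIs *of
the median* (1000 draws, seeded) — interval widths of a few tenths of a
point over many replicates are characteristic of a median CI rather than a
replicate-distribution interval.  Desk-scale defaults are 50 replicates and
a reduced GA (population 20, 10 generations); the full 1000-replicate,
population-50 configuration is a parameter change away.

## Synthetic spectra generator

The generator emulates the statistical structure of class-labelled NIR
soil spectra, not their radiative physics:

* 1816-point linear grid from 7500 to 4000 cm⁻¹ (≈1.93 cm⁻¹ spacing — the
  point count, not the nominal instrument resolution, is followed);
* Gaussian band shapes (a modelling convenience; real bands are closer to
  Lorentzian/Voigt, but band shape is irrelevant to classification
  structure);
* shared -OH/mineral combination bands near 7065, 5222 and 4527 cm⁻¹ with
  large between-sample amplitude scatter (variable bound water);
* class-discriminating bands in the diagnostic regions of the five classes:
  illite 4094/4050 cm⁻¹ (Albic Luvisols), -OH 7463–7037 and 5263–5222
  cm⁻¹, organics 5292/4320/4316 cm⁻¹, carbonate 4287 cm⁻¹ (amplified for
  Chernozems and Eutric Cambisols), 4505–4503 and 4046 cm⁻¹;
* a per-sample affine baseline with class-specific mean levels ordering the
  classes as observed in real spectra (Chernozems highest average
  absorbance, Albic Luvisols lowest), mimicking uncorrected scatter
  offsets;
* amplitude draws truncated at zero so absorbance stays non-negative;
* white noise (sd 0.01) everywhere, plus heteroscedastic channel noise
  (sd 0.14) on every channel farther than 90 cm⁻¹ from all diagnostic
  centers.

The heteroscedastic term is the deliberate design choice that makes
wavelength selection worthwhile, emulating the poor signal-to-noise of
strongly absorbing or uninformative regions in diffuse-reflectance
measurements.  Without it a full-spectrum PLS model, which averages
independent channel noise over 1816 channels and targets Y-covariance
directly, is essentially unbeatable by any 75-channel subset, and the
selection step would have nothing to contribute.  With it, the full
spectrum drags ~60% noisy channels into the latent variables while a good
subset escapes them — reproducing, qualitatively, the observed pattern:
full-spectrum models dominate calibration, selected subsets dominate
internal and external validation.

Default sample sizes are the study conditions: class counts
(36, 72, 29, 45, 48), n = 230.  Ground truth records every grid index
within one width of a class-discriminating band center, per class and
pooled; this is what the selection-enrichment tests consume.

What the generator does **not** emulate — and hence what passing tests do
not show about real soils: instrument line shapes and resolution effects,
multiplicative scatter, correlated (pink/drift) noise, within-class
mineralogical substructure, and any nonlinear absorbance–composition
relationship.  Passing the pipeline on synthetic data demonstrates the
correctness and the qualitative behaviour of the algorithms, not
field-level accuracy figures.

## Problem sizes in tests and the acceptance script

The published recognition tables are re-derived exactly from their printed
counts.  One published cell is internally inconsistent: the GA-selected
model's testing-block mean prints 93.15, while its own counts give
72/77 = 93.51 (and the accompanying text says 93.5%); the package follows
the counts.

The stochastic experiments run at reduced scale chosen once as a sensible
desk configuration: selection-enrichment uses 50 GA runs (population 20,
10 generations, 5-fold fitness) on a 200-channel, 10-informative-band
problem, combined against the exact hypergeometric null by Fisher's
method; the resampling comparison uses a 600-channel, half-size-sample
version of the default generator with 20 replicates per experiment and 5
experiment seeds.  The acceptance script's synthetic pipeline runs at the
full study shape (230 × 1816, 26 latent variables) with the reduced GA.

## Known limitations

* The GA fitness combination rule is a modelling choice (equal weights,
  no subset-size penalty); a size penalty could be added to the exposed
  weighting if parsimony mattered more than accuracy.
* `n_components` inside the GA defaults to the final model's 26; selecting
  it per subset (e.g. by nested CV) would be more principled and much more
  expensive.
* No probabilistic class posteriors; the argmax rule gives hard labels
  only.  Centroid or Mahalanobis assignment and NIPALS-LDA are plausible
  alternatives that are out of scope.
* No spectrometer-native file formats (SPC, JCAMP-DX) and no resampling
  between wavenumber grids; input is the wide CSV layout only.
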