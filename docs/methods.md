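# Methods

## The problem and the pipeline

Adenosine phosphates (AMP, ADP, ATP) give near-identical SERS spectra:
all three share the adenine moiety, whose ring-breathing (~730 cm⁻¹),
C-N/C-C stretch (~1330 cm⁻¹) and N7-C8/NH₂ (~1460 cm⁻¹) bands dominate the
fingerprint region, while the phosphate chain contributes comparatively
weak bands near 1075 and 1180 cm⁻¹. Recognizing which APs a mixture
contains is therefore a fine-grained 7-class problem — the seven volume
ratio patterns 1:0:0, 0:1:0, 0:0:1, 1:1:0, 1:0:1, 0:1:1, 1:1:1 — under
severe data scarcity (140 spectra, 20 per group, half of which must serve
as the test set).

`sersml` treats this as a pipeline of four fitted stages. Everything with
state — the feature mask, the group noise model, both augmentations, and
every classifier — is fitted on the training half of each swap fold only.
The held-out half is untouched until prediction; a perturbation of the
test spectra provably leaves every fitted component bit-identical (this is
asserted by tests).

## Synthetic data generator

No machine-readable AP SERS spectra are publicly deposited, so the
generator is a first-class module that emulates the statistical structure
the pipeline assumes:

* **Band model.** Lorentzian peaks by default (the natural Raman line
  shape), Gaussian available. Adenine bands (730/1330/1460 cm⁻¹, FWHM
  12/14/16, amplitudes 1.00/0.55/0.40) are identical across species up to
  per-species center offsets of {0, +2, +4} cm⁻¹ for AMP/ADP/ATP; phosphate
  bands (1075/1180 cm⁻¹) scale linearly with the phosphate count (1/2/3).
  Mixtures are fraction-weighted sums over the non-zero components.
  The offsets make the hardest confusions structural: ADP alone, AMP+ATP
  and the 1:1:1 mixture all carry the same mean phosphate weight and differ
  only in line shape — which is why the all-present group is the most
  error-prone, matching the behaviour expected of real mixtures.
* **Nuisance structure.** Per spectrum: a multiplicative log-normal
  enhancement factor (sd 0.15 on the log scale) modelling
  substrate-to-substrate SERS efficiency; a random quintic baseline with
  coefficients drawn uniformly per degree on the normalized coordinate
  (so the quintic corrector can remove it exactly in principle); additive
  white noise with sd equal to `noise_sd` times the spectrum's strongest
  clean band. The 200–650 cm⁻¹ stretch is band-free by construction so a
  pure-noise shift cluster exists for feature selection to find.
* **Calibration.** `noise_sd = 0.02` is part of the shipped default
  configuration, chosen once so that the full feature-selection +
  augmentation + MLP pipeline operates in the 0.85–0.95 pooled-accuracy
  band — a difficulty regime where preprocessing decisions matter, rather
  than a saturated or hopeless one.
* **What it does not model.** Electromagnetic enhancement physics,
  adsorption competition between species, wavenumber miscalibration,
  cosmic-ray spikes, heteroscedastic detector noise, and correlated
  baseline drift across replicates. Passing tests demonstrate the
  pipeline's correctness and its qualitative behaviour under this noise
  model, not performance on any particular instrument's data.

## Preprocessing

Order: crop → baseline → smooth → standardize. Cropping first means the
baseline is fitted only on the analyzed 200–1700 cm⁻¹ window (closed
interval, endpoints kept).

The quintic baseline is estimated by iterative peak-suppressed least
squares (ModPoly-style): fit a degree-5 polynomial, clip the working
signal at the fit wherever it exceeds it, refit; stop when the maximum
relative coefficient change falls below 1e-4 or after 100 iterations.
A single unweighted fit would be biased upward by the peaks; the clipping
iteration removes that bias (a narrow Lorentzian on a known quintic is
recovered to well within 5% of its true height). Fitting uses a scaled
polynomial basis for conditioning; convergence is judged on those scaled
coefficients.

Savitzky–Golay smoothing uses window 5 / degree 2 with polynomial edge
handling, so output length equals input length and any quadratic passes
through exactly. Standardization uses the sample standard deviation
(n−1); a spectrum whose post-correction sd is numerically zero (relative
threshold 1e-12) is rejected as degenerate rather than silently amplified.

## Feature selection

Each Raman shift becomes a point in R^(n_train) — its standardized
intensity profile across the training spectra — and k-means (k-means++
seeding, best of 10 restarts) partitions the shifts. The cluster count is
the elbow of the WCSS curve over k = 1..10: normalize both axes to [0, 1]
and take the k with maximal perpendicular distance to the chord joining
the curve's endpoints, ties toward smaller k. If duplicate rows collapse
centroids, empty clusters are compacted away so every reported cluster is
non-empty.

"Noise cluster" needs an automatic criterion: each cluster is scored by
the mean, over its shifts, of the between-group variance of the group-mean
intensities at that shift. Characteristic bands are exactly the shifts
whose mean intensity depends on the mixing group, so the lowest-scoring
cluster is the band-free one; `n_drop` (default 1) lowest-scoring clusters
are removed as a forced count, not a threshold. On default synthetic data
the retained set covers all configured band centers while discarding most
of the band-free grid (typically ~100 of 1501 shifts survive).

## Augmentation

The noise model is the per-group, per-shift sample sd of the training
spectra; each training spectrum spawns 40 copies with fresh `s_ij · N(0,1)`
noise. SMOTE draws exactly 100 synthetics per group by interpolating
uniformly between a random member and one of its 5 nearest same-group
neighbours (Euclidean metric, distance ties to the lower index). SMOTE
operates on the original 70 training points, not the noise-augmented pool,
keeping the two augmentations independent; both run in feature-selected
space. SMOTE is implemented natively because the setting — perfectly
balanced groups of 10 with an exact per-group synthetic count — is outside
the class-imbalance API of the usual oversampling libraries.

## Classification and evaluation

Grid search scored by mean accuracy over stratified 5-fold CV on the
training pool, refit on the full pool, ties broken by grid order. The
default grids are standard small-data ranges (LR C ∈ {0.01..100}; DT depth
2..10/none; kNN k ∈ {1,3,5,7,9}; LDA svd/lsqr+auto-shrinkage; RBF-SVM
C × γ; RF trees × depth; MLP hidden (50,)/(100,)/(100,50) × α). A "fast"
preset with one point per family supports multi-seed trend sweeps; a
singleton grid provably produces the same predictions as a degenerate grid
search. CV folds stratify on the group label; synthetic points may share a
fold with their source spectrum, a known optimism of pool-internal CV that
does not touch the held-out half.

The benchmark runs the two-fold train/test swap: stratified 70/70 split,
each half trained-on once, all 140 held-out predictions pooled into one
accuracy and one 7×7 confusion matrix per (condition × family) cell.
Masks and augmentation are refitted per fold by default
(`refit_mask_per_fold=False` reproduces the fit-once-on-everything
variant for fidelity experiments, at the cost of leakage). Cell failures
are isolated so one diverging family cannot abort the table.

## Problem sizes and determinism

Multi-seed quantities (trend means, elbow recovery) use the full
study-scale configuration — 140 spectra on the 1501-point grid — with the
fast grid preset; the acceptance script averages trends over 5 generator
replicates and elbow recovery over 10, sizes chosen to make the whole
recomputation about a minute on one CPU. All randomness flows through
explicit integer seeds (`numpy.random.default_rng`, scikit-learn
`random_state`), and regenerating any dataset, pool or report with the
same seed is bit-identical.

## Known limitations

* The true inter-species differences of AP SERS spectra (center shifts vs
  relative intensities) are not publicly quantified; the generator's
  offsets model them plausibly but are not inferred from data.
* Whether the original measurement software's baseline fit was iterative
  or single-pass is unknown; only the quintic model class is fixed.
* Group-level accuracy and per-analyte-bit accuracy coincide in ranking
  here because the 7 presence patterns are distinct; both are reported.
* No significance testing between families; observed orderings on a single
  dataset replicate are noisy, which is why trend statements are averaged
  over seeds.
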