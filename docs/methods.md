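# Methods

## Problem setting

The package classifies glucose concentration levels from Raman spectra of
glucose/deionized-water phantoms. The study design is ten concentration
levels — 5.0, 5.5, 6.0, 6.5, 7.0, 7.5, 10.0, 12.5, 15.0, 20.0 mmol/L,
coded 1–10 — with five replicate acquisitions per level and 2048
shift/intensity pairs per spectrum, shared axis across samples. The task
is 10-class classification of a 50 × 2048 matrix; the scientific question
is how much two preprocessing steps (variance-based index selection and
fluorescence-baseline removal) help three standard classifiers.

## Hotspot series extraction

A length-*l* window starting at index *j* ("intensity series") has mean
`S̄_j = (1/l) Σ I` and population variance `V_j = (1/l) Σ (I − S̄_j)²`; a
length-*N* spectrum has exactly *N − l + 1* windows. For each sample the
*k* highest-variance windows are selected; the union over all samples of
all indices they cover is the shared index mask, and every spectrum is
reduced to those columns. Defaults *l* = 10, *k* = 500.

Numerical choices:

* Variance uses the 1/*l* (population) normalization, not 1/(*l* − 1).
* Windows are ranked by the rank-equivalent score
  `l·Σw² − (Σw)² = l²·V`, which is exact for integer-valued counts, so
  mathematically tied windows compare exactly equal; ties are then broken
  toward the smaller start index via a stable sort. This makes selection
  fully deterministic.
* Overlapping selected windows are expected; the union deduplicates.
* The mask is computed from the full dataset by default, mirroring a
  global-mask protocol in which feature selection precedes the CV split.
  This leaks test-set variance structure into the feature choice;
  `HotspotSelector` is a scikit-learn transformer, so fitting it inside
  training folds (the `leakage_safe` mode of `run_comparison`) gives the
  unbiased variant. The default reproduces the protocol under study; the
  leakage-safe mode is the right choice for new analyses.

The selection only shortens the feature vector; it does not transform
intensities, so it cannot remove multiplicative or baseline nuisance.

## Fluorescence removal (Vancouver Raman Algorithm / IModPoly)

Fluorescence appears as a broad, smooth, high-intensity background well
approximated by a low-order polynomial. The corrector:

1. smooths the raw spectrum with an odd boxcar window (edge-truncated so
   constants are preserved; window 1 disables smoothing);
2. iteratively fits an order-*p* polynomial by least squares (on an axis
   internally rescaled to [−1, 1] for conditioning), computes
   DEV = s.d. of residuals, and clips every working point above
   `fit + DEV` down to that ceiling; points flagged as peaks by the first
   iteration (above `fit + DEV`) are excluded from all later fits, so
   strong Raman bands cannot drag the polynomial upward;
3. stops when the relative DEV change falls below `tol`, treating
   DEV = 0 as immediate convergence, or at `max_iter` (reported via
   `converged=False`, never an exception);
4. subtracts the final polynomial from the smoothed spectrum.

Defaults: `poly_order=5` (fluorescence is conventionally fitted at order
five or six), `smooth_window=7`, `tol=0.005`, `max_iter=100`. Corrected
intensities may undershoot zero near peak shoulders and are deliberately
not clipped — the non-negativity rule applies to raw detector counts,
and downstream models should see the full residual. On synthetic
degree-4 backgrounds with peaks at five times the local baseline, the
recovered baseline's RMSE over peak-free indices stays below 1% of the
background range (the acceptance script recomputes this).

## Classifiers and evaluation

Extra Trees, Random Forest (scikit-learn defaults unless tuned; seeded)
and an SVM with `gamma='scale'`. The SVM takes raw features without
per-feature standardization: on spectral matrices the large majority of
columns carry only noise, and standardizing inflates them to unit
variance, drowning the informative bands and collapsing the RBF kernel
toward a constant; `gamma='scale'` provides the needed global scale
adaptation instead. Tree ensembles are scale-insensitive and also take
raw features.

Evaluation is repeated stratified k-fold CV: 5 folds × 90 fresh shuffles
= 450 iterations by default (partition seeds derive from the CV seed;
results are bit-reproducible). With the balanced 10 × 5 design every
test fold holds exactly one sample per class. Metrics per iteration are
one-vs-rest: per-class `(TP+TN)/n`, `TN/(TN+FP)`, `TP/(TP+FN)` and a
rank-based (Mann–Whitney, midrank-tied) AUC from class scores (vote
fractions for ensembles, OvR decision values for the SVM), macro-averaged
over classes; a class absent from the true labels is excluded from the
macro with a warning. The plain fraction-correct is reported alongside
and is the quantity used to compare scenarios and to select grid-search
winners. Macro averaging (rather than micro) matches the
one-sample-per-class fold design; micro-averaged sensitivity would
collapse to fraction-correct.

Grid search enumerates the Cartesian product with keys in sorted order
and values in listed order, scores every combination under the same
repeated-CV protocol (usually with reduced repeats), and returns the
highest mean fraction-correct, ties to the first combination enumerated.
Hyperparameter names are validated against each model's tunable set
(`n_estimators`, `max_features`, `max_depth`, `max_leaf_nodes`,
`min_samples_split`, `min_samples_leaf` for the ensembles; `C`,
`kernel`, `gamma`, `degree` for the SVM). Tuning is not nested inside an
outer CV; the reported tuned scores are model-selection scores, not
unbiased generalization estimates, and are labeled as such.

## Synthetic data generator

The generator emulates the phantom study statistically:

```
I(x) = gain · (baseline(x) + Σ_p β·c·exp(−(x−μ_p)²/2w_p²)) + ε,  clipped at 0
```

* **Axis**: 2048 points over 200–3200 cm⁻¹.
* **Analyte bands**: Gaussians at 1060, 1125, 1366 and 1460 cm⁻¹
  (prominent glucose bands: C–O/C–C stretches, CH/OH deformations),
  width 20 cm⁻¹, apex response β = 10 counts per mmol/L per band. These
  fall at indices ≈ 587–860, inside the early 500–1250 index range where
  phantom spectra show their discriminative structure.
* **Fluorescence**: a fixed degree-5 polynomial template shaped like an
  autofluorescence hump (maximum near index 343, positive everywhere),
  scaled to 1000 counts. Per sample, each coefficient is perturbed with
  s.d. `baseline_jitter × baseline_scale`, damped as 1/(1+power) so the
  perturbation is a smooth low-order wobble. (Relative per-coefficient
  jitter is numerically unstable: the template's small tail value is a
  near-cancellation of large coefficients.) The template degree equals
  the corrector's default fit order, so baseline recovery is a fair test
  of the algorithm rather than of model mismatch.
* **Nuisance defaults**: `baseline_jitter=0.05` (≈ 50-count
  sample-to-sample fluorescence variability — the dominant nuisance, as
  in fluorescent aqueous phantoms), `gain_sd=0.02`, `noise_sd=2.0`
  additive Gaussian counts. Additive noise stands in for detector noise
  after basic acquisition-side noise reduction; shot noise, cosmic-ray
  spikes, etaloning and wavelength drift are not modeled.
* **Seeding**: per-replicate seeds are spawned from the master seed via
  `numpy.random.SeedSequence`; every stochastic op takes an explicit
  seed, and identical inputs give bit-identical datasets.

Under these defaults the adjacent-level apex separation (β × 0.5 mmol/L =
5 counts) is far below the fluorescence variability, so classifiers on
raw spectra sit near chance while baseline-corrected spectra classify
well — the comparison exercises the *direction* of the preprocessing
effect, not the absolute accuracies of any particular instrument. What
passing tests show is therefore that the pipeline's ordering (VRA >
root) and its bookkeeping are correct; they do not certify accuracy
levels on real cuvette measurements, whose noise structure, band
positions and fluorescence magnitude differ.

## Degenerate inputs and tie-breaks

* Zero intensities are accepted in raw spectra; strictly negative raw
  values are rejected (readers take `allow_negative=True` for corrected
  spectra).
* An all-zero or exactly polynomial spectrum converges in one IModPoly
  iteration (DEV = 0).
* An axis with fewer distinct values than `poly_order + 1` raises
  `SingularFit`; fewer samples than folds in any class raises
  `StratificationError`.
* `replicates=0` yields an empty dataset; empty datasets are rejected by
  selection, correction and comparison.
* Grid-search ties and window-variance ties both resolve to the earliest
  candidate in deterministic enumeration order.

## Problem sizes used by the test suite and acceptance script

Unit tests run on a 256-point, 30-sample variant of the design for
speed; the acceptance script and end-to-end tests use the full 2048-point
50-sample design. The scenario comparison there runs 10 CV repeats (50
iterations) per cell — the bookkeeping contract of the full 450-iteration
protocol is verified separately with a lean ensemble — and the
brute-force hotspot oracle covers arrays up to 64 points, where
exhaustive exact-rational re-ranking is cheap.

## Known limitations

* The global-mask default leaks variance structure across the CV split
  (see above); use `leakage_safe` for unbiased estimates.
* Hotspot selection can latch onto noise-induced variance in very noisy
  spectra, retaining non-informative regions.
* The polynomial baseline model cannot follow backgrounds that are not
  low-order-polynomial (e.g. sharp filter edges); peaks spanning a large
  fraction of the axis violate the peak-minority assumption of the
  clipping rule.
* Grid search is exhaustive only over the supplied value lists; no
  random or Bayesian search is provided.
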