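# Methods

This note describes the models and procedures implemented in `spadspec`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmark does and does not
demonstrate about real leaf data.

## The estimation problem

A chlorophyll meter reads a dimensionless SPAD value from a ~2×3 mm spot;
hyperspectral imaging measures reflectance for every pixel of a leaf across
400–1000 nm. The pipeline learns a map from band reflectance to SPAD on a
sample of leaves (each leaf contributing a ROI-averaged spectrum and a
meter reading), then applies that map per pixel to render whole-leaf SPAD
distribution maps. Because most of the 176 bands are redundant or
uninformative, characteristic-band selection precedes modelling: it
stabilises the regression, shrinks the model, and identifies the
chlorophyll-sensitive spectral regions.

## Reflectance calibration

`R = (DN_raw − DN_dark)/(DN_white − DN_dark)` element-wise. White/dark
references may be full cubes or single-row/column frames (broadcast along
the scan axis — line-scan systems typically record one reference line).
Where the denominator is zero the result is NaN, never ±inf; a cube whose
denominator vanishes everywhere is rejected. Reflectance outside [0, 1.5]
is kept — real specular pixels exceed 1 — but counted and logged, since no
published clipping rule exists for this instrument class.

ROI extraction averages pixels per rectangular ROI (0-based, half-open
intervals) and combines ROIs by weighted average. The default weight is the
ROI pixel count, which makes the combined spectrum identical to the plain
per-pixel mean over all ROI pixels; explicit weights override this. The
weighting of the "weighted average spectrum" is unspecified in the emulated
protocol, so it is exposed rather than fixed.

## Correlation screening (CA)

Per band, Spearman's ρ is the Pearson correlation of average-rank-transformed
reflectance and SPAD; the two-sided p-value uses the large-sample
t-approximation with n−2 degrees of freedom (a permutation oracle in the
test suite confirms its accuracy at n = 20). Selection keeps bands with
|ρ| > 0.65 and p < 0.01. The absolute value matters: visible-band
correlations are strongly negative (chlorophyll absorbs), NIR correlations
positive (denser mesophyll scatters), and both are signal. No
multiple-testing correction is applied — the rule is a per-band screen, and
is documented as such. Bands with constant reflectance yield NaN (undefined),
never a silent 0.

## sCARS

N Monte-Carlo runs (default 500). Each run fits a PLS model on a random
80 % sample of the leaves using the currently retained bands, and weights
each band by the *stability* of its regression coefficient: |mean| / SD over
B = 20 bootstrap refits within the run. A config switch restores the classic
plain-|coefficient| weight. The number of bands retained after run i follows
the exponential schedule `r_i = a·e^(−k·i)` with a, k fixed by `r_1 = 1`
(all p bands) and `r_N = 2/p` (two bands).

Which bands fill the schedule is decided in two steps per run: a
deterministic elite — the top half of the schedule count by weight, ties to
the lower band index — plus *adaptive reweighted sampling*: weighted
sampling without replacement for the remaining slots. Sampling without
replacement (rather than with replacement and deduplication) keeps the
retained count exactly on the schedule, which makes the count trajectory a
testable contract: all bands at run 1, exactly two at run N, non-increasing
throughout. Every run's retained subset is scored by 10-fold RMSECV on the
full sample; the global minimiser is the selection. The PLS component count
is chosen once per run by an inner 5-fold CV on the run's Monte-Carlo
sample (cap 10) and reused by that run's bootstrap refits — per-refit
component selection would multiply the cost ~50× without visibly changing
the stability weights.

## IRIV

Each round draws an n_rows × p binary inclusion design (Bernoulli(0.5),
rows redrawn until they contain ≥ 2 ones). Row k defines a variable subset,
fitted by PLS and scored by 5-fold RMSECV → RMSECV0[k]. Flipping column i
(include ↔ exclude) in every row produces RMSECVi[k]. With the ratio
`φ = RMSECV0/RMSECVi` split by the variable's original status —
φ0 over rows that included i, φi over rows that excluded it —

    DMEAN_i = mean(φ0) − mean(φi),

and a two-sided Mann–Whitney U test (normal approximation with tie
correction) compares the two ratio distributions. Classification:

| category      | rule                  |
|---------------|-----------------------|
| strong        | DMEAN < 0, p < 0.05   |
| weak          | DMEAN < 0, p > 0.05   |
| uninformative | DMEAN > 0, p > 0.05   |
| interfering   | DMEAN > 0, p < 0.05   |

Boundary cases (DMEAN = 0 or p = 0.05 exactly — measure-zero events) go to
the weaker class on their side. The sign convention is pinned by
construction: removing a variable that carries unique signal inflates
RMSECVi in the rows that contained it, pushing φ0 below 1 and DMEAN
negative; the test suite asserts this on a constructed system.

Rounds retain strong + weak variables until a round eliminates nothing;
below three survivors the iteration stops structurally (a design with ≥ 2
ones per row over two variables is all-ones, so no column can be excluded)
and hands over to backward elimination: repeatedly drop the variable whose
removal gives the smallest leave-one-variable-out RMSECV θ−i while
min θ−i ≤ θt, ties to the lower band index. The greedy path is verified
against exhaustive enumeration on a six-variable problem.

The PLS component count inside IRIV is min(5, |variables|−1, n−2), fixed
per round; inner component selection is disabled for speed and because the
classification depends on RMSECV *differences*, not its absolute optimum.
The design uses n_rows = 500 by default; the recovery experiments in the
tests and acceptance script use n_rows = 200, which keeps each Mann–Whitney
comparison at ~100 vs ~100 ratios — ample power for the planted effect
sizes — at less than half the cost.

### The PLS engine

IRIV evaluates on the order of `n_rows × (p+1) × folds` PLS fits per round
(~10⁵ at p = 176), so the inner loops use a dedicated PLS1 implementation
(`spadspec._pls`) rather than a general-purpose estimator object per fit.
Two forms are provided: a single-fit NIPALS PLS1, and a batched form for
many column subsets of one matrix. The batched form exploits the classical
equivalence of PLS1 with conjugate gradients on the normal equations
`(XᵀX)β = Xᵀy` started at zero: a masked (zeroed) column is constant, hence
centred to zero, hence inert, so every subset shares one Gram matrix and
each CG step for all subsets is a single BLAS matmul. Both forms agree with
each other and with scikit-learn's `PLSRegression(scale=False)` to near
machine precision (asserted in the tests; for a univariate response the
algorithms coincide). The user-facing PLSR model in `spadspec.models`
remains scikit-learn's.

## Regression models and evaluation

PLSR (scikit-learn, components by inner 5-fold CV, cap 10), XGBoost,
random forest, and gradient boosting (defaults: 500 trees, depth 3,
learning rate 0.1 — conventional boosted-ensemble settings; all exposed).
Fits are deterministic under the spec's seed, record their band subset and
wavelengths, and refuse empty band sets and non-finite fitted values.

**Rcv² is the squared Pearson correlation** of measured vs out-of-fold
predicted values — *not* `1 − SSres/SStot`. The two differ for biased
predictors: a systematically offset model can still score a high
correlation-R². This definition is always in [0, 1] and is the convention
of the evaluation protocol this package follows; both the per-fold means
(the reported Rcv², RMSEcv, MAEcv) and pooled out-of-fold metrics are
computed and stored, since the aggregation convention is ambiguous in the
field. MAE ≤ RMSE is asserted on every report. Folds are seeded and
stratified by leaf-position tier so each fold sees all tiers; k = n
(leave-one-out) is rejected because per-fold correlation needs ≥ 2 points.

## Inversion

Leaf masking thresholds NDVI = (NIR − red)/(NIR + red) at 0.3 (red = band
nearest 670 nm, NIR = band nearest 860 nm above 750 nm) and keeps the
largest connected component. Selected wavelengths are matched to the cube
grid by nearest neighbour within 1.8 nm — half the nominal 3.6 nm band
spacing. Predictions are **not** clipped to the meter range: linear models
extrapolating to impossible SPAD values at atypical pixels is a real,
reportable pathology, and clipping would hide it. Maps are rendered as
8-bit grayscale plus a green–yellow–red palette on fixed global limits
(default 0–80) so leaves share a scale; rendering is deterministic
(byte-identical re-renders). Summary statistics (min, max, mean, SD) are
computed over mask-true pixels only.

## Synthetic data

`generate_dataset` draws SPAD values from three leaf-position tiers
(defaults 66.0 / 61.0 / 48.3 mean SPAD for lower/middle/upper, SD 3.0 —
tier means follow the emulated study's measured values; the within-tier SD
is our choice, consistent with the few-unit spread of repeated tier
measurements and a ±1-unit meter). Reflectance is a fixed smooth
vegetation template (piecewise-Gaussian: low blue, green peak at 550 nm,
chlorophyll trough at 670 nm, sigmoid red edge to an NIR plateau ≈ 0.45)
plus a band-localised linear term `e_b · z` in the standardised SPAD z at
each planted band (negative e in the visible, positive in the NIR,
default |e| = 0.01), plus additive Gaussian noise (default SD 0.004),
optionally spectrally correlated by circular convolution with an
L2-normalised Gaussian kernel (default σ = 5 bands). Defaults give planted
bands marginal correlations of |ρ| ≈ 0.9, comparable to the strongest
bands of real vegetation spectra. An optional quadratic link
(`z + 0.4 z²`) plants curvature that no linear band combination can
remove, for linear-vs-ensemble comparisons. Standardisation uses the
configured population moments of the tier mixture, not sample moments, so
effect sizes are well-defined independent of n.

`generate_hypercube` encodes per-pixel spectra (same model) as 12-bit-scale
DN with constant dark ≈ 2 % and white ≈ 95 % frames, `raw = dark +
R·(white − dark)`. DN values are left as unquantised floats so calibration
inverts the encoding exactly — the round-trip is a float-precision test
anchor, not an instrument simulation. Background pixels get a flat
0.04-reflectance spectrum, separable from vegetation by NDVI by
construction.

### What the benchmark does not show

- **Correlated noise vs "extras".** With spectrally correlated noise, the
  neighbours of a planted band genuinely carry information (they help
  denoise it), and all three selectors legitimately retain them. A
  false-positive count is therefore only well-defined under white band
  noise, and the planted-recovery experiments use
  `spectral_corr_length = 0`. Under the correlated default, selections grow
  by 20–30 neighbour bands — correct behaviour, not selector error.
- The generator plants band-localised signal; real chlorophyll absorption
  features are broad and smooth, so real CA selections are contiguous
  regions rather than isolated bands (the redundant-block test in the
  pipeline suite emulates this regime explicitly).
- No radiative-transfer realism (PROSPECT-class leaf optics), no vein
  structure, no illumination gradients, no sensor quantisation or smile.
  Passing tests demonstrate algorithmic correctness and recoverability
  under the stated statistical structure — not instrument-level accuracy on
  real leaves.

## Numerical choices

- CG/PLS early termination at residual or curvature < 1e-12; rank-deficient
  subsets simply stop accumulating components (never an exception).
- RMSECV ratio denominators floored at 1e-12; identical φ distributions get
  p = 1 (no evidence) rather than a tie-breaking exception.
- sCARS schedule counts use round-before-ceil to keep `r_N·p = 2` exact in
  floats; weight ties break to the lower band index (stable argsort).
- Fold partitions are seeded `numpy.random.default_rng` permutations;
  every stochastic routine takes an explicit seed and is reproducible
  bit-for-bit.
- The inclusion design is redrawn (seed offset, logged) in the vanishingly
  rare event a column is constant; ten failures raise.

## Problem sizes

Test-suite and acceptance-script runs use the emulated study's scale
(n = 150 leaves, p = 176 bands) for the headline experiments, n_rows = 200
IRIV design rows, 100-run sCARS schedules for contract checks, and 36×36 px
leaves for inversion — sizes at which every experiment's statistical target
is comfortably powered. Defaults in the config objects (500 IRIV rows,
500 sCARS runs) match common practice for real analyses.

## Known limitations

- IRIV's cost grows as `n_rows × p²` per round; at p ≫ 500 a pre-screen
  (e.g. CA) is advisable before IRIV.
- The correlation-R² convention cannot detect calibration bias; inspect the
  stored pooled metrics and out-of-fold scatter when bias matters.
- ENVI I/O covers BSQ/BIL little-endian cubes with in-header wavelength
  lists — the subset produced by common line-scan plant-imaging systems.
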