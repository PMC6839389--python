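# Methods

## Signal model and preprocessing

A high-frequency skin scanner records a matrix of signed
radio-frequency (RF) echo samples; rows index depth, columns the
lateral travel of the probe. The display image is obtained by
full-wave rectification with a device offset,

    imgB = 2 · |imgRF| − offset .

The offset is a device constant whose value is generally unknown; it
is a required sidecar-metadata field with default 0. When the offset
is positive the conversion can produce negative intensities. These
are preserved, not clipped: the conversion is exact algebra feeding
the frequency analysis, and clipping happens only when an image is
rendered or written to an 8/16-bit raster. Because no portable RF
container exists, raw scans travel as a flat binary plus a JSON
sidecar declaring shape, sample type (`int16`/`int32`/`float32`/
`float64`), endianness, offset and transducer frequency.

No beamforming, time-gain compensation or Hilbert-envelope detection
is performed — the conversion above is the entire preprocessing
chain.

## Spectral representation

All frequency analysis uses the orthonormal 2-D type-II DCT,

    B_pq = α_p α_q Σ_{m,n} A_mn cos[π(2m+1)p / 2M] cos[π(2n+1)q / 2N],
    α_0 = 1/√M,  α_p = √(2/M) for p ≥ 1  (likewise α_q),

computed with `scipy.fft.dctn(type=2, norm="ortho")`. The orthonormal
scaling makes the transform energy-preserving (Parseval) and exactly
invertible; the test suite verifies the fast transform against a
literal quadruple-loop evaluation of the definition to 1e−10, and
energy conservation to 1e−9. `B[0,0]` is the DC (scaled mean) term;
"DC removal" zeroes exactly that coefficient.

### Whole-image features

An image maps to the economy singular values

    S = svd( log max(|dct2(img)|, ε) ),

a descending nonnegative vector of length `min(M, N)` — 384 at the
1024 × 384 scanner geometry. All values are kept: the leading values
describe the coarse spectral envelope shared across images, the tail
carries the discriminative detail, and no truncation threshold has to
be justified. Two numerical choices:

* ε (default 1e−12) floors the magnitudes before the log, because
  flat image regions generate exactly-zero DCT coefficients.
  `log(1e−12) ≈ −27.6` is comparable in magnitude to the log of
  typical informative coefficients, so the floor bounds the range
  without distorting it.
* the logarithm is natural; any fixed base rescales all features
  uniformly (and singular values linearly), so the choice is benign
  but fixed and documented here.

### Block statistic

For segmentation each 32 × 32 block is summarised by the mean
absolute DCT coefficient excluding DC,

    stat = ( Σ|B_pq| − |B_00| ) / (s² − 1) .

This is the arithmetic mean of transform amplitudes over the
alternating coefficients only — the definition simultaneously honours
the two requirements that only the amplitude index matters and that
the DC portion be removed. The statistic is zero for a constant
block, invariant to adding a constant, and large for broadband
texture such as speckle. Magnitudes are used raw (no log): the log
compression belongs to the classification path only. The minimum
block size is 4 px; 32 (default) and 16 are the practical sizes at
this geometry. Images not divisible by the block size are cropped
from the origin — trailing remainders are discarded rather than
padded, since padding would inject artificial spectral content.

## Classification

A shallow feed-forward pattern-recognition network maps the
384-vector of singular values to class posteriors. Architecture: two
tanh hidden layers of 10 units (configurable), softmax output,
targets one-hot. Training minimises the mean cross-entropy with
Møller's scaled conjugate gradient (SCG) — a full-batch
conjugate-gradient method that sizes steps from a
Levenberg–Marquardt-regularised quadratic model (initial
λ = 1e−6, σ = 1e−5) instead of a line search. A plain
gradient-descent optimizer is available behind a config switch.

Several fitting choices matter in the d = 384 ≫ n regime typical of
modest clinical datasets:

* features are z-scored per index with statistics from the training
  split, persisted with the model;
* an L2 penalty on connection weights (default 0.01, biases exempt)
  is added to the cross-entropy — without it the network interpolates
  a few-hundred-sample training set within tens of SCG iterations and
  generalisation collapses;
* the data is split stratified 70/15/15 (train/validation/test by
  default; `val_fraction` controls the validation share of what
  `train()` receives) and training stops when the validation
  cross-entropy has not improved for `patience` (12) epochs, keeping
  the best-validation weights;
* five independently initialised restarts are trained (symmetric
  uniform init scaled by fan-in, all seeded) and the restart with the
  lowest validation loss is kept. A minority of initialisations land
  in visibly poor minima; restarts remove that failure mode without
  touching the architecture.

Everything is deterministic given the seed: the split, the inits, and
SCG itself (full-batch, no stochastic gradients).

Evaluation reports the confusion matrix, per-class TP/FP/TN/FN
percentages, accuracy, ROC curves and the trapezoidal AUC (positive
class for binary problems, one-vs-rest macro average otherwise; ROC
machinery from scikit-learn, cross-checked in the tests against a
brute-force Mann–Whitney pairwise count). The class count is
configurable from 2 (benign/malignant default) to 4.

For held-out performance measurements under study conditions the
package uses stratified 5-fold cross-validation
(`classifier.crossval_evaluate`): each sample is scored exactly once
by a model that never saw it, which removes most of the binomial
noise a single small test partition would carry.

## Segmentation

Pipeline per image: tile → block statistic → per-image Otsu
threshold → label. The threshold is derived from the distribution of
per-block scalars, not from raw pixels: echo intensity is a relative
property, so the separation of "low" from "high" frequency content
must be recalibrated for every image. Blocks with a statistic above
the threshold are healthy (healthy tissue has the higher mean
spectral amplitude); the rest are suspicious. Labels are assigned
independently per block — no morphology or spatial smoothing.

### Otsu on continuous values

Classical Otsu assumes a grey-level histogram. For continuous block
statistics the implementation builds a 256-bin equal-width histogram
over the observed [min, max]; every interior bin edge is a candidate
threshold and the edge maximising ω₀ω₁(μ₀ − μ₁)² (class weights and
means computed from bin centres) is returned. Ties — including
floating-point near-ties below one part in 1e10 — break toward the
lowest edge, which makes the result independent of summation order.
An all-identical input raises a degenerate-histogram error; the
segmenter then declares the whole image healthy with a warning flag.

### Lesion-free images

Otsu always produces some split, even when the block statistics form
a single mode, where the "suspicious" class would be an arbitrary
slice of healthy speckle. The segmenter therefore accepts the split
only if the suspicious class is markedly darker in mean frequency
than the healthy class:

    mean(stat | suspicious) < min_contrast · mean(stat | healthy),

with `min_contrast` = 0.6 by default. The guard is grounded in the
physics of the task — malignant tissue's cosine-spectrum amplitude is
well below that of healthy tissue, not marginally below — and in the
behaviour of the statistic: healthy-only images yield class-mean
ratios near 0.85–0.95 (a split inside one mode), while genuine
lesions yield ratios far below 0.5. Images failing the guard are
returned as all-healthy with the `degenerate` flag set.
`min_contrast=1.0` disables the guard.

## Synthetic phantoms

The generator emulates exactly the statistical structure the method
exploits, and nothing else:

* **geometry** 1024 × 384 (depth × lateral) by default;
* **layers** three horizontal bands (epidermis/dermis/hypodermis) with
  boundaries at depth fractions 0.06 and 0.55 and mean echogenicities
  200/180/160 — mild contrast, because healthy skin looks
  approximately alike across depth and the block statistic must stay
  unimodal on lesion-free images;
* **speckle** multiplicative unit-mean gamma noise (shape 16,
  sd = 0.25), giving the signal-dependent variance characteristic of
  coherent imaging;
* **lesions** rectangles or ellipses whose interior is the local layer
  mean times an echogenicity drop factor in (0, 1), plus low-frequency
  heterogeneity: Gaussian-smoothed noise with correlation length
  ≥ half a block (σ = 16 px). The smoothing deliberately engineers
  the property the method detects — lesion spectra concentrated at
  low frequencies — so phantom-based tests validate the
  implementation, not the biological claim;
* **RF synthesis** randomly-signed half-amplitudes, so
  `2·|rf| − 0` reproduces the constructed B-mode bit-exactly;
* **ground truth** the pixel mask is exact; block-level truth marks a
  block as lesion when ≥ 50% of its pixels are lesion (symmetric
  majority rule).

Class templates for classification experiments: benign = 96 × 96 px
lesion, drop 0.55, heterogeneity 0.1; malignant = 224 × 160 px, drop
0.3, heterogeneity 0.35 (size jittered ±25% and position uniform in
the dermis per sample). Echo contrast and texture are the
discriminating structure; per-sample seeds derive from the master
seed, so datasets are fully reproducible.

What the phantoms do **not** model: acoustic wave propagation,
attenuation with depth, point-spread anisotropy, probe-pressure
artefacts, real lesion morphology, or inter-patient variability
beyond seeded noise. Passing tests on phantoms shows the pipelines
correctly implement the frequency-domain method under its own
assumptions; it says nothing about clinical sensitivity/specificity.

## Study conditions used by the seeded experiments

* Segmentation recovery: 20 phantoms, one rectangular lesion each,
  edges aligned to the 32-px block grid (making the ≥ 50% block truth
  exact), spanning 2–5 × 3–4 = 6–20 blocks, placed uniformly in the
  dermis; scored as block-level intersection-over-union. Lesion-free
  suspicion uses 5 null phantoms.
* Classification: 100 benign + 100 malignant phantoms, whole-image
  features, the [10, 10] SCG network, stratified 5-fold
  cross-validation; headline numbers are pooled out-of-fold accuracy
  and AUC. The complete experiment runs in well under a minute on one
  CPU, which keeps the default test suite fast.

## Known limitations

* The segmentation contrast guard is a scalar heuristic; a lesion
  occupying most of the image would shift both class means and could
  evade it (the Otsu split itself would still find the boundary).
* Block-level labelling cannot resolve sub-block lesion margins;
  boundary blocks under 50% lesion coverage are ground-truth healthy
  yet may contain lesion tissue.
* The classifier's four-class mode is implemented but untested
  against real lesion-type taxonomies.
* The phantom generator's speckle is spatially white before lesion
  smoothing; real speckle has a correlation length set by the
  point-spread function.
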