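# Methods

## Model

Breast density grading is treated as 4-class texture classification.
Each mammogram contributes one feature vector built from two texture
families computed over the breast region of interest (ROI):

**Multifractal alpha histograms.** A local measure µ_w(p) is evaluated
over square windows of odd width w centered at each pixel p, and the
Hölder exponent α_p is the ordinary-least-squares slope of log µ_w
against log w (windows w ∈ {1, 3, 5} by default; w = 1 is the pixel
itself). Four measures are provided: the window maximum, 1 − minimum,
the window sum, and the "iso" count of window pixels whose intensity is
within a tolerance τ of the center. Intensities are min-max normalized
to [0, 1] beforehand. The alpha image (α_p at every pixel) is summarized
by a 100-bin histogram over the ROI, with bin range equal to the
per-image [α_min, α_max] and heights normalized to ROI-pixel proportions
so that breasts of different areas are comparable.

**Local binary patterns.** P neighbors are sampled by bilinear
interpolation at angles 2πi/P (i = 0 east, counter-clockwise) on a
circle of radius R or an ellipse with semi-axes (R1, R2); each neighbor
contributes bit i = s(g_i − g_c) with s(x) = 1 iff x ≥ 0 (so a constant
patch codes as all-ones). The experiment-of-record configurations are
LBP (P=8, R=2), ELBP (P=8, R1=1, R2=4, semi-major axis along image
rows), and multi-resolution MLBP concatenating R=2 and R=4 histograms
(512 bins, each half normalized to sum 1).

The fused descriptor concatenates the 100-bin alpha histogram (first)
with the 512-bin MLBP histogram, giving 612 features. Dimensionality is
reduced by PCA — covariance with M−1 denominator, eigendecomposition,
descending eigenvalue order, deterministic eigenvector signs — or by the
bottleneck code of an hourglass autoencoder. Classification uses a
one-against-all SVM with exhaustive decade-step grid search inside
stratified k-fold cross-validation; standardization, PCA/autoencoder
fitting and grid search all use training folds only.

## Key parameters

| Parameter | Default | Notes |
|---|---|---|
| window sizes w | {1, 3, 5} | odd widths for the log–log regression |
| iso tolerance τ | 1/255 | 8-bit-equivalent intensity equality, normalized units |
| log floor ε | 1e-12 | floors intensities and measures before logs; keeps α finite |
| histogram bins | 100 (alpha), 2^P (LBP) | proportion-normalized over the ROI |
| LBP | P=8, R=2 | ELBP (1, 4); MLBP radii {2, 4} |
| PCA n | 45, or scan {5, 10, …, 70} | scan picks n jointly with SVM params by inner-CV accuracy |
| autoencoder | 11 hidden layers, code 64 | geometric widths, Adam 1e-3, 200 epochs, batch 32, BCE |
| SVM grid | γ ∈ [1e-4, 1e3], C ∈ [1e-3, 1e4] decades | kernels RBF/Poly/Sigmoid, degree 1–6 (Poly) |
| CV | stratified 5-fold outer, 3-fold inner | seeded, deterministic |

## Synthetic phantoms

The generator emulates only what the pipeline needs: a near-zero
background, a half-elliptical breast of fatty tissue (intensity 0.35)
against the left edge, a bright pectoral triangle (0.85) in the
upper-left corner of MLO views, faint smooth fibrous texture, and
Gaussian dense-tissue blobs (amplitude 0.45, scale ~7 px at 256×256)
added until the fraction of breast pixels above the fixed dense
threshold 0.60 reaches a target drawn inside the BI-RADS band of the
requested class. Additive Gaussian noise (sd 0.02 of the unit range) is
applied last and images are quantized to 16 bits. Dense tissue is kept
clear of the pectoral boundary, mimicking retroglandular fat and keeping
the pectoral bright cluster separable.

What the phantoms do **not** model: anatomically realistic parenchymal
patterns, lesions and calcifications, skin lines and labels, scanner
noise spectra, or the intensity calibration of real FFDM detectors.
Passing tests therefore demonstrate the internal correctness and the
directional behavior of the pipeline (denser phantoms → denser
descriptors → separable classes), not clinical-grade accuracy on real
mammograms.

Problem sizes used by the shipped experiments: 256×256 phantoms, 20 per
class for the fusion comparison, 40 phantoms for the segmentation sweep,
RBF-only decade grid (64 candidates) for the fusion experiment. These
are the package's default study conditions; all stages scale to larger
images and grids through the same interfaces.

## Numerical choices

- **Degenerate normalization**: a constant image min-max normalizes to
  all zeros; normalized intensities are floored at ε before measure
  evaluation so the summation/iso measures retain their exact
  constant-image scaling (µ ∝ w², hence α = 2 exactly), while the
  extremal measures give α = 0.
- **Padding** is edge-inclusive reflection ("symmetric") everywhere —
  measure windows, median filter, LBP sampling — so every pixel has a
  defined value; ROI masking then discards border-influenced pixels that
  fall outside the breast.
- **LBP ties**: bilinear interpolation is computed as two nested convex
  pair-mixes so four equal corner values reproduce their value exactly;
  otherwise floating-point jitter could flip the s(x ≥ 0) comparison on
  flat patches.
- **Alpha histogram range** is per-image, as the descriptor is defined;
  bins are therefore not aligned across images. This is a known
  comparability caveat of the descriptor, inherited deliberately.
- **Grid-search ties** break toward smaller C, smaller γ, lower degree,
  kernel order RBF < Poly < Sigmoid, after sorting samples into a
  canonical (label, feature-value) order, making the selected
  configuration independent of row order.
- **Pectoral removal** clears pixels left of a quadratic fit to the
  bright corner component's per-row boundary; it only removes pixels and
  is idempotent, since a second pass finds no bright component touching
  the (now empty) corner.
- **Paired t-test** degenerate rules: all-zero fold differences give
  p = 1; constant nonzero differences give p = 0.

## Design choices

- The multiclass SVM is genuinely one-against-all
  (`OneVsRestClassifier`), not the one-vs-one scheme a bare `SVC` uses.
- The autoencoder is implemented directly on numpy arrays (explicit
  backpropagation, Adam) so training is exactly reproducible from a
  seed; hidden widths interpolate geometrically between the input and
  code sizes since only the layer count and code size are prescribed.
- F1 is reported both support-weighted and macro; AUC is macro
  one-vs-rest from decision scores with the across-fold standard
  deviation as its spread.
- The summation and iso measures consume normalized intensities as well
  (normalization is only mandatory for the extremal measures), keeping
  all log arguments scale-free.
- Per-half normalization of MLBP histograms keeps each radius's block a
  probability distribution, so neither radius dominates the fused scale.

## Limitations

- Phantom realism is deliberately minimal (see above); reported
  synthetic accuracies are near ceiling and serve as directional checks.
- The ceiling has a concrete consequence for the fusion experiment: the
  iso alpha-histogram alone essentially reads off the dense-pixel
  fraction that defines the phantom classes, so the single-descriptor
  pipeline saturates and the fused iso+MLBP+PCA pipeline cannot improve
  on it; PCA fitted on ~64-sample training folds of the 612-dim fused
  space adds estimation noise worth one or two samples of 80. On data
  where the individual descriptors are genuinely imperfect and
  complementary, fusion is where this method earns its keep; the phantom
  cohort does not reproduce that regime.
- The pectoral-removal heuristic assumes the muscle appears as a bright
  corner-touching cluster after chest-wall-left orientation; unusual
  positioning would defeat the corner test.
- Rotation-invariant/uniform LBP variants are intentionally absent: the
  descriptors use raw 256-code histograms.
- DICOM support reads single-frame grayscale images only.
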