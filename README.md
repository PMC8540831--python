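# densitex

Texture-based classification of mammographic breast density.

Breast density — the proportion of fibro-glandular tissue in the breast —
is a strong risk factor for breast cancer and reduces mammographic
sensitivity. Radiologists grade it into four BI-RADS categories
(I: 0–25% dense tissue … IV: >75%), a visual assessment with substantial
inter-reader variability. `densitex` implements a reproducible
texture-analysis pipeline for this grading task:

1. **Pre-processing** — breast-region segmentation (multi-Otsu
   thresholding + morphology) and pectoral-muscle removal on MLO views
   (2-cluster intensity K-means + quadratic boundary fit), yielding a
   region-of-interest (ROI) mask.
2. **Multifractal features** — per-pixel Hölder exponents α estimated
   from the scaling law µ_w(p) = C·w^α of a local measure µ over window
   sizes w ∈ {1, 3, 5}, for four measures (maximum, inverse-minimum,
   summation, iso); the ROI-restricted, proportion-normalized 100-bin
   histogram of the resulting *alpha image* is the feature vector.
3. **Local binary patterns** — circular LBP (P=8, R=2; 256 bins),
   elliptical ELBP (R1=1, R2=4; 256 bins) and multi-resolution MLBP
   (R ∈ {2, 4}; 512 bins), with ROI-normalized code histograms.
4. **Fusion + selection** — the 612-length iso+MLBP concatenation,
   reduced by PCA (covariance eigendecomposition, top-n projection, n
   chosen by inner-CV accuracy) or by the bottleneck of an hourglass
   autoencoder (ReLU hidden layers, sigmoid output, binary cross
   entropy).
5. **Evaluation** — one-against-all SVM with exhaustive grid search
   (kernels RBF/Poly/Sigmoid, γ ∈ [1e-4, 1e3], C ∈ [1e-3, 1e4] at decade
   steps, degree 1–6) inside stratified 5-fold cross-validation;
   accuracy, macro one-vs-rest AUC, Cohen's kappa, F1 and paired t-tests.

Clinical mammogram datasets with BI-RADS labels are license-gated, so the
package ships a **synthetic phantom generator**: breast-shaped half-ellipse
phantoms with an MLO pectoral triangle and Gaussian dense-tissue blobs
whose dense-pixel fraction is driven into the BI-RADS band of the
requested class. Every stage is testable end-to-end on these phantoms.

## Worked example

```python
import densitex as dx

# a heterogeneously dense (BI-RADS III) MLO phantom
sample = dx.generate_phantom(dx.PhantomSpec(class_label="III", seed=11))
print(f"dense fraction: {sample.realized_dense_fraction:.3f}")

img = dx.GrayImage(sample.image, view="MLO")
norm, roi = dx.preprocess(img)
print(f"ROI Dice vs ground truth: "
      f"{dx.dice_coefficient(roi, sample.breast_mask):.3f}")

iso = dx.multifractal_descriptor(norm, roi,
                                 dx.MultifractalConfig(measure="iso"))
mlbp = dx.mlbp_descriptor(norm, roi)
fused = dx.concatenate_descriptors(iso, mlbp)
print(f"fused descriptor length: {fused.size}")
```

prints

```
dense fraction: 0.587
ROI Dice vs ground truth: 0.999
fused descriptor length: 612
```

The dense fraction 0.587 sits inside the class-III band (51–75%); the ROI
recovered by thresholding + pectoral removal overlaps the generator's
ground-truth breast mask almost perfectly; and the fused feature vector
concatenates the 100-bin alpha histogram with the 512-bin MLBP histogram.

A full experiment (extraction, cross-validated SVM per descriptor, t-test
table) runs from a YAML config via the CLI:

```bash
densitex synth --n-per-class 5 --seed 42 --out data/
densitex run --config examples/run.yaml --out runs/
```

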