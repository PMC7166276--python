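# idcgrade

Texture-analysis pipeline for grading breast **invasive ductal carcinoma
(IDC)** from contrast-enhanced MR slices. The clinical target is binary:
separate histological grade II from grade III lesions preoperatively, so
that imaging can inform the choice between treatment options before a
biopsy result exists. The package is aimed at medical-image-analysis
researchers who want a transparent, fully testable radiomics-style
baseline rather than a learned black box.

## The method

For each patient, three slices with a visible lesion are analyzed inside
60×60 px regions of interest (ROIs):

1. **Segmentation** — each ROI is decomposed with a 2-level discrete
   wavelet transform (`db2`, periodized); every pixel gets an 8-channel
   descriptor (intensity, six detail-subband magnitudes, level-2
   approximation) and is clustered by K-means minimizing
   J = Σᵢ Σ_{x∈Gᵢ} ‖x − Cᵢ‖². The brightest cluster, reduced to its
   largest 4-connected component, is the tumor mask.
2. **Texture features** — a Gabor bank of 5 wavelengths
   (λ ∈ {2, 4, 8, 16, 32} px) × 8 orientations (0°–157.5°), σ = 2π,
   γ = 1, φ = 0, filters each ROI; the feature is the mean complex
   magnitude over the tumor mask, Fⱼ = (1/n) Σ I(x, y). With the three
   raw-slice region means this gives 3×40 + 3 = **123 features** per
   patient.
3. **Feature ranking** — per z-scored feature, the mean squared distance
   D from grade-III samples to the grade-II point set is mapped to a
   separability score idx = 1 − e^{−(D/β)²} ∈ [0, 1); features are
   ranked by idx and the top-k (default 8) kept. A PCA baseline is
   included for comparison.
4. **Grading** — a kernel SVM (dual problem with box constraint
   0 ≤ αᵢ ≤ C and Σyᵢαᵢ = 0; linear, polynomial and Gaussian kernels,
   C ∈ {1, 2, 8, 16, 32}) is evaluated by stratified 3/4/5-fold
   cross-validation with pooled confusion counts; grade III is the
   positive class for accuracy/sensitivity/specificity.

Because the original patient cohort is not distributable, the package
ships a seeded **phantom generator**: 352×352 slices with a bright
textured lesion disk whose oriented sinusoidal texture differs by grade
(45° vs 90° at λ = 4 px), plus exact ground-truth masks — so
segmentation overlap, feature-ranking recovery and end-to-end grading
accuracy are all verifiable. See `docs/methods.md` for the full model
description and design rationale.

## Worked example

```python
import tempfile
from idcgrade.synthetic_phantoms import PhantomSpec, make_cohort
from idcgrade.gabor_features import build_bank, extract_cohort_features
from idcgrade.wavelet_segmentation import SegmentationConfig
from idcgrade.model import TextureGradingModel

with tempfile.TemporaryDirectory() as d:
    manifest, truths = make_cohort(PhantomSpec(), n_per_class=14, seed=7, out_dir=d)
    matrix = extract_cohort_features(manifest, SegmentationConfig(seed=11), build_bank())
    results = TextureGradingModel(matrix, k_features=8, n_folds=3).fit(seed=3)
    print(results.summary())
```

prints

```
Texture grading model (Gabor features + kernel SVM)
=======================================================
patients: 28   features: 123   subset size: 8
CV protocol: stratified 3-fold, seed 3, fold-internal ranking: True
selected kernel: gaussian s2=5   C = 1

pooled confusion   TP=13  FN=1  TN=14  FP=0
accuracy     96.43%
sensitivity  92.86%   (grade III detection)
specificity 100.00%   (grade II detection)

top-ranked features (full cohort):
    1. f_s2_l4_o45            D=3.9767  idx=0.9767
    2. f_s1_l4_o45            D=3.9622  idx=0.9761
    3. f_s1_l4_o90            D=3.9346  idx=0.9748
    4. f_s3_l4_o45            D=3.9339  idx=0.9747
    5. f_s3_l4_o90            D=3.9066  idx=0.9734
    6. f_s2_l4_o90            D=3.8835  idx=0.9723
    7. f_s2_l16_o112.5        D=2.4357  idx=0.7559
    8. f_s2_l16_o90           D=2.3687  idx=0.7365
```

Reading the output: 3-fold CV over the 28 phantom patients classifies
27/28 correctly with a Gaussian kernel (σ² = 5, C = 1), and the six
top-ranked features are exactly the bank responses at the injected
texture wavelength (λ = 4) and the two class orientations (45°, 90°)
across all three slices — the ranking recovered the planted signal.

The same pipeline is available from the shell:

```bash
idcgrade simulate --n-per-class 14 --seed 7 --out data/
idcgrade run --manifest data/manifest.csv --k 8 --folds 3 --seed 3 --out results/
```

with `segment`, `features`, `rank` and `evaluate` subcommands for the
individual stages. Real cohorts use the same manifest layout
(`patient_id, slice1..3, roi*_row/col, grade`) over grayscale PNG/TIFF
(or single-slice DICOM/NIfTI) images.

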