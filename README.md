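# cryptgrade

Quantitative grading of crypt architectural distortion in inflammatory
bowel disease (IBD) biopsy images.

Chronic IBD remodels the colonic mucosa: crypts lose their straight
tubular profile, crypt density falls, and the crypt bases pull away from
the muscularis mucosa. Pathologists grade this architectural distortion
Normal / Grade I / II / III, with substantial inter- and intra-observer
variability. `cryptgrade` automates the assessment for a single
well-oriented microscopy field:

1. **Segmentation** — median filtering and background subtraction, then a
   greedy active contour ("snake") minimizing
   `E = α·E_continuity + β·E_curvature + γ·E_image + κ·E_constraint`
   locates closed crypt outlines; the muscularis edge is the upper border
   of the dark band at the image bottom.
2. **Features** — eleven normalized morphometrics per image:
   - **fd1…fd9**: magnitudes of the Fourier descriptors
     `z_u = (1/K) Σ_k r_k e^{−2πiuk/K}` of each crypt's radial signature
     r(θ) about its centroid, with z₀ nullified (position), magnitudes
     divided by |z₁| (size) and phases dropped (rotation), averaged over
     crypts;
   - **mst_spacing**: mean edge length of the Euclidean minimum spanning
     tree over crypt moment-centroids (x̄ = M₁₀/M₀₀, ȳ = M₀₁/M₀₀),
     normalized by the maximum distance encountered in the tree;
   - **musc_distance**: mean perpendicular norm from the muscularis
     OLS line (y = ax + b) to the line fitted through the first-row crypt
     base points, normalized by the image diagonal.
3. **Classification** — a probabilistic neural network (Parzen-window
   Bayes classifier): class densities
   `f_i(v) = (1/n_i) Σ_w exp(−‖v−w‖²/2σ²)` over stored training patterns,
   decision `argmax_i p_i·L_i·f_i(v)`.

Because no clinical images are distributed, the package ships a synthetic
generator producing grade-parameterized mucosa fields with exact ground
truth (crypt outlines, centroids, muscularis edge), used throughout the
test suite. See `docs/methods.md` for models, parameters and limitations.

## Worked example

Simulate a small balanced cohort, extract features, train, and grade:

```sh
cryptgrade simulate --n-per-grade 3 --seed 11 --outdir cohort
cryptgrade extract cohort/*.png --out features.csv
cryptgrade train --features features.csv --out model.json --sigma 0.15
cryptgrade grade cohort/0009_III.png --model model.json
```

which prints

```
wrote 12 images to cohort
wrote 12 feature rows to features.csv
model with 12 patterns -> model.json
Grade III
```

The feature table shows the grade-dependent morphometry (excerpt;
`musc_distance` is the scale-normalized crypt-base-to-muscularis gap and
rises with severity, `n_crypts` falls):

```
  source_id    fd2  mst_spacing  musc_distance  n_crypts  grade
0000_NORMAL 11.029        0.600          0.016        24 NORMAL
     0003_I 28.224        0.686          0.031        12      I
    0006_II 10.671        0.824          0.047         9     II
   0009_III  8.304        0.896          0.074         4    III
```

Predicting the training cohort back and scoring it:

```sh
cryptgrade predict --model model.json --features features.csv --out pred.csv
cryptgrade evaluate --predictions pred.csv --reference features.csv
```

```
grade     precision   recall
Normal    100.00%    100.00%
Grade I   100.00%    100.00%
Grade II  100.00%    100.00%
Grade III 100.00%    100.00%
overall   100.00%   (n=12)
```

Here *precision* for a grade is the fraction of cases classified into
that grade that truly belong to it, *recall* the fraction of true cases
of the grade that were recovered, and *overall* the micro-average
(correct / total). A full PNN memorizes a separable training set, hence
the 100% training-phase recognition; held-out performance is what the
test suite's 120-field recovery benchmark measures (stratified 2/3–1/3
split, overall precision ≥ 85% required).

The same workflow runs from Python:

```python
from cryptgrade import (generate_cohort, extract_features, split_dataset,
                        train, classify, evaluate)

cases = []
for image, truth in generate_cohort(30, rng_seed=123):
    vec, qc = extract_features(image)
    cases.append((vec, truth.grade))
train_set, test_set = split_dataset(cases, 2/3, seed=123)
model = train([v for v, _ in train_set], [g for _, g in train_set], sigma=0.1)
report = evaluate([classify(model, v)[0] for v, _ in test_set],
                  [g for _, g in test_set])
print(report)
```

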