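# Methods

`cryptgrade` quantifies crypt architectural distortion — the histological
hallmark of chronicity in inflammatory bowel disease (IBD) — from single
well-oriented microscopy fields of colonic mucosa. This note records the
models, the numerical choices, and what the synthetic benchmark does and
does not establish.

## Pipeline overview

1. **Preprocessing.** The image (RGB converted by BT.709 luminance) is
   background-subtracted, contrast-rescaled to 0–255, and median-filtered.
   When a paired background exposure is available it is subtracted
   directly; otherwise the background is estimated morphologically: grey
   *closing* with a structuring radius much larger than a crypt radius
   (default 60 px) fills the dark crypt lumina and tracks the smooth
   illumination-modulated stroma. (Grey opening plays this role when the
   polarity flag marks objects brighter than their surround.) The estimate
   is computed on a 4×-downsampled copy and resized back, since the
   illumination field is smooth by construction; translation equivariance
   is therefore exact for shifts that are multiples of 4 px.

2. **Segmentation.** Otsu thresholding of the cleaned image, hole filling
   and size filtering seed one initial contour per candidate dark
   component (its convex hull, dilated 3 px, resampled to `n_vertices`).
   Each contour is refined by a discrete greedy active contour ("snake")
   minimizing

   `E = α Σ|v_i − v_{i−1}|² + β Σ|v_{i−1} − 2v_i + v_{i+1}|² − γ Σ G(v_i) + κ Σ max(0, r_i − 2·r̄₀)²`

   where `G` is the gradient magnitude of the Gaussian-smoothed image
   (σ = 2 px) and the last term is an inward pressure that blocks expansion
   beyond twice the initial mean radius. Each vertex in turn moves to the
   lowest-energy position of a 7×7 integer window, accepting only strict
   improvements of the terms it touches — so the total energy is provably
   non-increasing across accepted moves, with no step-size tuning and full
   determinism. Defaults: α = 0.4, β = 0.2, γ = 1.0, κ = 0.1, 64 vertices,
   stop when the largest per-vertex move of a sweep falls below 0.5 px or
   after 500 sweeps. A consequence of integer moves is that a dense contour
   on a featureless image stalls once the chord sagitta drops below 1 px;
   in practice initialization places contours within a few pixels of the
   lumen edge and the image term dominates. The muscularis mucosa is the
   upper edge of the largest dark component touching the bottom border,
   returned as an open polyline (well-oriented fields only; rotated
   specimens are out of scope).

3. **Shape features.** Each crypt outline is parametrized as `r(θ)` about
   its moment centroid, sampled at K = 64 equally spaced angles by exact
   ray–polygon intersection (maximum crossing for non-star-convex
   outlines; crossings are detected by half-open sign classes of the
   perpendicular coordinate, so a ray through a vertex cannot fall through
   a gap). The K-point DFT with the 1/K factor gives coefficients `z_u`;
   normalization nullifies `z_0` (position), divides magnitudes by `|z_1|`
   (size) and discards phases (rotation). Features fd1…fd9 are the
   normalized `|z_1|…|z_9|`; the per-image value is their mean over
   non-degenerate crypts.

   **A caveat worth knowing.** For a radial parametrization about the
   *area centroid*, the first harmonic cancels to first order in the
   distortion amplitude (the centroid of `r = R(1 + ε·cosθ)` shifts by
   `R·ε`, absorbing the cosθ term), so `|z_1|` is O(ε²) plus a
   discretization floor while `|z_2..9|` are O(ε). Dividing by `|z_1|`
   therefore makes fd2–fd9 *larger* for mildly distorted outlines and
   highly variable near circularity. The normalization is implemented as
   stated because it is the method's defining recipe; crypts with
   `|z_1| < 10⁻¹²·|z_0|` are flagged degenerate (maximally regular) and
   excluded from the image mean, with the all-degenerate case yielding a
   zero vector plus flag. The features remain grade-separating — the
   classifier does not require monotonicity — but the basal-gap and
   spacing features carry the ordered signal.

4. **Density feature.** Crypt centroids come from the discrete moments of
   the filled outline (`M_pq = Σ x^p y^q f(x,y)` over the binary mask,
   boundary pixels included; `x̄ = M10/M00`, `ȳ = M01/M00`). Kruskal's
   algorithm on the complete Euclidean graph (stable `(w, i, j)` edge
   order, union-find) yields the MST; the feature is the mean MST edge
   length divided by the maximum distance encountered in the tree. The
   denominator is read as the maximum *MST edge* (keeping the feature in
   (0, 1] and sensitive to spacing irregularity); the maximum pairwise
   distance is available via `mode="pairwise"`. Zero or one crypt
   saturates the feature at 1.0 with a sparse flag — crypt loss is the
   severe-disease direction, and a sentinel beats a non-finite entry.

5. **Basal-gap feature.** A first-order line `y = ax + b` is fitted by
   closed-form OLS to the muscularis polyline, and a second to the base
   points of the first row of crypts (crypts whose centroid distance to
   the muscularis line is within 1.5× the minimum; each contributes its
   boundary vertex nearest that line; fallback to the two nearest crypts).
   Perpendicular norms from every muscularis vertex to the crypt line are
   averaged. Because near-parallel fitted lines drive the mean/max-norm
   ratio to ≈ 1 regardless of the gap, the default feature is
   `mean norm / image diagonal` — the absolute gap, scale-normalized —
   with the mean/max ratio computed alongside and selectable via
   `mode="ratio"`. A missing muscularis or a single crypt saturates at
   1.0, mirroring the density sentinel.

6. **Classification.** A probabilistic neural network: training stores the
   min–max-scaled feature vectors verbatim (one hidden node per pattern)
   and the class-conditional density is the Parzen window
   `f_i(v) = (1/n_i) Σ exp(−‖v − w‖²/(2σ²))`. A vector is assigned to the
   class maximizing `p_i·L_i·f_i(v)`; priors default to empirical class
   frequencies, losses to 1, and exact ties break toward the lower grade
   (the conservative direction for a screening aid; configurable). Test
   vectors are clipped to [−0.5, 1.5] on the scaled axis to bound
   extrapolation. σ defaults to 0.1 on scaled features; `select_sigma`
   maximizes leave-one-out accuracy over a grid (ties → smallest σ). When
   every class score underflows (σ far too small) the decision falls back
   to the nearest stored pattern, with a warning. Models serialize to a
   single versioned JSON document.

7. **Evaluation.** Per-class precision uses the classifier-column
   denominator (correct over all cases *classified into* the grade) and
   recall the reference-row denominator; this is the only reading under
   which a 4×4 table with 9 true moderate cases, all recovered, plus one
   mild case misread as moderate gives 90% precision and 100% recall for
   the moderate grade. Overall precision is the micro-average
   (trace/total). Zero denominators yield an undefined flag rather than a
   number. The stratified splitter uses largest-remainder rounding of
   `fraction · n_class` so class totals add up to `round(fraction · n)`
   — e.g. grade counts (43, 39, 26, 10) at 2/3 split 79/39 with training
   counts (29, 26, 17, 7); classes with fewer than two cases go wholly to
   training with a warning.

## Synthetic benchmark

No clinical images ship with the package, so a generator provides fields
with exact ground truth. Each grade is parameterized by a boundary
distortion amplitude, a crypt count interval, a spacing jitter, and a
basal gap (crypt base to muscularis):

| grade  | distortion | crypt count | spacing jitter | basal gap (px) |
|--------|-----------:|------------:|---------------:|---------------:|
| Normal | 0.03       | 18–24       | 0.05           | 15             |
| I      | 0.15       | 12–18       | 0.15           | 25             |
| II     | 0.35       | 8–12        | 0.30           | 40             |
| III    | 0.60       | 4–8         | 0.45           | 60             |

Distortion and basal gap increase, and crypt density decreases, strictly
with severity, matching the qualitative histology of chronic IBD. The
spacing jitter (not fixed by the qualitative description) grows with grade
because architectural irregularity is itself the lesion; the gap jitter is
0.15 throughout. Crypt outlines are star-shaped:
`r(θ) = R(1 + d·Σ c_h cos(hθ + φ_h))`, harmonics h = 2…5 (a pure first
harmonic mostly displaces rather than distorts), coefficients rescaled so
the summed amplitude is ≤ 0.8, guaranteeing r > 0. Crypts are laid on a
jittered grid above the muscularis band, bottom row first, with rejection
sampling against overlap; unplaceable crypts are dropped and the ground
truth records actual counts. Rendering: stroma 185, lumina 70, muscularis
60 (8-bit gray), Gaussian blur σ = 1, a multiplicative low-order-polynomial
illumination field of exactly ±10% amplitude (so background subtraction is
exercised), and additive Gaussian noise σ = 5. The default canvas is
800×600 with base crypt radius `min(width, height)/24`; all sizes are
configurable and the features are scale-normalized.

What the generator does **not** emulate: H&E colour and stain variation,
inflammatory cells, crypt branching as a distinct topology (branching
appears only through harmonic distortion), mucin depletion, tissue tears,
or rotated/poorly oriented specimens. Passing the synthetic recovery
benchmark therefore shows that the pipeline recovers the geometry it
models, not that it grades real slides; on clinical material the
segmentation stage is the component most exposed to un-modelled variation.

## Numerical choices and degenerate inputs

- K = 64 radial samples (power of two, ≥ 7× the highest retained
  harmonic).
- `|z_1|` degeneracy guard: 10⁻¹²·|z_0| (absolute 10⁻¹² when z_0 = 0).
- Kruskal tie-break: stable sort by (weight, i, j), i < j; duplicate
  points produce zero-weight edges rather than errors.
- All-equal MST edges (or n ≤ 1) give spacing feature 1.0 exactly.
- Vertical point sets are rejected by the line fitter with a
  degenerate-orientation error (cannot occur for width-spanning
  muscularis polylines).
- Blank or crypt-free images yield the sentinel vector
  (0,…,0, 1.0, 1.0) and an unreadable-case status end to end — never a
  silent grade.
- Coordinates are 0-based pixel indices, x rightward, y downward; closed
  boundaries are stored counter-clockwise without a repeated end vertex.

## Problem sizes used by the test suite

The synthetic recovery benchmark uses 120 fields of 800×600 px (30 per
grade, seeded), a stratified 2/3–1/3 split and the default configuration;
held-out overall precision is required to reach 85%. Contour-seeding
recall is checked on a 50-field 400×300 cohort, centroid recovery
(Hungarian matching, 3 px) on a smaller multi-grade cohort. Oracle
equivalence tests run exhaustive MST enumeration up to n = 7 points
(Prüfer sequences) and the literal O(K²) DFT at K ≤ 64.

## Known limitations

- The |z_1| size normalization is noise-amplified near circular outlines
  (see above); averaging over crypts mitigates but does not remove this.
- The greedy snake moves on the integer grid; boundary localization is
  ±0.5 px at best, and featureless regions stall dense contours.
- The muscularis model assumes a single dark band touching the bottom
  border of a well-oriented field.
- The PNN stores every training pattern; classification cost grows
  linearly with the training set (irrelevant at this problem scale).
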