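# Methods

## Model and assumptions

The package treats a 2-D axial brain MR slice as an approximately
zygomorphic object: mirror-symmetric about a single vertical axis. Under
that assumption, healthy anatomy cancels in the difference between the
slice and its left-right reflection, and any bilaterally *asymmetric*
hyperintensity — the tumor model used throughout — survives as a positive
residual at its true location. The assumptions this rests on:

1. the symmetry axis coincides with the geometric image midline (column
   `(cols−1)/2`); the pipelines never estimate an anatomical midline.
   An optional integer recentering (`shift_search`) greedily minimizes the
   mirror residual over ±10 % of the width, for slices that are translated
   but not rotated; it is off by default.
2. lesions are hyperintense relative to the tissue at their mirror
   position (T2/FLAIR-like contrast);
3. natural hemispheric asymmetry and noise are small compared to lesion
   contrast.

Sign handling: `D = O − R` is kept signed (it is exactly
mirror-antisymmetric), and all downstream stages consume the rectified
field `max(D, 0)`. This keeps each lesion's evidence at its own location,
which is what makes bilateral and multiple lesions separable. The mirror
site of a bright lesion carries an equally negative residual that the
rectification discards rather than mistaking it for a second lesion.

## Pipeline stages and parameters

| parameter | default | units | role |
|---|---|---|---|
| `preprocess_radius` | 2 | px | disk radius of the grayscale opening; removes speckle smaller than ~5 px across without displacing lesion boundaries. Applied once (opening is idempotent). |
| `seed_frac` | 0.5 | — | HASA seed threshold as a fraction of the rectified-difference maximum |
| `seed_min_area` | 10 | px | smallest component accepted as a seed; rejects isolated noise pixels |
| `noise_floor` | 0.05 | intensity | rectified-difference maximum below which the slice is declared asymmetry-free |
| `ehasa_fraction` | 0.25 | — | EHASA binarization threshold as a fraction of `max(O)` |
| `mu` | 0.2 | — | contour-length weight, calibrated to unit-range intensities |
| `lambda1`, `lambda2` | 1.0 | — | inside/outside fidelity weights |
| `dt` | 0.5 | — | explicit step size |
| `eps` | 1.0 | φ-units | Heaviside/Dirac smoothing width |
| `max_iter` / `tol` | 500 / 1e-3 | — | iteration cap / convergence threshold |

All images are normalized to [0, 1] on read (DICOM: rescale slope/intercept,
then the linear display window when the file carries one, else min-max;
constant slices map to all-0.5 so pipelines trivially find nothing). The
uniform normalization makes the 25 %-of-max threshold scale-free.

`T = 0.25·max(O)` uses the *original* (preprocessed) image's maximum, not
the difference image's: on a normalized slice with a bright structure the
threshold is ≈ 0.25, well above natural-asymmetry residuals and well below
typical lesion contrast. An alternative threshold equal to the mean of the
rectified difference is available (`ehasa_use_mean`) for fidelity
experiments; it is far more permissive and not the default.

## Level-set numerics

* Smoothed Heaviside: arctan form, `H_ε(φ) = ½(1 + (2/π) arctan(φ/ε))`.
  Its delta has full support, so contours can nucleate or vanish anywhere
  and seeded fronts cannot get stuck on a zero gradient.
* Curvature `div(∇φ/|∇φ|)` by central differences (one-sided at borders)
  with 1e-8 added to the gradient-norm denominators.
* The force `μκ − λ1(I−c1)² + λ2(I−c2)²` is normalized by its maximum
  magnitude before the step `φ += dt·δ_ε(φ)·F/‖F‖_∞`. Normalization keeps
  the update a descent direction while making the front speed O(dt) even
  when `c1 ≈ c2` — the regime right after a checkerboard initialization,
  where raw forces nearly cancel and plain descent needs thousands of
  iterations to break the tie. Energy is observed (and tested) to be
  non-increasing per iteration on the two-phase disk fixture.
* Convergence is the δ_ε-weighted mean of |Δφ| falling below `tol`. The
  weighting restricts the mean to the active band around the contour; an
  image-wide mean would be dominated by the static far field of a
  signed-distance φ and stop a seeded evolution immediately.
* Region means are computed with exact (order-independent) summation
  `math.fsum`, and seed signed-distances analytically from disk geometry.
  Together with the symmetric discretizations above this makes both
  pipelines *exactly* equivariant under left-right mirroring — the
  equivariance test asserts bit-equality, not approximate agreement.
* Degenerate cases: an emptied region's mean falls back to the global mean
  (no NaNs); non-finite φ aborts with an error naming the iteration; a
  zero-contrast image short-circuits the baseline to an empty result.
* Optional signed-distance reinitialization every `reinit_every`
  iterations is available but off by default.
* Seeds initialize φ as the signed distance to the union of seed disks
  (radius = equivalent-area radius of the component, floored at 2 px);
  components are never merged before final labeling, which is what lets a
  two-lesion slice produce two regions. The no-seed (baseline) mode uses a
  `sin(πx/5)·sin(πy/5)` checkerboard, and reports the *brighter* phase as
  the object.

## The phantom generator

`make_phantom` renders: background 0.05; a bright elliptical brain (0.55);
a bilaterally symmetric skull/scalp rim (0.80) separated from the brain by
a dark gap — present because real slices have one, and because without it a
whole-image Chan–Vese has only a single bright component and the baseline
comparison would be vacuous; a mirrored pair of dark ventricles (0.25);
lesions as anti-aliased ellipses adding +0.40 (default) over the local
tissue; optional non-tumor bright artifacts (excluded from ground truth);
multiplicative per-pixel jitter up to ±2 % on one hemisphere (mild natural
asymmetry); and additive Gaussian noise, σ = 0.02 in the standard suite,
truncated at ±3σ so a single noise outlier can never imitate a lesion.
Ground truth is the union of ideal lesion ellipses, rendered before jitter
and noise, hence independent of the realization. All symmetric structures
are centered on the exact mirror axis, so a lesion-free, noise-free spec is
bit-exactly symmetric.

The standard suite fixes six 128×128 fixtures (symmetric, left-lesion,
right-lesion = exact mirror of left, bilateral-two-lesions,
midline-lesion, lesion-plus-artifact); the acceptance script adds one
512×512 case with ×4-scaled geometry to match a 512-row clinical
acquisition. 128×128 keeps a full pipeline run in the low seconds; the
method itself is resolution-agnostic.

What the phantoms do *not* emulate: MR bias fields, Rician noise, partial
volume at tissue interfaces, gyral/sulcal texture, head rotation, and
anatomically realistic midline curvature. Passing tests therefore
demonstrate the pipelines' *mechanics* (cancellation, localization,
thresholding, contour convergence, equivariance) — not clinical accuracy on
real scans, where midline estimation and intensity non-uniformity dominate
the error budget.

## Design choices that were genuinely open

* **Structuring element**: never dictated by the problem; a radius-2 disk
  removes speckle while preserving ≥ 6 px lesions. Exposed in config.
* **Seed selection**: "where high intensities aggregate" is implemented as
  *all* components above `seed_frac`·max surviving the area filter, not
  just the largest — required for multiple-tumor detection.
* **EHASA seeding**: the threshold stage yields a mask, not a point; seeds
  are the mask's components (the only locations available).
* **Border components** are kept by default (a large tumor may touch the
  brain edge); `drop_border_regions` discards them.
* **Baseline orientation**: a checkerboard-initialized contour may converge
  with either phase inside; the baseline reports the brighter phase, which
  is the only physically meaningful choice for hyperintense targets.

## Known limitations

* A lesion centered on the symmetry axis cancels in `D` and is missed by
  construction; the evaluation report flags this (`midline_limitation`)
  when a missed ground-truth lesion straddles the axis (within 5 % of the
  image width).
* A perfectly mirror-symmetric *pair* of identical lesions would likewise
  cancel; in practice exact bilateral identity is a measure-zero situation
  and mild asymmetry between the pair re-exposes both.
* Strong head tilt or rotation violates assumption 1; only integer
  horizontal translation is compensated, and only on request.
* Hypointense (dark) lesions are invisible to the rectified field by
  design; segmenting them would require the negative part instead.
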