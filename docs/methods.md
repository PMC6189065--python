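# Methods

## Problem and model

At inspiration the lung inflates non-uniformly: displacement is largest in
the basal and peripheral parenchyma and smallest near the apex and hilum.
Fibrosing interstitial disease stiffens exactly those basal/peripheral
regions, so diseased lungs expand less *and* more homogeneously. The
package quantifies this by registering the expiratory scan onto the
inspiratory one, reading off the per-voxel displacement (degree of lung
expansion, DLE), and summarizing its distribution.

All computation uses one coordinate contract: arrays are indexed (x, y, z)
with +x patient-left, +y posterior, +z superior; physical mm positions are
voxel-center based (`origin + index * spacing`, 0-based). Transforms map
expiratory physical points to inspiratory physical points.

## Registration chain

Stage order is fixed: **affine → TPS → demons**, each stage fitted in the
coordinates produced by the previous one, independently per lung (landmarks
at the carina carry side `both` and join both fits).

- **Surface-based affine.** Boundary voxel centers of the two lung masks
  (seeded uniform subsample, default 1500 points/side) are aligned by
  iterative closest point with a full 12-parameter least-squares update per
  iteration, initialized by centroid shift plus per-axis bounding-box
  scaling. Stops on relative RMS change < 1e-5 or 50 iterations. ICP needs
  non-coplanar clouds; degenerate input is rejected.
- **Thin-plate spline.** Exact interpolation with the 3D kernel φ(r) = r and
  no regularization; the linear system carries the affine polynomial part,
  so kernel weights satisfy the usual orthogonality conditions to
  machine precision and a pure translation yields zero weights. Source
  landmarks are pre-mapped by the affine stage.
- **Demons.** Classic additive demons: per-voxel update
  `(T − S∘φ) ∇T / (|∇T|² + (T − S∘φ)²/κ²)`, κ defaulting to the masked mean
  gradient magnitude, per-iteration step capped at half a voxel, Gaussian
  smoothing of the field (σ = 1.5 voxels) after every iteration, 3
  resolution levels × 50 iterations. The masked mean-squared HU difference
  is monitored; ten consecutive increases abort the level and the best
  field seen is returned. **Direction convention:** the expiratory image
  anchors the demons grid (the field maps expiratory points into the
  inspiratory image), so the demons total field composes directly with the
  affine/TPS stages; the stage is stored as a residual on the expiratory
  grid.

QC metrics: per-side mean ± SD landmark distance after any stage subset;
per-side |inspiratory − warped-expiratory| lung volume, the expiratory mask
pushed through the chain's fixed-point inverse (tolerance 0.05 mm, ≤ 30
iterations, nearest-neighbour resampling); Dice of repeated/derived masks
(both-empty convention: Dice = 1, flagged by construction).

## Segmentation

Aerated lung is isolated by an HU window (default [−1024, −200]; the upper
threshold is a per-subject choice in the −400…−200 range and is exposed,
not auto-tuned), keeping the two largest 26-connected components, with
morphological closing (radius 1) and hole filling so intrapulmonary
vessels/bronchi stay inside the mask.

## DLE and histogram statistics

Per-axis DLE uses **absolute** displacement components; per-axis means are
therefore below the 3D mean and all values are nonnegative, matching how
per-axis expansion histograms are reported in practice. Voxels are sampled
in the expiratory frame with no Jacobian volume-change weighting.
Statistics are computed on the binned distribution (bin width 1 mm anchored
at 0; bin centers as x_i) exactly as written in the README; kurtosis is
non-excess (normal ≈ 3); entropy uses log base 2 by default (recorded in
every output row). Percentiles use linear-interpolation empirical quantiles
of the raw voxel values — binned percentiles would differ by at most one
bin width. Degenerate input (single occupied bin) reports SD = 0,
entropy 0, uniformity 1, and skewness/kurtosis as undefined (None), never
NaN propagation. The upper/lower split is a supplied z-plane standing in
for the lower-lobar-bronchus branch level; anatomy finding is out of scope.
Standardized mean and SD divide by a reference vital capacity
VC = TLC_ref − RV_ref whose linear predictors must be supplied per cohort
(pluggable coefficients; none are bundled).

## Synthetic phantom

The generator is the package's study bed and defines the test conditions.

- **Geometry.** Two ellipsoidal lungs (semi-axes 0.15/0.24/0.32 of the grid
  extent) at −850 HU inside soft tissue at 0 HU filling the grid; additive
  Gaussian noise (SD 20 HU). A seeded binary tube tree per lung (5
  bifurcation levels, radii 3 → 1.2 mm, HU −100) supplies landmarks:
  branch points are *bronchial* (15/lung), terminal tips near the pleura
  are *vascular* (16/lung), plus one shared carina — 31 marks per lung,
  the density a reader would place.
- **Inflation field.** Analytic and smooth:
  `u(p) = s · d(p) · [A (p − apex) + bump(p)]` with diagonal affine
  inflation about the apex anchor (0.04 in x/y, 0.10 in z), plus a
  separable smoothstep bump growing toward the base and periphery (radial
  coefficient 0.08, basal bump 8 mm). The displacement gradient stays
  ≪ 1, so the forward map is diffeomorphic (checked via finite-difference
  Jacobians); inversion is a fixed-point iteration. The inspiratory volume
  is the expiratory one resampled through the exact inverse; the
  inspiratory mask is the analytic lung indicator at the preimage, and
  ground-truth landmark pairs satisfy `insp = exp + u(exp)` to < 1e-6 mm.
- **Fibrosis.** A smooth basal-peripheral shell (fraction 0.3 of the lung
  height) where displacement is multiplied by a damping factor 0.3 and HU
  rises toward −300. Two interpretable knobs reproduce the two observed
  effects of fibrosis: lower mean expansion and lower heterogeneity.
- **Reader jitter.** `observed_landmarks` adds isotropic Gaussian placement
  error (default 1 mm, the slice thickness a reader works at). Ground-truth
  pairs stay exact; the pipeline consumes the jittered ones.
- **Cohort.** Per-subject seeds from a SeedSequence; inflation scale
  ~ N(1, 0.12) truncated to [0.6, 1.4]; age ~ N(60, 10), height
  ~ N(1.55, 0.06) m; reference VC = 4.9·height − 4.55 L + N(0, 0.15).
  Synthetic FVC = 0.8 + 0.25·(lower-lung mean 3D DLE) + noise, the noise SD
  derived from the realized between-subject spread so the designed
  r² (default 0.6) is recoverable; zero noise makes the relation exact.
  The design quantity is measured exactly as the analysis measures it
  (1 mm-binned histogram mean), so the ground-truth bypass reproduces it
  bit-for-bit.

What the phantom does **not** emulate: airway/vessel anatomy beyond a
random binary tree, ribs and diaphragm, breathing-phase variability, CT
reconstruction physics, or segmentation ambiguity at the fibrotic pleura.
Passing tests therefore demonstrate correctness of the algorithms under
known smooth deformations with realistic contrast and noise — not clinical
accuracy on patient scans.

## Registration accuracy experiment

Ground-truth landmark pairs are exactly consistent with the analytic field,
so a TPS fitted *and* evaluated on the same marks has zero error by
construction and the demons stage could only appear harmful. The accuracy
experiment therefore (a) feeds the chain observed (jittered) landmarks,
(b) fits the TPS on bronchial marks only, and (c) evaluates every stage
against the exact, held-out vascular pairs. On 96³ phantoms the per-stage
mean error falls ≈ 10.7 → 3.3 → 2.2 → 0.9 mm, monotone across seeds, and
the full chain stays within two voxel spacings.

## Problem sizes and numerical choices

The default phantom is 96³ voxels at 2 mm (a 192 mm organ); statistical
Monte-Carlo experiments run the same organ at 32³ / 6 mm, where a fully
registered subject takes ~1 s, a scale chosen so cohort-level properties
are cheap to replicate. Group comparison uses the two-sided Mann–Whitney U:
exact by full enumeration of group labelings (tie-aware midranks) up to
combined n = 12, normal approximation with tie correction above.
Correlation selects Pearson when both variables pass Shapiro–Wilk at
α = 0.05, Spearman otherwise, and records the method per row; constant
input yields an undefined-correlation marker. Raw p-values are reported
without multiplicity correction (an optional Benjamini–Hochberg column can
be enabled in config). All randomness flows from explicit integer seeds;
identical configuration and seeds give byte-identical outputs.

## Known limitations

- The demons variant is the classic additive scheme, not diffeomorphic or
  log-domain demons; large-slip boundaries (e.g. lung sliding against the
  chest wall) are not modeled and not needed for the phantom.
- The upper/lower split plane and the reference-volume equations must be
  supplied for real data.
- Nearest-neighbour mask warping makes the volume-difference QC accurate to
  roughly a half-voxel boundary band; use ≥ 64³ grids when that metric
  matters.
- The exact Mann–Whitney enumeration is O(C(n, n1)) and is capped at
  combined n = 12 by default.
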