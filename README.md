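# lungexpand

Quantifies **inspiratory lung expansion** from paired expiratory and
inspiratory chest CT volumes. In fibrosing interstitial lung disease (ILD),
the basal and peripheral lung stiffens and inflates less; this package
measures that effect voxel by voxel and summarizes it with first-order
histogram statistics, for imaging researchers studying regional lung
mechanics.

## What it computes

1. **Registration chain** (expiration → inspiration), fitted per lung:
   - *surface-based affine*: iterative-closest-point on lung boundary point
     clouds, initialized by centroid shift + per-axis bounding-box scaling;
   - *landmark thin-plate spline*: exact 3D TPS (kernel φ(r)=r) on paired
     bronchial/vascular landmarks, fitted in post-affine coordinates;
   - *attenuation-based demons*: classic per-voxel force
     u = (T − S∘φ)·∇T / (|∇T|² + (T − S∘φ)²/κ²)
     with Gaussian field regularization, multiresolution, and a divergence
     guard.
2. **Degree of lung expansion (DLE)**: for each lung voxel, the absolute
   displacement |dx|, |dy|, |dz| (x horizontal, y ventrodorsal,
   z craniocaudal) and the 3D norm, in mm.
3. **Histogram statistics** on the binned DLE distribution
   (bin width 1 mm, centers x_i, probabilities P(x_i)):
   mean M = Σ x_i P(x_i); SD = √Σ(x_i−M)²P; skewness SD⁻³Σ(x_i−M)³P;
   (non-excess) kurtosis SD⁻⁴Σ(x_i−M)⁴P; entropy −Σ P log₂ P;
   uniformity Σ P²; plus the 5th–95th empirical percentiles, regional splits
   (right/left, upper/lower at a supplied z-plane), and standardization by a
   reference vital capacity (mm/L).
4. **Cohort statistics**: two-sided Mann–Whitney U group comparisons (exact
   by enumeration at small n) and Pearson/Spearman correlation with
   pulmonary-function covariates, gated by Shapiro–Wilk normality.

Because no clinical scans ship with the package, a **synthetic phantom
generator** provides paired volumes with an analytic ground-truth inflation
field (larger basally and peripherally, damped where "fibrosis" raises HU),
branching tube trees whose branch points serve as landmarks, and cohort
covariates with a designed FVC–expansion coupling.

## Worked example

```python
import lungexpand as lx
from lungexpand.cohort import register_pair

spec = lx.PhantomSpec(seed=0)                       # 96^3 voxels, 2 mm
exp_vol, exp_mask, truth = lx.make_phantom(spec)
insp_vol, insp_mask, lm = lx.warp_to_inspiration(exp_vol, truth)
obs = lx.observed_landmarks(lm, 1.0, seed=1)        # 1 mm reader jitter

chains, qc = register_pair(exp_vol, insp_vol,
                           lx.segment_lung(exp_vol), lx.segment_lung(insp_vol),
                           obs, tps_kinds="bronchial", seed=0)
print({k: round(v, 2) for k, v in qc.items() if isinstance(v, float)})
```

prints (seed 0):

```
{'registration_error_mean_right': 2.29, 'registration_error_sd_right': 0.88,
 'registration_error_mean_left': 2.16, 'registration_error_sd_left': 0.97,
 'volume_difference_cm3_right': 25.13, 'volume_difference_cm3_left': 22.23}
```

i.e. after the full chain the observed landmarks agree to ~2.2 mm per lung
(about one voxel) and the warped expiratory lung volume is within ~25 cm³
of the inspiratory one. Evaluated against the *exact* held-out vascular
landmark pairs, the per-stage mean error falls 10.74 → 3.20 → 2.03 →
0.91 mm (none → affine → +TPS → +demons).

DLE summaries then come from the composed field:

```python
from lungexpand.cohort import stitch_fields
from lungexpand import dle_maps, regional_summaries

field = stitch_fields(chains, exp_mask)
dmap = dle_maps(field, exp_mask, truth.split_z)
table = regional_summaries(dmap, vc_ref=truth.vc_ref)   # 36 rows
```

A CLI mirrors these steps (`lungexpand synth / segment / register / dle /
run`).

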