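"""Synthetic paired expiratory/inspiratory CT phantoms with known deformation.

The phantom emulates the structure the expansion analysis assumes:

* two ellipsoidal low-attenuation "lungs" (~-850 HU) inside a soft-tissue
  body (~0 HU), each containing a branching tube tree (bronchi/vessels,
  higher HU), with additive Gaussian HU noise;
* a smooth analytic inflation field anchored at the lung apex, composed of
  an affine inflation plus a separable bump that grows toward the lung base
  and periphery — healthy lungs expand most basally and peripherally;
* an optional "fibrotic" mode that multiplicatively damps the displacement
  and raises HU in a basal-peripheral shell, reproducing the two effects of
  fibrosis on expansion maps: lower mean and lower heterogeneity;
* paired landmarks at tube branch points (bronchial) and terminal tips
  near the pleura (vascular), consistent with the analytic field.

The phantom is built at expiration and warped to inspiration, matching the
registration direction (expiratory source inflated onto inspiratory target).
All geometry is expressed in physical mm as fractions of the grid extent, so
a 32^3 grid at 6 mm spacing is the same organ as 96^3 at 2 mm.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np
from scipy import ndimage

from .volume_io import BinaryMask, LandmarkSet, Volume3D

__all__ = [
    "PhantomSpec",
    "TrueField",
    "GroundTruth",
    "SubjectBundle",
    "make_phantom",
    "make_true_field",
    "warp_to_inspiration",
    "make_cohort",
]

# Field defaults (about the apex anchor): affine inflation coefficients per
# axis and the basal-peripheral bump.  Dimensionless except the bump
# amplitude (mm).
AFFINE_XY = 0.04
AFFINE_Z = 0.10
RADIAL_BUMP = 0.08
BASAL_BUMP_MM = 8.0

FIBROSIS_HU = -300.0  # HU toward which fibrotic lung is raised
VC_SLOPE_L_PER_M = 4.9  # synthetic reference VC = slope*height + intercept
VC_INTERCEPT_L = -4.55
VC_NOISE_SD_L = 0.15
FVC_SLOPE_L_PER_MM = 0.25  # synthetic FVC vs mean basal 3D expansion
FVC_INTERCEPT_L = 0.8
FVC_DESIGN_R2 = 0.6
SUBJECT_SCALE_SD = 0.12  # between-subject inflation variability


@dataclasses.dataclass
class PhantomSpec:
    """Parameters of one synthetic subject."""

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    lung_hu: float = -850.0
    body_hu: float = 0.0
    vessel_hu: float = -100.0
    noise_sd: float = 20.0
    n_branch_levels: int = 5
    fibrosis: bool = False
    fibrosis_fraction: float = 0.3
    fibrosis_damping: float = 0.3  # displacement multiplier inside fibrosis
    inflation_scale: float = 1.0  # per-subject multiplier of the whole field
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(n < 32 for n in self.grid_shape):
            raise ValueError("grid_shape must be at least (32, 32, 32)")
        if not 0.0 <= self.fibrosis_fraction <= 1.0:
            raise ValueError("fibrosis_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.fibrosis_damping < 1.0:
            raise ValueError("fibrosis_damping must be in [0, 1)")

    @property
    def extent(self) -> np.ndarray:
        return np.asarray(self.grid_shape) * np.asarray(self.spacing)


@dataclasses.dataclass
class _Geometry:
    """Physical-mm layout of body, lungs and fibrosis region."""

    extent: np.ndarray
    body_center: np.ndarray  # (x, y) of body axis
    body_radii: np.ndarray  # (x, y) elliptic-cylinder radii
    body_zrange: tuple[float, float]
    lung_centers: np.ndarray  # (2, 3): right (patient right = low x), left
    lung_semiaxes: np.ndarray  # (3,)
    apex: np.ndarray  # anchor point of the inflation field

    @classmethod
    def from_spec(cls, spec: PhantomSpec) -> "_Geometry":
        e = spec.extent
        cx, cy = e[0] / 2, e[1] / 2
        semi = np.array([0.15 * e[0], 0.24 * e[1], 0.32 * e[2]])
        zc = 0.52 * e[2]
        centers = np.array([
            [cx - 0.21 * e[0], cy, zc],  # patient right (low x)
            [cx + 0.21 * e[0], cy, zc],  # patient left
        ])
        apex = np.array([cx, cy, zc + semi[2]])
        return cls(
            extent=e,
            body_center=np.array([cx, cy]),
            body_radii=np.array([0.42 * e[0], 0.40 * e[1]]),
            body_zrange=(0.04 * e[2], 0.96 * e[2]),
            lung_centers=centers,
            lung_semiaxes=semi,
            apex=apex,
        )

    def lung_rho2(self, pts: np.ndarray) -> np.ndarray:
        """Squared normalized ellipsoid radius to the *nearest* lung."""
        pts = np.atleast_2d(pts)
        r2 = np.full(len(pts), np.inf)
        for c in self.lung_centers:
            d = (pts - c) / self.lung_semiaxes
            r2 = np.minimum(r2, np.einsum("ij,ij->i", d, d))
        return r2

    def lung_indicator(self, pts: np.ndarray) -> np.ndarray:
        return self.lung_rho2(pts) <= 1.0

    def side_of(self, pts: np.ndarray) -> np.ndarray:
        """'right' for x below the body midline, else 'left'."""
        pts = np.atleast_2d(pts)
        return np.where(pts[:, 0] < self.body_center[0], "right", "left")

    @property
    def lung_zrange(self) -> tuple[float, float]:
        zc = self.lung_centers[0, 2]
        return (zc - self.lung_semiaxes[2], zc + self.lung_semiaxes[2])


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclasses.dataclass
class TrueField:
    """Analytic expiration->inspiration displacement field (mm).

    ``u(p) = s * d(p) * [A (p - apex) + bump(p)]`` where A is a diagonal
    inflation about the apex anchor, the bump grows smoothly toward the lung
    base and periphery, s is the subject inflation scale, and d(p) in (0, 1]
    is the fibrosis damping (1 outside the fibrotic shell).
    """

    geom: _Geometry
    scale: float = 1.0
    fibrosis: bool = False
    fibrosis_fraction: float = 0.3
    fibrosis_damping: float = 0.3

    def damping(self, pts: np.ndarray) -> np.ndarray:
        """Smooth multiplier in (0, 1]; 1 everywhere for non-fibrotic fields."""
        pts = np.atleast_2d(pts)
        if not self.fibrosis:
            return np.ones(len(pts))
        w = self._fibrosis_weight(pts)
        return 1.0 - (1.0 - self.fibrosis_damping) * w

    def _fibrosis_weight(self, pts: np.ndarray) -> np.ndarray:
        """Smooth [0,1] indicator of the basal-peripheral fibrotic shell."""
        z_lo, z_hi = self.geom.lung_zrange
        z_f = z_lo + self.fibrosis_fraction * (z_hi - z_lo)
        tau = 0.04 * (z_hi - z_lo)
        basal = _sigmoid((z_f - pts[:, 2]) / tau)
        rho = np.sqrt(self.geom.lung_rho2(pts))
        peripheral = _sigmoid((rho - 0.45) / 0.12)
        return basal * np.maximum(peripheral, 0.25)

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        """Displacement (n, 3) mm at arbitrary physical points (n, 3) mm."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        g = self.geom
        apex = g.apex
        ez = g.lung_semiaxes[2] * 2.0  # apex-to-base span
        t = _smoothstep((apex[2] - pts[:, 2]) / ez)
        rho2 = np.clip(g.lung_rho2(pts), 0.0, 1.44)
        u = np.empty_like(pts)
        u[:, 0] = AFFINE_XY * (pts[:, 0] - apex[0]) + RADIAL_BUMP * t * (pts[:, 0] - g.body_center[0])
        u[:, 1] = AFFINE_XY * (pts[:, 1] - apex[1]) + RADIAL_BUMP * t * (pts[:, 1] - g.body_center[1])
        u[:, 2] = AFFINE_Z * (pts[:, 2] - apex[2]) - BASAL_BUMP_MM * t * rho2
        u *= self.scale * self.damping(pts)[:, None]
        return u

    def dense(self, grid: Volume3D) -> np.ndarray:
        """Sample the field at every voxel center of ``grid`` -> (nx,ny,nz,3)."""
        xs, ys, zs = grid.grid_coords()
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
        return self(pts).reshape(grid.shape + (3,))


@dataclasses.dataclass
class GroundTruth:
    """Everything the generator knows exactly about one subject."""

    field: TrueField
    landmark_pairs: LandmarkSet
    split_z: float  # mm; lower lung below, upper at/above
    vc_ref: float  # liters
    geom: _Geometry


# ---------------------------------------------------------------------------
# tube tree


@dataclasses.dataclass
class _Segment:
    start: np.ndarray
    end: np.ndarray
    radius: float
    terminal: bool


def _grow_tree(geom: _Geometry, lung: int, levels: int,
               rng: np.random.Generator) -> list[_Segment]:
    """Binary tube tree inside one lung ellipsoid; endpoints kept interior."""
    center = geom.lung_centers[lung]
    semi = geom.lung_semiaxes
    root = center + np.array([0.0, 0.0, 0.70 * semi[2]])
    base_len = 0.35 * semi[2]
    segments: list[_Segment] = []
    frontier = [(root, np.array([0.0, 0.0, -1.0]), 0)]
    while frontier:
        start, direction, level = frontier.pop()
        length = base_len * (0.78 ** level)
        radius = max(3.0 * (0.78 ** level), 1.2)
        end = start + direction * length
        # pull the endpoint inside rho = 0.85 of the ellipsoid
        d = (end - center) / semi
        rho = np.linalg.norm(d)
        if rho > 0.85:
            end = center + (end - center) * (0.85 / rho)
        terminal = level == levels - 1
        segments.append(_Segment(start, end, radius, terminal))
        if not terminal:
            # two children: tilt off the parent axis at a seeded azimuth
            az = rng.uniform(0.0, 2.0 * np.pi)
            for phi in (az, az + np.pi):
                tilt = np.deg2rad(rng.uniform(28.0, 42.0))
                child = _tilted(direction, tilt, phi)
                child[2] = min(child[2], -0.2)  # keep a downward bias
                child /= np.linalg.norm(child)
                frontier.append((end, child, level + 1))
    return segments


def _tilted(direction: np.ndarray, tilt: float, phi: float) -> np.ndarray:
    """Rotate ``direction`` by ``tilt`` toward azimuth ``phi`` about it."""
    d = direction / np.linalg.norm(direction)
    # orthonormal frame around d
    a = np.array([1.0, 0.0, 0.0])
    if abs(d[0]) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return np.cos(tilt) * d + np.sin(tilt) * (np.cos(phi) * e1 + np.sin(phi) * e2)


def _rasterize_segments(values: np.ndarray, grid: Volume3D,
                        segments: list[_Segment], hu: float) -> None:
    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    shape = np.asarray(grid.shape)
    for seg in segments:
        lo = np.minimum(seg.start, seg.end) - seg.radius
        hi = np.maximum(seg.start, seg.end) + seg.radius
        i0 = np.maximum(np.floor((lo - origin) / spacing).astype(int), 0)
        i1 = np.minimum(np.ceil((hi - origin) / spacing).astype(int) + 1, shape)
        if np.any(i0 >= i1):
            continue
        axes = [origin[a] + spacing[a] * np.arange(i0[a], i1[a]) for a in range(3)]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([X, Y, Z], axis=-1)
        ab = seg.end - seg.start
        denom = float(ab @ ab)
        ap = pts - seg.start
        t = np.clip((ap @ ab) / denom, 0.0, 1.0) if denom > 0 else 0.0
        closest = seg.start + t[..., None] * ab
        dist2 = np.sum((pts - closest) ** 2, axis=-1)
        sub = values[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
        sub[dist2 <= seg.radius ** 2] = hu


def _tree_landmarks(segments_by_lung: list[list[_Segment]],
                    geom: _Geometry, field: TrueField) -> LandmarkSet:
    pts, kinds, sides = [], [], []
    for lung, segments in enumerate(segments_by_lung):
        side = "right" if lung == 0 else "left"
        for seg in segments:
            pts.append(seg.end)
            kinds.append("vascular" if seg.terminal else "bronchial")
            sides.append(side)
    # carina: a single midline bronchial landmark shared by both lungs
    carina = np.array([geom.body_center[0], geom.body_center[1],
                       geom.lung_centers[0, 2] + 0.6 * geom.lung_semiaxes[2]])
    pts.append(carina)
    kinds.append("bronchial")
    sides.append("both")
    p_exp = np.asarray(pts)
    p_insp = p_exp + field(p_exp)
    return LandmarkSet(p_exp, p_insp, np.asarray(kinds, dtype=object),
                       np.asarray(sides, dtype=object))


# ---------------------------------------------------------------------------
# generator operations


def make_true_field(spec: PhantomSpec,
                    geom: _Geometry | None = None) -> TrueField:
    """Analytic inflation field for a spec (shared by volumes and landmarks)."""
    if geom is None:
        geom = _Geometry.from_spec(spec)
    return TrueField(
        geom=geom,
        scale=spec.inflation_scale,
        fibrosis=spec.fibrosis,
        fibrosis_fraction=spec.fibrosis_fraction,
        fibrosis_damping=spec.fibrosis_damping,
    )


def make_phantom(spec: PhantomSpec) -> tuple[Volume3D, BinaryMask, GroundTruth]:
    """Build the expiratory volume, its true lung mask and the ground truth."""
    geom = _Geometry.from_spec(spec)
    if 2.2 * geom.lung_semiaxes[0] * 2 > spec.extent[0]:
        raise ValueError("grid too small to contain two lungs")
    rng = np.random.default_rng(spec.seed)
    grid = Volume3D(np.zeros(spec.grid_shape, dtype=np.float32),
                    spacing=spec.spacing)

    xs, ys, zs = grid.grid_coords()
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    # soft tissue fills the grid: no exterior air, so the HU window isolates
    # exactly the two lungs
    values = np.full(spec.grid_shape, spec.body_hu, dtype=np.float32)

    lung = geom.lung_indicator(pts).reshape(spec.grid_shape)
    values[lung] = spec.lung_hu

    field = make_true_field(spec, geom)
    if spec.fibrosis:
        w = field._fibrosis_weight(pts).reshape(spec.grid_shape)
        values[lung] += ((FIBROSIS_HU - spec.lung_hu) * w)[lung]

    segments_by_lung = [
        _grow_tree(geom, lung_idx, spec.n_branch_levels, rng)
        for lung_idx in range(2)
    ]
    for segments in segments_by_lung:
        _rasterize_segments(values, grid, segments, spec.vessel_hu)

    if spec.noise_sd > 0:
        values += rng.normal(0.0, spec.noise_sd, size=spec.grid_shape).astype(np.float32)

    landmarks = _tree_landmarks(segments_by_lung, geom, field)
    z_lo, z_hi = geom.lung_zrange
    split_z = z_lo + 0.5 * (z_hi - z_lo)
    height = float(np.clip(rng.normal(1.55, 0.06), 1.35, 1.80))
    vc_ref = reference_vc_from_height(height, rng)

    exp_volume = Volume3D(values, spacing=spec.spacing)
    exp_mask = BinaryMask(lung, spacing=spec.spacing)
    truth = GroundTruth(field=field, landmark_pairs=landmarks,
                        split_z=split_z, vc_ref=vc_ref, geom=geom)
    return exp_volume, exp_mask, truth


def reference_vc_from_height(height_m: float,
                             rng: np.random.Generator | None = None) -> float:
    """Synthetic reference vital capacity (L), linear in height with noise."""
    vc = VC_SLOPE_L_PER_M * height_m + VC_INTERCEPT_L
    if rng is not None and VC_NOISE_SD_L > 0:
        vc += rng.normal(0.0, VC_NOISE_SD_L)
    return float(max(vc, 1.0))


def invert_field_on_grid(field: Callable[[np.ndarray], np.ndarray],
                         grid: Volume3D, tol_mm: float = 1e-3,
                         max_iter: int = 50) -> np.ndarray:
    """Fixed-point inverse of phi(p) = p + u(p) at every voxel center of grid.

    Returns preimage points (nx,ny,nz,3) with phi(preimage) = voxel center.
    Converges because the field's displacement gradient is bounded below 1.
    """
    xs, ys, zs = grid.grid_coords()
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    q = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    p = q.copy()
    for _ in range(max_iter):
        p_new = q - field(p)
        delta = np.max(np.abs(p_new - p))
        p = p_new
        if delta < tol_mm:
            break
    return p.reshape(grid.shape + (3,))


def _check_jacobian(field: TrueField, mask: BinaryMask) -> None:
    """Abort if the forward map phi = id + u folds anywhere on the mask."""
    h = min(mask.spacing)
    idx = np.argwhere(mask.values)
    if len(idx) > 20000:
        idx = idx[:: len(idx) // 20000]
    pts = mask.index_to_physical(idx)
    J = np.zeros((len(pts), 3, 3))
    for a in range(3):
        step = np.zeros(3)
        step[a] = h
        J[:, :, a] = (field(pts + step) - field(pts - step)) / (2 * h)
    J += np.eye(3)
    det = np.linalg.det(J)
    if np.any(det <= 0):
        raise ValueError(
            f"non-invertible deformation: min Jacobian determinant {det.min():.3g}"
        )


def warp_to_inspiration(exp_volume: Volume3D, truth: GroundTruth
                        ) -> tuple[Volume3D, BinaryMask, LandmarkSet]:
    """Resample the expiratory phantom to inspiration through the true field.

    The inspiratory value at grid point q is the expiratory value at
    phi^-1(q); the inspiratory mask is the analytic lung indicator at
    phi^-1(q), so its boundary is exact up to the voxel grid.
    """
    field = truth.field
    grid = exp_volume
    mask_like = BinaryMask(truth.geom.lung_indicator(
        grid.index_to_physical(np.argwhere(np.ones(grid.shape, dtype=bool)))
    ).reshape(grid.shape), spacing=grid.spacing, origin=grid.origin)
    _check_jacobian(field, mask_like)

    pre = invert_field_on_grid(field, grid)
    pre_idx = grid.physical_to_index(pre.reshape(-1, 3))
    warped = ndimage.map_coordinates(
        exp_volume.values.astype(np.float32),
        pre_idx.T, order=1, mode="nearest",
    ).reshape(grid.shape)
    insp_mask = truth.geom.lung_indicator(pre.reshape(-1, 3)).reshape(grid.shape)

    lm = truth.landmark_pairs
    insp_volume = Volume3D(warped, spacing=grid.spacing, origin=grid.origin)
    return insp_volume, BinaryMask(insp_mask, spacing=grid.spacing,
                                   origin=grid.origin), lm


def observed_landmarks(lm: LandmarkSet, placement_sd_mm: float = 1.0,
                       seed: int = 0) -> LandmarkSet:
    """Simulate reader landmark placement: isotropic Gaussian jitter on both
    the expiratory and inspiratory marks.

    The ground-truth pairs are exactly consistent with the analytic field;
    a human marking branch points on 1 mm slices is not, so the pipeline is
    fed these jittered "observed" pairs while accuracy is judged against the
    exact ones.
    """
    rng = np.random.default_rng(seed)
    return LandmarkSet(
        lm.points_exp + rng.normal(0.0, placement_sd_mm, lm.points_exp.shape),
        lm.points_insp + rng.normal(0.0, placement_sd_mm, lm.points_insp.shape),
        lm.kind, lm.side,
    )


# ---------------------------------------------------------------------------
# cohort


@dataclasses.dataclass
class SubjectBundle:
    """One cohort member: its spec, group label and covariates.

    Volumes are generated on demand from ``spec`` (deterministic); the
    covariates already reflect the subject's true expansion.
    """

    subject_id: str
    group: str  # "normal" | "ild"
    spec: PhantomSpec
    age: float
    height: float
    vc_ref: float
    fvc: float
    mean_basal_dle3d: float  # true mean 3D expansion of the lower lung (mm)


def _mean_basal_dle3d(spec: PhantomSpec) -> float:
    """True mean 3D expansion of the lower lung, measured exactly as the
    analysis measures it (1 mm-binned histogram mean of the magnitudes)."""
    from .histogram import HistogramConfig, histogram_summary

    geom = _Geometry.from_spec(spec)
    field = make_true_field(spec, geom)
    grid = Volume3D(np.zeros(spec.grid_shape, dtype=np.int8), spacing=spec.spacing)
    xs, ys, zs = grid.grid_coords()
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    inside = geom.lung_indicator(pts)
    z_lo, z_hi = geom.lung_zrange
    split = z_lo + 0.5 * (z_hi - z_lo)
    basal = inside & (pts[:, 2] < split)
    u = field(pts[basal])
    mags = np.linalg.norm(u, axis=1)
    return float(histogram_summary(mags, HistogramConfig()).mean)


def make_cohort(n_normal: int, n_fibrotic: int, base_spec: PhantomSpec,
                seed: int, fvc_noise_sd: float | None = None,
                design_r2: float = FVC_DESIGN_R2) -> list[SubjectBundle]:
    """Deterministic cohort of normal and fibrotic subjects with covariates.

    Synthetic FVC is a documented linear function of each subject's true
    mean basal 3D expansion plus Gaussian noise; the noise SD is derived
    from ``design_r2`` and the realized between-subject spread so the
    designed coefficient of determination is recoverable.  Passing
    ``fvc_noise_sd=0`` makes the relation exactly linear.
    """
    if n_normal < 1 or n_fibrotic < 1:
        raise ValueError("need at least one subject per group")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(2 * (n_normal + n_fibrotic) + 1)
    rng = np.random.default_rng(child_seeds[-1])

    bundles: list[SubjectBundle] = []
    groups = ["normal"] * n_normal + ["ild"] * n_fibrotic
    for i, group in enumerate(groups):
        subj_seed = int(child_seeds[2 * i] % (2 ** 31))
        srng = np.random.default_rng(int(child_seeds[2 * i + 1]))
        scale = float(np.clip(srng.normal(1.0, SUBJECT_SCALE_SD), 0.6, 1.4))
        spec = dataclasses.replace(
            base_spec,
            seed=subj_seed,
            fibrosis=(group == "ild"),
            inflation_scale=scale,
        )
        age = float(np.clip(srng.normal(60.0, 10.0), 35.0, 85.0))
        height = float(np.clip(srng.normal(1.55, 0.06), 1.35, 1.80))
        vc_ref = reference_vc_from_height(height, srng)
        x = _mean_basal_dle3d(spec)
        bundles.append(SubjectBundle(
            subject_id=f"subj{i:03d}", group=group, spec=spec,
            age=age, height=height, vc_ref=vc_ref, fvc=np.nan,
            mean_basal_dle3d=x,
        ))

    xs = np.array([b.mean_basal_dle3d for b in bundles])
    if fvc_noise_sd is None:
        sd_x = float(np.std(xs))
        fvc_noise_sd = FVC_SLOPE_L_PER_MM * sd_x * np.sqrt(
            (1.0 - design_r2) / design_r2)
    noise = rng.normal(0.0, fvc_noise_sd, size=len(bundles)) if fvc_noise_sd > 0 \
        else np.zeros(len(bundles))
    for b, eps in zip(bundles, noise):
        b.fvc = float(FVC_INTERCEPT_L + FVC_SLOPE_L_PER_MM * b.mean_basal_dle3d + eps)
    return bundles
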