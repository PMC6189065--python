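"""Three-stage expiration-to-inspiration registration chain.

Stage order is fixed: a surface-based affine (iterative closest point on
lung-boundary point clouds) globally inflates the expiratory lung onto the
inspiratory one; a thin-plate-spline fitted to paired bronchial/vascular
landmarks aligns the internal structures; an attenuation-driven demons
refinement locally diffuses the source toward the target.  Each stage is
fitted in the coordinates produced by the previous one, and the chain is
fitted independently per lung.

All transforms map expiratory physical mm points to inspiratory physical mm
points.  The demons stage is stored as a residual displacement sampled on
the expiratory grid, so chain evaluation at a point p is
``tps(affine(p)) + residual(p)``.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .segmentation import mask_volume
from .volume_io import BinaryMask, LandmarkSet, Volume3D

__all__ = [
    "AffineTransform",
    "TPSTransform",
    "DisplacementField",
    "TransformChain",
    "extract_surface_points",
    "affine_icp",
    "tps_fit",
    "tps_fit_points",
    "DemonsParams",
    "demons",
    "compose",
    "registration_error",
    "volume_difference",
    "split_sides",
]


@dataclasses.dataclass
class AffineTransform:
    matrix: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)
    center: np.ndarray = dataclasses.field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if abs(np.linalg.det(self.matrix)) <= 1e-8:
            raise ValueError("affine matrix is (near-)singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return (pts - self.center) @ self.matrix.T + self.center + self.translation


@dataclasses.dataclass
class TPSTransform:
    """3D thin-plate spline with kernel phi(r) = r, exact at control points."""

    control_points: np.ndarray  # (n, 3)
    kernel_weights: np.ndarray  # (n, 3)
    affine_part: AffineTransform

    def __post_init__(self) -> None:
        self.control_points = np.asarray(self.control_points, dtype=float).reshape(-1, 3)
        self.kernel_weights = np.asarray(self.kernel_weights, dtype=float).reshape(-1, 3)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        out = self.affine_part.apply(pts)
        # kernel term: sum_i w_i * |p - c_i|
        d = np.linalg.norm(pts[:, None, :] - self.control_points[None, :, :], axis=2)
        return out + d @ self.kernel_weights


@dataclasses.dataclass
class DisplacementField:
    """Dense mm-valued vector field sampled on the expiratory grid."""

    vectors: np.ndarray  # (nx, ny, nz, 3)
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError("field must have shape (nx, ny, nz, 3)")
        if not np.isfinite(self.vectors).all():
            raise ValueError("field contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]  # type: ignore[return-value]

    def interp(self, pts: np.ndarray) -> np.ndarray:
        """Trilinear sample of the field at physical points (n, 3)."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        idx = (pts - np.asarray(self.origin)) / np.asarray(self.spacing)
        out = np.empty_like(pts)
        for a in range(3):
            out[:, a] = ndimage.map_coordinates(
                self.vectors[..., a], idx.T, order=1, mode="nearest")
        return out


@dataclasses.dataclass
class TransformChain:
    """Ordered stages affine -> tps -> demons residual (any may be absent)."""

    affine: AffineTransform | None = None
    tps: TPSTransform | None = None
    residual: DisplacementField | None = None

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        q = pts
        if self.affine is not None:
            q = self.affine.apply(q)
        if self.tps is not None:
            q = self.tps.apply(q)
        if self.residual is not None:
            q = q + self.residual.interp(pts)
        return q

    def truncated(self, stages: Sequence[str]) -> "TransformChain":
        """Sub-chain with only the named stages (for per-stage QC)."""
        return TransformChain(
            affine=self.affine if "affine" in stages else None,
            tps=self.tps if "tps" in stages else None,
            residual=self.residual if "demons" in stages else None,
        )


# ---------------------------------------------------------------------------
# surface-based affine (ICP)


def extract_surface_points(m: BinaryMask, n_points: int = 2000,
                           seed: int = 0) -> np.ndarray:
    """Seeded uniform subsample of the mask's boundary voxel centers (mm)."""
    if m.n_foreground == 0:
        raise ValueError("empty mask has no surface")
    eroded = ndimage.binary_erosion(
        m.values, structure=ndimage.generate_binary_structure(3, 1),
        border_value=0)
    boundary = m.values & ~eroded
    idx = np.argwhere(boundary)
    if len(idx) < n_points:
        warnings.warn(f"only {len(idx)} boundary voxels < requested {n_points}; "
                      "returning all", stacklevel=2)
        chosen = idx
    else:
        rng = np.random.default_rng(seed)
        chosen = idx[rng.choice(len(idx), size=n_points, replace=False)]
    return m.index_to_physical(chosen)


def _check_noncoplanar(pts: np.ndarray, what: str) -> None:
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-6) < 3:
        raise ValueError(f"{what}: points are coplanar or degenerate")


def affine_icp(source_pts: np.ndarray, target_pts: np.ndarray,
               max_iter: int = 50, tol: float = 1e-5) -> AffineTransform:
    """Full-affine ICP: nearest-neighbour matches + least-squares update.

    Initialized with a centroid shift plus per-axis bounding-box scaling
    (the gross inflation), then iterated to convergence of the RMS distance.
    """
    source_pts = np.asarray(source_pts, dtype=float)
    target_pts = np.asarray(target_pts, dtype=float)
    if len(source_pts) < 4 or len(target_pts) < 4:
        raise ValueError("need at least 4 points per cloud")
    _check_noncoplanar(source_pts, "source cloud")
    _check_noncoplanar(target_pts, "target cloud")

    cs, ct = source_pts.mean(axis=0), target_pts.mean(axis=0)
    ext_s = np.ptp(source_pts, axis=0)
    ext_t = np.ptp(target_pts, axis=0)
    scale = np.where(ext_s > 0, ext_t / np.maximum(ext_s, 1e-9), 1.0)
    B = np.diag(scale)
    d = ct - B @ cs

    tree = cKDTree(target_pts)
    ones = np.ones((len(source_pts), 1))
    design = np.hstack([source_pts, ones])  # (n, 4)
    prev_rms = np.inf
    for _ in range(max_iter):
        moved = source_pts @ B.T + d
        dists, nn = tree.query(moved)
        rms = float(np.sqrt(np.mean(dists ** 2)))
        if prev_rms < np.inf and abs(prev_rms - rms) <= tol * max(rms, 1e-12):
            break
        prev_rms = rms
        matched = target_pts[nn]
        coef, *_ = np.linalg.lstsq(design, matched, rcond=None)
        B = coef[:3].T
        d = coef[3]
    return AffineTransform(matrix=B, translation=d)


# ---------------------------------------------------------------------------
# thin-plate spline


def tps_fit_points(src: np.ndarray, dst: np.ndarray) -> TPSTransform:
    """Exact-interpolation 3D TPS (kernel phi(r) = r, no regularization)."""
    src = np.asarray(src, dtype=float).reshape(-1, 3)
    dst = np.asarray(dst, dtype=float).reshape(-1, 3)
    n = len(src)
    if n < 4:
        raise ValueError("TPS needs at least 4 control points")
    _check_noncoplanar(src, "TPS control points")
    if len(np.unique(src.round(decimals=9), axis=0)) < n:
        raise ValueError("duplicate TPS control points: singular system")

    K = np.linalg.norm(src[:, None, :] - src[None, :, :], axis=2)
    P = np.hstack([np.ones((n, 1)), src])  # (n, 4)
    A = np.zeros((n + 4, n + 4))
    A[:n, :n] = K
    A[:n, n:] = P
    A[n:, :n] = P.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = dst
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular TPS system: {exc}") from exc
    w = sol[:n]
    a0 = sol[n]
    A3 = sol[n + 1:].T  # rows map (x, y, z)
    return TPSTransform(control_points=src, kernel_weights=w,
                        affine_part=AffineTransform(matrix=A3, translation=a0))


def tps_fit(landmarks: LandmarkSet, side: str | None = None,
            kind: str | None = None,
            pre_affine: AffineTransform | None = None) -> TPSTransform:
    """Fit a TPS from paired landmarks, optionally filtered by side/kind.

    ``pre_affine`` maps the expiratory landmarks first, so the TPS is fitted
    in post-affine coordinates (the chain's stage order).
    """
    lm = landmarks.select(side=side, kind=kind)
    if len(lm) == 0:
        raise ValueError(f"no landmarks for side={side!r} kind={kind!r}")
    src = lm.points_exp
    if pre_affine is not None:
        src = pre_affine.apply(src)
    return tps_fit_points(src, lm.points_insp)


# ---------------------------------------------------------------------------
# demons


@dataclasses.dataclass
class DemonsParams:
    levels: int = 3
    iterations: int = 50
    sigma_voxels: float = 1.5  # Gaussian field regularization per iteration
    kappa: float | None = None  # force normalization; default mean |grad T|
    divergence_patience: int = 10


def _downsample(arr: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return arr
    sm = ndimage.gaussian_filter(arr.astype(np.float32), sigma=factor / 2.0)
    return sm[::factor, ::factor, ::factor]


def demons(target: Volume3D, source: Volume3D,
           init_field: DisplacementField | None = None,
           params: DemonsParams | None = None,
           mask: BinaryMask | None = None) -> DisplacementField:
    """Classic additive demons with Gaussian field regularization.

    Per voxel, the update is ``(T - S o phi) grad T / (|grad T|^2 +
    (T - S o phi)^2 / kappa^2)`` where phi(p) = p + u(p) is the running total
    mapping (including ``init_field``); the field is smoothed after every
    iteration and the scheme runs coarse-to-fine.  The masked mean-squared
    difference is monitored: if it increases for ``divergence_patience``
    consecutive iterations the level stops and the best field seen is kept.
    Returns the total field (init included) on the target grid.

    Direction convention: the returned field lives on ``target``'s grid and
    maps each of its points *into* ``source`` (``source`` sampled at
    ``p + u(p)`` matches ``target`` at ``p``).  In the pipeline the
    expiratory image is therefore passed as ``target`` so the field shares
    the expiratory grid and composes with the affine/TPS stages, which also
    map expiratory points forward into inspiratory space.
    """
    if params is None:
        params = DemonsParams()
    if not target.same_grid(source):
        raise ValueError("demons requires target and source on the same grid")
    spacing = np.asarray(target.spacing)
    shape = target.shape

    u_full = (np.zeros(shape + (3,)) if init_field is None
              else np.array(init_field.vectors, dtype=float))
    if u_full.shape[:3] != shape:
        raise ValueError("init_field grid differs from the volumes")

    mask_arr = mask.values if mask is not None else np.ones(shape, dtype=bool)

    for level in range(params.levels):
        factor = 2 ** (params.levels - 1 - level)
        if min(shape) // factor < 8:
            continue  # level coarser than 8 voxels carries no signal
        T = _downsample(target.values.astype(np.float32), factor)
        S = _downsample(source.values.astype(np.float32), factor)
        M = mask_arr[::factor, ::factor, ::factor]
        sp = spacing * factor
        # resample the running field onto this level's grid
        zoom = np.asarray(T.shape) / np.asarray(u_full.shape[:3])
        u = np.stack([ndimage.zoom(u_full[..., a], zoom, order=1)
                      for a in range(3)], axis=-1)

        grad = np.stack(np.gradient(T, *sp), axis=-1)
        g2 = np.sum(grad ** 2, axis=-1)
        kappa = params.kappa
        if kappa is None:
            gm = np.sqrt(g2)[M]
            kappa = float(gm.mean()) if gm.size else 1.0
        kappa = max(kappa, 1e-6)
        step_cap = 0.5 * float(sp.min())

        I = np.stack(np.meshgrid(*[np.arange(n) for n in T.shape],
                                 indexing="ij"), axis=-1).astype(float)
        best_u, best_msd = u.copy(), np.inf
        prev_msd = np.inf
        rising = 0
        for _ in range(params.iterations):
            coords = (I + u / sp).transpose(3, 0, 1, 2)
            warped = ndimage.map_coordinates(S, coords, order=1, mode="nearest")
            diff = T - warped
            msd = float(np.mean(diff[M] ** 2)) if M.any() else float(np.mean(diff ** 2))
            if msd < best_msd:
                best_msd, best_u = msd, u.copy()
            rising = rising + 1 if msd > prev_msd else 0
            prev_msd = msd
            if rising >= params.divergence_patience:
                warnings.warn("demons diverging; returning best field",
                              stacklevel=2)
                break
            denom = g2 + (diff ** 2) / (kappa ** 2)
            with np.errstate(invalid="ignore", divide="ignore"):
                upd = diff[..., None] * grad / denom[..., None]
            upd[denom < 1e-9] = 0.0
            nrm = np.linalg.norm(upd, axis=-1, keepdims=True)
            np.clip(nrm, 1e-12, None, out=nrm)
            upd *= np.minimum(1.0, step_cap / nrm)
            u = u + upd
            for a in range(3):
                u[..., a] = ndimage.gaussian_filter(u[..., a], params.sigma_voxels)
        u = best_u
        if not np.isfinite(u).all():
            raise FloatingPointError("demons produced non-finite field values")
        zoom = np.asarray(shape) / np.asarray(u.shape[:3])
        u_full = np.stack([ndimage.zoom(u[..., a], zoom, order=1)
                           for a in range(3)], axis=-1)
    return DisplacementField(u_full, spacing=target.spacing, origin=target.origin)


# ---------------------------------------------------------------------------
# composition and QC


def compose(chain: TransformChain, grid: Volume3D) -> DisplacementField:
    """Dense field on ``grid``: chain(p) - p at every voxel center."""
    xs, ys, zs = grid.grid_coords()
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    vec = chain.apply(pts) - pts
    return DisplacementField(vec.reshape(grid.shape + (3,)),
                             spacing=grid.spacing, origin=grid.origin)


def registration_error(landmarks: LandmarkSet,
                       chain: "TransformChain | dict[str, TransformChain]",
                       ) -> dict[str, tuple[float, float]]:
    """Mean and SD (mm) of landmark distances after the chain, per side.

    ``chain`` may be a single chain or a per-side mapping; landmarks with
    side='both' enter both sides' statistics.
    """
    out: dict[str, tuple[float, float]] = {}
    for side in ("right", "left"):
        lm = landmarks.select(side=side)
        if len(lm) == 0:
            raise ValueError(f"no landmarks for side {side!r}")
        c = chain[side] if isinstance(chain, dict) else chain
        moved = c.apply(lm.points_exp)
        d = np.linalg.norm(moved - lm.points_insp, axis=1)
        out[side] = (float(d.mean()), float(d.std()))
    return out


def invert_displacement(field: DisplacementField, grid: Volume3D,
                        tol_mm: float = 0.05, max_iter: int = 30
                        ) -> tuple[np.ndarray, bool]:
    """Fixed-point inverse of phi = id + field at grid voxel centers.

    Returns (preimage points (nx,ny,nz,3), converged flag).
    """
    xs, ys, zs = grid.grid_coords()
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    q = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    p = q.copy()
    converged = False
    for _ in range(max_iter):
        p_new = q - field.interp(p)
        delta = float(np.max(np.abs(p_new - p)))
        p = p_new
        if delta < tol_mm:
            converged = True
            break
    return p.reshape(grid.shape + (3,)), converged


def volume_difference(insp_mask: BinaryMask, exp_mask: BinaryMask,
                      chain: TransformChain) -> tuple[float, bool]:
    """|volume(insp mask) - volume(chain-warped exp mask)| in cm^3.

    The expiratory mask is pushed to inspiratory space by nearest-neighbour
    resampling through the fixed-point approximate inverse of the chain's
    dense field.  The returned flag is False if the inversion did not reach
    its 0.05 mm tolerance.
    """
    grid = Volume3D(np.zeros(insp_mask.shape, dtype=np.int8),
                    spacing=insp_mask.spacing, origin=insp_mask.origin)
    field = compose(chain, Volume3D(np.zeros(exp_mask.shape, dtype=np.int8),
                                    spacing=exp_mask.spacing,
                                    origin=exp_mask.origin))
    pre, converged = invert_displacement(field, grid)
    if not converged:
        warnings.warn("chain inversion did not converge to 0.05 mm",
                      stacklevel=2)
    idx = exp_mask.physical_to_index(pre.reshape(-1, 3))
    warped = ndimage.map_coordinates(
        exp_mask.values.astype(np.uint8), idx.T, order=0, mode="constant",
        cval=0).reshape(insp_mask.shape).astype(bool)
    warped_mask = BinaryMask(warped, spacing=insp_mask.spacing,
                             origin=insp_mask.origin)
    return abs(mask_volume(insp_mask) - mask_volume(warped_mask)), converged


def split_sides(mask: BinaryMask) -> dict[str, BinaryMask]:
    """Right/left sub-masks split at the x midline of the mask's bounding box."""
    idx = np.argwhere(mask.values)
    if len(idx) == 0:
        raise ValueError("empty mask")
    mid = 0.5 * (idx[:, 0].min() + idx[:, 0].max())
    xs = np.arange(mask.shape[0])
    right = mask.values & (xs[:, None, None] <= mid)
    left = mask.values & (xs[:, None, None] > mid)
    return {
        "right": BinaryMask(right, spacing=mask.spacing, origin=mask.origin),
        "left": BinaryMask(left, spacing=mask.spacing, origin=mask.origin),
    }
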