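"""Degree-of-lung-expansion maps and first-order histogram statistics.

The degree of lung expansion (DLE) at a voxel is the absolute displacement
between the registered expiratory and inspiratory scans, taken per
anatomical axis (x horizontal, y ventrodorsal, z craniocaudal) and as the
3D Euclidean norm, in mm.  Summaries are computed from the binned
probability distribution of the DLE values:

    M  = sum_i x_i P(x_i)                    (mean, mm)
    SD = sqrt(sum_i (x_i - M)^2 P(x_i))      (contrast, mm)
    SK = SD^-3 sum_i (x_i - M)^3 P(x_i)      (asymmetry)
    K  = SD^-4 sum_i (x_i - M)^4 P(x_i)      (non-excess kurtosis; normal=3)
    E  = -sum_i P(x_i) log P(x_i)            (variability; log base 2)
    U  = sum_i P(x_i)^2                      (homogeneity)

where x_i are bin centers of width ``bin_width`` anchored at 0 mm.
Percentiles are computed on the raw voxel values (linear-interpolation
empirical quantiles), not on the binned distribution; the two differ by at
most one bin width.  When a reference vital capacity is supplied, mean and
SD are additionally standardized to mm/L.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .registration import DisplacementField
from .volume_io import BinaryMask

__all__ = [
    "PERCENTILES",
    "HistogramConfig",
    "binned_distribution",
    "HistogramSummary",
    "DLEMap",
    "dle_maps",
    "histogram_summary",
    "regional_summaries",
    "reference_vc",
]

PERCENTILES = (5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 95)

AXES = ("x", "y", "z", "3d")
ZONES = ("whole", "upper", "lower")
SIDES = ("right", "left", "both")


@dataclasses.dataclass
class HistogramConfig:
    bin_width: float = 1.0  # mm
    bin_origin: float = 0.0  # mm; left edge of the first bin
    log_base: float = 2.0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.log_base <= 1:
            raise ValueError("log_base must exceed 1")


@dataclasses.dataclass
class HistogramSummary:
    mean: float
    sd: float
    skewness: float | None  # None when SD == 0 (undefined)
    kurtosis: float | None
    entropy: float
    uniformity: float
    percentiles: dict[int, float]
    n_voxels: int
    bin_width: float
    log_base: float
    standardized_mean: float | None = None  # mm/L
    standardized_sd: float | None = None


@dataclasses.dataclass
class DLEMap:
    """Per-voxel absolute displacements restricted to the lung mask."""

    dle_x: np.ndarray  # (n,) mm, one entry per mask voxel
    dle_y: np.ndarray
    dle_z: np.ndarray
    dle_3d: np.ndarray
    side: np.ndarray  # (n,) "right"/"left"
    zone: np.ndarray  # (n,) "upper"/"lower"

    def values(self, axis: str) -> np.ndarray:
        return {"x": self.dle_x, "y": self.dle_y,
                "z": self.dle_z, "3d": self.dle_3d}[axis]

    def selector(self, zone: str, side: str) -> np.ndarray:
        keep = np.ones(len(self.dle_x), dtype=bool)
        if zone != "whole":
            keep &= self.zone == zone
        if side != "both":
            keep &= self.side == side
        return keep


def dle_maps(field: DisplacementField, exp_mask: BinaryMask, split_z: float,
             side_labels: np.ndarray | None = None) -> DLEMap:
    """Build the DLE map of one subject from the composed field.

    ``split_z`` is the mm z-coordinate of the upper/lower dividing plane
    (standing in for the lower-lobar-bronchus branch level); voxels with
    center z below it are "lower".  ``side_labels`` is an optional
    per-mask-voxel right/left array; by default sides are split at the x
    midline of the mask bounding box.
    """
    if field.grid_shape != exp_mask.shape:
        raise ValueError("field and mask must share the grid")
    idx = np.argwhere(exp_mask.values)
    if len(idx) == 0:
        raise ValueError("empty lung mask")
    pts = exp_mask.index_to_physical(idx)
    zmin, zmax = pts[:, 2].min(), pts[:, 2].max()
    if not (zmin <= split_z <= zmax):
        raise ValueError(
            f"split_z={split_z} mm outside the mask z-range [{zmin}, {zmax}]")
    vec = field.vectors[idx[:, 0], idx[:, 1], idx[:, 2]]
    if side_labels is None:
        mid = 0.5 * (pts[:, 0].min() + pts[:, 0].max())
        side_labels = np.where(pts[:, 0] < mid, "right", "left")
    zone = np.where(pts[:, 2] < split_z, "lower", "upper")
    return DLEMap(
        dle_x=np.abs(vec[:, 0]), dle_y=np.abs(vec[:, 1]),
        dle_z=np.abs(vec[:, 2]), dle_3d=np.linalg.norm(vec, axis=1),
        side=np.asarray(side_labels, dtype=object),
        zone=np.asarray(zone, dtype=object),
    )


def binned_distribution(values: np.ndarray, cfg: HistogramConfig
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Bin centers x_i and probabilities P(x_i) over the occupied range."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("need at least one value")
    if np.any(values < cfg.bin_origin):
        raise ValueError("values below the bin origin")
    w = cfg.bin_width
    ibin = np.floor((values - cfg.bin_origin) / w).astype(int)
    counts = np.bincount(ibin)
    first = int(np.argmax(counts > 0))
    counts = counts[first:]  # occupied range
    p = counts / counts.sum()
    centers = cfg.bin_origin + (np.arange(first, first + len(counts)) + 0.5) * w
    return centers, p


def histogram_summary(values: np.ndarray, cfg: HistogramConfig | None = None,
                      vc_ref: float | None = None) -> HistogramSummary:
    """The six binned-distribution statistics plus raw-value percentiles."""
    if cfg is None:
        cfg = HistogramConfig()
    values = np.asarray(values, dtype=float).ravel()
    centers, p = binned_distribution(values, cfg)
    w = cfg.bin_width

    mean = float(np.sum(centers * p))
    var = float(np.sum((centers - mean) ** 2 * p))
    sd = math.sqrt(var)
    if sd > 0:
        sk = float(np.sum((centers - mean) ** 3 * p) / sd ** 3)
        ku = float(np.sum((centers - mean) ** 4 * p) / sd ** 4)
    else:
        sk = ku = None  # undefined for a single occupied bin
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log(nz) / np.log(cfg.log_base)))
    uniformity = float(np.sum(p ** 2))
    pct = {q: float(np.percentile(values, q)) for q in PERCENTILES}
    return HistogramSummary(
        mean=mean, sd=sd, skewness=sk, kurtosis=ku,
        entropy=entropy, uniformity=uniformity,
        percentiles=pct, n_voxels=int(values.size),
        bin_width=w, log_base=cfg.log_base,
        standardized_mean=None if vc_ref is None else mean / vc_ref,
        standardized_sd=None if vc_ref is None else sd / vc_ref,
    )


def regional_summaries(dmap: DLEMap, cfg: HistogramConfig | None = None,
                       vc_ref: float | None = None) -> pd.DataFrame:
    """Tidy table of summaries over axis x zone x side (4 x 3 x 3 rows).

    Empty regions yield a row with NaN statistics and n_voxels = 0 rather
    than a fabricated summary.
    """
    if cfg is None:
        cfg = HistogramConfig()
    rows = []
    for axis in AXES:
        vals_all = dmap.values(axis)
        for zone in ZONES:
            for side in SIDES:
                sel = dmap.selector(zone, side)
                row: dict = {"axis": axis, "zone": zone, "side": side,
                             "n_voxels": int(sel.sum()),
                             "bin_width": cfg.bin_width,
                             "log_base": cfg.log_base}
                if sel.any():
                    s = histogram_summary(vals_all[sel], cfg, vc_ref)
                    row.update(
                        mean=s.mean, sd=s.sd, skewness=s.skewness,
                        kurtosis=s.kurtosis, entropy=s.entropy,
                        uniformity=s.uniformity,
                        standardized_mean=s.standardized_mean,
                        standardized_sd=s.standardized_sd,
                    )
                    row.update({f"p{q}": v for q, v in s.percentiles.items()})
                rows.append(row)
    df = pd.DataFrame(rows)
    stat_cols = ["mean", "sd", "skewness", "kurtosis", "entropy", "uniformity",
                 "standardized_mean", "standardized_sd"] + \
                [f"p{q}" for q in PERCENTILES]
    for c in stat_cols:
        if c not in df.columns:
            df[c] = np.nan
    return df


def reference_vc(age: float, height: float, sex: str,
                 equations: dict) -> float:
    """Reference vital capacity VC = TLC_ref - RV_ref, in liters.

    ``equations`` supplies linear predictors per sex, e.g.::

        {"female": {"tlc": {"intercept": -4.0, "height": 6.6, "age": 0.0},
                    "rv":  {"intercept": -1.5, "height": 2.2, "age": 0.02}}}

    with height in m and age in years.  Coefficient sets for real cohorts
    must be provided by the user.
    """
    try:
        eq = equations[sex]
        tlc_c, rv_c = eq["tlc"], eq["rv"]
    except KeyError as exc:
        raise ValueError(f"missing reference-volume coefficients: {exc}") from exc

    def _lin(c: dict) -> float:
        return (float(c.get("intercept", 0.0))
                + float(c.get("height", 0.0)) * height
                + float(c.get("age", 0.0)) * age)

    vc = _lin(tlc_c) - _lin(rv_c)
    if vc <= 0:
        raise ValueError(f"nonpositive reference VC ({vc:.3f} L) from the "
                         "supplied coefficients")
    return vc
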