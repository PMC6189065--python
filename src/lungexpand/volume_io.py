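"""Volumes, masks, landmark tables and the coordinate contract.

Every array in the package is indexed ``[i, j, k]`` along the patient axes
(x = left-right, y = ventro-dorsal, z = cranio-caudal), with +x toward the
patient's left, +y posterior and +z superior.  Physical coordinates are
voxel-center based::

    physical_mm = origin + index * spacing          (index 0-based)

On disk, volumes and displacement fields are NIfTI-1 (``.nii``/``.nii.gz``)
or MetaImage (``.mha``/``.mhd``); landmark tables are CSV with one paired
expiratory/inspiratory point per row.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import SimpleITK as sitk
import yaml

__all__ = [
    "Volume3D",
    "BinaryMask",
    "LandmarkSet",
    "read_volume",
    "write_volume",
    "read_field",
    "write_field",
    "read_landmarks",
    "write_landmarks",
    "load_config",
]

_VOLUME_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")

KINDS = ("bronchial", "vascular")
SIDES = ("right", "left", "both")


def _as_triple(v) -> tuple[float, float, float]:
    a = tuple(float(x) for x in v)
    if len(a) != 3:
        raise ValueError(f"expected 3 components, got {len(a)}")
    return a  # type: ignore[return-value]


@dataclasses.dataclass
class Volume3D:
    """A scalar voxel grid with physical spacing and origin (mm)."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"non-3D volume: ndim={self.values.ndim}")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Voxel-center physical coordinates (mm) of 0-based indices (n, 3)."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def physical_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Fractional 0-based indices of physical points (n, 3)."""
        pts = np.asarray(pts, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def grid_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis physical coordinates of voxel centers."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )  # type: ignore[return-value]

    def same_grid(self, other: "Volume3D", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclasses.dataclass
class BinaryMask(Volume3D):
    """A {0,1} mask sharing a Volume3D's grid."""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.dtype != bool:
            uniq = np.unique(self.values)
            if not np.isin(uniq, (0, 1)).all():
                raise ValueError("mask values must be 0/1")
            self.values = self.values.astype(bool)
        super().__post_init__()

    @property
    def n_foreground(self) -> int:
        return int(self.values.sum())


@dataclasses.dataclass
class LandmarkSet:
    """Paired expiratory/inspiratory landmark points in physical mm.

    ``side`` may be "right", "left" or "both" (e.g. the carina, which
    belongs to both lungs when the chain is fitted per lung).
    """

    points_exp: np.ndarray  # (n, 3) mm
    points_insp: np.ndarray  # (n, 3) mm
    kind: np.ndarray  # (n,) str in KINDS
    side: np.ndarray  # (n,) str in SIDES

    def __post_init__(self) -> None:
        self.points_exp = np.asarray(self.points_exp, dtype=float).reshape(-1, 3)
        self.points_insp = np.asarray(self.points_insp, dtype=float).reshape(-1, 3)
        self.kind = np.asarray(self.kind, dtype=object)
        self.side = np.asarray(self.side, dtype=object)
        n = len(self.points_exp)
        if not (len(self.points_insp) == len(self.kind) == len(self.side) == n):
            raise ValueError("landmark field lengths differ")
        if not (np.isfinite(self.points_exp).all() and np.isfinite(self.points_insp).all()):
            raise ValueError("landmark coordinates must be finite")
        bad = set(self.kind) - set(KINDS)
        if bad:
            raise ValueError(f"unknown landmark kind(s): {sorted(bad)}")
        bad = set(self.side) - set(SIDES)
        if bad:
            raise ValueError(f"unknown landmark side(s): {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.points_exp)

    def select(self, side: str | None = None, kind: str | None = None) -> "LandmarkSet":
        """Subset by side and/or kind; side='right'/'left' includes 'both' rows."""
        keep = np.ones(len(self), dtype=bool)
        if side is not None and side != "both":
            keep &= (self.side == side) | (self.side == "both")
        if kind is not None:
            keep &= self.kind == kind
        return LandmarkSet(
            self.points_exp[keep], self.points_insp[keep],
            self.kind[keep], self.side[keep],
        )


# ---------------------------------------------------------------------------
# volume / field I/O (SimpleITK handles both NIfTI and MetaImage)


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _VOLUME_SUFFIXES):
        raise ValueError(f"unsupported volume format: {path.name} "
                         f"(expected one of {_VOLUME_SUFFIXES})")


def _check_direction(img: sitk.Image, path: Path) -> None:
    d = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(d, np.eye(3), atol=1e-6):
        raise ValueError(
            f"{path}: non-identity direction matrix is outside this package's "
            "coordinate contract; resample to an axis-aligned grid first"
        )


def read_volume(path: str | Path) -> Volume3D:
    """Read a 3D HU-valued volume from NIfTI or MetaImage."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    _check_suffix(path)
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"non-3D image: {path} has dimension {img.GetDimension()}")
    _check_direction(img, path)
    arr = sitk.GetArrayFromImage(img)  # [z, y, x]
    values = np.ascontiguousarray(arr.transpose(2, 1, 0))
    return Volume3D(values, spacing=img.GetSpacing(), origin=img.GetOrigin())


def write_volume(v: Volume3D, path: str | Path) -> None:
    """Write a volume; integer dtypes round-trip bit-exactly, floats as float32."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    _check_suffix(path)
    vals = v.values
    if np.issubdtype(vals.dtype, np.floating):
        vals = vals.astype(np.float32)
    elif vals.dtype == bool:
        vals = vals.astype(np.uint8)
    img = sitk.GetImageFromArray(np.ascontiguousarray(vals.transpose(2, 1, 0)))
    img.SetSpacing(v.spacing)
    img.SetOrigin(v.origin)
    sitk.WriteImage(img, str(path))


def read_field(path: str | Path) -> tuple[np.ndarray, tuple, tuple]:
    """Read a 3-component mm displacement field; returns (vectors[x,y,z,3], spacing, origin)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    _check_suffix(path)
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3 or img.GetNumberOfComponentsPerPixel() != 3:
        raise ValueError(f"{path}: expected a 3D 3-component vector image")
    _check_direction(img, path)
    arr = sitk.GetArrayFromImage(img)  # [z, y, x, 3]
    vectors = np.ascontiguousarray(arr.transpose(2, 1, 0, 3)).astype(float)
    return vectors, img.GetSpacing(), img.GetOrigin()


def write_field(vectors: np.ndarray, spacing: Sequence[float],
                origin: Sequence[float], path: str | Path) -> None:
    path = Path(path)
    _check_suffix(path)
    arr = np.ascontiguousarray(
        np.asarray(vectors, dtype=np.float32).transpose(2, 1, 0, 3))
    img = sitk.GetImageFromArray(arr, isVector=True)
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    sitk.WriteImage(img, str(path))


# ---------------------------------------------------------------------------
# landmark CSV I/O

_LANDMARK_COLUMNS = ["side", "kind",
                     "x_exp", "y_exp", "z_exp",
                     "x_insp", "y_insp", "z_insp"]


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read a paired landmark CSV (one expiratory/inspiratory pair per row)."""
    df = pd.read_csv(path)
    missing = [c for c in _LANDMARK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"landmark CSV missing column(s): {missing}")
    coords = df[_LANDMARK_COLUMNS[2:]].apply(pd.to_numeric, errors="coerce")
    if coords.isna().any().any():
        raise ValueError("non-numeric landmark coordinate")
    return LandmarkSet(
        points_exp=coords[["x_exp", "y_exp", "z_exp"]].to_numpy(),
        points_insp=coords[["x_insp", "y_insp", "z_insp"]].to_numpy(),
        kind=df["kind"].to_numpy(),
        side=df["side"].to_numpy(),
    )


def write_landmarks(lm: LandmarkSet, path: str | Path) -> None:
    df = pd.DataFrame({
        "side": lm.side, "kind": lm.kind,
        "x_exp": lm.points_exp[:, 0], "y_exp": lm.points_exp[:, 1],
        "z_exp": lm.points_exp[:, 2],
        "x_insp": lm.points_insp[:, 0], "y_insp": lm.points_insp[:, 1],
        "z_insp": lm.points_insp[:, 2],
    })
    df.to_csv(path, index=False)


def load_config(path: str | Path) -> dict:
    """Load a YAML pipeline configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
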