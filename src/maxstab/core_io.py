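"""Domain containers and file IO.

All geometry is physical: a voxel index ``(i, j, k)`` (0-based, array axes)
maps to the physical point ``origin + direction @ (spacing * (i, j, k))`` in
millimetres.  NIfTI-1 is the interchange format for volumes, masks and dense
vector fields (vector dimension last); landmark sets are CSV with a
``name,x,y,z`` header.  Downstream modules exchange physical-space
coordinates only — voxel indices never cross module boundaries.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger("maxstab")

__all__ = [
    "ImageVolume", "BinaryMask", "LandmarkSet",
    "read_volume", "write_volume", "read_mask", "write_mask",
    "read_landmarks", "write_landmarks",
]


@dataclass
class ImageVolume:
    """A 3D scalar grid with physical geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Intensities in arbitrary units; must be finite.
    spacing : ndarray, shape (3,)
        Voxel edge lengths in mm; strictly positive.
    origin : ndarray, shape (3,)
        Physical position (mm) of voxel (0, 0, 0).
    direction : ndarray, shape (3, 3)
        Orthonormal axis direction matrix (columns are the physical
        directions of the array axes).
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"non-3D image: got {self.data.ndim} dimensions")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if np.any(self.spacing <= 0):
            raise ValueError(f"non-positive spacing: {self.spacing}")
        if not np.allclose(self.direction @ self.direction.T, np.eye(3), atol=1e-6):
            raise ValueError("direction matrix is not orthonormal")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite intensities")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> physical-point (mm) transform."""
        aff = np.eye(4)
        aff[:3, :3] = self.direction * self.spacing[None, :]
        aff[:3, 3] = self.origin
        return aff

    def voxel_to_physical(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return idx @ (self.direction * self.spacing[None, :]).T + self.origin

    def physical_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        inv = np.linalg.inv(self.direction * self.spacing[None, :])
        return (pts - self.origin) @ inv.T

    def physical_extent(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounding box (lower, upper) of the voxel centres, mm."""
        corners = np.array([[i, j, k] for i in (0, self.shape[0] - 1)
                            for j in (0, self.shape[1] - 1)
                            for k in (0, self.shape[2] - 1)], dtype=float)
        phys = self.voxel_to_physical(corners)
        return phys.min(axis=0), phys.max(axis=0)

    def same_grid(self, other: "ImageVolume | BinaryMask") -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing)
                and np.allclose(self.origin, other.origin)
                and np.allclose(self.direction, other.direction))

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        return replace(self, data=data)

    def checksum(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.data).tobytes())
        h.update(self.affine.tobytes())
        return h.hexdigest()[:12]


@dataclass
class BinaryMask(ImageVolume):
    """Boolean region on a reference grid (geometry identical to its volume)."""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype != bool:
            self.data = self.data.astype(bool)
        super().__post_init__()

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


class LandmarkSet:
    """Named physical-space points (mm), e.g. ``screw1.head`` or ``RU6.mb_cusp``.

    Screw landmarks follow the naming convention ``screw<i>.head`` /
    ``screw<i>.tip`` for mini-screw i = 1..4.
    """

    def __init__(self, entries: dict[str, np.ndarray] | None = None):
        self.entries: dict[str, np.ndarray] = {}
        for name, p in (entries or {}).items():
            self[name] = p

    def __setitem__(self, name: str, point) -> None:
        p = np.asarray(point, dtype=float).reshape(3)
        if not np.all(np.isfinite(p)):
            raise ValueError(f"non-finite coordinate for landmark {name!r}")
        self.entries[name] = p

    def __getitem__(self, name: str) -> np.ndarray:
        return self.entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def names(self) -> list[str]:
        return list(self.entries)

    def subset(self, names) -> "LandmarkSet":
        return LandmarkSet({n: self.entries[n] for n in names})

    def as_array(self, names=None) -> np.ndarray:
        names = list(names) if names is not None else self.names()
        return np.array([self.entries[n] for n in names])

    def screw_names(self) -> list[str]:
        return sorted(n for n in self.entries if n.startswith("screw"))

    def n_screws(self) -> int:
        heads = {n for n in self.entries if n.startswith("screw") and n.endswith(".head")}
        tips = {n.replace(".tip", ".head") for n in self.entries
                if n.startswith("screw") and n.endswith(".tip")}
        return len(heads & tips)

    def transformed(self, fn) -> "LandmarkSet":
        """Apply ``fn(point) -> point`` to every landmark."""
        return LandmarkSet({n: fn(p) for n, p in self.entries.items()})

    def __repr__(self) -> str:
        return f"LandmarkSet({len(self)} points: {', '.join(sorted(self.entries))})"


# ---------------------------------------------------------------------------
# NIfTI volume IO
# ---------------------------------------------------------------------------

def _from_nifti(img: nib.Nifti1Image) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    aff = img.affine
    lin = aff[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    if np.any(spacing <= 0):
        raise ValueError("non-positive spacing in NIfTI affine")
    direction = lin / spacing[None, :]
    return np.asarray(img.dataobj), spacing, aff[:3, 3].copy(), direction


def read_volume(path: str | Path) -> ImageVolume:
    """Read a 3D NIfTI volume, preserving geometry losslessly."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    data, spacing, origin, direction = _from_nifti(nib.load(str(path)))
    if data.ndim != 3:
        raise ValueError(f"non-3D image: {path} has {data.ndim} dimensions")
    vol = ImageVolume(data, spacing, origin, direction)
    logger.info("read_volume %s shape=%s checksum=%s", path.name, vol.shape, vol.checksum())
    return vol


def write_volume(vol: ImageVolume, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(vol.data), vol.affine)
    img.header.set_zooms(tuple(vol.spacing))
    nib.save(img, str(path))
    logger.info("write_volume %s checksum=%s", path.name, vol.checksum())
    return path


def read_mask(path: str | Path) -> BinaryMask:
    vol = read_volume(path)
    return BinaryMask(vol.data > 0, vol.spacing, vol.origin, vol.direction)


def write_mask(mask: BinaryMask, path: str | Path) -> Path:
    return write_volume(ImageVolume(mask.data.astype(np.uint8), mask.spacing,
                                    mask.origin, mask.direction), path)


# ---------------------------------------------------------------------------
# Landmark CSV IO
# ---------------------------------------------------------------------------

def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read a ``name,x,y,z`` CSV of physical-space landmarks (mm)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path)
    expected = ["name", "x", "y", "z"]
    if list(df.columns[:4]) != expected:
        raise ValueError(f"landmark file must have columns {expected}, got {list(df.columns)}")
    if df["name"].duplicated().any():
        dup = df["name"][df["name"].duplicated()].iloc[0]
        raise ValueError(f"duplicate landmark name: {dup!r}")
    coords = df[["x", "y", "z"]].apply(pd.to_numeric, errors="coerce")
    if coords.isna().any().any():
        raise ValueError("non-numeric coordinate in landmark file")
    return LandmarkSet({str(n): c for n, c in zip(df["name"], coords.to_numpy())})


def write_landmarks(lms: LandmarkSet, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        [(n, *lms[n]) for n in lms.names()], columns=["name", "x", "y", "z"]
    )
    df.to_csv(path, index=False, float_format="%.10g")
    return path
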