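"""Dense displacement-field algebra.

Fields are stored as ``(nx, ny, nz, 3)`` arrays of millimetre displacement
vectors under the convention *corresponding point = physical point +
displacement*.  Composition, inversion, exponentiation of stationary
velocities (scaling and squaring) and Jacobian checks all operate in voxel
units internally and assume an axis-aligned grid (identity direction
matrix), which is what the registration pipeline produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

from .core_io import BinaryMask, ImageVolume

__all__ = [
    "VectorField", "DisplacementFieldPair",
    "field_magnitude", "warp_scalar", "compose_fields", "invert_field",
    "jacobian_determinant", "exp_velocity",
    "read_field", "write_field",
]


@dataclass
class VectorField:
    """Dense displacement field (mm) on a regular grid."""

    data: np.ndarray  # (nx, ny, nz, 3), mm
    spacing: np.ndarray = dc_field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = dc_field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = dc_field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4 or self.data.shape[-1] != 3:
            raise ValueError("vector field must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite displacement values")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if not np.allclose(self.direction, np.eye(3), atol=1e-8):
            raise NotImplementedError("field algebra requires an axis-aligned grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]  # type: ignore[return-value]

    def same_grid(self, other) -> bool:
        return (self.shape == tuple(other.shape)
                and np.allclose(self.spacing, other.spacing)
                and np.allclose(self.origin, other.origin))

    def to_voxel(self) -> np.ndarray:
        """Displacements in voxel units, shape (3, nx, ny, nz)."""
        return np.moveaxis(self.data, -1, 0) / self.spacing[:, None, None, None].astype(np.float32)

    @classmethod
    def from_voxel(cls, disp_vox: np.ndarray, like: "VectorField | ImageVolume") -> "VectorField":
        data = np.moveaxis(disp_vox * np.asarray(like.spacing)[:, None, None, None].astype(np.float32), 0, -1)
        return cls(data, like.spacing, like.origin, like.direction)

    @classmethod
    def zeros(cls, like: "ImageVolume | VectorField") -> "VectorField":
        return cls(np.zeros(tuple(like.shape) + (3,), dtype=np.float32),
                   like.spacing, like.origin, like.direction)


@dataclass
class DisplacementFieldPair:
    """Mutually inverse forward/backward fields linking a volume pair.

    ``forward`` maps fixed/template points to their corresponding moving/target
    points; ``backward`` maps the other way.
    """

    forward: VectorField
    backward: VectorField
    report: object | None = None  # optional RegistrationReport from the producing run

    def __post_init__(self) -> None:
        if not self.forward.same_grid(self.backward):
            raise ValueError("forward and backward fields must share a grid")

    def inverse_consistency_mm(self) -> float:
        """Mean magnitude (mm) of forward composed with backward."""
        resid = compose_fields(self.forward, self.backward)
        return float(np.mean(np.linalg.norm(resid.data, axis=-1)))

    def min_jacobian(self) -> float:
        return min(float(jacobian_determinant(self.forward).data.min()),
                   float(jacobian_determinant(self.backward).data.min()))


# ---------------------------------------------------------------------------
# voxel-space kernels
# ---------------------------------------------------------------------------

def _sample(arr: np.ndarray, coords: np.ndarray, order: int = 1, mode: str = "nearest") -> np.ndarray:
    return map_coordinates(arr, coords, order=order, mode=mode, prefilter=(order > 1))


def _warp_by_vox(arr: np.ndarray, disp_vox: np.ndarray, order: int = 1,
                 mode: str = "nearest", cval: float = 0.0) -> np.ndarray:
    """Sample ``arr`` at x + disp(x); disp_vox shape (3, ...)."""
    idx = np.indices(arr.shape, dtype=np.float32)
    coords = idx + disp_vox
    kwargs = {"order": order, "mode": mode, "prefilter": order > 1}
    if mode == "constant":
        kwargs["cval"] = cval
    return map_coordinates(arr, coords, **kwargs)


def _compose_vox(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Displacement of (id+a) o (id+b): apply b first, then a.

    result(x) = b(x) + a(x + b(x)).
    """
    idx = np.indices(a.shape[1:], dtype=np.float32)
    coords = idx + b
    out = np.empty_like(a)
    for c in range(3):
        out[c] = _sample(a[c], coords) + b[c]
    return out


def _exp_vox(vel_vox: np.ndarray) -> np.ndarray:
    """Exponentiate a stationary velocity by scaling and squaring."""
    max_disp = float(np.max(np.linalg.norm(vel_vox, axis=0)))
    n = max(0, int(np.ceil(np.log2(max(max_disp, 1e-6) / 0.5))))
    phi = vel_vox / (2.0 ** n)
    for _ in range(n):
        phi = _compose_vox(phi, phi)
    return phi


def _invert_vox(disp_vox: np.ndarray, n_iter: int = 60, tol: float = 1e-3,
                damping: float = 0.5) -> np.ndarray:
    """Damped fixed-point inverse: u <- (1-λ) u + λ (-d(x + u(x))).

    Damping keeps the iteration contractive for displacement gradients up
    to (2-λ)/λ, well beyond the plain Picard limit of 1.
    """
    idx = np.indices(disp_vox.shape[1:], dtype=np.float32)
    u = -disp_vox.copy()
    for _ in range(n_iter):
        coords = idx + u
        new = np.empty_like(u)
        for c in range(3):
            new[c] = -_sample(disp_vox[c], coords)
        delta = float(np.max(np.abs(new - u)))
        u = (1.0 - damping) * u + damping * new
        if delta < tol:
            break
    return u


# ---------------------------------------------------------------------------
# public API (mm units)
# ---------------------------------------------------------------------------

def field_magnitude(fld: VectorField) -> ImageVolume:
    """Per-voxel Euclidean displacement magnitude (mm)."""
    mag = np.linalg.norm(fld.data.astype(np.float64), axis=-1)
    return ImageVolume(mag, fld.spacing, fld.origin, fld.direction)


def warp_scalar(vol: ImageVolume, fld: VectorField, order: int = 1) -> ImageVolume:
    """Pull a scalar volume back through ``id + field``.

    The output at x holds the input at ``x + field(x)``; warping a volume in
    the field's target space brings it onto the field's source grid.  Use
    ``order=0`` for label/mask volumes.
    """
    if tuple(vol.shape) != fld.shape or not np.allclose(vol.spacing, fld.spacing):
        raise ValueError("volume and field grids do not match")
    was_bool = vol.data.dtype == bool
    arr = vol.data.astype(np.float32)
    out = _warp_by_vox(arr, fld.to_voxel(), order=order)
    if was_bool:
        out = out > 0.5
    if isinstance(vol, BinaryMask):
        return BinaryMask(out, vol.spacing, vol.origin, vol.direction)
    return vol.with_data(out)


def compose_fields(a: VectorField, b: VectorField) -> VectorField:
    """Displacement of the composite map (id+a) o (id+b) (b applied first)."""
    if not a.same_grid(b):
        raise ValueError("fields on mismatched grids")
    return VectorField.from_voxel(_compose_vox(a.to_voxel(), b.to_voxel()), a)


def invert_field(fld: VectorField, n_iter: int = 15) -> VectorField:
    """Numerical inverse of ``id + field`` by fixed-point iteration."""
    return VectorField.from_voxel(_invert_vox(fld.to_voxel(), n_iter=n_iter), fld)


def exp_velocity(vel: VectorField) -> VectorField:
    """Group exponential of a stationary velocity field (scaling and squaring)."""
    return VectorField.from_voxel(_exp_vox(vel.to_voxel()), vel)


def jacobian_determinant(fld: VectorField) -> ImageVolume:
    """Determinant of the Jacobian of ``id + field`` by central differences.

    Positive everywhere is the working proxy for diffeomorphic validity.
    """
    d = fld.to_voxel()
    j = [[None] * 3 for _ in range(3)]
    for c in range(3):
        grads = np.gradient(d[c], axis=(0, 1, 2))
        for ax in range(3):
            j[c][ax] = grads[ax] + (1.0 if ax == c else 0.0)
    det = (j[0][0] * (j[1][1] * j[2][2] - j[1][2] * j[2][1])
           - j[0][1] * (j[1][0] * j[2][2] - j[1][2] * j[2][0])
           + j[0][2] * (j[1][0] * j[2][1] - j[1][1] * j[2][0]))
    return ImageVolume(det.astype(np.float64), fld.spacing, fld.origin, fld.direction)


# ---------------------------------------------------------------------------
# IO: 4D NIfTI, vector dimension last, mm units
# ---------------------------------------------------------------------------

def write_field(fld: VectorField, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    aff = np.eye(4)
    aff[:3, :3] = fld.direction * fld.spacing[None, :]
    aff[:3, 3] = fld.origin
    nib.save(nib.Nifti1Image(fld.data.astype(np.float32), aff), str(path))
    return path


def read_field(path: str | Path) -> VectorField:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 5:  # NIfTI vector convention (nx,ny,nz,1,3)
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(f"not a 3-vector field: shape {data.shape}")
    aff = img.affine
    spacing = np.linalg.norm(aff[:3, :3], axis=0)
    direction = aff[:3, :3] / spacing[None, :]
    return VectorField(data, spacing, aff[:3, 3], direction)
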