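"""Volume container, file I/O and world-coordinate plumbing.

Every module in :mod:`histocal` works on :class:`Volume`: a 3D scalar grid
with voxel spacing and world origin in millimetres.  The world convention is

    world(p_index) = origin + p_index * spacing   (component-wise)

with 0-based voxel indices addressing voxel *centers*, array axes ordered
(x, y, z), and axis 2 ("Z") the layer-normal / transducer axis.  Volumes are
axis-aligned by construction; files whose direction matrices are not
axis-aligned permutations/flips are rejected on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import SimpleITK as sitk
from scipy.ndimage import map_coordinates


class VolumeFormatError(ValueError):
    """Raised when a file cannot be interpreted as an axis-aligned 3D scalar volume."""


@dataclass
class Volume:
    """Axis-aligned 3D scalar image.

    Parameters
    ----------
    data:
        3D array indexed ``[x, y, z]``; arbitrary intensity units.
    spacing:
        Voxel pitch in mm along (x, y, z); strictly positive.
    origin:
        World position (mm) of the center of voxel (0, 0, 0).
    meta:
        Free-form metadata (e.g. simulator ground truth); not persisted in
        the image file itself, see :func:`write_volume`'s JSON sidecar.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3:
            raise VolumeFormatError(f"volume data must be 3D, got ndim={self.data.ndim}")
        if self.spacing.shape != (3,) or not np.all(np.isfinite(self.spacing)) or np.any(self.spacing <= 0):
            raise VolumeFormatError(f"spacing must be 3 strictly positive finite values, got {self.spacing}")
        if self.origin.shape != (3,) or not np.all(np.isfinite(self.origin)):
            raise VolumeFormatError(f"origin must be 3 finite values, got {self.origin}")
        if not np.all(np.isfinite(self.data)):
            raise VolumeFormatError("volume intensities must all be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        """World position (mm) of (possibly fractional) voxel index."""
        return self.origin + np.asarray(index, dtype=float) * self.spacing

    def world_to_index(self, point_mm: np.ndarray) -> np.ndarray:
        """Continuous voxel index of a world point (mm)."""
        return (np.asarray(point_mm, dtype=float) - self.origin) / self.spacing

    @property
    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        """World bounds (mm) spanned by voxel centers: (lower, upper)."""
        upper = self.origin + (np.array(self.shape) - 1) * self.spacing
        return self.origin.copy(), upper

    def center_mm(self) -> np.ndarray:
        """World position of the geometric volume center."""
        lo, hi = self.extent
        return 0.5 * (lo + hi)

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.spacing.copy(), self.origin.copy(), dict(self.meta))


@dataclass(frozen=True)
class BoxMM:
    """Axis-aligned world-space box, used to crop about the phantom."""

    lower: tuple[float, float, float]
    upper: tuple[float, float, float]

    def __post_init__(self) -> None:
        lo, hi = np.asarray(self.lower, float), np.asarray(self.upper, float)
        if not np.all(hi > lo):
            raise ValueError(f"BoxMM upper must exceed lower component-wise: {self.lower} vs {self.upper}")


# --- SimpleITK interop -------------------------------------------------------
#
# SimpleITK arrays are indexed [z, y, x]; direction matrices are row-major
# 3x3 in physical space.  On read we normalise any axis-aligned
# permutation/flip direction to the internal identity-direction (x, y, z)
# convention and fold it into origin/axis order.


def _direction_to_perm(direction: tuple[float, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Decompose a 3x3 direction matrix into (axis permutation, signs).

    Returns ``perm`` with ``perm[j]`` = physical axis that image axis j maps
    to, and the corresponding ±1 signs.  Raises for oblique matrices.
    """
    d = np.asarray(direction, dtype=float).reshape(3, 3)
    perm = np.full(3, -1, dtype=int)
    signs = np.zeros(3)
    for j in range(3):
        col = d[:, j]
        i = int(np.argmax(np.abs(col)))
        if not (np.isclose(abs(col[i]), 1.0, atol=1e-6) and np.allclose(np.delete(col, i), 0.0, atol=1e-6)):
            raise VolumeFormatError(
                "volume direction matrix is oblique (not an axis-aligned permutation/flip); unsupported"
            )
        perm[j] = i
        signs[j] = np.sign(col[i])
    if sorted(perm.tolist()) != [0, 1, 2]:
        raise VolumeFormatError("volume direction matrix is singular")
    return perm, signs


def from_sitk(image: sitk.Image) -> Volume:
    """Convert a SimpleITK image to the internal axis-aligned convention."""
    if image.GetDimension() != 3:
        raise VolumeFormatError(f"expected a 3D image, got {image.GetDimension()}D")
    if image.GetNumberOfComponentsPerPixel() != 1:
        raise VolumeFormatError(
            f"expected scalar voxels, got {image.GetNumberOfComponentsPerPixel()} components"
        )
    perm, signs = _direction_to_perm(image.GetDirection())
    arr = sitk.GetArrayFromImage(image)  # [z, y, x]
    data = np.transpose(arr, (2, 1, 0)).astype(np.float64)  # image axes (x, y, z)
    spacing = np.array(image.GetSpacing(), dtype=float)
    origin = np.array(image.GetOrigin(), dtype=float)

    # Physical-axis components: image axis j contributes along physical axis perm[j].
    out_data = data
    out_spacing = np.empty(3)
    out_origin = np.empty(3)
    # First flip image axes with negative direction, updating the origin.
    for j in range(3):
        if signs[j] < 0:
            out_data = np.flip(out_data, axis=j)
            origin[perm[j]] -= (out_data.shape[j] - 1) * spacing[j]
    # Then permute image axes into physical order.
    axis_order = np.argsort(perm)  # physical axis i comes from image axis axis_order[i]
    out_data = np.transpose(out_data, axes=tuple(axis_order))
    for i in range(3):
        j = axis_order[i]
        out_spacing[i] = spacing[j]
        out_origin[i] = origin[i]
    return Volume(np.ascontiguousarray(out_data), out_spacing, out_origin)


def to_sitk(volume: Volume, dtype=np.float32) -> sitk.Image:
    """Convert a Volume to a SimpleITK image (identity direction)."""
    arr = np.transpose(volume.data, (2, 1, 0)).astype(dtype)
    image = sitk.GetImageFromArray(np.ascontiguousarray(arr))
    image.SetSpacing(tuple(float(s) for s in volume.spacing))
    image.SetOrigin(tuple(float(o) for o in volume.origin))
    return image


_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".nrrd")


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUPPORTED_SUFFIXES):
        raise VolumeFormatError(
            f"unsupported volume format for {path.name!r}; expected one of {_SUPPORTED_SUFFIXES}"
        )


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI (.nii/.nii.gz) or NRRD (.nrrd) scalar 3D volume.

    Spacing and origin are taken from the file header; on-disk axis order
    and orientation flips are normalised to the internal (x, y, z)
    convention.  If a ``<stem>.json`` sidecar exists next to the file it is
    loaded into ``Volume.meta``.
    """
    path = Path(path)
    _check_suffix(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        image = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - ITK error text varies
        raise VolumeFormatError(f"unreadable volume file {path}: {exc}") from exc
    vol = from_sitk(image)
    sidecar = path.with_name(path.name.split(".")[0] + ".json")
    if sidecar.exists():
        vol.meta.update(json.loads(sidecar.read_text()))
    return vol


def write_volume(volume: Volume, path: str | Path, sidecar: bool = False) -> None:
    """Write a Volume to NIfTI or NRRD (chosen by extension).

    With ``sidecar=True`` the (JSON-serialisable part of) ``volume.meta`` is
    written to ``<stem>.json`` next to the image.
    """
    path = Path(path)
    _check_suffix(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    sitk.WriteImage(to_sitk(volume, dtype=np.float64), str(path))
    if sidecar and volume.meta:
        meta = _jsonable(volume.meta)
        path.with_name(path.name.split(".")[0] + ".json").write_text(json.dumps(meta, indent=2))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def crop(volume: Volume, box: BoxMM) -> Volume:
    """Crop to the voxels whose centers fall inside ``box``.

    The returned volume's origin is updated so world coordinates of the
    retained voxels are unchanged.
    """
    lo_w = np.asarray(box.lower, float)
    hi_w = np.asarray(box.upper, float)
    lo_idx = np.ceil(volume.world_to_index(lo_w) - 1e-9).astype(int)
    hi_idx = np.floor(volume.world_to_index(hi_w) + 1e-9).astype(int)
    lo_idx = np.maximum(lo_idx, 0)
    hi_idx = np.minimum(hi_idx, np.array(volume.shape) - 1)
    if np.any(hi_idx < lo_idx):
        raise ValueError("crop box does not contain any voxel center of the volume")
    sl = tuple(slice(a, b + 1) for a, b in zip(lo_idx, hi_idx))
    return Volume(
        volume.data[sl].copy(),
        volume.spacing.copy(),
        volume.index_to_world(lo_idx),
        dict(volume.meta),
    )


def sample(volume: Volume, points_mm: np.ndarray, background: float = 0.0) -> np.ndarray:
    """Trilinear interpolation of the volume at world points (mm).

    ``points_mm`` is (..., 3); returns an array of the leading shape.
    Points outside the voxel-center extent grade to ``background`` (the ROI
    cuboid is allowed to poke past a cropped volume edge).
    """
    pts = np.asarray(points_mm, dtype=float)
    lead_shape = pts.shape[:-1]
    flat = pts.reshape(-1, 3)
    idx = (flat - volume.origin) / volume.spacing  # (n, 3)
    out = map_coordinates(volume.data, idx.T, order=1, mode="constant", cval=background)
    return float(out[0]) if lead_shape == () else out.reshape(lead_shape)
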