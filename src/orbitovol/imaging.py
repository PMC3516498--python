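"""Volume data model, NIfTI I/O, coronal slice extraction, rigid resampling.

World coordinate convention (radiological RAS, mm): x = left -> right,
y = posterior -> anterior, z = inferior -> superior.  Voxel [i, j, k] has
its *center* at ``origin + spacing * (i, j, k)``; the volume extent along
each axis is the half-open interval covering all voxel centers plus half a
voxel on either end.  "Ventrodorsal" (front-to-back, the slicing direction)
is the -y direction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage as ndi

from .errors import ValidationError

#: grid-axis -> anatomical-axis codes for the canonical in-memory layout
RAS_AXES = ("R", "A", "S")


@dataclass
class VolumeImage:
    """A 3-D scalar intensity grid with voxel geometry.

    Parameters
    ----------
    voxels : (nx, ny, nz) ndarray
        Intensities in arbitrary (non-Hounsfield) units.
    spacing : (3,) ndarray
        Per-axis voxel size in mm; all components positive.
    origin : (3,) ndarray
        World position (mm) of the center of voxel [0, 0, 0].
    orientation : tuple of str
        Anatomical axis codes of the grid axes; always RAS internally.
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    orientation: tuple = RAS_AXES

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.voxels.ndim != 3:
            raise ValidationError(
                f"voxels must be 3-D, got {self.voxels.ndim}-D"
            )
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValidationError(
                f"spacing must be 3 positive lengths, got {self.spacing}"
            )
        if self.origin.shape != (3,):
            raise ValidationError("origin must be a 3-vector (mm)")
        codes = tuple(self.orientation)
        if sorted(c.upper().lstrip("+-")[-1] for c in codes) != ["A", "R", "S"]:
            raise ValidationError(
                f"orientation must be a signed permutation of R/A/S, got {codes}"
            )
        if min(self.voxels.shape) < 1:
            raise ValidationError("grid needs at least one voxel per axis")

    @property
    def shape(self):
        return self.voxels.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along a grid axis."""
        n = self.voxels.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def extent(self, axis: int):
        """Half-open world extent (mm) of the volume along an axis."""
        c = self.axis_coords(axis)
        h = self.spacing[axis] / 2
        return c[0] - h, c[-1] + h

    def contains_point(self, point_mm) -> bool:
        p = np.asarray(point_mm, dtype=float)
        return all(
            self.extent(a)[0] <= p[a] < self.extent(a)[1] for a in range(3)
        )

    def world_to_index(self, point_mm) -> np.ndarray:
        """Continuous voxel index of a world point."""
        return (np.asarray(point_mm, float) - self.origin) / self.spacing

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[:3, :3] = np.diag(self.spacing)
        a[:3, 3] = self.origin
        return a


@dataclass
class Slice2D:
    """A coronal (frontal-plane) cross-section.

    ``pixels[i0, i1]`` is indexed by (left-right, inferior-superior); the
    plane normal is the anterior-posterior axis.
    """

    pixels: np.ndarray
    pixel_spacing: np.ndarray  # (mm along x, mm along z)
    plane_position: float  # world y in mm of the extracted grid plane
    plane_axis: str = "A"
    origin2d: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        self.pixel_spacing = np.asarray(self.pixel_spacing, dtype=float)
        if np.any(self.pixel_spacing <= 0):
            raise ValidationError("pixel_spacing components must be > 0")


@dataclass
class RigidTransform:
    """World-space rigid map ``w' = rotation @ w + translation`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        R = self.rotation
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValidationError("rotation must be a 3x3 orthonormal matrix")
        if np.linalg.det(R) < 0:
            raise ValidationError("rotation must be proper (determinant +1)")
        if self.translation.shape != (3,):
            raise ValidationError("translation must be a 3-vector (mm)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points_mm) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points_mm, float))
        out = p @ self.rotation.T + self.translation
        return out[0] if np.asarray(points_mm).ndim == 1 else out

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, first: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``first`` then self."""
        return RigidTransform(
            self.rotation @ first.rotation,
            self.rotation @ first.translation + self.translation,
        )

    @property
    def angle_deg(self) -> float:
        """Rotation magnitude in degrees."""
        c = (np.trace(self.rotation) - 1) / 2
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def to_json(self, path):
        Path(path).write_text(
            json.dumps(
                {
                    "rotation": [float(v) for v in self.rotation.ravel()],
                    "translation": [float(v) for v in self.translation],
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path) -> "RigidTransform":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["rotation"]).reshape(3, 3), np.array(d["translation"]))


def read_volume(path) -> VolumeImage:
    """Read a NIfTI-1 volume into the canonical RAS layout.

    Raises
    ------
    ValidationError
        Missing file, unsupported format, non-3-D data, non-positive
        spacing, or an oblique affine (axis-aligned scans only).
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"volume file not found: {path}")
    if path.suffix == ".nrrd":
        raise ValidationError(
            "NRRD input is not supported; convert to NIfTI-1 (.nii/.nii.gz)"
        )
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad headers
        raise ValidationError(f"malformed volume header in {path}: {exc}") from exc
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValidationError(f"expected 3-D data, got shape {data.shape}")
    aff = img.affine
    lin = aff[:3, :3]
    if np.max(np.abs(lin - np.diag(np.diag(lin)))) > 1e-3 * max(
        1.0, np.abs(np.diag(lin)).max()
    ):
        raise ValidationError("oblique affine not supported; resample upstream")
    spacing = np.diag(lin).copy()
    if np.any(spacing <= 0):
        raise ValidationError(f"non-positive spacing in header: {spacing}")
    return VolumeImage(data, spacing, aff[:3, 3].copy())


def write_volume(vol: VolumeImage, path) -> None:
    """Write a volume as NIfTI-1; round-trips through :func:`read_volume`."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.voxels, dtype=np.float32), vol.affine)
    img.header.set_zooms(tuple(vol.spacing))
    try:
        nib.save(img, str(path))
    except OSError as exc:
        raise ValidationError(f"cannot write volume to {path}: {exc}") from exc


def extract_coronal_slice(vol: VolumeImage, y_mm: float) -> Slice2D:
    """Extract the native grid plane nearest to ventrodorsal position y_mm.

    Nearest-plane rule, no interpolation: every returned pixel value exists
    in the source volume.
    """
    lo, hi = vol.extent(1)
    if not (lo <= y_mm < hi):
        raise ValidationError(
            f"y={y_mm:.3f} mm outside volume extent [{lo:.3f}, {hi:.3f}) mm"
        )
    coords = vol.axis_coords(1)
    dist = np.abs(coords - y_mm)
    # deterministic tie-break toward the dorsal (smaller-y) plane when the
    # requested position is exactly midway between two planes
    near = np.flatnonzero(dist <= dist.min() + 1e-9 * vol.spacing[1])
    j = int(near[0])
    return Slice2D(
        pixels=vol.voxels[:, j, :],
        pixel_spacing=vol.spacing[[0, 2]],
        plane_position=float(coords[j]),
        origin2d=vol.origin[[0, 2]],
    )


def resample_rigid(
    vol: VolumeImage, t: RigidTransform, fill_value: float | None = None
) -> VolumeImage:
    """Resample a volume through a world-space rigid transform.

    The output grid is the input grid (same shape/spacing/origin); the
    output value at world point w is the trilinear interpolation of the
    input at ``t^{-1}(w)``.  Points mapped outside the source get
    ``fill_value`` (default: the source minimum, so that downstream bone
    thresholding sees dark fill).
    """
    if np.allclose(t.rotation, np.eye(3)) and np.allclose(t.translation, 0):
        return VolumeImage(vol.voxels.copy(), vol.spacing.copy(), vol.origin.copy())
    if fill_value is None:
        fill_value = float(vol.voxels.min())
    S = np.diag(vol.spacing)
    Sinv = np.diag(1.0 / vol.spacing)
    Rt = t.rotation.T
    # output index i -> source index j = Sinv Rt S i + Sinv (Rt (o - tr) - o)
    M = Sinv @ Rt @ S
    off = Sinv @ (Rt @ (vol.origin - t.translation) - vol.origin)
    out = ndi.affine_transform(
        np.asarray(vol.voxels, dtype=float),
        M,
        offset=off,
        order=1,
        mode="constant",
        cval=fill_value,
    )
    return VolumeImage(out, vol.spacing.copy(), vol.origin.copy())


def load_landmarks_json(path) -> dict:
    """Load ``{"name": [x, y, z], ...}`` landmark JSON (world mm)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"landmark file not found: {path}")
    raw = json.loads(path.read_text())
    out = {}
    for name, xyz in raw.items():
        arr = np.asarray(xyz, dtype=float)
        if arr.shape != (3,):
            raise ValidationError(f"landmark {name!r} is not a 3-D point: {xyz}")
        out[name] = arr
    return out


def save_landmarks_json(landmarks: dict, path) -> None:
    Path(path).write_text(
        json.dumps({k: [float(v) for v in p] for k, p in landmarks.items()}, indent=2)
    )
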