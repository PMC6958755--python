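"""Domain types and grid-aware volumetric operations.

Every stage of the pipeline works on 3D scalar volumes and binary masks that
carry their full voxel geometry (spacing in mm, origin, axis direction
matrix).  Masks are always set-algebra'd on a common grid: a geometry
mismatch is an error, never an implicit resample.  Arrays are indexed
``[x, y, z]`` (transposed relative to SimpleITK's ``[z, y, x]`` view).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

__all__ = [
    "MaskRole",
    "VolumetricImage",
    "BinaryMask",
    "LabeledComponents",
    "ComponentRecord",
    "load_volume",
    "save_volume",
    "dilate_mask",
    "spherical_footprint",
    "connected_components",
    "mask_union",
    "mask_subtract",
]

#: tolerance for declaring two voxel grids identical
GRID_ATOL = 1e-4


class MaskRole(str, Enum):
    ORGAN = "organ"
    SKELETON = "skeleton"
    SEARCH_REGION = "search_region"
    LESION = "lesion"
    MUSCLE_REFERENCE = "muscle_reference"
    READER = "reader"


@dataclass
class VolumetricImage:
    """3D scalar image with physical geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensities, arbitrary units.
    spacing : (sx, sy, sz)
        Voxel size in mm, all strictly positive.
    origin : (x, y, z)
        Physical coordinate of voxel (0, 0, 0) in mm.
    direction : (3, 3) ndarray
        Axis direction cosine matrix (rows ~ physical axes).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D data")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("volume contains non-finite values (NaN/Inf)")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def grid_compatible(self, other: "VolumetricImage | BinaryMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=GRID_ATOL)
            and np.allclose(self.origin, other.origin, atol=GRID_ATOL)
            and np.allclose(self.direction, other.direction, atol=GRID_ATOL)
        )

    def with_data(self, data: np.ndarray) -> "VolumetricImage":
        return replace(self, data=data)

    # -- SimpleITK bridge -------------------------------------------------
    def to_sitk(self, dtype=None) -> sitk.Image:
        arr = self.data if dtype is None else self.data.astype(dtype)
        if arr.dtype == bool:
            arr = arr.astype(np.uint8)
        img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        img.SetDirection(tuple(self.direction.ravel()))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "VolumetricImage":
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return cls(
            data=data,
            spacing=tuple(img.GetSpacing()),
            origin=tuple(img.GetOrigin()),
            direction=np.asarray(img.GetDirection()).reshape(3, 3),
        )


@dataclass
class BinaryMask:
    """Boolean volume sharing a :class:`VolumetricImage` grid."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))
    role: MaskRole | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D mask, got {self.data.ndim}D data")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)

    shape = VolumetricImage.shape
    voxel_volume_ml = VolumetricImage.voxel_volume_ml
    grid_compatible = VolumetricImage.grid_compatible
    to_sitk = VolumetricImage.to_sitk

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_ml(self) -> float:
        return self.voxel_count * self.voxel_volume_ml

    def with_data(self, data: np.ndarray, role: MaskRole | None = None) -> "BinaryMask":
        return replace(self, data=np.asarray(data).astype(bool), role=role or self.role)

    @classmethod
    def like(
        cls, ref: "VolumetricImage | BinaryMask", data: np.ndarray, role: MaskRole | None = None
    ) -> "BinaryMask":
        return cls(
            data=data,
            spacing=ref.spacing,
            origin=ref.origin,
            direction=ref.direction,
            role=role,
        )

    @classmethod
    def from_sitk(cls, img: sitk.Image, role: MaskRole | None = None) -> "BinaryMask":
        vol = VolumetricImage.from_sitk(img)
        return cls.like(vol, vol.data > 0, role=role)


@dataclass
class ComponentRecord:
    id: int
    voxel_count: int
    volume_ml: float
    bbox: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


@dataclass
class LabeledComponents:
    """Integer label volume (0 = background) with per-component records.

    Labels are contiguous ``1..K``, ordered by each component's first voxel
    in C-raster order, so labeling is deterministic.
    """

    labels: np.ndarray
    components: list[ComponentRecord]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    shape = VolumetricImage.shape  # type: ignore[assignment]
    grid_compatible = VolumetricImage.grid_compatible

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)

    @property
    def data(self) -> np.ndarray:  # for grid_compatible shape access
        return self.labels

    @property
    def n_components(self) -> int:
        return len(self.components)

    def binary(self, role: MaskRole | None = None) -> BinaryMask:
        return BinaryMask(
            data=self.labels > 0,
            spacing=self.spacing,
            origin=self.origin,
            direction=self.direction,
            role=role,
        )

    def component_mask(self, component_id: int) -> np.ndarray:
        return self.labels == component_id

    def select(self, keep_ids: Iterable[int]) -> "LabeledComponents":
        """Keep the given components, relabeling survivors 1..K' in order."""
        keep = sorted(set(int(i) for i in keep_ids))
        lut = np.zeros(len(self.components) + 1, dtype=self.labels.dtype)
        records = []
        for new_id, old_id in enumerate(keep, start=1):
            lut[old_id] = new_id
            old = self.components[old_id - 1]
            records.append(replace(old, id=new_id))
        return LabeledComponents(
            labels=lut[self.labels],
            components=records,
            spacing=self.spacing,
            origin=self.origin,
            direction=self.direction,
        )

    def to_table(self):
        import pandas as pd

        rows = [
            {
                "id": c.id,
                "voxel_count": c.voxel_count,
                "volume_ml": c.volume_ml,
                "bbox": str(c.bbox),
            }
            for c in self.components
        ]
        return pd.DataFrame(rows, columns=["id", "voxel_count", "volume_ml", "bbox"])


# ---------------------------------------------------------------------------
# I/O


def load_volume(path: str | Path) -> VolumetricImage:
    """Read a 3D volume (NIfTI or any SimpleITK-readable format).

    Fails loudly on missing files, non-3D data, or non-finite voxels rather
    than silently defaulting geometry.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"expected 3D volume, got {img.GetDimension()}D: {path}")
    if img.GetNumberOfComponentsPerPixel() != 1:
        raise ValueError(f"expected scalar volume: {path}")
    return VolumetricImage.from_sitk(img)


def load_mask(path: str | Path, role: MaskRole | None = None) -> BinaryMask:
    vol = load_volume(path)
    return BinaryMask.like(vol, vol.data > 0, role=role)


def save_volume(image: VolumetricImage | BinaryMask | LabeledComponents, path: str | Path) -> None:
    """Write a volume/mask/label map preserving geometry.

    Masks are written as uint8, label maps as uint16/uint32 as needed.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(image, BinaryMask):
        img = image.to_sitk(dtype=np.uint8)
    elif isinstance(image, LabeledComponents):
        dtype = np.uint16 if len(image.components) < 2**16 else np.uint32
        img = VolumetricImage(
            image.labels.astype(dtype),
            image.spacing,
            image.origin,
            image.direction,
        ).to_sitk()
    else:
        img = image.to_sitk()
    sitk.WriteImage(img, str(path))


# ---------------------------------------------------------------------------
# Mask morphology and algebra


def spherical_footprint(radius_mm: float, spacing: Sequence[float]) -> np.ndarray:
    """Boolean ellipsoidal footprint of a physical ball on an anisotropic grid.

    A voxel offset (dx, dy, dz) is in the footprint iff its voxel-center
    physical distance is <= radius_mm (closed ball).
    """
    if radius_mm < 0:
        raise ValueError(f"radius_mm must be >= 0, got {radius_mm}")
    half = [int(np.floor(radius_mm / s + 1e-9)) for s in spacing]
    grids = np.ogrid[tuple(slice(-h, h + 1) for h in half)]
    dist2 = sum((g * s) ** 2 for g, s in zip(grids, spacing))
    return dist2 <= radius_mm**2 + 1e-9


def dilate_mask(mask: BinaryMask, radius_mm: float) -> BinaryMask:
    """Dilate by a closed physical ball of ``radius_mm`` (spacing-aware).

    The output contains exactly the voxels whose center lies within
    ``radius_mm`` of some input-voxel center; the input is always a subset
    of the output.  ``radius_mm == 0`` is the identity.
    """
    if radius_mm < 0:
        raise ValueError(f"radius_mm must be >= 0, got {radius_mm}")
    if radius_mm == 0 or not mask.data.any():
        return mask.with_data(mask.data.copy())
    footprint = spherical_footprint(radius_mm, mask.spacing)
    out = ndimage.binary_dilation(mask.data, structure=footprint)
    return mask.with_data(out)


_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def connected_components(mask: BinaryMask, connectivity: int = 26) -> LabeledComponents:
    """Label connected components under 6/18/26-connectivity.

    Components are relabeled 1..K by first voxel in C-raster order so the
    labeling is deterministic regardless of backend scan order.
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of 6, 18, 26; got {connectivity}")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    raw, n = ndimage.label(mask.data, structure=structure)
    if n == 0:
        return LabeledComponents(
            labels=raw.astype(np.int32),
            components=[],
            spacing=mask.spacing,
            origin=mask.origin,
            direction=mask.direction,
        )
    flat = raw.ravel()
    nz = np.flatnonzero(flat)
    # first occurrence (in raster order) of each raw label
    first_idx = np.full(n + 1, flat.size, dtype=np.int64)
    np.minimum.at(first_idx, flat[nz], nz)
    order = np.argsort(first_idx[1:], kind="stable")  # raw label -> rank
    lut = np.zeros(n + 1, dtype=np.int32)
    lut[1 + order] = np.arange(1, n + 1, dtype=np.int32)
    labels = lut[raw]

    counts = np.bincount(labels.ravel(), minlength=n + 1)
    slices = ndimage.find_objects(labels)
    vox_ml = float(np.prod(mask.spacing)) / 1000.0
    components = []
    for k in range(1, n + 1):
        sl = slices[k - 1]
        bbox = tuple((s.start, s.stop) for s in sl)
        components.append(
            ComponentRecord(
                id=k,
                voxel_count=int(counts[k]),
                volume_ml=float(counts[k]) * vox_ml,
                bbox=bbox,  # type: ignore[arg-type]
            )
        )
    return LabeledComponents(
        labels=labels,
        components=components,
        spacing=mask.spacing,
        origin=mask.origin,
        direction=mask.direction,
    )


def _check_compatible(masks: Sequence[BinaryMask]) -> None:
    ref = masks[0]
    for m in masks[1:]:
        if not ref.grid_compatible(m):
            raise ValueError("masks are not grid-compatible (shape/spacing/origin/direction)")


def mask_union(masks: Sequence[BinaryMask]) -> BinaryMask:
    """Voxelwise union: true iff true in at least one input."""
    if not masks:
        raise ValueError("mask_union requires at least one mask")
    _check_compatible(masks)
    out = np.zeros_like(masks[0].data, dtype=bool)
    for m in masks:
        out |= m.data
    return masks[0].with_data(out)


def mask_subtract(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    """Set difference a \\ b on a shared grid."""
    _check_compatible([a, b])
    return a.with_data(a.data & ~b.data)
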