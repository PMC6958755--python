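"""Synthetic whole-body-like DWI/T1 phantom pairs with ground truth.

The generator emulates the image properties the pipeline exploits: a bright
high-b DWI appearance of focal marrow lesions inside a skeleton band, bright
normal organs elsewhere, a b0 volume consistent with a per-tissue apparent
diffusion coefficient through the two-point mono-exponential signal model,
and a T1-weighted volume in which lesions are hypointense relative to the
psoas muscle while most other tissue is brighter.  All volumes share one
grid, all ground-truth masks are returned, and generation is bitwise
reproducible for a fixed seed.

Geometry is deliberately schematic: an elliptical "body" cylinder, a curved
tubular "spine" as the skeleton band, ellipsoidal organ blobs, a box-shaped
psoas.  Anatomical realism is a non-goal; geometric and intensity realism at
the level the algorithm sees (contrasts, noise, spatial relations) is the
point.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import SimpleITK as sitk

from .core import BinaryMask, MaskRole, VolumetricImage

__all__ = [
    "OrganBlob",
    "TubeGeometry",
    "BoxRegion",
    "PhantomSpec",
    "Phantom",
    "generate_phantom_pair",
    "generate_cohort",
    "confounder_blob",
]

#: IQR of a unit-variance Gaussian; converts noise sigma to background IQR
GAUSSIAN_IQR = 1.3489795003921634


@dataclass(frozen=True)
class OrganBlob:
    """Ellipsoidal blob, physical coordinates in mm.

    ``in_atlas_mask`` marks blobs the atlas knows about (normal hyperintense
    organs).  Confounders — lesion-mimicking blobs the atlas does not cover —
    set it to False.
    """

    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    dwi_intensity: float
    t1_intensity: float
    adc: float = 1.1e-3
    in_atlas_mask: bool = True


@dataclass(frozen=True)
class TubeGeometry:
    """Curved vertical tube standing in for the spine/skeleton band."""

    radius_mm: float = 10.0
    curve_amplitude_mm: float = 6.0
    curve_period_mm: float = 280.0
    z_margin_mm: float = 15.0


@dataclass(frozen=True)
class BoxRegion:
    """Axis-aligned box, physical mm; center offset is relative to volume center."""

    offset_mm: tuple[float, float, float] = (26.0, 0.0, 0.0)
    size_mm: tuple[float, float, float] = (16.0, 16.0, 70.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Conditions of a synthetic subject.

    ``lesion_dwi_contrast`` is the lesion excess over the DWI background in
    multiples of the background interquartile range (IQR of the Gaussian
    noise floor); the default of 6 background-IQRs makes lesions clear
    outliers under the default patient threshold.  A "hard" setting of 3 is
    useful for sensitivity curves.
    """

    shape: tuple[int, int, int] = (64, 48, 112)
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    n_lesions: int = 5
    lesion_radius_mm: tuple[float, float] = (4.0, 8.0)
    lesion_dwi_contrast: float = 6.0
    organ_blobs: tuple[OrganBlob, ...] | None = None  # None -> default organs
    skeleton_geometry: TubeGeometry = field(default_factory=TubeGeometry)
    psoas_region: BoxRegion = field(default_factory=BoxRegion)
    noise_sigma: float = 5.0
    noise_model: Literal["gaussian", "rician"] = "rician"
    seed: int = 0
    # intensity / signal model constants
    dwi_background: float = 100.0
    dwi_air: float = 2.0
    t1_background: float = 300.0
    t1_psoas: float = 150.0
    t1_lesion: float = 80.0
    t1_air: float = 5.0
    b_high: float = 800.0
    b_low: float = 0.0
    adc_background: float = 1.4e-3
    adc_lesion: float = 0.7e-3
    adc_psoas: float = 1.3e-3
    dwi_psoas: float = 90.0

    @property
    def background_iqr(self) -> float:
        """Nominal IQR of the DWI background noise floor (1.0 if noise-free)."""
        return GAUSSIAN_IQR * self.noise_sigma if self.noise_sigma > 0 else 1.0

    @property
    def lesion_dwi_intensity(self) -> float:
        return self.dwi_background + self.lesion_dwi_contrast * self.background_iqr


@dataclass
class Phantom:
    """One synthetic subject: noisy volumes, truth masks, noise-free volumes."""

    dwi_high: VolumetricImage
    dwi_b0: VolumetricImage
    t1: VolumetricImage
    truth: dict[str, BinaryMask]  # lesion_mask, organ_mask, skeleton_mask, psoas_mask
    clean: dict[str, VolumetricImage]  # dwi_high, dwi_b0, t1, adc
    spec: PhantomSpec

    def __iter__(self):
        return iter((self.dwi_high, self.dwi_b0, self.t1, self.truth))


def _default_organs(spec: PhantomSpec) -> tuple[OrganBlob, ...]:
    cx, cy, cz = _volume_center_mm(spec)
    return (
        OrganBlob((cx + 34.0, cy, cz + 30.0), (9.0, 9.0, 14.0), 250.0, 280.0),
        OrganBlob((cx - 34.0, cy, cz + 30.0), (9.0, 9.0, 14.0), 250.0, 280.0),
        OrganBlob((cx - 30.0, cy + 14.0, cz - 55.0), (8.0, 8.0, 10.0), 220.0, 260.0),
    )


def confounder_blob(spec: PhantomSpec, z_frac: float = 0.75) -> OrganBlob:
    """A DWI-bright, T1-bright blob inside the skeleton band.

    It mimics a lesion on DWI but is hyperintense on T1 (above the psoas
    mean), so the T1 false-positive filter should remove it.  It is not part
    of the atlas organ mask, so atlas-based organ removal cannot catch it.
    """
    geom = spec.skeleton_geometry
    cx, cy, _ = _volume_center_mm(spec)
    zmin, zmax = _tube_z_range(spec)
    z = zmin + z_frac * (zmax - zmin)
    x = cx + geom.curve_amplitude_mm * np.sin(2 * np.pi * z / geom.curve_period_mm)
    r = min(5.0, geom.radius_mm - 2.0)
    return OrganBlob(
        center_mm=(float(x), float(cy), float(z)),
        radii_mm=(r, r, r),
        dwi_intensity=spec.lesion_dwi_intensity,
        t1_intensity=2.0 * spec.t1_background,
        adc=spec.adc_lesion,
        in_atlas_mask=False,
    )


def _volume_center_mm(spec: PhantomSpec) -> tuple[float, float, float]:
    return tuple((n - 1) * s / 2.0 for n, s in zip(spec.shape, spec.spacing))


def _tube_z_range(spec: PhantomSpec) -> tuple[float, float]:
    zmax_phys = (spec.shape[2] - 1) * spec.spacing[2]
    m = spec.skeleton_geometry.z_margin_mm
    return m, zmax_phys - m


def _coordinate_grids(spec: PhantomSpec):
    """Physical voxel-center coordinates, broadcastable to the volume shape."""
    axes = [np.arange(n) * s for n, s in zip(spec.shape, spec.spacing)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _tube_mask(spec: PhantomSpec, xg, yg, zg) -> np.ndarray:
    geom = spec.skeleton_geometry
    cx, cy, _ = _volume_center_mm(spec)
    zmin, zmax = _tube_z_range(spec)
    center_x = cx + geom.curve_amplitude_mm * np.sin(2 * np.pi * zg / geom.curve_period_mm)
    radial2 = (xg - center_x) ** 2 + (yg - cy) ** 2
    return (radial2 <= geom.radius_mm**2) & (zg >= zmin) & (zg <= zmax)


def _body_mask(spec: PhantomSpec, xg, yg, zg) -> np.ndarray:
    """Elliptical trunk, tapering toward high z (shoulders-to-legs narrowing).

    The taper gives the body outline a genuine z-gradient, as in real
    whole-body images, so registration is constrained along the body axis.
    """
    cx, cy, _ = _volume_center_mm(spec)
    zmax = (spec.shape[2] - 1) * spec.spacing[2]
    taper = 1.05 - 0.30 * (zg / zmax)
    rx = cx * 0.92 * taper
    ry = cy * 0.88 * taper
    return ((xg - cx) / rx) ** 2 + ((yg - cy) / ry) ** 2 <= 1.0


def _lung_masks(spec: PhantomSpec, xg, yg, zg) -> np.ndarray:
    """Paired low-signal 'lung' voids in the upper trunk."""
    cx, cy, cz = _volume_center_mm(spec)
    zmax = (spec.shape[2] - 1) * spec.spacing[2]
    zc = 0.82 * zmax
    out = np.zeros(spec.shape, dtype=bool)
    for sx in (-1.0, 1.0):
        out |= _ellipsoid((cx + sx * 22.0, cy, zc), (14.0, 16.0, 26.0), xg, yg, zg)
    return out


def _ellipsoid(center, radii, xg, yg, zg) -> np.ndarray:
    return (
        ((xg - center[0]) / radii[0]) ** 2
        + ((yg - center[1]) / radii[1]) ** 2
        + ((zg - center[2]) / radii[2]) ** 2
        <= 1.0
    )


def _place_lesions(spec: PhantomSpec, rng: np.random.Generator):
    """Sample non-touching lesion spheres strictly inside the tube."""
    geom = spec.skeleton_geometry
    cx, cy, _ = _volume_center_mm(spec)
    zmin, zmax = _tube_z_range(spec)
    rmin, rmax = spec.lesion_radius_mm
    placed: list[tuple[float, float, float, float]] = []  # x, y, z, r
    attempts = 0
    while len(placed) < spec.n_lesions:
        attempts += 1
        if attempts > 5000:
            raise RuntimeError(
                f"could not place {spec.n_lesions} lesions inside the skeleton band"
            )
        r = float(rng.uniform(rmin, rmax))
        max_radial = geom.radius_mm - r
        if max_radial <= 0 or zmax - zmin < 2 * r:
            raise RuntimeError("lesions do not fit inside the skeleton band")
        z = float(rng.uniform(zmin + r, zmax - r))
        rho = max_radial * np.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * np.pi)
        x = (
            cx
            + geom.curve_amplitude_mm * np.sin(2 * np.pi * z / geom.curve_period_mm)
            + rho * np.cos(phi)
        )
        y = cy + rho * np.sin(phi)
        ok = all(
            np.hypot(np.hypot(x - px, y - py), z - pz) >= r + pr + 5.0
            for px, py, pz, pr in placed
        )
        if ok:
            placed.append((x, y, float(z), r))
    return placed


def _add_noise(rng: np.random.Generator, clean: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    if spec.noise_sigma <= 0:
        return clean.copy()
    if spec.noise_model == "gaussian":
        return clean + rng.normal(0.0, spec.noise_sigma, clean.shape)
    # Rician: magnitude of a complex Gaussian around the clean signal
    re = clean + rng.normal(0.0, spec.noise_sigma, clean.shape)
    im = rng.normal(0.0, spec.noise_sigma, clean.shape)
    return np.hypot(re, im)


def generate_phantom_pair(spec: PhantomSpec) -> Phantom:
    """Generate one subject: (dwi_high, dwi_b0, t1) plus truth masks.

    The b0 volume is derived from the high-b volume through the forward
    mono-exponential model ``S0 = S_high * exp(b_high * ADC)`` with the
    per-tissue ADC map, so inverting the model on the noise-free volumes
    recovers the planted ADC exactly.
    """
    rng = np.random.default_rng(spec.seed)
    xg, yg, zg = _coordinate_grids(spec)

    body = _body_mask(spec, xg, yg, zg) & np.ones(spec.shape, dtype=bool)
    tube = _tube_mask(spec, xg, yg, zg) & body

    # psoas box
    cx, cy, cz = _volume_center_mm(spec)
    box = spec.psoas_region
    pc = (cx + box.offset_mm[0], cy + box.offset_mm[1], cz + box.offset_mm[2])
    psoas = (
        (np.abs(xg - pc[0]) <= box.size_mm[0] / 2)
        & (np.abs(yg - pc[1]) <= box.size_mm[1] / 2)
        & (np.abs(zg - pc[2]) <= box.size_mm[2] / 2)
    ) & body
    psoas &= ~tube  # reference muscle never inside the skeleton band

    organs = spec.organ_blobs if spec.organ_blobs is not None else _default_organs(spec)

    dwi = np.full(spec.shape, spec.dwi_air, dtype=float)
    t1 = np.full(spec.shape, spec.t1_air, dtype=float)
    adc = np.zeros(spec.shape, dtype=float)
    dwi[body] = spec.dwi_background
    t1[body] = spec.t1_background
    adc[body] = spec.adc_background
    lungs = _lung_masks(spec, xg, yg, zg) & body & ~tube
    dwi[lungs] = 30.0
    t1[lungs] = 60.0
    adc[lungs] = 1.0e-3
    dwi[psoas] = spec.dwi_psoas
    t1[psoas] = spec.t1_psoas
    adc[psoas] = spec.adc_psoas

    organ_truth = np.zeros(spec.shape, dtype=bool)
    for blob in organs:
        m = _ellipsoid(blob.center_mm, blob.radii_mm, xg, yg, zg) & body
        dwi[m] = blob.dwi_intensity
        t1[m] = blob.t1_intensity
        adc[m] = blob.adc
        if blob.in_atlas_mask:
            organ_truth |= m

    lesion_truth = np.zeros(spec.shape, dtype=bool)
    if spec.n_lesions > 0:
        for x, y, z, r in _place_lesions(spec, rng):
            m = _ellipsoid((x, y, z), (r, r, r), xg, yg, zg) & tube
            lesion_truth |= m
        dwi[lesion_truth] = spec.lesion_dwi_intensity
        t1[lesion_truth] = spec.t1_lesion
        adc[lesion_truth] = spec.adc_lesion

    b0 = dwi * np.exp((spec.b_high - spec.b_low) * adc)

    geom = dict(spacing=spec.spacing)
    clean = {
        "dwi_high": VolumetricImage(dwi.copy(), **geom),
        "dwi_b0": VolumetricImage(b0.copy(), **geom),
        "t1": VolumetricImage(t1.copy(), **geom),
        "adc": VolumetricImage(adc.copy(), **geom),
    }
    noisy = [
        VolumetricImage(_add_noise(rng, vol, spec), **geom) for vol in (dwi, b0, t1)
    ]
    truth = {
        "lesion_mask": BinaryMask(lesion_truth, role=MaskRole.LESION, **geom),
        "organ_mask": BinaryMask(organ_truth, role=MaskRole.ORGAN, **geom),
        "skeleton_mask": BinaryMask(tube, role=MaskRole.SKELETON, **geom),
        "psoas_mask": BinaryMask(psoas, role=MaskRole.MUSCLE_REFERENCE, **geom),
    }
    return Phantom(
        dwi_high=noisy[0],
        dwi_b0=noisy[1],
        t1=noisy[2],
        truth=truth,
        clean=clean,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Cohorts: smoothly deformed copies of one subject


def _random_deformation(
    reference: VolumetricImage,
    scale_mm: float,
    rng: np.random.Generator,
    mode: str = "bspline",
) -> sitk.Transform:
    """Random spatial perturbation.

    ``bspline``: smooth free-form displacement, control-point coefficients
    N(0, scale_mm).  ``rigid``: translation N(0, scale_mm) per axis plus a
    small rotation (sigma 2 degrees) about the volume center.
    """
    ref = reference.to_sitk(dtype=np.float64)
    if mode == "rigid":
        tx = sitk.Euler3DTransform()
        center = ref.TransformContinuousIndexToPhysicalPoint(
            [(s - 1) / 2.0 for s in ref.GetSize()]
        )
        tx.SetCenter(center)
        tx.SetRotation(*rng.normal(0.0, np.deg2rad(2.0), 3))
        tx.SetTranslation(tuple(rng.normal(0.0, scale_mm, 3)))
        return tx
    if mode != "bspline":
        raise ValueError(f"unknown perturbation mode: {mode}")
    mesh = [max(2, int(round(sz * sp / 90.0))) for sz, sp in zip(reference.shape, reference.spacing)]
    tx = sitk.BSplineTransformInitializer(ref, mesh)
    params = rng.normal(0.0, scale_mm, len(tx.GetParameters()))
    tx.SetParameters(tuple(params))
    return tx


def _resample(
    image: VolumetricImage, tx: sitk.Transform, nearest: bool = False
) -> np.ndarray:
    ref = image.to_sitk(dtype=np.float64)
    interp = sitk.sitkNearestNeighbor if nearest else sitk.sitkLinear
    out = sitk.Resample(ref, ref, tx, interp, 0.0, sitk.sitkFloat64)
    return sitk.GetArrayFromImage(out).transpose(2, 1, 0)


def generate_cohort(
    n_subjects: int,
    base_spec: PhantomSpec,
    deformation_scale: float = 6.0,
    seed: int = 0,
    perturbation: str = "bspline",
) -> list[Phantom]:
    """Smoothly deformed, intensity-jittered, independently-noised copies.

    Each subject applies a random B-spline warp (coefficient std
    ``deformation_scale`` mm) and a small global intensity scale to the
    noise-free base volumes, then adds fresh noise; truth masks are warped
    with nearest-neighbor so set relations (lesions inside the skeleton)
    are preserved exactly.  ``deformation_scale = 0`` yields subjects that
    differ only in noise realization; per-subject seeds are recorded in each
    returned spec.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    # the clean volumes keep the contrast defined by base_spec's noise level;
    # per-subject noise is injected after warping
    base = generate_phantom_pair(base_spec)
    master = np.random.default_rng(seed)
    subject_seeds = master.integers(0, 2**31 - 1, size=n_subjects)
    cohort = []
    for i, sub_seed in enumerate(subject_seeds):
        rng = np.random.default_rng(int(sub_seed))
        spec_i = replace(base_spec, seed=int(sub_seed))
        if deformation_scale > 0:
            tx = _random_deformation(
                base.clean["dwi_high"], deformation_scale, rng, mode=perturbation
            )
            vols = {
                k: _resample(v, tx) for k, v in base.clean.items() if k != "adc"
            }
            masks = {
                k: _resample(
                    VolumetricImage(m.data.astype(np.float64), m.spacing, m.origin, m.direction),
                    tx,
                    nearest=True,
                )
                > 0.5
                for k, m in base.truth.items()
            }
        else:
            vols = {k: v.data.copy() for k, v in base.clean.items() if k != "adc"}
            masks = {k: m.data.copy() for k, m in base.truth.items()}
        gain = float(rng.normal(1.0, 0.03))
        geom = dict(spacing=base_spec.spacing)
        noisy = {
            k: VolumetricImage(_add_noise(rng, gain * v, spec_i), **geom)
            for k, v in vols.items()
        }
        truth = {
            k: BinaryMask(m, role=base.truth[k].role, **geom) for k, m in masks.items()
        }
        clean = {k: VolumetricImage(gain * v, **geom) for k, v in vols.items()}
        cohort.append(
            Phantom(
                dwi_high=noisy["dwi_high"],
                dwi_b0=noisy["dwi_b0"],
                t1=noisy["t1"],
                truth=truth,
                clean=clean,
                spec=spec_i,
            )
        )
    return cohort
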