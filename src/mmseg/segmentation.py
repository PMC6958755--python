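"""Core lesion detector: quartile-outlier thresholding plus T1 filtering.

Inside the search region, lesion candidates are the intensity outliers

    DWI lesion intensity >= Q3 + k * (Q3 - Q1)

where Q1/Q3 are the first/third quartiles of the region's intensity
distribution and ``k`` is tuned per patient (typically 2.5-7.5, most often
4).  Candidates are split into connected components, and components that
are not hypointense on the co-registered T1-weighted volume — a fraction
``>= pct_cutoff`` of their voxels brighter than the mean psoas-muscle
intensity — are discarded as false positives (myeloma lesions sit at or
below muscle signal on T1).  No size criterion is applied anywhere.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import SimpleITK as sitk

from .core import (
    BinaryMask,
    LabeledComponents,
    VolumetricImage,
    connected_components,
)
from .registration import (
    AtlasBundle,
    RegistrationConfig,
    TransformChain,
    apply_transform,
    register_pair,
)
from .search_region import RegionSelectionParams, build_search_region

__all__ = [
    "ThresholdParams",
    "T1FilterParams",
    "compute_iqr_threshold",
    "threshold_segment",
    "align_t1",
    "psoas_reference_mean",
    "t1_component_filter",
    "run_pipeline",
    "PipelineResult",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThresholdParams:
    """Outlier multiplier ``k``; per-patient, typically 2.5-7.5, default 4."""

    k: float = 4.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"k must be > 0, got {self.k}")


@dataclass(frozen=True)
class T1FilterParams:
    """Component-removal cutoff: fraction of voxels above the psoas mean.

    Per patient, typically 0.60-0.99, default 0.90.
    """

    pct_cutoff: float = 0.90

    def __post_init__(self) -> None:
        if not (0 < self.pct_cutoff <= 1):
            raise ValueError(f"pct_cutoff must be in (0, 1], got {self.pct_cutoff}")


def compute_iqr_threshold(
    intensities, params: ThresholdParams | None = None
) -> float:
    """Q3 + k * (Q3 - Q1), quartiles by linear interpolation of order stats."""
    params = params or ThresholdParams()
    values = np.asarray(intensities, dtype=float).ravel()
    if values.size < 4:
        raise ValueError(f"need at least 4 intensities, got {values.size}")
    q1, q3 = np.percentile(values, [25.0, 75.0], method="linear")
    if q3 == q1:
        warnings.warn(
            "zero interquartile range: threshold degenerates to Q3", stacklevel=2
        )
    return float(q3 + params.k * (q3 - q1))


def threshold_segment(
    dwi: VolumetricImage,
    region: BinaryMask,
    params: ThresholdParams | None = None,
    connectivity: int = 26,
) -> LabeledComponents:
    """Segment outlier-bright voxels inside the search region.

    Quartiles are computed over region voxels only.  With zero IQR the
    region is (near-)constant and thresholding is meaningless: a warning is
    emitted and no components are returned.
    """
    params = params or ThresholdParams()
    if not dwi.grid_compatible(region):
        raise ValueError("DWI and search region are not grid-compatible")
    if region.voxel_count == 0:
        raise ValueError("search region is empty")
    values = dwi.data[region.data]
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        threshold = compute_iqr_threshold(values, params)
    if caught:  # zero IQR: every region voxel would pass the degenerate cut
        warnings.warn(
            "zero IQR in search region; returning no components", stacklevel=2
        )
        candidate = region.with_data(np.zeros_like(region.data))
    else:
        candidate = region.with_data(region.data & (dwi.data >= threshold))
    logger.info(
        "threshold %.4g over %d region voxels -> %d candidate voxels",
        threshold,
        region.voxel_count,
        candidate.voxel_count,
    )
    return connected_components(candidate, connectivity=connectivity)


def n4_bias_correct(image: VolumetricImage, shrink_factor: int = 4) -> VolumetricImage:
    """Hook: N4 bias-field correction, delegated to SimpleITK's N4 filter."""
    img = image.to_sitk(dtype=np.float32)
    small = sitk.Shrink(img, [shrink_factor] * 3)
    corrector = sitk.N4BiasFieldCorrectionImageFilter()
    corrector.Execute(small, sitk.Image(small.GetSize(), sitk.sitkUInt8) + 1)
    log_field = corrector.GetLogBiasFieldAsImage(img)
    corrected = img / sitk.Exp(log_field)
    return VolumetricImage.from_sitk(sitk.Cast(corrected, sitk.sitkFloat64))


def align_t1(
    t1: VolumetricImage,
    b0: VolumetricImage,
    cfg: RegistrationConfig | None = None,
    bias_correct: bool = False,
) -> VolumetricImage:
    """Resample T1w onto the DWI (b0) grid via rigid-only registration."""
    if bias_correct:
        t1 = n4_bias_correct(t1)
    cfg = cfg or RegistrationConfig()
    chain = register_pair(b0, t1, cfg, rigid_only=True)
    return apply_transform(t1, chain, b0, interpolation="linear")


def psoas_reference_mean(t1_aligned: VolumetricImage, psoas_mask: BinaryMask) -> float:
    """Arithmetic mean T1 intensity inside the psoas reference mask."""
    if not t1_aligned.grid_compatible(psoas_mask):
        raise ValueError("T1 and psoas mask are not grid-compatible")
    if psoas_mask.voxel_count == 0:
        raise ValueError("psoas mask is empty")
    return float(t1_aligned.data[psoas_mask.data].mean())


def t1_component_filter(
    components: LabeledComponents,
    t1_aligned: VolumetricImage,
    psoas_mean: float,
    params: T1FilterParams | None = None,
) -> LabeledComponents:
    """Drop components that are too bright on T1 relative to the psoas mean.

    For each component, ``f`` is the fraction of voxels with T1 strictly
    above ``psoas_mean``; the component is removed iff ``f >= pct_cutoff``.
    Survivors keep their voxel memberships exactly and are relabeled 1..K'
    in order.
    """
    params = params or T1FilterParams()
    if not components.grid_compatible(t1_aligned):
        raise ValueError("components and T1 are not grid-compatible")
    if not components.components:
        return components
    labels = components.labels
    n = len(components.components)
    above = np.bincount(
        labels[(labels > 0) & (t1_aligned.data > psoas_mean)], minlength=n + 1
    )
    keep = []
    for comp in components.components:
        f = above[comp.id] / comp.voxel_count
        if f < params.pct_cutoff:
            keep.append(comp.id)
        else:
            logger.info(
                "component %d removed by T1 filter (f=%.3f >= %.2f)",
                comp.id,
                f,
                params.pct_cutoff,
            )
    return components.select(keep)


@dataclass
class PipelineResult:
    components: LabeledComponents
    provenance: dict[str, Any]
    region: BinaryMask
    chain: TransformChain
    candidates: LabeledComponents | None = None  # pre-T1-filter components
    t1_aligned: VolumetricImage | None = None
    psoas_mean: float | None = None


def run_pipeline(
    dwi_high: VolumetricImage,
    dwi_b0: VolumetricImage,
    t1: VolumetricImage | None,
    atlas: AtlasBundle,
    psoas_mask: BinaryMask | None = None,
    threshold_params: ThresholdParams | None = None,
    t1_filter_params: T1FilterParams | None = None,
    region_params: RegionSelectionParams | None = None,
    reg_cfg: RegistrationConfig | None = None,
    use_t1_filter: bool = True,
    bias_correct: bool = False,
    connectivity: int = 26,
) -> PipelineResult:
    """Full detector: search region -> outlier threshold -> T1 filter.

    With ``use_t1_filter=False`` (or no T1 volume) the detector runs in
    DWI-only mode and skips the false-positive filter.  The provenance
    record captures every parameter, the per-stage counts, the threshold,
    and wall time.
    """
    threshold_params = threshold_params or ThresholdParams()
    t1_filter_params = t1_filter_params or T1FilterParams()
    region_params = region_params or RegionSelectionParams()
    t0 = time.perf_counter()
    use_t1 = use_t1_filter and t1 is not None
    if use_t1 and psoas_mask is None:
        raise ValueError("T1 filtering requires a psoas reference mask")

    region, chain = build_search_region(dwi_high, atlas, reg_cfg, region_params)
    candidates = threshold_segment(
        dwi_high, region, threshold_params, connectivity=connectivity
    )
    n_candidates = candidates.n_components

    t1_aligned = None
    psoas_mean = None
    final = candidates
    if use_t1:
        t1_aligned = align_t1(t1, dwi_b0, reg_cfg, bias_correct=bias_correct)
        psoas_mean = psoas_reference_mean(t1_aligned, psoas_mask)
        final = t1_component_filter(
            candidates, t1_aligned, psoas_mean, t1_filter_params
        )

    values = dwi_high.data[region.data]
    q1, q3 = np.percentile(values, [25.0, 75.0]) if values.size else (np.nan, np.nan)
    provenance = {
        "k": threshold_params.k,
        "t1_pct_cutoff": t1_filter_params.pct_cutoff,
        "t1_filter": use_t1,
        "bias_correct": bias_correct,
        "organ_dilation_mm": region_params.organ_dilation_mm,
        "skeleton_dilation_mm": region_params.skeleton_dilation_mm,
        "connectivity": connectivity,
        "region_voxels": region.voxel_count,
        "q1": float(q1),
        "q3": float(q3),
        "threshold": float(q3 + threshold_params.k * (q3 - q1)),
        "psoas_mean": psoas_mean,
        "n_candidate_components": n_candidates,
        "n_final_components": final.n_components,
        "wall_time_s": time.perf_counter() - t0,
    }
    logger.info(
        "pipeline: %d candidates -> %d lesions in %.1f s",
        n_candidates,
        final.n_components,
        provenance["wall_time_s"],
    )
    return PipelineResult(
        components=final,
        provenance=provenance,
        region=region,
        chain=chain,
        candidates=candidates,
        t1_aligned=t1_aligned,
        psoas_mean=psoas_mean,
    )
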