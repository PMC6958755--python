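"""Per-patient lesion search region: skeleton band minus hyperintense organs.

The atlas template is registered to the patient's high-b DWI; the atlas's
pre-drawn skeleton and organ masks are propagated through the resulting
chain; the skeleton band is dilated by 6 mm (to keep the appendicular
skeleton in), the organs by 4 mm (to guarantee complete removal); the
search region is the dilated skeleton minus the dilated organs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .core import BinaryMask, MaskRole, VolumetricImage, dilate_mask, mask_subtract
from .registration import (
    AtlasBundle,
    RegistrationConfig,
    TransformChain,
    register_pair,
    warp_mask,
)

__all__ = ["RegionSelectionParams", "build_search_region", "combine_region"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegionSelectionParams:
    """Spherical dilation radii (mm) for the warped atlas masks."""

    organ_dilation_mm: float = 4.0
    skeleton_dilation_mm: float = 6.0

    def __post_init__(self) -> None:
        if self.organ_dilation_mm < 0 or self.skeleton_dilation_mm < 0:
            raise ValueError("dilation radii must be >= 0")


def combine_region(
    skeleton: BinaryMask,
    organs: BinaryMask,
    params: RegionSelectionParams | None = None,
) -> BinaryMask:
    """dilate(skeleton, 6 mm) minus dilate(organs, 4 mm), both on one grid.

    Subtraction happens after both dilations so that organ removal is final:
    no organ voxel (nor its safety margin) can re-enter the region.
    """
    params = params or RegionSelectionParams()
    skel = dilate_mask(skeleton, params.skeleton_dilation_mm)
    org = dilate_mask(organs, params.organ_dilation_mm)
    region = mask_subtract(skel, org)
    return region.with_data(region.data, role=MaskRole.SEARCH_REGION)


def build_search_region(
    patient_dwi: VolumetricImage,
    atlas: AtlasBundle,
    cfg: RegistrationConfig | None = None,
    params: RegionSelectionParams | None = None,
    chain: TransformChain | None = None,
) -> tuple[BinaryMask, TransformChain]:
    """Construct the patient's lesion search region on the patient grid.

    Registers the atlas template onto the patient's high-b DWI (unless a
    precomputed ``chain`` is supplied), propagates both atlas masks, and
    combines them.  Raises if the resulting region is empty, which almost
    always indicates a failed registration.
    """
    params = params or RegionSelectionParams()
    if chain is None:
        chain = register_pair(patient_dwi, atlas.template, cfg)
    skeleton = warp_mask(atlas.skeleton_mask, chain, patient_dwi)
    organs = warp_mask(atlas.organ_mask, chain, patient_dwi)
    region = combine_region(skeleton, organs, params)
    logger.info(
        "search region: %d voxels (skeleton %d, organs %d after warp)",
        region.voxel_count,
        skeleton.voxel_count,
        organs.voxel_count,
    )
    if region.voxel_count == 0:
        raise RuntimeError("search region empty — check registration")
    return region, chain
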