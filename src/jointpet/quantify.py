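"""Global SUVmean extraction per joint and side.

The global SUVmean is the unweighted arithmetic mean of the SUV over all
voxels of the final bone mask.  :func:`quantify_joint` composes the whole
per-joint pipeline: ROI construction → HU thresholding (optionally seeded
region growing) → morphological closing → PET resampling onto the CT grid
→ SUV conversion → mean extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from jointpet.image_io import (
    InjectionMeta,
    SUVVolume,
    Volume,
    activity_to_suv,
    resample_to_grid,
)
from jointpet.roi import LandmarkSet, build_roi
from jointpet.segmentation import (
    DEFAULT_CLOSING_RADIUS,
    DEFAULT_LOWER_HU,
    DEFAULT_UPPER_HU,
    Mask,
    morphological_close,
    region_grow,
    threshold_bone,
)

__all__ = [
    "JointUptakeResult",
    "PipelineStageError",
    "global_suv_mean",
    "quantify_joint",
    "average_sides",
]


class PipelineStageError(RuntimeError):
    """An error raised by one stage of the quantification pipeline."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class JointUptakeResult:
    """Global SUVmean of one joint/side for one tracer, with provenance."""

    subject: str
    joint: str
    side: str
    tracer: str
    suv_mean: float
    voxel_count: int
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.voxel_count <= 0:
            raise ValueError("voxel_count must be positive")
        if self.suv_mean < 0:
            raise ValueError("suv_mean must be non-negative")


def global_suv_mean(
    suv: SUVVolume,
    mask: Mask,
    subject: str = "",
    joint: str = "",
    side: str = "",
) -> JointUptakeResult:
    """Unweighted mean SUV over the nonzero voxels of ``mask``.

    The SUV volume and the mask must share a grid shape; an empty mask is an
    error (no voxels segmented).
    """
    if suv.values.shape != mask.values.shape:
        raise ValueError(
            f"grid mismatch: SUV {suv.values.shape} vs mask {mask.values.shape}"
        )
    n = mask.voxel_count
    if n == 0:
        raise ValueError("no voxels segmented: empty mask")
    mean = float(suv.values[mask.values].mean())
    return JointUptakeResult(
        subject=subject,
        joint=joint,
        side=side,
        tracer=getattr(suv, "tracer", "unknown"),
        suv_mean=mean,
        voxel_count=n,
        provenance=dict(mask.provenance),
    )


def quantify_joint(
    ct: Volume,
    pet: Volume,
    meta: InjectionMeta,
    landmarks: LandmarkSet,
    joint: str,
    side: str,
    subject: str = "",
    lower_hu: float = DEFAULT_LOWER_HU,
    upper_hu: float = DEFAULT_UPPER_HU,
    closing_radius: int = DEFAULT_CLOSING_RADIUS,
    closing_mode: str = "slice2d",
    seeded_growing: bool = False,
    seed_hu: float = 300.0,
    connectivity: int = 26,
    roi_kwargs: dict | None = None,
) -> JointUptakeResult:
    """Run the full per-joint quantification pipeline.

    With ``seeded_growing`` the thresholded set inside the box is restricted
    to connected components containing voxels at or above ``seed_hu``
    (default 300 HU, confident cortical bone); otherwise plain thresholding
    is used.  Deterministic for fixed inputs and configuration.
    """
    try:
        box = build_roi(landmarks, ct, joint, side, **(roi_kwargs or {}))
    except Exception as e:  # noqa: BLE001 - tagged and re-raised
        raise PipelineStageError("roi", str(e)) from e
    try:
        if seeded_growing:
            thresholded = threshold_bone(ct, box, lower_hu, upper_hu)
            seed_idx = np.argwhere(thresholded.values & (ct.values >= seed_hu))
            if len(seed_idx) == 0:
                raise ValueError(f"no seed voxels at or above {seed_hu} HU inside the box")
            mask = region_grow(
                ct, seed_idx, lower_hu, upper_hu, connectivity=connectivity, box=box
            )
        else:
            mask = threshold_bone(ct, box, lower_hu, upper_hu)
        mask = morphological_close(mask, closing_radius, mode=closing_mode)
    except PipelineStageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("segmentation", str(e)) from e
    try:
        pet_on_ct = resample_to_grid(pet, ct)
        suv = activity_to_suv(pet_on_ct, meta)
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("suv", str(e)) from e
    try:
        return global_suv_mean(suv, mask, subject=subject, joint=joint, side=side)
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("quantify", str(e)) from e


def average_sides(left: JointUptakeResult, right: JointUptakeResult) -> float:
    """Subject-level uptake: the unweighted mean of left and right SUVmean."""
    for attr in ("subject", "joint", "tracer"):
        if getattr(left, attr) != getattr(right, attr):
            raise ValueError(
                f"cannot average sides with mismatched {attr}: "
                f"{getattr(left, attr)!r} vs {getattr(right, attr)!r}"
            )
    return 0.5 * (left.suv_mean + right.suv_mean)
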