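"""Bone segmentation: HU thresholding, region growing, morphological closing.

Bone is extracted inside an anatomical :class:`~jointpet.roi.RegionBox` by
keeping voxels in a Hounsfield band (default 150–1500 HU, inclusive),
optionally restricted to the connected components reachable from seed
voxels.  Morphological closing (dilation then erosion) with a disk
structuring element — by default a radius-20 disk applied per axial slice,
mirroring slice-based workstation behaviour — then fills the subcortical
cavity enclosed by the cortical shell, producing the final ROI mask.

Closing is implemented through exact Euclidean distance transforms, which
is equivalent to dilation/erosion with the Euclidean disk/ball structuring
element (an offset belongs to the element iff its norm is ≤ the radius)
while scaling to large radii.  The structuring element is clipped at the
volume border (background padding, no wraparound).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from jointpet.image_io import Volume
from jointpet.roi import RegionBox

__all__ = ["Mask", "threshold_bone", "region_grow", "morphological_close"]

DEFAULT_LOWER_HU = 150.0
DEFAULT_UPPER_HU = 1500.0
DEFAULT_CLOSING_RADIUS = 20


@dataclass(eq=False)
class Mask:
    """A binary voxel set on the CT grid with segmentation provenance.

    ``provenance`` records the thresholds, closing radius, connectivity and
    region box that produced the mask, so every downstream SUVmean is
    auditable.
    """

    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("mask must be a 3D array")

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    def __eq__(self, other) -> bool:
        return isinstance(other, Mask) and np.array_equal(self.values, other.values)


def _connectivity_structure(connectivity: int) -> np.ndarray:
    table = {6: 1, 18: 2, 26: 3}
    if connectivity not in table:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    return ndimage.generate_binary_structure(3, table[connectivity])


def threshold_bone(
    ct: Volume,
    box: RegionBox,
    lower: float = DEFAULT_LOWER_HU,
    upper: float = DEFAULT_UPPER_HU,
) -> Mask:
    """Voxels inside ``box`` whose HU lies in the closed band [lower, upper]."""
    if lower >= upper:
        raise ValueError(f"lower threshold {lower} must be below upper {upper}")
    m = np.zeros(ct.shape, dtype=bool)
    sub = ct.values[box.slices]
    m[box.slices] = (sub >= lower) & (sub <= upper)
    return Mask(
        m,
        provenance={
            "method": "threshold",
            "lower_hu": float(lower),
            "upper_hu": float(upper),
            "box": box.to_dict(),
        },
    )


def region_grow(
    ct: Volume,
    seeds,
    lower: float = DEFAULT_LOWER_HU,
    upper: float = DEFAULT_UPPER_HU,
    connectivity: int = 26,
    box: RegionBox | None = None,
) -> Mask:
    """Connected components of the HU-thresholded set that contain the seeds.

    Each seed voxel index must lie inside the volume and its HU must fall in
    ``[lower, upper]``; growing uses the given connectivity (default 26).
    When ``box`` is given, thresholding and growing are confined to it.
    """
    if lower >= upper:
        raise ValueError(f"lower threshold {lower} must be below upper {upper}")
    if box is not None:
        thresholded = threshold_bone(ct, box, lower, upper).values
    else:
        thresholded = (ct.values >= lower) & (ct.values <= upper)
    seeds = [tuple(int(c) for c in s) for s in seeds]
    if not seeds:
        raise ValueError("at least one seed voxel is required")
    for s in seeds:
        if any(c < 0 or c >= n for c, n in zip(s, ct.shape)):
            raise ValueError(f"seed {s} lies outside the volume {ct.shape}")
        hu = ct.values[s]
        if not (lower <= hu <= upper):
            raise ValueError(f"seed {s} has HU {hu:g} outside [{lower:g}, {upper:g}]")
        if not thresholded[s]:
            raise ValueError(f"seed {s} lies outside the region box")
    structure = _connectivity_structure(connectivity)
    labels, _ = ndimage.label(thresholded, structure=structure)
    keep = {labels[s] for s in seeds}
    grown = np.isin(labels, sorted(keep)) & thresholded
    prov = {
        "method": "region_grow",
        "lower_hu": float(lower),
        "upper_hu": float(upper),
        "connectivity": connectivity,
        "seeds": [list(s) for s in seeds],
    }
    if box is not None:
        prov["box"] = box.to_dict()
    return Mask(grown, provenance=prov)


def _dilate_edt(m: np.ndarray, radius: float) -> np.ndarray:
    if not m.any():
        return m.copy()
    return ndimage.distance_transform_edt(~m) <= radius


def _erode_edt(m: np.ndarray, radius: float) -> np.ndarray:
    if not m.any():
        return m.copy()
    return ndimage.distance_transform_edt(m) > radius


def _close_padded(m: np.ndarray, radius: int) -> np.ndarray:
    # pad by radius+1 so the border policy is plain background padding
    pad = radius + 1
    p = np.pad(m, pad, mode="constant", constant_values=False)
    closed = _erode_edt(_dilate_edt(p, radius), radius)
    sl = tuple(slice(pad, pad + n) for n in m.shape)
    return closed[sl]


def morphological_close(
    mask: Mask, radius: int = DEFAULT_CLOSING_RADIUS, mode: str = "slice2d"
) -> Mask:
    """Binary closing with a disk structuring element of ``radius`` voxels.

    ``mode="slice2d"`` (default) closes each axial (constant-z) slice with a
    2D disk; ``mode="ball3d"`` uses a 3D ball.  Radius 0 is the identity.
    If the input mask carries a region box in its provenance, the output is
    clipped back to that box.
    """
    if radius < 0:
        raise ValueError(f"closing radius must be non-negative, got {radius}")
    if mode not in ("slice2d", "ball3d"):
        raise ValueError(f"mode must be 'slice2d' or 'ball3d', got {mode!r}")
    box = mask.provenance.get("box")
    # When the mask is confined to a region box, closing the box subvolume
    # and clipping back is identical to closing the full volume and
    # clipping, because no foreground exists outside the box.
    if box is not None:
        sl = tuple(slice(lo, hi) for lo, hi in box["index_bounds"])
        src = mask.values[sl]
    else:
        sl = tuple(slice(0, n) for n in mask.values.shape)
        src = mask.values
    if radius == 0:
        closed = src.copy()
    elif mode == "ball3d":
        closed = _close_padded(src, radius)
    else:
        closed = np.empty_like(src)
        for k in range(src.shape[2]):
            closed[:, :, k] = _close_padded(src[:, :, k], radius)
    out = np.zeros_like(mask.values)
    out[sl] = closed
    prov = dict(mask.provenance)
    prov.update({"closing_radius": radius, "closing_mode": mode})
    return Mask(out, provenance=prov)
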