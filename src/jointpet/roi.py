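"""Anatomical rectangular regions for knee, hip, and SI joints.

Each region is derived from manually placed landmarks (mm world
coordinates) following fixed boundary rules:

* **knee** — an axial slab from 4 cm superior to 4 cm inferior of the
  intercondylar eminence; in-plane the box spans that side's half of the
  field of view, split at the midsagittal plane.
* **hip** — a box around the femoral head and acetabulum, excluding the
  femoral neck: lateral border at the femoral head–neck junction plane,
  medial border 2 mm lateral to the pelvic brim, superior/inferior borders
  1 cm beyond the superior/inferior edge of the femoral neck.
* **SI** — a box extending 2 cm laterally and 2 cm medially of the
  sacrum–ilium articulation line, vertically spanning the superior and
  inferior ends of the articulation.

Boxes carry both the mm bounds they were derived from and the half-open
voxel-index bounds on the CT grid; a voxel belongs to the box when its
center lies inside the (closed) mm box.  Boxes are clipped to the volume
extent and the clipping is recorded.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from jointpet.image_io import Volume

__all__ = [
    "KneeLandmarks",
    "HipLandmarks",
    "SILandmarks",
    "LandmarkSet",
    "RegionBox",
    "mm_box_to_index_bounds",
    "knee_roi",
    "hip_roi",
    "si_roi",
]

JOINTS = ("knee", "hip", "si")
SIDES = ("left", "right")

_EPS = 1e-9


@dataclass(frozen=True)
class KneeLandmarks:
    """Knee landmarks for one side: the intercondylar eminence (mm point)."""

    intercondylar_eminence: tuple[float, float, float]


@dataclass(frozen=True)
class HipLandmarks:
    """Hip landmarks for one side.

    ``head_neck_junction_x`` — sagittal (x) mm coordinate of the plane
    separating the femoral head from the neck (the lateral border).
    ``pelvic_brim_x`` — sagittal mm coordinate of the pelvic brim; the
    medial border sits 2 mm lateral of it.
    ``neck_edge_z`` — (inferior, superior) mm extent of the femoral-neck
    edge; the box extends 10 mm beyond each.
    """

    head_neck_junction_x: float
    pelvic_brim_x: float
    neck_edge_z: tuple[float, float]


@dataclass(frozen=True)
class SILandmarks:
    """SI-joint landmarks for one side.

    ``articulation_x`` — sagittal mm coordinate of the sacrum–ilium
    articulation line; ``articulation_z`` — its (inferior, superior) mm
    extent.
    """

    articulation_x: float
    articulation_z: tuple[float, float]


@dataclass
class LandmarkSet:
    """Per-subject landmarks keyed by joint and side, all in mm world space."""

    knee: dict[str, KneeLandmarks] = field(default_factory=dict)
    hip: dict[str, HipLandmarks] = field(default_factory=dict)
    si: dict[str, SILandmarks] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        doc: dict = {"knee": {}, "hip": {}, "si": {}}
        for side, lm in self.knee.items():
            doc["knee"][side] = {"intercondylar_eminence": list(lm.intercondylar_eminence)}
        for side, lm in self.hip.items():
            doc["hip"][side] = {
                "head_neck_junction_x": lm.head_neck_junction_x,
                "pelvic_brim_x": lm.pelvic_brim_x,
                "neck_edge_z": list(lm.neck_edge_z),
            }
        for side, lm in self.si.items():
            doc["si"][side] = {
                "articulation_x": lm.articulation_x,
                "articulation_z": list(lm.articulation_z),
            }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "LandmarkSet":
        doc = json.loads(Path(path).read_text())
        ls = cls()
        for side, d in doc.get("knee", {}).items():
            ls.knee[side] = KneeLandmarks(tuple(d["intercondylar_eminence"]))
        for side, d in doc.get("hip", {}).items():
            ls.hip[side] = HipLandmarks(
                float(d["head_neck_junction_x"]),
                float(d["pelvic_brim_x"]),
                tuple(d["neck_edge_z"]),
            )
        for side, d in doc.get("si", {}).items():
            ls.si[side] = SILandmarks(
                float(d["articulation_x"]), tuple(d["articulation_z"])
            )
        return ls


@dataclass(frozen=True)
class RegionBox:
    """An axis-aligned rectangular ROI on the CT grid.

    ``mm_bounds`` are the closed per-axis mm intervals the box was derived
    from; ``index_bounds`` the half-open ``[lo, hi)`` voxel-index intervals
    after clipping to the volume.  ``clipped`` records whether clipping
    truncated the mm box.
    """

    joint: str
    side: str
    mm_bounds: tuple[tuple[float, float], ...]
    index_bounds: tuple[tuple[int, int], ...]
    clipped: bool = False

    def __post_init__(self) -> None:
        for lo, hi in self.index_bounds:
            if hi <= lo:
                raise ValueError(f"empty region box on some axis: {self.index_bounds}")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in self.index_bounds)  # type: ignore[return-value]

    def contains_mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Boolean array of the given shape, true inside the box."""
        m = np.zeros(shape, dtype=bool)
        m[self.slices] = True
        return m

    def to_dict(self) -> dict:
        return {
            "joint": self.joint,
            "side": self.side,
            "mm_bounds": [list(b) for b in self.mm_bounds],
            "index_bounds": [list(b) for b in self.index_bounds],
            "clipped": self.clipped,
        }


def mm_box_to_index_bounds(
    mm_bounds, vol: Volume
) -> tuple[tuple[tuple[int, int], ...], bool]:
    """Convert closed mm intervals to half-open voxel-index intervals.

    A voxel is included when its center lies inside the closed mm interval
    on every axis; the result is clipped to the volume extent.  Returns the
    index bounds and a flag marking whether any clipping occurred.
    """
    out = []
    clipped = False
    for ax, (mm_lo, mm_hi) in enumerate(mm_bounds):
        if mm_hi < mm_lo:
            raise ValueError(f"inverted mm bounds on axis {ax}: ({mm_lo}, {mm_hi})")
        o, s, n = vol.origin[ax], vol.spacing[ax], vol.shape[ax]
        lo = math.ceil((mm_lo - o) / s - _EPS)
        hi = math.floor((mm_hi - o) / s + _EPS) + 1
        if lo < 0:
            lo, clipped = 0, True
        if hi > n:
            hi, clipped = n, True
        if hi <= lo:
            raise ValueError(
                f"region box lies outside the volume on axis {ax} "
                f"(mm [{mm_lo}, {mm_hi}], volume extent {vol.world_bounds()[ax]})"
            )
        out.append((lo, hi))
    return tuple(out), clipped


def _require(landmarks: dict, side: str, joint: str):
    if side not in landmarks:
        raise KeyError(f"missing {joint} landmarks for side {side!r}")
    return landmarks[side]


def _full_extent(vol: Volume, ax: int) -> tuple[float, float]:
    b = vol.world_bounds()[ax]
    return float(b[0]), float(b[1])


def knee_roi(
    landmarks: LandmarkSet,
    ct: Volume,
    side: str,
    slab_mm: float = 40.0,
    midsagittal_x: float | None = None,
) -> RegionBox:
    """Knee ROI: axial slab of ``±slab_mm`` (default ±40 mm) around the
    intercondylar eminence; in-plane the box spans the side's lateral half
    of the field of view, split at ``midsagittal_x`` (defaults to the
    volume's x-center).
    """
    lm = _require(landmarks.knee, side, "knee")
    ex, _, ez = lm.intercondylar_eminence
    xb = ct.world_bounds()[0]
    if midsagittal_x is None:
        midsagittal_x = float(xb.mean())
    if ex >= midsagittal_x:
        x_mm = (midsagittal_x, float(xb[1]))
    else:
        x_mm = (float(xb[0]), midsagittal_x)
    mm = (x_mm, _full_extent(ct, 1), (ez - slab_mm, ez + slab_mm))
    idx, clipped = mm_box_to_index_bounds(mm, ct)
    return RegionBox("knee", side, mm, idx, clipped)


def hip_roi(
    landmarks: LandmarkSet,
    ct: Volume,
    side: str,
    brim_margin_mm: float = 2.0,
    neck_margin_mm: float = 10.0,
    ap_bounds_mm: tuple[float, float] | None = None,
) -> RegionBox:
    """Hip ROI around the femoral head and acetabulum, excluding the neck.

    The lateral border is the femoral head–neck junction plane and the
    medial border sits ``brim_margin_mm`` (default 2 mm) lateral to the
    pelvic brim; the lateral direction is inferred from the junction lying
    lateral of the brim.  Vertically the box extends ``neck_margin_mm``
    (default 10 mm) beyond the femoral-neck edge.  The AP extent defaults
    to the full field of view.
    """
    lm = _require(landmarks.hip, side, "hip")
    jx, bx = lm.head_neck_junction_x, lm.pelvic_brim_x
    if jx == bx:
        raise ValueError("head–neck junction and pelvic brim coincide; zero-width hip box")
    lateral_sign = 1.0 if jx > bx else -1.0  # unit step from brim toward junction
    medial_x = bx + lateral_sign * brim_margin_mm
    # the medial border must stay on the brim's side of the junction plane
    if (medial_x - jx) * (bx - jx) <= 0:
        raise ValueError("medial border lies lateral to the lateral border; empty hip box")
    x_lo, x_hi = sorted((jx, medial_x))
    z_lo, z_hi = sorted(lm.neck_edge_z)
    mm = (
        (x_lo, x_hi),
        ap_bounds_mm if ap_bounds_mm is not None else _full_extent(ct, 1),
        (z_lo - neck_margin_mm, z_hi + neck_margin_mm),
    )
    idx, clipped = mm_box_to_index_bounds(mm, ct)
    return RegionBox("hip", side, mm, idx, clipped)


def si_roi(
    landmarks: LandmarkSet,
    ct: Volume,
    side: str,
    lateral_mm: float = 20.0,
    ap_bounds_mm: tuple[float, float] | None = None,
) -> RegionBox:
    """SI-joint ROI: ``±lateral_mm`` (default ±20 mm) about the
    sacrum–ilium articulation line, vertically spanning the articulation's
    superior and inferior ends.
    """
    lm = _require(landmarks.si, side, "SI")
    z_lo, z_hi = sorted(lm.articulation_z)
    if z_hi <= z_lo:
        raise ValueError("SI articulation has zero vertical extent")
    mm = (
        (lm.articulation_x - lateral_mm, lm.articulation_x + lateral_mm),
        ap_bounds_mm if ap_bounds_mm is not None else _full_extent(ct, 1),
        (z_lo, z_hi),
    )
    idx, clipped = mm_box_to_index_bounds(mm, ct)
    return RegionBox("si", side, mm, idx, clipped)


def build_roi(landmarks: LandmarkSet, ct: Volume, joint: str, side: str, **kw) -> RegionBox:
    """Dispatch to the joint-specific ROI builder."""
    if joint == "knee":
        return knee_roi(landmarks, ct, side, **kw)
    if joint == "hip":
        return hip_roi(landmarks, ct, side, **kw)
    if joint == "si":
        return si_roi(landmarks, ct, side, **kw)
    raise ValueError(f"unknown joint {joint!r}; expected one of {JOINTS}")
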