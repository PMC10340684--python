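"""Volume I/O, PET→CT resampling, and body-weight SUV conversion.

Geometry convention
-------------------
Volumes are axis-aligned scalar grids.  Array axes are ``(x, y, z)`` with

* ``x`` — left–right (sagittal direction; the midsagittal plane is a
  constant-``x`` plane),
* ``y`` — anterior–posterior,
* ``z`` — inferior–superior (axial slices are constant ``z``).

The world coordinate (mm) of voxel ``(i, j, k)`` is
``origin + (i, j, k) * spacing``.  Voxel indices are 0-based; boxes are
half-open ``[lo, hi)`` in index space.  NIfTI files are written with a
diagonal affine encoding exactly this mapping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "SUVVolume",
    "InjectionMeta",
    "F18_HALF_LIFE_MIN",
    "MBQ_PER_MCI",
    "read_volume",
    "write_volume",
    "read_mask_array",
    "write_mask_array",
    "resample_to_grid",
    "activity_to_suv",
]

#: Physical half-life of fluorine-18, minutes.
F18_HALF_LIFE_MIN = 109.77

#: 1 mCi = 37 MBq exactly.
MBQ_PER_MCI = 37.0


@dataclass(frozen=True, eq=False)
class Volume:
    """A 3D scalar grid with voxel spacing and world origin.

    ``values`` holds HU for CT, Bq/mL for PET, and dimensionless numbers for
    SUV volumes.  All three spacing components must be positive and the data
    must be finite.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axes: str = "xyz"
    modality: str = "unknown"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 3:
            raise ValueError(f"expected 3D volume, got {vals.ndim}D shape {vals.shape}")
        if min(vals.shape) < 1:
            raise ValueError(f"volume has an empty dimension: {vals.shape}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive components, got {self.spacing}")
        if not np.all(np.isfinite(vals)):
            raise ValueError("volume contains NaN or Inf values")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def world_bounds(self) -> np.ndarray:
        """Per-axis ``[lo, hi]`` mm coordinates of the first/last voxel centers."""
        lo = np.asarray(self.origin)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return np.stack([lo, hi], axis=1)

    def index_to_world(self, index) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(index) * np.asarray(self.spacing)

    def world_to_index(self, world) -> np.ndarray:
        """Continuous (fractional) voxel index of a world mm coordinate."""
        return (np.asarray(world) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def same_grid(self, other: "Volume", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass(frozen=True, eq=False)
class SUVVolume(Volume):
    """A :class:`Volume` whose values are body-weight SUV (dimensionless)."""

    tracer: str = "FDG"

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.values < 0):
            raise ValueError("SUV values must be non-negative")


@dataclass(frozen=True)
class InjectionMeta:
    """Injected dose, timing, and body weight needed for SUV normalization.

    The dose is stored canonically in MBq; use ``dose_unit="mCi"`` to pass
    doses in millicuries (1 mCi = 37 MBq).  Timestamps are ISO-8601 strings
    or :class:`datetime.datetime`.
    """

    injected_dose: float
    injection_time: str | datetime
    acquisition_time: str | datetime
    body_weight_kg: float
    tracer: str = "FDG"
    dose_unit: str = "MBq"
    half_life_min: float = F18_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        object.__setattr__(self, "injection_time", self._as_dt(self.injection_time))
        object.__setattr__(self, "acquisition_time", self._as_dt(self.acquisition_time))
        if self.dose_unit not in ("MBq", "mCi"):
            raise ValueError(f"dose_unit must be 'MBq' or 'mCi', got {self.dose_unit!r}")
        if self.injected_dose <= 0:
            raise ValueError("injected dose must be positive")
        if self.body_weight_kg <= 0:
            raise ValueError("body weight must be positive")
        if self.half_life_min <= 0:
            raise ValueError("half-life must be positive")
        if self.tracer not in ("FDG", "NaF"):
            raise ValueError(f"tracer must be 'FDG' or 'NaF', got {self.tracer!r}")
        if self.uptake_minutes < 0:
            raise ValueError("acquisition time precedes injection time")

    @staticmethod
    def _as_dt(t: str | datetime) -> datetime:
        return t if isinstance(t, datetime) else datetime.fromisoformat(t)

    @property
    def dose_mbq(self) -> float:
        if self.dose_unit == "mCi":
            return self.injected_dose * MBQ_PER_MCI
        return self.injected_dose

    @property
    def uptake_minutes(self) -> float:
        delta = self._as_dt(self.acquisition_time) - self._as_dt(self.injection_time)
        return delta.total_seconds() / 60.0

    def decayed_dose_mbq(self) -> float:
        """Injected dose decay-corrected to the acquisition time."""
        return self.dose_mbq * 2.0 ** (-self.uptake_minutes / self.half_life_min)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "injected_dose": self.injected_dose,
            "dose_unit": self.dose_unit,
            "injection_time": self._as_dt(self.injection_time).isoformat(),
            "acquisition_time": self._as_dt(self.acquisition_time).isoformat(),
            "body_weight_kg": self.body_weight_kg,
            "tracer": self.tracer,
            "half_life_min": self.half_life_min,
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "InjectionMeta":
        doc = json.loads(Path(path).read_text())
        return cls(
            injected_dose=float(doc["injected_dose"]),
            dose_unit=doc.get("dose_unit", "MBq"),
            injection_time=doc["injection_time"],
            acquisition_time=doc["acquisition_time"],
            body_weight_kg=float(doc["body_weight_kg"]),
            tracer=doc.get("tracer", "FDG"),
            half_life_min=float(doc.get("half_life_min", F18_HALF_LIFE_MIN)),
        )


def _affine(vol: Volume) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = vol.spacing
    aff[:3, 3] = vol.origin
    return aff


def write_volume(vol: Volume, path: str | Path) -> None:
    """Write a volume as NIfTI with a diagonal affine (spacing + origin)."""
    img = nib.Nifti1Image(vol.values.astype(np.float32), _affine(vol))
    nib.save(img, str(path))


def read_volume(path: str | Path, modality: str = "unknown") -> Volume:
    """Read a 3D NIfTI volume.

    Parameters
    ----------
    path : readable ``.nii``/``.nii.gz`` file.
    modality : ``"CT"`` (values interpreted as HU) or ``"PET"`` (Bq/mL);
        recorded on the returned volume, not rescaled.

    Raises
    ------
    FileNotFoundError, ValueError
        For a missing file, a non-3D image, or non-positive spacing.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such volume file: {p}")
    img = nib.load(str(p))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"non-positive voxel spacing in header: {zooms}")
    # axis-aligned grids only: the rotation part must be diag(spacing)
    rot = np.asarray(img.affine[:3, :3], dtype=float)
    if not np.allclose(rot, np.diag(zooms), atol=1e-4):
        raise ValueError(
            "volume affine is not a positive diagonal (rotated/sheared or "
            "flipped acquisition); reslice to an axis-aligned grid first"
        )
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return Volume(
        values=np.asarray(data, dtype=np.float64),
        spacing=tuple(float(z) for z in zooms),
        origin=origin,
        modality=modality,
    )


def write_mask_array(mask: np.ndarray, like: Volume, path: str | Path) -> None:
    """Write a binary array (on ``like``'s grid) as a uint8 0/1 NIfTI."""
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(like))
    nib.save(img, str(path))


def read_mask_array(path: str | Path) -> np.ndarray:
    vol = read_volume(path, modality="mask")
    return vol.values > 0.5


def resample_to_grid(moving: Volume, reference: Volume) -> Volume:
    """Resample ``moving`` onto ``reference``'s grid by trilinear interpolation.

    Interpolation is performed in world (mm) coordinates; reference voxels
    whose centers fall outside the moving volume's support are filled with 0.
    The two volumes must overlap in world space on every axis.
    """
    mb, rb = moving.world_bounds(), reference.world_bounds()
    for ax in range(3):
        if mb[ax, 1] < rb[ax, 0] or rb[ax, 1] < mb[ax, 0]:
            raise ValueError(
                f"moving and reference volumes are disjoint in world space on axis {ax}"
            )
    idx = [np.arange(n) for n in reference.shape]
    grids = np.meshgrid(*idx, indexing="ij")
    coords = np.empty((3,) + reference.shape, dtype=np.float64)
    for ax in range(3):
        world = reference.origin[ax] + grids[ax] * reference.spacing[ax]
        coords[ax] = (world - moving.origin[ax]) / moving.spacing[ax]
    out = ndimage.map_coordinates(
        moving.values, coords, order=1, mode="constant", cval=0.0
    )
    return Volume(
        values=out,
        spacing=reference.spacing,
        origin=reference.origin,
        modality=moving.modality,
    )


def activity_to_suv(
    pet: Volume,
    meta: InjectionMeta,
    decay_correct: bool = True,
    clip_negative: bool = True,
) -> SUVVolume:
    """Convert a PET activity-concentration volume (Bq/mL) to body-weight SUV.

    SUV = C / (D / W) with C the activity concentration in Bq/mL, D the
    injected dose in Bq — decay-corrected to the acquisition time when
    ``decay_correct`` is true (``D · 2^(−Δt/T½)``) — and W the body weight in
    grams, so that a uniform whole-body distribution gives SUV ≈ 1.
    """
    dose_mbq = meta.decayed_dose_mbq() if decay_correct else meta.dose_mbq
    dose_bq = dose_mbq * 1e6
    weight_g = meta.body_weight_kg * 1000.0
    vals = pet.values * (weight_g / dose_bq)
    if clip_negative:
        vals = np.clip(vals, 0.0, None)
    elif np.any(vals < 0):
        raise ValueError("negative activity values; pass clip_negative=True to zero them")
    return SUVVolume(
        values=vals,
        spacing=pet.spacing,
        origin=pet.origin,
        modality="SUV",
        tracer=meta.tracer,
    )
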