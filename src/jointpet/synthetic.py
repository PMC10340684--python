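"""Synthetic digital phantoms and clinical cohorts with known ground truth.

Two generators make every pipeline stage testable without any patient data:

* :func:`make_joint_phantom` — paired CT/PET volumes containing
  geometric bone at knee / hip / SI locations (cortical shell around a
  marrow cavity, built from spheres, tubes, and hollow boxes), landmarks
  placed at the true geometric features, injection metadata, and exact
  ground-truth masks.  HU classes are chosen so that the 150–1500 HU
  threshold rule reproduces the cortical shell exactly by construction,
  and the marrow cavity sits below 150 HU so that morphological closing
  demonstrably captures the subcortical interior.  PET activity is painted
  over the bone region dilated by a small margin (uptake extending into
  immediately adjacent tissue), so trilinear resampling inside the bone
  mask stays in the uniform-activity region and the designed SUV is
  recoverable.

* :func:`make_cohort` — a subject-level covariate table drawn from a
  Gaussian copula: a latent multivariate normal with a designed
  correlation matrix is mapped through per-variable truncated-normal
  quantile functions calibrated to published-range medians/IQRs.  Body
  weight is derived from BMI and height so the table is internally
  consistent; missing values are introduced completely at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from jointpet.image_io import (
    F18_HALF_LIFE_MIN,
    MBQ_PER_MCI,
    InjectionMeta,
    Volume,
    write_mask_array,
    write_volume,
)
from jointpet.roi import HipLandmarks, KneeLandmarks, LandmarkSet, SILandmarks

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "JointPhantom",
    "CohortSpec",
    "make_joint_phantom",
    "make_cohort",
    "write_phantom",
    "correlation_matrix",
    "DEFAULT_MARGINALS",
    "DEFAULT_CORRELATIONS",
    "TRACER_DOSE_MCI_PER_KG",
    "TRACER_UPTAKE_MIN",
]

#: Injected activity per body weight (mCi/kg) and uptake time (min) per tracer.
TRACER_DOSE_MCI_PER_KG = {"FDG": 0.11, "NaF": 0.08}
TRACER_UPTAKE_MIN = {"FDG": 180.0, "NaF": 90.0}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one digital joint phantom (both sides in one volume).

    HU classes default to cortical bone 1000, marrow 100, soft tissue 40,
    air −1000; noise is clipped so no class crosses the 150/1500 HU
    thresholds, keeping the threshold rule exact.  ``bone_suv`` and
    ``background_suv`` are the designed SUVs of the bone region (cortex +
    marrow) and surrounding tissue.
    """

    joint: str = "knee"
    tracer: str = "NaF"
    shape: tuple[int, int, int] = (128, 128, 160)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    cortical_hu: float = 1000.0
    marrow_hu: float = 100.0
    soft_tissue_hu: float = 40.0
    ct_noise_sd: float = 15.0
    bone_suv: float = 1.587
    background_suv: float = 0.4
    pet_spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    pet_noise_frac: float = 0.02
    activity_margin_mm: float = 4.0
    body_weight_kg: float = 77.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.joint not in ("knee", "hip", "si"):
            raise ValueError(f"unknown joint {self.joint!r}")
        if not 150.0 <= self.cortical_hu <= 1500.0:
            raise ValueError("cortical HU must lie within the 150–1500 HU bone band")
        if self.marrow_hu >= 150.0 or self.soft_tissue_hu >= 150.0:
            raise ValueError("marrow and soft-tissue HU must lie below 150 HU")
        if self.bone_suv < 0 or self.background_suv < 0:
            raise ValueError("designed SUVs must be non-negative")


@dataclass
class PhantomTruth:
    """Ground truth of a phantom.

    ``cortex_mask`` is exactly the set the 150–1500 HU threshold rule
    selects; ``joint_masks[side]`` is the designed final ROI per side
    (cortex plus enclosed marrow cavity); ``designed_suv_mean`` is the SUV
    painted over the bone region.
    """

    cortex_mask: np.ndarray
    joint_masks: dict[str, np.ndarray]
    designed_suv_mean: float


@dataclass
class JointPhantom:
    ct: Volume
    pet: Volume
    meta: InjectionMeta
    landmarks: LandmarkSet
    truth: PhantomTruth
    spec: PhantomSpec


def _mm_coords(shape, spacing, origin):
    x = origin[0] + np.arange(shape[0])[:, None, None] * spacing[0]
    y = origin[1] + np.arange(shape[1])[None, :, None] * spacing[1]
    z = origin[2] + np.arange(shape[2])[None, None, :] * spacing[2]
    return x, y, z


def _sphere(x, y, z, c, r):
    return (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2 <= r * r


def _tube_x(x, y, z, c, r, x_lo, x_hi):
    return ((y - c[1]) ** 2 + (z - c[2]) ** 2 <= r * r) & (x >= x_lo) & (x <= x_hi)


def _box(x, y, z, lo, hi):
    return (
        (x >= lo[0]) & (x <= hi[0])
        & (y >= lo[1]) & (y <= hi[1])
        & (z >= lo[2]) & (z <= hi[2])
    )


# geometric constants (mm) of the phantom families
_KNEE = dict(offset_x=60.0, z=80.0, radius=22.0, shell=6.0)
_HIP = dict(offset_x=64.0, z=200.0, radius=24.0, shell=6.0, neck_radius=10.0, neck_len=30.0)
_SI = dict(
    offset_x=41.0, z_lo=240.0, z_hi=300.0, half_x=18.0, half_y=20.0, wall=6.0
)


def _side_geometry(spec: PhantomSpec, side: str, coords, margin: float):
    """Outer and inner (cavity) membership for one side, dilated by ``margin``."""
    x, y, z = coords
    extent = np.asarray(spec.shape) * np.asarray(spec.spacing)
    mid = spec.origin[0] + (extent[0] - spec.spacing[0]) / 2.0
    y_c = spec.origin[1] + (extent[1] - spec.spacing[1]) / 2.0
    sign = 1.0 if side == "left" else -1.0
    if spec.joint == "knee":
        g = _KNEE
        c = (mid + sign * g["offset_x"], y_c, g["z"])
        outer = _sphere(x, y, z, c, g["radius"] + margin)
        inner = _sphere(x, y, z, c, g["radius"] - g["shell"]) if margin == 0 else None
        return outer, inner
    if spec.joint == "hip":
        g = _HIP
        c = (mid + sign * g["offset_x"], y_c, g["z"])
        junction_x = c[0] + sign * g["radius"]
        neck_lo = min(junction_x, junction_x + sign * g["neck_len"]) - margin
        neck_hi = max(junction_x, junction_x + sign * g["neck_len"]) + margin
        outer = _sphere(x, y, z, c, g["radius"] + margin) | _tube_x(
            x, y, z, c, g["neck_radius"] + margin, neck_lo, neck_hi
        )
        inner = _sphere(x, y, z, c, g["radius"] - g["shell"]) if margin == 0 else None
        return outer, inner
    g = _SI
    art_x = mid + sign * g["offset_x"]
    lo = (art_x - g["half_x"] - margin, y_c - g["half_y"] - margin, g["z_lo"] - margin)
    hi = (art_x + g["half_x"] + margin, y_c + g["half_y"] + margin, g["z_hi"] + margin)
    outer = _box(x, y, z, lo, hi)
    if margin == 0:
        w = g["wall"]
        inner = _box(
            x, y, z,
            (art_x - g["half_x"] + w, y_c - g["half_y"] + w, g["z_lo"] + w),
            (art_x + g["half_x"] - w, y_c + g["half_y"] - w, g["z_hi"] - w),
        )
    else:
        inner = None
    return outer, inner


def _landmarks_for(spec: PhantomSpec) -> LandmarkSet:
    extent = np.asarray(spec.shape) * np.asarray(spec.spacing)
    mid = spec.origin[0] + (extent[0] - spec.spacing[0]) / 2.0
    y_c = spec.origin[1] + (extent[1] - spec.spacing[1]) / 2.0
    ls = LandmarkSet()
    for side, sign in (("left", 1.0), ("right", -1.0)):
        if spec.joint == "knee":
            g = _KNEE
            ls.knee[side] = KneeLandmarks((mid + sign * g["offset_x"], y_c, g["z"]))
        elif spec.joint == "hip":
            g = _HIP
            cx = mid + sign * g["offset_x"]
            ls.hip[side] = HipLandmarks(
                head_neck_junction_x=cx + sign * g["radius"],
                pelvic_brim_x=cx - sign * (g["radius"] + 4.0),
                neck_edge_z=(g["z"] - 18.0, g["z"] + 18.0),
            )
        else:
            g = _SI
            ls.si[side] = SILandmarks(
                articulation_x=mid + sign * g["offset_x"],
                articulation_z=(g["z_lo"], g["z_hi"]),
            )
    return ls


def _injection_meta(spec: PhantomSpec) -> InjectionMeta:
    dose_mci = TRACER_DOSE_MCI_PER_KG[spec.tracer] * spec.body_weight_kg
    uptake = TRACER_UPTAKE_MIN[spec.tracer]
    t0 = "2023-01-01T08:00:00"
    t1 = f"2023-01-01T{8 + int(uptake) // 60:02d}:{int(uptake) % 60:02d}:00"
    return InjectionMeta(
        injected_dose=dose_mci * MBQ_PER_MCI,
        dose_unit="MBq",
        injection_time=t0,
        acquisition_time=t1,
        body_weight_kg=spec.body_weight_kg,
        tracer=spec.tracer,
        half_life_min=F18_HALF_LIFE_MIN,
    )


def make_joint_phantom(spec: PhantomSpec) -> JointPhantom:
    """Build a paired CT/PET phantom with ground truth. Deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    coords = _mm_coords(spec.shape, spec.spacing, spec.origin)

    cortex = np.zeros(spec.shape, dtype=bool)
    marrow = np.zeros(spec.shape, dtype=bool)
    joint_masks: dict[str, np.ndarray] = {}
    for side in ("left", "right"):
        outer, inner = _side_geometry(spec, side, coords, margin=0.0)
        cortex |= outer & ~inner
        marrow |= inner
        joint_masks[side] = outer  # cortex + enclosed cavity

    ct = np.full(spec.shape, spec.soft_tissue_hu)
    ct[marrow] = spec.marrow_hu
    ct[cortex] = spec.cortical_hu
    if spec.ct_noise_sd > 0:
        noise = rng.normal(0.0, spec.ct_noise_sd, spec.shape)
        ct = ct + noise
        # clip per class so no voxel crosses the 150/1500 HU thresholds
        soft = ~(cortex | marrow)
        ct[cortex] = np.clip(ct[cortex], 160.0, 1490.0)
        ct[marrow] = np.clip(ct[marrow], 0.0, 140.0)
        ct[soft] = np.clip(ct[soft], 0.0, 140.0)
    ct_vol = Volume(ct, spec.spacing, spec.origin, modality="CT")

    meta = _injection_meta(spec)
    # PET grid covering the CT extent
    ct_extent = np.asarray(spec.shape) * np.asarray(spec.spacing)
    pet_shape = tuple(
        int(np.ceil(e / s)) for e, s in zip(ct_extent, spec.pet_spacing)
    )
    pcoords = _mm_coords(pet_shape, spec.pet_spacing, spec.origin)
    activity_region = np.zeros(pet_shape, dtype=bool)
    for side in ("left", "right"):
        outer, _ = _side_geometry(spec, side, pcoords, margin=spec.activity_margin_mm)
        activity_region |= outer
    suv_map = np.where(activity_region, spec.bone_suv, spec.background_suv)
    # concentration (Bq/mL) that yields the designed SUV under the metadata
    bq_per_suv = meta.decayed_dose_mbq() * 1e6 / (spec.body_weight_kg * 1000.0)
    pet = suv_map * bq_per_suv
    if spec.pet_noise_frac > 0:
        pet = pet + rng.normal(0.0, spec.pet_noise_frac * spec.bone_suv * bq_per_suv, pet_shape)
        pet = np.clip(pet, 0.0, None)
    pet_vol = Volume(pet, spec.pet_spacing, spec.origin, modality="PET")

    truth = PhantomTruth(
        cortex_mask=cortex,
        joint_masks=joint_masks,
        designed_suv_mean=spec.bone_suv,
    )
    return JointPhantom(
        ct=ct_vol,
        pet=pet_vol,
        meta=meta,
        landmarks=_landmarks_for(spec),
        truth=truth,
        spec=spec,
    )


def write_phantom(phantom: JointPhantom, out_dir: str | Path, stem: str) -> dict[str, Path]:
    """Write a phantom's CT/PET/metadata/landmarks/truth masks to disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tracer = phantom.spec.tracer.lower()
    paths = {
        "ct": out / f"{stem}_ct.nii.gz",
        "pet": out / f"{stem}_{tracer}_pet.nii.gz",
        "meta": out / f"{stem}_{tracer}_meta.json",
        "landmarks": out / f"{stem}_landmarks.json",
        "truth": out / f"{stem}_truth_cortex.nii.gz",
    }
    write_volume(phantom.ct, paths["ct"])
    write_volume(phantom.pet, paths["pet"])
    phantom.meta.to_json(paths["meta"])
    phantom.landmarks.to_json(paths["landmarks"])
    write_mask_array(phantom.truth.cortex_mask, phantom.ct, paths["truth"])
    return paths


# ---------------------------------------------------------------------------
# synthetic cohorts
# ---------------------------------------------------------------------------

#: Marginal calibration per variable: (median, IQR, lower, upper).
#: Published-range values where available; serum leptin (ng/mL), sclerostin
#: (pg/mL) and DXA total fat (kg) use typical adult RA-cohort ranges.
DEFAULT_MARGINALS: dict[str, tuple[float, float, float, float]] = {
    "age": (60.5, 14.3, 25.0, 69.0),
    "height": (170.8, 18.8, 153.1, 188.7),
    "bmi": (28.5, 7.2, 18.7, 44.1),
    "leptin": (15.0, 18.0, 1.0, 60.0),
    "sclerostin": (550.0, 300.0, 100.0, 1500.0),
    "total_fat": (25.0, 12.0, 8.0, 60.0),
    "crp": (1.2, 1.0, 0.5, 3.1),
    "esr": (21.0, 32.0, 3.0, 66.0),
    "il1": (0.3, 0.1, 0.2, 0.9),
    "il6": (2.3, 2.3, 0.5, 8.7),
    "das28_crp": (4.1, 2.4, 1.6, 5.4),
    "vas_ptglobal": (46.5, 26.0, 4.0, 75.0),
    "fdg_knee": (0.402, 0.15, 0.15, 0.8),
    "naf_knee": (1.587, 0.6, 0.6, 3.2),
    "fdg_hip": (0.45, 0.15, 0.2, 0.9),
    "naf_hip": (2.0, 0.8, 0.8, 4.0),
    "fdg_si": (0.5, 0.18, 0.2, 1.0),
    "naf_si": (2.2, 0.9, 0.9, 4.5),
}

#: Designed latent correlations (variable, variable, rho).  The adiposity
#: block (BMI, leptin, total fat) drives uptake; FDG and NaF in the knee are
#: strongly coupled; patient global assessment is inversely related to hip
#: and SI FDG.
DEFAULT_CORRELATIONS: tuple[tuple[str, str, float], ...] = (
    ("bmi", "leptin", 0.60),
    ("bmi", "total_fat", 0.70),
    ("leptin", "total_fat", 0.60),
    ("bmi", "sclerostin", -0.30),
    ("leptin", "sclerostin", -0.25),
    ("crp", "esr", 0.50),
    ("crp", "das28_crp", 0.40),
    ("esr", "das28_crp", 0.30),
    ("das28_crp", "vas_ptglobal", 0.50),
    ("fdg_knee", "naf_knee", 0.77),
    ("bmi", "fdg_knee", 0.62),
    ("bmi", "naf_knee", 0.50),
    ("leptin", "naf_knee", 0.40),
    ("leptin", "fdg_knee", 0.45),
    ("total_fat", "naf_knee", 0.45),
    ("total_fat", "fdg_knee", 0.50),
    ("bmi", "naf_hip", 0.55),
    ("bmi", "naf_si", 0.54),
    ("leptin", "naf_hip", 0.45),
    ("leptin", "naf_si", 0.45),
    ("naf_knee", "naf_hip", 0.55),
    ("naf_knee", "naf_si", 0.55),
    ("naf_hip", "naf_si", 0.60),
    ("fdg_knee", "fdg_hip", 0.40),
    ("fdg_knee", "fdg_si", 0.40),
    ("fdg_hip", "fdg_si", 0.55),
    ("naf_hip", "total_fat", 0.40),
    ("naf_si", "total_fat", 0.40),
    ("fdg_knee", "naf_hip", 0.35),
    ("fdg_knee", "naf_si", 0.35),
    ("naf_knee", "fdg_hip", 0.30),
    ("naf_knee", "fdg_si", 0.30),
    ("vas_ptglobal", "fdg_hip", -0.55),
    ("vas_ptglobal", "fdg_si", -0.50),
    ("das28_crp", "fdg_hip", -0.35),
    ("das28_crp", "fdg_si", -0.30),
)

#: Default MCAR missingness rates (serum assays not obtained in everyone).
DEFAULT_MISSING_RATES: dict[str, float] = {
    "leptin": 0.10,
    "sclerostin": 0.15,
    "total_fat": 0.10,
}

_HANDEDNESS_PROBS = (("right", 13 / 18), ("left", 4 / 18), ("ambidextrous", 1 / 18))


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic clinical cohort.

    ``correlations`` lists designed latent (Gaussian-copula) correlations;
    the implied matrix must be symmetric positive semi-definite.  Marginals
    are truncated normals calibrated to ``marginals`` (median, IQR, range).
    """

    n: int = 18
    marginals: dict = field(default_factory=lambda: dict(DEFAULT_MARGINALS))
    correlations: tuple = DEFAULT_CORRELATIONS
    missing_rates: dict = field(default_factory=lambda: dict(DEFAULT_MISSING_RATES))
    laterality_sd_frac: float = 0.05
    laterality_shift_frac: float = 0.0
    seed: int = 0


def correlation_matrix(variables, pairs) -> np.ndarray:
    """Assemble a correlation matrix from (var, var, rho) pairs.

    Raises if the result is not symmetric positive semi-definite, naming
    the offending eigenvalue.
    """
    variables = list(variables)
    k = len(variables)
    idx = {v: i for i, v in enumerate(variables)}
    mat = np.eye(k)
    for a, b, rho in pairs:
        if a not in idx or b not in idx:
            continue
        if not -1.0 <= rho <= 1.0:
            raise ValueError(f"correlation {rho} for ({a}, {b}) outside [-1, 1]")
        mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = rho
    w = np.linalg.eigvalsh(mat)
    if w.min() < -1e-10:
        raise ValueError(
            f"target correlation matrix is not positive semi-definite "
            f"(smallest eigenvalue {w.min():.3g})"
        )
    return mat


def _truncnorm_ppf(u, median, iqr, lo, hi):
    scale = iqr / 1.349 if iqr > 0 else 1e-12
    a, b = (lo - median) / scale, (hi - median) / scale
    return sps.truncnorm.ppf(u, a, b, loc=median, scale=scale)


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a synthetic cohort table via a Gaussian copula.

    A latent multivariate normal with the designed correlation matrix is
    transformed through each variable's truncated-normal quantile function.
    Weight is derived as BMI·(height/100)² so the BMI invariant holds
    exactly; per-side uptake columns are the side average plus/minus half a
    small laterality difference.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    variables = list(spec.marginals)
    corr = correlation_matrix(variables, spec.correlations)
    # eigen decomposition handles the semi-definite case cholesky cannot
    w, v = np.linalg.eigh(corr)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((spec.n, len(variables))) @ root.T
    u = sps.norm.cdf(z)
    data = {}
    for j, name in enumerate(variables):
        med, iqr, lo, hi = spec.marginals[name]
        data[name] = _truncnorm_ppf(u[:, j], med, iqr, lo, hi)
    df = pd.DataFrame(data)
    df.insert(0, "subject", [f"S{i + 1:03d}" for i in range(spec.n)])
    if {"bmi", "height"}.issubset(df.columns):
        df["weight"] = df["bmi"] * (df["height"] / 100.0) ** 2
    hu = rng.uniform(size=spec.n)
    cut_right = _HANDEDNESS_PROBS[0][1]
    cut_left = cut_right + _HANDEDNESS_PROBS[1][1]
    df["handedness"] = np.where(
        hu < cut_right, "right", np.where(hu < cut_left, "left", "ambidextrous")
    )
    # per-side uptake columns around the side average
    for col in list(df.columns):
        if col.startswith(("fdg_", "naf_")) and not col.endswith(("_left", "_right")):
            avg = df[col].to_numpy()
            delta = rng.normal(
                spec.laterality_shift_frac * avg, spec.laterality_sd_frac * avg
            )
            left = np.clip(avg - delta / 2.0, 0.0, None)
            right = np.clip(avg + delta / 2.0, 0.0, None)
            df[f"{col}_left"] = left
            df[f"{col}_right"] = right
            df[col] = (left + right) / 2.0
    for name, rate in spec.missing_rates.items():
        if name in df.columns and rate > 0:
            miss = rng.uniform(size=spec.n) < rate
            df.loc[miss, name] = np.nan
    return df


def cohort_phantom_specs(
    table: pd.DataFrame,
    joint: str = "knee",
    tracer: str = "NaF",
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
) -> list[PhantomSpec]:
    """One phantom spec per cohort row, bone SUV taken from the uptake column."""
    base = base_spec or PhantomSpec(joint=joint, tracer=tracer)
    col = f"{tracer.lower()}_{joint.lower()}"
    if col not in table.columns:
        raise KeyError(f"cohort table lacks uptake column {col!r}")
    specs = []
    for i, (_, row) in enumerate(table.iterrows()):
        specs.append(
            replace(
                base,
                joint=joint,
                tracer=tracer,
                bone_suv=float(row[col]),
                seed=(seed + 1000 * i) % (2**31 - 1),
            )
        )
    return specs
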