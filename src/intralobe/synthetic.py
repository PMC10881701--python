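"""Synthetic phantom and cohort generation.

Replaces the unavailable clinical data with phantoms that carry the exact
statistical structure the downstream analysis assumes: a bilobar liver
(an ellipsoid split by a plane into a ~1:2 left:right volume ratio) bearing
one to three spherical lesions of at least 30 mm per lobe, a homogeneous
normal-liver background, a lobe-selective multiplicative enhancement rho on
the randomized (intra-arterially treated) lobe, and Poisson count noise.

The expected counts are, per voxel:

* outside the liver: 0;
* normal liver: ``background_counts``;
* lesion, control lobe: ``background_counts * uptake_multiplier``;
* lesion, treated lobe (post-cycle volumes): additionally ``* rho``.

All of a patient's lesions share one uptake multiplier, so in the
noise-free limit the measured tn_ia / tn_control equals rho exactly.
Misalignment between the baseline and post-cycle grids is simulated by
rendering the analytic geometry at rigidly transformed voxel centers; the
transform is recorded so VOI transfer can use the true registration.

Default statistical parameters are calibrated to a within-patient
intra-arterial PRRT trial in neuroendocrine liver metastases: geometric
mean control-lobe T/N 16.2, geometric mean enhancement 1.17, and a
within-patient log-ratio SD of 0.39.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .design import generate_randomization
from .grids import VOI, GridSpec, ImageVolume, RigidTransform, save_label_map, save_volume
from .response import DEFAULT_GRADING_RULES

__all__ = [
    "CohortConfig",
    "Lesion",
    "PatientPhantom",
    "ResponseProfile",
    "PlacementError",
    "build_phantom",
    "simulate_followup",
    "simulate_labs",
    "simulate_paired_tn",
    "simulate_tn_long",
    "generate_cohort",
]


class PlacementError(RuntimeError):
    """Raised when a lesion or reference VOI cannot be placed in a lobe."""


@dataclass(frozen=True)
class ResponseProfile:
    """Joint 3/6-month fractional-diameter-change mixture for one lobe.

    Trajectories (weights must sum to 1):

    * ``pr_early`` — responds by 3 months and stays in response;
    * ``pr_late``  — stable at 3 months, partial response by 6 months;
    * ``pd_late``  — stable at 3 months, progression by 6 months;
    * ``sd``       — stable throughout.

    Trajectories are drawn jointly (not per timepoint) so a deep early
    response cannot be followed by an uncorrelated rebound that would read
    as progression from the nadir.
    """

    w_pr_early: float = 0.25
    w_pr_late: float = 0.10
    w_pd_late: float = 0.04
    w_sd: float = 0.61
    point_mass_change: float | None = None

    def __post_init__(self) -> None:
        if self.point_mass_change is None:
            total = self.w_pr_early + self.w_pr_late + self.w_pd_late + self.w_sd
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"trajectory weights must sum to 1, got {total}")

    @classmethod
    def point_mass(cls, change: float) -> "ResponseProfile":
        """Every lobe changes by exactly ``change`` at both timepoints."""
        return cls(0.0, 0.0, 0.0, 1.0, point_mass_change=change)

    def draw(self, rng: np.random.Generator) -> tuple[float, float]:
        """One (change_3mo, change_6mo) pair, fractions of the baseline sum."""
        if self.point_mass_change is not None:
            return self.point_mass_change, self.point_mass_change
        u = rng.random()
        if u < self.w_pr_early:
            c3 = rng.uniform(-0.50, -0.35)
            c6 = c3 + rng.uniform(-0.05, 0.0) * (1 + c3)
        elif u < self.w_pr_early + self.w_pr_late:
            c3 = rng.uniform(-0.25, -0.05)
            c6 = rng.uniform(-0.50, -0.35)
        elif u < self.w_pr_early + self.w_pr_late + self.w_pd_late:
            c3 = rng.uniform(-0.05, 0.10)
            c6 = rng.uniform(0.30, 0.45)
        else:
            c3 = rng.uniform(-0.20, 0.05)
            c6 = c3 + rng.uniform(-0.05, 0.10) * (1 + c3)
        return c3, c6


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of the synthetic trial; defaults reproduce the study scale."""

    n_patients: int = 27
    n_cycles: int = 4
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)  # mm
    background_counts: float = 20.0  # expected counts/voxel in normal liver
    tn_true_log_mean: float = math.log(16.2)
    tn_true_log_sd: float = 0.8
    enhancement_log_mean: float = math.log(1.17)
    enhancement_log_sd: float = 0.39
    lesions_per_lobe_range: tuple[int, int] = (1, 3)
    lesion_diameter_range: tuple[float, float] = (30.0, 50.0)  # mm
    misalignment_max_translation: float = 0.0  # mm, per axis
    poisson_noise: bool = True
    liver_semiaxes: tuple[float, float, float] = (110.0, 85.0, 75.0)  # mm
    left_lobe_volume_fraction: float = 1.0 / 3.0
    normal_voi_radius: float = 16.0  # mm -> ~17 mL, above the 15 mL floor
    response_profile: ResponseProfile = field(default_factory=ResponseProfile)
    baseline_abnormal_rate: float = 0.08
    lab_toxicity_rate: float = 0.12
    n_followup_visits: int = 5
    dropout: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.background_counts <= 0:
            raise ValueError("background_counts must be strictly positive")
        lo, hi = self.lesions_per_lobe_range
        if not 1 <= lo <= hi <= 3:
            raise ValueError("lesions_per_lobe_range must lie within [1, 3]")
        dlo, dhi = self.lesion_diameter_range
        if dlo < 30.0:
            raise ValueError("lesion diameters must be >= 30 mm (eligibility floor)")
        if dlo > dhi:
            raise ValueError("lesion_diameter_range must be ordered")
        center = ((np.asarray(self.grid_shape) - 1) / 2) * np.asarray(self.voxel_spacing)
        margin = center - np.asarray(self.liver_semiaxes) - self.misalignment_max_translation
        if np.any(margin < 0):
            raise ValueError(
                "grid too small: the liver ellipsoid plus misalignment margin "
                f"exceeds the grid half-extent by {-margin.min():.1f} mm"
            )

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.grid_shape, self.voxel_spacing, (0.0, 0.0, 0.0), "baseline")


@dataclass(frozen=True)
class Lesion:
    lesion_id: str
    lobe: str
    center: tuple[float, float, float]  # mm, world coordinates
    diameter: float  # mm
    uptake_multiplier: float

    def __post_init__(self) -> None:
        if self.diameter < 30.0:
            raise ValueError("lesion diameter must be >= 30 mm")
        if self.uptake_multiplier <= 1.0:
            raise ValueError("lesion uptake multiplier must exceed 1")


@dataclass(frozen=True)
class PatientPhantom:
    """One synthetic patient: geometry, truth, and image volumes."""

    patient_id: str
    config: CohortConfig
    ia_lobe: str
    lesions: tuple[Lesion, ...]
    normal_center: tuple[float, float, float]
    true_tn: float
    true_enhancement: float
    liver_mask: VOI
    lobe_labels: np.ndarray  # 0 outside, 1 left, 2 right (baseline grid)
    lesion_vois: dict[str, VOI]  # true lesion masks on the baseline grid
    normal_voi: VOI
    baseline_volume: ImageVolume
    cycle_volumes: tuple[ImageVolume, ...]
    baseline_to_cycle_transforms: tuple[RigidTransform, ...]

    @property
    def control_lobe(self) -> str:
        return "left" if self.ia_lobe == "right" else "right"

    def rough_voi(self, lesion_id: str, margin_mm: float = 12.0) -> VOI:
        """Box-shaped rough VOI around a lesion on the baseline grid, as an
        operator would draw before threshold shrinking."""
        lesion = next(l for l in self.lesions if l.lesion_id == lesion_id)
        grid = self.baseline_volume.grid
        center = np.asarray(lesion.center)
        half = lesion.diameter / 2 + margin_mm
        lo = np.maximum(grid.nearest_indices(center - half)[0], 0)
        hi = np.minimum(grid.nearest_indices(center + half)[0],
                        np.asarray(grid.shape) - 1)
        ranges = [np.arange(lo[a], hi[a] + 1) for a in range(3)]
        ii, jj, kk = np.meshgrid(*ranges, indexing="ij")
        idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
        return VOI(idx, grid, label=lesion_id)


# ---------------------------------------------------------------------------
# Geometry helpers


def _split_offset(config: CohortConfig) -> float:
    """World-x of the plane splitting the ellipsoid at the left-lobe volume
    fraction (cap volume of a unit ball below t: 1 - (2 - 3t + t^3)/4)."""
    f = config.left_lobe_volume_fraction
    t = brentq(lambda t: 1 - (2 - 3 * t + t**3) / 4 - f, -1.0, 1.0)
    center = ((np.asarray(config.grid_shape) - 1) / 2) * np.asarray(config.voxel_spacing)
    return float(center[0] + t * config.liver_semiaxes[0])


def _liver_center(config: CohortConfig) -> np.ndarray:
    return ((np.asarray(config.grid_shape) - 1) / 2) * np.asarray(config.voxel_spacing)


def _voxel_world(grid: GridSpec) -> np.ndarray:
    """(N, 3) world coordinates of every voxel center."""
    axes = [np.arange(n) * s for n, s in zip(grid.shape, grid.spacing)]
    ii, jj, kk = np.meshgrid(*axes, indexing="ij")
    return np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1) + np.asarray(grid.origin)


def _render_geometry(
    world: np.ndarray,
    config: CohortConfig,
    lesions: tuple[Lesion, ...],
    x_split: float,
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Evaluate liver mask, lobe labels and lesion masks at world points."""
    center = _liver_center(config)
    rel = (world - center) / np.asarray(config.liver_semiaxes)
    liver = np.sum(rel**2, axis=1) <= 1.0
    lobes = np.zeros(world.shape[0], dtype=np.int16)
    lobes[liver & (world[:, 0] < x_split)] = 1  # left
    lobes[liver & (world[:, 0] >= x_split)] = 2  # right
    lesion_masks = {}
    for lesion in lesions:
        d = np.linalg.norm(world - np.asarray(lesion.center), axis=1)
        lesion_masks[lesion.lesion_id] = d <= lesion.diameter / 2
    return liver, lobes, lesion_masks


def _expectation(
    config: CohortConfig,
    liver: np.ndarray,
    lesion_masks: dict[str, np.ndarray],
    lesions: tuple[Lesion, ...],
    rho: float,
    ia_lobe: str,
) -> np.ndarray:
    exp = np.where(liver, config.background_counts, 0.0)
    for lesion in lesions:
        factor = lesion.uptake_multiplier * (rho if lesion.lobe == ia_lobe else 1.0)
        exp[lesion_masks[lesion.lesion_id]] = config.background_counts * factor
    return exp


def _sphere_voxels_inside(
    p: np.ndarray, radius: float, config: CohortConfig, lobe: str, x_split: float
) -> bool:
    """True when every voxel center within ``radius`` of ``p`` lies inside
    the liver ellipsoid, on the requested side of the lobe plane, and inside
    the grid.  This is the voxel-level invariant the phantom must satisfy
    (the analytic shrunk-ellipsoid test used for pre-filtering is only
    approximately conservative)."""
    spacing = np.asarray(config.voxel_spacing)
    lo = np.floor((p - radius) / spacing).astype(int)
    hi = np.ceil((p + radius) / spacing).astype(int)
    if np.any(lo < 0) or np.any(hi > np.asarray(config.grid_shape) - 1):
        return False
    ranges = [np.arange(lo[a], hi[a] + 1) * spacing[a] for a in range(3)]
    ii, jj, kk = np.meshgrid(*ranges, indexing="ij")
    w = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    w = w[np.linalg.norm(w - p, axis=1) <= radius]
    center = _liver_center(config)
    f = np.sum(((w - center) / np.asarray(config.liver_semiaxes)) ** 2, axis=1)
    if np.any(f > 1.0):
        return False
    if lobe == "left":
        return bool(np.all(w[:, 0] < x_split))
    return bool(np.all(w[:, 0] >= x_split))


def _place_sphere(
    rng: np.random.Generator,
    config: CohortConfig,
    lobe: str,
    radius: float,
    x_split: float,
    exclude: list[tuple[np.ndarray, float]],
    max_attempts: int = 2000,
) -> np.ndarray:
    """Rejection-sample a sphere center fully inside one lobe of the liver.

    Cheap analytic tests (shrunk semi-axes, lobe-plane margin, keep-out
    spheres) pre-filter candidates; the accepted center is the one whose
    voxelized sphere passes the exact containment check.
    """
    center = _liver_center(config)
    shrunk = np.asarray(config.liver_semiaxes) - radius
    if np.any(shrunk <= 0):
        raise PlacementError(f"sphere of radius {radius} mm cannot fit in the liver")
    # Feasible slab of center x-coordinates for this lobe (plane margin).
    if lobe == "left":
        x_lo, x_hi = center[0] - shrunk[0], x_split - radius
    else:
        x_lo, x_hi = x_split + radius, center[0] + shrunk[0]
    if x_hi <= x_lo:
        raise PlacementError(
            f"a {2 * radius:.0f} mm sphere cannot fit in the {lobe} lobe at all"
        )
    for _ in range(max_attempts):
        p = np.array([
            rng.uniform(x_lo, x_hi),
            center[1] + rng.uniform(-1, 1) * shrunk[1],
            center[2] + rng.uniform(-1, 1) * shrunk[2],
        ])
        if np.sum(((p - center) / shrunk) ** 2) > 1.0:
            continue
        if any(np.linalg.norm(p - c) < dmin for c, dmin in exclude):
            continue
        if not _sphere_voxels_inside(p, radius, config, lobe, x_split):
            continue
        return p
    raise PlacementError(
        f"could not place a {2 * radius:.0f} mm sphere in the {lobe} lobe "
        f"after {max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# Phantom construction


def build_phantom(
    config: CohortConfig, patient_seed: int, ia_lobe: str | None = None,
    patient_id: str | None = None,
) -> PatientPhantom:
    """Build one patient phantom: geometry, truth values, and all volumes.

    ``patient_seed`` drives every stochastic element of this patient
    (lesion placement, truth draws, noise, misalignment); the treated lobe
    may be supplied by the randomization list or drawn as a fair coin.
    """
    rng = np.random.default_rng(patient_seed)
    if ia_lobe is None:
        ia_lobe = ("left", "right")[int(rng.integers(0, 2))]
    if ia_lobe not in ("left", "right"):
        raise ValueError(f"ia_lobe must be 'left' or 'right', got {ia_lobe!r}")
    pid = patient_id or f"P{patient_seed}"
    x_split = _split_offset(config)

    true_tn = float(np.exp(rng.normal(config.tn_true_log_mean, config.tn_true_log_sd)))
    # A lesion-to-background ratio below 1/0.42 cannot be isolated by the
    # 42%-of-max threshold (background would pass it); such faint lesions
    # would not qualify as target lesions in the first place.
    true_tn = max(true_tn, 2.5)
    rho = float(np.exp(rng.normal(config.enhancement_log_mean, config.enhancement_log_sd)))

    # The healthy-liver reference VOI is placed first (its lobe is fixed by
    # the randomization); lesions then keep clear of it but may be confluent
    # with one another.
    control_lobe = "left" if ia_lobe == "right" else "right"
    normal_radius = config.normal_voi_radius
    normal_center = _place_sphere(rng, config, control_lobe, normal_radius, x_split, [])

    lesions: list[Lesion] = []
    for lobe in ("left", "right"):
        n_lesions = int(rng.integers(config.lesions_per_lobe_range[0],
                                     config.lesions_per_lobe_range[1] + 1))
        for i in range(n_lesions):
            diameter = float(rng.uniform(*config.lesion_diameter_range))
            exclude = (
                [(np.asarray(normal_center), diameter / 2 + normal_radius + 6.0)]
                if lobe == control_lobe else []
            )
            c = _place_sphere(rng, config, lobe, diameter / 2, x_split, exclude)
            lesions.append(Lesion(f"{pid}_{lobe}_{i + 1}", lobe, tuple(c), diameter, true_tn))
    lesions_t = tuple(lesions)

    grid = config.grid
    world = _voxel_world(grid)
    liver, lobes, lesion_masks = _render_geometry(world, config, lesions_t, x_split)
    shape = grid.shape

    liver_mask = VOI.from_mask(liver.reshape(shape), grid, "liver")
    lobe_labels = lobes.reshape(shape)
    lesion_vois = {
        lid: VOI.from_mask(mask.reshape(shape), grid, lid)
        for lid, mask in lesion_masks.items()
    }
    normal_mask = np.linalg.norm(world - normal_center, axis=1) <= normal_radius
    normal_voi = VOI.from_mask(normal_mask.reshape(shape), grid, "normal")

    _check_invariants(config, lesions_t, lesion_vois, normal_voi, liver_mask)

    def draw(expectation: np.ndarray) -> np.ndarray:
        if config.poisson_noise:
            return rng.poisson(expectation).astype(float)
        return expectation

    baseline_exp = _expectation(config, liver, lesion_masks, lesions_t, 1.0, ia_lobe)
    baseline_volume = ImageVolume(draw(baseline_exp).reshape(shape), grid)

    cycle_volumes = []
    transforms = []
    for cycle in range(1, config.n_cycles + 1):
        if config.misalignment_max_translation > 0:
            t = rng.uniform(-config.misalignment_max_translation,
                            config.misalignment_max_translation, size=3)
            transform = RigidTransform(np.eye(3), t)
        else:
            transform = RigidTransform.identity()
        cycle_grid = replace(grid, grid_id=f"cycle{cycle}")
        if transform.is_identity:
            c_liver, _, c_lesions = liver, lobes, lesion_masks
        else:
            c_world = transform.inverse().apply(_voxel_world(cycle_grid))
            c_liver, _, c_lesions = _render_geometry(c_world, config, lesions_t, x_split)
        exp = _expectation(config, c_liver, c_lesions, lesions_t, rho, ia_lobe)
        cycle_volumes.append(ImageVolume(draw(exp).reshape(shape), cycle_grid))
        transforms.append(transform)

    return PatientPhantom(
        patient_id=pid, config=config, ia_lobe=ia_lobe, lesions=lesions_t,
        normal_center=tuple(normal_center), true_tn=true_tn, true_enhancement=rho,
        liver_mask=liver_mask, lobe_labels=lobe_labels, lesion_vois=lesion_vois,
        normal_voi=normal_voi, baseline_volume=baseline_volume,
        cycle_volumes=tuple(cycle_volumes),
        baseline_to_cycle_transforms=tuple(transforms),
    )


def _check_invariants(config, lesions, lesion_vois, normal_voi, liver_mask) -> None:
    if normal_voi.volume_ml < 15.0:
        raise PlacementError(
            f"normal-tissue VOI is {normal_voi.volume_ml:.1f} mL, below the 15 mL floor"
        )
    liver_set = {tuple(i) for i in liver_mask.indices}
    normal_set = {tuple(i) for i in normal_voi.indices}
    for lid, voi in lesion_vois.items():
        vset = {tuple(i) for i in voi.indices}
        if vset & normal_set:
            raise PlacementError(f"lesion {lid} overlaps the normal-tissue VOI")
        if not vset <= liver_set:
            raise PlacementError(f"lesion {lid} extends outside the liver")
    for lobe in ("left", "right"):
        n = sum(1 for l in lesions if l.lobe == lobe)
        if not 1 <= n <= 3:
            raise PlacementError(f"{lobe} lobe has {n} lesions, need 1-3")


# ---------------------------------------------------------------------------
# Tabular simulators (follow-up, labs, and direct T/N draws)


def simulate_followup(
    phantom: PatientPhantom, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-lesion diameters at baseline, 3 and 6 months.

    One trajectory is drawn per lobe from ``config.response_profile`` (the
    same profile for both lobes: the no-differential-response null) and the
    fractional change is applied to every lesion of the lobe.
    """
    rows = []
    for lobe in ("left", "right"):
        c3, c6 = config.response_profile.draw(rng)
        for lesion in phantom.lesions:
            if lesion.lobe != lobe:
                continue
            rows.append({
                "patient_id": phantom.patient_id, "lobe": lobe,
                "lesion_id": lesion.lesion_id,
                "diameter_baseline": lesion.diameter,
                "diameter_3mo": lesion.diameter * (1 + c3),
                "diameter_6mo": lesion.diameter * (1 + c6),
            })
    return pd.DataFrame(rows)


#: Reference (normal) ranges used to draw unremarkable laboratory values.
NORMAL_RANGES: dict[str, tuple[float, float]] = {
    "albumin": (36, 50), "alat": (10, 38), "asat": (12, 38), "ggt": (10, 55),
    "alp": (40, 110), "bilirubin": (4, 19), "hemoglobin": (125, 165),
    "mcv": (82, 98), "thrombocytes": (160, 380), "leukocytes": (4.2, 10.0),
    "neutrophils": (2.0, 7.0), "lymphocytes": (1.1, 3.5), "egfr": (92, 120),
    "creatinine": (60, 105), "urea": (3.0, 7.8),
}


def _value_at_grade(analyte: str, grade: int, rng: np.random.Generator) -> float:
    """A value inside the given toxicity grade band for this analyte."""
    rule = DEFAULT_GRADING_RULES[analyte]
    if grade == 0:
        return float(rng.uniform(*NORMAL_RANGES[analyte]))
    grade = min(grade, len(rule.thresholds))
    t = rule.thresholds[grade - 1]
    if rule.direction == "high":
        upper = (rule.thresholds[grade] if grade < len(rule.thresholds) else t * 1.5)
        return float(rng.uniform(t, t + 0.9 * (upper - t)))
    lower = rule.thresholds[grade] if grade < len(rule.thresholds) else t * 0.5
    return float(rng.uniform(t - 0.9 * (t - lower), t))


def simulate_labs(
    phantom: PatientPhantom, config: CohortConfig, rng: np.random.Generator,
    analytes: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Laboratory time series (visit 0 = baseline) for the safety panel.

    A patient-analyte pair may start abnormal (grade 1-3) with probability
    ``baseline_abnormal_rate``; with probability ``lab_toxicity_rate`` one
    follow-up visit is pushed one grade above baseline (a treatment-emergent
    event under the delta rule).  Other visits fluctuate multiplicatively
    around baseline.
    """
    names = analytes or tuple(NORMAL_RANGES)
    unknown = set(names) - set(NORMAL_RANGES)
    if unknown:
        raise ValueError(f"unknown analyte(s): {sorted(unknown)}")
    rows = []
    for analyte in names:
        if rng.random() < config.baseline_abnormal_rate:
            base_grade = int(rng.integers(1, 4))
        else:
            base_grade = 0
        base_value = _value_at_grade(analyte, base_grade, rng)
        tox_visit = 0
        if rng.random() < config.lab_toxicity_rate:
            tox_visit = int(rng.integers(1, config.n_followup_visits + 1))
        rows.append({"patient_id": phantom.patient_id, "visit": 0,
                     "analyte": analyte, "value": base_value})
        for visit in range(1, config.n_followup_visits + 1):
            if visit == tox_visit:
                value = _value_at_grade(analyte, base_grade + 1, rng)
            else:
                value = base_value * float(np.exp(rng.normal(0.0, 0.06)))
            rows.append({"patient_id": phantom.patient_id, "visit": visit,
                         "analyte": analyte, "value": value})
    return pd.DataFrame(rows)


def simulate_paired_tn(
    n_patients: int,
    geometric_ratio: float,
    log_ratio_sd: float,
    rng: np.random.Generator,
    tn_log_mean: float = math.log(16.2),
    tn_log_sd: float = 0.8,
    cycle: int = 1,
    basis: str = "mean",
) -> pd.DataFrame:
    """Directly draw a single-cycle paired T/N table from the trial's model.

    log tn_control ~ N(tn_log_mean, tn_log_sd); the per-patient observed
    log-ratio ~ N(log geometric_ratio, log_ratio_sd).  This is the
    statistical level at which the paired analyses operate, bypassing image
    rendering for large replicate studies.
    """
    log_ctrl = rng.normal(tn_log_mean, tn_log_sd, size=n_patients)
    log_ratio = rng.normal(math.log(geometric_ratio), log_ratio_sd, size=n_patients)
    return pd.DataFrame({
        "patient_id": [f"P{i + 1}" for i in range(n_patients)],
        "cycle": cycle, "basis": basis,
        "tn_control": np.exp(log_ctrl),
        "tn_ia": np.exp(log_ctrl + log_ratio),
    })


def simulate_tn_long(
    n_patients: int,
    n_cycles: int,
    arm_effect: float,
    rng: np.random.Generator,
    patient_sd: float = 0.8,
    cycle_sd: float = 0.3,
    residual_sd: float = 0.2,
    mean: float = math.log(16.2),
) -> pd.DataFrame:
    """Multi-cycle paired table with explicit variance components.

    Generates log T/N = mean + b_patient + w_patient:cycle + arm_effect*arm
    + eps, i.e. exactly the two-level random-intercept structure the mixed
    model assumes, and returns the wide (tn_ia, tn_control) layout.
    """
    rows = []
    for i in range(n_patients):
        b = rng.normal(0.0, patient_sd)
        for c in range(1, n_cycles + 1):
            w = rng.normal(0.0, cycle_sd)
            log_ctrl = mean + b + w + rng.normal(0.0, residual_sd)
            log_ia = mean + b + w + arm_effect + rng.normal(0.0, residual_sd)
            rows.append({"patient_id": f"P{i + 1}", "cycle": c, "basis": "mean",
                         "tn_control": math.exp(log_ctrl), "tn_ia": math.exp(log_ia)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort-on-disk generation


def _patient_seeds(config: CohortConfig) -> list[int]:
    state = np.random.SeedSequence(config.seed).generate_state(config.n_patients)
    return [int(s) for s in state]


def _completed_cycles(config: CohortConfig, rng: np.random.Generator) -> list[int]:
    """Optional dropout: two patients stop after cycle 1, one after cycle 2."""
    completed = [config.n_cycles] * config.n_patients
    if config.dropout and config.n_patients >= 3 and config.n_cycles >= 2:
        dropouts = rng.choice(config.n_patients, size=3, replace=False)
        completed[dropouts[0]] = 1
        completed[dropouts[1]] = 1
        completed[dropouts[2]] = 2
    return completed


def generate_cohort(config: CohortConfig, outdir: str | Path) -> Path:
    """Generate and persist a full synthetic cohort.

    Writes, per patient, NIfTI volumes (baseline + completed cycles) and
    label maps (lobes; lesions; normal VOI as label 99), plus cohort-level
    CSV manifests (randomization, lesions, transforms, diameters, labs) and
    a JSON echo of the configuration.  Fully reproducible from
    (config, seed).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rand = generate_randomization(config.n_patients, config.seed)
    seeds = _patient_seeds(config)
    cohort_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    completed = _completed_cycles(config, cohort_rng)

    rand_rows, lesion_rows, transform_rows = [], [], []
    diam_frames, lab_frames = [], []
    for i, (ia_lobe, seed_i) in enumerate(zip(rand.assignments, seeds)):
        pid = f"P{i + 1:02d}"
        phantom = build_phantom(config, seed_i, ia_lobe=ia_lobe, patient_id=pid)
        pdir = out / pid
        pdir.mkdir(exist_ok=True)
        save_volume(phantom.baseline_volume, pdir / "baseline.nii.gz")
        for c in range(completed[i]):
            save_volume(phantom.cycle_volumes[c], pdir / f"cycle_{c + 1}.nii.gz")
        save_label_map(phantom.lobe_labels, config.grid, pdir / "lobes.nii.gz")
        labels = np.zeros(config.grid_shape, dtype=np.int16)
        for j, lesion in enumerate(phantom.lesions, start=1):
            ii, jj, kk = phantom.lesion_vois[lesion.lesion_id].indices.T
            labels[ii, jj, kk] = j
        ii, jj, kk = phantom.normal_voi.indices.T
        labels[ii, jj, kk] = 99
        save_label_map(labels, config.grid, pdir / "vois.nii.gz")

        rand_rows.append({"patient_id": pid, "ia_lobe": ia_lobe,
                          "patient_seed": seed_i, "completed_cycles": completed[i]})
        for j, lesion in enumerate(phantom.lesions, start=1):
            lesion_rows.append({
                "patient_id": pid, "lesion_id": lesion.lesion_id, "voi_label": j,
                "lobe": lesion.lobe, "diameter_mm": lesion.diameter,
                "center_x": lesion.center[0], "center_y": lesion.center[1],
                "center_z": lesion.center[2],
                "uptake_multiplier": lesion.uptake_multiplier,
            })
        for c, tr in enumerate(phantom.baseline_to_cycle_transforms[: completed[i]], 1):
            transform_rows.append({
                "patient_id": pid, "cycle": c,
                **{f"r{a}{b}": tr.rotation[a, b] for a in range(3) for b in range(3)},
                **{f"t{a}": tr.translation[a] for a in range(3)},
            })
        diam_frames.append(simulate_followup(phantom, config, cohort_rng))
        lab_frames.append(simulate_labs(phantom, config, cohort_rng))

    pd.DataFrame(rand_rows).to_csv(out / "randomization.csv", index=False)
    pd.DataFrame(lesion_rows).to_csv(out / "lesions.csv", index=False)
    pd.DataFrame(transform_rows).to_csv(out / "transforms.csv", index=False)
    pd.concat(diam_frames, ignore_index=True).to_csv(out / "diameters.csv", index=False)
    pd.concat(lab_frames, ignore_index=True).to_csv(out / "labs.csv", index=False)
    echo = asdict(config)
    echo["response_profile"] = asdict(config.response_profile)
    (out / "config.json").write_text(json.dumps(echo, indent=2, default=list) + "\n")
    return out
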