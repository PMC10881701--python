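"""Lesion VOI quantification on emission volumes.

The chain mirrors routine post-therapy SPECT/CT quantification of liver
metastases: lesion VOIs are segmented on the baseline receptor image by
shrinking a rough VOI to voxels at or above 42% of its maximum, transferred
onto each post-cycle emission grid through the known rigid transform, and
reduced to mean and peak counts per voxel.  The tumour-to-non-tumour (T/N)
ratio is the volume-weighted mean lesion uptake divided by the mean uptake
in a healthy-liver reference VOI in the control lobe.

Uptake is raw counts per voxel throughout; T/N is scale-free, so no SUV
calibration is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .grids import VOI, ImageVolume, RigidTransform

__all__ = [
    "UptakeResult",
    "TNResult",
    "segment_lesion_voi",
    "transfer_voi",
    "mean_uptake",
    "peak_uptake",
    "tn_ratio",
    "quantify_patient_cycle",
    "SEGMENT_THRESHOLD_FRACTION",
]

logger = logging.getLogger(__name__)

#: Fraction of the in-VOI maximum used to shrink the rough lesion VOI.
SEGMENT_THRESHOLD_FRACTION = 0.42

#: Diameter (mm) of the peak-uptake sphere.
PEAK_SPHERE_DIAMETER_MM = 10.0

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class UptakeResult:
    """Per-lesion uptake summary on one emission volume."""

    lesion_id: str
    lobe: str
    mean_uptake: float  # counts/voxel
    peak_uptake: float  # counts/voxel
    lesion_volume_ml: float
    normal_mean: float  # counts/voxel, control-lobe reference VOI


@dataclass(frozen=True)
class TNResult:
    """Within-patient T/N pair for one cycle on one basis."""

    patient_id: str
    cycle: int
    tn_ia: float
    tn_control: float
    basis: str  # "mean" or "peak"

    def __post_init__(self) -> None:
        if self.basis not in ("mean", "peak"):
            raise ValueError(f"basis must be 'mean' or 'peak', got {self.basis!r}")
        if self.tn_ia <= 0 or self.tn_control <= 0:
            raise ValueError("T/N ratios must be positive")


def _max_voxel(voi: VOI, volume: ImageVolume) -> tuple[np.ndarray, float]:
    """Hottest voxel of a VOI; ties broken by lowest lexicographic index.

    VOI indices are stored lexicographically sorted, so the first argmax hit
    is the tie-break winner.
    """
    vals = voi.values_in(volume)
    pos = int(np.argmax(vals))
    return voi.indices[pos], float(vals[pos])


def segment_lesion_voi(baseline_volume: ImageVolume, rough_voi: VOI) -> VOI:
    """Shrink a rough lesion VOI to >= 42% of its maximum voxel value.

    Only the 26-connected component containing the hottest voxel is kept, so
    disjoint hot structures caught by the rough VOI are discarded.  The
    hottest voxel is always retained.
    """
    max_idx, vmax = _max_voxel(rough_voi, baseline_volume)
    if vmax <= 0:
        raise ValueError(
            f"rough VOI {rough_voi.label!r} has maximum value {vmax}: no signal to threshold"
        )
    vals = rough_voi.values_in(baseline_volume)
    keep = vals >= SEGMENT_THRESHOLD_FRACTION * vmax

    mask = np.zeros(baseline_volume.grid.shape, dtype=bool)
    i, j, k = rough_voi.indices[keep].T
    mask[i, j, k] = True
    components, _ = ndimage.label(mask, structure=_STRUCT_26)
    comp_of_max = components[tuple(max_idx)]
    return VOI.from_mask(components == comp_of_max, baseline_volume.grid, rough_voi.label)


def transfer_voi(voi: VOI, transform: RigidTransform, target_volume: ImageVolume) -> VOI:
    """Map a VOI onto another grid through a rigid world-coordinate transform.

    Each source voxel center is mapped and assigned to the nearest target
    voxel; duplicates collapse and points leaving the target grid are dropped
    (with a logged count).
    """
    world = voi.grid.world_coordinates(voi.indices)
    target_idx = target_volume.grid.nearest_indices(transform.apply(world))
    inside = target_volume.grid.in_bounds(target_idx)
    n_dropped = int(np.sum(~inside))
    if n_dropped:
        logger.info(
            "transfer_voi: %d/%d voxels of %r fell outside grid %r",
            n_dropped, len(voi), voi.label, target_volume.grid.grid_id,
        )
    kept = target_idx[inside]
    if kept.shape[0] == 0:
        raise ValueError(
            f"VOI {voi.label!r} left the field of view of grid {target_volume.grid.grid_id!r}"
        )
    return VOI(kept, target_volume.grid, voi.label)


def mean_uptake(volume: ImageVolume, voi: VOI) -> float:
    """Arithmetic mean counts per voxel over the VOI."""
    return float(np.mean(voi.values_in(volume)))


def peak_uptake(
    volume: ImageVolume, voi: VOI, sphere_diameter: float = PEAK_SPHERE_DIAMETER_MM
) -> float:
    """Mean counts per voxel in a sphere centred on the VOI's hottest voxel.

    The sphere (default 1 cm diameter) may extend beyond the VOI but not
    beyond the grid; a voxel belongs to the sphere when its center lies
    within the radius of the hottest voxel's center (world coordinates).
    """
    radius = sphere_diameter / 2.0
    spacing = np.asarray(volume.grid.spacing)
    if radius < max(spacing) / 2.0:
        raise ValueError(
            f"sphere radius {radius} mm is below half the largest voxel dimension "
            f"{max(spacing) / 2.0} mm: the sphere could miss every voxel center"
        )
    max_idx, _ = _max_voxel(voi, volume)
    center = volume.grid.world_coordinates(max_idx[None, :])[0]

    # Bounding box in index space, clipped to the grid.
    reach = np.ceil(radius / spacing).astype(int)
    lo = np.maximum(max_idx - reach, 0)
    hi = np.minimum(max_idx + reach, np.asarray(volume.grid.shape) - 1)
    ranges = [np.arange(lo[a], hi[a] + 1) for a in range(3)]
    ii, jj, kk = np.meshgrid(*ranges, indexing="ij")
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    dist = np.linalg.norm(volume.grid.world_coordinates(idx) - center, axis=1)
    inside = idx[dist <= radius]
    i, j, k = inside.T
    return float(np.mean(volume.values[i, j, k]))


def tn_ratio(
    lesion_means: Sequence[float],
    lesion_volumes_ml: Sequence[float],
    normal_mean: float,
) -> float:
    """Volume-weighted mean lesion uptake divided by the reference uptake.

    Weights are VOI volumes in mL, so the numerator is the aggregate
    concentration over all target tissue.
    """
    u = np.asarray(lesion_means, dtype=float)
    v = np.asarray(lesion_volumes_ml, dtype=float)
    if u.size == 0 or u.size != v.size:
        raise ValueError("lesion means and volumes must be non-empty and of equal length")
    if np.any(v <= 0):
        raise ValueError("lesion volumes must be positive")
    if normal_mean <= 0:
        raise ValueError(f"normal-tissue mean uptake must be positive, got {normal_mean}")
    return float(np.sum(v * u) / np.sum(v) / normal_mean)


def quantify_patient_cycle(
    patient_id: str,
    cycle: int,
    lesion_vois: Iterable[tuple[str, str, VOI]],
    normal_voi: VOI,
    ia_lobe: str,
    cycle_volume: ImageVolume,
    transform: RigidTransform = RigidTransform(),
) -> tuple[list[TNResult], list[UptakeResult]]:
    """Quantify one patient-cycle: T/N on both lobes, mean and peak basis.

    ``lesion_vois`` yields ``(lesion_id, lobe, baseline_voi)`` triples; the
    baseline VOIs and the normal VOI are transferred onto the cycle grid
    through ``transform`` before extraction.  Returns the two TNResult rows
    (mean- and peak-based) plus per-lesion audit records.
    """
    per_lobe: dict[str, dict[str, list[float]]] = {}
    normal_cycle = transfer_voi(normal_voi, transform, cycle_volume)
    normal = mean_uptake(cycle_volume, normal_cycle)
    audits: list[UptakeResult] = []
    for lesion_id, lobe, voi in lesion_vois:
        moved = transfer_voi(voi, transform, cycle_volume)
        m = mean_uptake(cycle_volume, moved)
        p = peak_uptake(cycle_volume, moved)
        vol = moved.volume_ml
        d = per_lobe.setdefault(lobe, {"mean": [], "peak": [], "vol": []})
        d["mean"].append(m)
        d["peak"].append(p)
        d["vol"].append(vol)
        audits.append(UptakeResult(lesion_id, lobe, m, p, vol, normal))

    control_lobe = "left" if ia_lobe == "right" else "right"
    for lobe in (ia_lobe, control_lobe):
        if lobe not in per_lobe:
            raise ValueError(f"no lesion VOIs supplied for lobe {lobe!r}")

    results = []
    for basis in ("mean", "peak"):
        tn = {
            lobe: tn_ratio(per_lobe[lobe][basis], per_lobe[lobe]["vol"], normal)
            for lobe in (ia_lobe, control_lobe)
        }
        results.append(
            TNResult(patient_id, cycle, tn_ia=tn[ia_lobe], tn_control=tn[control_lobe],
                     basis=basis)
        )
    return results, audits
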