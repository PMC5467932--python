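"""24-region lung sampling and air/blood-fraction-corrected lung SUV.

Lung uptake is quantified three ways per region:

* ``SUV_M`` — the measured mean SUV of the region, mixture of air, blood
  and tissue;
* ``SUV_L = SUV_M / (1 + HU/1000)`` — corrected for the air volume
  fraction (mean uptake of bulk lung material), using the region's mean
  CT number as an air-fraction surrogate (air = −1000 HU, soft tissue ≈ 0);
* ``SUV_T = (SUV_M − f·SUV_B) / (1 + HU/1000 − f)`` — corrected for both
  air and blood, where ``SUV_B`` is the blood-pool SUV and ``f`` the lung
  blood volume fraction (default 0.16).

Corrections are applied to region means (mean HU and mean SUV are
recorded per region and then corrected); a per-voxel option is available
via :func:`suv_air_corrected` / :func:`suv_tissue_corrected` on arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import LUNG_REGION_KEYS, VoxelGrid
from .errors import DomainError, PartitionError

__all__ = [
    "LungRegionMeasure",
    "LungSummary",
    "partition_lung_regions",
    "blood_pool_suv",
    "suv_air_corrected",
    "suv_tissue_corrected",
    "measure_lung_regions",
    "lung_summary",
]

DEFAULT_BLOOD_FRACTION = 0.16


@dataclass
class LungRegionMeasure:
    """Mean HU/SUV and corrected SUVs for one of the 24 lung regions."""

    key: tuple[str, str, str, str]  # (side, level, zone, slab)
    mean_hu: float
    suv_m: float
    suv_l: float
    suv_t: float
    n_voxels: int


@dataclass
class LungSummary:
    """Subject-level averages over the included lung regions."""

    avg_suv_m: float
    avg_suv_l: float
    avg_suv_t: float
    included_regions: tuple[tuple[str, str, str, str], ...]
    suv_b: float
    blood_fraction: float


def _split_plane_x(mask: np.ndarray) -> int:
    """Voxel-index x of the sagittal split between the two lungs.

    Uses the midline of the widest empty x-gap strictly inside the mask's
    x-extent; falls back to the mask centroid when the lungs touch.
    """
    col_counts = mask.sum(axis=(1, 2))
    occupied = np.nonzero(col_counts)[0]
    lo, hi = occupied[0], occupied[-1]
    empty = np.nonzero(col_counts[lo:hi + 1] == 0)[0]
    if empty.size:
        # midpoint of the largest contiguous run of empty sagittal planes
        runs = np.split(empty, np.nonzero(np.diff(empty) > 1)[0] + 1)
        widest = max(runs, key=len)
        return int(lo + (widest[0] + widest[-1]) // 2)
    xs = np.nonzero(mask)[0]
    return int(np.round(xs.mean()))


def partition_lung_regions(
    lung_mask: VoxelGrid,
    side_split_x: int | None = None,
) -> dict[tuple[str, str, str, str], VoxelGrid]:
    """Partition a two-lung mask into the 24 standard regions.

    Per lung, the z-extent is divided into three equal-thickness levels
    (upper/mid/lower); each level is sampled as two equal z sub-slabs
    (12 regions per lung) and split at that lung's mid-coronal (y)
    plane into anterior/posterior halves. Returns 24 disjoint masks
    keyed (side, level, zone, slab) whose union is the input mask.

    Parameters
    ----------
    lung_mask : mask VoxelGrid covering both lungs.
    side_split_x : voxel index of the sagittal split plane; voxels with
        x-index < split are the left lung. Estimated from the mask's
        inter-lung gap when omitted.
    """
    m = lung_mask.values.astype(bool)
    if not m.any():
        raise PartitionError("empty lung mask")
    if side_split_x is None:
        side_split_x = _split_plane_x(m)

    xs = np.arange(m.shape[0])
    sides = {"L": m & (xs < side_split_x)[:, None, None],
             "R": m & (xs >= side_split_x)[:, None, None]}
    regions: dict[tuple[str, str, str, str], VoxelGrid] = {}
    for side, sm in sides.items():
        if not sm.any():
            raise PartitionError(f"no lung voxels on side {side!r} of the split plane")
        ix, iy, iz = np.nonzero(sm)
        z_lo, z_hi = iz.min(), iz.max()
        # six equal-thickness z slabs: three levels x two sub-slabs,
        # slab 0 most inferior; level 0 = "lower"
        edges = z_lo + (z_hi - z_lo + 1) * np.arange(1, 6) / 6.0
        sixth_idx = np.searchsorted(edges, np.arange(m.shape[2]), side="right")
        level_names = ("lower", "mid", "upper")
        y_mid = (iy.min() + iy.max() + 1) / 2.0
        ys = np.arange(m.shape[1])
        zone_of_y = np.where(ys < y_mid, "posterior", "anterior")
        for si in range(6):
            level = level_names[si // 2]
            slab = str(si % 2 + 1)
            in_slab = sm & (sixth_idx == si)[None, None, :]
            for zone in ("anterior", "posterior"):
                sub = in_slab & (zone_of_y == zone)[None, :, None]
                regions[(side, level, zone, slab)] = lung_mask.with_values(
                    sub.astype(np.uint8))
    # deterministic canonical ordering
    return {k: regions[k] for k in LUNG_REGION_KEYS}


def blood_pool_suv(suv: VoxelGrid, la_mask: VoxelGrid, aorta_mask: VoxelGrid) -> float:
    """Blood-pool reference SUV_B: pooled mean over LA ∪ descending aorta.

    The two masks should be restricted to cavity centers by the caller.
    The pooled (voxel-weighted) mean over the union is used, not the mean
    of the two per-structure means.
    """
    union = la_mask.values.astype(bool) | aorta_mask.values.astype(bool)
    if not la_mask.values.any() or not aorta_mask.values.any():
        raise DomainError("blood-pool masks must both be nonempty")
    return float(suv.values[union].mean(dtype=np.float64))


def suv_air_corrected(suv_m, hu):
    """SUV_L = SUV_M / (1 + HU/1000); scalar or elementwise on arrays."""
    hu = np.asarray(hu, dtype=float)
    if np.any(hu <= -1000):
        raise DomainError("HU must be > -1000 (pure air has no bulk material)")
    out = np.asarray(suv_m, dtype=float) / (1.0 + hu / 1000.0)
    return float(out) if out.ndim == 0 else out


def suv_tissue_corrected(suv_m, hu, suv_b, blood_fraction: float = DEFAULT_BLOOD_FRACTION):
    """SUV_T = (SUV_M − f·SUV_B) / (1 + HU/1000 − f).

    Negative results are returned as computed (with a warning), never
    clipped: truncation would bias cohort means.
    """
    f = float(blood_fraction)
    if not 0 <= f < 1:
        raise DomainError(f"blood fraction must be in [0, 1), got {f}")
    hu = np.asarray(hu, dtype=float)
    denom = 1.0 + hu / 1000.0 - f
    if np.any(denom <= 0):
        raise DomainError("air + blood fractions leave no tissue (denominator <= 0)")
    out = (np.asarray(suv_m, dtype=float) - f * suv_b) / denom
    if np.any(out < 0):
        warnings.warn("negative SUV_T (measured uptake below blood contribution)",
                      stacklevel=2)
    return float(out) if out.ndim == 0 else out


def measure_lung_regions(
    suv: VoxelGrid,
    ct_hu: VoxelGrid,
    regions: dict[tuple[str, str, str, str], VoxelGrid],
    suv_b: float,
    blood_fraction: float = DEFAULT_BLOOD_FRACTION,
) -> list[LungRegionMeasure]:
    """Record mean HU and mean SUV per region and correct the means."""
    out = []
    for key, mask in regions.items():
        sel = mask.values.astype(bool)
        n = int(sel.sum())
        if n == 0:
            raise DomainError(f"lung region {key} is empty")
        mean_hu = float(ct_hu.values[sel].mean(dtype=np.float64))
        suv_m = float(suv.values[sel].mean(dtype=np.float64))
        out.append(LungRegionMeasure(
            key=key,
            mean_hu=mean_hu,
            suv_m=suv_m,
            suv_l=suv_air_corrected(suv_m, mean_hu),
            suv_t=suv_tissue_corrected(suv_m, mean_hu, suv_b, blood_fraction),
            n_voxels=n,
        ))
    return out


def lung_summary(
    measures: list[LungRegionMeasure],
    suv_b: float,
    blood_fraction: float = DEFAULT_BLOOD_FRACTION,
    exclude_lower: bool = False,
) -> LungSummary:
    """Average per-region values over the included regions.

    With ``exclude_lower`` the lower level of both lungs (8 of the 24
    regions) is dropped, the convention used to suppress scatter from
    the liver and heart.
    """
    included = [m for m in measures if not (exclude_lower and m.key[1] == "lower")]
    if not included:
        raise DomainError("no lung regions left after exclusion")
    return LungSummary(
        avg_suv_m=float(np.mean([m.suv_m for m in included])),
        avg_suv_l=float(np.mean([m.suv_l for m in included])),
        avg_suv_t=float(np.mean([m.suv_t for m in included])),
        included_regions=tuple(m.key for m in included),
        suv_b=float(suv_b),
        blood_fraction=float(blood_fraction),
    )
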