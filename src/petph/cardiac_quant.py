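"""ED/ES extraction, RV cavity segmentation, volumes/EF and wall SUV.

The gated convention is fixed: frame 1 begins at the R wave, so frames
{1, 8} straddle end diastole and frames {4, 5} end systole. The two
frames are combined by MEAN by default so the SUV calibration of the
combined image is preserved (a raw-sum mode exists for count-space
data, where summing doubles the counts but not the concentration).

The manual cavity contouring step of the clinical workflow is replaced
by deterministic seeded region growing: the cavity is the connected
low-uptake component around the seed, bounded by the hot myocardial
wall, with the threshold referenced to the local wall maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_io import GatedPetSeries, VoxelGrid
from .errors import (ContourabilityError, DomainError, RegionLeakError,
                     SeedAboveThresholdError)

__all__ = [
    "CardiacMeasure",
    "ED_FRAMES",
    "ES_FRAMES",
    "extract_ed_es",
    "segment_rv_cavity",
    "cavity_volume",
    "ejection_metrics",
    "wall_max_suv",
    "rv_lv_ratio",
]

# 1-based gated frame numbers; fixed constants of the pipeline, not
# inferred from the volume curve.
ED_FRAMES = (1, 8)
ES_FRAMES = (4, 5)


@dataclass
class CardiacMeasure:
    """RV volumes/EF plus wall max SUVs and the RV/LV uptake ratio."""

    edv: float  # mL
    esv: float  # mL
    ef: float   # percent
    sv: float   # mL
    max_suv: dict[str, float] = field(default_factory=dict)
    rv_lv_ratio: float = float("nan")
    contourable: bool = True


def _combine(frames: list[VoxelGrid], numbers: tuple[int, ...],
             sum_mode: bool) -> VoxelGrid:
    stack = np.stack([frames[i - 1].values for i in numbers])
    vals = stack.sum(axis=0) if sum_mode else stack.mean(axis=0)
    return frames[0].with_values(vals)


def extract_ed_es(gated: GatedPetSeries, sum_mode: bool = False
                  ) -> tuple[VoxelGrid, VoxelGrid]:
    """Combine frames {1,8} into the ED image and {4,5} into the ES image."""
    if len(gated.frames) != 8:
        raise DomainError("gated series must have exactly 8 frames")
    ed = _combine(gated.frames, ED_FRAMES, sum_mode)
    es = _combine(gated.frames, ES_FRAMES, sum_mode)
    return ed, es


# face-connected (6-connectivity) structuring element
_STRUCT = ndimage.generate_binary_structure(3, 1)


def segment_rv_cavity(
    image: VoxelGrid,
    seed_point: tuple[int, int, int],
    threshold_fraction: float = 0.5,
    box_halfwidth_mm: tuple[float, float, float] = (60.0, 60.0, 70.0),
) -> VoxelGrid:
    """Grow the RV cavity from a seed inside the blood pool.

    The analysis box is centred on the seed with the given half-widths
    (clipped to the grid). The wall reference is the maximum image value
    in the box; voxels below ``threshold_fraction`` times that reference
    are cavity candidates, and the face-connected component containing
    the seed is returned as a full-grid mask.

    Raises
    ------
    SeedAboveThresholdError
        if the seed voxel is not below the threshold (e.g. wall uptake
        indistinguishable from cavity uptake — nothing to contour).
    RegionLeakError
        if the grown component touches the analysis box: the wall does
        not enclose the cavity, mirroring the non-contourable scans.
    """
    if not 0 < threshold_fraction < 1:
        raise DomainError(f"threshold fraction must be in (0,1), got {threshold_fraction}")
    seed = tuple(int(i) for i in seed_point)
    shape = image.shape
    if any(not 0 <= seed[a] < shape[a] for a in range(3)):
        raise DomainError(f"seed {seed} outside grid {shape}")

    half = [max(1, int(round(box_halfwidth_mm[a] / image.spacing[a]))) for a in range(3)]
    lo = [max(0, seed[a] - half[a]) for a in range(3)]
    hi = [min(shape[a], seed[a] + half[a] + 1) for a in range(3)]
    box = tuple(slice(lo[a], hi[a]) for a in range(3))
    sub = image.values[box]

    wall_ref = float(sub.max())
    thr = threshold_fraction * wall_ref
    seed_in_box = tuple(seed[a] - lo[a] for a in range(3))
    if not image.values[seed] < thr:
        raise SeedAboveThresholdError(
            f"seed value {image.values[seed]:.3g} is not below threshold {thr:.3g}; "
            "no cavity/wall contrast to contour")

    labels, _ = ndimage.label(sub < thr, structure=_STRUCT)
    comp = labels == labels[seed_in_box]
    # a component reaching a box face that is not a grid face means the
    # low-uptake region escapes the wall: not contourable
    for a in range(3):
        first = np.take(comp, 0, axis=a)
        last = np.take(comp, comp.shape[a] - 1, axis=a)
        if (first.any() and lo[a] > 0) or (last.any() and hi[a] < shape[a]):
            raise RegionLeakError(
                "cavity region leaked to the analysis-box boundary; "
                "myocardial wall does not enclose the cavity")
    mask = np.zeros(shape, dtype=np.uint8)
    mask[box] = comp.astype(np.uint8)
    return image.with_values(mask)


def cavity_volume(mask: VoxelGrid) -> float:
    """Mask volume in mL (voxel count × voxel volume in mm³ / 1000)."""
    return float(mask.values.astype(bool).sum()) * mask.voxel_volume_mm3 / 1000.0


def ejection_metrics(edv: float, esv: float) -> tuple[float, float]:
    """Ejection fraction (percent) and stroke volume (mL) from EDV/ESV."""
    if not edv > 0:
        raise DomainError(f"EDV must be > 0 mL, got {edv}")
    if not 0 <= esv <= edv:
        raise DomainError(f"require 0 <= ESV <= EDV, got ESV={esv}, EDV={edv}")
    sv = edv - esv
    return 100.0 * sv / edv, sv


def wall_max_suv(suv: VoxelGrid, roi: VoxelGrid) -> float:
    """Maximum SUV within a wall ROI."""
    sel = roi.values.astype(bool)
    if not sel.any():
        raise DomainError("empty wall ROI")
    return float(suv.values[sel].max())


def rv_lv_ratio(rv_max: float, lv_max: float) -> float:
    """RV free wall max SUV over LV free wall max SUV."""
    if not lv_max > 0:
        raise DomainError(f"LV max SUV must be > 0, got {lv_max}")
    return rv_max / lv_max


def measure_cardiac(
    suv_static: VoxelGrid,
    ed_image: VoxelGrid,
    es_image: VoxelGrid,
    walls: dict[str, VoxelGrid],
    seed_ed: tuple[int, int, int],
    seed_es: tuple[int, int, int] | None = None,
    threshold_fraction: float = 0.5,
    box_halfwidth_mm: tuple[float, float, float] = (60.0, 60.0, 70.0),
) -> CardiacMeasure:
    """Full cardiac read-out for one subject.

    Wall max SUVs are taken on the static (ungated) SUV image; cavity
    volumes on the combined ED/ES images. A contourability failure is
    reported via ``contourable=False`` with NaN volumes, mirroring the
    scans on which no contour could be drawn.
    """
    max_suv = {name: wall_max_suv(suv_static, roi) for name, roi in walls.items()}
    ratio = rv_lv_ratio(max_suv["rv_wall"], max_suv["lv_wall"]) \
        if {"rv_wall", "lv_wall"} <= max_suv.keys() else float("nan")
    try:
        ed_mask = segment_rv_cavity(ed_image, seed_ed, threshold_fraction,
                                    box_halfwidth_mm)
        es_mask = segment_rv_cavity(es_image, seed_es or seed_ed,
                                    threshold_fraction, box_halfwidth_mm)
    except ContourabilityError:
        nan = float("nan")
        return CardiacMeasure(edv=nan, esv=nan, ef=nan, sv=nan,
                              max_suv=max_suv, rv_lv_ratio=ratio,
                              contourable=False)
    edv = cavity_volume(ed_mask)
    esv = cavity_volume(es_mask)
    ef, sv = ejection_metrics(edv, min(esv, edv))
    return CardiacMeasure(edv=edv, esv=esv, ef=ef, sv=sv, max_suv=max_suv,
                          rv_lv_ratio=ratio, contourable=True)
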