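"""Volume data model, NIfTI I/O and SUV conversion.

Conventions (fixed throughout the package):

* axis order is (x, y, z) with x running patient-left to patient-right,
  y posterior to anterior and z inferior to superior;
* voxel indices are 0-based and refer to voxel centers;
* the physical coordinate of voxel ``i`` along an axis is
  ``origin + i * spacing`` (mm).

Activity volumes are decay-corrected scanner output in kBq/mL; no decay
correction is applied anywhere in this package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
import nibabel as nib
import numpy as np

from .errors import DomainError, FormatError

__all__ = [
    "VoxelGrid",
    "GatedPetSeries",
    "RoiSet",
    "Group",
    "SubjectRecord",
    "read_volume",
    "write_volume",
    "read_gated_series",
    "write_gated_series",
    "to_suv",
]

N_GATED_FRAMES = 8


@dataclass(eq=False)
class VoxelGrid:
    """A scalar field on a regular 3-D lattice.

    ``values`` may hold activity (kBq/mL), HU, SUV or a {0,1} mask;
    ``spacing`` and ``origin`` are in mm per the package axis convention.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise FormatError(f"VoxelGrid requires a 3-D array, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        if len(self.origin) != 3:
            raise FormatError("origin must have 3 components")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coordinates(self, axis: int) -> np.ndarray:
        """Physical voxel-center coordinates (mm) along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def with_values(self, values: np.ndarray) -> "VoxelGrid":
        """Same geometry, new scalar field."""
        return VoxelGrid(values, self.spacing, self.origin)

    def same_geometry(self, other: "VoxelGrid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def is_mask(self) -> bool:
        v = self.values
        return bool(np.isin(np.unique(v), (0, 1)).all())


def _require_mask(grid: VoxelGrid, name: str) -> None:
    if not grid.is_mask():
        raise FormatError(f"{name} is not a {{0,1}} mask")


@dataclass(eq=False)
class GatedPetSeries:
    """An 8-frame ECG-gated activity series with injection metadata.

    Frame 1 begins at the R wave (end diastole). Activity is in kBq/mL,
    dose in MBq, weight in kg, uptake time in minutes.
    """

    frames: list[VoxelGrid]
    injected_dose_mbq: float
    body_weight_kg: float
    uptake_time_min: float = 90.0

    def __post_init__(self) -> None:
        if len(self.frames) != N_GATED_FRAMES:
            raise DomainError(f"gated series requires exactly {N_GATED_FRAMES} frames, "
                              f"got {len(self.frames)}")
        ref = self.frames[0]
        for i, f in enumerate(self.frames[1:], start=2):
            if not ref.same_geometry(f):
                raise FormatError(f"frame {i} geometry differs from frame 1")
        for name, v in (("injected_dose_mbq", self.injected_dose_mbq),
                        ("body_weight_kg", self.body_weight_kg),
                        ("uptake_time_min", self.uptake_time_min)):
            if not v > 0:
                raise DomainError(f"{name} must be > 0, got {v}")


LUNG_SIDES = ("L", "R")
LUNG_LEVELS = ("upper", "mid", "lower")
LUNG_ZONES = ("anterior", "posterior")
LUNG_SLABS = ("1", "2")  # two sampled sub-slabs per level, 12 regions per lung
LUNG_REGION_KEYS = tuple(
    (s, lv, z, sl) for s in LUNG_SIDES for lv in LUNG_LEVELS
    for z in LUNG_ZONES for sl in LUNG_SLABS
)
WALL_NAMES = ("rv_wall", "lv_wall", "septum", "ra_wall")


@dataclass(eq=False)
class RoiSet:
    """Labelled masks for one subject, all on the same grid.

    ``lung_regions`` holds the 24 standard regions (12 per lung) keyed
    by (side, level, zone, slab); ``blood_pool`` the LA cavity and
    descending thoracic aorta; ``walls`` the four chamber-wall regions.
    """

    lung_regions: dict[tuple[str, str, str, str], VoxelGrid] = field(default_factory=dict)
    blood_pool: dict[str, VoxelGrid] = field(default_factory=dict)
    walls: dict[str, VoxelGrid] = field(default_factory=dict)
    rv_cavity_ed: VoxelGrid | None = None
    rv_cavity_es: VoxelGrid | None = None

    def validate(self) -> None:
        """Check mask-ness, shared geometry and lung-region disjointness."""
        all_masks: list[tuple[str, VoxelGrid]] = []
        all_masks += [("/".join(k), m) for k, m in self.lung_regions.items()]
        all_masks += list(self.blood_pool.items())
        all_masks += list(self.walls.items())
        if self.rv_cavity_ed is not None:
            all_masks.append(("rv_cavity_ed", self.rv_cavity_ed))
        if self.rv_cavity_es is not None:
            all_masks.append(("rv_cavity_es", self.rv_cavity_es))
        if not all_masks:
            return
        ref = all_masks[0][1]
        for name, m in all_masks:
            _require_mask(m, name)
            if not ref.same_geometry(m):
                raise FormatError(f"mask {name} not on the subject grid")
        if self.lung_regions:
            if len(self.lung_regions) != 24:
                raise FormatError(
                    f"lung_regions must have exactly 24 entries, got {len(self.lung_regions)}")
            stack = np.sum([m.values.astype(np.int64) for m in self.lung_regions.values()],
                           axis=0)
            if stack.max(initial=0) > 1:
                raise FormatError("lung regions overlap")


class Group(str, Enum):
    """Study group labels."""

    control = "control"
    idiopathic = "idiopathic"
    hereditary = "hereditary"
    other_PH = "other_PH"

    @property
    def is_ph(self) -> bool:
        return self is not Group.control


@dataclass
class SubjectRecord:
    """One subject: group label plus imaging, echo and clinical measures.

    Missing values are ``float('nan')`` and are propagated (dropped
    pairwise by the statistics layer), never silently zeroed.
    """

    id: str
    group: Group
    imaging: dict[str, float] = field(default_factory=dict)
    echo_inputs: "object | None" = None   # echo.EchoInputs
    echo_derived: "object | None" = None  # echo.EchoDerived
    clinical: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        for name, v in self.clinical.items():
            if np.isfinite(v) and v < 0 and name not in ("hr_recovery", "strain"):
                raise DomainError(f"clinical measure {name} must be nonnegative, got {v}")


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def read_volume(path: str | Path) -> VoxelGrid:
    """Read a single 3-D volume from a NIfTI file.

    Rejects missing files, non-3-D payloads and non-positive spacing.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises various types
        raise FormatError(f"cannot read {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got ndim={data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise FormatError(f"{path}: non-positive voxel spacing {spacing}")
    origin = tuple(float(o) for o in img.affine[:3, 3])
    return VoxelGrid(data, spacing, origin)


def write_volume(grid: VoxelGrid, path: str | Path) -> None:
    """Write a VoxelGrid to NIfTI, preserving values and geometry."""
    img = nib.Nifti1Image(np.asarray(grid.values), _affine(grid.spacing, grid.origin))
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


def write_gated_series(series: GatedPetSeries, out_dir: str | Path,
                       stem: str = "frame") -> None:
    """Write 8 single-frame NIfTI files plus a JSON metadata sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(series.frames, start=1):
        write_volume(frame, out_dir / f"{stem}_{i}.nii.gz")
    meta = {
        "injected_dose_mbq": series.injected_dose_mbq,
        "body_weight_kg": series.body_weight_kg,
        "uptake_time_min": series.uptake_time_min,
    }
    (out_dir / f"{stem}_meta.json").write_text(json.dumps(meta, indent=2))


def read_gated_series(src: str | Path, stem: str = "frame") -> GatedPetSeries:
    """Read a gated series from ``frame_1..frame_8`` files or one 4-D file.

    ``src`` is either a directory containing ``{stem}_1..8.nii.gz`` and
    ``{stem}_meta.json``, or a 4-D NIfTI path with a sibling
    ``<name>_meta.json``.
    """
    src = Path(src)
    if src.is_dir():
        meta = json.loads((src / f"{stem}_meta.json").read_text())
        frames = []
        for i in range(1, N_GATED_FRAMES + 1):
            for suffix in (".nii.gz", ".nii"):
                p = src / f"{stem}_{i}{suffix}"
                if p.exists():
                    frames.append(read_volume(p))
                    break
            else:
                raise FormatError(f"missing gated frame {i} in {src}")
    else:
        if not src.exists():
            raise FormatError(f"no such file: {src}")
        img = nib.load(str(src))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 4 or data.shape[3] != N_GATED_FRAMES:
            raise FormatError(f"{src}: expected a 4-D series with {N_GATED_FRAMES} frames")
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(o) for o in img.affine[:3, 3])
        frames = [VoxelGrid(data[..., i], spacing, origin) for i in range(N_GATED_FRAMES)]
        meta_path = src.with_name(src.name.split(".")[0] + "_meta.json")
        meta = json.loads(meta_path.read_text())
    return GatedPetSeries(frames, meta["injected_dose_mbq"], meta["body_weight_kg"],
                          meta.get("uptake_time_min", 90.0))


# ---------------------------------------------------------------------------
# SUV conversion


def to_suv(activity: VoxelGrid, dose_mbq: float, weight_kg: float) -> VoxelGrid:
    """Convert activity concentration to body-weight SUV.

    SUV = C [kBq/mL] / (dose [MBq→kBq] / weight [kg→g]), i.e.
    ``C * weight_kg / dose_mbq`` after unit cancellation, so a uniform
    distribution of the full dose over a water-density body of that weight
    gives SUV 1. Input must already be decay-corrected; no decay
    correction is applied here.
    """
    if not dose_mbq > 0:
        raise DomainError(f"injected dose must be > 0 MBq, got {dose_mbq}")
    if not weight_kg > 0:
        raise DomainError(f"body weight must be > 0 kg, got {weight_kg}")
    return activity.with_values(activity.values * (weight_kg / dose_mbq))


def suv_to_activity(suv: float | np.ndarray, dose_mbq: float,
                    weight_kg: float) -> float | np.ndarray:
    """Inverse of :func:`to_suv` on raw values (kBq/mL)."""
    if not dose_mbq > 0 or not weight_kg > 0:
        raise DomainError("dose and weight must be > 0")
    return suv * (dose_mbq / weight_kg)
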