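"""Synthetic beating-thorax phantom and cohort generator.

The imaging phantom is deliberately schematic — ellipsoidal chamber
shells, ellipsoidal lungs, a cylindrical descending aorta — so that
every ground truth is analytic: the RV cavity is an ellipsoid whose
volume follows a known gated cycle curve, lung voxels mix air, blood
and tissue with known fractions, and CT numbers follow the linear
air/soft-tissue mixing rule. Downstream quantification can therefore be
checked against exact truths rather than against another image pipeline.

The cohort generator draws per-subject measures from configurable
marginals through a Gaussian copula whose latent correlation is chosen
so that the *rank* correlations converge to the requested values
(rho_latent = 2·sin(pi·rho_s/6)). Echo inputs are produced by inverting
the derived-quantity formulas from latent draws, so the derivation
round-trips exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import ndtr

from . import lung_quant
from .core_io import (GatedPetSeries, Group, RoiSet, SubjectRecord, VoxelGrid,
                      suv_to_activity)
from .echo import EchoInputs, derive_echo
from .errors import SpecError

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "Marginal",
    "CohortSpec",
    "default_cycle_curve",
    "make_thorax",
    "make_cohort",
    "default_cohort_spec",
]

# --------------------------------------------------------------------------
# imaging phantom

DEFAULT_UPTAKE = {
    # SUV-scale tracer uptake per compartment
    "lv_wall": 3.0,
    "rv_wall": 4.2,       # RV/LV wall ratio 1.4, a pressure-overloaded RV
    "septum": 3.0,
    "ra_wall": 2.0,
    "blood": 1.0,
    "lung_tissue": 2.0,   # PH-like lung tissue uptake
    "soft": 0.6,
}

# paint-order labels; later paints win
_AIR, _BODY, _LUNG_L, _LUNG_R, _AORTA, _LA, _RA_WALL, _LV_WALL, _RV_WALL, \
    _SEPTUM, _LV_CAV, _RV_CAV = range(12)


def default_cycle_curve(edv: float, esv: float) -> tuple[float, ...]:
    """Cosine-like RV volume-fraction curve over the 8 gated frames.

    Normalised so frames 1 and 8 are exactly at EDV (fraction 1) and
    frames 4 and 5 exactly at ESV, matching the ED/ES summation rule.
    """
    vmin = esv / edv
    i = np.arange(1, 9)
    u = (1.0 - np.cos(2.0 * np.pi * (i - 4.5) / 8.0)) / 2.0
    t = (u - u[3]) / (u[0] - u[3])
    return tuple(float(v) for v in vmin + (1.0 - vmin) * t)


@dataclass
class PhantomSpec:
    """Geometry, uptake and acquisition parameters of the digital thorax.

    Lengths in mm, volumes in mL, uptake in SUV units; ``noise_sigma``
    is the SD of additive Gaussian noise in SUV units (converted to
    kBq/mL internally). Coordinates are patient-centred: x left→right,
    y posterior→anterior, z inferior→superior.
    """

    shape: tuple[int, int, int] = (116, 92, 100)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    include_lungs: bool = True

    true_rv_edv: float = 120.0
    true_rv_esv: float = 78.0
    cycle_curve: tuple[float, ...] | None = None
    rv_center: tuple[float, float, float] = (20.0, 4.0, -8.0)
    rv_axis_ratio: tuple[float, float, float] = (1.0, 1.3, 2.0)
    rv_wall_thickness: float = 6.0

    lv_center: tuple[float, float, float] = (-22.0, 0.0, -8.0)
    lv_cavity_semiaxes: tuple[float, float, float] = (14.0, 20.0, 32.0)
    lv_wall_thickness: float = 7.0
    septum_band_x: tuple[float, float] = (-8.0, -2.0)

    ra_center: tuple[float, float, float] = (30.0, -34.0, -60.0)
    ra_radius: float = 15.0
    ra_wall_thickness: float = 5.0
    la_center: tuple[float, float, float] = (-22.0, -42.0, -8.0)
    la_semiaxes: tuple[float, float, float] = (12.0, 12.0, 14.0)
    aorta_center_xy: tuple[float, float] = (-6.0, -52.0)
    aorta_radius: float = 9.0
    body_semiaxes_xy: tuple[float, float] = (110.0, 85.0)
    lung_center_abs_x: float = 78.0
    lung_center_yz: tuple[float, float] = (5.0, 0.0)
    lung_semiaxes: tuple[float, float, float] = (28.0, 48.0, 75.0)

    uptake: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_UPTAKE))
    air_fraction: float = 0.70
    blood_fraction: float = 0.16
    hu_air: float = -1000.0
    hu_soft: float = 0.0

    injected_dose_mbq: float = 370.0
    body_weight_kg: float = 74.0
    uptake_time_min: float = 90.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.air_fraction + self.blood_fraction <= 1:
            raise SpecError("air_fraction + blood_fraction must be in [0, 1]")
        if not self.true_rv_esv < self.true_rv_edv:
            raise SpecError("require ESV < EDV")
        if self.cycle_curve is None:
            self.cycle_curve = default_cycle_curve(self.true_rv_edv, self.true_rv_esv)
        cc = tuple(float(v) for v in self.cycle_curve)
        if len(cc) != 8:
            raise SpecError("cycle_curve must have 8 entries")
        if int(np.argmax(cc)) not in (0, 7) or int(np.argmin(cc)) not in (3, 4):
            raise SpecError("cycle curve must peak at frame 1 or 8 and "
                            "bottom at frame 4 or 5")
        self.cycle_curve = cc

    @classmethod
    def cardiac(cls, spacing: float = 2.0, true_rv_edv: float = 120.0,
                true_rv_esv: float = 78.0, noise_sigma: float = 0.0,
                seed: int = 0, **kw) -> "PhantomSpec":
        """A compact heart-only phantom for volume/EF recovery studies."""
        extent = (116.0, 96.0, 124.0)  # mm, covers the heart with margin
        shape = tuple(int(round(e / spacing)) for e in extent)
        return cls(shape=shape, spacing=(spacing,) * 3, include_lungs=False,
                   true_rv_edv=true_rv_edv, true_rv_esv=true_rv_esv,
                   noise_sigma=noise_sigma, seed=seed, **kw)

    def rv_cavity_semiaxes(self, volume_fraction: float = 1.0
                           ) -> tuple[float, float, float]:
        """ED-referenced cavity semi-axes scaled to a cycle volume fraction."""
        rx, ry, rz = self.rv_axis_ratio
        base = (3.0 * self.true_rv_edv * 1000.0 / (4.0 * math.pi * rx * ry * rz)) ** (1 / 3)
        s = volume_fraction ** (1 / 3)
        return (base * rx * s, base * ry * s, base * rz * s)


@dataclass
class PhantomTruth:
    """Generator ground truth used as the acceptance oracle."""

    edv: float
    esv: float
    ef: float  # percent
    sv: float
    uptake: dict[str, float]
    lung_suv_m: float
    mean_lung_hu: float
    air_fraction: float
    blood_fraction: float
    rois: RoiSet
    lung_mask: VoxelGrid | None
    seed: int


def _grid_coords(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = []
    for n, s in zip(spec.shape, spec.spacing):
        axes.append((np.arange(n) - (n - 1) / 2.0) * s)
    return tuple(axes)  # type: ignore[return-value]


def _origin(spec: PhantomSpec) -> tuple[float, float, float]:
    return tuple(-(n - 1) / 2.0 * s for n, s in zip(spec.shape, spec.spacing))


def _paint_ellipsoid(label: np.ndarray, coords, center, semiaxes, value: int,
                     band_x=None, invert_band: bool = False) -> None:
    """Paint an ellipsoid (optionally restricted to an x-band) onto labels."""
    xs, ys, zs = coords
    d = ((xs[:, None, None] - center[0]) / semiaxes[0]) ** 2 \
        + ((ys[None, :, None] - center[1]) / semiaxes[1]) ** 2 \
        + ((zs[None, None, :] - center[2]) / semiaxes[2]) ** 2
    inside = d <= 1.0
    if band_x is not None:
        in_band = (xs >= band_x[0]) & (xs <= band_x[1])
        sel = in_band[:, None, None] if not invert_band else ~in_band[:, None, None]
        inside &= sel
    label[inside] = value


def _check_fits(spec: PhantomSpec, center, semiaxes, name: str) -> None:
    for a in range(3):
        half = spec.shape[a] * spec.spacing[a] / 2.0
        if abs(center[a]) + semiaxes[a] > half + 1e-9:
            raise SpecError(f"{name} exceeds the grid along axis {a} "
                            f"(|{center[a]}| + {semiaxes[a]} > {half})")


def _static_labels(spec: PhantomSpec, coords) -> np.ndarray:
    xs, ys, zs = coords
    label = np.full(spec.shape, _AIR, dtype=np.uint8)
    bx, by = spec.body_semiaxes_xy
    body = ((xs[:, None] / bx) ** 2 + (ys[None, :] / by) ** 2) <= 1.0
    label[body[:, :, None] & np.ones(len(zs), bool)[None, None, :]] = _BODY
    if spec.include_lungs:
        cy, cz = spec.lung_center_yz
        for sign, lab in ((-1, _LUNG_L), (+1, _LUNG_R)):
            c = (sign * spec.lung_center_abs_x, cy, cz)
            _check_fits(spec, c, spec.lung_semiaxes, "lung")
            _paint_ellipsoid(label, coords, c, spec.lung_semiaxes, lab)
        ax, ay = spec.aorta_center_xy
        aorta = (((xs[:, None] - ax) / spec.aorta_radius) ** 2
                 + ((ys[None, :] - ay) / spec.aorta_radius) ** 2) <= 1.0
        zspan = np.abs(zs) <= 0.95 * spec.shape[2] * spec.spacing[2] / 2.0
        label[aorta[:, :, None] & zspan[None, None, :]] = _AORTA
        _paint_ellipsoid(label, coords, spec.la_center, spec.la_semiaxes, _LA)
    ra_outer = spec.ra_radius + spec.ra_wall_thickness
    _paint_ellipsoid(label, coords, spec.ra_center, (ra_outer,) * 3, _RA_WALL)
    _paint_ellipsoid(label, coords, spec.ra_center, (spec.ra_radius,) * 3, _BODY)
    return label


def _heart_labels(spec: PhantomSpec, coords, base: np.ndarray,
                  volume_fraction: float) -> np.ndarray:
    """Paint LV/RV walls, septum and cavities for one cycle phase."""
    label = base.copy()
    lv_out = tuple(s + spec.lv_wall_thickness for s in spec.lv_cavity_semiaxes)
    rv_cav = spec.rv_cavity_semiaxes(volume_fraction)
    rv_out = tuple(s + spec.rv_wall_thickness for s in rv_cav)
    _check_fits(spec, spec.lv_center, lv_out, "LV")
    _check_fits(spec, spec.rv_center, rv_out, "RV")
    _paint_ellipsoid(label, coords, spec.lv_center, lv_out, _LV_WALL)
    _paint_ellipsoid(label, coords, spec.rv_center, rv_out, _RV_WALL)
    # septum: the band of heart wall between the two cavities
    for c, s in ((spec.lv_center, lv_out), (spec.rv_center, rv_out)):
        _paint_ellipsoid(label, coords, c, s, _SEPTUM, band_x=spec.septum_band_x)
    _paint_ellipsoid(label, coords, spec.lv_center, spec.lv_cavity_semiaxes, _LV_CAV)
    _paint_ellipsoid(label, coords, spec.rv_center, rv_cav, _RV_CAV)
    return label


def _suv_of_labels(spec: PhantomSpec) -> np.ndarray:
    u = spec.uptake
    tissue_fraction = 1.0 - spec.air_fraction - spec.blood_fraction
    lung_suv = (spec.blood_fraction * u["blood"]
                + tissue_fraction * u["lung_tissue"])
    table = np.zeros(12)
    table[_AIR] = 0.0
    table[_BODY] = u["soft"]
    table[_LUNG_L] = table[_LUNG_R] = lung_suv
    table[_AORTA] = table[_LA] = table[_LV_CAV] = table[_RV_CAV] = u["blood"]
    table[_RA_WALL] = u["ra_wall"]
    table[_LV_WALL] = u["lv_wall"]
    table[_RV_WALL] = u["rv_wall"]
    table[_SEPTUM] = u["septum"]
    return table


def make_thorax(spec: PhantomSpec
                ) -> tuple[GatedPetSeries, VoxelGrid, PhantomTruth]:
    """Generate the gated activity series, the CT HU volume and the truth.

    Lung activity mixes the compartments linearly (air contributes
    nothing); lung HU is ``air_fraction·HU_air + (1−air_fraction)·HU_soft``.
    Noise is i.i.d. additive Gaussian with the spec's seed; rerunning
    with an identical spec is bit-identical.
    """
    coords = _grid_coords(spec)
    origin = _origin(spec)
    static = _static_labels(spec, coords)
    suv_table = _suv_of_labels(spec)
    rng = np.random.default_rng(spec.seed)
    sigma_act = suv_to_activity(spec.noise_sigma, spec.injected_dose_mbq,
                                spec.body_weight_kg) if spec.noise_sigma else 0.0

    frames: list[VoxelGrid] = []
    label_ed = label_es = None
    for fnum, frac in enumerate(spec.cycle_curve, start=1):
        label = _heart_labels(spec, coords, static, frac)
        if fnum == 1:
            label_ed = label
        if fnum == 4:
            label_es = label
        act = suv_to_activity(suv_table[label], spec.injected_dose_mbq,
                              spec.body_weight_kg).astype(np.float32)
        if sigma_act:
            act = act + rng.normal(0.0, sigma_act, size=act.shape).astype(np.float32)
        frames.append(VoxelGrid(act, spec.spacing, origin))

    hu = np.full(spec.shape, spec.hu_air, dtype=np.float32)
    hu[static != _AIR] = spec.hu_soft
    lung_sel = (static == _LUNG_L) | (static == _LUNG_R)
    lung_hu = spec.air_fraction * spec.hu_air + (1 - spec.air_fraction) * spec.hu_soft
    hu[lung_sel] = lung_hu
    ct = VoxelGrid(hu, spec.spacing, origin)

    assert label_ed is not None and label_es is not None
    rois = RoiSet(
        blood_pool=({"la": ct.with_values((static == _LA).astype(np.uint8)),
                     "aorta": ct.with_values((static == _AORTA).astype(np.uint8))}
                    if spec.include_lungs else {}),
        walls={
            "lv_wall": ct.with_values((label_ed == _LV_WALL).astype(np.uint8)),
            "rv_wall": ct.with_values((label_ed == _RV_WALL).astype(np.uint8)),
            "septum": ct.with_values((label_ed == _SEPTUM).astype(np.uint8)),
            "ra_wall": ct.with_values((label_ed == _RA_WALL).astype(np.uint8)),
        },
        rv_cavity_ed=ct.with_values((label_ed == _RV_CAV).astype(np.uint8)),
        rv_cavity_es=ct.with_values((label_es == _RV_CAV).astype(np.uint8)),
    )
    lung_mask = None
    if spec.include_lungs:
        lung_mask = ct.with_values(lung_sel.astype(np.uint8))
        rois.lung_regions = lung_quant.partition_lung_regions(lung_mask)
    rois.validate()

    tissue_fraction = 1.0 - spec.air_fraction - spec.blood_fraction
    truth = PhantomTruth(
        edv=spec.true_rv_edv, esv=spec.true_rv_esv,
        ef=100.0 * (spec.true_rv_edv - spec.true_rv_esv) / spec.true_rv_edv,
        sv=spec.true_rv_edv - spec.true_rv_esv,
        uptake=dict(spec.uptake),
        lung_suv_m=spec.blood_fraction * spec.uptake["blood"]
                   + tissue_fraction * spec.uptake["lung_tissue"],
        mean_lung_hu=lung_hu,
        air_fraction=spec.air_fraction, blood_fraction=spec.blood_fraction,
        rois=rois, lung_mask=lung_mask, seed=spec.seed,
    )
    series = GatedPetSeries(frames, spec.injected_dose_mbq,
                            spec.body_weight_kg, spec.uptake_time_min)
    return series, ct, truth


# --------------------------------------------------------------------------
# cohort generator


@dataclass(frozen=True)
class Marginal:
    """A marginal distribution given by its mean and SD.

    ``family`` is ``normal`` or ``lognormal``; for the lognormal the
    (mean, sd) are the distribution's own moments, from which the
    underlying log-scale parameters are solved.
    """

    mean: float
    sd: float
    family: str = "normal"
    lo: float | None = None  # optional truncation bounds (clipped, documented)
    hi: float | None = None

    def ppf(self, u: np.ndarray) -> np.ndarray:
        if self.family == "normal":
            x = sps.norm.ppf(u, loc=self.mean, scale=self.sd)
        elif self.family == "lognormal":
            s2 = math.log1p((self.sd / self.mean) ** 2)
            mu = math.log(self.mean) - s2 / 2.0
            x = sps.lognorm.ppf(u, s=math.sqrt(s2), scale=math.exp(mu))
        else:
            raise SpecError(f"unknown marginal family {self.family!r}")
        if self.lo is not None or self.hi is not None:
            x = np.clip(x, self.lo, self.hi)
        return x


# canonical measure order for the correlation matrix
COHORT_MEASURES = (
    "lung_suv_m", "lung_suv_l", "lung_suv_t", "rv_lv_ratio",
    "rved_volume", "rvef",
    "rap", "rvsp", "rved_area", "fractional_shortening",
    "rved_diam", "rves_diam", "tapse", "s_prime",
    "tei_index", "rv_ejection_time", "rvot_tvi",
    "ra_volume", "rv_thickness", "strain",
    "hr_end", "hr_recovery",
    "nt_probnp", "six_mwd", "camphor",
)


@dataclass
class CohortSpec:
    """Group sizes, per-group marginals and a shared rank-correlation matrix."""

    group_sizes: dict[Group, int]
    marginals: dict[Group, dict[str, Marginal]]
    rank_corr: pd.DataFrame  # symmetric, unit diagonal, over COHORT_MEASURES
    n_missing_strain: int = 2  # PH subjects without a strain read-out
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 2:
                raise SpecError(f"group {g} must have >= 2 subjects, got {n}")
        R = self.rank_corr.loc[list(COHORT_MEASURES), list(COHORT_MEASURES)].to_numpy()
        if not np.allclose(R, R.T):
            raise SpecError("rank-correlation matrix must be symmetric")
        if not np.allclose(np.diag(R), 1.0):
            raise SpecError("rank-correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-8:
            raise SpecError("rank-correlation matrix is not positive semidefinite")


def _corr_frame(pairs: dict[tuple[str, str], float]) -> pd.DataFrame:
    R = pd.DataFrame(np.eye(len(COHORT_MEASURES)),
                     index=COHORT_MEASURES, columns=COHORT_MEASURES)
    for (a, b), rho in pairs.items():
        R.loc[a, b] = R.loc[b, a] = rho
    return R


DEFAULT_RANK_CORR_PAIRS = {
    ("lung_suv_m", "lung_suv_l"): 0.8,
    ("lung_suv_l", "lung_suv_t"): 0.8,
    ("lung_suv_m", "lung_suv_t"): 0.7,
    ("rved_volume", "rvef"): -0.4,
    ("rved_volume", "rved_area"): 0.6,
    ("rved_volume", "rved_diam"): 0.5,
    ("rved_area", "rved_diam"): 0.5,
    ("rved_area", "rves_diam"): 0.35,
    ("rved_volume", "rves_diam"): 0.35,
    ("rvef", "rves_diam"): -0.3,
    ("rved_diam", "rves_diam"): 0.7,
    ("rv_lv_ratio", "rvsp"): 0.6,
    ("rv_lv_ratio", "nt_probnp"): 0.6,
    ("rvsp", "nt_probnp"): 0.5,
    ("rvef", "fractional_shortening"): 0.5,
}


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """Defaults anchored to the study's printed group summaries.

    Where a printed value exists (lung SUV_M, subgroup SUV_T, subgroup
    RV/LV ratios, group sizes) it is used exactly; remaining measures
    use plausible clinical values for a PH cohort vs. healthy controls.
    """
    N = Marginal  # noqa: N806 - local alias for brevity

    def ph(idio: "Marginal", hered: "Marginal", other: "Marginal"):
        return {Group.idiopathic: idio, Group.hereditary: hered,
                Group.other_PH: other}

    common_ph = {
        "lung_suv_m": N(0.50, 0.15, lo=0.05),
        "lung_suv_l": N(1.67, 0.50, lo=0.1),
        "rved_volume": N(170.0, 60.0, lo=40.0),
        "rvef": N(35.0, 10.0, lo=5.0, hi=80.0),
        "rap": N(9.0, 4.0, lo=1.0),
        "rvsp": N(75.0, 25.0, lo=20.0),
        "rved_area": N(28.0, 7.0, lo=8.0),
        "fractional_shortening": N(25.0, 10.0, lo=1.0, hi=99.0),
        "rved_diam": N(4.5, 0.8, lo=2.0),
        "rves_diam": N(3.8, 0.8, lo=1.5),
        "tapse": N(1.7, 0.4, lo=0.5),
        "s_prime": N(10.0, 2.5, lo=3.0),
        "tei_index": N(0.55, 0.20, lo=0.05),
        "rv_ejection_time": N(280.0, 40.0, lo=150.0),
        "rvot_tvi": N(14.0, 4.0, lo=5.0),
        "ra_volume": N(60.0, 25.0, lo=15.0),
        "rv_thickness": N(0.70, 0.20, lo=0.2),
        "strain": N(-15.0, 5.0, hi=-1.0),
        "hr_end": N(110.0, 15.0, lo=60.0),
        "hr_recovery": N(18.0, 10.0),
        "nt_probnp": N(1200.0, 1500.0, family="lognormal"),
        "six_mwd": N(380.0, 110.0, lo=50.0),
        "camphor": N(25.0, 12.0, family="lognormal"),
    }
    control = {
        **common_ph,
        "lung_suv_m": N(0.37, 0.09, lo=0.05),
        "lung_suv_l": N(1.35, 0.35, lo=0.1),
        "lung_suv_t": N(1.59, 0.38, lo=0.1),
        "rv_lv_ratio": N(0.37, 0.28, family="lognormal"),
        "rved_volume": N(95.0, 25.0, lo=40.0),
        "rvef": N(52.0, 8.0, lo=20.0, hi=80.0),
        "rap": N(4.0, 1.5, lo=1.0),
        "rvsp": N(28.0, 6.0, lo=15.0),
        "rved_area": N(18.0, 4.0, lo=8.0),
        "fractional_shortening": N(45.0, 8.0, lo=1.0, hi=99.0),
        "rved_diam": N(3.3, 0.4, lo=2.0),
        "rves_diam": N(2.4, 0.4, lo=1.2),
        "tapse": N(2.4, 0.3, lo=1.0),
        "s_prime": N(14.0, 2.5, lo=5.0),
        "tei_index": N(0.28, 0.08, lo=0.05),
        "rv_ejection_time": N(320.0, 30.0, lo=200.0),
        "rvot_tvi": N(20.0, 4.0, lo=8.0),
        "ra_volume": N(35.0, 10.0, lo=12.0),
        "rv_thickness": N(0.40, 0.10, lo=0.15),
        "strain": N(-25.0, 4.0, hi=-5.0),
        "hr_end": N(120.0, 15.0, lo=60.0),
        "hr_recovery": N(30.0, 10.0),
        "nt_probnp": N(60.0, 40.0, family="lognormal"),
        "six_mwd": N(550.0, 80.0, lo=200.0),
        "camphor": N(2.0, 2.0, family="lognormal"),
    }
    marginals = {
        Group.control: control,
        Group.idiopathic: {**common_ph,
                           "lung_suv_t": N(2.13, 0.63, lo=0.1),
                           "rv_lv_ratio": N(1.20, 0.75, family="lognormal")},
        Group.hereditary: {**common_ph,
                           "lung_suv_t": N(1.98, 0.81, lo=0.1),
                           "rv_lv_ratio": N(1.49, 1.23, family="lognormal")},
        Group.other_PH: {**common_ph,
                         "lung_suv_t": N(2.04, 0.73, lo=0.1),
                         "rv_lv_ratio": N(1.37, 1.05, family="lognormal")},
    }
    return CohortSpec(
        group_sizes={Group.control: 8, Group.idiopathic: 9,
                     Group.hereditary: 12, Group.other_PH: 9},
        marginals=marginals,
        rank_corr=_corr_frame(DEFAULT_RANK_CORR_PAIRS),
        seed=seed,
    )


def _latent_root(rank_corr: np.ndarray) -> np.ndarray:
    """Square root of the latent Gaussian correlation for the copula."""
    latent = 2.0 * np.sin(np.pi * rank_corr / 6.0)
    np.fill_diagonal(latent, 1.0)
    w, v = np.linalg.eigh(latent)
    if w.min() < -1e-8:
        raise SpecError("latent copula correlation is not positive semidefinite")
    return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def make_cohort(spec: CohortSpec
                ) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Draw a cohort of subject records plus the latent truth table.

    Latent correlated normals are mapped through each measure's marginal
    quantile function (Gaussian copula), preserving the requested rank
    correlations. Echo inputs are built by inverting the derived-echo
    formulas from the latent draws. Returns ``(records, truth)`` where
    ``truth`` holds every drawn latent value per subject.
    """
    R = spec.rank_corr.loc[list(COHORT_MEASURES), list(COHORT_MEASURES)].to_numpy()
    A = _latent_root(R)
    rng = np.random.default_rng(spec.seed)
    records: list[SubjectRecord] = []
    truth_rows: list[dict[str, object]] = []
    n_missing = spec.n_missing_strain
    k = len(COHORT_MEASURES)

    for group in (Group.control, Group.idiopathic, Group.hereditary, Group.other_PH):
        if group not in spec.group_sizes:
            continue
        n = spec.group_sizes[group]
        marg = spec.marginals[group]
        z = rng.standard_normal((n, k)) @ A.T
        u = ndtr(z)
        draws = {m: marg[m].ppf(u[:, j]) for j, m in enumerate(COHORT_MEASURES)}
        # physiologic consistency floors (documented truncations)
        draws["rvsp"] = np.maximum(draws["rvsp"], draws["rap"] + 1.0)
        for i in range(n):
            sid = f"{group.value}_{i + 1:03d}"
            lat = {m: float(draws[m][i]) for m in COHORT_MEASURES}
            # invert the derived-echo formulas from the latent draws
            trv = math.sqrt((lat["rvsp"] - lat["rap"]) / 4.0)
            rves_area = lat["rved_area"] * (1.0 - lat["fractional_shortening"] / 100.0)
            tco = lat["rv_ejection_time"] * (1.0 + lat["tei_index"])
            hr_1min = lat["hr_end"] - lat["hr_recovery"]
            strain = lat["strain"]
            if group.is_ph and n_missing > 0:
                strain = math.nan
                n_missing -= 1
            inputs = EchoInputs(
                tr_peak_velocity=trv, rap=lat["rap"],
                rved_area=lat["rved_area"], rves_area=rves_area,
                rved_diam=lat["rved_diam"], rves_diam=lat["rves_diam"],
                tapse=lat["tapse"], s_prime=lat["s_prime"],
                tv_closure_opening_time=tco,
                rv_ejection_time=lat["rv_ejection_time"],
                rvot_tvi=lat["rvot_tvi"], ra_volume=lat["ra_volume"],
                rv_thickness=lat["rv_thickness"], strain=strain,
                hr_end_6mwt=lat["hr_end"], hr_1min_recovery=hr_1min,
            )
            rves_volume = lat["rved_volume"] * (1.0 - lat["rvef"] / 100.0)
            records.append(SubjectRecord(
                id=sid, group=group,
                imaging={
                    "lung_suv_m": lat["lung_suv_m"],
                    "lung_suv_l": lat["lung_suv_l"],
                    "lung_suv_t": lat["lung_suv_t"],
                    "rv_lv_ratio": lat["rv_lv_ratio"],
                    "rved_volume": lat["rved_volume"],
                    "rves_volume": rves_volume,
                    "rvef": lat["rvef"],
                    "rv_sv": lat["rved_volume"] - rves_volume,
                },
                echo_inputs=inputs,
                echo_derived=derive_echo(inputs),
                clinical={
                    "nt_probnp": lat["nt_probnp"],
                    "six_mwd": lat["six_mwd"],
                    "hr_recovery": lat["hr_recovery"],
                    "camphor": lat["camphor"],
                },
            ))
            truth_rows.append({"id": sid, "group": group.value, **lat})
    truth = pd.DataFrame(truth_rows)
    return records, truth
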