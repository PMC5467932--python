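"""Closed-form echocardiographic and exercise-derived quantities.

Units are fixed: velocities m/s, lengths/excursions cm, areas cm²,
times ms, pressures mmHg, volumes mL, heart rates bpm. Any unit
conversion happens at the I/O boundary, never inside these formulas.

TAPSE, S', RA volume, RV wall thickness and strain are pass-through
measurements (no derivation exists for them here); they are validated
for range only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "EchoInputs",
    "EchoDerived",
    "rvsp",
    "fractional_shortening",
    "tei_index",
    "pvr_estimate",
    "heart_rate_recovery",
    "derive_echo",
    "append_derived",
]


@dataclass
class EchoInputs:
    """Raw per-subject echo/exercise measurements (NaN = missing)."""

    tr_peak_velocity: float = math.nan   # m/s
    rap: float = math.nan                # mmHg
    rved_area: float = math.nan          # cm^2
    rves_area: float = math.nan          # cm^2
    rved_diam: float = math.nan          # cm
    rves_diam: float = math.nan          # cm
    tapse: float = math.nan              # cm
    s_prime: float = math.nan            # cm/s
    tv_closure_opening_time: float = math.nan  # ms
    rv_ejection_time: float = math.nan   # ms
    rvot_tvi: float = math.nan           # cm
    ra_volume: float = math.nan          # mL
    rv_thickness: float = math.nan       # cm
    strain: float = math.nan             # percent, negative for shortening
    hr_end_6mwt: float = math.nan        # bpm
    hr_1min_recovery: float = math.nan   # bpm

    def __post_init__(self) -> None:
        for name in ("rved_area", "rves_area", "rved_diam", "rves_diam",
                     "tv_closure_opening_time", "rv_ejection_time", "rvot_tvi"):
            v = getattr(self, name)
            if np.isfinite(v) and v <= 0:
                raise DomainError(f"{name} must be > 0, got {v}")
        if (np.isfinite(self.rves_area) and np.isfinite(self.rved_area)
                and self.rves_area > self.rved_area):
            warnings.warn("RVES area exceeds RVED area (non-physiologic input)",
                          stacklevel=2)


@dataclass
class EchoDerived:
    """Quantities computed from :class:`EchoInputs`."""

    rvsp: float = math.nan                  # mmHg
    fractional_shortening: float = math.nan  # percent
    tei_index: float = math.nan             # dimensionless
    pvr_est: float = math.nan               # Wood units
    hrr: float = math.nan                   # bpm


def rvsp(tr_peak_velocity: float, rap: float) -> float:
    """RV systolic pressure by the simplified Bernoulli relation 4V² + RAP."""
    if tr_peak_velocity < 0 or rap < 0:
        raise DomainError("TR velocity and RAP must be nonnegative")
    return 4.0 * tr_peak_velocity**2 + rap


def fractional_shortening(rved_area: float, rves_area: float) -> float:
    """RV fractional area shortening, (EDA − ESA)/EDA × 100 (percent)."""
    if not rved_area > 0:
        raise DomainError(f"RVED area must be > 0, got {rved_area}")
    return (rved_area - rves_area) / rved_area * 100.0


def tei_index(tv_closure_opening_time: float, rv_ejection_time: float) -> float:
    """RV myocardial performance index, (TCO − ET)/ET."""
    if not rv_ejection_time > 0:
        raise DomainError(f"RV ejection time must be > 0, got {rv_ejection_time}")
    if not tv_closure_opening_time > 0:
        raise DomainError("TV closure-opening time must be > 0")
    return (tv_closure_opening_time - rv_ejection_time) / rv_ejection_time


def pvr_estimate(trv: float, rvot_tvi: float) -> float:
    """Echo PVR estimate, TRV/TVI(RVOT) × 10 + 0.16 Wood units."""
    if not rvot_tvi > 0:
        raise DomainError(f"RVOT TVI must be > 0, got {rvot_tvi}")
    if trv < 0:
        raise DomainError("TR velocity must be nonnegative")
    return trv / rvot_tvi * 10.0 + 0.16


def heart_rate_recovery(hr_end: float, hr_1min: float) -> float:
    """HR at walk end minus HR one minute later (bpm).

    A negative value (rate rises after stopping) is clinically meaningful
    and is preserved with a warning, not clamped.
    """
    if not hr_end > 0 or not hr_1min > 0:
        raise DomainError("heart rates must be > 0 bpm")
    hrr = hr_end - hr_1min
    if hrr < 0:
        warnings.warn("negative heart-rate recovery (rate rose after walk end)",
                      stacklevel=2)
    return hrr


def _maybe(fn, *args):
    """Apply a formula when all inputs are present, else NaN."""
    if any(not np.isfinite(a) for a in args):
        return math.nan
    return fn(*args)


def derive_echo(inputs: EchoInputs) -> EchoDerived:
    """Compute every derived quantity available from one subject's inputs."""
    return EchoDerived(
        rvsp=_maybe(rvsp, inputs.tr_peak_velocity, inputs.rap),
        fractional_shortening=_maybe(fractional_shortening,
                                     inputs.rved_area, inputs.rves_area),
        tei_index=_maybe(tei_index, inputs.tv_closure_opening_time,
                         inputs.rv_ejection_time),
        pvr_est=_maybe(pvr_estimate, inputs.tr_peak_velocity, inputs.rvot_tvi),
        hrr=_maybe(heart_rate_recovery, inputs.hr_end_6mwt, inputs.hr_1min_recovery),
    )


INPUT_COLUMNS = tuple(f.name for f in fields(EchoInputs))
DERIVED_COLUMNS = tuple(f.name for f in fields(EchoDerived))


def append_derived(table: pd.DataFrame) -> pd.DataFrame:
    """Append derived-echo columns to a one-row-per-subject table."""
    out = table.copy()
    derived = [derive_echo(EchoInputs(**{c: row.get(c, math.nan)
                                         for c in INPUT_COLUMNS}))
               for row in out.to_dict("records")]
    for col in DERIVED_COLUMNS:
        out[col] = [getattr(d, col) for d in derived]
    return out
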