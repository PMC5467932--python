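"""Group comparisons, Spearman correlation tables and Bland–Altman.

Two-sample comparisons can be computed either from raw samples or from
printed summary triplets (mean, SD, n) — the latter reproduces published
tests when only summary data are available. Welch (unequal-variance) is
the default; the pooled-variance test is available by flag. No
multiple-comparison correction is applied anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import Group, SubjectRecord
from .errors import ConstantInputError, DegenerateVarianceError, DomainError, TableError

__all__ = [
    "GroupSummary",
    "StatResult",
    "BlandAltmanResult",
    "summarize",
    "t_test_from_summary",
    "t_test_raw",
    "spearman",
    "bland_altman",
    "p_display",
    "records_to_frame",
    "build_tables",
]


@dataclass(frozen=True)
class GroupSummary:
    """Printed-style group summary: mean ± SD with group size."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise DomainError(f"SD must be >= 0, got {self.sd}")
        if self.n < 2:
            raise DomainError(f"group size must be >= 2, got {self.n}")


@dataclass(frozen=True)
class StatResult:
    statistic: float
    df: float
    p_two_sided: float
    method: str
    ci_95: tuple[float, float] | None = None


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    r: float
    n: int


def summarize(x) -> GroupSummary:
    """Mean, SD (n−1 denominator) and n of a sample, NaNs dropped."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise DomainError("need at least 2 finite observations")
    return GroupSummary(float(x.mean()), float(x.std(ddof=1)), int(x.size))


def t_test_from_summary(g1: GroupSummary, g2: GroupSummary,
                        method: str = "welch") -> StatResult:
    """Two-sample t-test from summary statistics.

    ``method='welch'``: t = (m1−m2)/√(s1²/n1 + s2²/n2) with
    Welch–Satterthwaite degrees of freedom. ``method='pooled'``: the
    classical equal-variance test. Returns the two-sided p and the 95%
    CI for the mean difference.
    """
    d = g1.mean - g2.mean
    if method == "welch":
        v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
        se = math.sqrt(v1 + v2)
        if se == 0:
            return _degenerate(d)
        df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    elif method == "pooled":
        df = g1.n + g2.n - 2
        sp2 = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / df
        se = math.sqrt(sp2 * (1 / g1.n + 1 / g2.n))
        if se == 0:
            return _degenerate(d)
    else:
        raise DomainError(f"unknown t-test method {method!r}")
    t = d / se
    p = 2.0 * sps.t.sf(abs(t), df)
    half = sps.t.ppf(0.975, df) * se
    return StatResult(t, df, float(p), method, (d - half, d + half))


def _degenerate(diff: float) -> StatResult:
    if diff == 0:
        # both groups constant and equal: no evidence against the null
        return StatResult(0.0, float("nan"), 1.0, "degenerate", (0.0, 0.0))
    raise DegenerateVarianceError(
        "zero variance in both groups with unequal means: t undefined")


def t_test_raw(x, y, method: str = "welch") -> StatResult:
    """Two-sample t-test on raw samples (NaNs dropped per sample)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return t_test_from_summary(summarize(x), summarize(y), method)


def spearman(x, y) -> StatResult:
    """Spearman rank correlation with pairwise-complete deletion.

    Ranks use average tie handling; the two-sided p comes from the
    t approximation t = ρ·√((n−2)/(1−ρ²)).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise DomainError("vectors must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 4:
        raise DomainError(f"need >= 4 complete pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ConstantInputError("rank correlation undefined for a constant vector")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return StatResult(rho, n - 2, p, "spearman")


def bland_altman(reading1, reading2) -> BlandAltmanResult:
    """Agreement between paired readings: mean difference and 95% limits.

    Differences are reading1 − reading2; limits are mean ± 1.96·SD
    (SD with n−1 denominator); ``r`` is the Pearson correlation of the
    paired readings themselves.
    """
    r1 = np.asarray(reading1, float)
    r2 = np.asarray(reading2, float)
    if r1.shape != r2.shape:
        raise DomainError("paired readings must have equal length")
    keep = np.isfinite(r1) & np.isfinite(r2)
    r1, r2 = r1[keep], r2[keep]
    n = r1.size
    if n < 2:
        raise DomainError(f"need >= 2 pairs, got {n}")
    diffs = r1 - r2
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    if r1.std() == 0 or r2.std() == 0:
        r = float("nan")  # correlation undefined for constant readings
    else:
        r = float(np.corrcoef(r1, r2)[0, 1])
    return BlandAltmanResult(mean_diff, sd_diff,
                             mean_diff - 1.96 * sd_diff,
                             mean_diff + 1.96 * sd_diff, r, n)


def p_display(p: float) -> float:
    """Round a p-value with the publication display convention.

    One decimal at or above 0.1, two decimals below, and one significant
    figure when two decimals would display as 0.00.
    """
    if not 0 <= p <= 1:
        raise DomainError(f"p must be in [0,1], got {p}")
    if p >= 0.095:  # rounds to >= 0.1 at one decimal
        return round(p, 1)
    if round(p, 2) >= 0.005:
        return round(p, 2)
    if p == 0:
        return 0.0
    digits = -int(math.floor(math.log10(p)))
    return round(p, digits)


# ---------------------------------------------------------------------------
# cohort tables

PET_MEASURES = ("rved_volume", "rves_volume", "rvef", "rv_sv", "rv_lv_ratio",
                "lung_suv_m", "lung_suv_l", "lung_suv_t")
ECHO_MEASURES = ("ra_volume", "rap", "rved_area", "rves_area", "rved_diam",
                 "rves_diam", "fractional_shortening", "rvsp", "tapse",
                 "tei_index", "s_prime", "strain", "pvr_est", "rv_thickness")
CLINICAL_MEASURES = ("nt_probnp", "six_mwd", "hr_recovery", "camphor")


def records_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Flatten subject records to a tidy one-row-per-subject table."""
    from . import echo as _echo  # local import to avoid cycles at import time

    rows = []
    for rec in records:
        row: dict[str, object] = {"id": rec.id, "group": rec.group.value}
        row.update(rec.imaging)
        row.update(rec.clinical)
        if rec.echo_inputs is not None:
            for col in _echo.INPUT_COLUMNS:
                row[col] = getattr(rec.echo_inputs, col)
            derived = rec.echo_derived or _echo.derive_echo(rec.echo_inputs)
            for col in _echo.DERIVED_COLUMNS:
                row[col] = getattr(derived, col)
        rows.append(row)
    return pd.DataFrame(rows)


def build_tables(records: list[SubjectRecord], method: str = "welch"
                 ) -> dict[str, pd.DataFrame]:
    """Build the study's statistical surface from a cohort.

    Returns tidy tables: ``groups`` (per-measure PH vs control summaries
    and t-tests), ``pet_vs_echo`` (Spearman grid of PET measures against
    echo parameters) and ``pet_vs_ntprobnp``. No multiple-comparison
    correction is applied.
    """
    df = records_to_frame(records)
    if df["group"].nunique() < 2:
        raise TableError("cohort must contain at least two groups")
    is_ph = df["group"] != Group.control.value
    ph, ctl = df[is_ph], df[~is_ph]
    if ph.empty or ctl.empty:
        raise TableError("need both a PH group and a control group")

    group_rows = []
    for measure in (*PET_MEASURES, *ECHO_MEASURES, *CLINICAL_MEASURES):
        if measure not in df.columns:
            continue
        g1 = summarize(ph[measure])
        g2 = summarize(ctl[measure])
        res = t_test_from_summary(g1, g2, method)
        group_rows.append({
            "measure": measure,
            "mean_ph": g1.mean, "sd_ph": g1.sd, "n_ph": g1.n,
            "mean_control": g2.mean, "sd_control": g2.sd, "n_control": g2.n,
            "t": res.statistic, "df": res.df,
            "p": res.p_two_sided, "p_display": p_display(res.p_two_sided),
            "method": res.method,
        })

    corr_rows, bnp_rows = [], []
    for pet in PET_MEASURES:
        if pet not in df.columns:
            continue
        for other in ECHO_MEASURES:
            if other not in df.columns:
                continue
            res = spearman(df[pet], df[other])
            corr_rows.append({"pet_measure": pet, "echo_measure": other,
                              "rho": res.statistic, "n": res.df + 2,
                              "p": res.p_two_sided,
                              "p_display": p_display(res.p_two_sided)})
        if "nt_probnp" in df.columns:
            res = spearman(df[pet], df["nt_probnp"])
            bnp_rows.append({"pet_measure": pet, "rho": res.statistic,
                             "n": res.df + 2, "p": res.p_two_sided,
                             "p_display": p_display(res.p_two_sided)})

    return {
        "groups": pd.DataFrame(group_rows),
        "pet_vs_echo": pd.DataFrame(corr_rows),
        "pet_vs_ntprobnp": pd.DataFrame(bnp_rows),
    }
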