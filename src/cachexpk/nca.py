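"""Per-subject non-compartmental analysis and group summaries.

Terminal-phase selection emulates the usual "best fit" automation: every
contiguous tail of at least three positive-concentration points that does
not start at the observed Cmax is fitted log-linearly, and the tail with
the largest adjusted R² wins (ties broken toward more points). λz is the
negative OLS slope of ln C on t; AUC_last is the linear trapezoid from the
first observation to the last measurable concentration (no back-
extrapolation to t = 0 — C0 is reported separately by the IV-bolus
convention of log-linear back-extrapolation through the first two points);
AUC_inf adds C_last/λz. Group summaries are geometric mean (geometric CV%),
except the terminal half-life which is summarized as median (min, max).

BQL (below-quantification) records are excluded from λz and AUC; the count
of excluded records is carried on the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import HOURS_PER_DAY, SubjectProfile

__all__ = [
    "NCAResult",
    "select_terminal_points",
    "fit_lambda_z",
    "auc_linear_trapezoid",
    "nca_parameters",
    "summarize_group",
    "nca_table",
    "LambdaZNotEstimable",
]


class LambdaZNotEstimable(ValueError):
    """Raised when no admissible terminal phase yields a positive λz."""


@dataclass(frozen=True)
class NCAResult:
    """Non-compartmental parameters for one subject (times in days)."""

    subject_id: str
    lambda_z: float          # 1/day
    n_lambda_points: int
    r2_adj: float
    auc_last: float          # day·μg/mL
    auc_inf: float           # day·μg/mL
    cl: float                # mL/day/kg
    vz: float                # mL/kg
    t_half: float            # days
    c0: float                # μg/mL
    pct_extrapolated: float  # percent of AUC_inf beyond the last sample
    n_bql_excluded: int = 0


def _usable(times_d: np.ndarray, concs: np.ndarray, bql: np.ndarray):
    keep = (~bql) & (concs > 0.0)
    return times_d[keep], concs[keep]


def _loglinear_fit(t: np.ndarray, c: np.ndarray) -> tuple[float, float, float]:
    """OLS of ln c on t → (slope, intercept, adjusted R²)."""
    y = np.log(c)
    n = t.size
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-24 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
    return float(slope), float(intercept), float(r2_adj)


def select_terminal_points(times_d: np.ndarray, concs: np.ndarray) -> np.ndarray:
    """Indices of the terminal log-linear phase.

    Evaluates every contiguous tail of >= 3 points that excludes the
    maximum-concentration point and returns the tail maximizing the
    adjusted R² of the log-linear fit; ties (within 1e-12) broken toward
    more points. Raises :class:`LambdaZNotEstimable` when fewer than three
    positive-concentration points remain after Cmax or no tail gives a
    positive λz.
    """
    times_d = np.asarray(times_d, dtype=float)
    concs = np.asarray(concs, dtype=float)
    n = times_d.size
    if n < 3:
        raise LambdaZNotEstimable("need at least 3 positive-concentration points")
    i_cmax = int(np.argmax(concs))

    def scan(starts) -> int | None:
        best: tuple[float, int] | None = None  # (r2_adj, n_points)
        best_start = None
        for start in starts:
            t, c = times_d[start:], concs[start:]
            slope, _b, r2_adj = _loglinear_fit(t, c)
            if slope >= 0.0:
                continue
            cand = (r2_adj, t.size)
            if best is None or cand[0] > best[0] + 1e-12 or (
                abs(cand[0] - best[0]) <= 1e-12 and cand[1] > best[1]
            ):
                best = cand
                best_start = start
        return best_start

    # prefer tails that exclude the Cmax point; fall back to all tails when
    # that leaves nothing admissible (e.g. a 3-point profile with Cmax first)
    best_start = scan(range(i_cmax + 1, n - 2))
    if best_start is None:
        best_start = scan(range(0, min(i_cmax + 1, n - 2)))
    if best_start is None:
        raise LambdaZNotEstimable("no admissible tail with positive lambda_z")
    return np.arange(best_start, n)


def fit_lambda_z(
    times_d: np.ndarray, concs: np.ndarray, indices: np.ndarray
) -> tuple[float, float, float]:
    """(λz, intercept, adjusted R²) from OLS of ln C on t over ``indices``."""
    idx = np.asarray(indices, dtype=int)
    if idx.size < 3:
        raise LambdaZNotEstimable("lambda_z regression needs >= 3 points")
    t = np.asarray(times_d, dtype=float)[idx]
    c = np.asarray(concs, dtype=float)[idx]
    if np.any(c <= 0.0):
        raise ValueError("lambda_z regression requires positive concentrations")
    slope, intercept, r2_adj = _loglinear_fit(t, c)
    lam = -slope
    if lam <= 0.0:
        raise LambdaZNotEstimable("non-positive lambda_z (rising terminal phase)")
    return lam, intercept, r2_adj


def auc_linear_trapezoid(times_d: np.ndarray, concs: np.ndarray) -> float:
    """Linear-trapezoid AUC (day·μg/mL) from the first to the last sample."""
    t = np.asarray(times_d, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t.size < 2:
        raise ValueError("AUC needs at least 2 records")
    if np.any(np.diff(t) <= 0.0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(c, t))


def nca_parameters(profile: SubjectProfile, dose: float | None = None) -> NCAResult:
    """Full non-compartmental parameter set for one subject.

    ``dose`` is μg/kg; defaults to the profile's dose event. Times are
    converted from hours to days. Raises :class:`LambdaZNotEstimable` when
    the terminal phase cannot be estimated and ValueError for a
    non-positive dose.
    """
    if dose is None:
        dose = profile.dose.amount
    if dose <= 0.0:
        raise ValueError("dose must be strictly positive for NCA")
    bql = np.array([r.bql for r in profile.records], dtype=bool)
    t_all = profile.times_h / HOURS_PER_DAY
    c_all = profile.concs
    t, c = _usable(t_all, c_all, bql)
    n_bql = int(bql.sum() + ((~bql) & (c_all <= 0.0)).sum())
    idx = select_terminal_points(t, c)
    lam, _intercept, r2_adj = fit_lambda_z(t, c, idx)
    auc_last = auc_linear_trapezoid(t, c)
    c_last = float(c[-1])
    auc_inf = auc_last + c_last / lam
    cl = dose / auc_inf
    vz = dose / (lam * auc_inf)
    # IV-bolus C0: log-linear back-extrapolation through the first two points
    s0 = (math.log(c[1]) - math.log(c[0])) / (t[1] - t[0])
    c0 = float(math.exp(math.log(c[0]) - s0 * t[0]))
    return NCAResult(
        subject_id=profile.subject_id,
        lambda_z=lam,
        n_lambda_points=int(idx.size),
        r2_adj=r2_adj,
        auc_last=auc_last,
        auc_inf=auc_inf,
        cl=cl,
        vz=vz,
        t_half=math.log(2.0) / lam,
        c0=c0,
        pct_extrapolated=100.0 * (auc_inf - auc_last) / auc_inf,
        n_bql_excluded=n_bql,
    )


def _geo_mean_cv(values: np.ndarray) -> tuple[float, float]:
    if np.any(values <= 0.0):
        raise ValueError("geometric summaries require strictly positive values")
    logs = np.log(values)
    gm = float(np.exp(logs.mean()))
    var_ln = float(logs.var(ddof=1)) if logs.size > 1 else 0.0
    gcv = 100.0 * math.sqrt(math.expm1(var_ln))
    return gm, gcv


def summarize_group(results: list[NCAResult]) -> dict:
    """Group summary in the study's reporting convention.

    Geometric mean (geometric CV%, n−1 denominator on the log variance)
    for C0, Vz, CL, AUC_last and AUC_inf; median (min, max) for the
    terminal half-life.
    """
    if not results:
        raise ValueError("empty group")
    out: dict = {"n": len(results)}
    for name in ("c0", "vz", "cl", "auc_last", "auc_inf"):
        vals = np.array([getattr(r, name) for r in results], dtype=float)
        gm, gcv = _geo_mean_cv(vals)
        out[name] = {"geo_mean": gm, "geo_cv_pct": gcv}
    th = np.array([r.t_half for r in results], dtype=float)
    out["t_half"] = {
        "median": float(np.median(th)),
        "min": float(th.min()),
        "max": float(th.max()),
    }
    return out


def nca_table(profiles: list[SubjectProfile]) -> pd.DataFrame:
    """Per-subject NCA results as a DataFrame; non-estimable subjects get
    NaN terminal parameters rather than being dropped."""
    rows = []
    for p in profiles:
        if p.dose.amount <= 0.0 or len(p.records) == 0:
            continue
        base = {"subject_id": p.subject_id, "dose_ug_kg": p.dose.amount,
                "tumour": p.covariates.tumour, "strain": p.covariates.strain,
                "dose_group": p.covariates.dose_group}
        try:
            r = nca_parameters(p)
            rows.append({**base, "lambda_z_per_day": r.lambda_z,
                         "n_lambda_points": r.n_lambda_points, "r2_adj": r.r2_adj,
                         "auc_last": r.auc_last, "auc_inf": r.auc_inf,
                         "cl_ml_day_kg": r.cl, "vz_ml_kg": r.vz,
                         "t_half_day": r.t_half, "c0_ug_ml": r.c0,
                         "pct_extrapolated": r.pct_extrapolated})
        except LambdaZNotEstimable:
            rows.append({**base, "lambda_z_per_day": np.nan})
    return pd.DataFrame(rows)
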