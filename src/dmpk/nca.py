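"""Non-compartmental analysis of plasma concentration-time profiles.

Standard NCA for preclinical PK: observed Cmax/Tmax, trapezoidal AUC
(linear, or linear-up/log-down), best-fit terminal slope selection by
adjusted r^2, extrapolated AUC, clearance and terminal-phase volume of
distribution, dose-normalised oral bioavailability, and group summaries.

Units are fixed by convention: time in h, concentration in ng/mL, dose in
mg/kg. Clearance then comes out in L/h/kg via

    CL = dose [mg/kg] * 1e6 [ng/mg] / (AUC_inf [ng*h/mL] * 1e3 [mL/L])

i.e. ``CL = 1000 * dose / AUC_inf``, and Vz = CL / lambda_z.

Below-limit-of-quantitation (BLQ) handling follows common NCA practice:
pre-Tmax BLQ samples are set to zero (absorption has not started), while
embedded and trailing BLQ samples are excluded from all calculations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConcentrationTimeProfile",
    "LambdaZFit",
    "NCAResult",
    "GroupSummary",
    "cmax_tmax",
    "auc_trapezoid",
    "select_lambda_z",
    "nca_single",
    "bioavailability",
    "normalize_oral_by_F",
    "fraction_of_hepatic_flow",
    "summarize_group",
    "MOUSE_HEPATIC_BLOOD_FLOW_L_H_KG",
]

LN2 = math.log(2.0)

#: Mouse hepatic blood flow in NCA units (3.6 L/h/kg = 60 mL/min/kg * 0.06).
MOUSE_HEPATIC_BLOOD_FLOW_L_H_KG = 3.6


@dataclass(frozen=True)
class ConcentrationTimeProfile:
    """One subject's dosed route and timed plasma concentrations."""

    subject_id: str
    route: str  # IV | PO
    dose: float  # mg/kg
    times: tuple[float, ...]  # h, strictly increasing
    concentrations: tuple[float, ...]  # ng/mL; 0 encodes BLQ
    lloq: float = 0.2  # ng/mL

    def __post_init__(self) -> None:
        if self.route not in ("IV", "PO"):
            raise ValueError("route must be 'IV' or 'PO'")
        if self.dose <= 0:
            raise ValueError("dose must be > 0")
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(
            self, "concentrations", tuple(float(c) for c in self.concentrations)
        )
        t = np.asarray(self.times)
        c = np.asarray(self.concentrations)
        if t.size != c.size:
            raise ValueError("times and concentrations must align")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")


def _quantifiable(profile: ConcentrationTimeProfile) -> tuple[np.ndarray, np.ndarray]:
    """Apply the BLQ convention; return (times, concs) used for NCA."""
    t = np.asarray(profile.times)
    c = np.asarray(profile.concentrations, dtype=float)
    blq = c < profile.lloq
    if np.all(blq):
        raise ValueError(f"profile {profile.subject_id}: no quantifiable samples")
    tmax_idx = int(np.argmax(np.where(blq, -np.inf, c)))
    keep = ~blq
    pre = np.arange(t.size) < tmax_idx
    # pre-Tmax BLQ -> 0 and kept; embedded/trailing BLQ -> dropped
    c = np.where(blq & pre, 0.0, c)
    keep |= pre
    return t[keep], c[keep]


def cmax_tmax(profile: ConcentrationTimeProfile) -> tuple[float, float]:
    """Observed maximum concentration and its time; ties go to the earlier time."""
    t, c = _quantifiable(profile)
    idx = int(np.argmax(c))  # argmax returns the first maximum -> earliest time
    return float(c[idx]), float(t[idx])


def auc_trapezoid(
    times: Sequence[float] | ConcentrationTimeProfile,
    concentrations: Sequence[float] | None = None,
    method: str = "linear",
) -> float:
    """AUC to the last quantifiable sample by the trapezoidal rule.

    ``method='linear'`` applies the linear trapezoid throughout; exact on
    piecewise-linear profiles. ``'linear_up_log_down'`` switches to the
    logarithmic trapezoid on strictly declining segments with both ends
    positive; exact on mono-exponential decay.
    """
    if isinstance(times, ConcentrationTimeProfile):
        t, c = _quantifiable(times)
    else:
        t = np.asarray(times, dtype=float)
        c = np.asarray(concentrations, dtype=float)
    if t.size < 2:
        raise ValueError("AUC needs >= 2 quantifiable samples")
    if method not in ("linear", "linear_up_log_down"):
        raise ValueError(f"unknown AUC method {method!r}")
    dt = np.diff(t)
    c0, c1 = c[:-1], c[1:]
    linear = dt * (c0 + c1) / 2.0
    if method == "linear":
        return float(linear.sum())
    down = (c1 < c0) & (c1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logseg = dt * (c0 - c1) / np.log(np.where(down, c0 / c1, math.e))
    return float(np.where(down, logseg, linear).sum())


@dataclass(frozen=True)
class LambdaZFit:
    """Terminal-slope selection result."""

    lambda_z: float | None  # 1/h; None when no terminal phase is identifiable
    n_points: int
    adj_r_squared: float
    t_half: float | None  # h

    @property
    def estimable(self) -> bool:
        return self.lambda_z is not None


def select_lambda_z(profile: ConcentrationTimeProfile, min_points: int = 3) -> LambdaZFit:
    """Best-fit terminal elimination rate by log-linear regression.

    Candidate windows end at the last quantifiable sample and extend
    backwards, excluding Cmax (and anything before it); among windows of
    >= ``min_points`` the one maximising adjusted r^2 wins, ties going to
    the window with fewer points. A non-positive slope in every window
    means no identifiable terminal phase (``lambda_z=None``).
    """
    t, c = _quantifiable(profile)
    pos = c > 0
    t, c = t[pos], c[pos]
    start = int(np.argmax(c)) + 1  # strictly after Tmax / excluding Cmax
    t_term, c_term = t[start:], c[start:]
    if t_term.size < min_points:
        # nothing to regress on (e.g. a still-rising profile): no terminal phase
        return LambdaZFit(lambda_z=None, n_points=0, adj_r_squared=float("nan"), t_half=None)
    best: tuple[float, int, float] | None = None  # (adj_r2, n, lambda_z)
    logc = np.log(c_term)
    for n in range(min_points, t_term.size + 1):
        fit = stats.linregress(t_term[-n:], logc[-n:])
        lz = -float(fit.slope)
        if lz <= 0:
            continue
        adj_r2 = 1.0 - (1.0 - float(fit.rvalue) ** 2) * (n - 1) / (n - 2)
        # strict > keeps the earlier (smaller-n) candidate on ties
        if best is None or adj_r2 > best[0] + 1e-12:
            best = (adj_r2, n, lz)
    if best is None:
        return LambdaZFit(lambda_z=None, n_points=0, adj_r_squared=float("nan"), t_half=None)
    adj_r2, n, lz = best
    return LambdaZFit(lambda_z=lz, n_points=n, adj_r_squared=adj_r2, t_half=LN2 / lz)


@dataclass(frozen=True)
class NCAResult:
    """Per-subject NCA parameters.

    ``cl`` and ``vz`` are CL/F and Vz/F when the route is oral; the
    bioavailability correction is a separate, explicit step.
    """

    subject_id: str
    route: str
    dose: float
    cmax: float
    tmax: float
    auc_last: float
    auc_inf: float | None
    lambda_z: float | None
    lambda_z_n_points: int
    lambda_z_adj_r2: float
    t_half: float | None
    cl: float | None  # L/h/kg (CL/F for PO)
    vz: float | None  # L/kg (Vz/F for PO)
    pct_extrapolated: float | None
    auc_method: str

    def to_dict(self) -> dict:
        return asdict(self)


def nca_single(
    profile: ConcentrationTimeProfile,
    auc_method: str = "linear",
    lambda_z_min_points: int = 3,
) -> NCAResult:
    """Full single-subject NCA.

    AUC_inf = AUC_last + C_last/lambda_z; CL (or CL/F) = dose/AUC_inf and
    Vz (or Vz/F) = CL/lambda_z, with the mg/kg-over-ng*h/mL unit conversion
    folded in. When no terminal phase is identifiable the extrapolated
    quantities are None and AUC_last is still reported.
    """
    t, c = _quantifiable(profile)
    cmax, tmax = cmax_tmax(profile)
    auc_last = auc_trapezoid(t, c, method=auc_method)
    try:
        lz = select_lambda_z(profile, min_points=lambda_z_min_points)
    except ValueError:
        lz = LambdaZFit(None, 0, float("nan"), None)
    auc_inf = cl = vz = pct_extrap = None
    if lz.estimable:
        c_last = c[c > 0][-1]
        auc_inf = auc_last + float(c_last) / lz.lambda_z
        pct_extrap = 100.0 * (auc_inf - auc_last) / auc_inf
        cl = 1000.0 * profile.dose / auc_inf  # L/h/kg
        vz = cl / lz.lambda_z
    return NCAResult(
        subject_id=profile.subject_id,
        route=profile.route,
        dose=profile.dose,
        cmax=cmax,
        tmax=tmax,
        auc_last=auc_last,
        auc_inf=auc_inf,
        lambda_z=lz.lambda_z,
        lambda_z_n_points=lz.n_points,
        lambda_z_adj_r2=lz.adj_r_squared,
        t_half=lz.t_half,
        cl=cl,
        vz=vz,
        pct_extrapolated=pct_extrap,
        auc_method=auc_method,
    )


def bioavailability(auc_po: float, dose_po: float, auc_iv: float, dose_iv: float) -> float:
    """Absolute oral bioavailability F (%) from dose-normalised AUCs."""
    if auc_po <= 0 or auc_iv <= 0:
        raise ValueError("AUCs must be > 0")
    if dose_po <= 0 or dose_iv <= 0:
        raise ValueError("doses must be > 0")
    return 100.0 * (auc_po / dose_po) / (auc_iv / dose_iv)


def normalize_oral_by_F(clf_or_vzf: float, f_fraction: float) -> float:
    """Convert CL/F (or Vz/F) to CL (or Vz) given bioavailability as a fraction."""
    if not 0 < f_fraction <= 1:
        raise ValueError("F must be in (0, 1]")
    return clf_or_vzf * f_fraction


def fraction_of_hepatic_flow(
    cl: float, hepatic_blood_flow: float = MOUSE_HEPATIC_BLOOD_FLOW_L_H_KG
) -> float:
    """Clearance as a percentage of hepatic blood flow (same units both)."""
    if hepatic_blood_flow <= 0:
        raise ValueError("hepatic blood flow must be > 0")
    return 100.0 * cl / hepatic_blood_flow


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- sample SD per NCA parameter across subjects."""

    n: int
    table: pd.DataFrame  # index: parameter; columns: mean, sd

    def __getitem__(self, parameter: str) -> tuple[float, float]:
        row = self.table.loc[parameter]
        return float(row["mean"]), float(row["sd"])


_SUMMARY_PARAMS = ("cmax", "tmax", "auc_last", "auc_inf", "lambda_z", "t_half", "cl", "vz")


def summarize_group(results: Sequence[NCAResult]) -> GroupSummary:
    """Arithmetic mean and sample SD of each parameter across subjects."""
    if len(results) < 2:
        raise ValueError("group summary needs >= 2 subjects")
    df = pd.DataFrame([r.to_dict() for r in results])[list(_SUMMARY_PARAMS)]
    table = pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1)})
    return GroupSummary(n=len(results), table=table)
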