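"""In vitro DMPK calculators.

Covers the standard discovery-stage assay mathematics:

* microsomal stability — mono-exponential substrate-depletion fit, intrinsic
  clearance, liver scaling, and well-stirred extrapolation to whole-body
  hepatic clearance (IVIVE);
* equilibrium-dialysis protein binding;
* blood-to-plasma partitioning;
* kinetic solubility (saturation-plateau estimate);
* PAMPA and Caco-2 apparent permeability;
* micromolar <-> ng/mL conversion.

The IVIVE chain, in order:

    k (min^-1)  ->  t1/2 = ln2/k
    CL_int      = (ln2 / t1/2) * V_inc / protein_mass        [mL/min/mg]
    CL_H,int    = CL_int * (mg protein / g liver) * (g liver / kg bw)
    fu_inc      = 1 / (1 + 10^(0.53*logP - 1.42))
    CL_H,pred   = Q * fu_p * (CL_H,int/fu_inc) / (Q + fu_p * CL_H,int/fu_inc)

where Q is hepatic blood flow (mL/min/kg) and fu_p the plasma fraction
unbound. CL_H,pred is bounded above by Q (flow-limited extraction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MicrosomalTimecourse",
    "SpeciesScaling",
    "MOUSE",
    "HUMAN",
    "DecayFit",
    "IVIVEResult",
    "DialysisMeasurement",
    "TranswellAssay",
    "SolubilityResult",
    "Caco2Result",
    "fit_monoexponential_decay",
    "clint_from_halflife",
    "scale_clint_to_liver",
    "fraction_unbound_microsomes",
    "well_stirred_clearance",
    "ivive_chain",
    "percent_bound",
    "fraction_unbound",
    "blood_plasma_ratio",
    "pampa_papp",
    "caco2_papp",
    "kinetic_solubility",
    "molar_convert",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class MicrosomalTimecourse:
    """Substrate-depletion time course in a liver-microsome incubation.

    ``response_ratios`` are analyte/IS peak-area ratios, proportional to the
    remaining parent concentration. Protein concentration and incubation
    volume default to the conventional 0.5 mg/mL in 0.5 mL.
    """

    species: str
    times: tuple[float, ...]  # min, strictly increasing from 0
    response_ratios: tuple[float, ...]
    protein_conc: float = 0.5  # mg/mL
    incubation_volume: float = 0.5  # mL
    nadph_present: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(self, "response_ratios", tuple(float(r) for r in self.response_ratios))
        t = np.asarray(self.times)
        if len(self.times) != len(self.response_ratios):
            raise ValueError("times and ratios must have equal length")
        if t.size and (t[0] < 0 or np.any(np.diff(t) <= 0)):
            raise ValueError("times must be strictly increasing from 0")
        if self.protein_conc <= 0 or self.incubation_volume <= 0:
            raise ValueError("protein concentration and volume must be > 0")

    @property
    def protein_mass(self) -> float:
        """Total microsomal protein in the incubation (mg)."""
        return self.protein_conc * self.incubation_volume


@dataclass(frozen=True)
class SpeciesScaling:
    """Physiological scaling constants for IVIVE.

    ``fu_plasma`` and ``hepatic_blood_flow`` may be omitted for species where
    the well-stirred prediction is not wanted; the chain then stops at
    CL_H,int.
    """

    species: str
    mg_protein_per_g_liver: float
    g_liver_per_kg_bw: float
    hepatic_blood_flow: float | None = None  # Q, mL/min/kg
    fu_plasma: float | None = None

    def __post_init__(self) -> None:
        if self.mg_protein_per_g_liver <= 0 or self.g_liver_per_kg_bw <= 0:
            raise ValueError("scaling factors must be > 0")
        if self.hepatic_blood_flow is not None and self.hepatic_blood_flow <= 0:
            raise ValueError("hepatic blood flow must be > 0")
        if self.fu_plasma is not None and not 0 < self.fu_plasma <= 1:
            raise ValueError("fu_plasma must be in (0, 1]")


MOUSE = SpeciesScaling("mouse", 45.0, 60.0, hepatic_blood_flow=90.0, fu_plasma=0.025)
HUMAN = SpeciesScaling("human", 32.0, 25.0)


@dataclass(frozen=True)
class DecayFit:
    """Log-linear depletion fit: first-order rate, half-life, stability flag."""

    k: float  # min^-1; <= 0 means no measurable depletion
    t_half: float  # min; inf when stable
    r_squared: float
    stable: bool


@dataclass(frozen=True)
class IVIVEResult:
    """Outputs of the full microsomes-to-hepatic-clearance chain."""

    species: str
    k: float
    t_half: float
    cl_int: float  # mL/min/mg protein
    cl_h_int: float  # mL/min/kg body weight
    fu_inc: float | None = None
    cl_h_predict: float | None = None  # mL/min/kg body weight


def fit_monoexponential_decay(tc: MicrosomalTimecourse) -> DecayFit:
    """Fit ln(ratio) vs time by ordinary least squares; k = -slope.

    A non-positive k (no depletion, e.g. a NADPH-free control or a
    metabolically stable compound) is flagged ``stable`` rather than raised.
    """
    if len(tc.times) < 3:
        raise ValueError("need >= 3 time points for a depletion fit")
    ratios = np.asarray(tc.response_ratios)
    if np.any(ratios <= 0):
        raise ValueError("all response ratios must be > 0 for log-linear fitting")
    fit = stats.linregress(tc.times, np.log(ratios))
    k = -float(fit.slope)
    stable = k <= 0
    t_half = math.inf if stable else LN2 / k
    return DecayFit(k=k, t_half=t_half, r_squared=float(fit.rvalue) ** 2, stable=stable)


def clint_from_halflife(t_half: float, incubation_volume: float, protein_mass: float) -> float:
    """Intrinsic clearance (mL/min/mg protein) from the depletion half-life."""
    if incubation_volume <= 0 or protein_mass <= 0:
        raise ValueError("volume and protein mass must be > 0")
    if t_half <= 0:
        raise ValueError("half-life must be > 0 (may be inf for stable compounds)")
    if math.isinf(t_half):
        return 0.0
    return (LN2 / t_half) * (incubation_volume / protein_mass)


def scale_clint_to_liver(cl_int: float, scaling: SpeciesScaling) -> float:
    """Scale CL_int to whole-liver intrinsic clearance (mL/min/kg bw)."""
    if cl_int < 0:
        raise ValueError("CL_int must be >= 0")
    return cl_int * scaling.mg_protein_per_g_liver * scaling.g_liver_per_kg_bw


def fraction_unbound_microsomes(log_p: float) -> float:
    """Fraction unbound in the microsomal incubation from lipophilicity.

    Empirical relationship fu_inc = 1 / (1 + 10^(0.53*logP - 1.42)),
    appropriate for basic/neutral compounds at 0.5 mg/mL microsomal protein.
    Strictly decreasing in logP, with range (0, 1).
    """
    if not math.isfinite(log_p):
        raise ValueError("logP must be finite")
    return 1.0 / (1.0 + 10.0 ** (0.53 * log_p - 1.42))


def well_stirred_clearance(
    cl_h_int: float, fu_plasma: float, fu_inc: float, hepatic_blood_flow: float
) -> float:
    """Well-stirred model hepatic clearance (mL/min/kg).

    CL_H,int is first corrected for nonspecific microsomal binding
    (divided by fu_inc); the result is always strictly below Q.
    """
    if hepatic_blood_flow <= 0:
        raise ValueError("hepatic blood flow must be > 0")
    if not 0 < fu_plasma <= 1 or not 0 < fu_inc <= 1:
        raise ValueError("fractions unbound must be in (0, 1]")
    if cl_h_int < 0:
        raise ValueError("CL_H,int must be >= 0")
    clu = fu_plasma * cl_h_int / fu_inc
    return hepatic_blood_flow * clu / (hepatic_blood_flow + clu)


def ivive_chain(
    tc: MicrosomalTimecourse,
    scaling: SpeciesScaling,
    log_p: float | None = None,
) -> IVIVEResult:
    """Run the full chain from a depletion time course to predicted CL_H.

    The well-stirred step runs only when the species scaling carries both a
    hepatic blood flow and a plasma fraction unbound and logP is given;
    otherwise the result stops at CL_H,int.
    """
    fit = fit_monoexponential_decay(tc)
    cl_int = clint_from_halflife(fit.t_half, tc.incubation_volume, tc.protein_mass)
    cl_h_int = scale_clint_to_liver(cl_int, scaling)
    fu_inc = cl_h_predict = None
    if log_p is not None:
        fu_inc = fraction_unbound_microsomes(log_p)
        if scaling.hepatic_blood_flow is not None and scaling.fu_plasma is not None:
            cl_h_predict = well_stirred_clearance(
                cl_h_int, scaling.fu_plasma, fu_inc, scaling.hepatic_blood_flow
            )
    return IVIVEResult(
        species=tc.species,
        k=fit.k,
        t_half=fit.t_half,
        cl_int=cl_int,
        cl_h_int=cl_h_int,
        fu_inc=fu_inc,
        cl_h_predict=cl_h_predict,
    )


# ---------------------------------------------------------------------------
# Protein binding and partitioning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DialysisMeasurement:
    """Equilibrium-dialysis donor/receiver pair (same units both sides)."""

    donor_conc: float
    receiver_conc: float
    matrix: str = "plasma"  # plasma | brain homogenate

    def __post_init__(self) -> None:
        if self.donor_conc <= 0:
            raise ValueError("donor concentration must be > 0")
        if self.receiver_conc < 0 or self.receiver_conc > self.donor_conc:
            raise ValueError("receiver concentration must lie in [0, donor]")


def percent_bound(d: DialysisMeasurement) -> float:
    """Degree of protein binding (%) = 100 * (donor - receiver) / donor."""
    return 100.0 * (d.donor_conc - d.receiver_conc) / d.donor_conc


def fraction_unbound(d: DialysisMeasurement) -> float:
    """fu = receiver / donor, the complementary free fraction."""
    return d.receiver_conc / d.donor_conc


def blood_plasma_ratio(c_blood: float, c_plasma: float) -> float:
    """Blood-to-plasma concentration ratio R_b/p."""
    if c_plasma <= 0:
        raise ValueError("plasma concentration must be > 0")
    return c_blood / c_plasma


# ---------------------------------------------------------------------------
# Permeability
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TranswellAssay:
    """Two-chamber permeability assay geometry plus sampled concentrations.

    For PAMPA a single end-point measurement is sufficient (``times`` of
    length 1); for Caco-2 provide the receiver time course plus the
    withdrawal bookkeeping (each sample removes ``withdrawal_volume`` from
    the receiver, replaced by blank buffer).
    """

    donor_volume: float  # Vd, mL
    acceptor_volume: float  # Va, mL (receiver)
    area: float  # A, cm^2
    times: tuple[float, ...]  # s
    acceptor_conc: tuple[float, ...]  # per time point, receiver chamber
    donor_conc: tuple[float, ...] = ()  # per time point where sampled
    apical_c0: float | None = None  # initial donor conc (Caco-2: nmol/mL)
    withdrawal_volume: float = 0.1  # mL per receiver sample (Caco-2)
    teer: float | None = None  # ohm*cm^2, monolayer-integrity QC

    def __post_init__(self) -> None:
        for name in ("donor_volume", "acceptor_volume", "area"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(self, "acceptor_conc", tuple(float(c) for c in self.acceptor_conc))
        object.__setattr__(self, "donor_conc", tuple(float(c) for c in self.donor_conc))
        if len(self.times) != len(self.acceptor_conc):
            raise ValueError("times and acceptor concentrations must align")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


#: Conventional PAMPA plate geometry: donor 0.3 mL, acceptor 0.2 mL,
#: 0.3 cm^2 filter, 5 h (18000 s) incubation.
PAMPA_GEOMETRY = dict(donor_volume=0.3, acceptor_volume=0.2, area=0.3)
PAMPA_DURATION_S = 18000.0

#: Caco-2 12-well insert: 1.12 cm^2, apical 0.5 mL donor, basolateral 1.5 mL.
CACO2_AREA_CM2 = 1.12
CACO2_RECEIVER_ML = 1.5
CACO2_TEER_MIN = 400.0


def pampa_papp(assay: TranswellAssay) -> float:
    """PAMPA apparent permeability (cm/s) from the end-point mass balance.

    Papp = -ln(1 - Ca(t)/Ceq) / (A * (1/Vd + 1/Va) * t), where Ceq is the
    well-mixed equilibrium concentration (Cd*Vd + Ca*Va)/(Vd + Va). The
    acceptor concentration approaching Ceq means the assay has equilibrated
    and the log term diverges, so Ca >= Ceq is rejected.
    """
    if not assay.donor_conc:
        raise ValueError("PAMPA needs the donor concentration at the end point")
    t = assay.times[-1]
    ca = assay.acceptor_conc[-1]
    cd = assay.donor_conc[-1]
    vd, va = assay.donor_volume, assay.acceptor_volume
    ceq = (cd * vd + ca * va) / (vd + va)
    if ca >= ceq:
        raise ValueError("acceptor at/above equilibrium concentration; assay saturated")
    if ca == 0:
        return 0.0
    return float(-math.log(1.0 - ca / ceq) / (assay.area * (1.0 / vd + 1.0 / va) * t))


@dataclass(frozen=True)
class Caco2Result:
    papp: float  # cm/s
    dq_dt: float  # amount/s, slope of cumulative transport
    r_squared: float
    monolayer_ok: bool  # TEER at/above the acceptance floor (or not recorded)


def caco2_papp(
    assay: TranswellAssay,
    linear_window: tuple[float, float] | None = None,
    withdrawal_correction: bool = True,
) -> Caco2Result:
    """Caco-2 apparent permeability (cm/s) from the receiver time course.

    The cumulative transported amount at sample n is
    ``C_n * V_receiver + sum_{i<n} C_i * V_withdrawn`` — each earlier sample
    physically removed analyte that must be added back, otherwise the flux
    (and hence Papp) is underestimated. dQ/dt is the least-squares slope of
    cumulative amount vs time, by default over all sampled points; pass
    ``linear_window`` (s) to restrict to the linear phase.

    A recorded TEER below 400 ohm*cm^2 marks the monolayer as failed
    (``monolayer_ok=False``); the value is still computed.
    """
    if assay.apical_c0 is None or assay.apical_c0 <= 0:
        raise ValueError("Caco-2 needs the initial apical concentration C0 > 0")
    if len(assay.times) < 3:
        raise ValueError("need >= 3 receiver samples")
    t = np.asarray(assay.times)
    c = np.asarray(assay.acceptor_conc)
    withdrawn = np.concatenate(([0.0], np.cumsum(c[:-1] * assay.withdrawal_volume)))
    q = c * assay.acceptor_volume + (withdrawn if withdrawal_correction else 0.0)
    if linear_window is not None:
        mask = (t >= linear_window[0]) & (t <= linear_window[1])
        if mask.sum() < 2:
            raise ValueError("linear window contains < 2 samples")
        t, q = t[mask], q[mask]
    if np.all(q == 0):
        slope, r2 = 0.0, 1.0
    else:
        fit = stats.linregress(t, q)
        slope, r2 = float(fit.slope), float(fit.rvalue) ** 2
    return Caco2Result(
        papp=slope / (assay.area * assay.apical_c0),
        dq_dt=slope,
        r_squared=r2,
        monolayer_ok=assay.teer is None or assay.teer >= CACO2_TEER_MIN,
    )


# ---------------------------------------------------------------------------
# Solubility and unit conversion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SolubilityResult:
    solubility: float  # ug/mL
    saturated_nominals: tuple[float, ...]
    unsaturated: bool  # True when no level showed saturation


def kinetic_solubility(
    nominal_vs_measured: Sequence[tuple[float, float]],
    deviation_threshold: float = 0.8,
) -> SolubilityResult:
    """Plateau estimate of kinetic solubility from a dilution series.

    A nominal level counts as saturated when the measured concentration
    falls below ``deviation_threshold * nominal``; the solubility is the
    mean measured value across saturated levels. If nothing saturates the
    highest measured value is returned with ``unsaturated=True``.
    """
    if not len(nominal_vs_measured):
        raise ValueError("need at least one (nominal, measured) pair")
    saturated = [(n, m) for n, m in nominal_vs_measured if m < deviation_threshold * n]
    if not saturated:
        return SolubilityResult(
            solubility=float(max(m for _, m in nominal_vs_measured)),
            saturated_nominals=(),
            unsaturated=True,
        )
    return SolubilityResult(
        solubility=float(np.mean([m for _, m in saturated])),
        saturated_nominals=tuple(n for n, _ in saturated),
        unsaturated=False,
    )


#: Default molar mass (g/mol), inferred from a protonated precursor at m/z 484.
DEFAULT_MOLAR_MASS = 483.0


def molar_convert(value: float, direction: str, molar_mass: float = DEFAULT_MOLAR_MASS) -> float:
    """Convert between uM and ng/mL: ng/mL = uM * molar mass (g/mol)."""
    if molar_mass <= 0:
        raise ValueError("molar mass must be > 0")
    if direction in ("uM->ng/mL", "um_to_ng_ml"):
        return value * molar_mass
    if direction in ("ng/mL->uM", "ng_ml_to_um"):
        return value / molar_mass
    raise ValueError(f"unknown direction {direction!r}")
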