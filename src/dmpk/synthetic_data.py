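"""Synthetic-data generators with known ground truth for every assay stage.

Each generator emulates one experimental design of a small-molecule DMPK
study and embeds its generating parameters in the returned object, so that
every estimator in the analysis modules can be exercised as a round trip
against truth:

* one-compartment IV-bolus and first-order-absorption oral plasma profiles
  with lognormal inter-subject variability, proportional residual error and
  LLOQ censoring;
* mono-exponential microsomal depletion (with flat NADPH-free controls);
* equilibrium dialysis at a stated fraction unbound;
* two-chamber diffusion for PAMPA (exact closed form) and constant-flux
  linear-phase transport for Caco-2, including receiver-withdrawal
  bookkeeping;
* heteroscedastic (proportional-error) calibration batches around a known
  response line, with QC replicates;
* tissue profiles at fixed tissue-to-plasma ratios.

All randomness flows through a single ``numpy.random.Generator`` derived
from the config seed: a fixed seed reproduces output bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .invitro import (
    MicrosomalTimecourse,
    DialysisMeasurement,
    TranswellAssay,
    PAMPA_GEOMETRY,
    PAMPA_DURATION_S,
    CACO2_AREA_CM2,
    CACO2_RECEIVER_ML,
)
from .nca import ConcentrationTimeProfile
from .quantitation import CalibrationStandard, QCLevel, DEFAULT_QC_NOMINALS

__all__ = [
    "PKSimulationConfig",
    "CalibrationBatch",
    "DEFAULT_PK_SAMPLING_H",
    "MICROSOMAL_SAMPLING_MIN",
    "CALIBRATION_LEVELS_NG_ML",
    "simulate_plasma_profiles",
    "simulate_microsomal_decay",
    "simulate_dialysis",
    "simulate_transwell",
    "simulate_calibration_batch",
    "simulate_tissue_profiles",
    "profiles_to_frame",
]

#: In vivo sampling schedule (h): 5 min, 15 min, 30 min, 1, 2, 4, 8, 24 h.
DEFAULT_PK_SAMPLING_H: tuple[float, ...] = (5 / 60, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 24.0)

#: Microsomal incubation sampling (min).
MICROSOMAL_SAMPLING_MIN: tuple[float, ...] = (0.0, 5.0, 10.0, 20.0, 30.0, 45.0, 60.0)

#: Nine-point calibration series, 0.2-500 ng/mL.
CALIBRATION_LEVELS_NG_ML: tuple[float, ...] = (0.2, 0.5, 1.0, 2.0, 5.0, 20.0, 50.0, 200.0, 500.0)


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int | None = None):
    """Median-1 lognormal multiplier with the requested coefficient of variation."""
    if cv < 0:
        raise ValueError("CV must be >= 0")
    if cv == 0:
        return np.ones(size) if size else 1.0
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return np.exp(rng.normal(0.0, sigma, size))


@dataclass(frozen=True)
class PKSimulationConfig:
    """Ground truth and study design for a simulated plasma PK study.

    The defaults mirror a mouse single-dose design: IV 2.5 mg/kg or oral
    10 mg/kg, LLOQ 0.2 ng/mL, the standard 8-point sampling schedule, and
    inter-subject CVs sized so that simulated group summaries show the
    ~30-40% SD/mean spread typical of small-n mouse PK.
    """

    model: str  # iv_bolus_1cpt | oral_1cpt
    cl: float  # L/h/kg (true systemic clearance)
    v: float  # L/kg
    dose: float  # mg/kg
    ka: float | None = None  # 1/h, oral only
    f: float = 1.0  # bioavailability fraction, oral only
    times: tuple[float, ...] = DEFAULT_PK_SAMPLING_H
    n_subjects: int = 1
    cv_cl: float = 0.3
    cv_v: float = 0.3
    cv_ka: float = 0.3
    residual_cv: float = 0.0
    lloq: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("iv_bolus_1cpt", "oral_1cpt"):
            raise ValueError(f"unknown model {self.model!r}")
        if min(self.cl, self.v, self.dose) <= 0:
            raise ValueError("CL, V and dose must be > 0")
        if self.model == "oral_1cpt":
            if self.ka is None or self.ka <= 0:
                raise ValueError("oral model needs ka > 0")
            if not 0 < self.f <= 1:
                raise ValueError("F must be in (0, 1]")
        if any(cv < 0 for cv in (self.cv_cl, self.cv_v, self.cv_ka, self.residual_cv)):
            raise ValueError("CVs must be >= 0")


def _one_compartment_conc(
    model: str, t: np.ndarray, cl: float, v: float, dose: float, ka: float | None, f: float
) -> np.ndarray:
    """Closed-form concentration (ng/mL) for dose in mg/kg, V in L/kg."""
    ke = cl / v
    dose_ng_per_ml_v = dose * 1000.0 / v  # mg/kg over L/kg -> ug/mL... x1000 -> ng/mL
    if model == "iv_bolus_1cpt":
        return dose_ng_per_ml_v * np.exp(-ke * t)
    if ka == ke:  # degenerate absorption: perturb to keep the closed form valid
        ka = ke * (1.0 + 1e-6)
    return (
        f * dose_ng_per_ml_v * ka / (ka - ke) * (np.exp(-ke * t) - np.exp(-ka * t))
    )


def simulate_plasma_profiles(cfg: PKSimulationConfig) -> list[ConcentrationTimeProfile]:
    """Simulate per-subject plasma profiles with LLOQ censoring.

    Subject parameters are drawn lognormally (median = truth) around the
    configured CL, V and ka; proportional residual noise is applied per
    sample; anything below the LLOQ is reported as 0 (BLQ), never as a
    small positive value.
    """
    rng = np.random.default_rng(cfg.seed)
    t = np.asarray(cfg.times)
    route = "IV" if cfg.model == "iv_bolus_1cpt" else "PO"
    profiles = []
    for i in range(cfg.n_subjects):
        cl_i = cfg.cl * _lognormal_factor(rng, cfg.cv_cl)
        v_i = cfg.v * _lognormal_factor(rng, cfg.cv_v)
        ka_i = cfg.ka * _lognormal_factor(rng, cfg.cv_ka) if cfg.ka else None
        conc = _one_compartment_conc(cfg.model, t, cl_i, v_i, cfg.dose, ka_i, cfg.f)
        conc = conc * _lognormal_factor(rng, cfg.residual_cv, size=t.size)
        conc = np.where(conc < cfg.lloq, 0.0, conc)
        profiles.append(
            ConcentrationTimeProfile(
                subject_id=f"{route.lower()}{i + 1:03d}",
                route=route,
                dose=cfg.dose,
                times=tuple(t),
                concentrations=tuple(conc),
                lloq=cfg.lloq,
            )
        )
    return profiles


def profiles_to_frame(profiles: Sequence[ConcentrationTimeProfile]) -> pd.DataFrame:
    """Long-format table (the CSV exchange schema) for simulated profiles."""
    rows = [
        {
            "subject_id": p.subject_id,
            "route": p.route,
            "dose_mg_per_kg": p.dose,
            "time_h": t,
            "conc_ng_per_ml": c,
        }
        for p in profiles
        for t, c in zip(p.times, p.concentrations)
    ]
    return pd.DataFrame(rows)


def simulate_microsomal_decay(
    k: float,
    cv: float = 0.0,
    seed: int = 0,
    species: str = "mouse",
    times: Sequence[float] = MICROSOMAL_SAMPLING_MIN,
    nadph_present: bool = True,
) -> MicrosomalTimecourse:
    """Mono-exponential depletion ratios, flat when NADPH is absent.

    ratio(t) = exp(-k t) * (1 + noise); the NADPH-free control is generated
    with k = 0 regardless of the requested rate.
    """
    if k < 0:
        raise ValueError("depletion rate k must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    k_eff = k if nadph_present else 0.0
    ratios = np.exp(-k_eff * t) * _lognormal_factor(rng, cv, size=t.size)
    return MicrosomalTimecourse(
        species=species,
        times=tuple(t),
        response_ratios=tuple(ratios),
        nadph_present=nadph_present,
    )


def simulate_dialysis(
    fu: float,
    donor_conc: float = 100.0,
    cv: float = 0.0,
    seed: int = 0,
    matrix: str = "plasma",
) -> DialysisMeasurement:
    """Equilibrium dialysis: receiver = fu * donor, optional noise on the receiver."""
    if not 0 < fu <= 1:
        raise ValueError("fu must be in (0, 1]")
    rng = np.random.default_rng(seed)
    receiver = min(donor_conc, fu * donor_conc * float(_lognormal_factor(rng, cv)))
    return DialysisMeasurement(donor_conc=donor_conc, receiver_conc=receiver, matrix=matrix)


def simulate_transwell(
    assay: str,
    papp: float,
    c0: float = 10.0,
    cv: float = 0.0,
    seed: int = 0,
    times_s: Sequence[float] | None = None,
    teer: float | None = None,
) -> TranswellAssay:
    """Two-chamber permeability data from a known true Papp (cm/s).

    PAMPA uses the exact mass-balance solution
    ``Ca(t) = Ceq (1 - exp(-Papp A (1/Vd + 1/Va) t))`` with
    ``Ceq = C0 Vd / (Vd + Va)``, sampled at the end point. Caco-2 uses the
    sink-condition linear phase (flux Papp*A*C0) with 0.1 mL receiver
    withdrawals replaced by blank buffer at each sampling time, so the raw
    receiver concentrations genuinely carry the withdrawal artefact.
    """
    if papp < 0:
        raise ValueError("Papp must be >= 0")
    rng = np.random.default_rng(seed)
    if assay == "pampa":
        vd, va, area = (
            PAMPA_GEOMETRY["donor_volume"],
            PAMPA_GEOMETRY["acceptor_volume"],
            PAMPA_GEOMETRY["area"],
        )
        t_end = times_s[-1] if times_s else PAMPA_DURATION_S
        ceq = c0 * vd / (vd + va)
        ca = ceq * (1.0 - math.exp(-papp * area * (1 / vd + 1 / va) * t_end))
        ca *= float(_lognormal_factor(rng, cv))
        cd = (c0 * vd - ca * va) / vd  # mass balance
        return TranswellAssay(
            donor_volume=vd,
            acceptor_volume=va,
            area=area,
            times=(t_end,),
            acceptor_conc=(ca,),
            donor_conc=(cd,),
        )
    if assay == "caco2":
        t = np.asarray(times_s if times_s is not None else [1800, 3600, 5400, 7200], dtype=float)
        flux = papp * CACO2_AREA_CM2 * c0  # nmol/s, constant under sink conditions
        withdrawal, v_r = 0.1, CACO2_RECEIVER_ML
        concs, amount = [], 0.0
        prev_t = 0.0
        for ti in t:
            amount += flux * (ti - prev_t)
            c_i = (amount / v_r) * float(_lognormal_factor(rng, cv))
            concs.append(c_i)
            amount -= c_i * withdrawal  # sample removed, replaced by blank buffer
            prev_t = ti
        return TranswellAssay(
            donor_volume=0.5,
            acceptor_volume=v_r,
            area=CACO2_AREA_CM2,
            times=tuple(t),
            acceptor_conc=tuple(concs),
            apical_c0=c0,
            withdrawal_volume=withdrawal,
            teer=teer,
        )
    raise ValueError(f"unknown assay {assay!r}")


@dataclass(frozen=True)
class CalibrationBatch:
    """Simulated calibration standards plus QC replicates with known truth."""

    standards: tuple[CalibrationStandard, ...]
    qc_levels: tuple[QCLevel, ...]
    true_slope: float
    true_intercept: float


def simulate_calibration_batch(
    slope: float = 0.023,
    intercept: float = 0.006,
    cv: float = 0.0,
    seed: int = 0,
    levels: Sequence[float] = CALIBRATION_LEVELS_NG_ML,
    qc_nominals: Mapping[str, float] = DEFAULT_QC_NOMINALS,
    qc_replicates: int = 3,
    n_runs: int = 1,
    qc_bias: Mapping[str, float] | None = None,
) -> CalibrationBatch:
    """Heteroscedastic calibration responses around a known line.

    Standards get proportional (constant-CV) noise on the response — the
    error structure that motivates 1/x^2 weighting. QC replicate values are
    produced as back-calculated concentrations around nominal with the same
    proportional error, optionally shifted by a per-level fractional bias
    (``qc_bias={'HQC': 0.05}`` injects +5%).
    """
    rng = np.random.default_rng(seed)
    is_area = 1000.0
    standards = tuple(
        CalibrationStandard(
            nominal_conc=x,
            analyte_area=(slope * x + intercept) * float(_lognormal_factor(rng, cv)) * is_area,
            is_area=is_area,
        )
        for x in levels
    )
    qc_bias = qc_bias or {}
    qcs = []
    for run in range(1, n_runs + 1):
        for name, nominal in qc_nominals.items():
            shift = 1.0 + qc_bias.get(name, 0.0)
            values = nominal * shift * _lognormal_factor(rng, cv, size=qc_replicates)
            qcs.append(
                QCLevel(
                    name=name,
                    nominal_conc=nominal,
                    replicate_values=tuple(float(v) for v in values),
                    run_id=f"run{run}",
                )
            )
    return CalibrationBatch(
        standards=standards,
        qc_levels=tuple(qcs),
        true_slope=slope,
        true_intercept=intercept,
    )


def simulate_tissue_profiles(
    plasma_by_time: Mapping[float, float],
    kp_by_tissue: Mapping[str, float],
    cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Tissue contents (ng/g) at fixed tissue-to-plasma ratios.

    content(tissue, t) = Kp_tissue * plasma(t) * (1 + noise); the truth Kp
    values are recoverable exactly on noiseless output.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for tissue, kp in kp_by_tissue.items():
        if kp < 0:
            raise ValueError("Kp must be >= 0")
        for t, plasma in sorted(plasma_by_time.items()):
            rows.append(
                {
                    "tissue": tissue,
                    "time_h": t,
                    "content_ng_per_g": kp * plasma * float(_lognormal_factor(rng, cv)),
                }
            )
    return pd.DataFrame(rows)
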