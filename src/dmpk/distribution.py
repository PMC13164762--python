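"""Tissue and brain disposition metrics.

Converts total tissue contents (ng/g) and plasma concentrations (ng/mL)
into the metrics that matter for CNS exposure: unbound concentrations via
fraction-unbound values from equilibrium dialysis, total tissue-to-plasma
ratios (Kp), the unbound brain-to-plasma partition coefficient
(Kp,uu,brain), and exposure-vs-potency flags against a cellular IC50.

ng/g and ng/mL are treated as numerically commensurate (tissue density
~1 g/mL), the universal convention for Kp.

A published disposition table typically rounds each intermediate before
deriving ratios from the printed cells; the ``RoundingPolicy`` makes that
reproduction explicit and auditable. ``"none"`` (full precision) is the
computational default; ``"printed"`` rounds values to two significant
figures below 10, to the nearest integer at or above 10, and ratios to two
decimals, deriving each ratio from the already-rounded numerator and
denominator as a typesetter would.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "FractionUnbound",
    "RoundingPolicy",
    "BrainPenetrationRow",
    "unbound",
    "kpuu_brain",
    "tissue_kp",
    "exposure_vs_ic50",
    "brain_penetration_table",
    "flag_discrepancies",
]


@dataclass(frozen=True)
class FractionUnbound:
    """Fraction unbound in plasma and brain homogenate (from dialysis)."""

    fu_plasma: float = 0.025
    fu_brain: float = 0.057

    def __post_init__(self) -> None:
        for name in ("fu_plasma", "fu_brain"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass(frozen=True)
class RoundingPolicy:
    """How intermediate values are rounded before ratios are formed."""

    mode: str = "none"  # none | printed

    def __post_init__(self) -> None:
        if self.mode not in ("none", "printed"):
            raise ValueError("rounding mode must be 'none' or 'printed'")

    def value(self, x: float) -> float:
        """Round a concentration/content the way a report table prints it."""
        if self.mode == "none" or x == 0:
            return x
        if abs(x) >= 10:
            return float(round(x))
        # two significant figures
        exp = math.floor(math.log10(abs(x)))
        return float(round(x, 1 - exp))

    def ratio(self, x: float) -> float:
        """Round a dimensionless ratio (two decimals under 'printed')."""
        return x if self.mode == "none" else float(round(x, 2))


FULL_PRECISION = RoundingPolicy("none")
PRINTED = RoundingPolicy("printed")


def unbound(value: float, fu: float, policy: RoundingPolicy = FULL_PRECISION) -> float:
    """Unbound concentration/content = total * fraction unbound."""
    if not 0 < fu <= 1:
        raise ValueError("fraction unbound must be in (0, 1]")
    if value < 0:
        raise ValueError("total concentration must be >= 0")
    return policy.value(value * fu)


def kpuu_brain(
    brain_content: float,
    plasma_conc: float,
    fu: FractionUnbound | None = None,
    policy: RoundingPolicy = FULL_PRECISION,
) -> float:
    """Unbound brain-to-plasma partition coefficient.

    Kp,uu = (brain * fu_brain) / (plasma * fu_plasma). Under the ``printed``
    policy the unbound numerator and denominator are rounded first and the
    ratio is then rounded to two decimals, mirroring how a published table
    derives its cells.
    """
    fu = fu or FractionUnbound()
    if plasma_conc <= 0:
        raise ValueError("plasma concentration must be > 0")
    ub = unbound(brain_content, fu.fu_brain, policy)
    up = unbound(plasma_conc, fu.fu_plasma, policy)
    return policy.ratio(ub / up)


def tissue_kp(tissue_content: float, plasma_conc: float) -> float:
    """Total tissue-to-plasma ratio at a matched time point."""
    if plasma_conc <= 0:
        raise ValueError("plasma concentration must be > 0")
    if tissue_content < 0:
        raise ValueError("tissue content must be >= 0")
    return tissue_content / plasma_conc


def exposure_vs_ic50(conc: float, ic50: float) -> tuple[float, bool]:
    """Concentration as a multiple of the IC50, with an above/below flag."""
    if ic50 <= 0:
        raise ValueError("IC50 must be > 0")
    ratio = conc / ic50
    return ratio, ratio >= 1.0


@dataclass(frozen=True)
class BrainPenetrationRow:
    """One time point of the brain-penetration summary."""

    time_h: float
    brain_content: float  # ng/g, total
    unbound_brain: float  # ng/g
    plasma_conc: float  # ng/mL, total
    unbound_plasma: float  # ng/mL
    kp_uu: float
    unbound_brain_vs_ic50: float | None = None


def brain_penetration_table(
    brain_by_time: Mapping[float, float],
    plasma_by_time: Mapping[float, float],
    fu: FractionUnbound | None = None,
    ic50: float | None = None,
    policy: RoundingPolicy = FULL_PRECISION,
) -> pd.DataFrame:
    """Brain-penetration summary across matched time points.

    Returns one row per time point present in both inputs, with total and
    unbound brain/plasma values, Kp,uu, and (when an IC50 is given) the
    unbound-brain-to-IC50 multiple.
    """
    fu = fu or FractionUnbound()
    times = sorted(set(brain_by_time) & set(plasma_by_time))
    if not times:
        raise ValueError("no matched time points between brain and plasma tables")
    rows = []
    for t in times:
        b, p = brain_by_time[t], plasma_by_time[t]
        ub = unbound(b, fu.fu_brain, policy)
        row = BrainPenetrationRow(
            time_h=t,
            brain_content=b,
            unbound_brain=ub,
            plasma_conc=p,
            unbound_plasma=unbound(p, fu.fu_plasma, policy),
            kp_uu=kpuu_brain(b, p, fu, policy),
            unbound_brain_vs_ic50=(ub / ic50 if ic50 else None),
        )
        rows.append(row.__dict__)
    return pd.DataFrame(rows).set_index("time_h")


def flag_discrepancies(computed: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Cell-by-cell comparison of a computed table against reference values.

    ``computed`` should be built under the ``printed`` rounding policy so
    that both frames carry the same number of printed digits; cells are then
    compared exactly (to 1e-9, guarding float representation). Returns a
    boolean frame, True where the computed cell does NOT reproduce the
    reference. Discrepancies are reported, never silently matched:
    downstream consumers decide what to do with flagged cells.
    """
    common_cols = [c for c in reference.columns if c in computed.columns]
    comp = computed.loc[reference.index, common_cols].astype(float)
    ref = reference[common_cols].astype(float)
    return (comp - ref).abs() > 1e-9
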