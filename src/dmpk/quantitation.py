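"""Calibration-curve fitting, back-calculation, and bioanalytical
method-validation statistics.

Implements the quantitation layer of an LC-MS/MS assay: weighted
least-squares calibration of analyte/IS peak-area ratios against nominal
concentration, back-calculation of unknowns, and the ICH M10 / FDA-style
batch-acceptance statistics (accuracy, precision, recovery, matrix effect,
carryover, selectivity, storage and matrix stability).

Conventions
-----------
* Concentrations are ng mL^-1 throughout; responses are dimensionless
  analyte-to-IS area ratios.
* Accuracy is expressed as % bias, precision as % RSD with the sample
  (n-1) standard deviation.
* Acceptance limits default to the regulatory ones: +/-20% bias / 20% RSD
  at the LLOQ, +/-15% / 15% elsewhere; carryover at most 20% of the LLOQ
  analyte response and 5% of the IS response; storage recovery within
  85-115% of fresh.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "Weighting",
    "CalibrationStandard",
    "CalibrationModel",
    "BackCalculated",
    "QCLevel",
    "ThresholdSet",
    "AccuracyPrecisionRow",
    "CarryoverResult",
    "SelectivityResult",
    "ValidationReport",
    "fit_calibration",
    "predict_response",
    "back_calculate",
    "accuracy_precision",
    "recovery",
    "matrix_effect",
    "carryover_check",
    "selectivity_check",
    "storage_stability",
    "matrix_incubation_remaining",
    "compile_validation_report",
]


class Weighting(str, enum.Enum):
    """Weighting scheme for the calibration regression."""

    NONE = "none"
    ONE_OVER_X = "1/x"
    ONE_OVER_X2 = "1/x2"

    def weights(self, x: np.ndarray) -> np.ndarray:
        if self is Weighting.NONE:
            return np.ones_like(x)
        if np.any(x <= 0):
            raise ValueError(
                f"weighting {self.value!r} requires strictly positive "
                "nominal concentrations"
            )
        return 1.0 / x if self is Weighting.ONE_OVER_X else 1.0 / x**2


@dataclass(frozen=True)
class CalibrationStandard:
    """One calibration point: areas at a known nominal concentration."""

    nominal_conc: float  # ng/mL, > 0
    analyte_area: float
    is_area: float

    def __post_init__(self) -> None:
        if self.nominal_conc <= 0:
            raise ValueError("standard nominal concentration must be > 0")
        if self.is_area <= 0:
            raise ValueError("internal-standard area must be > 0")
        if self.analyte_area < 0:
            raise ValueError("analyte area must be >= 0")

    @property
    def response(self) -> float:
        """Analyte-to-IS peak-area ratio."""
        return self.analyte_area / self.is_area


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted linear calibration: response = intercept + slope * conc."""

    slope: float
    intercept: float
    weighting: Weighting
    r_squared: float
    lloq: float
    uloq: float

    def __post_init__(self) -> None:
        if self.lloq >= self.uloq:
            raise ValueError("calibration range requires lloq < uloq")


@dataclass(frozen=True)
class BackCalculated:
    """Back-calculated concentration with range flags (never clamped)."""

    conc: float
    below_lloq: bool
    above_uloq: bool


def _responses(standards: Sequence[CalibrationStandard]) -> tuple[np.ndarray, np.ndarray]:
    x = np.array([s.nominal_conc for s in standards], dtype=float)
    y = np.array([s.response for s in standards], dtype=float)
    return x, y


def fit_calibration(
    standards: Sequence[CalibrationStandard],
    weighting: Weighting | str = Weighting.ONE_OVER_X2,
) -> CalibrationModel:
    """Weighted least-squares linear fit of response vs nominal concentration.

    With weighting ``1/x2`` the weights are ``1 / nominal**2``, the standard
    choice for bioanalytical assays spanning three orders of magnitude: it
    equalises the relative (rather than absolute) residuals so the low end
    of the curve is not swamped by the high standards.

    ``r_squared`` is the weighted coefficient of determination,
    ``1 - SS_res_w / SS_tot_w`` with both sums taken about the
    weighted mean of the responses.

    Raises
    ------
    ValueError
        If fewer than two distinct nominal levels are supplied (degenerate
        design) or a nonpositive nominal is used with 1/x or 1/x2 weighting.
    """
    weighting = Weighting(weighting)
    x, y = _responses(standards)
    if np.unique(x).size < 2:
        raise ValueError("calibration needs >= 2 distinct nominal levels")
    w = weighting.weights(x)
    fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    intercept, slope = fit.params
    return CalibrationModel(
        slope=float(slope),
        intercept=float(intercept),
        weighting=weighting,
        r_squared=float(fit.rsquared),
        lloq=float(x.min()),
        uloq=float(x.max()),
    )


def predict_response(model: CalibrationModel, conc: float) -> float:
    """Expected response at a concentration under the fitted line."""
    return model.intercept + model.slope * conc


def back_calculate(model: CalibrationModel, response: float) -> BackCalculated:
    """Invert the calibration line; flag out-of-range results without clamping."""
    if model.slope == 0:
        raise ValueError("calibration slope is zero; model is not invertible")
    conc = (response - model.intercept) / model.slope
    return BackCalculated(
        conc=conc,
        below_lloq=conc < model.lloq,
        above_uloq=conc > model.uloq,
    )


# ---------------------------------------------------------------------------
# Batch acceptance statistics
# ---------------------------------------------------------------------------

QC_LEVEL_NAMES = ("LLOQ", "LQC", "MQC", "HQC")

#: QC nominal concentrations of the validated assay (ng/mL); configurable
#: per QCLevel, these are only the conventional defaults.
DEFAULT_QC_NOMINALS: Mapping[str, float] = {
    "LLOQ": 0.2,
    "LQC": 0.5,
    "MQC": 100.0,
    "HQC": 375.0,
}


@dataclass(frozen=True)
class QCLevel:
    """Back-calculated QC replicates at one level within one analytical run."""

    name: str  # LLOQ | LQC | MQC | HQC
    nominal_conc: float
    replicate_values: tuple[float, ...]
    run_id: str = "run1"

    def __post_init__(self) -> None:
        if self.name not in QC_LEVEL_NAMES:
            raise ValueError(f"unknown QC level {self.name!r}")
        if self.nominal_conc <= 0:
            raise ValueError("QC nominal must be > 0")
        object.__setattr__(self, "replicate_values", tuple(float(v) for v in self.replicate_values))


@dataclass(frozen=True)
class ThresholdSet:
    """Acceptance limits for the validation statistics.

    All limits are percentages (of nominal, of mean, or of reference
    response) and must be positive.
    """

    bias_limit_lloq: float = 20.0
    bias_limit: float = 15.0
    rsd_limit_lloq: float = 20.0
    rsd_limit: float = 15.0
    carryover_analyte_fraction: float = 0.20
    carryover_is_fraction: float = 0.05
    matrix_effect_limit: float = 15.0
    stability_low: float = 85.0
    stability_high: float = 115.0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in asdict(self).values()):
            raise ValueError("all acceptance limits must be > 0")

    def bias_limit_for(self, level: str) -> float:
        return self.bias_limit_lloq if level == "LLOQ" else self.bias_limit

    def rsd_limit_for(self, level: str) -> float:
        return self.rsd_limit_lloq if level == "LLOQ" else self.rsd_limit


@dataclass(frozen=True)
class AccuracyPrecisionRow:
    """Bias/RSD for one QC level under one grouping."""

    level: str
    nominal: float
    grouping: str  # intra_day | inter_day
    run_id: str | None  # None when pooled across runs
    n: int
    bias_pct: float
    rsd_pct: float
    bias_pass: bool
    rsd_pass: bool


def _bias_rsd(values: np.ndarray, nominal: float) -> tuple[float, float]:
    mean = values.mean()
    if mean == 0:
        raise ValueError("mean of replicates is zero; RSD undefined")
    bias = 100.0 * (mean - nominal) / nominal
    sd = values.std(ddof=1)
    return float(bias), float(100.0 * sd / mean)


def accuracy_precision(
    levels: Iterable[QCLevel],
    grouping: str = "intra_day",
    thresholds: ThresholdSet | None = None,
) -> list[AccuracyPrecisionRow]:
    """Per-level accuracy (% bias) and precision (% RSD).

    ``intra_day`` groups replicates by ``run_id``; ``inter_day`` pools all
    replicates of a level across runs (not mean-of-daily-means), which is
    the batch-acceptance convention when the pooling rule is not otherwise
    dictated.
    """
    if grouping not in ("intra_day", "inter_day"):
        raise ValueError("grouping must be 'intra_day' or 'inter_day'")
    thresholds = thresholds or ThresholdSet()
    rows: list[AccuracyPrecisionRow] = []
    df = pd.DataFrame(
        [
            {"level": q.name, "nominal": q.nominal_conc, "run_id": q.run_id, "value": v}
            for q in levels
            for v in q.replicate_values
        ]
    )
    if df.empty:
        return rows
    keys = ["level", "nominal"] + (["run_id"] if grouping == "intra_day" else [])
    for key, grp in df.groupby(keys, sort=False):
        level, nominal = key[0], key[1]
        values = grp["value"].to_numpy()
        if values.size < 2:
            raise ValueError(f"level {level}: need >= 2 replicates for statistics")
        bias, rsd = _bias_rsd(values, nominal)
        rows.append(
            AccuracyPrecisionRow(
                level=level,
                nominal=float(nominal),
                grouping=grouping,
                run_id=key[2] if grouping == "intra_day" else None,
                n=int(values.size),
                bias_pct=bias,
                rsd_pct=rsd,
                bias_pass=abs(bias) <= thresholds.bias_limit_for(level),
                rsd_pass=rsd <= thresholds.rsd_limit_for(level),
            )
        )
    return rows


def recovery(extracted_areas: Sequence[float], postspiked_areas: Sequence[float]) -> float:
    """Extraction recovery (%): extracted vs post-extraction-spiked areas."""
    if not len(extracted_areas) or not len(postspiked_areas):
        raise ValueError("recovery needs non-empty area lists")
    post = float(np.mean(postspiked_areas))
    if post <= 0:
        raise ValueError("post-extracted mean area must be > 0")
    return 100.0 * float(np.mean(extracted_areas)) / post


def matrix_effect(postspiked_areas: Sequence[float], neat_areas: Sequence[float]) -> float:
    """Matrix effect (%): ion enhancement (+) or suppression (-) vs neat solution."""
    neat = float(np.mean(neat_areas))
    if neat <= 0:
        raise ValueError("neat mean area must be > 0")
    return 100.0 * (float(np.mean(postspiked_areas)) / neat - 1.0)


@dataclass(frozen=True)
class CarryoverResult:
    analyte_fraction: float
    is_fraction: float
    analyte_pass: bool
    is_pass: bool

    @property
    def passed(self) -> bool:
        return self.analyte_pass and self.is_pass


def carryover_check(
    blank_analyte_response: float,
    lloq_analyte_response: float,
    blank_is_response: float,
    lloq_is_response: float,
    thresholds: ThresholdSet | None = None,
) -> CarryoverResult:
    """Residual signal in a blank injected after the HQC, as LLOQ fractions."""
    thresholds = thresholds or ThresholdSet()
    if lloq_analyte_response <= 0 or lloq_is_response <= 0:
        raise ValueError("LLOQ reference responses must be > 0")
    fa = blank_analyte_response / lloq_analyte_response
    fi = blank_is_response / lloq_is_response
    return CarryoverResult(
        analyte_fraction=fa,
        is_fraction=fi,
        analyte_pass=fa <= thresholds.carryover_analyte_fraction,
        is_pass=fi <= thresholds.carryover_is_fraction,
    )


@dataclass(frozen=True)
class SelectivityResult:
    per_source: tuple[CarryoverResult, ...]

    @property
    def passed(self) -> bool:
        return all(r.passed for r in self.per_source)


def selectivity_check(
    blank_responses_by_source: Sequence[tuple[float, float]],
    lloq_analyte_response: float,
    lloq_is_response: float,
    thresholds: ThresholdSet | None = None,
) -> SelectivityResult:
    """Blank-matrix interference per source, against the LLOQ/IS limits.

    Each source contributes ``(blank_analyte_response, blank_is_response)``;
    six independent matrix lots are conventional.
    """
    if not len(blank_responses_by_source):
        raise ValueError("selectivity needs >= 1 blank source")
    results = tuple(
        carryover_check(a, lloq_analyte_response, i, lloq_is_response, thresholds)
        for a, i in blank_responses_by_source
    )
    return SelectivityResult(per_source=results)


def storage_stability(
    stored_values: Sequence[float],
    fresh_values: Sequence[float],
    thresholds: ThresholdSet | None = None,
) -> tuple[float, bool]:
    """Stability recovery (%) of stored vs freshly prepared QCs, with pass flag."""
    thresholds = thresholds or ThresholdSet()
    fresh = float(np.mean(fresh_values))
    if fresh <= 0:
        raise ValueError("fresh mean must be > 0")
    pct = 100.0 * float(np.mean(stored_values)) / fresh
    return pct, thresholds.stability_low <= pct <= thresholds.stability_high


def matrix_incubation_remaining(conc_5h: float, conc_0h: float) -> float:
    """Percent analyte remaining after matrix incubation (enzymatic stability)."""
    if conc_0h <= 0:
        raise ValueError("time-zero concentration must be > 0")
    return 100.0 * conc_5h / conc_0h


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Self-contained validation summary: statistics plus the limits used.

    Every pass flag stored here is a pure function of the statistics and the
    threshold set, so the report can be re-audited without the raw data.
    """

    thresholds: ThresholdSet
    calibration: CalibrationModel | None = None
    intra_day: list[AccuracyPrecisionRow] = field(default_factory=list)
    inter_day: list[AccuracyPrecisionRow] = field(default_factory=list)
    recovery_pct: dict[str, float] = field(default_factory=dict)
    matrix_effect_pct: dict[str, float] = field(default_factory=dict)
    carryover: CarryoverResult | None = None
    selectivity: SelectivityResult | None = None
    stability_pct: dict[str, tuple[float, bool]] = field(default_factory=dict)

    @property
    def accuracy_precision_pass(self) -> bool:
        rows = self.intra_day + self.inter_day
        return all(r.bias_pass and r.rsd_pass for r in rows)

    @property
    def matrix_effect_pass(self) -> bool:
        lim = self.thresholds.matrix_effect_limit
        return all(abs(v) <= lim for v in self.matrix_effect_pct.values())

    @property
    def stability_pass(self) -> bool:
        return all(ok for _, ok in self.stability_pct.values())

    @property
    def overall_pass(self) -> bool:
        checks = [self.accuracy_precision_pass, self.matrix_effect_pass, self.stability_pass]
        if self.carryover is not None:
            checks.append(self.carryover.passed)
        if self.selectivity is not None:
            checks.append(self.selectivity.passed)
        return all(checks)

    def to_frame(self) -> pd.DataFrame:
        """Accuracy/precision rows as a tidy table."""
        return pd.DataFrame([asdict(r) for r in self.intra_day + self.inter_day])

    def to_dict(self) -> dict:
        d = {
            "thresholds": asdict(self.thresholds),
            "calibration": (
                {
                    "slope": self.calibration.slope,
                    "intercept": self.calibration.intercept,
                    "weighting": self.calibration.weighting.value,
                    "r_squared": self.calibration.r_squared,
                    "range_ng_ml": [self.calibration.lloq, self.calibration.uloq],
                }
                if self.calibration
                else None
            ),
            "accuracy_precision": [asdict(r) for r in self.intra_day + self.inter_day],
            "recovery_pct": self.recovery_pct,
            "matrix_effect_pct": self.matrix_effect_pct,
            "carryover": asdict(self.carryover) if self.carryover else None,
            "selectivity": (
                [asdict(r) for r in self.selectivity.per_source] if self.selectivity else None
            ),
            "stability_pct": {k: {"recovery_pct": v, "pass": ok} for k, (v, ok) in self.stability_pct.items()},
            "pass": {
                "accuracy_precision": self.accuracy_precision_pass,
                "matrix_effect": self.matrix_effect_pass,
                "stability": self.stability_pass,
                "carryover": self.carryover.passed if self.carryover else None,
                "selectivity": self.selectivity.passed if self.selectivity else None,
                "overall": self.overall_pass,
            },
        }
        return d


def compile_validation_report(
    standards: Sequence[CalibrationStandard] | None = None,
    qc_levels: Iterable[QCLevel] = (),
    weighting: Weighting | str = Weighting.ONE_OVER_X2,
    thresholds: ThresholdSet | None = None,
    recovery_areas: Mapping[str, tuple[Sequence[float], Sequence[float]]] | None = None,
    matrix_areas: Mapping[str, tuple[Sequence[float], Sequence[float]]] | None = None,
    carryover_responses: tuple[float, float, float, float] | None = None,
    selectivity_blanks: Sequence[tuple[float, float]] | None = None,
    lloq_responses: tuple[float, float] | None = None,
    stability_values: Mapping[str, tuple[Sequence[float], Sequence[float]]] | None = None,
) -> ValidationReport:
    """Run every validation statistic for which inputs are supplied.

    Parameters are keyed the way a validation batch is organised:
    ``recovery_areas[level] = (extracted, post_spiked)``,
    ``matrix_areas[level] = (post_spiked, neat)``,
    ``stability_values[condition] = (stored, fresh)``.
    """
    thresholds = thresholds or ThresholdSet()
    report = ValidationReport(thresholds=thresholds)
    if standards:
        report.calibration = fit_calibration(standards, weighting)
    qc_levels = list(qc_levels)
    if qc_levels:
        report.intra_day = accuracy_precision(qc_levels, "intra_day", thresholds)
        report.inter_day = accuracy_precision(qc_levels, "inter_day", thresholds)
    for level, (extracted, post) in (recovery_areas or {}).items():
        report.recovery_pct[level] = recovery(extracted, post)
    for level, (post, neat) in (matrix_areas or {}).items():
        report.matrix_effect_pct[level] = matrix_effect(post, neat)
    if carryover_responses is not None:
        report.carryover = carryover_check(*carryover_responses, thresholds=thresholds)
    if selectivity_blanks is not None:
        if lloq_responses is None:
            raise ValueError("selectivity needs lloq_responses=(analyte, is)")
        report.selectivity = selectivity_check(
            selectivity_blanks, lloq_responses[0], lloq_responses[1], thresholds
        )
    for condition, (stored, fresh) in (stability_values or {}).items():
        report.stability_pct[condition] = storage_stability(stored, fresh, thresholds)
    return report
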