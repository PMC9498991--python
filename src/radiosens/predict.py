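"""Grade prediction by inverting the fitted linear laws, and phenotype
classification.

Because SF2 and pATMmax are both linear in the CTCAE grade, a measured
value maps back onto a continuous grade, ``(intercept - value)/|slope|``,
clamped to [0, 5]; the rounded grade (nearest integer, half-up) is reported
alongside, together with an interval propagated from the law's parameter
confidence bounds.  Predictions from different endpoints are deliberately
kept separate -- no merging rule is imposed.

Cell lines are also classified into the four response categories seen in
the data: radioresistant (grade-0-like), intermediate, hyper-radiosensitive
(ATM-like: grade-5 survival and/or absent pATM activity), and LIG4-like
(normal DSB recognition but > 30 residual gamma-H2AX foci).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .cohort import CellLineRecord, patmmax
from .exceptions import MissingDataError, ParameterError
from .laws import FitResult, fit_law
from .simulate import GroundTruthParams

__all__ = [
    "PHENOTYPES",
    "GradePrediction",
    "GradePredictor",
    "grade_from_sf2",
    "grade_from_patmmax",
    "classify_phenotype",
]

PHENOTYPES = ("radioresistant", "intermediate", "hyper_radiosensitive",
              "lig4_like")


@dataclass(frozen=True)
class GradePrediction:
    """A continuous and rounded CTCAE grade inferred from one endpoint."""

    continuous_grade: float
    rounded_grade: int
    source_endpoint: str
    interval: Optional[Tuple[float, float]] = None


def _clamp_grade(value: float) -> float:
    return min(max(value, 0.0), 5.0)


def _round_half_up(value: float) -> int:
    return int(np.floor(value + 0.5))


def _invert_linear(value: float, fit: FitResult, endpoint: str) -> GradePrediction:
    if fit.law != "linear":
        raise ParameterError(
            f"grade inversion needs a linear law, got {fit.law!r}"
        )
    slope, intercept = fit.params["a1"], fit.params["a2"]
    if slope >= 0:
        raise ParameterError(
            f"grade inversion needs a negative slope, got {slope}"
        )
    continuous = _clamp_grade((intercept - value) / abs(slope))
    interval = None
    ci_slope = fit.ci95.get("a1")
    ci_intercept = fit.ci95.get("a2")
    if ci_slope and ci_intercept and all(
        np.isfinite(b) for b in (*ci_slope, *ci_intercept)
    ):
        corners = [
            _clamp_grade((b0 - value) / abs(b1))
            for b0 in ci_intercept for b1 in ci_slope if b1 < 0
        ]
        if corners:
            interval = (min(corners), max(corners))
    return GradePrediction(
        continuous_grade=continuous,
        rounded_grade=_round_half_up(continuous),
        source_endpoint=endpoint,
        interval=interval,
    )


def grade_from_sf2(sf2: float, fit: FitResult) -> GradePrediction:
    """Invert the linear SF2-grade law: each ~11.7 % survival lost is one
    extra CTCAE grade."""
    return _invert_linear(sf2, fit, "sf2")


def grade_from_patmmax(patm: float, fit: FitResult) -> GradePrediction:
    """Invert the linear pATMmax-grade law: each ~6.8 pATM foci lost is one
    extra CTCAE grade."""
    return _invert_linear(patm, fit, "patmmax")


class GradePredictor(BaseEstimator):
    """Predict CTCAE grade from one endpoint via the linear law.

    Either construct from an existing fit (``GradePredictor.from_fit``)
    or call ``fit(endpoint_values, grades)``, which regresses the endpoint
    on the grade and stores the law.  ``predict`` returns continuous
    grades clamped to [0, 5]; ``predict_rounded`` the integer grades.
    """

    def __init__(self, endpoint: str = "sf2"):
        self.endpoint = endpoint

    @classmethod
    def from_fit(cls, fit: FitResult, endpoint: str = "sf2") -> "GradePredictor":
        est = cls(endpoint=endpoint)
        est._set_fit(fit)
        return est

    def _set_fit(self, fit: FitResult) -> None:
        if fit.law != "linear" or fit.params["a1"] >= 0:
            raise ParameterError(
                "grade prediction needs a linear law with negative slope"
            )
        self.fit_result_ = fit
        self.slope_ = fit.params["a1"]
        self.intercept_ = fit.params["a2"]

    def fit(self, X, y):
        grades = np.asarray(y, dtype=float).reshape(-1)
        values = np.asarray(X, dtype=float).reshape(-1)
        self._set_fit(fit_law(grades, values, "linear"))
        return self

    def predict(self, X):
        check_is_fitted(self, "fit_result_")
        values = np.asarray(X, dtype=float).reshape(-1)
        continuous = (self.intercept_ - values) / abs(self.slope_)
        return np.clip(continuous, 0.0, 5.0)

    def predict_rounded(self, X):
        return np.floor(self.predict(X) + 0.5).astype(int)


def classify_phenotype(record: CellLineRecord,
                       params: Optional[GroundTruthParams] = None,
                       fit: Optional[FitResult] = None) -> str:
    """Classify a cell line into the four response categories.

    Checked in order of specificity:

    1. ``lig4_like`` -- early gamma-H2AX foci in the radioresistant range
       (>= 80 % of the physically induced DSB yield, dose x ~40 per Gy)
       together with residual foci above the LIG4 threshold (30/cell):
       normal recognition, gross repair defect.
    2. ``hyper_radiosensitive`` -- pATMmax ~ 0 (no nuclear ATM activity)
       or SF2 within the grade-5 band.
    3. ``radioresistant`` -- predicted grade rounds to 0 (from pATMmax
       against the linear law, or SF2 against the grade-0 band).
    4. ``intermediate`` otherwise.
    """
    params = params or GroundTruthParams()
    if record.patm_10min is None and record.patm_1h is None:
        raise MissingDataError(
            f"record {record.id!r}: pATM endpoints required for classification"
        )
    if record.h2ax_24h is None:
        raise MissingDataError(
            f"record {record.id!r}: h2ax_24h required for classification"
        )
    patm = patmmax(record)
    max_early = params.dose * params.dsb_per_gy
    grade5_band = params.grade5_sf2_mean + 2.0 * params.sf2_sd

    if (record.h2ax_10min is not None
            and record.h2ax_10min >= 0.8 * max_early
            and record.h2ax_24h > params.lig4_residual_h2ax_min):
        return "lig4_like"
    if patm <= 1.0 or (record.sf2 is not None and record.sf2 <= grade5_band):
        return "hyper_radiosensitive"
    if fit is not None:
        predicted = grade_from_patmmax(patm, fit).rounded_grade
    else:
        slope, intercept = params.patm_slope, params.patm_intercept
        predicted = _round_half_up(_clamp_grade((intercept - patm) / abs(slope)))
    if predicted == 0:
        return "radioresistant"
    return "intermediate"
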