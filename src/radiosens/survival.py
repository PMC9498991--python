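"""Linear-quadratic clonogenic survival fitting.

The LQ model writes the clonogenic surviving fraction after an acute dose
D as ``S(D) = exp(-(alpha D + beta D^2))`` with ``alpha`` (per Gy) and
``beta`` (per Gy^2) both non-negative.  Radiosensitivity is summarized by
SF2 = 100 S(2 Gy).

Fitting is done in log space, where the model is linear in (alpha, beta):
``-ln S = alpha D + beta D^2`` solved by non-negative least squares.  This
is exact, convex, and matches the model's parameterization; the dose-0
point defines the plating efficiency and is excluded from the regression
(S = 1 there by construction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import DataError, InsufficientDataError
from .simulate import SurvivalAssay

__all__ = [
    "LQFit",
    "LinearQuadraticSurvival",
    "compute_plating_efficiency",
    "surviving_fraction",
    "fit_lq",
    "fit_assay",
]


@dataclass(frozen=True)
class LQFit:
    """Fitted LQ parameters; ``sf2 = 100 exp(-2 alpha - 4 beta)``."""

    alpha: float
    beta: float
    sf2: float
    residual_sse: float

    def survival(self, dose):
        dose = np.asarray(dose, dtype=float)
        return np.exp(-(self.alpha * dose + self.beta * dose ** 2))


def compute_plating_efficiency(colonies0: int, seeded0: int) -> float:
    """Fraction of unirradiated seeded cells forming > 50-cell colonies."""
    if seeded0 < 1:
        raise DataError(f"seeded cells must be >= 1, got {seeded0}")
    if colonies0 < 0:
        raise DataError(f"colony count must be >= 0, got {colonies0}")
    if colonies0 > seeded0:
        raise DataError(
            f"more colonies ({colonies0}) than seeded cells ({seeded0})"
        )
    return colonies0 / seeded0


def surviving_fraction(colonies: float, seeded: float, pe: float) -> float:
    """Surviving fraction: colonies / (seeded x plating efficiency)."""
    if pe <= 0:
        raise DataError(f"plating efficiency must be > 0, got {pe}")
    return colonies / (seeded * pe)


class LinearQuadraticSurvival(RegressorMixin, BaseEstimator):
    """Least-squares LQ survival model with non-negative alpha, beta.

    Parameters
    ----------
    dose_at_sf : float, default=2.0
        Dose (Gy) at which the summary surviving fraction (``sf_``, in
        percent) is evaluated after fitting.

    Attributes
    ----------
    alpha_ : float
        Linear coefficient (per Gy).
    beta_ : float
        Quadratic coefficient (per Gy^2).
    sf2_ : float
        100 x fitted survival at ``dose_at_sf`` Gy.
    residual_sse_ : float
        Sum of squared residuals in -ln S space.
    result_ : LQFit
        The frozen fit summary.
    """

    def __init__(self, dose_at_sf: float = 2.0):
        self.dose_at_sf = dose_at_sf

    def fit(self, X, y):
        doses = np.asarray(X, dtype=float).reshape(-1)
        survival = np.asarray(y, dtype=float).reshape(-1)
        if doses.shape != survival.shape:
            raise DataError("doses and survival fractions differ in length")
        positive = doses > 0
        doses, survival = doses[positive], survival[positive]
        if len(doses) < 3:
            raise InsufficientDataError(
                f"need >= 3 positive-dose points, got {len(doses)}"
            )
        if np.any(survival <= 0):
            raise DataError("survival fractions must be > 0 (log undefined)")
        if np.any(survival > 1.0 + 1e-12):
            raise DataError("survival fractions must be <= 1")
        design = np.column_stack([doses, doses ** 2])
        target = -np.log(survival)
        coef, _ = nnls(design, target)
        self.alpha_, self.beta_ = float(coef[0]), float(coef[1])
        residuals = target - design @ coef
        self.residual_sse_ = float(residuals @ residuals)
        self.sf2_ = 100.0 * float(
            np.exp(-(self.alpha_ * self.dose_at_sf
                     + self.beta_ * self.dose_at_sf ** 2))
        )
        self.result_ = LQFit(self.alpha_, self.beta_, self.sf2_,
                             self.residual_sse_)
        return self

    def predict(self, X):
        check_is_fitted(self, "alpha_")
        return self.result_.survival(np.asarray(X, dtype=float).reshape(-1))


def fit_lq(doses, survival) -> LQFit:
    """Fit the LQ model to (dose, surviving-fraction) points."""
    return LinearQuadraticSurvival().fit(doses, survival).result_


def fit_assay(assay: SurvivalAssay) -> LQFit:
    """Fit an assay: PE from the 0 Gy point, then the LQ regression."""
    zero = np.flatnonzero(assay.doses == 0)
    if len(zero) == 0:
        raise DataError("assay must include a 0 Gy point for PE")
    i = int(zero[0])
    if assay.colonies[i] > assay.seeded_cells[i]:
        raise DataError("more colonies than seeded cells at 0 Gy")
    pe = assay.colonies[i] / assay.seeded_cells[i]
    if pe <= 0:
        raise DataError("plating efficiency is 0; cannot normalize")
    mask = assay.doses > 0
    survival = [
        surviving_fraction(c, s, pe)
        for c, s in zip(assay.colonies[mask], assay.seeded_cells[mask])
    ]
    survival = np.minimum(np.asarray(survival, dtype=float), 1.0)
    survival = np.maximum(survival, 1e-12)
    return fit_lq(assay.doses[mask], survival)
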