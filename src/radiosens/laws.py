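"""Fitting candidate mathematical laws to endpoint pairs.

The analysis links pairs of radiosensitivity endpoints by trying a small
family of laws -- linear, proportional (through the origin), quadratic
("curvilinear"), exponential and power -- keeping the best least-squares
fit, and declaring the link "complex" when even the best fit is poor.
Exponential and power laws are fitted by true nonlinear least squares on
the natural scale (initialized from the log-linearized regression), so the
reported SSE/RMSE are on the scale of the data.

95 % confidence bounds come from the parameter covariance with Student-t
quantiles at n - p degrees of freedom; adjusted r^2 uses
``1 - (1 - r^2)(n - 1)/(n - p - 1)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Tuple

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .cohort import Cohort, Genotype, patmmax
from .exceptions import (
    DomainError,
    FitError,
    InsufficientDataError,
)

__all__ = [
    "LAWS",
    "FitResult",
    "EndpointLawModel",
    "fit_law",
    "fit_proportional",
    "select_best_law",
    "fit_endpoint_laws",
]

LAWS = ("linear", "proportional", "quadratic", "exponential", "power")

#: number of free parameters per law
_N_PARAMS = {"linear": 2, "proportional": 1, "quadratic": 3,
             "exponential": 2, "power": 2}


@dataclass(frozen=True)
class FitResult:
    """A fitted law with parameters, CIs and goodness-of-fit.

    ``params`` maps parameter names to values (``a1``/``a2`` for linear and
    proportional laws, ``a``/``b`` for exponential and power,
    ``a1``/``a2``/``a3`` for quadratic); ``ci95`` maps the same names to
    (low, high) 95 % confidence bounds.  ``complex_flag`` is set by
    :func:`select_best_law` when no candidate law fits acceptably.
    """

    law: str
    params: Dict[str, float]
    ci95: Dict[str, Tuple[float, float]]
    r2: float
    r2_adjusted: float
    sse: float
    rmse: float
    n: int
    complex_flag: bool = False

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.law == "linear":
            return p["a1"] * x + p["a2"]
        if self.law == "proportional":
            return p["a1"] * x
        if self.law == "quadratic":
            return p["a1"] * x ** 2 + p["a2"] * x + p["a3"]
        if self.law == "exponential":
            return p["a"] * np.exp(p["b"] * x)
        if self.law == "power":
            return p["a"] * np.power(x, p["b"])
        raise ValueError(f"unknown law {self.law!r}")

    def to_dict(self) -> dict:
        """Serializable report row (function, parameters, CIs, fit quality)."""
        return {
            "law": self.law,
            "params": dict(self.params),
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "r2": self.r2,
            "r2_adjusted": self.r2_adjusted,
            "sse": self.sse,
            "rmse": self.rmse,
            "n": self.n,
            "complex_flag": self.complex_flag,
        }


def _check_xy(x, y, min_points: int):
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.shape != y.shape:
        raise InsufficientDataError("x and y differ in length")
    if len(x) < min_points:
        raise InsufficientDataError(
            f"need >= {min_points} points, got {len(x)}"
        )
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DomainError("x and y must be finite")
    return x, y


def _goodness(y: np.ndarray, residuals: np.ndarray, n_params: int):
    n = len(y)
    sse = float(residuals @ residuals)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if sst == 0 else 1.0 - sse / sst
    df_adj = n - n_params - 1
    r2_adj = r2 if df_adj <= 0 else 1.0 - (1.0 - r2) * (n - 1) / df_adj
    df = max(n - n_params, 1)
    rmse = math.sqrt(sse / df)
    return r2, r2_adj, sse, rmse


def _ci_from_cov(values: np.ndarray, cov: np.ndarray, names, df: int):
    ci = {}
    tq = stats.t.ppf(0.975, df) if df > 0 else math.inf
    for i, name in enumerate(names):
        se = math.sqrt(max(cov[i, i], 0.0)) if np.isfinite(cov[i, i]) else math.inf
        ci[name] = (values[i] - tq * se, values[i] + tq * se)
    return ci


def _fit_linear_family(x, y, degree: int, names) -> FitResult:
    # polynomial design, highest power first, with intercept
    design = np.column_stack([x ** d for d in range(degree, -1, -1)])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise FitError("rank-deficient design (x values carry no variation)")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    residuals = y - design @ coef
    n_params = degree + 1
    r2, r2_adj, sse, rmse = _goodness(y, residuals, n_params)
    df = len(y) - n_params
    sigma2 = sse / df if df > 0 else 0.0
    cov = sigma2 * np.linalg.inv(design.T @ design)
    law = "linear" if degree == 1 else "quadratic"
    return FitResult(law=law, params=dict(zip(names, map(float, coef))),
                     ci95=_ci_from_cov(coef, cov, names, df),
                     r2=r2, r2_adjusted=r2_adj, sse=sse, rmse=rmse, n=len(y))


def fit_proportional(x, y) -> FitResult:
    """Single-parameter through-origin least squares: a1 = sum(xy)/sum(x^2)."""
    x, y = _check_xy(x, y, min_points=1)
    sxx = float(x @ x)
    if sxx == 0:
        raise FitError("all x are 0; proportional law is unidentifiable")
    a1 = float(x @ y) / sxx
    residuals = y - a1 * x
    r2, r2_adj, sse, rmse = _goodness(y, residuals, 1)
    df = len(y) - 1
    sigma2 = sse / df if df > 0 else 0.0
    cov = np.array([[sigma2 / sxx]])
    return FitResult(law="proportional", params={"a1": a1},
                     ci95=_ci_from_cov(np.array([a1]), cov, ["a1"], df),
                     r2=r2, r2_adjusted=r2_adj, sse=sse, rmse=rmse, n=len(y))


def _fit_curve(x, y, law: str) -> FitResult:
    if law == "exponential":
        if np.any(y <= 0):
            raise DomainError("exponential law requires y > 0")
        model: Callable = lambda x, a, b: a * np.exp(b * x)
        # log-linearized start values
        slope, intercept = np.polyfit(x, np.log(y), 1)
        p0 = (math.exp(intercept), slope)
        names = ("a", "b")
    elif law == "power":
        if np.any(y <= 0):
            raise DomainError("power law requires y > 0")
        if np.any(x <= 0):
            raise DomainError("power law requires x > 0")
        model = lambda x, a, b: a * np.power(x, b)
        slope, intercept = np.polyfit(np.log(x), np.log(y), 1)
        p0 = (math.exp(intercept), slope)
        names = ("a", "b")
    else:  # pragma: no cover - guarded by caller
        raise ValueError(law)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = optimize.curve_fit(model, x, y, p0=p0, maxfev=20000)
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitError(f"{law} fit did not converge: {exc}") from exc
    residuals = y - model(x, *popt)
    r2, r2_adj, sse, rmse = _goodness(y, residuals, 2)
    df = len(y) - 2
    return FitResult(law=law, params=dict(zip(names, map(float, popt))),
                     ci95=_ci_from_cov(popt, pcov, names, df),
                     r2=r2, r2_adjusted=r2_adj, sse=sse, rmse=rmse, n=len(y))


def fit_law(x, y, law: str) -> FitResult:
    """Least-squares fit of one candidate law to an endpoint pair."""
    if law not in LAWS:
        raise ValueError(f"unknown law {law!r}; choose from {LAWS}")
    x, y = _check_xy(x, y, min_points=2 if law == "proportional" else 3)
    if law == "linear":
        return _fit_linear_family(x, y, 1, ("a1", "a2"))
    if law == "quadratic":
        return _fit_linear_family(x, y, 2, ("a1", "a2", "a3"))
    if law == "proportional":
        return fit_proportional(x, y)
    return _fit_curve(x, y, law)


def select_best_law(x, y, complex_threshold: float = 0.70,
                    rmse_tol: float = 0.10) -> FitResult:
    """Fit every applicable law; keep the lowest-RMSE fit.

    An extra parameter must buy a substantially better fit: among laws
    whose RMSE lies within ``rmse_tol`` (relative) of the minimum, the one
    with the fewest parameters wins.  When even the winner's adjusted r^2
    falls below ``complex_threshold`` the link between the two endpoints
    is flagged "complex" (to be resolved by crossing other laws).
    """
    x, y = _check_xy(x, y, min_points=3)
    candidates = []
    for law in LAWS:
        try:
            candidates.append(fit_law(x, y, law))
        except (DomainError, FitError):
            continue
    if not candidates:
        raise FitError("no candidate law could be fitted")
    best_rmse = min(f.rmse for f in candidates)
    near = [f for f in candidates if f.rmse <= best_rmse * (1.0 + rmse_tol)]
    best = min(near, key=lambda f: (_N_PARAMS[f.law], f.rmse))
    if best.r2_adjusted < complex_threshold:
        best = FitResult(**{**best.__dict__, "complex_flag": True})
    return best


class EndpointLawModel(RegressorMixin, BaseEstimator):
    """Scikit-learn style wrapper around the candidate-law fits.

    Parameters
    ----------
    law : str, default="auto"
        One of ``linear``, ``proportional``, ``quadratic``, ``exponential``,
        ``power``, or ``auto`` for best-law selection.
    complex_threshold : float, default=0.70
        Adjusted-r^2 acceptability threshold used in ``auto`` mode.

    Attributes
    ----------
    result_ : FitResult
    law_ : str
        The fitted (possibly selected) law.
    params_ : dict
    complex_flag_ : bool
    """

    def __init__(self, law: str = "auto", complex_threshold: float = 0.70):
        self.law = law
        self.complex_threshold = complex_threshold

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        if self.law == "auto":
            self.result_ = select_best_law(x, y, self.complex_threshold)
        else:
            self.result_ = fit_law(x, y, self.law)
        self.law_ = self.result_.law
        self.params_ = dict(self.result_.params)
        self.complex_flag_ = self.result_.complex_flag
        return self

    def predict(self, X):
        check_is_fitted(self, "result_")
        return self.result_.predict(np.asarray(X, dtype=float).reshape(-1))


#: the five inter-endpoint relations of the reference analysis and how each
#: is modelled (endpoint extraction, law, and record filter)
_LAW_PLAN = (
    ("sf2_vs_grade", "linear", "ctcae_grade", "sf2", None),
    ("sf2_vs_mn24h", "exponential", "mn_24h", "sf2", None),
    ("sf2_vs_h2ax24h", "exponential", "h2ax_24h", "sf2", "no_atm"),
    ("patmmax_vs_grade", "linear", "ctcae_grade", "patmmax", None),
    ("sf2_vs_patmmax", "proportional", "patmmax", "sf2", "no_lig4"),
)


def _endpoint_value(record, name: str) -> Optional[float]:
    if name == "patmmax":
        if record.patm_10min is None and record.patm_1h is None:
            return None
        return patmmax(record)
    return getattr(record, name)


def fit_endpoint_laws(cohort: Cohort, complex_threshold: float = 0.70,
                      include: Optional[Tuple[str, ...]] = None) -> Dict[str, FitResult]:
    """Fit the five reference inter-endpoint laws on a cohort.

    Records missing either endpoint of a pair are dropped for that pair.
    Two phenotype-driven exclusions apply: ATM-null lines are excluded from
    the SF2-vs-residual-H2AX fit (their nil residual-foci count reflects
    the absence of H2AX phosphorylation, not repaired DSBs), and LIG4
    lines are excluded from the SF2-vs-pATMmax proportional fit (their
    normal ATM activity with grade-5 survival is the known fourth-category
    outlier of that relation, and a through-origin fit has no intercept to
    absorb it).  Both lines stay in every other fit.
    """
    results: Dict[str, FitResult] = {}
    for name, law, xfield, yfield, flt in _LAW_PLAN:
        if include is not None and name not in include:
            continue
        xs, ys = [], []
        for rec in cohort:
            if flt == "no_atm" and rec.genotype is Genotype.ATM_HOMOZYGOUS:
                continue
            if flt == "no_lig4" and rec.genotype is Genotype.LIG4_MUTATED:
                continue
            xv = _endpoint_value(rec, xfield)
            yv = _endpoint_value(rec, yfield)
            if xv is None or yv is None:
                continue
            xs.append(xv)
            ys.append(yv)
        results[name] = fit_law(xs, ys, law)
    return results
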