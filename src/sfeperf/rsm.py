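"""Response-surface regression on coded CCD factors.

Fits ordinary-least-squares polynomial models of three kinds:

``linear``
    intercept + main effects A, B, C
``2fi``
    linear + two-factor interactions AB, AC, BC
``quadratic``
    2fi + pure quadratic terms A^2, B^2, C^2

All fitting happens on the *coded* scale, so coefficient magnitudes are
directly comparable across factors (the Design-Expert convention). Fit
quality is summarised by R^2, the usual degrees-of-freedom adjusted R^2, and
predicted R^2 computed from the PRESS statistic (leave-one-out residuals
``e_i / (1 - h_ii)`` via the hat matrix).

The lack-of-fit test splits the residual sum of squares into pure error —
estimated from replicated design points, for a CCD the centre runs — and
lack-of-fit, and compares their mean squares with an F test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize as sp_optimize
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .design import DesignTable, FactorSpec, code_levels
from .exceptions import NotFittedError, RankDeficiencyError

__all__ = [
    "ResponseSurfaceRegressor",
    "LackOfFitResult",
    "fit_model",
    "anova",
    "predict_at",
    "optimize_response",
    "model_terms",
]

_ORDERS = ("linear", "2fi", "quadratic")


def model_terms(order: str, names: Sequence[str] = ("A", "B", "C")) -> list[str]:
    """Term labels (excluding the intercept) for a model order."""
    if order not in _ORDERS:
        raise ValueError(f"order must be one of {_ORDERS}, got {order!r}")
    a, b, c = names
    terms = [a, b, c]
    if order in ("2fi", "quadratic"):
        terms += [a + b, a + c, b + c]
    if order == "quadratic":
        terms += [a + "^2", b + "^2", c + "^2"]
    return terms


def _expand(X: np.ndarray, order: str) -> np.ndarray:
    a, b, c = X[:, 0], X[:, 1], X[:, 2]
    cols = [a, b, c]
    if order in ("2fi", "quadratic"):
        cols += [a * b, a * c, b * c]
    if order == "quadratic":
        cols += [a * a, b * b, c * c]
    return np.column_stack(cols)


@dataclass
class LackOfFitResult:
    """Lack-of-fit F test against pure error from replicated runs."""

    ss_lack_of_fit: float
    df_lack_of_fit: int
    ss_pure_error: float
    df_pure_error: int
    f_statistic: float | None
    p_value: float | None
    available: bool
    reason: str = ""


class ResponseSurfaceRegressor(RegressorMixin, BaseEstimator):
    """OLS polynomial response-surface model on three coded factors.

    Parameters
    ----------
    order : {"linear", "2fi", "quadratic"}, default "quadratic"
        Which polynomial family to fit.
    factor_names : tuple of str, default ("A", "B", "C")
        Labels used for term names in reports.

    Attributes
    ----------
    intercept_ : float
    coef_ : ndarray of shape (n_terms,)
        Non-intercept coefficients, ordered as :meth:`terms_`.
    terms_ : list of str
        Non-intercept term labels.
    r2_, adj_r2_, pred_r2_ : float
        Coefficient of determination, its df-adjusted version, and the
        PRESS-based predicted R^2. ``nan`` when the response is constant
        (see ``degenerate_response_``).
    press_ : float
        Prediction error sum of squares from leave-one-out residuals.
    f_statistic_, f_pvalue_ : float
        Overall model F test.
    term_pvalues_ : dict
        Partial (type III) p-value per non-intercept term.
    lack_of_fit_ : LackOfFitResult or None
        Populated by :meth:`anova_` / :func:`anova`.
    degenerate_response_ : bool
        True when SS_total == 0 so R^2-type statistics are undefined.
    """

    def __init__(self, order: str = "quadratic", factor_names=("A", "B", "C")):
        self.order = order
        self.factor_names = factor_names

    # ------------------------------------------------------------------ fit
    def fit(self, X, y):
        if self.order not in _ORDERS:
            raise ValueError(f"order must be one of {_ORDERS}, got {self.order!r}")
        X, y = check_X_y(X, y, ensure_min_features=3)
        if X.shape[1] != 3:
            raise ValueError(f"expected 3 coded factors, got {X.shape[1]} columns")
        terms = model_terms(self.order, self.factor_names)
        M = sm.add_constant(_expand(X, self.order), has_constant="add")
        n, p = M.shape
        if n <= p:
            raise ValueError(f"need more runs ({n}) than model terms ({p})")
        rank = np.linalg.matrix_rank(M)
        if rank < p:
            # identify columns whose removal restores full rank
            bad = []
            for j in range(1, p):
                keep = [k for k in range(p) if k != j]
                if np.linalg.matrix_rank(M[:, keep]) == rank:
                    bad.append(terms[j - 1])
            raise RankDeficiencyError(bad or terms)

        res = sm.OLS(y, M).fit()
        h = res.get_influence().hat_matrix_diag
        press = float(np.sum((res.resid / (1.0 - h)) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))

        self.n_features_in_ = 3
        self.terms_ = terms
        self.intercept_ = float(res.params[0])
        self.coef_ = np.asarray(res.params[1:], dtype=float)
        self.press_ = press
        self.residuals_ = np.asarray(res.resid, dtype=float)
        self.leverage_ = np.asarray(h, dtype=float)
        self.ss_total_ = ss_tot
        self.ss_residual_ = float(np.sum(res.resid**2))
        self.degenerate_response_ = ss_tot <= 1e-300
        if self.degenerate_response_:
            self.r2_ = self.adj_r2_ = self.pred_r2_ = float("nan")
            self.f_statistic_ = self.f_pvalue_ = float("nan")
            self.term_pvalues_ = {t: float("nan") for t in terms}
        else:
            self.r2_ = float(res.rsquared)
            self.adj_r2_ = float(res.rsquared_adj)
            self.pred_r2_ = 1.0 - press / ss_tot
            self.f_statistic_ = float(res.fvalue)
            self.f_pvalue_ = float(res.f_pvalue)
            self.term_pvalues_ = {
                t: float(p) for t, p in zip(terms, res.pvalues[1:])
            }
        self.df_residual_ = int(res.df_resid)
        self.lack_of_fit_ = None
        self._sm_result = res
        return self

    # -------------------------------------------------------------- predict
    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, ensure_min_features=3)
        return self.intercept_ + _expand(X, self.order) @ self.coef_

    # ---------------------------------------------------------------- anova
    def anova_(self, X, y) -> LackOfFitResult:
        """Lack-of-fit test using pure error from replicated design points.

        Rows of ``X`` that are exactly identical are treated as replicates;
        for the standard CCD these are the centre runs.
        """
        check_is_fitted(self, "coef_")
        X, y = check_X_y(X, y, ensure_min_features=3)
        df = pd.DataFrame(X)
        groups = df.groupby(list(df.columns), sort=False).indices
        ss_pe = 0.0
        df_pe = 0
        for idx in groups.values():
            if len(idx) > 1:
                vals = y[list(idx)]
                ss_pe += float(np.sum((vals - vals.mean()) ** 2))
                df_pe += len(idx) - 1
        ss_res = float(np.sum((y - self.predict(X)) ** 2))
        df_res = len(y) - (len(self.terms_) + 1)
        if df_pe == 0:
            result = LackOfFitResult(
                ss_lack_of_fit=ss_res,
                df_lack_of_fit=df_res,
                ss_pure_error=0.0,
                df_pure_error=0,
                f_statistic=None,
                p_value=None,
                available=False,
                reason="no replicated design points; pure error not estimable",
            )
        else:
            ss_lof = max(ss_res - ss_pe, 0.0)
            df_lof = df_res - df_pe
            if df_lof <= 0:
                result = LackOfFitResult(
                    ss_lof, df_lof, ss_pe, df_pe, None, None, False,
                    reason="model saturates the distinct design points",
                )
            else:
                f = (ss_lof / df_lof) / (ss_pe / df_pe)
                p = float(stats.f.sf(f, df_lof, df_pe))
                result = LackOfFitResult(ss_lof, df_lof, ss_pe, df_pe, f, p, True)
        self.lack_of_fit_ = result
        return result

    # --------------------------------------------------------------- report
    def summary_frame(self) -> pd.DataFrame:
        check_is_fitted(self, "coef_")
        return pd.DataFrame(
            {
                "term": self.terms_,
                "coefficient": self.coef_,
                "p_value": [self.term_pvalues_[t] for t in self.terms_],
                "significant": [
                    self.term_pvalues_[t] < 0.05 for t in self.terms_
                ],
            }
        )

    def to_dict(self) -> dict:
        check_is_fitted(self, "coef_")
        lof = self.lack_of_fit_
        return {
            "order": self.order,
            "intercept": self.intercept_,
            "coefficients": dict(zip(self.terms_, map(float, self.coef_))),
            "r2": self.r2_,
            "adj_r2": self.adj_r2_,
            "pred_r2": self.pred_r2_,
            "press": self.press_,
            "f_statistic": self.f_statistic_,
            "f_pvalue": self.f_pvalue_,
            "term_pvalues": self.term_pvalues_,
            "lack_of_fit_pvalue": (lof.p_value if lof and lof.available else None),
        }


# ---------------------------------------------------------------- wrappers


def fit_model(
    design: DesignTable, response: Sequence[float] | pd.Series, order: str
) -> ResponseSurfaceRegressor:
    """Fit a response-surface model to a design table and response vector."""
    y = np.asarray(response, dtype=float)
    est = ResponseSurfaceRegressor(order=order)
    est.fit(design.coded_matrix(), y)
    return est


def anova(
    fitted: ResponseSurfaceRegressor,
    design: DesignTable,
    response: Sequence[float] | pd.Series,
) -> LackOfFitResult:
    """Populate the fitted model's lack-of-fit statistics from replicates."""
    return fitted.anova_(design.coded_matrix(), np.asarray(response, dtype=float))


def predict_at(
    fitted: ResponseSurfaceRegressor,
    actual_point: Sequence[float],
    factors: Sequence[FactorSpec],
    warn_outside: bool = True,
) -> float:
    """Predict the response at a point given on the actual factor scale.

    Points outside the coded axial box are extrapolations; a warning is
    emitted but the polynomial is still evaluated.
    """
    try:
        check_is_fitted(fitted, "coef_")
    except Exception as exc:  # sklearn NotFittedError
        raise NotFittedError("model must be fitted before predicting") from exc
    coded = code_levels(actual_point, factors)
    lo = np.array([f.code(f.axial_low) for f in factors])
    hi = np.array([f.code(f.axial_high) for f in factors])
    if warn_outside and (np.any(coded < lo - 1e-9) or np.any(coded > hi + 1e-9)):
        import warnings

        warnings.warn(
            f"point {tuple(actual_point)} lies outside the design region; "
            "prediction is an extrapolation",
            stacklevel=2,
        )
    return float(fitted.predict(coded.reshape(1, -1))[0])


def _quadratic_stationary_point(est: ResponseSurfaceRegressor) -> np.ndarray | None:
    """Analytic stationary point of a quadratic surface, or None."""
    if est.order != "quadratic":
        return None
    b = est.coef_[:3]
    ab, ac, bc = est.coef_[3:6]
    aa, bb, cc = est.coef_[6:9]
    H = np.array([[2 * aa, ab, ac], [ab, 2 * bb, bc], [ac, bc, 2 * cc]])
    if abs(np.linalg.det(H)) < 1e-12:
        return None
    return np.linalg.solve(H, -b)


def optimize_response(
    fitted: ResponseSurfaceRegressor,
    factors: Sequence[FactorSpec],
    bounds: Sequence[tuple[float, float]] | None = None,
    maximize: bool = True,
    n_starts_per_axis: int = 4,
) -> tuple[np.ndarray, float]:
    """Optimise the fitted polynomial over a coded box.

    Multi-start L-BFGS-B from a deterministic grid of starting points; for
    quadratic models the interior stationary point is also checked
    analytically. For models without curvature (linear, 2fi) the optimum
    necessarily sits on the box boundary.

    Parameters
    ----------
    bounds : list of (low, high) in coded units, optional
        Defaults to the coded axial box of ``factors``.

    Returns
    -------
    (actual_optimum, predicted_value)
        Optimum on the actual factor scale and the model prediction there.
    """
    check_is_fitted(fitted, "coef_")
    if bounds is None:
        bounds = [(f.code(f.axial_low), f.code(f.axial_high)) for f in factors]
    bounds = [tuple(map(float, b)) for b in bounds]
    sign = -1.0 if maximize else 1.0

    def objective(x):
        return sign * float(fitted.predict(x.reshape(1, -1))[0])

    grids = [np.linspace(lo, hi, n_starts_per_axis) for lo, hi in bounds]
    starts = [np.array(p) for p in itertools.product(*grids)]
    sp = _quadratic_stationary_point(fitted)
    if sp is not None and all(
        lo - 1e-9 <= v <= hi + 1e-9 for v, (lo, hi) in zip(sp, bounds)
    ):
        starts.append(np.clip(sp, [b[0] for b in bounds], [b[1] for b in bounds]))

    best_x, best_f = None, np.inf
    for x0 in starts:
        res = sp_optimize.minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-10},
        )
        if res.fun < best_f - 1e-8:
            best_x, best_f = res.x, res.fun
    coded_opt = np.clip(best_x, [b[0] for b in bounds], [b[1] for b in bounds])
    from .design import decode_levels

    actual = decode_levels(coded_opt, factors)
    return actual, float(fitted.predict(coded_opt.reshape(1, -1))[0])
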