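"""Stepwise multiple linear regression (SMLR) and per-group curve fits.

SMLR selects, from a candidate pool of spectral indices, the subset
that explains the most variation in a yield trait: forward entry of the
candidate with the smallest partial-F p-value (equivalently the t-test
of its coefficient given the current model) when below ``alpha_enter``,
followed by backward removal of any included variable whose p-value
exceeds ``alpha_remove``, iterated to a fixed point.  The final model is
reported as an ordinary-least-squares fit with R² and RMSE
(``sqrt(SSE/n)``; the n-denominator convention is configurable).

Per-group fits compare a linear and a quadratic model of a trait on a
single index, keeping the quadratic only when it improves R² by more
than a parsimony margin, and attach the significance code of the
model's overall F test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin


def significance_code(p: float) -> str:
    """Star coding: *** p<0.001, ** p<0.01, * p<0.05, else ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class RegressionReport:
    """Final SMLR model for one dependent trait."""

    dependent: str
    selected: list
    coefficients: dict          # {"intercept": b0, name: slope, ...}
    r_squared: float
    rmse: float
    n: int

    def equation(self, ndigits: int = 3) -> str:
        terms = [f"{self.coefficients['intercept']:.{ndigits}f}"]
        for name in self.selected:
            b = self.coefficients[name]
            terms.append(f"{'+' if b >= 0 else '-'} {abs(b):.{ndigits}f}({name})")
        return f"{self.dependent} = " + " ".join(terms)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        y = np.full(len(X), self.coefficients["intercept"], dtype=float)
        for name in self.selected:
            y += self.coefficients[name] * X[name].to_numpy(float)
        return y


def fit_report(X, y, ddof: int = 0):
    """OLS fit with intercept; returns (coefficients, r_squared, rmse).

    ``rmse = sqrt(SSE / (n - ddof))``; the default ddof=0 uses the plain
    n denominator.  R² is NaN when y is constant (SST = 0).
    """
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(y)) == X.shape[1]:
        X = X.T
    y = np.asarray(y, float)
    n = len(y)
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design matrix")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = np.nan if sst == 0 else 1.0 - sse / sst
    rmse = float(np.sqrt(sse / (n - ddof)))
    return beta, r2, rmse


class StepwiseLinearRegression(BaseEstimator, RegressorMixin):
    """scikit-learn style stepwise OLS over named candidate columns.

    Parameters
    ----------
    alpha_enter : float, default 0.05
        Largest partial-F p-value at which a candidate may enter.
    alpha_remove : float, default 0.10
        Smallest p-value at which an included variable is removed;
        must be >= alpha_enter or the procedure could cycle.
    rmse_ddof : int, default 0
        Denominator correction for the reported RMSE.

    Fitted attributes: ``selected_`` (entry order), ``coef_``,
    ``intercept_``, ``r_squared_``, ``rmse_``, ``report_``.
    """

    def __init__(self, alpha_enter: float = 0.05, alpha_remove: float = 0.10,
                 rmse_ddof: int = 0):
        self.alpha_enter = alpha_enter
        self.alpha_remove = alpha_remove
        self.rmse_ddof = rmse_ddof

    def fit(self, X: pd.DataFrame, y, dependent_name: str | None = None):
        if self.alpha_remove < self.alpha_enter:
            raise ValueError("alpha_remove must be >= alpha_enter")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, float),
                             columns=[f"x{i}" for i in range(np.shape(X)[1])])
        if X.shape[1] == 0:
            raise ValueError("empty candidate set")
        if X.isna().any().any() or pd.isna(np.asarray(y, float)).any():
            raise ValueError("missing cells in X or y")
        y = pd.Series(np.asarray(y, float), index=X.index)
        candidates = list(X.columns)
        selected: list = []
        sst = float(((y - y.mean()) ** 2).sum())
        while True:
            changed = False
            # forward entry: smallest partial-F p-value below alpha_enter;
            # skipped once the model is numerically perfect (p-values on
            # round-off residuals are meaningless)
            if selected and sst > 0:
                _, r2_now, _ = fit_report(X[selected].to_numpy(float),
                                          y.to_numpy())
                if r2_now > 1.0 - 1e-10:
                    break
            best_name, best_p = None, np.inf
            for name in candidates:
                if name in selected:
                    continue
                p = self._term_pvalue(X, y, selected + [name], name)
                if p is not None and p < best_p - 1e-15:
                    best_name, best_p = name, p
            if best_name is not None and best_p < self.alpha_enter:
                selected.append(best_name)
                changed = True
            # backward elimination: drop worst variable above alpha_remove
            while selected:
                pvals = {
                    name: self._term_pvalue(X, y, selected, name) for name in selected
                }
                worst = max(pvals, key=lambda k: pvals[k])
                if pvals[worst] is not None and pvals[worst] > self.alpha_remove:
                    selected.remove(worst)
                    changed = True
                else:
                    break
            if not changed:
                break
        beta, r2, rmse = fit_report(
            X[selected].to_numpy(float) if selected else np.empty((len(y), 0)),
            y.to_numpy(),
            ddof=self.rmse_ddof,
        )
        coefs = {"intercept": float(beta[0])}
        coefs.update({name: float(b) for name, b in zip(selected, beta[1:])})
        self.selected_ = selected
        self.intercept_ = coefs["intercept"]
        self.coef_ = np.array([coefs[name] for name in selected])
        self.r_squared_ = 0.0 if (not selected and np.isnan(r2)) else r2
        self.rmse_ = rmse
        self.report_ = RegressionReport(
            dependent=dependent_name or getattr(y, "name", None) or "y",
            selected=list(selected),
            coefficients=coefs,
            r_squared=self.r_squared_,
            rmse=rmse,
            n=len(y),
        )
        return self

    @staticmethod
    def _term_pvalue(X, y, model_terms, term):
        design = sm.add_constant(X[model_terms].to_numpy(float))
        if np.linalg.matrix_rank(design) < design.shape[1]:
            return None  # collinear with current model; cannot enter
        res = sm.OLS(y.to_numpy(), design).fit()
        return float(res.pvalues[model_terms.index(term) + 1])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.report_.predict(X)


def smlr(
    candidates: pd.DataFrame,
    dependent: pd.Series,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
    dependent_name: str | None = None,
) -> RegressionReport:
    """Stepwise selection; thin wrapper over StepwiseLinearRegression."""
    est = StepwiseLinearRegression(alpha_enter=alpha_enter, alpha_remove=alpha_remove)
    est.fit(candidates, dependent, dependent_name=dependent_name
            or getattr(dependent, "name", None))
    return est.report_


@dataclass
class GroupFit:
    """Best single-index fit (linear or quadratic) within one group."""

    group: str
    x_name: str
    y_name: str
    form: str                   # "L" or "Q"
    coefficients: np.ndarray    # ascending powers
    r_squared: float
    significance: str


def best_group_fit(
    x, y, group: str = "", x_name: str = "", y_name: str = "",
    q_margin: float = 0.01,
) -> GroupFit:
    """Fit linear and quadratic models of y on x; keep Q only if its R²
    beats L's by more than ``q_margin`` (parsimony tie-break)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 points to compare L and Q fits")
    bL, r2L, _ = fit_report(x[:, None], y)
    bQ, r2Q, _ = fit_report(np.column_stack([x, x**2]), y)
    if np.isnan(r2L):
        raise ValueError("constant response; fit undefined")
    use_q = r2Q > r2L + q_margin
    form = "Q" if use_q else "L"
    beta = bQ if use_q else bL
    r2 = r2Q if use_q else r2L
    p_model = len(beta) - 1
    if r2 >= 1.0:
        p_overall = 0.0
    else:
        f = (r2 / p_model) / ((1 - r2) / (n - p_model - 1))
        p_overall = float(stats.f.sf(f, p_model, n - p_model - 1))
    return GroupFit(
        group=group,
        x_name=x_name,
        y_name=y_name,
        form=form,
        coefficients=np.asarray(beta),
        r_squared=float(r2),
        significance=significance_code(p_overall),
    )
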