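"""EMS demand regression: stepwise OLS over census predictors.

The demand model is an ordinary-least-squares regression of per-area EMS
case counts on census small-area predictors (age-group population counts
and the number of companies with more than five employees), with
forward-entry / backward-removal stepwise selection driven by partial-F
p-values (the classic SPSS "stepwise" semantics).  The fitted model is an
sklearn-compatible estimator so it can sit in pipelines and be
cross-validated, and it serialises to JSON for the planning pipeline.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .errors import SingularDesignError, StepwiseCyclingError
from . import reference

__all__ = [
    "StepwiseOLS",
    "fit_ols",
    "stepwise_select",
    "predict_cases",
    "niigata_demand_model",
]


def _as_frame(X, feature_names=None) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("design matrix must be 2-dimensional")
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    return pd.DataFrame(X, columns=list(feature_names))


def _check_full_rank(X: pd.DataFrame) -> None:
    """Raise SingularDesignError naming collinear columns, via pivoted QR."""
    M = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    r = np.linalg.matrix_rank(M)
    if r == M.shape[1]:
        return
    _, _, piv = linalg.qr(M, pivoting=True, mode="economic")
    bad = sorted(piv[r:])
    names = ["intercept" if j == 0 else X.columns[j - 1] for j in bad]
    raise SingularDesignError(names)


class StepwiseOLS(RegressorMixin, BaseEstimator):
    """OLS demand model with optional stepwise predictor selection.

    Parameters
    ----------
    p_enter, p_remove:
        Partial-F p-value thresholds for forward entry and backward
        removal.  ``p_enter`` must not exceed ``p_remove`` (prevents
        cycling).  ``p_enter=1`` enters every candidate, which makes the
        estimator an ordinary full OLS fit.
    clip_negative:
        When True (default), ``predict`` floors fitted demand at zero —
        case counts cannot be negative.  The raw affine prediction is
        available with ``predict(X, clip_negative=False)``.

    Attributes
    ----------
    intercept_ : float
    coef_ : ndarray of shape (n_features,)
        Dense coefficient vector; unselected predictors hold 0.
    selected_ : list of str
        Predictors in the final model, in order of entry.
    se_, pvalues_ : pd.Series indexed by ``['intercept'] + selected_``
    rsquared_ : float, defined as 0 for a zero-variance response.
    """

    def __init__(self, p_enter: float = 0.05, p_remove: float = 0.10,
                 clip_negative: bool = True):
        self.p_enter = p_enter
        self.p_remove = p_remove
        self.clip_negative = clip_negative

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        if not (0 < self.p_enter <= self.p_remove):
            raise ValueError(
                f"need 0 < p_enter <= p_remove, got "
                f"({self.p_enter}, {self.p_remove})"
            )
        Xf = _as_frame(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != len(Xf):
            raise ValueError("X and y length mismatch")
        if len(y) < Xf.shape[1] + 2:
            raise ValueError(
                f"need at least n_features + 2 = {Xf.shape[1] + 2} rows, "
                f"got {len(y)}"
            )
        self.feature_names_in_ = np.asarray(Xf.columns, dtype=object)
        self.n_features_in_ = Xf.shape[1]

        if self.p_enter >= 1.0:
            selected = list(Xf.columns)
            _check_full_rank(Xf)
        else:
            selected = self._stepwise(Xf, y)
        self._finalize(Xf, y, selected)
        return self

    def _pvalue_of_last(self, Xf, y, cols):
        """p-value of the last column in an OLS of y on cols (partial F)."""
        res = sm.OLS(y, sm.add_constant(Xf[cols], has_constant="add")).fit()
        return float(res.pvalues.iloc[-1])

    def _stepwise(self, Xf: pd.DataFrame, y: np.ndarray) -> list[str]:
        selected: list[str] = []
        visited = {frozenset()}
        if np.var(y) == 0:
            return selected
        while True:
            changed = False
            # forward entry: best candidate by partial-F p-value
            remaining = [c for c in Xf.columns if c not in selected]
            if remaining:
                pvals = {}
                for c in remaining:
                    try:
                        pvals[c] = self._pvalue_of_last(Xf, y, selected + [c])
                    except Exception:  # singular with this candidate
                        continue
                if pvals:
                    best = min(pvals, key=lambda c: (pvals[c], c))
                    if pvals[best] < self.p_enter:
                        selected.append(best)
                        changed = True
            # backward removal: drop worst until all significant
            while selected:
                res = sm.OLS(
                    y, sm.add_constant(Xf[selected], has_constant="add")
                ).fit()
                pv = res.pvalues.iloc[1:]  # skip intercept
                worst = pv.idxmax()
                if pv[worst] > self.p_remove:
                    selected.remove(worst)
                    changed = True
                else:
                    break
            state = frozenset(selected)
            if not changed:
                break
            if state in visited:
                raise StepwiseCyclingError(
                    f"stepwise selection revisited predictor set {sorted(state)}"
                )
            visited.add(state)
        return selected

    def _finalize(self, Xf, y, selected):
        names = ["intercept"] + list(selected)
        if np.var(y) == 0:
            # degenerate response: intercept-only, R^2 defined as 0
            self.intercept_ = float(np.mean(y))
            self.coef_ = np.zeros(self.n_features_in_)
            self.selected_ = []
            self.se_ = pd.Series([0.0], index=["intercept"], name="se")
            self.pvalues_ = pd.Series([np.nan], index=["intercept"],
                                      name="p")
            self.rsquared_ = 0.0
            self._result_ = None
            return
        res = sm.OLS(
            y, sm.add_constant(Xf[list(selected)], has_constant="add")
        ).fit()
        self.intercept_ = float(res.params.iloc[0])
        coef = np.zeros(self.n_features_in_)
        for name, b in res.params.iloc[1:].items():
            coef[list(Xf.columns).index(name)] = b
        self.coef_ = coef
        self.selected_ = list(selected)
        self.se_ = pd.Series(res.bse.to_numpy(), index=names, name="se")
        self.pvalues_ = pd.Series(res.pvalues.to_numpy(), index=names,
                                  name="p")
        self.rsquared_ = float(res.rsquared)
        self._result_ = res

    # -- prediction --------------------------------------------------------

    def predict(self, X, clip_negative: bool | None = None):
        check_is_fitted(self, "coef_")
        if clip_negative is None:
            clip_negative = self.clip_negative
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names_in_ if c not in X]
            if missing:
                raise KeyError(f"missing predictor columns: {missing}")
            M = X[list(self.feature_names_in_)].to_numpy(dtype=float)
        else:
            M = np.asarray(X, dtype=float)
            if M.ndim == 1:
                M = M.reshape(1, -1)
            if M.shape[1] != self.n_features_in_:
                raise ValueError(
                    f"expected {self.n_features_in_} features, got {M.shape[1]}"
                )
        yhat = self.intercept_ + M @ self.coef_
        if clip_negative:
            yhat = np.maximum(yhat, 0.0)
        return yhat

    # -- serialisation -----------------------------------------------------

    def coefficients(self) -> pd.Series:
        """Nonzero coefficients as a Series indexed by predictor name."""
        check_is_fitted(self, "coef_")
        return pd.Series(
            {n: self.coef_[list(self.feature_names_in_).index(n)]
             for n in self.selected_},
            name="coef", dtype=float,
        )

    def to_dict(self) -> dict:
        check_is_fitted(self, "coef_")
        return {
            "intercept": self.intercept_,
            "coefficients": self.coefficients().to_dict(),
            "standard_errors": self.se_.to_dict(),
            "p_values": {
                k: (None if np.isnan(v) else v)
                for k, v in self.pvalues_.items()
            },
            "r_squared": self.rsquared_,
            "selected_predictors": list(self.selected_),
            "feature_names": list(self.feature_names_in_),
            "p_enter": self.p_enter,
            "p_remove": self.p_remove,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_coefficients(cls, intercept: float, coefficients: dict,
                          standard_errors: dict | None = None,
                          r_squared: float = float("nan"),
                          clip_negative: bool = True) -> "StepwiseOLS":
        """Build a ready-to-predict model from known coefficients."""
        m = cls(clip_negative=clip_negative)
        names = list(coefficients)
        m.feature_names_in_ = np.asarray(names, dtype=object)
        m.n_features_in_ = len(names)
        m.intercept_ = float(intercept)
        m.coef_ = np.asarray([coefficients[n] for n in names], dtype=float)
        m.selected_ = names
        se = {"intercept": np.nan, **(standard_errors or {})}
        m.se_ = pd.Series([se.get(n, np.nan) for n in ["intercept"] + names],
                          index=["intercept"] + names, name="se")
        m.pvalues_ = pd.Series(np.nan, index=["intercept"] + names, name="p")
        m.rsquared_ = float(r_squared)
        m._result_ = None
        return m

    @classmethod
    def from_dict(cls, d: dict) -> "StepwiseOLS":
        m = cls.from_coefficients(
            d["intercept"], d["coefficients"],
            d.get("standard_errors"), d.get("r_squared", float("nan")),
        )
        m.p_enter = d.get("p_enter", 0.05)
        m.p_remove = d.get("p_remove", 0.10)
        return m

    @classmethod
    def from_json(cls, path) -> "StepwiseOLS":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_ols(design, response) -> StepwiseOLS:
    """Full OLS fit of the response on every design column (no selection)."""
    return StepwiseOLS(p_enter=1.0, p_remove=1.0).fit(design, response)


def stepwise_select(table: pd.DataFrame,
                    candidate_predictors: Sequence[str],
                    response: str | np.ndarray,
                    p_enter: float = 0.05,
                    p_remove: float = 0.10) -> StepwiseOLS:
    """Stepwise OLS of a response column on candidate predictor columns."""
    y = table[response] if isinstance(response, str) else response
    return StepwiseOLS(p_enter=p_enter, p_remove=p_remove).fit(
        table[list(candidate_predictors)], y
    )


def predict_cases(model: StepwiseOLS, table: pd.DataFrame,
                  clip_negative: bool = True) -> np.ndarray:
    """Per-area predicted EMS case counts for any predictor table."""
    return model.predict(table, clip_negative=clip_negative)


def niigata_demand_model(clip_negative: bool = True) -> StepwiseOLS:
    """The published Niigata demand model, ready for prediction.

    cases = 0.006*pop_0_4 + 0.021*pop_15_64 + 0.102*pop_80_over
            + 0.433*companies_5plus - 0.268
    """
    return StepwiseOLS.from_coefficients(
        reference.NIIGATA_MODEL_INTERCEPT,
        reference.NIIGATA_MODEL_COEFFICIENTS.to_dict(),
        reference.NIIGATA_MODEL_STANDARD_ERRORS.to_dict(),
        reference.NIIGATA_MODEL_R_SQUARED,
        clip_negative=clip_negative,
    )
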