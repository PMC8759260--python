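"""Prediction of broad white-blood-cell percentages from methylation.

Multivariate partial-least-squares regression of measured cell
percentages on [beta values, age, sex], sklearn-estimator style.  The
number of PLS components is chosen by k-fold cross-validation on the
training data (the grid defaults to 1..20).  Predictions are clipped at
zero, since negative cell percentages are meaningless.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold


class CellCountPredictor(BaseEstimator, RegressorMixin):
    """PLS predictor of cell-type percentages from beta values + age + sex.

    Parameters
    ----------
    n_components : int or None
        Fixed number of PLS components; ``None`` selects from
        ``component_grid`` by cross-validation.
    component_grid : sequence of int
        Candidate component counts for CV selection.
    cv : int
        Number of CV folds.
    """

    def __init__(self, n_components: Optional[int] = None,
                 component_grid: Sequence[int] = tuple(range(1, 21)),
                 cv: int = 5, random_state: int = 0):
        self.n_components = n_components
        self.component_grid = component_grid
        self.cv = cv
        self.random_state = random_state

    @staticmethod
    def _design(beta: pd.DataFrame, age: pd.Series, sex: pd.Series) -> np.ndarray:
        sex_num = (pd.Series(sex).astype(str).str.upper()
                   .map({"M": 1.0, "F": 0.0, "1": 1.0, "0": 0.0}))
        if sex_num.isna().any():
            raise ValueError("sex must be coded M/F or 0/1")
        return np.column_stack([beta.values.astype(float),
                                np.asarray(age, dtype=float),
                                sex_num.values])

    def fit(self, beta: pd.DataFrame, counts: pd.DataFrame,
            age: pd.Series, sex: pd.Series) -> "CellCountPredictor":
        """Fit on training samples with complete measured counts."""
        if counts.isna().any().any():
            raise ValueError("training samples must have complete measured counts")
        X = self._design(beta, age, sex)
        Y = counts.values.astype(float)
        n = X.shape[0]
        max_comp = min(n - 1, X.shape[1])
        grid = [k for k in self.component_grid if k <= max_comp]
        if self.n_components is not None:
            if self.n_components > max_comp or self.n_components >= n:
                raise ValueError("fewer training samples than components")
            best = self.n_components
        else:
            if not grid:
                raise ValueError("fewer training samples than any candidate component count")
            best = self._select_components(X, Y, grid)
        self.n_components_ = best
        self.cpgs_ = list(beta.columns)
        self.targets_ = list(counts.columns)
        self.pls_ = PLSRegression(n_components=best, scale=True)
        self.pls_.fit(X, Y)
        return self

    def _select_components(self, X: np.ndarray, Y: np.ndarray, grid: list[int]) -> int:
        kf = KFold(n_splits=min(self.cv, X.shape[0]), shuffle=True,
                   random_state=self.random_state)
        scores = []
        for k in grid:
            sse = 0.0
            for tr, te in kf.split(X):
                if k >= len(tr):
                    sse = np.inf
                    break
                m = PLSRegression(n_components=k, scale=True)
                m.fit(X[tr], Y[tr])
                sse += float(np.sum((Y[te] - m.predict(X[te])) ** 2))
            scores.append(sse)
        return grid[int(np.argmin(scores))]

    def predict(self, beta: pd.DataFrame, age: pd.Series, sex: pd.Series) -> pd.DataFrame:
        """Predict percentages for all samples; values clipped at 0."""
        X = self._design(beta[self.cpgs_], age, sex)
        pred = np.clip(self.pls_.predict(X), 0.0, None)
        return pd.DataFrame(pred, index=beta.index, columns=self.targets_)


def fit_cellcount_predictor(beta: pd.DataFrame, age: pd.Series, sex: pd.Series,
                            counts: pd.DataFrame, **kwargs) -> CellCountPredictor:
    """Functional wrapper over :class:`CellCountPredictor`."""
    return CellCountPredictor(**kwargs).fit(beta, counts, age, sex)


def predict_cellcounts(predictor: CellCountPredictor, beta: pd.DataFrame,
                       age: pd.Series, sex: pd.Series) -> pd.DataFrame:
    return predictor.predict(beta, age, sex)
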