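"""LMG (Shapley) relative-importance decomposition of regression R^2.

Path coefficients are poor guides to practical importance when predictors
are correlated.  The LMG statistic assigns each predictor the average of its
incremental R^2 contribution over all orderings in which predictors can
enter the model; contributions are non-negative for PSD inputs and sum
exactly to the full-model R^2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = ["r2_from_corr", "lmg", "ImportanceDecomposition"]

_RIDGE = 1e-10


def _corr_from_input(data, outcome: str, predictors: list[str]):
    """Accept either a correlation matrix (DataFrame) or raw data columns."""
    cols = [outcome] + list(predictors)
    if isinstance(data, pd.DataFrame) and data.shape[0] == data.shape[1] \
            and set(cols).issubset(data.columns) \
            and set(cols).issubset(data.index):
        return data.loc[cols, cols].to_numpy(dtype=float)
    frame = data[cols] if isinstance(data, pd.DataFrame) else pd.DataFrame(data)[cols]
    return frame.corr().to_numpy()


def r2_from_corr(R: np.ndarray, outcome: int | str = 0,
                 predictors: list | None = None) -> float:
    """R^2 of the outcome on a predictor subset, from a correlation matrix.

    R^2(S) = r_yS' R_SS^-1 r_yS and R^2(empty) = 0.  A singular predictor
    block falls back to a tiny ridge with a warning.
    """
    R = np.asarray(R, dtype=float)
    names = None
    if isinstance(outcome, str):
        raise TypeError("pass integer indices to r2_from_corr")
    preds = list(predictors if predictors is not None
                 else [i for i in range(R.shape[0]) if i != outcome])
    if not preds:
        return 0.0
    Rss = R[np.ix_(preds, preds)]
    ry = R[preds, outcome]
    try:
        beta = np.linalg.solve(Rss, ry)
    except np.linalg.LinAlgError:
        warnings.warn("singular predictor block; applying ridge fallback")
        beta = np.linalg.solve(Rss + _RIDGE * np.eye(len(preds)), ry)
    return float(ry @ beta)


@dataclass
class ImportanceDecomposition:
    """Per-predictor LMG contributions to the outcome's R^2."""
    outcome: str
    lmg_values: pd.Series        # R^2 units, sums to total_r2
    total_r2: float

    @property
    def shares(self) -> pd.Series:
        """Percentage of the explained variance attributed to each predictor."""
        if self.total_r2 == 0:
            return self.lmg_values * np.nan
        return 100.0 * self.lmg_values / self.total_r2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lmg": self.lmg_values, "share_pct": self.shares})

    def __repr__(self):
        rows = ", ".join(f"{k}={v:.1f}%" for k, v in self.shares.items())
        return (f"ImportanceDecomposition({self.outcome}: R2="
                f"{self.total_r2:.3f}; {rows})")


def lmg(data, outcome: str, predictors: list[str]) -> ImportanceDecomposition:
    """Exact LMG decomposition by the subset-weight formula.

    LMG(x) = sum over subsets S of the other predictors of
    |S|! (k-|S|-1)! / k! * (R^2(S+{x}) - R^2(S)); identical to averaging
    incremental contributions over all k! orderings, without enumerating
    them.  ``data`` may be raw respondent data or a named correlation
    matrix.  Exact enumeration is limited to 12 predictors.
    """
    predictors = list(predictors)
    k = len(predictors)
    if k == 0:
        raise ValueError("need at least one predictor")
    if k > 12:
        raise ValueError("exact LMG limited to 12 predictors")
    R = _corr_from_input(data, outcome, predictors)
    pidx = list(range(1, k + 1))

    # cache R^2 per subset
    r2 = {(): 0.0}
    for size in range(1, k + 1):
        for S in combinations(pidx, size):
            r2[S] = r2_from_corr(R, 0, list(S))

    values = {}
    kfact = math.factorial(k)
    for j, name in zip(pidx, predictors):
        others = [i for i in pidx if i != j]
        total = 0.0
        for size in range(0, k):
            w = math.factorial(size) * math.factorial(k - size - 1) / kfact
            for S in combinations(others, size):
                total += w * (r2[tuple(sorted(S + (j,)))] - r2[S])
        values[name] = total
    series = pd.Series(values, name="lmg")
    return ImportanceDecomposition(outcome=outcome, lmg_values=series,
                                   total_r2=r2[tuple(pidx)])
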