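"""Reliability and validity diagnostics for the measurement model.

Implements the conventional battery: Cronbach's alpha, composite reliability
(CR) and average variance extracted (AVE) from standardized loadings, the
Fornell-Larcker discriminant-validity criterion, Harman's single-factor
share, and the marker-variable check for common method bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survey import SurveyDataset

__all__ = [
    "cronbach_alpha", "composite_stats", "estimate_loadings",
    "fornell_larcker", "harman_single_factor", "marker_check",
    "reliability_report", "discriminant_report", "DiscriminantReport",
]


def cronbach_alpha(items: np.ndarray | pd.DataFrame,
                   standardized: bool = False) -> float:
    """Cronbach's alpha of an n x k item matrix.

    alpha = k/(k-1) * (1 - sum(item variances) / var(row sums)), computed on
    raw covariances by default; ``standardized=True`` computes it on the
    item correlation matrix instead.
    """
    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need an n x k matrix with k >= 2 items")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    if standardized:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance item")
        X = X / sd
    k = X.shape[1]
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("zero total variance")
    return float(k / (k - 1) * (1.0 - X.var(axis=0, ddof=1).sum() / total_var))


def composite_stats(loadings) -> dict[str, float]:
    """CR and AVE from standardized loadings.

    AVE = mean(lambda^2);  CR = (sum lambda)^2 / ((sum lambda)^2 + sum(1 - lambda^2)).
    """
    lam = np.asarray(loadings, dtype=float)
    if lam.size == 0:
        raise ValueError("empty loading vector")
    if np.any(lam <= 0) or np.any(lam > 1):
        raise ValueError("standardized loadings must lie in (0, 1]")
    ave = float(np.mean(lam ** 2))
    s = lam.sum()
    cr = float(s ** 2 / (s ** 2 + np.sum(1 - lam ** 2)))
    return {"CR": cr, "AVE": ave}


def estimate_loadings(items: pd.DataFrame | np.ndarray,
                      max_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    """Standardized loadings of a single-factor model for one construct.

    Principal-axis factoring on the item correlation matrix with iterated
    communalities (deterministic).  For two items the loading is
    sqrt(|r12|) for both.
    """
    X = np.asarray(items, dtype=float)
    R = np.corrcoef(X, rowvar=False)
    k = R.shape[0]
    if k == 2:
        return np.full(2, np.sqrt(abs(R[0, 1])))
    # start communalities at squared multiple correlations
    h = np.clip(np.diag(R) - 1 / np.diag(np.linalg.inv(R)), 0.05, 0.995)
    for _ in range(max_iter):
        Rr = R.copy()
        np.fill_diagonal(Rr, h)
        w, V = np.linalg.eigh(Rr)
        lam = V[:, -1] * np.sqrt(max(w[-1], 0.0))
        if lam.sum() < 0:
            lam = -lam
        h_new = np.clip(lam ** 2, 0.0, 0.9995)
        if np.max(np.abs(h_new - h)) < tol:
            h = h_new
            break
        h = h_new
    Rr = R.copy()
    np.fill_diagonal(Rr, h)
    w, V = np.linalg.eigh(Rr)
    lam = V[:, -1] * np.sqrt(max(w[-1], 0.0))
    if lam.sum() < 0:
        lam = -lam
    return np.clip(lam, 0.0, 1.0)


@dataclass
class DiscriminantReport:
    """Fornell-Larcker table: correlations with sqrt(AVE) on the diagonal."""
    table: pd.DataFrame
    verdicts: pd.DataFrame       # boolean pass per construct pair
    kind: str                    # 'composite' or 'latent' correlations

    @property
    def all_pass(self) -> bool:
        k = len(self.table)
        mask = ~np.eye(k, dtype=bool)
        return bool(self.verdicts.to_numpy()[mask].all())


def fornell_larcker(correlations: pd.DataFrame | np.ndarray,
                    aves: dict[str, float] | np.ndarray,
                    names: list[str] | None = None,
                    kind: str = "composite") -> DiscriminantReport:
    """Fornell-Larcker criterion: sqrt(AVE) must exceed every correlation.

    A pair passes iff both constructs' sqrt(AVE) exceed the absolute
    off-diagonal correlation.
    """
    if isinstance(correlations, pd.DataFrame):
        names = list(correlations.columns)
        R = correlations.to_numpy(dtype=float)
    else:
        R = np.asarray(correlations, dtype=float)
        if names is None:
            raise ValueError("names required with a bare matrix")
    if isinstance(aves, dict):
        ave_vec = np.array([aves[n] for n in names], dtype=float)
    else:
        ave_vec = np.asarray(aves, dtype=float)
    if len(ave_vec) != len(names) or R.shape != (len(names), len(names)):
        raise ValueError("dimension mismatch between correlations and AVEs")
    diag = np.sqrt(ave_vec)
    table = R.copy()
    np.fill_diagonal(table, diag)
    off = np.abs(R)
    ok = (diag[:, None] > off) & (diag[None, :] > off)
    np.fill_diagonal(ok, True)
    return DiscriminantReport(
        table=pd.DataFrame(table, index=names, columns=names),
        verdicts=pd.DataFrame(ok, index=names, columns=names),
        kind=kind)


def harman_single_factor(survey: SurveyDataset | pd.DataFrame) -> float:
    """Variance share (%) of the largest factor of all items pooled.

    Computed as the first eigenvalue of the item correlation matrix divided
    by the number of items (principal-components operationalisation,
    deterministic).  Shares well below 50% indicate common method variance
    is not dominant.
    """
    X = survey.scored_items() if isinstance(survey, SurveyDataset) else survey
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 items")
    R = np.corrcoef(X, rowvar=False)
    if not np.all(np.isfinite(R)):
        raise ValueError("singular or constant item encountered")
    w = np.linalg.eigvalsh(R)
    return float(w[-1] / X.shape[1] * 100.0)


def marker_check(survey: SurveyDataset, marker: str = "MK",
                 threshold: float = 0.15) -> dict:
    """Maximum |correlation| between the marker composite and focal composites.

    The marker is a theoretically unrelated construct; correlations below
    the conventional 0.15 bound argue against pervasive method bias.
    """
    comps = survey.composites()
    if marker not in comps.columns:
        raise ValueError(f"marker construct {marker!r} not present")
    focal = [c for c in comps.columns if c != marker]
    rs = comps[focal].corrwith(comps[marker]).abs()
    return {"max_abs_r": float(rs.max()), "worst": str(rs.idxmax()),
            "threshold": threshold, "pass": bool(rs.max() < threshold),
            "correlations": rs.to_dict()}


def reliability_report(survey: SurveyDataset,
                       constructs: list[str] | None = None) -> pd.DataFrame:
    """Per-construct alpha, CR, AVE and item count, estimated from the data."""
    rows = []
    for c in constructs or survey.constructs():
        items = survey.scored_items(c)
        lam = estimate_loadings(items)
        stats = composite_stats(np.clip(lam, 1e-6, 1.0))
        rows.append({"construct": c, "items": items.shape[1],
                     "alpha": cronbach_alpha(items), **stats})
    return pd.DataFrame(rows).set_index("construct")


def discriminant_report(survey: SurveyDataset,
                        constructs: list[str] | None = None) -> DiscriminantReport:
    """Fornell-Larcker report on composite correlations with estimated AVEs."""
    names = constructs or survey.constructs()
    comps = survey.composites(names)
    rel = reliability_report(survey, names)
    return fornell_larcker(comps.corr(),
                           {c: float(rel.loc[c, "AVE"]) for c in names},
                           names=names, kind="composite")
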