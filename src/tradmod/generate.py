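"""Synthetic survey generation.

Two regimes produce respondent-level data with the statistical structure the
downstream analyses assume:

``corr-matched``
    Latent construct scores are drawn from a multivariate normal whose
    correlation matrix is *calibrated* so the observed (discretized,
    composite-level) correlations reproduce the spec's target matrix.  Used
    for measurement-validation and relative-importance work.

``model-generated``
    Exogenous constructs are drawn with the spec's exogenous correlations and
    endogenous constructs are built from the standardized structural
    equations plus Gaussian disturbances, so the structural coefficients are
    the ground truth.  Used for SEM parameter-recovery work.

No single generator can reproduce both the printed correlation matrix and
the printed path coefficients - they are mutually inconsistent (the implied
sum of beta*r for purchase intention exceeds the printed R^2) - hence the
two regimes.

Item responses are produced by :func:`latent_to_likert`: threshold
discretization of ``shift + loading*z + sqrt(1-loading^2)*noise``, with
reverse-scored items generated in reversed orientation.  Generation loadings
are calibrated so *observed* within-construct item correlations equal the
target AVEs (see :mod:`tradmod.likert`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import likert
from .population import AGE_GROUPS, PopulationSpec, build_population_spec, \
    nearest_positive_definite
from .survey import SurveyDataset

__all__ = [
    "generate_respondents", "latent_to_likert", "generate_survey",
    "SurveyGenerator", "structural_latent_cov",
]


# ----------------------------------------------------------------------
# structural construction (model-generated regime)
# ----------------------------------------------------------------------

def structural_latent_cov(paths: dict[tuple[str, str], float],
                          exo_corr: dict[tuple[str, str], float]):
    """Implied covariance of a unit-variance recursive structural system.

    Every variable is normalized to variance 1: each endogenous variable is
    ``sum(beta * predictor) + disturbance`` with disturbance variance
    ``1 - var(systematic part)``.  Returns ``(order, cov, disturbances)``.

    Raises ``ValueError`` if the coefficients leave no room for a
    non-negative disturbance variance (systematic variance >= 1) or if the
    path graph is cyclic.
    """
    endo = {}
    for (lhs, rhs), beta in paths.items():
        endo.setdefault(lhs, {})[rhs] = beta
    variables = sorted({v for pair in paths for v in pair})
    exo = [v for v in variables if v not in endo]

    order = list(exo)
    pending = dict(endo)
    while pending:
        ready = [v for v, preds in pending.items()
                 if all(p in order for p in preds)]
        if not ready:
            raise ValueError(f"cyclic structural paths involving {sorted(pending)}")
        for v in sorted(ready):
            order.append(v)
            del pending[v]

    k = len(order)
    cov = np.eye(k)
    idx = {v: i for i, v in enumerate(order)}
    for a in exo:
        for b in exo:
            if a != b:
                r = exo_corr.get((a, b), exo_corr.get((b, a), 0.0))
                cov[idx[a], idx[b]] = r
    disturbances = {}
    for v in order:
        if v not in endo:
            continue
        preds = list(endo[v])
        beta = np.array([endo[v][p] for p in preds])
        sub = cov[np.ix_([idx[p] for p in preds], [idx[p] for p in preds])]
        sys_var = float(beta @ sub @ beta)
        if sys_var >= 1.0:
            raise ValueError(
                f"{v}: systematic variance {sys_var:.3f} >= 1; "
                "coefficients inconsistent with unit variances")
        disturbances[v] = 1.0 - sys_var
        for other in order:
            j = idx[other]
            if other == v:
                continue
            c = float(beta @ cov[[idx[p] for p in preds], j])
            cov[idx[v], j] = cov[j, idx[v]] = c
    return order, cov, disturbances


# ----------------------------------------------------------------------
# calibration
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class CalibratedDesign:
    """Per-construct generation parameters and the latent draw structure.

    ``draw_corr`` is the construct-by-construct latent correlation matrix the
    generator actually samples from; ``urban_corr`` the latent correlation of
    each construct with the standardized urban dummy (model-generated regime
    only, zero elsewhere).
    """
    shifts: dict[str, float]
    loadings: dict[str, float]
    draw_corr: np.ndarray
    urban_corr: np.ndarray
    repair_delta: float


_CALIB_CACHE: dict[tuple, CalibratedDesign] = {}


def _model_implied_targets(spec: PopulationSpec):
    """Latent correlation targets implied by the structural equations.

    Core constructs get the correlations implied by the spec's standardized
    paths (with the spec's exogenous correlations); constructs outside the
    structural system keep their spec correlations among themselves and are
    independent of it; the urban dummy enters through its paths.
    """
    paths = dict(spec.structural_paths)
    core = sorted({v for pair in paths for v in pair} - {"URBAN"})
    exo = [v for v in core if v not in {lhs for lhs, _ in paths}]
    exo_corr = {(x, y): spec.corr(x, y)
                for i, x in enumerate(exo) for y in exo[i + 1:]}
    order, cov, _ = structural_latent_cov(paths, exo_corr)
    idx = {v: i for i, v in enumerate(order)}
    names = list(spec.names)
    k = len(names)
    target = np.eye(k)
    urban = np.zeros(k)
    for i, a in enumerate(names):
        if a in idx and "URBAN" in idx:
            urban[i] = cov[idx[a], idx["URBAN"]]
        for j in range(i + 1, k):
            b = names[j]
            if a in idx and b in idx:
                r = cov[idx[a], idx[b]]
            elif a not in idx and b not in idx:
                r = spec.corr(a, b)      # extras keep spec structure
            else:
                r = 0.0
            target[i, j] = target[j, i] = r
    return target, urban


def calibrated_design(spec: PopulationSpec, regime: str,
                      continuous: bool = False) -> CalibratedDesign:
    """Solve the generation parameters for a (spec, regime) pair; cached.

    In continuous mode no discretization happens, so targets need no
    attenuation correction and literal loadings sqrt(AVE) are used.
    """
    key = (spec.fingerprint(), regime, continuous)
    if key in _CALIB_CACHE:
        return _CALIB_CACHE[key]
    t = spec.thresholds
    names = list(spec.names)
    k = len(names)
    shifts = {c.name: likert.solve_shift(c.mean, t) for c in spec.constructs}
    if continuous:
        loadings = {c.name: c.loading for c in spec.constructs}
    else:
        loadings = {c.name: likert.solve_within_loading(c.ave, shifts[c.name], t)
                    for c in spec.constructs}

    urban = np.zeros(k)
    if regime == "corr-matched":
        if continuous:
            R, delta = spec.correlations.copy(), 0.0
        else:
            R = np.eye(k)
            for i in range(k):
                for j in range(i + 1, k):
                    a, b = names[i], names[j]
                    R[i, j] = R[j, i] = likert.solve_latent_corr(
                        float(spec.correlations[i, j]),
                        loadings[a], loadings[b], shifts[a], shifts[b],
                        spec.construct(a).n_items, spec.construct(b).n_items, t)
            R, delta = nearest_positive_definite(R)
    elif regime == "model-generated":
        target, urban_t = _model_implied_targets(spec)
        if continuous:
            R, urban = target, urban_t
            delta = 0.0
        else:
            R = np.eye(k)
            for i in range(k):
                a = names[i]
                urban[i] = likert.solve_cont_latent_corr(
                    float(urban_t[i]), loadings[a], shifts[a], t)
                for j in range(i + 1, k):
                    b = names[j]
                    R[i, j] = R[j, i] = likert.solve_pair_latent_corr(
                        float(target[i, j]), loadings[a], loadings[b],
                        shifts[a], shifts[b], t)
            # joint PD check including the dummy dimension
            full = np.empty((k + 1, k + 1))
            full[:k, :k] = R
            full[:k, k] = full[k, :k] = urban
            full[k, k] = 1.0
            full, delta = nearest_positive_definite(full)
            R, urban = full[:k, :k], full[:k, k]
    else:
        raise ValueError(f"unknown regime {regime!r}")
    design = CalibratedDesign(shifts, loadings, R, urban, delta)
    _CALIB_CACHE[key] = design
    return design


# ----------------------------------------------------------------------
# respondent-level latent scores
# ----------------------------------------------------------------------

def _draw_demographics(spec: PopulationSpec, n: int, rng: np.random.Generator):
    urban = rng.random(n) < spec.urban_proportion
    groups = list(spec.age_proportions)
    probs = np.array([spec.age_proportions[g] for g in groups])
    ages = rng.choice(groups, size=n, p=probs / probs.sum())
    return urban, ages


def generate_respondents(spec: PopulationSpec, n: int, seed: int,
                         regime: str = "corr-matched",
                         correlations: np.ndarray | None = None) -> pd.DataFrame:
    """Draw ``n`` respondents' latent construct z-scores plus demographics.

    In the ``corr-matched`` regime latents are multivariate normal with the
    spec's (or the supplied) correlation matrix; the urban->MFSC effect is
    injected as a mean shift of ``urban_effect`` z-units between urban and
    rural respondents (variance-preserving, overall mean 0).  In the
    ``model-generated`` regime endogenous constructs are built from the
    spec's structural equations (see :func:`structural_latent_cov`);
    constructs outside the structural system keep their spec correlations
    among themselves but are independent of it.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    urban, ages = _draw_demographics(spec, n, rng)
    p = spec.urban_proportion
    pq = p * (1 - p)
    names = list(spec.names)

    if regime == "corr-matched":
        R = spec.correlations if correlations is None else np.asarray(correlations)
        e = spec.urban_effect if "MFSC" in names else 0.0
        a = np.sqrt(max(1.0 - e * e * pq, 1e-12))
        R_draw = R.copy()
        if e and "MFSC" in names:
            i = names.index("MFSC")
            R_draw[i, :] = np.clip(R_draw[i, :] / a, -1, 1)
            R_draw[:, i] = R_draw[i, :]
            R_draw[i, i] = 1.0
            R_draw, _ = nearest_positive_definite(R_draw)
        L = np.linalg.cholesky(R_draw)
        z = rng.standard_normal((n, len(names))) @ L.T
        if e and "MFSC" in names:
            i = names.index("MFSC")
            z[:, i] = a * z[:, i] + e * (urban - p)
        latents = pd.DataFrame(z, columns=names)
    elif regime == "model-generated":
        paths = dict(spec.structural_paths)
        all_nodes = sorted({v for pair in paths for v in pair})
        endo_nodes = {lhs for lhs, _ in paths}
        exo = [v for v in all_nodes if v not in endo_nodes and v != "URBAN"]
        exo_corr = {(x, y): spec.corr(x, y)
                    for i, x in enumerate(exo) for y in exo[i + 1:]}
        order, _, dist = structural_latent_cov(paths, exo_corr)
        uz = ((urban - p) / np.sqrt(pq)) if pq > 0 else np.zeros(n)
        z: dict[str, np.ndarray] = {"URBAN": uz}
        if exo:
            sub = spec.subset_correlations(exo)
            L = np.linalg.cholesky(sub)
            ze = rng.standard_normal((n, len(exo))) @ L.T
            for j, v in enumerate(exo):
                z[v] = ze[:, j]
        for v in order:
            if v in dist:  # endogenous, built in topological order
                val = np.zeros(n)
                for (lhs, rhs), b in paths.items():
                    if lhs == v:
                        val += b * z[rhs]
                z[v] = val + np.sqrt(dist[v]) * rng.standard_normal(n)
        # constructs outside the structural system: spec correlations among
        # themselves, independent of the system
        extras = [c for c in names if c not in z]
        if extras:
            sub = spec.subset_correlations(extras)
            L = np.linalg.cholesky(sub)
            zx = rng.standard_normal((n, len(extras))) @ L.T
            for j, v in enumerate(extras):
                z[v] = zx[:, j]
        latents = pd.DataFrame({v: z[v] for v in names})
    else:
        raise ValueError(f"unknown regime {regime!r}")

    latents["location"] = np.where(urban, "urban", "rural")
    latents["age_group"] = ages
    return latents


# ----------------------------------------------------------------------
# discretization to items
# ----------------------------------------------------------------------

def latent_to_likert(latents: pd.DataFrame, spec: PopulationSpec, seed: int,
                     loadings: dict[str, float] | None = None,
                     shifts: dict[str, float] | None = None,
                     continuous: bool = False) -> SurveyDataset:
    """Discretize latent z-scores into integer 1-5 item responses.

    Reverse-scored items are generated in reversed orientation (negated
    propensity, mirrored shift) and flipped back (``6 - x``) only at scoring
    time.  With ``continuous=True`` no thresholds are applied and items are
    returned on the raw construct scale (``mean + sd*(lambda*z + noise)``).
    """
    rng = np.random.default_rng(seed)
    t = spec.thresholds
    cols: dict[str, np.ndarray] = {}
    present = [c for c in spec.constructs if c.name in latents.columns]
    if not present:
        raise ValueError("no spec construct found in the latent table")
    for c in present:
        lam = (loadings or {}).get(c.name, c.loading)
        if lam is None or not (0 < lam <= 1):
            raise ValueError(f"missing or invalid loading for construct {c.name}")
        if continuous:
            s_direct = s_rev = None
        else:
            s_direct = (shifts or {}).get(c.name)
            if s_direct is None:
                s_direct = likert.solve_shift(c.mean, t)
            s_rev = likert.solve_shift(6.0 - c.mean, t)
        z = latents[c.name].to_numpy()
        for item, rev in zip(c.items, c.reverse):
            noise = rng.standard_normal(len(z))
            score = lam * z + np.sqrt(max(1.0 - lam * lam, 0.0)) * noise
            if continuous:
                cols[item] = ((6.0 - c.mean) - c.sd * score if rev
                              else c.mean + c.sd * score)
            else:
                prop = (s_rev - score) if rev else (s_direct + score)
                cols[item] = likert.discretize(prop, t)
    frame = pd.DataFrame(cols, index=latents.index)
    for dem in ("location", "age_group"):
        if dem in latents.columns:
            frame[dem] = latents[dem]
    cmap = {i: m for i, m in spec.construct_map().items() if i in frame.columns}
    meta = {"continuous": bool(continuous), "spec": spec.fingerprint()}
    if continuous:
        ds = SurveyDataset.__new__(SurveyDataset)
        ds.data, ds.construct_map, ds.metadata = frame, cmap, meta
        return ds
    return SurveyDataset(frame, cmap, meta)


# ----------------------------------------------------------------------
# orchestration
# ----------------------------------------------------------------------

class SurveyGenerator:
    """Reusable generator with pre-computed moment calibration.

    Build once per (spec, regime) and call :meth:`sample` repeatedly; the
    calibration solves (threshold shifts, generation loadings, latent draw
    matrix) are cached.
    """

    def __init__(self, spec: PopulationSpec | None = None,
                 regime: str = "model-generated", continuous: bool = False):
        self.spec = spec or build_population_spec({})
        if regime not in ("model-generated", "corr-matched"):
            raise ValueError(f"unknown regime {regime!r}")
        self.regime = regime
        self.continuous = continuous
        self.design = calibrated_design(self.spec, regime, continuous)

    def latents(self, n: int, seed: int) -> pd.DataFrame:
        if self.regime == "corr-matched":
            return generate_respondents(self.spec, n, seed, "corr-matched",
                                        correlations=self.design.draw_corr)
        # model-generated: joint normal with the (calibration-corrected)
        # model-implied correlations, conditioned on the urban dummy
        if n < 2:
            raise ValueError("n must be >= 2")
        spec = self.spec
        rng = np.random.default_rng(seed)
        urban, ages = _draw_demographics(spec, n, rng)
        p = spec.urban_proportion
        pq = p * (1 - p)
        uz = ((urban - p) / np.sqrt(pq)) if pq > 0 else np.zeros(n)
        r_u = self.design.urban_corr
        cond = self.design.draw_corr - np.outer(r_u, r_u)
        cond, _ = nearest_positive_definite(
            cond / np.sqrt(np.outer(np.diag(cond), np.diag(cond))))
        scale = np.sqrt(np.clip(1.0 - r_u ** 2, 1e-12, None))
        L = np.linalg.cholesky(cond) * scale[:, None]
        z = uz[:, None] * r_u + rng.standard_normal((n, len(r_u))) @ L.T
        latents = pd.DataFrame(z, columns=list(spec.names))
        latents["location"] = np.where(urban, "urban", "rural")
        latents["age_group"] = ages
        return latents

    def sample(self, n: int, seed: int) -> SurveyDataset:
        ss = np.random.SeedSequence(int(seed))
        s_lat, s_items = (int(c.generate_state(1)[0] % (2 ** 31))
                          for c in ss.spawn(2))
        lat = self.latents(n, s_lat)
        loadings = None if self.continuous else self.design.loadings
        shifts = None if self.continuous else self.design.shifts
        ds = latent_to_likert(lat, self.spec, s_items, loadings=loadings,
                              shifts=shifts, continuous=self.continuous)
        ds.metadata.update({"seed": int(seed), "regime": self.regime,
                            "n": int(n)})
        return ds


def generate_survey(config: dict | None = None, n: int = 1076,
                    seed: int = 0, regime: str | None = None) -> SurveyDataset:
    """One-call generation: config -> spec -> latents -> Likert survey."""
    config = dict(config or {})
    regime = regime or config.pop("regime", "model-generated")
    n = int(config.pop("n", n))
    spec = build_population_spec(config)
    return SurveyGenerator(spec, regime).sample(n, seed)
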