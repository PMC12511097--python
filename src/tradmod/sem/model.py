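"""Covariance-structure (SEM) engine.

The model is held in RAM form: for the stacked vector of observed and latent
variables ``v = A v + u`` with ``cov(u) = S``, so the implied moments are

    Sigma(theta) = F (I - A)^-1 S (I - A)^-T F'      (F selects observed rows)
    mu(theta)    = F (I - A)^-1 m

with directed coefficients (loadings Lambda, structural paths B/Gamma) in
``A``, variances/covariances (Phi, Psi, Theta) in ``S`` and intercepts /
latent means in ``m``.  Maximum-likelihood estimation minimizes

    F_ML = ln|Sigma| - ln|S_obs| + tr(S_obs Sigma^-1) - p  [+ d' Sigma^-1 d]

via L-BFGS on an internal parameterization with log-transformed variances
(positivity by construction), using the analytic gradient.  Multi-group
estimation minimizes the (n_g - 1)-weighted sum of group discrepancies with
equality constraints expressed through shared parameter labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .syntax import ModelDescription, Term, parse_model

__all__ = ["SemModel", "MultigroupSemModel", "CompiledGroup", "compile_model"]


# ----------------------------------------------------------------------
# compilation
# ----------------------------------------------------------------------

@dataclass
class Param:
    group: int
    matrix: str          # 'A' (directed), 'S' (symmetric), 'M' (means)
    i: int
    j: int
    label: str
    block: str           # LISREL block: Lambda_y/Lambda_x/B/Gamma/Phi/Psi/Theta_eps/Theta_delta/nu/alpha
    fixed: float | None = None
    start: float = 0.0
    category: str = ""   # loadings/paths/lv/residuals/intercepts/means


@dataclass
class CompiledGroup:
    """A compiled single-group model: node bookkeeping plus parameter list."""
    observed: list[str]
    latents: list[str]
    params: list[Param]
    endogenous: list[str]      # nodes with incoming regressions
    exogenous: list[str]       # latents/regressors without incoming edges
    mean_structure: bool

    @property
    def names(self) -> list[str]:
        return self.observed + self.latents

    @property
    def n_obs_vars(self) -> int:
        return len(self.observed)

    def index(self, name: str) -> int:
        return self.names.index(name)


def _acyclic(edges: set[tuple[str, str]], nodes: list[str]) -> bool:
    out = {n: [] for n in nodes}
    for child, parent in edges:
        out[parent].append(child)
    seen, stack = {}, []

    def visit(n):
        state = seen.get(n)
        if state == 1:
            return False
        if state == 2:
            return True
        seen[n] = 1
        ok = all(visit(c) for c in out[n])
        seen[n] = 2
        return ok

    return all(visit(n) for n in nodes)


def compile_model(desc: ModelDescription | str,
                  observed: list[str],
                  S_obs: np.ndarray,
                  mean_obs: np.ndarray | None = None,
                  group: int = 0,
                  shared: tuple[str, ...] = ("loadings", "paths", "lv",
                                             "residuals", "intercepts", "means"),
                  mean_structure: bool = False,
                  free_latent_means: bool = False) -> CompiledGroup:
    """Compile a model description against the observed-variable order.

    ``shared`` lists parameter categories whose labels are common across
    groups (others get a per-group suffix); with a single group everything
    is shared.  ``free_latent_means`` frees latent means (used for
    non-reference groups at the scalar-invariance level).
    """
    if isinstance(desc, str):
        desc = parse_model(desc)
    latents = [n for n in desc.latents]
    # observed regressor/outcome nodes used directly
    reg_nodes = {lhs for lhs, _ in desc.regressions} | \
                {t.name for _, t in desc.regressions}
    for n in sorted(reg_nodes):
        if n not in latents and n not in observed:
            raise ValueError(f"regression variable {n!r} is neither a latent "
                             "nor an observed column")
    indicators = []
    for lat, terms in desc.measurement.items():
        for t in terms:
            if t.name not in observed:
                raise ValueError(f"indicator {t.name!r} of {lat} not in data")
            indicators.append(t.name)
    for lat in latents:
        if not desc.measurement.get(lat) and lat not in reg_nodes:
            raise ValueError(f"latent {lat!r} has no indicators and no paths")

    edges = {(t.name, lat) for lat, ts in desc.measurement.items() for t in ts}
    edges |= {(lhs, t.name) for lhs, t in desc.regressions}
    names = observed + latents
    if not _acyclic(edges, names):
        raise ValueError("structural model is cyclic (non-recursive)")

    endo = sorted({lhs for lhs, _ in desc.regressions})
    incoming = {c for c, _ in edges}
    exo = [n for n in latents if n not in incoming]
    exo += [n for n in observed
            if n in reg_nodes and n not in incoming]

    sfx = lambda cat: "" if cat in shared else f".g{group}"
    idx = {n: k for k, n in enumerate(names)}
    p = len(observed)
    Sd = np.asarray(S_obs, dtype=float)
    params: list[Param] = []

    explicit: dict[tuple[str, str], Term] = {}
    for a, b, term in desc.covariances:
        key = (a, b) if idx[a] <= idx[b] else (b, a)
        explicit[key] = term

    def obs_block(item: str) -> str:
        # indicator of an exogenous latent -> Theta_delta, else Theta_eps
        for lat, ts in desc.measurement.items():
            if any(t.name == item for t in ts):
                return "Theta_delta" if lat in exo else "Theta_eps"
        return "Theta_eps"

    # --- loadings
    for lat, terms in desc.measurement.items():
        block = "Lambda_x" if lat in exo else "Lambda_y"
        for k, t in enumerate(terms):
            fixed = t.fixed
            if k == 0 and fixed is None and t.label is None:
                fixed = 1.0                       # identification scaling
            ref = terms[0].name
            denom = Sd[observed.index(ref), observed.index(ref)]
            start = Sd[observed.index(t.name), observed.index(ref)] / denom \
                if denom > 0 else 0.7
            label = t.label or f"{lat}=~{t.name}{sfx('loadings')}"
            params.append(Param(group, "A", idx[t.name], idx[lat], label,
                                block, fixed, float(start), "loadings"))

    # --- regressions
    for lhs, t in desc.regressions:
        block = "Gamma" if t.name in exo else "B"
        label = t.label or f"{lhs}~{t.name}{sfx('paths')}"
        params.append(Param(group, "A", idx[lhs], idx[t.name], label, block,
                            t.fixed, 0.0, "paths"))

    def ref_var(node: str) -> float:
        """rough total-variance scale for a node."""
        if node in observed:
            return float(Sd[observed.index(node), observed.index(node)])
        terms = desc.measurement.get(node)
        if terms:
            r = observed.index(terms[0].name)
            return float(Sd[r, r])
        return 1.0

    # --- variances / covariances
    done = set()

    def add_S(a: str, b: str, block: str, category: str, start: float):
        key = (a, b) if idx[a] <= idx[b] else (b, a)
        if key in done:
            return
        done.add(key)
        term = explicit.get(key)
        label = (term.label if term and term.label else
                 (f"{key[0]}~~{key[1]}{sfx(category)}"))
        fixed = term.fixed if term else None
        params.append(Param(group, "S", idx[key[0]], idx[key[1]], label,
                            block, fixed, start, category))

    # explicit first (user statements win)
    for (a, b), term in explicit.items():
        if a == b:
            block = ("Phi" if a in exo else
                     "Psi" if a in latents or a in endo else obs_block(a))
            start = max(0.5 * ref_var(a), 1e-3)
        else:
            block = "Phi" if (a in exo and b in exo) else "Psi"
            start = 0.0
        add_S(a, b, block, "lv" if (a in latents or b in latents or a in exo)
              else "residuals", start)

    for item in indicators:
        add_S(item, item, obs_block(item), "residuals",
              max(0.4 * ref_var(item), 1e-3))
    for lat in latents:
        if lat in exo:
            add_S(lat, lat, "Phi", "lv", max(0.6 * ref_var(lat), 1e-3))
        else:
            add_S(lat, lat, "Psi", "lv", max(0.4 * ref_var(lat), 1e-3))
    for n in exo:
        if n in observed:
            add_S(n, n, "Phi", "lv", max(ref_var(n), 1e-3))
    for a_i in range(len(exo)):
        for b_i in range(a_i + 1, len(exo)):
            a, b = exo[a_i], exo[b_i]
            start = 0.0
            if a in observed and b in observed:
                start = float(Sd[observed.index(a), observed.index(b)])
            add_S(a, b, "Phi", "lv", start)
    for n in endo:
        if n in observed and (n, n) not in done:
            add_S(n, n, "Psi", "residuals", max(0.4 * ref_var(n), 1e-3))

    # --- means
    if mean_structure:
        if mean_obs is None:
            raise ValueError("mean structure requested but no sample means")
        for j, col in enumerate(observed):
            if col in exo:
                # exogenous observed: saturated mean, group-specific
                params.append(Param(group, "M", idx[col], 0,
                                    f"{col}~1.g{group}", "nu", None,
                                    float(mean_obs[j]), "means"))
            elif col in indicators or col in endo:
                params.append(Param(group, "M", idx[col], 0,
                                    f"{col}~1{sfx('intercepts')}", "nu", None,
                                    float(mean_obs[j]), "intercepts"))
        for lat in latents:
            if free_latent_means and group > 0:
                params.append(Param(group, "M", idx[lat], 0,
                                    f"{lat}~1.g{group}", "alpha", None, 0.0,
                                    "means"))
            else:
                params.append(Param(group, "M", idx[lat], 0,
                                    f"{lat}~1.g{group}", "alpha", 0.0, 0.0,
                                    "means"))

    return CompiledGroup(observed=list(observed), latents=latents,
                         params=params, endogenous=endo, exogenous=exo,
                         mean_structure=mean_structure)


# ----------------------------------------------------------------------
# the numerical core
# ----------------------------------------------------------------------

@dataclass
class _GroupData:
    S: np.ndarray
    n: int
    mean: np.ndarray | None
    compiled: CompiledGroup = None
    # scatter indices, filled by _Engine
    A_rows: np.ndarray = None
    A_cols: np.ndarray = None
    A_theta: np.ndarray = None
    A_base: np.ndarray = None
    S_rows: np.ndarray = None
    S_cols: np.ndarray = None
    S_theta: np.ndarray = None
    S_base: np.ndarray = None
    M_rows: np.ndarray = None
    M_theta: np.ndarray = None
    M_base: np.ndarray = None
    logdet_S: float = 0.0


class _Engine:
    """Shared machinery for single- and multi-group ML estimation."""

    def __init__(self, groups: list[_GroupData]):
        self.groups = groups
        labels: dict[str, int] = {}
        starts: list[float] = []
        is_var: list[bool] = []
        for g in groups:
            for prm in g.compiled.params:
                if prm.fixed is not None:
                    continue
                if prm.label not in labels:
                    labels[prm.label] = len(starts)
                    starts.append(prm.start)
                    is_var.append(prm.matrix == "S" and prm.i == prm.j)
                else:
                    k = labels[prm.label]
                    is_var[k] = is_var[k] and (prm.matrix == "S" and prm.i == prm.j)
        self.labels = labels
        self.label_list = list(labels)
        self.start = np.asarray(starts, dtype=float)
        self.is_variance = np.asarray(is_var, dtype=bool)
        self.start[self.is_variance] = np.maximum(self.start[self.is_variance], 1e-3)
        self.n_free = len(starts)

        for g in groups:
            t = len(g.compiled.names)
            A_base = np.zeros((t, t))
            S_base = np.zeros((t, t))
            M_base = np.zeros(t)
            Ar, Ac, At, Sr, Sc, St, Mr, Mt = [], [], [], [], [], [], [], []
            for prm in g.compiled.params:
                if prm.matrix == "A":
                    if prm.fixed is not None:
                        A_base[prm.i, prm.j] = prm.fixed
                    else:
                        Ar.append(prm.i); Ac.append(prm.j)
                        At.append(labels[prm.label])
                elif prm.matrix == "S":
                    if prm.fixed is not None:
                        S_base[prm.i, prm.j] = S_base[prm.j, prm.i] = prm.fixed
                    else:
                        Sr.append(prm.i); Sc.append(prm.j)
                        St.append(labels[prm.label])
                else:
                    if prm.fixed is not None:
                        M_base[prm.i] = prm.fixed
                    else:
                        Mr.append(prm.i); Mt.append(labels[prm.label])
            g.A_rows, g.A_cols = np.asarray(Ar, int), np.asarray(Ac, int)
            g.A_theta = np.asarray(At, int)
            g.A_base = A_base
            g.S_rows, g.S_cols = np.asarray(Sr, int), np.asarray(Sc, int)
            g.S_theta = np.asarray(St, int)
            g.S_base = S_base
            g.M_rows, g.M_theta = np.asarray(Mr, int), np.asarray(Mt, int)
            g.M_base = M_base
            sign, logdet = np.linalg.slogdet(g.S)
            if sign <= 0:
                raise ValueError("sample covariance matrix is not positive definite")
            g.logdet_S = logdet
        self.weights = np.array([g.n - 1 for g in groups], dtype=float)

    # -- parameter transforms ------------------------------------------
    def to_internal(self, theta_nat: np.ndarray) -> np.ndarray:
        x = theta_nat.copy()
        x[self.is_variance] = np.log(np.maximum(x[self.is_variance], 1e-10))
        return x

    def to_natural(self, theta_int: np.ndarray) -> np.ndarray:
        x = theta_int.copy()
        x[self.is_variance] = np.exp(np.clip(x[self.is_variance], -40, 40))
        return x

    # -- evaluation -----------------------------------------------------
    def group_matrices(self, g: _GroupData, theta_nat: np.ndarray):
        A = g.A_base.copy()
        if len(g.A_rows):
            A[g.A_rows, g.A_cols] = theta_nat[g.A_theta]
        S = g.S_base.copy()
        if len(g.S_rows):
            vals = theta_nat[g.S_theta]
            S[g.S_rows, g.S_cols] = vals
            S[g.S_cols, g.S_rows] = vals
        M = g.M_base.copy()
        if len(g.M_rows):
            M[g.M_rows] = theta_nat[g.M_theta]
        return A, S, M

    def group_implied(self, g: _GroupData, theta_nat: np.ndarray):
        A, S, M = self.group_matrices(g, theta_nat)
        t = A.shape[0]
        p = g.compiled.n_obs_vars
        T = np.linalg.solve(np.eye(t) - A, np.eye(t))
        G = T[:p, :]
        Sigma = G @ S @ G.T
        mu = G @ M if g.compiled.mean_structure else None
        return Sigma, mu, (A, S, M, T, G)

    def group_fml_grad(self, g: _GroupData, theta_nat: np.ndarray,
                       want_grad: bool = True):
        Sigma, mu, (A, S, M, T, G) = self.group_implied(g, theta_nat)
        p = g.compiled.n_obs_vars
        try:
            c = np.linalg.cholesky(Sigma)
        except np.linalg.LinAlgError:
            return 1e12, np.zeros(self.n_free)
        logdet = 2 * np.log(np.diag(c)).sum()
        Sigma_inv = np.linalg.inv(Sigma)
        f = logdet - g.logdet_S + float(np.trace(g.S @ Sigma_inv)) - p
        d = None
        if g.compiled.mean_structure:
            d = g.mean - mu
            f += float(d @ Sigma_inv @ d)
        if not want_grad:
            return f, None
        W = Sigma_inv - Sigma_inv @ g.S @ Sigma_inv
        if d is not None:
            sd = Sigma_inv @ d
            W -= np.outer(sd, sd)
        GtWG = G.T @ W @ G
        dA = 2.0 * (GtWG @ S @ T.T)
        if d is not None:
            gsd = G.T @ (Sigma_inv @ d)
            dA += -2.0 * np.outer(gsd, T @ M)
        grad = np.zeros(self.n_free)
        if len(g.A_rows):
            np.add.at(grad, g.A_theta, dA[g.A_rows, g.A_cols])
        if len(g.S_rows):
            fac = np.where(g.S_rows == g.S_cols, 1.0, 2.0)
            np.add.at(grad, g.S_theta, fac * GtWG[g.S_rows, g.S_cols])
        if len(g.M_rows):
            dM = -2.0 * (G.T @ (Sigma_inv @ d))
            np.add.at(grad, g.M_theta, dM[g.M_rows])
        return f, grad

    def objective_nat(self, theta_nat: np.ndarray):
        total_f = 0.0
        total_g = np.zeros(self.n_free)
        for w, g in zip(self.weights, self.groups):
            f, gr = self.group_fml_grad(g, theta_nat)
            if f >= 1e12:
                return 1e12, np.zeros(self.n_free)
            total_f += w * f
            total_g += w * gr
        return total_f, total_g

    def objective_internal(self, theta_int: np.ndarray):
        nat = self.to_natural(theta_int)
        f, grad = self.objective_nat(nat)
        grad = grad.copy()
        grad[self.is_variance] *= nat[self.is_variance]
        return f, grad

    # -- optimization ---------------------------------------------------
    def fit(self, starts: int = 5, seed: int = 0, gtol: float = 1e-6,
            maxiter: int = 2000):
        """Quasi-Newton minimisation with random restarts on failure."""
        rng = np.random.default_rng(seed)
        x0 = self.to_internal(self.start.copy())
        best = None
        for attempt in range(max(1, starts)):
            x = x0 if attempt == 0 else \
                x0 + rng.normal(0, 0.1 * (1 + attempt), size=x0.shape)
            res = minimize(self.objective_internal, x, jac=True,
                           method="L-BFGS-B",
                           options={"maxiter": maxiter, "ftol": 1e-14,
                                    "gtol": gtol})
            f, gr = self.objective_internal(res.x)
            gnorm = float(np.linalg.norm(gr, ord=np.inf))
            cand = (f, gnorm, res.x)
            if best is None or f < best[0] - 1e-9:
                best = cand
            if f < 1e11 and gnorm < max(gtol * max(abs(f), 1.0), 1e-5):
                best = cand
                break
        f, gnorm, x = best
        if f >= 1e11:
            raise RuntimeError("SEM optimization failed to find an admissible "
                               "solution after restarts")
        converged = gnorm < max(gtol * max(abs(f), 1.0), 1e-4)
        return self.to_natural(x), f, converged, gnorm

    # -- standard errors -------------------------------------------------
    def standard_errors(self, theta_nat: np.ndarray) -> np.ndarray:
        """SEs from the numeric Hessian of objective/2 in natural space."""
        q = self.n_free
        H = np.zeros((q, q))
        for k in range(q):
            h = 1e-5 * max(1.0, abs(theta_nat[k]))
            xp = theta_nat.copy(); xp[k] += h
            xm = theta_nat.copy(); xm[k] -= h
            _, gp = self.objective_nat(xp)
            _, gm = self.objective_nat(xm)
            H[:, k] = (gp - gm) / (2 * h)
        H = (H + H.T) / 2 / 2.0      # Hessian of objective/2
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
        var = np.diag(cov)
        se = np.full(q, np.nan)
        ok = var > 0
        se[ok] = np.sqrt(var[ok])
        return se


# ----------------------------------------------------------------------
# public model classes
# ----------------------------------------------------------------------

def _prepare_data(data: pd.DataFrame, desc: ModelDescription):
    """Subset the data to the columns the model references, in data order."""
    wanted = set()
    for terms in desc.measurement.values():
        wanted |= {t.name for t in terms}
    for lhs, t in desc.regressions:
        wanted |= {lhs, t.name}
    for a, b, _ in desc.covariances:
        wanted |= {a, b}
    cols = [c for c in data.columns if c in wanted]
    X = data[cols].astype(float).to_numpy()
    S = np.cov(X, rowvar=False, ddof=1)
    return cols, S, X.mean(axis=0), X.shape[0]


class SemModel:
    """A covariance-structure model bound to one sample.

    Construct from raw data (``data=`` DataFrame) or summary statistics
    (``sample_cov``, ``nobs`` and optionally ``sample_mean``), then call
    :meth:`fit`.
    """

    def __init__(self, spec: str | ModelDescription,
                 data: pd.DataFrame | None = None,
                 sample_cov: np.ndarray | pd.DataFrame | None = None,
                 nobs: int | None = None,
                 sample_mean: np.ndarray | None = None,
                 mean_structure: bool = False):
        self.desc = parse_model(spec) if isinstance(spec, str) else spec
        self.mean_structure = mean_structure
        if data is not None:
            cols, S, mean, n = _prepare_data(data, self.desc)
        else:
            if sample_cov is None or nobs is None:
                raise ValueError("provide data= or (sample_cov=, nobs=)")
            if isinstance(sample_cov, pd.DataFrame):
                cols = list(sample_cov.columns)
                S = sample_cov.to_numpy(dtype=float)
            else:
                raise ValueError("sample_cov must be a labelled DataFrame")
            S = np.asarray(S, dtype=float)
            mean = np.asarray(sample_mean, dtype=float) if sample_mean is not None else None
            n = int(nobs)
        if n <= S.shape[0]:
            raise ValueError("need more observations than observed variables")
        self.columns, self.sample_cov, self.sample_mean, self.nobs = cols, S, mean, n
        compiled = compile_model(self.desc, cols, S, mean,
                                 mean_structure=mean_structure)
        gd = _GroupData(S=S, n=n, mean=mean, compiled=compiled)
        self._engine = _Engine([gd])
        self.compiled = compiled

    @classmethod
    def from_survey(cls, survey, spec: str | ModelDescription,
                    mean_structure: bool = False,
                    urban_column: str = "urban") -> "SemModel":
        """Build from a :class:`~tradmod.survey.SurveyDataset`.

        Reverse-scored items are un-reversed and the location demographic is
        dummy-coded (1 = urban, 0 = rural) into ``urban_column``.
        """
        frame = survey.scored_items().copy()
        if "location" in survey.data.columns:
            frame[urban_column] = (survey.data["location"] == "urban").astype(float)
        return cls(spec, data=frame, mean_structure=mean_structure)

    def fit(self, starts: int = 5, seed: int = 0, se: bool = True,
            gtol: float = 1e-6):
        from .results import SemResults
        theta, obj, converged, gnorm = self._engine.fit(starts=starts,
                                                        seed=seed, gtol=gtol)
        se_vec = self._engine.standard_errors(theta) if se else None
        return SemResults(self._engine, theta, obj, converged, gnorm, se_vec)


class MultigroupSemModel:
    """Simultaneous estimation over several groups with equality constraints.

    ``equal`` is a subset of {"loadings", "paths", "lv", "residuals",
    "intercepts"}: listed categories share one parameter per label across
    groups (metric invariance = equal loadings; scalar adds intercepts with
    latent means freed in non-reference groups).
    """

    def __init__(self, spec: str | ModelDescription,
                 groups: dict[str, pd.DataFrame],
                 equal: tuple[str, ...] = (),
                 mean_structure: bool = False):
        if len(groups) < 2:
            raise ValueError("need at least two groups")
        self.desc = parse_model(spec) if isinstance(spec, str) else spec
        self.group_names = list(groups)
        self.equal = tuple(equal)
        self.mean_structure = mean_structure
        free_lm = mean_structure and "intercepts" in equal
        gds = []
        ref_cols = None
        for gi, name in enumerate(self.group_names):
            data = groups[name]
            if hasattr(data, "scored_items"):   # SurveyDataset
                frame = data.scored_items().copy()
                if "location" in data.data.columns:
                    frame["urban"] = (data.data["location"] == "urban").astype(float)
                data = frame
            cols, S, mean, n = _prepare_data(data, self.desc)
            if ref_cols is None:
                ref_cols = cols
            elif cols != ref_cols:
                raise ValueError("groups have incompatible indicator sets")
            compiled = compile_model(self.desc, cols, S, mean, group=gi,
                                     shared=self.equal,
                                     mean_structure=mean_structure,
                                     free_latent_means=free_lm)
            gds.append(_GroupData(S=S, n=n, mean=mean, compiled=compiled))
        self._engine = _Engine(gds)
        self.columns = ref_cols

    def fit(self, starts: int = 5, seed: int = 0, se: bool = False,
            gtol: float = 1e-6):
        from .results import SemResults
        theta, obj, converged, gnorm = self._engine.fit(starts=starts,
                                                        seed=seed, gtol=gtol)
        se_vec = self._engine.standard_errors(theta) if se else None
        return SemResults(self._engine, theta, obj, converged, gnorm, se_vec,
                          group_names=self.group_names)
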