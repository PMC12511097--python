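"""Fitted-model results: estimates, fit indices, standardized solution."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["SemResults"]


class SemResults:
    """Estimates and diagnostics of a (multi-)group SEM fit.

    Attributes of note: ``params``/``bse`` (pandas Series by parameter
    label), ``chi2``/``df``, ``fml``, ``fit_indices()``,
    ``standardized_solution()`` and ``rsquared`` (per endogenous latent,
    from the standardized disturbances).
    """

    def __init__(self, engine, theta, objective, converged, gnorm, se=None,
                 group_names=None):
        self._engine = engine
        self.theta = np.asarray(theta, dtype=float)
        self.objective = float(objective)
        self.converged = bool(converged)
        self.grad_norm = float(gnorm)
        self._se = se
        self.group_names = group_names or ["all"]

    # ------------------------------------------------------------------
    @property
    def params(self) -> pd.Series:
        return pd.Series(self.theta, index=self._engine.label_list, name="estimate")

    @property
    def bse(self) -> pd.Series:
        if self._se is None:
            raise ValueError("standard errors were not requested at fit time")
        return pd.Series(self._se, index=self._engine.label_list, name="se")

    @property
    def tvalues(self) -> pd.Series:
        return (self.params / self.bse).rename("t")

    @property
    def nobs(self) -> int:
        return int(sum(g.n for g in self._engine.groups))

    @property
    def n_groups(self) -> int:
        return len(self._engine.groups)

    @property
    def chi2(self) -> float:
        """Sum over groups of (n_g - 1) * F_g at the optimum."""
        return max(self.objective, 0.0)

    @property
    def fml(self) -> float:
        """Pooled discrepancy value (chi2 / sum(n_g - 1))."""
        return self.chi2 / self._engine.weights.sum()

    @property
    def df(self) -> int:
        moments = 0
        for g in self._engine.groups:
            p = g.compiled.n_obs_vars
            moments += p * (p + 1) // 2
            if g.compiled.mean_structure:
                moments += p
        return moments - self._engine.n_free

    @property
    def heywood(self) -> list[str]:
        """Labels of near-zero variance estimates (inadmissibility flags)."""
        out = []
        for lbl, v, isv in zip(self._engine.label_list, self.theta,
                               self._engine.is_variance):
            if isv and v < 1e-5:
                out.append(lbl)
        return out

    # ------------------------------------------------------------------
    def implied_cov(self, group: int = 0) -> pd.DataFrame:
        g = self._engine.groups[group]
        Sigma, _, _ = self._engine.group_implied(g, self.theta)
        cols = g.compiled.observed
        return pd.DataFrame(Sigma, index=cols, columns=cols)

    def implied_mean(self, group: int = 0) -> pd.Series:
        g = self._engine.groups[group]
        _, mu, _ = self._engine.group_implied(g, self.theta)
        if mu is None:
            raise ValueError("no mean structure in this model")
        return pd.Series(mu, index=g.compiled.observed)

    # ------------------------------------------------------------------
    def baseline_chi2(self) -> tuple[float, int]:
        """Independence-model chi-square and df (free variances/means)."""
        chi2, df = 0.0, 0
        for w, g in zip(self._engine.weights, self._engine.groups):
            sd = np.sqrt(np.diag(g.S))
            R = g.S / np.outer(sd, sd)
            sign, logdet = np.linalg.slogdet(R)
            chi2 += w * (-logdet)
            p = g.compiled.n_obs_vars
            df += p * (p - 1) // 2
        return chi2, df

    def srmr(self) -> float:
        """RMS standardized residual covariance (lower triangle incl. diag)."""
        sq, cnt = 0.0, 0
        for gi, g in enumerate(self._engine.groups):
            Sigma = self.implied_cov(gi).to_numpy()
            sd = np.sqrt(np.diag(g.S))
            resid = (g.S - Sigma) / np.outer(sd, sd)
            il = np.tril_indices_from(resid)
            sq += float((resid[il] ** 2).sum())
            cnt += len(il[0])
        return float(np.sqrt(sq / cnt))

    def fit_indices(self) -> dict[str, float]:
        """CFI, TLI, RMSEA, SRMR plus chi2/df bookkeeping."""
        chi2, df = self.chi2, self.df
        chi2_b, df_b = self.baseline_chi2()
        num = max(chi2 - df, 0.0)
        den = max(chi2_b - df_b, num, 1e-12)
        cfi = 1.0 - num / den
        if df > 0 and df_b > 0 and chi2_b / df_b > 1:
            tli = ((chi2_b / df_b) - (chi2 / df)) / ((chi2_b / df_b) - 1.0)
        else:
            tli = 1.0
        n_eff = self._engine.weights.sum()
        if df > 0:
            rmsea = np.sqrt(max(chi2 - df, 0.0) / (df * n_eff)) \
                * np.sqrt(self.n_groups)
        else:
            rmsea = 0.0
        return {"chi2": chi2, "df": df, "chi2_baseline": chi2_b,
                "df_baseline": df_b, "CFI": float(cfi), "TLI": float(tli),
                "RMSEA": float(rmsea), "SRMR": self.srmr()}

    # ------------------------------------------------------------------
    def _param_rows(self):
        for gi, g in enumerate(self._engine.groups):
            names = g.compiled.names
            for prm in g.compiled.params:
                yield gi, g, names, prm

    def standardized_solution(self) -> pd.DataFrame:
        """All parameters rescaled to unit-variance latent/observed metric."""
        rows = []
        cache = {}
        for gi, g, names, prm in self._param_rows():
            if gi not in cache:
                A, S, M = self._engine.group_matrices(g, self.theta)
                t = A.shape[0]
                T = np.linalg.solve(np.eye(t) - A, np.eye(t))
                V = T @ S @ T.T
                cache[gi] = (A, S, np.sqrt(np.maximum(np.diag(V), 1e-12)))
            A, S, sd = cache[gi]
            est = prm.fixed if prm.fixed is not None else \
                self.theta[self._engine.labels[prm.label]]
            if prm.matrix == "A":
                std = est * sd[prm.j] / sd[prm.i]
                op = "=~" if prm.block.startswith("Lambda") else "~"
                lhs, rhs = names[prm.i], names[prm.j]
                if op == "=~":
                    lhs, rhs = rhs, lhs
            elif prm.matrix == "S":
                std = est / (sd[prm.i] * sd[prm.j])
                op = "~~"
                lhs, rhs = names[prm.i], names[prm.j]
            else:
                std = est / sd[prm.i]
                op = "~1"
                lhs, rhs = names[prm.i], ""
            rows.append({"group": self.group_names[gi], "lhs": lhs, "op": op,
                         "rhs": rhs, "label": prm.label, "block": prm.block,
                         "estimate": est, "std": std,
                         "free": prm.fixed is None})
        return pd.DataFrame(rows)

    def std_path(self, lhs: str, rhs: str, group: int | str = 0) -> float:
        """Standardized structural coefficient for ``lhs ~ rhs``."""
        sol = self.standardized_solution()
        gname = group if isinstance(group, str) else self.group_names[group]
        hit = sol[(sol.op == "~") & (sol.lhs == lhs) & (sol.rhs == rhs)
                  & (sol.group == gname)]
        if hit.empty:
            raise KeyError(f"no path {lhs} ~ {rhs} in group {gname}")
        return float(hit["std"].iloc[0])

    @property
    def rsquared(self) -> pd.Series:
        """R^2 = 1 - standardized disturbance variance, per endogenous node."""
        out = {}
        for gi, g in enumerate(self._engine.groups):
            A, S, M = self._engine.group_matrices(g, self.theta)
            t = A.shape[0]
            T = np.linalg.solve(np.eye(t) - A, np.eye(t))
            V = T @ S @ T.T
            names = g.compiled.names
            for node in g.compiled.endogenous:
                k = names.index(node)
                tot = V[k, k]
                r2 = 1.0 - S[k, k] / tot if tot > 0 else np.nan
                key = node if self.n_groups == 1 else f"{node}.{self.group_names[gi]}"
                out[key] = float(r2)
        return pd.Series(out, name="rsquared")

    # ------------------------------------------------------------------
    def summary(self) -> str:
        fi = self.fit_indices()
        lines = [
            "SEM maximum-likelihood results",
            "=" * 34,
            f"groups: {', '.join(self.group_names)}   n = {self.nobs}",
            f"free parameters: {self._engine.n_free}   df: {self.df}",
            f"chi2 = {self.chi2:.3f}   F_ML = {self.fml:.6f}   "
            f"converged: {self.converged} (|grad| {self.grad_norm:.2e})",
            f"CFI = {fi['CFI']:.3f}  TLI = {fi['TLI']:.3f}  "
            f"RMSEA = {fi['RMSEA']:.3f}  SRMR = {fi['SRMR']:.3f}",
        ]
        if self.heywood:
            lines.append(f"WARNING Heywood-like variances: {', '.join(self.heywood)}")
        sol = self.standardized_solution()
        sol = sol[sol.free]
        have_se = self._se is not None
        lines.append("")
        lines.append(f"{'parameter':<28}{'est':>10}{'std':>10}"
                     + (f"{'se':>10}{'t':>9}" if have_se else ""))
        seen = set()
        for _, r in sol.iterrows():
            if r.label in seen:
                continue
            seen.add(r.label)
            name = f"{r.lhs} {r.op} {r.rhs}".strip()
            line = f"{name:<28}{r.estimate:>10.3f}{r['std']:>10.3f}"
            if have_se:
                se = self.bse[r.label]
                tv = r.estimate / se if se and np.isfinite(se) and se > 0 else np.nan
                line += f"{se:>10.3f}{tv:>9.2f}"
            lines.append(line)
        r2 = self.rsquared
        if len(r2):
            lines.append("")
            lines.append("R-squared: " + "  ".join(f"{k}={v:.3f}"
                                                   for k, v in r2.items()))
        return "\n".join(lines)

    def __repr__(self):
        return (f"<SemResults chi2={self.chi2:.2f} df={self.df} "
                f"converged={self.converged}>")
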