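"""Population specification for the synthetic consumer survey.

The default :class:`PopulationSpec` encodes the package's reference scenario: a
Northern-China consumer population for traditional-Chinese-medicine (TCM)
functional foods, described by eight psychological constructs plus a method
marker.  Core constructs:

``CI``
    Cultural identity - pride in and resonance with traditional culture.
``MFSC``
    Medicine-food separation cognition - the categorical "medicine is for
    sickness, food is for meals" schema that acts as a cognitive barrier to
    hybrid food/medicine products.
``ATT``, ``PP``, ``PI``, ``PB``
    Attitude, perceived price, purchase intention, purchase behaviour.
``FN``, ``HL``
    Food neophobia and health literacy, used to discriminate MFSC from
    neighbouring constructs.
``MK``
    A theoretically unrelated marker construct (packaging-design preference)
    used for common-method-bias diagnostics.

The spec carries the latent inter-construct correlation matrix, construct
means/SDs on the 1-5 Likert scale, per-construct item counts and standardized
loadings, demographic composition (urban share, age-group shares) and the
standardized urban->MFSC effect.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PopulationSpec",
    "ConstructSpec",
    "build_population_spec",
    "nearest_positive_definite",
    "default_spec",
    "CONSTRUCTS",
    "AGE_GROUPS",
]

#: canonical construct order
CONSTRUCTS = ("CI", "MFSC", "ATT", "PP", "PI", "PB", "FN", "HL", "MK")

AGE_GROUPS = ("18-25", "26-40", "41-55", "56+")

# Inter-construct correlations of the reference population (unprinted pairs
# involving FN/HL/MK default to zero).
_DEFAULT_CORR = {
    ("CI", "MFSC"): -0.451, ("CI", "ATT"): 0.652, ("CI", "PP"): -0.315,
    ("CI", "PI"): 0.689, ("CI", "PB"): 0.557,
    ("MFSC", "ATT"): -0.510, ("MFSC", "PP"): 0.388, ("MFSC", "PI"): -0.598,
    ("MFSC", "PB"): -0.482,
    ("ATT", "PP"): -0.421, ("ATT", "PI"): 0.753, ("ATT", "PB"): 0.612,
    ("PP", "PI"): -0.499, ("PP", "PB"): -0.380,
    ("PI", "PB"): 0.701,
    ("MFSC", "FN"): 0.237, ("MFSC", "HL"): -0.052,
    ("FN", "HL"): -0.345,
}

# (items, AVE, mean, sd, reverse-flags).  AVE doubles as the squared
# standardized loading (equal loadings per construct).  Means other than PI
# are unanchored conventions; PI mean/SD are the survey anchors 3.73/1.07.
_DEFAULT_CONSTRUCTS = {
    "CI":   (3, 0.778, 3.80, 1.00, (False, False, False)),
    "MFSC": (3, 0.710, 3.00, 1.00, (True, True, True)),
    "ATT":  (3, 0.805, 3.70, 1.00, (False, False, False)),
    "PP":   (3, 0.757, 3.20, 1.00, (False, False, False)),
    "PI":   (3, 0.824, 3.73, 1.07, (False, False, False)),
    "PB":   (2, 0.748, 3.10, 1.00, (False, False)),
    "FN":   (3, 0.750, 2.90, 1.00, (True, False, False)),
    "HL":   (3, 0.7208, 3.50, 1.00, (False, False, False)),
    "MK":   (3, 0.700, 3.00, 1.00, (False, False, False)),
}

_DEFAULT_DEMOGRAPHICS = {
    "urban_proportion": 0.546,
    "age_proportions": {"18-25": 0.218, "26-40": 0.451, "41-55": 0.249, "56+": 0.082},
}

#: standardized structural coefficients of the reference path model
DEFAULT_STRUCTURAL_PATHS = {
    ("ATT", "CI"): 0.410,
    ("PI", "CI"): 0.340,
    ("PI", "MFSC"): -0.290,
    ("PI", "ATT"): 0.440,
    ("PI", "PP"): -0.270,
    ("PB", "PI"): 0.590,
    ("MFSC", "URBAN"): 0.260,
}


class SpecValidationError(ValueError):
    """Raised when a population-spec field violates its invariants."""


@dataclass(frozen=True)
class ConstructSpec:
    name: str
    n_items: int
    loading: float          # standardized loading, identical across items
    mean: float             # construct mean on the 1-5 scale
    sd: float               # construct SD on the 1-5 scale
    reverse: tuple[bool, ...]  # reverse-scored flag per item

    @property
    def ave(self) -> float:
        return self.loading ** 2

    @property
    def items(self) -> tuple[str, ...]:
        return tuple(f"{self.name}{i + 1}" for i in range(self.n_items))


@dataclass(frozen=True)
class PopulationSpec:
    """Validated description of the synthetic survey population."""

    constructs: tuple[ConstructSpec, ...]
    correlations: np.ndarray          # latent correlation matrix, spec order
    urban_proportion: float
    age_proportions: dict[str, float]
    urban_effect: float               # standardized urban->MFSC effect
    thresholds: np.ndarray            # strictly increasing z-scale cut points
    repair_delta: float = 0.0         # max |change| applied by the PD repair
    structural_paths: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_STRUCTURAL_PATHS))

    # -- convenience ----------------------------------------------------
    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.constructs)

    def construct(self, name: str) -> ConstructSpec:
        for c in self.constructs:
            if c.name == name:
                return c
        raise KeyError(name)

    def corr(self, a: str, b: str) -> float:
        i, j = self.names.index(a), self.names.index(b)
        return float(self.correlations[i, j])

    def subset_correlations(self, names: list[str]) -> np.ndarray:
        idx = [self.names.index(n) for n in names]
        return self.correlations[np.ix_(idx, idx)].copy()

    def construct_map(self) -> dict[str, dict]:
        """item -> {construct, reverse} mapping for every item."""
        out = {}
        for c in self.constructs:
            for item, rev in zip(c.items, c.reverse):
                out[item] = {"construct": c.name, "reverse": bool(rev)}
        return out

    def fingerprint(self) -> str:
        payload = {
            "constructs": [dataclasses.asdict(c) for c in self.constructs],
            "corr": np.round(self.correlations, 12).tolist(),
            "urban": self.urban_proportion,
            "ages": self.age_proportions,
            "effect": self.urban_effect,
            "thresholds": np.round(self.thresholds, 12).tolist(),
            "paths": {f"{a}<-{b}": v for (a, b), v in sorted(self.structural_paths.items())},
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def nearest_positive_definite(corr: np.ndarray, eps: float = 1e-8):
    """Repair a symmetric matrix to the nearest PD correlation matrix.

    Eigenvalues are clipped at ``eps`` and the result rescaled back to unit
    diagonal (simple, order-independent).  Returns ``(repaired, max_delta)``
    where ``max_delta`` is the largest absolute entry change.
    """
    corr = np.asarray(corr, dtype=float)
    w, V = np.linalg.eigh(corr)
    if w.min() >= eps:
        return corr.copy(), 0.0
    w = np.clip(w, eps, None)
    fixed = (V * w) @ V.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    fixed = (fixed + fixed.T) / 2
    return fixed, float(np.abs(fixed - corr).max())


def _default_thresholds() -> np.ndarray:
    from scipy.stats import norm
    return norm.ppf([0.2, 0.4, 0.6, 0.8])


def default_spec() -> "PopulationSpec":
    """The package's reference population spec."""
    return build_population_spec({})


def build_population_spec(config: dict | None = None) -> PopulationSpec:
    """Assemble and validate a :class:`PopulationSpec` from a config mapping.

    ``config`` may override any default: ``constructs`` (mapping name ->
    ``{items, ave | loading, mean, sd, reverse}``), ``correlations`` (mapping
    ``"A,B" -> r`` or a full matrix under ``matrix``/``names``),
    ``urban_proportion``, ``age_proportions``, ``urban_effect``,
    ``thresholds``.  A non-PD correlation matrix is repaired to the nearest
    PD matrix; the largest entry change is recorded on the spec.
    """
    config = dict(config or {})

    cdefs = {}
    overrides = config.get("constructs", {})
    names = list(_DEFAULT_CONSTRUCTS)
    for extra in overrides:
        if extra not in names:
            names.append(extra)
    for name in names:
        base = _DEFAULT_CONSTRUCTS.get(name)
        ov = dict(overrides.get(name, {}))
        if base is None and not ov:
            raise SpecValidationError(f"construct {name!r} has no definition")
        n_items = int(ov.get("items", base[0] if base else 3))
        if "loading" in ov:
            loading = float(ov["loading"])
        elif "ave" in ov:
            loading = float(np.sqrt(ov["ave"]))
        else:
            loading = float(np.sqrt(base[1]))
        mean = float(ov.get("mean", base[2] if base else 3.0))
        sd = float(ov.get("sd", base[3] if base else 1.0))
        reverse = tuple(ov.get("reverse", base[4] if base else (False,) * n_items))
        if len(reverse) != n_items:
            raise SpecValidationError(
                f"construct {name!r}: reverse flags ({len(reverse)}) != items ({n_items})")
        if not (0.0 < loading < 1.0):
            raise SpecValidationError(
                f"construct {name!r}: loading {loading} outside (0, 1)")
        if not (1.0 <= mean <= 5.0) or sd < 0:
            raise SpecValidationError(f"construct {name!r}: invalid mean/sd")
        cdefs[name] = ConstructSpec(name, n_items, loading, mean, sd, reverse)

    constructs = tuple(cdefs[n] for n in names)

    # --- correlation matrix
    k = len(names)
    if "correlation_matrix" in config:
        R = np.asarray(config["correlation_matrix"], dtype=float)
        if R.shape != (k, k):
            raise SpecValidationError(
                f"correlation_matrix shape {R.shape} does not match {k} constructs")
    else:
        R = np.eye(k)
        entries = dict(_DEFAULT_CORR)
        for key, v in config.get("correlations", {}).items():
            a, b = (s.strip() for s in key.split(","))
            entries[(a, b)] = float(v)
        for (a, b), v in entries.items():
            if a not in names or b not in names:
                continue
            i, j = names.index(a), names.index(b)
            R[i, j] = R[j, i] = v
    if not np.allclose(R, R.T, atol=1e-10):
        raise SpecValidationError("correlation matrix is not symmetric")
    if np.abs(R).max() > 1 + 1e-12:
        raise SpecValidationError("correlation entries outside [-1, 1]")
    if not np.allclose(np.diag(R), 1.0):
        raise SpecValidationError("correlation matrix diagonal is not 1")
    R, delta = nearest_positive_definite(R)

    # --- demographics
    urban = float(config.get("urban_proportion",
                             _DEFAULT_DEMOGRAPHICS["urban_proportion"]))
    if not (0.0 <= urban <= 1.0):
        raise SpecValidationError("urban_proportion outside [0, 1]")
    ages = dict(config.get("age_proportions",
                           _DEFAULT_DEMOGRAPHICS["age_proportions"]))
    if abs(sum(ages.values()) - 1.0) > 1e-6:
        raise SpecValidationError("age_proportions do not sum to 1")
    if any(p < 0 for p in ages.values()):
        raise SpecValidationError("age_proportions must be non-negative")

    effect = float(config.get("urban_effect", 0.26))

    thresholds = np.asarray(config.get("thresholds", _default_thresholds()),
                            dtype=float)
    if np.any(np.diff(thresholds) <= 0):
        raise SpecValidationError("thresholds must be strictly increasing")

    paths = dict(DEFAULT_STRUCTURAL_PATHS)
    for key, v in config.get("structural_paths", {}).items():
        lhs, rhs = (s.strip() for s in key.split("<-"))
        paths[(lhs, rhs)] = float(v)

    return PopulationSpec(
        constructs=constructs, correlations=R, urban_proportion=urban,
        age_proportions=ages, urban_effect=effect, thresholds=thresholds,
        repair_delta=delta, structural_paths=paths)
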