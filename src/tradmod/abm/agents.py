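"""Agent population: psychological states, demographics, network embedding."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..population import PopulationSpec, default_spec
from .network import EdgeList, build_network

__all__ = ["AgentPopulation", "init_agents", "STATE_NAMES"]

#: psychological state variables carried by every agent
STATE_NAMES = ("CI", "MFSC", "ATT", "PP")


@dataclass
class AgentPopulation:
    """Per-agent states on the 1-5 scale plus demographics and the network."""

    states: np.ndarray            # (n, 4) columns = STATE_NAMES
    age_group: np.ndarray         # str array
    location: np.ndarray          # 'urban' / 'rural'
    network: EdgeList
    pi: np.ndarray | None = None          # current purchase intention
    purchased: np.ndarray | None = None   # current purchase flags
    state_means: np.ndarray = field(default=None)   # z-scoring anchors
    state_sds: np.ndarray = field(default=None)

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=float)
        n = self.states.shape[0]
        if self.states.shape != (n, len(STATE_NAMES)):
            raise ValueError("states must be (n, 4)")
        if np.any(self.states < 1.0) or np.any(self.states > 5.0):
            raise ValueError("states must lie in [1, 5]")
        if self.network.n_nodes != n:
            raise ValueError("network size does not match population size")
        if self.pi is None:
            self.pi = np.zeros(n)
        if self.purchased is None:
            self.purchased = np.zeros(n, dtype=bool)

    @property
    def n(self) -> int:
        return self.states.shape[0]

    def copy(self) -> "AgentPopulation":
        return AgentPopulation(self.states.copy(), self.age_group.copy(),
                               self.location.copy(), self.network,
                               self.pi.copy(), self.purchased.copy(),
                               self.state_means, self.state_sds)

    def zscores(self) -> np.ndarray:
        """States standardized by the fixed population anchors."""
        sds = np.maximum(self.state_sds, 1e-12)   # degenerate spec -> z = 0
        return (self.states - self.state_means) / sds


def init_agents(source: PopulationSpec | "object" = None,
                network: EdgeList | None = None,
                n: int = 1000, m: int = 3, seed: int = 0) -> AgentPopulation:
    """Initialize agents from a population spec or an observed survey.

    From a spec: states are multivariate normal with the spec's means, SDs
    and inter-construct correlations, clipped to [1, 5]; demographics follow
    the spec proportions.  From a survey (anything with ``composites()``):
    agents bootstrap whole respondent rows, so the joint composite
    distribution is preserved.  z-scoring anchors are always the spec (or
    survey) means/SDs, frozen at initialisation.
    """
    rng = np.random.default_rng(seed)
    if network is None:
        network = build_network(n, m, seed=int(rng.integers(2 ** 31)))
    n = network.n_nodes

    if source is None:
        source = default_spec()

    if isinstance(source, PopulationSpec):
        names = list(STATE_NAMES)
        means = np.array([source.construct(c).mean for c in names])
        sds = np.array([source.construct(c).sd for c in names])
        R = source.subset_correlations(names)
        L = np.linalg.cholesky(R)
        z = rng.standard_normal((n, len(names))) @ L.T
        states = np.clip(means + z * sds, 1.0, 5.0)
        urban = rng.random(n) < source.urban_proportion
        groups = list(source.age_proportions)
        probs = np.array([source.age_proportions[g] for g in groups])
        ages = rng.choice(groups, size=n, p=probs / probs.sum())
        location = np.where(urban, "urban", "rural")
    else:
        comp = source.composites(list(STATE_NAMES))
        rows = rng.integers(0, len(comp), size=n)
        states = np.clip(comp.to_numpy()[rows], 1.0, 5.0)
        means = comp.mean().to_numpy()
        sds = comp.std(ddof=1).to_numpy()
        dem = source.demographics()
        if len(dem.columns) == 2:
            ages = dem["age_group"].to_numpy()[rows].astype(str)
            location = dem["location"].to_numpy()[rows].astype(str)
        else:
            ages = np.full(n, "26-40")
            location = np.full(n, "urban")

    return AgentPopulation(states=states, age_group=np.asarray(ages, dtype=object),
                           location=np.asarray(location, dtype=object),
                           network=network, state_means=means, state_sds=sds)
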