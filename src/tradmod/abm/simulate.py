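"""The agent-based market simulator.

Each of the 100 synchronous time steps:

1.  Purchase intention in z-space from the standardized structural
    coefficients, ``PI_z = sum(beta * z(state)) + eps`` with
    ``eps ~ N(0, sigma^2)``, destandardized through the survey anchors
    (default mean 3.73, SD 1.07) and clipped to [1, 5].
2.  Purchase occurs when PI exceeds a stochastic threshold drawn per
    agent-step from N(threshold_mean, threshold_sd^2).
3.  Cultural identity diffuses along network edges: an agent moves toward
    neighbours with *higher* CI at rate tau (the cultural transmission
    rate); gaps to lower-CI neighbours are ignored, so CI ratchets upward.
    The default aggregation divides the summed positive gaps by the degree
    (``mean`` mode); the literal ``sum`` mode is available but explodes
    toward the scale ceiling for hub degrees of order 1/tau.

z-scoring uses the frozen population anchors, so interventions that raise
absolute CI levels translate into intention gains.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .agents import STATE_NAMES, AgentPopulation

__all__ = ["SimulationParams", "SimulationResult", "MarketSimulation", "step"]

#: standardized intention coefficients (CI, MFSC, ATT, PP)
DEFAULT_BETAS = {"CI": 0.34, "MFSC": -0.29, "ATT": 0.44, "PP": -0.27}


@dataclass(frozen=True)
class SimulationParams:
    betas: dict = field(default_factory=lambda: dict(DEFAULT_BETAS))
    noise_sd: float = 1.0          # z-units; POM-calibrated (see methods note)
    tau: float = 0.05              # cultural transmission rate per step
    threshold_mean: float = 3.4    # purchase threshold, 1-5 scale
    threshold_sd: float = 0.5
    steps: int = 100
    n_agents: int = 1000
    attachment: int = 3            # BA attachment parameter m
    pi_anchor_mean: float = 3.73   # destandardization anchors, 1-5 scale
    pi_anchor_sd: float = 1.07
    diffusion_mode: str = "mean"   # 'mean' (sum of positive gaps / degree) | 'sum'

    def __post_init__(self):
        if self.tau < 0 or self.noise_sd < 0 or self.threshold_sd < 0:
            raise ValueError("tau and SDs must be non-negative")
        if self.steps < 1 or self.attachment < 1:
            raise ValueError("steps and attachment must be >= 1")
        if self.diffusion_mode not in ("mean", "sum"):
            raise ValueError("diffusion_mode must be 'mean' or 'sum'")

    def beta_vector(self) -> np.ndarray:
        return np.array([self.betas[c] for c in STATE_NAMES])


@dataclass
class SimulationResult:
    """Per-step trajectories plus the final population snapshot."""
    mean_pi: np.ndarray
    sd_pi: np.ndarray
    mean_ci: np.ndarray
    purchase_rate: np.ndarray
    final: AgentPopulation
    params: SimulationParams
    seed: int
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "step": np.arange(len(self.mean_pi)),
            "mean_pi": self.mean_pi, "sd_pi": self.sd_pi,
            "mean_ci": self.mean_ci, "purchase_rate": self.purchase_rate})

    def window_stats(self, last: int = 20) -> dict[str, float]:
        """Time-averaged mean and SD of PI over the final ``last`` steps."""
        return {"mean_pi": float(self.mean_pi[-last:].mean()),
                "sd_pi": float(self.sd_pi[-last:].mean()),
                "purchase_rate": float(self.purchase_rate[-last:].mean())}

    def plot(self, ax=None):
        """Trajectory diagnostic: mean PI, mean CI and purchase rate."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        t = np.arange(len(self.mean_pi))
        ax.plot(t, self.mean_pi, label="mean PI")
        ax.fill_between(t, self.mean_pi - self.sd_pi, self.mean_pi + self.sd_pi,
                        alpha=0.15)
        ax.plot(t, self.mean_ci, label="mean CI")
        ax2 = ax.twinx()
        ax2.plot(t, self.purchase_rate, color="grey", ls="--",
                 label="purchase rate")
        ax2.set_ylabel("purchase rate")
        ax.set_xlabel("step")
        ax.set_ylabel("1-5 scale")
        ax.legend(loc="upper left")
        return ax


def step(pop: AgentPopulation, params: SimulationParams,
         rng: np.random.Generator) -> AgentPopulation:
    """One synchronous update; returns the population (mutated in place)."""
    n = pop.n
    z = pop.zscores()
    pi_z = z @ params.beta_vector() + rng.normal(0.0, params.noise_sd, size=n)
    pop.pi = np.clip(params.pi_anchor_mean + params.pi_anchor_sd * pi_z, 1.0, 5.0)
    thresholds = rng.normal(params.threshold_mean, params.threshold_sd, size=n)
    pop.purchased = pop.pi > thresholds

    net = pop.network
    ci = pop.states[:, 0]
    acc = np.zeros(n)
    np.add.at(acc, net.src, np.maximum(ci[net.dst] - ci[net.src], 0.0))
    np.add.at(acc, net.dst, np.maximum(ci[net.src] - ci[net.dst], 0.0))
    if params.diffusion_mode == "mean":
        acc = acc / np.maximum(net.degree, 1.0)
    pop.states[:, 0] = np.clip(ci + params.tau * acc, 1.0, 5.0)
    return pop


class MarketSimulation:
    """Simulation bound to a parameter set and an initial population.

    ``run`` iterates :func:`step` and records population trajectories;
    deterministic given ``seed``.
    """

    def __init__(self, params: SimulationParams | None = None,
                 population: AgentPopulation | None = None, seed: int = 0):
        from .agents import init_agents
        self.params = params or SimulationParams()
        self.seed = int(seed)
        if population is None:
            population = init_agents(n=self.params.n_agents,
                                     m=self.params.attachment,
                                     seed=self.seed)
        self.initial = population

    def run(self) -> SimulationResult:
        params = self.params
        pop = self.initial.copy()
        rng = np.random.default_rng(self.seed + 1_000_003)
        mean_pi = np.empty(params.steps)
        sd_pi = np.empty(params.steps)
        mean_ci = np.empty(params.steps)
        rate = np.empty(params.steps)
        for t in range(params.steps):
            pop = step(pop, params, rng)
            mean_pi[t] = pop.pi.mean()
            sd_pi[t] = pop.pi.std()
            mean_ci[t] = pop.states[:, 0].mean()
            rate[t] = pop.purchased.mean()
        return SimulationResult(mean_pi, sd_pi, mean_ci, rate, pop, params,
                                self.seed)
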