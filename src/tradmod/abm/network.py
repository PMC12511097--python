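"""Scale-free social network construction and edge-list I/O."""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["build_network", "EdgeList"]


class EdgeList:
    """Undirected network held as flat edge arrays (fast neighbour sums)."""

    def __init__(self, src: np.ndarray, dst: np.ndarray, n_nodes: int):
        self.src = np.asarray(src, dtype=np.int64)
        self.dst = np.asarray(dst, dtype=np.int64)
        if len(self.src) and (self.src == self.dst).any():
            raise ValueError("self-loops are not allowed")
        self.n_nodes = int(n_nodes)
        self.degree = np.bincount(
            np.concatenate([self.src, self.dst]),
            minlength=self.n_nodes).astype(float)

    @property
    def n_edges(self) -> int:
        return len(self.src)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"source": self.src, "target": self.dst}).to_csv(
            path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "EdgeList":
        df = pd.read_csv(path)
        n = int(max(df["source"].max(), df["target"].max())) + 1
        return cls(df["source"].to_numpy(), df["target"].to_numpy(), n)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(zip(self.src.tolist(), self.dst.tolist()))
        return g


def build_network(n: int, m: int = 3, seed: int = 0) -> EdgeList:
    """Barabasi-Albert preferential-attachment graph as an edge list.

    Grows a scale-free network: each new node attaches to ``m`` existing
    nodes with probability proportional to degree, yielding hub agents with
    very high degree.  Deterministic given ``seed``.
    """
    if not (n > m >= 1):
        raise ValueError("need n > m >= 1")
    g = nx.barabasi_albert_graph(n, m, seed=int(seed))
    edges = np.asarray(g.edges(), dtype=np.int64)
    if edges.size == 0:
        edges = edges.reshape(0, 2)
    return EdgeList(edges[:, 0], edges[:, 1], n)
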