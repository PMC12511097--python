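"""The respondent-by-item survey container and its CSV/JSON serialisation."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SurveyDataset", "share_percent"]


def share_percent(count: int, total: int, ndigits: int = 1) -> float:
    """Percentage share, rounded as printed in sample-description tables."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, ndigits)


@dataclass
class SurveyDataset:
    """Integer 1-5 Likert responses plus demographics and a construct map.

    ``data`` holds one row per respondent with item columns named
    ``<construct><index>`` (e.g. ``CI1``) and demographic columns
    ``location`` (urban/rural) and ``age_group``.  ``construct_map`` maps
    each item to its construct and reverse-scoring flag.
    """

    data: pd.DataFrame
    construct_map: dict[str, dict]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        items = self.item_names()
        vals = self.data[items].to_numpy()
        if vals.size and (np.any(vals < 1) or np.any(vals > 5)
                          or not np.issubdtype(vals.dtype, np.number)):
            raise ValueError("item responses must be integers in 1..5")

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    def item_names(self, construct: str | None = None) -> list[str]:
        if construct is None:
            return [c for c in self.data.columns if c in self.construct_map]
        return [i for i, m in self.construct_map.items()
                if m["construct"] == construct and i in self.data.columns]

    def constructs(self) -> list[str]:
        seen = []
        for m in self.construct_map.values():
            if m["construct"] not in seen:
                seen.append(m["construct"])
        return seen

    def scored_items(self, construct: str | None = None) -> pd.DataFrame:
        """Item responses with reverse-scored items flipped (6 - x)."""
        items = self.item_names(construct)
        out = self.data[items].astype(float).copy()
        for it in items:
            if self.construct_map[it]["reverse"]:
                out[it] = 6.0 - out[it]
        return out

    def composites(self, constructs: list[str] | None = None) -> pd.DataFrame:
        """Unit-weighted construct means of (un-reversed) items."""
        names = constructs or self.constructs()
        out = {}
        for c in names:
            out[c] = self.scored_items(c).mean(axis=1)
        return pd.DataFrame(out, index=self.data.index)

    def demographics(self) -> pd.DataFrame:
        cols = [c for c in ("location", "age_group") if c in self.data.columns]
        return self.data[cols]

    def split_by(self, column: str) -> dict[str, "SurveyDataset"]:
        out = {}
        for val, sub in self.data.groupby(column, observed=True):
            out[str(val)] = SurveyDataset(sub.reset_index(drop=True),
                                          self.construct_map,
                                          dict(self.metadata))
        return out

    # ------------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write the table as CSV with a ``.meta.json`` sidecar."""
        path = Path(path)
        self.data.to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(
            {"construct_map": self.construct_map, "metadata": self.metadata},
            indent=2, sort_keys=True))

    @classmethod
    def read_csv(cls, path: str | Path) -> "SurveyDataset":
        path = Path(path)
        data = pd.read_csv(path)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(sidecar.read_text())
        return cls(data, meta["construct_map"], meta.get("metadata", {}))
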