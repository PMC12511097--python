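"""Sequential measurement-invariance testing (configural / metric / scalar).

Fits the same multi-group CFA three times with increasing cross-group
constraints and applies the conventional |dCFI| <= 0.01 decision rule
between consecutive levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model import MultigroupSemModel

__all__ = ["invariance_sequence", "InvarianceReport"]

_LEVELS = (
    ("configural", ()),
    ("metric", ("loadings",)),
    ("scalar", ("loadings", "intercepts")),
)


@dataclass
class InvarianceReport:
    table: pd.DataFrame          # per level: chi2, df, CFI, TLI, RMSEA, dCFI, verdict
    cutoff: float = 0.01

    @property
    def all_supported(self) -> bool:
        return bool(self.table["supported"].all())

    def __repr__(self):
        return "InvarianceReport:\n" + self.table.to_string()


def invariance_sequence(groups: dict, spec: str, cutoff: float = 0.01,
                        seed: int = 0, starts: int = 3) -> InvarianceReport:
    """Run configural -> metric -> scalar invariance tests.

    ``groups`` maps group name to a DataFrame or SurveyDataset; ``spec`` is
    the measurement (CFA) model.  All levels are estimated with a mean
    structure (saturated means below the scalar level) so chi-squares are
    nested and comparable; a level is "supported" when the CFI drop from
    the previous level is at most ``cutoff``.
    """
    if len(groups) < 2:
        raise ValueError("invariance testing needs at least two groups")
    rows = []
    prev_cfi = None
    for level, equal in _LEVELS:
        model = MultigroupSemModel(spec, groups, equal=equal,
                                   mean_structure=True)
        res = model.fit(starts=starts, seed=seed, se=False)
        fi = res.fit_indices()
        dcfi = None if prev_cfi is None else fi["CFI"] - prev_cfi
        rows.append({
            "level": level, "chi2": fi["chi2"], "df": fi["df"],
            "CFI": fi["CFI"], "TLI": fi["TLI"], "RMSEA": fi["RMSEA"],
            "dCFI": dcfi,
            "supported": True if dcfi is None else abs(dcfi) <= cutoff,
        })
        prev_cfi = fi["CFI"]
    table = pd.DataFrame(rows).set_index("level")
    return InvarianceReport(table=table, cutoff=cutoff)
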