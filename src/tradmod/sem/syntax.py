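"""Tiny lavaan-style model description language.

Statements, one per line (``#`` comments allowed)::

    CI =~ CI1 + CI2 + CI3        # measurement: latent =~ indicators
    ATT ~ CI                     # regression: outcome ~ predictors
    CI ~~ PP                     # (co)variance
    urban ~~ 0*urban             # fixed value
    PI =~ a*PI1 + a*PI2          # shared label -> equality constraint

``latent F =~ i1 i2 i3`` and ``path Y <- X`` spellings are accepted as
aliases.  A numeric prefix fixes a parameter; a symbolic prefix names it
(parameters sharing a name are constrained equal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["ModelDescription", "parse_model"]


@dataclass
class Term:
    name: str
    fixed: float | None = None
    label: str | None = None


@dataclass
class ModelDescription:
    measurement: dict[str, list[Term]] = field(default_factory=dict)   # latent -> indicators
    regressions: list[tuple[str, Term]] = field(default_factory=list)  # (lhs, rhs term)
    covariances: list[tuple[str, str, Term]] = field(default_factory=list)

    @property
    def latents(self) -> list[str]:
        return list(self.measurement)


def _parse_term(tok: str) -> Term:
    tok = tok.strip()
    if "*" in tok:
        prefix, name = tok.split("*", 1)
        prefix = prefix.strip()
        name = name.strip()
        try:
            return Term(name, fixed=float(prefix))
        except ValueError:
            return Term(name, label=prefix)
    return Term(tok)


def _split_terms(rhs: str) -> list[Term]:
    toks = []
    for chunk in rhs.replace("+", " ").split():
        toks.append(_parse_term(chunk))
    return toks


def parse_model(text: str) -> ModelDescription:
    desc = ModelDescription()
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("latent "):
            line = line[len("latent "):]
        if line.startswith("path ") and "<-" in line:
            body = line[len("path "):]
            lhs, rhs = body.split("<-", 1)
            line = f"{lhs.strip()} ~ {rhs.strip()}"
        if "=~" in line:
            lhs, rhs = line.split("=~", 1)
            lhs = lhs.strip()
            desc.measurement.setdefault(lhs, []).extend(_split_terms(rhs))
        elif "~~" in line:
            lhs, rhs = line.split("~~", 1)
            lhs = lhs.strip()
            for term in _split_terms(rhs):
                desc.covariances.append((lhs, term.name, term))
        elif "~" in line:
            lhs, rhs = line.split("~", 1)
            lhs = lhs.strip()
            for term in _split_terms(rhs):
                desc.regressions.append((lhs, term))
        else:
            raise ValueError(f"cannot parse model line: {raw!r}")
    return desc
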