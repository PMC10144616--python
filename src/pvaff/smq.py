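"""Grouping of medical-history preferred terms into SMQ-style categories.

Spontaneous-report databases record a patient's primary diseases as MedDRA
preferred terms. For risk-factor analysis these are collapsed into five
binary history groups — osteoporosis, cancer, arthritis, systemic lupus
erythematosus and renal disorder — each defined by one or more standardized
MedDRA query (SMQ) code with an attached list of member terms.

Matching is case-insensitive exact-term matching after whitespace trimming,
mirroring how preferred terms are matched in MedDRA practice; no substring
or hierarchy traversal is performed. The package ships a small synthetic
term list (``data/smq_toy.yaml``); real SMQ exports can be supplied in the
same schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

#: The five history groups used in the analysis, in canonical order.
HISTORY_GROUPS: tuple[str, ...] = (
    "osteoporosis",
    "cancer",
    "arthritis",
    "sle",
    "renal_disorder",
)


def _fold(term: str) -> str:
    return " ".join(str(term).split()).casefold()


@dataclass(frozen=True)
class SmqGroup:
    """One history group: its SMQ codes and the union of their member terms."""

    name: str
    smq_codes: tuple[str, ...]
    terms: frozenset[str]  # case-folded


@dataclass(frozen=True)
class SmqMap:
    """Mapping from the five history-group names to their term sets."""

    groups: Mapping[str, SmqGroup] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(HISTORY_GROUPS) - set(self.groups)
        extra = set(self.groups) - set(HISTORY_GROUPS)
        if missing:
            raise ValueError(f"SMQ config missing group(s): {sorted(missing)}")
        if extra:
            raise ValueError(f"SMQ config has unknown group(s): {sorted(extra)}")
        for name, grp in self.groups.items():
            if not grp.terms:
                raise ValueError(f"SMQ group {name!r} has an empty term list")

    def __getitem__(self, name: str) -> SmqGroup:
        return self.groups[name]


def load_smq_config(path: str | Path) -> SmqMap:
    """Load an SMQ group definition file (YAML: group -> [{code, terms}]).

    Raises ``ValueError`` for unknown or missing group names and for groups
    whose term list is empty.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return _build_map(raw)


def load_default_smq() -> SmqMap:
    """Load the synthetic toy term lists shipped with the package."""
    text = resources.files("pvaff.data").joinpath("smq_toy.yaml").read_text("utf-8")
    return _build_map(yaml.safe_load(text))


def _build_map(raw: Mapping) -> SmqMap:
    if not isinstance(raw, Mapping):
        raise ValueError("SMQ config must map group names to SMQ entries")
    groups = {}
    for name, entries in raw.items():
        codes = []
        terms: set[str] = set()
        for entry in entries or []:
            codes.append(str(entry.get("code", "")))
            terms.update(_fold(t) for t in entry.get("terms", []))
        groups[str(name)] = SmqGroup(str(name), tuple(codes), frozenset(terms))
    return SmqMap(groups)


def assign_history_groups(
    disease_terms: Iterable[str], smq: SmqMap
) -> dict[str, bool]:
    """Flag each history group whose term set contains any of the diseases.

    A term may belong to several groups; flags are set independently, so the
    assignment is monotone in the term set and order-independent.
    """
    folded = {_fold(t) for t in disease_terms}
    return {
        name: not folded.isdisjoint(smq[name].terms) for name in HISTORY_GROUPS
    }
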