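"""Variable registry: maps each analysis variable to its domain, timepoint and unit.

The registry drives everything downstream: which columns form the 50-node
network (44 non-imaging markers + 6 medial-temporal white-matter neurite-density
tracts), how nodes are grouped into modules, and which variables may be missing
without excluding a participant.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

#: Recognised variable domains.
DOMAINS = (
    "diet",
    "b_vitamins",
    "fatty_acid",
    "immune",
    "lipids",
    "other_blood",
    "clinical",
    "wm_nd",
    "wm_od",
    "gm_volume",
    "cognition",
)

TIMEPOINTS = ("baseline", "year12")

#: Mapping from a registry domain to its upper-level-network module label.
#: Fatty acids are absent on purpose: their modules (FA1..FAk) come from
#: hierarchical clustering, not from the registry.
DOMAIN_MODULES = {
    "diet": "Diet",
    "b_vitamins": "BVitamins",
    "immune": "Cytokines",
    "lipids": "Lipids",
    "other_blood": "OtherBlood",
    "clinical": "Clinical",
    "wm_nd": "WM",
}


@dataclass(frozen=True)
class Variable:
    name: str
    abbreviation: str
    domain: str
    timepoint: str
    unit: str
    network: bool


@dataclass
class VariableRegistry:
    """Ordered collection of analysis variables.

    Parameters
    ----------
    entries
        Variables in canonical order. Node order of the lower-level network
        follows this order restricted to ``network=True`` entries.
    """

    entries: list[Variable] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [v.name for v in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("registry variable names must be unique")
        for v in self.entries:
            if v.domain not in DOMAINS:
                raise ValueError(f"unknown domain {v.domain!r} for {v.name!r}")
            if v.timepoint not in TIMEPOINTS:
                raise ValueError(f"unknown timepoint {v.timepoint!r} for {v.name!r}")

    # -- lookups ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return any(v.name == name for v in self.entries)

    def __getitem__(self, name: str) -> Variable:
        for v in self.entries:
            if v.name == name:
                return v
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.entries]

    @property
    def network_nodes(self) -> list[str]:
        """The node set of the lower-level network, in canonical order."""
        return [v.name for v in self.entries if v.network]

    def domain_of(self, name: str) -> str:
        return self[name].domain

    def by_domain(self, domain: str, network_only: bool = False) -> list[str]:
        return [
            v.name
            for v in self.entries
            if v.domain == domain and (v.network or not network_only)
        ]

    @property
    def fatty_acids(self) -> list[str]:
        return self.by_domain("fatty_acid")

    def domain_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for v in self.entries:
            counts[v.domain] = counts.get(v.domain, 0) + 1
        return counts

    # -- I/O -------------------------------------------------------------
    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "VariableRegistry":
        required = {"name", "abbreviation", "domain", "timepoint", "unit", "network"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"registry file missing columns: {sorted(missing)}")
        entries = [
            Variable(
                name=str(r["name"]),
                abbreviation=str(r["abbreviation"]),
                domain=str(r["domain"]),
                timepoint=str(r["timepoint"]),
                unit=str(r["unit"]),
                network=bool(int(r["network"])),
            )
            for _, r in frame.iterrows()
        ]
        return cls(entries)

    @classmethod
    def from_csv(cls, path) -> "VariableRegistry":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [v.name for v in self.entries],
                "abbreviation": [v.abbreviation for v in self.entries],
                "domain": [v.domain for v in self.entries],
                "timepoint": [v.timepoint for v in self.entries],
                "unit": [v.unit for v in self.entries],
                "network": [int(v.network) for v in self.entries],
            }
        )


def default_registry() -> VariableRegistry:
    """The packaged 60-variable registry.

    Contains the 50 network nodes (2 diet scores, 2 B vitamins, 26 blood
    fatty acids, 3 cytokines, 4 lipids, 5 other blood markers, CVR, BMI and
    6 white-matter neurite-density tracts) plus the non-network variables
    (6 orientation-dispersion tracts, 3 grey-matter volumes, MMSE).
    """
    ref = importlib.resources.files("cohortnet.data") / "default_registry.csv"
    with importlib.resources.as_file(ref) as path:
        return VariableRegistry.from_csv(path)
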