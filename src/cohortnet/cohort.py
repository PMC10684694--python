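"""Cohort table: one row per participant, with covariates and analysis variables.

The table is a thin wrapper around a pandas DataFrame with a fixed column
contract: ``participant_id``, the carrier label ``apoe4`` (0/1, missing
allowed before filtering), covariates (``age``, ``sex``, ``education``,
``icv``), the clinical flags ``hypertension``/``diabetes``, and one column per
registry variable. Missing cells are NaN; the completeness filter removes rows
that cannot enter the 50-column network matrix.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registry import VariableRegistry, default_registry

#: Columns with a reserved, non-variable meaning.
COVARIATE_COLUMNS = (
    "participant_id",
    "apoe4",
    "age",
    "sex",
    "education",
    "icv",
    "hypertension",
    "diabetes",
)

GROUP_COLUMN = "apoe4"


def compute_cvr(hypertension, diabetes):
    """Cardiovascular-risk count: hypertension flag + diabetes flag, in {0,1,2}."""
    h = np.asarray(hypertension)
    d = np.asarray(diabetes)
    for flag, label in ((h, "hypertension"), (d, "diabetes")):
        vals = flag[~pd.isna(flag)]
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"{label} flag must be binary 0/1")
    out = h + d
    return out.item() if out.ndim == 0 else out


@dataclass
class ExclusionReport:
    """Counts of rows dropped by the completeness filter, by reason."""

    n_input: int
    n_retained: int
    missing_group: int
    missing_marker: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


@dataclass
class CohortTable:
    """Participants x (covariates + analysis variables)."""

    data: pd.DataFrame
    registry: VariableRegistry = field(default_factory=default_registry)

    def __post_init__(self) -> None:
        if "participant_id" not in self.data.columns:
            raise ValueError("participant_id column required")
        ids = self.data["participant_id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].tolist()
            raise ValueError(f"duplicate participant_id: {dupes[:5]}")
        if GROUP_COLUMN not in self.data.columns:
            raise ValueError("group label required")
        self.data = self.data.reset_index(drop=True)

    # -- basic views -----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def variables(self) -> list[str]:
        return [v for v in self.registry.names if v in self.data.columns]

    def group_mask(self, carrier: bool) -> pd.Series:
        return self.data[GROUP_COLUMN] == (1 if carrier else 0)

    def subset(self, mask) -> "CohortTable":
        return CohortTable(self.data.loc[mask].reset_index(drop=True), self.registry)

    def group_table(self, carrier: bool) -> "CohortTable":
        return self.subset(self.group_mask(carrier).to_numpy())

    @classmethod
    def concat(cls, tables) -> "CohortTable":
        tables = list(tables)
        frame = pd.concat([t.data for t in tables], ignore_index=True)
        return cls(frame, tables[0].registry)

    def network_matrix(self) -> pd.DataFrame:
        """The participants x 50 matrix of network-node values."""
        return self.data[self.registry.network_nodes]

    # -- I/O -------------------------------------------------------------
    def write_csv(self, path) -> None:
        # %.17g guarantees bit-identical round-trips for finite doubles
        self.data.to_csv(path, index=False, float_format="%.17g")


def load_cohort(path, registry: VariableRegistry | None = None) -> CohortTable:
    """Read a cohort CSV.

    Columns must resolve to registry variable names or reserved covariate
    columns; anything else is kept but reported with a warning. Empty cells
    are preserved as missing.
    """
    registry = registry or default_registry()
    frame = pd.read_csv(path, float_precision="round_trip")
    if GROUP_COLUMN not in frame.columns:
        raise ValueError("group label required")
    known = set(COVARIATE_COLUMNS) | set(registry.names)
    unknown = [c for c in frame.columns if c not in known]
    if unknown:
        warnings.warn(f"unknown columns ignored by the analysis: {unknown}")
    return CohortTable(frame, registry)


def filter_complete(
    table: CohortTable, registry: VariableRegistry | None = None
) -> tuple[CohortTable, ExclusionReport]:
    """Listwise completeness on the group label and the 50 network variables.

    Non-network variables (MMSE, orientation dispersion, volumes) may be
    missing without exclusion: only the network matrix must be complete.
    """
    registry = registry or table.registry
    nodes = [v for v in registry.network_nodes if v in table.data.columns]
    missing_nodes = [v for v in registry.network_nodes if v not in table.data.columns]
    if missing_nodes:
        raise ValueError(f"table lacks network variables: {missing_nodes[:5]}")

    group_ok = table.data[GROUP_COLUMN].notna()
    marker_ok = table.data[nodes].notna().all(axis=1)
    keep = group_ok & marker_ok

    report = ExclusionReport(
        n_input=table.n,
        n_retained=int(keep.sum()),
        missing_group=int((~group_ok).sum()),
        # a row missing both the genotype and a marker counts under missing_group
        missing_marker=int((group_ok & ~marker_ok).sum()),
    )
    if report.n_retained == 0:
        raise ValueError("no complete cases")
    retained = table.subset(keep.to_numpy())
    retained.data[GROUP_COLUMN] = retained.data[GROUP_COLUMN].astype(int)
    return retained, report
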