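"""Subgroup stratification by key-node combinations and permutation contrasts.

Strata are defined by combining the genotype group with criteria on key
variables — an exact ordinal value (e.g. CVR = 2) or a dichotomization at a
threshold (default: the within-group median; suffix "+" means above, "-"
means not above). The outcome (default: right-ILF white-matter neurite
density) is residualized on age and sex and compared across strata by a
permutation test on mean differences with max-statistic correction over the
pairwise family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import yaml

from .adjust import residualize
from .cohort import GROUP_COLUMN, CohortTable

DEFAULT_OUTCOME = "wm_nd_right_ilf"


@dataclass
class StratumSpec:
    """One stratum: a genotype group plus variable criteria.

    ``criteria`` maps a variable name to a rule string: ``"=2"`` (exact
    ordinal value), ``"+"`` (above threshold) or ``"-"`` (not above).
    ``thresholds`` overrides the default within-group median cutoffs.
    """

    name: str
    group: str = "both"  # carrier | noncarrier | both
    criteria: dict[str, str] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.criteria:
            raise ValueError("criteria must be non-empty")
        if self.group not in ("carrier", "noncarrier", "both"):
            raise ValueError("group must be carrier, noncarrier or both")

    @classmethod
    def list_from_yaml(cls, path) -> list["StratumSpec"]:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return [cls(**entry) for entry in raw]


def _spec_mask(table: CohortTable, spec: StratumSpec) -> np.ndarray:
    df = table.data
    if spec.group == "both":
        mask = np.ones(len(df), dtype=bool)
    else:
        mask = (df[GROUP_COLUMN] == (1 if spec.group == "carrier" else 0)).to_numpy()
    for var, rule in spec.criteria.items():
        if var not in df.columns:
            raise ValueError(f"unknown variable {var!r}")
        values = df[var].to_numpy(dtype=float)
        if rule.startswith("="):
            mask &= values == float(rule[1:])
        elif rule in ("+", "-"):
            if var in spec.thresholds:
                cut = spec.thresholds[var]
            else:
                cut = float(np.nanmedian(values[mask])) if mask.any() else np.nan
            if not np.isfinite(cut):
                raise ValueError(f"threshold for {var!r} is not finite")
            mask &= (values > cut) if rule == "+" else (values <= cut)
        else:
            raise ValueError(f"unknown rule {rule!r} for {var!r}")
    return mask


def stratify(table: CohortTable, specs: list[StratumSpec]) -> dict[str, list[str]]:
    """Assign participants to strata; overlapping specs are an error.

    Returns stratum name -> participant ids; participants matching no
    stratum are reported with a warning (they are simply outside the
    analysis, not an error).
    """
    assigned = np.zeros(table.n, dtype=int)
    out: dict[str, list[str]] = {}
    for spec in specs:
        mask = _spec_mask(table, spec)
        if (assigned[mask] > 0).any():
            raise ValueError("overlapping criteria: a participant matched two strata")
        assigned[mask] += 1
        ids = table.data.loc[mask, "participant_id"].tolist()
        if not ids:
            warnings.warn(f"stratum {spec.name!r} is empty")
        out[spec.name] = ids
    n_out = int((assigned == 0).sum())
    if n_out:
        warnings.warn(f"{n_out} participants match no stratum")
    return out


@dataclass
class StratumContrast:
    stratum_a: str
    stratum_b: str
    mean_a: float
    mean_b: float
    diff: float
    p_raw: float
    p_adj: float


def compare_strata(
    table: CohortTable,
    strata: dict[str, list[str]],
    outcome: str = DEFAULT_OUTCOME,
    n_perm: int = 10_000,
    seed: int = 0,
) -> list[StratumContrast]:
    """Pairwise permutation contrasts of the residualized outcome.

    The outcome is residualized on age and sex over the union of strata; for
    each permutation the stratum labels are shuffled jointly and the maximum
    pairwise |t| recorded, giving max-statistic corrected p-values across the
    pairwise family.
    """
    names = [k for k, ids in strata.items() if ids]
    if len(names) < 2:
        raise ValueError("need at least 2 non-empty strata")
    for k in names:
        if len(strata[k]) < 3:
            raise ValueError(f"stratum too small: {k!r}")

    id_to_row = {pid: i for i, pid in enumerate(table.data["participant_id"])}
    rows = [id_to_row[pid] for k in names for pid in strata[k]]
    labels = np.concatenate(
        [np.full(len(strata[k]), i) for i, k in enumerate(names)]
    )
    sub = table.data.iloc[rows]
    resid = residualize(
        sub[outcome].to_numpy(dtype=float),
        sub[["age", "sex"]].to_numpy(dtype=float),
    )

    pairs = list(combinations(range(len(names)), 2))

    def pair_ts(values: np.ndarray, lab: np.ndarray) -> np.ndarray:
        ts = np.empty(len(pairs))
        for p, (i, j) in enumerate(pairs):
            a, b = values[lab == i], values[lab == j]
            na, nb = len(a), len(b)
            pooled = ((a.var(ddof=1) * (na - 1) + b.var(ddof=1) * (nb - 1))
                      / (na + nb - 2))
            se = np.sqrt(pooled * (1 / na + 1 / nb))
            ts[p] = abs(a.mean() - b.mean()) / se if se > 0 else 0.0
        return ts

    t_obs = pair_ts(resid, labels)
    rng = np.random.default_rng(seed)
    exceed_max = np.zeros(len(pairs))
    exceed_each = np.zeros(len(pairs))
    for _ in range(n_perm):
        t_star = pair_ts(resid, labels[rng.permutation(len(labels))])
        exceed_max += t_star.max() >= t_obs
        exceed_each += t_star >= t_obs
    p_adj = (1 + exceed_max) / (1 + n_perm)
    p_raw = (1 + exceed_each) / (1 + n_perm)

    results = []
    for p, (i, j) in enumerate(pairs):
        a, b = resid[labels == i], resid[labels == j]
        results.append(
            StratumContrast(
                stratum_a=names[i],
                stratum_b=names[j],
                mean_a=float(a.mean()),
                mean_b=float(b.mean()),
                diff=float(a.mean() - b.mean()),
                p_raw=float(p_raw[p]),
                p_adj=float(max(p_adj[p], p_raw[p])),
            )
        )
    return results
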