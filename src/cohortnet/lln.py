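"""Lower-level network: residualized correlations -> soft threshold -> TOM.

The 50-node weighted network is built in three steps, following weighted
correlation network analysis practice:

1. a 50x50 correlation matrix of the network variables after residualizing
   each on age and sex;
2. unsigned soft thresholding, ``a_ij = |r_ij|**beta``, which suppresses weak
   correlations without a hard cutoff; beta is either supplied or picked by
   the scale-free topology criterion;
3. the topological overlap measure,

   ``W_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)``,

   which rewards node pairs that share neighbours, bounded in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .adjust import residualize
from .cohort import CohortTable
from .registry import VariableRegistry


@dataclass
class LowerLevelNetwork:
    nodes: list[str]
    W: pd.DataFrame  # symmetric, unit diagonal, entries in [0, 1]
    beta: float
    correlation_kind: str
    group: str = ""

    def to_edge_list(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.nodes):
            for j in range(i + 1, len(self.nodes)):
                rows.append((a, self.nodes[j], float(self.W.iloc[i, j])))
        return pd.DataFrame(rows, columns=["node_a", "node_b", "W"])

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for _, r in self.to_edge_list().iterrows():
            g.add_edge(r["node_a"], r["node_b"], weight=r["W"])
        return g


def correlation_matrix(
    table: CohortTable,
    registry: VariableRegistry | None = None,
    adjust: tuple[str, ...] = ("age", "sex"),
    kind: str = "pearson",
) -> pd.DataFrame:
    """Correlation of the covariate-residualized network variables."""
    registry = registry or table.registry
    nodes = registry.network_nodes
    if table.n < 10:
        raise ValueError("need at least 10 rows for a correlation matrix")
    if kind not in ("pearson", "spearman"):
        raise ValueError("kind must be 'pearson' or 'spearman'")
    cov = (
        table.data[list(adjust)].to_numpy(dtype=float)
        if adjust
        else np.empty((table.n, 0))
    )
    resid = np.column_stack(
        [residualize(table.data[v].to_numpy(dtype=float), cov) for v in nodes]
    )
    if (resid.std(axis=0) < 1e-12).any():
        bad = [v for v, s in zip(nodes, resid.std(axis=0)) if s < 1e-12]
        raise ValueError(f"constant variable after residualization: {bad}")
    if kind == "spearman":
        resid = stats.rankdata(resid, axis=0)
    r = np.corrcoef(resid, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=nodes, columns=nodes)


def soft_threshold(r, beta: float) -> np.ndarray:
    """Unsigned power adjacency ``a_ij = |r_ij|**beta`` with a zero diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    a = np.abs(np.asarray(r, dtype=float)) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def scale_free_fit(a: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-distribution fit (negative if the
    slope is positive, i.e. not scale-free-like)."""
    k = a.sum(axis=0)
    if np.allclose(k, 0):
        return -1.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_k, log_p = [], []
    for b in range(n_bins):
        members = k[which == b]
        if len(members) == 0 or members.mean() <= 0:
            continue
        log_k.append(np.log10(members.mean()))
        log_p.append(np.log10(len(members) / len(k)))
    if len(log_k) < 3:
        return -1.0
    slope, _, r_value, *_ = stats.linregress(log_k, log_p)
    return float(np.sign(-slope) * r_value**2)


def pick_beta(
    r,
    candidates=tuple(range(1, 21)),
    r2_target: float = 0.8,
    default: int = 6,
) -> int:
    """Smallest power whose degree distribution is scale-free-like.

    Falls back to ``default`` (with a warning) when no candidate reaches the
    target R^2 — e.g. for degenerate or block-constant inputs.
    """
    r = np.asarray(r, dtype=float)
    for beta in candidates:
        if scale_free_fit(soft_threshold(r, beta)) >= r2_target:
            return int(beta)
    warnings.warn(
        f"no candidate power reached scale-free R^2 >= {r2_target}; using {default}"
    )
    return int(default)


def topological_overlap(a) -> np.ndarray:
    """Unsigned TOM of a soft-thresholded adjacency; entries in [0, 1]."""
    a = np.asarray(a, dtype=float)
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if a.min() < 0 or a.max() > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    shared = a @ a
    k = a.sum(axis=0)
    k_min = np.minimum.outer(k, k)
    denom = k_min + 1.0 - a
    w = (shared + a) / denom
    np.fill_diagonal(w, 1.0)
    return np.clip(w, 0.0, 1.0)


def build_lln(
    table: CohortTable,
    registry: VariableRegistry | None = None,
    beta: int | str = "auto",
    adjust: tuple[str, ...] = ("age", "sex"),
    kind: str = "pearson",
    weights: str = "tom",
    group: str = "",
) -> LowerLevelNetwork:
    """Full pipeline from a complete cohort table to a LowerLevelNetwork.

    ``weights='adjacency'`` keeps the soft-powered correlations as edge
    weights instead of their topological overlap.
    """
    registry = registry or table.registry
    r = correlation_matrix(table, registry, adjust=adjust, kind=kind)
    chosen = pick_beta(r.to_numpy()) if beta == "auto" else int(beta)
    a = soft_threshold(r.to_numpy(), chosen)
    if weights == "tom":
        w = topological_overlap(a)
    elif weights == "adjacency":
        w = a.copy()
        np.fill_diagonal(w, 1.0)
    else:
        raise ValueError("weights must be 'tom' or 'adjacency'")
    nodes = list(r.columns)
    return LowerLevelNetwork(
        nodes=nodes,
        W=pd.DataFrame(w, index=nodes, columns=nodes),
        beta=chosen,
        correlation_kind=kind,
        group=group,
    )
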