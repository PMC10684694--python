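"""Module partition and upper-level network of average connectivity.

Modules combine biologically predefined domains (diet, B vitamins, cytokines,
lipids, other blood markers, clinical, white matter) with data-driven
hierarchical clustering of the 26 blood fatty acids (FA1..FAk, largest
first). The upper-level network's edge weight between modules q and q' is the
mean lower-level weight over all cross-module node pairs (W^ave), with edges
banded by percentile rank among all module pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .lln import LowerLevelNetwork
from .registry import DOMAIN_MODULES, VariableRegistry

#: Canonical module ordering (FA clusters expand in place).
_MODULE_ORDER = (
    "Diet", "BVitamins", "FA*", "Cytokines", "Lipids", "OtherBlood", "Clinical", "WM",
)

WM_MODULE = "WM"


@dataclass
class ModulePartition:
    assignment: dict[str, str]  # node -> module label
    modules: list[str]  # ordered labels
    source: dict[str, str] = field(default_factory=dict)  # module -> predefined|clustered

    def members(self, module: str) -> list[str]:
        return [n for n, m in self.assignment.items() if m == module]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"node": list(self.assignment), "module": list(self.assignment.values())}
        )


@dataclass
class UpperLevelNetwork:
    modules: list[str]
    Wave: pd.DataFrame  # module x module mean cross-module LLN weight
    percentile_category: dict[tuple[str, str], int]
    within_density: pd.Series | None = None  # mean within-module weight, exported only

    def edge(self, a: str, b: str) -> float:
        return float(self.Wave.loc[a, b])

    def to_edge_list(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.modules):
            for j in range(i + 1, len(self.modules)):
                b = self.modules[j]
                rows.append((a, b, self.edge(a, b), self.percentile_category[(a, b)]))
        return pd.DataFrame(rows, columns=["module_a", "module_b", "Wave", "band"])


# ---------------------------------------------------------------------------
def cluster_fatty_acids(
    similarity: pd.DataFrame,
    method: str = "average",
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6),
    min_size: int = 2,
) -> list[list[str]]:
    """Agglomerative clustering of the fatty acids on distance 1 - similarity.

    The cut is chosen to maximise the mean silhouette over candidate cluster
    counts, requiring every cluster to have at least ``min_size`` members;
    if no cut qualifies, all acids fall into a single cluster (with a
    warning). Clusters are returned largest first (FA1 is the largest).
    """
    names = list(similarity.columns)
    if len(names) < 3:
        raise ValueError("need at least 3 fatty-acid nodes to cluster")
    sim = similarity.to_numpy(dtype=float)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    if np.allclose(dist[np.triu_indices_from(dist, 1)],
                   dist[np.triu_indices_from(dist, 1)].flat[0]):
        warnings.warn("all pairwise similarities equal; returning a single cluster")
        return [list(names)]

    z = linkage(squareform(dist, checks=False), method=method)
    best_labels, best_score = None, -np.inf
    for k in k_range:
        labels = fcluster(z, t=k, criterion="maxclust")
        if len(np.unique(labels)) != k:
            continue
        sizes = np.bincount(labels)[1:]
        if sizes.min() < min_size:
            continue
        score = silhouette_score(dist, labels, metric="precomputed")
        if score > best_score + 1e-12:
            best_labels, best_score = labels, score
    if best_labels is None:
        warnings.warn("no cut satisfied the minimum-size policy; single cluster")
        return [list(names)]

    clusters = [
        [names[i] for i in np.flatnonzero(best_labels == lab)]
        for lab in np.unique(best_labels)
    ]
    # largest first; ties broken by first-member input order (stable)
    clusters.sort(key=lambda c: (-len(c), names.index(c[0])))
    return clusters


def build_partition(
    registry: VariableRegistry, fa_clusters: list[list[str]]
) -> ModulePartition:
    """Map network nodes to modules: registry domains plus FA1..FAk."""
    fa_set = set(registry.fatty_acids)
    clustered = [n for c in fa_clusters for n in c]
    if sorted(clustered) != sorted(fa_set):
        raise ValueError("fa_clusters must partition the registry's fatty acids")

    assignment: dict[str, str] = {}
    source: dict[str, str] = {}
    for node in registry.network_nodes:
        domain = registry.domain_of(node)
        if domain == "fatty_acid":
            continue
        if domain not in DOMAIN_MODULES:
            raise ValueError(f"node {node!r} has no module for domain {domain!r}")
        assignment[node] = DOMAIN_MODULES[domain]
        source[DOMAIN_MODULES[domain]] = "predefined"
    fa_labels = []
    for i, cluster in enumerate(fa_clusters, start=1):
        label = f"FA{i}"
        fa_labels.append(label)
        source[label] = "clustered"
        for node in cluster:
            assignment[node] = label

    modules = []
    for slot in _MODULE_ORDER:
        modules.extend(fa_labels if slot == "FA*" else [slot])
    missing = [n for n in registry.network_nodes if n not in assignment]
    if missing:
        raise ValueError(f"unassigned nodes: {missing}")
    return ModulePartition(assignment=assignment, modules=modules, source=source)


def build_uln(
    lln: LowerLevelNetwork,
    partition: ModulePartition,
    percentiles: tuple[float, ...] = (50.0, 75.0, 90.0),
) -> UpperLevelNetwork:
    """Average cross-module connectivity W^ave with percentile edge bands."""
    w = lln.W.to_numpy()
    node_idx = {n: i for i, n in enumerate(lln.nodes)}
    members = {}
    for q in partition.modules:
        idx = [node_idx[n] for n in partition.members(q) if n in node_idx]
        if not idx:
            raise ValueError(f"empty module {q!r}")
        members[q] = np.array(idx)

    m = len(partition.modules)
    wave = np.ones((m, m))
    within = {}
    for i, qa in enumerate(partition.modules):
        ia = members[qa]
        if len(ia) > 1:
            block = w[np.ix_(ia, ia)]
            within[qa] = float(block[np.triu_indices(len(ia), 1)].mean())
        else:
            within[qa] = float("nan")
        for j in range(i + 1, m):
            ib = members[partition.modules[j]]
            wave[i, j] = wave[j, i] = float(w[np.ix_(ia, ib)].mean())

    pairs = [
        (partition.modules[i], partition.modules[j])
        for i in range(m)
        for j in range(i + 1, m)
    ]
    values = np.array([wave[partition.modules.index(a), partition.modules.index(b)]
                       for a, b in pairs])
    cuts = np.percentile(values, percentiles)
    category = {
        pair: int(np.searchsorted(cuts, v, side="right"))
        for pair, v in zip(pairs, values)
    }
    return UpperLevelNetwork(
        modules=list(partition.modules),
        Wave=pd.DataFrame(wave, index=partition.modules, columns=partition.modules),
        percentile_category=category,
        within_density=pd.Series(within),
    )


def wm_edge_table(uln: UpperLevelNetwork, wm_module: str = WM_MODULE) -> pd.DataFrame:
    """WM-incident upper-level edges ranked by W^ave, highest first.

    Ties are broken by module-label order (stable), with a warning so the
    arbitrary ordering is visible.
    """
    if wm_module not in uln.modules:
        raise ValueError(f"no module {wm_module!r} in the network")
    rows = [
        (q, uln.edge(q, wm_module),
         uln.percentile_category[tuple(sorted((q, wm_module),
                                              key=uln.modules.index))])
        for q in uln.modules
        if q != wm_module
    ]
    frame = pd.DataFrame(rows, columns=["module", "Wave", "band"])
    if frame["Wave"].duplicated().any():
        warnings.warn("tied Wave values; ranked by module-label order")
    order = {q: i for i, q in enumerate(uln.modules)}
    frame = frame.sort_values(
        by=["Wave", "module"],
        ascending=[False, True],
        kind="stable",
        key=lambda s: s.map(order) if s.name == "module" else s,
    ).reset_index(drop=True)
    return frame
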