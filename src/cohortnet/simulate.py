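"""Synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes: two
genotype groups of configurable size, 26 blood fatty acids drawn from planted
correlation blocks (defaults 21/3/2 — the large cluster of placeholders, the
behenic/lignoceric/nervonic trio, and DHA/total-n3), group-specific
cross-domain couplings (by default a stronger cytokine–white-matter coupling
in carriers), linear age and sex effects on every continuous variable, and an
appended batch of incomplete rows carrying missing genotype or blood-marker
data that the completeness filter should remove.

Everything is a Gaussian latent mapped onto the registry's variable set; the
generator makes no claim of marginal realism (assay units, skew) — it exists
so that covariance structure, covariate adjustment and group contrasts are
all non-trivial and recoverable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .cohort import CohortTable
from .registry import VariableRegistry, default_registry

#: Sampling order of the fatty acids used for planted blocks: placeholders
#: first (the large cluster), then the trio, then the DHA/total-n3 pair.
_FA_BLOCK_ORDER = (
    [f"fa_{i:02d}" for i in range(6, 27)]
    + ["behenic_acid", "lignoceric_acid", "nervonic_acid"]
    + ["dha", "total_n3"]
)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort. Defaults are the study conditions."""

    n_noncarrier: int = 113
    n_carrier: int = 43
    n_missing: int = 44  # incomplete rows appended, raw n = 200
    seed: int = 0
    age_mean: float = 68.0
    age_sd: float = 6.7
    fa_block_sizes: tuple[int, ...] = (21, 3, 2)
    rho_within: float = 0.7
    rho_between: float = 0.1
    rho_domain: float = 0.3  # correlation inside every non-fatty-acid domain
    #: (domain_a, domain_b, strength in non-carriers, strength in carriers)
    group_edges: tuple[tuple[str, str, float, float], ...] = (
        ("immune", "wm_nd", 0.10, 0.45),
    )
    age_effect: float = 0.03  # per year, on every continuous variable
    sex_effect: float = 0.5
    noise_sd: float = 1.0
    p_female: float = 0.77
    p_education: float = 0.55
    p_hypertension: float = 0.6
    p_diabetes: float = 0.4

    def __post_init__(self) -> None:
        if sum(self.fa_block_sizes) != 26:
            raise ValueError("fa_block_sizes must sum to 26")
        for rho in (self.rho_within, self.rho_between, self.rho_domain):
            if not -1.0 < rho < 1.0:
                raise ValueError("correlations must lie in (-1, 1)")
        for *_, s_nc, s_c in self.group_edges:
            if not (-1.0 < s_nc < 1.0 and -1.0 < s_c < 1.0):
                raise ValueError("group edge strengths must lie in (-1, 1)")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "fa_block_sizes" in raw:
            raw["fa_block_sizes"] = tuple(raw["fa_block_sizes"])
        if "group_edges" in raw:
            raw["group_edges"] = tuple(tuple(e) for e in raw["group_edges"])
        return cls(**raw)


def planted_fa_partition(config: SimulationConfig) -> list[list[str]]:
    """The generating partition of the 26 fatty acids, largest block first."""
    blocks: list[list[str]] = []
    start = 0
    for size in config.fa_block_sizes:
        blocks.append(_FA_BLOCK_ORDER[start : start + size])
        start += size
    return sorted(blocks, key=len, reverse=True)


def _nearest_correlation(c: np.ndarray) -> np.ndarray:
    """Eigenvalue-clip repair to the nearest positive-definite correlation."""
    vals, vecs = np.linalg.eigh(c)
    if vals.min() > 1e-8:
        return c
    warnings.warn(
        f"generating matrix not positive definite (min eig {vals.min():.2e}); "
        "clipping eigenvalues"
    )
    vals = np.clip(vals, 1e-8, None)
    repaired = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def generating_correlation(
    config: SimulationConfig, carrier: bool, registry: VariableRegistry | None = None
) -> pd.DataFrame:
    """The 50x50 latent correlation matrix for one genotype group."""
    registry = registry or default_registry()
    nodes = registry.network_nodes
    idx = {name: i for i, name in enumerate(nodes)}
    c = np.eye(len(nodes))

    # within-domain blocks for the non-fatty-acid domains
    for domain in ("diet", "b_vitamins", "immune", "lipids", "other_blood",
                   "clinical", "wm_nd"):
        members = [idx[v] for v in registry.by_domain(domain, network_only=True)]
        for a in members:
            for b in members:
                if a != b:
                    c[a, b] = config.rho_domain

    # planted fatty-acid blocks
    fa_names = [v for v in _FA_BLOCK_ORDER if v in idx]
    block_of: dict[str, int] = {}
    start = 0
    for bi, size in enumerate(config.fa_block_sizes):
        for name in fa_names[start : start + size]:
            block_of[name] = bi
        start += size
    for a in fa_names:
        for b in fa_names:
            if a != b:
                rho = config.rho_within if block_of[a] == block_of[b] else config.rho_between
                c[idx[a], idx[b]] = rho

    # group-specific cross-domain couplings
    for dom_a, dom_b, s_nc, s_c in config.group_edges:
        strength = s_c if carrier else s_nc
        for a in registry.by_domain(dom_a, network_only=True):
            for b in registry.by_domain(dom_b, network_only=True):
                c[idx[a], idx[b]] = c[idx[b], idx[a]] = strength

    c = _nearest_correlation(c)
    return pd.DataFrame(c, index=nodes, columns=nodes)


def _antithetic_ages(n: int, mean: float, sd: float, rng: np.random.Generator):
    """Ages symmetric around `mean`: sample mean is exactly `mean` for even n,
    so a split at the sample mean yields two equal strata."""
    half = n // 2
    d = np.abs(rng.normal(0.0, sd, size=half))
    d = np.maximum(d, 1e-3)  # keep every age strictly off the mean
    ages = np.concatenate([mean + d, mean - d])
    if n % 2:
        ages = np.append(ages, mean + rng.normal(0.0, sd))
    return rng.permutation(ages)


def simulate_cohort(
    config: SimulationConfig, registry: VariableRegistry | None = None
) -> CohortTable:
    """Draw a full synthetic cohort, deterministic given ``config.seed``.

    Rows 1..(n_noncarrier + n_carrier) are complete; ``n_missing`` additional
    rows carry a missing genotype or a missing blood marker (equal chance).
    """
    registry = registry or default_registry()
    rng = np.random.default_rng(config.seed)
    nodes = registry.network_nodes
    n_ret = config.n_noncarrier + config.n_carrier

    frames = []
    for carrier, n_rows in ((False, config.n_noncarrier), (True, config.n_carrier)):
        corr = generating_correlation(config, carrier, registry).to_numpy()
        chol = np.linalg.cholesky(corr)
        z = rng.standard_normal((n_rows, len(nodes))) @ chol.T
        frames.append(pd.DataFrame(config.noise_sd * z, columns=nodes))
    values = pd.concat(frames, ignore_index=True)

    group = np.concatenate(
        [np.zeros(config.n_noncarrier), np.ones(config.n_carrier)]
    )
    age = _antithetic_ages(n_ret, config.age_mean, config.age_sd, rng)
    sex = (rng.random(n_ret) < config.p_female).astype(int)
    education = (rng.random(n_ret) < config.p_education).astype(int)

    # covariate effects on every continuous network variable (CVR handled below)
    continuous = [v for v in nodes if v != "cvr"]
    shift = config.age_effect * (age - config.age_mean) + config.sex_effect * sex
    values[continuous] = values[continuous].add(shift, axis=0)

    # ordinal CVR: threshold the clinical latent (plus idiosyncratic noise)
    # into hypertension and diabetes flags, then count
    latent = values["cvr"].to_numpy() + config.age_effect * (age - config.age_mean)
    lat_sd = np.sqrt(config.noise_sd**2 + 0.25)
    hyp = (latent + 0.5 * rng.standard_normal(n_ret)
           > lat_sd * norm.ppf(1 - config.p_hypertension)).astype(int)
    dia = (latent + 0.5 * rng.standard_normal(n_ret)
           > lat_sd * norm.ppf(1 - config.p_diabetes)).astype(int)
    values["cvr"] = hyp + dia

    # non-network variables: independent latents with the same covariate effects
    extra = {}
    for name in registry.names:
        if name in nodes:
            continue
        base = rng.standard_normal(n_ret) * config.noise_sd + shift
        if name == "icv":
            base = 1.4e6 + 1.0e5 * base
        elif name in ("left_hippocampus", "right_hippocampus"):
            base = 3900.0 + 400.0 * base
        elif name == "mmse":
            base = np.clip(np.round(27.0 + 2.0 * base), 0, 30)
        extra[name] = base

    frame = pd.DataFrame(
        {
            "participant_id": [f"P{i:04d}" for i in range(1, n_ret + 1)],
            "apoe4": group,
            "age": age,
            "sex": sex,
            "education": education,
            "hypertension": hyp,
            "diabetes": dia,
        }
    )
    frame = pd.concat([frame, values, pd.DataFrame(extra)], axis=1)

    if config.n_missing:
        frame = pd.concat(
            [frame, _incomplete_rows(config, registry, rng, n_ret)],
            ignore_index=True,
        )
    return CohortTable(frame, registry)


def _incomplete_rows(config, registry, rng, offset):
    """Rows excluded downstream: genotype or one random blood marker missing."""
    nodes = registry.network_nodes
    blood = [
        v for v in nodes
        if registry.domain_of(v)
        in ("b_vitamins", "fatty_acid", "immune", "lipids", "other_blood")
    ]
    rows = []
    for i in range(config.n_missing):
        row = {
            "participant_id": f"P{offset + i + 1:04d}",
            "apoe4": float(rng.integers(0, 2)),
            "age": rng.normal(config.age_mean, config.age_sd),
            "sex": int(rng.random() < config.p_female),
            "education": int(rng.random() < config.p_education),
            "hypertension": int(rng.random() < config.p_hypertension),
            "diabetes": int(rng.random() < config.p_diabetes),
        }
        for v in nodes:
            row[v] = rng.standard_normal()
        row["cvr"] = row["hypertension"] + row["diabetes"]
        for name in registry.names:
            if name not in nodes:
                row[name] = rng.standard_normal()
        if rng.random() < 0.5:
            row["apoe4"] = np.nan
        else:
            row[blood[rng.integers(0, len(blood))]] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_null_pair(
    config: SimulationConfig, registry: VariableRegistry | None = None
) -> tuple[CohortTable, CohortTable]:
    """Two group tables drawn from one identical joint distribution.

    Group-specific couplings are equalised at their non-carrier strength, so
    any edge difference the comparison pipeline flags is a false positive.
    The returned tables carry the non-carrier / carrier labels (and sizes)
    so they can be concatenated into a null cohort via ``CohortTable.concat``.
    """
    null_edges = tuple((a, b, s_nc, s_nc) for a, b, s_nc, _ in config.group_edges)
    null_cfg = replace(config, group_edges=null_edges, n_missing=0)
    cohort = simulate_cohort(null_cfg, registry)
    return cohort.group_table(False), cohort.group_table(True)
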