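"""Covariate-adjusted group comparisons and partial correlations.

Three nested linear models contrast carriers and non-carriers:

* model 1 — carrier status + age + sex
* model 2 — model 1 + age x carrier interaction
* model 3 — model 2 + education + cardiovascular-risk count

Education is appended automatically when the outcome is MMSE, and intracranial
volume when the outcome is a hippocampal volume. Family-wise correction across
an outcome family uses the Freedman–Lane permutation scheme with the
max-|t| statistic: residuals of the reduced model (all covariates, no carrier
terms) are permuted, the full model refit, and the family maximum recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import GROUP_COLUMN, CohortTable

_MODEL_COVARIATES = {1: (), 2: ("age_x_apoe4",), 3: ("age_x_apoe4", "education", "cvr")}
#: outcome -> covariates appended regardless of the model
_AUTO_EXTRAS = {
    "mmse": ("education",),
    "left_hippocampus": ("icv",),
    "right_hippocampus": ("icv",),
}


@dataclass
class RegressionResult:
    outcome: str
    model: int
    B: float
    ci_low: float
    ci_high: float
    p_raw: float
    p_adj: float | None
    n: int
    covariates: tuple[str, ...]
    t_value: float = field(repr=False, default=float("nan"))


@dataclass
class PartialCorrelationResult:
    var_x: str
    var_y: str
    R: float
    p_raw: float
    p_adj: float | None
    n: int


# ---------------------------------------------------------------------------
def residualize(y, covariates) -> np.ndarray:
    """Least-squares residuals of ``y`` on the covariate design (intercept added).

    The residual mean is zero to numerical precision; variables lying exactly
    in the covariate span residualise to the zero vector.
    """
    y = np.asarray(y, dtype=float)
    x = np.atleast_2d(np.asarray(covariates, dtype=float))
    if x.shape[0] != y.shape[0]:
        if x.shape[1] == y.shape[0]:
            x = x.T
        else:
            raise ValueError("length mismatch between y and covariates")
    design = np.column_stack([np.ones(len(y)), x]) if x.size else np.ones((len(y), 1))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate design")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def _design(table: CohortTable, model: int, outcome: str, extra_covariates=()):
    if model not in (1, 2, 3):
        raise ValueError("model must be 1, 2 or 3")
    df = table.data
    cols = {"apoe4": df[GROUP_COLUMN].astype(float), "age": df["age"], "sex": df["sex"]}
    for name in _MODEL_COVARIATES[model] + tuple(_AUTO_EXTRAS.get(outcome, ())) + tuple(extra_covariates):
        if name in cols:
            continue
        if name == "age_x_apoe4":
            cols[name] = df["age"] * df[GROUP_COLUMN].astype(float)
        else:
            cols[name] = df[name]
    x = pd.DataFrame(cols)
    return sm.add_constant(x, has_constant="add")


def fit_group_model(
    table: CohortTable,
    outcome: str,
    model: int = 1,
    extra_covariates: tuple[str, ...] = (),
) -> RegressionResult:
    """OLS contrast of carriers vs non-carriers for one outcome.

    ``B`` is the unstandardized carrier-indicator coefficient in outcome
    units, with a raw 95% t confidence interval.
    """
    y = table.data[outcome].astype(float)
    x = _design(table, model, outcome, extra_covariates)
    keep = y.notna() & x.notna().all(axis=1)
    y, x = y[keep], x[keep]
    if y.nunique() <= 1:
        raise ValueError(f"constant outcome {outcome!r}")
    if len(y) <= x.shape[1] + 1:
        raise ValueError("too few rows for the requested model")
    if np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
        raise ValueError("singular design (is one group empty?)")
    fit = sm.OLS(y, x).fit()
    ci = fit.conf_int().loc["apoe4"]
    return RegressionResult(
        outcome=outcome,
        model=model,
        B=float(fit.params["apoe4"]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_raw=float(fit.pvalues["apoe4"]),
        p_adj=None,
        n=int(fit.nobs),
        covariates=tuple(c for c in x.columns if c != "const"),
        t_value=float(fit.tvalues["apoe4"]),
    )


# ---------------------------------------------------------------------------
def _group_t_stats(y_mat: np.ndarray, x: np.ndarray, group_col: int) -> np.ndarray:
    """|t| of the carrier coefficient for each column of ``y_mat`` under OLS."""
    n, p = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y_mat  # p x K
    resid = y_mat - x @ beta
    s2 = (resid**2).sum(axis=0) / (n - p)
    se = np.sqrt(s2 * xtx_inv[group_col, group_col])
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.abs(beta[group_col] / se)


def permutation_adjust(
    table: CohortTable,
    outcomes: list[str],
    model: int = 1,
    n_perm: int = 10_000,
    seed: int = 0,
    method: str = "maxT",
) -> dict[str, float]:
    """Permutation-corrected p-values for a family of outcomes.

    Freedman–Lane: residuals of the reduced model (covariates only, no carrier
    terms) are permuted jointly across the family, the full model refit and
    the max |t| recorded; ``p_adj = (1 + #{max|t*| >= |t|}) / (1 + n_perm)``.
    ``method='fdr'`` instead computes per-outcome permutation p-values and
    applies Benjamini–Hochberg. Adjusted values are floored at the parametric
    raw p so that p_adj >= p_raw always holds.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if not outcomes:
        raise ValueError("empty outcome family")
    if method not in ("maxT", "fdr"):
        raise ValueError("method must be 'maxT' or 'fdr'")

    df = table.data
    keep = df[outcomes].notna().all(axis=1)
    for outcome in outcomes:
        if _AUTO_EXTRAS.get(outcome):
            raise ValueError(
                "outcomes with outcome-specific covariates cannot share a family design"
            )
    x_full = _design(table, model, outcomes[0]).loc[keep].to_numpy(dtype=float)
    y_mat = df.loc[keep, outcomes].to_numpy(dtype=float)

    carrier_cols = [
        i for i, c in enumerate(_design(table, model, outcomes[0]).columns)
        if c in ("apoe4", "age_x_apoe4")
    ]
    names = list(_design(table, model, outcomes[0]).columns)
    group_col = names.index("apoe4")
    x_reduced = np.delete(x_full, carrier_cols, axis=1)

    # reduced-model fit: fitted values + residuals per outcome
    beta_r, *_ = np.linalg.lstsq(x_reduced, y_mat, rcond=None)
    fitted = x_reduced @ beta_r
    resid = y_mat - fitted

    t_obs = _group_t_stats(y_mat, x_full, group_col)
    p_raw = 2 * stats.t.sf(t_obs, df=x_full.shape[0] - x_full.shape[1])

    rng = np.random.default_rng(seed)
    n = y_mat.shape[0]
    exceed_max = np.zeros(len(outcomes))
    exceed_each = np.zeros(len(outcomes))
    for _ in range(n_perm):
        y_star = fitted + resid[rng.permutation(n)]
        t_star = _group_t_stats(y_star, x_full, group_col)
        exceed_max += t_star.max() >= t_obs
        exceed_each += t_star >= t_obs

    if method == "maxT":
        p_adj = (1 + exceed_max) / (1 + n_perm)
    else:
        from .resample import bh_fdr

        p_adj = bh_fdr((1 + exceed_each) / (1 + n_perm))
    p_adj = np.maximum(p_adj, p_raw)
    return dict(zip(outcomes, np.minimum(p_adj, 1.0)))


def age_stratified_compare(
    table: CohortTable, outcome: str, split: float
) -> tuple[RegressionResult, RegressionResult]:
    """Model-1 contrast within the younger (< split) and older (>= split) strata."""
    young = table.data["age"] < split
    if young.all() or not young.any():
        raise ValueError("empty stratum")
    return (
        fit_group_model(table.subset(young.to_numpy()), outcome, model=1),
        fit_group_model(table.subset((~young).to_numpy()), outcome, model=1),
    )


# ---------------------------------------------------------------------------
def partial_correlation(
    table: CohortTable,
    var_x: str,
    var_y: str,
    covariates: tuple[str, ...] = ("age", "sex"),
) -> PartialCorrelationResult:
    """Pearson correlation of two covariate-residualized variables.

    The p-value uses a t reference with ``n - 2 - k`` degrees of freedom,
    where k is the number of covariates; with no covariates this reduces to
    the plain Pearson correlation test.
    """
    df = table.data
    cov = df[list(covariates)].to_numpy(dtype=float) if covariates else np.empty((len(df), 0))
    rx = residualize(df[var_x].to_numpy(dtype=float), cov)
    ry = residualize(df[var_y].to_numpy(dtype=float), cov)
    if rx.std() < 1e-12 or ry.std() < 1e-12:
        raise ValueError("degenerate after adjustment")
    # commutative form: exactly symmetric under (x, y) exchange
    r = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    n, k = len(rx), len(covariates)
    dof = n - 2 - k
    if dof <= 0:
        raise ValueError("too few rows for partial correlation")
    r_clip = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_clip * np.sqrt(dof / (1 - r_clip**2))
    p = float(2 * stats.t.sf(abs(t), dof))
    return PartialCorrelationResult(var_x, var_y, R=r, p_raw=p, p_adj=None, n=n)


def partial_correlation_family(
    table: CohortTable,
    pairs: list[tuple[str, str]],
    covariates: tuple[str, ...] = ("age", "sex"),
    n_perm: int = 1000,
    seed: int = 0,
) -> list[PartialCorrelationResult]:
    """Max-|R| permutation correction across a family of variable pairs.

    One shared row permutation per iteration is applied to the residualized
    right-hand member of every pair, preserving the family's dependence
    structure on the left-hand side.
    """
    results = [partial_correlation(table, x, y, covariates) for x, y in pairs]
    df = table.data
    cov = df[list(covariates)].to_numpy(dtype=float) if covariates else np.empty((len(df), 0))
    rx = np.column_stack(
        [residualize(df[x].to_numpy(dtype=float), cov) for x, _ in pairs]
    )
    ry = np.column_stack(
        [residualize(df[y].to_numpy(dtype=float), cov) for _, y in pairs]
    )
    rx = rx / np.linalg.norm(rx, axis=0)
    ry = ry / np.linalg.norm(ry, axis=0)
    r_obs = np.abs(np.einsum("ij,ij->j", rx, ry))

    rng = np.random.default_rng(seed)
    n = rx.shape[0]
    exceed = np.zeros(len(pairs))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_star = np.abs(np.einsum("ij,ij->j", rx, ry[perm]))
        exceed += r_star.max() >= r_obs
    p_adj = (1 + exceed) / (1 + n_perm)
    for res, p in zip(results, p_adj):
        res.p_adj = float(max(p, res.p_raw))
    return results
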