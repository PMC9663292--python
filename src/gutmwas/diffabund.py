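"""Dual-method differential abundance with consensus calling.

Two feature-wise linear models are run in parallel on every feature passing
a prevalence filter:

* ``lm_log2_relab`` — OLS of log2(relative abundance + pseudocount) on case
  status plus technical covariates; the pseudocount is half the smallest
  nonzero relative abundance of the feature. Fold change is ``2^beta``.
* ``bias_corrected_da`` — OLS of ``ln(count + 1) - y`` on the same terms,
  where ``y`` is a per-sample sampling fraction estimated by alternating
  least squares on grouped log counts; this approximates testing absolute
  rather than relative abundances. Fold change is ``exp(beta)``.

Each model's p-values are BH-adjusted, and a feature is called associated
when it reaches FDR < 0.05 by one method and FDR <= 0.1 by the other, with
a consistent coefficient sign.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "prevalence_filter",
    "build_design",
    "lm_log2_relab",
    "SamplingFractions",
    "estimate_sampling_fractions",
    "bias_corrected_abundances",
    "bias_corrected_da",
    "bh_fdr",
    "consensus_calls",
    "covariate_rerun",
]

CASE_TERM = "case_status"


def prevalence_filter(table: pd.DataFrame, min_prevalence: float = 0.05) -> pd.DataFrame:
    """Keep features detected (>0) in at least ``min_prevalence`` of samples."""
    if table.shape[1] == 0:
        raise ValueError("empty feature table")
    prev = (table > 0).mean(axis=0)
    kept = table.loc[:, prev >= min_prevalence]
    logger.info("prevalence filter: kept %d / %d features", kept.shape[1], table.shape[1])
    if kept.shape[1] == 0:
        raise ValueError("prevalence filter dropped every feature")
    return kept


def build_design(
    metadata: pd.DataFrame, formula_terms: list[str], case_label: str = "case"
) -> tuple[np.ndarray, list[str]]:
    """Design matrix from metadata columns: intercept first, then one column
    per term. ``case_status`` is coded 1 for cases; other categorical columns
    become dummies (first level dropped); quantitative columns are z-scored.
    Constant columns (e.g., a single collection kit) are dropped."""
    cols: list[np.ndarray] = [np.ones(len(metadata))]
    names = ["intercept"]
    for term in formula_terms:
        if term not in metadata.columns:
            raise KeyError(f"metadata has no column {term!r}")
        col = metadata[term]
        if term == CASE_TERM:
            cols.append((col == case_label).to_numpy(float))
            names.append(term)
            continue
        if col.dtype.kind in "OUSb":  # categorical
            levels = sorted(col.dropna().unique())
            for lev in levels[1:]:
                cols.append((col == lev).to_numpy(float))
                names.append(f"{term}[{lev}]")
            continue
        x = col.to_numpy(float)
        uniq = np.unique(x[~np.isnan(x)])
        if len(uniq) <= 1:
            continue  # constant: collinear with intercept
        if not set(uniq) <= {0.0, 1.0}:
            x = (x - np.nanmean(x)) / np.nanstd(x, ddof=1)
        cols.append(x)
        names.append(term)
    return np.column_stack(cols), names


def _ols_per_feature(y: np.ndarray, x: np.ndarray, target: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized OLS of each column of ``y`` on ``x``; returns (beta, se, p)
    for coefficient ``target``. Rank-deficient designs yield NaN with a warning."""
    n, p = x.shape
    rank = np.linalg.matrix_rank(x)
    if rank < p:
        warnings.warn("singular design matrix; coefficients set to NaN")
        m = y.shape[1]
        return np.full(m, np.nan), np.full(m, np.nan), np.full(m, np.nan)
    coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv_diag = np.diag(np.linalg.inv(x.T @ x))
    se = np.sqrt(sigma2 * xtx_inv_diag[target])
    beta = coef[target]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)
    return beta, se, pvals


def feature_pseudocounts(relab: pd.DataFrame) -> pd.Series:
    """Half the smallest nonzero value of each feature (MaAsLin2 convention)."""
    arr = relab.to_numpy(float)
    masked = np.where(arr > 0, arr, np.inf)
    mins = masked.min(axis=0)
    global_min = mins[np.isfinite(mins)].min() if np.isfinite(mins).any() else 1e-9
    mins = np.where(np.isfinite(mins), mins, global_min)
    return pd.Series(mins / 2.0, index=relab.columns)


def _assemble(
    features, beta, se, pvals, fc_base: float, prevalence: np.ndarray, method: str
) -> pd.DataFrame:
    q = bh_fdr(pd.Series(pvals, index=features))
    fc = fc_base**beta
    return pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "p": pvals,
            "q": q.to_numpy(),
            "fold_change": fc,
            "fc_lo": fc_base ** (beta - 1.96 * se),
            "fc_hi": fc_base ** (beta + 1.96 * se),
            "prevalence": prevalence,
            "method": method,
        },
        index=pd.Index(features, name="feature"),
    )


def lm_log2_relab(
    relab: pd.DataFrame, metadata: pd.DataFrame, formula_terms: list[str]
) -> pd.DataFrame:
    """Feature-wise OLS on log2 relative abundances (MaAsLin2-style).

    Returns one row per feature: beta (log2 scale), se, p, BH q, fold change
    ``2^beta`` with 1.96*se Wald CI, and prevalence.
    """
    if not relab.index.equals(metadata.index):
        raise ValueError("relab and metadata sample indices differ")
    x, names = build_design(metadata, formula_terms)
    target = names.index(CASE_TERM)
    pseudo = feature_pseudocounts(relab)
    y = np.log2(relab.to_numpy(float) + pseudo.to_numpy()[None, :])
    beta, se, pvals = _ols_per_feature(y, x, target)
    return _assemble(relab.columns, beta, se, pvals, 2.0, (relab > 0).mean(axis=0).to_numpy(), "lm-log2relab")


@dataclass
class SamplingFractions:
    """Per-sample ln-scale offsets relating observed counts to absolute abundances."""

    y: pd.Series  # mean-centered
    converged: bool
    n_iter: int


def estimate_sampling_fractions(
    counts: pd.DataFrame, group, tol: float = 1e-6, max_iter: int = 100
) -> SamplingFractions:
    """Alternating least squares on z = ln(count + 1).

    Iterates between group-wise feature means mu(f, g) of (z - y) and sample
    offsets y(s) = feature-mean of (z - mu), centering y each round, until
    max |delta y| < tol. The group structure keeps genuine group-level
    abundance differences out of the sampling fractions.
    """
    z = np.log(counts.to_numpy(float) + 1.0)
    group = np.asarray(group)
    groups = np.unique(group)
    n = z.shape[0]
    y = np.zeros(n)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        resid = z - y[:, None]
        mu = np.empty_like(z)
        for grp in groups:
            mask = group == grp
            mu[mask] = resid[mask].mean(axis=0, keepdims=True)
        y_new = (z - mu).mean(axis=1)
        y_new -= y_new.mean()
        delta = np.abs(y_new - y).max()
        y = y_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn("sampling-fraction estimation did not converge")
    return SamplingFractions(pd.Series(y, index=counts.index, name="y"), converged, it)


def bias_corrected_abundances(counts: pd.DataFrame, fractions: SamplingFractions) -> pd.DataFrame:
    """exp(ln(count + 1) - y): observed abundances corrected for sampling fraction."""
    if not counts.index.equals(fractions.y.index):
        raise ValueError("counts and sampling fractions are not aligned")
    z = np.log(counts.to_numpy(float) + 1.0)
    return pd.DataFrame(
        np.exp(z - fractions.y.to_numpy()[:, None]), index=counts.index, columns=counts.columns
    )


def bias_corrected_da(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    formula_terms: list[str],
    fractions: SamplingFractions | None = None,
) -> pd.DataFrame:
    """Feature-wise OLS on bias-corrected log abundances (ANCOM-BC-style).

    beta is on the natural-log scale; fold change is ``exp(beta)``.
    """
    if not counts.index.equals(metadata.index):
        raise ValueError("counts and metadata sample indices differ")
    if fractions is None:
        fractions = estimate_sampling_fractions(counts, metadata[CASE_TERM].to_numpy())
    x, names = build_design(metadata, formula_terms)
    target = names.index(CASE_TERM)
    z = np.log(counts.to_numpy(float) + 1.0) - fractions.y.to_numpy()[:, None]
    beta, se, pvals = _ols_per_feature(z, x, target)
    return _assemble(
        counts.columns, beta, se, pvals, float(np.e), (counts > 0).mean(axis=0).to_numpy(), "bias-corrected"
    )


def bh_fdr(p: pd.Series | np.ndarray) -> pd.Series:
    """Benjamini-Hochberg step-up q-values; NaN p propagates NaN q."""
    s = pd.Series(np.asarray(p, float)) if not isinstance(p, pd.Series) else p.astype(float)
    if ((s < 0) | (s > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = pd.Series(np.nan, index=s.index)
    ok = s.notna()
    if ok.any():
        q.loc[ok] = multipletests(s[ok].to_numpy(), method="fdr_bh")[1]
    return q


def consensus_calls(
    a: pd.DataFrame, b: pd.DataFrame, primary: float = 0.05, secondary: float = 0.1
) -> pd.DataFrame:
    """Consensus rule over two DA results sharing a feature universe.

    A feature is called when (q_a < 0.05 and q_b <= 0.1) or vice versa.
    Tiers: ``both<0.05``, ``primary<0.05&other<=0.1``, ``not-significant``.
    Discordant coefficient signs demote a would-be call with a warning.
    """
    if set(a.index) != set(b.index):
        raise ValueError("DA results cover different feature universes")
    b = b.loc[a.index]
    qa, qb = a["q"].to_numpy(), b["q"].to_numpy()
    sa, sb = np.sign(a["beta"].to_numpy()), np.sign(b["beta"].to_numpy())
    with np.errstate(invalid="ignore"):
        called = ((qa < primary) & (qb <= secondary)) | ((qb < primary) & (qa <= secondary))
    called = called & ~np.isnan(qa) & ~np.isnan(qb)
    discord = called & (sa * sb < 0)
    if discord.any():
        warnings.warn(f"{discord.sum()} feature(s) met the consensus rule with discordant signs; demoted")
        called &= ~discord
    tier = np.where(
        called & (qa < primary) & (qb < primary),
        "both<0.05",
        np.where(called, "primary<0.05&other<=0.1", "not-significant"),
    )
    direction = np.where(called, np.where(sa > 0, "elevated", "reduced"), "none")
    return pd.DataFrame(
        {"direction": direction, "tier": tier, "q_a": qa, "q_b": qb, "called": called},
        index=a.index,
    )


def covariate_rerun(
    features: list[str],
    relab: pd.DataFrame,
    metadata: pd.DataFrame,
    extra_terms: list[str],
    base_terms: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, int, int]:
    """Re-test called features in an extended model with extra covariates.

    Samples missing any model variable are dropped listwise. Returns the
    case-status DA table (BH over the restricted set), a per-covariate symbol
    table (``++``/``--`` at FDR < 0.05, ``+``/``-`` at FDR < 0.15, blank
    otherwise), and the per-group analytic sample sizes.
    """
    base_terms = base_terms or [CASE_TERM, "total_sequence_count"]
    terms = base_terms + [t for t in extra_terms if t not in base_terms]
    missing = [t for t in terms if t not in metadata.columns]
    if missing:
        raise KeyError(f"metadata lacks terms: {missing}")
    keep = metadata[terms].notna().all(axis=1)
    md = metadata.loc[keep]
    sub = relab.loc[keep, features]
    x, names = build_design(md, terms)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # locate the offending term incrementally
        for j in range(2, x.shape[1] + 1):
            if np.linalg.matrix_rank(x[:, :j]) < j:
                raise ValueError(f"design is singular after adding term {names[j - 1]!r}")
    pseudo = feature_pseudocounts(relab[features])  # pseudocounts from the full table
    y = np.log2(sub.to_numpy(float) + pseudo.to_numpy()[None, :])
    target = names.index(CASE_TERM)
    beta, se, pvals = _ols_per_feature(y, x, target)
    case_tab = _assemble(features, beta, se, pvals, 2.0, (sub > 0).mean(axis=0).to_numpy(), "lm-log2relab")

    symbols = pd.DataFrame("", index=pd.Index(features, name="feature"), columns=names[1:])
    for j, name in enumerate(names[1:], start=1):
        bj, _, pj = _ols_per_feature(y, x, j)
        qj = bh_fdr(pd.Series(pj, index=features))
        sym = np.where(
            qj < 0.05,
            np.where(bj > 0, "++", "--"),
            np.where(qj < 0.15, np.where(bj > 0, "+", "-"), ""),
        )
        symbols[name] = sym
    n_case = int((md[CASE_TERM] == "case").sum())
    n_control = int((md[CASE_TERM] != "case").sum())
    return case_tab, symbols, n_case, n_control
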