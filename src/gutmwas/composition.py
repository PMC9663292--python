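"""Global composition analysis on the simplex.

The sample x feature count table is mapped to Euclidean space with the
centered log-ratio transform ``clr(x) = log(x + 1) - mean(log(x + 1))``
(natural log, +1 pseudocount on counts), so that Euclidean distances between
clr rows are Aitchison distances. On those distances we provide:

* PCA (distance-preserving, since the distances are Euclidean by origin),
* PERMANOVA via the Gower-centered distance matrix (McArdle-Anderson), with
  optional covariates partitioned sequentially before the group term,
* PERMDISP: ANOVA on distances to group spatial medians (Weiszfeld),
* a sequential chi-squared decomposition of a 2 x k frequency table that
  tags, step by step, the category driving the difference (used for
  enterotype distributions).

Permutation p-values use the (1 + exceedances) / (1 + permutations)
estimator, so the smallest reportable p at 9,999 permutations is 1e-4.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "clr_transform",
    "aitchison_pca",
    "PCAResult",
    "PermutationTestResult",
    "permanova",
    "permdisp",
    "SequentialStep",
    "sequential_chisq",
]


def clr_transform(counts: pd.DataFrame) -> pd.DataFrame:
    """Centered log-ratio of each sample's count vector: log(x+1) - mean(log(x+1)).

    Rows of the result sum to zero (centering identity).
    """
    if counts.shape[1] == 0:
        raise ValueError("clr transform needs at least one feature")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    logx = np.log(counts.to_numpy(float) + 1.0)
    return pd.DataFrame(logx - logx.mean(axis=1, keepdims=True), index=counts.index, columns=counts.columns)


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x PCs
    explained_pct: np.ndarray  # percent variance per PC, sums to 100


def aitchison_pca(clr: pd.DataFrame) -> PCAResult:
    """PCA of the column-centered clr matrix.

    Euclidean distances in the full PC space equal the Aitchison distances of
    the input samples (rotation preserves distances).
    """
    if clr.shape[0] < 3:
        raise ValueError("PCA needs at least 3 samples")
    x = clr.to_numpy(float)
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u * s
    var = s**2
    keep = var > var.max() * 1e-12 if var.max() > 0 else slice(None)
    scores = scores[:, keep]
    var = var[keep]
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=clr.index, columns=cols),
        explained_pct=100.0 * var / var.sum(),
    )


@dataclass
class PermutationTestResult:
    statistic: float
    n_permutations: int
    p_value: float


def _gower_center(dist: np.ndarray) -> np.ndarray:
    a = -0.5 * dist**2
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _check_dist(dist) -> np.ndarray:
    d = np.asarray(dist, float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    return d


def _hat_trace(x: np.ndarray, g: np.ndarray) -> float:
    # tr(H G) with H = X (X'X)^+ X'; equals SS explained by X for centered G
    q, _ = np.linalg.qr(x)
    return float(np.einsum("ij,ij->", q, g @ q))


def _design(labels: np.ndarray, covariates: np.ndarray | None) -> tuple[np.ndarray, np.ndarray, int]:
    n = len(labels)
    groups, codes = np.unique(labels, return_inverse=True)
    dummies = np.zeros((n, len(groups) - 1))
    for k in range(1, len(groups)):
        dummies[codes == k, k - 1] = 1.0
    intercept = np.ones((n, 1))
    if covariates is None or covariates.size == 0:
        x_cov = intercept
    else:
        x_cov = np.hstack([intercept, covariates])
    x_full = np.hstack([x_cov, dummies])
    return x_cov, x_full, len(groups)


def permanova_f(dist, labels, covariates: np.ndarray | None = None) -> float:
    """Pseudo-F of the group term after sequential covariate partitioning."""
    d = _check_dist(dist)
    labels = np.asarray(labels)
    g = _gower_center(d)
    x_cov, x_full, k = _design(labels, covariates)
    ss_total = float(np.trace(g))
    ss_cov = _hat_trace(x_cov, g)
    ss_full = _hat_trace(x_full, g)
    ss_group = ss_full - ss_cov
    df_group = k - 1
    df_resid = len(labels) - np.linalg.matrix_rank(x_full)
    ss_resid = ss_total - ss_full
    return (ss_group / df_group) / (ss_resid / df_resid)


def _permutation_p(observed: float, stat_fn, labels: np.ndarray, n_perm, seed) -> tuple[int, float]:
    """Label-permutation p. ``n_perm="exhaustive"`` enumerates all distinct
    arrangements and returns the plain proportion (identity included)."""
    if n_perm == "exhaustive":
        vals = [stat_fn(np.asarray(perm)) for perm in set(itertools.permutations(labels))]
        return len(vals), float(np.mean([v >= observed - 1e-12 for v in vals]))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if stat_fn(rng.permutation(labels)) >= observed - 1e-12:
            exceed += 1
    return n_perm, (1 + exceed) / (1 + n_perm)


def permanova(
    dist,
    labels,
    covariates: np.ndarray | None = None,
    n_perm: int | str = 9999,
    seed: int = 0,
) -> PermutationTestResult:
    """PERMANOVA on a distance matrix; p by permuting group labels.

    ``covariates`` (samples x q, optional) are partitioned out before the
    group term, sequentially, and held fixed under permutation.
    """
    d = _check_dist(dist)
    labels = np.asarray(labels)
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if (counts == 1).any():
        warnings.warn("a group has a single sample; pseudo-F is unstable")
    g = _gower_center(d)
    x_cov, _, k = _design(labels, covariates)
    ss_total = float(np.trace(g))
    ss_cov = _hat_trace(x_cov, g)

    def stat(perm_labels: np.ndarray) -> float:
        _, x_full, _ = _design(perm_labels, covariates)
        ss_full = _hat_trace(x_full, g)
        ss_group = ss_full - ss_cov
        df_resid = len(perm_labels) - np.linalg.matrix_rank(x_full)
        return (ss_group / (k - 1)) / ((ss_total - ss_full) / df_resid)

    observed = stat(labels)
    n_used, p = _permutation_p(observed, stat, labels, n_perm, seed)
    return PermutationTestResult(observed, n_used, p)


def _spatial_median(points: np.ndarray, tol: float = 1e-8, max_iter: int = 1000) -> np.ndarray:
    """Geometric median by Weiszfeld iteration; centroid fallback on non-convergence."""
    m = points.mean(axis=0)
    if len(points) == 1:
        return points[0].copy()
    for _ in range(max_iter):
        norms = np.linalg.norm(points - m, axis=1)
        # small floor keeps the iteration defined when m lands on a data point
        w = 1.0 / np.maximum(norms, 1e-12)
        m_new = (points * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(m_new - m) < tol:
            return m_new
        m = m_new
    warnings.warn("Weiszfeld iteration did not converge; falling back to centroid")
    return points.mean(axis=0)


def _embed(dist: np.ndarray) -> np.ndarray:
    """Classical scaling coordinates (positive-eigenvalue axes)."""
    g = _gower_center(dist)
    vals, vecs = np.linalg.eigh(g)
    keep = vals > max(vals.max(), 0) * 1e-10
    return vecs[:, keep] * np.sqrt(vals[keep])


def permdisp(dist, labels, n_perm: int | str = 9999, seed: int = 0) -> PermutationTestResult:
    """Homogeneity of multivariate dispersion: ANOVA F on distances to group
    spatial medians, permutation p over group labels."""
    d = _check_dist(dist)
    labels = np.asarray(labels)
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).all():
        raise ValueError("dispersion undefined with a single point per group")
    coords = _embed(d)

    def stat(perm_labels: np.ndarray) -> float:
        z = np.empty(len(perm_labels))
        for grp in groups:
            mask = perm_labels == grp
            med = _spatial_median(coords[mask])
            z[mask] = np.linalg.norm(coords[mask] - med, axis=1)
        if np.allclose(z, z[0]):
            raise ValueError("all distances to medians are equal; F undefined")
        return float(stats.f_oneway(*[z[perm_labels == grp] for grp in groups]).statistic)

    observed = stat(labels)
    n_used, p = _permutation_p(observed, stat, labels, n_perm, seed)
    return PermutationTestResult(observed, n_used, p)


@dataclass
class SequentialStep:
    category: str
    contribution: float  # (O-E)^2/E summed over the category's two cells
    step_chi2: float
    step_df: int
    step_p: float
    low_expected: bool  # any expected cell < 1 at this step


def sequential_chisq(table: pd.DataFrame, alpha: float = 0.05) -> list[SequentialStep]:
    """Iteratively tag the category contributing most to a 2 x k chi-squared.

    While the Pearson chi-squared on the current table is significant at
    ``alpha`` (and more than one category remains), record the category with
    the largest summed contribution, drop it, recompute expecteds on the
    reduced table, and repeat. Ties in contribution (within 1e-12) go to the
    lexicographically first category. No continuity correction at any step,
    so contributions decompose the statistic exactly.
    """
    tab = table.copy()
    if tab.shape[0] != 2 or tab.shape[1] < 2:
        raise ValueError("table must be 2 x k with k >= 2")
    if (tab.to_numpy().sum(axis=1) == 0).any() or (tab.to_numpy().sum(axis=0) == 0).any():
        raise ValueError("row and column sums must be positive")
    steps: list[SequentialStep] = []
    while tab.shape[1] >= 2:
        obs = tab.to_numpy(float)
        chi2, p, df, expected = stats.chi2_contingency(obs, correction=False)
        if p >= alpha:
            break
        contrib = ((obs - expected) ** 2 / expected).sum(axis=0)
        best = contrib.max()
        tied = [c for c, v in zip(tab.columns, contrib) if v >= best - 1e-12]
        if len(tied) > 1:
            logger.info("sequential_chisq tie between %s; tagging %s", tied, sorted(tied)[0])
        category = sorted(tied)[0]
        steps.append(
            SequentialStep(
                category=str(category),
                contribution=float(contrib[list(tab.columns).index(category)]),
                step_chi2=float(chi2),
                step_df=int(df),
                step_p=float(p),
                low_expected=bool((expected < 1).any()),
            )
        )
        tab = tab.drop(columns=[category])
    return steps
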