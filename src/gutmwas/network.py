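"""Compositional correlation networks via SparCC, with permutation nulls.

SparCC estimates correlations between underlying absolute abundances from
compositional count data: per iteration, per-sample fractions are drawn from
Dirichlet(counts + 1); the log-ratio variance matrix
``T_ij = var(ln f_i / ln f_j)`` is reduced to basis variances ``w`` under the
sparsity assumption by solving the linear system with diagonal ``D - 1`` and
off-diagonal 1, and ``r_ij = (w_i + w_j - T_ij) / (2 sqrt(w_i w_j))``.
Strongly correlated pairs (|r| above an exclusion threshold) are iteratively
removed from the system to protect the sparsity assumption. The final matrix
is the element-wise median over iterations, clipped to [-1, 1].

Significance comes from a taxon-wise permutation null: each feature's counts
are shuffled independently across samples, SparCC is re-run, and the p-value
of a pair is the plain proportion of random |r| at least as large as the
observed |r|. Edges with |r| above a threshold and permutation p below a
threshold form an unweighted graph on which Louvain communities and degrees
are computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "sparcc",
    "permutation_pvalues",
    "CorrelationNetwork",
    "build_network",
    "louvain_clusters",
    "map_hits",
    "mean_degree",
    "export_graphml",
]


def _logratio_variances(log_fracs: np.ndarray) -> np.ndarray:
    cov = np.cov(log_fracs, rowvar=False)
    v = np.diag(cov)
    return v[:, None] + v[None, :] - 2.0 * cov


def _basis_correlations(
    t_mat: np.ndarray, exclusion_threshold: float, exclusion_rounds: int
) -> np.ndarray:
    """Solve for basis variances under sparsity, iteratively excluding the
    most correlated pair above the threshold; returns one r estimate.
    Components with non-positive basis variance yield NaN correlations."""
    d = t_mat.shape[0]
    m = np.ones((d, d)) + np.diag(np.full(d, d - 2.0))
    t_vec = t_mat.sum(axis=1)
    excluded = np.zeros((d, d), dtype=bool)
    r = None
    for round_ in range(exclusion_rounds + 1):
        w = np.linalg.solve(m, t_vec)
        bad = w <= 0
        w_safe = np.where(bad, np.nan, w)
        denom = 2.0 * np.sqrt(np.outer(w_safe, w_safe))
        r = (w_safe[:, None] + w_safe[None, :] - t_mat) / denom
        np.fill_diagonal(r, 1.0)
        r = np.clip(r, -1.0, 1.0)
        if round_ == exclusion_rounds:
            break
        cand = np.abs(np.nan_to_num(r, nan=0.0))
        np.fill_diagonal(cand, 0.0)
        cand[excluded] = 0.0
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= exclusion_threshold:
            break
        excluded[i, j] = excluded[j, i] = True
        m[i, i] -= 1.0
        m[j, j] -= 1.0
        m[i, j] -= 1.0
        m[j, i] -= 1.0
        t_vec[i] -= t_mat[i, j]
        t_vec[j] -= t_mat[i, j]
    return r


def sparcc(
    counts: pd.DataFrame,
    n_iterations: int = 100,
    exclusion_threshold: float = 0.1,
    exclusion_rounds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """SparCC correlation matrix of a samples x features count table."""
    if counts.shape[1] < 4:
        raise ValueError("SparCC needs at least 4 features for identifiability")
    if counts.shape[0] < 10:
        warnings.warn("fewer than 10 samples; SparCC estimates will be noisy")
    arr = counts.to_numpy(float)
    rng = np.random.default_rng(seed)
    estimates = np.empty((n_iterations, arr.shape[1], arr.shape[1]))
    for it in range(n_iterations):
        gammas = rng.standard_gamma(arr + 1.0)
        fracs = gammas / gammas.sum(axis=1, keepdims=True)
        t_mat = _logratio_variances(np.log(fracs))
        estimates[it] = _basis_correlations(t_mat, exclusion_threshold, exclusion_rounds)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices stay NaN
        r = np.nanmedian(estimates, axis=0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(np.clip(r, -1.0, 1.0), index=counts.columns, columns=counts.columns)


def permutation_pvalues(
    counts: pd.DataFrame,
    observed_r: pd.DataFrame,
    n_random: int = 1000,
    seed: int = 0,
    n_iterations: int = 20,
    exclusion_threshold: float = 0.1,
    exclusion_rounds: int = 10,
) -> pd.DataFrame:
    """Permutation p-values for SparCC correlations.

    Each of ``n_random`` datasets shuffles every feature's counts
    independently across samples (breaking inter-feature dependence while
    preserving marginals); SparCC is re-run at ``n_iterations`` (reduced from
    the observed run for tractability), and ``p_ij`` is the proportion of
    random ``|r|`` >= observed ``|r|`` (ties count as exceedances).
    """
    if n_random < 100:
        warnings.warn("fewer than 100 random datasets gives coarse p-value resolution")
    arr = counts.to_numpy(np.int64)
    obs = np.abs(observed_r.to_numpy(float))
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(obs)
    n_samples, n_features = arr.shape
    for _ in range(n_random):
        perm = np.empty_like(arr)
        for j in range(n_features):
            perm[:, j] = arr[rng.permutation(n_samples), j]
        r_rand = sparcc(
            pd.DataFrame(perm, columns=counts.columns),
            n_iterations=n_iterations,
            exclusion_threshold=exclusion_threshold,
            exclusion_rounds=exclusion_rounds,
            seed=int(rng.integers(2**31)),
        ).to_numpy()
        exceed += (np.abs(r_rand) >= obs).astype(float)
    p = exceed / n_random
    np.fill_diagonal(p, 0.0)
    return pd.DataFrame(p, index=observed_r.index, columns=observed_r.columns)


@dataclass
class CorrelationNetwork:
    r: pd.DataFrame
    perm_p: pd.DataFrame
    edges: list[tuple[str, str, float]]
    graph: nx.Graph
    cluster_id: dict[str, int] = field(default_factory=dict)
    degree: dict[str, int] = field(default_factory=dict)
    hit_annotation: dict[str, str] = field(default_factory=dict)


def build_network(
    r: pd.DataFrame,
    perm_p: pd.DataFrame,
    r_threshold: float = 0.2,
    p_threshold: float = 0.05,
) -> CorrelationNetwork:
    """Threshold correlations into an undirected graph.

    An edge requires ``|r| > r_threshold`` (strict) and ``perm_p <
    p_threshold``; negative correlations are kept. Features without any edge
    are excluded from the node set.
    """
    if not r.index.equals(perm_p.index) or not r.columns.equals(perm_p.columns):
        raise ValueError("r and perm_p matrices are not aligned")
    feats = list(r.index)
    rv, pv = r.to_numpy(float), perm_p.to_numpy(float)
    graph = nx.Graph()
    edges = []
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            if np.isnan(rv[i, j]):
                continue
            if abs(rv[i, j]) > r_threshold and pv[i, j] < p_threshold:
                edges.append((feats[i], feats[j], float(rv[i, j])))
                graph.add_edge(feats[i], feats[j], r=float(rv[i, j]))
    if not edges:
        warnings.warn("no edges passed the thresholds; returning an empty network")
    net = CorrelationNetwork(r=r, perm_p=perm_p, edges=edges, graph=graph)
    net.degree = {n: int(d) for n, d in graph.degree()}
    return net


def louvain_clusters(network: CorrelationNetwork, seed: int = 0, weighted: bool = False) -> dict[str, int]:
    """Louvain community detection on the thresholded graph (unweighted by
    default; ``weighted=True`` uses |r| as edge weight). Cluster ids are
    arbitrary integers; the assignment is stored on the network."""
    if network.graph.number_of_nodes() == 0:
        network.cluster_id = {}
        return {}
    g = network.graph
    if weighted:
        g = g.copy()
        for u, v, data in g.edges(data=True):
            data["weight"] = abs(data.get("r", 1.0))
    communities = nx.community.louvain_communities(g, weight="weight" if weighted else None, seed=seed)
    assignment = {}
    for cid, members in enumerate(sorted(communities, key=lambda c: (-len(c), sorted(c)[0]))):
        for node in members:
            assignment[node] = cid
    network.cluster_id = assignment
    return assignment


def map_hits(network: CorrelationNetwork, calls: pd.DataFrame) -> pd.DataFrame:
    """Annotate network nodes with consensus-call directions and summarize
    per cluster: node count, elevated/reduced hit counts, mean degree."""
    direction = calls["direction"] if "direction" in calls else pd.Series(dtype=object)
    network.hit_annotation = {
        node: (direction.get(node, "none") if direction.get(node, "none") in ("elevated", "reduced") else "none")
        for node in network.graph.nodes
    }
    rows = []
    clusters = sorted(set(network.cluster_id.values()))
    for cid in clusters:
        members = [n for n, c in network.cluster_id.items() if c == cid]
        ann = [network.hit_annotation[m] for m in members]
        rows.append(
            {
                "cluster": cid,
                "n_nodes": len(members),
                "n_elevated": ann.count("elevated"),
                "n_reduced": ann.count("reduced"),
                "mean_degree": float(np.mean([network.degree[m] for m in members])),
            }
        )
    return pd.DataFrame(rows)


def mean_degree(network: CorrelationNetwork, feature_set: list[str]) -> float:
    """Mean degree of a designated feature set within the network (features
    absent from the node set count as degree 0)."""
    return float(np.mean([network.degree.get(f, 0) for f in feature_set]))


def export_graphml(network: CorrelationNetwork, path) -> None:
    g = network.graph.copy()
    for node in g.nodes:
        g.nodes[node]["cluster"] = int(network.cluster_id.get(node, -1))
        g.nodes[node]["degree"] = int(network.degree.get(node, 0))
        g.nodes[node]["hit"] = network.hit_annotation.get(node, "none")
    nx.write_graphml(g, path)
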