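"""Graph-theoretic node metrics and composite hub ranking.

All measures are defined on the binary, symmetric, zero-diagonal adjacency
matrix A (weighted generalizations are out of scope):

* degree           D_i  = sum_j A[i, j]
* clustering       CC_i = (# connected triangles through i) / (D_i (D_i - 1) / 2)
* betweenness      B_i  = sum over unordered pairs {x, y}, x != i != y, of
                          (# shortest x-y paths through i) / (# shortest x-y paths),
                          unnormalized; disconnected pairs contribute 0.

A node is hub-like when its degree and betweenness are high and its
clustering coefficient is low.  Each measure is ranked 1..N (fractional
mean ranks on ties) with rank N assigned to the most hub-like value; the
hub rank is the mean of the three per-measure ranks, and the relative hub
rank divides by N so that networks of different size (the 27-node AAN
versus the 85-node whole-brain graph) can be compared on a common (0, 1]
scale.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .connectivity import AdjacencyMatrix, ConnectivityMatrix, symmetrize
from .errors import ConfigError, ValidationError


def degree(adj: AdjacencyMatrix, node: str | int | None = None):
    """Degree of one node, or the full degree vector if ``node`` is None."""
    d = adj.degree_vector()
    if node is None:
        return d
    i = adj.labels.index(node) if isinstance(node, str) else node
    return int(d[i])


def clustering_coefficient(adj: AdjacencyMatrix, node: str | int | None = None):
    """Local clustering coefficient(s).

    Nodes with fewer than two neighbors have no potential neighbor pairs;
    they are assigned CC = 1.0 so that, under the "low CC marks hubs" rank
    direction, degenerate leaf/isolated nodes sink to the bottom of the
    CC ranking instead of masquerading as hubs.
    """
    a = adj.a
    n = a.shape[0]
    d = a.sum(axis=1)
    cc = np.ones(n, dtype=float)
    for i in range(n):
        if d[i] >= 2:
            nbrs = np.flatnonzero(a[i])
            triangles = a[np.ix_(nbrs, nbrs)].sum() / 2.0
            cc[i] = triangles / (d[i] * (d[i] - 1) / 2.0)
    if node is None:
        return cc
    i = adj.labels.index(node) if isinstance(node, str) else node
    return float(cc[i])


def betweenness(adj: AdjacencyMatrix) -> np.ndarray:
    """Unnormalized betweenness centrality over unordered node pairs."""
    g = nx.from_numpy_array(adj.a)
    bc = nx.betweenness_centrality(g, normalized=False)
    return np.array([bc[i] for i in range(len(adj.labels))], dtype=float)


def rank_measures(d: Sequence[float], b: Sequence[float],
                  cc: Sequence[float]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-measure ranks in [1, N]; rank N = most hub-like.

    Degree and betweenness are ranked ascending (largest value gets rank N);
    clustering is ranked descending (smallest value gets rank N).  Ties
    receive the mean of the tied rank positions, which preserves the
    rank-sum invariant sum(ranks) = N (N + 1) / 2.
    """
    d = np.asarray(d, dtype=float)
    b = np.asarray(b, dtype=float)
    cc = np.asarray(cc, dtype=float)
    if not (d.shape == b.shape == cc.shape) or d.ndim != 1 or d.size < 2:
        raise ValidationError("rank_measures needs three aligned vectors of length >= 2")
    return rankdata(d), rankdata(b), rankdata(-cc)


def hub_rank(rank_d: np.ndarray, rank_b: np.ndarray,
             rank_cc: np.ndarray) -> np.ndarray:
    """Composite hub rank: elementwise mean of the three per-measure ranks."""
    return (np.asarray(rank_d) + np.asarray(rank_b) + np.asarray(rank_cc)) / 3.0


def relative_hub_rank(hub_ranks: np.ndarray, n: int) -> np.ndarray:
    """Hub rank normalized by network size N onto (0, 1]."""
    if n <= 0:
        raise ConfigError(f"network size must be positive, got {n}")
    return np.asarray(hub_ranks, dtype=float) / float(n)


def hub_rank_delta(rel_whole: pd.Series, rel_aan: pd.Series) -> pd.Series:
    """Relative hub rank change, whole-brain minus AAN, per seed ROI.

    Positive values mean a region is more hub-like in the context of the
    whole-brain network; negative values mean it matters more within the
    AAN itself.
    """
    if list(rel_whole.index) != list(rel_aan.index):
        raise ValidationError("hub_rank_delta: index mismatch between networks")
    return rel_whole - rel_aan


def node_metrics(adj: AdjacencyMatrix) -> pd.DataFrame:
    """All per-node measures, ranks and hub ranks as one table."""
    d = degree(adj)
    cc = clustering_coefficient(adj)
    b = betweenness(adj)
    rank_d, rank_b, rank_cc = rank_measures(d, b, cc)
    hr = hub_rank(rank_d, rank_b, rank_cc)
    n = len(adj.labels)
    return pd.DataFrame({
        "abbrev": adj.labels,
        "degree": d,
        "betweenness": b,
        "clustering": cc,
        "rank_D": rank_d,
        "rank_B": rank_b,
        "rank_CC": rank_cc,
        "hub_rank": hr,
        "relative_hub_rank": relative_hub_rank(hr, n),
        "network_size": n,
    })


def assemble_whole_brain(c: ConnectivityMatrix, th: float = 0.5,
                         mode: str = "max") -> AdjacencyMatrix:
    """Extended adjacency over all M targets (seeds + cortical regions).

    Tractography seeds only from the AAN regions, so the rectangular CP
    matrix provides the symmetrized seed block plus directed seed->cortical
    estimates; a seed-cortical edge exists when that single estimate
    exceeds ``th``, and cortical-cortical edges are structurally absent
    (target-only nodes).
    """
    if not (0 <= th < 1):
        raise ConfigError(f"threshold must satisfy 0 <= th < 1, got {th}")
    n, m = c.n_seeds, len(c.targets)
    a = np.zeros((m, m), dtype=np.int8)
    seed_adj = (symmetrize(c.seed_block(), mode=mode) > th).astype(np.int8)
    np.fill_diagonal(seed_adj, 0)
    a[:n, :n] = seed_adj
    if m > n:
        ext = (c.cp[:, n:] > th).astype(np.int8)
        a[:n, n:] = ext
        a[n:, :n] = ext.T
    return AdjacencyMatrix(labels=list(c.targets), a=a, threshold_used=th)


def group_degree_summary(adjacencies: Mapping[str, AdjacencyMatrix],
                         groups: Mapping[str, str]) -> pd.DataFrame:
    """Mean per-seed degree within each age group (rows = groups).

    ``adjacencies`` maps subject id to that subject's adjacency;
    ``groups`` maps subject id to its age-group label.
    """
    missing = [s for s in groups if s not in adjacencies]
    if missing:
        raise ValidationError(f"no adjacency for subjects {missing}")
    by_group: dict[str, list[np.ndarray]] = {}
    labels_ref: list[str] | None = None
    for subj, group in groups.items():
        adj = adjacencies[subj]
        if labels_ref is None:
            labels_ref = adj.labels
        elif adj.labels != labels_ref:
            raise ValidationError(f"subject {subj}: node labels differ across subjects")
        by_group.setdefault(group, []).append(adj.degree_vector())
    empty = [g for g, rows in by_group.items() if not rows]
    if empty or not by_group:
        raise ValidationError(f"empty age group(s): {empty or 'all'}")
    data = {g: np.mean(rows, axis=0) for g, rows in by_group.items()}
    return pd.DataFrame.from_dict(data, orient="index", columns=labels_ref)
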