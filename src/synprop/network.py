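"""PPI network construction and structural manipulation.

Edges arrive as STRING-style (protein_a, protein_b, combined_score)
records; construction keeps edges above a confidence threshold,
z-scores the surviving combined scores and maps them through the
logistic function so every weight lies in (0, 1).  Utilities report the
structural statistics of the resulting graph, subsample its edges for
density ablations, and highlight user-supplied edge subsets.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .datatypes import EdgeList, PPINetwork


@dataclass
class NetworkStats:
    """Structural summary; density and mean degree are reported over the
    connected (degree >= 1) node set, with all-node variants alongside."""

    n_nodes_total: int
    n_nodes_connected: int
    n_edges: int
    density_connected_pct: float
    density_all_pct: float
    mean_degree_connected: float
    mean_degree_all: float
    max_degree: int
    mean_edge_weight: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def build_network(
    edges: EdgeList, protein_ids: list[str], score_threshold: float = 0.4
) -> PPINetwork:
    """Assemble the weighted adjacency matrix from an edge list.

    Only edges with combined score strictly above ``score_threshold`` are
    kept (the conventional STRING medium-confidence cut at 0.4).
    Endpoints outside ``protein_ids`` are dropped and counted; duplicate
    edges collapse to their maximum score.  Kept scores are z-scored
    (over the kept set, sample sd) and logistic-mapped into (0, 1); if
    fewer than two distinct scores survive, all weights default to 0.5.
    An empty result is legal: the model then degrades to edgeless
    per-protein shrinkage.
    """
    index = {p: i for i, p in enumerate(protein_ids)}
    d = len(protein_ids)
    best: dict[tuple[int, int], float] = {}
    n_dropped = 0
    for a, b, s in zip(edges.protein_a, edges.protein_b, edges.score):
        if a not in index or b not in index:
            n_dropped += 1
            continue
        if s <= score_threshold:
            continue
        i, j = index[a], index[b]
        key = (min(i, j), max(i, j))
        if s > best.get(key, -1.0):
            best[key] = float(s)
    W = np.zeros((d, d))
    if best:
        scores = np.array(list(best.values()))
        sd = scores.std(ddof=1) if scores.size > 1 else 0.0
        if sd > 0:
            weights = expit((scores - scores.mean()) / sd)
        else:
            weights = np.full(scores.size, 0.5)
        for (i, j), w in zip(best.keys(), weights):
            W[i, j] = W[j, i] = w
    net = PPINetwork(weights=W, protein_ids=list(protein_ids))
    net.n_dropped_endpoints = n_dropped  # type: ignore[attr-defined]
    return net


def network_stats(network: PPINetwork) -> NetworkStats:
    """Structural statistics: density, degrees and mean edge weight.

    Density over connected nodes is n_edges / C(n_connected, 2) * 100;
    mean connected degree is 2 * n_edges / n_connected.  An edgeless
    network reports zeros throughout.
    """
    W = network.weights
    degree_count = (W > 0).sum(axis=1)
    n_total = W.shape[0]
    connected = degree_count >= 1
    n_conn = int(connected.sum())
    triu = np.triu(W, k=1)
    edge_weights = triu[triu > 0]
    m = int(edge_weights.size)

    def density(nodes: int) -> float:
        pairs = math.comb(nodes, 2)
        return 100.0 * m / pairs if pairs else 0.0

    return NetworkStats(
        n_nodes_total=n_total,
        n_nodes_connected=n_conn,
        n_edges=m,
        density_connected_pct=density(n_conn),
        density_all_pct=density(n_total),
        mean_degree_connected=2.0 * m / n_conn if n_conn else 0.0,
        mean_degree_all=2.0 * m / n_total if n_total else 0.0,
        max_degree=int(degree_count.max(initial=0)),
        mean_edge_weight=float(edge_weights.mean()) if m else 0.0,
    )


def subsample_edges(network: PPINetwork, fraction: float, seed: int = 0) -> PPINetwork:
    """Keep round(fraction * E) uniformly chosen edges; nodes unchanged.

    Deterministic for a given seed.  Used to probe how prediction
    quality depends on PPI edge density (e.g. fractions 0.2/0.4/0.6/0.8).
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    iu, ju = np.where(np.triu(network.weights, k=1) > 0)
    m = iu.size
    n_keep = int(round(fraction * m))
    rng = np.random.default_rng(seed)
    keep = rng.choice(m, size=n_keep, replace=False)
    W = np.zeros_like(network.weights)
    W[iu[keep], ju[keep]] = network.weights[iu[keep], ju[keep]]
    W = W + W.T
    return PPINetwork(weights=W, protein_ids=list(network.protein_ids))


def highlight_edges(
    network: PPINetwork, edge_subset: list[tuple[str, str]]
) -> tuple[PPINetwork, list[tuple[str, str]]]:
    """Set the weights of listed existing edges to exactly 1.

    Both triangle entries change; everything else is untouched, so the
    operation is idempotent.  Pairs that do not name an existing edge are
    returned in a rejects list rather than raising.
    """
    index = {p: i for i, p in enumerate(network.protein_ids)}
    W = network.weights.copy()
    rejects: list[tuple[str, str]] = []
    for a, b in edge_subset:
        if a not in index or b not in index:
            rejects.append((a, b))
            continue
        i, j = index[a], index[b]
        if i == j or W[i, j] == 0:
            rejects.append((a, b))
            continue
        W[i, j] = W[j, i] = 1.0
    return PPINetwork(weights=W, protein_ids=list(network.protein_ids)), rejects


def edgeless(protein_ids: list[str]) -> PPINetwork:
    """All-zero network: propagation reduces to per-protein shrinkage."""
    d = len(protein_ids)
    return PPINetwork(weights=np.zeros((d, d)), protein_ids=list(protein_ids))
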