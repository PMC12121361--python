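"""Synthetic data with the statistical structure the model assumes.

The generator plays the role of the study cohort: it draws a sparse
weighted interaction graph, bounded expression values, per-protein
propagation intensities and per-biomarker estimation weights, then
samples Bernoulli positivity labels from the model's own generative
chain X -> Z = (Phi + L)^{-1} Phi X -> P_b = sigma(theta_b^T Z) ->
Y_b ~ Bernoulli(P_b).  Everything downstream of a spec is fixed by its
seed.  Defaults describe a desk-scale cohort: 30 target proteins, 2000
participants, graph density near the 5.5% observed in real
STRING-derived target networks, propagation intensities centered on
1.25 (their empirically reported scale), and unit-scale estimation
weights.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.special import expit

from .datatypes import (
    DEFAULT_BIOMARKERS,
    BiomarkerLabels,
    EdgeList,
    ExpressionMatrix,
    PPINetwork,
    RawExpressionTable,
)
from .model import normalized_laplacian, propagate
from .network import build_network


@dataclass
class SyntheticSpec:
    """Parameters of the generative process; ``seed`` fixes everything."""

    d: int = 30
    n: int = 2000
    graph_model: str = "erdos-renyi"  # or "planted-modules"
    density: float = 0.055
    n_modules: int = 3
    phi: np.ndarray | None = None  # planted; drawn around phi_loc if None
    phi_loc: float = 1.25
    phi_spread: float = 0.5
    theta: dict[str, np.ndarray] | None = None  # planted; drawn if None
    theta_scale: float = 1.0
    biomarkers: tuple[str, ...] = DEFAULT_BIOMARKERS
    latent: str = "uniform"  # or "logistic-normal"
    logit_noise_sd: float = 0.0
    missing_rate: float = 0.0
    n_covariates: int = 0
    covariate_scale: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d < 2 or self.n < 2:
            raise ValueError("d and n must both be >= 2")
        if not 0.0 < self.density <= 1.0:
            raise ValueError("density must lie in (0, 1]")
        if self.graph_model not in ("erdos-renyi", "planted-modules"):
            raise ValueError("graph_model must be 'erdos-renyi' or 'planted-modules'")
        if self.latent not in ("uniform", "logistic-normal"):
            raise ValueError("latent must be 'uniform' or 'logistic-normal'")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass
class SyntheticDataset:
    """Generated fixture bundle with the planted ground truth attached."""

    X: ExpressionMatrix
    network: PPINetwork
    edges: EdgeList
    labels: BiomarkerLabels
    true_phi: np.ndarray
    true_theta: dict[str, np.ndarray]
    true_logits: dict[str, np.ndarray]
    raw: RawExpressionTable | None = None
    covariates: np.ndarray | None = None
    true_beta: dict[str, np.ndarray] | None = None


def _protein_ids(d: int) -> list[str]:
    return [f"PROT{i:04d}" for i in range(d)]


def make_network(spec: SyntheticSpec) -> tuple[PPINetwork, EdgeList]:
    """Random weighted graph at the requested density, plus its edge list.

    Edges are drawn uniformly at random ("erdos-renyi") or with a 5x
    preference for within-module pairs ("planted-modules", mimicking the
    modular sub-network structure of real PPI maps).  Combined scores are
    uniform in (0.45, 1), i.e. above the STRING medium-confidence cut, so
    the edge list round-trips through network construction.
    """
    rng = np.random.default_rng(spec.seed)
    ids = _protein_ids(spec.d)
    pairs = np.array([(i, j) for i in range(spec.d) for j in range(i + 1, spec.d)])
    m = max(1, int(round(spec.density * len(pairs))))
    if spec.graph_model == "erdos-renyi":
        chosen = rng.choice(len(pairs), size=m, replace=False)
    else:
        module = rng.integers(spec.n_modules, size=spec.d)
        w = np.where(module[pairs[:, 0]] == module[pairs[:, 1]], 5.0, 1.0)
        chosen = rng.choice(len(pairs), size=m, replace=False, p=w / w.sum())
    chosen = np.sort(chosen)
    scores = rng.uniform(0.45, 1.0, size=m)
    edges = EdgeList(
        protein_a=[ids[i] for i, _ in pairs[chosen]],
        protein_b=[ids[j] for _, j in pairs[chosen]],
        score=scores,
    )
    return build_network(edges, ids, score_threshold=0.4), edges


def make_dataset(
    spec: SyntheticSpec, network: PPINetwork | None = None, edges: EdgeList | None = None
) -> SyntheticDataset:
    """Draw a full dataset from the model's own generative process."""
    rng = np.random.default_rng(spec.seed + 1)
    if network is None:
        network, edges = make_network(spec)
    ids = list(network.protein_ids)
    d, n = spec.d, spec.n
    if len(ids) != d:
        raise ValueError("supplied network size does not match spec.d")

    if spec.latent == "uniform":
        Xv = rng.uniform(0.0, 1.0, size=(d, n))
    else:
        Xv = expit(rng.standard_normal((d, n)))
    sample_ids = [f"S{j:05d}" for j in range(n)]
    X = ExpressionMatrix(values=Xv, protein_ids=ids, sample_ids=sample_ids)

    phi = (
        np.asarray(spec.phi, dtype=float)
        if spec.phi is not None
        else np.clip(np.abs(rng.normal(spec.phi_loc, spec.phi_spread, size=d)), 0.1, None)
    )
    theta = (
        {b: np.asarray(v, dtype=float) for b, v in spec.theta.items()}
        if spec.theta is not None
        else {b: rng.normal(0.0, spec.theta_scale, size=d) for b in spec.biomarkers}
    )

    L = normalized_laplacian(network)
    Z = propagate(X, L, phi).values
    # center each task's logits so prevalence stays in a workable range
    covariates = beta = None
    if spec.n_covariates > 0:
        covariates = rng.standard_normal((n, spec.n_covariates))
        beta = {
            b: rng.normal(0.0, spec.covariate_scale, size=spec.n_covariates)
            for b in spec.biomarkers
        }
    logits: dict[str, np.ndarray] = {}
    labels: dict[str, np.ndarray] = {}
    for b in spec.biomarkers:
        lg = theta[b] @ Z
        lg = lg - np.median(lg)
        if covariates is not None:
            lg = lg + covariates @ beta[b]
        if spec.logit_noise_sd > 0:
            lg = lg + rng.normal(0.0, spec.logit_noise_sd, size=n)
        logits[b] = lg
        labels[b] = (rng.uniform(size=n) < expit(lg)).astype(int)

    raw = None
    if spec.missing_rate > 0:
        V = Xv.copy()
        punch = rng.uniform(size=(d, n)) < spec.missing_rate
        # never blank an entire protein row or sample column
        punch[:, punch.all(axis=0)] = False
        punch[punch.all(axis=1), :] = False
        V[punch] = np.nan
        raw = RawExpressionTable(values=V, protein_ids=ids, sample_ids=sample_ids)

    return SyntheticDataset(
        X=X,
        network=network,
        edges=edges,
        labels=BiomarkerLabels(labels=labels, sample_ids=sample_ids),
        true_phi=phi,
        true_theta=theta,
        true_logits=logits,
        raw=raw,
        covariates=covariates,
        true_beta=beta,
    )


def connected_random_network(
    d: int, n_edges: int, seed: int = 0, weight: float = 0.5
) -> PPINetwork:
    """Random graph on d nodes with exactly n_edges edges, every node of
    degree >= 1 (a uniform spanning tree plus uniformly drawn extras).

    Handy for reproducing printed structural statistics of a network of
    known size, e.g. 93 connected proteins with 234 interactions.
    """
    if n_edges < d - 1:
        raise ValueError("need at least d - 1 edges to connect every node")
    rng = np.random.default_rng(seed)
    tree = nx.random_labeled_tree(d, seed=int(rng.integers(2**31 - 1)))
    chosen = {tuple(sorted(e)) for e in tree.edges}
    pairs = [(i, j) for i in range(d) for j in range(i + 1, d)]
    if n_edges > len(pairs):
        raise ValueError("n_edges exceeds the complete graph")
    remaining = [p for p in pairs if p not in chosen]
    extra = rng.choice(len(remaining), size=n_edges - len(chosen), replace=False)
    chosen.update(remaining[i] for i in extra)
    W = np.zeros((d, d))
    for i, j in chosen:
        W[i, j] = W[j, i] = weight
    return PPINetwork(weights=W, protein_ids=_protein_ids(d))
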