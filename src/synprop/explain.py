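"""Explainability analyses for a fitted propagation model.

Because the model is shallow — one closed-form propagation step and one
linear-logistic read-out per biomarker — its parameters are directly
interpretable: phi_i measures how strongly protein i resists
propagation, theta_b weighs each protein's propagated value in the risk
logit.  This module adds leave-one-protein-out importance (delta AUROC),
the top-10% "major protein" rule combining estimation weights with
importance, risk scores restricted to protein subsets, and group-wise
significance of independent vs. synergetic effects.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    BiomarkerLabels,
    ExpressionMatrix,
    PPINetwork,
    RiskScores,
    SynergyMatrix,
)
from .model import ModelParams, estimate_risk, normalized_laplacian, propagate
from .evaluate import auroc
from .targets import dea_test


def loo_importance(
    params: ModelParams,
    X: ExpressionMatrix,
    network: PPINetwork,
    labels: BiomarkerLabels,
    mode: str = "zero-row",
) -> pd.Series:
    """Per-protein importance: baseline minus protein-excluded mean AUROC.

    "zero-row" (default) zeroes the protein's row of the synergetic
    matrix Z at prediction time, excluding it from every risk logit
    without refitting; "remove-node" instead deletes the node from the
    network and re-propagates, capturing its role as a conduit too.
    Positive values mean the protein helps discrimination.
    """
    if mode not in ("zero-row", "remove-node"):
        raise ValueError("mode must be 'zero-row' or 'remove-node'")
    L = normalized_laplacian(network)
    Z = propagate(X, L, params.phi).values
    names = [b for b in params.biomarkers if b in labels.labels]

    def mean_auroc(Zv: np.ndarray) -> float:
        return float(
            np.mean(
                [auroc(estimate_risk(Zv, params.theta[b]), labels.labels[b]) for b in names]
            )
        )

    baseline = mean_auroc(Z)
    deltas = np.zeros(X.n_proteins)
    for i in range(X.n_proteins):
        if mode == "zero-row":
            Zi = Z.copy()
            Zi[i, :] = 0.0
        else:
            W = network.weights.copy()
            W[i, :] = 0.0
            W[:, i] = 0.0
            Li = normalized_laplacian(PPINetwork(W, network.protein_ids))
            Zi = propagate(X, Li, params.phi).values
            Zi[i, :] = 0.0
        deltas[i] = baseline - mean_auroc(Zi)
    return pd.Series(deltas, index=pd.Index(X.protein_ids, name="protein_id"), name="delta_auroc")


def major_proteins(
    theta_b: np.ndarray | pd.Series,
    importance: np.ndarray | pd.Series,
    protein_ids: list[str] | None = None,
    top_frac: float = 0.10,
) -> list[str]:
    """Proteins in the top ``top_frac`` of BOTH the estimation weights
    (signed, i.e. risk-increasing) and the importance scores.

    The cut keeps ceil(top_frac * d) proteins per ranking; ties are
    broken by protein-id order.  Output preserves protein-id order.
    """
    if isinstance(theta_b, pd.Series):
        protein_ids = protein_ids or list(theta_b.index)
        theta_b = theta_b.to_numpy()
    if isinstance(importance, pd.Series):
        protein_ids = protein_ids or list(importance.index)
        importance = importance.to_numpy()
    if protein_ids is None:
        raise ValueError("protein_ids required with plain arrays")
    theta_b = np.asarray(theta_b, dtype=float)
    importance = np.asarray(importance, dtype=float)
    d = len(protein_ids)
    if theta_b.shape != (d,) or importance.shape != (d,):
        raise ValueError("rankings must cover the same protein universe")
    n_top = int(np.ceil(top_frac * d))

    def top(values: np.ndarray) -> set[int]:
        order = sorted(range(d), key=lambda i: (-values[i], protein_ids[i]))
        return set(order[:n_top])

    shared = top(theta_b) & top(importance)
    return [p for i, p in enumerate(protein_ids) if i in shared]


def subset_risk(
    params: ModelParams,
    Z: SynergyMatrix | np.ndarray,
    protein_subset: list[str],
    protein_ids: list[str] | None = None,
) -> RiskScores:
    """Risks computed with theta entries outside ``protein_subset`` zeroed.

    The full subset reproduces ordinary prediction exactly; the empty
    subset yields 0.5 everywhere.  Because the logit is linear in theta,
    logits over disjoint subsets add up to the full-model logit.
    """
    if isinstance(Z, SynergyMatrix):
        protein_ids = protein_ids or list(Z.protein_ids)
        sample_ids = list(Z.sample_ids)
        Zv = Z.values
    else:
        sample_ids = []
        Zv = np.asarray(Z, dtype=float)
    if protein_ids is None:
        raise ValueError("protein_ids required with plain arrays")
    unknown = sorted(set(protein_subset) - set(protein_ids))
    if unknown:
        raise ValueError(f"unknown proteins in subset: {unknown}")
    keep = np.array([p in set(protein_subset) for p in protein_ids])
    scores = {}
    for b in params.biomarkers:
        theta = np.where(keep, params.theta[b], 0.0)
        scores[b] = estimate_risk(Zv, theta)
    return RiskScores(scores=scores, sample_ids=sample_ids)


def effect_significance(
    values: np.ndarray, y: np.ndarray, protein_ids: list[str] | None = None
) -> pd.Series:
    """Per-protein -log10 p of case/control discrimination for one matrix."""
    res = dea_test(values, y, protein_ids)
    return res.table["neg_log10_p"]


def compare_effects(
    X: ExpressionMatrix,
    Z: SynergyMatrix,
    labels: BiomarkerLabels,
) -> pd.DataFrame:
    """Paired -log10 p tables of independent (X) vs synergetic (Z) effects.

    One row per protein, columns ``<biomarker>_independent`` and
    ``<biomarker>_synergetic``; larger values on the synergetic side mean
    propagation sharpened the group separation.
    """
    cols = {}
    for b in labels.biomarkers:
        y = labels.labels[b]
        cols[f"{b}_independent"] = effect_significance(X.values, y, X.protein_ids).to_numpy()
        cols[f"{b}_synergetic"] = effect_significance(Z.values, y, X.protein_ids).to_numpy()
    return pd.DataFrame(cols, index=pd.Index(X.protein_ids, name="protein_id"))


def protein_report(
    params: ModelParams,
    importance: pd.Series,
    top_frac: float = 0.10,
) -> pd.DataFrame:
    """One-row-per-protein summary: phi, per-biomarker theta, importance,
    and major-protein flags per biomarker under the top-10% rule."""
    if params.protein_ids is None:
        raise ValueError("params must carry protein identifiers")
    ids = params.protein_ids
    table = pd.DataFrame({"phi": params.phi}, index=pd.Index(ids, name="protein_id"))
    for b in params.biomarkers:
        table[f"theta_{b}"] = params.theta[b]
    table["importance"] = importance.reindex(ids).to_numpy()
    for b in params.biomarkers:
        majors = set(
            major_proteins(params.theta[b], table["importance"].to_numpy(), ids, top_frac)
        )
        table[f"major_{b}"] = [p in majors for p in ids]
    return table
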