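"""Expression preprocessing: missingness filter, kNN imputation, scaling.

The pipeline mirrors standard proteomic-panel practice: drop proteins
with more than 5% missing measurements, impute the remainder from the
k nearest samples, then map each protein row through z-score
standardization followed by the logistic function so every entry lands
in (0, 1).
"""
from __future__ import annotations

import numpy as np
from scipy.special import expit

from .datatypes import ExpressionMatrix, RawExpressionTable


def filter_missing(
    raw: RawExpressionTable, max_missing_frac: float = 0.05
) -> RawExpressionTable:
    """Keep proteins whose missing fraction is <= ``max_missing_frac``.

    The boundary is inclusive: a protein missing in exactly 5% of samples
    is retained, since only strictly greater missingness is excluded.
    Row order is preserved.
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must lie in [0, 1]")
    keep = raw.missing_fraction <= max_missing_frac
    if not keep.any():
        raise ValueError(
            f"no protein passes the {max_missing_frac:.0%} missingness filter"
        )
    return RawExpressionTable(
        values=raw.values[keep],
        protein_ids=[p for p, k in zip(raw.protein_ids, keep) if k],
        sample_ids=list(raw.sample_ids),
    )


def knn_impute(raw: RawExpressionTable, k: int = 10) -> RawExpressionTable:
    """Impute each missing entry from the k nearest samples.

    For a missing entry (protein i, sample j), candidate neighbors are
    the other samples in which protein i was observed; they are ranked by
    Euclidean distance computed over the proteins jointly observed with
    sample j, ties broken by lower sample index, and the imputed value is
    the mean of protein i across the k nearest of them.  Observed entries
    are never modified.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    V = raw.values.copy()
    mask = raw.missing_mask
    d, n = V.shape
    observed_per_protein = (~mask).sum(axis=1)
    short = observed_per_protein < k
    if short.any():
        worst = raw.protein_ids[int(np.argmax(short))]
        raise ValueError(
            f"protein {worst!r} has fewer than k={k} observed samples; "
            "filter or lower k first"
        )
    obs = ~mask
    for j in range(n):
        miss_rows = np.where(mask[:, j])[0]
        if miss_rows.size == 0:
            continue
        shared = obs[:, j][:, None] & obs  # proteins observed in both j and j'
        shared[:, j] = False
        n_shared = shared.sum(axis=0)
        if (n_shared[np.arange(n) != j] == 0).all():
            raise ValueError(
                f"sample {raw.sample_ids[j]!r} shares no observed protein "
                "with any other sample; cannot impute"
            )
        diff = np.where(shared, V[:, [j]] - np.where(obs, V, 0.0), 0.0)
        dist = np.sqrt(np.einsum("ij,ij->j", diff, diff))
        dist[j] = np.inf
        dist[n_shared == 0] = np.inf
        order = np.argsort(dist, kind="stable")  # stable: lower index wins ties
        for i in miss_rows:
            donors = order[obs[i, order]][:k]
            V[i, j] = V[i, donors].mean()
    return RawExpressionTable(
        values=V, protein_ids=list(raw.protein_ids), sample_ids=list(raw.sample_ids)
    )


def zscore_logistic_scale(raw: RawExpressionTable) -> ExpressionMatrix:
    """Per-protein z-score (sample sd, ddof=1) followed by the logistic map.

    A value at the row mean maps to 0.5, at mean + 1 sd to ~0.7311.
    Constant rows (sd = 0) map to 0.5 everywhere by convention.  Output
    entries are strictly inside (0, 1).
    """
    if raw.missing_mask.any():
        raise ValueError("input still contains missing values; impute first")
    V = raw.values
    mean = V.mean(axis=1, keepdims=True)
    sd = V.std(axis=1, ddof=1, keepdims=True) if V.shape[1] > 1 else np.zeros_like(mean)
    z = np.where(sd > 0, (V - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return ExpressionMatrix(
        values=expit(z),
        protein_ids=list(raw.protein_ids),
        sample_ids=list(raw.sample_ids),
    )


def preprocess(
    raw: RawExpressionTable, max_missing_frac: float = 0.05, k: int = 10
) -> ExpressionMatrix:
    """Full pipeline: filter -> impute (only if needed) -> scale."""
    table = filter_missing(raw, max_missing_frac)
    if table.missing_mask.any():
        table = knn_impute(table, k)
    return zscore_logistic_scale(table)
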