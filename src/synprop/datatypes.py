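"""Shared data containers for the propagation pipeline.

The central objects are a proteins x participants expression matrix (the
"independent effects" X), its propagated counterpart (the "synergetic
effects" Z), and a symmetric weighted protein-protein interaction network
aligned to the same protein identifiers.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default biomarker task names, in a fixed order: amyloid-beta ratio
#: (reciprocal convention, higher = riskier), glial fibrillary acidic
#: protein, neurofilament light chain, and phosphorylated tau 181.
DEFAULT_BIOMARKERS: tuple[str, ...] = ("Abeta", "GFAP", "NfL", "pTau")


def _require_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Complete proteins x samples matrix of (preprocessed) expression values."""

    values: np.ndarray
    protein_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.protein_ids = list(self.protein_ids)
        self.sample_ids = list(self.sample_ids)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-d array")
        d, n = self.values.shape
        if d < 1 or n < 1:
            raise ValueError("expression matrix must be non-empty")
        if len(self.protein_ids) != d or len(self.sample_ids) != n:
            raise ValueError(
                f"identifier lengths ({len(self.protein_ids)}, {len(self.sample_ids)}) "
                f"do not match matrix shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite entries")
        _require_unique(self.protein_ids, "protein")
        _require_unique(self.sample_ids, "sample")

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class SynergyMatrix:
    """Propagated (PPI-aware) counterpart of an :class:`ExpressionMatrix`."""

    values: np.ndarray
    protein_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("synergy values must be a 2-d array")
        if len(self.protein_ids) != self.values.shape[0]:
            raise ValueError("protein identifiers do not match matrix shape")
        if len(self.sample_ids) != self.values.shape[1]:
            raise ValueError("sample identifiers do not match matrix shape")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("synergy matrix contains non-finite entries")


@dataclass
class PPINetwork:
    """Symmetric nonnegative weighted interaction network with zero diagonal."""

    weights: np.ndarray
    protein_ids: list[str]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.protein_ids = list(self.protein_ids)
        W = self.weights
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("network weights must be a square matrix")
        if len(self.protein_ids) != W.shape[0]:
            raise ValueError("protein identifiers do not match weight matrix")
        _require_unique(self.protein_ids, "protein")
        asym = np.abs(W - W.T)
        if asym.max(initial=0.0) > 1e-10:
            i, j = np.unravel_index(np.argmax(asym), W.shape)
            raise ValueError(
                f"weight matrix is not symmetric at ({self.protein_ids[i]}, "
                f"{self.protein_ids[j]}): {W[i, j]} vs {W[j, i]}"
            )
        if np.abs(np.diag(W)).max(initial=0.0) > 0:
            i = int(np.argmax(np.abs(np.diag(W))))
            raise ValueError(f"nonzero diagonal (self-loop) at {self.protein_ids[i]}")
        if W.min(initial=0.0) < 0:
            i, j = np.unravel_index(np.argmin(W), W.shape)
            raise ValueError(
                f"negative weight at ({self.protein_ids[i]}, {self.protein_ids[j]}): {W[i, j]}"
            )
        if W.max(initial=0.0) > 1 + 1e-10:
            i, j = np.unravel_index(np.argmax(W), W.shape)
            raise ValueError(
                f"weight above 1 at ({self.protein_ids[i]}, {self.protein_ids[j]}): {W[i, j]}"
            )

    @property
    def n_proteins(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, k=1)))


@dataclass
class RawExpressionTable:
    """Raw expression table that may contain missing entries (NaN)."""

    values: np.ndarray
    protein_ids: list[str]
    sample_ids: list[str]
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.protein_ids = list(self.protein_ids)
        self.sample_ids = list(self.sample_ids)
        if self.values.ndim != 2:
            raise ValueError("raw values must be a 2-d array")
        if len(self.protein_ids) != self.values.shape[0]:
            raise ValueError("protein identifiers do not match matrix shape")
        if len(self.sample_ids) != self.values.shape[1]:
            raise ValueError("sample identifiers do not match matrix shape")
        _require_unique(self.protein_ids, "protein")
        _require_unique(self.sample_ids, "sample")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise ValueError("missing mask shape does not match values")
            if not np.array_equal(self.missing_mask, np.isnan(self.values)):
                raise ValueError("missing mask inconsistent with NaN pattern")

    @property
    def missing_fraction(self) -> np.ndarray:
        """Per-protein fraction of missing samples."""
        return self.missing_mask.mean(axis=1)


@dataclass
class BiomarkerLabels:
    """Binary positivity labels per biomarker, aligned to sample identifiers."""

    labels: dict[str, np.ndarray]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        _require_unique(self.sample_ids, "sample")
        n = len(self.sample_ids)
        clean: dict[str, np.ndarray] = {}
        for name, vec in self.labels.items():
            arr = np.asarray(vec)
            if arr.shape != (n,):
                raise ValueError(f"label vector for {name!r} has wrong length")
            if not np.isin(arr, (0, 1)).all():
                raise ValueError(f"label vector for {name!r} is not binary 0/1")
            clean[name] = arr.astype(int)
        self.labels = clean

    @property
    def biomarkers(self) -> list[str]:
        return list(self.labels)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class EdgeList:
    """STRING-style undirected edge records with combined confidence scores."""

    protein_a: list[str]
    protein_b: list[str]
    score: np.ndarray

    def __post_init__(self) -> None:
        self.protein_a = list(self.protein_a)
        self.protein_b = list(self.protein_b)
        self.score = np.asarray(self.score, dtype=float)
        if not (len(self.protein_a) == len(self.protein_b) == len(self.score)):
            raise ValueError("edge list columns have unequal lengths")
        for a, b in zip(self.protein_a, self.protein_b):
            if a == b:
                raise ValueError(f"self-loop on {a!r} in edge list")
        if len(self.score) and (self.score.min() < 0 or self.score.max() > 1):
            raise ValueError("combined scores must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.score)


@dataclass
class RiskScores:
    """Per-biomarker predicted risks, each entry strictly inside (0, 1)."""

    scores: dict[str, np.ndarray]
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, vec in self.scores.items():
            arr = np.asarray(vec, dtype=float)
            if arr.min(initial=0.5) <= 0 or arr.max(initial=0.5) >= 1:
                raise ValueError(f"risk scores for {name!r} must lie strictly in (0, 1)")
            self.scores[name] = arr
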