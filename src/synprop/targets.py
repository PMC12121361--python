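"""Differential-expression screening and target-protein selection.

Each protein is compared between biomarker-positive and -negative groups
with a Welch two-sample t-test (unequal variances); proteins significant
at the chosen threshold for every biomarker form the shared target set
that the propagation model is trained on.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DEAResult:
    """Per-protein two-group test outputs for one biomarker."""

    table: pd.DataFrame  # index protein_id; columns statistic, p_value, direction, neg_log10_p

    @property
    def significant(self) -> pd.Series:
        return self.table["p_value"]

    def deps(self, alpha: float = 0.05) -> list[str]:
        """Proteins differentially expressed at p < alpha (strict)."""
        return list(self.table.index[self.table["p_value"] < alpha])


def dea_test(
    values: np.ndarray, y: np.ndarray, protein_ids: list[str] | None = None
) -> DEAResult:
    """Welch t-test per protein row between case (y=1) and control (y=0).

    Uses the Welch-Satterthwaite degrees of freedom and two-sided
    p-values.  Degenerate rows where both groups have zero variance and
    identical means are reported as t = 0, p = 1; zero-variance rows with
    different means get p = 0 and are flagged.
    """
    values = np.asarray(values, dtype=float)
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("both groups need at least 2 samples")
    case, ctrl = values[:, y == 1], values[:, y == 0]
    stat, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    mean_diff = case.mean(axis=1) - ctrl.mean(axis=1)
    degenerate = (case.std(axis=1) == 0) & (ctrl.std(axis=1) == 0)
    stat = np.where(degenerate & (mean_diff == 0), 0.0, stat)
    p = np.where(degenerate & (mean_diff == 0), 1.0, p)
    p = np.where(degenerate & (mean_diff != 0), 0.0, p)
    if protein_ids is None:
        protein_ids = [f"P{i}" for i in range(values.shape[0])]
    with np.errstate(divide="ignore"):
        neg_log10 = -np.log10(np.clip(p, 1e-300, None))
    table = pd.DataFrame(
        {
            "statistic": stat,
            "p_value": p,
            "direction": np.where(mean_diff > 0, "up", "down"),
            "neg_log10_p": neg_log10,
        },
        index=pd.Index(protein_ids, name="protein_id"),
    )
    return DEAResult(table=table)


@dataclass
class TargetSelection:
    """Outcome of intersecting per-biomarker DEP lists."""

    targets: list[str]
    dep_counts: dict[str, int]
    union_size: int
    report: pd.DataFrame


def select_targets(
    dea_by_biomarker: dict[str, DEAResult], alpha: float = 0.05
) -> TargetSelection:
    """Intersect per-biomarker DEP sets at p < alpha, preserving input order.

    Proteins must be significant in EVERY biomarker's test to qualify.
    An empty intersection is legal (a warning-level situation, not an
    error); per-biomarker DEP counts and the union size are reported
    alongside.
    """
    if not dea_by_biomarker:
        raise ValueError("no DEA results supplied")
    names = list(dea_by_biomarker)
    base = list(dea_by_biomarker[names[0]].table.index)
    for b in names[1:]:
        if list(dea_by_biomarker[b].table.index) != base:
            raise ValueError(f"DEA result for {b!r} covers a different protein set")
    dep_sets = {b: set(dea_by_biomarker[b].deps(alpha)) for b in names}
    shared = set.intersection(*dep_sets.values())
    union = set.union(*dep_sets.values())
    targets = [p for p in base if p in shared]
    cols: dict[str, np.ndarray] = {}
    for b in names:
        t = dea_by_biomarker[b].table
        cols[f"{b}_statistic"] = t["statistic"].to_numpy()
        cols[f"{b}_p_value"] = t["p_value"].to_numpy()
        cols[f"{b}_direction"] = t["direction"].to_numpy()
    report = pd.DataFrame(cols, index=pd.Index(base, name="protein_id"))
    report["target"] = [p in shared for p in base]
    return TargetSelection(
        targets=targets,
        dep_counts={b: len(dep_sets[b]) for b in names},
        union_size=len(union),
        report=report,
    )
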