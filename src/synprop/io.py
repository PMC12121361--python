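"""Readers, writers and run manifests.

All on-disk formats are plain delimited text (TSV/CSV) or JSON:
expression matrices are proteins x samples with a header row of sample
identifiers, edge lists are STRING-style three-column tables (scores in
[0, 1] or the 0-1000 serialization, auto-detected), labels are
samples x biomarkers, and fitted parameters serialize to a
protein-id-keyed JSON bundle.  Readers validate and reject rather than
silently coerce.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import BiomarkerLabels, EdgeList, ExpressionMatrix, RawExpressionTable
from .model import ModelParams

log = logging.getLogger("synprop")

_NA_STRINGS = {"", "NA", "NaN", "nan", "NAN", "null", "None"}


def _sniff_delimiter(path: str | Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_expression(path: str | Path, transpose: bool = False) -> RawExpressionTable:
    """Read a proteins x samples delimited table with optional missing cells.

    First column holds protein identifiers, the header row sample
    identifiers; blank/NA cells mark missing values.  ``transpose`` flips
    a samples x proteins file into the canonical orientation.  Duplicate
    identifiers and non-numeric cells raise with coordinates.
    """
    sep = _sniff_delimiter(path)
    df = pd.read_csv(
        path, sep=sep, index_col=0, dtype=str, keep_default_na=False, na_values=[]
    )
    if transpose:
        df = df.T
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate protein identifier: {dup!r}")
    if pd.Index(df.columns).duplicated().any():
        dup = pd.Index(df.columns)[pd.Index(df.columns).duplicated()][0]
        raise ValueError(f"duplicate sample identifier: {dup!r}")
    values = np.empty(df.shape, dtype=float)
    for cj, col in enumerate(df.columns):
        for ri, cell in enumerate(df[col]):
            cell = cell.strip()
            if cell in _NA_STRINGS:
                values[ri, cj] = np.nan
                continue
            try:
                values[ri, cj] = float(cell)
            except ValueError as exc:
                raise ValueError(
                    f"non-numeric cell {cell!r} at protein {df.index[ri]!r}, "
                    f"sample {col!r}"
                ) from exc
    return RawExpressionTable(
        values=values,
        protein_ids=[str(p) for p in df.index],
        sample_ids=[str(s) for s in df.columns],
    )


def write_expression(
    matrix: ExpressionMatrix | RawExpressionTable, path: str | Path, sep: str = "\t"
) -> None:
    df = pd.DataFrame(
        matrix.values, index=matrix.protein_ids, columns=matrix.sample_ids
    )
    df.index.name = "protein_id"
    df.to_csv(path, sep=sep, na_rep="NA")


def read_edges(path: str | Path) -> EdgeList:
    """Read a STRING-style (protein_a, protein_b, combined_score) table.

    A header row is detected by a non-numeric third field.  Scores given
    as integers in 0-1000 are divided by 1000; scores already in [0, 1]
    pass through.  Self-loops are dropped with a logged count; scores
    outside both dialects raise.
    """
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, skipinitialspace=True)
    if df.shape[1] < 3:
        raise ValueError(f"edge list needs 3 columns, found {df.shape[1]}")
    try:
        float(df.iloc[0, 2])
    except ValueError:
        df = df.iloc[1:].reset_index(drop=True)
    if df.empty:
        return EdgeList(protein_a=[], protein_b=[], score=np.array([]))
    try:
        scores = df.iloc[:, 2].astype(float).to_numpy()
    except ValueError as exc:
        raise ValueError(f"non-numeric combined score in {path}") from exc
    if scores.max(initial=0.0) > 1.0:
        if scores.max() > 1000 or scores.min() < 0:
            raise ValueError("combined scores fit neither the [0,1] nor 0-1000 dialect")
        scores = scores / 1000.0
    elif scores.min(initial=0.0) < 0:
        raise ValueError("negative combined score")
    a = df.iloc[:, 0].astype(str).str.strip().tolist()
    b = df.iloc[:, 1].astype(str).str.strip().tolist()
    keep = [i for i in range(len(a)) if a[i] != b[i]]
    n_loops = len(a) - len(keep)
    if n_loops:
        log.info("dropped %d self-loop edge(s)", n_loops)
    return EdgeList(
        protein_a=[a[i] for i in keep],
        protein_b=[b[i] for i in keep],
        score=scores[keep],
    )


def write_edges(edges: EdgeList, path: str | Path, header: bool = True) -> None:
    df = pd.DataFrame(
        {"protein_a": edges.protein_a, "protein_b": edges.protein_b, "combined_score": edges.score}
    )
    df.to_csv(path, sep="\t", index=False, header=header)


def read_labels(path: str | Path) -> BiomarkerLabels:
    """Read samples x biomarkers binary labels (first column sample ids)."""
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate sample identifier: {dup!r}")
    return BiomarkerLabels(
        labels={str(c): df[c].to_numpy() for c in df.columns},
        sample_ids=[str(s) for s in df.index],
    )


def write_labels(labels: BiomarkerLabels, path: str | Path, sep: str = ",") -> None:
    df = pd.DataFrame(labels.labels, index=labels.sample_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep)


def write_params(params: ModelParams, path: str | Path) -> None:
    """Serialize fitted parameters as a protein-id-keyed JSON bundle."""
    ids = params.protein_ids or [f"P{i}" for i in range(params.phi.size)]
    bundle: dict = {
        "delta": params.delta,
        "eta": params.eta,
        "phi": {p: float(v) for p, v in zip(ids, params.phi)},
        "theta": {
            b: {p: float(v) for p, v in zip(ids, vec)} for b, vec in params.theta.items()
        },
    }
    if params.beta is not None:
        bundle["beta"] = {b: [float(v) for v in vec] for b, vec in params.beta.items()}
        bundle["cov_mean"] = [float(v) for v in params.cov_mean]
        bundle["cov_std"] = [float(v) for v in params.cov_std]
    Path(path).write_text(json.dumps(bundle, indent=1, sort_keys=True))


def read_params(path: str | Path) -> ModelParams:
    bundle = json.loads(Path(path).read_text())
    ids = list(bundle["phi"])
    phi = np.array([bundle["phi"][p] for p in ids])
    theta = {b: np.array([vec[p] for p in ids]) for b, vec in bundle["theta"].items()}
    beta = cov_mean = cov_std = None
    if "beta" in bundle:
        beta = {b: np.array(v) for b, v in bundle["beta"].items()}
        cov_mean = np.array(bundle["cov_mean"])
        cov_std = np.array(bundle["cov_std"])
    return ModelParams(
        phi=phi,
        theta=theta,
        delta=bundle.get("delta", 1e-3),
        eta=bundle.get("eta", 1e-3),
        protein_ids=ids,
        beta=beta,
        cov_mean=cov_mean,
        cov_std=cov_std,
    )


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_manifest(
    path: str | Path,
    command: str,
    config: dict,
    inputs: list[str | Path],
    outputs: list[str | Path],
) -> None:
    """Machine-readable record of a run: config, seeds and input checksums."""
    manifest = {
        "command": command,
        "config": config,
        "inputs": {str(p): file_checksum(p) for p in inputs if Path(p).exists()},
        "outputs": [str(p) for p in outputs],
    }
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True))
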