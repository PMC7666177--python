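"""Readers and writers for the tabular formats the pipeline speaks.

TSV is the canonical dialect (header row, first column = identifier);
MatrixMarket triplet files with companion row/column name files are
supported for sparse count matrices, GMT for gene-set collections, YAML
for parameters, and a JSON manifest with content hashes for provenance.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp
import yaml

from .ddrtree import DDRTreeParams, LatentTreeModel
from .preprocess import ExpressionMatrix

__all__ = [
    "read_expression",
    "write_expression",
    "read_gene_sets",
    "write_gene_sets",
    "read_metadata",
    "write_metadata",
    "save_model",
    "load_model",
    "write_manifest",
]


def read_expression(
    path: str | Path,
    format: str = "tsv",
    rows_path: str | Path | None = None,
    cols_path: str | Path | None = None,
    scale: str = "counts",
) -> ExpressionMatrix:
    """Read a genes x samples matrix.

    ``tsv``/``csv``: first column gene ids, header sample ids.
    ``mtx_triplet``: a MatrixMarket file plus row/column name files (one
    id per line; default ``<stem>.rows.txt`` / ``<stem>.cols.txt``).
    Duplicate ids and non-numeric cells are rejected with the offending
    line named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        dup = df.index[df.index.duplicated()].unique()
        if len(dup):
            raise ValueError(f"duplicate gene id(s) in {path.name}: {list(map(str, dup))}")
        bad = df.columns[~df.dtypes.map(lambda d: np.issubdtype(d, np.number))]
        if len(bad):
            for col in bad:
                coerced = pd.to_numeric(df[col], errors="coerce")
                row = int(np.flatnonzero(coerced.isna() & df[col].notna())[0])
                raise ValueError(
                    f"non-numeric cell in {path.name}, column {col!r}, line {row + 2}"
                )
        if df.isna().any().any():
            gene = df.index[df.isna().any(axis=1)][0]
            raise ValueError(f"missing value in {path.name} at gene {gene!r}")
        return ExpressionMatrix.from_frame(df, scale=scale)
    if format == "mtx_triplet":
        rows_path = Path(rows_path) if rows_path else path.with_suffix("").with_suffix(".rows.txt")
        cols_path = Path(cols_path) if cols_path else path.with_suffix("").with_suffix(".cols.txt")
        mat = sio.mmread(path)
        if sp.issparse(mat):
            mat = mat.toarray()
        genes = rows_path.read_text().split()
        samples = cols_path.read_text().split()
        if len(set(genes)) != len(genes):
            dup = sorted({g for g in genes if genes.count(g) > 1})
            raise ValueError(f"duplicate gene id(s) in {rows_path.name}: {dup}")
        return ExpressionMatrix(np.asarray(mat, dtype=float), genes, samples, scale=scale)
    raise ValueError(f"unknown format: {format!r}")


def write_expression(expr: ExpressionMatrix, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        df = expr.to_frame()
        df.index.name = "gene_id"
        df.to_csv(path, sep=sep)
    elif format == "mtx_triplet":
        sio.mmwrite(str(path), sp.coo_matrix(expr.values))
        path.with_suffix("").with_suffix(".rows.txt").write_text("\n".join(expr.gene_ids) + "\n")
        path.with_suffix("").with_suffix(".cols.txt").write_text("\n".join(expr.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown format: {format!r}")


def read_gene_sets(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT collection: name, description, then member genes,
    tab-separated.  Duplicates within a set are removed with a warning."""
    path = Path(path)
    out: dict[str, list[str]] = {}
    lines = path.read_text().splitlines()
    if not lines:
        warnings.warn(f"{path.name} is empty")
    for ln, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path.name} line {ln}: expected name, description, >=1 gene")
        name, _desc, *genes = fields
        genes = [g for g in genes if g]
        deduped = list(dict.fromkeys(genes))
        if len(deduped) < len(genes):
            warnings.warn(
                f"{path.name} line {ln}: {len(genes) - len(deduped)} duplicate gene(s) in {name!r}"
            )
        out[name] = deduped
    return out


def write_gene_sets(sets: dict[str, list[str]], path: str | Path, description: str = "") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description or name] + list(genes)) + "\n")


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    return df


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = meta.copy()
    out.index.name = out.index.name or "sample_id"
    out.to_csv(path, sep="\t")


def _write_matrix_tsv(arr: np.ndarray, path: Path, prefix: str) -> None:
    df = pd.DataFrame(arr)
    df.index = [f"{prefix}{i}" for i in range(arr.shape[0])]
    df.to_csv(path, sep="\t")


def save_model(model: LatentTreeModel, directory: str | Path) -> None:
    """Serialize a fitted model: W/Z/Y/R as TSV matrices, B as an
    edge-list TSV, params and the objective trace as YAML."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    _write_matrix_tsv(model.W, d / "W.tsv", "g")
    _write_matrix_tsv(model.Z, d / "Z.tsv", "dim")
    _write_matrix_tsv(model.Y, d / "Y.tsv", "dim")
    _write_matrix_tsv(model.R, d / "R.tsv", "s")
    iu, ju = np.nonzero(np.triu(model.B))
    pd.DataFrame({"from": iu, "to": ju}).to_csv(d / "B_edges.tsv", sep="\t", index=False)
    if model.gene_means is not None:
        pd.DataFrame({"mean": model.gene_means}).to_csv(d / "gene_means.tsv", sep="\t", index=False)
    p = model.params
    meta = {
        "params": {
            "d": p.d, "K": p.K, "lambda_": float(p.lambda_), "gamma_": p.gamma_,
            "sigma_": p.sigma_, "max_iter": p.max_iter, "tol": p.tol, "seed": p.seed,
        },
        "objective_trace": [float(v) for v in model.objective_trace],
    }
    (d / "model.yaml").write_text(yaml.safe_dump(meta))


def load_model(directory: str | Path) -> LatentTreeModel:
    d = Path(directory)
    meta = yaml.safe_load((d / "model.yaml").read_text())
    params = DDRTreeParams(**meta["params"])

    def mat(name):
        return pd.read_csv(d / name, sep="\t", index_col=0).to_numpy(dtype=float)

    W, Z, Y, R = mat("W.tsv"), mat("Z.tsv"), mat("Y.tsv"), mat("R.tsv")
    K = Y.shape[1]
    B = np.zeros((K, K), dtype=int)
    edges = pd.read_csv(d / "B_edges.tsv", sep="\t")
    B[edges["from"], edges["to"]] = 1
    B |= B.T
    gm_path = d / "gene_means.tsv"
    gene_means = (
        pd.read_csv(gm_path, sep="\t")["mean"].to_numpy() if gm_path.exists() else None
    )
    return LatentTreeModel(
        W=W, Z=Z, Y=Y, B=B, R=R, params=params,
        gene_means=gene_means, objective_trace=list(meta["objective_trace"]),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(
    directory: str | Path,
    stage: str,
    inputs: dict,
    params: dict,
    seed: int,
    artifacts: list[str | Path],
) -> Path:
    """Record what a stage consumed and produced, with content hashes, so
    identical config + seed yields identical manifests."""
    d = Path(directory)
    entry = {
        "stage": stage,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "params": params,
        "seed": seed,
        "artifacts": {
            str(Path(a).relative_to(d)): _sha256(Path(a)) for a in artifacts
        },
    }
    path = d / f"manifest_{stage}.json"
    path.write_text(json.dumps(entry, indent=2, sort_keys=True) + "\n")
    return path
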