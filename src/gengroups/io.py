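"""Sparse-matrix and table exporters/readers.

Sparse symmetric matrices travel as 1-based lower-triangle coordinate
triplets (row ≥ col), row-major sorted — the plain-text dialect mixed-model
programs accept for inverse relationship matrices. For A* the r group
rows/columns come first (codes 1..r), which the file header documents.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp


def write_sparse_triplets(
    M: sp.spmatrix,
    path: str | Path,
    header_lines: list[str] | None = None,
) -> None:
    """Write the lower triangle of a symmetric sparse matrix as
    ``row col value`` triplets, 1-based, row-major sorted; ``#`` comment
    header lines first."""
    coo = sp.coo_matrix(sp.tril(M))
    order = np.lexsort((coo.col, coo.row))
    rows = coo.row[order] + 1
    cols = coo.col[order] + 1
    vals = coo.data[order]
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        for r, c, v in zip(rows, cols, vals):
            fh.write(f"{r} {c} {v:.12g}\n")


def read_sparse_triplets(path: str | Path, n: int | None = None) -> sp.csr_matrix:
    """Read 1-based lower-triangle triplets back into a symmetric CSR matrix."""
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            r, c, v = line.split()
            rows.append(int(r) - 1)
            cols.append(int(c) - 1)
            vals.append(float(v))
    dim = n if n is not None else (max(max(rows), max(cols)) + 1 if rows else 0)
    M = sp.coo_matrix((vals, (rows, cols)), shape=(dim, dim)).tocsr()
    lower = sp.tril(M, k=-1)
    return (M + lower.T).tocsr()


def write_dense_csv(
    A: np.ndarray, ids: list[str], path: str | Path,
    header_lines: list[str] | None = None,
) -> None:
    """Dense symmetric matrix as labelled CSV (small n only)."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        pd.DataFrame(A, index=ids, columns=ids).to_csv(fh)


def write_q_matrix(
    Q: np.ndarray, ids: list[str], labels: list[str], path: str | Path,
    header_lines: list[str] | None = None,
) -> None:
    """Q as CSV: individual id plus one genome-fraction column per group."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df = pd.DataFrame(Q, columns=labels)
        df.insert(0, "id", ids)
        df.to_csv(fh, index=False)


def read_q_matrix(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Inverse of :func:`write_q_matrix`: (Q, ids, labels)."""
    df = pd.read_csv(path, comment="#")
    ids = df["id"].astype(str).tolist()
    labels = [c for c in df.columns if c != "id"]
    return df[labels].to_numpy(dtype=float), ids, labels
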