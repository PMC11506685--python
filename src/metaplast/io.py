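"""Plain-text I/O: dense expression TSV/CSV, metadata TSV, MatrixMarket counts.

All outputs are diff-able text; runs can emit a manifest JSON of output
content hashes for reproducibility checks.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from scipy import io as sio
from scipy import sparse

from .scoring import ExpressionMatrix, SampleMetadata

__all__ = [
    "read_expression",
    "write_expression",
    "read_metadata",
    "write_metadata",
    "read_mtx",
    "write_mtx",
    "write_manifest",
]


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression(path, scale_tag: str = "linear") -> ExpressionMatrix:
    """Dense gene-by-sample matrix from TSV/CSV (genes in rows, header = samples)."""
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(values=df, scale_tag=scale_tag)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep=_sep(path), index_label="gene_id")


def read_metadata(path) -> SampleMetadata:
    """Sample metadata TSV with a mandatory sample_id column."""
    df = pd.read_csv(path, sep=_sep(path))
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: metadata requires a 'sample_id' column")
    return SampleMetadata(table=df.set_index("sample_id"))


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index_label="sample_id")


def read_mtx(directory) -> tuple[sparse.csr_matrix, list[str], list[str]]:
    """Sparse counts from <dir>/matrix.mtx with features.tsv/barcodes.tsv sidecars."""
    d = Path(directory)
    mat = sparse.csr_matrix(sio.mmread(d / "matrix.mtx"))
    genes = (d / "features.tsv").read_text().split()
    cells = (d / "barcodes.tsv").read_text().split()
    if mat.shape != (len(genes), len(cells)):
        raise ValueError(
            f"{d}: matrix shape {mat.shape} does not match sidecars "
            f"({len(genes)} features, {len(cells)} barcodes)"
        )
    return mat, genes, cells


def write_mtx(counts, gene_ids, cell_ids, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(str(d / "matrix.mtx"), sparse.coo_matrix(counts))
    (d / "features.tsv").write_text("\n".join(gene_ids) + "\n")
    (d / "barcodes.tsv").write_text("\n".join(cell_ids) + "\n")


def write_manifest(paths, out_path) -> dict:
    """Manifest JSON mapping each output file to its sha256 content hash."""
    entries = {}
    for p in paths:
        p = Path(p)
        entries[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    with open(out_path, "w") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True)
    return entries
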