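"""Single-cell quality-control filtering on per-cell summary metrics.

Five rules, applied with strict comparisons so boundary cells are kept:
UMIs below 200 or above 20,000, detected genes above 4,500, mitochondrial
fraction above 10%, and a gene-to-UMI complexity ratio below 0.8. The ratio
defaults to log10(genes)/log10(UMIs) — the standard per-cell library
complexity score — because a raw genes/UMI quotient of 0.8 would reject
essentially every genuine cell; raw mode is available via ``ratio_mode``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = ["QCThresholds", "CellQCRecord", "compute_qc_metrics", "apply_qc_filters", "qc_report"]

RULES = ("umi_low", "umi_high", "genes_high", "mito_high", "ratio_low")


@dataclass(frozen=True)
class QCThresholds:
    umi_min: int = 200
    umi_max: int = 20_000
    genes_max: int = 4_500
    mito_max: float = 10.0  # percent
    ratio_min: float = 0.8

    def __post_init__(self):
        if self.umi_min <= 0 or self.umi_max <= 0 or self.genes_max <= 0:
            raise ValueError("thresholds must be positive")
        if self.umi_min >= self.umi_max:
            raise ValueError("umi_min must be below umi_max")


@dataclass
class CellQCRecord:
    cell_id: str
    umi_count: int
    gene_count: int
    mito_pct: float
    gene_umi_ratio: float
    verdict: str | None = None  # keep | drop
    failed_rules: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.gene_count > self.umi_count:
            raise ValueError(
                f"cell {self.cell_id}: gene_count {self.gene_count} exceeds "
                f"umi_count {self.umi_count}"
            )


def compute_qc_metrics(
    counts,
    gene_ids: list[str],
    cell_ids: list[str],
    mito_gene_ids: set[str] = frozenset(),
) -> list[CellQCRecord]:
    """Per-cell QC metrics from a gene-by-cell integer count matrix.

    ``counts`` may be a scipy sparse matrix or dense array. mito_pct is the
    percentage of UMIs from mitochondrial genes (0 for empty cells); the
    complexity ratio is log10(genes)/log10(UMIs) when both exceed 1, else 0.
    """
    mat = sparse.csc_matrix(counts)
    if mat.shape != (len(gene_ids), len(cell_ids)):
        raise ValueError(
            f"counts shape {mat.shape} does not match {len(gene_ids)} genes x "
            f"{len(cell_ids)} cells"
        )
    data = mat.data
    if data.size and (data < 0).any():
        raise ValueError("negative entries in count matrix")
    if data.size and not np.allclose(data, np.round(data)):
        raise ValueError("non-integer entries in count matrix")
    umi = np.asarray(mat.sum(axis=0)).ravel()
    gene_count = mat.getnnz(axis=0)
    mito_idx = [i for i, g in enumerate(gene_ids) if g in mito_gene_ids]
    if mito_idx:
        mito_umi = np.asarray(mat[mito_idx, :].sum(axis=0)).ravel()
    else:
        mito_umi = np.zeros_like(umi)
    records = []
    for j, cell in enumerate(cell_ids):
        u, g = int(umi[j]), int(gene_count[j])
        mito = 100.0 * mito_umi[j] / u if u > 0 else 0.0
        ratio = float(np.log10(g) / np.log10(u)) if (g > 1 and u > 1) else 0.0
        records.append(
            CellQCRecord(
                cell_id=cell, umi_count=u, gene_count=g, mito_pct=float(mito),
                gene_umi_ratio=ratio,
            )
        )
    return records


def apply_qc_filters(
    records: list[CellQCRecord],
    thresholds: QCThresholds = QCThresholds(),
    ratio_mode: str = "log",
    doublet_flags: dict[str, bool] | None = None,
) -> list[CellQCRecord]:
    """Set verdicts: drop iff any rule fails (strict comparisons keep boundaries).

    A cell at exactly umi = 200, umi = 20000, genes = 4500, mito = 10% or
    ratio = 0.8 passes. ``ratio_mode`` 'raw' re-derives the ratio as
    gene_count/umi_count instead of the stored log-scale ratio. An optional
    external per-cell doublet flag drops flagged cells after the five rules.
    """
    if ratio_mode not in ("log", "raw"):
        raise ValueError(f"ratio_mode must be 'log' or 'raw', got {ratio_mode!r}")
    out = []
    for rec in records:
        failed = set()
        if rec.umi_count < thresholds.umi_min:
            failed.add("umi_low")
        if rec.umi_count > thresholds.umi_max:
            failed.add("umi_high")
        if rec.gene_count > thresholds.genes_max:
            failed.add("genes_high")
        if rec.mito_pct > thresholds.mito_max:
            failed.add("mito_high")
        if ratio_mode == "raw":
            ratio = rec.gene_count / rec.umi_count if rec.umi_count > 0 else 0.0
        else:
            ratio = rec.gene_umi_ratio
        if ratio < thresholds.ratio_min:
            failed.add("ratio_low")
        if doublet_flags and doublet_flags.get(rec.cell_id, False):
            failed.add("doublet")
        out.append(
            CellQCRecord(
                cell_id=rec.cell_id,
                umi_count=rec.umi_count,
                gene_count=rec.gene_count,
                mito_pct=rec.mito_pct,
                gene_umi_ratio=rec.gene_umi_ratio,
                verdict="drop" if failed else "keep",
                failed_rules=frozenset(failed),
            )
        )
    return out


def qc_report(records: list[CellQCRecord]) -> pd.DataFrame:
    """One row per cell: metrics, verdict and failed rules (TSV-ready)."""
    return pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in records],
            "umi_count": [r.umi_count for r in records],
            "gene_count": [r.gene_count for r in records],
            "mito_pct": [r.mito_pct for r in records],
            "gene_umi_ratio": [r.gene_umi_ratio for r in records],
            "verdict": [r.verdict for r in records],
            "failed_rules": [",".join(sorted(r.failed_rules)) for r in records],
        }
    ).set_index("cell_id")
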