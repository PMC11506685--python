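"""Tumor-microenvironment profiling: ssGSEA immune scores and R_o/e enrichment.

ssGSEA (single-sample gene set enrichment) scores one signature in one sample
from the ranks of the signature genes in that sample's expression-sorted gene
list; being rank-based, the scores are invariant to monotone transforms of a
sample's expression vector. R_o/e is the ratio of observed to expected cell
counts under cell-type x group independence; values above 1 mean the cell
type is enriched in that group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats.contingency import expected_freq

__all__ = ["SignatureSet", "RoeTable", "ssgsea_scores", "roe"]


@dataclass(frozen=True)
class SignatureSet:
    """Named gene sets (e.g. immune cell-type signatures)."""

    signatures: dict[str, frozenset[str]]

    def __post_init__(self):
        sigs = {name: frozenset(genes) for name, genes in self.signatures.items()}
        for name, genes in sigs.items():
            if not genes:
                raise ValueError(f"signature {name!r} is empty")
        object.__setattr__(self, "signatures", sigs)

    @classmethod
    def from_gmt(cls, path) -> "SignatureSet":
        sigs = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{path}: line {lineno}: expected >= 3 fields")
                name, _, *genes = fields
                if name in sigs:
                    raise ValueError(f"{path}: line {lineno}: duplicate signature {name!r}")
                sigs[name] = frozenset(g for g in genes if g)
        return cls(signatures=sigs)

    def __len__(self) -> int:
        return len(self.signatures)


def _enrichment_score(order: list[str], members: set[str], alpha: float) -> float:
    """Running-sum enrichment of `members` in the descending-ranked `order`.

    Position i (1-based, best rank first) carries rank weight N - i + 1.
    Members increment the running sum by their weight^alpha normalized over
    the member total; non-members decrement by 1/(N - |S|). The score is the
    sum of the running sum over all positions.
    """
    n = len(order)
    n_in = len(members)
    if n_in == 0 or n_in >= n:
        raise ValueError("signature must be a proper nonempty subset of ranked genes")
    weights = np.arange(n, 0, -1, dtype=float) ** alpha
    in_mask = np.fromiter((g in members for g in order), dtype=bool, count=n)
    denom_in = weights[in_mask].sum()
    steps = np.where(in_mask, weights / denom_in, -1.0 / (n - n_in))
    return float(np.cumsum(steps).sum())


def ssgsea_scores(
    expr,
    sigs: SignatureSet,
    alpha: float = 0.25,
    rescale: bool = True,
) -> pd.DataFrame:
    """Signature-by-sample ssGSEA scores.

    ``expr`` is an ExpressionMatrix or a gene-by-sample DataFrame. Genes are
    ranked per sample by descending expression (ties broken by gene id).
    Signatures with no genes in the matrix produce an all-NaN row. With
    ``rescale`` (default) scores are linearly rescaled so the full
    signature-by-sample matrix spans [0, 1].
    """
    values = expr.values if hasattr(expr, "scale_tag") else expr
    if not isinstance(values, pd.DataFrame):
        raise TypeError("expr must be an ExpressionMatrix or DataFrame")
    gene_ids = np.array(values.index)
    present = {
        name: set(g for g in genes if g in values.index) for name, genes in sigs.signatures.items()
    }
    out = pd.DataFrame(
        np.nan, index=pd.Index(sorted(sigs.signatures), name="signature"), columns=values.columns
    )
    arr = values.to_numpy(dtype=float)
    # stable sort on gene id first, then descending expression -> deterministic ties
    id_order = np.argsort(gene_ids, kind="mergesort")
    for s_idx, sample in enumerate(values.columns):
        col = arr[:, s_idx][id_order]
        order_idx = id_order[np.argsort(-col, kind="mergesort")]
        order = list(gene_ids[order_idx])
        for name in out.index:
            members = present[name]
            if not members or len(members) >= len(order):
                continue
            out.loc[name, sample] = _enrichment_score(order, members, alpha)
    if rescale:
        finite = out.to_numpy()[np.isfinite(out.to_numpy())]
        if finite.size:
            lo, hi = finite.min(), finite.max()
            out = (out - lo) / (hi - lo) if hi > lo else out * 0.0
    return out


@dataclass(frozen=True)
class RoeTable:
    """Observed/expected cell-count ratios per cell type and group."""

    values: pd.DataFrame  # cell types x groups
    observed: pd.DataFrame
    expected: pd.DataFrame


def roe(cell_types, groups) -> RoeTable:
    """R_o/e: observed over expected cell counts per (cell type, group).

    Expected counts come from independence of type and group
    (row_total x col_total / grand_total). Requires >= 2 types and >= 2
    groups with nonzero totals.
    """
    cell_types = pd.Series(cell_types)
    groups = pd.Series(groups)
    if len(cell_types) != len(groups):
        raise ValueError("cell_types and groups must have equal length")
    if len(cell_types) == 0:
        raise ValueError("empty input")
    observed = pd.crosstab(cell_types, groups)
    observed.index.name = "cell_type"
    observed.columns.name = "group"
    if observed.shape[0] < 2 or observed.shape[1] < 2:
        raise ValueError(
            f"need >= 2 cell types and >= 2 groups, got {observed.shape[0]} x {observed.shape[1]}"
        )
    expected = pd.DataFrame(
        expected_freq(observed.to_numpy()), index=observed.index, columns=observed.columns
    )
    if (expected.to_numpy() <= 0).any():
        raise RuntimeError("zero expected count despite nonzero margins")
    return RoeTable(values=observed / expected, observed=observed, expected=expected)
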