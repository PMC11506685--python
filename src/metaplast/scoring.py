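"""Pathway activity scoring and intra-sample pathway-pair dominance.

The activity score of a pathway in a sample is the PPI-weighted mean of the
log-scale expression of the pathway's expressed genes. Comparing two pathways
*within* one sample (a dominance call: which of the pair scores higher) makes
the downstream statistics invariant to any per-sample monotone rescaling,
which is what removes sample-level batch effects from the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pathways import PathwayDatabase, pair_id

__all__ = [
    "ExpressionMatrix",
    "SampleMetadata",
    "ActivityMatrix",
    "DominanceMatrix",
    "assign_age_groups",
    "coverage_gate",
    "compute_activity",
    "pairwise_dominance",
]

AGE_GROUP_LABELS = ("young", "middle", "old")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene-by-sample expression values.

    ``scale_tag`` records whether values are linear (TPM/FPKM-like, transformed
    to log2(v+1) before scoring) or already log-scale.
    """

    values: pd.DataFrame  # genes x samples
    scale_tag: str = "linear"

    def __post_init__(self):
        if self.scale_tag not in ("linear", "log"):
            raise ValueError(f"scale_tag must be 'linear' or 'log', got {self.scale_tag!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        if self.values.size == 0:
            raise ValueError("empty expression matrix")
        if self.scale_tag == "linear" and (self.values.to_numpy() < 0).any():
            raise ValueError("negative entries in a linear-scale expression matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def log_values(self) -> pd.DataFrame:
        """Values on log scale: log2(v+1) for linear input, unchanged for log."""
        if self.scale_tag == "log":
            return self.values
        return np.log2(self.values + 1.0)


@dataclass
class SampleMetadata:
    """Per-sample age, group label and continuous covariates.

    Backed by a DataFrame indexed by sample_id with an optional ``age`` column
    (years), an optional ``group`` column, and arbitrary covariate columns.
    """

    table: pd.DataFrame

    def __post_init__(self):
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")
        self.table = self.table.copy()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def ages(self) -> pd.Series:
        if "age" not in self.table.columns:
            raise ValueError("metadata has no 'age' column")
        return self.table["age"]

    @property
    def groups(self) -> pd.Series:
        if "group" not in self.table.columns:
            raise ValueError("metadata has no 'group' column; run assign_age_groups")
        return self.table["group"]

    def covariate(self, name: str) -> pd.Series:
        if name not in self.table.columns:
            raise KeyError(f"covariate {name!r} not in metadata")
        return self.table[name]


def assign_age_groups(
    meta: SampleMetadata,
    mode: str = "quartile",
    thresholds: tuple[float, float] | None = None,
) -> SampleMetadata:
    """Label each sample young / middle / old from its age.

    quartile mode: young = age <= Q1, old = age >= Q3 (quartiles by linear
    interpolation between order statistics; boundary samples fall in the
    extreme group), middle otherwise. fixed mode: half-open intervals
    [0, t1) / [t1, t2) / [t2, inf) — e.g. thresholds (50, 65) put age 50 in
    the middle group and age 65 in the old group.
    """
    ages = meta.ages
    missing = ages.index[ages.isna()].tolist()
    if missing:
        raise ValueError(f"samples with missing age: {missing}")
    ages_arr = ages.to_numpy(dtype=float)
    if mode == "quartile":
        q1, q3 = np.quantile(ages_arr, [0.25, 0.75])
        labels = np.where(ages_arr <= q1, "young", np.where(ages_arr >= q3, "old", "middle"))
    elif mode == "fixed":
        if thresholds is None or len(thresholds) != 2:
            raise ValueError("fixed mode requires two thresholds")
        t1, t2 = thresholds
        if not t1 < t2:
            raise ValueError(f"thresholds must be increasing, got {thresholds}")
        labels = np.where(ages_arr < t1, "young", np.where(ages_arr < t2, "middle", "old"))
    else:
        raise ValueError(f"unknown age-grouping mode {mode!r}")
    table = meta.table.copy()
    table["group"] = labels
    return SampleMetadata(table=table)


@dataclass
class ActivityMatrix:
    """Pathway-by-sample activity scores plus the coverage gate outcome.

    ``scores`` contains rows only for pathways that passed the coverage gate;
    ``coverage`` and ``scored`` cover every pathway in the database, and
    ``expressed_genes`` records which pathway genes counted as expressed.
    """

    scores: pd.DataFrame  # scored pathways x samples
    coverage: pd.Series  # pathway -> fraction of genes expressed
    scored: pd.Series  # pathway -> bool
    expressed_genes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        if not set(self.scores.index) <= set(self.scored.index[self.scored]):
            raise ValueError("scores present for pathways that did not pass the gate")
        cov = self.coverage.to_numpy(dtype=float)
        if ((cov < 0) | (cov > 1)).any():
            raise ValueError("coverage outside [0, 1]")

    @property
    def scored_ids(self) -> list[str]:
        return list(self.scores.index)

    def pair_signal(self, pathway_a: str, pathway_b: str) -> pd.Series:
        """Per-sample activity difference score(A) - score(B)."""
        return self.scores.loc[pathway_a] - self.scores.loc[pathway_b]

    def to_tsv(self, path) -> None:
        self.scores.to_csv(path, sep="\t", index_label="pathway_id")


def coverage_gate(
    db: PathwayDatabase,
    expr: ExpressionMatrix,
    min_fraction: float = 0.30,
    min_samples: int = 1,
) -> ActivityMatrix:
    """Gate pathways on the fraction of their genes detected in the cohort.

    A gene is expressed if it is present in the matrix and nonzero in at
    least ``min_samples`` samples; a pathway is scored iff its expressed
    fraction is >= ``min_fraction`` (boundary inclusive: 3 of 10 genes pass
    the default 30% gate). Returns an ActivityMatrix skeleton with empty
    scores; feed it to :func:`compute_activity`.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    nonzero_samples = (expr.values != 0).sum(axis=1)
    detected = set(nonzero_samples.index[nonzero_samples >= min_samples])
    coverage = {}
    scored = {}
    expressed = {}
    for p in db:
        genes = [g for g in p.genes if g in detected]
        coverage[p.pathway_id] = len(genes) / p.size
        scored[p.pathway_id] = coverage[p.pathway_id] >= min_fraction
        expressed[p.pathway_id] = genes
    ids = db.pathway_ids
    return ActivityMatrix(
        scores=pd.DataFrame(index=pd.Index([], name="pathway_id"), columns=expr.sample_ids),
        coverage=pd.Series(coverage, name="coverage").loc[ids],
        scored=pd.Series(scored, name="scored").loc[ids],
        expressed_genes=expressed,
    )


def compute_activity(
    db: PathwayDatabase, expr: ExpressionMatrix, gate: ActivityMatrix
) -> ActivityMatrix:
    """Score every gated pathway in every sample.

    score(P, s) = sum_g w_g * x_{g,s} / sum_g w_g over the expressed genes of
    P, with x the log-scale expression.
    """
    logx = expr.log_values()
    rows = {}
    for p in db:
        if not gate.scored.get(p.pathway_id, False):
            continue
        genes = gate.expressed_genes[p.pathway_id]
        if not genes:
            raise RuntimeError(
                f"pathway {p.pathway_id} passed the gate with no expressed genes"
            )
        w = np.array([p.weights[g] for g in genes], dtype=float)
        sub = logx.loc[genes].to_numpy(dtype=float)
        rows[p.pathway_id] = w @ sub / w.sum()
    scores = pd.DataFrame.from_dict(rows, orient="index", columns=expr.sample_ids)
    scores.index.name = "pathway_id"
    return ActivityMatrix(
        scores=scores,
        coverage=gate.coverage,
        scored=gate.scored,
        expressed_genes=gate.expressed_genes,
    )


@dataclass
class DominanceMatrix:
    """Ternary pair-by-sample dominance calls.

    +1: the pair's first (lexicographically smaller) pathway scores higher in
    that sample, -1: the second does, 0: tie within tolerance.
    """

    calls: pd.DataFrame  # pair_id x samples, values in {-1, 0, +1}
    pair_index: pd.DataFrame  # pair_id -> pathway_a, pathway_b

    def __post_init__(self):
        vals = self.calls.to_numpy()
        if not np.isin(vals, (-1, 0, 1)).all():
            raise ValueError("dominance calls must be in {-1, 0, +1}")
        if list(self.calls.index) != list(self.pair_index.index):
            raise ValueError("calls index does not match pair_index")

    def to_tsv(self, path) -> None:
        self.calls.to_csv(path, sep="\t", index_label="pair_id")


def pairwise_dominance(
    act: ActivityMatrix,
    pairs: list[tuple[str, str]],
    tie_tol: float = 1e-9,
) -> DominanceMatrix:
    """Call per-sample dominance for each pathway pair.

    call = +1 when score(A, s) - score(B, s) > tie_tol, -1 when below
    -tie_tol, 0 otherwise. Both pathways of every pair must be scored.
    """
    scored = set(act.scored_ids)
    for a, b in pairs:
        if a not in scored or b not in scored:
            missing = [x for x in (a, b) if x not in scored]
            raise ValueError(f"pair ({a}, {b}) references unscored pathway(s) {missing}")
    idx = [pair_id(a, b) for a, b in pairs]
    a_ids = [a for a, _ in pairs]
    b_ids = [b for _, b in pairs]
    diff = act.scores.loc[a_ids].to_numpy() - act.scores.loc[b_ids].to_numpy()
    calls = np.zeros(diff.shape, dtype=np.int8)
    calls[diff > tie_tol] = 1
    calls[diff < -tie_tol] = -1
    calls_df = pd.DataFrame(calls, index=pd.Index(idx, name="pair_id"), columns=act.scores.columns)
    pair_df = pd.DataFrame(
        {"pathway_a": a_ids, "pathway_b": b_ids}, index=pd.Index(idx, name="pair_id")
    )
    return DominanceMatrix(calls=calls_df, pair_index=pair_df)
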