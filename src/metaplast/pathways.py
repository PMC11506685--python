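"""Metabolic pathway gene sets and their within-pathway PPI-derived gene weights.

A pathway here is a named gene set (KEGG-style metabolic pathway). Genes carry
nonnegative weights used by the activity score; by default every gene weighs 1,
and :func:`attach_ppi_weights` replaces the defaults with a bounded connectivity
weight derived from a protein–protein interaction network restricted to the
pathway's own genes.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, replace

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayDefinition",
    "PathwayDatabase",
    "PPIEdgeList",
    "read_gmt",
    "write_gmt",
    "read_ppi_edges",
    "attach_ppi_weights",
    "enumerate_pairs",
]


@dataclass(frozen=True)
class PathwayDefinition:
    """A named gene set with per-gene nonnegative weights.

    Genes are opaque, case-sensitive symbols stored in lexicographic order.
    """

    pathway_id: str
    name: str
    genes: tuple[str, ...]
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        genes = tuple(sorted(self.genes))
        object.__setattr__(self, "genes", genes)
        if len(genes) < 2:
            raise ValueError(
                f"pathway {self.pathway_id!r} needs at least 2 genes, got {len(genes)}"
            )
        if len(set(genes)) != len(genes):
            raise ValueError(f"pathway {self.pathway_id!r} has duplicate genes")
        weights = dict(self.weights) if self.weights else {g: 1.0 for g in genes}
        object.__setattr__(self, "weights", weights)
        if set(weights) != set(genes):
            raise ValueError(
                f"pathway {self.pathway_id!r}: weight keys do not match gene set"
            )
        if any(w < 0 for w in weights.values()):
            raise ValueError(f"pathway {self.pathway_id!r}: negative weight")
        if not any(w > 0 for w in weights.values()):
            raise ValueError(f"pathway {self.pathway_id!r}: all weights are zero")

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class PathwayDatabase:
    """An ordered collection of pathways with unique ids."""

    pathways: tuple[PathwayDefinition, ...]
    source_tag: str = ""

    def __post_init__(self):
        object.__setattr__(self, "pathways", tuple(self.pathways))
        ids = [p.pathway_id for p in self.pathways]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate pathway ids: {dupes}")

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def __getitem__(self, pathway_id: str) -> PathwayDefinition:
        for p in self.pathways:
            if p.pathway_id == pathway_id:
                return p
        raise KeyError(pathway_id)

    @property
    def pathway_ids(self) -> list[str]:
        return [p.pathway_id for p in self.pathways]

    def summary(self) -> dict:
        return {
            "source_tag": self.source_tag,
            "n_pathways": len(self),
            "pathways": [
                {"pathway_id": p.pathway_id, "name": p.name, "n_genes": p.size}
                for p in self.pathways
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


@dataclass(frozen=True)
class PPIEdgeList:
    """Undirected weighted gene–gene edges.

    Self-loops are discarded; duplicate undirected edges (in either
    orientation) are collapsed by summing their weights.
    """

    edges: tuple[tuple[str, str, float], ...]

    def __post_init__(self):
        collapsed: dict[tuple[str, str], float] = {}
        for rec in self.edges:
            a, b, w = rec
            w = float(w)
            if w <= 0:
                raise ValueError(f"edge ({a}, {b}) has non-positive weight {w}")
            if a == b:
                continue
            key = (a, b) if a < b else (b, a)
            collapsed[key] = collapsed.get(key, 0.0) + w
        object.__setattr__(
            self,
            "edges",
            tuple((a, b, w) for (a, b), w in sorted(collapsed.items())),
        )

    def __len__(self) -> int:
        return len(self.edges)


def read_gmt(path) -> PathwayDatabase:
    """Read a GMT file (tab-separated: id, description, genes...).

    Duplicate genes within a line are dropped with a warning; a line with
    fewer than 3 fields or a repeated pathway id raises ``ValueError``.
    All gene weights are initialized to 1.
    """
    pathways = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            pid, desc, *genes = fields
            genes = [g for g in genes if g]
            if pid in seen:
                raise ValueError(f"{path}: line {lineno}: duplicate pathway id {pid!r}")
            seen.add(pid)
            uniq = list(dict.fromkeys(genes))
            if len(uniq) < len(genes):
                logger.warning(
                    "%s: line %d: pathway %s has %d duplicate gene entries, deduplicated",
                    path, lineno, pid, len(genes) - len(uniq),
                )
            pathways.append(PathwayDefinition(pathway_id=pid, name=desc, genes=tuple(uniq)))
    return PathwayDatabase(pathways=tuple(pathways), source_tag=str(path))


def write_gmt(db: PathwayDatabase, path) -> None:
    """Write a database back to GMT; genes in canonical (lexicographic) order."""
    with open(path, "w") as fh:
        for p in db:
            fh.write("\t".join([p.pathway_id, p.name, *p.genes]) + "\n")


def read_ppi_edges(path) -> PPIEdgeList:
    """Read a 2–3 column TSV edge list (gene_a, gene_b[, weight]); weight defaults to 1."""
    edges = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected >= 2 columns")
            a, b = fields[0], fields[1]
            w = float(fields[2]) if len(fields) > 2 else 1.0
            edges.append((a, b, w))
    return PPIEdgeList(edges=tuple(edges))


def attach_ppi_weights(
    db: PathwayDatabase, ppi: PPIEdgeList, floor: float = 1.0
) -> PathwayDatabase:
    """Derive gene weights from within-pathway PPI connectivity.

    For each pathway the PPI subgraph induced by its genes is formed and each
    gene's weight set to ``floor + d_g / max_d`` where ``d_g`` is the gene's
    weighted degree in that subgraph. Genes with no within-pathway edges get
    ``floor``; a pathway whose induced subgraph is empty keeps uniform
    weights of 1. With the default floor of 1, hub genes count at most twice
    as much as peripheral ones.
    """
    if floor < 0:
        raise ValueError(f"floor must be nonnegative, got {floor}")
    out = []
    for p in db:
        members = set(p.genes)
        degree = dict.fromkeys(p.genes, 0.0)
        any_edge = False
        for a, b, w in ppi.edges:
            if a in members and b in members:
                degree[a] += w
                degree[b] += w
                any_edge = True
        if not any_edge:
            out.append(replace(p, weights={g: 1.0 for g in p.genes}))
            continue
        max_d = max(degree.values())
        weights = {g: floor + d / max_d for g, d in degree.items()}
        out.append(replace(p, weights=weights))
    return PathwayDatabase(pathways=tuple(out), source_tag=db.source_tag)


def enumerate_pairs(db: PathwayDatabase) -> list[tuple[str, str]]:
    """All unordered pathway pairs, lexicographically smaller id first.

    For n pathways this yields n(n-1)/2 candidate pairs.
    """
    ids = sorted(db.pathway_ids)
    if len(ids) < 2:
        raise ValueError(f"need at least 2 pathways to enumerate pairs, got {len(ids)}")
    return list(itertools.combinations(ids, 2))


def pair_id(a: str, b: str) -> str:
    """Canonical string id for an unordered pathway pair."""
    if a == b:
        raise ValueError(f"pair endpoints must differ: {a!r}")
    lo, hi = sorted((a, b))
    return f"{lo}|{hi}"


def split_pair_id(pid: str) -> tuple[str, str]:
    a, _, b = pid.partition("|")
    if not a or not b:
        raise ValueError(f"malformed pair id {pid!r}")
    return a, b


def pairs_table(pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Pair list as a DataFrame indexed by canonical pair id."""
    idx = [pair_id(a, b) for a, b in pairs]
    return pd.DataFrame(
        {"pathway_a": [a for a, _ in pairs], "pathway_b": [b for _, b in pairs]},
        index=pd.Index(idx, name="pair_id"),
    )
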