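"""Metabo-plastic network: pathways as nodes, top switch events as edges.

Events from several cohorts are merged into a multigraph (the same pair may
recur once per cohort, and recurrence counts toward degree); hub pathways are
the high-degree nodes. Betweenness is computed on the simple graph collapsed
across cohorts with exact Brandes traversal.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .pathways import split_pair_id
from .switches import SwitchResult

__all__ = ["select_top_events", "build_network", "hub_pathways", "node_table"]

WEIGHT_CLIP = 50.0  # cap on -log10(adjusted_p) per edge


def select_top_events(results: list[SwitchResult], k: int = 200) -> list[SwitchResult]:
    """Top-k events by ascending adjusted p, ties broken by pair id."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    ranked = sorted(results, key=lambda r: (r.adjusted_p, r.pair_id))
    return ranked[:k]


def build_network(event_lists: dict[str, list[SwitchResult]]) -> nx.MultiGraph:
    """Union the cohorts' top events into one multigraph.

    Each event contributes one edge tagged with its cohort, adjusted p, odds
    ratio and direction; an edge weight of min(-log10(adjusted_p), 50) feeds
    the nodes' weighted degree.
    """
    import numpy as np

    g = nx.MultiGraph()
    for cohort, events in event_lists.items():
        for ev in events:
            a, b = split_pair_id(ev.pair_id)
            if a == b:
                raise ValueError(f"event with identical endpoints: {ev.pair_id}")
            with np.errstate(divide="ignore"):
                w = float(min(-np.log10(ev.adjusted_p), WEIGHT_CLIP)) if ev.adjusted_p >= 0 else 0.0
            g.add_edge(
                a,
                b,
                cohort_tag=cohort,
                adjusted_p=ev.adjusted_p,
                odds_ratio=ev.odds_ratio,
                direction=ev.direction,
                weight=w,
            )
    return g


def hub_pathways(net: nx.MultiGraph, top_n: int | None = None) -> pd.DataFrame:
    """Rank pathways by degree (multi-cohort edges counted separately).

    Ties broken by weighted degree (summed clipped -log10 adjusted p) then
    pathway id. Betweenness (unnormalized pair counts, Brandes) on the
    cohort-collapsed simple graph is reported as an auxiliary column.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    degree = dict(net.degree())
    wdegree = dict(net.degree(weight="weight"))
    simple = nx.Graph(net)
    btw = nx.betweenness_centrality(simple, normalized=False)
    df = pd.DataFrame(
        {
            "degree": pd.Series(degree),
            "weighted_degree": pd.Series(wdegree),
            "betweenness": pd.Series(btw),
        }
    )
    df.index.name = "pathway_id"
    df = df.sort_values(
        by=["degree", "weighted_degree", "pathway_id"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    return df.head(top_n) if top_n is not None else df


def node_table(net: nx.MultiGraph) -> pd.DataFrame:
    """All nodes with degree / weighted degree / betweenness attributes."""
    return hub_pathways(net)


def write_graphml(net: nx.MultiGraph, path) -> None:
    nx.write_graphml(net, path)


def write_edge_tsv(net: nx.MultiGraph, path) -> None:
    rows = [
        {
            "pathway_a": a,
            "pathway_b": b,
            "cohort_tag": d.get("cohort_tag"),
            "adjusted_p": d.get("adjusted_p"),
            "odds_ratio": d.get("odds_ratio"),
            "direction": d.get("direction"),
        }
        for a, b, d in net.edges(data=True)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
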