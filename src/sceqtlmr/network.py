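"""High-confidence interaction graph, betweenness centrality, hub ranking.

Consumes a weighted protein-interaction edge list (STRING-style: two gene
symbols and a confidence score, either already in [0,1] or STRING's
0-1000 integer scale, auto-detected). Edges below the confidence cutoff
(default 0.7, the conventional high-confidence bar) are discarded, hub
genes are ranked by unweighted shortest-path betweenness centrality, and
the final candidate table intersects top hubs with prioritized genes and
colocalization evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "InteractionGraph",
    "build_graph",
    "betweenness",
    "rank_hubs",
    "core_candidates",
]


@dataclass
class InteractionGraph:
    """Undirected confidence-filtered interaction graph.

    ``unmapped``: genes from the universe that appear in no input edge;
    ``isolated``: genes whose every edge fell below the cutoff.
    """

    graph: nx.Graph
    min_score: float
    unmapped: tuple[str, ...] = ()
    isolated: tuple[str, ...] = ()

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def _normalize_scores(scores: np.ndarray) -> np.ndarray:
    """Auto-detect STRING's 0-1000 integer scale vs a [0,1] scale."""
    if scores.size and scores.max() > 1.0:
        scores = scores / 1000.0
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("edge scores must lie in [0,1] (or 0-1000)")
    return scores


def build_graph(edges: pd.DataFrame, genes: Sequence[str],
                min_score: float = 0.7) -> InteractionGraph:
    """Filter an edge list into a high-confidence undirected graph.

    ``edges`` needs columns (gene_a, gene_b, score); STRING exports with
    (protein1, protein2, combined_score) are accepted as synonyms. Edges
    are kept iff both endpoints are in ``genes`` and score >= ``min_score``;
    self-loops are dropped; duplicate undirected pairs keep the maximum
    score. Construction is idempotent and independent of row order.
    """
    cols = {c.lower(): c for c in edges.columns}
    a = cols.get("gene_a", cols.get("protein1"))
    b = cols.get("gene_b", cols.get("protein2"))
    s = cols.get("score", cols.get("combined_score"))
    if a is None or b is None or s is None:
        raise ValueError("edge list needs (gene_a, gene_b, score) columns")
    scores = _normalize_scores(edges[s].to_numpy(dtype=float))

    universe = set(genes)
    seen_in_edges: set[str] = set()
    G = nx.Graph()
    dropped_endpoints: set[str] = set()
    for (ga, gb, sc) in zip(edges[a].astype(str), edges[b].astype(str), scores):
        seen_in_edges.update((ga, gb))
        if ga == gb:
            continue
        if ga not in universe or gb not in universe:
            continue
        dropped_endpoints.update((ga, gb))
        if sc < min_score:
            continue
        if G.has_edge(ga, gb):
            G[ga][gb]["score"] = max(G[ga][gb]["score"], sc)
        else:
            G.add_edge(ga, gb, score=sc)

    unmapped = tuple(sorted(g for g in universe if g not in seen_in_edges))
    isolated = tuple(sorted(g for g in dropped_endpoints if g not in G))
    return InteractionGraph(graph=G, min_score=min_score,
                            unmapped=unmapped, isolated=isolated)


def betweenness(graph: InteractionGraph) -> dict[str, float]:
    """Exact unweighted betweenness centrality, pair-normalized for an
    undirected graph with endpoints excluded; deterministic."""
    return dict(nx.betweenness_centrality(graph.graph, normalized=True))


def rank_hubs(centrality: dict[str, float], graph: InteractionGraph,
              k: int = 10) -> pd.DataFrame:
    """Top-``k`` hub genes: descending betweenness, ties broken by
    descending degree then gene symbol. ``k`` beyond the node count
    returns every node (flagged via the ``truncated`` attrs entry)."""
    deg = dict(graph.graph.degree)
    ordered = sorted(centrality,
                     key=lambda g: (-centrality[g], -deg.get(g, 0), g))
    take = ordered[:k]
    df = pd.DataFrame({
        "gene": take,
        "betweenness": [centrality[g] for g in take],
        "degree": [deg.get(g, 0) for g in take],
    })
    df.attrs["truncated"] = k > len(ordered)
    return df


def core_candidates(hubs: pd.DataFrame, priorities: pd.DataFrame,
                    coloc: Optional[pd.DataFrame] = None,
                    pph4_min: float = 0.8) -> tuple[pd.DataFrame, list[str]]:
    """Final follow-up candidates: hub genes that are also high- or
    medium-priority drug targets, annotated with colocalization evidence.

    ``coloc`` (optional) needs columns (gene, PPH4); a gene tested in
    several cell types contributes its maximum PPH4. Returns the candidate
    table ordered by betweenness plus the list of hub genes excluded
    (absent from the priority table or low priority).
    """
    prio = priorities.set_index("gene")
    pph4 = {}
    if coloc is not None and len(coloc):
        pph4 = coloc.groupby("gene")["PPH4"].max().to_dict()
    rows, excluded = [], []
    for _, hub in hubs.iterrows():
        g = hub["gene"]
        if g not in prio.index or prio.loc[g, "tier"] not in ("high", "medium"):
            excluded.append(g)
            continue
        p4 = pph4.get(g, np.nan)
        rows.append({
            "gene": g, "betweenness": hub["betweenness"],
            "degree": hub["degree"], "priority_tier": prio.loc[g, "tier"],
            "priority_score": prio.loc[g, "score"], "PPH4": p4,
            "colocalized": bool(p4 > pph4_min) if np.isfinite(p4) else False,
        })
    out = pd.DataFrame(rows, columns=["gene", "betweenness", "degree",
                                      "priority_tier", "priority_score",
                                      "PPH4", "colocalized"])
    if len(out):
        out = out.sort_values("betweenness", ascending=False,
                              kind="stable").reset_index(drop=True)
    return out, excluded
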