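"""Tissue-specific protein-interaction subnetworks.

The global scored interaction graph is filtered at a strict score threshold
(score > 0.7 by default; STRING-style 0-1000 scores are auto-rescaled). A
subnetwork is specific to a tissue when its proteins are both (i) classified
tissue-specific for that tissue and (ii) members of a co-expression module
whose activity in that tissue is significantly positive. Only connected
components with at least ``min_component`` proteins are reported; a tissue
whose gate yields no qualifying component has a valid empty network.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = ["TissueNetwork", "load_ppi", "ppi_from_frame", "extract_tissue_network", "network_hubs"]


@dataclass
class TissueNetwork:
    tissue: str
    graph: nx.Graph
    components: list = field(default_factory=list)
    hubs: list = field(default_factory=list)

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def edges(self) -> list:
        return [(a, b, d["score"]) for a, b, d in self.graph.edges(data=True)]

    def is_empty(self) -> bool:
        return self.graph.number_of_nodes() == 0


def ppi_from_frame(df: pd.DataFrame, min_score: float = 0.7) -> nx.Graph:
    """Build the filtered interaction graph from an edge-list DataFrame.

    Expects columns protein1, protein2, combined_score. Scores above 1
    anywhere mean the STRING 0-1000 scale and are divided by 1000. Unordered
    duplicate pairs keep their maximum score; self-loops are rejected, as are
    negative scores. Only edges with score strictly above ``min_score``
    survive.
    """
    required = {"protein1", "protein2", "combined_score"}
    if not required.issubset(df.columns):
        raise ValueError(f"edge list must have columns {sorted(required)}")
    scores = pd.to_numeric(df["combined_score"], errors="coerce")
    if scores.isna().any():
        raise ValueError("malformed (non-numeric) interaction scores")
    if (scores < 0).any():
        raise ValueError("negative interaction scores")
    if (scores > 1).any():
        scores = scores / 1000.0
        if (scores > 1).any():
            raise ValueError("interaction scores exceed the 0-1000 STRING scale")
    if (df["protein1"] == df["protein2"]).any():
        raise ValueError("self-interactions are not allowed")

    graph = nx.Graph()
    for a, b, s in zip(df["protein1"], df["protein2"], scores):
        if s <= min_score:
            continue
        if graph.has_edge(a, b):
            graph[a][b]["score"] = max(graph[a][b]["score"], float(s))
        else:
            graph.add_edge(a, b, score=float(s))
    return graph


def load_ppi(path, min_score: float = 0.7) -> nx.Graph:
    """Read a scored edge-list TSV and return the filtered global graph."""
    df = pd.read_csv(path, sep="\t")
    return ppi_from_frame(df, min_score=min_score)


def extract_tissue_network(
    ppi: nx.Graph,
    tau_table: pd.DataFrame,
    modules,
    tissue: str,
    activity_p: float = 0.05,
    min_component: int = 3,
) -> TissueNetwork:
    """Induced subgraph over genes passing the tissue-specificity gate.

    A gene passes when it is TissueSpecific for ``tissue`` and belongs to at
    least one module with nes > 0 and p < ``activity_p`` in that tissue.
    """
    known = set(tau_table["max_tissue"].unique())
    for m in modules:
        known |= set(m.activity)
    if tissue not in known:
        raise ValueError(f"unknown tissue {tissue!r}")

    ts_genes = set(
        tau_table.index[
            (tau_table["category"] == "TissueSpecific")
            & (tau_table["max_tissue"] == tissue)
        ]
    )
    active_genes: set = set()
    for m in modules:
        nes, p = m.activity.get(tissue, (0.0, 1.0))
        if nes > 0 and p < activity_p:
            active_genes |= set(m.genes)
    gate = ts_genes & active_genes & set(ppi.nodes)

    sub = ppi.subgraph(gate)
    components = [sorted(c) for c in nx.connected_components(sub) if len(c) >= min_component]
    components.sort(key=lambda c: (-len(c), c[0]))
    keep = set().union(*components) if components else set()
    graph = nx.Graph(sub.subgraph(keep))
    net = TissueNetwork(tissue=tissue, graph=graph, components=components)
    net.hubs = network_hubs(net, k=3) if components else []
    return net


def network_hubs(network: TissueNetwork, k: int = 3) -> list:
    """Degree-ranked genes; ties by summed incident scores, then gene id."""
    g = network.graph
    if g.number_of_nodes() == 0:
        return []
    rows = []
    for node in g.nodes:
        deg = g.degree(node)
        wsum = sum(d["score"] for _, _, d in g.edges(node, data=True))
        rows.append((node, deg, wsum))
    rows.sort(key=lambda r: (-r[1], -r[2], r[0]))
    return [(node, int(deg), float(wsum)) for node, deg, wsum in rows[:k]]
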