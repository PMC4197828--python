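"""Merged PPI / transcription-factor-target networks and hub calling.

Protein-protein interactions (undirected) and TF-target interactions
(directed) are merged into one gene graph restricted to a universe of
genes of interest (typically the clustered genes).  A pair of genes
connected through both sources contributes a single neighbour relation
carrying both type tags, so a node's degree counts distinct validated
interaction partners regardless of edge type or direction.  Regulatory
hubs are nodes whose degree strictly exceeds a cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class InteractionGraph:
    """Undirected neighbour graph with per-edge type tags.

    ``graph`` edges carry a ``types`` attribute (sorted tuple drawn from
    {"ppi", "tf_target"}); directed TF->target orientations are kept in
    ``tf_directions`` for export.  ``n_skipped`` counts malformed input
    rows that were dropped.
    """

    graph: nx.Graph
    tf_directions: list[tuple[str, str]]
    n_skipped: int = 0

    @property
    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for a, b, data in self.graph.edges(data=True):
            for t in data["types"]:
                if t == "tf_target":
                    for src, tgt in self.tf_directions:
                        if {src, tgt} == {a, b}:
                            rows.append({"a": src, "b": tgt, "type": t})
                else:
                    rows.append({"a": min(a, b), "b": max(a, b), "type": t})
        return pd.DataFrame(rows, columns=["a", "b", "type"]).drop_duplicates()

    def to_sif(self, path) -> None:
        with open(path, "w") as fh:
            for _, row in self.edge_table().iterrows():
                fh.write(f"{row['a']}\t{row['type']}\t{row['b']}\n")

    def to_graphml(self, path) -> None:
        g = self.graph.copy()
        for a, b, data in g.edges(data=True):
            data["types"] = ",".join(data["types"])
        nx.write_graphml(g, str(path))


def _iter_edge_rows(edges: pd.DataFrame | Iterable, default_type: str):
    if isinstance(edges, pd.DataFrame):
        for row in edges.itertuples(index=False):
            yield getattr(row, "a", None), getattr(row, "b", None), getattr(row, "type", default_type)
    else:
        for item in edges:
            if len(item) == 2:
                yield item[0], item[1], default_type
            else:
                yield item[0], item[1], item[2]


def build_network(
    ppi_edges: pd.DataFrame | Iterable,
    tf_edges: pd.DataFrame | Iterable,
    universe: Iterable[str],
) -> InteractionGraph:
    """Merge typed edge lists into a deduplicated neighbour graph.

    Edges are kept only when both endpoints belong to ``universe``;
    self-loops are dropped, duplicates within and across sources collapse
    onto a single neighbour relation that accumulates type tags, and
    genes left without any edge do not appear in the graph.  Malformed
    rows (missing endpoints) are skipped and counted.
    """
    universe = set(universe)
    g = nx.Graph()
    tf_directions: list[tuple[str, str]] = []
    skipped = 0
    for source, default in ((ppi_edges, "ppi"), (tf_edges, "tf_target")):
        for a, b, etype in _iter_edge_rows(source, default):
            if not isinstance(a, str) or not isinstance(b, str) or not a or not b:
                skipped += 1
                continue
            if a == b or a not in universe or b not in universe:
                continue
            if g.has_edge(a, b):
                g[a][b]["types"] = tuple(sorted(set(g[a][b]["types"]) | {etype}))
            else:
                g.add_edge(a, b, types=(etype,))
            if etype == "tf_target" and (a, b) not in tf_directions:
                tf_directions.append((a, b))
    return InteractionGraph(graph=g, tf_directions=tf_directions, n_skipped=skipped)


def hub_report(graph: InteractionGraph, hub_cutoff: int = 19) -> tuple[pd.DataFrame, dict]:
    """Per-node degrees and the hub call (degree strictly above the cutoff).

    Returns the node table (node, degree, hub) sorted by decreasing
    degree, and a summary dict with min / median / q3 / max degree and
    the hub count.
    """
    if hub_cutoff < 1:
        raise ValueError("hub_cutoff must be >= 1")
    degrees = graph.degrees
    if not degrees:
        raise ValueError("graph is empty")
    table = pd.DataFrame(
        {"node": list(degrees), "degree": list(degrees.values())}
    ).sort_values(["degree", "node"], ascending=[False, True], ignore_index=True)
    table["hub"] = table["degree"] > hub_cutoff
    vals = table["degree"].to_numpy()
    summary = {
        "min_degree": int(vals.min()),
        "median_degree": float(np.median(vals)),
        "q3_degree": float(np.percentile(vals, 75)),
        "max_degree": int(vals.max()),
        "n_nodes": int(len(vals)),
        "n_edges": int(graph.graph.number_of_edges()),
        "n_hubs": int(table["hub"].sum()),
    }
    return table, summary
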