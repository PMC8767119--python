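"""Tripartite lncRNA-miRNA-mRNA network assembly and summaries."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .edges import InteractionEdge


@dataclass
class RegulatoryNetwork:
    edges: list[InteractionEdge]
    node_classes: dict[str, str]  # id -> mRNA | lncRNA | miRNA
    node_direction: dict[str, str] = field(default_factory=dict)  # up/down/not_DE

    def __post_init__(self) -> None:
        seen = set()
        for edge in self.edges:
            if edge.source_id == edge.target_id:
                raise ValueError(f"self-edge on {edge.source_id}")
            key = (edge.source_id, edge.target_id, edge.edge_type)
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)
        touched = {n for e in self.edges for n in (e.source_id, e.target_id)}
        for node in touched:
            if node not in self.node_classes:
                raise ValueError(f"node {node!r} has no declared class")
        # only keep classes for touched nodes (every node has >= 1 edge)
        self.node_classes = {n: self.node_classes[n] for n in touched}

    def composition(self) -> dict[str, int]:
        counts = {"mRNA": 0, "lncRNA": 0, "miRNA": 0}
        for cls in self.node_classes.values():
            counts[cls] += 1
        counts["edges"] = len(self.edges)
        return counts

    def degree_table(self) -> pd.DataFrame:
        degree: dict[str, int] = {}
        for edge in self.edges:
            degree[edge.source_id] = degree.get(edge.source_id, 0) + 1
            degree[edge.target_id] = degree.get(edge.target_id, 0) + 1
        rows = [
            {
                "node": node,
                "node_class": self.node_classes[node],
                "direction": self.node_direction.get(node, "not_DE"),
                "degree": deg,
            }
            for node, deg in sorted(degree.items())
        ]
        return pd.DataFrame(rows, columns=["node", "node_class", "direction", "degree"])


def _dedupe(edges: list[InteractionEdge]) -> list[InteractionEdge]:
    best: dict[tuple, InteractionEdge] = {}
    for edge in edges:
        key = (edge.source_id, edge.target_id, edge.edge_type)
        if key not in best or edge.score < best[key].score:
            best[key] = edge
    return sorted(best.values())


def build_network(
    cis: list[InteractionEdge],
    trans: list[InteractionEdge],
    mirna_targets: list[InteractionEdge],
    etms: list[InteractionEdge],
    precursors: list[InteractionEdge],
    node_classes: dict[str, str],
    node_direction: dict[str, str] | None = None,
    mirna_anchored: bool = True,
) -> RegulatoryNetwork:
    """Merge typed edge sets into one tripartite network.

    With ``mirna_anchored`` (default) a lncRNA node is kept only if it
    participates in at least one miRNA edge (target, eTM or precursor), and
    cis/trans edges are kept only when their lncRNA is kept; mRNA nodes
    enter through a surviving edge. Set ``mirna_anchored=False`` to include
    every cis/trans pair. Node classes must be consistent across inputs.
    """
    all_edges = _dedupe(cis + trans + mirna_targets + etms + precursors)
    for edge in all_edges:
        for node in (edge.source_id, edge.target_id):
            if node not in node_classes:
                raise ValueError(f"edge endpoint {node!r} has no declared class")

    if mirna_anchored:
        anchored_lnc = set()
        for edge in _dedupe(mirna_targets + etms + precursors):
            for node in (edge.source_id, edge.target_id):
                if node_classes[node] == "lncRNA":
                    anchored_lnc.add(node)
        kept = []
        for edge in all_edges:
            if edge.edge_type in ("cis", "trans"):
                lnc = (
                    edge.source_id
                    if node_classes[edge.source_id] == "lncRNA"
                    else edge.target_id
                )
                if lnc not in anchored_lnc:
                    continue
            elif edge.edge_type.startswith("miRNA_target"):
                other = (
                    edge.target_id
                    if node_classes[edge.source_id] == "miRNA"
                    else edge.source_id
                )
                if node_classes[other] == "lncRNA" and other not in anchored_lnc:
                    continue  # unreachable by construction; kept for clarity
            kept.append(edge)
        all_edges = kept

    return RegulatoryNetwork(
        edges=all_edges,
        node_classes=node_classes,
        node_direction=node_direction or {},
    )
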