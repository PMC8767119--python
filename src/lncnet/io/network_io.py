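"""Network serialization: 3-column edge-list TSV and GraphML.

Every edge endpoint must have a declared node class (mRNA/lncRNA/miRNA);
the class travels as a node attribute so downstream viewers can style node
shapes by molecule type. Both formats round-trip losslessly at the
edge-multiset level.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx

from ..edges import NODE_CLASSES, InteractionEdge


class NetworkIOError(ValueError):
    pass


def _check(edges: list[InteractionEdge], node_classes: dict[str, str]) -> None:
    for cls in node_classes.values():
        if cls not in NODE_CLASSES:
            raise NetworkIOError(f"unknown node class {cls!r}")
    for edge in edges:
        for node in (edge.source_id, edge.target_id):
            if node not in node_classes:
                raise NetworkIOError(
                    f"edge references node {node!r} with no declared class"
                )


def write_edge_list(
    edges: list[InteractionEdge],
    node_classes: dict[str, str],
    path: str | Path,
) -> None:
    """Write edges as TSV plus a sidecar ``<path>.nodes.tsv`` node table."""
    _check(edges, node_classes)
    path = Path(path)
    with open(path, "w") as handle:
        handle.write("source\ttarget\tedge_type\tscore\n")
        for edge in sorted(edges):
            handle.write(
                f"{edge.source_id}\t{edge.target_id}\t{edge.edge_type}"
                f"\t{edge.score:.6g}\n"
            )
    nodes_path = path.with_suffix(path.suffix + ".nodes.tsv")
    touched = {n for e in edges for n in (e.source_id, e.target_id)}
    with open(nodes_path, "w") as handle:
        handle.write("node\tnode_class\n")
        for node in sorted(touched):
            handle.write(f"{node}\t{node_classes[node]}\n")


def read_edge_list(path: str | Path) -> tuple[list[InteractionEdge], dict[str, str]]:
    path = Path(path)
    edges = []
    with open(path) as handle:
        header = handle.readline()
        if not header.startswith("source\ttarget\tedge_type"):
            raise NetworkIOError(f"{path}: unexpected edge-list header")
        for line in handle:
            src, tgt, etype, score = line.rstrip("\n").split("\t")
            edges.append(InteractionEdge(src, tgt, etype, float(score)))
    node_classes = {}
    nodes_path = path.with_suffix(path.suffix + ".nodes.tsv")
    if nodes_path.exists():
        with open(nodes_path) as handle:
            handle.readline()
            for line in handle:
                node, cls = line.rstrip("\n").split("\t")
                node_classes[node] = cls
    return edges, node_classes


def to_graph(
    edges: list[InteractionEdge], node_classes: dict[str, str]
) -> nx.MultiDiGraph:
    _check(edges, node_classes)
    graph = nx.MultiDiGraph()
    for edge in sorted(edges):
        for node in (edge.source_id, edge.target_id):
            if node not in graph:
                graph.add_node(node, node_class=node_classes[node])
        graph.add_edge(
            edge.source_id,
            edge.target_id,
            edge_type=edge.edge_type,
            score=edge.score,
        )
    return graph


def write_graphml(
    edges: list[InteractionEdge],
    node_classes: dict[str, str],
    path: str | Path,
) -> None:
    nx.write_graphml(to_graph(edges, node_classes), str(path))


def read_graphml(path: str | Path) -> tuple[list[InteractionEdge], dict[str, str]]:
    graph = nx.read_graphml(str(path))
    edges = [
        InteractionEdge(u, v, data["edge_type"], float(data["score"]))
        for u, v, data in graph.edges(data=True)
    ]
    node_classes = {n: d["node_class"] for n, d in graph.nodes(data=True)}
    return edges, node_classes
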