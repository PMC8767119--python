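"""Typed interaction edges shared by the target callers and the network."""

from __future__ import annotations

from dataclasses import dataclass

EDGE_TYPES = (
    "precursor",
    "miRNA_target_mRNA",
    "miRNA_target_lncRNA",
    "eTM",
    "cis",
    "trans",
)

NODE_CLASSES = ("mRNA", "lncRNA", "miRNA")


@dataclass(frozen=True, order=True)
class InteractionEdge:
    """A typed link between two identified features.

    ``score`` semantics depend on ``edge_type``: expectation for miRNA
    target edges and eTMs, alignment identity for precursor edges, Pearson r
    for cis/trans edges.
    """

    source_id: str
    target_id: str
    edge_type: str
    score: float

    def __post_init__(self) -> None:
        if self.edge_type not in EDGE_TYPES:
            raise ValueError(f"unknown edge type {self.edge_type!r}")
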