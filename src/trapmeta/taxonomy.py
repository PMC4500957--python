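"""Rank-labelled taxonomy used to roll rRNA reference assignments up to genera.

The tree is deliberately lightweight: a table of nodes (id, parent, rank,
name) each carrying one of the community categories used throughout the
analysis — Bacteria, SAR protists (Stramenopiles + Alveolata + Rhizaria),
green algae (Chlorophyta), Metazoa, other eukaryotes — plus Host and
Unclassified buckets, and an organellar flag on reference leaves so that
mitochondrial/plastid rRNA can be excluded from community profiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

CATEGORIES = ("Bacteria", "SAR", "Chlorophyta", "Metazoa", "OtherEukaryote")
ROOT_ID = "root"
ROOT_NAME = "cellular organisms"

# rank order from root down; used to validate parent-above-child
RANK_ORDER = ("no rank", "superkingdom", "phylum", "genus", "reference")


@dataclass
class Node:
    node_id: str
    parent_id: str | None
    rank: str
    name: str
    category: str
    organellar: bool = False


@dataclass
class TaxonomyTree:
    """Rooted taxonomy with category labels and organellar flags."""

    nodes: dict[str, Node] = field(default_factory=dict)

    def add_node(self, node: Node) -> None:
        if node.node_id in self.nodes:
            raise ValueError(f"duplicate node id {node.node_id!r}")
        if node.parent_id is not None:
            parent = self.nodes.get(node.parent_id)
            if parent is None:
                raise ValueError(f"unknown parent {node.parent_id!r}")
            if RANK_ORDER.index(parent.rank) >= RANK_ORDER.index(node.rank):
                raise ValueError(
                    f"parent rank {parent.rank!r} not above child {node.rank!r}")
        elif self.nodes:
            raise ValueError("tree already has a root")
        self.nodes[node.node_id] = node

    # -- queries ---------------------------------------------------------

    def lineage(self, node_id: str) -> list[Node]:
        """Path from the node up to (and including) the root."""
        out = []
        cur = self.nodes[node_id]
        while True:
            out.append(cur)
            if cur.parent_id is None:
                return out
            cur = self.nodes[cur.parent_id]

    def ancestor_at_rank(self, node_id: str, rank: str) -> Node | None:
        for node in self.lineage(node_id):
            if node.rank == rank:
                return node
        return None

    def genus_of(self, node_id: str) -> Node | None:
        """First ancestor (or self) of rank genus; None when the lineage
        stops above genus."""
        return self.ancestor_at_rank(node_id, "genus")

    def phylum_of(self, node_id: str) -> Node | None:
        return self.ancestor_at_rank(node_id, "phylum")

    def category_of(self, node_id: str) -> str:
        return self.nodes[node_id].category

    def references(self) -> list[Node]:
        return [n for n in self.nodes.values() if n.rank == "reference"]

    def genera(self) -> list[Node]:
        return [n for n in self.nodes.values() if n.rank == "genus"]

    def is_organellar(self, node_id: str) -> bool:
        return self.nodes[node_id].organellar

    # -- I/O -------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "node_id": n.node_id,
                "parent_id": "" if n.parent_id is None else n.parent_id,
                "rank": n.rank,
                "name": n.name,
                "category": n.category,
                "organellar_flag": int(n.organellar),
            }
            for n in self.nodes.values()
        ]
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TaxonomyTree":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        tree = cls()
        for row in df.itertuples(index=False):
            tree.add_node(Node(
                node_id=row.node_id,
                parent_id=row.parent_id or None,
                rank=row.rank,
                name=row.name,
                category=row.category,
                organellar=bool(int(row.organellar_flag)),
            ))
        return tree
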