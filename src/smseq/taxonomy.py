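"""Rank-labelled taxonomy tree used by the cell-annotation stage.

The tree follows the NCBI-style node table convention: every node has a
taxon id, a parent id, a rank and a name; the root is its own parent.
Ranks are constrained to the eight canonical levels used throughout the
package, and rank depth must strictly increase from root to leaf.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

RANKS = ("root", "domain", "phylum", "class", "order", "family", "genus", "species")
RANK_DEPTH = {r: i for i, r in enumerate(RANKS)}


@dataclass(frozen=True)
class TaxNode:
    taxon_id: str
    parent_id: str
    rank: str
    name: str


@dataclass
class TaxonomyTree:
    """Rooted taxonomy with parent/children indexes and LCA support."""

    nodes: dict[str, TaxNode]
    root: str = field(init=False)
    children: dict[str, list[str]] = field(init=False)

    def __post_init__(self) -> None:
        roots = [t for t, n in self.nodes.items()
                 if n.parent_id == t or n.parent_id in ("", "0", None)]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {roots}")
        self.root = roots[0]
        self.children = {t: [] for t in self.nodes}
        for t, n in self.nodes.items():
            if t == self.root:
                continue
            if n.parent_id not in self.nodes:
                raise ValueError(f"node {t} has unknown parent {n.parent_id}")
            self.children[n.parent_id].append(t)
        for kids in self.children.values():
            kids.sort()
        # acyclicity + rank monotonicity along every root path
        for t in self.nodes:
            path = self.path_to_root(t)
            if path[-1] != self.root:
                raise ValueError(f"node {t} does not reach the root")
            depths = [RANK_DEPTH[self.nodes[p].rank] for p in path]
            if any(a <= b for a, b in zip(depths, depths[1:])):
                raise ValueError(f"rank does not strictly increase on path to {t}")

    def path_to_root(self, taxon_id: str) -> list[str]:
        """Ancestor chain [taxon_id, ..., root]; raises on cycles."""
        path, seen = [], set()
        t = taxon_id
        while True:
            if t in seen:
                raise ValueError(f"cycle detected at {t}")
            seen.add(t)
            path.append(t)
            if t == self.root:
                return path
            t = self.nodes[t].parent_id

    def path_from_root(self, taxon_id: str) -> list[str]:
        return self.path_to_root(taxon_id)[::-1]

    def depth(self, taxon_id: str) -> int:
        return len(self.path_to_root(taxon_id)) - 1

    def rank(self, taxon_id: str) -> str:
        return self.nodes[taxon_id].rank

    def name(self, taxon_id: str) -> str:
        return self.nodes[taxon_id].name

    def is_leaf(self, taxon_id: str) -> bool:
        return not self.children[taxon_id]

    def lca(self, a: str, b: str) -> str:
        pa = self.path_from_root(a)
        pb = self.path_from_root(b)
        last = self.root
        for x, y in zip(pa, pb):
            if x != y:
                break
            last = x
        return last

    def lca_many(self, taxa: Iterable[str]) -> str:
        taxa = list(taxa)
        if not taxa:
            raise ValueError("lca of empty set")
        out = taxa[0]
        for t in taxa[1:]:
            out = self.lca(out, t)
        return out

    def ancestor_at_rank(self, taxon_id: str, rank: str) -> str | None:
        for t in self.path_to_root(taxon_id):
            if self.nodes[t].rank == rank:
                return t
        return None

    def postorder(self) -> list[str]:
        order: list[str] = []
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
            else:
                stack.append((node, True))
                for c in self.children[node]:
                    stack.append((c, False))
        return order

    def leaves(self) -> list[str]:
        return [t for t in self.nodes if self.is_leaf(t)]

    # -- I/O: TSV with columns taxon_id, parent_id, rank, name ------------

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "TaxonomyTree":
        nodes = {
            str(r.taxon_id): TaxNode(str(r.taxon_id), str(r.parent_id), r.rank, str(r.name))
            for r in df.itertuples(index=False)
        }
        return cls(nodes)

    @classmethod
    def read_tsv(cls, path) -> "TaxonomyTree":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls.from_table(df)

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(n.taxon_id, n.parent_id, n.rank, n.name) for n in self.nodes.values()],
            columns=["taxon_id", "parent_id", "rank", "name"],
        )

    def write_tsv(self, path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)
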