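"""MIC-Anno: per-cell taxonomic annotation.

Each read is classified by its canonical k-mer hits against the
taxon-labelled index; per cell, read assignments are summed leaf-to-root
into clade (cumulative) counts, and the annotation path is chosen
root-to-leaf by greedily descending into the child with the largest
clade count. Each selected node carries an exact one-sided binomial
P-value for "the winner beats a uniform draw over the competing
children", reported for filtering but never used to truncate the path.
The purity of a cell at a rank is the fraction of its classified reads
that fall inside the annotated clade at that rank.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd
from scipy.stats import binom

from .kmer import KmerIndex, canonical_kmers
from .taxonomy import TaxonomyTree

UNCLASSIFIED = "*UNCLASSIFIED*"


@dataclass
class NodeCounts:
    """Per-cell direct and cumulative (clade) read counts per taxon."""

    direct: dict[str, int]
    cumulative: dict[str, int]

    def total_classified(self, tree: TaxonomyTree) -> int:
        return self.cumulative.get(tree.root, 0)


@dataclass
class BarcodeAnnotation:
    cell_id: str
    # ordered root->leaf: (rank, taxon_id, cumulative_count, p_value)
    path: list[tuple[str, str, int, float]] = field(default_factory=list)
    terminal_taxon: str | None = None
    n_classified: int = 0

    @property
    def assigned(self) -> bool:
        return self.terminal_taxon is not None

    def taxon_at_rank(self, rank: str) -> str | None:
        for r, t, _, _ in self.path:
            if r == rank:
                return t
        return None


def classify_read(
    seq: str, idx: KmerIndex, tree: TaxonomyTree, min_hits: int = 1
) -> str:
    """Assign a read to a taxon by scoring root-to-leaf paths with k-mer hits.

    Every canonical k-mer of the read that exists in the index votes for
    its taxon; each root-to-leaf path is scored by the summed hits on its
    nodes, the read goes to the deepest hit node of the best path, and
    tied best paths resolve to the LCA of their deepest hit nodes.
    """
    hits: Counter = Counter()
    for km in canonical_kmers(seq, idx.k):
        t = idx.labels.get(km)
        if t is not None:
            hits[t] += 1
    if sum(hits.values()) < min_hits or not hits:
        return UNCLASSIFIED

    best_score = -1
    best_deepest: list[str] = []
    stack: list[tuple[str, int, str | None]] = [
        (tree.root, hits.get(tree.root, 0), tree.root if tree.root in hits else None)
    ]
    while stack:
        node, score, deepest = stack.pop()
        kids = tree.children[node]
        if kids:
            for c in kids:
                c_score = score + hits.get(c, 0)
                c_deepest = c if c in hits else deepest
                stack.append((c, c_score, c_deepest))
        else:
            if deepest is None:
                continue
            if score > best_score:
                best_score, best_deepest = score, [deepest]
            elif score == best_score:
                best_deepest.append(deepest)
    if not best_deepest:
        return UNCLASSIFIED
    return tree.lca_many(best_deepest)


def aggregate_counts(assignments: Iterable[str], tree: TaxonomyTree) -> NodeCounts:
    """Leaf-to-root clade sums over one cell's read-level taxon assignments."""
    direct: Counter = Counter()
    for t in assignments:
        if t != UNCLASSIFIED:
            if t not in tree.nodes:
                raise ValueError(f"assignment to unknown taxon {t!r}")
            direct[t] += 1
    cumulative: dict[str, int] = {}
    for node in tree.postorder():
        cumulative[node] = direct.get(node, 0) + sum(
            cumulative[c] for c in tree.children[node]
        )
    cumulative = {t: c for t, c in cumulative.items() if c > 0}
    return NodeCounts(direct=dict(direct), cumulative=cumulative)


def selection_pvalue(c_top: int, n: int, n_children: int) -> float:
    """P[Binomial(n, 1/C) >= c_top]: the winning child against a uniform null."""
    if n_children <= 1:
        return 1.0
    return float(binom.sf(c_top - 1, n, 1.0 / n_children))


def annotate_cell(
    nc: NodeCounts, tree: TaxonomyTree, cell_id: str = ""
) -> BarcodeAnnotation:
    """Greedy root-to-leaf descent through the clade counts.

    At each node the child with the largest cumulative count is selected
    (ties: larger direct count, then lexicographic taxon id); descent
    stops at a leaf or when no child has a nonzero count. P-values are
    attached per selected node and reported only.
    """
    total = nc.cumulative.get(tree.root, 0)
    ann = BarcodeAnnotation(cell_id=cell_id, n_classified=total)
    if total < 1:
        return ann
    node = tree.root
    ann.path.append((tree.rank(node), node, total, 1.0))
    while True:
        contenders = [c for c in tree.children[node] if nc.cumulative.get(c, 0) > 0]
        if not contenders:
            break
        contenders.sort(
            key=lambda c: (-nc.cumulative[c], -nc.direct.get(c, 0), c)
        )
        winner = contenders[0]
        n = sum(nc.cumulative[c] for c in contenders)
        p = selection_pvalue(nc.cumulative[winner], n, len(contenders))
        ann.path.append((tree.rank(winner), winner, nc.cumulative[winner], p))
        node = winner
    ann.terminal_taxon = node
    return ann


def compute_purity(
    nc: NodeCounts, ann: BarcodeAnnotation, tree: TaxonomyTree, rank: str
) -> float | None:
    """Clade-read fraction at the annotated node of the requested rank.

    Unclassified reads enter neither term; None when the annotation path
    has no node at that rank.
    """
    taxon = ann.taxon_at_rank(rank)
    if taxon is None:
        return None
    total = nc.total_classified(tree)
    if total == 0:
        return None
    return nc.cumulative.get(taxon, 0) / total


def annotate_cells(
    per_cell_assignments: dict[str, list[str]],
    tree: TaxonomyTree,
    purity_ranks: tuple[str, ...] = ("genus", "species"),
) -> pd.DataFrame:
    """Annotation table over cells: terminal taxon, per-rank ids/P-values, purity."""
    rows = []
    for cell_id, assignments in per_cell_assignments.items():
        nc = aggregate_counts(assignments, tree)
        ann = annotate_cell(nc, tree, cell_id=cell_id)
        row: dict = {
            "cell_id": cell_id,
            "n_reads": len(assignments),
            "n_classified": ann.n_classified,
            "terminal_taxon": ann.terminal_taxon,
            "terminal_name": tree.name(ann.terminal_taxon) if ann.assigned else None,
        }
        for rank, taxon, cum, p in ann.path:
            row[f"{rank}_taxon"] = taxon
            row[f"{rank}_name"] = tree.name(taxon)
            row[f"{rank}_count"] = cum
            row[f"{rank}_pvalue"] = p
        for rank in purity_ranks:
            row[f"purity_{rank}"] = compute_purity(nc, ann, tree, rank)
        rows.append(row)
    return pd.DataFrame(rows)
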