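"""MIC-Phage: host-phage transcriptional association analysis.

Prophage transcription inside a bacterial cell shows up as reads mapping
to phage genomes. After rRNA/tRNA background is removed by k-mer
containment, reads are pseudo-assigned to phage genomes with the same
uniqueness and UMI-dedup semantics as the gene matrix; genus-associated
phages are detected with the marker-gene machinery, the most active
phages per genus are shortlisted, and every candidate (genus, phage)
pair is validated against genome alignments: a solid association needs
at least one alignment of >= 3 kb length at > 80% identity between the
phage and a genome of the genus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import anndata as ad
import numpy as np
import pandas as pd

from .bac import build_matrix, find_markers
from .kmer import FeatureKmerIndex, canonical_kmers

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class HostPhageAssociation:
    genus: str
    phage_id: str
    log2_fc: float
    p_adj: float
    validated: bool
    best_length: int
    best_identity: float


# ---------------------------------------------------------------------------
# rRNA/tRNA background filter
# ---------------------------------------------------------------------------

def build_containment_set(sequences: Iterable[str], k: int = 21) -> frozenset[str]:
    kmers: set[str] = set()
    for seq in sequences:
        kmers.update(canonical_kmers(seq, k))
    return frozenset(kmers)


def rrna_containment(seq: str, rrna_kmers: frozenset[str], k: int = 21) -> float:
    """Fraction of a read's canonical k-mers found in the rRNA/tRNA set."""
    n = hit = 0
    for km in canonical_kmers(seq, k):
        n += 1
        if km in rrna_kmers:
            hit += 1
    return hit / n if n else 0.0


def filter_rrna_trna(
    reads: Sequence[tuple],
    rrna_kmers: frozenset[str],
    k: int = 21,
    max_containment: float = 0.2,
    seq_of=lambda r: r[-1],
) -> list:
    """Drop reads whose rRNA/tRNA k-mer containment exceeds the threshold."""
    return [r for r in reads if rrna_containment(seq_of(r), rrna_kmers, k) <= max_containment]


# ---------------------------------------------------------------------------
# phage matrix and genus markers
# ---------------------------------------------------------------------------

def build_phage_matrix(
    reads: Iterable[tuple[str, str, str]],
    phage_index: FeatureKmerIndex,
    cell_meta: pd.DataFrame | None = None,
    min_hit_frac: float = 0.5,
) -> ad.AnnData:
    """Cells x phage UMI matrix from (cell_id, umi, cdna) reads.

    Same unique-best assignment and directional UMI dedup as the gene
    matrix; features are phage genome ids.
    """
    from .bac import assign_reads

    assignments = assign_reads(reads, phage_index, min_hit_frac=min_hit_frac)
    return build_matrix(assignments, cell_meta=cell_meta, exclude_biotypes=())


def genus_phage_markers(
    phage_matrix: ad.AnnData,
    genus_labels: Sequence[str],
    logfc_threshold: float = 0.1,
    min_genus_frac: float = 0.03,
) -> pd.DataFrame:
    """One-genus-vs-rest phage markers after the genus abundance filter.

    Cells of genera holding <= ``min_genus_frac`` of all cells are
    removed first; the marker table additionally carries the total UMI
    count of each phage within its genus (its transcriptional activity).
    """
    labels = np.asarray(genus_labels)
    if labels.shape[0] != phage_matrix.n_obs:
        raise ValueError("genus labels must match number of cells")
    frac = pd.Series(labels).value_counts(normalize=True)
    abundant = set(frac[frac > min_genus_frac].index)
    mask = np.isin(labels, list(abundant))
    sub, sub_labels = phage_matrix[mask].copy(), labels[mask]
    if len(set(sub_labels)) < 2:
        raise ValueError("need at least 2 genera after the abundance filter")
    table = find_markers(sub, sub_labels, logfc_threshold=logfc_threshold, min_pct=0.0)
    X = sub.X.toarray() if hasattr(sub.X, "toarray") else np.asarray(sub.X)
    col = {f: i for i, f in enumerate(sub.var_names)}
    totals = []
    for row in table.itertuples(index=False):
        totals.append(int(X[sub_labels == row.group, col[row.feature]].sum()))
    table["total_umis"] = totals
    return table.rename(columns={"feature": "phage_id", "group": "genus"})


def select_top_phages(markers: pd.DataFrame, k: int = 20) -> dict[str, list[str]]:
    """Top-k phages per genus by transcriptional activity.

    Activity = total UMI count of the phage within the genus; ties break
    by log2 fold change, then phage id. Positive-direction markers only
    (a genus-associated phage is enriched, not depleted). A genus with
    fewer than k phages keeps them all.
    """
    pos = markers[markers["log2_fc"] > 0]
    out: dict[str, list[str]] = {}
    for genus, grp in pos.groupby("genus", sort=True):
        ranked = grp.sort_values(
            by=["total_umis", "log2_fc", "phage_id"], ascending=[False, False, True]
        )
        out[genus] = ranked["phage_id"].head(k).tolist()
    return out


# ---------------------------------------------------------------------------
# alignment-based validation
# ---------------------------------------------------------------------------

def read_blast6(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BLAST6_COLUMNS)
    if (df["length"] < 1).any():
        raise ValueError("alignment length must be >= 1")
    if ((df["pident"] < 0) | (df["pident"] > 100)).any():
        raise ValueError("percent identity must lie in [0, 100]")
    return df


def validate_associations(
    candidates: pd.DataFrame,
    alignments: pd.DataFrame,
    subject_genus: dict[str, str],
    min_len: int = 3000,
    min_ident: float = 80.0,
) -> list[HostPhageAssociation]:
    """Validate candidate (genus, phage) pairs against genome alignments.

    A pair is validated iff some alignment of the phage against a genome
    of that genus has length >= ``min_len`` ("at least 3 kb") and
    identity strictly > ``min_ident`` ("above 80%"): length 3000 passes,
    identity exactly 80.0 fails. The best alignment (longest, then most
    identical) is retained either way; phages with no alignment rows are
    unvalidated.

    ``candidates`` needs columns genus, phage_id, log2_fc, p_adj;
    ``subject_genus`` maps alignment subject ids to genus taxa.
    """
    aln = alignments.copy()
    aln["genus"] = aln["sseqid"].map(subject_genus)
    out: list[HostPhageAssociation] = []
    for row in candidates.itertuples(index=False):
        rel = aln[(aln["qseqid"] == row.phage_id) & (aln["genus"] == row.genus)]
        if rel.empty:
            out.append(
                HostPhageAssociation(row.genus, row.phage_id, row.log2_fc,
                                     row.p_adj, False, 0, 0.0)
            )
            continue
        best = rel.sort_values(by=["length", "pident"], ascending=False).iloc[0]
        passing = (rel["length"] >= min_len) & (rel["pident"] > min_ident)
        out.append(
            HostPhageAssociation(
                row.genus, row.phage_id, row.log2_fc, row.p_adj,
                bool(passing.any()), int(best["length"]), float(best["pident"]),
            )
        )
    return out


def associations_table(assocs: Iterable[HostPhageAssociation]) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.genus, a.phage_id, a.log2_fc, a.p_adj, a.validated, a.best_length, a.best_identity)
         for a in assocs],
        columns=["genus", "phage_id", "log2_fc", "p_adj", "validated", "best_len", "best_ident"],
    )


# ---------------------------------------------------------------------------
# per-genus phage read statistics
# ---------------------------------------------------------------------------

def phage_read_stats(
    cell_table: pd.DataFrame,
    phage_assignments: pd.DataFrame,
) -> pd.DataFrame:
    """Per-genus phage detection summary.

    ``cell_table`` needs columns cell_id, genus, n_reads (total reads in
    the cell); ``phage_assignments`` is the read-level table
    (cell_id, feature_id, umi). Reports mean phages detected per cell
    and the mean per-cell fraction of reads assigned to phages.
    """
    if phage_assignments.empty:
        per_cell = pd.DataFrame(columns=["cell_id", "n_phages", "phage_reads"])
    else:
        per_cell = (
            phage_assignments.groupby("cell_id")
            .agg(n_phages=("feature_id", "nunique"), phage_reads=("umi", "size"))
            .reset_index()
        )
    merged = cell_table.merge(per_cell, on="cell_id", how="left").fillna(
        {"n_phages": 0, "phage_reads": 0}
    )
    merged["phage_read_fraction"] = np.clip(
        merged["phage_reads"] / merged["n_reads"].clip(lower=1), 0.0, 1.0
    )
    return (
        merged.groupby("genus")
        .agg(
            n_cells=("cell_id", "size"),
            mean_phages_per_cell=("n_phages", "mean"),
            mean_phage_read_fraction=("phage_read_fraction", "mean"),
        )
        .reset_index()
    )
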