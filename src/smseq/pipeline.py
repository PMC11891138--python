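"""End-to-end orchestration: extract -> anno -> bac -> phage.

Each stage exists twice: an in-memory function operating on parsed
objects (used by tests and the simulator loop) and the file-based
``run_pipeline`` driver that loads the standard formats, runs the stages
in order, writes every stage's outputs before the next starts, and
emits a run report with a read-conservation ledger.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import __version__
from .anno import annotate_cells, classify_read
from .bac import (
    assign_reads,
    build_matrix,
    cluster_cells,
    filter_species,
    find_markers,
    gene_sequences,
    read_gene_models,
)
from .kmer import FeatureKmerIndex, KmerIndex, read_fasta, taxon_from_header
from .phage import (
    associations_table,
    build_containment_set,
    filter_rrna_trna,
    genus_phage_markers,
    phage_read_stats,
    read_blast6,
    select_top_phages,
    validate_associations,
)
from .readproc import (
    CellUnit,
    ReadStructure,
    build_cell_units,
    call_cells,
    count_barcodes,
    extract_read,
    load_whitelist,
    merge_barcodes,
    read_fastq_pairs,
    trim_artifacts,
)
from .taxonomy import TaxonomyTree


@dataclass
class PipelineConfig:
    """Validated run configuration; unknown keys are rejected on load."""

    r1: str
    r2: str
    whitelist: str
    ref_fasta: str
    taxonomy_tsv: str
    genes_gff: str
    outdir: str
    seed: int = 0
    phage_fasta: str | None = None
    rrna_fasta: str | None = None
    alignments_tsv: str | None = None
    barcode_len: int = 20
    umi_len: int = 8
    preindex_mm: int = 1
    max_bc_dist: int = 2
    min_tail_run: int = 6
    k: int = 21
    min_hits: int = 1
    min_hit_frac: float = 0.5
    min_frac: float = 0.03
    keep_all_species: bool = False
    n_pcs: int = 20
    n_neighbors: int = 15
    resolution: float = 0.5
    logfc: float = 0.1
    min_pct: float = 0.1
    top_k: int = 20
    min_len: int = 3000
    min_ident: float = 80.0
    max_containment: float = 0.2
    unassigned_policy: str = "drop"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        missing = {k for k in ("r1", "r2", "whitelist", "ref_fasta",
                               "taxonomy_tsv", "genes_gff", "outdir")} - set(raw)
        if missing:
            raise ValueError(f"missing required config keys: {sorted(missing)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# stage 1: extraction / cell calling
# ---------------------------------------------------------------------------

@dataclass
class ExtractResult:
    units: list[CellUnit]
    knee_threshold: int
    n_input: int
    n_dropped_extract: int
    n_dropped_trim: int
    n_discarded: int
    n_unassigned_preindex: int
    n_accepted_barcodes: int
    merge_map: dict[str, str] = field(repr=False, default_factory=dict)

    @property
    def ledger(self) -> dict[str, int]:
        in_cells = sum(u.n_reads for u in self.units)
        return {
            "input_reads": self.n_input,
            "dropped_extract": self.n_dropped_extract,
            "dropped_trim": self.n_dropped_trim,
            "discarded_barcode": self.n_discarded,
            "dropped_unassigned_preindex": self.n_unassigned_preindex,
            "reads_in_cells": in_cells,
            "balanced": in_cells
            + self.n_dropped_extract
            + self.n_dropped_trim
            + self.n_discarded
            + self.n_unassigned_preindex
            == self.n_input,
        }


def extract_stage(
    pairs: Iterable,
    rs: ReadStructure,
    max_bc_dist: int = 2,
    min_tail_run: int = 6,
    unassigned_policy: str = "drop",
) -> ExtractResult:
    n_input = 0
    n_drop_extract = 0
    n_drop_trim = 0
    extracted = []
    for pair in pairs:
        n_input += 1
        er = extract_read(pair, rs)
        if er is None:
            n_drop_extract += 1
            continue
        cdna = trim_artifacts(er.cdna, min_tail_run=min_tail_run)
        if not cdna:
            n_drop_trim += 1
            continue
        if cdna != er.cdna:
            er = type(er)(er.read_id, er.raw_barcode, er.umi, er.preindex_id, cdna)
        extracted.append(er)
    bc = count_barcodes(extracted)
    accepted, knee = call_cells(bc)
    merge_map = merge_barcodes(bc, accepted, max_dist=max_bc_dist)
    units, n_discard, n_unassigned = build_cell_units(
        extracted, merge_map, unassigned_policy=unassigned_policy
    )
    return ExtractResult(
        units=units,
        knee_threshold=knee,
        n_input=n_input,
        n_dropped_extract=n_drop_extract,
        n_dropped_trim=n_drop_trim,
        n_discarded=n_discard,
        n_unassigned_preindex=n_unassigned,
        n_accepted_barcodes=len(accepted),
        merge_map=merge_map,
    )


# ---------------------------------------------------------------------------
# stage 2: taxonomic annotation
# ---------------------------------------------------------------------------

def anno_stage(
    units: list[CellUnit],
    index: KmerIndex,
    tree: TaxonomyTree,
    min_hits: int = 1,
) -> pd.DataFrame:
    per_cell = {
        u.cell_id: [classify_read(r.cdna, index, tree, min_hits=min_hits) for r in u.reads]
        for u in units
    }
    return annotate_cells(per_cell, tree)


# ---------------------------------------------------------------------------
# stage 3: expression matrix / clustering / markers
# ---------------------------------------------------------------------------

def bac_stage(
    units: list[CellUnit],
    gene_index: FeatureKmerIndex,
    gene_meta: pd.DataFrame,
    anno: pd.DataFrame,
    min_hit_frac: float = 0.5,
    min_frac: float = 0.03,
    keep_all: bool = False,
    n_pcs: int = 20,
    n_neighbors: int = 15,
    resolution: float = 0.5,
    logfc: float = 0.1,
    min_pct: float = 0.1,
    seed: int = 0,
) -> dict:
    reads = [(u.cell_id, r.umi, r.cdna) for u in units for r in u.reads]
    assignments = assign_reads(reads, gene_index, min_hit_frac=min_hit_frac)
    cell_meta = anno.set_index("cell_id")[
        [c for c in ("species_taxon", "genus_taxon", "purity_species", "purity_genus") if c in anno]
    ].rename(columns={"species_taxon": "species", "genus_taxon": "genus"})
    adata = build_matrix(assignments, cell_meta=cell_meta, feature_meta=gene_meta)
    result: dict = {"assignments": assignments, "matrix": adata}
    if "species" in adata.obs:
        annotated = adata[adata.obs["species"].notna().values].copy()
        filtered = filter_species(annotated, min_frac=min_frac, keep_all=keep_all)
    else:
        filtered = adata.copy()
    result["filtered"] = filtered
    if filtered.n_obs >= 3:
        labels = cluster_cells(
            filtered, n_pcs=n_pcs, n_neighbors=n_neighbors,
            resolution=resolution, seed=seed,
        )
        result["clusters"] = labels
        if len(set(labels)) >= 2:
            result["markers"] = find_markers(
                filtered, labels, logfc_threshold=logfc, min_pct=min_pct
            )
    return result


# ---------------------------------------------------------------------------
# stage 4: host-phage associations
# ---------------------------------------------------------------------------

def phage_stage(
    units: list[CellUnit],
    phage_index: FeatureKmerIndex,
    rrna_kmers: frozenset[str],
    anno: pd.DataFrame,
    alignments: pd.DataFrame,
    subject_genus: dict[str, str],
    k: int = 21,
    max_containment: float = 0.2,
    min_hit_frac: float = 0.5,
    logfc: float = 0.1,
    min_genus_frac: float = 0.03,
    top_k: int = 20,
    min_len: int = 3000,
    min_ident: float = 80.0,
) -> dict:
    reads = [(u.cell_id, r.umi, r.cdna) for u in units for r in u.reads]
    kept = filter_rrna_trna(reads, rrna_kmers, k=k, max_containment=max_containment)
    assignments = assign_reads(kept, phage_index, min_hit_frac=min_hit_frac)
    genus_of = anno.set_index("cell_id")["genus_taxon"] if "genus_taxon" in anno else pd.Series(dtype=object)
    result: dict = {"n_reads_kept": len(kept), "n_reads_in": len(reads),
                    "assignments": assignments}
    if assignments.empty:
        result["associations"] = associations_table([])
        return result
    adata = build_matrix(assignments, exclude_biotypes=())
    labels = np.asarray([genus_of.get(c) for c in adata.obs_names], dtype=object)
    keep = np.array([l is not None and not pd.isna(l) for l in labels])
    adata, labels = adata[keep].copy(), labels[keep].astype(str)
    result["matrix"] = adata
    try:
        markers = genus_phage_markers(
            adata, labels, logfc_threshold=logfc, min_genus_frac=min_genus_frac
        )
    except ValueError as exc:
        warnings.warn(f"phage marker stage skipped: {exc}", stacklevel=2)
        result["associations"] = associations_table([])
        return result
    result["markers"] = markers
    top = select_top_phages(markers, k=top_k)
    result["top_phages"] = top
    cand_rows = []
    for genus, phage_ids in top.items():
        sub = markers[(markers["genus"] == genus) & (markers["phage_id"].isin(phage_ids))]
        for r in sub.itertuples(index=False):
            cand_rows.append((r.genus, r.phage_id, r.log2_fc, r.p_adj_bonferroni))
    candidates = pd.DataFrame(cand_rows, columns=["genus", "phage_id", "log2_fc", "p_adj"])
    assocs = validate_associations(
        candidates, alignments, subject_genus, min_len=min_len, min_ident=min_ident
    )
    result["associations"] = associations_table(assocs)
    cell_table = pd.DataFrame(
        {
            "cell_id": [u.cell_id for u in units],
            "genus": [genus_of.get(u.cell_id) for u in units],
            "n_reads": [u.n_reads for u in units],
        }
    ).dropna(subset=["genus"])
    result["read_stats"] = phage_read_stats(cell_table, assignments)
    return result


# ---------------------------------------------------------------------------
# file-based driver
# ---------------------------------------------------------------------------

def _genus_of_genome(ref_fasta, tree: TaxonomyTree) -> dict[str, str]:
    mapping = {}
    for header, _ in read_fasta(ref_fasta):
        seqid = header.split()[0].rsplit("|", 1)[0]
        taxon = taxon_from_header(header)
        mapping[seqid] = tree.ancestor_at_rank(taxon, "genus") or taxon
    return mapping


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage in order, writing outputs and a JSON run report."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("r1", "r2", "whitelist", "ref_fasta", "taxonomy_tsv", "genes_gff"):
        p = getattr(cfg, name)
        if not Path(p).exists():
            raise FileNotFoundError(f"input {name} not found: {p}")

    rs = ReadStructure(
        barcode_len=cfg.barcode_len,
        umi_len=cfg.umi_len,
        preindex_whitelist=load_whitelist(cfg.whitelist),
        preindex_max_mismatch=cfg.preindex_mm,
    )
    extract = extract_stage(
        read_fastq_pairs(cfg.r1, cfg.r2), rs,
        max_bc_dist=cfg.max_bc_dist, min_tail_run=cfg.min_tail_run,
        unassigned_policy=cfg.unassigned_policy,
    )
    cells_df = pd.DataFrame(
        {
            "cell_id": [u.cell_id for u in extract.units],
            "n_reads": [u.n_reads for u in extract.units],
            "n_raw_barcodes": [len(u.member_barcodes) for u in extract.units],
        }
    )
    cells_df.to_csv(out / "cells.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(u.cell_id, r.read_id, r.umi) for u in extract.units for r in u.reads],
        columns=["cell_id", "read_id", "umi"],
    ).to_csv(out / "read_assignment.tsv", sep="\t", index=False)

    tree = TaxonomyTree.read_tsv(cfg.taxonomy_tsv)
    index = KmerIndex.from_fasta(cfg.ref_fasta, tree, k=cfg.k)
    anno = anno_stage(extract.units, index, tree, min_hits=cfg.min_hits)
    anno.to_csv(out / "annotation.tsv", sep="\t", index=False)

    references = {h.split()[0].rsplit("|", 1)[0]: s for h, s in read_fasta(cfg.ref_fasta)}
    genes = read_gene_models(cfg.genes_gff)
    gene_index = FeatureKmerIndex.build(gene_sequences(genes, references), k=cfg.k)
    gene_meta = pd.DataFrame(
        {"taxon_id": [g.taxon_id for g in genes], "biotype": [g.biotype for g in genes]},
        index=pd.Index([g.gene_id for g in genes], name="feature_id"),
    )
    bac = bac_stage(
        extract.units, gene_index, gene_meta, anno,
        min_hit_frac=cfg.min_hit_frac, min_frac=cfg.min_frac,
        keep_all=cfg.keep_all_species, n_pcs=cfg.n_pcs,
        n_neighbors=cfg.n_neighbors, resolution=cfg.resolution,
        logfc=cfg.logfc, min_pct=cfg.min_pct, seed=cfg.seed,
    )
    _write_matrix(bac["filtered"], out / "matrix")
    if "clusters" in bac:
        pd.DataFrame(
            {"cell_id": list(bac["filtered"].obs_names), "cluster": bac["clusters"]}
        ).to_csv(out / "clusters.tsv", sep="\t", index=False)
    if "markers" in bac:
        bac["markers"].to_csv(out / "markers.tsv", sep="\t", index=False)

    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": asdict(cfg),
        "ledger": extract.ledger,
        "knee_threshold": extract.knee_threshold,
        "n_cells": len(extract.units),
        "n_cells_filtered": int(bac["filtered"].n_obs),
    }

    if cfg.phage_fasta and cfg.rrna_fasta and cfg.alignments_tsv:
        phages = [(h.split()[0], s) for h, s in read_fasta(cfg.phage_fasta)]
        phage_index = FeatureKmerIndex.build(phages, k=cfg.k)
        rrna_kmers = build_containment_set(
            [s for _, s in read_fasta(cfg.rrna_fasta)], k=cfg.k
        )
        phage = phage_stage(
            extract.units, phage_index, rrna_kmers, anno,
            read_blast6(cfg.alignments_tsv), _genus_of_genome(cfg.ref_fasta, tree),
            k=cfg.k, max_containment=cfg.max_containment,
            min_hit_frac=cfg.min_hit_frac, logfc=cfg.logfc,
            min_genus_frac=cfg.min_frac, top_k=cfg.top_k,
            min_len=cfg.min_len, min_ident=cfg.min_ident,
        )
        phage["associations"].to_csv(out / "associations.tsv", sep="\t", index=False)
        if "read_stats" in phage:
            phage["read_stats"].to_csv(out / "phage_read_stats.tsv", sep="\t", index=False)
        report["n_associations_validated"] = int(phage["associations"]["validated"].sum())

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


def _write_matrix(adata, prefix: Path) -> None:
    from scipy.io import mmwrite

    prefix.parent.mkdir(parents=True, exist_ok=True)
    mmwrite(str(prefix) + ".mtx", adata.X)
    pd.Series(adata.obs_names).to_csv(str(prefix) + "_barcodes.tsv", sep="\t",
                                      index=False, header=False)
    pd.Series(adata.var_names).to_csv(str(prefix) + "_features.tsv", sep="\t",
                                      index=False, header=False)


def summarize(run_dir) -> dict:
    """Recompute headline metrics from a run directory's outputs."""
    run = Path(run_dir)
    out: dict = {"warnings": []}
    cells_path = run / "cells.tsv"
    if cells_path.exists():
        cells = pd.read_csv(cells_path, sep="\t")
        out["n_cells"] = int(len(cells))
        out["median_reads_per_cell"] = float(cells["n_reads"].median())
    else:
        out["warnings"].append("cells.tsv missing")
    anno_path = run / "annotation.tsv"
    if anno_path.exists():
        anno = pd.read_csv(anno_path, sep="\t")
        if "species_taxon" in anno:
            out["n_species"] = int(anno["species_taxon"].nunique())
    else:
        out["warnings"].append("annotation.tsv missing")
    mtx_path = run / "matrix.mtx"
    if mtx_path.exists():
        from scipy.io import mmread

        X = mmread(str(mtx_path)).tocsr()
        out["median_genes_per_cell"] = float(np.median(np.asarray((X > 0).sum(axis=1)).ravel()))
        out["median_umis_per_cell"] = float(np.median(np.asarray(X.sum(axis=1)).ravel()))
    else:
        out["warnings"].append("matrix.mtx missing")
    assoc_path = run / "associations.tsv"
    if assoc_path.exists():
        assoc = pd.read_csv(assoc_path, sep="\t")
        out["n_associations"] = int(len(assoc))
        out["n_associations_validated"] = int(assoc["validated"].sum())
    return out
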