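"""MIC-Bac: single-microbe gene expression matrix and downstream analysis.

Reads are pseudo-assigned to genes by canonical k-mer hits with a
uniqueness rule (a read counts only when exactly one gene wins), PCR
duplicates are collapsed per (cell, gene) with the directional UMI
network, and the resulting sparse cells x genes UMI matrix feeds the
abundance filter, clustering, marker-gene, co-occurrence and saturation
analyses.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import spearmanr

from .kmer import FeatureKmerIndex, revcomp
from .readproc import hamming
from .stats import benjamini_hochberg, bonferroni, wilcoxon_test

AMBIGUOUS = "*AMBIGUOUS*"
UNASSIGNED = "*UNASSIGNED*"


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    taxon_id: str
    seqid: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    name: str = ""
    biotype: str = "CDS"


_ATTR_RE = re.compile(r"(\w+)[=\s]\"?([^;\"]+)\"?")


def read_gene_models(path) -> list[GeneModel]:
    """Parse a GFF3-like gene table (attributes carry gene_id/taxon_id/biotype)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise ValueError(f"malformed gene row: {line!r}")
            attrs = dict(_ATTR_RE.findall(f[8]))
            genes.append(
                GeneModel(
                    gene_id=attrs["gene_id"],
                    taxon_id=attrs.get("taxon_id", ""),
                    seqid=f[0],
                    start=int(f[3]),
                    end=int(f[4]),
                    strand=f[6],
                    name=attrs.get("gene_name", attrs["gene_id"]),
                    biotype=attrs.get("biotype", f[2] if f[2] != "gene" else "CDS"),
                )
            )
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene_id in gene models")
    return genes


def write_gene_models(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"gene_id={g.gene_id};taxon_id={g.taxon_id};biotype={g.biotype};gene_name={g.name}"
            fh.write(
                f"{g.seqid}\tsmseq\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def gene_sequences(
    genes: Iterable[GeneModel], references: dict[str, str]
) -> list[tuple[str, str]]:
    """(gene_id, spliced sequence) for the feature k-mer index."""
    out = []
    for g in genes:
        ref = references[g.seqid]
        if not (1 <= g.start <= g.end <= len(ref)):
            raise ValueError(f"gene {g.gene_id} outside reference bounds")
        seq = ref[g.start - 1 : g.end]
        if g.strand == "-":
            seq = revcomp(seq)
        out.append((g.gene_id, seq))
    return out


# ---------------------------------------------------------------------------
# read -> gene assignment
# ---------------------------------------------------------------------------

def assign_gene(
    cdna: str, gene_index: FeatureKmerIndex, min_hit_frac: float = 0.5
) -> str:
    """Unique-best k-mer pseudo-assignment.

    The read is assigned when exactly one feature attains the maximal
    hit count and that count covers at least ``min_hit_frac`` of the
    read's k-mers; multiple maxima are AMBIGUOUS (discarded downstream,
    preserving unique-mapping semantics).
    """
    counts, n_kmers = gene_index.hit_counts(cdna)
    if not counts or n_kmers == 0:
        return UNASSIGNED
    best = max(counts.values())
    winners = [f for f, c in counts.items() if c == best]
    if len(winners) > 1:
        return AMBIGUOUS
    if best < min_hit_frac * n_kmers:
        return UNASSIGNED
    return winners[0]


def assign_reads(
    reads: Iterable[tuple[str, str, str]],
    gene_index: FeatureKmerIndex,
    min_hit_frac: float = 0.5,
) -> pd.DataFrame:
    """Read-level assignment table from (cell_id, umi, cdna) triples.

    One row per uniquely assigned read: cell_id, feature_id, umi.
    """
    rows = []
    for cell_id, umi, cdna in reads:
        g = assign_gene(cdna, gene_index, min_hit_frac=min_hit_frac)
        if g not in (AMBIGUOUS, UNASSIGNED):
            rows.append((cell_id, g, umi))
    return pd.DataFrame(rows, columns=["cell_id", "feature_id", "umi"])


# ---------------------------------------------------------------------------
# UMI deduplication (directional network collapse)
# ---------------------------------------------------------------------------

def dedup_umis(umi_counts: dict[str, int]) -> int:
    """Molecule count for one (cell, gene) bucket.

    Directed edge u -> v when Hamming(u, v) = 1 and
    count(u) >= 2 * count(v) - 1; clusters grow greedily from the
    highest-count unabsorbed UMI (ties: lexicographic), absorbing
    transitively. The molecule count is the number of cluster seeds.
    """
    if not umi_counts:
        return 0
    order = sorted(umi_counts, key=lambda u: (-umi_counts[u], u))
    absorbed: set[str] = set()
    n_clusters = 0
    for seed in order:
        if seed in absorbed:
            continue
        n_clusters += 1
        stack = [seed]
        absorbed.add(seed)
        while stack:
            u = stack.pop()
            cu = umi_counts[u]
            for v in order:
                if v in absorbed:
                    continue
                if hamming(u, v) == 1 and cu >= 2 * umi_counts[v] - 1:
                    absorbed.add(v)
                    stack.append(v)
    return n_clusters


# ---------------------------------------------------------------------------
# matrix construction
# ---------------------------------------------------------------------------

def build_matrix(
    assignments: pd.DataFrame,
    cell_meta: pd.DataFrame | None = None,
    feature_meta: pd.DataFrame | None = None,
    exclude_biotypes: Sequence[str] = ("rRNA", "tRNA"),
) -> ad.AnnData:
    """Sparse cells x features UMI-count matrix from read-level assignments.

    Each entry is the directional-dedup molecule count of its
    (cell, feature) bucket. Features whose ``biotype`` metadata is in
    ``exclude_biotypes`` are removed (rRNA/tRNA background by default).
    ``assignments`` is a (cell_id, feature_id, umi) table with one row
    per read — either from :func:`assign_reads` or imported from an
    external aligner/feature-counter tool chain.
    """
    if assignments.empty:
        X = sparse.csr_matrix((0, 0), dtype=np.int64)
        return ad.AnnData(X=X, obs=pd.DataFrame(index=pd.Index([], name="cell_id")),
                          var=pd.DataFrame(index=pd.Index([], name="feature_id")))
    reads_per_umi = (
        assignments.groupby(["cell_id", "feature_id", "umi"], sort=True)
        .size()
        .reset_index(name="n_reads")
    )
    cells = sorted(reads_per_umi["cell_id"].unique())
    feats = sorted(reads_per_umi["feature_id"].unique())
    cell_ix = {c: i for i, c in enumerate(cells)}
    feat_ix = {f: i for i, f in enumerate(feats)}
    rows, cols, vals = [], [], []
    for (cell, feat), grp in reads_per_umi.groupby(["cell_id", "feature_id"], sort=True):
        n = dedup_umis(dict(zip(grp["umi"], grp["n_reads"])))
        rows.append(cell_ix[cell])
        cols.append(feat_ix[feat])
        vals.append(n)
    X = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(cells), len(feats)), dtype=np.int64
    )
    obs = pd.DataFrame(index=pd.Index(cells, name="cell_id"))
    var = pd.DataFrame(index=pd.Index(feats, name="feature_id"))
    if cell_meta is not None:
        obs = obs.join(cell_meta, how="left")
    if feature_meta is not None:
        var = var.join(feature_meta, how="left")
    adata = ad.AnnData(X=X, obs=obs, var=var)
    if exclude_biotypes and "biotype" in adata.var:
        keep = ~adata.var["biotype"].isin(list(exclude_biotypes))
        adata = adata[:, keep.values].copy()
    return adata


def filter_species(
    adata: ad.AnnData,
    min_frac: float = 0.03,
    rank_col: str = "species",
    keep_all: bool = False,
) -> ad.AnnData:
    """Keep cells of abundant taxa only (strictly > ``min_frac`` of cells)."""
    if keep_all:
        return adata.copy()
    if rank_col not in adata.obs:
        raise ValueError(f"cell metadata lacks {rank_col!r}")
    if adata.obs[rank_col].isna().any():
        raise ValueError("every cell must be annotated before filtering")
    frac = adata.obs[rank_col].value_counts(normalize=True)
    abundant = set(frac[frac > min_frac].index)
    mask = adata.obs[rank_col].isin(abundant).values
    if not mask.any():
        raise ValueError(f"no taxon exceeds {min_frac:.0%} of cells; nothing left")
    return adata[mask].copy()


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_cells(
    adata: ad.AnnData,
    n_pcs: int = 20,
    n_neighbors: int = 15,
    resolution: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Standard single-cell clustering: normalise, log1p, PCA, kNN, Leiden."""
    import scanpy as sc

    if adata.n_obs < 2:
        raise ValueError("clustering requires at least 2 cells")
    work = ad.AnnData(X=adata.X.copy(), obs=adata.obs[[]].copy(), var=adata.var[[]].copy())
    if n_neighbors >= work.n_obs:
        warnings.warn(
            f"n_neighbors={n_neighbors} >= n_cells={work.n_obs}; lowering", stacklevel=2
        )
        n_neighbors = max(2, work.n_obs - 1)
    n_pcs = min(n_pcs, work.n_obs - 1, work.n_vars - 1)
    sc.pp.normalize_total(work, target_sum=1e4)
    sc.pp.log1p(work)
    sc.pp.pca(work, n_comps=n_pcs, random_state=seed)
    sc.pp.neighbors(work, n_neighbors=n_neighbors, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        sc.tl.leiden(
            work, resolution=resolution, random_state=seed, flavor="leidenalg",
            key_added="cluster",
        )
    return work.obs["cluster"].astype(str).to_numpy()


# ---------------------------------------------------------------------------
# marker genes
# ---------------------------------------------------------------------------

def _normalized(adata: ad.AnnData, target_sum: float = 1e4) -> np.ndarray:
    X = adata.X.toarray() if sparse.issparse(adata.X) else np.asarray(adata.X, float)
    totals = X.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return X / totals * target_sum


def find_markers(
    adata: ad.AnnData,
    labels: Sequence[str],
    logfc_threshold: float = 0.1,
    min_pct: float = 0.1,
) -> pd.DataFrame:
    """One-group-vs-rest marker detection.

    Per feature and group: two-sided Wilcoxon rank-sum on
    depth-normalised expression (exact for group sizes <= 8, else
    tie-corrected normal approximation), log2 fold change of
    pseudocounted normalised means, Bonferroni over the tests actually
    performed. Features failing the |log2FC| or detection-fraction
    screens are skipped before correction.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != adata.n_obs:
        raise ValueError("labels length must match number of cells")
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValueError("marker detection requires at least 2 groups")
    norm = _normalized(adata)
    feats = list(adata.var_names)
    rows = []
    for g in groups:
        mask = labels == g
        inn, out = norm[mask], norm[~mask]
        for j, feat in enumerate(feats):
            a, b = inn[:, j], out[:, j]
            pct_in = float(np.mean(a > 0))
            pct_out = float(np.mean(b > 0))
            log2_fc = float(np.log2((a.mean() + 1.0) / (b.mean() + 1.0)))
            if abs(log2_fc) < logfc_threshold:
                continue
            if max(pct_in, pct_out) < min_pct:
                continue
            p = wilcoxon_test(a, b)
            rows.append((feat, g, log2_fc, p, pct_in, pct_out))
    table = pd.DataFrame(
        rows, columns=["feature", "group", "log2_fc", "p_value", "pct_in", "pct_out"]
    )
    table["p_adj_bonferroni"] = bonferroni(table["p_value"]) if len(table) else []
    return table


def cooccurrence(
    adata: ad.AnnData,
    geneset_a: Sequence[str],
    geneset_b: Sequence[str],
) -> pd.DataFrame:
    """Pairwise Spearman co-occurrence between two gene sets.

    Correlations are computed on depth-normalised expression across the
    given cells; P-values are BH-adjusted across all pairs. Genes with
    constant raw counts carry no co-occurrence signal: their rho is NaN
    and the pair is flagged.
    """
    missing = (set(geneset_a) | set(geneset_b)) - set(adata.var_names)
    if missing:
        raise ValueError(f"genes absent from matrix: {sorted(missing)[:5]}")
    raw = adata.X.toarray() if sparse.issparse(adata.X) else np.asarray(adata.X, float)
    norm = _normalized(adata)
    col = {g: i for i, g in enumerate(adata.var_names)}
    rows = []
    for ga in geneset_a:
        for gb in geneset_b:
            a, b = norm[:, col[ga]], norm[:, col[gb]]
            if np.ptp(raw[:, col[ga]]) == 0 or np.ptp(raw[:, col[gb]]) == 0:
                rows.append((ga, gb, np.nan, np.nan, True))
                continue
            if ga == gb:
                rows.append((ga, gb, 1.0, 0.0, False))
                continue
            rho, p = spearmanr(a, b)
            rows.append((ga, gb, float(rho), float(p), False))
    table = pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "rho", "p_value", "zero_variance"]
    )
    ok = ~table["p_value"].isna()
    table["p_adj"] = np.nan
    if ok.any():
        table.loc[ok, "p_adj"] = benjamini_hochberg(table.loc[ok, "p_value"])
    return table


# ---------------------------------------------------------------------------
# saturation
# ---------------------------------------------------------------------------

def saturation_curve(
    assignments: pd.DataFrame,
    fractions: Sequence[float] = (0.1, 0.25, 0.5, 0.75, 1.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Median genes and UMIs per cell at read subsampling fractions.

    Reads (rows of the assignment table) are subsampled without
    replacement at each fraction with a fixed seed and the matrix is
    rebuilt downstream of assignment.
    """
    for f in fractions:
        if not (0 < f <= 1):
            raise ValueError(f"fractions must lie in (0, 1], got {f}")
    rng = np.random.default_rng(seed)
    n = len(assignments)
    rows = []
    for f in sorted(fractions):
        take = n if f == 1.0 else int(round(f * n))
        idx = rng.choice(n, size=take, replace=False)
        sub = assignments.iloc[np.sort(idx)]
        adata = build_matrix(sub, exclude_biotypes=())
        if adata.n_obs == 0:
            rows.append((f, 0.0, 0.0))
            continue
        X = adata.X
        genes_per_cell = np.asarray((X > 0).sum(axis=1)).ravel()
        umis_per_cell = np.asarray(X.sum(axis=1)).ravel()
        rows.append((f, float(np.median(genes_per_cell)), float(np.median(umis_per_cell))))
    return pd.DataFrame(rows, columns=["fraction", "median_genes_per_cell", "median_umis_per_cell"])
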