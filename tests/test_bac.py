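"""Gene assignment, UMI dedup, matrix construction, and marker analysis."""

from __future__ import annotations

import anndata as ad
import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from smseq.bac import (
    AMBIGUOUS,
    UNASSIGNED,
    assign_gene,
    build_matrix,
    cluster_cells,
    cooccurrence,
    dedup_umis,
    filter_species,
    find_markers,
    saturation_curve,
)
from smseq.kmer import FeatureKmerIndex
from smseq.readproc import hamming


class TestAssignGene:
    def _index(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        self.g1 = "".join(rng.choice(bases, size=120))
        self.g2 = "".join(rng.choice(bases, size=120))
        return FeatureKmerIndex.build([("g1", self.g1), ("g2", self.g2)], k=21)

    def test_read_inside_gene(self):
        idx = self._index()
        assert assign_gene(self.g1[10:90], idx) == "g1"

    def test_equal_overlap_is_ambiguous(self):
        idx = self._index()
        read = self.g1[80:120] + self.g2[0:40]
        assert assign_gene(read, idx) == AMBIGUOUS

    def test_foreign_read_unassigned(self):
        idx = self._index()
        rng = np.random.default_rng(99)
        read = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 80)])
        assert assign_gene(read, idx) == UNASSIGNED

    def test_simulated_reads_assign_correctly(self, bundle, gene_index):
        """Error-free reads from known genes assign uniquely >= 99% of the time."""
        truth = bundle.truth_reads
        gene_reads = truth[truth.category == "gene"].head(2000)
        id_to_read = {rp.read_id: rp for rp in bundle.read_pairs}
        correct = total = 0
        for row in gene_reads.itertuples(index=False):
            cdna = id_to_read[row.read_id].seq2[6:]
            got = assign_gene(cdna, gene_index)
            total += 1
            correct += got == row.feature_id
        assert correct / total >= 0.99


def oracle_dedup(umi_counts: dict[str, int]) -> int:
    """Connected-absorption oracle on the explicit directional graph."""
    g = nx.DiGraph()
    g.add_nodes_from(umi_counts)
    for u in umi_counts:
        for v in umi_counts:
            if u != v and hamming(u, v) == 1 and umi_counts[u] >= 2 * umi_counts[v] - 1:
                g.add_edge(u, v)
    claimed: set[str] = set()
    seeds = 0
    for u in sorted(umi_counts, key=lambda x: (-umi_counts[x], x)):
        if u in claimed:
            continue
        seeds += 1
        # absorb everything reachable through still-unclaimed nodes
        frontier = [u]
        claimed.add(u)
        while frontier:
            node = frontier.pop()
            for nxt in g.successors(node):
                if nxt not in claimed:
                    claimed.add(nxt)
                    frontier.append(nxt)
    return seeds


class TestDedupUmis:
    def test_classic_error_collapse(self):
        assert dedup_umis({"AAAAAAAA": 10, "AAAAAAAT": 1}) == 1

    def test_distant_umis_stay_separate(self):
        assert dedup_umis({"AAAAAAAA": 5, "TTTTTTTT": 5}) == 2

    def test_count_condition_blocks_absorption(self):
        # 2*5-1 = 9 > 8: the neighbour is too abundant to be an error
        assert dedup_umis({"AAAAAAAA": 8, "AAAAAAAT": 5}) == 2

    def test_empty(self):
        assert dedup_umis({}) == 0

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_absorption_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 13))
        # short alphabet-2 UMIs make Hamming-1 neighbours common
        umis = {"".join(np.array(list("AT"))[rng.integers(0, 2, 4)]): 0 for _ in range(n)}
        counts = {u: int(rng.integers(1, 30)) for u in umis}
        assert dedup_umis(counts) == oracle_dedup(counts)


class TestBuildMatrix:
    def test_empty_input(self):
        m = build_matrix(pd.DataFrame(columns=["cell_id", "feature_id", "umi"]))
        assert m.shape == (0, 0)

    def test_distinct_umis_count_separately(self):
        df = pd.DataFrame(
            {"cell_id": ["c"] * 3, "feature_id": ["g"] * 3,
             "umi": ["AAAAAAAA", "CCCCCCCC", "GGGGGGGG"]}
        )
        m = build_matrix(df, exclude_biotypes=())
        assert m.X.toarray().tolist() == [[3]]

    def test_rrna_features_excluded_by_default(self):
        df = pd.DataFrame(
            {"cell_id": ["c", "c"], "feature_id": ["g1", "g2"],
             "umi": ["AAAAAAAA", "CCCCCCCC"]}
        )
        meta = pd.DataFrame({"biotype": ["CDS", "rRNA"]},
                            index=pd.Index(["g1", "g2"], name="feature_id"))
        m = build_matrix(df, feature_meta=meta)
        assert list(m.var_names) == ["g1"]

    def test_total_invariant_under_reordering(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "cell_id": rng.choice(["c1", "c2", "c3"], 200),
                "feature_id": rng.choice(["g1", "g2"], 200),
                "umi": ["".join(np.array(list("ACGT"))[rng.integers(0, 4, 8)]) for _ in range(200)],
            }
        )
        m1 = build_matrix(df, exclude_biotypes=())
        m2 = build_matrix(df.sample(frac=1, random_state=0), exclude_biotypes=())
        assert m1.X.sum() == m2.X.sum()

    def test_dedup_bounded_by_distinct_umis_and_reads(self, bundle, extract_result, gene_index):
        from smseq.bac import assign_reads

        reads = [(u.cell_id, r.umi, r.cdna) for u in extract_result.units[:30] for r in u.reads]
        a = assign_reads(reads, gene_index)
        m = build_matrix(a, exclude_biotypes=())
        per_bucket = a.groupby(["cell_id", "feature_id"]).agg(
            distinct=("umi", "nunique"), reads=("umi", "size")
        )
        X = m.X.toarray()
        for (cell, feat), row in per_bucket.iterrows():
            v = X[list(m.obs_names).index(cell), list(m.var_names).index(feat)]
            assert v <= row.distinct <= row.reads


class TestFilterSpecies:
    def _matrix(self, species: list[str]) -> ad.AnnData:
        n = len(species)
        return ad.AnnData(
            X=sparse.csr_matrix(np.ones((n, 2))),
            obs=pd.DataFrame({"species": species},
                             index=[f"c{i}" for i in range(n)]),
        )

    def test_three_percent_boundary_is_strict(self):
        species = ["s1"] * 97 + ["s2"] * 3  # exactly 3%: not > 3%
        out = filter_species(self._matrix(species))
        assert set(out.obs["species"]) == {"s1"}
        species = ["s1"] * 96 + ["s2"] * 4
        out = filter_species(self._matrix(species))
        assert set(out.obs["species"]) == {"s1", "s2"}

    def test_keep_all_is_identity(self):
        m = self._matrix(["s1"] * 99 + ["s2"])
        out = filter_species(m, keep_all=True)
        assert out.shape == m.shape

    def test_all_removed_raises(self):
        m = self._matrix(["s%d" % i for i in range(50)])
        with pytest.raises(ValueError, match="nothing left"):
            filter_species(m, min_frac=0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_direct_proportion_filter(self, seed):
        rng = np.random.default_rng(seed)
        species = [f"s{int(i)}" for i in rng.integers(0, 8, size=200)]
        m = self._matrix(species)
        out = filter_species(m, min_frac=0.05)
        frac = pd.Series(species).value_counts(normalize=True)
        expected = {s for s in species if frac[s] > 0.05}
        assert set(out.obs["species"]) == expected


class TestClusterAndMarkers:
    def test_duplicated_cell_forms_one_cluster(self):
        X = np.tile([5, 0, 2, 0, 1], (50, 1))
        adata = ad.AnnData(X=sparse.csr_matrix(X.astype(float)))
        labels = cluster_cells(adata, n_pcs=2, n_neighbors=5, seed=0)
        assert len(set(labels)) == 1

    def test_two_separated_groups_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(8, size=(40, 10))
        b = rng.poisson(8, size=(40, 10))
        X = np.zeros((80, 20))
        X[:40, :10], X[40:, 10:] = a, b
        adata = ad.AnnData(X=sparse.csr_matrix(X.astype(float)))
        labels = cluster_cells(adata, n_pcs=5, n_neighbors=10, seed=0)
        from sklearn.metrics import adjusted_rand_score

        truth = [0] * 40 + [1] * 40
        assert adjusted_rand_score(truth, labels) >= 0.95

    def test_markers_worked_example_p(self):
        # feature 0 takes values {1,2,3} vs {10,11,12}; a complementary
        # feature keeps library sizes equal so ranks survive normalisation
        v = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        X = np.column_stack([v, 20 - v])
        adata = ad.AnnData(X=sparse.csr_matrix(X))
        t = find_markers(adata, ["a", "a", "a", "b", "b", "b"],
                         logfc_threshold=0.0, min_pct=0.0)
        row = t[(t.group == "b") & (t.feature == "0")].iloc[0]
        assert row.p_value == pytest.approx(0.1)
        assert row.p_adj_bonferroni == pytest.approx(min(1.0, 0.1 * len(t)))

    def test_identical_groups_give_p_one_and_zero_fc(self):
        X = np.array([[4.0], [4.0], [4.0], [4.0]])
        adata = ad.AnnData(X=sparse.csr_matrix(X))
        t = find_markers(adata, ["a", "a", "b", "b"], logfc_threshold=0.0, min_pct=0.0)
        assert (t.p_value == 1.0).all() and (t.log2_fc == 0.0).all()

    def test_logfc_threshold_screens_rows(self):
        rng = np.random.default_rng(4)
        X = rng.poisson(5, size=(30, 8)).astype(float)
        adata = ad.AnnData(X=sparse.csr_matrix(X))
        labels = ["a"] * 15 + ["b"] * 15
        t = find_markers(adata, labels, logfc_threshold=0.3, min_pct=0.0)
        assert (t.log2_fc.abs() >= 0.3).all()


class TestCooccurrence:
    def _adata(self, X):
        return ad.AnnData(X=sparse.csr_matrix(np.asarray(X, dtype=float)),
                          var=pd.DataFrame(index=[f"g{i}" for i in range(np.asarray(X).shape[1])]))

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        adata = self._adata(rng.poisson(5, size=(30, 3)))
        t = cooccurrence(adata, ["g0"], ["g0"])
        assert t.iloc[0].rho == 1.0

    def test_zero_variance_flagged(self):
        X = np.ones((20, 2))
        X[:, 1] = np.arange(20)
        t = cooccurrence(self._adata(X), ["g0"], ["g1"])
        assert bool(t.iloc[0].zero_variance) and np.isnan(t.iloc[0].rho)

    def test_coregulated_pair_detected(self):
        # g0/g1 share a latent factor; a high constant background gene
        # keeps library sizes stable so normalisation preserves the signal
        rng = np.random.default_rng(3)
        latent = rng.gamma(2, 2, size=200)
        X = np.column_stack([
            rng.poisson(latent * 3),
            rng.poisson(latent * 3),
            rng.poisson(5, size=200),
            np.full(200, 1000),
        ])
        t = cooccurrence(self._adata(X), ["g0"], ["g1", "g2"])
        coreg = t[(t.gene_a == "g0") & (t.gene_b == "g1")].iloc[0]
        assert coreg.rho > 0.3 and coreg.p_adj < 0.05

    def test_independent_genes_near_zero_mean_rho(self):
        rhos = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = np.column_stack([
                rng.poisson(5, size=40),
                rng.poisson(5, size=40),
                rng.poisson(1000, size=40),  # library-size noise dominates
            ])
            t = cooccurrence(self._adata(X), ["g0"], ["g1"])
            rhos.append(t.iloc[0].rho)
        assert abs(np.nanmean(rhos)) < 0.05

    def test_missing_gene_raises(self):
        with pytest.raises(ValueError, match="absent"):
            cooccurrence(self._adata(np.ones((5, 2))), ["g0"], ["nope"])


class TestSaturation:
    def _assignments(self, seed=0, n=4000):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "cell_id": [f"c{int(i)}" for i in rng.integers(0, 40, n)],
                "feature_id": [f"g{int(i)}" for i in rng.integers(0, 60, n)],
                "umi": ["".join(np.array(list("ACGT"))[rng.integers(0, 4, 8)]) for _ in range(n)],
            }
        )

    def test_full_fraction_reproduces_matrix(self):
        a = self._assignments()
        t = saturation_curve(a, fractions=[1.0], seed=0)
        m = build_matrix(a, exclude_biotypes=())
        genes = np.median(np.asarray((m.X > 0).sum(axis=1)))
        assert t.iloc[0].median_genes_per_cell == genes

    def test_zero_fraction_rejected(self):
        with pytest.raises(ValueError):
            saturation_curve(self._assignments(), fractions=[0.0], seed=0)

    def test_median_genes_monotone_in_fraction(self):
        a = self._assignments()
        for seed in range(5):
            t = saturation_curve(a, fractions=[0.2, 0.5, 1.0], seed=seed)
            med = t.median_genes_per_cell.to_numpy()
            assert np.all(np.diff(med) >= 0)
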