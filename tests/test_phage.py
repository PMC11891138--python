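"""Host-phage association analysis: filtering, selection, validation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from smseq.phage import (
    BLAST6_COLUMNS,
    associations_table,
    build_containment_set,
    filter_rrna_trna,
    read_blast6,
    rrna_containment,
    select_top_phages,
    validate_associations,
)


def _aln(rows):
    """Alignment frame from (qseqid, sseqid, pident, length) tuples."""
    full = [
        [q, s, p, ln, 0, 0, 1, ln, 1, ln, 1e-9, 2 * ln] for q, s, p, ln in rows
    ]
    return pd.DataFrame(full, columns=BLAST6_COLUMNS)


def _cands(pairs):
    return pd.DataFrame(
        [(g, p, 1.0, 0.01) for g, p in pairs],
        columns=["genus", "phage_id", "log2_fc", "p_adj"],
    )


class TestRrnaFilter:
    def setup_method(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        self.rrna = "".join(rng.choice(bases, size=400))
        self.kmers = build_containment_set([self.rrna], k=21)
        self.rng = rng

    def test_exact_substring_removed(self):
        read = self.rrna[50:130]
        assert rrna_containment(read, self.kmers) == 1.0
        kept = filter_rrna_trna([("c", "u", read)], self.kmers)
        assert kept == []

    def test_unrelated_read_kept(self):
        read = "".join(np.array(list("ACGT"))[self.rng.integers(0, 4, 80)])
        assert rrna_containment(read, self.kmers) == 0.0
        kept = filter_rrna_trna([("c", "u", read)], self.kmers)
        assert len(kept) == 1

    def test_threshold_boundary(self):
        # a read whose containment is exactly the threshold stays
        read = self.rrna[0:30] + "".join(np.array(list("ACGT"))[self.rng.integers(0, 4, 50)])
        c = rrna_containment(read, self.kmers)
        assert 0 < c < 1
        assert filter_rrna_trna([("c", "u", read)], self.kmers, max_containment=c)
        assert not filter_rrna_trna([("c", "u", read)], self.kmers, max_containment=c - 1e-9)

    def test_simulated_rrna_mix_scrubbed(self, bundle, extract_result):
        """An rRNA-heavy read mix drops to a small residual after filtering."""
        truth = bundle.truth_reads.set_index("read_id")["category"]
        reads = [(u.cell_id, r.read_id, r.cdna)
                 for u in extract_result.units[:80] for r in u.reads]
        kmers = build_containment_set(bundle.rrna_sequences, k=21)
        kept = filter_rrna_trna(reads, kmers, k=21)
        frac_before = np.mean([truth[r[1]] == "rrna" for r in reads])
        frac_after = np.mean([truth[r[1]] == "rrna" for r in kept])
        assert frac_before > 0.1
        assert frac_after < 0.05


class TestSelectTop:
    def _markers(self, n_genera=9, n_phages=25, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g in range(n_genera):
            for p in range(n_phages):
                rows.append(
                    (f"phage{g:02d}_{p:02d}", f"g{g}", float(rng.uniform(0.2, 3)),
                     float(rng.uniform(0, 1e-3)), 0.5, 0.01, 1.0,
                     int(rng.integers(1, 5000)))
                )
        return pd.DataFrame(
            rows, columns=["phage_id", "genus", "log2_fc", "p_value", "pct_in",
                           "pct_out", "p_adj_bonferroni", "total_umis"]
        )

    def test_nine_genera_yield_180(self):
        top = select_top_phages(self._markers(), k=20)
        assert sum(len(v) for v in top.values()) == 180
        assert len(top) == 9

    def test_small_genus_keeps_all(self):
        m = self._markers(n_genera=1, n_phages=5)
        top = select_top_phages(m, k=20)
        assert len(top["g0"]) == 5

    def test_negative_markers_excluded(self):
        m = self._markers(n_genera=1, n_phages=10)
        m.loc[m.index[:4], "log2_fc"] = -0.5
        top = select_top_phages(m, k=20)
        assert len(top["g0"]) == 6

    @pytest.mark.parametrize("seed", range(10))
    def test_ranking_matches_brute_force_sort(self, seed):
        m = self._markers(n_genera=3, n_phages=30, seed=seed)
        # force activity ties so secondary keys matter
        m["total_umis"] = m["total_umis"] % 7
        top = select_top_phages(m, k=10)
        for genus, grp in m.groupby("genus"):
            expected = sorted(
                grp.itertuples(index=False),
                key=lambda r: (-r.total_umis, -r.log2_fc, r.phage_id),
            )[:10]
            assert top[genus] == [r.phage_id for r in expected]


class TestValidate:
    def test_default_thresholds_validate(self):
        aln = _aln([("p1", "G1", 85.0, 3500)])
        out = validate_associations(_cands([("gA", "p1")]), aln, {"G1": "gA"})
        assert out[0].validated and out[0].best_length == 3500

    def test_length_bound(self):
        aln = _aln([("p1", "G1", 99.0, 2999)])
        out = validate_associations(_cands([("gA", "p1")]), aln, {"G1": "gA"})
        assert not out[0].validated

    def test_boundary_semantics(self):
        # "at least 3 kb" is inclusive, "above 80%" is strict
        aln = _aln([("p1", "G1", 80.0, 3000)])
        assert not validate_associations(_cands([("gA", "p1")]), aln, {"G1": "gA"})[0].validated
        aln = _aln([("p1", "G1", 80.1, 3000)])
        assert validate_associations(_cands([("gA", "p1")]), aln, {"G1": "gA"})[0].validated

    def test_no_alignment_rows_unvalidated(self):
        out = validate_associations(_cands([("gA", "p1")]), _aln([]), {})
        assert not out[0].validated and out[0].best_length == 0

    def test_wrong_genus_alignment_ignored(self):
        aln = _aln([("p1", "G1", 95.0, 5000)])
        out = validate_associations(_cands([("gB", "p1")]), aln, {"G1": "gA"})
        assert not out[0].validated

    def test_pure_filter_and_monotone_in_thresholds(self):
        rng = np.random.default_rng(1)
        cands = _cands([(f"g{i%4}", f"p{i}") for i in range(30)])
        rows = [(f"p{i}", f"G{i%4}", float(rng.uniform(60, 100)),
                 int(rng.integers(500, 6000))) for i in range(30)]
        aln = _aln(rows)
        genus_map = {f"G{i}": f"g{i}" for i in range(4)}
        base = validate_associations(cands, aln, genus_map)
        assert len(base) == len(cands)  # output covers exactly the candidates
        base_set = {(a.genus, a.phage_id) for a in base if a.validated}
        for min_len, min_ident in [(3500, 80.0), (3000, 90.0), (4000, 95.0)]:
            harder = validate_associations(cands, aln, genus_map,
                                           min_len=min_len, min_ident=min_ident)
            harder_set = {(a.genus, a.phage_id) for a in harder if a.validated}
            assert harder_set <= base_set

    def test_blast6_reader_validates_ranges(self, tmp_path):
        p = tmp_path / "aln.tsv"
        _aln([("p1", "G1", 95.0, 100)]).to_csv(p, sep="\t", header=False, index=False)
        assert len(read_blast6(p)) == 1
        _aln([("p1", "G1", 120.0, 100)]).to_csv(p, sep="\t", header=False, index=False)
        with pytest.raises(ValueError, match="identity"):
            read_blast6(p)

    def test_associations_table_round_trip(self):
        aln = _aln([("p1", "G1", 85.0, 3500)])
        out = validate_associations(_cands([("gA", "p1")]), aln, {"G1": "gA"})
        df = associations_table(out)
        assert list(df.columns) == ["genus", "phage_id", "log2_fc", "p_adj",
                                    "validated", "best_len", "best_ident"]
        assert bool(df.iloc[0].validated)


class TestPhageReadStats:
    def test_all_bacterial_cell_has_zero_fraction(self):
        from smseq.phage import phage_read_stats

        cells = pd.DataFrame({"cell_id": ["c1"], "genus": ["gA"], "n_reads": [100]})
        empty = pd.DataFrame(columns=["cell_id", "feature_id", "umi"])
        t = phage_read_stats(cells, empty)
        assert t.iloc[0].mean_phage_read_fraction == 0.0
        assert t.iloc[0].mean_phages_per_cell == 0.0

    def test_fractions_bounded(self):
        from smseq.phage import phage_read_stats

        cells = pd.DataFrame({"cell_id": ["c1"], "genus": ["gA"], "n_reads": [10]})
        assigns = pd.DataFrame(
            {"cell_id": ["c1"] * 4, "feature_id": ["p1", "p1", "p2", "p2"],
             "umi": ["AAAA", "CCCC", "GGGG", "TTTT"]}
        )
        t = phage_read_stats(cells, assigns)
        assert 0.0 <= t.iloc[0].mean_phage_read_fraction <= 1.0
        assert t.iloc[0].mean_phages_per_cell == 2

    def test_recovers_planted_fraction_per_genus(self, bundle, extract_result, annotation):
        """Measured per-genus phage-read fractions track the simulator truth."""
        from smseq.bac import assign_reads
        from smseq.kmer import FeatureKmerIndex
        from smseq.phage import phage_read_stats

        b = bundle
        phage_index = FeatureKmerIndex.build(sorted(b.phages.items()))
        units = extract_result.units
        reads = [(u.cell_id, r.umi, r.cdna) for u in units for r in u.reads]
        assigns = assign_reads(reads, phage_index)
        genus_of = annotation.set_index("cell_id")["genus_taxon"]
        cells = pd.DataFrame(
            {"cell_id": [u.cell_id for u in units],
             "genus": [genus_of.get(u.cell_id) for u in units],
             "n_reads": [u.n_reads for u in units]}
        ).dropna(subset=["genus"])
        stats = phage_read_stats(cells, assigns).set_index("genus")
        truth = b.truth_reads.merge(
            b.truth_cells[["cell_ref", "genus"]], on="cell_ref", how="inner"
        )
        per_cell = truth.groupby(["cell_ref", "genus"]).agg(
            n=("read_id", "size"),
            phage=("category", lambda c: (c == "phage").sum()),
        ).reset_index()
        per_cell["frac"] = per_cell.phage / per_cell.n
        expected = per_cell.groupby("genus")["frac"].mean()
        for genus in expected.index:
            assert stats.loc[genus].mean_phage_read_fraction == pytest.approx(
                expected[genus], abs=0.02
            )
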