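"""Shared fixtures: one canonical community bundle processed once per session."""

from __future__ import annotations

import warnings

import pandas as pd
import pytest

from smseq.bac import gene_sequences
from smseq.kmer import FeatureKmerIndex, KmerIndex
from smseq.pipeline import anno_stage, extract_stage
from smseq.sim import SimConfig, simulate_community

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def bundle():
    """Canonical community: 5 species / 2 genera, 300 cells, ~60k reads."""
    return simulate_community(SimConfig(seed=7))


@pytest.fixture(scope="session")
def small_bundle():
    """Light community for file-based pipeline tests."""
    return simulate_community(
        SimConfig(seed=11, n_cells=80, n_ambient_barcodes=200,
                  molecules_per_cell_median=80.0)
    )


@pytest.fixture(scope="session")
def extract_result(bundle):
    return extract_stage(bundle.read_pairs, bundle.read_structure)


@pytest.fixture(scope="session")
def taxon_index(bundle):
    return KmerIndex.build(
        [(bundle.genome_taxon[s], seq) for s, seq in bundle.genomes.items()],
        bundle.taxonomy,
    )


@pytest.fixture(scope="session")
def annotation(bundle, extract_result, taxon_index):
    return anno_stage(extract_result.units, taxon_index, bundle.taxonomy)


@pytest.fixture(scope="session")
def gene_index(bundle):
    return FeatureKmerIndex.build(gene_sequences(bundle.genes, dict(bundle.genomes)))


@pytest.fixture(scope="session")
def gene_meta(bundle):
    return pd.DataFrame(
        {
            "taxon_id": [g.taxon_id for g in bundle.genes],
            "biotype": [g.biotype for g in bundle.genes],
        },
        index=pd.Index([g.gene_id for g in bundle.genes], name="feature_id"),
    )


@pytest.fixture(scope="session")
def truth_cell_ids(bundle):
    """cell_id -> (species, genus) from the simulator truth table."""
    t = bundle.truth_cells.copy()
    t["cell_id"] = t["barcode"] + ":" + t["preindex_id"].astype(str)
    t = t.drop_duplicates("cell_id")
    return t.set_index("cell_id")[["species", "genus"]]


@pytest.fixture(scope="session")
def mock5_bundle():
    """Five species / five genera mock community (5% contamination)."""
    from smseq.sim import mock5_fixture

    return mock5_fixture(seed=7, contamination_rate=0.05)


@pytest.fixture(scope="session")
def gene_assignments(extract_result, gene_index):
    from smseq.bac import assign_reads

    reads = [(u.cell_id, r.umi, r.cdna)
             for u in extract_result.units for r in u.reads]
    return assign_reads(reads, gene_index)
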