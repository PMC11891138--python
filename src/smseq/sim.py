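"""Synthetic single-microbe community generator with machine-readable truth.

The simulator emits everything the pipeline consumes — reference genomes
with a taxonomy, gene models, phage genomes, an rRNA reference, paired
FASTQ with barcodes/UMIs/pre-indexes, and a planted genome-alignment
table — together with read-level and cell-level ground truth, so every
pipeline stage has a closed test loop.

Generative model, in brief: each cell is one bacterium of a known
species captured in a droplet. A cell produces LogNormal-many mRNA
molecules; each molecule comes from a gene of its genome (an rRNA gene
with the configured background probability, a prophage with the
configured activity when the cell's genus hosts one, another species
entirely with the contamination probability) and is sequenced
1 + Poisson(duplication) times. Droplet doublets place two cells behind
one barcode, distinguishable by their pre-index tubes. Ambient barcodes
contribute a low-count noise floor so the barcode rank curve has a knee.
Substitution errors hit barcodes and UMIs per base; cDNA is error-free
by default so assignment logic is exercised separately from barcode
recovery.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bac import GeneModel, write_gene_models
from .phage import BLAST6_COLUMNS
from .readproc import ReadPair, ReadStructure
from .taxonomy import TaxNode, TaxonomyTree

# Synthetic 12-entry pre-index whitelist (6 bp, pairwise Hamming >= 3), a
# stand-in for the instrument's proprietary tube tags.
PREINDEX_WHITELIST: tuple[str, ...] = (
    "AAAAAA", "AACCCG", "ACGGTA", "AGTTGC", "CATGCT", "CCACTC",
    "CGCAAG", "GTAACT", "GCGTTG", "GGTCGA", "TTTGGG", "TGATAC",
)

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic community."""

    seed: int
    n_species: int = 5
    genera_sizes: tuple[int, ...] = (3, 2)  # species per genus
    genome_length: int = 15000
    genes_per_genome: int = 40
    gene_length: int = 250
    rrna_gene_fraction: float = 0.1
    shared_genus_fraction: float = 0.1  # genome fraction shared within a genus
    n_cells: int = 300
    molecules_per_cell_median: float = 150.0
    molecules_per_cell_sigma: float = 0.35
    duplication_rate: float = 0.3  # extra reads per molecule (Poisson mean)
    read_length: int = 80
    n_ambient_barcodes: int = 600
    ambient_max_reads: int = 5
    contamination_rate: float = 0.05
    doublet_rate: float = 0.05
    barcode_error_rate: float = 0.005  # per base, substitutions
    umi_error_rate: float = 0.002
    rrna_read_fraction: float = 0.2
    polya_tail_prob: float = 0.2
    polya_tail_len: int = 8
    phage_genome_length: int = 8000
    prophage_insert_length: int = 4000
    prophage_activity: float = 0.10  # molecule share in host-genus cells
    n_true_phages: int = 4
    n_decoy_phages: int = 2

    def __post_init__(self) -> None:
        if sum(self.genera_sizes) != self.n_species:
            raise ValueError("genera_sizes must sum to n_species")
        for name in ("contamination_rate", "doublet_rate", "rrna_read_fraction",
                     "prophage_activity", "rrna_gene_fraction", "shared_genus_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.genes_per_genome * self.gene_length > self.genome_length:
            raise ValueError("genes do not fit in the genome")
        if self.read_length > self.gene_length:
            raise ValueError("read_length must not exceed gene_length")


def mock5_config(seed: int, contamination_rate: float = 0.0) -> SimConfig:
    """Five species in five distinct genera — the mock-community design."""
    return SimConfig(
        seed=seed,
        n_species=5,
        genera_sizes=(1, 1, 1, 1, 1),
        contamination_rate=contamination_rate,
    )


@dataclass
class SimBundle:
    """In-memory simulation output plus ground truth."""

    config: SimConfig
    taxonomy: TaxonomyTree
    genomes: dict[str, str]          # seqid -> sequence
    genome_taxon: dict[str, str]     # seqid -> species taxon
    genes: list[GeneModel]
    phages: dict[str, str]           # phage_id -> sequence
    rrna_sequences: list[str]
    whitelist: tuple[str, ...]
    read_pairs: list[ReadPair]
    truth_reads: pd.DataFrame
    truth_cells: pd.DataFrame
    truth_pairs: pd.DataFrame
    alignments: pd.DataFrame
    read_structure: ReadStructure = field(init=False)

    def __post_init__(self) -> None:
        self.read_structure = ReadStructure(preindex_whitelist=self.whitelist)


# ---------------------------------------------------------------------------
# construction helpers
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    k = rng.binomial(len(seq), rate)
    if k == 0:
        return seq
    out = list(seq)
    for pos in rng.choice(len(seq), size=k, replace=False):
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alternatives[rng.integers(0, 3)]
    return "".join(out)


def _build_taxonomy(cfg: SimConfig) -> tuple[TaxonomyTree, list[str], dict[str, str]]:
    nodes = {
        "r": TaxNode("r", "r", "root", "root"),
        "d1": TaxNode("d1", "r", "domain", "Bacteria"),
        "p1": TaxNode("p1", "d1", "phylum", "Simulobacterota"),
        "c1": TaxNode("c1", "p1", "class", "Simulobacteria"),
        "o1": TaxNode("o1", "c1", "order", "Simulales"),
    }
    species_ids: list[str] = []
    species_genus: dict[str, str] = {}
    s = 0
    for g, size in enumerate(cfg.genera_sizes, start=1):
        nodes[f"f{g}"] = TaxNode(f"f{g}", "o1", "family", f"Family_{g}")
        nodes[f"g{g}"] = TaxNode(f"g{g}", f"f{g}", "genus", f"Genus_{g}")
        for _ in range(size):
            s += 1
            sid = f"s{s}"
            nodes[sid] = TaxNode(sid, f"g{g}", "species", f"Species_{g}_{s}")
            species_ids.append(sid)
            species_genus[sid] = f"g{g}"
    return TaxonomyTree(nodes), species_ids, species_genus


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def simulate_community(cfg: SimConfig) -> SimBundle:
    """Generate one community; deterministic for a fixed config/seed."""
    rng = np.random.default_rng(cfg.seed)
    tree, species_ids, species_genus = _build_taxonomy(cfg)
    genera = [f"g{g}" for g in range(1, len(cfg.genera_sizes) + 1)]

    # genomes: per-genus ancestral segment + species-private remainder
    shared_len = int(cfg.shared_genus_fraction * cfg.genome_length)
    genus_shared = {g: _random_dna(rng, shared_len) for g in genera}
    genomes: dict[str, str] = {}
    genome_taxon: dict[str, str] = {}
    genes: list[GeneModel] = []
    species_gene_ids: dict[str, list[str]] = {}
    species_rrna_ids: dict[str, list[str]] = {}
    rrna_sequences: list[str] = []
    n_rrna = max(1, int(round(cfg.rrna_gene_fraction * cfg.genes_per_genome)))
    for sid in species_ids:
        seqid = f"genome_{sid}"
        private = _random_dna(rng, cfg.genome_length - shared_len)
        seq = private + genus_shared[species_genus[sid]]
        genomes[seqid] = seq
        genome_taxon[seqid] = sid
        gids, rids = [], []
        for i in range(cfg.genes_per_genome):
            start = i * cfg.gene_length + 1  # genes tile the private region
            end = start + cfg.gene_length - 1
            biotype = "rRNA" if i < n_rrna else "CDS"
            gid = f"{sid}_gene{i:03d}"
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(gene_id=gid, taxon_id=sid, seqid=seqid, start=start,
                          end=end, strand=strand, name=gid, biotype=biotype)
            )
            if biotype == "rRNA":
                rids.append(gid)
                rrna_sequences.append(seq[start - 1 : end])
            else:
                gids.append(gid)
        species_gene_ids[sid] = gids
        species_rrna_ids[sid] = rids
    gene_by_id = {g.gene_id: g for g in genes}

    # phages: true ones are inserted as prophages into one genome of the
    # host genus (appended past the gene region) and get a validating
    # alignment row; decoys are never inserted and get failing rows.
    phages: dict[str, str] = {}
    phage_host: dict[str, str] = {}
    phage_carrier: dict[str, str] = {}
    phage_true: dict[str, bool] = {}
    phage_active_region: dict[str, tuple[str, int, int]] = {}
    aln_rows: list[list] = []
    species_by_genus: dict[str, list[str]] = {}
    for sid in species_ids:
        species_by_genus.setdefault(species_genus[sid], []).append(sid)
    n_phages = cfg.n_true_phages + cfg.n_decoy_phages
    for i in range(n_phages):
        pid = f"phage{i:02d}"
        seq = _random_dna(rng, cfg.phage_genome_length)
        phages[pid] = seq
        host = genera[i % len(genera)]
        phage_host[pid] = host
        is_true = i < cfg.n_true_phages
        phage_true[pid] = is_true
        host_species = species_by_genus[host][i % len(species_by_genus[host])]
        phage_carrier[pid] = host_species
        host_seqid = f"genome_{host_species}"
        if is_true:
            ins_start = int(rng.integers(0, cfg.phage_genome_length - cfg.prophage_insert_length + 1))
            insert = seq[ins_start : ins_start + cfg.prophage_insert_length]
            sstart = len(genomes[host_seqid]) + 1
            genomes[host_seqid] = genomes[host_seqid] + insert
            ident = float(np.round(rng.uniform(90.0, 99.5), 1))
            aln_rows.append(
                [pid, host_seqid, ident, cfg.prophage_insert_length, 0, 0,
                 ins_start + 1, ins_start + cfg.prophage_insert_length,
                 sstart, sstart + cfg.prophage_insert_length - 1, 0.0, 2 * cfg.prophage_insert_length]
            )
            phage_active_region[pid] = (pid, ins_start, ins_start + cfg.prophage_insert_length)
        else:
            # failing evidence: short alignment, or long at low identity
            if i % 2 == 0:
                length, ident = int(rng.integers(1200, 2500)), float(np.round(rng.uniform(85, 95), 1))
            else:
                length, ident = int(rng.integers(3200, 4000)), float(np.round(rng.uniform(60, 79.5), 1))
            aln_rows.append(
                [pid, host_seqid, ident, length, 0, 0, 1, length, 1, length, 1e-5, length]
            )
            phage_active_region[pid] = (pid, 0, cfg.phage_genome_length)
    alignments = pd.DataFrame(aln_rows, columns=BLAST6_COLUMNS)
    species_phages: dict[str, list[str]] = {}
    for pid, carrier in phage_carrier.items():
        species_phages.setdefault(carrier, []).append(pid)

    # cells and droplets
    n_cells = cfg.n_cells
    cell_species = [species_ids[int(i)] for i in rng.integers(0, len(species_ids), size=n_cells)]
    cell_preindex = rng.integers(0, len(PREINDEX_WHITELIST), size=n_cells)
    n_doublets = int(round(cfg.doublet_rate * n_cells))
    n_droplets = n_cells - n_doublets
    barcodes: set[str] = set()
    while len(barcodes) < n_droplets + cfg.n_ambient_barcodes:
        barcodes.add(_random_dna(rng, 20))
    barcode_list = sorted(barcodes)
    rng.shuffle(barcode_list)
    droplet_barcodes = barcode_list[:n_droplets]
    ambient_barcodes = barcode_list[n_droplets:]
    # last 2*n_doublets cells pair up into the last n_doublets droplets
    cell_barcode = [""] * n_cells
    for i in range(n_cells - 2 * n_doublets):
        cell_barcode[i] = droplet_barcodes[i]
    for d in range(n_doublets):
        b = droplet_barcodes[n_droplets - n_doublets + d]
        cell_barcode[n_cells - 2 * n_doublets + 2 * d] = b
        cell_barcode[n_cells - 2 * n_doublets + 2 * d + 1] = b

    mols = rng.lognormal(
        mean=np.log(cfg.molecules_per_cell_median),
        sigma=cfg.molecules_per_cell_sigma,
        size=n_cells,
    ).astype(int)
    mols = np.maximum(mols, 10)

    whitelist = PREINDEX_WHITELIST
    r1_parts: list[str] = []
    r2_parts: list[str] = []
    ids: list[str] = []
    truth_rows: list[tuple] = []
    read_no = 0

    def emit(cell_ref: str, barcode: str, pid: int, species: str, category: str,
             feature: str, source_seq: str, umi: str, n_reads: int) -> None:
        nonlocal read_no
        pos = int(rng.integers(0, len(source_seq) - cfg.read_length + 1))
        cdna = source_seq[pos : pos + cfg.read_length]
        if rng.random() < 0.5:
            from .kmer import revcomp
            cdna = revcomp(cdna)
        tail = "A" * cfg.polya_tail_len if rng.random() < cfg.polya_tail_prob else ""
        for _ in range(n_reads):
            read_no += 1
            rid = f"read{read_no:07d}"
            obs_bc = _mutate(rng, barcode, cfg.barcode_error_rate)
            obs_umi = _mutate(rng, umi, cfg.umi_error_rate)
            r1_parts.append(obs_bc + obs_umi + "T" * 12)
            r2_parts.append(whitelist[pid] + cdna + tail)
            ids.append(rid)
            truth_rows.append((rid, cell_ref, barcode, pid, species, category, feature, umi))

    for ci in range(n_cells):
        sid = cell_species[ci]
        genus = species_genus[sid]
        pid = int(cell_preindex[ci])
        bc = cell_barcode[ci]
        cell_ref = f"cell{ci:04d}"
        active = species_phages.get(sid, [])
        for _ in range(mols[ci]):
            umi = _random_dna(rng, 8)
            n_reads = 1 + int(rng.poisson(cfg.duplication_rate))
            u = rng.random()
            if active and u < cfg.prophage_activity:
                phage = active[int(rng.integers(0, len(active)))]
                _, a, b = phage_active_region[phage]
                emit(cell_ref, bc, pid, sid, "phage", phage, phages[phage][a:b], umi, n_reads)
            elif u < cfg.prophage_activity * bool(active) + cfg.contamination_rate:
                other = sid
                while other == sid:
                    other = species_ids[int(rng.integers(0, len(species_ids)))]
                gid = species_gene_ids[other][int(rng.integers(0, len(species_gene_ids[other])))]
                g = gene_by_id[gid]
                emit(cell_ref, bc, pid, other, "contam", gid,
                     genomes[g.seqid][g.start - 1 : g.end], umi, n_reads)
            elif u < cfg.prophage_activity * bool(active) + cfg.contamination_rate + cfg.rrna_read_fraction:
                rid_ = species_rrna_ids[sid][int(rng.integers(0, len(species_rrna_ids[sid])))]
                g = gene_by_id[rid_]
                emit(cell_ref, bc, pid, sid, "rrna", rid_,
                     genomes[g.seqid][g.start - 1 : g.end], umi, n_reads)
            else:
                gid = species_gene_ids[sid][int(rng.integers(0, len(species_gene_ids[sid])))]
                g = gene_by_id[gid]
                emit(cell_ref, bc, pid, sid, "gene", gid,
                     genomes[g.seqid][g.start - 1 : g.end], umi, n_reads)

    # ambient noise floor
    for ai, bc in enumerate(ambient_barcodes):
        n = int(rng.integers(1, cfg.ambient_max_reads + 1))
        for _ in range(n):
            sid = species_ids[int(rng.integers(0, len(species_ids)))]
            gid = species_gene_ids[sid][int(rng.integers(0, len(species_gene_ids[sid])))]
            g = gene_by_id[gid]
            pid = int(rng.integers(0, len(whitelist)))
            emit("AMBIENT", bc, pid, sid, "ambient", gid,
                 genomes[g.seqid][g.start - 1 : g.end], _random_dna(rng, 8), 1)

    read_pairs = [
        ReadPair(rid, s1, s2, "I" * len(s1), "I" * len(s2))
        for rid, s1, s2 in zip(ids, r1_parts, r2_parts)
    ]
    truth_reads = pd.DataFrame(
        truth_rows,
        columns=["read_id", "cell_ref", "barcode", "preindex_id", "species",
                 "category", "feature_id", "umi"],
    )
    truth_cells = pd.DataFrame(
        {
            "cell_ref": [f"cell{ci:04d}" for ci in range(n_cells)],
            "barcode": cell_barcode,
            "preindex_id": cell_preindex,
            "species": cell_species,
            "genus": [species_genus[s] for s in cell_species],
            "n_molecules": mols,
        }
    )
    counts = truth_reads.groupby("cell_ref").size()
    truth_cells["n_reads"] = truth_cells["cell_ref"].map(counts).fillna(0).astype(int)
    truth_pairs = pd.DataFrame(
        [(phage_host[p], p, phage_true[p]) for p in phages],
        columns=["genus", "phage_id", "is_true_pair"],
    )
    return SimBundle(
        config=cfg,
        taxonomy=tree,
        genomes=genomes,
        genome_taxon=genome_taxon,
        genes=genes,
        phages=phages,
        rrna_sequences=rrna_sequences,
        whitelist=whitelist,
        read_pairs=read_pairs,
        truth_reads=truth_reads,
        truth_cells=truth_cells,
        truth_pairs=truth_pairs,
        alignments=alignments,
    )


# ---------------------------------------------------------------------------
# fixture bundles on disk
# ---------------------------------------------------------------------------

def write_bundle(bundle: SimBundle, outdir) -> dict[str, str]:
    """Write the bundle in the standard formats; returns file checksums."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "reference.fa", "w") as fh:
        for seqid, seq in sorted(bundle.genomes.items()):
            fh.write(f">{seqid}|{bundle.genome_taxon[seqid]}\n{seq}\n")
    bundle.taxonomy.write_tsv(out / "taxonomy.tsv")
    write_gene_models(bundle.genes, out / "genes.gff")
    with open(out / "phages.fa", "w") as fh:
        for pid, seq in sorted(bundle.phages.items()):
            fh.write(f">{pid}\n{seq}\n")
    with open(out / "rrna.fa", "w") as fh:
        for i, seq in enumerate(bundle.rrna_sequences):
            fh.write(f">rrna{i:03d}\n{seq}\n")
    with open(out / "whitelist.txt", "w") as fh:
        fh.write("\n".join(bundle.whitelist) + "\n")
    with open(out / "reads_R1.fastq", "w") as fh:
        for rp in bundle.read_pairs:
            fh.write(f"@{rp.read_id}\n{rp.seq1}\n+\n{rp.qual1}\n")
    with open(out / "reads_R2.fastq", "w") as fh:
        for rp in bundle.read_pairs:
            fh.write(f"@{rp.read_id}\n{rp.seq2}\n+\n{rp.qual2}\n")
    bundle.alignments.to_csv(out / "alignments.tsv", sep="\t", header=False, index=False)
    bundle.truth_reads.to_csv(out / "truth_reads.tsv", sep="\t", index=False)
    bundle.truth_cells.to_csv(out / "truth_cells.tsv", sep="\t", index=False)
    bundle.truth_pairs.to_csv(out / "truth_pairs.tsv", sep="\t", index=False)
    checksums = {}
    for p in sorted(out.iterdir()):
        if p.name == "checksums.tsv" or p.is_dir():
            continue
        checksums[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    with open(out / "checksums.tsv", "w") as fh:
        for name, digest in checksums.items():
            fh.write(f"{name}\t{digest}\n")
    return checksums


def write_fixture(outdir, seed: int = 7) -> SimBundle:
    """The canonical test bundle: 5 species / 2 genera, 300 cells, ~60k reads."""
    bundle = simulate_community(SimConfig(seed=seed))
    write_bundle(bundle, outdir)
    return bundle


def mock5_fixture(seed: int = 7, contamination_rate: float = 0.0) -> SimBundle:
    """In-memory bundle emulating a five-species mock community."""
    return simulate_community(mock5_config(seed, contamination_rate=contamination_rate))
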