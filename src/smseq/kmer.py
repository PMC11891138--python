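"""Canonical k-mer machinery: taxon-labelled LCA indexes and feature indexes.

A canonical k-mer is the lexicographic minimum of a k-mer and its reverse
complement, so both strands of a transcript hit the same index entries.
Two index flavours share this primitive:

* :class:`KmerIndex` — k-mer -> taxon id, where a k-mer seen in several
  genomes is labelled with the lowest common ancestor of their taxa
  (Kraken-style database, built in memory at desk scale).
* :class:`FeatureKmerIndex` — k-mer -> tuple of feature ids (genes or
  phage genomes), used for pseudo-assignment with a uniqueness rule.

K-mers containing non-ACGT characters are never indexed or looked up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO

from .taxonomy import TaxonomyTree

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_K = 21


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmers(seq: str, k: int) -> Iterator[str]:
    """Yield the canonical form of every ACGT-only k-mer of ``seq``."""
    seq = seq.upper()
    n = len(seq)
    if n < k:
        return
    rc = revcomp(seq)
    for i in range(n - k + 1):
        fwd = seq[i : i + k]
        if "N" in fwd:
            continue
        rev = rc[n - k - i : n - i]
        yield fwd if fwd <= rev else rev


def read_fasta(path) -> list[tuple[str, str]]:
    """(header, sequence) pairs; the full header line minus '>' is kept."""
    return [(rec.description, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def taxon_from_header(header: str) -> str:
    """Reference headers carry the taxon id after the last '|' delimiter."""
    if "|" not in header:
        raise ValueError(f"no '|taxon_id' field in FASTA header: {header!r}")
    return header.rsplit("|", 1)[1].strip().split()[0]


@dataclass
class KmerIndex:
    """Map canonical k-mer -> taxon id (LCA over all source genomes)."""

    k: int
    labels: dict[str, str] = field(default_factory=dict)

    @classmethod
    def build(
        cls,
        genomes: Iterable[tuple[str, str]],
        tree: TaxonomyTree,
        k: int = DEFAULT_K,
    ) -> "KmerIndex":
        """``genomes`` yields (taxon_id, sequence); unknown taxa are an error."""
        labels: dict[str, str] = {}
        for taxon, seq in genomes:
            if taxon not in tree.nodes:
                raise ValueError(f"genome labelled with unknown taxon {taxon!r}")
            for km in set(canonical_kmers(seq, k)):
                prev = labels.get(km)
                if prev is None:
                    labels[km] = taxon
                elif prev != taxon:
                    labels[km] = tree.lca(prev, taxon)
        return cls(k=k, labels=labels)

    @classmethod
    def from_fasta(cls, path, tree: TaxonomyTree, k: int = DEFAULT_K) -> "KmerIndex":
        genomes = [(taxon_from_header(h), s) for h, s in read_fasta(path)]
        return cls.build(genomes, tree, k=k)

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, kmer: str) -> str | None:
        return self.labels.get(kmer)


@dataclass
class FeatureKmerIndex:
    """Map canonical k-mer -> tuple of feature ids containing it."""

    k: int
    members: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @classmethod
    def build(cls, features: Iterable[tuple[str, str]], k: int = DEFAULT_K) -> "FeatureKmerIndex":
        """``features`` yields (feature_id, sequence)."""
        members: dict[str, tuple[str, ...]] = {}
        for fid, seq in features:
            for km in set(canonical_kmers(seq, k)):
                prev = members.get(km)
                if prev is None:
                    members[km] = (fid,)
                elif fid not in prev:
                    members[km] = prev + (fid,)
        return cls(k=k, members=members)

    def __len__(self) -> int:
        return len(self.members)

    def hit_counts(self, seq: str) -> tuple[dict[str, int], int]:
        """Per-feature hit counts over the read's canonical k-mers.

        Returns (counts, n_kmers) where n_kmers is the number of ACGT
        k-mers the read contributes (hit or not).
        """
        counts: dict[str, int] = {}
        n = 0
        for km in canonical_kmers(seq, self.k):
            n += 1
            hit = self.members.get(km)
            if hit:
                for fid in hit:
                    counts[fid] = counts.get(fid, 0) + 1
        return counts, n
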