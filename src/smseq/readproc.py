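"""Read processing: barcode/UMI extraction, trimming, cell calling, merging.

Raw paired reads carry the cell barcode (20 bp) and UMI (8 bp) on R1 and
the pre-index tag plus cDNA on R2. The pre-index is a short tube-specific
tag on the reverse-transcription primer (12 variants); it lets two
bacteria co-encapsulated in one droplet be split into two cells. Real
cells are called from the knee of the log-log barcode rank/count curve,
and sequencing errors in barcodes are absorbed by merging every
non-accepted barcode into its nearest accepted barcode within Hamming
distance 2.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Iterable, Iterator

import numpy as np

UNASSIGNED = -1
DISCARD = "*DISCARD*"

_SUB_ALPHABET = "ACGTN"


def hamming(a: str, b: str) -> int:
    """Mismatch count; any position involving an N counts as a mismatch."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y or x == "N" or y == "N" for x, y in zip(a, b))


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    seq1: str
    seq2: str
    qual1: str = ""
    qual2: str = ""


@dataclass(frozen=True)
class ReadStructure:
    """Layout of barcode/UMI on R1 and pre-index on R2.

    The exact layout is instrument configuration, so every offset is a
    parameter; the defaults put the 20 bp barcode at the start of R1,
    the 8 bp UMI directly after it, and the pre-index at the start of R2.
    """

    barcode_len: int = 20
    umi_len: int = 8
    barcode_offset: int = 0
    umi_offset: int | None = None  # default: directly after the barcode
    preindex_whitelist: tuple[str, ...] = ()
    preindex_offset: int = 0
    preindex_max_mismatch: int = 1
    max_n_bases: int = 0  # tolerated N's in barcode+UMI before dropping

    def __post_init__(self) -> None:
        wl = self.preindex_whitelist
        if wl:
            if len(set(wl)) != len(wl):
                raise ValueError("pre-index whitelist entries must be unique")
            if len({len(w) for w in wl}) != 1:
                raise ValueError("pre-index whitelist entries must be equal length")

    @property
    def umi_start(self) -> int:
        if self.umi_offset is not None:
            return self.umi_offset
        return self.barcode_offset + self.barcode_len

    @property
    def preindex_len(self) -> int:
        return len(self.preindex_whitelist[0]) if self.preindex_whitelist else 0


@dataclass(frozen=True)
class ExtractedRead:
    read_id: str
    raw_barcode: str
    umi: str
    preindex_id: int
    cdna: str


@dataclass
class BarcodeCounts:
    counts: dict[str, int]
    total_reads: int

    @classmethod
    def from_counter(cls, c: Counter) -> "BarcodeCounts":
        return cls(counts=dict(c), total_reads=sum(c.values()))


@dataclass
class CellUnit:
    """An accepted cell: (merged droplet barcode, pre-index tube)."""

    barcode: str
    preindex_id: int
    member_barcodes: set[str] = field(default_factory=set)
    reads: list[ExtractedRead] = field(default_factory=list)

    @property
    def cell_id(self) -> str:
        return f"{self.barcode}:{self.preindex_id}"

    @property
    def n_reads(self) -> int:
        return len(self.reads)


# ---------------------------------------------------------------------------
# extraction and trimming
# ---------------------------------------------------------------------------

def match_preindex(seq: str, rs: ReadStructure) -> int:
    """Best whitelist entry within the mismatch budget, or UNASSIGNED.

    Equidistant best matches are ambiguous and left UNASSIGNED.
    """
    wl = rs.preindex_whitelist
    if not wl:
        return UNASSIGNED
    L = rs.preindex_len
    window = seq[rs.preindex_offset : rs.preindex_offset + L]
    if len(window) < L:
        return UNASSIGNED
    best, best_d, tied = UNASSIGNED, L + 1, False
    for i, entry in enumerate(wl):
        d = hamming(window, entry)
        if d < best_d:
            best, best_d, tied = i, d, False
        elif d == best_d:
            tied = True
    if tied or best_d > rs.preindex_max_mismatch:
        return UNASSIGNED
    return best


def extract_read(pair: ReadPair, rs: ReadStructure) -> ExtractedRead | None:
    """Slice barcode/UMI from R1 and the pre-index from R2; None = dropped."""
    need = max(rs.barcode_offset + rs.barcode_len, rs.umi_start + rs.umi_len)
    if len(pair.seq1) < need:
        return None
    barcode = pair.seq1[rs.barcode_offset : rs.barcode_offset + rs.barcode_len]
    umi = pair.seq1[rs.umi_start : rs.umi_start + rs.umi_len]
    if (barcode + umi).count("N") > rs.max_n_bases:
        return None
    pid = match_preindex(pair.seq2, rs)
    if rs.preindex_len:
        off = rs.preindex_offset
        cdna = pair.seq2[:off] + pair.seq2[off + rs.preindex_len :]
    else:
        cdna = pair.seq2
    if not cdna:
        return None
    return ExtractedRead(pair.read_id, barcode, umi, pid, cdna)


def _strip_adapters(seq: str, adapters: Iterable[str]) -> str:
    for ad in adapters:
        la = len(ad)
        if la == 0 or la > len(seq):
            continue
        if seq.startswith(ad) or hamming(seq[:la], ad) <= 1:
            seq = seq[la:]
        if la <= len(seq) and (seq.endswith(ad) or hamming(seq[-la:], ad) <= 1):
            seq = seq[:-la]
    return seq


def trim_artifacts(seq: str, min_tail_run: int = 6, adapters: Iterable[str] = ()) -> str:
    """Remove dA-tailing artifacts and configured adapters.

    The terminal homopolymer run of A at the 3' end (or T at the 5' end,
    its reverse-complement image) is removed when at least
    ``min_tail_run`` long; adapters are stripped from either end at up to
    one mismatch. The whole pass iterates to a fixed point, so trimming
    is idempotent.
    """
    while True:
        out = _strip_adapters(seq, adapters) if adapters else seq
        n = len(out)
        run = n - len(out.rstrip("A"))
        if run >= min_tail_run:
            out = out[: n - run]
        run = len(out) - len(out.lstrip("T"))
        if run >= min_tail_run:
            out = out[run:]
        if out == seq:
            return out
        seq = out


# ---------------------------------------------------------------------------
# cell calling
# ---------------------------------------------------------------------------

def count_barcodes(reads: Iterable[ExtractedRead]) -> BarcodeCounts:
    return BarcodeCounts.from_counter(Counter(r.raw_barcode for r in reads))


def call_cells(bc: BarcodeCounts, min_barcodes: int = 10) -> tuple[set[str], int]:
    """Knee-point cell calling on the log-log barcode rank plot.

    Barcodes are ranked by descending count and collapsed to distinct
    count levels; the knee is the inflection of the log-log rank curve —
    the largest log-count drop between consecutive levels, i.e. the
    cliff separating real cells from the ambient noise floor. Every
    barcode with count >= the count at the top of that cliff is
    accepted. Tiny inputs (fewer than ``min_barcodes`` distinct
    barcodes) and flat inputs accept everything.
    """
    if not bc.counts:
        raise ValueError("call_cells requires at least one barcode")
    items = sorted(bc.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    counts = np.array([c for _, c in items], dtype=float)
    if len(items) < min_barcodes:
        return {b for b, _ in items}, 1
    if counts[0] == counts[-1]:
        return {b for b, _ in items}, int(counts[0])
    levels = np.unique(counts)[::-1]
    y = np.log10(levels)
    knee = int(np.argmax(-np.diff(y)))
    threshold = int(levels[knee])
    accepted = {b for b, c in items if c >= threshold}
    return accepted, threshold


# ---------------------------------------------------------------------------
# barcode merging
# ---------------------------------------------------------------------------

def _variants(seq: str, dist: int) -> Iterator[str]:
    """All strings at exactly ``dist`` substitutions from ``seq``."""
    n = len(seq)
    for pos in combinations(range(n), dist):
        options = [[c for c in _SUB_ALPHABET if c != seq[p]] for p in pos]
        for subs in product(*options):
            out = list(seq)
            for p, c in zip(pos, subs):
                out[p] = c
            yield "".join(out)


def merge_barcodes(
    bc: BarcodeCounts, accepted: set[str], max_dist: int = 2
) -> dict[str, str]:
    """Map every observed barcode to its accepted barcode or DISCARD.

    Non-accepted barcodes merge into the accepted barcode at minimal
    Hamming distance when that distance is <= ``max_dist``; ties go to
    the accepted barcode with the higher read count, then the
    lexicographically smaller one. Implemented by enumerating the
    substitution neighbourhoods of the accepted barcodes, which is exact
    and avoids the quadratic pairwise scan.
    """
    missing = accepted - set(bc.counts)
    if missing:
        raise ValueError(f"accepted barcodes absent from counts: {sorted(missing)[:3]}")
    # priority: higher count first, then lexicographic
    def prio(b: str) -> tuple[int, str]:
        return (-bc.counts[b], b)

    tiers: list[dict[str, str]] = []
    for d in range(1, max_dist + 1):
        tier: dict[str, str] = {}
        for acc in accepted:
            for v in _variants(acc, d):
                best = tier.get(v)
                if best is None or prio(acc) < prio(best):
                    tier[v] = acc
        tiers.append(tier)

    out: dict[str, str] = {}
    for raw in bc.counts:
        if raw in accepted:
            out[raw] = raw
            continue
        for tier in tiers:
            hit = tier.get(raw)
            if hit is not None:
                out[raw] = hit
                break
        else:
            out[raw] = DISCARD
    return out


# ---------------------------------------------------------------------------
# cell units
# ---------------------------------------------------------------------------

def build_cell_units(
    reads: Iterable[ExtractedRead],
    merge_map: dict[str, str],
    unassigned_policy: str = "drop",
) -> tuple[list[CellUnit], int, int]:
    """Partition reads into (merged barcode, pre-index) cells.

    Reads whose barcode merges to DISCARD are discarded; reads with an
    unassigned pre-index are dropped (default) or pooled into a
    per-barcode unit with pre-index UNASSIGNED (policy
    ``"pool-per-barcode"``). Returns (units, n_discarded, n_unassigned_dropped).
    """
    if unassigned_policy not in ("drop", "pool-per-barcode"):
        raise ValueError(f"unknown pre-index policy {unassigned_policy!r}")
    units: dict[tuple[str, int], CellUnit] = {}
    n_discard = 0
    n_unassigned = 0
    for r in reads:
        merged = merge_map.get(r.raw_barcode, DISCARD)
        if merged == DISCARD:
            n_discard += 1
            continue
        pid = r.preindex_id
        if pid == UNASSIGNED and unassigned_policy == "drop":
            n_unassigned += 1
            continue
        key = (merged, pid)
        unit = units.get(key)
        if unit is None:
            unit = units[key] = CellUnit(barcode=merged, preindex_id=pid)
        unit.member_barcodes.add(r.raw_barcode)
        unit.reads.append(r)
    ordered = [units[k] for k in sorted(units)]
    return ordered, n_discard, n_unassigned


# ---------------------------------------------------------------------------
# FASTQ I/O
# ---------------------------------------------------------------------------

def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fastq_pairs(r1_path, r2_path) -> Iterator[ReadPair]:
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with _open_text(r1_path) as f1, _open_text(r2_path) as f2:
        for (id1, s1, q1), (id2, s2, q2) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2), strict=True
        ):
            rid = id1.split()[0]
            if rid != id2.split()[0]:
                raise ValueError(f"R1/R2 read ids differ: {id1!r} vs {id2!r}")
            yield ReadPair(rid, s1.upper(), s2.upper(), q1, q2)


def load_whitelist(path) -> tuple[str, ...]:
    with open(path) as fh:
        entries = tuple(line.strip().upper() for line in fh if line.strip())
    return entries
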