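"""Seed-and-extend short-read alignment.

Replicates the alignment policy used for repeat quantification: a read aligns
only where its first ``seed_len`` bases match the reference exactly (zero
mismatches in the seed), the remainder is extended by ungapped Hamming
comparison up to ``max_mismatches``, and exactly one best alignment is kept
per read, with a deterministic tie-break.  Both strands are searched.  A
separate mode retains only reads placing exactly once in an entire genome,
used for intron/intergenic compartment counting.

``exhaustive_align_read`` is a brute-force full-scan implementation of the
same model (every offset of every entry, both strands) used for validation;
it shares no search machinery with the seeded path.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

from .reference import CodingDB, RepeatDB

logger = logging.getLogger(__name__)

# Reference N is encoded as 1 and read N as 2 so that N never matches
# anything, including another N.
_REF_N, _READ_N = 1, 2
_RC = bytes.maketrans(b"ACGTN", b"TGCAN")


def revcomp(seq: str) -> str:
    return seq.upper().translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _encode(seq_bytes: bytes, n_code: int) -> np.ndarray:
    arr = np.frombuffer(seq_bytes, dtype=np.uint8).copy()
    arr[arr == ord("N")] = n_code
    return arr


@dataclass(frozen=True)
class AlignerConfig:
    seed_len: int = 20
    max_mismatches: int = 3  # cap on mismatches outside the (exact) seed
    read_len: int = 76
    both_strands: bool = True

    def __post_init__(self):
        if self.seed_len > self.read_len:
            raise ValueError("seed_len must not exceed read_len")


@dataclass(frozen=True)
class AlignmentHit:
    read_id: str
    entry_id: object
    family: str
    offset: int
    strand: str
    mismatches: int


class SeedIndex:
    """Exact-seed lookup over every ``seed_len``-mer of a sequence database.

    Only forward entry sequence is indexed; minus-strand hits are found by
    looking up the reverse-complemented read, which is equivalent to indexing
    entry reverse complements.  Seeds containing N are not indexed (N never
    matches).
    """

    def __init__(self, db, seed_len: int = 20):
        if isinstance(db, RepeatDB):
            items = [(e.entry_id, e.family, e.sequence) for e in db.entries]
        elif isinstance(db, CodingDB):
            items = [(name, "", seq) for name, seq in db.entries]
        elif isinstance(db, dict):  # genome: chrom -> sequence
            items = [(name, "", seq) for name, seq in db.items()]
        else:
            raise TypeError(f"cannot index {type(db).__name__}")
        if not items:
            raise ValueError("empty database")

        self.seed_len = seed_len
        self.ids = [it[0] for it in items]
        self.families = [it[1] for it in items]
        lens = np.array([len(it[2]) for it in items], dtype=np.int64)
        self.entry_lens = lens
        self.entry_starts = np.concatenate(([0], np.cumsum(lens)[:-1]))
        self.cat = _encode("".join(it[2] for it in items).encode(), _REF_N)

        seed_map: dict[bytes, list[int]] = {}
        k = seed_len
        for i_entry, (start, (_, _, seq)) in enumerate(zip(self.entry_starts, items)):
            b = seq.encode()
            if len(b) < k:
                logger.warning("entry %s shorter than seed (%d < %d); unindexed",
                               self.ids[i_entry], len(b), k)
                continue
            for i in range(len(b) - k + 1):
                kmer = b[i : i + k]
                if b"N" in kmer:
                    continue
                seed_map.setdefault(kmer, []).append(int(start) + i)
        self.seed_map = {kmer: np.asarray(pos, dtype=np.int64) for kmer, pos in seed_map.items()}

    @property
    def n_indexed_positions(self):
        return sum(len(v) for v in self.seed_map.values())

    def entry_of(self, global_pos):
        """Entry index containing each global position (vectorized)."""
        return np.searchsorted(self.entry_starts, global_pos, side="right") - 1


def _strand_candidates(index: SeedIndex, read_b: bytes, strand: str, cfg: AlignerConfig):
    """Surviving placements for one strand.

    Returns (entry_idx, offset, mismatches) arrays; empty arrays if none.
    For the minus strand the read's first ``seed_len`` bases correspond to the
    *last* ``seed_len`` bases of the reverse-complemented read on the forward
    entry, so the seed key is taken from the tail of the reverse complement.
    """
    k, rlen = cfg.seed_len, len(read_b)
    empty = (np.empty(0, np.int64),) * 3
    if strand == "+":
        query = read_b
        seed = read_b[:k]
        shift = 0
    else:
        query = read_b.upper().translate(_RC)[::-1]
        seed = query[-k:]
        shift = rlen - k
    if b"N" in seed:
        return empty  # N in the seed region can never match exactly
    pos = index.seed_map.get(seed)
    if pos is None:
        return empty
    start = pos - shift
    eidx = index.entry_of(np.maximum(start, 0))
    ok = (start >= index.entry_starts[eidx]) & (
        start + rlen <= index.entry_starts[eidx] + index.entry_lens[eidx]
    )
    if not ok.any():
        return empty
    start, eidx = start[ok], eidx[ok]
    q = _encode(query, _READ_N)
    windows = index.cat[start[:, None] + np.arange(rlen)]
    mism = (windows != q).sum(axis=1).astype(np.int64)
    keep = mism <= cfg.max_mismatches
    return eidx[keep], (start - index.entry_starts[eidx])[keep], mism[keep]


def _all_placements(index, read_seq: str, cfg):
    """All surviving (entry_idx, offset, strand_rank, mismatches) placements."""
    read_b = read_seq.upper().encode()[: cfg.read_len]
    if len(read_b) < cfg.seed_len:
        return None
    parts = []
    strands = ("+", "-") if cfg.both_strands else ("+",)
    for rank, strand in enumerate(strands):
        eidx, off, mism = _strand_candidates(index, read_b, strand, cfg)
        if len(eidx):
            parts.append((eidx, off, np.full(len(eidx), rank, np.int64), mism))
    if not parts:
        return None
    return tuple(np.concatenate([p[i] for p in parts]) for i in range(4))


def _best(placements):
    """Deterministic minimum: (mismatches, entry, + before -, offset)."""
    eidx, off, srank, mism = placements
    order = np.lexsort((off, srank, eidx, mism))
    i = order[0]
    return int(eidx[i]), int(off[i]), "+-"[int(srank[i])], int(mism[i])


def align_read(read_id: str, read_seq: str, index: SeedIndex, cfg: AlignerConfig) -> AlignmentHit | None:
    """Best seed-constrained alignment of one read, or None."""
    placements = _all_placements(index, read_seq, cfg)
    if placements is None:
        return None
    eidx, off, strand, mism = _best(placements)
    return AlignmentHit(read_id, index.ids[eidx], index.families[eidx], off, strand, mism)


ALIGN_COLUMNS = ["read_id", "entry_id", "family", "offset", "strand", "mismatches"]


def align_batch(reads, index: SeedIndex, cfg: AlignerConfig):
    """Align a batch of reads; one best hit per read.

    ``reads`` is an iterable of ``(read_id, sequence)`` or a FASTQ path.
    Returns ``(table, summary)`` where the table has one row per aligned read
    and summary counts {total, aligned, unaligned}.
    """
    if isinstance(reads, (str, bytes)) or hasattr(reads, "__fspath__"):
        reads = read_fastq(reads)
    rows = []
    total = 0
    for read_id, seq in reads:
        total += 1
        hit = align_read(read_id, seq, index, cfg)
        if hit is not None:
            rows.append((hit.read_id, hit.entry_id, hit.family, hit.offset,
                         hit.strand, hit.mismatches))
    table = pd.DataFrame(rows, columns=ALIGN_COLUMNS)
    summary = {"total": total, "aligned": len(rows), "unaligned": total - len(rows)}
    return table, summary


def align_unique_genome(reads, genome_index: SeedIndex, cfg: AlignerConfig):
    """Retain only reads with exactly one surviving placement genome-wide."""
    if isinstance(reads, (str, bytes)) or hasattr(reads, "__fspath__"):
        reads = read_fastq(reads)
    rows = []
    total = 0
    for read_id, seq in reads:
        total += 1
        placements = _all_placements(genome_index, seq, cfg)
        if placements is None or len(placements[0]) != 1:
            continue
        eidx, off, strand, mism = _best(placements)
        rows.append((read_id, genome_index.ids[eidx], genome_index.families[eidx],
                     off, strand, mism))
    table = pd.DataFrame(rows, columns=ALIGN_COLUMNS)
    summary = {"total": total, "aligned": len(rows), "unaligned": total - len(rows)}
    return table, summary


# ---------------------------------------------------------------------------
# Brute-force reference scan (validation path — no seed hashing)
# ---------------------------------------------------------------------------

class ExhaustiveScanner:
    """Full Hamming scan of every offset/strand under the same alignment model.

    Precomputes, per read length, the set of concatenated-array offsets whose
    window lies within a single entry.  Used to validate the seeded aligner;
    quadratic in database size per read.
    """

    def __init__(self, index: SeedIndex):
        self.index = index
        self._valid_cache: dict[int, np.ndarray] = {}

    def _valid_offsets(self, rlen):
        if rlen not in self._valid_cache:
            idx = self.index
            n = len(idx.cat) - rlen + 1
            if n <= 0:
                self._valid_cache[rlen] = np.zeros(0, dtype=bool)
            else:
                starts = np.arange(n)
                eidx = idx.entry_of(starts)
                self._valid_cache[rlen] = (
                    starts + rlen <= idx.entry_starts[eidx] + idx.entry_lens[eidx]
                )
        return self._valid_cache[rlen]

    def align_read(self, read_seq: str, cfg: AlignerConfig):
        """Best placement as (entry_idx, offset, strand, mismatches) or None."""
        idx = self.index
        read_b = read_seq.upper().encode()[: cfg.read_len]
        rlen = len(read_b)
        if rlen < cfg.seed_len:
            return None
        valid = self._valid_offsets(rlen)
        noff = len(valid)
        if noff == 0:
            return None
        cat = idx.cat
        parts = []
        strands = ("+", "-") if cfg.both_strands else ("+",)
        for rank, strand in enumerate(strands):
            if strand == "+":
                q = _encode(read_b, _READ_N)
                seed_lo, seed_hi = 0, cfg.seed_len
            else:
                q = _encode(read_b.upper().translate(_RC)[::-1], _READ_N)
                seed_lo, seed_hi = rlen - cfg.seed_len, rlen
            acc = np.zeros(noff, dtype=np.uint8)
            seed_acc = np.zeros(noff, dtype=np.uint8)
            for p in range(rlen):
                neq = cat[p : p + noff] != q[p]
                acc += neq
                if seed_lo <= p < seed_hi:
                    seed_acc += neq
            ok = valid & (seed_acc == 0) & (acc <= cfg.max_mismatches)
            if ok.any():
                starts = np.flatnonzero(ok)
                eidx = idx.entry_of(starts)
                parts.append((eidx, starts - idx.entry_starts[eidx],
                              np.full(len(starts), rank, np.int64),
                              acc[ok].astype(np.int64)))
        if not parts:
            return None
        placements = tuple(np.concatenate([p[i] for p in parts]) for i in range(4))
        eidx, off, strand, mism = _best(placements)
        return eidx, off, strand, mism


def exhaustive_align_read(read_seq, index, cfg):
    """One-shot convenience wrapper around :class:`ExhaustiveScanner`."""
    return ExhaustiveScanner(index).align_read(read_seq, cfg)


# ---------------------------------------------------------------------------
# FASTQ I/O
# ---------------------------------------------------------------------------

def read_fastq(path):
    """Yield ``(read_id, sequence)`` from a (possibly gzipped) FASTQ file."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as fh:
        it = SeqIO.parse(fh, "fastq")
        i = 0
        while True:
            try:
                rec = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"{path}: malformed FASTQ record at index {i}: {exc}") from None
            yield rec.id, str(rec.seq).upper()
            i += 1


def write_fastq(path, reads):
    """Write ``(read_id, sequence)`` pairs as FASTQ with uniform quality."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_alignment_table(table: pd.DataFrame, path):
    table.to_csv(path, sep="\t", index=False)


def read_alignment_table(path):
    return pd.read_csv(path, sep="\t", dtype={"read_id": str})
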