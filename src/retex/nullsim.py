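"""Uniform-transcription null simulation.

Under the random/background-transcription hypothesis, reads derived from
repeat (or coding) sequence should fall uniformly over that sequence space.
The null is operationalized directly: fixed-length reads are extracted
verbatim at start positions drawn uniformly over all valid (entry, offset)
pairs of the database, in many independent datasets, and each dataset is then
aligned and counted exactly like an observed library — so any alignment bias
affects null and observed counts alike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import AlignerConfig, SeedIndex, align_batch, revcomp
from .quantify import FamilyCountMatrix, assemble_matrix, count_by_family
from .reference import CodingDB, RepeatDB


@dataclass(frozen=True)
class NullConfig:
    n_datasets: int = 100
    reads_per_dataset: int = 50_000   # desk-scale default; study-scale via config
    read_len: int = 76
    rng_seed: int = 0
    source: str = "repeats"           # {repeats, ccds}

    def __post_init__(self):
        if min(self.n_datasets, self.reads_per_dataset, self.read_len) <= 0:
            raise ValueError("n_datasets, reads_per_dataset and read_len must be positive")
        if self.source not in ("repeats", "ccds"):
            raise ValueError(f"unknown source {self.source!r}")


def _db_items(db):
    if isinstance(db, RepeatDB):
        return [(e.entry_id, e.family, e.sequence) for e in db.entries]
    if isinstance(db, CodingDB):
        return [(name, "", seq) for name, seq in db.entries]
    raise TypeError(f"cannot simulate from {type(db).__name__}")


class UniformReadSimulator:
    """Draws reads uniformly over all valid start positions of a database.

    An entry of length L contributes ``L - read_len + 1`` valid starts, so
    entry selection is weighted by valid-start count, not by entry count;
    entries shorter than the read length contribute no reads.  Strand is
    uniform; sequences are copied verbatim (no sequencing error).
    """

    def __init__(self, db, read_len: int = 76):
        items = _db_items(db)
        self.read_len = read_len
        kept = [(i, f, s) for i, f, s in items if len(s) >= read_len]
        if not kept:
            raise ValueError(f"no database entry reaches read length {read_len}")
        self.ids = [i for i, _, _ in kept]
        self.families = [f for _, f, _ in kept]
        self.seqs = [s for _, _, s in kept]
        self.valid_starts = np.array([len(s) - read_len + 1 for s in self.seqs], dtype=np.int64)
        self.cum = np.cumsum(self.valid_starts)
        self.total_starts = int(self.cum[-1])

    def start_shares(self) -> pd.Series:
        """Each family's share of valid start positions (the null expectation)."""
        s = pd.Series(self.valid_starts, index=self.families, dtype=float)
        shares = s.groupby(level=0).sum()
        return shares / shares.sum()

    def draw(self, n_reads: int, rng: np.random.Generator, id_prefix: str = "sim"):
        """Draw reads; returns (reads, origins).

        ``reads`` is a list of (read_id, sequence); ``origins`` records the
        true source entry, family, offset and strand per read.
        """
        flat = rng.integers(0, self.total_starts, size=n_reads)
        entry = np.searchsorted(self.cum, flat, side="right")
        offset = flat - (self.cum[entry] - self.valid_starts[entry])
        minus = rng.random(n_reads) < 0.5
        reads, origins = [], []
        L = self.read_len
        for i in range(n_reads):
            e, o = int(entry[i]), int(offset[i])
            seq = self.seqs[e][o : o + L]
            strand = "-" if minus[i] else "+"
            if strand == "-":
                seq = revcomp(seq)
            rid = f"{id_prefix}_{i}"
            reads.append((rid, seq))
            origins.append((rid, self.ids[e], self.families[e], o, strand))
        origins = pd.DataFrame(origins,
                               columns=["read_id", "entry_id", "family", "offset", "strand"])
        return reads, origins


def simulate_uniform_reads(db, cfg: NullConfig):
    """Yield ``(dataset_id, reads, origins)`` for each independent dataset.

    Datasets use distinct child seeds spawned from ``cfg.rng_seed`` so they
    are independent yet reproducible.
    """
    sim = UniformReadSimulator(db, read_len=cfg.read_len)
    children = np.random.SeedSequence(cfg.rng_seed).spawn(cfg.n_datasets)
    for d, child in enumerate(children):
        rng = np.random.default_rng(child)
        reads, origins = sim.draw(cfg.reads_per_dataset, rng, id_prefix=f"{cfg.source}{d}")
        yield f"{cfg.source}_{d}", reads, origins


def null_counts(db, cfg: NullConfig, index: SeedIndex, aligner_cfg: AlignerConfig,
                families) -> FamilyCountMatrix:
    """Align each simulated dataset to the repeat index and count by family.

    The index must be the same one used for observed reads; the aligner
    configuration is shared so both conditions see identical biases.
    """
    condition = "simulated_repeats" if cfg.source == "repeats" else "simulated_ccds"
    columns = []
    for dataset_id, reads, _ in simulate_uniform_reads(db, cfg):
        table, _ = align_batch(reads, index, aligner_cfg)
        columns.append(count_by_family(table, families, dataset_id))
    return assemble_matrix(columns, condition)
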