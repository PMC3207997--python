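"""Seed-and-extend aligner: seed rule, best-hit selection, oracle equivalence."""

import numpy as np
import pandas as pd
import pytest

import retex as rx
from retex.align import ExhaustiveScanner, revcomp

CFG = rx.AlignerConfig()


def _db(*seqs, family="L1"):
    entries = [
        rx.reference.RepeatEntry(i, f"r{i}", family, "chr1", 0, len(s), s)
        for i, s in enumerate(seqs)
    ]
    return rx.RepeatDB(entries=entries, flank_bp=0)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestIndex:
    def test_seed_positions_count(self):
        idx = rx.SeedIndex(_db("ACGT" * 25), seed_len=20)
        assert idx.n_indexed_positions == 100 - 20 + 1

    def test_short_entry_contributes_nothing(self):
        idx = rx.SeedIndex(_db("ACGTACGTACGTACGTACG"), seed_len=20)  # 19 bp
        assert idx.n_indexed_positions == 0

    def test_seeds_containing_n_not_indexed(self):
        rng = np.random.default_rng(0)
        seq = _random_seq(rng, 60)
        seq_n = seq[:30] + "N" + seq[31:]
        plain = rx.SeedIndex(_db(seq), seed_len=20)
        with_n = rx.SeedIndex(_db(seq_n), seed_len=20)
        assert with_n.n_indexed_positions == plain.n_indexed_positions - 20


class TestAlignRead:
    rng = np.random.default_rng(1)
    entry = _random_seq(rng, 300)

    def _index(self):
        return rx.SeedIndex(_db(self.entry), seed_len=20)

    def test_exact_substring_aligns_at_its_offset(self):
        read = self.entry[37:113]
        hit = rx.align_read("r", read, self._index(), CFG)
        assert (hit.offset, hit.strand, hit.mismatches) == (37, "+", 0)

    def test_mismatch_inside_seed_kills_alignment(self):
        read = list(self.entry[37:113])
        read[10] = {"A": "C"}.get(read[10], "A")
        assert rx.align_read("r", "".join(read), self._index(), CFG) is None

    def test_mismatches_outside_seed_counted_and_optimal(self):
        read = list(self.entry[37:113])
        for pos in (30, 60):
            read[pos] = {"A": "C"}.get(read[pos], "A")
        read = "".join(read)
        idx = self._index()
        hit = rx.align_read("r", read, idx, CFG)
        assert hit.mismatches == 2
        oracle = ExhaustiveScanner(idx).align_read(read, CFG)
        assert oracle == (0, hit.offset, hit.strand, 2)

    def test_minus_strand_found_via_reverse_complement(self):
        read = revcomp(self.entry[100:176])
        hit = rx.align_read("r", read, self._index(), CFG)
        assert (hit.offset, hit.strand, hit.mismatches) == (100, "-", 0)

    def test_read_shorter_than_seed_unalignable(self):
        assert rx.align_read("r", "ACGTACGTACGT", self._index(), CFG) is None

    def test_trimming_keeps_five_prime_end(self):
        long_read = self.entry[37:113] + "ACGTACGTAC"  # 86 bp before trim
        hit = rx.align_read("r", long_read, self._index(), CFG)
        assert (hit.offset, hit.mismatches) == (37, 0)


class TestBatch:
    def test_empty_batch(self, small_index):
        table, summary = rx.align_batch([], small_index, CFG)
        assert len(table) == 0
        assert summary == {"total": 0, "aligned": 0, "unaligned": 0}

    def test_reads_drawn_from_entries_all_align(self, small_db, small_index):
        rng = np.random.default_rng(2)
        reads = []
        for i in range(200):
            e = small_db.entries[rng.integers(len(small_db.entries))]
            if len(e) < 76:
                continue
            o = rng.integers(0, len(e) - 76 + 1)
            reads.append((f"q{i}", e.sequence[o : o + 76]))
        table, summary = rx.align_batch(reads, small_index, CFG)
        assert summary["aligned"] == summary["total"] == len(reads)

    def test_batch_agrees_with_exhaustive_oracle(self, small_syn, small_index):
        expr = rx.ExpressionConfig(n_reads=400, error_rate=0.01, rng_seed=3)
        reads, _ = rx.make_reads(small_syn, expr, sample_seed=30)
        table, _ = rx.align_batch(reads, small_index, CFG)
        hits = {r.read_id: r for r in table.itertuples()}
        scanner = ExhaustiveScanner(small_index)
        for rid, seq in reads:
            oracle = scanner.align_read(seq, CFG)
            if oracle is None:
                assert rid not in hits
            else:
                eidx, off, strand, mism = oracle
                assert hits[rid].mismatches == mism
                assert (hits[rid].entry_id, hits[rid].offset, hits[rid].strand) == (
                    small_index.ids[eidx], off, strand)

    def test_seed_region_is_exact_for_every_hit(self, small_syn, small_db, small_index):
        expr = rx.ExpressionConfig(n_reads=300, error_rate=0.02, rng_seed=4)
        reads, _ = rx.make_reads(small_syn, expr, sample_seed=31)
        table, _ = rx.align_batch(reads, small_index, CFG)
        seqs = dict(reads)
        by_id = {e.entry_id: e for e in small_db.entries}
        for row in table.itertuples():
            read = seqs[row.read_id][: CFG.read_len]
            ref = by_id[row.entry_id].sequence[row.offset : row.offset + len(read)]
            if row.strand == "-":
                ref = revcomp(ref)
            mism = sum(a != b for a, b in zip(read, ref))
            assert mism == row.mismatches <= CFG.max_mismatches
            assert read[: CFG.seed_len] == ref[: CFG.seed_len]

    def test_determinism(self, small_syn, small_index):
        expr = rx.ExpressionConfig(n_reads=200, error_rate=0.01, rng_seed=5)
        reads, _ = rx.make_reads(small_syn, expr, sample_seed=32)
        t1, _ = rx.align_batch(reads, small_index, CFG)
        t2, _ = rx.align_batch(reads, small_index, CFG)
        pd.testing.assert_frame_equal(t1, t2)

    def test_alignment_count_monotone_in_max_mismatches(self, small_syn, small_index):
        expr = rx.ExpressionConfig(n_reads=300, error_rate=0.03, rng_seed=6)
        reads, _ = rx.make_reads(small_syn, expr, sample_seed=33)
        aligned = []
        for mm in (0, 1, 3, 6):
            cfg = rx.AlignerConfig(max_mismatches=mm)
            _, summary = rx.align_batch(reads, small_index, cfg)
            aligned.append(summary["aligned"])
        assert aligned == sorted(aligned)


class TestUniqueGenome:
    rng = np.random.default_rng(7)
    unique_region = _random_seq(rng, 400)
    dup = _random_seq(rng, 150)
    genome = {"chrA": unique_region + dup, "chrB": dup + _random_seq(rng, 300)}

    def _index(self):
        return rx.SeedIndex(self.genome, seed_len=20)

    def test_single_copy_read_retained(self):
        reads = [("u", self.unique_region[50:126])]
        table, _ = rx.align_unique_genome(reads, self._index(), CFG)
        assert list(table["read_id"]) == ["u"]

    def test_duplicated_read_discarded(self):
        reads = [("d", self.dup[10:86])]
        table, _ = rx.align_unique_genome(reads, self._index(), CFG)
        assert len(table) == 0

    def test_multiplicity_matches_exhaustive_enumeration(self):
        idx = self._index()
        scanner = ExhaustiveScanner(idx)
        rng = np.random.default_rng(8)
        cat = self.unique_region + self.dup
        reads = []
        for i in range(60):
            s = rng.integers(0, len(cat) - 76)
            seq = cat[s : s + 76]
            if rng.random() < 0.5:
                seq = revcomp(seq)
            reads.append((f"q{i}", seq))
        table, _ = rx.align_unique_genome(reads, idx, CFG)
        kept = set(table["read_id"])
        for rid, seq in reads:
            n = _count_placements(seq, self.genome, CFG)
            assert (rid in kept) == (n == 1), (rid, n)


def _count_placements(read, genome, cfg):
    """Brute-force count of seed-satisfying placements across the genome."""
    total = 0
    for chrom_seq in genome.values():
        for query in (read, revcomp(read)):
            for o in range(len(chrom_seq) - len(query) + 1):
                window = chrom_seq[o : o + len(query)]
                mism = sum(a != b for a, b in zip(query, window))
                if query is read:
                    seed_ok = query[: cfg.seed_len] == window[: cfg.seed_len]
                else:
                    seed_ok = query[-cfg.seed_len :] == window[-cfg.seed_len :]
                if seed_ok and mism <= cfg.max_mismatches:
                    total += 1
    return total


class TestFastqIO:
    def test_roundtrip_and_malformed(self, tmp_path):
        p = tmp_path / "r.fq"
        rx.write_fastq(p, [("a", "ACGT"), ("b", "GGGTTT")])
        assert list(rx.read_fastq(p)) == [("a", "ACGT"), ("b", "GGGTTT")]
        p2 = tmp_path / "bad.fq"
        p2.write_text("@a\nACGT\n+\nII\n")  # quality length mismatch
        with pytest.raises(ValueError, match="record"):
            list(rx.read_fastq(p2))
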