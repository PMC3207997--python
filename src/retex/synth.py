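"""Synthetic genomes, repeat annotations, genes and read sets.

The generator emulates the statistical structure the analysis assumes: a
genome roughly 45% repeat-derived across a dozen families; L1-like families
whose copies are mostly 5'-truncated (truncation removes the 5' end, leaving
a geometric-length 3' remnant) with only a minority full length; genes with
log-normal expression, optionally carrying an embedded repeat copy; and 76 bp
reads drawn from a mixture of gene transcripts, family-weighted repeat
transcription, and uniform background transcription.

With every family's expression multiplier at 1, the repeat component draws
read starts uniformly over the *flank-extended* repeat intervals — exactly
the valid-start space of the flanked repeat database — so multiplier-1 data
is generated under the uniform-transcription null that the simulation module
operationalizes.  Multipliers above or below 1 plant family-specific over- or
under-expression (the Alu-up / L1-down pattern) for recovery tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .align import revcomp
from .reference import CodingDB, FamilyTaxonomy, RepeatAnnotation

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class FamilySpec:
    """One repeat family: consensus length, genomic share, decay, truncation."""

    consensus_len: int
    weight: float                    # relative share of planted repeat bp
    divergence: float = 0.1          # per-base substitution rate of copies
    full_length_fraction: float = 1.0
    truncation_mean: int = 500       # mean retained 3' length of truncated copies
    min_retained: int = 80


#: Desk-scale default family mix: ~12 families, Alu-like short/abundant,
#: L1-like long and mostly truncated.
DEFAULT_FAMILY_SPECS: dict[str, FamilySpec] = {
    "Alu_SINE":  FamilySpec(300, 0.30, 0.05),
    "L1":        FamilySpec(3000, 0.20, 0.08, full_length_fraction=0.10, truncation_mean=600),
    "L2":        FamilySpec(2400, 0.08, 0.15, full_length_fraction=0.15, truncation_mean=500),
    "ERV":       FamilySpec(1500, 0.08, 0.10, full_length_fraction=0.50, truncation_mean=700),
    "LTR":       FamilySpec(600, 0.06, 0.10),
    "TcMar":     FamilySpec(800, 0.05, 0.12, full_length_fraction=0.70, truncation_mean=400),
    "hAT":       FamilySpec(600, 0.05, 0.12, full_length_fraction=0.70, truncation_mean=300),
    "DNA":       FamilySpec(500, 0.04, 0.12, full_length_fraction=0.80, truncation_mean=300),
    "CR1":       FamilySpec(1000, 0.04, 0.15, full_length_fraction=0.30, truncation_mean=400),
    "Satellite": FamilySpec(170, 0.04, 0.03),
    "MIR":       FamilySpec(260, 0.04, 0.20),
    "Other":     FamilySpec(400, 0.02, 0.10, full_length_fraction=0.80, truncation_mean=250),
}


@dataclass(frozen=True)
class SyntheticGenomeConfig:
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 150_000, "chr2": 100_000})
    families: dict[str, FamilySpec] = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_SPECS))
    target_repeat_fraction: float = 0.45
    n_genes: int = 30
    gene_len: int = 1500
    embedded_repeat_fraction: float = 0.1
    min_gap: int = 110               # > 2 x 50 bp flank: flanked entries stay disjoint
    allow_overlap: bool = False
    rng_seed: int = 0


@dataclass
class SyntheticGenome:
    genome: dict[str, str]
    annotations: list[RepeatAnnotation]
    truth: pd.DataFrame              # copy_id, family, chrom, start, end, strand, ...
    genes: pd.DataFrame              # gene_id, chrom, start, end, has_repeat
    consensus: dict[str, str]
    config: SyntheticGenomeConfig

    @property
    def taxonomy(self) -> FamilyTaxonomy:
        return FamilyTaxonomy(families=list(self.config.families))

    @property
    def repeat_bp(self) -> int:
        return int((self.truth["end"] - self.truth["start"]).sum())

    @property
    def repeat_fraction(self) -> float:
        return self.repeat_bp / sum(len(s) for s in self.genome.values())

    def coding_db(self) -> CodingDB:
        entries = [(row["gene_id"], self.genome[row["chrom"]][row["start"]:row["end"]])
                   for _, row in self.genes.iterrows()]
        return CodingDB(entries=entries)

    def write(self, out_dir):
        from pathlib import Path
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "genome.fa", "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
        with open(out_dir / "repeats.bed", "w") as fh:
            for a in self.annotations:
                fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.name}\t{a.family}\t{a.strand}\n")
        self.truth.to_csv(out_dir / "truth_repeats.tsv", sep="\t", index=False)
        self.genes.to_csv(out_dir / "truth_genes.tsv", sep="\t", index=False)
        self.coding_db().write(out_dir / "ccds.fa")


def _random_seq(rng, n) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _mutate(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def make_genome(cfg: SyntheticGenomeConfig) -> SyntheticGenome:
    """Build a genome with planted, truth-tracked repeat copies and genes.

    Copies are planted non-overlapping with at least ``min_gap`` background
    between them (and to chromosome ends), drawn per family until the
    family's bp share of the repeat target is met; truncation keeps the 3'
    end of the consensus.  Gaps are random background sequence.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    genome_bp = sum(cfg.chrom_lengths.values())
    target_bp = cfg.target_repeat_fraction * genome_bp
    weight_sum = sum(f.weight for f in cfg.families.values())

    consensus = {fam: _random_seq(rng, spec.consensus_len)
                 for fam, spec in cfg.families.items()}

    # draw copy sequences family by family until each family's bp target is met
    copies = []   # (family, seq, strand, full_length, retained, divergence)
    for fam, spec in cfg.families.items():
        fam_target = target_bp * spec.weight / weight_sum
        fam_bp = 0
        fam_copies = []
        while fam_bp < fam_target:
            full = rng.random() < spec.full_length_fraction
            if full:
                retained = spec.consensus_len
            else:
                draw = rng.geometric(1.0 / max(spec.truncation_mean, 1))
                retained = int(min(spec.consensus_len, max(spec.min_retained, draw)))
            seq = _mutate(rng, consensus[fam][-retained:], spec.divergence)
            strand = "+" if rng.random() < 0.5 else "-"
            fam_copies.append((fam, seq, strand, full, retained))
            fam_bp += retained
        # drop the last copy if that lands closer to the target
        if len(fam_copies) > 1 and (fam_bp - fam_target) > (fam_target - (fam_bp - fam_copies[-1][4])):
            fam_bp -= fam_copies[-1][4]
            fam_copies.pop()
        copies.extend(fam_copies)

    # genes become placement blocks too: an embedded gene is a gene-length
    # block of background with one (small) repeat copy planted inside it, so
    # genes always fit and never collide with other copies
    n_embedded = int(round(cfg.n_genes * cfg.embedded_repeat_fraction))
    embeddable = [i for i, c in enumerate(copies) if c[4] + 160 <= cfg.gene_len]
    rng.shuffle(embeddable)
    embedded_idx = set(embeddable[:n_embedded])
    if len(embedded_idx) < n_embedded:
        logger.warning("only %d of %d embedded genes have a small enough copy",
                       len(embedded_idx), n_embedded)

    blocks = []  # (kind, seq_or_len, payload)
    for i, copy in enumerate(copies):
        if i in embedded_idx:
            pad = cfg.gene_len - copy[4]
            a = int(rng.integers(80, pad - 80 + 1))
            blocks.append(("embedded_gene", cfg.gene_len, (copy, a)))
        else:
            blocks.append(("copy", copy[4], copy))
    for _ in range(cfg.n_genes - len(embedded_idx)):
        blocks.append(("gene", cfg.gene_len, None))

    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]

    # first-fit assignment to chromosomes with guaranteed min_gap everywhere
    per_chrom: dict[str, list] = {c: [] for c in cfg.chrom_lengths}
    chrom_used = {c: cfg.min_gap for c in cfg.chrom_lengths}  # leading gap
    for block in blocks:
        placed = False
        for chrom in sorted(cfg.chrom_lengths,
                            key=lambda c: chrom_used[c] / cfg.chrom_lengths[c]):
            need = chrom_used[chrom] + block[1] + cfg.min_gap
            if need <= cfg.chrom_lengths[chrom]:
                per_chrom[chrom].append(block)
                chrom_used[chrom] = need
                placed = True
                break
        if not placed:
            raise ValueError("requested repeat copies exceed genome capacity")

    genome = {}
    truth_rows, gene_rows = [], []
    copy_id = 0
    gene_id = 0

    def emit_copy(chrom, cursor, copy, parts):
        nonlocal copy_id
        fam, seq, strand, full, retained = copy
        parts.append(revcomp(seq) if strand == "-" else seq)
        truth_rows.append({
            "copy_id": f"{fam}_{copy_id}", "family": fam, "chrom": chrom,
            "start": cursor, "end": cursor + retained, "strand": strand,
            "full_length": full, "retained_len": retained,
        })
        copy_id += 1
        return cursor + retained

    for chrom, length in cfg.chrom_lengths.items():
        chrom_blocks = per_chrom[chrom]
        n = len(chrom_blocks)
        blocks_bp = sum(b[1] for b in chrom_blocks)
        extra = length - blocks_bp - (n + 1) * cfg.min_gap
        if extra < 0:
            raise ValueError("requested repeat copies exceed genome capacity")
        bonus = rng.multinomial(extra, np.full(n + 1, 1.0 / (n + 1))) if n else [extra]
        parts = []
        cursor = 0
        for i, (kind, blen, payload) in enumerate(chrom_blocks):
            gap = cfg.min_gap + int(bonus[i])
            parts.append(_random_seq(rng, gap))
            cursor += gap
            if kind == "copy":
                cursor = emit_copy(chrom, cursor, payload, parts)
            elif kind == "gene":
                gene_rows.append({"gene_id": f"gene_{gene_id}", "chrom": chrom,
                                  "start": cursor, "end": cursor + blen,
                                  "has_repeat": False})
                gene_id += 1
                parts.append(_random_seq(rng, blen))
                cursor += blen
            else:  # embedded_gene: background | copy | background
                copy, a = payload
                gene_rows.append({"gene_id": f"gene_{gene_id}", "chrom": chrom,
                                  "start": cursor, "end": cursor + blen,
                                  "has_repeat": True})
                gene_id += 1
                parts.append(_random_seq(rng, a))
                cursor = emit_copy(chrom, cursor + a, copy, parts)
                tail = blen - a - copy[4]
                parts.append(_random_seq(rng, tail))
                cursor += tail
        parts.append(_random_seq(rng, cfg.min_gap + int(bonus[n]) if n else length))
        genome[chrom] = "".join(parts)
        assert len(genome[chrom]) == length

    truth = pd.DataFrame(truth_rows, columns=["copy_id", "family", "chrom", "start",
                                              "end", "strand", "full_length", "retained_len"])
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end", "has_repeat"])
    annotations = [
        RepeatAnnotation(r["chrom"], r["start"], r["end"], r["strand"],
                         r["copy_id"], r["family"])
        for r in truth_rows
    ]
    return SyntheticGenome(genome=genome, annotations=annotations, truth=truth,
                           genes=genes, consensus=consensus, config=cfg)


# ---------------------------------------------------------------------------
# Read generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionConfig:
    """Mixture law for synthetic reads.

    Component weights: ``background_fraction`` (uniform over the genome),
    ``gene_fraction`` (log-normal per-gene levels), and ``repeat_fraction``
    whose family split is proportional to multiplier x flanked start-share.
    With all multipliers at 1 the repeat component equals the uniform null
    over the flanked repeat space.  ``full_length_only`` restricts a family's
    reads to its full-length copies (promoter-driven L1-style expression);
    ``five_prime_window`` further restricts starts to the element's first W
    bases.
    """

    multipliers: dict[str, float] = field(default_factory=dict)
    background_fraction: float = 0.10
    gene_fraction: float = 0.60
    repeat_fraction: float = 0.30
    gene_log_sigma: float = 1.0
    n_reads: int = 10_000
    read_len: int = 76
    error_rate: float = 0.005
    flank_bp: int = 50
    full_length_only: frozenset = frozenset()
    five_prime_window: dict[str, int] = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        for fam, lam in self.multipliers.items():
            if lam <= 0:
                raise ValueError(f"multiplier for {fam} must be positive")


def _copy_start_ranges(syn: SyntheticGenome, expr: ExpressionConfig):
    """Per family, valid genomic read-start ranges over flanked copy intervals."""
    L = expr.read_len
    ranges: dict[str, list[tuple[str, int, int, str]]] = {f: [] for f in syn.config.families}
    for _, row in syn.truth.iterrows():
        fam = row["family"]
        if fam in expr.full_length_only and not row["full_length"]:
            continue
        chrom_len = len(syn.genome[row["chrom"]])
        window = expr.five_prime_window.get(fam)
        if window is None:
            lo = max(0, int(row["start"]) - expr.flank_bp)
            hi = min(chrom_len, int(row["end"]) + expr.flank_bp) - L
        elif row["strand"] == "+":
            lo = int(row["start"])
            hi = min(int(row["start"]) + window, int(row["end"])) - L
        else:  # 5' end of a minus-strand element sits at its genomic end
            hi = int(row["end"]) - L
            lo = max(int(row["start"]), int(row["end"]) - window)
        if hi >= lo:
            ranges[fam].append((row["chrom"], lo, hi, row["copy_id"]))
    return ranges


def family_start_shares(syn: SyntheticGenome, expr: ExpressionConfig) -> pd.Series:
    """Family shares of flanked valid start positions (multiplier-1 law)."""
    ranges = _copy_start_ranges(syn, replace(expr, full_length_only=frozenset(),
                                             five_prime_window={}))
    totals = {fam: float(sum(hi - lo + 1 for _, lo, hi, _ in rs))
              for fam, rs in ranges.items()}
    s = pd.Series(totals)
    return s / s.sum()


def draw_gene_levels(syn: SyntheticGenome, expr: ExpressionConfig) -> pd.Series:
    """Log-normal per-gene expression levels, fixed by the expression seed."""
    rng = np.random.default_rng(np.random.SeedSequence((expr.rng_seed, 0x6E65)))
    levels = rng.lognormal(mean=0.0, sigma=expr.gene_log_sigma, size=len(syn.genes))
    return pd.Series(levels, index=syn.genes["gene_id"])


def make_reads(syn: SyntheticGenome, expr: ExpressionConfig,
               sample_seed: int | None = None,
               gene_levels: pd.Series | None = None,
               id_prefix: str = "obs", paired: bool = False):
    """Draw one sample's reads from the configured mixture.

    Returns ``(reads, origins)``, or ``(reads1, reads2, origins)`` when
    ``paired`` (mates are independent draws from the same law, matching their
    treatment as technical replicates downstream).  ``sample_seed`` varies
    the read draw between technical/biological replicates while gene levels
    stay fixed by the expression seed.
    """
    rng = np.random.default_rng(
        sample_seed if sample_seed is not None else expr.rng_seed)
    if gene_levels is None:
        gene_levels = draw_gene_levels(syn, expr)

    shares = family_start_shares(syn, expr)
    lam = pd.Series({f: expr.multipliers.get(f, 1.0) for f in shares.index})
    fam_weight = (lam * shares)
    comp_names = ["background", "gene"] + list(fam_weight.index)
    weights = np.array([expr.background_fraction,
                        expr.gene_fraction if len(syn.genes) else 0.0]
                       + list(expr.repeat_fraction * fam_weight))
    weights = weights / weights.sum()

    ranges = _copy_start_ranges(syn, expr)
    fam_cum = {}
    for fam, rs in ranges.items():
        sizes = np.array([hi - lo + 1 for _, lo, hi, _ in rs], dtype=np.int64)
        fam_cum[fam] = (np.cumsum(sizes), sizes) if len(rs) else (None, None)

    chroms = list(syn.genome)
    chrom_sizes = np.array([len(syn.genome[c]) - expr.read_len + 1 for c in chroms],
                           dtype=np.int64)
    chrom_p = chrom_sizes / chrom_sizes.sum()
    gene_p = (gene_levels / gene_levels.sum()).to_numpy() if len(syn.genes) else None
    gene_rows = syn.genes.to_dict("records")

    n_total = expr.n_reads * (2 if paired else 1)
    comp_draw = rng.choice(len(comp_names), size=n_total, p=weights)
    reads, origins = [], []
    L = expr.read_len
    for i in range(n_total):
        comp = comp_names[comp_draw[i]]
        if comp == "background":
            ci = rng.choice(len(chroms), p=chrom_p)
            chrom = chroms[ci]
            start = int(rng.integers(0, chrom_sizes[ci]))
            source = chrom
        elif comp == "gene":
            g = gene_rows[int(rng.choice(len(gene_rows), p=gene_p))]
            chrom = g["chrom"]
            start = int(rng.integers(g["start"], g["end"] - L + 1))
            source = g["gene_id"]
        else:
            cum, sizes = fam_cum[comp]
            if cum is None:
                # family has no eligible copies under the restrictions;
                # fall back to background so read pairing stays intact
                comp = "background"
                ci = rng.choice(len(chroms), p=chrom_p)
                chrom = chroms[ci]
                start = int(rng.integers(0, chrom_sizes[ci]))
                source = chrom
                cum = sizes = None
        if comp not in ("background", "gene") and cum is not None:
            flat = int(rng.integers(0, cum[-1]))
            j = int(np.searchsorted(cum, flat, side="right"))
            chrom, lo, hi, copy_ref = ranges[comp][j]
            start = lo + (flat - (int(cum[j]) - int(sizes[j])))
            source = copy_ref
        seq = syn.genome[chrom][start : start + L]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = revcomp(seq)
        if expr.error_rate > 0:
            seq = _mutate(rng, seq, expr.error_rate)
        if paired:
            rid = f"{id_prefix}_{i // 2}/{1 + i % 2}"
        else:
            rid = f"{id_prefix}_{i}"
        reads.append((rid, seq))
        origins.append((rid, comp, source, chrom, start, strand))

    origins = pd.DataFrame(origins, columns=["read_id", "component", "source",
                                             "chrom", "start", "strand"])
    if not paired:
        return reads, origins
    return reads[0::2], reads[1::2], origins
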