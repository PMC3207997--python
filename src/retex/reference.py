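"""Repeat and coding-sequence reference construction.

The quantification strategy aligns reads not to the genome assembly but to a
*repeat database*: one entry per annotated repeat instance, extracted from the
genome with a fixed flank of unique sequence on each side so that reads
spanning a repeat/unique junction are still captured.  Entries are tagged with
a family label from a configurable taxonomy (Alu_SINE, L1, ERV, ...), the unit
at which expression is quantified.  A parallel database of coding transcript
sequences supports the alternative null in which apparent repeat expression is
driven by uniform transcription of coding sequence.
"""

from __future__ import annotations

import fnmatch
import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 12 family labels used in all count tables, in report order.
DEFAULT_FAMILIES = (
    "Alu_SINE", "ERV", "TcMar", "hAT", "DNA", "L1",
    "L2", "LTR", "CR1", "Satellite", "MIR", "Other",
)

#: RepeatMasker class/family strings -> family label; first match wins.
DEFAULT_CLASS_PATTERNS = (
    ("SINE/Alu*", "Alu_SINE"),
    ("LTR/ERV*", "ERV"),
    ("LTR/HERV*", "ERV"),
    ("DNA/TcMar*", "TcMar"),
    ("DNA/hAT*", "hAT"),
    ("DNA*", "DNA"),
    ("LINE/L1*", "L1"),
    ("LINE/L2*", "L2"),
    ("LTR*", "LTR"),
    ("LINE/CR1*", "CR1"),
    ("Satellite*", "Satellite"),
    ("SINE/MIR*", "MIR"),
)

VALID_BASES = frozenset(b"ACGTN")


class FamilyTaxonomy:
    """Ordered family labels plus a pattern map from annotation class strings.

    Unmatched classes fall into the catch-all ``Other`` label, which is always
    present.  Patterns are shell-style globs matched in order; an annotation
    whose class string is already a family label maps to itself.
    """

    def __init__(self, families=DEFAULT_FAMILIES, patterns=DEFAULT_CLASS_PATTERNS):
        families = list(families)
        if "Other" not in families:
            families.append("Other")
        if len(set(families)) != len(families):
            raise ValueError("family labels must be unique")
        self.families = families
        self.patterns = list(patterns)
        for _, fam in self.patterns:
            if fam not in families:
                raise ValueError(f"pattern target {fam!r} not in family list")

    def assign(self, class_string: str) -> str:
        if class_string in self.families:
            return class_string
        for pattern, fam in self.patterns:
            if fnmatch.fnmatchcase(class_string, pattern):
                return fam
        return "Other"

    def __contains__(self, label):
        return label in self.families

    def __iter__(self):
        return iter(self.families)


@dataclass(frozen=True)
class RepeatAnnotation:
    """One annotated repeat instance, 0-based half-open genome coordinates."""

    chrom: str
    start: int
    end: int
    strand: str
    name: str
    family: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start},{self.end}) for {self.name}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class RepeatEntry:
    entry_id: int
    name: str
    family: str
    chrom: str
    flanked_start: int
    flanked_end: int
    sequence: str

    def __len__(self):
        return len(self.sequence)


@dataclass
class RepeatDB:
    """Flank-extended repeat reference: one entry per annotated instance.

    Entries are stored in genome-forward orientation; the aligner searches
    both strands.  Overlapping annotations (or overlapping flanks) yield
    duplicated sequence, so ``total_bp`` may exceed the distinct genomic
    footprint.
    """

    entries: list[RepeatEntry]
    flank_bp: int = 50

    @property
    def total_bp(self) -> int:
        return sum(len(e) for e in self.entries)

    def families_present(self):
        return sorted({e.family for e in self.entries})

    def write(self, out_dir):
        """Persist as FASTA plus a TSV index."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        records = [
            SeqRecord(
                Seq(e.sequence),
                id=f"{e.entry_id}|{e.family}|{e.chrom}:{e.flanked_start}-{e.flanked_end}",
                description="",
            )
            for e in self.entries
        ]
        SeqIO.write(records, out_dir / "repeats.fa", "fasta")
        with open(out_dir / "repeats.tsv", "w") as fh:
            fh.write("entry_id\tname\tfamily\tchrom\tflanked_start\tflanked_end\tlength\n")
            for e in self.entries:
                fh.write(
                    f"{e.entry_id}\t{e.name}\t{e.family}\t{e.chrom}\t"
                    f"{e.flanked_start}\t{e.flanked_end}\t{len(e)}\n"
                )

    @classmethod
    def read(cls, db_dir, flank_bp=50):
        db_dir = Path(db_dir)
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(db_dir / "repeats.fa", "fasta")}
        entries = []
        with open(db_dir / "repeats.tsv") as fh:
            header = fh.readline()
            for line in fh:
                eid, name, fam, chrom, fs, fe, _ = line.rstrip("\n").split("\t")
                key = f"{eid}|{fam}|{chrom}:{fs}-{fe}"
                entries.append(
                    RepeatEntry(int(eid), name, fam, chrom, int(fs), int(fe), seqs[key])
                )
        return cls(entries=entries, flank_bp=flank_bp)


@dataclass
class CodingDB:
    """Coding transcript sequences used for the coding-space null simulation."""

    entries: list[tuple[str, str]] = field(default_factory=list)

    @property
    def total_bp(self):
        return sum(len(s) for _, s in self.entries)

    def write(self, path):
        records = [SeqRecord(Seq(s), id=name, description="") for name, s in self.entries]
        SeqIO.write(records, str(path), "fasta")


def _check_alphabet(seq: str, context: str):
    bad = set(seq.encode()) - VALID_BASES
    if bad:
        chars = ", ".join(chr(b) for b in sorted(bad))
        raise ValueError(f"{context}: ambiguity characters other than N not allowed ({chars})")


def read_genome(path) -> dict[str, str]:
    """Read a genome FASTA into a dict of uppercased chromosome sequences."""
    genome = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        _check_alphabet(seq, f"chromosome {rec.id}")
        genome[rec.id] = seq
    if not genome:
        raise ValueError(f"no sequences in {path}")
    return genome


def parse_repeat_annotations(path, taxonomy: FamilyTaxonomy) -> list[RepeatAnnotation]:
    """Parse repeat annotations from RepeatMasker ``.out`` or 6-column BED.

    RepeatMasker coordinates are 1-based inclusive and converted to the
    package's 0-based half-open convention; BED is used as-is.  Each record's
    class string is mapped through the taxonomy (unmatched -> ``Other``).
    """
    path = Path(path)
    text = path.read_text().splitlines()
    if path.suffix == ".out" or _looks_like_repeatmasker(text):
        return _parse_repeatmasker(text, taxonomy, path)
    return _parse_bed6(text, taxonomy, path)


def _looks_like_repeatmasker(lines):
    for line in lines[:3]:
        if line.strip().lower().startswith(("sw", "score")):
            return True
    return False


def _parse_repeatmasker(lines, taxonomy, path):
    anns = []
    for lineno, line in enumerate(lines, 1):
        stripped = line.strip()
        if not stripped or stripped.lower().startswith(("sw", "score")):
            continue
        fields = stripped.split()
        if len(fields) < 11:
            raise ValueError(f"{path}:{lineno}: malformed RepeatMasker line ({len(fields)} fields)")
        try:
            chrom = fields[4]
            start = int(fields[5]) - 1  # 1-based inclusive -> 0-based
            end = int(fields[6])
            strand = "+" if fields[8] == "+" else "-"  # 'C' marks complement
            name = fields[9]
            cls = fields[10]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed RepeatMasker line: {exc}") from None
        anns.append(RepeatAnnotation(chrom, start, end, strand, name, taxonomy.assign(cls)))
    return anns


def _parse_bed6(lines, taxonomy, path):
    anns = []
    for lineno, line in enumerate(lines, 1):
        stripped = line.strip()
        if not stripped or stripped.startswith(("#", "track", "browser")):
            continue
        fields = stripped.split()
        if len(fields) < 6:
            raise ValueError(f"{path}:{lineno}: expected 6 BED columns, got {len(fields)}")
        try:
            chrom, start, end, name, cls, strand = fields[:6]
            anns.append(
                RepeatAnnotation(chrom, int(start), int(end), strand, name, taxonomy.assign(cls))
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed BED line: {exc}") from None
    return anns


def build_repeat_db(genome, annotations, flank_bp: int = 50) -> RepeatDB:
    """Extract every annotated repeat with ``flank_bp`` of context on each side.

    Flanks are clipped at chromosome bounds.  Entries keep genome orientation
    regardless of the annotation strand.  ``genome`` is a FASTA path or a
    dict of chromosome sequences.
    """
    if not isinstance(genome, dict):
        genome = read_genome(genome)
    missing = sorted({a.chrom for a in annotations} - set(genome))
    if missing:
        raise ValueError(f"annotation chromosomes missing from genome: {', '.join(missing)}")
    entries = []
    for i, ann in enumerate(annotations):
        chrom_len = len(genome[ann.chrom])
        if ann.end > chrom_len:
            raise ValueError(
                f"annotation {ann.name} [{ann.start},{ann.end}) exceeds "
                f"{ann.chrom} length {chrom_len}"
            )
        fs = max(0, ann.start - flank_bp)
        fe = min(chrom_len, ann.end + flank_bp)
        seq = genome[ann.chrom][fs:fe].upper()
        entries.append(RepeatEntry(i, ann.name, ann.family, ann.chrom, fs, fe, seq))
    return RepeatDB(entries=entries, flank_bp=flank_bp)


def distinct_coverage_bp(annotations, flank_bp=0):
    """Distinct genomic bp covered by (optionally flanked) annotations."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for a in annotations:
        by_chrom.setdefault(a.chrom, []).append((max(0, a.start - flank_bp), a.end + flank_bp))
    total = 0
    for ivs in by_chrom.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s
    return total


def build_coding_db(source) -> CodingDB:
    """Load coding transcript sequences from FASTA, dropping all-N records."""
    entries = []
    n_records = 0
    for rec in SeqIO.parse(str(source), "fasta"):
        n_records += 1
        seq = str(rec.seq).upper()
        if not seq:
            continue
        _check_alphabet(seq, f"coding record {rec.id}")
        if set(seq) == {"N"}:
            logger.warning("coding record %s is all N; dropped", rec.id)
            continue
        entries.append((rec.id, seq))
    if n_records == 0:
        raise ValueError(f"empty coding FASTA: {source}")
    return CodingDB(entries=entries)
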