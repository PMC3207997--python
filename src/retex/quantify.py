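"""Family-level read counting and frequency summaries.

Because the repeat database is internally repetitive, reads are not assigned
to loci: each read contributes its single best hit to the *family* of the
entry it hit, accumulating counts along a notional consensus element per
family.  Columns are samples (technical replicates are separate columns until
pooled); a condition label distinguishes observed libraries from the
simulated uniform-transcription datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("observed", "simulated_repeats", "simulated_ccds")


@dataclass
class FamilyCountMatrix:
    """Families x samples integer counts with per-sample condition labels."""

    counts: pd.DataFrame                      # index: families, columns: samples
    conditions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        unknown = set(self.conditions.values()) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown condition labels: {unknown}")

    @property
    def families(self):
        return list(self.counts.index)

    @property
    def samples(self):
        return list(self.counts.columns)

    def columns_for(self, condition: str):
        return [s for s in self.samples if self.conditions.get(s) == condition]

    def subset(self, condition: str) -> "FamilyCountMatrix":
        cols = self.columns_for(condition)
        return FamilyCountMatrix(self.counts[cols].copy(),
                                 {c: condition for c in cols})

    def hstack(self, other: "FamilyCountMatrix") -> "FamilyCountMatrix":
        if list(self.counts.index) != list(other.counts.index):
            raise ValueError("family ordering mismatch")
        return FamilyCountMatrix(pd.concat([self.counts, other.counts], axis=1),
                                 {**self.conditions, **other.conditions})

    def write(self, path):
        out = self.counts.copy()
        out.index.name = "family"
        with open(path, "w") as fh:
            fh.write("#conditions\t" + "\t".join(
                self.conditions.get(s, "observed") for s in out.columns) + "\n")
            out.to_csv(fh, sep="\t")

    @classmethod
    def read(cls, path):
        with open(path) as fh:
            first = fh.readline().rstrip("\n").split("\t")
            df = pd.read_csv(fh, sep="\t", index_col=0)
        conditions = dict(zip(df.columns, first[1:]))
        return cls(df, conditions)


def count_by_family(alignments: pd.DataFrame, families, sample_id: str,
                    known_entries=None) -> pd.Series:
    """One count column: reads per family from a one-hit-per-read table.

    ``families`` fixes row order; families with no hits get 0.  If
    ``known_entries`` is given, hits referencing entries outside it raise.
    """
    families = list(families)
    if alignments["read_id"].duplicated().any():
        raise ValueError("alignment table has more than one row for some read")
    if known_entries is not None:
        bad = set(alignments["entry_id"]) - set(known_entries)
        if bad:
            raise ValueError(f"alignments reference unknown entries: {sorted(bad)[:5]}")
    grouped = alignments.groupby("family").size()
    unknown = set(grouped.index) - set(families)
    if unknown:
        raise ValueError(f"hit families outside taxonomy: {sorted(unknown)}")
    col = grouped.reindex(families, fill_value=0).astype(np.int64)
    col.name = sample_id
    return col


def assemble_matrix(columns: list[pd.Series], condition: str | dict) -> FamilyCountMatrix:
    df = pd.concat(columns, axis=1)
    if isinstance(condition, str):
        conditions = {c: condition for c in df.columns}
    else:
        conditions = dict(condition)
    return FamilyCountMatrix(df, conditions)


def pool_samples(matrix: FamilyCountMatrix, pool_map: dict[str, str]) -> FamilyCountMatrix:
    """Sum technical-replicate columns into biological samples.

    ``pool_map`` maps each column to its pooled sample id; pooling is an
    elementwise count sum.  Conditions must agree within a pool.
    """
    pooled = {}
    conditions = {}
    for col in matrix.samples:
        target = pool_map.get(col, col)
        pooled.setdefault(target, []).append(col)
        cond = matrix.conditions.get(col, "observed")
        if conditions.setdefault(target, cond) != cond:
            raise ValueError(f"pool {target} mixes conditions")
    df = pd.DataFrame({t: matrix.counts[cols].sum(axis=1) for t, cols in pooled.items()})
    return FamilyCountMatrix(df, conditions)


def frequencies(matrix: FamilyCountMatrix) -> pd.DataFrame:
    """Per-sample family frequencies (columns sum to 1).

    Zero-depth columns are returned as NaN and flagged with a warning rather
    than raising, so partial runs remain inspectable.
    """
    totals = matrix.counts.sum(axis=0)
    freq = matrix.counts / totals.replace(0, np.nan)
    return freq


def frequency_summary(matrix: FamilyCountMatrix) -> pd.DataFrame:
    """Mean +/- sd of family frequencies per condition.

    The mean is the frequency of the pooled counts over the condition's
    samples (pooling the samples); the sd is the across-sample standard
    deviation of per-sample frequencies.
    """
    freq = frequencies(matrix)
    rows = {}
    for cond in CONDITIONS:
        cols = matrix.columns_for(cond)
        if not cols:
            continue
        pooled = matrix.counts[cols].sum(axis=1)
        rows[(cond, "mean")] = pooled / pooled.sum() if pooled.sum() else pooled * np.nan
        rows[(cond, "sd")] = freq[cols].std(axis=1, ddof=1) if len(cols) > 1 else 0.0
    return pd.DataFrame(rows)


def compartment_counts(unique_alignments: pd.DataFrame,
                       compartments: dict[str, pd.DataFrame],
                       mappable_total: int,
                       read_len: int = 76) -> pd.DataFrame:
    """Count genome-unique reads falling inside each compartment.

    ``compartments`` maps a name (e.g. ``intronic``, ``intergenic``) to a BED
    frame with columns chrom/start/end; intervals must be disjoint across
    compartments.  A read is assigned when its alignment interval lies fully
    within a compartment interval.  Returns counts and fractions of
    ``mappable_total``.
    """
    ivs = []
    for name, bed in compartments.items():
        for _, row in bed.iterrows():
            ivs.append((row["chrom"], int(row["start"]), int(row["end"]), name))
    by_chrom: dict[str, list] = {}
    for chrom, s, e, name in sorted(ivs):
        lst = by_chrom.setdefault(chrom, [])
        if lst and s < lst[-1][1]:
            raise ValueError(
                f"compartment intervals overlap on {chrom}: "
                f"{lst[-1][3]} [{lst[-1][0]},{lst[-1][1]}) vs {name} [{s},{e})")
        lst.append((s, e, None, name))

    counts = {name: 0 for name in compartments}
    for _, row in unique_alignments.iterrows():
        chrom, start = row["entry_id"], int(row["offset"])
        end = start + read_len
        lst = by_chrom.get(chrom)
        if not lst:
            continue
        starts = [iv[0] for iv in lst]
        i = np.searchsorted(starts, start, side="right") - 1
        if i >= 0 and lst[i][0] <= start and end <= lst[i][1]:
            counts[lst[i][3]] += 1

    rows = []
    for name in compartments:
        frac = counts[name] / mappable_total if mappable_total else np.nan
        rows.append({"compartment": name, "reads": counts[name], "fraction": frac})
    return pd.DataFrame(rows)


def repeat_fraction(aligned_to_repeats: int, mappable_total: int) -> float:
    """Fraction of mappable reads assigned to the repeat database."""
    if mappable_total <= 0:
        raise ValueError("mappable_total must be positive")
    frac = aligned_to_repeats / mappable_total
    if not 0.0 <= frac <= 1.0:
        raise ValueError("aligned_to_repeats exceeds mappable_total")
    return frac
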