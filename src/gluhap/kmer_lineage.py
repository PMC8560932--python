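"""Lineage classification of genome bins from lineage-specific k-mer counts.

A 100-kb bin of a (wheat) assembly is assigned to a lineage when that
lineage's specific k-mer count exceeds every other lineage's count by more
than a margin (default 0.01% of the bin size).  Colocalization asks which
lineage the bins overlapping a query gene belong to.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "UNASSIGNED",
    "margin_for",
    "classify_bins",
    "colocalize_gene",
    "ColocalizationCall",
    "read_bin_counts",
    "classification_to_bed",
]

UNASSIGNED = "UNASSIGNED"
DEFAULT_BIN_SIZE = 100_000
DEFAULT_MARGIN_FRACTION = 0.0001  # 0.01% of the bin size


def margin_for(bin_size: int, margin_fraction: float = DEFAULT_MARGIN_FRACTION) -> float:
    """Count margin for a bin: ``margin_fraction * bin_size`` (10 for 100 kb)."""
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    if margin_fraction < 0:
        raise ValueError("margin_fraction must be >= 0")
    return margin_fraction * bin_size


def _count_columns(counts: pd.DataFrame) -> list[str]:
    cols = [c for c in counts.columns if c.startswith("count_")]
    if len(cols) < 2:
        raise ValueError("need count_<lineage> columns for at least 2 lineages")
    return cols


def classify_bins(counts: pd.DataFrame, margin: float) -> pd.DataFrame:
    """Assign each bin to the lineage that beats all others by > margin.

    The rule is applied symmetrically to every lineage column; ties at
    exactly ``count_L == count_M + margin`` stay UNASSIGNED (strict
    inequality).  Returns a copy with an ``assigned`` column.
    """
    cols = _count_columns(counts)
    out = counts.copy()
    assigned = pd.Series(UNASSIGNED, index=counts.index, dtype=object)
    for col in cols:
        others = [c for c in cols if c != col]
        wins = pd.Series(True, index=counts.index)
        for oc in others:
            wins &= counts[col] > counts[oc] + margin
        assigned[wins] = col.removeprefix("count_")
    out["assigned"] = assigned
    return out


@dataclass(frozen=True)
class ColocalizationCall:
    """Lineage assignment of the bins overlapping a gene interval."""

    chrom: str
    start: int
    end: int
    bins: tuple[tuple[int, str], ...]  # (bin_start, assigned lineage)
    consensus: str  # single lineage, UNASSIGNED, or MIXED

    @property
    def lineages(self) -> tuple[str, ...]:
        return tuple(sorted({l for _, l in self.bins}))


def colocalize_gene(
    classification: pd.DataFrame,
    chrom: str,
    start: int,
    end: int,
    bin_size: int = DEFAULT_BIN_SIZE,
    assembly: str | None = None,
) -> ColocalizationCall:
    """Lineage call(s) of every classified bin overlapping a 1-based interval.

    A 1-based position p falls in bin ``floor((p-1)/bin_size)``, so an
    interval boundary exactly at a bin edge counts only the containing bin.
    """
    df = classification
    if assembly is not None:
        df = df[df["assembly"] == assembly]
    if chrom not in set(df["chrom"]):
        raise ValueError(f"chromosome {chrom!r} absent from bin classification")
    if start > end:
        raise ValueError("start > end")
    first = (start - 1) // bin_size * bin_size
    last = (end - 1) // bin_size * bin_size
    sel = df[(df["chrom"] == chrom) & (df["bin_start"] >= first) & (df["bin_start"] <= last)]
    sel = sel.sort_values("bin_start")
    bins = tuple((int(r.bin_start), str(r.assigned)) for r in sel.itertuples())
    if not bins:
        raise ValueError(
            f"no classified bins overlap {chrom}:{start}-{end} (bin_size={bin_size})"
        )
    uniq = sorted({l for _, l in bins})
    consensus = uniq[0] if len(uniq) == 1 else "MIXED"
    return ColocalizationCall(chrom, start, end, bins, consensus)


def read_bin_counts(path) -> pd.DataFrame:
    """Bin count TSV: assembly, chrom, bin_start, count_<lineage>..."""
    df = pd.read_csv(path, sep="\t")
    required = {"assembly", "chrom", "bin_start"}
    if not required <= set(df.columns):
        raise ValueError(f"bin count table must have columns {sorted(required)}")
    _count_columns(df)
    return df


def classification_to_bed(classification: pd.DataFrame, path, bin_size: int = DEFAULT_BIN_SIZE) -> None:
    """Classified bins as BED (0-based half-open, name = assigned lineage)."""
    with open(path, "w") as fh:
        for r in classification.itertuples():
            fh.write(f"{r.chrom}\t{int(r.bin_start)}\t{int(r.bin_start) + bin_size}\t{r.assigned}\n")
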