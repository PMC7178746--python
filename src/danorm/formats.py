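"""Fragment and interval I/O plus coordinate-level preprocessing.

ATAC-seq paired-end fragments arrive as 10-column BEDPE (one line per proper
pair, both mate intervals and strands).  This module parses and writes that
dialect, applies the Tn5 insertion-site correction, collapses records to the
"minimal" fragment-span dialect used for counting, and removes intervals
overlapping blacklisted genome regions.

All coordinates are 0-based half-open (BED family convention).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd

from ._intervals import overlap_any_mask

#: Canonical 10 BEDPE columns, in file order.
BEDPE_COLUMNS = [
    "chrom1", "start1", "end1",
    "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2",
]

_INT_COLS = ["start1", "end1", "start2", "end2"]


class BedpeFormatError(ValueError):
    """Raised for malformed BEDPE input; message carries the line number."""


@dataclasses.dataclass
class FragmentSet:
    """A collection of paired-end fragments (10-column BEDPE dialect).

    df holds the ten standard columns (coordinates as int64, name/score/strands
    as strings) plus any extra columns preserved verbatim.  `tn5_shifted` is a
    provenance flag: the Tn5 correction must be applied exactly once.
    """

    df: pd.DataFrame
    tn5_shifted: bool = False
    extra_columns: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "FragmentSet":
        return FragmentSet(self.df.copy(), self.tn5_shifted, self.extra_columns)


@dataclasses.dataclass
class GenomeTable:
    """Ordered chromosome -> length (bp) map."""

    lengths: dict[str, int]

    def __post_init__(self):
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    def __getitem__(self, chrom: str) -> int:
        return self.lengths[chrom]

    def __iter__(self):
        return iter(self.lengths)

    def items(self):
        return self.lengths.items()


@dataclasses.dataclass
class RegionSet:
    """Genomic intervals (peaks, windows, bins or promoters) with scores.

    df columns: chrom, start, end, name, score, strand.  `provenance`
    records what the intervals are.
    """

    df: pd.DataFrame
    provenance: str = "peaks"

    REQUIRED = ("chrom", "start", "end")

    def __post_init__(self):
        df = self.df
        for col, default in (("name", "."), ("score", 0.0), ("strand", ".")):
            if col not in df.columns:
                df = df.assign(**{col: default})
        if len(df) and not (df["start"] < df["end"]).all():
            bad = df.index[df["start"] >= df["end"]][0]
            raise ValueError(f"region {bad}: start >= end")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def validate_genome(self, genome: GenomeTable) -> None:
        for c, s, e in zip(self.df["chrom"], self.df["start"], self.df["end"]):
            if c not in genome.lengths:
                raise ValueError(f"chromosome {c!r} absent from genome table")
            if s < 0 or e > genome[c]:
                raise ValueError(f"interval {c}:{s}-{e} outside chromosome bounds")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_chrom_sizes(path) -> GenomeTable:
    """Read a UCSC-style chrom.sizes file (name<TAB>length)."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected name<TAB>length")
            name = parts[0]
            if name in lengths:
                raise ValueError(f"{path}: line {lineno}: duplicate chromosome {name!r}")
            lengths[name] = int(parts[1])
    return GenomeTable(lengths)


def read_bedpe(path) -> FragmentSet:
    """Parse 10-column BEDPE.  Extra columns beyond the ten are preserved.

    Raises BedpeFormatError naming the offending line for short lines,
    non-integer coordinates, start >= end, or mates on different chromosomes.
    """
    rows: list[list[str]] = []
    n_extra = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise BedpeFormatError(
                    f"{path}: line {lineno}: expected >=10 tab-separated columns, "
                    f"got {len(parts)}")
            try:
                s1, e1, s2, e2 = (int(parts[i]) for i in (1, 2, 4, 5))
            except ValueError as exc:
                raise BedpeFormatError(
                    f"{path}: line {lineno}: non-integer coordinate ({exc})") from None
            if s1 < 0 or s2 < 0 or s1 >= e1 or s2 >= e2:
                raise BedpeFormatError(
                    f"{path}: line {lineno}: require 0 <= start < end for each mate")
            if parts[0] != parts[3]:
                raise BedpeFormatError(
                    f"{path}: line {lineno}: mates on different chromosomes")
            n_extra = max(n_extra, len(parts) - 10)
            rows.append(parts)
    extra_names = tuple(f"extra{i + 1}" for i in range(n_extra))
    cols = BEDPE_COLUMNS + list(extra_names)
    norm_rows = [r + [""] * (len(cols) - len(r)) for r in rows]
    df = pd.DataFrame(norm_rows, columns=cols) if rows else pd.DataFrame(columns=cols)
    for c in _INT_COLS:
        df[c] = df[c].astype(np.int64) if len(df) else df[c].astype(np.int64)
    return FragmentSet(df, tn5_shifted=False, extra_columns=extra_names)


def write_bedpe(frags: FragmentSet, path) -> None:
    """Write 10 standard columns (plus preserved extras) tab-separated."""
    cols = BEDPE_COLUMNS + list(frags.extra_columns)
    with open(path, "w") as fh:
        for row in frags.df[cols].itertuples(index=False):
            fh.write("\t".join(str(v) for v in row) + "\n")


def read_minimal(path) -> pd.DataFrame:
    """Read minimal (3-column) fragment records: chrom, start, end."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={"chrom": str, "start": np.int64, "end": np.int64})
    if len(df) and not (df["start"] < df["end"]).all():
        raise ValueError(f"{path}: minimal fragment with start >= end")
    return df


def write_minimal(frags: pd.DataFrame, path) -> None:
    frags[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def _read_bedlike(path, ncols_expected, names, provenance) -> RegionSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=names,
                     dtype={"chrom": str})
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return RegionSet(df[[c for c in df.columns if c in
                         ("chrom", "start", "end", "name", "score", "strand")]],
                     provenance=provenance)


def read_bed(path, provenance="peaks") -> RegionSet:
    """Read BED3 or BED6 (extra columns ignored)."""
    probe = pd.read_csv(path, sep="\t", header=None, comment="#", nrows=1)
    ncol = probe.shape[1]
    base = ["chrom", "start", "end", "name", "score", "strand"]
    names = base[:min(ncol, 6)] + [f"x{i}" for i in range(max(0, ncol - 6))]
    return _read_bedlike(path, ncol, names, provenance)


def read_broadpeak(path, provenance="peaks") -> RegionSet:
    """ENCODE broadPeak: BED6 + signalValue, pValue, qValue (9 columns)."""
    names = ["chrom", "start", "end", "name", "score", "strand",
             "signalValue", "pValue", "qValue"]
    return _read_bedlike(path, 9, names, provenance)


def read_narrowpeak(path, provenance="peaks") -> RegionSet:
    """ENCODE narrowPeak: broadPeak + summit offset (10 columns)."""
    names = ["chrom", "start", "end", "name", "score", "strand",
             "signalValue", "pValue", "qValue", "peak"]
    return _read_bedlike(path, 10, names, provenance)


def write_bed6(regions: RegionSet, path) -> None:
    regions.df[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Coordinate-level preprocessing
# ---------------------------------------------------------------------------

def tn5_shift(frags: FragmentSet) -> FragmentSet:
    """Correct fragment 5' ends for the 9-bp duplication Tn5 leaves at each
    insertion site: plus-strand mates have their start increased by 4 bp,
    minus-strand mates their end decreased by 5 bp.

    Raises ValueError if any strand is not '+'/'-', if the shift would
    produce start >= end, or if it was already applied (provenance flag).
    """
    if frags.tn5_shifted:
        raise ValueError("fragments already Tn5-shifted; refusing to shift twice")
    df = frags.df.copy()
    if len(df) == 0:
        return FragmentSet(df, tn5_shifted=True, extra_columns=frags.extra_columns)
    for mate in ("1", "2"):
        strand = df[f"strand{mate}"]
        bad = ~strand.isin(["+", "-"])
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"record {i} ({df['name'].iloc[i]}): mate {mate} strand "
                f"{strand.iloc[i]!r} is not '+' or '-'")
        plus = (strand == "+").to_numpy()
        start = df[f"start{mate}"].to_numpy(copy=True)
        end = df[f"end{mate}"].to_numpy(copy=True)
        start[plus] += 4
        end[~plus] -= 5
        bad = (start >= end) | (start < 0)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"record {i} ({df['name'].iloc[i]}): Tn5 shift of mate {mate} "
                f"produces invalid interval [{start[i]}, {end[i]})")
        df[f"start{mate}"] = start
        df[f"end{mate}"] = end
    return FragmentSet(df, tn5_shifted=True, extra_columns=frags.extra_columns)


def bedpe_minimal_convert(frags: FragmentSet) -> pd.DataFrame:
    """Collapse each pair to its outermost fragment span
    [min(mate starts), max(mate ends)).

    The strand pair is carried along so fragment identity (for duplicate
    counting) is preserved.
    """
    df = frags.df
    out = pd.DataFrame({
        "chrom": df["chrom1"].to_numpy(),
        "start": np.minimum(df["start1"].to_numpy(), df["start2"].to_numpy())
        if len(df) else np.array([], dtype=np.int64),
        "end": np.maximum(df["end1"].to_numpy(), df["end2"].to_numpy())
        if len(df) else np.array([], dtype=np.int64),
    })
    if len(df):
        out["name"] = df["name"].to_numpy()
        out["strand1"] = df["strand1"].to_numpy()
        out["strand2"] = df["strand2"].to_numpy()
    else:
        out["name"] = pd.Series(dtype=str)
        out["strand1"] = pd.Series(dtype=str)
        out["strand2"] = pd.Series(dtype=str)
    return out


def filter_blacklist(obj, blacklist: RegionSet):
    """Drop records overlapping any blacklist interval by >= 1 bp.

    Accepts a RegionSet or a minimal-fragment DataFrame; returns the same
    type with survivor order preserved.
    """
    if len(blacklist) == 0:
        return obj
    if isinstance(obj, RegionSet):
        mask = overlap_any_mask(obj.df, blacklist.df)
        return RegionSet(obj.df[~mask].reset_index(drop=True),
                         provenance=obj.provenance)
    mask = overlap_any_mask(obj, blacklist.df)
    return obj[~mask].reset_index(drop=True)


def drop_chromosomes(obj, chroms: Iterable[str]):
    """Remove records on user-named chromosomes (e.g. chrM)."""
    names = set(chroms)
    if isinstance(obj, FragmentSet):
        keep = ~obj.df["chrom1"].isin(names)
        return FragmentSet(obj.df[keep].reset_index(drop=True),
                           obj.tn5_shifted, obj.extra_columns)
    if isinstance(obj, RegionSet):
        keep = ~obj.df["chrom"].isin(names)
        return RegionSet(obj.df[keep].reset_index(drop=True), obj.provenance)
    keep = ~obj["chrom"].isin(names)
    return obj[keep].reset_index(drop=True)
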