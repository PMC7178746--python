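"""Fragment counting over regions, windows and large genomic bins, plus
FRiP and log2-CPM abundance transforms."""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from ._intervals import overlap_hits
from .formats import GenomeTable, RegionSet


@dataclasses.dataclass
class CountMatrix:
    """Integer fragment counts: m regions x n samples.

    lib_sizes are per-sample total fragment counts of the FULL library (not
    column sums; regions typically cover a small genome fraction).
    conditions assigns each sample to an experimental group.
    """

    regions: RegionSet
    samples: list[str]
    conditions: list[str]
    counts: np.ndarray
    lib_sizes: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.lib_sizes = np.asarray(self.lib_sizes, dtype=float)
        m, n = self.counts.shape
        if m != len(self.regions):
            raise ValueError("counts rows != number of regions")
        if n != len(self.samples) or n != len(self.conditions):
            raise ValueError("counts columns != number of samples/conditions")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def shape(self):
        return self.counts.shape

    def subset_rows(self, mask) -> "CountMatrix":
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            RegionSet(self.regions.df.iloc[idx].reset_index(drop=True),
                      provenance=self.regions.provenance),
            self.samples, self.conditions, self.counts[idx], self.lib_sizes)

    # -- TSV + JSON sidecar interchange ------------------------------------
    def to_tsv(self, path, sidecar=None):
        df = self.regions.df[["chrom", "start", "end", "name"]].copy()
        for j, s in enumerate(self.samples):
            df[s] = self.counts[:, j]
        df.to_csv(path, sep="\t", index=False)
        if sidecar is not None:
            with open(sidecar, "w") as fh:
                json.dump({"samples": self.samples,
                           "conditions": self.conditions,
                           "lib_sizes": self.lib_sizes.tolist()}, fh, indent=1)

    @classmethod
    def from_tsv(cls, path, sidecar=None) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t")
        meta_cols = ["chrom", "start", "end", "name"]
        samples = [c for c in df.columns if c not in meta_cols]
        counts = df[samples].to_numpy(dtype=np.int64)
        regions = RegionSet(df[meta_cols])
        if sidecar is not None:
            with open(sidecar) as fh:
                meta = json.load(fh)
            return cls(regions, meta["samples"], meta["conditions"], counts,
                       np.asarray(meta["lib_sizes"], dtype=float))
        return cls(regions, samples, ["?"] * len(samples), counts,
                   counts.sum(axis=0).astype(float))


def count_fragments(fragments: dict[str, pd.DataFrame], regions: RegionSet,
                    conditions: dict[str, str],
                    lib_sizes: dict[str, int] | None = None,
                    mode: str = "overlap") -> CountMatrix:
    """Count per-sample fragments in regions.

    ``mode="overlap"``: a fragment increments every region it overlaps by
    >= 1 bp (so one fragment can contribute to two adjacent regions).
    ``mode="midpoint"``: a fragment is assigned to the region(s) containing
    its midpoint.  Library sizes default to total fragments per library.
    """
    samples = list(fragments)
    m = len(regions)
    counts = np.zeros((m, len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        frag = fragments[s]
        if mode == "midpoint":
            mid = (frag["start"] + frag["end"]) // 2
            frag = pd.DataFrame({"chrom": frag["chrom"], "start": mid,
                                 "end": mid + 1})
        elif mode != "overlap":
            raise ValueError(f"unknown counting mode {mode!r}")
        for hit_rows in overlap_hits(frag, regions.df):
            for g in hit_rows:
                counts[g, j] += 1
    libs = np.array([lib_sizes[s] if lib_sizes else len(fragments[s])
                     for s in samples], dtype=float)
    return CountMatrix(regions, samples, [conditions[s] for s in samples],
                       counts, libs)


def bin_genome_counts(fragments: dict[str, pd.DataFrame], genome: GenomeTable,
                      conditions: dict[str, str], bin_width: int = 10_000,
                      lib_sizes: dict[str, int] | None = None) -> CountMatrix:
    """Counts in non-overlapping genome tiles of ``bin_width`` bp (the last
    partial tile of each chromosome is dropped).  These large bins feed TMM
    scale-factor estimation."""
    rows = []
    for chrom, length in genome.items():
        for s in range(0, (length // bin_width) * bin_width, bin_width):
            rows.append((chrom, s, s + bin_width))
    bins = RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]),
                     provenance="bins")
    return count_fragments(fragments, bins, conditions, lib_sizes=lib_sizes)


def frip(counts: CountMatrix) -> np.ndarray:
    """Fraction of reads in peaks per sample: in-peak column sum / library size."""
    if (counts.lib_sizes <= 0).any():
        raise ValueError("library sizes must be positive for FRiP")
    return counts.counts.sum(axis=0) / counts.lib_sizes


def log2cpm(counts: np.ndarray, effective_lib_sizes: np.ndarray,
            prior: float = 0.5) -> np.ndarray:
    """voom-style log2 counts per million:
    log2((count + prior) / (L_eff + 1) * 1e6)."""
    L = np.asarray(effective_lib_sizes, dtype=float)
    if (L <= 0).any():
        raise ValueError("effective library sizes must be positive")
    return np.log2((np.asarray(counts, dtype=float) + prior) / (L + 1.0) * 1e6)


def ave_log2cpm(counts: np.ndarray, effective_lib_sizes: np.ndarray,
                prior: float = 0.5) -> np.ndarray:
    """Per-region average log2-CPM (the MA-plot abundance axis A)."""
    return log2cpm(counts, effective_lib_sizes, prior).mean(axis=1)
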