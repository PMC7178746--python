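"""Query-region definition: naive-overlap consensus peaks and de-novo
sliding windows with local-background enrichment filtering.

Two routes produce the regions over which accessibility is compared:

* ``naive_overlap`` — the ENCODE reproducibility rule: keep pooled-replicate
  peaks that overlap every individual replicate's peak set by at least 50%.
* ``make_windows`` + ``local_enrichment_filter`` + ``abundance_filter`` —
  genome-wide fixed-width windows (default 300 bp), kept when their fragment
  density exceeds a fold threshold (default 3x) over the surrounding local
  neighborhood (default 2 kb) and their average abundance clears a log2-CPM
  floor.  Significant windows are merged after testing, with a Simes combined
  p-value per merged region so type-I error control survives the merge.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from ._intervals import build_trees
from .formats import GenomeTable, RegionSet


@dataclasses.dataclass
class WindowConfig:
    """Sliding-window parameters.

    width/spacing/neighborhood in bp; fold_threshold is a linear fold of
    window fragment density over neighborhood density; min_abundance is an
    average log2-CPM floor (None = derive from a 5-fragment pseudo-region,
    see ``default_min_abundance``).
    """

    width: int = 300
    spacing: int | None = None
    neighborhood: int = 2000
    fold_threshold: float = 3.0
    min_abundance: float | None = None

    def __post_init__(self):
        if self.spacing is None:
            self.spacing = self.width
        if self.width <= 0 or self.spacing <= 0:
            raise ValueError("width and spacing must be positive")
        if self.neighborhood <= self.width:
            raise ValueError("neighborhood must exceed window width")
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")


def naive_overlap(pooled: RegionSet, replicates: list[RegionSet],
                  mode: str = "either") -> RegionSet:
    """ENCODE naive-overlap consensus: pooled peaks confirmed by every replicate.

    A pooled peak P is kept iff for EVERY replicate set there is a replicate
    peak R overlapping it by >= 50% of min(len(P), len(R)) (``mode="either"``,
    the `bedtools intersect -e -f 0.5 -F 0.5` semantics) or >= 50% of len(P)
    (``mode="pooled"``).  Output preserves pooled input order.
    """
    if len(replicates) < 2:
        raise ValueError("naive overlap requires >= 2 replicate peak sets")
    if mode not in ("either", "pooled"):
        raise ValueError(f"unknown overlap mode {mode!r}")
    pdf = pooled.df
    keep = np.ones(len(pdf), dtype=bool)
    for rep in replicates:
        trees = build_trees(rep.df)
        rstart = rep.df["start"].to_numpy()
        rend = rep.df["end"].to_numpy()
        for i, (c, s, e) in enumerate(zip(pdf["chrom"], pdf["start"], pdf["end"])):
            if not keep[i]:
                continue
            tree = trees.get(c)
            ok = False
            if tree is not None:
                for iv in tree.overlap(int(s), int(e)):
                    j = iv.data
                    ov = min(e, rend[j]) - max(s, rstart[j])
                    lp = e - s
                    lr = rend[j] - rstart[j]
                    denom = min(lp, lr) if mode == "either" else lp
                    if ov * 2 >= denom:
                        ok = True
                        break
            keep[i] &= ok
    return RegionSet(pdf[keep].reset_index(drop=True), provenance="peaks")


def make_windows(genome: GenomeTable, cfg: WindowConfig) -> RegionSet:
    """Tile each chromosome with fixed-width windows starting at 0, stepping
    by ``cfg.spacing``; windows running past the chromosome end are dropped."""
    rows = []
    for chrom, length in genome.items():
        starts = np.arange(0, length - cfg.width + 1, cfg.spacing, dtype=np.int64)
        for s in starts:
            rows.append((chrom, int(s), int(s + cfg.width)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"]) if rows else \
        pd.DataFrame(columns=["chrom", "start", "end"])
    if len(df):
        df["name"] = [f"win_{c}_{s}" for c, s in zip(df["chrom"], df["start"])]
    return RegionSet(df, provenance="windows")


def local_enrichment_filter(window_counts, neighborhood_counts,
                            cfg: WindowConfig) -> np.ndarray:
    """Keep-mask: window fragment density > fold_threshold x neighborhood density.

    Counts are pooled across samples.  Neighborhood counts must exclude the
    window's own fragments and cover (neighborhood - width) bp.  The
    neighborhood count is first scaled to the window's footprint, then a
    0.5-count continuity correction enters numerator and denominator, so an
    empty window over an empty neighborhood has ratio exactly 1 and is
    dropped for any threshold > 1.
    """
    if window_counts.counts.shape[0] != neighborhood_counts.counts.shape[0]:
        raise ValueError("window and neighborhood matrices are not row-aligned")
    w = window_counts.counts.sum(axis=1).astype(float)
    b = neighborhood_counts.counts.sum(axis=1).astype(float)
    scaled_b = b * cfg.width / (cfg.neighborhood - cfg.width)
    return (w + 0.5) / (scaled_b + 0.5) > cfg.fold_threshold


def default_min_abundance(lib_sizes: np.ndarray, prior: float = 0.5) -> float:
    """Average log2-CPM of a hypothetical region holding 5 fragments at the
    mean library size — the default low-abundance floor."""
    mean_lib = float(np.mean(lib_sizes))
    return float(np.log2((5 + prior) / (mean_lib + 1) * 1e6))


def abundance_filter(counts, min_abundance: float | None = None,
                     effective_lib_sizes: np.ndarray | None = None) -> np.ndarray:
    """Keep-mask: average log2-CPM across samples >= min_abundance."""
    from .quantify import log2cpm

    lib = counts.lib_sizes if effective_lib_sizes is None else effective_lib_sizes
    if min_abundance is None:
        min_abundance = default_min_abundance(lib)
    ave = log2cpm(counts.counts, lib).mean(axis=1)
    return ave >= min_abundance


def simes(pvals: np.ndarray) -> float:
    """Simes combined p-value: min over ranked p of k*p_(i)/i."""
    p = np.sort(np.asarray(pvals, dtype=float))
    k = len(p)
    if k == 0:
        raise ValueError("no p-values to combine")
    return float(np.min(k * p / np.arange(1, k + 1)))


@dataclasses.dataclass
class MergedRegion:
    chrom: str
    start: int
    end: int
    members: list[int]
    p_combined: float
    logfc: float  # representative: member with smallest p


def merge_windows(da: pd.DataFrame, gap: int = 100) -> pd.DataFrame:
    """Merge tested windows within ``gap`` bp on the same chromosome.

    ``da`` needs columns chrom/start/end/p/logFC, coordinate-sorted within
    chromosome.  Each merged region gets a Simes combined p over its member
    windows and the logFC of its smallest-p member; BH-FDR is then applied
    across merged regions.
    """
    from .datest import bh_fdr

    required = {"chrom", "start", "end", "p", "logFC"}
    if not required <= set(da.columns):
        raise ValueError(f"merge_windows needs columns {sorted(required)}")
    regions: list[MergedRegion] = []
    for chrom, sub in da.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        idx = sub.index.to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur = [0]
        for i in range(1, len(sub)):
            if starts[i] - ends[max(cur)] <= gap:
                cur.append(i)
            else:
                regions.append(_finish_cluster(chrom, sub, idx, starts, ends, cur))
                cur = [i]
        if cur:
            regions.append(_finish_cluster(chrom, sub, idx, starts, ends, cur))
    out = pd.DataFrame({
        "chrom": [r.chrom for r in regions],
        "start": [r.start for r in regions],
        "end": [r.end for r in regions],
        "n_windows": [len(r.members) for r in regions],
        "members": [r.members for r in regions],
        "p": [r.p_combined for r in regions],
        "logFC": [r.logfc for r in regions],
    })
    out["q"] = bh_fdr(out["p"].to_numpy()) if len(out) else []
    return out


def _finish_cluster(chrom, sub, idx, starts, ends, cur) -> MergedRegion:
    pv = sub["p"].to_numpy()[cur]
    lf = sub["logFC"].to_numpy()[cur]
    best = int(np.argmin(pv))
    return MergedRegion(
        chrom=chrom,
        start=int(starts[cur].min()),
        end=int(ends[cur].max()),
        members=[int(idx[i]) for i in cur],
        p_combined=simes(pv),
        logfc=float(lf[best]),
    )


def encode_score(p: float, cap: float = 1000.0) -> float:
    """ENCODE-style score column: -log10(p), capped."""
    with np.errstate(divide="ignore"):
        return float(min(-np.log10(max(p, 1e-300)), cap))
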