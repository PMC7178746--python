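"""Per-chromosome interval-tree helpers shared by the overlap operations."""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd
from intervaltree import IntervalTree


def build_trees(df: pd.DataFrame, chrom="chrom", start="start", end="end"):
    """Build one IntervalTree per chromosome; tree data = positional row index.

    Coordinates are 0-based half-open, matching intervaltree's native
    semantics (a query [s, e) hits stored [a, b) iff s < b and a < e).
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for i, (c, s, e) in enumerate(
        zip(df[chrom].to_numpy(), df[start].to_numpy(), df[end].to_numpy())
    ):
        trees[c].addi(int(s), int(e), i)
    return trees


def overlap_any_mask(query: pd.DataFrame, subject: pd.DataFrame,
                     qcols=("chrom", "start", "end")) -> np.ndarray:
    """Boolean mask over `query` rows: True iff the row overlaps any subject
    interval by >= 1 bp."""
    trees = build_trees(subject)
    qc, qs, qe = (query[c].to_numpy() for c in qcols)
    mask = np.zeros(len(query), dtype=bool)
    for i in range(len(query)):
        t = trees.get(qc[i])
        if t is not None and t.overlaps(int(qs[i]), int(qe[i])):
            mask[i] = True
    return mask


def overlap_hits(query: pd.DataFrame, subject: pd.DataFrame) -> list[list[int]]:
    """For each query row, positional indices of all overlapping subject rows."""
    trees = build_trees(subject)
    out: list[list[int]] = []
    for c, s, e in zip(query["chrom"].to_numpy(), query["start"].to_numpy(),
                       query["end"].to_numpy()):
        t = trees.get(c)
        if t is None:
            out.append([])
        else:
            out.append(sorted(iv.data for iv in t.overlap(int(s), int(e))))
    return out
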