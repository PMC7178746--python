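"""Count-normalization methods for differential accessibility.

Six interchangeable methods, each encoding a different assumption about
what between-library differences are technical:

* ``libsize`` — scale to total library size; trusts global differences as
  possibly real, corrects only sequencing depth.
* ``reads_in_peaks`` — scale to in-peak column sums; removes global
  efficiency differences (FRiP differences) between libraries.
* ``tmm`` — trimmed mean of M-values over large genomic bins; assumes most
  bins unchanged, robust to a minority of true changes.
* ``loess`` — per-sample local regression of M on A; removes any
  abundance-dependent (trended) bias, assuming a symmetric null bulk.
* ``quantile`` — forces identical signal distributions across libraries
  (applied to log2-CPM).
* ``none``/``log2cpm_only`` — depth scaling only, via the log2-CPM transform.

Factor methods return per-sample scale factors (geometric mean 1) consumed
as effective library sizes; loess returns per-observation log2-scale
offsets; quantile returns the transformed matrix itself.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

from .quantify import CountMatrix


@dataclasses.dataclass
class NormalizationResult:
    """Output of one normalization method.

    Exactly one of ``factors`` (per-sample, geometric mean 1), ``offsets``
    (m x n log2-scale, row-centered) or ``transformed`` (m x n matrix) is
    set, depending on the method.  ``effective_lib_sizes`` = L_i * s_i for
    factor methods, plain L_i otherwise.
    """

    method: str
    effective_lib_sizes: np.ndarray
    factors: np.ndarray | None = None
    offsets: np.ndarray | None = None
    transformed: np.ndarray | None = None


def _geomean_one(raw: np.ndarray) -> np.ndarray:
    raw = np.asarray(raw, dtype=float)
    if (raw <= 0).any():
        raise ValueError("non-positive scale factor")
    return raw / np.exp(np.mean(np.log(raw)))


def norm_libsize(counts: CountMatrix) -> NormalizationResult:
    """Scale factors proportional to total library size, geometric mean 1."""
    if (counts.lib_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    s = _geomean_one(counts.lib_sizes)
    return NormalizationResult("libsize", counts.lib_sizes * s, factors=s)


def norm_reads_in_peaks(counts: CountMatrix) -> NormalizationResult:
    """Like libsize but with in-peak column sums as the depth measure, so
    out-of-peak (efficiency) differences do not enter the factors."""
    colsums = counts.counts.sum(axis=0).astype(float)
    if (colsums <= 0).any():
        raise ValueError("a sample has zero reads in peaks")
    s = _geomean_one(colsums)
    return NormalizationResult("reads_in_peaks", counts.lib_sizes * s, factors=s)


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

def _tmm_pair_factor(obs: np.ndarray, ref: np.ndarray, lib_obs: float,
                     lib_ref: float, logratio_trim: float,
                     abundance_trim: float) -> float:
    """TMM factor of one sample against the reference column.

    Bins with a zero in either sample are excluded pairwise.  Trimming
    discards the trim fraction from EACH tail (edgeR's rank bounds:
    keep floor(n*trim)+1 .. n - floor(n*trim)), so logratio_trim=0.30
    removes the most extreme 30% of M values on each side — this is what
    makes the factor ignore an asymmetric minority of truly changing bins.
    The factor is the precision-weighted mean of surviving M values with
    delta-method weights 1 / ((L-y)/(Ly) + (Lr-yr)/(Lr yr)), on the linear
    scale.
    """
    keep = (obs > 0) & (ref > 0)
    o = obs[keep].astype(float)
    r = ref[keep].astype(float)
    n = len(o)
    if n == 0:
        return 1.0
    po, pr = o / lib_obs, r / lib_ref
    M = np.log2(po / pr)
    A = 0.5 * np.log2(po * pr)
    var = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)

    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abundance_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(M)
    rank_a = rankdata(A)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if keep2.sum() < 10:
        warnings.warn("fewer than 10 bins survive TMM trimming; "
                      "falling back to the untrimmed weighted mean")
        keep2 = np.ones(n, dtype=bool)
    w = 1.0 / var[keep2]
    f = 2.0 ** (np.sum(w * M[keep2]) / np.sum(w))
    return float(f) if np.isfinite(f) and f > 0 else 1.0


def norm_tmm(bin_counts: CountMatrix, logratio_trim: float = 0.30,
             abundance_trim: float = 0.05) -> NormalizationResult:
    """Trimmed mean of M-values over large genomic bins (edgeR defaults:
    trim 30% per tail by M, 5% per tail by A; upper-quartile reference
    column)."""
    y = bin_counts.counts.astype(float)
    if y.shape[1] < 2:
        raise ValueError("TMM needs >= 2 samples")
    lib = bin_counts.lib_sizes.astype(float)
    # Reference: column whose upper-quartile CPM is closest to the mean.
    f75 = np.array([np.quantile(y[:, j] / lib[j], 0.75) for j in range(y.shape[1])])
    refcol = int(np.argmin(np.abs(f75 - f75.mean())))
    raw = np.array([
        1.0 if j == refcol else
        _tmm_pair_factor(y[:, j], y[:, refcol], lib[j], lib[refcol],
                         logratio_trim, abundance_trim)
        for j in range(y.shape[1])
    ])
    s = _geomean_one(raw)
    return NormalizationResult("tmm", lib * s, factors=s)


# ---------------------------------------------------------------------------
# Loess
# ---------------------------------------------------------------------------

def norm_loess(counts: CountMatrix, span: float = 0.7,
               iterations: int = 3) -> NormalizationResult:
    """Abundance-dependent offsets from a robust local-linear fit of M on A.

    Works on log2(count + 0.5).  For each sample the deviation from the
    per-region row mean (M_gi) is smoothed against the row mean (A_g) with
    tricube-weighted local linear regression (span ``span``, ``iterations``
    robustifying reweights).  The default span of 0.7 follows the cyclic-
    loess normalization convention: the bias being removed is smooth in
    abundance, and a wide neighborhood keeps a truly-changing minority of
    regions from dragging the fit while the robust reweights protect the
    trend shape.  The fit is the per-observation offset, then
    offsets are row-centered so they sum to zero across samples within each
    region.  Downstream log2 abundances are corrected by subtraction.
    """
    y = np.log2(counts.counts.astype(float) + 0.5)
    A = y.mean(axis=1)
    m, n = y.shape
    offsets = np.zeros((m, n))
    if np.ptp(A) > 0:
        order = np.argsort(A, kind="stable")
        delta = 0.01 * np.ptp(A)  # R lowess-style interpolation shortcut
        for j in range(n):
            M = y[:, j] - A
            fit = lowess(M[order], A[order], frac=span, it=iterations,
                         delta=delta, return_sorted=False)
            offsets[order, j] = fit
        offsets -= offsets.mean(axis=1, keepdims=True)
    return NormalizationResult("loess", counts.lib_sizes.astype(float),
                               offsets=offsets)


# ---------------------------------------------------------------------------
# Quantile
# ---------------------------------------------------------------------------

def norm_quantile(mat: np.ndarray) -> NormalizationResult:
    """Classic quantile normalization of a (log2-CPM) matrix.

    Target distribution = across-column mean of order statistics; each value
    maps to the target at its within-column rank, ties receiving the mean of
    their target quantiles (implemented by interpolating the target at
    average ranks).  All output columns share identical sorted values.
    """
    x = np.asarray(mat, dtype=float)
    if np.isnan(x).any():
        raise ValueError("quantile normalization requires complete data")
    m, n = x.shape
    target = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    grid = np.arange(1, m + 1, dtype=float)
    for j in range(n):
        ranks = rankdata(x[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, target)
    return NormalizationResult("quantile", np.full(n, np.nan), transformed=out)


def norm_none(counts: CountMatrix) -> NormalizationResult:
    """Depth scaling only (the plain log2-CPM route)."""
    return NormalizationResult("log2cpm_only", counts.lib_sizes.astype(float),
                               factors=np.ones(len(counts.samples)))
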