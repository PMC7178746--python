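"""Differential-accessibility testing.

Primary engine: weighted linear modeling on (normalized) log2-CPM with
empirical-Bayes variance moderation — per-region weighted least squares, a
scaled-inverse-chi-square prior on residual variances fitted by
moment-matching on log s^2, and a moderated t-statistic with d0 + d_g
degrees of freedom.  Precision weights come from a mean-variance trend fit
(the voom idiom).

Secondary engine: a two-group negative-binomial exact test conditional on
the per-region total, with a method-of-moments common dispersion.

Both feed Benjamini–Hochberg FDR control.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, polygamma
from scipy.stats import norm as normal_dist
from scipy.stats import t as t_dist
from statsmodels.nonparametric.smoothers_lowess import lowess

from .normalize import (NormalizationResult, norm_libsize, norm_loess,
                        norm_none, norm_quantile, norm_reads_in_peaks,
                        norm_tmm)
from .quantify import CountMatrix, log2cpm


@dataclasses.dataclass
class EBayesParams:
    """Empirical-Bayes variance-moderation hyperparameters."""

    d0: float            # prior degrees of freedom (may be inf)
    s0_sq: float         # prior variance
    d_resid: float       # residual df per region (n - p)


def design_matrix(conditions: list[str]):
    """Two-group design: intercept + indicator of the second condition (in
    order of first appearance).  Returns (X, contrast); the contrast picks
    the condition effect, so logFC = second condition minus first."""
    levels = list(dict.fromkeys(conditions))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 conditions, got {levels}")
    x = np.column_stack([np.ones(len(conditions)),
                         [1.0 if c == levels[1] else 0.0 for c in conditions]])
    return x, np.array([0.0, 1.0])


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(p, dtype=float)
    if len(p) == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values outside [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# voom-style precision weights
# ---------------------------------------------------------------------------

def voom_weights(y: np.ndarray, design: np.ndarray, span: float = 0.5) -> np.ndarray:
    """Precision weights from the mean-variance trend of log2 abundances.

    Per-region OLS residual standard deviations are square-root-transformed
    and smoothed (lowess, ``span``) against mean abundance; each observation's
    weight is predicted-sqrt-sd at its fitted value, raised to the -4th power
    and clipped to [1e-6, 1e6].  Requires residual df >= 1 (replication).
    """
    y = np.asarray(y, dtype=float)
    m, n = y.shape
    p = design.shape[1]
    if n - p < 1:
        raise ValueError("no residual degrees of freedom: replicates required")
    pinv = np.linalg.pinv(design)           # p x n
    beta = y @ pinv.T                       # m x p
    fitted = beta @ design.T                # m x n
    resid = y - fitted
    s = np.sqrt((resid ** 2).sum(axis=1) / (n - p))
    sqrt_s = np.sqrt(s)
    abund = y.mean(axis=1)
    if np.ptp(abund) == 0:
        pred = np.full_like(y, sqrt_s.mean())
    else:
        trend = lowess(sqrt_s, abund, frac=span, it=3,
                       delta=0.01 * np.ptp(abund), return_sorted=True)
        tx, ty = trend[:, 0], trend[:, 1]
        tx, idx = np.unique(tx, return_index=True)
        ty = ty[idx]
        pred = np.interp(fitted, tx, ty)
    w = pred.astype(float) ** -4
    return np.clip(w, 1e-6, 1e6)


# ---------------------------------------------------------------------------
# Moderated linear-model engine
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_fdist(s_sq: np.ndarray, d: float) -> tuple[float, float]:
    """Moment-match a scaled-F prior to observed residual variances.

    On e_g = log s_g^2 - digamma(d/2) + log(d/2): the excess of var(e) over
    trigamma(d/2) identifies the prior df d0 via the trigamma inverse, and
    mean(e) identifies the prior variance s0^2.  Zero variances are excluded.
    Returns (d0, s0_sq); d0 = inf when the observed spread is no larger than
    the chi-square sampling spread.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    s_sq = s_sq[s_sq > 0]
    if len(s_sq) < 2:
        return np.inf, float(np.mean(s_sq)) if len(s_sq) else 1.0
    e = np.log(s_sq) - digamma(d / 2) + np.log(d / 2)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, d / 2))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + digamma(d0 / 2) - np.log(d0 / 2)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return d0, s0_sq


def fit_moderated(y: np.ndarray, weights: np.ndarray | None,
                  design: np.ndarray, contrast: np.ndarray,
                  abundance: np.ndarray | None = None,
                  d0_override: float | None = None):
    """Per-region weighted least squares with empirical-Bayes moderation.

    Returns (DAResult frame without thresholding, EBayesParams).  Columns:
    logFC (contrast estimate, log2), A (abundance), t, p, q.
    ``d0_override`` forces the prior df (0 recovers the ordinary t-test).
    """
    y = np.asarray(y, dtype=float)
    m, n = y.shape
    x = np.asarray(design, dtype=float)
    p = x.shape[1]
    d = n - p
    if d < 1:
        raise ValueError("residual df < 1")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)

    xtwx = np.einsum("np,gn,nq->gpq", x, w, x)          # m x p x p
    xtwy = np.einsum("np,gn->gp", x, w * y)             # m x p
    beta = np.linalg.solve(xtwx, xtwy[..., None])[..., 0]
    resid = y - beta @ x.T
    s_sq = np.einsum("gn,gn->g", w, resid ** 2) / d
    cov_unscaled = np.linalg.inv(xtwx)
    v = np.einsum("p,gpq,q->g", contrast, cov_unscaled, contrast)

    if d0_override is not None:
        d0 = float(d0_override)
        s0_sq = float(np.median(s_sq[s_sq > 0])) if np.isfinite(d0) and d0 > 0 \
            else float(np.median(s_sq[s_sq > 0])) if len(s_sq) else 1.0
    else:
        d0, s0_sq = fit_fdist(s_sq, d)
    if np.isinf(d0):
        s_post = np.full(m, s0_sq)
    elif d0 == 0:
        s_post = s_sq.copy()
    else:
        s_post = (d0 * s0_sq + d * s_sq) / (d0 + d)
    s_post = np.maximum(s_post, 1e-300)

    logfc = beta @ contrast
    tstat = logfc / np.sqrt(s_post * v)
    df_total = d0 + d
    if np.isinf(df_total):
        pvals = 2.0 * normal_dist.sf(np.abs(tstat))
    else:
        pvals = 2.0 * t_dist.sf(np.abs(tstat), df_total)
    res = pd.DataFrame({
        "logFC": logfc,
        "A": y.mean(axis=1) if abundance is None else np.asarray(abundance),
        "t": tstat,
        "p": pvals,
        "q": bh_fdr(pvals),
    })
    return res, EBayesParams(d0=d0, s0_sq=s0_sq, d_resid=d)


# ---------------------------------------------------------------------------
# Negative-binomial exact test
# ---------------------------------------------------------------------------

def estimate_common_dispersion(counts: np.ndarray, conditions: list[str]) -> float:
    """Method-of-moments common NB dispersion (variance = mu + phi mu^2):
    phi = mean over regions of max(0, (s^2 - mu) / mu^2), with the pooled
    within-group sample variance and overall mean per region."""
    y = np.asarray(counts, dtype=float)
    cond = np.asarray(conditions)
    groups = list(dict.fromkeys(conditions))
    ss = np.zeros(y.shape[0])
    dfree = 0
    for g in groups:
        cols = cond == g
        ng = cols.sum()
        if ng > 1:
            ss += (ng - 1) * y[:, cols].var(axis=1, ddof=1)
            dfree += ng - 1
    if dfree == 0:
        raise ValueError("no within-group replication for dispersion estimation")
    s2 = ss / dfree
    mu = y.mean(axis=1)
    ok = mu > 0
    phi = np.maximum(0.0, (s2[ok] - mu[ok]) / mu[ok] ** 2)
    return float(phi.mean()) if ok.any() else 0.0


def _log_conditional_pmf(s: int, r_a: float, r_b: float) -> np.ndarray:
    """log P(S_A = k | S_A + S_B = s) for sums of iid NB variables sharing
    the success probability: a negative-hypergeometric (beta-binomial) law
    with shape parameters (r_a, r_b).  Vectorized over k = 0..s."""
    k = np.arange(s + 1, dtype=float)
    logp = (gammaln(k + r_a) - gammaln(k + 1) - gammaln(r_a)
            + gammaln(s - k + r_b) - gammaln(s - k + 1) - gammaln(r_b)
            - (gammaln(s + r_a + r_b) - gammaln(s + 1.0) - gammaln(r_a + r_b)))
    return logp - np.logaddexp.reduce(logp)  # renormalize for stability


def _log_binom_pmf(s: int, prob: float) -> np.ndarray:
    k = np.arange(s + 1, dtype=float)
    return (gammaln(s + 1.0) - gammaln(k + 1) - gammaln(s - k + 1)
            + k * np.log(prob) + (s - k) * np.log1p(-prob))


def nb_exact_test(counts: CountMatrix,
                  effective_lib_sizes: np.ndarray | None = None,
                  dispersion: float | None = None,
                  tie_split: bool = False) -> pd.DataFrame:
    """Two-group exact test on counts rescaled to a common effective depth.

    Counts are multiplied by (geometric-mean effective size / own effective
    size) and rounded; conditional on each region's total, the group-A sum
    follows a beta-binomial law with shapes n_A/phi, n_B/phi (binomial when
    phi = 0).  Two-sided p doubles the smaller tail (capped at 1);
    ``tie_split`` uses half the observed point mass instead (mid-p style
    halving of the boundary term in both tails).
    """
    groups = list(dict.fromkeys(counts.conditions))
    if len(groups) != 2:
        raise ValueError("exact test needs exactly 2 conditions")
    cond = np.asarray(counts.conditions)
    cols_a = cond == groups[0]
    cols_b = cond == groups[1]
    n_a, n_b = int(cols_a.sum()), int(cols_b.sum())

    lib = counts.lib_sizes if effective_lib_sizes is None else \
        np.asarray(effective_lib_sizes, dtype=float)
    common = np.exp(np.mean(np.log(lib)))
    y = np.rint(counts.counts * (common / lib)[None, :]).astype(np.int64)

    if dispersion is None:
        dispersion = estimate_common_dispersion(y, list(cond))
    phi = float(dispersion)

    sum_a = y[:, cols_a].sum(axis=1)
    sum_b = y[:, cols_b].sum(axis=1)
    tot = sum_a + sum_b
    pvals = np.ones(len(tot))
    for g in range(len(tot)):
        s = int(tot[g])
        if s == 0:
            continue
        if phi > 0:
            logp = _log_conditional_pmf(s, n_a / phi, n_b / phi)
        else:
            logp = _log_binom_pmf(s, n_a / (n_a + n_b))
        pmf = np.exp(logp)
        a = int(sum_a[g])
        point = pmf[a]
        lower = pmf[: a + 1].sum()
        upper = pmf[a:].sum()
        if tie_split:
            lower -= 0.5 * point
            upper -= 0.5 * point
        pvals[g] = min(1.0, 2.0 * min(lower, upper))

    lambda_a = counts.counts[:, cols_a].sum(axis=1) / n_a
    lambda_b = counts.counts[:, cols_b].sum(axis=1) / n_b
    logfc = np.log2((sum_b / n_b + 0.5) / (sum_a / n_a + 0.5))
    a_val = 0.5 * np.log2(np.maximum(lambda_a * lambda_b, 0.25))
    return pd.DataFrame({"logFC": logfc, "A": a_val, "p": pvals,
                         "q": bh_fdr(pvals)})


# ---------------------------------------------------------------------------
# Orchestration of one full approach (Table-style grid row)
# ---------------------------------------------------------------------------

NORMALIZERS = ("libsize", "reads_in_peaks", "tmm", "loess", "quantile", "none")


def run_approach(counts: CountMatrix, method: str, engine: str = "moderated",
                 bins: CountMatrix | None = None, fdr: float = 0.10,
                 min_abundance: float | None = None,
                 filter_low_abundance: bool = False) -> tuple[pd.DataFrame, dict]:
    """One complete DA analysis: optional abundance filter, normalization,
    testing engine, BH-FDR and direction calls.

    ``method`` chooses the normalization; ``engine`` is "moderated"
    (weighted linear model + empirical Bayes) or "nb_exact" (factor-based
    normalizations only).  TMM uses ``bins`` (large genomic bins) when
    supplied, else the count matrix itself.  Returns (result frame with
    region coordinates, approach descriptor dict).
    """
    from .peaks import abundance_filter

    if method not in NORMALIZERS:
        raise ValueError(f"unknown normalization {method!r}")
    if engine not in ("moderated", "nb_exact"):
        raise ValueError(f"unknown engine {engine!r}")
    if engine == "nb_exact" and method in ("quantile", "loess"):
        raise ValueError(f"{method} normalization is incompatible with the "
                         "count-scale exact test")

    work = counts
    if filter_low_abundance:
        keep = abundance_filter(counts, min_abundance)
        work = counts.subset_rows(keep)

    if method == "libsize":
        nr = norm_libsize(work)
    elif method == "reads_in_peaks":
        nr = norm_reads_in_peaks(work)
    elif method == "tmm":
        nr = norm_tmm(bins if bins is not None else work)
        nr = NormalizationResult("tmm", work.lib_sizes * nr.factors,
                                 factors=nr.factors)
    elif method == "loess":
        nr = norm_loess(work)
    elif method == "quantile":
        base = log2cpm(work.counts, work.lib_sizes)
        nr = norm_quantile(base)
        nr.effective_lib_sizes = work.lib_sizes.astype(float)
    else:
        nr = norm_none(work)

    design, contrast = design_matrix(work.conditions)
    if engine == "moderated":
        if nr.transformed is not None:
            y = nr.transformed
        else:
            y = log2cpm(work.counts, nr.effective_lib_sizes)
            if nr.offsets is not None:
                y = y - nr.offsets
        w = voom_weights(y, design)
        res, eb = fit_moderated(y, w, design, contrast)
    else:
        res = nb_exact_test(work, effective_lib_sizes=nr.effective_lib_sizes)
        eb = None

    res = pd.concat(
        [work.regions.df[["chrom", "start", "end", "name"]].reset_index(drop=True),
         res.reset_index(drop=True)], axis=1)
    res["direction"] = np.where(res["q"] < fdr, np.sign(res["logFC"]), 0.0)
    descriptor = {
        "regions": counts.regions.provenance,
        "normalization": method,
        "engine": engine,
        "fdr": fdr,
        "m_tested": int(len(res)),
        "factors": None if nr.factors is None else nr.factors.tolist(),
    }
    if eb is not None:
        descriptor["d0"] = float(eb.d0)
        descriptor["s0_sq"] = float(eb.s0_sq)
    return res, descriptor
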