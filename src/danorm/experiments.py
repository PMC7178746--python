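"""Self-contained validation experiments on synthetic data.

Each function simulates its own inputs from a seed, runs the package's
machinery, and returns the measured quantities.  They encode the package's
reference study conditions (documented in the methods note):

* normalization oracles — TMM vs. an independent brute-force trimmed
  weighted mean, quantile's defining sorted-column identity, loess removal
  of an injected linear M(A) trend;
* the direction-flip experiment — 20% of regions truly gaining
  accessibility; depth scaling preserves the asymmetry while conservative
  normalizations redistribute significance symmetrically;
* null calibration — no signal, no bias: discoveries should be rare and
  the realized false-discovery rate bounded by the nominal level;
* complexity machinery — Lander-Waterman recovery of a planted molecule
  count, the thinning expectation against empirical thinning, and
  reproducibility of DA calls across subsampling seeds;
* exact small-instance oracles — consensus peaks, the NB exact test,
  Simes/BH, and hypergeometric enrichment against direct enumeration;
* the end-to-end fragment pipeline with planted differential peaks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import binomtest, rankdata

from . import diagnostics, pipeline, quantify, synthetic
from .complexity import (DuplicateHistogram, estimate_complexity,
                         expected_distinct_after_thinning)
from .datest import bh_fdr, nb_exact_test, run_approach
from .formats import RegionSet
from .normalize import norm_loess, norm_quantile, norm_tmm
from .peaks import naive_overlap, simes
from .quantify import log2cpm


# ---------------------------------------------------------------------------
# 1. Normalization oracles
# ---------------------------------------------------------------------------

def _tmm_bruteforce(counts, lib, logratio_trim=0.30, abundance_trim=0.05):
    """Plain-python TMM: explicit ranks, trims and weighted mean, written
    independently of the vectorized implementation."""
    counts = np.asarray(counts, dtype=float)
    m, n = counts.shape
    f75 = [np.quantile(counts[:, j] / lib[j], 0.75) for j in range(n)]
    ref = int(np.argmin(np.abs(np.array(f75) - np.mean(f75))))
    raw = []
    for j in range(n):
        if j == ref:
            raw.append(1.0)
            continue
        rows = [g for g in range(m) if counts[g, j] > 0 and counts[g, ref] > 0]
        M = {g: np.log2((counts[g, j] / lib[j]) / (counts[g, ref] / lib[ref]))
             for g in rows}
        A = {g: 0.5 * np.log2((counts[g, j] / lib[j])
                              * (counts[g, ref] / lib[ref])) for g in rows}
        w = {g: 1.0 / ((lib[j] - counts[g, j]) / (lib[j] * counts[g, j])
                       + (lib[ref] - counts[g, ref]) / (lib[ref] * counts[g, ref]))
             for g in rows}
        k = len(rows)
        lo_m = int(np.floor(k * logratio_trim)) + 1
        lo_a = int(np.floor(k * abundance_trim)) + 1
        rm = dict(zip(rows, rankdata([M[g] for g in rows])))
        ra = dict(zip(rows, rankdata([A[g] for g in rows])))
        keep = [g for g in rows if lo_m <= rm[g] <= k + 1 - lo_m
                and lo_a <= ra[g] <= k + 1 - lo_a]
        if len(keep) < 10:
            keep = rows
        raw.append(2.0 ** (sum(w[g] * M[g] for g in keep)
                           / sum(w[g] for g in keep)))
    raw = np.asarray(raw)
    return raw / np.exp(np.mean(np.log(raw)))


def normalization_oracles(seed: int) -> dict:
    rng = np.random.default_rng(seed)

    # TMM vs brute force on a <=1,000-bin matrix
    counts = rng.negative_binomial(10, 0.1, size=(900, 4))
    lib = counts.sum(axis=0).astype(float)
    cm = _count_matrix(counts, lib)
    tmm_diff = float(np.max(np.abs(norm_tmm(cm).factors
                                   - _tmm_bruteforce(counts, lib))))

    # quantile: all sorted output columns bit-identical
    x = rng.normal(size=(500, 5)) * np.r_[1, 2, 3, 4, 5] + np.r_[0, 1, 2, 3, 4]
    out = norm_quantile(x).transformed
    ref = np.sort(out[:, 0])
    q_diff = float(max(np.max(np.abs(np.sort(out[:, j]) - ref))
                       for j in range(1, out.shape[1])))

    # loess: injected linear M(A) trend reduced below 0.1
    cfg = synthetic.CountSimConfig(m=5000, frac_da=0.0, trend_bias=0.5,
                                   phi=0.05)
    cm2, _ = synthetic.simulate_counts(cfg, seed + 1)
    trend_before, trend_after = _residual_trend(cm2)
    return {
        "tmm_oracle_max_abs_diff": tmm_diff,
        "quantile_sorted_col_max_diff": q_diff,
        "loess_trend_before": trend_before,
        "loess_trend_after": trend_after,
        "n": 900,
    }


def _count_matrix(counts, lib):
    import pandas as pd

    m, n = counts.shape
    regions = RegionSet(pd.DataFrame({
        "chrom": "chrE", "start": np.arange(m) * 1000,
        "end": np.arange(m) * 1000 + 500,
        "name": [f"bin{g}" for g in range(m)]}), provenance="bins")
    return quantify.CountMatrix(regions, [f"s{j}" for j in range(n)],
                                ["a"] * (n // 2) + ["b"] * (n - n // 2),
                                counts, np.asarray(lib, dtype=float))


def _residual_trend(cm):
    """Max |loess trend of M on A| over the central 90% abundance range,
    before and after loess offset correction."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    cond = np.asarray(cm.conditions)
    y0 = log2cpm(cm.counts, cm.lib_sizes)
    res = norm_loess(cm)
    out = []
    for y in (y0, y0 - res.offsets):
        M = y[:, cond == cond[-1]].mean(1) - y[:, cond == cond[0]].mean(1)
        A = y0.mean(axis=1)
        order = np.argsort(A)
        fit = lowess(M[order], A[order], frac=0.5, it=3,
                     delta=0.01 * np.ptp(A), return_sorted=False)
        lo, hi = np.quantile(A, [0.05, 0.95])
        central = (A[order] >= lo) & (A[order] <= hi)
        out.append(float(np.abs(fit[central]).max()))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# 2. Direction flip
# ---------------------------------------------------------------------------

#: Study conditions of the direction-flip experiment: 20% of regions truly
#: gain accessibility (strong de-novo openings, log2 effect 4.5), no
#: technical bias, NB dispersion 0.1, three replicates per condition.
DIRECTION_FLIP_CONFIG = dict(m=10_000, n_per_condition=3, frac_da=0.2,
                             up_fraction=1.0, lfc=4.5, phi=0.1)


def direction_flip(seed: int, fdr: float = 0.10) -> dict:
    cfg = synthetic.CountSimConfig(**DIRECTION_FLIP_CONFIG)
    cm, _ = synthetic.simulate_counts(cfg, seed)
    out = {"n": cfg.m}
    for method in ("libsize", "tmm", "loess", "quantile"):
        res, _ = run_approach(cm, method, fdr=fdr)
        sig = res["q"].to_numpy() < fdr
        up = int((sig & (res["logFC"].to_numpy() > 0)).sum())
        down = int((sig & (res["logFC"].to_numpy() < 0)).sum())
        p = float(binomtest(up, up + down).pvalue) if up + down else 1.0
        out[method] = {"up": up, "down": down,
                       "up_fraction": up / max(up + down, 1),
                       "sign_binom_p": p}
    return out


# ---------------------------------------------------------------------------
# 3. Null calibration
# ---------------------------------------------------------------------------

def null_calibration(seed: int, n_reps: int = 200, m: int = 2000,
                     fdr: float = 0.05,
                     methods=("none", "libsize", "tmm", "loess",
                              "quantile")) -> dict:
    """No DA, no bias: per method, the mean number of discoveries and the
    mean false-discovery proportion (= P(any rejection) under the global
    null) over ``n_reps`` independent simulated experiments."""
    out = {"n": n_reps, "m": m}
    for method in methods:
        disc = np.zeros(n_reps)
        for r in range(n_reps):
            cfg = synthetic.CountSimConfig(m=m, frac_da=0.0)
            cm, _ = synthetic.simulate_counts(cfg, seed + 10_000 + r)
            res, _ = run_approach(cm, method, fdr=fdr)
            disc[r] = int((res["q"].to_numpy() < fdr).sum())
        fdp = (disc > 0).astype(float)  # all discoveries are false
        out[method] = {
            "mean_discoveries": float(disc.mean()),
            "empirical_fdr": float(fdp.mean()),
            "mc_bound": fdr + 2 * float(np.sqrt(fdr * (1 - fdr) / n_reps)),
        }
    return out


# ---------------------------------------------------------------------------
# 4. Complexity machinery
# ---------------------------------------------------------------------------

def complexity_recovery(seed: int, n_true: int = 10_000, reads: int = 50_000,
                        n_seeds: int = 100) -> dict:
    """Median relative error of the saturation-model complexity estimate
    over ``n_seeds`` libraries of ``reads`` draws from ``n_true`` molecules."""
    errs = []
    for k in range(n_seeds):
        rng = np.random.default_rng(seed + 20_000 + k)
        draws = rng.integers(0, n_true, size=reads)
        _, mult = np.unique(draws, return_counts=True)
        j, nj = np.unique(mult, return_counts=True)
        est = estimate_complexity(DuplicateHistogram(dict(zip(j, nj))))
        errs.append(abs(est.n_estimated - n_true) / n_true)
    return {"median_rel_error": float(np.median(errs)), "n": n_seeds}


def thinning_expectation(seed: int, reps: int = 1000, p: float = 0.4) -> dict:
    """Closed-form expected distinct count after thinning vs. the empirical
    mean over ``reps`` seeded thinnings of a 3-bin histogram."""
    h = DuplicateHistogram({1: 300, 2: 150, 4: 50})
    reads = np.repeat(np.arange(500), [1] * 300 + [2] * 150 + [4] * 50)
    means = []
    for r in range(reps):
        rng = np.random.default_rng(seed + 30_000 + r)
        kept = reads[rng.random(len(reads)) < p]
        means.append(len(np.unique(kept)))
    expected = expected_distinct_after_thinning(h, p)
    return {"expected": expected, "empirical_mean": float(np.mean(means)),
            "rel_error": float(abs(np.mean(means) - expected) / expected),
            "n": reps}


#: Conditions of the subsampling-reproducibility experiment: six deep
#: libraries (60k molecules, 114-132k reads so complexities differ), 20 of
#: 200 peaks changing threefold (half up, half down).
REPRODUCIBILITY_CONFIG = dict(
    n_molecules=(60_000,) * 6,
    n_reads=(120_000, 132_000, 114_000, 120_000, 126_000, 120_000),
    frac_da_peaks=0.1, effect=3.0)


def subsample_reproducibility(seed: int, fdr: float = 0.05) -> dict:
    """Jaccard similarity of significant DA region sets between two
    complexity-equalization subsampling seeds on the same libraries."""
    cfg = synthetic.FragmentSimConfig(**REPRODUCIBILITY_CONFIG)
    libs, genome, pk, _ = synthetic.simulate_fragments(cfg, seed)
    conds = dict(zip(libs, cfg.conditions))
    sets = []
    for sub_seed in (seed + 40_001, seed + 40_002):
        res, _ = pipeline.fragments_to_da(libs, genome, pk, conds,
                                          seed=sub_seed, method="loess",
                                          fdr=fdr)
        sets.append(set(res.loc[res["q"].to_numpy() < fdr, "name"]))
    a, b = sets
    jac = len(a & b) / max(len(a | b), 1)
    return {"jaccard": float(jac), "n_calls": [len(a), len(b)],
            "n": len(pk)}


# ---------------------------------------------------------------------------
# 5. Exact small-instance oracles
# ---------------------------------------------------------------------------

def small_instance_oracles(seed: int) -> dict:
    import pandas as pd
    from scipy.stats import nbinom

    rng = np.random.default_rng(seed + 50_000)

    # naive overlap vs all-pairs checker on random peak sets
    def rand_regions(n):
        s = rng.integers(0, 20_000, size=n)
        return RegionSet(pd.DataFrame({
            "chrom": "chr1", "start": s,
            "end": s + rng.integers(50, 400, size=n),
            "name": [f"p{i}" for i in range(n)]}))

    mismatches = 0
    for _ in range(5):
        pooled, reps = rand_regions(60), [rand_regions(50), rand_regions(50)]
        got = {(r.start, r.end) for _, r in naive_overlap(pooled, reps).df.iterrows()}
        want = set()
        for _, p in pooled.df.iterrows():
            ok_all = True
            for rep in reps:
                ok = False
                for _, r in rep.df.iterrows():
                    ov = min(p.end, r.end) - max(p.start, r.start)
                    if ov > 0 and 2 * ov >= min(p.end - p.start, r.end - r.start):
                        ok = True
                        break
                ok_all &= ok
            if ok_all:
                want.add((p.start, p.end))
        mismatches += len(got ^ want)

    # NB exact test vs enumeration through scipy's nbinom pmf
    phi = 0.2
    rows = [[int(a) for a in rng.integers(0, 8, size=4)] for _ in range(25)]
    rows = [r for r in rows if sum(r) <= 30]
    cm = _count_matrix(np.asarray(rows), np.full(4, 1000.0))
    res = nb_exact_test(cm, dispersion=phi)
    nb_diff = 0.0
    for i, r in enumerate(rows):
        s = sum(r)
        a_obs = r[0] + r[1]
        if s == 0:
            want = 1.0
        else:
            k = np.arange(s + 1)
            joint = nbinom.pmf(k, 2 / phi, 0.3) * nbinom.pmf(s - k, 2 / phi, 0.3)
            pmf = joint / joint.sum()
            want = min(1.0, 2 * min(pmf[: a_obs + 1].sum(), pmf[a_obs:].sum()))
        nb_diff = max(nb_diff, abs(res["p"].iloc[i] - want))

    # Simes and BH against direct formulas
    pv = rng.random(8)
    simes_diff = abs(simes(pv) - min(sorted(pv)[i] * 8 / (i + 1)
                                     for i in range(8)))
    pvec = rng.random(40)
    q_direct = np.minimum(1, np.array([
        min(sorted(pvec)[j] * 40 / (j + 1)
            for j in range(int(rankdata(pvec)[i]) - 1, 40))
        for i in range(40)]))
    bh_diff = float(np.max(np.abs(bh_fdr(pvec) - q_direct)))

    # hypergeometric enrichment vs combinatorial enumeration (universe <= 20)
    universe = set(range(15))
    annotated = set(rng.choice(15, size=6, replace=False).tolist())
    hits = set(rng.choice(15, size=5, replace=False).tolist())
    _, p_hyper = diagnostics.enrichment(hits, annotated, universe)
    observed = len(hits & annotated)
    total = match = 0
    for draw in itertools.combinations(universe, len(hits)):
        total += 1
        match += len(set(draw) & annotated) >= observed
    hyper_diff = abs(p_hyper - match / total)

    return {"naive_overlap_mismatches": int(mismatches),
            "nb_exact_max_abs_diff": float(nb_diff),
            "simes_abs_diff": float(simes_diff),
            "bh_max_abs_diff": bh_diff,
            "hypergeom_abs_diff": float(hyper_diff),
            "n": len(rows)}


# ---------------------------------------------------------------------------
# 6. End-to-end pipeline
# ---------------------------------------------------------------------------

#: Conditions of the end-to-end experiment: 200 peaks, 20 planted (half up,
#: half down, 2.5-fold), three replicate libraries per condition with
#: unequal depths so complexity equalization has work to do.
END_TO_END_CONFIG = dict(
    n_molecules=(30_000,) * 6,
    n_reads=(60_000, 75_000, 60_000, 50_000, 60_000, 70_000),
    frac_da_peaks=0.1, effect=2.5)


def end_to_end(seed: int, n_reps: int = 3, fdr: float = 0.10) -> dict:
    """Fragments -> shift -> minimal -> equalize -> count -> loess -> test.

    Empirical FDR is the mean false-discovery proportion over ``n_reps``
    independently simulated experiments; sensitivity is the mean fraction
    of planted peaks recovered."""
    fdps, sens = [], []
    for r in range(n_reps):
        cfg = synthetic.FragmentSimConfig(**END_TO_END_CONFIG)
        libs, genome, pk, truth = synthetic.simulate_fragments(cfg,
                                                               seed + 60_000 + r)
        conds = dict(zip(libs, cfg.conditions))
        res, _ = pipeline.fragments_to_da(libs, genome, pk, conds,
                                          seed=seed + 61_000 + r,
                                          method="loess", fdr=fdr)
        sig = res["q"].to_numpy() < fdr
        is_da = truth.is_da.to_numpy()
        tp = int((sig & is_da).sum())
        fp = int((sig & ~is_da).sum())
        fdps.append(fp / max(tp + fp, 1))
        sens.append(tp / is_da.sum())
    return {"empirical_fdr": float(np.mean(fdps)),
            "sensitivity": float(np.mean(sens)),
            "nominal_fdr": fdr, "n": n_reps}
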