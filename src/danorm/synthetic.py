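"""Synthetic data with known truth: NB count experiments with injected
normalization biases, and paired-end fragment libraries with controlled
molecular complexity.

The count generator produces the regimes whose analysis this package is
about: a configurable fraction of truly differential regions (with a
controllable up/down balance), a global efficiency multiplier on one
condition, and an abundance-dependent (trended) M distortion — the bias
shape that local regression can remove but linear scale factors cannot.
The fragment generator draws reads with replacement from a finite molecule
pool so duplication rates, and hence estimated library complexity, are
under direct control.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .formats import FragmentSet, GenomeTable, RegionSet
from .quantify import CountMatrix

BEDPE_COLS_DTYPES = {
    "chrom1": str, "start1": np.int64, "end1": np.int64,
    "chrom2": str, "start2": np.int64, "end2": np.int64,
    "name": str, "score": str, "strand1": str, "strand2": str,
}


@dataclasses.dataclass
class CountSimConfig:
    """Conditions for the NB count experiment.

    m regions, n_per_condition samples in each of two groups ("ctrl",
    "mut").  Baseline region log2-mean counts ~ Normal(baseline_mu,
    baseline_sigma) at the reference depth.  NB dispersion phi (variance =
    mu + phi mu^2; typical replicated ATAC values 0.05-0.2).  frac_da
    regions carry a true log2 fold change of magnitude lfc (up with
    probability up_fraction) in the second condition.  global_bias
    multiplies all second-condition means (efficiency bias); trend_bias adds
    an M distortion linear in baseline abundance, trend_bias * (a_g -
    mean(a)), to the second condition.  lib_sizes are expected per-sample
    fragment totals over the simulated regions.
    """

    m: int = 10_000
    n_per_condition: int = 3
    baseline_mu: float = 6.5
    baseline_sigma: float = 1.0
    phi: float = 0.1
    frac_da: float = 0.1
    lfc: float = 1.0
    up_fraction: float = 0.5
    global_bias: float = 1.0
    trend_bias: float = 0.0
    lib_sizes: np.ndarray | None = None

    def __post_init__(self):
        if not 0 <= self.frac_da <= 1:
            raise ValueError("frac_da must lie in [0, 1]")
        if self.phi < 0 or self.global_bias <= 0:
            raise ValueError("phi must be >= 0 and global_bias > 0")


def simulate_counts(cfg: CountSimConfig, seed: int):
    """Draw a two-condition NB count matrix and its truth table.

    mean_gi = L_i * q_g * 2^(x_i * (delta_g + log2(global_bias) + trend_g))
    with q_g the normalized baseline relative abundance, x_i the condition-B
    indicator, delta_g the true lfc of DA regions, and trend_g the linear-
    in-abundance distortion.  Counts ~ NB(mean, phi); Poisson when phi = 0.
    Deterministic per seed (one substream for structure, one for counts).
    """
    rng_struct = np.random.default_rng(seed)
    rng_counts = np.random.default_rng(seed + 1_000_003)
    m, n = cfg.m, cfg.n_per_condition

    a = rng_struct.normal(cfg.baseline_mu, cfg.baseline_sigma, size=m)
    q = 2.0 ** a
    q /= q.sum()

    n_da = int(round(cfg.frac_da * m))
    da_idx = rng_struct.choice(m, size=n_da, replace=False)
    is_da = np.zeros(m, dtype=bool)
    is_da[da_idx] = True
    sign = np.where(rng_struct.random(n_da) < cfg.up_fraction, 1.0, -1.0)
    true_lfc = np.zeros(m)
    true_lfc[da_idx] = sign * cfg.lfc

    trend = cfg.trend_bias * (a - a.mean())
    effect_b = true_lfc + np.log2(cfg.global_bias) + trend

    lib = np.full(2 * n, float(cfg.m) * 2.0 ** cfg.baseline_mu) \
        if cfg.lib_sizes is None else np.asarray(cfg.lib_sizes, dtype=float)
    cond_b = np.r_[np.zeros(n), np.ones(n)]
    mean = lib[None, :] * q[:, None] * 2.0 ** (cond_b[None, :] * effect_b[:, None])

    if cfg.phi == 0:
        counts = rng_counts.poisson(mean)
    else:
        r = 1.0 / cfg.phi
        counts = rng_counts.negative_binomial(r, r / (r + mean))

    samples = [f"ctrl_{i + 1}" for i in range(n)] + \
              [f"mut_{i + 1}" for i in range(n)]
    conditions = ["ctrl"] * n + ["mut"] * n
    regions = RegionSet(pd.DataFrame({
        "chrom": "chrSim",
        "start": np.arange(m, dtype=np.int64) * 1000,
        "end": np.arange(m, dtype=np.int64) * 1000 + 500,
        "name": [f"region_{g}" for g in range(m)],
    }), provenance="peaks")
    cm = CountMatrix(regions, samples, conditions, counts, lib)
    truth = pd.DataFrame({"is_da": is_da, "true_lfc": true_lfc,
                          "baseline_log2_mean": a, "trend_effect": trend})
    truth.attrs["efficiency_factor"] = {"ctrl": 1.0, "mut": cfg.global_bias}
    return cm, truth


@dataclasses.dataclass
class FragmentSimConfig:
    """Conditions for the paired-end fragment libraries.

    One chromosome of ``genome_length`` bp carrying ``n_peaks`` accessible
    peaks of ``peak_width`` bp.  Per library, ``n_molecules`` distinct
    fragments are placed (a ``frip`` fraction inside peaks, weighted by
    per-peak accessibility), then ``n_reads`` reads are drawn with
    replacement from those molecules, so R >= N makes duplication
    near-certain.  ``frac_da_peaks`` of the peaks change accessibility
    ``effect``-fold in the second condition (half up, half down when
    ``balanced``).  Fragment lengths ~ Uniform[120, 400); 50-bp mates.
    """

    genome_length: int = 1_000_000
    n_peaks: int = 200
    peak_width: int = 600
    frip: float = 0.5
    n_molecules: tuple[int, ...] = (40_000, 40_000, 40_000,
                                    40_000, 40_000, 40_000)
    n_reads: tuple[int, ...] = (80_000, 80_000, 80_000,
                                80_000, 80_000, 80_000)
    conditions: tuple[str, ...] = ("ctrl", "ctrl", "ctrl", "mut", "mut", "mut")
    frac_da_peaks: float = 0.1
    effect: float = 2.0
    balanced: bool = True

    def __post_init__(self):
        if not (len(self.n_molecules) == len(self.n_reads)
                == len(self.conditions)):
            raise ValueError("per-library tuples must share one length")
        if self.n_peaks * self.peak_width >= self.genome_length:
            raise ValueError("peaks do not fit in the genome")


def simulate_fragments(cfg: FragmentSimConfig, seed: int):
    """Generate per-library FragmentSets with controlled complexity.

    Returns (libraries: dict sample -> FragmentSet, genome, peaks: RegionSet,
    truth: DataFrame with per-peak is_da/true_fold).  Library k uses PRNG
    substream seed + 7919 * (k + 1); peak placement uses the base seed.
    """
    rng = np.random.default_rng(seed)
    n_lib = len(cfg.n_molecules)
    genome = GenomeTable({"chr1": cfg.genome_length})

    # evenly spaced peaks with lognormal accessibility weights
    gap = cfg.genome_length // cfg.n_peaks
    starts = np.arange(cfg.n_peaks) * gap + (gap - cfg.peak_width) // 2
    peaks = RegionSet(pd.DataFrame({
        "chrom": "chr1", "start": starts, "end": starts + cfg.peak_width,
        "name": [f"peak_{i}" for i in range(cfg.n_peaks)],
    }), provenance="peaks")
    base_w = rng.lognormal(0.0, 0.5, size=cfg.n_peaks)

    n_da = int(round(cfg.frac_da_peaks * cfg.n_peaks))
    da_idx = rng.choice(cfg.n_peaks, size=n_da, replace=False)
    fold = np.ones(cfg.n_peaks)
    if cfg.balanced:
        half = n_da // 2
        fold[da_idx[:half]] = cfg.effect
        fold[da_idx[half:]] = 1.0 / cfg.effect
    else:
        fold[da_idx] = cfg.effect

    libraries: dict[str, FragmentSet] = {}
    names = []
    counters: dict[str, int] = {}
    for k in range(n_lib):
        cond = cfg.conditions[k]
        counters[cond] = counters.get(cond, 0) + 1
        names.append(f"{cond}_{counters[cond]}")
    for k, sample in enumerate(names):
        lib_rng = np.random.default_rng(seed + 7919 * (k + 1))
        w = base_w * (fold if cfg.conditions[k] == "mut" else 1.0)
        n_mol = cfg.n_molecules[k]

        in_peak = lib_rng.random(n_mol) < cfg.frip
        peak_of = lib_rng.choice(cfg.n_peaks, size=n_mol, p=w / w.sum())
        length = lib_rng.integers(120, 400, size=n_mol)
        frag_start = np.empty(n_mol, dtype=np.int64)
        inside = np.flatnonzero(in_peak)
        outside = np.flatnonzero(~in_peak)
        # center uniform within the peak so molecule identities rarely collide
        centers = starts[peak_of[inside]] + lib_rng.integers(
            0, cfg.peak_width, size=len(inside))
        frag_start[inside] = centers - length[inside] // 2
        frag_start[outside] = lib_rng.integers(
            0, cfg.genome_length - 400, size=len(outside))
        frag_start = np.clip(frag_start, 0, cfg.genome_length - 401)
        frag_end = frag_start + length

        draws = lib_rng.integers(0, n_mol, size=cfg.n_reads[k])
        s = frag_start[draws]
        e = frag_end[draws]
        df = pd.DataFrame({
            "chrom1": "chr1", "start1": s, "end1": s + 50,
            "chrom2": "chr1", "start2": e - 50, "end2": e,
            "name": [f"{sample}_r{i}" for i in range(len(draws))],
            "score": ".", "strand1": "+", "strand2": "-",
        })
        libraries[sample] = FragmentSet(df)

    truth = pd.DataFrame({"peak": peaks.df["name"], "is_da": fold != 1.0,
                          "true_fold": fold, "base_weight": base_w})
    return libraries, genome, peaks, truth
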