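"""Library molecular complexity: estimation from duplicate frequencies and
seeded subsampling to equalize complexity across libraries.

PCR duplication rates carry information about how many distinct molecules a
library contains.  From the duplicate-frequency histogram (how many distinct
fragment identities were seen exactly j times) we estimate the number of
distinct molecules in the underlying library with the Lander–Waterman
saturation model C = N(1 - exp(-R/N)), then thin deeper libraries by seeded
Bernoulli subsampling so all libraries reach the same expected number of
distinct fragments.  Unequal complexity otherwise confounds count
comparisons between conditions.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .formats import FragmentSet


@dataclasses.dataclass
class DuplicateHistogram:
    """Map j -> n_j: number of distinct fragment identities seen exactly j times."""

    counts: dict[int, int]

    def __post_init__(self):
        for j, n in self.counts.items():
            if j < 1 or n < 0 or int(j) != j or int(n) != n:
                raise ValueError(f"invalid histogram entry {j}: {n}")
        self.counts = {int(j): int(n) for j, n in sorted(self.counts.items()) if n > 0}

    @property
    def distinct(self) -> int:
        """C = sum n_j, the number of distinct identities observed."""
        return sum(self.counts.values())

    @property
    def reads(self) -> int:
        """R = sum j * n_j, the total number of records."""
        return sum(j * n for j, n in self.counts.items())


@dataclasses.dataclass
class ComplexityEstimate:
    n_estimated: float      # N-hat: distinct molecules in the underlying library
    distinct: int           # C observed
    reads: int              # R observed
    method: str = "lander-waterman"


def duplicate_histogram(fragments: pd.DataFrame) -> DuplicateHistogram:
    """Duplicate-frequency histogram over fragment identity tuples.

    Identity = (chrom, start, end) plus the strand pair when present, so two
    fragments count as duplicates only if they share all coordinates.
    """
    if len(fragments) == 0:
        return DuplicateHistogram({})
    keys = ["chrom", "start", "end"]
    keys += [c for c in ("strand1", "strand2") if c in fragments.columns]
    mult = fragments.groupby(keys, observed=True).size()
    hist = mult.value_counts()
    return DuplicateHistogram({int(j): int(n) for j, n in hist.items()})


def estimate_complexity(h: DuplicateHistogram) -> ComplexityEstimate:
    """Solve C = N(1 - exp(-R/N)) for N by bisection on [C, 1e12*C].

    Requires some duplication (R > C); a fully unique library gives an
    unbounded estimate and raises ValueError.
    """
    C, R = h.distinct, h.reads
    if C == 0:
        raise ValueError("empty histogram: no fragments observed")
    if R == C:
        raise ValueError("no duplicates observed; complexity is unbounded")

    def f(n):
        return C - n * (1.0 - np.exp(-R / n))

    # f(C) = C*exp(-R/C) > 0; f(inf) -> C - R < 0, so a root is bracketed.
    n_hat = brentq(f, C, 1e12 * C, rtol=1e-9, xtol=1e-9)
    return ComplexityEstimate(float(n_hat), C, R)


def expected_distinct_after_thinning(h: DuplicateHistogram, p: float) -> float:
    """E[distinct identities] after keeping each record independently with
    probability p: sum_j n_j * (1 - (1-p)^j)."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    return float(sum(n * (1.0 - (1.0 - p) ** j) for j, n in h.counts.items()))


def solve_subsample_rate(h: DuplicateHistogram, target_distinct: float) -> float:
    """Keep-probability p whose expected distinct count equals the target.

    The expectation is strictly increasing in p, so bisection on [0, 1]
    converges; tolerance 1e-9.
    """
    C = h.distinct
    if not 0 < target_distinct <= C:
        raise ValueError(f"target {target_distinct} outside (0, C={C}]")
    if target_distinct == C:
        return 1.0

    def f(p):
        return expected_distinct_after_thinning(h, p) - target_distinct

    return float(brentq(f, 0.0, 1.0, xtol=1e-9, rtol=8.9e-16))


def subsample_fragments(fragments, p: float, seed: int, dedup: bool = False):
    """Keep each record independently with probability p (seeded generator).

    Accepts a FragmentSet or a minimal-fragment DataFrame; deterministic for
    fixed (input order, p, seed).  With ``dedup`` the survivors are collapsed
    to distinct identity tuples AFTER thinning.
    """
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    df = fragments.df if isinstance(fragments, FragmentSet) else fragments
    keep = rng.random(len(df)) < p
    out = df[keep].reset_index(drop=True)
    if dedup and len(out):
        keys = [c for c in ("chrom", "start", "end", "strand1", "strand2",
                            "chrom1", "start1", "end1", "start2", "end2")
                if c in out.columns]
        out = out.drop_duplicates(subset=keys).reset_index(drop=True)
    if isinstance(fragments, FragmentSet):
        return FragmentSet(out, fragments.tn5_shifted, fragments.extra_columns)
    return out


def equalize_complexity(libraries: list[pd.DataFrame], seed: int,
                        dedup: bool = False):
    """Thin libraries so all reach the same expected distinct-fragment count.

    The reference is the library with the smallest observed distinct count C
    (operationally, the least complex yield); every other library is thinned
    so its EXPECTED distinct count after thinning equals that C, and the
    reference is left unthinned (p = 1).  The Lander-Waterman complexity
    estimate N-hat of each library is reported alongside, since "equivalent
    complexity" can also be read as equal N-hat; thinning cannot change the
    underlying N, so the matched quantity here is the observable one.
    Per-library PRNG streams use seed + library index so adding a library
    does not perturb the others.

    Returns (thinned libraries, report DataFrame with reads/distinct/
    estimated complexity/subsample p/seed per library).
    """
    if len(libraries) < 2:
        raise ValueError("need >= 2 libraries to equalize")
    hists = [duplicate_histogram(lib if isinstance(lib, pd.DataFrame) else lib.df)
             for lib in libraries]
    ests = [estimate_complexity(h) for h in hists]
    ref = int(np.argmin([h.distinct for h in hists]))
    target = float(hists[ref].distinct)
    rates = []
    for i, h in enumerate(hists):
        if i == ref or h.distinct <= target:
            rates.append(1.0)
        else:
            rates.append(solve_subsample_rate(h, target))
    thinned = [subsample_fragments(lib, rates[i], seed + i, dedup=dedup)
               for i, lib in enumerate(libraries)]
    report = pd.DataFrame({
        "library": np.arange(len(libraries)),
        "reads": [e.reads for e in ests],
        "distinct": [e.distinct for e in ests],
        "estimated_complexity": [e.n_estimated for e in ests],
        "subsample_p": rates,
        "seed": [seed + i for i in range(len(libraries))],
        "target_distinct": target,
        "is_reference": [i == ref for i in range(len(libraries))],
    })
    return thinned, report
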