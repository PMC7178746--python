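import numpy as np
import pytest
from scipy.stats import rankdata

from danorm.normalize import (norm_libsize, norm_loess, norm_quantile,
                              norm_reads_in_peaks, norm_tmm)
from danorm.quantify import CountMatrix

from conftest import make_regions


def cm_from(counts, lib=None):
    counts = np.asarray(counts)
    m, n = counts.shape
    regions = make_regions([("chr1", i * 1000, i * 1000 + 500) for i in range(m)])
    lib = np.asarray(lib, dtype=float) if lib is not None \
        else counts.sum(axis=0).astype(float)
    return CountMatrix(regions, [f"s{j}" for j in range(n)],
                       ["a"] * (n // 2) + ["b"] * (n - n // 2), counts, lib)


class TestFactorMethods:
    def test_libsize_equal_and_ratio(self):
        cm = cm_from(np.ones((5, 2), dtype=int), lib=[1e6, 1e6])
        assert np.allclose(norm_libsize(cm).factors, 1.0)
        cm2 = cm_from(np.ones((5, 2), dtype=int), lib=[1e6, 2e6])
        f = norm_libsize(cm2).factors
        assert np.allclose(f, [1 / np.sqrt(2), np.sqrt(2)])

    def test_libsize_permutation_equivariant(self, rng):
        lib = rng.integers(1e5, 1e7, size=4).astype(float)
        cm = cm_from(np.ones((5, 4), dtype=int), lib=lib)
        f = norm_libsize(cm).factors
        perm = rng.permutation(4)
        cmp_ = cm_from(np.ones((5, 4), dtype=int), lib=lib[perm])
        assert np.allclose(norm_libsize(cmp_).factors, f[perm])

    def test_reads_in_peaks_tracks_in_peak_depth_only(self, rng):
        base = rng.integers(1, 100, size=(30, 1))
        counts = np.hstack([base, 3 * base])
        cm = cm_from(counts, lib=[1e6, 1e6])
        f = norm_reads_in_peaks(cm).factors
        assert f[1] / f[0] == pytest.approx(3.0)
        # adding out-of-peak fragments changes libsize factors, not these
        cm_more_lib = cm_from(counts, lib=[1e6, 5e6])
        assert np.allclose(norm_reads_in_peaks(cm_more_lib).factors, f)
        assert not np.allclose(norm_libsize(cm_more_lib).factors,
                               norm_libsize(cm).factors)

    def test_geometric_mean_is_one(self, rng):
        counts = rng.integers(1, 500, size=(100, 5))
        for res in (norm_libsize(cm_from(counts)),
                    norm_reads_in_peaks(cm_from(counts)),
                    norm_tmm(cm_from(counts))):
            assert np.exp(np.mean(np.log(res.factors))) == pytest.approx(1.0,
                                                                         abs=1e-12)


def tmm_oracle(counts, lib, logratio_trim=0.30, abundance_trim=0.05):
    """Independent brute-force TMM: explicit sort-based trimming and a plain
    python weighted mean, reference chosen by upper-quartile rule."""
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
        M, A, w = {}, {}, {}
        for g in rows:
            po, pr = counts[g, j] / lib[j], counts[g, ref] / lib[ref]
            M[g] = np.log2(po / pr)
            A[g] = 0.5 * np.log2(po * pr)
            w[g] = 1.0 / ((lib[j] - counts[g, j]) / (lib[j] * counts[g, j])
                          + (lib[ref] - counts[g, ref]) / (lib[ref] * counts[g, ref]))
        k = len(rows)
        lo_m = int(np.floor(k * logratio_trim)) + 1
        lo_a = int(np.floor(k * abundance_trim)) + 1
        rank_m = dict(zip(rows, rankdata([M[g] for g in rows])))
        rank_a = dict(zip(rows, rankdata([A[g] for g in rows])))
        keep = [g for g in rows
                if lo_m <= rank_m[g] <= k + 1 - lo_m
                and lo_a <= rank_a[g] <= k + 1 - lo_a]
        if len(keep) < 10:
            keep = rows
        num = sum(w[g] * M[g] for g in keep)
        den = sum(w[g] for g in keep)
        raw.append(2.0 ** (num / den))
    raw = np.asarray(raw)
    return raw / np.exp(np.mean(np.log(raw)))


class TestTMM:
    def test_pure_depth_difference_absorbed(self, rng):
        a = rng.integers(5, 200, size=(400, 1))
        counts = np.hstack([a, 2 * a])
        cm = cm_from(counts)  # lib sizes = column sums, ratio exactly 2
        assert np.allclose(norm_tmm(cm).factors, 1.0, atol=1e-10)

    def test_identical_columns_give_unit_factors(self, rng):
        a = rng.integers(5, 200, size=(300, 1))
        cm = cm_from(np.hstack([a, a]))
        assert np.allclose(norm_tmm(cm).factors, 1.0)

    def test_matches_bruteforce_oracle(self, rng):
        counts = rng.negative_binomial(10, 0.1, size=(800, 4))
        lib = counts.sum(axis=0).astype(float)
        cm = cm_from(counts, lib=lib)
        got = norm_tmm(cm).factors
        want = tmm_oracle(counts, lib)
        assert np.allclose(got, want, atol=1e-6)

    def test_minority_gain_corrected_to_null_median_zero(self, rng):
        # 1,000 null bins + 100 bins with a 4x gain in sample B
        null = rng.negative_binomial(20, 0.2, size=(1000, 1))
        gained = rng.negative_binomial(20, 0.2, size=(100, 1))
        a = np.vstack([null, gained])
        b = np.vstack([null, 4 * gained]) + 0
        counts = np.hstack([a, b])
        lib = counts.sum(axis=0).astype(float)
        cm = cm_from(counts, lib=lib)
        f = norm_tmm(cm).factors
        eff = lib * f
        nz = (counts[:1000, 0] > 0) & (counts[:1000, 1] > 0)
        m_null = np.log2((counts[:1000, 1][nz] / eff[1])
                         / (counts[:1000, 0][nz] / eff[0]))
        assert abs(np.median(m_null)) < 0.05


class TestLoess:
    def test_identical_samples_zero_offsets(self, rng):
        a = rng.integers(5, 500, size=(300, 1))
        cm = cm_from(np.hstack([a, a]))
        res = norm_loess(cm)
        assert np.abs(res.offsets).max() < 1e-8

    def test_constant_log_shift_split_evenly(self, rng):
        a = rng.integers(16, 4096, size=(500, 1))
        cm = cm_from(np.hstack([a, 2 * a]))  # +1 in log2 for sample B
        res = norm_loess(cm)
        # after row-centering the +1 shift splits into -0.5 / +0.5
        assert np.median(res.offsets[:, 1]) == pytest.approx(0.5, abs=0.02)
        assert np.median(res.offsets[:, 0]) == pytest.approx(-0.5, abs=0.02)

    def test_offsets_row_centered(self, rng):
        counts = rng.negative_binomial(5, 0.05, size=(400, 4))
        res = norm_loess(cm_from(counts))
        assert np.abs(res.offsets.mean(axis=1)).max() < 1e-12

    def test_removes_injected_linear_trend(self, rng):
        from statsmodels.nonparametric.smoothers_lowess import lowess
        m = 3000
        base = rng.normal(7, 1.5, size=m)
        noise = rng.normal(0, 0.1, size=(m, 2))
        ya = base + noise[:, 0]
        yb = base + noise[:, 1] + 0.5 * (base - base.mean())  # M = 0.5*A trend
        counts = np.rint(2 ** np.column_stack([ya, yb])).astype(int)
        cm = cm_from(counts, lib=[1e6, 1e6])
        res = norm_loess(cm)
        y = np.log2(counts + 0.5) - res.offsets
        M = y[:, 1] - y[:, 0]
        A = np.log2(counts + 0.5).mean(axis=1)
        order = np.argsort(A)
        fit = lowess(M[order], A[order], frac=0.5, it=3,
                     delta=0.01 * np.ptp(A), return_sorted=False)
        lo, hi = np.quantile(A, [0.05, 0.95])
        central = (A[order] >= lo) & (A[order] <= hi)
        assert np.abs(fit[central]).max() < 0.1


class TestQuantile:
    def test_two_column_worked_example(self):
        out = norm_quantile(np.array([[1.0, 2.0], [3.0, 4.0]])).transformed
        assert np.allclose(out, [[1.5, 1.5], [3.5, 3.5]])

    def test_identical_columns_unchanged(self, rng):
        col = rng.normal(size=50)
        x = np.column_stack([col, col, col])
        assert np.allclose(norm_quantile(x).transformed, x)

    def test_sorted_columns_identical(self, rng):
        x = rng.normal(size=(200, 4)) * [1, 2, 3, 4] + [0, 1, 2, 3]
        out = norm_quantile(x).transformed
        ref = np.sort(out[:, 0])
        for j in range(1, 4):
            assert np.allclose(np.sort(out[:, j]), ref)

    def test_ties_get_mean_target_quantile(self):
        x = np.array([[1.0, 5.0], [1.0, 6.0], [2.0, 7.0], [3.0, 8.0]])
        out = norm_quantile(x).transformed
        # the tied pair in column 0 shares the mean of target quantiles 1, 2
        assert out[0, 0] == out[1, 0]
        target = np.sort(x, axis=0).mean(axis=1)
        assert out[0, 0] == pytest.approx((target[0] + target[1]) / 2)
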