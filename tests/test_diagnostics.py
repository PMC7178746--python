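import itertools

import numpy as np
import pandas as pd
import pytest

from danorm import diagnostics as dg
from danorm.formats import RegionSet

from conftest import make_regions


def da_frame(A, M, q):
    return pd.DataFrame({"A": A, "logFC": M, "q": q})


class TestMAData:
    def test_null_data_flat_trend(self, rng):
        m = 3000
        da = da_frame(rng.normal(7, 1.5, m), rng.normal(0, 0.3, m),
                      rng.random(m))
        md = dg.ma_data(da)
        assert abs(md.median_m) < 0.05
        assert max(abs(md.trend_range[0]), abs(md.trend_range[1])) < 0.1

    def test_constant_shift_recovered(self, rng):
        m = 2000
        da = da_frame(rng.normal(7, 1.5, m), rng.normal(1.0, 0.3, m),
                      rng.random(m))
        md = dg.ma_data(da)
        assert md.trend_range[0] == pytest.approx(1.0, abs=0.1)
        assert md.trend_range[1] == pytest.approx(1.0, abs=0.1)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no regions"):
            dg.ma_data(da_frame([], [], []))


class TestFdrAtRejectionRate:
    def test_counting_example(self):
        q = np.arange(1, 21) / 100.0  # 0.01 .. 0.20
        da = da_frame(np.zeros(20), np.zeros(20), q)
        assert dg.fdr_at_rejection_rate(da, rate=0.25) == pytest.approx(0.05)

    def test_constant_q(self):
        da = da_frame(np.zeros(20), np.zeros(20), np.full(20, 0.5))
        assert dg.fdr_at_rejection_rate(da, rate=0.05) == 0.5

    def test_too_few_regions(self):
        da = da_frame(np.zeros(5), np.zeros(5), np.zeros(5))
        with pytest.raises(ValueError):
            dg.fdr_at_rejection_rate(da, rate=0.05)


def tss_set(rows):
    """rows: (chrom, pos, strand, gene)."""
    return RegionSet(pd.DataFrame(
        [(c, p, p + 1, g, 0.0, s) for c, p, s, g in rows],
        columns=["chrom", "start", "end", "name", "score", "strand"]),
        provenance="promoters")


class TestPromoterAnnotation:
    def test_symmetric_window_boundary(self):
        tss = tss_set([("chr1", 10_000, "+", "geneA")])
        prom = make_regions([("chr1", 12_999, 13_100)])   # 1 bp overlap
        dist = make_regions([("chr1", 13_000, 13_100)])   # just outside
        assert dg.annotate_promoters(prom, tss).region_class[0] == "promoter"
        assert dg.annotate_promoters(dist, tss).region_class[0] == "distal"

    def test_minus_strand_window_flipped(self):
        # yeast-style -2000/+200: on '-' the upstream side lies at larger coords
        tss = tss_set([("chr1", 50_000, "-", "geneB")])
        upstream_region = make_regions([("chr1", 51_000, 51_100)])
        ann = dg.annotate_promoters(upstream_region, tss,
                                    upstream=2000, downstream=200)
        assert ann.region_class[0] == "promoter"
        downstream_far = make_regions([("chr1", 48_000, 48_100)])
        ann2 = dg.annotate_promoters(downstream_far, tss,
                                     upstream=2000, downstream=200)
        assert ann2.region_class[0] == "distal"

    def test_best_gene_fdr_is_minimum(self):
        tss = tss_set([("chr1", 10_000, "+", "geneA")])
        regions = make_regions([("chr1", 9_000, 9_200), ("chr1", 10_500, 10_700)])
        ann = dg.annotate_promoters(regions, tss, q=np.array([0.2, 0.04]))
        assert ann.gene_best_q.loc[0, "best_q"] == pytest.approx(0.04)

    def test_classes_partition_regions_and_strand_flip_invariance(self, rng):
        tss_rows = [("chr1", int(p), s, f"g{i}") for i, (p, s) in
                    enumerate(zip(rng.integers(5_000, 95_000, 20),
                                  rng.choice(["+", "-"], 20)))]
        regions = make_regions([("chr1", int(s), int(s) + 300)
                                for s in rng.integers(0, 99_000, 50)])
        ann = dg.annotate_promoters(regions, tss_set(tss_rows))
        assert (ann.region_class == "promoter").sum() \
            + (ann.region_class == "distal").sum() == 50
        flipped = [(c, p, "-" if s == "+" else "+", g)
                   for c, p, s, g in tss_rows]
        ann_f = dg.annotate_promoters(regions, tss_set(flipped))
        assert (ann.region_class == ann_f.region_class).all()

    def test_multi_gene_links_and_nearest_only(self):
        tss = tss_set([("chr1", 10_000, "+", "near"),
                       ("chr1", 11_000, "+", "far")])
        region = make_regions([("chr1", 9_900, 10_100)])
        both = dg.annotate_promoters(region, tss)
        assert set(both.links["gene"]) == {"near", "far"}
        one = dg.annotate_promoters(region, tss, nearest_only=True)
        assert set(one.links["gene"]) == {"near"}


class TestCompare:
    def _da(self, q, lfc):
        n = len(q)
        return pd.DataFrame({"chrom": ["chr1"] * n,
                             "start": np.arange(n) * 1000,
                             "end": np.arange(n) * 1000 + 500,
                             "A": np.zeros(n), "logFC": lfc, "q": q})

    def test_identical_inputs_intersect_fully(self):
        da = self._da([0.01, 0.5, 0.02], [1.0, -0.5, -2.0])
        out = dg.compare_approaches({"x": da, "y": da.copy()}, fdr=0.10)
        assert out["per_approach"]["x"] == out["per_approach"]["y"]
        assert out["per_approach"]["x"]["up"] == 1
        assert out["per_approach"]["x"]["down"] == 1

    def test_upset_counts_match_enumeration(self):
        tss = tss_set([("chr1", (i + 1) * 10_000, "+", f"g{i}")
                       for i in range(6)])
        regions = make_regions([("chr1", (i + 1) * 10_000 - 100,
                                 (i + 1) * 10_000 + 100) for i in range(6)])
        ann = dg.annotate_promoters(regions, tss)
        # approach x significant on genes {0,1,2}; y on {2,3}; z on {5}
        qx = np.array([0.01, 0.01, 0.01, 0.9, 0.9, 0.9])
        qy = np.array([0.9, 0.9, 0.01, 0.01, 0.9, 0.9])
        qz = np.array([0.9, 0.9, 0.9, 0.9, 0.9, 0.01])
        results = {k: self._da(q, np.ones(6))
                   for k, q in [("x", qx), ("y", qy), ("z", qz)]}
        out = dg.compare_approaches(results, {k: ann for k in results},
                                    fdr=0.10)
        assert out["pairwise_gene_overlap"]["x&y"] == 1
        assert out["pairwise_gene_overlap"]["x&z"] == 0
        assert out["upset_gene_counts"] == {"x": 2, "x&y": 1, "y": 1, "z": 1}


class TestPRCurve:
    def test_perfect_separation(self):
        curve = dg.pr_curve(np.array([0.01, 0.02, 0.8, 0.9]),
                            np.array([True, True, False, False]))
        assert curve.aupr == pytest.approx(1.0)

    def test_constant_score_single_point_at_prevalence(self):
        curve = dg.pr_curve(np.full(10, 0.5),
                            np.array([True] * 3 + [False] * 7))
        assert len(curve.recall) == 1
        assert curve.precision[0] == pytest.approx(0.3)
        assert curve.aupr == pytest.approx(0.3)

    def test_four_gene_worked_case(self):
        # scores 0.9/0.8/0.7/0.6 (fdr 0.1/0.2/0.3/0.4), labels 1/0/1/0
        curve = dg.pr_curve(np.array([0.1, 0.2, 0.3, 0.4]),
                            np.array([True, False, True, False]))
        assert curve.aupr == pytest.approx((1.0 + 2 / 3) / 2)

    def test_matches_sklearn_average_precision(self, rng):
        from sklearn.metrics import average_precision_score
        fdr = rng.random(200)
        y = rng.random(200) < 0.3
        curve = dg.pr_curve(fdr, y)
        assert curve.aupr == pytest.approx(
            average_precision_score(y, 1 - fdr), abs=1e-12)

    def test_random_scores_aupr_near_prevalence(self, rng):
        y = np.r_[np.ones(30, bool), np.zeros(70, bool)]
        auprs = [dg.pr_curve(rng.random(100), y).aupr for _ in range(300)]
        assert np.mean(auprs) == pytest.approx(0.3, abs=0.03)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            dg.pr_curve(np.array([0.1]), np.array([False]))


class TestEnrichment:
    def test_worked_example(self):
        universe = set(range(10))
        annotated = set(range(5))
        hits = {0, 1, 2, 3}
        oe, p = dg.enrichment(hits, annotated, universe)
        assert oe == pytest.approx(2.0)
        assert p == pytest.approx(5 / 210)

    def test_limits(self):
        universe = set(range(10))
        s = set(range(4))
        assert dg.enrichment(universe, s, universe)[0] == pytest.approx(1.0)
        oe, p = dg.enrichment({7, 8}, s, universe)
        assert oe == 0.0 and p == pytest.approx(1.0)

    def test_matches_bruteforce_enumeration(self, rng):
        universe = set(range(12))
        annotated = set(rng.choice(12, size=5, replace=False).tolist())
        hits = set(rng.choice(12, size=4, replace=False).tolist())
        oe, p = dg.enrichment(hits, annotated, universe)
        observed = len(hits & annotated)
        total = hit = 0
        for draw in itertools.combinations(universe, len(hits)):
            total += 1
            if len(set(draw) & annotated) >= observed:
                hit += 1
        assert p == pytest.approx(hit / total, abs=1e-12)


class TestClassMeans:
    def test_known_class_shifts_recovered(self, rng):
        tss = tss_set([("chr1", (i + 1) * 5_000, "+", f"g{i}")
                       for i in range(90)])
        regions = make_regions([("chr1", (i + 1) * 5_000 - 50,
                                 (i + 1) * 5_000 + 50) for i in range(90)])
        classes = {f"g{i}": ("up" if i < 30 else "down" if i < 60 else "stable")
                   for i in range(90)}
        shift = np.r_[np.ones(30), -np.ones(30), np.zeros(30)]
        da = pd.DataFrame({"logFC": shift + rng.normal(0, 0.2, 90),
                           "A": np.zeros(90), "q": np.full(90, 0.5)})
        ann = dg.annotate_promoters(regions, tss, q=da["q"].to_numpy())
        out = dg.class_mean_logfc({"t1": da}, {"t1": ann}, classes)
        vals = out.set_index("cls")["mean_M"]
        se = 0.2 / np.sqrt(30)
        assert vals["up"] == pytest.approx(1.0, abs=4 * se)
        assert vals["down"] == pytest.approx(-1.0, abs=4 * se)
        assert vals["stable"] == pytest.approx(0.0, abs=4 * se)

    def test_single_gene_class_and_empty_class_warning(self):
        tss = tss_set([("chr1", 5_000, "+", "g0")])
        regions = make_regions([("chr1", 4_950, 5_050)])
        da = pd.DataFrame({"logFC": [0.7], "A": [0.0], "q": [0.1]})
        ann = dg.annotate_promoters(regions, tss)
        with pytest.warns(UserWarning, match="empty"):
            out = dg.class_mean_logfc({"t1": da}, {"t1": ann},
                                      {"g0": "up", "gX": "down"})
        assert out.loc[0, "mean_M"] == pytest.approx(0.7)
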