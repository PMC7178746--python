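"""Interpretive layer over DA results: MA trends, FDR-threshold behavior,
promoter annotation, cross-approach comparison, precision–recall against
differential expression, and hypergeometric enrichment."""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.nonparametric.smoothers_lowess import lowess

from ._intervals import overlap_hits
from .formats import RegionSet


@dataclasses.dataclass
class MAData:
    """Per-region (A, M, significant) points with a loess trend of M on A.

    ``band`` is an approximate 95% interval around the trend (fit +/- 1.96 x
    global residual sd — a display aid, not an inferential band).
    """

    df: pd.DataFrame          # columns A, M, significant
    trend_a: np.ndarray       # sorted A grid
    trend_m: np.ndarray       # loess fit at trend_a
    band: float               # half-width of the approximate 95% band
    median_m: float
    trend_range: tuple[float, float]


def ma_data(da: pd.DataFrame, span: float = 0.5, fdr: float = 0.10) -> MAData:
    """MA representation of a DA result (columns A, logFC, q required)."""
    if len(da) == 0:
        raise ValueError("no regions in DA result")
    a = da["A"].to_numpy(dtype=float)
    m = da["logFC"].to_numpy(dtype=float)
    order = np.argsort(a, kind="stable")
    if np.ptp(a) == 0:
        fit = np.full(len(a), m.mean())
    else:
        fit = lowess(m[order], a[order], frac=span, it=3,
                     delta=0.01 * np.ptp(a), return_sorted=False)
    resid_sd = float(np.std(m[order] - fit))
    df = pd.DataFrame({"A": a, "M": m, "significant": da["q"].to_numpy() < fdr})
    return MAData(df=df, trend_a=a[order], trend_m=fit,
                  band=1.96 * resid_sd,
                  median_m=float(np.median(m)),
                  trend_range=(float(fit.min()), float(fit.max())))


def plot_ma(ma: MAData, path, title: str = "") -> None:
    """Write an MA-plot panel (requires matplotlib; optional extra)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    sig = ma.df["significant"].to_numpy()
    ax.scatter(ma.df["A"][~sig], ma.df["M"][~sig], s=3, c="black", alpha=0.3)
    ax.scatter(ma.df["A"][sig], ma.df["M"][sig], s=3, c="red", alpha=0.5)
    ax.fill_between(ma.trend_a, ma.trend_m - ma.band, ma.trend_m + ma.band,
                    color="gray", alpha=0.3)
    ax.plot(ma.trend_a, ma.trend_m, c="blue")
    ax.axhline(0, ls=":", c="gray")
    ax.set_xlabel("A (average log2 abundance)")
    ax.set_ylabel("M (log2 fold change)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def fdr_at_rejection_rate(da: pd.DataFrame, rate: float = 0.05) -> float:
    """Smallest FDR threshold that rejects at least ``rate`` of tested
    regions: the q-value of the ceil(rate*m)-th smallest q."""
    m = len(da)
    if m < 1.0 / rate:
        raise ValueError(f"need at least {int(np.ceil(1 / rate))} regions")
    k = int(np.ceil(rate * m))
    return float(np.sort(da["q"].to_numpy())[k - 1])


# ---------------------------------------------------------------------------
# Promoter annotation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PromoterAnnotation:
    region_class: np.ndarray          # "promoter" | "distal" per region
    links: pd.DataFrame               # region_index, gene
    gene_best_q: pd.DataFrame         # gene, best_q (min over linked regions)


def promoter_windows(tss: RegionSet, upstream: int, downstream: int) -> RegionSet:
    """Strand-oriented promoter windows [TSS-upstream, TSS+downstream).

    The TSS base is the interval start for '+' records and end-1 for '-';
    minus-strand windows are mirror images (upstream lies at larger
    coordinates).  Windows are clipped at zero.
    """
    df = tss.df
    pos = np.where(df["strand"].to_numpy() == "-",
                   df["end"].to_numpy() - 1, df["start"].to_numpy())
    minus = df["strand"].to_numpy() == "-"
    start = np.where(minus, pos - downstream + 1, pos - upstream)
    end = np.where(minus, pos + upstream + 1, pos + downstream)
    out = pd.DataFrame({"chrom": df["chrom"].to_numpy(),
                        "start": np.maximum(start, 0), "end": end,
                        "name": df["name"].to_numpy(),
                        "strand": df["strand"].to_numpy()})
    return RegionSet(out, provenance="promoters")


def annotate_promoters(regions: RegionSet | pd.DataFrame, tss: RegionSet,
                       upstream: int = 3000, downstream: int = 3000,
                       q: np.ndarray | None = None,
                       nearest_only: bool = False) -> PromoterAnnotation:
    """Classify regions as promoter (>= 1 bp overlap with a TSS window) or
    distal, and link promoter regions to gene ids.

    A region overlapping several promoter windows links to every gene
    (``nearest_only`` keeps only the gene whose TSS is closest to the region
    midpoint).  With per-region FDR values ``q``, each gene's best (lowest)
    promoter FDR is reported.
    """
    rdf = regions.df if isinstance(regions, RegionSet) else regions
    windows = promoter_windows(tss, upstream, downstream)
    hits = overlap_hits(rdf, windows.df)
    gene_names = windows.df["name"].to_numpy()
    tss_pos = np.where(windows.df["strand"].to_numpy() == "-",
                       tss.df["end"].to_numpy() - 1, tss.df["start"].to_numpy())
    cls = np.array(["promoter" if h else "distal" for h in hits])
    link_rows = []
    mid = (rdf["start"].to_numpy() + rdf["end"].to_numpy()) // 2
    for i, h in enumerate(hits):
        if not h:
            continue
        if nearest_only and len(h) > 1:
            h = [h[int(np.argmin(np.abs(tss_pos[h] - mid[i])))]]
        for j in h:
            link_rows.append((i, gene_names[j]))
    links = pd.DataFrame(link_rows, columns=["region_index", "gene"])
    if q is not None and len(links):
        links["q"] = np.asarray(q, dtype=float)[links["region_index"]]
        best = links.groupby("gene", as_index=False)["q"].min() \
                    .rename(columns={"q": "best_q"})
    else:
        best = pd.DataFrame(columns=["gene", "best_q"])
    return PromoterAnnotation(region_class=cls, links=links, gene_best_q=best)


# ---------------------------------------------------------------------------
# Cross-approach comparison
# ---------------------------------------------------------------------------

def compare_approaches(results: dict[str, pd.DataFrame],
                       annotations: dict[str, PromoterAnnotation] | None = None,
                       fdr: float = 0.10) -> dict:
    """Summarize several DA results side by side.

    Per approach: significant up/down counts; with annotations also
    promoter/distal splits, up/down within promoters, and the per-approach
    gene sets with all pairwise and k-way intersection counts (upset-style).
    """
    if len(results) < 2:
        raise ValueError("need >= 2 approaches to compare")
    summary = {}
    gene_sets: dict[str, frozenset] = {}
    for name, da in results.items():
        sig = da["q"].to_numpy() < fdr
        up = int((sig & (da["logFC"].to_numpy() > 0)).sum())
        down = int((sig & (da["logFC"].to_numpy() < 0)).sum())
        entry = {"significant": int(sig.sum()), "up": up, "down": down}
        if annotations and name in annotations:
            ann = annotations[name]
            is_prom = ann.region_class == "promoter"
            entry["promoter"] = int((sig & is_prom).sum())
            entry["distal"] = int((sig & ~is_prom).sum())
            entry["promoter_up"] = int((sig & is_prom
                                        & (da["logFC"].to_numpy() > 0)).sum())
            entry["promoter_down"] = int((sig & is_prom
                                          & (da["logFC"].to_numpy() < 0)).sum())
            links = ann.links
            sig_idx = set(np.flatnonzero(sig & is_prom))
            genes = frozenset(links.loc[links["region_index"].isin(sig_idx),
                                        "gene"])
            gene_sets[name] = genes
            entry["genes_with_da_promoter"] = len(genes)
        summary[name] = entry

    out = {"per_approach": summary}
    if gene_sets:
        names = list(gene_sets)
        pairwise = {f"{a}&{b}": len(gene_sets[a] & gene_sets[b])
                    for i, a in enumerate(names) for b in names[i + 1:]}
        universe = set().union(*gene_sets.values())
        patterns: dict[str, int] = {}
        for gene in universe:
            key = "&".join(n for n in names if gene in gene_sets[n])
            patterns[key] = patterns.get(key, 0) + 1
        out["pairwise_gene_overlap"] = pairwise
        out["upset_gene_counts"] = patterns
    return out


# ---------------------------------------------------------------------------
# Precision–recall vs. differential expression
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PRCurve:
    recall: np.ndarray
    precision: np.ndarray
    aupr: float
    prevalence: float


def pr_curve(gene_best_fdr: np.ndarray, de_status: np.ndarray) -> PRCurve:
    """Precision–recall of predicting DE status from promoter-DA confidence.

    Score = 1 - FDR, swept descending with ties grouped; AUPR is the
    step-interpolated integral sum(delta-recall x precision), the average-
    precision convention.
    """
    score = 1.0 - np.asarray(gene_best_fdr, dtype=float)
    y = np.asarray(de_status, dtype=bool)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("no positive genes")
    if (~y).sum() == 0:
        warnings.warn("no negative genes; precision is trivially 1")
    order = np.argsort(-score, kind="stable")
    score_sorted = score[order]
    y_sorted = y[order]
    tp = np.cumsum(y_sorted)
    n_taken = np.arange(1, len(y) + 1)
    # group ties: keep only the last index of each distinct score
    last = np.r_[score_sorted[1:] != score_sorted[:-1], True]
    recall = tp[last] / n_pos
    precision = tp[last] / n_taken[last]
    prev_recall = np.r_[0.0, recall[:-1]]
    aupr = float(np.sum((recall - prev_recall) * precision))
    return PRCurve(recall=recall, precision=precision, aupr=aupr,
                   prevalence=n_pos / len(y))


def enrichment(hits: set, annotated_set: set, universe: set) -> tuple[float, float]:
    """Observed/expected ratio and upper-tail cumulative hypergeometric p for
    overlap of ``hits`` with ``annotated_set`` inside ``universe``."""
    if not (hits <= universe and annotated_set <= universe):
        raise ValueError("hits and annotated set must lie within the universe")
    n_u, n_h, n_s = len(universe), len(hits), len(annotated_set)
    observed = len(hits & annotated_set)
    expected = n_h * n_s / n_u if n_u else 0.0
    if expected == 0:
        return float("nan"), 1.0
    oe = observed / expected
    p = float(hypergeom.sf(observed - 1, n_u, n_s, n_h))
    return oe, p


def class_mean_logfc(da_by_timepoint: dict[str, pd.DataFrame],
                     annotations: dict[str, PromoterAnnotation],
                     gene_classes: dict[str, str]) -> pd.DataFrame:
    """Mean promoter-region logFC per expression class per timepoint.

    ``gene_classes`` maps gene -> class label (e.g. stable/up/down).  Each
    promoter-linked region contributes its M to every linked gene's class.
    Empty classes are omitted with a warning.  Returns a frame with columns
    timepoint, cls, mean_M, n.
    """
    classes = sorted(set(gene_classes.values()))
    rows = []
    for tp, da in da_by_timepoint.items():
        links = annotations[tp].links
        m = da["logFC"].to_numpy()
        for cls in classes:
            genes = {g for g, c in gene_classes.items() if c == cls}
            sel = links[links["gene"].isin(genes)]
            if len(sel) == 0:
                warnings.warn(f"class {cls!r} empty at timepoint {tp}")
                continue
            vals = m[sel["region_index"].to_numpy()]
            rows.append((tp, cls, float(vals.mean()), len(vals)))
    return pd.DataFrame(rows, columns=["timepoint", "cls", "mean_M", "n"])
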