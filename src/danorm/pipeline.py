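"""End-to-end convenience workflow: fragment libraries to DA calls.

Chains the preprocessing and testing stages in their canonical order —
Tn5 shift, minimal conversion, optional blacklist filtering, complexity
equalization, counting over query regions plus large bins, normalization
and testing — so callers (and the reproducibility checks) exercise the
whole path with one call.
"""

from __future__ import annotations

from . import complexity, datest, formats, quantify
from .formats import FragmentSet, GenomeTable, RegionSet


def fragments_to_da(libraries: dict[str, FragmentSet], genome: GenomeTable,
                    regions: RegionSet, conditions: dict[str, str], seed: int,
                    method: str = "loess", engine: str = "moderated",
                    fdr: float = 0.10, blacklist: RegionSet | None = None,
                    equalize: bool = True, bin_width: int = 10_000):
    """Run the full fragment-to-DA workflow.

    Returns (DA result frame, dict of per-stage reports).  ``seed`` drives
    the complexity-equalization subsampling only; all other stages are
    deterministic.
    """
    reports: dict = {}
    shifted = {k: formats.tn5_shift(v) for k, v in libraries.items()}
    minimal = {k: formats.bedpe_minimal_convert(v) for k, v in shifted.items()}
    if blacklist is not None and len(blacklist):
        minimal = {k: formats.filter_blacklist(v, blacklist)
                   for k, v in minimal.items()}
    if equalize:
        labels = list(minimal)
        thinned, report = complexity.equalize_complexity(
            [minimal[k] for k in labels], seed)
        minimal = dict(zip(labels, thinned))
        report.insert(0, "label", labels)
        reports["equalize"] = report
    counts = quantify.count_fragments(minimal, regions, conditions)
    bins = quantify.bin_genome_counts(minimal, genome, conditions,
                                      bin_width=bin_width)
    res, descriptor = datest.run_approach(counts, method, engine=engine,
                                          bins=bins, fdr=fdr)
    reports["approach"] = descriptor
    reports["frip"] = dict(zip(counts.samples,
                               map(float, quantify.frip(counts))))
    return res, reports
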