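import numpy as np
import pandas as pd
import pytest

from danorm.formats import BEDPE_COLUMNS, FragmentSet, GenomeTable, RegionSet


def make_fragments(rows):
    """Build a FragmentSet from (chrom, s1, e1, s2, e2, name, strand1, strand2)."""
    df = pd.DataFrame(
        [(c, s1, e1, c, s2, e2, name, ".", st1, st2)
         for c, s1, e1, s2, e2, name, st1, st2 in rows],
        columns=BEDPE_COLUMNS)
    for col in ("start1", "end1", "start2", "end2"):
        df[col] = df[col].astype(np.int64)
    return FragmentSet(df)


def make_regions(rows, provenance="peaks"):
    """Build a RegionSet from (chrom, start, end) or (chrom, start, end, name)."""
    recs = [r if len(r) == 4 else (*r, f"r{i}") for i, r in enumerate(rows)]
    return RegionSet(pd.DataFrame(recs, columns=["chrom", "start", "end", "name"]),
                     provenance=provenance)


@pytest.fixture
def genome():
    return GenomeTable({"chr1": 100_000, "chr2": 50_000})


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
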