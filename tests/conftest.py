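import numpy as np
import pytest

from fragloop.genome import (
    GeneModel,
    GenomeSegment,
    RestrictionFragment,
    SegmentUniverse,
)


def universe_from_lengths(frag_lengths_by_chrom, min_len=500):
    """Build a SegmentUniverse from explicit fragment lengths per chromosome."""
    from fragloop.genome import merge_fragments

    frags = []
    for chrom, lengths in frag_lengths_by_chrom.items():
        pos = 0
        for ln in lengths:
            frags.append(RestrictionFragment(chrom, pos, pos + ln))
            pos += ln
    return SegmentUniverse(merge_fragments(frags, min_len=min_len))


def universe_from_segments(spans_by_chrom):
    """Segments given directly as (start, end) spans tiling each chromosome."""
    segs = []
    sid = 0
    for chrom, spans in spans_by_chrom.items():
        for start, end in spans:
            segs.append(GenomeSegment(chrom, start, end, sid, 2))
            sid += 1
    return SegmentUniverse(segs)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def uniform_universe():
    """20 segments of 1 kb on one chromosome."""
    return universe_from_segments(
        {"chr1": [(i * 1000, (i + 1) * 1000) for i in range(20)]}
    )


@pytest.fixture(scope="session")
def default_pipeline_result():
    """One small full pipeline run shared by read-only tests."""
    from fragloop import SimConfig, run_pipeline

    cfg = SimConfig(
        seed=42,
        n_chromosomes=1,
        chrom_length=800_000,
        total_contacts=120_000,
        n_genes=80,
        n_loops=20,
        n_promoter_loops=5,
    )
    return run_pipeline(cfg)
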