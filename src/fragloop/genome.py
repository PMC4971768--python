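"""Segment universe construction: in-silico digestion, fragment merging,
gene and promoter coordinate models.

All coordinates are 0-based half-open internally. GFF3 (1-based closed) is
converted at the I/O boundary (see :mod:`fragloop.io`).

The atomic unit of the pipeline is the *segment*: a run of consecutive
restriction fragments merged until a minimum length is reached. Contacts are
counted between segments, and the distance between two segments is the
distance between their centers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "RestrictionFragment",
    "GenomeSegment",
    "GeneModel",
    "PromoterRegion",
    "SegmentUniverse",
    "digest_genome",
    "merge_fragments",
    "segment_distance",
    "promoter_regions",
]


@dataclass(frozen=True)
class RestrictionFragment:
    """One restriction fragment; fragments tile each chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"fragment end must exceed start: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomeSegment:
    """A merged run of restriction fragments.

    ``fragment_end_count`` (E) counts restriction-fragment ends contained in
    the segment: one per interior fragment boundary plus the two segment
    boundaries, i.e. ``n_fragments + 1``. E is never below 2.
    """

    chrom: str
    start: int
    end: int
    id: int
    fragment_end_count: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"segment end must exceed start: {self}")
        if self.fragment_end_count < 2:
            raise ValueError("a segment contains at least 2 fragment ends")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class GeneModel:
    """A gene reduced to the coordinates the pipeline needs.

    For a plus-strand gene ``tss < tts``; for a minus-strand gene
    ``tss > tts``. "Downstream" always means in the direction of
    transcription.
    """

    id: str
    chrom: str
    strand: str
    tss: int
    tts: int
    expression_level: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.strand == "+" and not self.tss < self.tts:
            raise ValueError(f"plus-strand gene requires tss < tts: {self}")
        if self.strand == "-" and not self.tss > self.tts:
            raise ValueError(f"minus-strand gene requires tss > tts: {self}")

    @property
    def length(self) -> int:
        return abs(self.tts - self.tss)

    @property
    def body_start(self) -> int:
        return min(self.tss, self.tts)

    @property
    def body_end(self) -> int:
        return max(self.tss, self.tts)

    @property
    def direction(self) -> int:
        """+1 for plus strand, -1 for minus strand."""
        return 1 if self.strand == "+" else -1


@dataclass(frozen=True)
class PromoterRegion:
    """TSS +/- flank window, strand-independent, clipped to the chromosome."""

    gene_id: str
    chrom: str
    start: int
    end: int
    clipped: bool = False


def digest_genome(
    sequences: Mapping[str, str], motif: str = "GATC"
) -> List[RestrictionFragment]:
    """Cut every chromosome at each motif occurrence.

    The cut is placed at the motif start (DpnII cuts 5' of GATC, leaving the
    site on the downstream fragment). A chromosome without the motif yields a
    single fragment; an empty sequence yields none.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    motif = motif.upper()
    pattern = re.compile(f"(?={re.escape(motif)})")
    fragments: List[RestrictionFragment] = []
    for chrom, seq in sequences.items():
        seq = seq.upper()
        n = len(seq)
        if n == 0:
            continue
        cuts = [m.start() for m in pattern.finditer(seq) if m.start() > 0]
        bounds = [0] + cuts + [n]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            fragments.append(RestrictionFragment(chrom, lo, hi))
    return fragments


def _check_tiling(frags: Sequence[RestrictionFragment]) -> None:
    for prev, cur in zip(frags[:-1], frags[1:]):
        if cur.start != prev.end:
            raise ValueError(
                f"fragments do not tile the chromosome: gap/overlap between "
                f"{prev} and {cur} — malformed digestion"
            )


def merge_fragments(
    fragments: Sequence[RestrictionFragment], min_len: int = 500
) -> List[GenomeSegment]:
    """Greedy left-to-right merge of fragments into segments of >= min_len.

    Consecutive fragments are accumulated until the running length reaches
    ``min_len``, then a segment is emitted. A trailing remainder shorter than
    ``min_len`` is absorbed into the previously emitted segment. A single
    fragment already >= min_len becomes its own segment (fragments are never
    split). A chromosome shorter than ``min_len`` yields one short segment.
    """
    segments: List[GenomeSegment] = []
    by_chrom: Dict[str, List[RestrictionFragment]] = {}
    for f in fragments:
        by_chrom.setdefault(f.chrom, []).append(f)

    next_id = 0
    for chrom, frags in by_chrom.items():
        frags = sorted(frags, key=lambda f: f.start)
        _check_tiling(frags)
        emitted: List[Tuple[int, int, int]] = []  # (start, end, n_fragments)
        acc_start = frags[0].start
        acc_n = 0
        for f in frags:
            acc_n += 1
            if f.end - acc_start >= min_len:
                emitted.append((acc_start, f.end, acc_n))
                acc_start = f.end
                acc_n = 0
        if acc_n > 0:
            if emitted:
                s, _, m = emitted[-1]
                emitted[-1] = (s, frags[-1].end, m + acc_n)
            else:
                emitted.append((acc_start, frags[-1].end, acc_n))
        for start, end, n_frag in emitted:
            segments.append(
                GenomeSegment(chrom, start, end, next_id, n_frag + 1)
            )
            next_id += 1
    return segments


def segment_distance(a: GenomeSegment, b: GenomeSegment) -> int:
    """Genomic distance between segment centers; same chromosome only."""
    if a.chrom != b.chrom:
        raise ValueError(
            "segment distance is defined for intra-chromosomal pairs only"
        )
    return abs(a.center - b.center)


def promoter_regions(
    genes: Iterable[GeneModel],
    chrom_sizes: Mapping[str, int],
    flank: int = 500,
) -> List[PromoterRegion]:
    """[TSS - flank, TSS + flank) per gene, clipped to chromosome bounds."""
    out = []
    for g in genes:
        size = chrom_sizes[g.chrom]
        start, end = g.tss - flank, g.tss + flank
        clipped = start < 0 or end > size
        out.append(
            PromoterRegion(g.id, g.chrom, max(0, start), min(size, end), clipped)
        )
    return out


class SegmentUniverse:
    """Array-backed view of the segment universe for vectorized operations.

    Segments are stored sorted by (chromosome, start); ids are the global
    ordinals assigned at merge time. Provides point-to-segment lookup,
    per-chromosome index ranges, and a centromere tag.
    """

    def __init__(self, segments: Sequence[GenomeSegment]):
        if not segments:
            raise ValueError("empty segment universe")
        segs = sorted(segments, key=lambda s: (s.chrom, s.start))
        self.segments: List[GenomeSegment] = segs
        self.chrom = np.array([s.chrom for s in segs])
        self.start = np.array([s.start for s in segs], dtype=np.int64)
        self.end = np.array([s.end for s in segs], dtype=np.int64)
        self.id = np.array([s.id for s in segs], dtype=np.int64)
        self.length = self.end - self.start
        self.center = (self.start + self.end) // 2
        self.end_count = np.array(
            [s.fragment_end_count for s in segs], dtype=np.int64
        )
        self.centromeric = np.zeros(len(segs), dtype=bool)
        # row index per segment id
        self._row_of_id = np.empty(len(segs), dtype=np.int64)
        self._row_of_id[self.id] = np.arange(len(segs))
        # contiguous chromosome blocks
        self.chrom_slices: Dict[str, slice] = {}
        names, starts = np.unique(self.chrom, return_index=True)
        order = np.argsort(starts)
        bounds = list(starts[order]) + [len(segs)]
        for name, lo, hi in zip(names[order], bounds[:-1], bounds[1:]):
            self.chrom_slices[str(name)] = slice(int(lo), int(hi))

    def __len__(self) -> int:
        return len(self.segments)

    def row(self, seg_id: int | np.ndarray) -> np.ndarray:
        return self._row_of_id[seg_id]

    def locate(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Segment id containing each position; -1 if outside the tiling."""
        positions = np.asarray(positions, dtype=np.int64)
        if chrom not in self.chrom_slices:
            return np.full(positions.shape, -1, dtype=np.int64)
        sl = self.chrom_slices[chrom]
        starts = self.start[sl]
        ends = self.end[sl]
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = (idx >= 0) & (positions < ends[np.clip(idx, 0, len(ends) - 1)])
        out = np.where(ok, self.id[sl][np.clip(idx, 0, len(ends) - 1)], -1)
        return out

    def tag_centromeres(
        self, mask: Mapping[str, Sequence[Tuple[int, int]]]
    ) -> None:
        """Mark segments overlapping (>= 1 bp) any masked interval."""
        for chrom, intervals in mask.items():
            if chrom not in self.chrom_slices:
                continue
            sl = self.chrom_slices[chrom]
            for lo, hi in intervals:
                hit = (self.start[sl] < hi) & (self.end[sl] > lo)
                self.centromeric[sl] |= hit

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "id": self.id,
                "length": self.length,
                "center": self.center,
                "fragment_end_count": self.end_count,
                "centromeric": self.centromeric,
            }
        )
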