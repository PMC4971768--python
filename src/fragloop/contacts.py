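"""Hi-C pair ingestion: assignment of mate positions to segments,
aggregation into segment-pair counts, and distance/region filters.

Contacts are held in a pandas DataFrame with columns

    seg_a, seg_b : segment ids with seg_a < seg_b
    count        : aggregated read count k (>= 1 for observed records)
    distance     : center-to-center distance D in bp

Only intra-chromosomal pairs are represented; inter-chromosomal pairs are
out of scope for sub-kilobase loop calling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome import SegmentUniverse

__all__ = [
    "AssignmentStats",
    "assign_pairs",
    "filter_contacts",
    "contact_frame",
]

CONTACT_COLUMNS = ["seg_a", "seg_b", "count", "distance"]


@dataclass
class AssignmentStats:
    """Bookkeeping from pair assignment: every input pair is accounted for."""

    n_input: int
    n_assigned: int
    n_intra_segment: int
    n_inter_chromosomal: int
    n_unmapped: int

    def check(self) -> None:
        total = (
            self.n_assigned
            + self.n_intra_segment
            + self.n_inter_chromosomal
            + self.n_unmapped
        )
        if total != self.n_input:
            raise AssertionError("pair bookkeeping does not balance")


def contact_frame(
    seg_a: np.ndarray, seg_b: np.ndarray, count: np.ndarray, universe: SegmentUniverse
) -> pd.DataFrame:
    """Build a canonical contact table (seg_a < seg_b, distances filled in)."""
    a = np.minimum(seg_a, seg_b).astype(np.int64)
    b = np.maximum(seg_a, seg_b).astype(np.int64)
    ra, rb = universe.row(a), universe.row(b)
    dist = np.abs(universe.center[ra] - universe.center[rb])
    return pd.DataFrame(
        {"seg_a": a, "seg_b": b, "count": np.asarray(count, dtype=np.int64),
         "distance": dist}
    )


def assign_pairs(
    pairs: pd.DataFrame, universe: SegmentUniverse
) -> Tuple[pd.DataFrame, AssignmentStats]:
    """Assign each mate to its containing segment and aggregate pair counts.

    ``pairs`` needs columns chrom1, pos1, chrom2, pos2 (strand columns, if
    present, are ignored: the mate anchor is the 5' mapped coordinate).
    Pairs with a mate outside the segment tiling are skipped and counted;
    intra-segment pairs are recorded in the stats but produce no
    inter-segment record. Inter-chromosomal pairs are out of scope.
    """
    n_input = len(pairs)
    same_chrom = (pairs["chrom1"] == pairs["chrom2"]).to_numpy()
    n_inter = int(n_input - same_chrom.sum())
    intra = pairs.loc[same_chrom]

    seg1 = np.full(len(intra), -1, dtype=np.int64)
    seg2 = np.full(len(intra), -1, dtype=np.int64)
    chroms = intra["chrom1"].to_numpy()
    pos1 = intra["pos1"].to_numpy()
    pos2 = intra["pos2"].to_numpy()
    for chrom in np.unique(chroms):
        m = chroms == chrom
        seg1[m] = universe.locate(str(chrom), pos1[m])
        seg2[m] = universe.locate(str(chrom), pos2[m])

    mapped = (seg1 >= 0) & (seg2 >= 0)
    n_unmapped = int((~mapped).sum())
    self_pair = mapped & (seg1 == seg2)
    n_self = int(self_pair.sum())
    keep = mapped & ~self_pair

    a = np.minimum(seg1[keep], seg2[keep])
    b = np.maximum(seg1[keep], seg2[keep])
    if len(a):
        key = a * len(universe) + b
        uniq, counts = np.unique(key, return_counts=True)
        contacts = contact_frame(
            uniq // len(universe), uniq % len(universe), counts, universe
        )
    else:
        contacts = pd.DataFrame(
            {c: pd.Series(dtype=np.int64) for c in CONTACT_COLUMNS}
        )
    stats = AssignmentStats(
        n_input=n_input,
        n_assigned=int(keep.sum()),
        n_intra_segment=n_self,
        n_inter_chromosomal=n_inter,
        n_unmapped=n_unmapped,
    )
    stats.check()
    return contacts.sort_values(["seg_a", "seg_b"], ignore_index=True), stats


def filter_contacts(
    contacts: pd.DataFrame,
    universe: SegmentUniverse,
    d_min: int = 2000,
    d_max: int = 25000,
    mask: Mapping[str, Sequence[Tuple[int, int]]] | None = None,
) -> pd.DataFrame:
    """Keep contacts with d_min <= D <= d_max, away from masked regions.

    The distance window is inclusive at both ends. A segment overlapping a
    masked (centromeric) interval by >= 1 bp disqualifies every contact it
    participates in. Idempotent.
    """
    if mask is not None:
        universe.tag_centromeres(mask)
    d = contacts["distance"].to_numpy()
    keep = (d >= d_min) & (d <= d_max)
    if universe.centromeric.any():
        cen_a = universe.centromeric[universe.row(contacts["seg_a"].to_numpy())]
        cen_b = universe.centromeric[universe.row(contacts["seg_b"].to_numpy())]
        keep &= ~(cen_a | cen_b)
    return contacts.loc[keep].reset_index(drop=True)
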