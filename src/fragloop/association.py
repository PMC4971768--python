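"""Feature-overlap flags and shift-coordinate permutation nulls.

Enrichment claims about loop anchors (repressive-mark promoters, Pol II
binding, coupled expression) are tested against nulls built by translating
the feature track along the chromosome (breaking the label-position
coupling while keeping spatial autocorrelation) or by reassigning
expression levels from distant neighbors in gene order.

Feature tracks are DataFrames with columns chrom, start, end and an
optional feature_id (assigned on first shift so wrapped pieces of one
feature still count once).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome import GeneModel, PromoterRegion, SegmentUniverse

__all__ = [
    "EnrichmentResult",
    "flag_promoters",
    "promoter_pair_interactions",
    "shift_features",
    "empirical_enrichment",
    "expression_shuffle",
    "signal_ratio",
    "classify_gene_pair_loops",
]


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts)
    s, e = starts[order], ends[order]
    ms, me = [s[0]], [e[0]]
    for a, b in zip(s[1:], e[1:]):
        if a <= me[-1]:
            me[-1] = max(me[-1], b)
        else:
            ms.append(a)
            me.append(b)
    return np.array(ms), np.array(me)


def _covered_length(start: int, end: int, ms: np.ndarray, me: np.ndarray) -> int:
    """Overlap of [start, end) with a merged, sorted interval set."""
    if len(ms) == 0:
        return 0
    lo = np.searchsorted(me, start, side="right")
    hi = np.searchsorted(ms, end, side="left")
    if hi <= lo:
        return 0
    ov = np.minimum(me[lo:hi], end) - np.maximum(ms[lo:hi], start)
    return int(np.clip(ov, 0, None).sum())


def flag_promoters(
    promoters: Sequence[PromoterRegion],
    peaks: pd.DataFrame,
    min_overlap_frac: float = 0.3,
) -> Dict[str, bool]:
    """gene id -> True iff >= min_overlap_frac of the promoter is covered
    by (the union of) peaks. The threshold is inclusive."""
    merged: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in peaks.groupby("chrom"):
        merged[str(chrom)] = _merge_intervals(
            grp["start"].to_numpy(), grp["end"].to_numpy()
        )
    flags = {}
    for p in promoters:
        ms, me = merged.get(p.chrom, (np.array([]), np.array([])))
        cov = _covered_length(p.start, p.end, ms, me)
        flags[p.gene_id] = cov >= min_overlap_frac * (p.end - p.start)
    return flags


def _assign_promoter(
    seg_start: int,
    seg_end: int,
    chrom: str,
    promoters: Sequence[PromoterRegion],
    tss_of: Mapping[str, int],
) -> Optional[str]:
    """Promoter (gene id) with maximal >=1 bp overlap; tie -> nearest TSS."""
    best: Optional[str] = None
    best_ov = 0
    best_d = None
    center = (seg_start + seg_end) // 2
    for p in promoters:
        if p.chrom != chrom:
            continue
        ov = min(p.end, seg_end) - max(p.start, seg_start)
        if ov <= 0:
            continue
        d = abs(tss_of[p.gene_id] - center)
        if ov > best_ov or (ov == best_ov and (best_d is None or d < best_d)):
            best, best_ov, best_d = p.gene_id, ov, d
    return best


def promoter_pair_interactions(
    loops: pd.DataFrame,
    promoters: Sequence[PromoterRegion],
    flags: Mapping[str, bool],
    universe: SegmentUniverse,
    genes: Sequence[GeneModel],
    min_span: int = 6000,
) -> Tuple[int, int]:
    """(n promoter-pair interactions, n with both promoters flagged).

    A promoter-pair interaction is a significant loop with span >= min_span
    whose two segments each overlap (>= 1 bp) a distinct promoter. All
    orientations (convergent, divergent, tandem) count. A segment touching
    several promoters is assigned the one with maximal overlap, ties
    resolved by nearest TSS.
    """
    tss_of = {g.id: g.tss for g in genes}
    sig = loops.loc[loops["significant"]] if "significant" in loops else loops
    sig = sig.loc[sig["distance"] >= min_span]
    n_pairs = 0
    n_dual = 0
    for a, b in zip(sig["seg_a"].to_numpy(), sig["seg_b"].to_numpy()):
        ra, rb = int(universe.row(int(a))), int(universe.row(int(b)))
        chrom = str(universe.chrom[ra])
        pa = _assign_promoter(
            int(universe.start[ra]), int(universe.end[ra]), chrom, promoters, tss_of
        )
        pb = _assign_promoter(
            int(universe.start[rb]), int(universe.end[rb]), chrom, promoters, tss_of
        )
        if pa is None or pb is None or pa == pb:
            continue
        n_pairs += 1
        if flags.get(pa, False) and flags.get(pb, False):
            n_dual += 1
    return n_pairs, n_dual


def shift_features(
    track: pd.DataFrame,
    offset: int,
    chrom_sizes: Mapping[str, int],
) -> pd.DataFrame:
    """Translate every interval by ``offset`` bp, wrapping circularly.

    Feature identity (``feature_id``) and total covered length are exactly
    conserved; an interval pushed past a chromosome end is represented as
    two pieces sharing one feature_id. |offset| must be smaller than every
    chromosome length involved.
    """
    track = track.copy()
    if "feature_id" not in track.columns:
        track["feature_id"] = np.arange(len(track))
    rows: List[dict] = []
    for _, rec in track.iterrows():
        chrom = rec["chrom"]
        size = chrom_sizes[chrom]
        if abs(offset) >= size:
            raise ValueError("shift offset must be smaller than the chromosome")
        length = rec["end"] - rec["start"]
        ns = (rec["start"] + offset) % size
        ne = ns + length
        base = {k: rec[k] for k in track.columns if k not in ("start", "end")}
        if ne <= size:
            rows.append({**base, "start": int(ns), "end": int(ne)})
        else:
            rows.append({**base, "start": int(ns), "end": int(size)})
            rows.append({**base, "start": 0, "end": int(ne - size)})
    return pd.DataFrame(rows, columns=list(track.columns))


@dataclass
class EnrichmentResult:
    """Observed statistic vs shift/permutation nulls, add-one empirical p."""

    observed: float
    nulls: List[float]
    p_value: float


def empirical_enrichment(observed: float, nulls: Sequence[float]) -> EnrichmentResult:
    """p = (1 + #{null >= observed}) / (1 + #nulls)."""
    nulls = list(nulls)
    if not nulls:
        raise ValueError("at least one null value required")
    ge = sum(1 for v in nulls if v >= observed)
    return EnrichmentResult(
        observed=float(observed),
        nulls=[float(v) for v in nulls],
        p_value=(1 + ge) / (1 + len(nulls)),
    )


def expression_shuffle(
    genes: Sequence[GeneModel],
    lag: int = 20,
    direction: str = "down",
) -> Dict[str, int]:
    """Reassign expression levels from the lag-th neighbor in gene order.

    Genes are ordered along each chromosome by body start; gene i receives
    the level of gene i+lag ("down") or i-lag ("up"), wrapping within the
    chromosome. The per-chromosome multiset of levels is preserved exactly.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    step = lag if direction == "down" else -lag
    out: Dict[str, int] = {}
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, gs in by_chrom.items():
        gs = sorted(gs, key=lambda g: g.body_start)
        n = len(gs)
        levels = [g.expression_level for g in gs]
        for i, g in enumerate(gs):
            out[g.id] = levels[(i + step) % n]
    return out


def signal_ratio(
    signal_cov: np.ndarray,
    control_cov: np.ndarray,
    universe: SegmentUniverse,
    pseudocount: float = 1.0,
) -> np.ndarray:
    """ln(signal/control) per segment after depth normalization.

    Both tracks are scaled to the mean of the two totals; the pseudocount
    (read-equivalents) is added to numerator and denominator. A segment is
    "enriched" when the ratio exceeds 1, i.e. the log-ratio is positive.
    """
    s = np.asarray(signal_cov, dtype=np.float64)
    c = np.asarray(control_cov, dtype=np.float64)
    if s.shape != (len(universe),) or c.shape != (len(universe),):
        raise ValueError("coverage must have one value per segment")
    if pseudocount <= 0 and np.any(c == 0):
        raise ValueError("zero control coverage requires a pseudocount")
    target = (s.sum() + c.sum()) / 2.0
    s_n = s * (target / s.sum()) if s.sum() > 0 else s
    c_n = c * (target / c.sum()) if c.sum() > 0 else c
    return np.log((s_n + pseudocount) / (c_n + pseudocount))


def classify_gene_pair_loops(
    loops: pd.DataFrame,
    genes: Sequence[GeneModel],
    universe: SegmentUniverse,
    max_span: int = 6000,
    enrichment_flags: Optional[np.ndarray] = None,
) -> Tuple[int, int]:
    """(n within-gene, n between-gene) loops among gene-body loops.

    Considers significant loops with span < max_span whose two segments
    both overlap gene bodies; each segment is assigned the gene of maximal
    overlap. With ``enrichment_flags`` (per-segment booleans, e.g. Pol II
    log-ratio > 0), only loops flagged on both sides are counted.
    """
    sig = loops.loc[loops["significant"]] if "significant" in loops else loops
    sig = sig.loc[sig["distance"] < max_span]
    bodies = [(g.chrom, g.body_start, g.body_end, g.id) for g in genes]

    def gene_of(row: int) -> Optional[str]:
        chrom = str(universe.chrom[row])
        s, e = int(universe.start[row]), int(universe.end[row])
        best, best_ov = None, 0
        for gc, gs, ge, gid in bodies:
            if gc != chrom:
                continue
            ov = min(ge, e) - max(gs, s)
            if ov > best_ov:
                best, best_ov = gid, ov
        return best

    n_within = n_between = 0
    for a, b in zip(sig["seg_a"].to_numpy(), sig["seg_b"].to_numpy()):
        ra, rb = int(universe.row(int(a))), int(universe.row(int(b)))
        if enrichment_flags is not None and not (
            enrichment_flags[ra] and enrichment_flags[rb]
        ):
            continue
        ga, gb = gene_of(ra), gene_of(rb)
        if ga is None or gb is None:
            continue
        if ga == gb:
            n_within += 1
        else:
            n_between += 1
    return n_within, n_between
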