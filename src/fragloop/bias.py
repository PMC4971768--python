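"""Segment-level bias model and bias-adjusted contact probabilities.

Two multiplicative technical factors are estimated per segment:

* beta — sequencing "visibility" (PCR efficiency + mappability), defined as
  the ratio of the segment's length-normalized genomic-resequencing coverage
  to the genome-wide mean. Segments with beta outside [0.05, 20] are
  unusable and are removed both as anchors and from partner/denominator
  sets.
* f(E) — the fragment-end-density effect: Hi-C depth rises log-linearly
  with the number of restriction-fragment ends a segment contains.

For an anchor segment A, the contact probability with partner B is

    p_AB = f(D_B) f(E_B) l_B beta_B / sum_j f(D_j) f(E_j) l_j beta_j

normalized over all usable partners within the analysis window on both
sides of the anchor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .decay import DecayModel
from .genome import SegmentUniverse

__all__ = [
    "SegmentBias",
    "EndDensityModel",
    "AdjustedProbabilities",
    "estimate_beta",
    "apply_beta_filter",
    "fit_end_density",
    "adjusted_probabilities",
    "partner_weights",
]

BETA_LO = 0.05
BETA_HI = 20.0


@dataclass
class SegmentBias:
    """Per-segment beta table. ``usable`` is the inclusive [lo, hi] gate."""

    beta: np.ndarray
    usable: np.ndarray

    def to_frame(self, universe: SegmentUniverse) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": universe.id,
                "beta": self.beta[universe.row(universe.id)],
                "fragment_end_count": universe.end_count,
                "usable": self.usable[universe.row(universe.id)],
            }
        )


def estimate_beta(
    coverage: np.ndarray,
    universe: SegmentUniverse,
    lo: float = BETA_LO,
    hi: float = BETA_HI,
) -> SegmentBias:
    """beta_i = length-normalized coverage_i / genome-wide mean.

    ``coverage`` holds per-segment read (or base) totals indexed by segment
    row; multiple resequencing datasets should be pooled by summing depth
    before calling. mean(beta) == 1 by construction.
    """
    cov = np.asarray(coverage, dtype=np.float64)
    if cov.shape != (len(universe),):
        raise ValueError("coverage must have one value per segment")
    if cov.sum() <= 0:
        raise ValueError("zero total resequencing coverage")
    norm = cov / universe.length
    beta = norm / norm.mean()
    usable = (beta >= lo) & (beta <= hi)
    return SegmentBias(beta=beta, usable=usable)


def apply_beta_filter(
    contacts: pd.DataFrame,
    bias: SegmentBias,
    universe: SegmentUniverse,
) -> pd.DataFrame:
    """Drop contacts where either segment fails the beta gate."""
    ua = bias.usable[universe.row(contacts["seg_a"].to_numpy())]
    ub = bias.usable[universe.row(contacts["seg_b"].to_numpy())]
    return contacts.loc[ua & ub].reset_index(drop=True)


@dataclass
class EndDensityModel:
    """log-linear depth ~ fragment-end-count model, mean multiplier 1.

    multiplier(E) = scale * E**slope; the scale is set so the mean
    multiplier over the segments used in the fit equals 1 (it cancels in
    the probability normalization either way).
    """

    slope: float
    scale: float

    def multiplier(self, end_count) -> np.ndarray | float:
        e = np.asarray(end_count, dtype=np.float64)
        out = self.scale * np.power(e, self.slope)
        return float(out) if np.isscalar(end_count) else out

    __call__ = multiplier


def fit_end_density(
    hic_depth: np.ndarray,
    universe: SegmentUniverse,
    length_normalize: bool = True,
) -> EndDensityModel:
    """Least-squares fit of log depth on log fragment-end count.

    Depth is length-normalized before the regression by default: segment
    length enters the probability model as its own explicit factor, and
    longer segments mechanically contain more fragment ends, so leaving the
    length effect in the response would double-count it. Segments with zero
    depth are excluded from the fit. With fewer than 10 distinct end counts
    (or a single one) the model degenerates to a constant multiplier of 1.
    """
    depth = np.asarray(hic_depth, dtype=np.float64)
    if depth.shape != (len(universe),):
        raise ValueError("depth must have one value per segment")
    y_raw = depth / universe.length if length_normalize else depth.copy()
    ok = y_raw > 0
    e = universe.end_count[ok].astype(np.float64)
    if len(np.unique(e)) < 2:
        return EndDensityModel(slope=0.0, scale=1.0)
    x = np.log(e)
    y = np.log(y_raw[ok])
    slope, intercept = np.polyfit(x, y, 1)
    raw = np.power(universe.end_count[ok].astype(np.float64), slope)
    scale = 1.0 / raw.mean()
    return EndDensityModel(slope=float(slope), scale=float(scale))


@dataclass
class AdjustedProbabilities:
    """Simplex of contact probabilities from one anchor to its partners."""

    anchor: int
    partners: np.ndarray   # segment ids
    p: np.ndarray          # probabilities, sum to 1

    def probability_of(self, seg_id: int) -> float:
        idx = np.nonzero(self.partners == seg_id)[0]
        return float(self.p[idx[0]]) if len(idx) else 0.0


def partner_weights(
    universe: SegmentUniverse,
    decay: DecayModel,
    bias: Optional[SegmentBias] = None,
    end_model: Optional[EndDensityModel] = None,
) -> np.ndarray:
    """Distance-independent weight per segment: f(E) * l * beta.

    Unusable segments get weight 0, removing them from every anchor's
    partner set and denominator.
    """
    w = universe.length.astype(np.float64).copy()
    if end_model is not None:
        w *= end_model.multiplier(universe.end_count)
    if bias is not None:
        w *= np.where(bias.usable, bias.beta, 0.0)
    return w


def window_rows(
    universe: SegmentUniverse, anchor_row: int, d_min: int, d_max: int
) -> np.ndarray:
    """Rows of all segments within [d_min, d_max] of the anchor's center,
    both directions, same chromosome."""
    chrom = str(universe.chrom[anchor_row])
    sl = universe.chrom_slices[chrom]
    centers = universe.center[sl]
    c0 = universe.center[anchor_row]
    lo = np.searchsorted(centers, c0 - d_max, side="left")
    hi = np.searchsorted(centers, c0 + d_max, side="right")
    rows = np.arange(sl.start + lo, sl.start + hi)
    d = np.abs(universe.center[rows] - c0)
    return rows[(d >= d_min) & (d <= d_max)]


def adjusted_probabilities(
    anchor: int,
    universe: SegmentUniverse,
    decay: DecayModel,
    bias: Optional[SegmentBias] = None,
    end_model: Optional[EndDensityModel] = None,
    d_min: int = 2000,
    d_max: int = 25000,
) -> AdjustedProbabilities:
    """Bias-adjusted contact probabilities of one anchor with its window.

    Partners are all usable segments with d_min <= D <= d_max up- and
    downstream; probabilities are proportional to f(D) f(E) l beta and sum
    to 1. Raises if the anchor is unusable or has no usable partner.
    """
    arow = int(universe.row(anchor))
    if bias is not None and not bias.usable[arow]:
        raise ValueError(f"anchor segment {anchor} fails the beta filter")
    rows = window_rows(universe, arow, d_min, d_max)
    w = partner_weights(universe, decay, bias, end_model)[rows]
    d = np.abs(universe.center[rows] - universe.center[arow]).astype(np.float64)
    weights = w * decay.evaluate(d)
    keep = weights > 0
    rows, weights = rows[keep], weights[keep]
    if len(rows) == 0:
        raise ValueError(f"anchor segment {anchor} has no usable partner")
    p = weights / weights.sum()
    return AdjustedProbabilities(
        anchor=anchor, partners=universe.id[rows], p=p
    )
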