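"""Distance-decay model: equal-occupancy binning of contacts by genomic
distance, log-log smoothing-spline fit, and antitonic (non-increasing)
projection.

The fitted model f(D) maps genomic distance to expected per-bp contact
intensity. It is fitted on 50 equal-occupancy bins by default, in natural
log space, and is strictly positive and non-increasing over its domain
[D_1, D_n]; evaluation outside the domain clamps to the boundary value.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import LSQUnivariateSpline
from sklearn.isotonic import IsotonicRegression

__all__ = ["DecayBin", "DecayModel", "equal_occupancy_bins", "bin_statistics", "fit_decay"]


@dataclass(frozen=True)
class DecayBin:
    """One equal-occupancy distance bin.

    ``c`` is the per-bp contact intensity N / (b - a + 1); ``d`` the
    count-weighted mean distance of the contacts in the bin.
    """

    index: int
    a: int          # lowest distance in the bin (bp)
    b: int          # highest distance in the bin (bp)
    n_contacts: int
    c: float
    d: float


def bin_statistics(distances: np.ndarray, counts: np.ndarray) -> tuple[float, float]:
    """(C, D) for one bin: per-bp intensity and count-weighted mean distance.

    The intensity denominator is the distance span b - a + 1 (1 for a
    single-distance bin). The mean uses the contact counts as weights; a
    denominator of summed distances would not yield a mean and is not used.
    """
    distances = np.asarray(distances, dtype=np.float64)
    counts = np.asarray(counts, dtype=np.float64)
    if counts.sum() <= 0:
        raise ValueError("empty bin")
    a, b = distances.min(), distances.max()
    c = counts.sum() / (b - a + 1.0)
    d = float(np.average(distances, weights=counts))
    return float(c), d


def equal_occupancy_bins(contacts: pd.DataFrame, n_bins: int = 50) -> List[DecayBin]:
    """Split contacts, sorted by distance, into bins of (nearly) equal reads.

    Contacts sharing one distance value are never split across bins: the
    boundary moves to the next distinct distance, so occupancies are equal
    only up to that granularity (exactly equal within +/-1 when all
    distances are distinct and the total divides evenly).
    """
    agg = (
        contacts.groupby("distance")["count"].sum().sort_index()
    )
    dists = agg.index.to_numpy(dtype=np.int64)
    counts = agg.to_numpy(dtype=np.int64)
    total = int(counts.sum())
    if len(dists) < n_bins:
        raise ValueError(
            f"only {len(dists)} distinct distances for {n_bins} bins; "
            "reduce n_bins"
        )
    if total < n_bins:
        raise ValueError("fewer contacts than bins")

    cum = np.cumsum(counts)
    bins: List[DecayBin] = []
    start = 0  # index into dists
    for i in range(n_bins):
        if start >= len(dists):
            break
        target = total * (i + 1) / n_bins
        # last bin takes everything that remains
        if i == n_bins - 1:
            stop = len(dists)
        else:
            stop = int(np.searchsorted(cum, target - 1e-9, side="left")) + 1
            stop = max(stop, start + 1)
            stop = min(stop, len(dists))
            # leave at least one distance per remaining bin when possible
            remaining_bins = n_bins - i - 1
            stop = min(stop, len(dists) - remaining_bins) if len(dists) - remaining_bins > start else stop
        d_slice = dists[start:stop]
        n_slice = counts[start:stop]
        c, d = bin_statistics(d_slice, n_slice)
        bins.append(
            DecayBin(
                index=len(bins),
                a=int(d_slice.min()),
                b=int(d_slice.max()),
                n_contacts=int(n_slice.sum()),
                c=c,
                d=d,
            )
        )
        start = stop
    return bins


@dataclass
class DecayModel:
    """Monotone log-log distance-decay curve.

    Piecewise-linear in (ln D, ln C) between the fitted knots; clamped to
    the boundary values outside [D_1, D_n]. ``smoothing`` is the number of
    interior knots of the underlying cubic least-squares spline.
    """

    log_d: np.ndarray   # ln distance at knots, increasing
    log_c: np.ndarray   # ln intensity at knots, non-increasing
    smoothing: int

    @property
    def domain(self) -> tuple[float, float]:
        return float(np.exp(self.log_d[0])), float(np.exp(self.log_d[-1]))

    def evaluate(self, d) -> np.ndarray | float:
        """Expected per-bp contact intensity at distance ``d`` (bp)."""
        d_arr = np.asarray(d, dtype=np.float64)
        if np.any(d_arr <= 0):
            raise ValueError("distance must be positive")
        out = np.exp(np.interp(np.log(d_arr), self.log_d, self.log_c))
        return float(out) if np.isscalar(d) else out

    __call__ = evaluate

    def loglog_slope(self) -> float:
        """Overall least-squares slope of ln f vs ln D across the domain."""
        x, y = self.log_d, self.log_c
        return float(np.polyfit(x, y, 1)[0])

    def to_tsv(self) -> str:
        buf = io.StringIO()
        buf.write(f"# fragloop decay model\tsmoothing={self.smoothing}\n")
        pd.DataFrame(
            {"distance": np.exp(self.log_d), "log_intensity": self.log_c}
        ).to_csv(buf, sep="\t", index=False, float_format="%.10g")
        return buf.getvalue()

    @classmethod
    def from_tsv(cls, text: str) -> "DecayModel":
        lines = text.splitlines()
        smoothing = int(lines[0].split("smoothing=")[1])
        df = pd.read_csv(io.StringIO("\n".join(lines[1:])), sep="\t")
        return cls(
            log_d=np.log(df["distance"].to_numpy()),
            log_c=df["log_intensity"].to_numpy(),
            smoothing=smoothing,
        )


def fit_decay(bins: Sequence[DecayBin], smoothing: int = 4) -> DecayModel:
    """Cubic smoothing fit of (ln D, ln C) then non-increasing projection.

    ``smoothing`` counts interior knots of the least-squares cubic spline
    (default 4, i.e. effective degrees of freedom 8 on 50 bins). Fitted
    values at the bin distances are projected to the nearest non-increasing
    sequence (antitonic regression in log space) and interpolated linearly
    in log-log space between knots.
    """
    if len(bins) < 4:
        raise ValueError("need at least 4 bins to fit a decay model")
    d = np.array([b.d for b in bins], dtype=np.float64)
    c = np.array([b.c for b in bins], dtype=np.float64)
    if np.any(c <= 0) or np.any(~np.isfinite(np.log(c))):
        raise ValueError("non-positive bin intensity; cannot take logs")
    order = np.argsort(d)
    x, y = np.log(d[order]), np.log(c[order])
    # collapse duplicate distances (rare): keep the mean log intensity
    ux, inv = np.unique(x, return_inverse=True)
    if len(ux) < len(x):
        uy = np.zeros_like(ux)
        for i in range(len(ux)):
            uy[i] = y[inv == i].mean()
        x, y = ux, uy
    n_knots = min(smoothing, max(0, len(x) - 8))
    if n_knots > 0 and len(x) >= 8:
        q = np.linspace(0, 1, n_knots + 2)[1:-1]
        t = np.quantile(x, q)
        spline = LSQUnivariateSpline(x, y, t, k=3)
        fitted = spline(x)
    else:
        # too few points for a cubic spline: straight line in log-log space
        fitted = np.polyval(np.polyfit(x, y, 1), x)
    iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
    mono = iso.fit_transform(x, fitted)
    return DecayModel(log_d=x, log_c=np.asarray(mono, dtype=np.float64),
                      smoothing=smoothing)
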