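"""Significance testing of segment-pair contacts.

Each observed pair count AB is modelled as the sum of two negative-binomial
draws, one per anchoring direction:

    AB = X + Y,  X ~ NB(r = A_hat, p = p_AB),  Y ~ NB(r = B_hat, p = p_BA)

where p_AB (p_BA) is the bias-adjusted probability that anchor A (B)
contacts B (A) among all its window partners, and A_hat (B_hat) is the
estimated "failed trials" background parameter of the anchor, built from
the anchor's other contacts with the tested pair's own reads excluded.
The p-value of an observed count k is the upper tail

    p = 1 - sum_{j=0}^{k-1} P(AB = j)

with P(AB = j) the exact convolution of the two NB mass functions.
Benjamini-Hochberg correction is applied over the family of all tested
(observed, filtered) pairs; loops are calls with q below the threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .bias import EndDensityModel, SegmentBias, partner_weights, window_rows
from .decay import DecayModel
from .genome import SegmentUniverse

__all__ = [
    "BackgroundEstimate",
    "nb_pmf",
    "nb_log_pmf_table",
    "convolution_pvalue",
    "estimate_background",
    "call_loops",
]

_P_EPS = 1e-12
_P_MAX = 1.0 - 1e-9


def nb_pmf(k: int, r: float, p: float) -> float:
    """Negative-binomial pmf C(k+r-1, k) p^k (1-p)^r for real r >= 0.

    ``p`` is the per-trial event probability, ``r`` the (possibly
    non-integer) number of failed trials. r = 0 degenerates to a point
    mass at zero. Computed in log space via the gamma function.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if r < 0:
        raise ValueError("r must be non-negative")
    if r == 0:
        return 1.0 if k == 0 else 0.0
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie in (0, 1) for r > 0")
    log_pmf = (
        gammaln(k + r) - gammaln(r) - gammaln(k + 1)
        + k * math.log(p) + r * math.log1p(-p)
    )
    return float(math.exp(log_pmf))


def nb_log_pmf_table(kmax: int, r: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Matrix of log pmf values, shape (len(r), kmax + 1), j = 0..kmax.

    Rows with r == 0 get the degenerate point mass at zero.
    """
    r = np.asarray(r, dtype=np.float64)
    p = np.clip(np.asarray(p, dtype=np.float64), _P_EPS, _P_MAX)
    j = np.arange(kmax + 1, dtype=np.float64)
    rr = np.where(r > 0, r, 1.0)  # placeholder to keep gammaln finite
    logpmf = (
        gammaln(j[None, :] + rr[:, None])
        - gammaln(rr[:, None])
        - gammaln(j[None, :] + 1.0)
        + j[None, :] * np.log(p)[:, None]
        + rr[:, None] * np.log1p(-p)[:, None]
    )
    degenerate = r <= 0
    if degenerate.any():
        logpmf[degenerate, :] = -np.inf
        logpmf[degenerate, 0] = 0.0
    return logpmf


def convolution_pvalue(
    k: int, a_hat: float, b_hat: float, p_ab: float, p_ba: float
) -> float:
    """Upper-tail probability of observing >= k reads under AB = X + Y.

    Exact convolution of the two NB mass functions, accumulated with
    compensated summation and floored at 0 against rounding. k = 0 returns
    1 (empty sum). A degenerate background (a_hat = b_hat = 0) puts all
    mass at zero: p-value 1 for k = 0, 0 otherwise.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if k == 0:
        return 1.0
    if a_hat == 0.0 and b_hat == 0.0:
        return 0.0
    px = [nb_pmf(i, a_hat, min(max(p_ab, _P_EPS), _P_MAX)) for i in range(k)]
    py = [nb_pmf(i, b_hat, min(max(p_ba, _P_EPS), _P_MAX)) for i in range(k)]
    cy = np.cumsum(py)
    # P(AB <= k-1) = sum_i P(X=i) P(Y <= k-1-i)
    below = math.fsum(px[i] * cy[k - 1 - i] for i in range(k))
    return max(0.0, 1.0 - below)


@dataclass
class BackgroundEstimate:
    """A_hat and its per-partner components for one anchor.

    r_i = (A' - C_Ai) / ((A' - C_Ai) + (i_total - C_Ai)), 0.5 when the
    denominator is 0, with A' the anchor depth after removing the excluded
    pair's reads; A_hat = sum_i C_Ai r_i over the remaining partners.
    """

    anchor: int
    a_hat: float
    partners: np.ndarray = field(default_factory=lambda: np.array([], int))
    c: np.ndarray = field(default_factory=lambda: np.array([], int))
    r: np.ndarray = field(default_factory=lambda: np.array([], float))


def estimate_background(
    anchor: int,
    contacts: pd.DataFrame,
    exclude_partner: Optional[int] = None,
) -> BackgroundEstimate:
    """Background parameter A_hat of one anchor from its observed contacts.

    Depths are windowed: each segment's total is the sum of its contact
    counts in the (already filtered) table. When ``exclude_partner`` is
    given, that pair's reads are removed from the anchor depth and the
    partner is dropped from the sum, so the tested pair does not inform its
    own background.
    """
    a = contacts["seg_a"].to_numpy()
    b = contacts["seg_b"].to_numpy()
    kk = contacts["count"].to_numpy(dtype=np.float64)
    depth: dict[int, float] = {}
    for s, cnt in zip(np.concatenate([a, b]), np.concatenate([kk, kk])):
        depth[int(s)] = depth.get(int(s), 0.0) + float(cnt)

    mine = (a == anchor) | (b == anchor)
    partners = np.where(a[mine] == anchor, b[mine], a[mine])
    c = kk[mine]
    a_total = depth.get(anchor, 0.0)
    if exclude_partner is not None:
        m = partners != exclude_partner
        a_total -= float(c[~m].sum())
        partners, c = partners[m], c[m]
    i_total = np.array([depth[int(pp)] for pp in partners])
    x = a_total - c
    y = i_total - c
    if np.any(x < -1e-9) or np.any(y < -1e-9):
        raise ValueError("negative depth difference: bookkeeping error")
    denom = x + y
    r = np.where(denom > 0, np.divide(x, np.where(denom > 0, denom, 1.0)), 0.5)
    return BackgroundEstimate(
        anchor=anchor,
        a_hat=float(np.sum(c * r)),
        partners=partners.astype(np.int64),
        c=c.astype(np.int64),
        r=r,
    )


def _directional_tables(
    contacts: pd.DataFrame,
    universe: SegmentUniverse,
    decay: DecayModel,
    bias: Optional[SegmentBias],
    end_model: Optional[EndDensityModel],
    d_min: int,
    d_max: int,
) -> pd.DataFrame:
    """Per ordered (anchor -> partner) row: p_anchor_partner and A_hat.

    A_hat for (anchor, partner) excludes the pair's own reads from the
    anchor depth and drops the partner from the sum.
    """
    seg_a = contacts["seg_a"].to_numpy()
    seg_b = contacts["seg_b"].to_numpy()
    count = contacts["count"].to_numpy(dtype=np.float64)
    dist = contacts["distance"].to_numpy(dtype=np.float64)

    anchor = np.concatenate([seg_a, seg_b])
    partner = np.concatenate([seg_b, seg_a])
    kvec = np.concatenate([count, count])
    dvec = np.concatenate([dist, dist])

    n_seg = len(universe)
    depth = np.bincount(anchor, weights=kvec, minlength=n_seg)

    # p_anchor->partner = f(D) w_partner / denom_anchor
    w = partner_weights(universe, decay, bias, end_model)
    arow = universe.row(anchor)
    prow = universe.row(partner)
    fd = decay.evaluate(dvec)
    numer = fd * w[prow]

    denom = np.zeros(n_seg)
    for anchor_id in np.unique(anchor):
        row = int(universe.row(int(anchor_id)))
        rows = window_rows(universe, row, d_min, d_max)
        dd = np.abs(universe.center[rows] - universe.center[row]).astype(float)
        denom[anchor_id] = float(np.sum(w[rows] * decay.evaluate(dd)))

    with np.errstate(invalid="ignore", divide="ignore"):
        p_dir = np.where(denom[anchor] > 0, numer / np.where(denom[anchor] > 0, denom[anchor], 1.0), np.nan)

    # A_hat per ordered pair, vectorized within each anchor block
    order = np.argsort(anchor, kind="stable")
    a_hat = np.empty(len(anchor))
    anch_sorted = anchor[order]
    blocks = np.flatnonzero(np.diff(anch_sorted)) + 1
    starts = np.concatenate([[0], blocks])
    ends = np.concatenate([blocks, [len(anch_sorted)]])
    for s, e in zip(starts, ends):
        idx = order[s:e]
        cvec = kvec[idx]
        itot = depth[partner[idx]]
        a_tot = depth[anchor[idx[0]]]
        # X[b, i] = (A_tot - C_b) - C_i ; Y[i] = i_tot - C_i
        x = (a_tot - cvec)[:, None] - cvec[None, :]
        y = (itot - cvec)[None, :]
        den = x + y
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(den > 0, x / np.where(den > 0, den, 1.0), 0.5)
        contrib = cvec[None, :] * r
        np.fill_diagonal(contrib, 0.0)
        a_hat[idx] = contrib.sum(axis=1)

    n = len(seg_a)
    return pd.DataFrame(
        {
            "seg_a": seg_a,
            "seg_b": seg_b,
            "count": contacts["count"].to_numpy(),
            "distance": contacts["distance"].to_numpy(),
            "p_ab": p_dir[:n],
            "p_ba": p_dir[n:],
            "a_hat": a_hat[:n],
            "b_hat": a_hat[n:],
        }
    )


def _batch_pvalues(
    k: np.ndarray,
    a_hat: np.ndarray,
    b_hat: np.ndarray,
    p_ab: np.ndarray,
    p_ba: np.ndarray,
    chunk: int = 20000,
) -> np.ndarray:
    """Vectorized convolution p-values for many pairs."""
    k = np.asarray(k, dtype=np.int64)
    out = np.empty(len(k), dtype=np.float64)
    p_ab = np.clip(p_ab, _P_EPS, _P_MAX)
    p_ba = np.clip(p_ba, _P_EPS, _P_MAX)

    zero = k == 0
    out[zero] = 1.0

    one = k == 1
    if one.any():
        log0 = a_hat[one] * np.log1p(-p_ab[one]) + b_hat[one] * np.log1p(-p_ba[one])
        deg = (a_hat[one] == 0) & (b_hat[one] == 0)
        v = -np.expm1(log0)
        v[deg] = 0.0
        out[one] = np.maximum(v, 0.0)

    rest = np.flatnonzero(k >= 2)
    # sort by k so chunks share a small kmax
    rest = rest[np.argsort(k[rest])]
    for s in range(0, len(rest), chunk):
        idx = rest[s : s + chunk]
        kmax = int(k[idx].max()) - 1
        lx = nb_log_pmf_table(kmax, a_hat[idx], p_ab[idx])
        ly = nb_log_pmf_table(kmax, b_hat[idx], p_ba[idx])
        px = np.exp(lx)
        cy = np.cumsum(np.exp(ly), axis=1)
        kk = k[idx]
        below = np.zeros(len(idx))
        for i in range(kmax + 1):
            col = kk - 1 - i
            valid = col >= 0
            if not valid.any():
                break
            gather = cy[np.arange(len(idx)), np.clip(col, 0, kmax)]
            below += np.where(valid, px[:, i] * gather, 0.0)
        vals = np.maximum(0.0, 1.0 - below)
        deg = (a_hat[idx] == 0) & (b_hat[idx] == 0)
        vals[deg] = 0.0
        out[idx] = vals
    return out


def call_loops(
    contacts: pd.DataFrame,
    universe: SegmentUniverse,
    decay: DecayModel,
    bias: Optional[SegmentBias] = None,
    end_model: Optional[EndDensityModel] = None,
    q_threshold: float = 0.01,
    d_min: int = 2000,
    d_max: int = 25000,
) -> pd.DataFrame:
    """Score every observed, filtered contact and BH-correct the family.

    Returns one row per tested pair with columns seg_a, seg_b, count,
    distance, p_ab, p_ba, a_hat, b_hat, expected, p_value, q_value,
    significant. Pairs whose anchor has no usable partners are skipped.
    """
    if bias is not None:
        from .bias import apply_beta_filter

        contacts = apply_beta_filter(contacts, bias, universe)
    contacts = contacts.loc[contacts["count"] >= 1].reset_index(drop=True)
    if len(contacts) == 0:
        return pd.DataFrame(
            columns=[
                "seg_a", "seg_b", "count", "distance", "p_ab", "p_ba",
                "a_hat", "b_hat", "expected", "p_value", "q_value",
                "significant",
            ]
        )
    table = _directional_tables(
        contacts, universe, decay, bias, end_model, d_min, d_max
    )
    usable = np.isfinite(table["p_ab"]) & np.isfinite(table["p_ba"])
    table = table.loc[usable].reset_index(drop=True)

    pv = _batch_pvalues(
        table["count"].to_numpy(),
        table["a_hat"].to_numpy(),
        table["b_hat"].to_numpy(),
        table["p_ab"].to_numpy(),
        table["p_ba"].to_numpy(),
    )
    table["expected"] = (
        table["a_hat"] * table["p_ab"] / (1.0 - table["p_ab"])
        + table["b_hat"] * table["p_ba"] / (1.0 - table["p_ba"])
    )
    table["p_value"] = pv
    _, qv, _, _ = multipletests(pv, method="fdr_bh")
    table["q_value"] = qv
    table["significant"] = table["q_value"] < q_threshold
    return table.sort_values(["seg_a", "seg_b"], ignore_index=True)
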