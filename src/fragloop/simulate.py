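"""Synthetic Hi-C generator with known ground truth.

Emulates the study conditions end to end: a genome digestible by a 4-bp
cutter with geometric restriction-site spacing, non-overlapping genes with
decile expression levels, a power-law contact decay restricted to the
2-25 kb analysis window, multiplicative segment biases (log-normal
"visibility" beta and a fragment-end-density effect), planted loops —
generic pairs, 5'-3' gene self-loops, promoter-promoter pairs — and ChIP
peak / resequencing-coverage / expression tracks.

The generative intensity for a segment pair at distance D is

    lambda_AB ∝ D^-alpha * f_E(E_A) f_E(E_B) * l_A l_B * beta_A beta_B

times the planted fold for enriched pairs, scaled to the configured total.
Counts are Poisson by default (an optional negative-binomial size knob adds
dispersion); all randomness flows from one seeded generator, so identical
seed + config give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .contacts import contact_frame
from .genome import GeneModel, SegmentUniverse

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_genome",
    "simulate_biases",
    "plant_loops",
    "simulate_contacts",
    "simulate_reseq_coverage",
    "simulate_tracks",
    "contacts_to_pairs",
    "enumerate_window_pairs",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Generator settings; the defaults are the package's study conditions."""

    seed: int
    n_chromosomes: int = 2
    chrom_length: int = 2_000_000
    motif: str = "GATC"
    motif_spacing_mean: float = 256.0
    min_segment_len: int = 500
    # contact decay
    decay_exponent: float = 1.0
    d_min: int = 2000
    d_max: int = 25000
    total_contacts: int = 400_000
    nb_dispersion: Optional[float] = None   # NB size; None = Poisson counts
    # segment biases
    beta_sigma: float = 0.25                # log-normal sigma of beta
    end_density_exponent: float = 1.0       # Hi-C depth ~ E**gamma
    # planted loops
    n_loops: int = 50
    loop_fold: float = 10.0
    loop_span: Tuple[int, int] = (2500, 15000)   # log-uniform span range
    n_promoter_loops: int = 20
    promoter_loop_span: Tuple[int, int] = (6000, 20000)
    self_loop_fraction: float = 0.1
    self_loop_tts_inset: int = 500
    # genes
    n_genes: int = 400
    gene_length_log_mean: float = 7.7       # ln bp; median ~2.2 kb
    gene_length_log_sigma: float = 0.6
    gene_min_len: int = 300
    gene_max_len: int = 15000
    intergenic_mean: float = 1500.0
    # tracks
    peak_fraction: float = 0.2
    peak_coupling: float = 0.0
    peak_halfwidth: int = 400
    reseq_coverage: float = 30.0            # fold coverage
    reseq_read_length: int = 100

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.loop_fold < 1 or self.total_contacts <= 0:
            raise ValueError("rates must be positive and enrichment >= 1")

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "loop_span" in data:
            data["loop_span"] = tuple(data["loop_span"])
        if "promoter_loop_span" in data:
            data["promoter_loop_span"] = tuple(data["promoter_loop_span"])
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """What was planted, keyed the way the pipeline reports calls."""

    planted: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["seg_a", "seg_b", "fold", "kind", "gene_id"]
        )
    )
    self_loop_genes: List[str] = field(default_factory=list)
    promoter_loop_pairs: List[Tuple[str, str]] = field(default_factory=list)
    flagged_promoter_genes: List[str] = field(default_factory=list)
    beta_true: Optional[np.ndarray] = None
    end_multiplier_true: Optional[np.ndarray] = None

    def planted_keys(self, n_segments: int) -> np.ndarray:
        a = self.planted["seg_a"].to_numpy(dtype=np.int64)
        b = self.planted["seg_b"].to_numpy(dtype=np.int64)
        return a * n_segments + b


def _random_chromosome(
    length: int, motif: str, spacing_mean: float, rng: np.random.Generator
) -> str:
    """Random sequence whose only motif occurrences sit at geometric gaps."""
    m = len(motif)
    motif_bytes = np.frombuffer(motif.encode(), dtype=np.uint8)
    seq = _BASES[rng.integers(0, 4, size=length)]
    n_est = int(length / spacing_mean * 2) + 16
    gaps = rng.geometric(1.0 / spacing_mean, size=n_est)
    cuts = np.cumsum(np.maximum(gaps, m))
    cuts = cuts[cuts <= length - m]
    if len(cuts):
        seq[cuts[:, None] + np.arange(m)] = motif_bytes
    # knock out accidental occurrences (mutating the 2nd base cannot create
    # a new occurrence nor touch a planted one for GATC-like motifs)
    hit = np.ones(length - m + 1, dtype=bool)
    for i, b in enumerate(motif_bytes):
        hit &= seq[i : length - m + 1 + i] == b
    occ = np.flatnonzero(hit)
    accidental = np.setdiff1d(occ, cuts, assume_unique=False)
    if len(accidental):
        seq[accidental + 1] = motif_bytes[0]
    return seq.tobytes().decode("ascii")


def simulate_genome(
    config: SimConfig, rng: np.random.Generator
) -> Tuple[Dict[str, str], List[GeneModel], Dict[str, int]]:
    """Random genome + non-overlapping gene annotation.

    Genes are packed left to right with exponential intergenic gaps,
    log-normal lengths, random strands and uniform decile expression
    levels (0-9). Raises if the configured gene count cannot be placed.
    """
    sequences: Dict[str, str] = {}
    chrom_sizes: Dict[str, int] = {}
    for i in range(config.n_chromosomes):
        name = f"chr{i + 1}"
        sequences[name] = _random_chromosome(
            config.chrom_length, config.motif, config.motif_spacing_mean, rng
        )
        chrom_sizes[name] = config.chrom_length

    genes: List[GeneModel] = []
    per_chrom = int(np.ceil(config.n_genes / config.n_chromosomes))
    counter = 0
    for name in sequences:
        pos = 1000
        placed = 0
        while placed < per_chrom and counter < config.n_genes:
            gap = int(rng.exponential(config.intergenic_mean)) + 200
            glen = int(
                np.clip(
                    rng.lognormal(
                        config.gene_length_log_mean, config.gene_length_log_sigma
                    ),
                    config.gene_min_len,
                    config.gene_max_len,
                )
            )
            start = pos + gap
            end = start + glen
            if end > config.chrom_length - 1000:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            tss, tts = (start, end) if strand == "+" else (end, start)
            genes.append(
                GeneModel(
                    id=f"g{counter:05d}",
                    chrom=name,
                    strand=strand,
                    tss=tss,
                    tts=tts,
                    expression_level=int(rng.integers(0, 10)),
                )
            )
            pos = end
            placed += 1
            counter += 1
    if counter < config.n_genes:
        raise ValueError(
            f"infeasible gene packing: placed {counter} of {config.n_genes}"
        )
    return sequences, genes, chrom_sizes


def simulate_biases(
    universe: SegmentUniverse, config: SimConfig, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """True per-segment beta (log-normal, mean 1) and end-density
    multiplier E**gamma (mean 1)."""
    if config.beta_sigma > 0:
        beta = rng.lognormal(0.0, config.beta_sigma, size=len(universe))
    else:
        beta = np.ones(len(universe))
    beta = beta / beta.mean()
    fe = np.power(universe.end_count.astype(np.float64), config.end_density_exponent)
    fe = fe / fe.mean()
    return beta, fe


def enumerate_window_pairs(
    universe: SegmentUniverse, d_min: int, d_max: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All intra-chromosomal segment row pairs (a < b) with
    d_min <= center distance <= d_max."""
    rows_a: List[np.ndarray] = []
    rows_b: List[np.ndarray] = []
    for chrom, sl in universe.chrom_slices.items():
        c = universe.center[sl].astype(np.int64)
        n = len(c)
        lo = np.searchsorted(c, c + d_min, side="left")
        hi = np.searchsorted(c, c + d_max, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            continue
        a = np.repeat(np.arange(n), counts)
        offsets = np.arange(total) - np.repeat(
            np.concatenate([[0], np.cumsum(counts)[:-1]]), counts
        )
        b = np.repeat(lo, counts) + offsets
        rows_a.append(a + sl.start)
        rows_b.append(b + sl.start)
    ra = np.concatenate(rows_a)
    rb = np.concatenate(rows_b)
    d = np.abs(universe.center[rb] - universe.center[ra])
    keep = (d >= d_min) & (d <= d_max)
    return ra[keep], rb[keep], d[keep]


def _nearest_segment_at(
    universe: SegmentUniverse, chrom: str, target_center: int
) -> int:
    sl = universe.chrom_slices[chrom]
    c = universe.center[sl]
    i = int(np.clip(np.searchsorted(c, target_center), 1, len(c) - 1))
    i = i if abs(c[i] - target_center) < abs(c[i - 1] - target_center) else i - 1
    return sl.start + i


def plant_loops(
    universe: SegmentUniverse,
    genes: Sequence[GeneModel],
    config: SimConfig,
    rng: np.random.Generator,
) -> GroundTruth:
    """Choose the enriched pairs: generic loops with log-uniform spans,
    gene self-loops (TSS segment to the segment 500 bp short of the TTS)
    and promoter-promoter loops."""
    truth = GroundTruth()
    used: set = set()
    records: List[dict] = []

    def try_add(row_a: int, row_b: int, kind: str, gene_id: str = "") -> bool:
        if row_a == row_b:
            return False
        a, b = sorted((int(universe.id[row_a]), int(universe.id[row_b])))
        d = abs(int(universe.center[universe.row(a)]) - int(universe.center[universe.row(b)]))
        if not (config.d_min <= d <= config.d_max) or (a, b) in used:
            return False
        used.add((a, b))
        records.append(
            {"seg_a": a, "seg_b": b, "fold": config.loop_fold, "kind": kind,
             "gene_id": gene_id}
        )
        return True

    # generic loops
    lo, hi = config.loop_span
    attempts = 0
    planted = 0
    while planted < config.n_loops and attempts < config.n_loops * 200:
        attempts += 1
        row_a = int(rng.integers(0, len(universe)))
        span = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        sign = 1 if rng.random() < 0.5 else -1
        chrom = str(universe.chrom[row_a])
        target = int(universe.center[row_a] + sign * span)
        row_b = _nearest_segment_at(universe, chrom, target)
        if try_add(row_a, row_b, "generic"):
            planted += 1

    # gene self-loops: 5' (TSS) segment to the segment just inside the 3' end
    eligible = []
    for g in genes:
        point_3p = g.tts - g.direction * config.self_loop_tts_inset
        if (point_3p - g.tss) * g.direction <= 0:
            continue
        seg5 = int(universe.locate(g.chrom, np.array([g.tss]))[0])
        seg3 = int(universe.locate(g.chrom, np.array([point_3p]))[0])
        if seg5 < 0 or seg3 < 0 or seg5 == seg3:
            continue
        d = abs(
            int(universe.center[universe.row(seg5)])
            - int(universe.center[universe.row(seg3)])
        )
        if config.d_min <= d <= config.d_max:
            eligible.append((g, seg5, seg3))
    n_pick = int(round(config.self_loop_fraction * len(eligible)))
    if n_pick and eligible:
        order = rng.permutation(len(eligible))[:n_pick]
        for idx in order:
            g, seg5, seg3 = eligible[idx]
            if try_add(int(universe.row(seg5)), int(universe.row(seg3)),
                       "self_loop", g.id):
                truth.self_loop_genes.append(g.id)

    # promoter-promoter loops
    p_lo, p_hi = config.promoter_loop_span
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    candidates: List[Tuple[GeneModel, GeneModel, int, int]] = []
    for chrom, gs in by_chrom.items():
        gs = sorted(gs, key=lambda g: g.tss)
        for i, gi in enumerate(gs):
            for gj in gs[i + 1 :]:
                span = abs(gj.tss - gi.tss)
                if span > p_hi:
                    break
                if span < p_lo:
                    continue
                si = int(universe.locate(chrom, np.array([gi.tss]))[0])
                sj = int(universe.locate(chrom, np.array([gj.tss]))[0])
                if si >= 0 and sj >= 0 and si != sj:
                    candidates.append((gi, gj, si, sj))
    if config.n_promoter_loops and candidates:
        order = rng.permutation(len(candidates))
        taken = 0
        for idx in order:
            if taken >= config.n_promoter_loops:
                break
            gi, gj, si, sj = candidates[idx]
            if try_add(int(universe.row(si)), int(universe.row(sj)),
                       "promoter_pair", f"{gi.id}|{gj.id}"):
                truth.promoter_loop_pairs.append((gi.id, gj.id))
                taken += 1

    truth.planted = pd.DataFrame(
        records, columns=["seg_a", "seg_b", "fold", "kind", "gene_id"]
    )
    return truth


def simulate_contacts(
    universe: SegmentUniverse,
    config: SimConfig,
    rng: np.random.Generator,
    truth: Optional[GroundTruth] = None,
    beta_true: Optional[np.ndarray] = None,
    end_multiplier_true: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Draw per-pair counts from the factor model; returns observed
    (count >= 1) contacts."""
    ra, rb, d = enumerate_window_pairs(universe, config.d_min, config.d_max)
    if len(ra) == 0:
        raise ValueError("no pairs in the analysis window")
    w = universe.length.astype(np.float64).copy()
    if beta_true is not None:
        w = w * beta_true
    if end_multiplier_true is not None:
        w = w * end_multiplier_true
    lam = np.power(d.astype(np.float64), -config.decay_exponent) * w[ra] * w[rb]
    if truth is not None and len(truth.planted):
        key = universe.id[ra] * len(universe) + universe.id[rb]
        fold = pd.Series(
            truth.planted["fold"].to_numpy(),
            index=truth.planted_keys(len(universe)),
        )
        hit = pd.Series(key).map(fold).fillna(1.0).to_numpy()
        lam = lam * hit
    total = lam.sum()
    if total <= 0:
        raise ValueError("total expected contact count is zero")
    lam *= config.total_contacts / total
    if config.nb_dispersion is None:
        counts = rng.poisson(lam)
    else:
        size = float(config.nb_dispersion)
        counts = rng.negative_binomial(size, size / (size + lam))
    keep = counts > 0
    return contact_frame(
        universe.id[ra[keep]], universe.id[rb[keep]], counts[keep], universe
    ).sort_values(["seg_a", "seg_b"], ignore_index=True)


def simulate_reseq_coverage(
    universe: SegmentUniverse,
    beta_true: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-segment genomic resequencing read counts: Poisson around
    beta * length * coverage / read_length."""
    expect = (
        beta_true
        * universe.length
        * config.reseq_coverage
        / config.reseq_read_length
    )
    return rng.poisson(expect).astype(np.float64)


def simulate_tracks(
    genes: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
    config: SimConfig,
    rng: np.random.Generator,
    truth: Optional[GroundTruth] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """ChIP peak track + expression table.

    Peaks are TSS-centered intervals wide enough to flag a promoter.
    With coupling c, each gene participating in a planted promoter-pair
    loop receives a peak with probability c; other genes receive one with
    the background probability ``peak_fraction``.
    """
    coupled = set()
    if truth is not None:
        for ga, gb in truth.promoter_loop_pairs:
            coupled.update((ga, gb))
    rows = []
    flagged = []
    for g in genes:
        if g.id in coupled:
            take = rng.random() < config.peak_coupling
        else:
            take = rng.random() < config.peak_fraction
        if take:
            size = chrom_sizes[g.chrom]
            start = max(0, g.tss - config.peak_halfwidth)
            end = min(size, g.tss + config.peak_halfwidth)
            rows.append({"chrom": g.chrom, "start": start, "end": end})
            flagged.append(g.id)
    if truth is not None:
        truth.flagged_promoter_genes = flagged
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    expression = pd.DataFrame(
        {"gene_id": [g.id for g in genes],
         "level": [g.expression_level for g in genes]}
    )
    return peaks, expression


def contacts_to_pairs(
    contacts: pd.DataFrame,
    universe: SegmentUniverse,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Expand aggregated contacts into mate-pair records with uniform
    positions inside each segment (for exercising the ingestion path)."""
    reps = contacts["count"].to_numpy()
    a = np.repeat(contacts["seg_a"].to_numpy(), reps)
    b = np.repeat(contacts["seg_b"].to_numpy(), reps)
    ra, rb = universe.row(a), universe.row(b)
    pos1 = rng.integers(universe.start[ra], universe.end[ra])
    pos2 = rng.integers(universe.start[rb], universe.end[rb])
    strands = np.array(["+", "-"])
    return pd.DataFrame(
        {
            "chrom1": universe.chrom[ra],
            "pos1": pos1,
            "strand1": strands[rng.integers(0, 2, len(a))],
            "chrom2": universe.chrom[rb],
            "pos2": pos2,
            "strand2": strands[rng.integers(0, 2, len(a))],
        }
    )
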