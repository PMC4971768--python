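"""End-to-end pipeline on synthetic inputs: simulate -> digest -> fit ->
call -> classify, with evaluation helpers against the planted truth.

Every stage runs the same code paths as on real inputs; the generator only
replaces the wet-lab data. All randomness flows from the single seed in
the SimConfig, so a repeated run is byte-identical.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import io as fio
from .bias import (
    EndDensityModel,
    SegmentBias,
    apply_beta_filter,
    estimate_beta,
    fit_end_density,
)
from .caller import call_loops
from .contacts import filter_contacts
from .decay import DecayModel, equal_occupancy_bins, fit_decay
from .geneloops import classify_genes
from .genome import GeneModel, SegmentUniverse, digest_genome, merge_fragments
from .simulate import (
    GroundTruth,
    SimConfig,
    plant_loops,
    simulate_biases,
    simulate_contacts,
    simulate_genome,
    simulate_reseq_coverage,
    simulate_tracks,
)

__all__ = ["PipelineResult", "run_pipeline", "evaluate_loop_calls",
           "evaluate_gene_loops"]


@dataclass
class PipelineResult:
    config: SimConfig
    universe: SegmentUniverse
    genes: List[GeneModel]
    chrom_sizes: Dict[str, int]
    truth: GroundTruth
    contacts: pd.DataFrame
    decay: DecayModel
    bias: SegmentBias
    end_model: EndDensityModel
    loops: pd.DataFrame
    gene_classes: pd.DataFrame
    peaks: pd.DataFrame
    expression: pd.DataFrame

    def output_tables(self) -> Dict[str, str]:
        """Canonical text renderings of every output, for writing/hashing."""
        return {
            "segments.bed": self.universe.to_frame().to_csv(sep="\t", index=False),
            "decay.tsv": self.decay.to_tsv(),
            "loops.tsv": self.loops.to_csv(sep="\t", index=False, float_format="%.10g"),
            "gene_classes.tsv": self.gene_classes.to_csv(sep="\t", index=False),
            "contacts.tsv": self.contacts.to_csv(sep="\t", index=False),
        }

    def output_hash(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.output_tables()):
            h.update(name.encode())
            h.update(self.output_tables()[name].encode())
        return h.hexdigest()

    def write_outputs(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        for name, text in self.output_tables().items():
            with open(os.path.join(out_dir, name), "w") as fh:
                fh.write(text)


def run_pipeline(
    config: SimConfig,
    q_threshold: float = 0.01,
    n_bins: int = 50,
) -> PipelineResult:
    """Full synthetic run: generate inputs, estimate every model from the
    generated data only, call loops and classify gene self-loops."""
    rng = np.random.default_rng(config.seed)
    sequences, genes, chrom_sizes = simulate_genome(config, rng)

    fragments = digest_genome(sequences, config.motif)
    segments = merge_fragments(fragments, min_len=config.min_segment_len)
    universe = SegmentUniverse(segments)

    beta_true, fe_true = simulate_biases(universe, config, rng)
    truth = plant_loops(universe, genes, config, rng)
    truth.beta_true = beta_true
    truth.end_multiplier_true = fe_true

    contacts = simulate_contacts(
        universe, config, rng, truth, beta_true, fe_true
    )
    reseq = simulate_reseq_coverage(universe, beta_true, config, rng)
    peaks, expression = simulate_tracks(genes, chrom_sizes, config, rng, truth)

    # estimation uses only the generated observables
    contacts = filter_contacts(contacts, universe, config.d_min, config.d_max)
    bias = estimate_beta(reseq, universe)
    contacts = apply_beta_filter(contacts, bias, universe)

    hic_depth = np.zeros(len(universe))
    both = np.concatenate([contacts["seg_a"].to_numpy(), contacts["seg_b"].to_numpy()])
    weights = np.concatenate([contacts["count"].to_numpy()] * 2).astype(float)
    np.add.at(hic_depth, universe.row(both), weights)
    end_model = fit_end_density(hic_depth, universe)

    bins = equal_occupancy_bins(contacts, n_bins=n_bins)
    decay = fit_decay(bins)

    loops = call_loops(
        contacts, universe, decay, bias, end_model,
        q_threshold=q_threshold, d_min=config.d_min, d_max=config.d_max,
    )
    gene_classes = classify_genes(genes, loops, universe)

    return PipelineResult(
        config=config,
        universe=universe,
        genes=genes,
        chrom_sizes=chrom_sizes,
        truth=truth,
        contacts=contacts,
        decay=decay,
        bias=bias,
        end_model=end_model,
        loops=loops,
        gene_classes=gene_classes,
        peaks=peaks,
        expression=expression,
    )


def evaluate_loop_calls(
    loops: pd.DataFrame, truth: GroundTruth, n_segments: int
) -> Dict[str, float]:
    """Recall over planted pairs and empirical FDR of significant calls."""
    sig = loops.loc[loops["significant"]]
    called = set(zip(sig["seg_a"].to_numpy(), sig["seg_b"].to_numpy()))
    planted = set(
        zip(truth.planted["seg_a"].to_numpy(), truth.planted["seg_b"].to_numpy())
    )
    n_true_called = len(called & planted)
    recall = n_true_called / len(planted) if planted else float("nan")
    fdr = (len(called) - n_true_called) / len(called) if called else 0.0
    return {
        "recall": recall,
        "fdr": fdr,
        "n_called": float(len(called)),
        "n_planted": float(len(planted)),
    }


def evaluate_gene_loops(
    gene_classes: pd.DataFrame, truth: GroundTruth
) -> Dict[str, float]:
    """Recall of planted self-loop genes classified 3' only or both."""
    if not truth.self_loop_genes:
        return {"recall": float("nan"), "n_planted": 0.0}
    table = gene_classes.set_index("gene_id")
    hit = 0
    for gid in truth.self_loop_genes:
        if gid in table.index and table.loc[gid, "category"] in ("3' only", "both"):
            hit += 1
    return {
        "recall": hit / len(truth.self_loop_genes),
        "n_planted": float(len(truth.self_loop_genes)),
    }
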