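"""Test a promoter-mark association against shift-coordinate nulls.

Plants 25 promoter-promoter loops whose genes all carry a ChIP peak on
their promoters (coupling 1.0), counts interacting promoter pairs with
the mark on both sides, and compares the count against nulls built by
translating the peak track +/-10 and +/-20 kb along the chromosome.
"""

import numpy as np

import fragloop as fl
import fragloop.simulate as sim
from fragloop.genome import promoter_regions

cfg = fl.SimConfig(
    seed=2,
    n_chromosomes=1,
    chrom_length=2_000_000,
    total_contacts=1000,
    n_loops=0,
    n_promoter_loops=25,
    self_loop_fraction=0.0,
    n_genes=200,
    peak_coupling=1.0,
)
rng = np.random.default_rng(cfg.seed)
seqs, genes, sizes = sim.simulate_genome(cfg, rng)
universe = fl.SegmentUniverse(
    fl.merge_fragments(fl.digest_genome(seqs), cfg.min_segment_len)
)
truth = sim.plant_loops(universe, genes, cfg, rng)
peaks, _ = sim.simulate_tracks(genes, sizes, cfg, rng, truth)

loops = truth.planted.copy()
ra = universe.row(loops["seg_a"].to_numpy())
rb = universe.row(loops["seg_b"].to_numpy())
loops["distance"] = np.abs(universe.center[ra] - universe.center[rb])
loops["significant"] = True
promoters = promoter_regions(genes, sizes)


def dual_count(track):
    flags = fl.flag_promoters(promoters, track)
    return fl.promoter_pair_interactions(loops, promoters, flags, universe, genes)[1]


observed = dual_count(peaks)
nulls = [dual_count(fl.shift_features(peaks, off, sizes))
         for off in (10_000, -10_000, 20_000, -20_000)]
result = fl.empirical_enrichment(observed, nulls)

print(f"promoter-pair loops planted:      {len(truth.promoter_loop_pairs)}")
print(f"dual-marked pairs observed:       {observed}")
print(f"dual-marked pairs, shifted nulls: {nulls}")
print(f"empirical p (add-one):            {result.p_value:.3f}")
print()
print("Shifting the peak coordinates breaks the peak-loop coupling while")
print("keeping the mark's spatial autocorrelation; with four shift nulls")
print("the smallest attainable p is 1/5 = 0.2.")
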