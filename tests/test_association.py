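"""Promoter flags, promoter-pair interactions, shift nulls and
expression reassignment."""

import numpy as np
import pandas as pd
import pytest

from fragloop.association import (
    classify_gene_pair_loops,
    empirical_enrichment,
    expression_shuffle,
    flag_promoters,
    promoter_pair_interactions,
    shift_features,
    signal_ratio,
)
from fragloop.genome import GeneModel, PromoterRegion
from conftest import universe_from_segments


def peaks_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestFlagPromoters:
    def test_threshold_inclusive_at_30_percent(self):
        prom = [PromoterRegion("g1", "c", 1000, 2000)]
        flags = flag_promoters(prom, peaks_df([("c", 1000, 1300)]))
        assert flags["g1"] is True or flags["g1"] == True  # noqa: E712

    def test_below_threshold_and_no_overlap(self):
        prom = [
            PromoterRegion("g1", "c", 1000, 2000),
            PromoterRegion("g2", "c", 9000, 10_000),
        ]
        flags = flag_promoters(prom, peaks_df([("c", 1000, 1299)]))
        assert not flags["g1"] and not flags["g2"]

    def test_overlapping_peaks_counted_once(self):
        prom = [PromoterRegion("g1", "c", 1000, 2000)]
        flags = flag_promoters(
            prom, peaks_df([("c", 1000, 1200), ("c", 1100, 1250)])
        )
        assert not flags["g1"]  # union covers 250 bp < 300

    def test_agrees_with_base_by_base_counter(self, rng):
        prom = [PromoterRegion(f"g{i}", "c", i * 3000, i * 3000 + 1000) for i in range(20)]
        rows = [
            ("c", int(s), int(s + rng.integers(50, 900)))
            for s in rng.integers(0, 60_000, 40)
        ]
        flags = flag_promoters(prom, peaks_df(rows), 0.3)
        covered = np.zeros(100_000, dtype=bool)
        for _, s, e in rows:
            covered[s:e] = True
        for p in prom:
            want = covered[p.start : p.end].sum() >= 0.3 * (p.end - p.start)
            assert flags[p.gene_id] == want


class TestPromoterPairs:
    @pytest.fixture
    def setting(self):
        universe = universe_from_segments(
            {"c": [(i * 1000, (i + 1) * 1000) for i in range(40)]}
        )
        genes = [
            GeneModel("gA", "c", "+", 2_500, 5_000),
            GeneModel("gB", "c", "+", 10_500, 13_000),
            GeneModel("gC", "c", "+", 20_500, 23_000),
        ]
        promoters = [
            PromoterRegion(g.id, "c", g.tss - 500, g.tss + 500) for g in genes
        ]
        return universe, genes, promoters

    def _loops(self, pairs):
        df = pd.DataFrame(
            {"seg_a": [min(p) for p in pairs], "seg_b": [max(p) for p in pairs]}
        )
        df["distance"] = 1000 * (df.seg_b - df.seg_a)
        df["significant"] = True
        return df

    def test_counts_and_dual_flags(self, setting):
        universe, genes, promoters = setting
        # segments 2 (gA promoter), 10 (gB), 20 (gC)
        loops = self._loops([(2, 10), (10, 20)])
        flags = {"gA": True, "gB": True, "gC": False}
        n, dual = promoter_pair_interactions(
            loops, promoters, flags, universe, genes
        )
        assert (n, dual) == (2, 1)

    def test_span_threshold(self, setting):
        universe, genes, promoters = setting
        loops = self._loops([(2, 10)])
        loops.loc[0, "distance"] = 5999
        flags = {"gA": True, "gB": True, "gC": True}
        assert promoter_pair_interactions(
            loops, promoters, flags, universe, genes
        ) == (0, 0)

    def test_no_promoter_overlap(self, setting):
        universe, genes, promoters = setting
        loops = self._loops([(30, 38)])
        assert promoter_pair_interactions(
            loops, promoters, {}, universe, genes
        ) == (0, 0)


class TestShift:
    sizes = {"c": 10_000}

    def test_identity(self):
        track = peaks_df([("c", 100, 300), ("c", 5_000, 5_500)])
        out = shift_features(track, 0, self.sizes)
        assert out[["start", "end"]].values.tolist() == [[100, 300], [5000, 5500]]

    def test_wrap_conserves_count_and_length(self):
        track = peaks_df([("c", 9_800, 10_000), ("c", 9_900, 9_950)])
        out = shift_features(track, 500, self.sizes)
        assert out["feature_id"].nunique() == 2
        total = (out["end"] - out["start"]).sum()
        assert total == 250

    def test_composition_is_identity(self):
        track = peaks_df([("c", 9_700, 9_900), ("c", 200, 450)])
        back = shift_features(shift_features(track, 700, self.sizes), -700, self.sizes)
        merged = (
            back.groupby("feature_id")
            .apply(lambda g: (g["end"] - g["start"]).sum(), include_groups=False)
            .tolist()
        )
        assert merged == [200, 250]
        # non-wrapping features return to their original coordinates
        row = back.loc[back.feature_id == 1].iloc[0]
        assert (row.start, row.end) == (200, 450)

    def test_offset_larger_than_chromosome_rejected(self):
        with pytest.raises(ValueError):
            shift_features(peaks_df([("c", 0, 10)]), 10_000, self.sizes)


class TestEnrichment:
    def test_observed_above_all_nulls(self):
        r = empirical_enrichment(10, [1, 2, 3, 4])
        assert r.p_value == pytest.approx(0.2)

    def test_observed_below_all_nulls(self):
        r = empirical_enrichment(0, [1, 2, 3, 4])
        assert r.p_value == pytest.approx(1.0)

    def test_requires_nulls(self):
        with pytest.raises(ValueError):
            empirical_enrichment(1, [])


class TestExpressionShuffle:
    def _genes(self, levels, chrom="c"):
        return [
            GeneModel(f"g{i}", chrom, "+", 1000 + 5000 * i, 3000 + 5000 * i,
                      expression_level=lv)
            for i, lv in enumerate(levels)
        ]

    def test_rotation_by_one(self):
        out = expression_shuffle(self._genes([1, 2, 3]), lag=1, direction="down")
        assert [out["g0"], out["g1"], out["g2"]] == [2, 3, 1]

    def test_full_wrap_is_identity(self):
        genes = self._genes([4, 5, 6, 7])
        out = expression_shuffle(genes, lag=4, direction="up")
        assert [out[g.id] for g in genes] == [4, 5, 6, 7]

    def test_multiset_preserved_per_chromosome(self, rng):
        levels = rng.integers(0, 10, 30).tolist()
        genes = self._genes(levels)
        out = expression_shuffle(genes, lag=20, direction="down")
        assert sorted(out.values()) == sorted(levels)


class TestSignalRatio:
    def test_equal_coverage_zero(self, uniform_universe):
        cov = np.full(len(uniform_universe), 10.0)
        lr = signal_ratio(cov, cov, uniform_universe, pseudocount=0.0)
        np.testing.assert_allclose(lr, 0.0)

    def test_doubled_signal_ln2(self, uniform_universe):
        n = len(uniform_universe)
        sig = np.full(n, 10.0)
        sig[3] = 20.0
        ctl = np.full(n, 10.0)
        ctl[7] = 20.0  # keep totals equal so normalization is neutral
        lr = signal_ratio(sig, ctl, uniform_universe, pseudocount=0.0)
        assert lr[3] == pytest.approx(np.log(2.0))

    def test_zero_control_needs_pseudocount(self, uniform_universe):
        n = len(uniform_universe)
        ctl = np.full(n, 10.0)
        ctl[0] = 0.0
        with pytest.raises(ValueError):
            signal_ratio(np.full(n, 10.0), ctl, uniform_universe, pseudocount=0.0)


class TestGenePairLoops:
    def test_within_vs_between(self):
        universe = universe_from_segments(
            {"c": [(i * 1000, (i + 1) * 1000) for i in range(30)]}
        )
        genes = [
            GeneModel("long", "c", "+", 2_000, 8_000),
            GeneModel("next", "c", "+", 9_000, 12_000),
        ]
        loops = pd.DataFrame(
            {
                "seg_a": [2, 6],
                "seg_b": [6, 10],
                "distance": [4000, 4000],
                "significant": [True, True],
            }
        )
        assert classify_gene_pair_loops(loops, genes, universe) == (1, 1)
        # enrichment restriction: flag only the within-gene loop's anchors
        flags = np.zeros(len(universe), dtype=bool)
        flags[[2, 6]] = True
        assert classify_gene_pair_loops(
            loops, genes, universe, enrichment_flags=flags
        ) == (1, 0)

    def test_span_threshold_exclusive(self):
        universe = universe_from_segments(
            {"c": [(i * 1000, (i + 1) * 1000) for i in range(30)]}
        )
        genes = [GeneModel("g", "c", "+", 1_000, 15_000)]
        loops = pd.DataFrame(
            {"seg_a": [2], "seg_b": [8], "distance": [6000], "significant": [True]}
        )
        assert classify_gene_pair_loops(loops, genes, universe) == (0, 0)
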