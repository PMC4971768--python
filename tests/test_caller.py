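"""Negative-binomial convolution test: pmf, p-values, background
estimation and the BH-corrected caller."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fragloop.caller import (
    call_loops,
    convolution_pvalue,
    estimate_background,
    nb_pmf,
)
from fragloop.contacts import contact_frame
from fragloop.decay import DecayModel
from conftest import universe_from_segments


def flat_decay():
    return DecayModel(
        log_d=np.log([2000.0, 25000.0]), log_c=np.array([0.0, 0.0]), smoothing=0
    )


def brute_force_pvalue(k, a_hat, b_hat, p_ab, p_ba):
    """Independent oracle: scipy pmfs and an explicit double loop."""

    def pmf(i, r, p):
        if r == 0:
            return 1.0 if i == 0 else 0.0
        return stats.nbinom.pmf(i, r, 1.0 - p)

    below = 0.0
    for j in range(k):
        for i in range(j + 1):
            below += pmf(i, a_hat, p_ab) * pmf(j - i, b_hat, p_ba)
    return max(0.0, 1.0 - below)


class TestNbPmf:
    def test_zero_count_closed_form(self):
        assert nb_pmf(0, 3.7, 0.2) == pytest.approx((1 - 0.2) ** 3.7, rel=1e-12)

    def test_geometric_reduction(self):
        for k in range(6):
            assert nb_pmf(k, 1.0, 0.3) == pytest.approx(
                0.3**k * 0.7, rel=1e-12
            )

    def test_gamma_generalized_against_library(self):
        # non-integer r checked against the independent scipy implementation
        assert nb_pmf(3, 2.5, 0.1) == pytest.approx(
            stats.nbinom.pmf(3, 2.5, 0.9), abs=1e-12
        )

    def test_degenerate_r_zero(self):
        assert nb_pmf(0, 0.0, 0.5) == 1.0
        assert nb_pmf(4, 0.0, 0.5) == 0.0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            nb_pmf(2, 1.5, 1.0)

    def test_mass_sums_to_one(self, rng):
        for _ in range(5):
            r = rng.uniform(0.2, 20)
            p = rng.uniform(1e-3, 0.3)
            total = sum(nb_pmf(k, r, p) for k in range(4000))
            assert total == pytest.approx(1.0, abs=1e-8)


class TestConvolutionPvalue:
    def test_k_zero_is_one(self):
        assert convolution_pvalue(0, 3.0, 4.0, 0.05, 0.04) == 1.0

    def test_matches_bruteforce(self, rng):
        for _ in range(25):
            k = int(rng.integers(1, 40))
            a, b = rng.uniform(0.1, 30, 2)
            pab, pba = rng.uniform(1e-4, 0.2, 2)
            assert convolution_pvalue(k, a, b, pab, pba) == pytest.approx(
                brute_force_pvalue(k, a, b, pab, pba), abs=1e-10
            )

    def test_single_nb_limit(self):
        # with no B-side background the p-value is the plain NB survival
        for k in (1, 3, 10):
            got = convolution_pvalue(k, 4.2, 0.0, 0.03, 0.05)
            want = stats.nbinom.sf(k - 1, 4.2, 1 - 0.03)
            assert got == pytest.approx(want, abs=1e-12)

    def test_monotone_in_k(self):
        vals = [convolution_pvalue(k, 3.2, 5.1, 0.02, 0.015) for k in range(1, 15)]
        assert all(a >= b for a, b in zip(vals[:-1], vals[1:]))

    def test_degenerate_background(self):
        assert convolution_pvalue(0, 0.0, 0.0, 0.1, 0.1) == 1.0
        assert convolution_pvalue(3, 0.0, 0.0, 0.1, 0.1) == 0.0


class TestBackground:
    def _contacts(self, universe, entries):
        a = np.array([e[0] for e in entries])
        b = np.array([e[1] for e in entries])
        k = np.array([e[2] for e in entries])
        return contact_frame(a, b, k, universe)

    @pytest.fixture
    def universe(self):
        return universe_from_segments(
            {"chr1": [(i * 1000, (i + 1) * 1000) for i in range(40)]}
        )

    def test_symmetric_depths_give_half(self, universe):
        # A-0 and A-1 with equal counts; partners' depths equal A's depth
        c = self._contacts(
            universe, [(10, 14, 4), (10, 6, 4), (14, 18, 4), (6, 2, 4)]
        )
        est = estimate_background(10, c)
        np.testing.assert_allclose(est.r, 0.5)
        assert est.a_hat == pytest.approx(0.5 * 8)

    def test_denominator_zero_falls_back_to_half(self, universe):
        # single pair carries all reads of both segments
        c = self._contacts(universe, [(5, 9, 7)])
        est = estimate_background(5, c)
        np.testing.assert_allclose(est.r, 0.5)
        assert est.a_hat == pytest.approx(3.5)

    def test_worked_ratio_example(self, universe):
        # A_total=10, i_total=30, C_Ai=5 -> r = 5/30, contribution 5/6
        c = self._contacts(
            universe, [(10, 14, 5), (10, 6, 5), (14, 18, 25)]
        )
        est = estimate_background(10, c)
        i = int(np.flatnonzero(est.partners == 14)[0])
        assert est.r[i] == pytest.approx(5 / 30)
        assert (est.c[i] * est.r[i]) == pytest.approx(5 / 6)

    def test_excluded_pair_does_not_inform_background(self, universe):
        c = self._contacts(
            universe, [(10, 14, 5), (10, 6, 3), (10, 18, 2)]
        )
        est = estimate_background(10, c, exclude_partner=14)
        assert 14 not in est.partners
        # anchor depth seen by r excludes the 5 reads of pair (10, 14)
        ref = self._contacts(universe, [(10, 6, 3), (10, 18, 2)])
        est_ref = estimate_background(10, ref)
        assert est.a_hat == pytest.approx(est_ref.a_hat)

    def test_doubling_one_pair_leaves_disjoint_backgrounds_alone(self, universe):
        base = [(2, 6, 3), (6, 10, 2), (20, 24, 4), (24, 28, 5)]
        c1 = self._contacts(universe, base)
        c2 = self._contacts(universe, [(2, 6, 6)] + base[1:])
        for anchor in (20, 24, 28):
            e1 = estimate_background(anchor, c1)
            e2 = estimate_background(anchor, c2)
            assert e1.a_hat == pytest.approx(e2.a_hat)


class TestCallLoops:
    @pytest.fixture
    def universe(self):
        return universe_from_segments(
            {"chr1": [(i * 1000, (i + 1) * 1000) for i in range(60)]}
        )

    def _background_contacts(self, universe, rng, enriched=None):
        rows = []
        n = len(universe)
        for i in range(n):
            for j in range(i + 2, min(i + 20, n)):
                k = int(rng.poisson(8))
                if enriched and (i, j) == enriched:
                    k += 60
                if k > 0:
                    rows.append((i, j, k))
        a = np.array([r[0] for r in rows])
        b = np.array([r[1] for r in rows])
        k = np.array([r[2] for r in rows])
        return contact_frame(a, b, k, universe)

    def test_enriched_pair_ranks_first(self, universe, rng):
        contacts = self._background_contacts(universe, rng, enriched=(20, 30))
        loops = call_loops(contacts, universe, flat_decay())
        top = loops.sort_values("p_value").iloc[0]
        assert (top.seg_a, top.seg_b) == (20, 30)
        assert top.significant

    def test_q_thresholds_nest(self, universe, rng):
        contacts = self._background_contacts(universe, rng, enriched=(20, 30))
        strict = call_loops(contacts, universe, flat_decay(), q_threshold=0.01)
        relaxed = call_loops(contacts, universe, flat_decay(), q_threshold=0.05)
        s_set = set(map(tuple, strict.loc[strict.significant, ["seg_a", "seg_b"]].values))
        r_set = set(map(tuple, relaxed.loc[relaxed.significant, ["seg_a", "seg_b"]].values))
        assert s_set <= r_set

    def test_row_order_invariance(self, universe, rng):
        contacts = self._background_contacts(universe, rng)
        shuffled = contacts.sample(frac=1.0, random_state=9).reset_index(drop=True)
        l1 = call_loops(contacts, universe, flat_decay())
        l2 = call_loops(shuffled, universe, flat_decay())
        pd.testing.assert_frame_equal(l1, l2)

    def test_pvalues_in_unit_interval(self, universe, rng):
        contacts = self._background_contacts(universe, rng)
        loops = call_loops(contacts, universe, flat_decay())
        assert ((loops.p_value >= 0) & (loops.p_value <= 1)).all()
        assert ((loops.q_value >= 0) & (loops.q_value <= 1)).all()
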