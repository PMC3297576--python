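import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from isletseq.differential import (
    LOG2_CAP,
    PairTestResult,
    bh_adjust,
    call_unit,
    delta_splice_index,
    fisher_exact_two_sided,
    fisher_gene_pair,
    fisher_pvalues_for_margins,
    fisher_transcript_pair,
    log2_expression_change,
    tissue_enrichment_call,
)


def oracle_fisher(a, b, c, d):
    """Independent brute-force oracle: enumerate all tables with the same
    margins, conditioning on the *column* margins (the implementation
    conditions on rows), in exact rational arithmetic."""
    c1, c2 = a + c, b + d
    r1 = a + b
    n = c1 + c2
    denom = math.comb(n, r1)
    p_obs = Fraction(math.comb(c1, a) * math.comb(c2, b), denom)
    total = Fraction(0)
    for x in range(0, min(c1, r1) + 1):
        y = r1 - x
        if 0 <= y <= c2:
            p = Fraction(math.comb(c1, x) * math.comb(c2, y), denom)
            if p <= p_obs:
                total += p
    return float(min(total, Fraction(1)))


class TestFisherExact:
    def test_no_association(self):
        p, sign = fisher_gene_pair(5, 10, 5, 10)
        assert p == 1.0
        assert sign == 0

    def test_extreme_table_closed_form(self):
        """[[0,10],[10,0]] has p = 2 / C(20,10)."""
        p = fisher_exact_two_sided(0, 10, 10, 0)
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-12)
        _, sign = fisher_gene_pair(0, 10, 10, 10)
        assert sign < 0

    def test_worked_table_against_oracle(self):
        p = fisher_exact_two_sided(30, 970, 10, 990)
        assert p == pytest.approx(oracle_fisher(30, 970, 10, 990), rel=1e-10)
        _, sign = fisher_gene_pair(30, 1000, 10, 1000)
        assert sign > 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy_on_random_tables(self, seed):
        """Cross-check against the independent scipy implementation on both
        small (exact path) and large (pmf path) tables."""
        rng = np.random.default_rng(seed)
        for hi in (30, 500, 20_000):
            a, b, c, d = (int(rng.integers(0, hi)) for _ in range(4))
            ours = fisher_exact_two_sided(a, b, c, d)
            ref = scipy_fisher([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, rel=1e-7, abs=1e-12)

    def test_batch_margins_agree_with_scalar(self):
        for r1, r2, c1 in [(10, 12, 8), (25, 5, 17), (40, 40, 40)]:
            batch = fisher_pvalues_for_margins(r1, r2, c1)
            for a, p in batch.items():
                assert p == fisher_exact_two_sided(a, r1 - a, c1 - a, r2 - (c1 - a))

    def test_condition_swap_preserves_p_and_flips_sign(self):
        p1, s1 = fisher_gene_pair(30, 1000, 10, 900)
        p2, s2 = fisher_gene_pair(10, 900, 30, 1000)
        assert p1 == pytest.approx(p2, rel=1e-12)
        assert s1 == -s2

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            fisher_gene_pair(11, 10, 5, 10)
        with pytest.raises(ValueError):
            fisher_exact_two_sided(-1, 2, 3, 4)

    def test_transcript_pair_and_skip_semantics(self):
        p, _ = fisher_transcript_pair(50, 50, 50, 50)
        assert p == 1.0
        p, sign = fisher_transcript_pair(40, 10, 10, 40)
        assert p == pytest.approx(oracle_fisher(40, 10, 10, 40), rel=1e-10)
        assert sign > 0


@settings(deadline=None, derandomize=True, max_examples=150)
@given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40), st.integers(0, 40))
def test_fisher_invariant_under_transpose_and_row_swap(a, b, c, d):
    """The two-sided p-value depends on the table only through its margins
    and cell probabilities: transposing or swapping rows leaves it fixed."""
    p = fisher_exact_two_sided(a, b, c, d)
    assert fisher_exact_two_sided(a, c, b, d) == pytest.approx(p, rel=1e-12, abs=1e-300)
    assert fisher_exact_two_sided(c, d, a, b) == pytest.approx(p, rel=1e-12, abs=1e-300)
    assert 0.0 <= p <= 1.0


@settings(deadline=None, derandomize=True, max_examples=150)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
def test_bh_bounds_and_order_preservation(p):
    """Adjusted values stay in [p_i, 1] and preserve the input ordering."""
    adj = bh_adjust(p)
    assert np.all(adj <= 1.0 + 1e-15)
    assert np.all(adj >= np.asarray(p) - 1e-15)
    for i in range(len(p)):
        for j in range(len(p)):
            if p[i] <= p[j]:
                assert adj[i] <= adj[j] + 1e-12


class TestBhAdjust:
    def oracle(self, p):
        n = len(p)
        order = np.argsort(p, kind="stable")
        adj = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * n / rank)
            adj[i] = running
        return adj

    def test_textbook_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04, 0.05]), [0.05] * 5
        )

    def test_all_ones_and_singleton(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0]), [1.0, 1.0])
        np.testing.assert_allclose(bh_adjust([0.37]), [0.37])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_stepup_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=int(rng.integers(1, 40)))
        np.testing.assert_allclose(bh_adjust(p), self.oracle(p), rtol=1e-12)

    def test_adjustment_never_decreases(self):
        rng = np.random.default_rng(99)
        p = rng.uniform(size=20)
        assert np.all(bh_adjust(p) >= p - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestEffectSizes:
    @pytest.mark.parametrize(
        "cyt,ctl,expected",
        [(8, 2, 2.0), (3, 3, 0.0), (5, 0, LOG2_CAP), (0, 5, -LOG2_CAP)],
    )
    def test_log2_change(self, cyt, ctl, expected):
        assert log2_expression_change(cyt, ctl) == expected

    def test_log2_change_undefined_both_zero(self):
        assert math.isnan(log2_expression_change(0, 0))

    def test_delta_splice_index(self):
        assert delta_splice_index(0.8, 0.5) == pytest.approx(0.3)
        assert delta_splice_index(0.5, 0.5) == 0.0
        assert math.isnan(delta_splice_index(None, 0.5))

    def test_swap_flips_signs(self):
        assert log2_expression_change(8, 2) == -log2_expression_change(2, 8)
        assert delta_splice_index(0.8, 0.5) == -delta_splice_index(0.5, 0.8)


def _pairs(unit, spec):
    """spec: list of (p_adj, sign, log2)."""
    return [
        PairTestResult(unit, f"P{i}", p, p, l, s) for i, (p, s, l) in enumerate(spec)
    ]


class TestCallUnit:
    def test_four_up_one_ns_is_up(self):
        call = call_unit(_pairs("g", [(0.01, 1, 1.0)] * 4 + [(0.5, 1, 0.2)]))
        assert call.call == "up"
        assert call.n_significant_up == 4

    def test_opposite_direction_blocks_call(self):
        call = call_unit(_pairs("g", [(0.01, 1, 1.0)] * 4 + [(0.01, -1, -1.0)]))
        assert call.call == "unchanged"

    def test_three_of_five_insufficient(self):
        call = call_unit(_pairs("g", [(0.01, 1, 1.0)] * 3 + [(0.5, 1, 0.1)] * 2))
        assert call.call == "unchanged"

    def test_tie_direction_cannot_contribute(self):
        # significant p but exactly equal proportions: sign 0, direction none
        call = call_unit(_pairs("g", [(0.01, 0, 0.0)] * 5))
        assert call.call == "unchanged"

    def test_median_of_significant_effects(self):
        call = call_unit(
            _pairs("g", [(0.01, 1, 1.0), (0.01, 1, 2.0), (0.01, 1, 3.0), (0.01, 1, 4.0), (0.5, 1, 9.0)])
        )
        assert call.median_significant_log2 == pytest.approx(2.5)

    def test_too_few_pairs_is_error(self):
        with pytest.raises(ValueError, match="min_consistent"):
            call_unit(_pairs("g", [(0.01, 1, 1.0)] * 3))


class TestTissueEnrichment:
    def test_strong_enrichment(self):
        call, med = tissue_enrichment_call(
            islet_gene_reads=[1000] * 5,
            islet_totals=[100_000] * 5,
            islet_rpkm=[100.0] * 5,
            background_gene_reads=100,
            background_total=100_000,
            background_rpkm=10.0,
        )
        assert call == "islet_enriched"
        assert med == pytest.approx(math.log2(10.0))

    def test_identical_proportions_ns(self):
        call, med = tissue_enrichment_call(
            [100] * 5, [10_000] * 5, [10.0] * 5, 100, 10_000, 10.0
        )
        assert call == "ns"
        assert math.isnan(med)

    def test_mixed_directions_ns(self):
        call, _ = tissue_enrichment_call(
            [1000, 1000, 1000, 1000, 10],
            [100_000] * 5,
            [100.0] * 4 + [1.0],
            100,
            100_000,
            10.0,
        )
        assert call == "ns"

    def test_too_few_islet_samples(self):
        with pytest.raises(ValueError):
            tissue_enrichment_call([100] * 3, [1000] * 3, [1.0] * 3, 10, 1000, 1.0)
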