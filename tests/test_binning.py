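"""Bin schemes, tail merging and the same-bin stratification rule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from varconcord.binning import (
    BinScheme,
    categorical_scheme,
    concordance_by_factor,
    empirical_coverage_bins,
    gc_bins,
    is_transition,
    merge_tail_bins,
    sturges_bins,
)
from conftest import make_callset, make_consensus


class TestEmpiricalCoverageBins:
    scheme = empirical_coverage_bins()

    @pytest.mark.parametrize("coverage,label", [
        (1, "1-4x"), (4, "1-4x"), (5, "5-19x"), (19, "5-19x"),
        (20, "20-79x"), (79, "20-79x"), (80, "80-199x"), (199, "80-199x"),
        (200, "≥200x"), (5000, "≥200x"),
    ])
    def test_boundaries(self, coverage, label):
        idx = self.scheme.assign([coverage])[0]
        assert self.scheme.bin_labels()[idx] == label

    def test_zero_coverage_out_of_range(self):
        assert self.scheme.assign([0])[0] == -1


class TestSturgesBins:
    @pytest.mark.parametrize("n,k", [(2, 2), (100, 8), (37268, 17)])
    def test_bin_count_follows_sturges_formula(self, n, k):
        assert math.ceil(math.log2(n) + 1) == k  # independent arithmetic
        rng = np.random.default_rng(1)
        scheme = sturges_bins(rng.random(n), factor_name="f")
        assert scheme.n_bins == k

    def test_log10_transform_equal_width_on_log_scale(self):
        scheme = sturges_bins([1, 10, 100, 1000], factor_name="vac",
                              transform="log10")
        assert scheme.edges[0] == pytest.approx(0.0)
        assert scheme.edges[-1] == pytest.approx(3.0)
        widths = np.diff(scheme.edges)
        assert np.allclose(widths, widths[0])
        # assignment happens on the log scale
        assert scheme.assign([1])[0] == 0
        assert scheme.assign([1000])[0] == scheme.n_bins - 1

    def test_constant_values_single_bin_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            scheme = sturges_bins([5.0, 5.0, 5.0], factor_name="f")
        assert scheme.n_bins == 1
        assert scheme.assign([5.0])[0] == 0

    def test_log10_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            sturges_bins([0.0, 1.0], factor_name="f", transform="log10")

    @given(st.lists(st.floats(min_value=-100, max_value=100,
                              allow_nan=False), min_size=2, max_size=200))
    @settings(deadline=None, max_examples=50)
    def test_partition_property(self, values):
        """Every in-range value maps to exactly one bin."""
        scheme = sturges_bins(values, factor_name="f")
        idx = scheme.assign(values)
        assert np.all(idx >= 0)
        assert np.all(idx < scheme.n_bins)


class TestMergeTailBins:
    def _scheme(self, n_bins):
        return BinScheme(factor_name="f", edges=tuple(float(i) for i in range(n_bins + 1)))

    def test_both_sparse_tails_absorbed(self):
        merged = merge_tail_bins(self._scheme(4), [2, 500, 600, 3], min_count=10)
        assert merged.n_bins == 2
        assert merged.edges == (0.0, 2.0, 4.0)

    def test_no_op_when_all_bins_large(self):
        scheme = self._scheme(2)
        merged = merge_tail_bins(scheme, [100, 100], min_count=10)
        assert merged.edges == scheme.edges

    def test_cascading_merge_preserves_membership_order(self):
        scheme = self._scheme(5)
        merged = merge_tail_bins(scheme, [1, 1, 50, 60, 1], min_count=5)
        assert merged.edges == (0.0, 3.0, 5.0)  # three edges remain
        values = np.array([0.5, 1.5, 2.5, 3.5, 4.5])
        before = scheme.assign(values)
        after = merged.assign(values)
        # coarsening: relative order preserved, no value skips a bin boundary
        assert np.all(np.diff(after) >= 0)
        for i in range(len(values) - 1):
            if before[i] == before[i + 1]:
                assert after[i] == after[i + 1]

    def test_all_below_threshold_collapses_with_warning(self):
        with pytest.warns(UserWarning, match="min_count"):
            merged = merge_tail_bins(self._scheme(3), [1, 2, 1], min_count=100)
        assert merged.n_bins == 1

    def test_interior_sparse_bin_untouched(self):
        merged = merge_tail_bins(self._scheme(5), [50, 1, 60, 1, 70], min_count=5)
        assert merged.n_bins == 5


class TestCategoricalSchemes:
    def test_twelve_substitution_categories(self):
        scheme = categorical_scheme("substitution_type")
        assert scheme.n_bins == 12
        assert len(set(scheme.categories)) == 12

    @pytest.mark.parametrize("sub,expected", [
        ("A>G", True), ("C>T", True), ("G>A", True), ("T>C", True),
        ("A>C", False), ("A>T", False), ("C>A", False), ("C>G", False),
        ("G>C", False), ("G>T", False), ("T>A", False), ("T>G", False),
    ])
    def test_transition_flags(self, sub, expected):
        assert is_transition(sub) is expected

    def test_annotation_categories(self):
        scheme = categorical_scheme("annotation")
        assert scheme.n_bins == 10
        assert scheme.assign(["exonic"])[0] >= 0
        assert scheme.assign(["nonsense-class"])[0] == -1

    def test_gc_split_at_half(self):
        scheme = gc_bins()
        assert scheme.assign([0.3])[0] == 0
        assert scheme.assign([0.7])[0] == 1


class TestConcordanceByFactor:
    def test_position_in_different_coverage_bins_excluded(self):
        a = make_callset([7], coverage=30.0)
        b = make_callset([7], replicate_id="r2", coverage=150.0)
        strat = concordance_by_factor(a, b, "coverage", empirical_coverage_bins())
        assert sum(br.n_positions for br in strat.bins) == 0

    def test_single_bin_perfect_concordance(self):
        a = make_callset([1, 2, 3], coverage=30.0)
        b = make_callset([1, 2, 3], replicate_id="r2", coverage=40.0)
        strat = concordance_by_factor(a, b, "coverage", empirical_coverage_bins())
        by_label = {br.label: br for br in strat.bins}
        assert by_label["20-79x"].rate == 1.0
        assert all(br.n_positions == 0 for br in strat.bins if br.label != "20-79x")

    def test_hand_enumerated_six_position_pair(self):
        # positions 1-3 in 20-79x both reps; 4 in 5-19x both; 5 split bins;
        # genotype differs at position 2, position 6 variant in a only
        a = make_callset([1, 2, 3, 4, 5, 6],
                         genotypes=[("A", "G")] * 4 + [("A", "G"), ("A", "G")],
                         coverage=[30.0, 40.0, 50.0, 10.0, 25.0, 35.0])
        b = make_callset([1, 2, 3, 4, 5], replicate_id="r2",
                         genotypes=[("A", "G"), ("G", "G"), ("A", "G"),
                                    ("A", "G"), ("A", "G")],
                         coverage=[35.0, 45.0, 55.0, 12.0, 90.0])
        # position 6 has no record in b and no consensus: excluded
        strat = concordance_by_factor(a, b, "coverage", empirical_coverage_bins())
        by_label = {br.label: br for br in strat.bins}
        big = by_label["20-79x"]
        assert big.n_positions == 3 and big.n_concordant == 2
        assert big.n1 == 3 and big.n2 == 3
        assert big.rate == pytest.approx(2 / 3)
        small = by_label["5-19x"]
        assert small.n_positions == 1 and small.rate == 1.0
        assert by_label["80-199x"].n_positions == 0

    def test_consensus_supplies_factor_for_one_sided_variant(self):
        a = make_callset([5], coverage=30.0)
        b = make_callset([], replicate_id="r2")
        b.consensus = make_consensus({5: "A"}, coverage=25.0)
        strat = concordance_by_factor(a, b, "coverage", empirical_coverage_bins())
        by_label = {br.label: br for br in strat.bins}
        # both values in 20-79x: position kept, discordant (variant in a only)
        assert by_label["20-79x"].n_positions == 1
        assert by_label["20-79x"].n_concordant == 0
        assert by_label["20-79x"].n1 == 1 and by_label["20-79x"].n2 == 0

    def test_substitution_factor_uses_calling_replicate(self):
        a = make_callset([1], coverage=30.0)  # A>G
        b = make_callset([], replicate_id="r2")
        b.consensus = make_consensus({1: "A"}, coverage=30.0)
        strat = concordance_by_factor(a, b, "substitution_type",
                                      categorical_scheme("substitution_type"))
        by_label = {br.label: br for br in strat.bins}
        assert by_label["A>G"].n_positions == 1
        assert by_label["A>G"].n_concordant == 0

    def test_same_bin_rule_symmetric(self):
        a = make_callset([1, 2, 3], coverage=[30.0, 10.0, 250.0])
        b = make_callset([1, 2, 4], replicate_id="r2",
                         coverage=[45.0, 90.0, 30.0])
        s_ab = concordance_by_factor(a, b, "coverage", empirical_coverage_bins())
        s_ba = concordance_by_factor(b, a, "coverage", empirical_coverage_bins())
        for x, y in zip(s_ab.bins, s_ba.bins):
            assert x.n_positions == y.n_positions
            assert x.n_concordant == y.n_concordant

    def test_stratified_concordant_counts_bounded_by_unstratified(self, sim_pair):
        from varconcord.concordance import snv_concordance
        reps, _, _ = sim_pair
        a, b = reps.replicates
        nc = snv_concordance(a, b).n_concordant
        strat = concordance_by_factor(a, b, "coverage", empirical_coverage_bins())
        assert sum(br.n_concordant for br in strat.bins) <= nc

    def test_constant_factor_equals_unstratified_rate(self):
        a = make_callset([1, 2, 3], genotypes=[("A", "G"), ("G", "G"), ("A", "G")],
                         coverage=50.0)
        b = make_callset([1, 2, 3], replicate_id="r2",
                         genotypes=[("A", "G"), ("A", "G"), ("A", "G")],
                         coverage=50.0)
        from varconcord.concordance import snv_concordance
        strat = concordance_by_factor(a, b, "coverage", empirical_coverage_bins())
        by_label = {br.label: br for br in strat.bins}
        assert by_label["20-79x"].rate == pytest.approx(snv_concordance(a, b).rate)

    def test_scheme_factor_mismatch_rejected(self):
        a = make_callset([1], coverage=30.0)
        b = make_callset([1], replicate_id="r2", coverage=30.0)
        with pytest.raises(ValueError):
            concordance_by_factor(a, b, "vaf", empirical_coverage_bins())

    def test_value_fn_supplies_position_level_factor(self):
        a = make_callset([1, 2], genotypes=[("A", "G"), ("A", "G")])
        b = make_callset([1, 2], replicate_id="r2",
                         genotypes=[("A", "G"), ("G", "G")])
        gc_of = {1: 0.3, 2: 0.7}
        strat = concordance_by_factor(a, b, "gc_content", gc_bins(),
                                      value_fn=lambda key: gc_of[key[1]])
        low, high = strat.bins
        assert low.n_positions == 1 and low.n_concordant == 1
        assert high.n_positions == 1 and high.n_concordant == 0
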