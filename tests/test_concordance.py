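"""Concordance rate Rc, whole-region concordance and replicate metrics."""

import numpy as np
import pytest
from scipy import stats

from varconcord.concordance import (
    ConcordanceResult,
    allcall_concordance,
    coverage_correlation,
    lin_ccc,
    metric_correlations,
    rate_percent,
    replicate_concordance,
    snv_concordance,
)
from varconcord.io import CallSet, ReplicateSet

from conftest import make_callset, make_consensus


def brute_force_rc(a: CallSet, b: CallSet) -> ConcordanceResult:
    """Independent oracle: position-by-position enumeration."""
    nc = 0
    for key in set(a.variants) | set(b.variants):
        va, vb = a.variants.get(key), b.variants.get(key)
        if va is not None and vb is not None and \
                sorted(va.genotype) == sorted(vb.genotype):
            nc += 1
    return ConcordanceResult(nc, len(a.variants), len(b.variants))


def random_pair(rng, max_positions=50):
    """Random small call-set pair over a shared position pool, with random
    genotypes so that shared positions may agree or disagree."""
    genotypes = [("A", "G"), ("G", "G"), ("A", "T"), ("C", "G")]
    pool = rng.integers(1, 2 * max_positions, size=max_positions)
    sets = []
    for rep in "ab":
        chosen = np.unique(pool[rng.random(max_positions) < 0.6])
        gts = [genotypes[i] for i in rng.integers(0, len(genotypes), len(chosen))]
        sets.append(make_callset(
            [int(p) for p in chosen], sample_id="s", replicate_id=rep,
            genotypes=[g if "A" in g or g == ("G", "G") else ("A", "G") for g in gts]))
    return sets


class TestSnvConcordance:
    def test_hand_enumerated_pair(self):
        # a: p1 p2 p3; b: p1 p2 p4 p5; equal genotype at p1, differ at p2
        a = make_callset([1, 2, 3], genotypes=[("A", "G"), ("G", "G"), ("A", "G")])
        b = make_callset([1, 2, 4, 5], replicate_id="r2",
                         genotypes=[("A", "G"), ("A", "G"), ("A", "G"), ("A", "G")])
        r = snv_concordance(a, b)
        assert (r.n_concordant, r.n_total_1, r.n_total_2) == (1, 3, 4)
        assert r.rate == pytest.approx(1 / 3.5)

    def test_identical_sets_fully_concordant(self):
        a = make_callset(range(1, 11))
        b = make_callset(range(1, 11), replicate_id="r2")
        r = snv_concordance(a, b)
        assert r.n_concordant == 10 and r.rate == 1.0

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a, b = random_pair(rng)
            assert snv_concordance(a, b).rate == snv_concordance(b, a).rate

    def test_discordant_addition_lowers_rate(self):
        a = make_callset([1, 2, 3])
        b = make_callset([1, 2, 3], replicate_id="r2")
        base = snv_concordance(a, b).rate
        b2 = make_callset([1, 2, 3, 99], replicate_id="r2")
        assert snv_concordance(a, b2).rate < base

    def test_concordant_addition_raises_rate_toward_one(self):
        a = make_callset([1, 2, 99])
        b = make_callset([1, 2, 50], replicate_id="r2")
        base = snv_concordance(a, b).rate
        a2 = make_callset([1, 2, 99, 7])
        b2 = make_callset([1, 2, 50, 7], replicate_id="r2")
        grown = snv_concordance(a2, b2).rate
        assert base < grown <= 1.0

    def test_empty_sets_error(self):
        a = make_callset([])
        b = make_callset([], replicate_id="r2")
        with pytest.raises(ZeroDivisionError):
            snv_concordance(a, b)

    def test_different_samples_rejected(self):
        a = make_callset([1], sample_id="x")
        b = make_callset([1], sample_id="y")
        with pytest.raises(ValueError):
            snv_concordance(a, b)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b = random_pair(rng)
            if not a.variants and not b.variants:
                continue
            got = snv_concordance(a, b)
            exp = brute_force_rc(a, b)
            assert (got.n_concordant, got.n_total_1, got.n_total_2) == \
                   (exp.n_concordant, exp.n_total_1, exp.n_total_2)


class TestReplicateAveraging:
    def test_duplicate_passthrough(self):
        a = make_callset([1, 2], replicate_id="r1")
        b = make_callset([1, 3], replicate_id="r2")
        reps = ReplicateSet(sample_id="s", replicates=[a, b])
        rc = replicate_concordance(reps)
        assert len(rc.pairwise) == 1
        assert rc.rate == snv_concordance(a, b).rate

    def test_triplicate_mean_of_three_pairs(self):
        sets = [make_callset([1, 2, 3, i + 10], replicate_id=f"r{i}")
                for i in range(3)]
        reps = ReplicateSet(sample_id="s", replicates=sets)
        rc = replicate_concordance(reps)
        assert len(rc.pairwise) == 3
        assert rc.rate == pytest.approx(np.mean([r.rate for r in rc.pairwise]))

    def test_identical_triplicates_rate_one(self):
        sets = [make_callset(range(5), replicate_id=f"r{i}") for i in range(3)]
        assert replicate_concordance(ReplicateSet("s", sets)).rate == 1.0

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            ReplicateSet(sample_id="s", replicates=[make_callset([1])])


class TestAllCallConcordance:
    def _pair(self, calls_a, calls_b):
        a = make_callset([], replicate_id="r1")
        a.consensus = make_consensus(calls_a)
        b = make_callset([], replicate_id="r2")
        b.consensus = make_consensus(calls_b)
        return a, b

    def test_hand_counted_with_ambiguous_excluded(self):
        # 100 positions: 97 equal, 2 involve N, 1 mismatch
        calls_a = {i: "A" for i in range(1, 101)}
        calls_b = dict(calls_a)
        calls_b[5] = "N"
        calls_a[6] = "N"
        calls_b[7] = "G"
        a, b = self._pair(calls_a, calls_b)
        r = allcall_concordance(a, b, exclude_ambiguous=True)
        assert (r.n_concordant, r.n_total_mean) == (97, 98)
        assert r.rate == pytest.approx(97 / 98)

    def test_inclusive_mode_counts_n_vs_base_discordant(self):
        calls_a = {1: "A", 2: "N", 3: "N"}
        calls_b = {1: "A", 2: "C", 3: "N"}
        a, b = self._pair(calls_a, calls_b)
        r = allcall_concordance(a, b, exclude_ambiguous=False)
        # N-vs-N concordant, N-vs-base discordant
        assert (r.n_concordant, r.n_total_mean) == (2, 3)

    def test_all_ambiguous_one_side_errors(self):
        calls_a = {i: "N" for i in range(1, 6)}
        calls_b = {i: "A" for i in range(1, 6)}
        a, b = self._pair(calls_a, calls_b)
        with pytest.raises(ValueError):
            allcall_concordance(a, b, exclude_ambiguous=True)

    def test_excluding_ambiguous_cannot_lower_rate_when_n_discordant(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = 50
            calls_a, calls_b = {}, {}
            for pos in range(1, n + 1):
                ca = rng.choice(["A", "G", "N"], p=[0.7, 0.2, 0.1])
                cb = rng.choice(["A", "G", "N"], p=[0.7, 0.2, 0.1])
                if ca == "N" and cb == "N":  # keep every N discordant
                    cb = "A"
                calls_a[pos], calls_b[pos] = ca, cb
            a, b = self._pair(calls_a, calls_b)
            incl = allcall_concordance(a, b, exclude_ambiguous=False)
            try:
                excl = allcall_concordance(a, b, exclude_ambiguous=True)
            except ValueError:
                continue
            assert excl.rate >= incl.rate


class TestCoverageCorrelation:
    def _pair(self, cov_a, cov_b):
        a = make_callset([], replicate_id="r1")
        a.consensus = make_consensus({p: "A" for p in cov_a}, coverage=cov_a)
        b = make_callset([], replicate_id="r2")
        b.consensus = make_consensus({p: "A" for p in cov_b}, coverage=cov_b)
        return a, b

    def test_identical_and_scaled_vectors_give_r_one(self):
        cov = {p: float(10 + 3 * p) for p in range(1, 11)}
        a, b = self._pair(cov, cov)
        assert coverage_correlation(a, b) == pytest.approx(1.0)
        a, b = self._pair(cov, {p: 2 * v for p, v in cov.items()})
        assert coverage_correlation(a, b) == pytest.approx(1.0)

    def test_matches_closed_form_pearson(self):
        x = {1: 12.0, 2: 40.0, 3: 7.0, 4: 99.0, 5: 18.0}
        y = {1: 20.0, 2: 35.0, 3: 11.0, 4: 70.0, 5: 30.0}
        a, b = self._pair(x, y)
        xv = np.array(list(x.values()))
        yv = np.array(list(y.values()))
        expected = (((xv - xv.mean()) * (yv - yv.mean())).sum()
                    / np.sqrt(((xv - xv.mean()) ** 2).sum()
                              * ((yv - yv.mean()) ** 2).sum()))
        assert coverage_correlation(a, b) == pytest.approx(expected)

    def test_zero_coverage_positions_dropped(self):
        x = {1: 0.0, 2: 40.0, 3: 7.0, 4: 99.0, 5: 18.0}
        y = {1: 20.0, 2: 35.0, 3: 11.0, 4: 70.0, 5: 30.0}
        a, b = self._pair(x, y)
        xv = np.array([40.0, 7.0, 99.0, 18.0])  # position 1 dropped
        yv = np.array([35.0, 11.0, 70.0, 30.0])
        r, _ = stats.pearsonr(xv, yv)
        assert coverage_correlation(a, b) == pytest.approx(r)


class TestMetricCorrelations:
    def test_identity_gives_rho_and_ccc_one(self):
        x = [1.0, 5.0, 3.0, 9.0, 2.0, 7.0]
        m = metric_correlations(x, x)
        assert m.spearman_rho == pytest.approx(1.0)
        assert m.lin_ccc == pytest.approx(1.0)

    def test_location_shift_attenuates_ccc_not_rho(self):
        x = np.array([1.0, 5.0, 3.0, 9.0, 2.0, 7.0])
        m = metric_correlations(x, x + 4.0)
        assert m.spearman_rho == pytest.approx(1.0)
        assert m.lin_ccc < 1.0

    def test_ccc_matches_direct_formula_and_pearson_bound(self):
        x = np.array([3.1, 9.4, 2.2, 7.7, 5.0, 6.3])
        y = np.array([4.0, 8.1, 3.5, 9.9, 4.2, 5.8])
        expected = (2 * np.cov(x, y, ddof=1)[0, 1]
                    / (x.var(ddof=1) + y.var(ddof=1) + (x.mean() - y.mean()) ** 2))
        got = lin_ccc(x, y)
        assert got == pytest.approx(expected)
        r, _ = stats.pearsonr(x, y)
        assert abs(got) <= abs(r) + 1e-12

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            metric_correlations([1.0, 2.0], [1.0, 2.0])


def test_rate_percent_rounds_half_up():
    assert rate_percent(ConcordanceResult.from_mean_total(567, 880)) == 64.4
    # 3/2000 = 0.15% exactly: half-up gives 0.2 (float round() would give 0.1)
    assert rate_percent(ConcordanceResult.from_mean_total(3, 2000)) == 0.2
    assert rate_percent(ConcordanceResult.from_mean_total(3667521, 3668018),
                        decimals=4) == 99.9865
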