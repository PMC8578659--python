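import itertools

import numpy as np
import pytest

from hicarch.enrichment import (
    contacts_between,
    contacts_log2fc,
    contacts_within,
    enrichment_test,
    mann_whitney_u,
    pcc_difference,
    sample_random_regions,
)
from hicarch.matrix import ContactMatrix, downsample_counts
from hicarch.regions import Interval, RegionSet

BS = 150_000


def _oe(values, mask=None):
    return ContactMatrix("chrT", BS, values, kind="oe", mask=mask)


def _sym(rng, n, lo=0.5, hi=2.0):
    u = rng.uniform(lo, hi, (n, n))
    return np.triu(u) + np.triu(u, 1).T


def regions_of_bins(bins):
    return RegionSet([Interval("chrT", b * BS, (b + 1) * BS) for b in bins])


# --------------------------------------------------------- contact values


class TestContactsWithin:
    def test_all_bins_gives_full_upper_triangle(self):
        rng = np.random.default_rng(0)
        v = _sym(rng, 10)
        vals = contacts_within(_oe(v), regions_of_bins(range(10)))
        iu = np.triu_indices(10, k=1)
        np.testing.assert_allclose(np.sort(vals), np.sort(v[iu]))

    def test_uniform_oe_mean_one(self):
        vals = contacts_within(_oe(np.ones((30, 30))), regions_of_bins([2, 5, 9, 20]))
        assert vals.mean() == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        v = _sym(rng, 20)
        bins = [3, 4, 11, 15, 16]
        vals = contacts_within(_oe(v), regions_of_bins(bins))
        oracle = [v[i, j] for i, j in itertools.combinations(bins, 2)]
        np.testing.assert_allclose(np.sort(vals), np.sort(oracle))

    def test_planted_block_mean(self):
        v = np.ones((40, 40))
        block = np.arange(10, 20)
        v[np.ix_(block, block)] = 2.0
        vals = contacts_within(_oe(v), regions_of_bins(block))
        assert vals.mean() == pytest.approx(2.0)

    def test_masked_bins_dropped(self):
        rng = np.random.default_rng(2)
        v = _sym(rng, 10)
        mask = np.zeros(10, bool)
        mask[4] = True
        with_mask = contacts_within(_oe(v, mask=mask), regions_of_bins([3, 4, 5, 6]))
        no4 = contacts_within(_oe(v), regions_of_bins([3, 5, 6]))
        np.testing.assert_allclose(np.sort(with_mask), np.sort(no4))

    def test_too_few_bins_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            contacts_within(_oe(np.ones((10, 10))), regions_of_bins([3]))


class TestContactsBetween:
    def test_uniform_oe_mean_one(self):
        vals = contacts_between(
            _oe(np.ones((30, 30))), regions_of_bins([5]), regions_of_bins([10, 20])
        )
        assert vals.mean() == pytest.approx(1.0)

    def test_focal_pairs_excluded(self):
        rng = np.random.default_rng(3)
        v = _sym(rng, 20)
        focal = regions_of_bins([5, 6])
        other = regions_of_bins([5, 6, 10, 12])
        vals = contacts_between(_oe(v), focal, other)
        oracle = sorted(v[i, j] for i in (5, 6) for j in (10, 12))
        np.testing.assert_allclose(np.sort(vals), oracle)

    def test_planted_focal_drop_log2fc(self):
        # focal-block contacts 2.0 in condition a, 1.0 in b -> log2 fc = -1 (b/a)
        v_a = np.ones((40, 40))
        v_b = np.ones((40, 40))
        focal_bins, block = [5], np.arange(20, 30)
        for f in focal_bins:
            v_a[f, block] = v_a[block, f] = 2.0
        a = contacts_between(_oe(v_a), regions_of_bins(focal_bins), regions_of_bins(block))
        b = contacts_between(_oe(v_b), regions_of_bins(focal_bins), regions_of_bins(block))
        assert np.log2(b.mean() / a.mean()) == pytest.approx(-1.0)

    def test_no_usable_pairs_errors(self):
        with pytest.raises(ValueError):
            contacts_between(
                _oe(np.ones((10, 10))), regions_of_bins([3]), regions_of_bins([3])
            )


# ---------------------------------------------------------- random regions


class TestSampleRandomRegions:
    def test_forced_placement(self):
        template = RegionSet([Interval("chrA", 0, 1000)])
        reps = sample_random_regions(template, {"chrA": 1000}, 3, seed=0)
        for rs in reps:
            assert rs[0] == Interval("chrA", 0, 1000)

    def test_length_multiset_preserved(self):
        template = RegionSet([
            Interval("chrA", 0, 500), Interval("chrA", 700, 2000),
            Interval("chrA", 2500, 2600),
        ])
        reps = sample_random_regions(template, {"chrA": 100_000}, 5, seed=1)
        for rs in reps:
            assert sorted(rs.lengths()) == sorted(template.lengths())
            assert rs.total_length() == template.total_length()

    def test_non_overlapping_within_replicate(self):
        template = RegionSet([Interval("chrA", 0, 3000)] * 5)
        reps = sample_random_regions(template, {"chrA": 20_000}, 10, seed=2)
        for rs in reps:
            ivs = sorted(rs, key=lambda iv: iv.start)
            for u, w in zip(ivs, ivs[1:]):
                assert u.end <= w.start

    def test_deterministic_given_seed(self):
        template = RegionSet([Interval("chrA", 0, 500)] * 3)
        a = sample_random_regions(template, {"chrA": 50_000}, 4, seed=9)
        b = sample_random_regions(template, {"chrA": 50_000}, 4, seed=9)
        assert [list(rs) for rs in a] == [list(rs) for rs in b]

    def test_impossible_packing_errors(self):
        template = RegionSet([Interval("chrA", 0, 600)] * 2)
        with pytest.raises(ValueError, match="could not place"):
            sample_random_regions(template, {"chrA": 1000}, 1, seed=0)

    def test_missing_chrom_size_errors(self):
        template = RegionSet([Interval("chrB", 0, 100)])
        with pytest.raises(ValueError, match="chromosome size"):
            sample_random_regions(template, {"chrA": 1000}, 1, seed=0)

    def test_masked_regions_avoided(self):
        template = RegionSet([Interval("chrA", 0, 100)])
        masked = RegionSet([Interval("chrA", 0, 900)])
        reps = sample_random_regions(template, {"chrA": 1000}, 5, seed=3,
                                     masked_bp=masked)
        for rs in reps:
            assert rs[0].start >= 900


# ------------------------------------------------------------ Mann-Whitney


class TestMannWhitneyU:
    def test_exact_separated_case(self):
        # all 20 assignments of {1..6} into two triples: only the observed
        # split and its mirror are as extreme -> p = 2/20 = 0.1 exactly
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_exact_enumeration_oracle(self):
        # x beats y in 7 of 9 pairs (2>1; 5>1,3,4; 9>1,3,4)
        x, y = [2.0, 5.0, 9.0], [1.0, 3.0, 4.0]
        u, p = mann_whitney_u(x, y)
        assert u == sum(a > b for a in x for b in y) == 7
        # enumeration over all C(6,3)=20 labelings of the pooled sample:
        # two-sided p = 2 * min tail probability at the observed U
        pooled = sorted(x + y)
        us = np.array([
            sum(a > b
                for a in (pooled[i] for i in combo)
                for b in (pooled[i] for i in range(6) if i not in combo))
            for combo in itertools.combinations(range(6), 3)
        ])
        p_exact = min(1.0, 2 * min((us >= 7).mean(), (us <= 7).mean()))
        assert p == pytest.approx(p_exact, abs=1e-12)
        assert p == pytest.approx(0.4, abs=1e-12)

    def test_identical_samples_p_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        _, p = mann_whitney_u(x, x)
        assert p > 0.9

    def test_all_tied_degenerate(self):
        u, p = mann_whitney_u([1.0] * 5, [1.0] * 7)
        assert p == 1.0

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_never_reports_zero(self):
        x = np.arange(200, dtype=float)
        y = x + 1000.0
        _, p = mann_whitney_u(x, y)
        assert p > 0.0

    def test_type_one_error_calibration(self):
        # [DERIVED] simulation: same-distribution samples, alpha=0.05
        rng = np.random.default_rng(42)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            _, p = mann_whitney_u(x, y)
            rejections += p < 0.05
        assert 0.035 <= rejections / n_sim <= 0.065


# --------------------------------------------------------- enrichment test

class TestEnrichmentTest:
    def test_single_replicate_p_mean_is_p(self):
        rng = np.random.default_rng(4)
        v = _sym(rng, 60)
        r = enrichment_test(_oe(v), regions_of_bins([5, 6, 20, 21]),
                            n_replicates=1, seed=0)
        assert r.p_mean == r.p_values[0]
        assert len(r.null_values) == 1

    def test_p_mean_is_arithmetic_mean(self):
        rng = np.random.default_rng(5)
        v = _sym(rng, 80)
        r = enrichment_test(_oe(v), regions_of_bins([5, 6, 30, 31, 50]),
                            n_replicates=5, seed=1)
        assert r.p_mean == pytest.approx(r.p_values.mean())
        assert (r.p_values > 0).all() and (r.p_values <= 1).all()

    def test_deterministic(self):
        rng = np.random.default_rng(6)
        v = _sym(rng, 60)
        regions = regions_of_bins([4, 5, 22, 23])
        a = enrichment_test(_oe(v), regions, n_replicates=4, seed=11)
        b = enrichment_test(_oe(v), regions, n_replicates=4, seed=11)
        np.testing.assert_array_equal(a.p_values, b.p_values)
        np.testing.assert_array_equal(a.u_stats, b.u_stats)

    def test_planted_block_detected_and_direction(self):
        v = np.ones((100, 100))
        rng = np.random.default_rng(7)
        v += np.triu(rng.normal(0, 0.01, (100, 100)))
        v = (v + v.T) / 2
        block = np.arange(30, 50)
        v[np.ix_(block, block)] *= 3.0
        r = enrichment_test(_oe(v), regions_of_bins(block), n_replicates=10, seed=3)
        assert r.p_mean < 0.01
        assert r.direction == "enriched"

    def test_exchangeability_of_observed_values(self):
        rng = np.random.default_rng(8)
        v = _sym(rng, 40)
        bins = [3, 7, 15, 22, 30]
        obs1 = np.sort(contacts_within(_oe(v), regions_of_bins(bins)))
        perm = rng.permutation(40)
        vperm = v[np.ix_(perm, perm)]
        inv = np.empty(40, int)
        inv[perm] = np.arange(40)
        obs2 = np.sort(contacts_within(_oe(vperm), regions_of_bins(inv[bins])))
        np.testing.assert_allclose(obs1, obs2)


# --------------------------------------------------- PCC diff and log2 fc


class TestPccDifference:
    def _pcc(self, values):
        return ContactMatrix("chrT", BS, values, kind="pcc")

    def test_identical_matrices_give_zero(self):
        rng = np.random.default_rng(9)
        v = np.clip(_sym(rng, 20, -1, 1), -1, 1)
        np.fill_diagonal(v, 1.0)
        m = self._pcc(v)
        assert pcc_difference(m, m, regions_of_bins([2, 3]), regions_of_bins([10, 11])) == 0.0

    def test_constant_shift(self):
        a = np.full((20, 20), 0.8)
        b = np.full((20, 20), 0.3)
        np.fill_diagonal(a, 1.0)
        np.fill_diagonal(b, 1.0)
        d = pcc_difference(self._pcc(a), self._pcc(b),
                           regions_of_bins([2, 3]), regions_of_bins([10, 11]))
        assert d == pytest.approx(0.5)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(10)
        va = np.clip(_sym(rng, 25, -1, 1), -1, 1)
        vb = np.clip(_sym(rng, 25, -1, 1), -1, 1)
        np.fill_diagonal(va, 1.0)
        np.fill_diagonal(vb, 1.0)
        x, y = [2, 3, 9], [12, 17, 20]
        d = pcc_difference(self._pcc(va), self._pcc(vb),
                           regions_of_bins(x), regions_of_bins(y))
        oa = np.mean([va[i, j] for i in x for j in y])
        ob = np.mean([vb[i, j] for i in x for j in y])
        assert d == pytest.approx(oa - ob, abs=1e-12)


class TestContactsLog2fc:
    def test_identical_matrices_all_zero(self):
        rng = np.random.default_rng(11)
        v = _sym(rng, 30)
        m = _oe(v)
        table = contacts_log2fc(m, m, regions_of_bins([2, 3]),
                                {"g1": regions_of_bins([10, 11]),
                                 "g2": regions_of_bins([20, 25])})
        np.testing.assert_allclose(table["log2fc"], 0.0)

    def test_doubled_contacts_give_one(self):
        rng = np.random.default_rng(12)
        v = _sym(rng, 30)
        a = _oe(2 * v)
        b = _oe(v)
        table = contacts_log2fc(a, b, regions_of_bins([2, 3]),
                                {"g": regions_of_bins([10, 15])})
        assert table.loc["g", "log2fc"] == pytest.approx(1.0)

    def test_downsampled_inputs_recover_planted_sign(self):
        # raw matrices with a planted focal-contact drop; depth-matched first
        rng = np.random.default_rng(13)
        n = 60
        base = rng.poisson(40, (n, n))
        base = np.triu(base) + np.triu(base, 1).T
        drop = base.copy().astype(float)
        x_bins, g_bins = [5, 6], [30, 31, 32]
        for i in x_bins:
            for j in g_bins:
                drop[i, j] = drop[j, i] = drop[i, j] // 4
        m_a = ContactMatrix("chrT", BS, base.astype(float), kind="raw")
        m_b = ContactMatrix("chrT", BS, drop, kind="raw")
        target = int(min(m_a.upper_triangle_total(), m_b.upper_triangle_total()))
        m_a = downsample_counts(m_a, target, seed=1)
        m_b = downsample_counts(m_b, target, seed=2)
        table = contacts_log2fc(m_a, m_b, regions_of_bins(x_bins),
                                {"g": regions_of_bins(g_bins)})
        assert table.loc["g", "log2fc"] > 0.5  # a has more focal contacts
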