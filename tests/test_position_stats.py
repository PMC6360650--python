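import numpy as np
import pytest
from scipy import stats as sps

from poremod.position_stats import (
    DetectionConfig,
    SiteScore,
    combine_fisher,
    combine_stouffer,
    default_weights,
    detect_modifications,
    ks_statistic,
    neighborhood_rank,
    ranked_sites,
    t_test,
    u_test,
)
from conftest import make_read


def brute_force_ks_d(x, y):
    """Supremum of |F1 - F2| evaluated at every pooled sample point."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    best = 0.0
    for v in np.concatenate([x, y]):
        best = max(best, abs(np.mean(x <= v) - np.mean(y <= v)))
    return best


class TestKSStatistic:
    def test_handworked_example(self):
        d, _ = ks_statistic([1.0, 2, 3], [1.5, 2.5])
        assert d == pytest.approx(1 / 3)

    def test_identical_groups(self):
        d, p = ks_statistic([1.0, 2, 3], [1.0, 2, 3])
        assert d == 0.0
        assert p == 1.0

    def test_disjoint_supports(self):
        d, p = ks_statistic([0.0, 1, 2], [5.0, 6, 7])
        assert d == 1.0
        assert p < 0.2

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_on_random_instances(self, seed):
        r = np.random.default_rng(seed)
        x = r.normal(size=r.integers(1, 13))
        y = r.normal(size=r.integers(1, 13))
        d, _ = ks_statistic(x, y)
        assert d == pytest.approx(brute_force_ks_d(x, y), abs=1e-14)
        assert d == pytest.approx(sps.ks_2samp(x, y).statistic, abs=1e-14)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ks_statistic([], [1.0])


class TestRankAndTTests:
    def test_identical_groups_not_significant(self, rng):
        x = rng.normal(size=50)
        assert u_test(x, x) > 0.9
        assert t_test(x, x) == 1.0

    def test_location_shift_detected_by_all(self, rng):
        x = rng.normal(0.0, 1.0, size=300)
        y = rng.normal(1.0, 1.0, size=300)
        assert u_test(x, y) < 0.01
        assert t_test(x, y) < 0.01
        assert ks_statistic(x, y)[1] < 0.01

    def test_pure_scale_change_only_ks_detects(self, rng):
        """Same mean, different variance: KS has power, U and t do not."""
        x = rng.normal(0.0, 1.0, size=500)
        y = rng.normal(0.0, 3.0, size=500)
        assert ks_statistic(x, y)[1] < 1e-6
        assert u_test(x, y) > 0.01
        assert t_test(x, y) > 0.01

    def test_u_matches_scipy_asymptotic(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(0.3, 1.0, size=55)
        expected = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic"
        ).pvalue
        assert u_test(x, y) == pytest.approx(expected, rel=1e-10)

    def test_t_matches_scipy(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(0.3, 1.0, size=55)
        expected = sps.ttest_ind(x, y, equal_var=True).pvalue
        assert t_test(x, y) == pytest.approx(expected, rel=1e-10)

    def test_zero_variance_t_gives_one(self):
        assert t_test([1.0, 1.0, 1.0], [1.0, 1.0]) == 1.0


class TestCombiners:
    def test_stouffer_flat_half_is_zero(self):
        z, p = combine_stouffer([0.5] * 5, [0.25, 0.5, 1, 0.5, 0.25])
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(0.5)

    def test_stouffer_handworked_window(self):
        z, p = combine_stouffer(
            [0.5, 0.5, 0.01, 0.5, 0.5], [0.25, 0.5, 1, 0.5, 0.25]
        )
        assert z == pytest.approx(1.825, abs=5e-4)
        assert p == pytest.approx(0.034, abs=5e-4)

    def test_single_term_identity(self):
        _, p = combine_stouffer([0.1234], [1.0])
        assert p == pytest.approx(0.1234, rel=1e-12)
        assert combine_fisher([0.1234]) == pytest.approx(0.1234, rel=1e-12)

    def test_fisher_all_ones(self):
        assert combine_fisher([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_fisher_chi_square_oracle(self):
        p = combine_fisher([0.1, 0.1, 0.1])
        assert p == pytest.approx(sps.chi2.sf(-2 * 3 * np.log(0.1), 6), rel=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_scipy_combine_pvalues(self, seed):
        r = np.random.default_rng(seed)
        ps = r.uniform(1e-6, 1 - 1e-6, size=5)
        w = r.uniform(0.1, 2.0, size=5)
        z, p = combine_stouffer(ps, w)
        ref = sps.combine_pvalues(1 - ps, method="stouffer", weights=w)
        # scipy combines lower-tail p; 1-p flips to our upper-tail form
        assert z == pytest.approx(-ref.statistic, rel=1e-10)
        ref_f = sps.combine_pvalues(ps, method="fisher")
        assert combine_fisher(ps) == pytest.approx(ref_f.pvalue, rel=1e-10)

    def test_weight_rescaling_invariance(self):
        ps = [0.2, 0.01, 0.6]
        w = np.array([0.5, 1.0, 0.5])
        z1, p1 = combine_stouffer(ps, w)
        z2, p2 = combine_stouffer(ps, 7.3 * w)
        assert z1 == pytest.approx(z2, rel=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-12)

    @pytest.mark.parametrize("combiner", ["stouffer", "fisher"])
    def test_monotone_in_each_p(self, combiner):
        base = [0.3, 0.2, 0.4]
        w = [0.5, 1.0, 0.5]
        for i in range(3):
            smaller = list(base)
            smaller[i] = base[i] / 2
            if combiner == "stouffer":
                p_base = combine_stouffer(base, w)[1]
                p_small = combine_stouffer(smaller, w)[1]
            else:
                p_base = combine_fisher(base)
                p_small = combine_fisher(smaller)
            assert p_small <= p_base

    def test_degenerate_p_clamped_not_crashing(self):
        z, p = combine_stouffer([0.0, 1.0], [1.0, 1.0])
        assert np.isfinite(z) and 0 < p <= 1

    def test_default_weights_halving(self):
        np.testing.assert_allclose(
            default_weights([-2, -1, 0, 1, 2]), [0.25, 0.5, 1.0, 0.5, 0.25]
        )


def site(pos, p, base="A"):
    return SiteScore(
        ref_position=pos, ref_base=base, m=10, n=10, D=None,
        p_single=p, log10_p_single=np.log10(p),
        p_combined=p, log10_p_combined=np.log10(p),
    )


class TestNeighborhoodRank:
    def test_close_neighbor_suppressed(self):
        sites = [site(100, 1e-9), site(101, 1e-8), site(200, 1e-6)]
        out = neighborhood_rank(sites, window=2)
        by_pos = {s.ref_position: s.rank for s in out}
        assert by_pos[100] == 1
        assert by_pos[101] is None
        assert by_pos[200] == 2

    def test_distant_sites_keep_p_order(self):
        sites = [site(0, 0.5), site(10, 0.01), site(20, 0.1)]
        out = neighborhood_rank(sites, window=2)
        assert [s.ref_position for s in ranked_sites(out)] == [10, 20, 0]

    def test_adjacent_tie_leftmost_wins(self):
        sites = [site(51, 1e-4), site(50, 1e-4)]
        out = neighborhood_rank(sites, window=1)
        by_pos = {s.ref_position: s.rank for s in out}
        assert by_pos[50] == 1 and by_pos[51] is None

    def test_result_independent_of_input_order(self):
        a = [site(5, 0.2), site(6, 0.1), site(30, 0.05), site(31, 0.3)]
        b = list(reversed([site(5, 0.2), site(6, 0.1), site(30, 0.05), site(31, 0.3)]))
        ra = {s.ref_position: s.rank for s in neighborhood_rank(a, 2)}
        rb = {s.ref_position: s.rank for s in neighborhood_rank(b, 2)}
        assert ra == rb


class TestDetectPipeline:
    def test_single_shifted_site_ranks_first(self, rng):
        ref = "ACGTACGTACGTACGTACGT"
        mod_pos = 9
        g1, g2 = [], []
        for i in range(6):
            counts = [8] * len(ref)
            r1 = make_read(f"m{i}", 0, ref, counts, rng)
            # large shift at the modified position only
            off = r1.offsets[mod_pos]
            r1.signals[off : off + 8] += 4.0
            g1.append(r1)
            g2.append(make_read(f"c{i}", 0, ref, counts, rng))
        sites = detect_modifications(
            g1, g2, ref, DetectionConfig(combiner="stouffer", normalize=False)
        )
        assert ranked_sites(sites)[0].ref_position == mod_pos

    def test_combiner_none_orders_by_single_p(self, rng):
        ref = "ACGTACGTACGTACGTACGT"
        g1 = [make_read(f"m{i}", 0, ref, [6] * 20, rng) for i in range(6)]
        g2 = [make_read(f"c{i}", 0, ref, [6] * 20, rng) for i in range(6)]
        sites = detect_modifications(
            g1, g2, ref, DetectionConfig(combiner="none", normalize=False)
        )
        for s in sites:
            assert s.p_combined == pytest.approx(s.p_single)
            assert s.Z is None

    def test_no_coverage_returns_empty(self):
        out = detect_modifications([], [], "ACGT", DetectionConfig())
        assert out == []

    def test_truncated_window_at_sequence_ends(self, rng):
        """Sites near the ends combine over the available neighbors only."""
        ref = "ACGTAC"
        g1 = [make_read(f"m{i}", 0, ref, [6] * 6, rng) for i in range(5)]
        g2 = [make_read(f"c{i}", 0, ref, [6] * 6, rng) for i in range(5)]
        sites = detect_modifications(
            g1, g2, ref, DetectionConfig(combiner="stouffer", normalize=False)
        )
        edge = next(s for s in sites if s.ref_position == 0)
        ps = {s.ref_position: s.p_single for s in sites}
        z, p = combine_stouffer(
            [ps[0], ps[1], ps[2]], default_weights([0, 1, 2])
        )
        assert edge.p_combined == pytest.approx(p, rel=1e-9)

    def test_deterministic_given_inputs(self, rng):
        ref = "ACGTACGTAC"
        g1 = [make_read(f"m{i}", 0, ref, [5] * 10, rng) for i in range(5)]
        g2 = [make_read(f"c{i}", 0, ref, [5] * 10, rng) for i in range(5)]
        a = detect_modifications(g1, g2, ref, DetectionConfig(normalize=False))
        b = detect_modifications(g1, g2, ref, DetectionConfig(normalize=False))
        assert [(s.ref_position, s.rank, s.p_combined) for s in a] == [
            (s.ref_position, s.rank, s.p_combined) for s in b
        ]
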