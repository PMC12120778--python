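import numpy as np
import pytest

from cemito.core import ActiveZone, SynapticSite
from cemito.synapse_proximity import (
    band_coverage,
    build_sites,
    degrees,
    fanout,
    mito_to_synapse_distances,
    near_far_partition,
    nearest_mito_distances,
    randomization_null,
    saturation_threshold,
)


def _zone(zid, pre, partners, size=1000.0, centroid=(0.0, 0.0, 0.0)):
    return ActiveZone(zid, pre, 10, size, centroid, partners)


class TestDegrees:
    def test_three_partner_zone_adds_three_to_out_degree(self):
        out_deg, in_deg = degrees([_zone(1, 5, (2, 3, 4))])
        assert out_deg[5] == 3
        assert in_deg == {2: 1, 3: 1, 4: 1}

    def test_out_degree_sums_fanouts(self):
        out_deg, _ = degrees([_zone(1, 5, (2,)), _zone(2, 5, (3, 4))])
        assert out_deg[5] == 3

    def test_in_degree_counts_incidences(self):
        zones = [_zone(i, 1, (9,)) for i in range(1, 5)]
        _, in_deg = degrees(zones)
        assert in_deg[9] == 4

    def test_fanout_consistency_with_out_degree(self):
        zones = [_zone(1, 5, (2, 3)), _zone(2, 5, (4, 6, 7))]
        out_deg, _ = degrees(zones)
        assert out_deg[5] == sum(fanout(z) for z in zones)

    def test_zero_degree_cells_absent(self):
        out_deg, in_deg = degrees([_zone(1, 5, (2,))])
        assert 2 not in out_deg and 5 not in in_deg


class TestNearestDistances:
    def test_minimum_over_cell_mitochondria(self):
        sites = [SynapticSite(0, "pre", 1, 1, (0.0, 0.0, 0.0))]
        mbc = {1: [(10, (100.0, 0.0, 0.0)), (11, (0.0, 200.0, 0.0))]}
        recs, _ = nearest_mito_distances(sites, mbc)
        assert recs[0].distance == pytest.approx(100.0)
        assert recs[0].nearest_mito_id == 10

    def test_post_site_measured_against_partner_cell(self):
        zones = [_zone(1, 5, (7,), centroid=(0.0, 0.0, 0.0))]
        sites = build_sites(zones)
        mbc = {5: [(1, (10.0, 0.0, 0.0))], 7: [(2, (0.0, 500.0, 0.0))]}
        recs, _ = nearest_mito_distances(sites, mbc)
        post = next(r for r in recs if r.kind == "post")
        assert post.cell_id == 7
        assert post.distance == pytest.approx(500.0)

    def test_site_without_mitochondria_excluded_with_reason(self):
        sites = [SynapticSite(0, "pre", 1, 99, (0.0, 0.0, 0.0))]
        recs, excluded = nearest_mito_distances(sites, {})
        assert recs == []
        assert excluded[0][1] == "no_mitochondria_in_cell"

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_min_over_all_pairs(self, seed):
        rng = np.random.default_rng(seed)
        sites = [SynapticSite(i, "pre", i, int(rng.integers(1, 4)),
                              tuple(rng.uniform(0, 1000, 3)))
                 for i in range(20)]
        mbc = {c: [(c * 100 + k, tuple(rng.uniform(0, 1000, 3)))
                   for k in range(int(rng.integers(1, 5)))]
               for c in (1, 2, 3)}
        recs, _ = nearest_mito_distances(sites, mbc)
        for s, r in zip(sites, recs):
            brute = min(np.linalg.norm(np.subtract(pos, s.position))
                        for _, pos in mbc[s.cell_id])
            assert r.distance == pytest.approx(brute)

    def test_mito_to_synapse_distances(self):
        zones = [_zone(1, 5, (7,), centroid=(0.0, 0.0, 0.0))]
        sites = build_sites(zones)
        mbc = {5: [(1, (30.0, 0.0, 0.0))], 7: [(2, (0.0, 40.0, 0.0))]}
        recs = mito_to_synapse_distances(sites, mbc)
        rec5 = next(r for r in recs if r.cell_id == 5)
        rec7 = next(r for r in recs if r.cell_id == 7)
        assert rec5.d_syn_pre == pytest.approx(30.0)
        assert np.isnan(rec5.d_syn_post)  # cell 5 receives nothing
        assert rec7.d_syn_post == pytest.approx(40.0)


class TestRandomizationNull:
    def test_single_mitochondrion_null_equals_observed_everywhere(self):
        sites = [SynapticSite(0, "pre", 1, 1, (0.0, 0.0, 0.0))]
        mbc = {1: [(10, (300.0, 0.0, 0.0))]}
        null = randomization_null(sites, mbc, n_config=25, seed=0)
        assert np.all(null.samples == 300.0)

    def test_null_mean_matches_exact_enumeration(self):
        """Cell mitochondria at 1, 3, 5 um: the null expectation is the
        plain average 3 um; the empirical mean over 1000 configurations
        must lie within 3 Monte-Carlo SDs of it."""
        sites = [SynapticSite(0, "pre", 1, 1, (0.0, 0.0, 0.0))]
        mbc = {1: [(10, (1000.0, 0.0, 0.0)), (11, (3000.0, 0.0, 0.0)),
                   (12, (5000.0, 0.0, 0.0))]}
        null = randomization_null(sites, mbc, n_config=1000, seed=1)
        exact_mean = 3000.0
        exact_sd = np.sqrt(np.mean((np.array([1000, 3000, 5000]) - 3000.0) ** 2))
        mc_sd = exact_sd / np.sqrt(1000)
        assert abs(null.samples.mean() - exact_mean) <= 3 * mc_sd

    def test_observed_nearest_never_exceeds_any_null_draw_per_site(self):
        rng = np.random.default_rng(2)
        sites = [SynapticSite(i, "pre", i, 1, tuple(rng.uniform(0, 1e4, 3)))
                 for i in range(10)]
        mbc = {1: [(k, tuple(rng.uniform(0, 1e4, 3))) for k in range(5)]}
        recs, _ = nearest_mito_distances(sites, mbc)
        null = randomization_null(sites, mbc, n_config=50, seed=3)
        obs = np.array([r.distance for r in recs])
        assert np.all(obs[None, :] <= null.samples + 1e-9)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        sites = [SynapticSite(i, "pre", i, 1, tuple(rng.uniform(0, 1e4, 3)))
                 for i in range(5)]
        mbc = {1: [(k, tuple(rng.uniform(0, 1e4, 3))) for k in range(4)]}
        a = randomization_null(sites, mbc, n_config=20, seed=7)
        b = randomization_null(sites, mbc, n_config=20, seed=7)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_band_coverage_of_a_null_draw_is_high(self):
        rng = np.random.default_rng(5)
        sites = [SynapticSite(i, "pre", i, 1, tuple(rng.uniform(0, 1e4, 3)))
                 for i in range(100)]
        mbc = {1: [(k, tuple(rng.uniform(0, 1e4, 3))) for k in range(6)]}
        null = randomization_null(sites, mbc, n_config=300, seed=8)
        held = randomization_null(sites, mbc, n_config=1, seed=99,
                                  bin_edges=null.bin_edges)
        assert band_coverage(held.samples[0], null) >= 0.9


class TestSaturationThreshold:
    def _fixture_distances(self):
        """Per-bin increments 0.40,0.25,0.12,0.08,0.06,0.04 then a 5% tail."""
        counts = [(0.05, 40), (0.15, 25), (0.25, 12), (0.35, 8), (0.45, 6),
                  (0.55, 4), (0.85, 5)]
        d = []
        for center_um, n in counts:
            d += [center_um * 1000.0] * n
        return d

    def test_increment_fixture_yields_point_six_um(self):
        thr, degenerate = saturation_threshold(self._fixture_distances(),
                                               bin_width_nm=100.0)
        assert thr == pytest.approx(600.0)
        assert not degenerate

    def test_single_occupied_bin(self):
        thr, _ = saturation_threshold([250.0] * 50, bin_width_nm=100.0)
        assert thr == pytest.approx(300.0)

    def test_scale_equivariance(self):
        d = self._fixture_distances()
        thr1, _ = saturation_threshold(d, bin_width_nm=100.0)
        thr2, _ = saturation_threshold([2 * x for x in d], bin_width_nm=200.0)
        assert thr2 == pytest.approx(2 * thr1)

    def test_first_bin_saturation_flagged_degenerate(self):
        thr, degenerate = saturation_threshold([10.0] * 100, bin_width_nm=100.0)
        assert degenerate and thr == pytest.approx(100.0)


class TestNearFarPartition:
    def _recs(self):
        class R:
            def __init__(self, d, v):
                self.distance, self.size = d, v
        return [R(500.0, 1.0), R(1500.0, 2.0)]

    def test_split_at_threshold(self):
        g = near_far_partition(self._recs(), 1100.0, value=lambda r: r.size)
        assert g.near == [1.0] and g.far == [2.0]

    def test_tie_inclusive_near(self):
        g = near_far_partition(self._recs(), 500.0, value=lambda r: r.size)
        assert g.near == [1.0]

    def test_empty_far_group_skips_comparison(self):
        g = near_far_partition(self._recs(), 2000.0, value=lambda r: r.size)
        assert not g.comparison_possible
        assert g.skipped_reason == "far_group_empty"
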