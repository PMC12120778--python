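import numpy as np
import pytest

from cemito.core import CapacityError, ValidationError
from cemito.reconstruction import connected_components_26
from cemito.stats_embed import wilcoxon_rank_sum
from cemito.synapse_proximity import (
    build_sites,
    nearest_mito_distances,
    randomization_null,
)
from cemito.synthetic_data import (
    CountLaw,
    LengthLaw,
    SyntheticSpec,
    generate_training_pairs,
    generate_world,
)


class TestSpecValidation:
    def test_kappa_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            SyntheticSpec(coupling_kappa=1.5).validate()

    def test_mito_wider_than_neurite_rejected(self):
        with pytest.raises(ValidationError):
            SyntheticSpec(mito_radius=200.0, neurite_radius=160.0).validate()

    def test_grid_too_small_rejected(self):
        with pytest.raises(ValidationError, match="grid_shape"):
            generate_world(SyntheticSpec(grid_shape=(10, 10, 10)))

    def test_overcrowded_spec_raises_capacity_error_naming_cell(self):
        spec = SyntheticSpec(n_neurites=4, tube_length_voxels=120,
                             mito_count_law=CountLaw(kind="constant", value=40),
                             seed=0)
        with pytest.raises(CapacityError, match="neurite"):
            generate_world(spec)


class TestGenerateWorld:
    def test_constant_count_yields_exact_disjoint_capsules(self):
        spec = SyntheticSpec(n_neurites=1, n_muscles=0,
                             mito_count_law=CountLaw(kind="constant", value=3),
                             coupling_kappa=0.0, tube_length_voxels=300, seed=2)
        truth = generate_world(spec)
        assert len(truth.mitochondria) == 3
        labels = connected_components_26(truth.mito_labels.labels > 0)
        assert labels.max() == 3

    def test_full_coupling_bounds_nearest_zone_distance_along_axis(self):
        spec = SyntheticSpec(coupling_kappa=1.0, coupling_radius=500.0,
                             pre_post_asymmetry=1.0, n_muscles=0,
                             mito_count_law=CountLaw(kind="poisson", mean=3),
                             n_neurites=9, tube_length_voxels=300, seed=3)
        truth = generate_world(spec)
        # along-centerline (z) offset to the chosen site is bounded by the
        # window; check against the nearest site's z coordinate
        sites_z = {}
        for z in truth.active_zones:
            sites_z.setdefault(z.presyn_cell_id, []).append(z.centroid[2])
            for p in z.partners:
                sites_z.setdefault(p, []).append(z.centroid[2])
        for tm in truth.mitochondria:
            zs = np.asarray(sites_z.get(tm.cell_id, []))
            if len(zs) == 0:
                continue
            dz = np.abs(zs - tm.centroid[2]).min()
            # clamping at tube ends can only reduce the offset
            assert dz <= 500.0 + 1e-6

    def test_containment_every_mito_voxel_inside_its_cell(self, small_world):
        mito = small_world.mito_labels.labels
        cells = small_world.cell_labels.labels
        cell_of = {m.mito_id: m.cell_id for m in small_world.mitochondria}
        for mid, cid in cell_of.items():
            sel = mito == mid
            assert sel.any()
            assert np.all(cells[sel] == cid)

    def test_zone_centroids_lie_inside_presynaptic_cell(self, small_world):
        grid = small_world.cell_labels
        rx, ry, rz = grid.resolution
        for z in small_world.active_zones:
            ix = int(round(z.centroid[0] / rx))
            iy = int(round(z.centroid[1] / ry))
            iz = int(round(z.centroid[2] / rz))
            assert grid.labels[iz, iy, ix] == z.presyn_cell_id

    def test_zone_size_is_voxcount_times_voxel_volume(self, small_world):
        voxvol = small_world.cell_labels.voxel_volume
        for z in small_world.active_zones:
            assert z.size == pytest.approx(z.voxel_count * voxvol)

    def test_same_seed_reproduces_world_exactly(self):
        spec = SyntheticSpec(n_neurites=4, n_muscles=1, tube_length_voxels=200,
                             mito_count_law=CountLaw(kind="poisson", mean=2), seed=5)
        a, b = generate_world(spec), generate_world(spec)
        np.testing.assert_array_equal(a.mito_labels.labels, b.mito_labels.labels)
        assert [z.centroid for z in a.active_zones] == [z.centroid for z in b.active_zones]

    def test_different_seeds_differ_voxelwise(self):
        base = dict(n_neurites=4, n_muscles=0, tube_length_voxels=300,
                    mito_count_law=CountLaw(kind="poisson", mean=3))
        a = generate_world(SyntheticSpec(**base, seed=1))
        b = generate_world(SyntheticSpec(**base, seed=2))
        assert not np.array_equal(a.mito_labels.labels, b.mito_labels.labels)

    def test_fanout_frequencies_match_generating_pmf(self):
        """Empirical fan-out over >=1000 zones within 3 SD per bin."""
        pmf = np.array(SyntheticSpec().fanout_pmf)
        counts = np.zeros(5)
        n = 0
        for seed in range(4):
            spec = SyntheticSpec(n_neurites=16, tube_length_voxels=300, n_muscles=0,
                                 zones_per_neurite_mean=20.0,
                                 mito_count_law=CountLaw(kind="constant", value=1),
                                 seed=100 + seed)
            truth = generate_world(spec)
            for z in truth.active_zones:
                counts[z.fanout - 1] += 1
                n += 1
        assert n >= 1000
        freq = counts / n
        sd = np.sqrt(pmf * (1 - pmf) / n)
        assert np.all(np.abs(freq - pmf) <= 3 * sd + 1e-12)

    def test_single_mito_cells_observed_equals_null(self):
        """With exactly one mitochondrion per cell, the nearest-mitochondrion
        distances coincide with every random-assignment configuration, so a
        rank test cannot distinguish observed from null (kappa = 0)."""
        spec = SyntheticSpec(coupling_kappa=0.0, n_muscles=0, n_neurites=16,
                             tube_length_voxels=300,
                             mito_count_law=CountLaw(kind="constant", value=1),
                             seed=21)
        truth = generate_world(spec)
        sites = build_sites(truth.active_zones)
        mbc = {}
        for m in truth.mitochondria:
            mbc.setdefault(m.cell_id, []).append((m.mito_id, m.centroid))
        recs, _ = nearest_mito_distances(sites, mbc)
        null = randomization_null(sites, mbc, n_config=50, seed=9)
        obs = np.array([r.distance for r in recs])
        assert np.allclose(np.sort(obs), np.sort(null.samples[0]))
        res = wilcoxon_rank_sum(obs, null.samples[7])
        assert res.p_value > 0.01


class TestTrainingPairs:
    def test_pair_count_and_density_band(self):
        spec = SyntheticSpec(seed=4)
        pairs = generate_training_pairs(spec, 4, 128)
        assert len(pairs) == 4
        lo, hi = spec.pair_density_band
        for img, mask in pairs:
            assert img.shape == mask.shape == (128, 128)
            assert lo <= mask.mean() <= hi

    def test_zero_noise_interior_darker_than_background_mean(self):
        spec = SyntheticSpec(pair_noise_scale=0.0, seed=4)
        img, mask = generate_training_pairs(spec, 1, 96)[0]
        assert img[mask].max() < img[~mask].mean()

    def test_fixed_seed_is_byte_identical(self):
        spec = SyntheticSpec(seed=11)
        a = generate_training_pairs(spec, 2, 64)
        b = generate_training_pairs(spec, 2, 64)
        for (ia, ma), (ib, mb) in zip(a, b):
            assert ia.tobytes() == ib.tobytes()
            assert ma.tobytes() == mb.tobytes()

    def test_too_small_section_rejected(self):
        with pytest.raises(ValidationError):
            generate_training_pairs(SyntheticSpec(), 1, 32)
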