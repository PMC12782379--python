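import numpy as np
import pytest
import trimesh

from conftest import angle_between
from pact.eval_local import (CANONICAL_DIRECTIONS, PronouncedDeviations,
                             SignedDistanceField, aggregate_regions,
                             cluster_deviations, default_eps, label_region,
                             pronounced_mask, signed_distances)


def field_from_values(values, points=None):
    values = np.asarray(values, dtype=float)
    if points is None:
        points = np.column_stack([np.arange(len(values)),
                                  np.zeros(len(values)),
                                  np.zeros(len(values))])
    return SignedDistanceField(points=points, distances=values)


class TestSignedDistances:
    def test_identical_meshes_give_zero(self, base_socket):
        socket, _, _ = base_socket
        field = signed_distances(socket, socket, n=4000, seed=0)
        assert np.abs(field.distances).max() < 1e-6

    def test_concentric_spheres_signed_offset(self):
        ref = trimesh.creation.icosphere(subdivisions=4, radius=50.0)
        pred = trimesh.creation.icosphere(subdivisions=4, radius=51.0)
        field = signed_distances(pred, ref, n=6000, seed=0)
        assert field.distances.mean() == pytest.approx(1.0, rel=0.05)
        assert (field.distances > 0).mean() > 0.99

    def test_swapping_arguments_flips_the_sign(self):
        ref = trimesh.creation.icosphere(subdivisions=4, radius=50.0)
        pred = trimesh.creation.icosphere(subdivisions=4, radius=51.0)
        fwd = signed_distances(pred, ref, n=6000, seed=0)
        rev = signed_distances(ref, pred, n=6000, seed=0)
        assert fwd.distances.mean() == pytest.approx(-rev.distances.mean(), rel=0.05)


class TestPronouncedMask:
    def test_forced_arithmetic_example(self):
        flagged = pronounced_mask(field_from_values([1, 2, 3, -1, -5]))
        assert flagged.threshold_pos == pytest.approx(2.0)
        assert flagged.threshold_neg == pytest.approx(-3.0)
        assert sorted(flagged.flagged_values.tolist()) == [-5.0, 3.0]

    def test_all_zero_field_flags_nothing(self):
        flagged = pronounced_mask(field_from_values(np.zeros(100)))
        assert flagged.threshold_pos is None
        assert flagged.threshold_neg is None
        assert flagged.mask.sum() == 0

    def test_single_sign_group(self):
        flagged = pronounced_mask(field_from_values([0.5, 1.5, 2.5]))
        assert flagged.threshold_neg is None
        assert flagged.threshold_pos == pytest.approx(1.5)
        assert flagged.mask.sum() == 1

    def test_large_field_matches_independent_recomputation(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=20_000)
        flagged = pronounced_mask(field_from_values(values))
        thr_pos = values[values > 0].mean()
        thr_neg = values[values < 0].mean()
        expected = (values > thr_pos) | (values < thr_neg)
        assert np.array_equal(flagged.mask, expected)


class TestClusterDeviations:
    def make_flagged(self, points, values):
        return PronouncedDeviations(
            points=points, values=values,
            mask=np.ones(len(points), dtype=bool),
            threshold_pos=0.1, threshold_neg=-0.1)

    def planted_patch(self, center, n, rng, sd=2.0):
        return rng.normal(0.0, sd, size=(n, 3)) + center

    def test_two_planted_patches_recovered(self):
        rng = np.random.default_rng(0)
        a = self.planted_patch(np.array([0.0, 0.0, 0.0]), 200, rng)
        b = self.planted_patch(np.array([40.0, 0.0, 0.0]), 200, rng)
        points = np.vstack([a, b])
        values = np.ones(400)
        regions = cluster_deviations(self.make_flagged(points, values),
                                     eps=5.0, min_samples=10)
        assert len(regions) == 2
        centroids = sorted(r.centroid[0] for r in regions)
        assert abs(centroids[0] - 0.0) < 2.0
        assert abs(centroids[1] - 40.0) < 2.0

    def test_sparse_noise_yields_no_regions(self):
        rng = np.random.default_rng(1)
        points = rng.uniform(-100, 100, size=(150, 3))
        values = np.ones(150)
        regions = cluster_deviations(self.make_flagged(points, values),
                                     eps=3.0, min_samples=10)
        assert regions == []

    def test_duplicated_patch_stays_one_region(self):
        rng = np.random.default_rng(2)
        a = self.planted_patch(np.array([5.0, 5.0, 5.0]), 150, rng)
        points = np.vstack([a, a])
        values = np.ones(300)
        regions = cluster_deviations(self.make_flagged(points, values),
                                     eps=5.0, min_samples=10)
        assert len(regions) == 1

    def test_signs_clustered_separately(self):
        rng = np.random.default_rng(3)
        a = self.planted_patch(np.zeros(3), 150, rng)
        values = np.concatenate([np.ones(75), -np.ones(75)])
        regions = cluster_deviations(self.make_flagged(a, values),
                                     eps=5.0, min_samples=10)
        assert sorted(r.sign for r in regions) == ["deflation", "inflation"]


class TestAggregateRegions:
    def region(self, centroid, pid, sign="inflation"):
        from pact.eval_local import DeviationRegion
        c = np.asarray(centroid, dtype=float)
        return DeviationRegion(points=c[None, :] + np.zeros((3, 3)),
                               centroid=c, sign=sign, participant_id=pid)

    def test_common_direction_recovered_across_participants(self):
        direction = np.array([0.0, 1.0, 1.0]) / np.sqrt(2)
        rng = np.random.default_rng(4)
        regions, scale = [], {}
        for i, pid in enumerate(["A", "B", "C"]):
            length = 60.0 + 10 * i
            c = direction * 0.5 * length + rng.normal(0, 1.0, 3)
            regions.append(self.region(c, pid))
            scale[pid] = length
        common = aggregate_regions(regions, norm_scale=scale,
                                   eps_norm=0.15, min_samples=2)
        assert len(common) == 1
        assert common[0].incidence == 3
        assert angle_between(common[0].direction, direction) < 10.0

    def test_single_region_passthrough(self):
        direction = np.array([1.0, 0.0, 0.0])
        regions = [self.region(direction * 30.0, "A")]
        common = aggregate_regions(regions, norm_scale={"A": 60.0},
                                   eps_norm=0.1, min_samples=1)
        assert len(common) == 1
        assert np.abs(common[0].direction_sd).max() == 0.0
        assert angle_between(common[0].direction, direction) < 1e-9

    def test_unit_vector_norm_and_format(self):
        regions = [self.region([0.0, 20.0, 10.0], "A"),
                   self.region([0.0, 22.0, 9.0], "B")]
        common = aggregate_regions(regions, norm_scale={"A": 60.0, "B": 60.0},
                                   eps_norm=0.2, min_samples=2)
        assert len(common) == 1
        assert np.linalg.norm(common[0].direction) == pytest.approx(1.0, abs=1e-6)
        text = common[0].format_direction()
        assert "x^" in text and "(" in text and "z^" in text

    def test_empty_input_gives_empty_output(self):
        assert aggregate_regions([], norm_scale={}) == []


class TestLabels:
    def test_canonical_directions_are_unit(self):
        for v in CANONICAL_DIRECTIONS.values():
            assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-9)

    def test_nearest_direction_labelling(self):
        assert label_region([0.0, 0.0, -1.0]) == "distal_tip"
        assert label_region([0.0, 0.9, 0.3]) == "anterior_distal_trimline"


def test_default_eps_has_density_floor():
    # scale-relative term dominates for dense sampling ...
    assert default_eps(100.0, 1e4, 1_000_000) == pytest.approx(2.5)
    # ... and the spacing floor takes over when samples are sparse
    sparse = default_eps(100.0, 1e4, 100)
    assert sparse == pytest.approx(3.0 * 10.0)
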