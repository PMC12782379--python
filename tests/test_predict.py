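import numpy as np
import pytest
import trimesh
from sklearn.base import clone
from sklearn.exceptions import NotFittedError

from pact.errors import InputError
from pact.mesh_core import mesh_volume, slice_area
from pact.predict import (ScalingFactors, SocketPredictor, anisotropic_factors,
                          apply_scaling, length_normalize, measure_extent,
                          predict_socket, retrieve_best_match, shape_distance)


def brute_force_distance(P, Q):
    diff = P[:, None, :] - Q[None, :, :]
    return float(np.linalg.norm(diff, axis=2).min(axis=1).mean())


class TestShapeDistance:
    def test_identical_clouds_give_zero(self):
        rng = np.random.default_rng(0)
        P = rng.normal(size=(200, 3))
        assert shape_distance(P, P) == 0.0

    def test_single_point_pair(self):
        assert shape_distance(np.array([[0.0, 0.0, 0.0]]),
                              np.array([[3.0, 4.0, 0.0]])) == pytest.approx(5.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.normal(size=(500, 3)) * 10
        Q = rng.normal(size=(400, 3)) * 10
        assert shape_distance(P, Q) == pytest.approx(
            brute_force_distance(P, Q), abs=1e-9)

    def test_symmetric_variant_averages_directions(self):
        rng = np.random.default_rng(3)
        P = rng.normal(size=(300, 3))
        Q = rng.normal(size=(300, 3)) + 2.0
        sym = shape_distance(P, Q, symmetric=True)
        expected = 0.5 * (brute_force_distance(P, Q) + brute_force_distance(Q, P))
        assert sym == pytest.approx(expected, abs=1e-9)


class TestLengthNormalize:
    def test_equal_lengths_leave_mesh_unchanged(self, cohort5):
        library, _ = cohort5
        entry = library[library.ids[0]]
        length = np.ptp(entry.limb.vertices[:, 2])
        sf, scaled = length_normalize(length, entry)
        assert sf == pytest.approx(1.0)
        assert np.abs(scaled.vertices - entry.limb.vertices).max() < 1e-12

    def test_half_length(self, cohort5):
        library, _ = cohort5
        entry = library[library.ids[0]]
        length = np.ptp(entry.limb.vertices[:, 2])
        sf, scaled = length_normalize(length / 2.0, entry)
        assert sf == pytest.approx(0.5)
        assert np.ptp(scaled.vertices[:, 2]) == pytest.approx(length / 2.0, abs=0.1)

    def test_reference_cohort_extreme_ratio(self):
        # longest limb in the reference table over the shortest
        assert round(123.1 / 35.4, 3) == 3.477

    def test_nonpositive_length_rejected(self, cohort5):
        library, _ = cohort5
        with pytest.raises(InputError):
            length_normalize(0.0, library[library.ids[0]])


class TestExtents:
    def test_axis_aligned_box(self):
        box = trimesh.creation.box(extents=[30.0, 40.0, 80.0])
        assert measure_extent(box, "x") == pytest.approx(30.0)
        assert measure_extent(box, "y") == pytest.approx(40.0)

    def test_elliptic_cylinder(self):
        cyl = trimesh.creation.cylinder(radius=1.0, height=10.0, sections=256)
        cyl.vertices = cyl.vertices * [25.0, 15.0, 1.0]
        assert measure_extent(cyl, "x") == pytest.approx(50.0, rel=0.01)
        assert measure_extent(cyl, "y") == pytest.approx(30.0, rel=0.01)

    def test_extents_are_frame_dependent(self):
        # a rotated box reports rotated-frame extents: documents that the
        # measurement axes are anatomical, not object-intrinsic
        box = trimesh.creation.box(extents=[30.0, 40.0, 80.0])
        Rz = np.array([[np.cos(np.pi / 4), -np.sin(np.pi / 4), 0],
                       [np.sin(np.pi / 4), np.cos(np.pi / 4), 0],
                       [0, 0, 1.0]])
        rot = box.copy()
        rot.vertices = box.vertices @ Rz.T
        assert measure_extent(rot, "x") != pytest.approx(30.0, rel=0.01)

    def test_identical_meshes_give_unit_factors(self, base_limb):
        limb, _ = base_limb
        sf_ap, sf_ml = anisotropic_factors(limb, limb)
        assert sf_ap == pytest.approx(1.0)
        assert sf_ml == pytest.approx(1.0)

    def test_constructed_ap_scaling_recovered(self, base_limb):
        limb, _ = base_limb
        stretched = limb.copy()
        stretched.vertices = limb.vertices * [1.0, 1.2, 1.0]
        sf_ap, sf_ml = anisotropic_factors(stretched, limb)
        assert sf_ap == pytest.approx(1.2, rel=0.01)
        assert sf_ml == pytest.approx(1.0, rel=0.01)


class TestApplyScaling:
    def test_unit_factors_are_identity(self, base_socket):
        socket, _, _ = base_socket
        out = apply_scaling(socket, ScalingFactors(1.0, 1.0, 1.0))
        assert np.abs(out.vertices - socket.vertices).max() < 1e-12

    def test_isotropic_doubling_multiplies_volume_by_eight(self, base_socket):
        socket, _, _ = base_socket
        out = apply_scaling(socket, ScalingFactors(2.0, 1.0, 1.0))
        v0 = mesh_volume(socket, pitch=0.8)
        v1 = mesh_volume(out, pitch=1.6)
        assert v1 / v0 == pytest.approx(8.0, rel=0.02)

    def test_anisotropic_factors_scale_slice_areas(self, base_socket):
        socket, _, _ = base_socket
        out = apply_scaling(socket, ScalingFactors(1.0, 1.1, 0.9))
        zmin, zmax = socket.bounds[:, 2]
        for frac in (0.3, 0.5, 0.7):
            z = zmin + frac * (zmax - zmin)
            ratio = slice_area(out, z).area / slice_area(socket, z).area
            assert ratio == pytest.approx(1.1 * 0.9, rel=0.01)

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(InputError):
            ScalingFactors(0.0, 1.0, 1.0)


class TestRetrieval:
    def test_library_limb_retrieves_itself(self, cohort5):
        library, _ = cohort5
        pid = library.ids[1]
        matched, sf_k, d, dists = retrieve_best_match(
            library[pid].limb, library, n=4000, seed=0)
        assert matched == pid
        assert sf_k == pytest.approx(1.0)
        assert d < 0.05

    def test_isotropic_scale_invariance(self, cohort5):
        library, _ = cohort5
        pid = library.ids[1]
        query = library[pid].limb.copy()
        query.vertices = query.vertices * 1.3
        matched, sf_k, d, _ = retrieve_best_match(query, library, n=4000, seed=0)
        assert matched == pid
        assert sf_k == pytest.approx(1.3, rel=1e-6)
        assert d < 0.05

    def test_winner_matches_exhaustive_oracle(self, cohort5):
        library, _ = cohort5
        query = library[library.ids[3]].limb.copy()
        query.vertices = query.vertices * [1.05, 0.95, 1.1]
        matched, _, _, dists = retrieve_best_match(query, library, n=3000, seed=2)
        assert matched == min(dists, key=dists.get)
        assert set(dists) == set(library.ids)


class TestPredictSocket:
    def test_identity_pipeline_returns_own_socket(self, cohort5):
        library, _ = cohort5
        pid = library.ids[0]
        result = predict_socket(library[pid].limb, library)
        assert result.matched_id == pid
        f = result.factors
        assert (f.sf_k, f.sf_ml, f.sf_ap) == pytest.approx((1.0, 1.0, 1.0))
        assert np.abs(result.socket.vertices - library[pid].socket.vertices).max() < 1e-9

    def test_planted_factor_recovery(self, cohort5):
        library, _ = cohort5
        pid = library.ids[2]
        sf_k, sf_ml, sf_ap = 1.2, 1.1, 0.9
        query = library[pid].limb.copy()
        query.vertices = query.vertices * [sf_k * sf_ml, sf_k * sf_ap, sf_k]
        result = predict_socket(query, library)
        assert result.matched_id == pid
        assert result.factors.sf_k == pytest.approx(sf_k, rel=0.01)
        assert result.factors.sf_ml == pytest.approx(sf_ml, rel=0.02)
        assert result.factors.sf_ap == pytest.approx(sf_ap, rel=0.02)

    def test_predicted_socket_length_follows_sf_k(self, cohort5):
        library, _ = cohort5
        pid = library.ids[0]
        query = library[pid].limb.copy()
        query.vertices = query.vertices * 1.25
        result = predict_socket(query, library)
        expected = 1.25 * np.ptp(library[pid].socket.vertices[:, 2])
        assert np.ptp(result.socket.vertices[:, 2]) == pytest.approx(expected, abs=0.1)


class TestEstimatorInterface:
    def test_get_set_params_and_clone(self):
        est = SocketPredictor(n_samples=1234, random_state=9)
        params = est.get_params()
        assert params["n_samples"] == 1234
        cloned = clone(est)
        assert cloned.get_params() == params
        cloned.set_params(n_samples=99)
        assert cloned.n_samples == 99
        assert est.n_samples == 1234

    def test_predict_before_fit_raises(self, base_limb):
        limb, _ = base_limb
        with pytest.raises(NotFittedError):
            SocketPredictor().predict(limb)

    def test_fit_sets_trailing_underscore_attributes(self, cohort5):
        library, _ = cohort5
        est = SocketPredictor(n_samples=2000).fit(library)
        assert est.n_entries_ == 5
        assert est.library_ is library
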