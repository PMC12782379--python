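import numpy as np
import pytest

from pact.errors import InputError
from pact.eval_local import signed_distances
from pact.mesh_core import slice_area
from pact.synthetic import (LimbParams, PlantedPatch, PopulationSpec,
                            SocketDesignParams, derive_socket, generate_cohort,
                            generate_limb)


class TestGenerateLimb:
    def test_cylindrical_limb_has_constant_slice_area(self):
        params = LimbParams(length=80.0, a0=30.0, b0=30.0, taper=1.0,
                            shape="cylindrical", noise_sd=0.0)
        limb, _ = generate_limb(params, seed=0)
        expected = np.pi * 30.0**2
        for z in (-10.0, -40.0, -70.0):
            assert slice_area(limb, z).area == pytest.approx(expected, rel=0.01)

    def test_conical_taper_ratio_in_slice_areas(self):
        params = LimbParams(length=90.0, taper=0.5, shape="conical", noise_sd=0.0)
        limb, _ = generate_limb(params, seed=0)
        proximal = slice_area(limb, -0.9).area
        distal = slice_area(limb, -89.1).area
        # rho at the sampled heights via the profile itself
        rho_p = params.profile(np.array([0.9 / 90.0]))[0]
        rho_d = params.profile(np.array([89.1 / 90.0]))[0]
        assert distal / proximal == pytest.approx((rho_d / rho_p) ** 2, rel=0.02)

    def test_seed_determinism_is_bitwise(self):
        params = LimbParams(noise_sd=0.3)
        a, _ = generate_limb(params, seed=5)
        b, _ = generate_limb(params, seed=5)
        assert np.array_equal(a.vertices, b.vertices)
        assert np.array_equal(a.faces, b.faces)

    def test_z_extent_equals_nominal_length(self):
        params = LimbParams(length=67.4, noise_sd=0.4)
        limb, _ = generate_limb(params, seed=2)
        assert np.ptp(limb.vertices[:, 2]) == pytest.approx(67.4, abs=0.5)

    def test_landmarks_sit_on_the_proximal_rim(self):
        limb, lm = generate_limb(LimbParams(noise_sd=0.0), seed=0)
        for p in (lm.medial_epicondyle, lm.lateral_epicondyle, lm.olecranon):
            d = np.linalg.norm(limb.vertices - p, axis=1).min()
            assert d < 1e-9

    def test_watertight_with_positive_volume(self, base_limb):
        limb, _ = base_limb
        assert limb.is_watertight
        assert limb.volume > 0

    def test_invalid_params_rejected(self):
        with pytest.raises(InputError):
            LimbParams(shape="conical", taper=0.9)
        with pytest.raises(InputError):
            LimbParams(shape="cylindrical", taper=0.8)
        with pytest.raises(InputError):
            LimbParams(length=-1.0)


class TestDeriveSocket:
    def test_constant_clearance_offsets_equivalent_radius(self, base_limb):
        # offsetting ellipse semi-axes (a, b) by c changes the equivalent
        # radius sqrt(ab) by c up to (sqrt(a)-sqrt(b))^2/2, negligible here
        limb, _ = base_limb
        socket, _, _ = derive_socket(limb, SocketDesignParams(
            clearance=2.0, cutout=False))
        for z in (-20.0, -40.0, -60.0):
            r_limb = np.sqrt(slice_area(limb, z).area / np.pi)
            r_sock = np.sqrt(slice_area(socket, z).area / np.pi)
            assert r_sock - r_limb == pytest.approx(2.0, abs=0.15)

    def test_socket_contains_limb_where_clearance_positive(self, base_limb, base_socket):
        limb, _ = base_limb
        socket, _, _ = base_socket
        field = signed_distances(limb, socket, n=4000, seed=0)
        # limb samples must lie inside the socket: negative signed distance
        assert (field.distances < 0).mean() > 0.995

    def test_planted_inflation_patch_shows_positive_cluster(self, base_limb, base_socket):
        limb, _ = base_limb
        socket, _, _ = base_socket
        direction = np.array([0.0, 1.0, -1.0]) / np.sqrt(2)
        patched, _, _ = derive_socket(limb, SocketDesignParams(
            patches=[PlantedPatch(direction=direction, amplitude=3.0)]))
        field = signed_distances(patched, socket, n=8000, seed=0)
        hot = field.distances > 1.5
        assert hot.sum() > 50
        centroid = field.points[hot].mean(axis=0)
        unit = centroid / np.linalg.norm(centroid)
        assert np.degrees(np.arccos(np.clip(unit @ direction, -1, 1))) < 20.0

    def test_cutout_slices_are_open_but_finite(self, base_socket):
        socket, _, obturator = base_socket
        section = slice_area(socket, obturator[2])
        assert section.area > 0
        # the cutout removes the posterior arc: enclosed area is less than
        # the full chord-closed hull of an uncut slice
        assert len(section.loops) >= 1

    def test_trimline_to_tip_distance_exceeds_45pct_of_length(self, base_limb, base_socket):
        limb, _ = base_limb
        socket, _, _ = base_socket
        length = np.ptp(limb.vertices[:, 2])
        # anterior-distal trimline: topmost socket vertex near theta = 90 deg
        v = np.asarray(socket.vertices)
        anterior = v[np.abs(np.degrees(np.arctan2(v[:, 1], v[:, 0])) - 90.0) < 10.0]
        trim_z = anterior[:, 2].max()
        tip_z = v[:, 2].min()
        assert trim_z - tip_z > 0.45 * length

    def test_registration_points_lie_on_the_surface(self, base_socket):
        socket, indent, obturator = base_socket
        v = np.asarray(socket.vertices)
        assert np.linalg.norm(v - indent, axis=1).min() < 1e-9
        assert np.linalg.norm(v - obturator, axis=1).min() < 3.0


class TestGenerateCohort:
    def test_cohort_mean_length_tracks_population(self, cohort19):
        library, _ = cohort19
        lengths = np.array([e.meta.limb_length for e in library.entries])
        spec = PopulationSpec()
        se = spec.length_sd / np.sqrt(len(lengths))
        assert abs(lengths.mean() - spec.length_mean) < 2.0 * se

    def test_length_class_labels_follow_cutoff_rule(self, cohort19):
        library, _ = cohort19
        spec = PopulationSpec()
        for e in library.entries:
            assert e.meta.length_class == spec.length_class(e.meta.limb_length)

    def test_regeneration_reproduces_manifest_hash(self):
        _, t1 = generate_cohort(4, seed=9)
        _, t2 = generate_cohort(4, seed=9)
        assert t1["_manifest_hash"] == t2["_manifest_hash"]

    def test_large_draw_converges_to_population_moments(self):
        # law-of-large-numbers check on the sampling distributions alone
        from pact.synthetic import _draw_limb_params
        spec = PopulationSpec()
        rng = np.random.default_rng(1)
        draws = [_draw_limb_params(rng, spec) for _ in range(500)]
        lengths = np.array([d.length for d in draws])
        shapes = [d.shape for d in draws]
        assert abs(lengths.mean() - spec.length_mean) < 3.0
        # truncation to [35, 125] shrinks the SD slightly
        assert abs(lengths.std(ddof=1) - spec.length_sd) < 4.0
        conical_frac = np.mean([s == "conical" for s in shapes])
        assert abs(conical_frac - 10 / 19) < 0.07

    def test_ground_truth_covers_every_participant(self, cohort5):
        library, truth = cohort5
        for pid in library.ids:
            assert "limb_params" in truth[pid]
            assert "design" in truth[pid]

    def test_too_small_cohort_rejected(self):
        with pytest.raises(InputError):
            generate_cohort(1, seed=0)
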