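"""Generator tests: analytic ground truth, determinism, scripted events."""

import numpy as np
import pytest

from macquant.quantify import contour_length
from macquant.synthdata import (Event, GenerationError, SyntheticConfig,
                                generate_cluster_frame,
                                generate_domain_sequence,
                                generate_kinetic_series)


class TestDomainSequence:
    def test_single_disk_ground_truth_matches_circle(self, disk_scene):
        _, seq, truth = disk_scene
        assert truth.domain_count[0] == 1
        assert truth.contour_length_um[0] == pytest.approx(2 * np.pi * 10, rel=1e-3)
        assert truth.domain_areas_um2[0][0] == pytest.approx(np.pi * 100, rel=1e-3)
        assert seq.data.shape == (1, 2, 200, 200)

    def test_empty_scene_is_pure_background(self):
        config = SyntheticConfig(n_domains=0, n_frames=2, noise_sigma=0.0,
                                 background_amplitude=0.0, image_shape=(64, 64))
        seq, truth = generate_domain_sequence(config)
        assert truth.domain_count.tolist() == [0, 0]
        assert truth.contour_length_um.tolist() == [0.0, 0.0]
        membrane = seq.channel("membrane")
        assert np.allclose(membrane, membrane.flat[0])

    def test_seed_determinism_bit_identical(self):
        kw = dict(n_frames=2, n_domains=3, n_clusters=4, seed=11,
                  image_shape=(128, 128))
        seq_a, truth_a = generate_domain_sequence(SyntheticConfig(**kw))
        seq_b, truth_b = generate_domain_sequence(SyntheticConfig(**kw))
        assert np.array_equal(seq_a.data, seq_b.data)
        assert np.array_equal(truth_a.masks, truth_b.masks)
        assert np.array_equal(truth_a.cluster_centroids_um,
                              truth_b.cluster_centroids_um)

    def test_different_seed_changes_output(self):
        kw = dict(n_frames=1, n_domains=3, image_shape=(128, 128))
        seq_a, _ = generate_domain_sequence(SyntheticConfig(seed=1, **kw))
        seq_b, _ = generate_domain_sequence(SyntheticConfig(seed=2, **kw))
        assert not np.array_equal(seq_a.data, seq_b.data)

    def test_split_event_steps_count_and_conserves_area(self, split_scene):
        _, _, truth = split_scene
        assert truth.domain_count.tolist() == [2] * 5 + [3] * 5
        areas = np.array([a.sum() for a in truth.domain_areas_um2])
        assert np.ptp(areas) / areas.mean() < 0.005
        assert np.ptp(truth.lo_area_um2) / truth.lo_area_um2.mean() < 0.005

    def test_fuse_event_drops_count_by_one(self, fuse_scene):
        _, _, truth = fuse_scene
        assert truth.domain_count.tolist() == [2] * 4 + [1] * 4
        assert np.ptp(truth.lo_area_um2) / truth.lo_area_um2.mean() < 0.005

    def test_lo_area_constant_under_translate_and_deform(self):
        config = SyntheticConfig(
            n_frames=6, n_domains=2, seed=6, image_shape=(200, 200),
            event_script=(
                {"frame": 1, "kind": "translate", "domain_ids": (0,),
                 "params": {"step_um": (0.3, -0.2)}},
                {"frame": 2, "kind": "deform", "domain_ids": (1,),
                 "params": {"mode": 3, "rate": 0.02}},
            ))
        _, truth = generate_domain_sequence(config)
        assert np.ptp(truth.lo_area_um2) / truth.lo_area_um2.mean() < 0.005

    def test_kinetic_sequence_contour_follows_model(self, kinetic_scene):
        config, _, truth = kinetic_scene
        Lf, tau, t0 = config.kinetic_params
        expected = Lf * -np.expm1(-np.clip(truth.times_min - t0, 0, None) / tau)
        delta = truth.contour_length_um - truth.contour_length_um[0]
        assert delta == pytest.approx(expected, abs=0.5)

    def test_event_referencing_unknown_domain_errors(self):
        config = SyntheticConfig(
            n_frames=3, n_domains=1, image_shape=(128, 128),
            event_script=({"frame": 1, "kind": "split", "domain_ids": (7,),
                           "params": {}},))
        with pytest.raises(GenerationError, match="unknown domain ids"):
            generate_domain_sequence(config)

    def test_overpacked_scene_errors_naming_domain(self):
        config = SyntheticConfig(n_domains=30, image_shape=(96, 96),
                                 domain_radius_range=(2.5, 3.0))
        with pytest.raises(GenerationError, match="domain"):
            generate_domain_sequence(config)

    def test_measured_perimeter_consistent_with_analytic(self, noisy_scene):
        """quantify's perimeter of the noiseless truth mask matches the
        polygon-exact perimeter of the scripted shapes within 2%."""
        config, _, truth = noisy_scene
        for f in range(truth.masks.shape[0]):
            measured = contour_length(truth.masks[f], config.pixel_size)
            assert measured == pytest.approx(truth.contour_length_um[f], rel=0.02)


class TestKineticSeries:
    def test_zero_at_t0(self):
        data = generate_kinetic_series((188.0, 9.5, 1.0), [1.0])
        assert data[0, 1] == 0.0

    def test_approaches_plateau(self):
        data = generate_kinetic_series((188.0, 9.5, 1.0), [1e6])
        assert data[0, 1] == pytest.approx(188.0, rel=1e-6)

    def test_closed_form_value(self):
        data = generate_kinetic_series((100.0, 5.0, 1.0), [6.0])
        assert data[0, 1] == pytest.approx(100 * (1 - np.exp(-1)), abs=1e-9)

    def test_noise_is_seeded(self):
        t = np.linspace(1, 30, 20)
        a = generate_kinetic_series((100, 5, 1), t, noise_sigma_um=3.0, seed=5)
        b = generate_kinetic_series((100, 5, 1), t, noise_sigma_um=3.0, seed=5)
        c = generate_kinetic_series((100, 5, 1), t, noise_sigma_um=3.0, seed=6)
        assert np.array_equal(a, b) and not np.array_equal(a, c)

    def test_invalid_tau_and_times(self):
        with pytest.raises(ValueError, match="tau"):
            generate_kinetic_series((100.0, -1.0, 1.0), [2.0])
        with pytest.raises(ValueError, match="t0"):
            generate_kinetic_series((100.0, 5.0, 1.0), [0.5])


class TestClusterFrame:
    def test_peak_near_requested_centroid(self):
        config = SyntheticConfig(image_shape=(100, 100), pixel_size=0.16,
                                 noise_sigma=0.0, background_amplitude=0.0)
        frame = generate_cluster_frame([[50 * 0.16, 50 * 0.16]], config)
        peak = np.unravel_index(np.argmax(frame), frame.shape)
        assert np.hypot(peak[0] - 50, peak[1] - 50) <= 1.0

    def test_empty_centroids_give_background_only(self):
        config = SyntheticConfig(image_shape=(64, 64), noise_sigma=0.0,
                                 background_amplitude=0.0)
        frame = generate_cluster_frame([], config)
        assert np.allclose(frame, frame.flat[0])

    def test_out_of_bounds_centroid_errors(self):
        config = SyntheticConfig(image_shape=(64, 64), pixel_size=0.16)
        with pytest.raises(GenerationError, match="outside"):
            generate_cluster_frame([[200.0, 5.0]], config)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"pixel_size": 0.0},
        {"n_frames": 0},
        {"domain_phase": "sideways"},
        {"background_amplitude": 1.5},
        {"domain_radius_range": (30.0, 40.0), "image_shape": (64, 64)},
    ])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            SyntheticConfig(**kw)

    def test_unknown_event_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            Event(frame=0, kind="teleport", domain_ids=(0,))

    def test_yaml_roundtrip(self, tmp_path):
        config = SyntheticConfig(n_frames=4, n_domains=2, seed=3,
                                 kinetic_params=(50.0, 4.0, 1.0),
                                 event_script=({"frame": 2, "kind": "translate",
                                                "domain_ids": (0,),
                                                "params": {"step_um": (0.1, 0.0)}},))
        path = tmp_path / "config.yaml"
        config.to_yaml(path)
        loaded = SyntheticConfig.from_yaml(path)
        assert loaded.kinetic_params == (50.0, 4.0, 1.0)
        assert loaded.event_script[0].kind == "translate"
        assert loaded.n_frames == 4
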