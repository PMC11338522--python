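"""Generator contracts: determinism, geometry invariants, photon
conservation, and the closed forms of the FRAP and morphology simulators."""

import numpy as np
import pytest

from axoncontact import synth
from axoncontact.errors import ParameterError
from axoncontact.presets import get_preset


class TestAxonTrace:
    def test_arc_length_and_branch_bounds(self):
        t = synth.make_axon_trace(30, 500, 3, seed=1)
        assert t.length_nm == pytest.approx(30_000)
        assert len(t.branch_points_nm) == 3
        assert all(0 <= b <= 30_000 for b in t.branch_points_nm)

    def test_deterministic(self):
        a = synth.make_axon_trace(30, 500, 2, seed=7)
        b = synth.make_axon_trace(30, 500, 2, seed=7)
        assert np.array_equal(a.vertices, b.vertices)
        assert a.branch_points_nm == b.branch_points_nm

    @pytest.mark.parametrize("kwargs", [
        {"length_um": 0.5}, {"width_nm": 0.0}, {"n_branches": -1},
    ])
    def test_parameter_errors(self, kwargs):
        args = {"length_um": 30, "width_nm": 500, "n_branches": 0, "seed": 1}
        args.update(kwargs)
        with pytest.raises(ParameterError):
            synth.make_axon_trace(**args)


class TestScene:
    def test_bound_count_matches_rounded_fraction(self, straight_trace):
        scene = synth.make_scene(straight_trace, 200, 0.45, 30, 50, seed=3)
        assert scene.bound.sum() == 90  # round(0.45 * 200)

    def test_empty_scene(self, straight_trace):
        scene = synth.make_scene(straight_trace, 0, 0.5, 30, 50, seed=3)
        assert scene.n_puncta == 0

    def test_all_bound_zero_distance_lie_on_surface(self, straight_trace):
        scene = synth.make_scene(straight_trace, 50, 1.0, 0.0, 50, seed=9)
        d = scene.distance_to_tubule_axis(scene.positions_nm)
        assert np.allclose(d, 50.0, atol=1e-6)

    def test_every_bound_punctum_within_bind_distance(self, small_scene):
        d = small_scene.distance_to_tubule_axis(
            small_scene.positions_nm[small_scene.bound]
        )
        assert np.all(d <= small_scene.er_tubule_radius_nm + 30 + 1e-9)

    def test_unbound_outside_binding_shell(self, small_scene):
        d = small_scene.distance_to_tubule_axis(
            small_scene.positions_nm[~small_scene.bound]
        )
        assert np.all(d > small_scene.er_tubule_radius_nm + 30)

    def test_deterministic(self, straight_trace):
        a = synth.make_scene(straight_trace, 100, 0.3, 20, 50, seed=5)
        b = synth.make_scene(straight_trace, 100, 0.3, 20, 50, seed=5)
        assert np.array_equal(a.positions_nm, b.positions_nm)
        assert np.array_equal(a.amplitudes, b.amplitudes)

    def test_bad_bound_fraction(self, straight_trace):
        with pytest.raises(ParameterError):
            synth.make_scene(straight_trace, 10, 1.2, 30, 50, seed=1)


class TestRender:
    def test_zero_photon_scale_dark_image(self, small_scene):
        img = synth.render_channel(small_scene, "puncta", 20, 60, 0.0, 0.0, 1)
        assert img.intensities.sum() == 0

    def test_noiseless_total_conserves_photons(self, small_scene):
        for fwhm in (60.0, 120.0):
            img = synth.render_channel(
                small_scene, "puncta", 20, fwhm, 100.0, 0.0, 1, noise=False
            )
            expected = 100.0 * small_scene.amplitudes.sum()
            assert img.intensities.sum() == pytest.approx(expected, rel=0.01)

    def test_single_punctum_peak_at_its_pixel(self, straight_trace):
        scene = synth.make_scene(straight_trace, 1, 0.0, 0.0, 50, seed=2,
                                 amplitude_cv=0.0)
        img = synth.render_channel(scene, "puncta", 20, 60, 50.0, 0.0, 1,
                                   noise=False)
        ny, nx, margin = synth._render_grid(scene, 20, 60)
        r, c = np.unravel_index(np.argmax(img.intensities), img.shape)
        x, y = scene.positions_nm[0, 0], scene.positions_nm[0, 1]
        exp_c = int((x + margin) / 20)
        exp_r = int((y + ny * 20 / 2.0) / 20)
        assert abs(r - exp_r) <= 1 and abs(c - exp_c) <= 1

    def test_same_seed_identical(self, small_scene):
        a = synth.render_channel(small_scene, "puncta", 20, 60, 100, 1.0, 11)
        b = synth.render_channel(small_scene, "puncta", 20, 60, 100, 1.0, 11)
        assert np.array_equal(a.intensities, b.intensities)

    def test_undersampling_rejected(self, small_scene):
        with pytest.raises(ParameterError):
            synth.render_channel(small_scene, "puncta", 100, 60, 10, 0, 1)


class TestLocalizations:
    def test_zero_blinks_empty_puncta_channel(self, small_scene):
        tab = synth.emit_localizations(small_scene, 10, 0.0, seed=4)
        assert (tab["channel"] == "ribo").sum() == 0

    def test_blink_count_near_poisson_mean(self, straight_trace):
        scene = synth.make_scene(straight_trace, 100, 0.5, 30, 50, seed=8)
        tab = synth.emit_localizations(scene, 10, 5.0, seed=11)
        n = (tab["channel"] == "ribo").sum()
        assert abs(n - 500) < 3 * np.sqrt(500)

    def test_tiny_precision_recovers_positions(self, straight_trace):
        scene = synth.make_scene(straight_trace, 20, 0.0, 0.0, 50, seed=8)
        tab = synth.emit_localizations(scene, 1e-9, 1.0, seed=2)
        ribo = tab[tab["channel"] == "ribo"]
        got = np.sort(ribo["x_nm"].to_numpy())
        # every localization coincides with some punctum's x position
        diffs = np.min(
            np.abs(got[:, None] - scene.positions_nm[None, :, 0]), axis=1
        )
        assert np.all(diffs < 1e-3)


class TestConditionPair:
    def test_noiseless_paired_scaling_is_exact(self):
        from axoncontact.pipeline import quantify_pair

        preset = get_preset("fig1-kd-puro")
        pair = synth.simulate_condition_pair(
            preset, 3, 123, paired_geometry=True, noise=False
        )
        vals = quantify_pair(pair)
        ratio = np.array(vals["test"]) / np.array(vals["control"])
        assert np.allclose(ratio, preset.scale_factor, rtol=1e-9)

    def test_deterministic(self):
        preset = get_preset("fig1-kd-puro")
        a = synth.simulate_condition_pair(preset, 2, 99)
        b = synth.simulate_condition_pair(preset, 2, 99)
        for sa, sb in zip(a.control + a.test, b.control + b.test):
            assert np.array_equal(sa.image.intensities, sb.image.intensities)

    def test_empty_groups(self):
        preset = get_preset("fig1-kd-puro")
        pair = synth.simulate_condition_pair(preset, 0, 1)
        assert pair.control == () and pair.test == ()

    def test_contact_preset_rejected(self):
        from axoncontact.errors import ConfigError

        with pytest.raises(ConfigError):
            synth.simulate_condition_pair(get_preset("fig2-sted-contact"), 2, 1)


class TestFrapSim:
    def test_no_recovery_flat_postbleach(self):
        s = synth.simulate_frap(100, 0.8, 0.0, 120, 0.0, 3, 20, 30, 0.0, 1)
        post = s.raw[3:]
        assert np.allclose(post, post[0])

    def test_full_recovery_returns_to_prebleach(self):
        s = synth.simulate_frap(100, 1.0, 1.0, 10, 0.0, 3, 400, 30, 0.0, 1)
        assert s.raw[-1] == pytest.approx(100, rel=1e-4)

    def test_closed_form_at_one_tau(self):
        s = synth.simulate_frap(100, 1.0, 0.4, 120, 0.0, 3, 40, 30, 0.0, 1)
        # 120 s after the bleach = 4 frames after bleach_index
        val = s.raw[s.bleach_index + 4]
        assert val == pytest.approx(100 * 0.4 * (1 - np.exp(-1)), rel=1e-9)

    def test_reference_decays_with_acquisition_bleaching(self):
        s = synth.simulate_frap(100, 0.9, 0.5, 120, 0.01, 3, 20, 30, 0.0, 1)
        expected = 100 * np.exp(-0.01 * np.arange(20))
        assert np.allclose(s.reference, expected)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ParameterError):
            synth.simulate_frap(100, 1.0, 0.4, 120, 0.0, 3, 3, 30, 0.0, 1)


class TestMorphologySim:
    def test_no_branching_gives_n_primary_tips(self):
        m = synth.simulate_morphology(4, 30, 0.0, seed=1)
        assert len(m.segments_um) == 4

    def test_deterministic_mask(self):
        a = synth.simulate_morphology(3, 30, 0.5, seed=5)
        b = synth.simulate_morphology(3, 30, 0.5, seed=5)
        assert np.array_equal(a.mask.mask, b.mask.mask)

    def test_single_straight_neurite_ground_truth(self):
        # one 35 um neurite crosses the 10/20/30 um circles exactly once
        segs = [((0.0, 0.0), (35.0, 0.0))]
        gt = synth.analytic_sholl(segs, [10, 20, 30, 40])
        assert gt.tolist() == [1, 1, 1, 0]
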