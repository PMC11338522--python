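"""Contact estimator: exact brute-force oracles on tiny grids, morphology
of the dilation, flip-null behavior and parameter recovery on synthetic
two-channel segments."""

import itertools

import numpy as np
import pytest

from axoncontact import contact, synth
from axoncontact.contact import ContactConfig
from axoncontact.core import BinaryMask, PixelImage
from axoncontact.errors import (
    DegenerateInputError,
    ParameterError,
    UndefinedFractionError,
)
from axoncontact.pipeline import quantify_contact
from axoncontact.presets import get_preset


def brute_contact_fraction(intensities, mask):
    inside = total = 0.0
    for r in range(intensities.shape[0]):
        for c in range(intensities.shape[1]):
            total += intensities[r, c]
            if mask[r, c]:
                inside += intensities[r, c]
    return inside / total


def brute_dilate(mask, radius_px):
    out = np.zeros_like(mask)
    offsets = [
        (dr, dc)
        for dr in range(-radius_px, radius_px + 1)
        for dc in range(-radius_px, radius_px + 1)
        if dr * dr + dc * dc <= radius_px * radius_px
    ]
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c]:
                for dr, dc in offsets:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1]:
                        out[rr, cc] = True
    return out


class TestSegmentErMask:
    def test_two_level_image_recovers_ridge(self):
        arr = np.full((6, 10), 10.0)
        arr[2:4] = 200.0
        img = PixelImage(arr, 20.0)
        mask = contact.segment_er_mask(img)
        assert np.array_equal(mask.mask, arr > mask.threshold_used)
        assert np.array_equal(mask.mask, arr == 200.0)

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateInputError):
            contact.segment_er_mask(PixelImage(np.zeros((4, 4)), 20.0))

    def test_fixed_threshold_at_max_gives_empty_mask(self):
        arr = np.arange(16.0).reshape(4, 4)
        mask = contact.segment_er_mask(
            PixelImage(arr, 20.0), method="fixed", fixed_threshold=15.0
        )
        assert not mask.mask.any()

    def test_fixed_without_threshold_rejected(self):
        with pytest.raises(ParameterError):
            contact.segment_er_mask(
                PixelImage(np.arange(4.0).reshape(2, 2), 20.0), method="fixed"
            )


class TestDilateMask:
    def test_zero_distance_identity(self):
        m = BinaryMask(np.eye(5, dtype=bool), 10.0)
        assert np.array_equal(contact.dilate_mask(m, 0).mask, m.mask)

    def test_subpixel_distance_dilates_one_pixel(self):
        arr = np.zeros((5, 5), dtype=bool)
        arr[2, 2] = True
        m = contact.dilate_mask(BinaryMask(arr, 10.0), 5.0)
        expected = np.zeros((5, 5), dtype=bool)
        for dr, dc in [(0, 0), (0, 1), (0, -1), (1, 0), (-1, 0)]:
            expected[2 + dr, 2 + dc] = True
        assert np.array_equal(m.mask, expected)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("distance_nm", [5.0, 10.0, 25.0])
    def test_matches_brute_force_on_small_grids(self, seed, distance_nm):
        rng = np.random.default_rng(seed)
        arr = rng.random((5, 5)) > 0.6
        m = contact.dilate_mask(BinaryMask(arr, 10.0), distance_nm)
        r = max(int(np.ceil(distance_nm / 10.0)), 1)
        assert np.array_equal(m.mask, brute_dilate(arr, r))

    def test_output_superset_of_input(self):
        rng = np.random.default_rng(3)
        arr = rng.random((8, 8)) > 0.7
        out = contact.dilate_mask(BinaryMask(arr, 10.0), 15.0).mask
        assert np.all(out[arr])


class TestContactFraction:
    def test_uniform_image_half_mask(self):
        img = PixelImage(np.ones((4, 4)), 10.0)
        mask = np.zeros((4, 4), dtype=bool)
        mask[:2] = True
        assert contact.contact_fraction(img, BinaryMask(mask, 10.0)) == 0.5

    def test_hand_computed_three_by_three(self):
        arr = np.ones((3, 3))
        arr[1, 1] = 8.0
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = mask[0, 0] = mask[0, 1] = True
        frac = contact.contact_fraction(
            PixelImage(arr, 10.0), BinaryMask(mask, 10.0)
        )
        assert frac == pytest.approx((8 + 2) / 16)  # = 0.625

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        arr = rng.random((5, 5)) + 0.01
        mask = rng.random((5, 5)) > 0.5
        got = contact.contact_fraction(
            PixelImage(arr, 10.0), BinaryMask(mask, 10.0)
        )
        assert got == pytest.approx(brute_contact_fraction(arr, mask), abs=1e-12)

    def test_zero_intensity_rejected(self):
        with pytest.raises(UndefinedFractionError):
            contact.contact_fraction(
                PixelImage(np.zeros((3, 3)), 10.0),
                BinaryMask(np.ones((3, 3), dtype=bool), 10.0),
            )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            contact.contact_fraction(
                PixelImage(np.ones((3, 3)), 10.0),
                BinaryMask(np.ones((4, 4), dtype=bool), 10.0),
            )


class TestFlipNull:
    def test_mirror_symmetric_image_unchanged(self):
        arr = np.array([[1.0, 2.0, 2.0, 1.0], [3.0, 1.0, 1.0, 3.0]])
        mask = np.zeros((2, 4), dtype=bool)
        mask[:, 0] = True
        img = PixelImage(arr, 10.0)
        m = BinaryMask(mask, 10.0)
        assert contact.flip_null(img, m) == contact.contact_fraction(img, m)

    def test_uniform_image_equals_area_fraction(self):
        img = PixelImage(np.ones((4, 6)), 10.0)
        mask = np.zeros((4, 6), dtype=bool)
        mask[1, 2] = mask[3, 4] = True
        m = BinaryMask(mask, 10.0)
        assert contact.flip_null(img, m) == pytest.approx(m.area_fraction)


class TestRenderLocalizations:
    def test_single_localization_unit_pixel(self):
        import pandas as pd

        tab = pd.DataFrame({
            "x_nm": [25.0], "y_nm": [35.0], "precision_nm": [10.0],
            "frame": [0], "channel": ["ribo"],
        })
        img = contact.render_localizations(tab, 10.0)["ribo"]
        assert img.intensities.sum() == 1.0
        assert img.intensities[3, 2] == 1.0

    def test_half_open_binning_one_pixel_apart(self):
        import pandas as pd

        tab = pd.DataFrame({
            "x_nm": [9.999, 10.0], "y_nm": [5.0, 5.0],
            "precision_nm": [10.0, 10.0], "frame": [0, 0],
            "channel": ["ribo", "ribo"],
        })
        img = contact.render_localizations(tab, 10.0)["ribo"]
        assert img.intensities[0, 0] == 1.0 and img.intensities[0, 1] == 1.0

    def test_blur_conserves_count(self, straight_trace):
        # all emitters near the tubule, well inside the grid, so no mass is
        # lost at the reconstruction borders
        scene = synth.make_scene(straight_trace, 80, 1.0, 10, 50, seed=6)
        tab = synth.emit_localizations(scene, 5.0, 3.0, seed=6)
        imgs = contact.render_localizations(tab, 20.0, blur_sd_nm=20.0)
        for channel, img in imgs.items():
            n = (tab["channel"] == channel).sum()
            assert img.intensities.sum() == pytest.approx(n, rel=0.01)

    def test_empty_table_rejected(self):
        import pandas as pd

        with pytest.raises(DegenerateInputError):
            contact.render_localizations(
                pd.DataFrame(columns=["x_nm", "y_nm", "precision_nm",
                                      "frame", "channel"]), 10.0
            )


class TestAnalyzeSegment:
    def test_uniform_ribo_fraction_equals_area_fraction(self):
        er = np.full((6, 10), 10.0)
        er[2:4] = 200.0
        res = contact.analyze_segment(
            PixelImage(er, 20.0), PixelImage(np.ones((6, 10)), 20.0)
        )
        assert res.fraction_in_mask == pytest.approx(res.mask_area_fraction)

    def test_enlarged_never_below_mask_fraction(self):
        preset = get_preset("fig2-sted-contact")
        segs = synth.simulate_contact_segments(preset, 4, 17)
        for seg in segs:
            res = contact.analyze_segment(
                seg.er_image, seg.ribo_image,
                ContactConfig(dilate_nm=preset.dilate_nm),
            )
            assert res.fraction_in_enlarged >= res.fraction_in_mask

    def test_monotone_in_dilation_distance(self):
        preset = get_preset("fig2-sted-contact")
        seg = synth.simulate_contact_segments(preset, 1, 21)[0]
        mask = contact.segment_er_mask(seg.er_image)
        fracs = [
            contact.contact_fraction(
                seg.ribo_image, contact.dilate_mask(mask, d)
            )
            for d in [0, 5, 20, 40, 80, 160]
        ]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))


class TestRecovery:
    def test_flip_null_unbiased_on_uniform_scenes(self):
        # puncta uniform in the cylinder (no binding): flipping cannot
        # change the expected overlap, so the mean paired difference is
        # within 2 standard errors of zero
        from axoncontact.presets import SimulationPreset

        base = dict(get_preset("fig2-sted-contact").params)
        base["bound_fraction"] = 0.0
        base["bind_distance_nm"] = 0.0
        preset = SimulationPreset("uniform-null", "contact", base)
        segs = synth.simulate_contact_segments(preset, 50, 31)
        df = quantify_contact(segs, ContactConfig(dilate_nm=5.0))
        diff = df["fraction_in_mask"] - df["fraction_flipped"]
        sem = diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) < 2 * sem

    def test_contact_fraction_increases_with_bound_fraction(self):
        preset = get_preset("fig2-sted-contact")
        means = []
        for bf in (0.1, 0.3, 0.5, 0.7, 0.9):
            segs = synth.simulate_contact_segments(
                preset, 10, 77, bound_fraction=bf
            )
            df = quantify_contact(segs, ContactConfig(dilate_nm=5.0))
            means.append(df["fraction_in_mask"].mean())
        assert all(b > a for a, b in zip(means, means[1:]))
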