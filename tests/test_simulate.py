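"""Simulator physics: spectral integration, noise statistics, scene building."""

import numpy as np
import pytest

from chromacal import (
    CameraModel,
    CameraSensitivity,
    CaptureSettings,
    IlluminantSPD,
    Reflectance,
    ideal_channel_response,
    make_card_scene,
    make_grey_scene,
    render_frame,
    render_pair,
    xyz_ground_truth,
)
from chromacal.errors import LayoutError
from chromacal.simulate import auto_exposure_time
from chromacal.standards import (
    cie_cmf,
    gaussian_camera_sensitivity,
    illuminant_d50,
    led_flash,
    screen_flash,
)


class TestIdealChannelResponse:
    def test_zero_reflectance_gives_zero_response(self, grid, flat_reflectance):
        resp = ideal_channel_response(
            flat_reflectance(0.0),
            IlluminantSPD(np.ones(grid.n_bins), grid=grid),
            gaussian_camera_sensitivity(),
        )
        assert np.all(resp == 0)

    def test_single_bin_identity(self, grid, flat_reflectance):
        """Unit reflectance × unit power × unit sensitivity in one 10 nm bin."""
        chan = np.zeros(grid.n_bins)
        chan[5] = 1.0
        sens = CameraSensitivity(r=chan, g=chan, b=chan, grid=grid)
        resp = ideal_channel_response(
            flat_reflectance(1.0), IlluminantSPD(np.ones(grid.n_bins), grid=grid), sens
        )
        assert resp == pytest.approx([10.0, 10.0, 10.0])

    def test_matches_term_by_term_summation_oracle(self, grid):
        ramp = Reflectance(np.linspace(0.0, 1.0, grid.n_bins), grid=grid)
        illum = IlluminantSPD(np.full(grid.n_bins, 2.0), grid=grid)
        sens = gaussian_camera_sensitivity()
        shading = 0.7
        resp = ideal_channel_response(ramp, illum, sens, shading=shading)
        for k, chan in enumerate("rgb"):
            expected = 0.0
            for i in range(grid.n_bins):
                expected += (
                    ramp.values[i] * illum.values[i] * getattr(sens, chan)[i]
                ) * grid.step_nm
            assert resp[k] == pytest.approx(shading * expected, rel=1e-12)

    def test_invalid_shading_rejected(self, grid, flat_reflectance):
        with pytest.raises(ValueError):
            ideal_channel_response(
                flat_reflectance(0.5),
                IlluminantSPD(np.ones(grid.n_bins), grid=grid),
                gaussian_camera_sensitivity(),
                shading=0.0,
            )


class TestXYZGroundTruth:
    def test_perfect_reflector_has_unit_luminance(self, flat_reflectance):
        xyz = xyz_ground_truth(flat_reflectance(1.0), illuminant_d50(), cie_cmf())
        assert xyz[1] == pytest.approx(1.0, abs=1e-12)

    def test_perfect_reflector_sits_at_d50_white_point(self, flat_reflectance):
        xyz = xyz_ground_truth(flat_reflectance(1.0), illuminant_d50(), cie_cmf())
        x, y = xyz[0] / xyz.sum(), xyz[1] / xyz.sum()
        assert x == pytest.approx(0.3457, abs=5e-4)
        assert y == pytest.approx(0.3585, abs=5e-4)

    def test_black_surface_gives_zero_tristimulus(self, flat_reflectance):
        xyz = xyz_ground_truth(flat_reflectance(0.0), illuminant_d50(), cie_cmf())
        assert np.all(xyz == 0)


@pytest.fixture
def grey_scene():
    return make_grey_scene(reflectance_value=0.35, shape=(100, 100))


class TestRenderFrame:
    def test_dark_frame_is_black_level_everywhere(self, grey_scene, phone_a):
        frame = render_frame(
            grey_scene, phone_a, CaptureSettings(0.01, flash_on=False, seed=0), None
        )
        assert np.all(frame.dn == phone_a.black_level)

    def test_noiseless_uniform_patch_is_flat_per_channel(self, grey_scene, phone_a):
        frame = render_frame(
            grey_scene, phone_a, CaptureSettings(0.01, flash_on=True, noise=False), None
        )
        chan = frame.channel_map()
        for ch in (0, 1, 2):
            vals = np.asarray(frame.dn)[chan == ch]
            assert np.ptp(vals) == 0

    def test_poisson_statistics_match_closed_form(self, grey_scene, phone_a):
        """Mean within 3 SE of expectation; variance/mean ratio near 1."""
        t = auto_exposure_time(grey_scene, phone_a, target_fraction=0.2)
        noiseless = render_frame(
            grey_scene, phone_a, CaptureSettings(t, flash_on=True, noise=False), None
        )
        noisy = render_frame(
            grey_scene, phone_a, CaptureSettings(t, flash_on=True, seed=42), None
        )
        chan = noisy.channel_map()
        for ch in (0, 1, 2):
            expected = (np.asarray(noiseless.dn, float) - phone_a.black_level)[
                chan == ch
            ] * phone_a.gain
            counts = (np.asarray(noisy.dn, float) - phone_a.black_level)[
                chan == ch
            ] * phone_a.gain
            mu = expected.mean()
            assert mu >= 100
            se = np.sqrt(mu / counts.size)
            assert abs(counts.mean() - mu) < 3 * se
            assert 0.9 < counts.var() / counts.mean() < 1.1

    def test_noiseless_response_linear_in_exposure(self, grey_scene, phone_a):
        t = auto_exposure_time(grey_scene, phone_a, target_fraction=0.1)
        sig = {}
        for k in (1.0, 2.0, 4.0):
            f = render_frame(
                grey_scene, phone_a, CaptureSettings(k * t, flash_on=True, noise=False), None
            )
            sig[k] = np.asarray(f.dn, float).mean() - phone_a.black_level
        assert abs(sig[2.0] / (2 * sig[1.0]) - 1) < 1e-9
        assert abs(sig[4.0] / (4 * sig[1.0]) - 1) < 1e-9

    def test_flash_and_ambient_expectations_add_exactly(self, grey_scene, phone_a):
        ambient = screen_flash()  # any second source works
        t = 0.002

        def expectation(flash_on, amb):
            f = render_frame(
                grey_scene, phone_a, CaptureSettings(t, flash_on=flash_on, noise=False), amb
            )
            return np.asarray(f.dn, float) - phone_a.black_level

        both = expectation(True, ambient)
        flash_only = expectation(True, None)
        ambient_only = expectation(False, ambient)
        assert np.allclose(both, flash_only + ambient_only, atol=1e-9)


class TestRenderPair:
    def test_no_ambient_noflash_frame_is_dark(self, grey_scene, phone_a):
        _, noflash = render_pair(
            grey_scene, phone_a, CaptureSettings(0.01, seed=1), None
        )
        assert np.all(noflash.dn == phone_a.black_level)

    def test_pair_shares_exposure_and_iso(self, grey_scene, phone_a):
        flash, noflash = render_pair(
            grey_scene, phone_a, CaptureSettings(0.01, iso_scale=2.0, seed=1), None
        )
        assert flash.exposure_time == noflash.exposure_time
        assert flash.iso_scale == noflash.iso_scale
        assert flash.flash_on and not noflash.flash_on

    def test_noisy_pair_difference_matches_flash_only_expectation(
        self, grey_scene, phone_a
    ):
        ambient = screen_flash().scaled(0.3)
        t = auto_exposure_time(grey_scene, phone_a, target_fraction=0.3)
        flash, noflash = render_pair(
            grey_scene, phone_a, CaptureSettings(t, seed=7), ambient
        )
        ideal = render_frame(
            grey_scene, phone_a, CaptureSettings(t, flash_on=True, noise=False), None
        )
        n = flash.dn.size
        diff = (np.asarray(flash.dn, float) - np.asarray(noflash.dn, float)).mean()
        expected = (np.asarray(ideal.dn, float) - phone_a.black_level).mean()
        # var of the mean difference = (flash var + noflash var) / n
        amb_frame = render_frame(
            grey_scene, phone_a, CaptureSettings(t, flash_on=False, noise=False), ambient
        )
        amb_expected = (np.asarray(amb_frame.dn, float) - phone_a.black_level).mean()
        se = np.sqrt((expected + 2 * amb_expected) / n)
        assert abs(diff - expected) < 3 * se


class TestSceneBuilding:
    def test_card_layout_places_disjoint_uniform_patches(self, classic_bank):
        scene = make_card_scene(classic_bank, (4, 6))
        assert len(scene.patches) == 24
        assert np.all(scene.shading_field == 1.0)
        total_area = sum(p.rect[2] * p.rect[3] for p in scene.patches)
        assert total_area == scene.shape[0] * scene.shape[1]

    def test_radial_falloff_darkens_corners(self, classic_bank):
        scene = make_card_scene(
            classic_bank, (4, 6), shading_profile="radial", falloff_strength=0.5
        )
        corner = scene.patch_shading(scene.patches[0].patch_id)
        center = scene.patch_shading(scene.patches[9].patch_id)
        assert corner < center

    def test_too_many_spectra_raise_layout_error(self, classic_bank):
        with pytest.raises(LayoutError):
            make_card_scene(classic_bank, (2, 3))

    def test_grey_scene_render_matches_ideal_response(self, phone_a):
        scene = make_grey_scene(reflectance_value=0.4, shape=(20, 20))
        frame = render_frame(
            scene, phone_a, CaptureSettings(0.01, flash_on=True, noise=False), None
        )
        resp = ideal_channel_response(
            scene.patches[0].reflectance, phone_a.flash_spd, phone_a.sensitivity
        )
        chan = frame.channel_map()
        for ch in (0, 1, 2):
            dn = np.asarray(frame.dn, float)[chan == ch] - phone_a.black_level
            assert np.allclose(dn, resp[ch] * 0.01 / phone_a.gain)

    def test_distinct_cameras_disagree_on_native_rgb(self, classic_bank):
        refl = classic_bank["red"]
        illum = led_flash()
        a = ideal_channel_response(refl, illum, gaussian_camera_sensitivity())
        b = ideal_channel_response(
            refl, illum, gaussian_camera_sensitivity((610.0, 545.0, 455.0), (50.0, 55.0, 40.0))
        )
        assert not np.allclose(a, b, rtol=1e-3)
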