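"""Optical/camera models and synthetic frame rendering."""

import numpy as np
import pytest
from scipy import stats

from nwloc.array_model import generate_layout, place_molecules
from nwloc.image_synthesis import (
    CameraModel,
    OpticalModel,
    default_enhancement_profile,
    enhancement_at,
    render_brightfield,
    render_fluorescence,
    sample_photons,
)


class TestOpticalModel:
    def test_default_psf_is_diffraction_limited(self, optics):
        assert optics.psf_sigma_um == pytest.approx(0.21 * 0.670 / 1.2)

    def test_enhancement_profile_mean_order_of_magnitude(self, optics):
        assert optics.mean_enhancement() == pytest.approx(10.0)

    def test_enhancement_interpolation_and_bounds(self, optics):
        prof = optics.enhancement_profile
        # exact at nodes
        assert enhancement_at(optics, prof[0, 0]) == pytest.approx(prof[0, 1])
        assert enhancement_at(optics, prof[-1, 0]) == pytest.approx(prof[-1, 1])
        # linear in between
        mid = enhancement_at(optics, 1.25)
        assert prof[:, 1].min() < mid < prof[:, 1].max()
        with pytest.raises(ValueError):
            enhancement_at(optics, -0.1)
        with pytest.raises(ValueError):
            enhancement_at(optics, 99.0)

    def test_defocus_monotone_increasing(self, optics):
        dz = np.array([0.0, 0.5, 1.0, 2.5])
        sd = optics.defocus_sigma_um(dz)
        assert sd[0] == pytest.approx(optics.psf_sigma_um)
        assert np.all(np.diff(sd) > 0)

    def test_invalid_profiles_rejected(self):
        with pytest.raises(ValueError):
            OpticalModel(enhancement_profile=np.array([[0.0, -1.0]]))
        with pytest.raises(ValueError):
            OpticalModel(enhancement_profile=np.array([[0.0, 1.0, 2.0]]))
        with pytest.raises(ValueError):
            OpticalModel(psf_sigma_um=10.0)  # inconsistent with diffraction limit

    def test_custom_ramp(self):
        prof = default_enhancement_profile(base=1.0, tip=3.0)
        assert prof[0, 1] == 1.0 and prof[-1, 1] == 3.0
        assert np.all(np.diff(prof[:, 1]) >= 0)


class TestCameraModel:
    def test_coordinate_roundtrip(self, small_camera):
        xy = np.array([[0.5, 1.0], [3.3, 2.2]])
        assert np.allclose(small_camera.px_to_um(small_camera.um_to_px(xy)), xy)

    def test_pixel_center_convention(self, small_camera):
        # integer pixel-index coordinates are pixel centers
        um = small_camera.px_to_um(np.array([0.0, 0.0]))
        assert np.allclose(um, small_camera.pixel_size_um / 2.0)

    def test_for_layout_covers_field(self, small_layout):
        cam = CameraModel.for_layout(small_layout)
        w, h = small_layout.field_size_um
        assert cam.shape[1] * cam.pixel_size_um >= w
        assert cam.shape[0] * cam.pixel_size_um >= h

    def test_validation(self):
        with pytest.raises(ValueError):
            CameraModel(pixel_size_um=0.0)
        with pytest.raises(ValueError):
            CameraModel(dark_offset=-5.0)


class TestSamplePhotons:
    def test_exact_conservation(self):
        psf = np.random.default_rng(0).random((7, 7))
        counts = sample_photons(psf, 12345, seed_or_rng=1)
        assert counts.sum() == 12345
        assert counts.shape == psf.shape

    def test_zero_photons(self):
        assert sample_photons(np.ones((3, 3)), 0).sum() == 0

    def test_errors(self):
        with pytest.raises(ValueError):
            sample_photons(np.ones((3, 3)), -1)
        with pytest.raises(ValueError):
            sample_photons(np.zeros((3, 3)), 10)
        with pytest.raises(ValueError):
            sample_photons(-np.ones((3, 3)), 10)

    def test_multinomial_distribution_oracle(self):
        # chi-square goodness of fit of sampled counts vs the pixel map
        rng = np.random.default_rng(5)
        xs = np.arange(9) - 4.0
        psf = np.outer(np.exp(-xs**2 / 4), np.exp(-xs**2 / 4))
        n = 100_000
        counts = sample_photons(psf, n, seed_or_rng=rng)
        p = psf / psf.sum()
        keep = (p * n) > 10  # standard chi-square validity cut
        chi2 = np.sum((counts[keep] - n * p[keep]) ** 2 / (n * p[keep]))
        dof = keep.sum() - 1
        assert stats.chi2.sf(chi2, dof) > 0.01


class TestRenderFluorescence:
    def test_noiseless_expectation_matches_components(self, populated, optics):
        layout, gt = populated
        cam = CameraModel.for_layout(layout)
        frame = render_fluorescence(gt, layout, optics, cam, shot_noise=False)
        assert np.allclose(frame.image, frame.expected_image())
        # expected photons written back per molecule
        exp = gt.molecules["expected_photons"].to_numpy()
        assert np.all(exp > 0)
        enh = gt.molecules["enhanced"].to_numpy()
        base = cam.base_photon_rate * cam.exposure_ms
        assert np.allclose(exp[~enh], base)
        assert np.all(exp[enh] >= base)  # enhancement >= profile base > 1

    def test_photon_conservation_noiseless(self, optics):
        # an interior molecule's expected window integrates to ~ its photons
        layout = generate_layout(n_rows=12, n_cols=12, defect_fraction=0.0, seed=1)
        gt = place_molecules(layout, 0.02, seed=12)
        cam = CameraModel.for_layout(layout)
        frame = render_fluorescence(gt, layout, optics, cam, shot_noise=False)
        total_expected = gt.molecules["expected_photons"].to_numpy()
        rendered = frame.expected_nw.sum() + frame.expected_sub.sum()
        # edge-clipped tails may lose a small fraction
        assert rendered <= total_expected.sum() + 1e-6
        assert rendered > 0.9 * total_expected.sum()

    def test_empty_ground_truth_statistics(self, small_layout, optics):
        gt = place_molecules(small_layout, 0.0, seed=0)
        cam = CameraModel.for_layout(small_layout, exposure_ms=100.0)
        frame = render_fluorescence(gt, small_layout, optics, cam, seed=8)
        bg = optics.background_photon_rate * cam.exposure_ms
        mean_expected = bg * cam.gain + cam.dark_offset
        assert frame.image.mean() == pytest.approx(mean_expected, rel=0.02)
        # variance ~ Poisson(bg) + read noise
        var_expected = bg * cam.gain**2 + cam.read_noise**2
        assert frame.image.var() == pytest.approx(var_expected, rel=0.1)

    def test_seeded_reproducibility(self, populated, optics):
        layout, gt = populated
        cam = CameraModel.for_layout(layout)
        a = render_fluorescence(gt, layout, optics, cam, seed=3).image
        b = render_fluorescence(gt, layout, optics, cam, seed=3).image
        assert np.array_equal(a, b)

    def test_missing_wire_reference_raises(self, small_layout, optics):
        gt = place_molecules(small_layout, 0.5, seed=1)
        missing = np.flatnonzero(small_layout.status == "missing")
        assert len(missing) > 0  # deterministic for the fixture seed
        gt.molecules.loc[gt.molecules.index[0], ["target", "wire_index"]] = (
            "wire", missing[0],
        )
        cam = CameraModel.for_layout(small_layout)
        with pytest.raises(ValueError, match="missing wire"):
            render_fluorescence(gt, small_layout, optics, cam, seed=0)

    def test_uint16_quantization(self, populated, optics):
        layout, gt = populated
        cam = CameraModel.for_layout(layout)
        frame = render_fluorescence(gt, layout, optics, cam, seed=2)
        q = frame.as_uint16()
        assert q.dtype == np.uint16
        assert np.all(np.abs(q.astype(float) - np.clip(frame.image, 0, 65535)) <= 0.5)


class TestRenderBrightfield:
    def test_wires_dark_at_sites(self, small_layout):
        cam = CameraModel.for_layout(small_layout)
        bf = render_brightfield(small_layout, cam, contrast=-0.3)
        present = small_layout.status != "missing"
        px = cam.um_to_px(small_layout.positions_um[present])
        rc = np.round(px[:, ::-1]).astype(int)
        rc[:, 0] = np.clip(rc[:, 0], 0, bf.shape[0] - 1)
        rc[:, 1] = np.clip(rc[:, 1], 0, bf.shape[1] - 1)
        site_vals = bf[rc[:, 0], rc[:, 1]]
        assert np.all(site_vals < np.median(bf))

    def test_missing_sites_blank(self):
        lay = generate_layout(n_rows=12, n_cols=12, defect_fraction=0.9,
                              missing_fraction_of_defects=1.0, seed=2,
                              jitter_sd_um=0.0)
        cam = CameraModel.for_layout(lay)
        bf = render_brightfield(lay, cam, contrast=-0.3)
        missing = lay.status == "missing"
        assert missing.sum() > 0
        px = cam.um_to_px(lay.positions_um[missing])
        rc = np.round(px[:, ::-1]).astype(int)
        vals = bf[rc[:, 0], rc[:, 1]]
        assert np.allclose(vals, 1000.0, atol=1e-6)

    def test_contrast_validation(self, small_layout):
        cam = CameraModel.for_layout(small_layout)
        with pytest.raises(ValueError):
            render_brightfield(small_layout, cam, contrast=-1.5)
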