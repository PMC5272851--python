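"""Filters, attenuation-map estimation, TEW correction, FBP and OSEM."""

import warnings

import numpy as np
import pytest

from spectsbr import (
    CameraModel,
    PhantomSpec,
    ProjectionSet,
    ReconSpec,
    build_phantom,
    butterworth_filter,
    estimate_attenuation_map,
    fbp,
    head_mu_map,
    osem,
    reconstruct_study,
    simulate_scan,
    tew_correct,
)
from spectsbr.phantoms import OUTSIDE, STRIATAL_LABELS
from spectsbr.projector import RotationProjector


class TestButterworth:
    def test_constant_image_unchanged(self):
        img = np.full((32, 32), 7.3)
        out = butterworth_filter(img, cutoff=0.55, order=10, pixel_size_mm=4.0)
        assert np.allclose(out, img, rtol=1e-10)

    def test_half_power_at_cutoff(self):
        # pure sinusoid exactly at fc -> amplitude scaled by 1/sqrt(2);
        # n and fc chosen so fc sits exactly on the DFT frequency grid
        n, pix = 100, 4.0
        fc = 0.5  # cycles/cm -> 20 full cycles over the 40 cm support
        x_cm = np.arange(n) * pix / 10.0
        sig = np.sin(2 * np.pi * fc * x_cm)
        out = butterworth_filter(sig[None, :], fc, 10, pix, axes=(1,))[0]
        assert out.max() == pytest.approx(sig.max() / np.sqrt(2.0), rel=0.01)

    def test_white_noise_spectrum_matches_gain(self, rng):
        n, pix = 256, 4.0
        noise = rng.standard_normal((64, n))
        out = butterworth_filter(noise, 0.55, 10, pix, axes=(1,))
        f = np.fft.rfftfreq(n, d=pix / 10.0)
        p_in = np.abs(np.fft.rfft(noise, axis=1)) ** 2
        p_out = np.abs(np.fft.rfft(out, axis=1)) ** 2
        gain2 = 1.0 / (1.0 + (f / 0.55) ** 20)
        band = (f > 0.05) & (f < 1.0)
        measured = (p_out[:, band].mean(axis=0)) / (p_in[:, band].mean(axis=0))
        assert np.allclose(measured, gain2[band], atol=0.05)

    def test_cutoff_above_nyquist_warns_and_is_identity(self, rng):
        img = rng.random((16, 16))
        with pytest.warns(UserWarning, match="Nyquist"):
            out = butterworth_filter(img, cutoff=5.0, order=10, pixel_size_mm=4.0)
        assert np.allclose(out, img, atol=1e-3)

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            butterworth_filter(np.ones((4, 4)), 0.0, 10, 4.0)


class TestTEW:
    def _scan(self, ph, sc_l, sc_u):
        shape = (4, 8, 8)
        mk = lambda v: np.full(shape, float(v))
        return ProjectionSet(
            mk(ph), mk(sc_l), mk(sc_u), angles=np.arange(4) * 90.0
        )

    def test_empty_satellites_leave_photopeak_untouched(self):
        p = self._scan(100, 0, 0)
        assert np.array_equal(tew_correct(p), p.ph)

    def test_hand_computed_subtraction(self):
        # ph=100, sc_l=sc_u=7 per bin, w_ph=32, w_sc=7:
        # estimate = (1 + 1) * 16 = 32 -> corrected = 68
        p = self._scan(100, 7, 7)
        assert np.allclose(tew_correct(p), 68.0)

    def test_floor_at_zero(self):
        p = self._scan(10, 70, 70)
        corrected = tew_correct(p)
        assert np.all(corrected == 0)

    def test_window_width_validation(self):
        with pytest.raises(ValueError, match="width"):
            self._scan(1, 1, 1).w_sc = 0  # construction-time check
            ProjectionSet(
                np.ones((1, 2, 2)), np.ones((1, 2, 2)), np.ones((1, 2, 2)),
                angles=[0.0], w_sc=0.0,
            )


class TestAttenuationMap:
    def test_known_ellipsoid_axes_recovered(self):
        spec = PhantomSpec(filling_ratio=1.0).desk_scale()
        vol = build_phantom(spec)
        amap = estimate_attenuation_map(
            vol.activity, spec.voxel_size_mm, mode="threshold_contour",
            threshold_fraction=0.1,
        )
        # central slice section should match the head ellipse within a voxel
        z = vol.shape[2] // 2
        head = vol.labels[:, :, z] != OUTSIDE
        est = amap.mu[:, :, z] > 0
        x_extent_err = abs(est.any(axis=1).sum() - head.any(axis=1).sum()) / 2
        y_extent_err = abs(est.any(axis=0).sum() - head.any(axis=0).sum()) / 2
        assert x_extent_err <= 1.0
        assert y_extent_err <= 1.0
        assert set(np.unique(amap.mu)) <= {0.0, 0.143}

    def test_fixed_ellipse_equatorial_axes(self):
        spec = PhantomSpec(filling_ratio=1.0).desk_scale()
        vol = build_phantom(spec)
        amap = estimate_attenuation_map(
            vol.activity, spec.voxel_size_mm, mode="fixed_ellipse"
        )
        z = vol.shape[2] // 2
        est = amap.mu[:, :, z] > 0
        # 140 x 190 mm at 4 mm voxels -> 35 x 47.5 voxel extents
        assert est.any(axis=1).sum() == pytest.approx(140 / 4.0, abs=1)
        assert est.any(axis=0).sum() == pytest.approx(190 / 4.0, abs=1)

    def test_all_zero_volume_gives_empty_map(self):
        amap = estimate_attenuation_map(np.zeros((16, 16, 8)), 4.0)
        assert np.all(amap.mu == 0)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            estimate_attenuation_map(np.ones((8, 8, 4)), 4.0, mode="magic")


class TestOSEM:
    def test_zero_projections_fixed_point(self, clean_scan):
        p = ProjectionSet(
            np.zeros_like(clean_scan.ph),
            np.zeros_like(clean_scan.ph),
            np.zeros_like(clean_scan.ph),
            clean_scan.angles,
            meta=dict(clean_scan.meta),
        )
        vol = osem(p, ReconSpec.for_method("IRNC", 120))
        assert np.all(vol.data == 0)

    def test_output_non_negative(self, realistic_scan):
        vol = osem(realistic_scan, ReconSpec.for_method("IRNC", 120))
        assert vol.data.min() >= 0

    def test_invalid_subset_count_rejected(self, clean_scan):
        with pytest.raises(ValueError, match="subsets"):
            osem(clean_scan, ReconSpec(method="IRNC", subsets=500))

    def test_em_likelihood_monotone_on_noiseless_data(self):
        # plain EM (1 subset) on a small instance: Poisson log-likelihood
        # of the fit must be non-decreasing over full iterations
        rng = np.random.default_rng(0)
        shape = (32, 32, 2)
        x_true = np.zeros(shape)
        x_true[10:22, 8:24, :] = 1.0
        x_true[14:18, 12:16, :] = 8.0
        angles = np.arange(0, 360, 12.0)
        projector = RotationProjector(shape, angles, 4.0)
        y = projector.forward(x_true)
        x = np.ones(shape)
        sens = projector.backward(np.ones_like(y))
        eps = 1e-12
        ll = []
        for _ in range(12):
            fp = projector.forward(x)
            with np.errstate(divide="ignore", invalid="ignore"):
                ll.append(float(np.sum(y * np.log(np.maximum(fp, eps)) - fp)))
            x = x * projector.backward(y / np.maximum(fp, eps)) / np.maximum(sens, eps)
        diffs = np.diff(ll)
        assert np.all(diffs > -1e-6 * np.abs(np.asarray(ll[:-1])))

    def test_convergence_on_clean_data(self, desk_spec, desk_phantom, clean_camera):
        scan = simulate_scan(desk_phantom, clean_camera, attenuation=False, noise=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vol = osem(
                scan, ReconSpec.for_method("IRNC", 120, butterworth_cutoff=1.2)
            )
        st = np.isin(desk_phantom.labels, STRIATAL_LABELS)
        bg = (desk_phantom.labels != OUTSIDE) & ~st
        sbr = vol.data[st].mean() / vol.data[bg].mean() - 1.0
        assert 8.5 <= sbr <= 9.5


class TestFBPAndDispatch:
    def test_uniform_phantom_stays_uniform(self, clean_camera):
        # default 2 mm grid: discretisation bias at 4 mm voxels is larger
        spec = PhantomSpec(filling_ratio=1.0)
        vol = build_phantom(spec)
        scan = simulate_scan(vol, clean_camera, attenuation=False, noise=False)
        recon = fbp(scan)
        st = np.isin(vol.labels, STRIATAL_LABELS)
        bg = (vol.labels != OUTSIDE) & ~st
        ratio = recon.data[st].mean() / recon.data[bg].mean()
        assert 0.95 <= ratio <= 1.05

    def test_angle_ordering_invariance(self, clean_scan):
        recon = fbp(clean_scan)
        perm = np.random.default_rng(0).permutation(len(clean_scan.angles))
        shuffled = ProjectionSet(
            clean_scan.ph[perm], clean_scan.sc_l[perm], clean_scan.sc_u[perm],
            clean_scan.angles[perm], meta=dict(clean_scan.meta),
        )
        recon2 = fbp(shuffled)
        assert np.allclose(recon.data, recon2.data, atol=1e-8)

    def test_acsc_equals_irnc_when_corrections_are_noops(self, clean_scan):
        # zero satellite windows: TEW is the identity, so OSEM on corrected
        # projections must match OSEM on the raw photopeak bin-for-bin
        spec = ReconSpec.for_method("IRNC", 120)
        a = osem(clean_scan, spec)
        b = osem(clean_scan, spec, projections=tew_correct(clean_scan))
        assert np.allclose(a.data, b.data)

    def test_unknown_method_rejected(self, clean_scan):
        with pytest.raises(ValueError, match="unknown method"):
            reconstruct_study(clean_scan, "OSEM3D")

    def test_provenance_recorded(self, realistic_scan):
        vol = reconstruct_study(realistic_scan, "ACSC")
        assert vol.meta["recon"] == "ACSC"
        assert vol.meta["attenuation_corrected"] is True
        assert vol.meta["tew_corrected"] is True

    def test_irac_raises_central_intensity(self, desk_spec, desk_phantom, default_camera):
        scan = simulate_scan(desk_phantom, default_camera, seed=21)
        scan.meta["study_type"] = "phantom"
        irnc = reconstruct_study(scan, "IRNC")
        irac = reconstruct_study(scan, "IRAC")
        centre = np.s_[24:40, 24:40, 12:20]
        edge = desk_phantom.labels == 7  # rim
        ratio_irnc = irnc.data[centre].mean() / irnc.data[edge].mean()
        ratio_irac = irac.data[centre].mean() / irac.data[edge].mean()
        assert ratio_irac > ratio_irnc
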