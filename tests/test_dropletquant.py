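"""Droplet segmentation, partition coefficients, dye corrections, and FRAP."""

import numpy as np
import pytest
from skimage.filters import threshold_otsu

from phasekit import dropletquant as dq
from phasekit import synthetic_data as synth
from phasekit.synthetic_data import DropletSpec


def brute_force_otsu(image: np.ndarray) -> float:
    """Exhaustive intra-class variance minimizer over all observed levels."""
    levels = np.unique(image)
    best_t, best_var = levels[0], np.inf
    for t in levels[:-1]:
        lo, hi = image[image <= t], image[image > t]
        w_lo, w_hi = lo.size / image.size, hi.size / image.size
        var = w_lo * lo.var() + w_hi * hi.var()
        if var < best_var:
            best_t, best_var = t, var
    return float(best_t)


class TestDyeCorrection:
    wavelengths = np.linspace(650, 800, 151)

    def _gaussian_spectrum(self, scale):
        return scale * np.exp(-((self.wavelengths - 700.0) ** 2) / (2 * 30.0**2))

    def test_viscosity_independent_spectra_give_unity(self):
        spectra = [self._gaussian_spectrum(1.0) for _ in range(4)]
        corr = dq.dye_correction_from_spectra(
            self.wavelengths, spectra, [1e-3, 0.1, 0.5, 1.0], bandpass_nm=(650, 800)
        )
        assert corr.c_corr == pytest.approx(1.0)

    def test_plateau_value_recovered(self):
        # integrated emission ramps up and plateaus at 1.43x the water value
        scales = {1e-3: 1.0, 0.05: 1.2, 0.5: 1.43, 1.0: 1.43, 5.0: 1.43}
        corr = dq.dye_correction_from_spectra(
            self.wavelengths,
            [self._gaussian_spectrum(s) for s in scales.values()],
            list(scales.keys()),
            bandpass_nm=(650, 800),
            dye="AF647",
        )
        assert corr.c_corr == pytest.approx(1.43, rel=1e-6)

    def test_no_spectrum_above_floor_rejected(self):
        with pytest.raises(ValueError, match="floor"):
            dq.dye_correction_from_spectra(
                self.wavelengths, [self._gaussian_spectrum(1.0)], [1e-3], bandpass_nm=(650, 800)
            )

    def test_published_presets(self):
        assert dq.DYE_CORRECTIONS["AF488"].c_corr == 0.73
        assert dq.DYE_CORRECTIONS["AF647"].c_corr == 1.43


class TestSegmentation:
    def test_speckle_only_image_yields_no_objects(self, rng):
        """Isolated hot pixels are below the 2-µm size filter."""
        img = np.full((128, 128), 100.0)
        hot = rng.integers(0, 128, size=(20, 2))
        img[hot[:, 0], hot[:, 1]] = 1000.0
        res = dq.segment_droplets(dq.FluorescenceImage(img, pixel_size_um=0.2))
        assert res.n_objects == 0

    def test_size_filter_keeps_only_large_disks(self):
        droplets = [
            DropletSpec(10, 10, 2.0), DropletSpec(10, 30, 2.0), DropletSpec(10, 44, 2.5),
            DropletSpec(30, 10, 2.0), DropletSpec(30, 30, 2.0),
            DropletSpec(44, 44, 0.5), DropletSpec(44, 20, 0.5), DropletSpec(40, 5, 0.5),
        ]
        images, _, _ = synth.gen_droplet_images(
            droplets, {"AF647": {"pc": 10, "c_corr": 1.0}}, pixel_size_um=0.2
        )
        res = dq.segment_droplets(images["AF647"], min_diameter_um=2.0)
        assert res.n_objects == 5
        assert np.all(res.diameters_um > 2.0)

    def test_otsu_matches_brute_force_minimizer(self, rng):
        # 64 integer grey levels, histogrammed at the same resolution
        img = rng.integers(0, 32, size=(64, 64)).astype(float)
        img[20:44, 20:44] = rng.integers(32, 64, size=(24, 24))
        t_skimage = threshold_otsu(img, nbins=64)
        t_brute = brute_force_otsu(img)
        # both thresholds must induce the same binary classification
        assert np.array_equal(img > t_skimage, img > t_brute)

    def test_count_non_increasing_in_min_diameter(self):
        droplets = [DropletSpec(10, 10, 1.0), DropletSpec(25, 25, 2.0), DropletSpec(40, 40, 4.0)]
        images, _, _ = synth.gen_droplet_images(
            droplets, {"AF647": {"pc": 10, "c_corr": 1.0}}, pixel_size_um=0.2
        )
        counts = [
            dq.segment_droplets(images["AF647"], min_diameter_um=d).n_objects
            for d in (0.5, 2.0, 5.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_constant_image_has_no_threshold(self):
        with pytest.raises(ValueError, match="no threshold"):
            dq.segment_droplets(dq.FluorescenceImage(np.ones((32, 32)), pixel_size_um=0.2))


class TestPartitionCoefficient:
    def _setup(self, pc=25.0, c_corr=1.43, poisson=False, seed=0):
        droplets = [DropletSpec(12, 12, 3.0), DropletSpec(32, 32, 4.0)]
        images, buffer, truth = synth.gen_droplet_images(
            droplets,
            {"AF647": {"pc": pc, "c_corr": c_corr}},
            pixel_size_um=0.2,
            poisson_noise=poisson,
            seed=seed,
        )
        seg = dq.segment_droplets(images["AF647"])
        return images["AF647"], seg, buffer

    def test_methods_formula_hand_arithmetic(self):
        """PC = [(I_DP − I_bkrd)/c_corr]/(I_LP − I_bkrd): 900/100/10 at c_corr 1.43 → 6.915."""
        data = np.full((100, 100), 100.0)
        yy, xx = np.indices(data.shape)
        data[(yy - 30) ** 2 + (xx - 30) ** 2 <= 15**2] = 900.0
        img = dq.FluorescenceImage(data, pixel_size_um=0.2, channel="AF647")
        seg = dq.segment_droplets(img)
        buffer = dq.FluorescenceImage(np.full((100, 100), 10.0), pixel_size_um=0.2)
        corr = dq.DyeCorrection(dye="AF647", bandpass_nm=(650, 800), c_corr=1.43)
        res = dq.partition_coefficient(img, seg, buffer, corr)
        assert (res.i_dp, res.i_lp, res.i_bkrd) == (900.0, 100.0, 10.0)
        assert res.pc == pytest.approx(((900 - 10) / 1.43) / (100 - 10))
        assert res.pc == pytest.approx(6.915, abs=5e-4)

    def test_noiseless_forward_inverse_identity(self):
        img, seg, buffer = self._setup(pc=25.0, c_corr=1.43)
        res = dq.partition_coefficient(img, seg, buffer, dq.DYE_CORRECTIONS["AF647"])
        assert res.pc == pytest.approx(25.0, rel=1e-12)

    def test_uniform_intensity_gives_unit_pc(self):
        """I_DP = I_LP with c_corr = 1 and I_bkrd = 0 must give PC = 1.

        The mask comes from a visible channel; the measured channel is flat.
        """
        img, seg, buffer = self._setup(pc=25.0, c_corr=1.43)
        flat = dq.FluorescenceImage(np.full_like(img.data, 110.0), pixel_size_um=0.2)
        zero_buffer = dq.FluorescenceImage(np.zeros_like(buffer.data), pixel_size_um=0.2)
        corr = dq.DyeCorrection(dye="x", bandpass_nm=(0, 1), c_corr=1.0)
        res = dq.partition_coefficient(flat, seg, zero_buffer, corr)
        assert res.pc == pytest.approx(1.0)

    def test_poisson_noise_recovery_within_5_percent(self):
        img, seg, buffer = self._setup(pc=25.0, c_corr=1.43, poisson=True, seed=3)
        res = dq.partition_coefficient(img, seg, buffer, dq.DYE_CORRECTIONS["AF647"])
        assert res.pc == pytest.approx(25.0, rel=0.05)

    def test_scale_invariance(self):
        img, seg, buffer = self._setup()
        res1 = dq.partition_coefficient(img, seg, buffer, dq.DYE_CORRECTIONS["AF647"])
        scaled_img = dq.FluorescenceImage(img.data * 7.5, pixel_size_um=0.2, channel="AF647")
        scaled_buf = dq.FluorescenceImage(buffer.data * 7.5, pixel_size_um=0.2)
        res2 = dq.partition_coefficient(scaled_img, seg, scaled_buf, dq.DYE_CORRECTIONS["AF647"])
        assert res2.pc == pytest.approx(res1.pc, rel=1e-12)

    def test_mask_from_one_channel_applies_to_other(self):
        """Mask computed on the high-SNR channel transfers unchanged."""
        droplets = [DropletSpec(12, 12, 3.0), DropletSpec(32, 32, 4.0)]
        images, buffer, _ = synth.gen_droplet_images(
            droplets,
            {"AF647": {"pc": 25, "c_corr": 1.43}, "AF488": {"pc": 5, "c_corr": 0.73}},
            pixel_size_um=0.2,
        )
        seg = dq.segment_droplets(images["AF647"])  # mask channel
        res = dq.partition_coefficient(images["AF488"], seg, buffer, dq.DYE_CORRECTIONS["AF488"])
        assert res.pc == pytest.approx(5.0, rel=1e-12)

    def test_light_phase_roi_avoids_droplets(self):
        _, seg, _ = self._setup()
        roi = dq.place_light_phase_roi(seg)
        assert not roi[seg.mask].any()

    def test_light_phase_below_background_rejected(self):
        img, seg, _ = self._setup()
        bright_buffer = dq.FluorescenceImage(
            np.full_like(img.data, 1e6), pixel_size_um=0.2
        )
        with pytest.raises(ValueError, match="light phase"):
            dq.partition_coefficient(img, seg, bright_buffer, dq.DYE_CORRECTIONS["AF647"])


class TestFrap:
    def test_flat_post_bleach_trace_is_immobile(self):
        trace, _ = synth.gen_frap(mobile_fraction=0.0, tau_s=3.0)
        fit = dq.fit_frap(trace)
        assert fit.converged
        assert fit.mobile_fraction == pytest.approx(0.0, abs=1e-6)

    def test_noiseless_full_recovery_closed_form(self):
        trace, _ = synth.gen_frap(mobile_fraction=1.0, tau_s=5.0, n_post=120, dt_s=0.5)
        fit = dq.fit_frap(trace)
        assert fit.mobile_fraction == pytest.approx(1.0, abs=1e-6)
        assert fit.half_time_s == pytest.approx(5.0 * np.log(2), abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 5, 11])
    def test_noisy_recovery_within_10_percent(self, seed):
        trace, _ = synth.gen_frap(
            mobile_fraction=0.8, tau_s=3.0, noise_sigma=0.02,
            n_post=200, dt_s=0.2, seed=seed,
        )
        fit = dq.fit_frap(trace)
        assert fit.mobile_fraction == pytest.approx(0.8, rel=0.10)
        assert fit.tau_s == pytest.approx(3.0, rel=0.10)

    def test_pre_bleach_permutation_invariant(self, rng):
        trace, _ = synth.gen_frap(mobile_fraction=0.6, tau_s=2.0, noise_sigma=0.01, seed=8)
        fit1 = dq.fit_frap(trace)
        perm = np.arange(trace.bleach_index)
        rng.shuffle(perm)
        shuffled = dq.FrapTrace(
            time_s=trace.time_s,
            intensity=np.concatenate([trace.intensity[perm], trace.intensity[trace.bleach_index:]]),
            bleach_index=trace.bleach_index,
        )
        fit2 = dq.fit_frap(shuffled)
        assert fit2.mobile_fraction == pytest.approx(fit1.mobile_fraction)

    def test_too_few_frames_rejected(self):
        trace, _ = synth.gen_frap(mobile_fraction=0.5, tau_s=1.0, n_pre=2)
        with pytest.raises(ValueError):
            dq.fit_frap(trace)
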