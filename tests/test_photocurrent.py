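import numpy as np
import pytest

from pvretina import photocurrent as pc
from pvretina.constants import ELEMENTARY_CHARGE_C
from pvretina.plasmonics import NanoparticleSpec, cross_section_spectrum


class TestBareLayer:
    def test_absorption_coefficient(self):
        assert pc.absorption_coefficient(0.0, 500.0) == 0.0
        assert pc.absorption_coefficient(0.105, 500.0) == pytest.approx(
            4 * np.pi * 0.105 / 500e-9, rel=1e-12
        )
        assert pc.absorption_coefficient(0.1, 1000.0) == pytest.approx(
            0.5 * pc.absorption_coefficient(0.1, 500.0)
        )

    def test_dark_layer_generates_nothing(self, base_layer):
        assert pc.generation_rate(base_layer, pc.IlluminationSpec(500.0, 0.0)) == 0.0

    def test_generation_linear_in_intensity(self, base_layer):
        g1 = pc.generation_rate(base_layer, pc.IlluminationSpec(550.0, 0.2))
        g2 = pc.generation_rate(base_layer, pc.IlluminationSpec(550.0, 0.4))
        assert g2 == pytest.approx(2.0 * g1, rel=1e-12)

    def test_generation_consistent_with_jsc(self, base_layer):
        # G = Jsc / (q L) at the calibration anchor
        light = pc.IlluminationSpec(500.0, 0.26)
        g = pc.generation_rate(base_layer, light)
        assert g == pytest.approx(22.0 / (ELEMENTARY_CHARGE_C * 100e-9), rel=1e-9)

    @pytest.mark.parametrize(
        "wavelength,intensity,expected",
        [
            (500.0, 0.26, 22.0),
            (610.0, 0.26, 3.1),
            (610.0, 0.38, (0.38 / 0.26) * 3.1),
        ],
    )
    def test_jsc_anchors(self, base_layer, wavelength, intensity, expected):
        jsc = pc.jsc_bare(base_layer, pc.IlluminationSpec(wavelength, intensity))
        assert jsc == pytest.approx(expected, rel=1e-9)

    def test_scaled_intensity_anchors_near_printed(self, base_layer):
        # the reported 0.38 mW/mm^2 pair (34, 4.5) deviates <= 6% from linearity
        j500 = pc.jsc_bare(base_layer, pc.IlluminationSpec(500.0, 0.38))
        j610 = pc.jsc_bare(base_layer, pc.IlluminationSpec(610.0, 0.38))
        assert j500 == pytest.approx(34.0, rel=0.06)
        assert j610 == pytest.approx(4.5, rel=0.06)

    def test_wavelength_outside_blend_rejected(self, base_layer):
        from pvretina.materials import RangeError

        with pytest.raises(RangeError):
            pc.jsc_bare(base_layer, pc.IlluminationSpec(900.0, 0.26))


class TestVolumeRatios:
    def test_geometric_cross_section_maps_to_unity(self):
        r = 10.0
        v1, v2 = pc.effective_volume_ratios(np.pi * r**2, 4 * np.pi * r**2, r)
        assert v1 == pytest.approx(1.0)
        assert v2 == pytest.approx(8.0)  # r_scat = 2r

    def test_equals_q_abs_to_three_halves(self, np10):
        s = cross_section_spectrum(np10)
        v1, _ = pc.effective_volume_ratios(s.c_abs_nm2, s.c_scat_nm2, 10.0)
        assert np.allclose(v1, s.q_abs**1.5, rtol=1e-12)


class TestPlasmonicJsc:
    def test_fs_zero_reduces_to_bare(self, base_layer, np10, gain_r10):
        layer = pc.PlasmonicLayerSpec(base_layer, np10, 0.0, gain=gain_r10)
        light = pc.IlluminationSpec(610.0, 0.26)
        assert pc.jsc_plasmonic(layer, light) == pytest.approx(
            pc.jsc_bare(base_layer, light), rel=1e-15
        )

    def test_affine_in_filling_fraction(self, base_layer, np10, gain_r10):
        light = pc.IlluminationSpec(610.0, 0.26)
        js = [
            pc.jsc_plasmonic(
                pc.PlasmonicLayerSpec(base_layer, np10, fs, gain=gain_r10), light
            )
            for fs in (0.05, 0.10, 0.15)
        ]
        assert js[2] - js[1] == pytest.approx(js[1] - js[0], rel=1e-9)

    def test_linear_in_intensity(self, base_layer, np10, gain_r10):
        layer = pc.PlasmonicLayerSpec(base_layer, np10, 0.15, gain=gain_r10)
        j1 = pc.jsc_plasmonic(layer, pc.IlluminationSpec(610.0, 0.13))
        j2 = pc.jsc_plasmonic(layer, pc.IlluminationSpec(610.0, 0.26))
        assert j2 == pytest.approx(2.0 * j1, rel=1e-9)

    @pytest.mark.parametrize("fs,printed", [(0.10, 35.0), (0.15, 51.0), (0.20, 67.0)])
    def test_reported_triple_reproduced(self, base_layer, np10, gain_r10, fs, printed):
        layer = pc.PlasmonicLayerSpec(base_layer, np10, fs, gain=gain_r10)
        jsc = pc.jsc_plasmonic(layer, pc.IlluminationSpec(610.0, 0.26))
        assert abs(jsc - printed) < 1.0

    def test_fs_cap_enforced(self, base_layer, np10, gain_r10):
        with pytest.raises(ValueError, match="cap"):
            pc.PlasmonicLayerSpec(base_layer, np10, 0.25, gain=gain_r10)
        pc.PlasmonicLayerSpec(
            base_layer, np10, 0.25, gain=gain_r10, allow_unsafe_fs=True
        )

    def test_occupancy_violation_raises_then_clips(self, base_layer, np10, gain_r10):
        light = pc.IlluminationSpec(610.0, 0.26)
        layer = pc.PlasmonicLayerSpec(
            base_layer, np10, 0.30, gain=gain_r10, allow_unsafe_fs=True
        )
        with pytest.raises(pc.OccupancyError):
            pc.jsc_plasmonic(layer, light)
        clipped = pc.PlasmonicLayerSpec(
            base_layer, np10, 0.30, gain=gain_r10, allow_unsafe_fs=True,
            clip_occupancy=True,
        )
        with pytest.warns(UserWarning, match="clipped"):
            j = pc.jsc_plasmonic(clipped, light)
        assert j > 0

    def test_derived_mode_overshoots_reported_currents(self, base_layer, np10):
        # bulk-gold alpha2 is documented as non-reproducing (order-of-magnitude high)
        layer = pc.PlasmonicLayerSpec(base_layer, np10, 0.15, alpha2_mode="derived")
        j = pc.jsc_plasmonic(layer, pc.IlluminationSpec(610.0, 0.26))
        assert j > 3.0 * 51.0


class TestCalibrateKappa:
    LIGHT = pc.IlluminationSpec(610.0, 0.26)

    def test_printed_triple(self, base_layer, np10):
        gain, diag = pc.calibrate_kappa(
            pc.TRIPLE_R10_I026, self.LIGHT, base_layer, np10
        )
        assert diag["max_abs_residual_a_m2"] < 1.0
        # raw OLS on the printed points: slope 320 A/m^2 per unit fs, intercept 3
        assert diag["raw_affine_slope_a_m2"] == pytest.approx(320.0, abs=1e-9)
        assert diag["raw_affine_intercept_a_m2"] == pytest.approx(3.0, abs=1e-9)
        assert gain.kappa_per_m > 0

    def test_perfect_affine_data_zero_residuals(self, base_layer, np10, gain_r10):
        light = self.LIGHT
        data = []
        for fs in (0.10, 0.15, 0.20):
            layer = pc.PlasmonicLayerSpec(base_layer, np10, fs, gain=gain_r10)
            data.append((fs, pc.jsc_plasmonic(layer, light)))
        gain, diag = pc.calibrate_kappa(data, light, base_layer, np10)
        assert diag["max_abs_residual_a_m2"] == pytest.approx(0.0, abs=1e-9)
        assert gain.kappa_per_m == pytest.approx(gain_r10.kappa_per_m, rel=1e-9)

    def test_rank_deficiency(self, base_layer, np10):
        with pytest.raises(pc.RankDeficiencyError):
            pc.calibrate_kappa(
                [(0.1, 35.0), (0.1, 36.0)], self.LIGHT, base_layer, np10
            )

    def test_r10_calibration_predicts_r75_triple_at_038(self, base_layer, gain_r10):
        # intensity re-scaling x(0.38/0.26) plus S(lambda, r) size scaling
        np75 = NanoparticleSpec.packaged(7.5)
        light = pc.IlluminationSpec(610.0, 0.38)
        for fs, printed in pc.TRIPLE_R75_I038:
            layer = pc.PlasmonicLayerSpec(base_layer, np75, fs, gain=gain_r10)
            assert pc.jsc_plasmonic(layer, light) == pytest.approx(printed, rel=0.05)

    def test_parameter_recovery_with_noise(self, base_layer, np10, gain_r10):
        """kappa* is recovered within 3 SE (known sigma) in >= 95% of replicates."""
        rng = np.random.default_rng(17)
        light = self.LIGHT
        kappa_star = gain_r10.kappa_per_m
        fs_arr = np.array([0.10, 0.15, 0.20])
        sigma = 0.5
        clean = np.array(
            [
                pc.jsc_plasmonic(
                    pc.PlasmonicLayerSpec(base_layer, np10, fs, gain=gain_r10), light
                )
                for fs in fs_arr
            ]
        )
        pre = pc._prefactor(light.intensity_w_m2, 610.0, 100.0)
        se_known = sigma / (pre * np.sqrt(np.sum(fs_arr**2)))
        hits = 0
        for _ in range(200):
            noisy = clean + rng.normal(0.0, sigma, size=3)
            gain, _ = pc.calibrate_kappa(
                list(zip(fs_arr, noisy)), light, base_layer, np10
            )
            if abs(gain.kappa_per_m - kappa_star) <= 3.0 * se_known:
                hits += 1
        assert hits >= 190  # 95% of 200


class TestJscSpectrum:
    def test_bare_spectrum_single_peak_near_500(self, base_layer, np10, gain_r10):
        layer = pc.PlasmonicLayerSpec(base_layer, np10, 0.0, gain=gain_r10)
        df = pc.jsc_spectrum(layer, 0.26)
        j = df["jsc_A_per_m2"].to_numpy()
        interior_max = df["wavelength_nm"].to_numpy()[np.argmax(j)]
        assert abs(interior_max - 500.0) <= 4.0
        from scipy.signal import argrelmax

        assert len(argrelmax(j)[0]) == 1

    def test_loaded_spectrum_has_blend_and_lspr_peaks(self, base_layer, gain_r10):
        from scipy.signal import argrelmax

        for r in (7.5, 10.0):
            layer = pc.PlasmonicLayerSpec(
                base_layer, NanoparticleSpec.packaged(r), 0.15, gain=gain_r10
            )
            df = pc.jsc_spectrum(layer, 0.26)
            wl = df["wavelength_nm"].to_numpy()
            peaks = wl[argrelmax(df["jsc_A_per_m2"].to_numpy())[0]]
            assert any(abs(p - 500.0) <= 10.0 for p in peaks)
            assert any(abs(p - 610.0) <= 10.0 for p in peaks)

    def test_500nm_current_non_increasing_in_fs(self, base_layer, np10, gain_r10):
        vals = []
        for fs in (0.0, 0.10, 0.15, 0.20):
            layer = pc.PlasmonicLayerSpec(base_layer, np10, fs, gain=gain_r10)
            df = pc.jsc_spectrum(layer, 0.26, np.array([500.0]))
            vals.append(df["jsc_A_per_m2"].iloc[0])
        assert np.all(np.diff(vals) <= 0)

    def test_small_particles_need_max_loading_for_lspr_gain(self, base_layer, gain_r10):
        # at r = 5 nm the 610 nm enhancement over 500 nm appears only at fs = 20%
        np5 = NanoparticleSpec.packaged(5.0)
        grid = np.array([500.0, 610.0])
        ratios = {}
        for fs in (0.10, 0.20):
            layer = pc.PlasmonicLayerSpec(base_layer, np5, fs, gain=gain_r10)
            j = pc.jsc_spectrum(layer, 0.26, grid)["jsc_A_per_m2"].to_numpy()
            ratios[fs] = j[1] / j[0]
        assert ratios[0.10] < 1.0 < ratios[0.20]
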