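"""Forward model: lattice transform, pixel intensities, background, noise."""
import numpy as np
import pytest

import spreadsim as sp
from spreadsim.crystal import mosaic_ensemble, random_orientation
from spreadsim.curves import HC_EV_ANGSTROM, make_grid
from spreadsim.detector import DetectorPanel, pixel_to_s1, polarization_factor, solid_angle
from spreadsim.sfcalc import build_sfset
from spreadsim.simulate import (SimulationConfig, add_noise, background_model,
                                calibration_pattern, f_latt_sq, fractional_hkl,
                                simulate_image)
from spreadsim.spectrum import SASESpectrum

from conftest import toy_config


class TestFLattSq:
    def test_laue_peak_value(self):
        assert f_latt_sq(np.zeros(3), 10, 12, 15) == pytest.approx((10 * 12 * 15) ** 2)

    def test_half_maximum_of_f_latt(self):
        # F_latt (not squared) falls to half at |dx| = sqrt(0.63 ln 2) ~ 0.661
        na = 10
        dx = np.sqrt(0.63 * np.log(2.0))
        val = f_latt_sq(np.array([dx / na, 0, 0]), na, na, na)
        peak = f_latt_sq(np.zeros(3), na, na, na)
        assert np.sqrt(val / peak) == pytest.approx(0.5, rel=1e-12)

    def test_fwhm_matches_grating_function(self):
        # the 0.63 constant makes the Gaussian peak width match the
        # rectangular-domain grating function sin^2(pi N x)/sin^2(pi x)
        N = 10
        x = np.linspace(1e-9, 0.5, 200_000)
        grating = (np.sin(np.pi * N * x) / np.sin(np.pi * x)) ** 2
        half = N ** 2 / 2
        fwhm_grating = 2 * x[np.argmax(grating < half)]
        gauss = f_latt_sq(np.stack([x, np.zeros_like(x), np.zeros_like(x)], axis=-1),
                          N, N, N) / float(N) ** 6
        fwhm_gauss = 2 * x[np.argmax(gauss < 0.5)]
        assert abs(fwhm_gauss - fwhm_grating) / fwhm_grating < 0.15

    def test_invalid_domain_counts(self):
        with pytest.raises(ValueError):
            f_latt_sq(np.zeros(3), 0, 5, 5)


class TestFractionalHkl:
    def test_laue_condition_gives_integers(self):
        cell = sp.UnitCell(10, 12, 14)
        o = random_orientation(cell, seed=3)
        h_int = np.array([2.0, -1.0, 3.0])
        q = o.A_star @ h_int
        lam = 1.5
        s0 = np.array([0, 0, 1.0]) / lam
        s1 = s0 + q
        h = fractional_hkl(o.A_star, s0, s1)
        assert np.allclose(h, h_int, atol=1e-10)

    def test_frame_invariance(self):
        from scipy.spatial.transform import Rotation
        cell = sp.UnitCell(10, 12, 14)
        o = random_orientation(cell, seed=4)
        s0 = np.array([0, 0, 1.0]) / 1.7
        s1 = s0 + o.A_star @ np.array([1.0, 2.0, -1.0])
        R = Rotation.from_euler("zyx", [20, -10, 5], degrees=True).as_matrix()
        h1 = fractional_hkl(o.A_star, s0, s1)
        h2 = fractional_hkl(R @ o.A_star, R @ s0, R @ s1)
        assert np.allclose(h1, h2, atol=1e-9)

    def test_singular_matrix_rejected(self):
        with pytest.raises(ValueError):
            fractional_hkl(np.zeros((3, 3)), np.zeros(3), np.ones(3))


class TestBackground:
    PANEL = DetectorPanel(n_fast=64, n_slow=64, pixel_size=0.11, distance=3.0,
                          beam_center=(32.0, 32.0))

    def test_zero_paths_zero(self):
        fast, slow = np.arange(64), np.full(64, 32)
        bg = background_model(self.PANEL, fast, slow, water_path_um=0.0,
                              air_path_mm=0.0)
        assert np.allclose(bg, 0.0)

    def test_water_ring_peaks_in_3_to_4_A_band(self):
        from spreadsim.detector import pixel_resolution
        fast = np.arange(33, 64)
        slow = np.full_like(fast, 32)
        bg = background_model(self.PANEL, fast, slow, air_path_mm=0.0)
        d = pixel_resolution(self.PANEL, fast, slow, 7122.0)
        # normalize out the geometric factors to isolate the water curve
        geom = (polarization_factor(self.PANEL, fast, slow)
                * solid_angle(self.PANEL, fast, slow))
        curve = bg / geom
        assert 3.0 <= d[np.argmax(curve)] <= 4.0

    def test_linear_in_photons_and_path(self):
        fast, slow = np.array([40]), np.array([32])
        b1 = background_model(self.PANEL, fast, slow, total_photons=1e12)
        b2 = background_model(self.PANEL, fast, slow, total_photons=2e12)
        assert b2[0] == pytest.approx(2 * b1[0])
        w1 = background_model(self.PANEL, fast, slow, water_path_um=100, air_path_mm=0)
        w2 = background_model(self.PANEL, fast, slow, water_path_um=200, air_path_mm=0)
        assert w2[0] == pytest.approx(2 * w1[0])


class TestNoise:
    PANEL = DetectorPanel(n_fast=32, n_slow=32, pixel_size=0.11, distance=3.0,
                          beam_center=(16.0, 16.0))

    def _image(self, lam):
        from spreadsim.simulate import SimulatedImage
        return SimulatedImage(photons=np.full((32, 32), float(lam)))

    def test_zero_expectation_zero_counts(self):
        img = add_noise(self._image(0.0), self.PANEL, seed=1, panel_seed=2)
        assert (img.counts == 0).all()

    def test_poisson_mean_within_3_sigma(self):
        lam = 500.0
        img = add_noise(self._image(lam), self.PANEL, seed=3, panel_seed=4,
                        calibration=False)
        n = img.counts.size
        assert abs(img.counts.mean() - lam) < 3 * np.sqrt(lam / n)

    def test_calibration_pattern_fixed_across_shots(self):
        a = add_noise(self._image(1000.0), self.PANEL, seed=1, panel_seed=7)
        b = add_noise(self._image(1000.0), self.PANEL, seed=2, panel_seed=7)
        # different Poisson draws, identical fixed-pattern factors
        assert not np.array_equal(a.counts, b.counts)
        assert np.array_equal(calibration_pattern(self.PANEL, 7),
                              calibration_pattern(self.PANEL, 7))

    def test_calibration_sd_is_one_percent(self):
        pat = calibration_pattern(DetectorPanel(), 11)
        assert pat.std() == pytest.approx(0.01, rel=0.02)
        assert pat.mean() == pytest.approx(1.0, abs=1e-4)


class TestSimulateImage:
    @pytest.fixture(scope="class")
    def tiny(self):
        """Small crystal, small panel, 5-channel grid, one domain."""
        rng = np.random.default_rng(5)
        cell = sp.UnitCell(15.0, 12.0, 10.0)
        grid = make_grid(5, 7100, 7150)
        atoms = [sp.AtomSite("C", tuple(rng.uniform(0, 1, 3)), b_iso=8.0)
                 for _ in range(4)]
        atoms.append(sp.AtomSite("Fe", (0.3, 0.4, 0.3), b_iso=8.0,
                                 is_refinable_metal=True))
        hkl = sp.generate_hkl(cell, 2.0, 5.0, anomalous=True)
        sfset = build_sfset(atoms, hkl, cell, grid)
        fp = np.full((1, 5), -5.0)
        fdp = np.full((1, 5), 3.0)
        panel = DetectorPanel(n_fast=200, n_slow=200, pixel_size=0.11,
                              distance=18.0, beam_center=(100.0, 100.0))
        # orient the crystal so that reflection (5, 1, 1) meets the Laue
        # condition exactly at the active channel's energy
        from scipy.spatial.transform import Rotation
        from spreadsim.crystal import Orientation, reciprocal_B
        grid5 = make_grid(5, 7100, 7150)
        lam2 = grid5.wavelengths[2]
        B = reciprocal_B(cell)
        h_sel = np.array([3.0, 1.0, 1.0])
        q0 = B @ h_sel
        qn = np.linalg.norm(q0)
        qz = -qn ** 2 * lam2 / 2.0
        q_target = np.array([-np.sqrt(qn ** 2 - qz ** 2), 0.0, qz])
        R, _ = Rotation.align_vectors([q_target / qn], [q0 / qn])
        orientation = Orientation(R.as_matrix(), B, cell)
        ensemble = mosaic_ensemble(0.05, 1, seed=1)
        config = SimulationConfig(d_eff_nm=30.0, n_domains=1,
                                  include_background=False,
                                  apply_poisson=False, apply_calibration=False)
        flu = np.zeros(5)
        flu[2] = 1e12
        spectrum = SASESpectrum(grid, flu)
        return config, panel, orientation, ensemble, spectrum, sfset, fp, fdp

    def test_zero_fluence_background_only(self, tiny):
        config, panel, orientation, ensemble, spectrum, sfset, fp, fdp = tiny
        from dataclasses import replace
        cfg = replace(config, include_background=True)
        empty = SASESpectrum(spectrum.grid, np.zeros(5))
        img = simulate_image(cfg, panel, orientation, ensemble, empty, sfset,
                             fp, fdp, seed=1)
        assert np.allclose(img.photons, 0.0)  # background scales with photons

    def test_linearity_in_fluence(self, tiny):
        config, panel, orientation, ensemble, spectrum, sfset, fp, fdp = tiny
        img1 = simulate_image(config, panel, orientation, ensemble, spectrum,
                              sfset, fp, fdp, seed=1)
        doubled = SASESpectrum(spectrum.grid, 2 * spectrum.fluence)
        img2 = simulate_image(config, panel, orientation, ensemble, doubled,
                              sfset, fp, fdp, seed=1)
        assert np.allclose(img2.photons, 2 * img1.photons, rtol=1e-12)

    def test_matches_scalar_reference_implementation(self, tiny):
        config, panel, orientation, ensemble, spectrum, sfset, fp, fdp = tiny
        img = simulate_image(config, panel, orientation, ensemble, spectrum,
                             sfset, fp, fdp, seed=1)
        # independent scalar implementation of the kinematic pixel sum
        na, nb, nc = config.domain_cells(sfset.cell)
        w = config.volume_weight(sfset.cell, 1)
        I = sfset.intensities(fp, fdp)
        lam_ch = spectrum.grid.wavelengths
        AD = ensemble.rotations[0] @ orientation.A_star
        inv_AD = np.linalg.inv(AD)
        checked = 0
        rng = np.random.default_rng(0)
        for fast in rng.integers(0, 200, 60):
            for slow in rng.integers(0, 200, 1):
                expected = 0.0
                for c in range(5):
                    if spectrum.fluence[c] == 0:
                        continue
                    s1 = pixel_to_s1(panel, float(fast), float(slow)) / lam_ch[c]
                    s0 = np.array([0, 0, 1.0]) / lam_ch[c]
                    S = s1 - s0
                    h = np.linalg.solve(orientation.A_star, S)
                    h0 = np.rint(h).astype(int)
                    idx = sfset.lookup(h0)
                    if idx is None:
                        continue
                    dh = np.linalg.solve(AD, S) - h0
                    dx2 = (dh[0] * na) ** 2 + (dh[1] * nb) ** 2 + (dh[2] * nc) ** 2
                    flatt2 = (na * nb * nc) ** 2 * np.exp(-2 * dx2 / 0.63)
                    P = polarization_factor(panel, float(fast), float(slow))
                    dO = solid_angle(panel, float(fast), float(slow))
                    expected += (config.r_e_m ** 2 * P * dO * w
                                 * spectrum.fluence[c] / 1e-12 * I[idx, c] * flatt2)
                got = img.photons[slow, fast]
                if expected > 1e-12 or got > 1e-12:
                    assert got == pytest.approx(expected, rel=1e-9)
                    checked += 1
        assert checked > 0

    def test_deterministic_with_seeds(self, toy_system):
        fxa = sp.make_fixture(toy_system, n_images=2, seed=77, config=toy_config())
        fxb = sp.make_fixture(toy_system, n_images=2, seed=77, config=toy_config())
        assert len(fxa.boxes) == len(fxb.boxes)
        for a, b in zip(fxa.boxes, fxb.boxes):
            assert a.h0 == b.h0 and a.bounds == b.bounds
            assert np.array_equal(a.counts, b.counts)

    def test_streak_centroid_moves_inward_with_energy(self, tiny):
        # Bragg's law: higher-energy photons diffract to smaller radius
        config, panel, orientation, ensemble, _, sfset, fp, fdp = tiny
        grid = make_grid(5, 7100, 7150)
        radii = {}
        for c in (0, 4):
            flu = np.zeros(5)
            flu[c] = 1e12
            img = simulate_image(config, panel, orientation, ensemble,
                                 SASESpectrum(grid, flu), sfset, fp, fdp, seed=1)
            tot = img.photons.sum()
            if tot == 0:
                continue
            slow, fast = np.mgrid[0:200, 0:200]
            x = (fast + 0.5 - 100.0)
            y = (slow + 0.5 - 100.0)
            r = np.sqrt(x ** 2 + y ** 2)
            # centroid radius of the brightest spot region
            m = img.photons > 0.01 * img.photons.max()
            radii[c] = float((r[m] * img.photons[m]).sum() / img.photons[m].sum())
        if len(radii) == 2:
            assert radii[4] < radii[0]
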