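"""Kinematic forward model: photons per pixel for polychromatic still shots.

For each pixel i the expected Bragg signal is the energy-channel sum

    I_i = r_e^2 P_i dOmega_i sum_c J0(c) |F_true(c; h0)|^2 sum_D F_latt^2[S(c)]

with J0 the incident fluence (photons per channel per m^2), F_true the
unit-cell structure factor at the nearest integer Miller index h0, and
F_latt the transform of the finite mosaic domain, modelled as a Gaussian
reciprocal-lattice peak

    F_latt = N_cells exp(-dx^2 / 0.63),
    dx^2 = (dh Na)^2 + (dk Nb)^2 + (dl Nc)^2

whose 0.63 constant makes its volume and FWHM match a rectangular domain
of Na x Nb x Nc cells.  The 25 sampled domains stand in for the whole
illuminated volume, so the domain sum carries a volume-ratio weight
(illuminated cells / (n_domains * cells per domain)).  Water and air
scatter add a smooth radial background; measurement noise is a fixed
per-pixel calibration pattern (1% sd) followed by Poisson sampling.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .crystal import MosaicEnsemble, Orientation, UnitCell
from .curves import HC_EV_ANGSTROM
from .detector import DetectorPanel, pixel_to_s1, polarization_factor, solid_angle
from .sfcalc import StructureFactorSet
from .spectrum import SASESpectrum

__all__ = [
    "SimulationConfig",
    "SimulatedImage",
    "fractional_hkl",
    "f_latt_sq",
    "background_model",
    "simulate_image",
    "add_noise",
    "calibration_pattern",
]

R_E_CODATA_M = 2.8179403262e-15  # classical electron radius


@dataclass(frozen=True)
class SimulationConfig:
    crystal_path_um: float = 4.0
    beam_area_um2: float = 1.0
    d_eff_nm: float = 400.0          # mosaic-domain FWHM diameter
    n_domains: int = 25
    Na: int | None = None            # unit cells per domain edge (derived if None)
    Nb: int | None = None
    Nc: int | None = None
    r_e_m: float = R_E_CODATA_M
    include_background: bool = True
    apply_poisson: bool = True
    apply_calibration: bool = True
    oversample: int = 1
    water_path_um: float = 100.0
    air_path_mm: float = 10.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_domains < 1 or self.oversample < 1:
            raise ValueError("n_domains and oversample must be >= 1")

    def domain_cells(self, cell: UnitCell) -> tuple[int, int, int]:
        d_eff_A = self.d_eff_nm * 10.0
        na = self.Na or max(1, round(d_eff_A / cell.a))
        nb = self.Nb or max(1, round(d_eff_A / cell.b))
        nc = self.Nc or max(1, round(d_eff_A / cell.c))
        return na, nb, nc

    def volume_weight(self, cell: UnitCell, n_domains: int | None = None) -> float:
        """Illuminated cells / (n_domains * cells per domain).  The domain
        count defaults to the simulation ensemble size but must match the
        ensemble actually summed over (e.g. the 200-member analysis one)."""
        na, nb, nc = self.domain_cells(cell)
        v_cell_m3 = cell.volume * 1e-30
        illuminated = (self.crystal_path_um * 1e-6) * (self.beam_area_um2 * 1e-12) / v_cell_m3
        return illuminated / ((n_domains or self.n_domains) * na * nb * nc)


@dataclass
class SimulatedImage:
    """Expected photons plus (optionally) noisy integer counts."""

    photons: np.ndarray              # (n_slow, n_fast) expected photons
    counts: np.ndarray | None = None  # after calibration + Poisson
    metadata: dict = field(default_factory=dict)

    @property
    def observed(self) -> np.ndarray:
        return self.counts if self.counts is not None else self.photons


def fractional_hkl(A_star: np.ndarray, s0: np.ndarray, s1: np.ndarray) -> np.ndarray:
    """Real-valued Miller index h = A*^-1 (s1 - s0); both wavevectors must
    have length 1/lambda."""
    A = np.asarray(A_star, dtype=float)
    if abs(np.linalg.det(A)) < 1e-300:
        raise ValueError("singular orientation matrix")
    S = np.asarray(s1, dtype=float) - np.asarray(s0, dtype=float)
    return np.linalg.solve(A, S.T if S.ndim > 1 else S).T if S.ndim > 1 \
        else np.linalg.solve(A, S)


def f_latt_sq(delta_h: np.ndarray, Na: int, Nb: int, Nc: int) -> np.ndarray:
    """|F_latt|^2 for fractional offsets delta_h (..., 3) from the RLP center."""
    if min(Na, Nb, Nc) < 1:
        raise ValueError("domain cell counts must be >= 1")
    d = np.asarray(delta_h, dtype=float)
    dx2 = (d[..., 0] * Na) ** 2 + (d[..., 1] * Nb) ** 2 + (d[..., 2] * Nc) ** 2
    n_cells = float(Na) * Nb * Nc
    return n_cells ** 2 * np.exp(-2.0 * dx2 / 0.63)


def _latt_profile_sum(inv_A_domains: np.ndarray, S: np.ndarray, h0: np.ndarray,
                      Na: int, Nb: int, Nc: int) -> np.ndarray:
    """sum_D |F_latt|^2 for scattering vectors S (n, 3) about integer h0 (n, 3).

    Shared by the forward simulation and the inference profile builder so the
    two stay numerically identical when given the same domain ensemble.
    """
    n_cells = float(Na) * Nb * Nc
    scale = np.array([Na, Nb, Nc], dtype=float)
    acc = np.zeros(len(S))
    h0f = h0.astype(float)
    for invA in inv_A_domains:
        delta = (S @ invA.T - h0f) * scale
        acc += np.exp(-2.0 * np.einsum("ni,ni->n", delta, delta) / 0.63)
    return n_cells ** 2 * acc


def background_model(panel: DetectorPanel, fast, slow,
                     water_path_um: float = 100.0, air_path_mm: float = 10.0,
                     total_photons: float = 1e12, energy: float = 7122.0,
                     polarization_fraction: float = 1.0) -> np.ndarray:
    """Smooth radial background from the liquid carrier and the air path.

    Parametric stand-in: water scatters into a broad ring peaking in the
    3-4 A band (|S| ~ 0.29 1/A), air is forward-peaked; both scale linearly
    with path length and pulse photons and follow P * dOmega per pixel.
    """
    fast = np.asarray(fast, dtype=float)
    lam = HC_EV_ANGSTROM / energy
    s1 = pixel_to_s1(panel, fast, slow)
    two_theta = np.arccos(np.clip(s1[..., 2], -1.0, 1.0))
    s = 2.0 * np.sin(two_theta / 2.0) / lam
    # per-steradian scattering fractions (qualitative magnitudes)
    water = 4.0e-6 * (water_path_um / 100.0) * (
        np.exp(-0.5 * ((s - 0.294) / 0.07) ** 2) + 0.15 * np.exp(-0.5 * (s / 0.15) ** 2))
    air = 2.0e-6 * (air_path_mm / 10.0) * np.exp(-0.5 * (s / 0.08) ** 2)
    P = polarization_factor(panel, fast, slow, polarization_fraction)
    dOmega = solid_angle(panel, fast, slow)
    return total_photons * P * dOmega * (water + air)


def calibration_pattern(panel: DetectorPanel, panel_seed: int) -> np.ndarray:
    """Fixed-pattern per-pixel gain factors ~ N(1, calibration_noise_sd);
    identical across shots for a given panel seed."""
    rng = np.random.default_rng(panel_seed)
    return rng.normal(1.0, panel.calibration_noise_sd,
                      size=(panel.n_slow, panel.n_fast))


def simulate_image(config: SimulationConfig, panel: DetectorPanel,
                   orientation: Orientation, ensemble: MosaicEnsemble,
                   spectrum: SASESpectrum, sfset: StructureFactorSet,
                   truth_fp: np.ndarray, truth_fdp: np.ndarray,
                   seed: int | None = None,
                   pixels: tuple[np.ndarray, np.ndarray] | None = None,
                   panel_seed: int | None = None) -> SimulatedImage:
    """Expected photons for one still shot (optionally restricted to a pixel
    subset), then calibration + Poisson noise per the config flags.

    ``truth_fp``/``truth_fdp`` are the per-site (M, n_channels) ground-truth
    anomalous corrections feeding F_true.
    """
    if spectrum.grid != sfset.grid:
        raise ValueError("spectrum and structure factors use different grids")
    ny, nx = panel.n_slow, panel.n_fast
    if pixels is None:
        fast, slow = np.meshgrid(np.arange(nx), np.arange(ny))
        fast, slow = fast.ravel(), slow.ravel()
    else:
        fast, slow = (np.asarray(p).ravel() for p in pixels)

    intensities = sfset.intensities(truth_fp, truth_fdp)  # (n_refl, n_ch)
    bragg = _bragg_expected(config, panel, orientation, ensemble, spectrum,
                            sfset, intensities, fast, slow)
    photons = np.zeros((ny, nx))
    photons[slow, fast] = bragg
    if config.include_background:
        photons[slow, fast] += background_model(
            panel, fast, slow, config.water_path_um, config.air_path_mm,
            total_photons=spectrum.total_photons)
    image = SimulatedImage(photons=photons, metadata={
        "seed": seed, "panel_seed": panel_seed,
        "pixel_origin": "pixel-center-at-index-plus-half",
    })
    if config.apply_poisson or config.apply_calibration:
        add_noise(image, panel, seed=seed, panel_seed=panel_seed,
                  calibration=config.apply_calibration,
                  poisson=config.apply_poisson)
    return image


def _bragg_expected(config, panel, orientation, ensemble, spectrum, sfset,
                    intensities, fast, slow) -> np.ndarray:
    os = config.oversample
    if os > 1:
        offs = (np.arange(os) + 0.5) / os - 0.5
        df, ds = np.meshgrid(offs, offs)
        sub_f = (fast[:, None] + df.ravel()[None]).ravel()
        sub_s = (slow[:, None] + ds.ravel()[None]).ravel()
        vals = _bragg_expected_points(config, panel, orientation, ensemble,
                                      spectrum, sfset, intensities, sub_f, sub_s)
        return vals.reshape(len(fast), os * os).mean(axis=1)
    return _bragg_expected_points(config, panel, orientation, ensemble,
                                  spectrum, sfset, intensities,
                                  fast.astype(float), slow.astype(float))


def _bragg_expected_points(config, panel, orientation, ensemble, spectrum,
                           sfset, intensities, fast, slow) -> np.ndarray:
    cell = sfset.cell
    na, nb, nc = config.domain_cells(cell)
    weight = config.volume_weight(cell, ensemble.n_domains)
    s1_unit = pixel_to_s1(panel, fast, slow)
    P = polarization_factor(panel, fast, slow)
    dOmega = solid_angle(panel, fast, slow)
    area_m2 = config.beam_area_um2 * 1e-12
    A_ref = orientation.A_star
    inv_A_ref = np.linalg.inv(A_ref)
    inv_A_dom = np.array([np.linalg.inv(UD @ A_ref) for UD in ensemble.rotations])
    lam = spectrum.grid.wavelengths
    s0_dir = np.array([0.0, 0.0, 1.0])
    out = np.zeros(len(fast))
    prefac = config.r_e_m ** 2 * P * dOmega / area_m2
    for c in range(spectrum.grid.n_channels):
        J0 = spectrum.fluence[c]
        if J0 <= 0:
            continue
        S = (s1_unit - s0_dir) / lam[c]
        h0 = np.rint(S @ inv_A_ref.T).astype(int)
        uniq, inverse = np.unique(h0, axis=0, return_inverse=True)
        I_uniq = np.zeros(len(uniq))
        for u, hrow in enumerate(uniq):
            idx = sfset.lookup(hrow)
            if idx is not None:
                I_uniq[u] = intensities[idx, c]
        I_px = I_uniq[inverse]
        live = I_px > 0
        if not live.any():
            continue
        latt = _latt_profile_sum(inv_A_dom, S[live], h0[live], na, nb, nc)
        out[live] += J0 * I_px[live] * latt
    return prefac * weight * out


def add_noise(image: SimulatedImage, panel: DetectorPanel, seed=None,
              panel_seed=None, calibration: bool = True,
              poisson: bool = True) -> SimulatedImage:
    """Apply the fixed-pattern calibration factors (panel seed) and Poisson
    shot noise (image seed) to the expected photons, in that order."""
    lam = image.photons
    if (lam < 0).any():
        raise ValueError("expected photon counts must be non-negative")
    if calibration:
        lam = lam * calibration_pattern(panel, panel_seed if panel_seed is not None else 0)
        lam = np.clip(lam, 0.0, None)
    if poisson:
        rng = np.random.default_rng(seed)
        image.counts = rng.poisson(lam).astype(np.int64)
    else:
        image.counts = None if not calibration else lam
    return image
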