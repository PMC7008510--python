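"""Stochastic SASE-like per-pulse X-ray spectra.

Self-amplified spontaneous emission pulses are spiky and random: each shot
is a different superposition of narrow longitudinal modes under a broad
envelope whose center jitters from shot to shot.  The generator emulates
the measured single-shot statistics this package is designed around:
per-pulse mean energies jitter with sd 6.3 eV about the 7120 eV set point,
the run-cumulative spectrum has a FWHM of about 22 eV, and the run-average
integrated flux is 1e12 photons per pulse.

The per-pulse envelope FWHM default (16 eV) is a derived design constant:
envelope width and mean-energy jitter add in quadrature, and
sqrt(16^2 + (2.355 * 6.3)^2) ~ 21.9 eV reproduces the cumulative width.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import EnergyGrid, make_grid

__all__ = ["SASESpectrum", "generate_sase", "ensemble_stats",
           "read_spectrum_tsv", "write_spectrum_tsv"]


@dataclass
class SASESpectrum:
    """Fluence per channel for one pulse (photons / channel / pulse)."""

    grid: EnergyGrid
    fluence: np.ndarray

    def __post_init__(self) -> None:
        self.fluence = np.asarray(self.fluence, dtype=float)
        if self.fluence.shape != (self.grid.n_channels,):
            raise ValueError("fluence length must match the grid")
        if (self.fluence < 0).any():
            raise ValueError("fluence must be non-negative")

    @property
    def total_photons(self) -> float:
        return float(self.fluence.sum())

    @property
    def mean_energy(self) -> float:
        tot = self.fluence.sum()
        if tot == 0:
            raise ValueError("empty spectrum has no mean energy")
        return float(self.fluence @ self.grid.channel_centers / tot)


def generate_sase(seed=None, grid: EnergyGrid | None = None,
                  set_point: float = 7120.0, jitter_sd: float = 6.3,
                  envelope_fwhm: float = 16.0, n_spikes: int = 60,
                  spike_width: float = 0.6, mean_total: float = 1e12,
                  total_sd_frac: float = 0.2) -> SASESpectrum:
    """One stochastic pulse, downsampled to the working grid.

    ``n_spikes`` narrow Gaussian spikes (sd ``spike_width`` eV, exponential
    amplitudes) are placed under a Gaussian envelope centered at
    ``set_point + N(0, jitter_sd)``, low-pass filtered so no feature is
    narrower than about 1 eV, scaled to a lognormal total photon count with
    run mean ``mean_total``, and binned onto the grid.
    """
    if min(envelope_fwhm, spike_width) <= 0 or n_spikes < 1:
        raise ValueError("widths and spike count must be positive")
    rng = np.random.default_rng(seed)
    grid = grid or make_grid()
    step = 0.25
    fine = np.arange(grid.e_min - 30.0, grid.e_max + 30.0 + step / 2, step)
    center = set_point + rng.normal(0.0, jitter_sd)
    env_sd = envelope_fwhm / 2.3548200450309493
    pos = rng.normal(center, env_sd, n_spikes)
    amp = rng.exponential(1.0, n_spikes)
    spec = (amp[:, None] * np.exp(-0.5 * ((fine[None] - pos[:, None]) / spike_width) ** 2)).sum(axis=0)
    # low-pass: Gaussian kernel, sd 0.4 eV, suppresses sub-eV structure
    half = int(np.ceil(4 * 0.4 / step))
    kern = np.exp(-0.5 * (np.arange(-half, half + 1) * step / 0.4) ** 2)
    kern /= kern.sum()
    spec = np.convolve(spec, kern, mode="same")
    # lognormal total with mean mean_total: mu = -sigma^2/2
    sigma = np.sqrt(np.log(1.0 + total_sd_frac ** 2))
    total = mean_total * rng.lognormal(-sigma ** 2 / 2.0, sigma)
    spec *= total / max(spec.sum(), 1e-300)
    # photon-conserving binning of in-window samples
    idx = np.floor((fine - grid.e_min) / grid.spacing).astype(int)
    ok = (idx >= 0) & (idx < grid.n_channels)
    fluence = np.bincount(idx[ok], weights=spec[ok], minlength=grid.n_channels)
    return SASESpectrum(grid, fluence)


def _fwhm(x: np.ndarray, y: np.ndarray) -> float:
    """Full width at half maximum by linear interpolation at half max."""
    half = y.max() / 2.0
    above = y >= half
    if not above.any():
        return 0.0
    i0 = int(np.argmax(above))
    i1 = len(y) - 1 - int(np.argmax(above[::-1]))
    if i0 == 0:
        left = x[0]
    else:
        left = x[i0 - 1] + (half - y[i0 - 1]) * (x[i0] - x[i0 - 1]) / (y[i0] - y[i0 - 1])
    if i1 == len(y) - 1:
        right = x[-1]
    else:
        right = x[i1] + (half - y[i1]) * (x[i1 + 1] - x[i1]) / (y[i1 + 1] - y[i1])
    return float(right - left)


def ensemble_stats(spectra: list[SASESpectrum]) -> tuple[float, float, float]:
    """(sd of per-pulse mean energies [eV], cumulative FWHM [eV],
    mean total photons) over a run of pulses."""
    if len(spectra) < 2:
        raise ValueError("need at least two spectra")
    means = np.array([s.mean_energy for s in spectra])
    totals = np.array([s.total_photons for s in spectra])
    cum = np.sum([s.fluence for s in spectra], axis=0)
    grid = spectra[0].grid
    return (float(means.std(ddof=1)), _fwhm(grid.channel_centers, cum),
            float(totals.mean()))


def write_spectrum_tsv(spectrum: SASESpectrum, path) -> None:
    pd.DataFrame({"energy_eV": spectrum.grid.channel_centers,
                  "photons": spectrum.fluence}).to_csv(
        path, sep="\t", index=False, float_format="%.6e")


def read_spectrum_tsv(path) -> SASESpectrum:
    df = pd.read_csv(path, sep="\t")
    e = df["energy_eV"].to_numpy()
    spacing = float(np.diff(e).mean())
    grid = EnergyGrid(len(e), float(e[0] - spacing / 2), float(e[-1] + spacing / 2))
    return SASESpectrum(grid, df["photons"].to_numpy())
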