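"""Flat-panel detector geometry: pixels to scattering vectors and back.

Laboratory frame: beam along +z, fast (horizontal) axis +x, slow axis +y,
with the beam E-vector horizontal (along x).  Pixel centers sit at
index + 0.5 in fractional pixel coordinates; this convention is stored in
the experiment metadata so no half-pixel ambiguity can creep in between
simulation and analysis.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import HC_EV_ANGSTROM

__all__ = [
    "DetectorPanel",
    "pixel_to_s1",
    "s1_to_pixel",
    "solid_angle",
    "polarization_factor",
    "pixel_resolution",
    "energy_per_pixel",
    "roi_mask",
]

PIXEL_ORIGIN_CONVENTION = "pixel-center-at-index-plus-half"


@dataclass(frozen=True)
class DetectorPanel:
    n_fast: int = 3000
    n_slow: int = 3000
    pixel_size: float = 0.11        # mm
    distance: float = 141.7         # mm
    beam_center: tuple[float, float] = (1500.0, 1500.0)  # fractional (fast, slow) px
    gain: float = 1.0               # counts per photon
    calibration_noise_sd: float = 0.01  # fractional fixed-pattern gain spread

    def __post_init__(self) -> None:
        if self.n_fast < 1 or self.n_slow < 1 or self.pixel_size <= 0 or self.distance <= 0:
            raise ValueError("invalid panel geometry")

    def pixel_xy_mm(self, fast, slow) -> tuple[np.ndarray, np.ndarray]:
        """Lab-frame x, y (mm) of pixel centers for index arrays."""
        fast = np.asarray(fast, dtype=float)
        slow = np.asarray(slow, dtype=float)
        x = (fast + 0.5 - self.beam_center[0]) * self.pixel_size
        y = (slow + 0.5 - self.beam_center[1]) * self.pixel_size
        return x, y


def pixel_to_s1(panel: DetectorPanel, fast, slow) -> np.ndarray:
    """Unit vector(s) from the sample to pixel centers, shape (..., 3)."""
    x, y = panel.pixel_xy_mm(fast, slow)
    v = np.stack(np.broadcast_arrays(x, y, np.full_like(x, panel.distance)), axis=-1)
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def s1_to_pixel(panel: DetectorPanel, s1_unit: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse projection: fractional (fast, slow) pixel indices of the ray."""
    s1 = np.asarray(s1_unit, dtype=float)
    if np.any(s1[..., 2] <= 0):
        raise ValueError("ray does not intersect the forward detector plane")
    scale = panel.distance / s1[..., 2]
    x = s1[..., 0] * scale
    y = s1[..., 1] * scale
    fast = x / panel.pixel_size + panel.beam_center[0] - 0.5
    slow = y / panel.pixel_size + panel.beam_center[1] - 0.5
    return fast, slow


def solid_angle(panel: DetectorPanel, fast, slow) -> np.ndarray:
    """Solid angle (sr) of pixels: area * cos(psi) / R^2 with obliquity psi."""
    x, y = panel.pixel_xy_mm(fast, slow)
    R2 = x * x + y * y + panel.distance ** 2
    area = (panel.pixel_size * 1e-3) ** 2  # m^2 (units cancel in the ratio)
    return area * (panel.distance / np.sqrt(R2)) / (R2 * 1e-6)


def polarization_factor(panel: DetectorPanel, fast, slow,
                        polarization_fraction: float = 1.0) -> np.ndarray:
    """Kahn polarization factor.  Fraction 1 means fully polarized along x
    (horizontal); 0.5 reproduces the unpolarized (1 + cos^2 2theta)/2."""
    if not 0 <= polarization_fraction <= 1:
        raise ValueError("polarization fraction must lie in [0, 1]")
    s1 = pixel_to_s1(panel, fast, slow)
    p = polarization_fraction
    return p * (1.0 - s1[..., 0] ** 2) + (1 - p) * (1.0 - s1[..., 1] ** 2)


def pixel_resolution(panel: DetectorPanel, fast, slow, energy: float) -> np.ndarray:
    """Bragg resolution d = lambda / (2 sin theta) seen by pixels, in A."""
    if energy <= 0:
        raise ValueError("energy must be positive")
    x, y = panel.pixel_xy_mm(fast, slow)
    r = np.hypot(x, y)
    theta = 0.5 * np.arctan2(r, panel.distance)
    lam = HC_EV_ANGSTROM / energy
    with np.errstate(divide="ignore"):
        return lam / (2.0 * np.sin(theta))


def energy_per_pixel(panel: DetectorPanel, d: float, energy: float) -> float:
    """Radial energy gradient |dE/dr| * pixel_size (eV/pixel) for a fixed
    Miller-index magnitude (fixed d): a streaked spot maps energy to radius
    through Bragg's law, E = hc / (2 d sin theta), r = L tan 2theta."""
    lam = HC_EV_ANGSTROM / energy
    sin_t = lam / (2.0 * d)
    if not 0 < sin_t < 1:
        raise ValueError("reflection not visible at this energy")
    theta = np.arcsin(sin_t)
    two_theta = 2.0 * theta
    if two_theta >= np.pi / 2:
        raise ValueError("reflection scatters beyond the forward panel")
    r = panel.distance * np.tan(two_theta)
    rmax = np.hypot(panel.n_fast * panel.pixel_size,
                    panel.n_slow * panel.pixel_size)
    if r > rmax:
        raise ValueError("reflection falls outside the panel")
    # dE/dr = dE/dtheta * dtheta/d(2theta) * d(2theta)/dr
    dE_dtheta = -energy / np.tan(theta)
    dtwotheta_dr = np.cos(two_theta) ** 2 / panel.distance
    return float(abs(dE_dtheta * 0.5 * dtwotheta_dr) * panel.pixel_size)


def roi_mask(panel: DetectorPanel, d_range: tuple[float, float] = (2.1, 2.5),
             position_angle_range: tuple[float, float] = (150.0, 210.0),
             energy: float = 7122.0) -> np.ndarray:
    """Boolean (n_slow, n_fast) mask of the analysis region of interest:
    a resolution annulus intersected with a position-angle wedge (degrees,
    measured counter-clockwise from +x; the range may wrap through 360)."""
    fast, slow = np.meshgrid(np.arange(panel.n_fast), np.arange(panel.n_slow))
    d = pixel_resolution(panel, fast, slow, energy)
    ann = (d >= min(d_range)) & (d <= max(d_range))
    x, y = panel.pixel_xy_mm(fast, slow)
    ang = np.degrees(np.arctan2(y, x)) % 360.0
    lo, hi = position_angle_range[0] % 360.0, position_angle_range[1] % 360.0
    if position_angle_range[1] - position_angle_range[0] >= 360.0:
        wedge = np.ones_like(ann)
    elif position_angle_range[0] == position_angle_range[1]:
        wedge = np.zeros_like(ann)
    elif lo <= hi:
        wedge = (ang >= lo) & (ang <= hi)
    else:
        wedge = (ang >= lo) | (ang <= hi)
    return ann & wedge
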