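"""Prediction-driven spot extraction: shoeboxes around Bragg streaks.

Spot positions are predicted from known (or estimated) orientations rather
than found in the image: for every candidate reflection the Laue energy is
computed from the reciprocal position, and reflections whose acceptance
window — broadened by the mosaic width eta and the finite domain size —
overlaps the spectral range are projected onto the panel.  The shoebox
bounds cover the full energy streak plus a margin; peak pixels are masked
where the predicted (unit-scale) Bragg model exceeds a fraction of the
spot maximum, and an initial background plane is fitted to the remainder.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .crystal import MosaicEnsemble, Orientation
from .curves import HC_EV_ANGSTROM
from .detector import DetectorPanel, s1_to_pixel
from .simulate import SimulatedImage

__all__ = [
    "Shoebox",
    "SpotPrediction",
    "predict_spots",
    "cut_shoeboxes",
    "fit_background_plane",
]


@dataclass
class SpotPrediction:
    h0: tuple[int, int, int]
    centroid: tuple[float, float]        # fractional (fast, slow)
    bounds: tuple[int, int, int, int]    # fast0, fast1, slow0, slow1 (half-open)
    energy_lo: float
    energy_hi: float
    d: float


@dataclass
class Shoebox:
    image_id: int
    spot_id: int
    h0: tuple[int, int, int]
    bounds: tuple[int, int, int, int]
    counts: np.ndarray                   # (nslow, nfast) observed k_i
    peak_mask: np.ndarray | None = None
    background_plane: tuple[float, float, float] = (0.0, 0.0, 0.0)
    centroid: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        f0, f1, s0, s1 = self.bounds
        if self.counts.shape != (s1 - s0, f1 - f0):
            raise ValueError("counts shape does not match bounds")
        if (self.counts < 0).any():
            raise ValueError("observed counts must be non-negative")

    @property
    def n_pixels(self) -> int:
        return self.counts.size

    def pixel_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(fast, slow) integer index arrays for all shoebox pixels, raveled."""
        f0, f1, s0, s1 = self.bounds
        fast, slow = np.meshgrid(np.arange(f0, f1), np.arange(s0, s1))
        return fast.ravel(), slow.ravel()

    def local_pq(self) -> tuple[np.ndarray, np.ndarray]:
        """Slow (p) and fast (q) coordinates relative to the box center."""
        f0, f1, s0, s1 = self.bounds
        q, p = np.meshgrid(np.arange(f1 - f0, dtype=float) - (f1 - f0 - 1) / 2,
                           np.arange(s1 - s0, dtype=float) - (s1 - s0 - 1) / 2)
        return p.ravel(), q.ravel()


def predict_spots(orientation: Orientation, panel: DetectorPanel,
                  hkl: np.ndarray, energy_range: tuple[float, float],
                  eta_deg: float = 0.05, d_eff_nm: float = 400.0,
                  margin: int = 3, n_sigma: float = 3.0) -> list[SpotPrediction]:
    """Reflections whose reciprocal-lattice peak crosses the Ewald shell
    swept by [E_lo, E_hi], projected onto the panel.

    The acceptance window of a reflection at reciprocal position q is
    dE/E = eps / sin(theta) with eps the angular half-width of the peak
    (n_sigma * eta plus the domain-size term 0.66 / (D_eff |q|))."""
    E_lo, E_hi = energy_range
    A = orientation.A_star
    hkl = np.asarray(hkl, dtype=int)
    q = hkl @ A.T                            # (N, 3) reciprocal vectors, 1/A
    q2 = np.einsum("ni,ni->n", q, q)
    qn = np.sqrt(q2)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam_B = -2.0 * q[:, 2] / q2          # Laue wavelength, A
    ok = lam_B > 0
    E_B = np.where(ok, HC_EV_ANGSTROM / np.where(ok, lam_B, 1.0), np.inf)
    sin_theta = np.clip(qn * np.where(ok, lam_B, 1.0) / 2.0, 1e-9, 1.0)
    eps = n_sigma * np.radians(eta_deg) + n_sigma * 0.66 / (d_eff_nm * 10.0 * qn)
    dE = np.where(ok, E_B, 0.0) * eps / sin_theta
    with np.errstate(invalid="ignore"):
        visible = ok & (E_B + dE >= E_lo) & (E_B - dE <= E_hi)
    preds: list[SpotPrediction] = []
    for i in np.nonzero(visible)[0]:
        e_lo = max(E_B[i] - dE[i], E_lo)
        e_hi = min(E_B[i] + dE[i], E_hi)
        pix = []
        for e in (e_lo, 0.5 * (e_lo + e_hi), e_hi):
            lam = HC_EV_ANGSTROM / e
            s1 = np.array([0.0, 0.0, 1.0]) / lam + q[i]
            s1 /= np.linalg.norm(s1)
            if s1[2] <= 0:
                break
            pix.append(s1_to_pixel(panel, s1))
        if len(pix) < 3:
            continue
        fasts = np.array([p[0] for p in pix])
        slows = np.array([p[1] for p in pix])
        f0 = int(np.floor(fasts.min())) - margin
        f1 = int(np.ceil(fasts.max())) + margin + 1
        s0 = int(np.floor(slows.min())) - margin
        s1b = int(np.ceil(slows.max())) + margin + 1
        if f1 <= 0 or s1b <= 0 or f0 >= panel.n_fast or s0 >= panel.n_slow:
            continue
        preds.append(SpotPrediction(
            h0=tuple(int(x) for x in hkl[i]),
            centroid=(float(pix[1][0]), float(pix[1][1])),
            bounds=(f0, f1, s0, s1b),
            energy_lo=float(e_lo), energy_hi=float(e_hi),
            d=float(1.0 / qn[i])))
    return preds


def cut_shoeboxes(image: SimulatedImage, predictions: list[SpotPrediction],
                  roi: np.ndarray | None = None, image_id: int = 0,
                  min_spots: int = 3) -> tuple[list[Shoebox], bool]:
    """Clip predicted boxes to the panel, keep those with centroid inside the
    region of interest, and flag images with fewer than ``min_spots`` boxes."""
    data = image.observed
    ny, nx = data.shape
    boxes: list[Shoebox] = []
    for k, pred in enumerate(predictions):
        f0, f1, s0, s1 = pred.bounds
        f0c, f1c = max(f0, 0), min(f1, nx)
        s0c, s1c = max(s0, 0), min(s1, ny)
        if f1c - f0c < 3 or s1c - s0c < 3:
            continue
        cf, cs = int(round(pred.centroid[0])), int(round(pred.centroid[1]))
        if not (0 <= cf < nx and 0 <= cs < ny):
            continue
        if roi is not None and not roi[cs, cf]:
            continue
        boxes.append(Shoebox(
            image_id=image_id, spot_id=k, h0=pred.h0,
            bounds=(f0c, f1c, s0c, s1c),
            counts=np.asarray(data[s0c:s1c, f0c:f1c]),
            centroid=pred.centroid))
    return boxes, len(boxes) >= min_spots


def find_spots_threshold(image: SimulatedImage, threshold: float,
                         min_pixels: int = 2) -> list[tuple[float, float]]:
    """Diagnostic image-driven spot finder: connected regions of pixels above
    ``threshold``, returned as intensity-weighted (fast, slow) centroids.
    The analysis pipeline is prediction-driven; this exists only to
    sanity-check predictions against what is visible in an image."""
    from scipy import ndimage
    data = np.asarray(image.observed, dtype=float)
    labels, n = ndimage.label(data > threshold)
    out = []
    for i in range(1, n + 1):
        mask = labels == i
        if mask.sum() < min_pixels:
            continue
        slow, fast = np.nonzero(mask)
        w = data[mask]
        out.append((float((fast * w).sum() / w.sum()),
                    float((slow * w).sum() / w.sum())))
    return out


def fit_background_plane(shoebox: Shoebox) -> tuple[float, float, float]:
    """Least-squares plane g = a p + b q + c over non-peak pixels (p slow,
    q fast, both relative to the box center).  Falls back to a constant
    plane when the unmasked geometry is degenerate."""
    p, q = shoebox.local_pq()
    k = shoebox.counts.ravel().astype(float)
    if shoebox.peak_mask is not None:
        free = ~shoebox.peak_mask.ravel()
    else:
        free = np.ones_like(k, dtype=bool)
    if free.sum() < 3:
        return (0.0, 0.0, float(k[free].mean()) if free.any() else float(k.mean()))
    X = np.stack([p[free], q[free], np.ones(free.sum())], axis=1)
    try:
        coef, *_ = np.linalg.lstsq(X, k[free], rcond=None)
        if not np.isfinite(coef).all():
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        return (0.0, 0.0, float(k[free].mean()))
    a, b, c = (float(v) for v in coef)
    shoebox.background_plane = (a, b, c)
    return a, b, c
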