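"""Unit cells, orientation matrices and mosaic-domain ensembles.

The crystal orientation is carried in reciprocal space as A* = U B
(Busing & Levy): B holds the reciprocal basis vectors (a*|b*|c*) in a
conventional reference setting (a* along +x, b* in the x-y plane) and U is
the per-shot rotation.  Mosaicity is modelled as an ensemble of rigid
domains, each rotated from the reference orientation by a small random
rotation whose axis is uniform on the hemisphere and whose signed magnitude
is Gaussian with sd eta.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "UnitCell",
    "Orientation",
    "MosaicEnsemble",
    "reciprocal_B",
    "random_orientation",
    "mosaic_ensemble",
    "missetting_angle",
    "generate_hkl",
]


@dataclass(frozen=True)
class UnitCell:
    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    space_group: str = "P1"  # "P1" or "C2" (unique axis b)

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180)")
        if self.space_group not in ("P1", "C2"):
            raise ValueError("only P1 and C2 are supported")
        if np.linalg.det(self.metric_tensor()) <= 0:
            raise ValueError("metric tensor not positive definite")

    def metric_tensor(self) -> np.ndarray:
        al, be, ga = np.radians([self.alpha, self.beta, self.gamma])
        a, b, c = self.a, self.b, self.c
        return np.array([
            [a * a, a * b * np.cos(ga), a * c * np.cos(be)],
            [a * b * np.cos(ga), b * b, b * c * np.cos(al)],
            [a * c * np.cos(be), b * c * np.cos(al), c * c],
        ])

    def reciprocal_metric_tensor(self) -> np.ndarray:
        return np.linalg.inv(self.metric_tensor())

    @property
    def volume(self) -> float:
        return float(np.sqrt(np.linalg.det(self.metric_tensor())))

    def d_spacing(self, hkl: np.ndarray) -> np.ndarray:
        """Resolution d = 1/|S| for integer Miller indices (..., 3)."""
        hkl = np.asarray(hkl, dtype=float)
        gstar = self.reciprocal_metric_tensor()
        s2 = np.einsum("...i,ij,...j->...", hkl, gstar, hkl)
        with np.errstate(divide="ignore"):
            return 1.0 / np.sqrt(s2)


def reciprocal_B(cell: UnitCell) -> np.ndarray:
    """Busing-Levy B matrix: columns are a*, b*, c* in the reference setting
    (a* along +x, b* in the x-y plane).  Units 1/Angstrom, no 2*pi."""
    gstar = cell.reciprocal_metric_tensor()
    a_s, b_s, c_s = np.sqrt(np.diag(gstar))
    cos_gs = gstar[0, 1] / (a_s * b_s)
    cos_bs = gstar[0, 2] / (a_s * c_s)
    sin_gs = np.sqrt(max(1.0 - cos_gs ** 2, 0.0))
    sin_bs = np.sqrt(max(1.0 - cos_bs ** 2, 0.0))
    al = np.radians(cell.alpha)
    return np.array([
        [a_s, b_s * cos_gs, c_s * cos_bs],
        [0.0, b_s * sin_gs, -c_s * sin_bs * np.cos(al)],
        [0.0, 0.0, 1.0 / cell.c],
    ])


@dataclass(frozen=True)
class Orientation:
    """Crystal setting A* = U B; columns of A* are the reciprocal basis."""

    U: np.ndarray
    B: np.ndarray
    cell: UnitCell

    def __post_init__(self) -> None:
        U = np.asarray(self.U, dtype=float)
        if abs(np.linalg.det(U) - 1.0) > 1e-8 or np.abs(U.T @ U - np.eye(3)).max() > 1e-8:
            raise ValueError("U must be a proper rotation")
        object.__setattr__(self, "U", U)
        object.__setattr__(self, "B", np.asarray(self.B, dtype=float))

    @property
    def A_star(self) -> np.ndarray:
        return self.U @ self.B

    def direct_matrix(self) -> np.ndarray:
        """Columns are the real-space basis vectors a, b, c in the lab frame."""
        return np.linalg.inv(self.A_star).T

    def rotated(self, R: np.ndarray) -> "Orientation":
        return Orientation(R @ self.U, self.B, self.cell)


def random_orientation(cell: UnitCell, seed=None) -> Orientation:
    """Orientation with U drawn uniformly (Haar) from SO(3)."""
    rng = np.random.default_rng(seed)
    U = Rotation.random(rng=rng).as_matrix()
    return Orientation(U, reciprocal_B(cell), cell)


@dataclass(frozen=True)
class MosaicEnsemble:
    rotations: np.ndarray  # (n, 3, 3)
    eta: float             # degrees

    @property
    def n_domains(self) -> int:
        return len(self.rotations)


def mosaic_ensemble(eta: float, n: int, seed=None,
                    recenter: bool = False) -> MosaicEnsemble:
    """n domain rotations: axes uniform on the unit hemisphere, signed
    magnitudes ~ N(0, eta degrees).

    A finite draw has a nonzero mean rotation (~eta/sqrt(n)); with
    ``recenter`` the ensemble is premultiplied by the inverse of its mean so
    it represents a zero-mean smooth mosaic distribution exactly — the
    assumption an analysis ensemble stands for.
    """
    if eta < 0 or n < 1:
        raise ValueError("eta must be >= 0 and n >= 1")
    rng = np.random.default_rng(seed)
    if eta == 0.0:
        return MosaicEnsemble(np.broadcast_to(np.eye(3), (n, 3, 3)).copy(), 0.0)
    phi = rng.uniform(0, 2 * np.pi, n)
    cos_t = rng.uniform(0.0, 1.0, n)  # hemisphere: z >= 0
    sin_t = np.sqrt(1.0 - cos_t ** 2)
    axes = np.stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=1)
    angles = np.radians(rng.normal(0.0, eta, n))
    mats = Rotation.from_rotvec(axes * angles[:, None]).as_matrix()
    if recenter:
        mean_inv = Rotation.from_matrix(mats).mean().inv().as_matrix()
        mats = np.einsum("ij,njk->nik", mean_inv, mats)
    return MosaicEnsemble(mats, eta)


def missetting_angle(o1: Orientation, o2: Orientation) -> float:
    """Mean angle (degrees) between corresponding real-space basis vectors."""
    if o1.cell != o2.cell:
        raise ValueError("orientations refer to different cells")
    A1, A2 = o1.direct_matrix(), o2.direct_matrix()
    angles = []
    for j in range(3):
        v1, v2 = A1[:, j], A2[:, j]
        cosang = np.clip(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1.0, 1.0)
        angles.append(np.degrees(np.arccos(cosang)))
    return float(np.mean(angles))


def mean_orientation(reference: Orientation, ensemble: MosaicEnsemble) -> Orientation:
    """Orientation whose U is the rotation average over the domain ensemble
    (the 'fine-grained' ground truth of a mosaic crystal)."""
    Us = np.einsum("nij,jk->nik", ensemble.rotations, reference.U)
    mean = Rotation.from_matrix(Us).mean().as_matrix()
    return Orientation(mean, reference.B, reference.cell)


def _symmetry_images(hkl: np.ndarray, space_group: str, anomalous: bool) -> list[np.ndarray]:
    h, k, l = hkl[:, 0], hkl[:, 1], hkl[:, 2]
    images = [hkl]
    if space_group == "C2":
        images.append(np.stack([-h, k, -l], axis=1))  # 2-fold along b
    if not anomalous:
        images = images + [-im for im in images]      # add Friedel mates
    return images


def generate_hkl(cell: UnitCell, d_min: float, d_max: float,
                 anomalous: bool = True) -> np.ndarray:
    """Unique Miller indices with d_min <= d <= d_max (inclusive bounds).

    C-centering absences (h + k odd) are removed for C2; the set is reduced
    to the asymmetric unit of the point group, keeping Friedel mates
    distinct when ``anomalous``.
    """
    if not 0 < d_min < d_max:
        raise ValueError("require 0 < d_min < d_max")
    gstar = cell.reciprocal_metric_tensor()
    # conservative index bounds from the direct cell edges
    hmax = int(np.ceil(cell.a / d_min)) + 1
    kmax = int(np.ceil(cell.b / d_min)) + 1
    lmax = int(np.ceil(cell.c / d_min)) + 1
    h, k, l = np.meshgrid(np.arange(-hmax, hmax + 1),
                          np.arange(-kmax, kmax + 1),
                          np.arange(-lmax, lmax + 1), indexing="ij")
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    if cell.space_group == "C2":
        hkl = hkl[(hkl[:, 0] + hkl[:, 1]) % 2 == 0]
    s2 = np.einsum("ni,ij,nj->n", hkl.astype(float), gstar, hkl.astype(float))
    d = 1.0 / np.sqrt(s2)
    hkl = hkl[(d >= d_min) & (d <= d_max)]
    # keep the lexicographically largest member of each symmetry orbit
    keep = np.ones(len(hkl), dtype=bool)
    for im in _symmetry_images(hkl, cell.space_group, anomalous)[1:]:
        # lexicographic hkl >= im
        gt = (hkl[:, 0] > im[:, 0]) | (
            (hkl[:, 0] == im[:, 0]) & ((hkl[:, 1] > im[:, 1]) | (
                (hkl[:, 1] == im[:, 1]) & (hkl[:, 2] >= im[:, 2]))))
        keep &= gt
    return hkl[keep]
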