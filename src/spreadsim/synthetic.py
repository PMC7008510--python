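"""Toy-system factory: a small two-metal crystal and end-to-end fixtures.

The toy stands in for a metalloprotein with a mixed-valence metal pair: a
small P1 cell holding ~20 light atoms plus two Fe sites at least 2.7 A
apart, one assigned charge +3 (oxidized) and one +2 (reduced).  The metal
fraction of the total scattering is deliberately higher than in a real
protein so that anomalous-curve recovery converges with hundreds rather
than tens of thousands of images; the data-size behaviour is demonstrated
qualitatively by sweeping image counts.

``make_fixture`` runs the forward simulator over many shots — one fixed
25-domain mosaic ensemble reused for every image, a fresh random
orientation and SASE spectrum per shot — cuts region-of-interest
shoeboxes, and returns everything the inference engine and the tests
need, including the ground-truth ledger.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .crystal import (MosaicEnsemble, Orientation, UnitCell, generate_hkl,
                      mosaic_ensemble, random_orientation)
from .curves import EdgeModelParams, EnergyGrid, ScatteringCurve, make_grid, synth_edge_curve
from .detector import DetectorPanel, roi_mask
from .sfcalc import AtomSite, StructureFactorSet, build_sfset
from .shoeboxes import Shoebox, cut_shoeboxes, fit_background_plane, predict_spots
from .simulate import SimulationConfig, background_model, simulate_image
from .spectrum import SASESpectrum, generate_sase

__all__ = [
    "ToySystem",
    "Fixture",
    "make_toy_system",
    "make_fixture",
    "inject_orientation_errors",
    "toy_panel",
]

LIGHT_ELEMENTS = ["C"] * 12 + ["N"] * 4 + ["O"] * 4

# Mosaic-domain FWHM for the toy geometry.  At the pulled-in toy detector a
# pixel subtends ~1e-3 1/A of reciprocal space; 60 nm domains give the
# reciprocal-lattice peak a comparable width, so the 25-domain sum is a
# quasi-smooth sampling of the mosaic continuum (the assumption the
# analysis profiles rest on), just as 400 nm domains are for the
# full-scale detector geometry.
TOY_D_EFF_NM = 60.0


@dataclass
class ToySystem:
    cell: UnitCell
    atoms: list[AtomSite]
    truth_curves: dict[int, ScatteringCurve]     # per metal site
    truth_assignment: dict[int, int]             # site -> charge
    edge_params: EdgeModelParams

    @property
    def metal_sites(self) -> list[AtomSite]:
        return [a for a in self.atoms if a.is_refinable_metal]

    def metal_distance_A(self) -> float:
        m = self.metal_sites
        G = self.cell.metric_tensor()
        d = np.asarray(m[0].frac_xyz) - np.asarray(m[1].frac_xyz)
        return float(np.sqrt(d @ G @ d))


def make_toy_system(seed: int = 0, grid: EnergyGrid | None = None,
                    cell: UnitCell | None = None,
                    n_light: int = 20, min_metal_distance: float = 2.7,
                    edge_params: EdgeModelParams | None = None) -> ToySystem:
    """Reproducible toy crystal with two Fe sites in different valence
    states (site 0 oxidized +3, site 1 reduced +2)."""
    rng = np.random.default_rng(seed)
    grid = grid or make_grid(50)
    cell = cell or UnitCell(40.0, 32.0, 24.0)
    params = edge_params or EdgeModelParams()
    atoms: list[AtomSite] = []
    for i in range(n_light):
        el = LIGHT_ELEMENTS[i % len(LIGHT_ELEMENTS)]
        atoms.append(AtomSite(el, tuple(rng.uniform(0, 1, 3)),
                              occupancy=1.0, b_iso=float(rng.uniform(10, 20))))
    # metal pair: fixed fractional positions >= 2.7 A apart
    fe1 = np.array([0.30, 0.40, 0.35])
    offset_frac = np.array([max(min_metal_distance, 3.2) / cell.a, 0.0, 0.0])
    fe2 = fe1 + offset_frac
    atoms.append(AtomSite("Fe", tuple(fe1), b_iso=12.0, is_refinable_metal=True))
    atoms.append(AtomSite("Fe", tuple(fe2), b_iso=12.0, is_refinable_metal=True))
    assignment = {0: 3, 1: 2}
    curves = {m: synth_edge_curve(params, q, grid, site_label=f"Fe{m + 1}(+{q})")
              for m, q in assignment.items()}
    return ToySystem(cell, atoms, curves, assignment, params)


def toy_panel() -> DetectorPanel:
    """Pulled-back wedge geometry: the panel images the left-side 150-210
    degree wedge of the 2.1-2.5 A annulus with ~8 eV per pixel of radial
    energy dispersion (beam center far off-panel to the right)."""
    return DetectorPanel(n_fast=288, n_slow=512, pixel_size=0.11,
                         distance=60.0, beam_center=(700.0, 256.0))


@dataclass
class Fixture:
    """Simulated dataset plus ground truth for recovery scoring."""

    system: ToySystem
    grid: EnergyGrid
    panel: DetectorPanel
    config: SimulationConfig
    sfset: StructureFactorSet
    ensemble_sim: MosaicEnsemble
    eta: float
    boxes: list[Shoebox] = field(default_factory=list)
    spectra: np.ndarray | None = None            # (n_images, n_channels)
    orientations: list[Orientation] = field(default_factory=list)
    kept_images: list[int] = field(default_factory=list)
    truth: dict = field(default_factory=dict)
    roi: np.ndarray | None = None

    @property
    def truth_fp(self) -> np.ndarray:
        return np.stack([self.system.truth_curves[m].f_prime
                         for m in range(len(self.system.metal_sites))])

    @property
    def truth_fdp(self) -> np.ndarray:
        return np.stack([self.system.truth_curves[m].f_double_prime
                         for m in range(len(self.system.metal_sites))])

    def save(self, directory) -> None:
        """Write the dataset to a directory (JSON/TSV; exact round-trip)."""
        import json
        from pathlib import Path
        from .curves import write_curve_tsv
        from .io import write_experiment_json
        out = Path(directory)
        (out / "truth").mkdir(parents=True, exist_ok=True)
        write_experiment_json(out / "experiment.json", self.panel,
                              self.system.cell,
                              extra={"eta_deg": self.eta,
                                     "kept_images": self.kept_images,
                                     "grid": [self.grid.n_channels,
                                              self.grid.e_min, self.grid.e_max]})
        np.savetxt(out / "spectra.tsv", self.spectra, delimiter="\t")
        np.savetxt(out / "hkl.tsv", self.sfset.hkl, fmt="%d", delimiter="\t")
        doc = {
            "config": {k: getattr(self.config, k) for k in
                       ("crystal_path_um", "beam_area_um2", "d_eff_nm",
                        "n_domains", "r_e_m", "include_background",
                        "apply_poisson", "apply_calibration", "oversample",
                        "water_path_um", "air_path_mm", "master_seed")},
            "orientations_U": [o.U.tolist() for o in self.orientations],
            "ensemble_rotations": np.asarray(self.ensemble_sim.rotations).tolist(),
            "atoms": [[a.element, list(a.frac_xyz), a.occupancy, a.b_iso,
                       a.is_refinable_metal] for a in self.system.atoms],
            "assignment": {str(k): v for k, v in self.system.truth_assignment.items()},
            "panel_seed": self.truth.get("panel_seed"),
            "boxes": [{
                "image_id": b.image_id, "spot_id": b.spot_id,
                "h0": list(b.h0), "bounds": list(b.bounds),
                "plane": list(b.background_plane), "centroid": list(b.centroid),
                "counts": b.counts.ravel().tolist(),
                "peak_mask": (b.peak_mask.ravel().astype(int).tolist()
                              if b.peak_mask is not None else None),
            } for b in self.boxes],
        }
        (out / "dataset.json").write_text(json.dumps(doc))
        for m, cur in self.system.truth_curves.items():
            write_curve_tsv(cur, out / "truth" / f"site{m}.tsv")

    @classmethod
    def load(cls, directory) -> "Fixture":
        import json
        from pathlib import Path
        from .crystal import reciprocal_B
        from .curves import EnergyGrid, read_curve_tsv
        from .io import read_experiment_json
        src = Path(directory)
        panel, cell, _, meta = read_experiment_json(src / "experiment.json")
        doc = json.loads((src / "dataset.json").read_text())
        grid = EnergyGrid(*[t(v) for t, v in zip((int, float, float), meta["grid"])])
        cfg = SimulationConfig(**doc["config"])
        atoms = [AtomSite(el, tuple(xyz), occ, b, bool(metal))
                 for el, xyz, occ, b, metal in doc["atoms"]]
        assignment = {int(k): v for k, v in doc["assignment"].items()}
        curves = {m: read_curve_tsv(src / "truth" / f"site{m}.tsv", f"site{m}")
                  for m in assignment}
        for m in curves:
            curves[m].grid = grid
        system = ToySystem(cell, atoms, curves, assignment, EdgeModelParams())
        hkl = np.loadtxt(src / "hkl.tsv", dtype=int, delimiter="\t")
        sfset = build_sfset(atoms, hkl, cell, grid)
        B = reciprocal_B(cell)
        orientations = [Orientation(np.array(U), B, cell)
                        for U in doc["orientations_U"]]
        ensemble = MosaicEnsemble(np.array(doc["ensemble_rotations"]),
                                  meta["eta_deg"])
        boxes = []
        for bd in doc["boxes"]:
            f0, f1, s0, s1 = bd["bounds"]
            counts = np.array(bd["counts"], dtype=np.int64).reshape(s1 - s0, f1 - f0)
            mask = (np.array(bd["peak_mask"], dtype=bool).reshape(counts.shape)
                    if bd["peak_mask"] is not None else None)
            boxes.append(Shoebox(bd["image_id"], bd["spot_id"], tuple(bd["h0"]),
                                 tuple(bd["bounds"]), counts, mask,
                                 tuple(bd["plane"]), tuple(bd["centroid"])))
        fx = cls(system=system, grid=grid, panel=panel, config=cfg, sfset=sfset,
                 ensemble_sim=ensemble, eta=meta["eta_deg"], boxes=boxes,
                 spectra=np.loadtxt(src / "spectra.tsv", delimiter="\t", ndmin=2),
                 orientations=orientations, kept_images=meta["kept_images"])
        fx.truth = {"curves": curves, "assignment": assignment,
                    "orientations": orientations, "G": 1.0,
                    "panel_seed": doc["panel_seed"]}
        return fx


def make_fixture(system: ToySystem, n_images: int = 180, seed: int = 0,
                 grid: EnergyGrid | None = None,
                 panel: DetectorPanel | None = None,
                 config: SimulationConfig | None = None,
                 eta: float = 0.05, n_sim_domains: int = 25,
                 d_range: tuple[float, float] = (2.1, 2.5),
                 sim_d_range: tuple[float, float] = (2.0, 2.7),
                 position_angle_range: tuple[float, float] = (150.0, 210.0),
                 margin: int = 3, peak_mask_frac: float = 0.01,
                 min_spots: int = 3) -> Fixture:
    """Simulate ``n_images`` still shots and cut region-of-interest
    shoeboxes.  Structure factors cover ``sim_d_range`` so that streaks
    from just-out-of-range neighbours still land in the simulated pixels;
    analysis shoeboxes are restricted to ``d_range``."""
    grid = grid or system.truth_curves[0].grid
    panel = panel or toy_panel()
    config = config or SimulationConfig(d_eff_nm=TOY_D_EFF_NM, master_seed=seed)
    rng = np.random.default_rng(seed)
    hkl_sim = generate_hkl(system.cell, sim_d_range[0], sim_d_range[1], anomalous=True)
    sfset = build_sfset(system.atoms, hkl_sim, system.cell, grid)
    ensemble = mosaic_ensemble(eta, n_sim_domains, seed=rng.integers(2 ** 31))
    roi = roi_mask(panel, d_range, position_angle_range)
    fx = Fixture(system=system, grid=grid, panel=panel, config=config,
                 sfset=sfset, ensemble_sim=ensemble, eta=eta, roi=roi)
    truth_fp, truth_fdp = fx.truth_fp, fx.truth_fdp
    d_of = system.cell.d_spacing(hkl_sim)
    in_range = (d_of >= d_range[0]) & (d_of <= d_range[1])
    hkl_target = hkl_sim[in_range]
    panel_seed = int(rng.integers(2 ** 31))
    spectra = np.zeros((n_images, grid.n_channels))
    orientations: list[Orientation] = []
    boxes_all: list[Shoebox] = []
    kept: list[int] = []
    truth_planes: dict[tuple, tuple] = {}
    for L in range(n_images):
        orientation = random_orientation(system.cell, seed=rng.integers(2 ** 31))
        spectrum = generate_sase(seed=rng.integers(2 ** 31), grid=grid)
        orientations.append(orientation)
        spectra[L] = spectrum.fluence
        preds = predict_spots(orientation, panel, hkl_target,
                              (grid.e_min, grid.e_max), eta_deg=eta,
                              d_eff_nm=config.d_eff_nm, margin=margin)
        if not preds:
            continue
        fasts, slows = [], []
        for p in preds:
            f0, f1, s0, s1 = p.bounds
            ff, ss = np.meshgrid(np.arange(max(f0, 0), min(f1, panel.n_fast)),
                                 np.arange(max(s0, 0), min(s1, panel.n_slow)))
            fasts.append(ff.ravel())
            slows.append(ss.ravel())
        fast = np.concatenate(fasts)
        slow = np.concatenate(slows)
        uniq = np.unique(np.stack([fast, slow], axis=1), axis=0)
        fast, slow = uniq[:, 0], uniq[:, 1]
        image = simulate_image(config, panel, orientation, ensemble, spectrum,
                               sfset, truth_fp, truth_fdp,
                               seed=int(rng.integers(2 ** 31)),
                               pixels=(fast, slow), panel_seed=panel_seed)
        img_boxes, ok = cut_shoeboxes(image, preds, roi=roi, image_id=L,
                                      min_spots=min_spots)
        if not ok:
            continue
        # peak masks from the noiseless Bragg model, then background planes
        bg_full = background_model(panel, fast, slow, config.water_path_um,
                                   config.air_path_mm,
                                   total_photons=spectrum.total_photons)
        bragg = np.zeros_like(image.photons)
        bragg[slow, fast] = image.photons[slow, fast] - bg_full
        for box in img_boxes:
            f0, f1, s0, s1 = box.bounds
            sig = bragg[s0:s1, f0:f1]
            box.peak_mask = sig > peak_mask_frac * max(sig.max(), 1e-12)
            fit_background_plane(box)
            bgbox = image.photons[s0:s1, f0:f1] - sig
            pp, qq = box.local_pq()
            X = np.stack([pp, qq, np.ones_like(pp)], axis=1)
            coef, *_ = np.linalg.lstsq(X, bgbox.ravel(), rcond=None)
            truth_planes[(L, box.spot_id)] = tuple(float(v) for v in coef)
        boxes_all.extend(img_boxes)
        kept.append(L)
    fx.boxes = boxes_all
    fx.spectra = spectra
    fx.orientations = orientations
    fx.kept_images = kept
    fx.truth = {
        "curves": system.truth_curves,
        "assignment": system.truth_assignment,
        "orientations": orientations,
        "planes": truth_planes,
        "G": 1.0,
        "panel_seed": panel_seed,
    }
    return fx


def inject_orientation_errors(fixture_or_orientations, scale_deg: float = 0.011,
                              seed: int = 0) -> list[Orientation]:
    """Per-image random horizontal/vertical missets whose combined rotation
    magnitude has median ~= ``scale_deg`` (Rayleigh median correction)."""
    from scipy.spatial.transform import Rotation
    rng = np.random.default_rng(seed)
    sd = scale_deg / np.sqrt(2.0 * np.log(2.0))
    orientations = (fixture_or_orientations.orientations
                    if isinstance(fixture_or_orientations, Fixture)
                    else fixture_or_orientations)
    perturbed = []
    for o in orientations:
        rx, ry = rng.normal(0.0, sd, 2)
        R = (Rotation.from_euler("x", rx, degrees=True)
             * Rotation.from_euler("y", ry, degrees=True)).as_matrix()
        perturbed.append(o.rotated(R))
    return perturbed


def assemble_dataset(fixture: Fixture, n_analysis_domains: int = 200,
                     ensemble_seed: int = 99, orientations=None,
                     fine_grained: bool = True, dtype=np.float32):
    """Build the flattened refinement payload from a fixture: per-image
    geometric profiles with a large, re-centered analysis ensemble, plus all
    shoeboxes.

    ``orientations`` overrides the per-image orientations (e.g. the
    profile-refined estimates); indexed by image id.  By default the
    fine-grained ground truth is used — the average setting over the
    simulation's mosaic ensemble, which is what "accurately known
    orientations" means for a mosaic crystal (the nominal setting sits
    ~eta/sqrt(n_domains) away from it).
    """
    from .crystal import mean_orientation
    from .inference import PrecomputedProfiles, SpreadData, build_profiles
    ens = mosaic_ensemble(fixture.eta, n_analysis_domains, seed=ensemble_seed,
                          recenter=True)
    per_img: dict[int, list[Shoebox]] = {}
    for b in fixture.boxes:
        per_img.setdefault(b.image_id, []).append(b)
    if orientations is None:
        if fine_grained:
            orientations = [mean_orientation(o, fixture.ensemble_sim)
                            for o in fixture.orientations]
        else:
            orientations = fixture.orientations
    profiles, boxes, h_index = [], [], []
    for L in fixture.kept_images:
        prof = build_profiles(orientations[L], ens, fixture.panel, per_img[L],
                              fixture.sfset, fixture.config, dtype=dtype)
        profiles.extend(prof.profiles)
        boxes.extend(per_img[L])
        h_index.extend(fixture.sfset.lookup(b.h0) for b in per_img[L])
    return SpreadData(fixture.sfset, fixture.spectra, boxes,
                      PrecomputedProfiles(profiles, fixture.grid, n_analysis_domains),
                      np.array(h_index))


def orientation_recovery_study(fixture: Fixture, scale_deg: float = 0.011,
                               seed: int = 5, n_analysis_domains: int = 200,
                               ensemble_seed: int = 99, max_boxes: int = 8,
                               start_curves: tuple[np.ndarray, np.ndarray] | None = None
                               ) -> dict:
    """Inject per-image orientation errors and refine them away.

    Missets with median rotation magnitude ``scale_deg`` are applied to the
    fine-grained ground truth of every image (the average setting over the
    simulation's mosaic ensemble — which is what data-derived orientation
    estimates track); the two-parameter profile-based refinement is run per
    image and residual missetting angles are measured against the same
    fine-grained truth.  Returns before/after residuals and their medians
    (degrees).
    """
    from .crystal import mean_orientation, missetting_angle
    from .inference import refine_orientation
    fine_truth = {L: mean_orientation(fixture.orientations[L], fixture.ensemble_sim)
                  for L in fixture.kept_images}
    perturbed_list = inject_orientation_errors(
        [fine_truth[L] for L in fixture.kept_images], scale_deg, seed=seed)
    perturbed = dict(zip(fixture.kept_images, perturbed_list))
    ens = mosaic_ensemble(fixture.eta, n_analysis_domains, seed=ensemble_seed,
                          recenter=True)
    per_img: dict[int, list[Shoebox]] = {}
    for b in fixture.boxes:
        per_img.setdefault(b.image_id, []).append(b)
    fp, fdp = (start_curves if start_curves is not None
               else (fixture.truth_fp, fixture.truth_fdp))
    before, after = [], []
    for L in fixture.kept_images:
        fine = fine_truth[L]
        before.append(missetting_angle(perturbed[L], fine))
        _, _, refined = refine_orientation(
            per_img[L], fixture.panel, perturbed[L], ens, fixture.sfset,
            fixture.config, fixture.spectra[L], fp, fdp, max_boxes=max_boxes)
        after.append(missetting_angle(refined, fine))
    return {
        "before": before,
        "after": after,
        "median_before": float(np.median(before)),
        "median_after": float(np.median(after)),
        "n_images": len(after),
    }
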