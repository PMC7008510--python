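"""Pixel likelihood, gradients, group refinement and profile building."""
import numpy as np
import pytest
from scipy.stats import poisson as poisson_dist

import spreadsim as sp
from spreadsim.crystal import mosaic_ensemble
from spreadsim.curves import ScatteringCurve, smoothness_prior_nll
from spreadsim.inference import (SpreadModel, build_profiles, poisson_nll)
from spreadsim.simulate import background_model

from conftest import assemble_data, boxes_by_image


@pytest.fixture(scope="module")
def small_data(small_fixture):
    ens = mosaic_ensemble(small_fixture.eta, 200, seed=99)
    return assemble_data(small_fixture, ens, dtype=np.float64)


@pytest.fixture(scope="module")
def small_model(small_data):
    return SpreadModel(small_data)


def truth_params(fx, data):
    fp, fdp = fx.truth_fp, fx.truth_fdp
    planes = np.array([b.background_plane for b in data.boxes])
    return fp, fdp, planes


class TestPoissonNll:
    def test_worked_value(self):
        assert poisson_nll(np.array([0]), np.array([1.0])) == pytest.approx(1.0)

    def test_minimum_at_lambda_equals_k(self):
        k = 7.0
        lams = np.linspace(3, 12, 181)
        vals = [poisson_nll(np.array([k]), np.array([l])) for l in lams]
        assert lams[np.argmin(vals)] == pytest.approx(k, abs=0.06)

    def test_equals_exact_pmf_up_to_constant(self):
        rng = np.random.default_rng(1)
        k = rng.integers(0, 50, 100)
        lam = rng.uniform(0.1, 40, 100)
        from scipy.special import gammaln
        exact = -(poisson_dist.logpmf(k, lam)) - gammaln(k + 1.0)
        ours = np.array([poisson_nll(np.array([ki]), np.array([li]))
                         for ki, li in zip(k, lam)])
        assert np.allclose(ours, exact, atol=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            poisson_nll(np.array([1]), np.array([0.0]))
        with pytest.raises(ValueError):
            poisson_nll(np.array([-1]), np.array([1.0]))


class TestProfiles:
    def test_nonnegative_and_peaked(self, small_data):
        ratios = []
        for prof in small_data.profiles.profiles:
            assert (prof >= 0).all()
            per_channel = prof.sum(axis=0)
            ratios.append(per_channel.max() / max(per_channel.min(), 1e-300))
        # on-Ewald channels dominate off-Ewald ones for the typical spot
        # (broad streaks from small domains can be nearly flat)
        assert np.median(ratios) > 5.0

    def test_channel_support_contiguous(self, small_data):
        # with the 200-member analysis ensemble a spot's channel coverage has
        # no interior holes (motivation for the large ensemble)
        for prof in small_data.profiles.profiles:
            per_channel = prof.sum(axis=0)
            live = per_channel > per_channel.max() * 1e-6
            idx = np.nonzero(live)[0]
            assert (np.diff(idx) == 1).all()

    def test_matches_simulator_with_shared_ensemble(self, noiseless_fixture):
        # using the simulation ensemble, the profile-based model reproduces
        # the simulator's noiseless pixels exactly (ground-truth params, G=1)
        fx = noiseless_fixture
        data = assemble_data(fx, fx.ensemble_sim, dtype=np.float64, fine_grained=False)
        I = fx.sfset.intensities(fx.truth_fp, fx.truth_fdp)
        worst = 0.0
        for i, box in enumerate(data.boxes):
            B = data.profiles.profiles[i] @ (fx.spectra[box.image_id] * I[data.h_index[i]])
            fast, slow = box.pixel_indices()
            bg = background_model(fx.panel, fast, slow,
                                  total_photons=fx.spectra[box.image_id].sum())
            obs = box.counts.ravel()
            big = obs > 1.0
            if big.any():
                worst = max(worst, np.abs((B + bg)[big] - obs[big]).max()
                            / obs[big].max())
        assert worst < 1e-6


class TestTotalLoss:
    def test_prior_composition(self, small_fixture, small_model, small_data):
        fp, fdp, planes = truth_params(small_fixture, small_data)
        G = np.ones(small_data.n_images)
        lb = small_model.total_loss(fp, fdp, G, planes)
        expected_prior = sum(
            smoothness_prior_nll(ScatteringCurve(f"s{m}", small_fixture.grid,
                                                 fp[m], fdp[m]))
            for m in range(2))
        assert lb.prior_nll == pytest.approx(expected_prior, rel=1e-12)
        assert lb.total == lb.data_nll + lb.prior_nll

    def test_matches_scalar_reference_two_boxes(self, small_fixture, small_data):
        # fully scalar (per-pixel loop) likelihood on a 2-shoebox subset
        fx = small_fixture
        sub = small_data.subset([small_data.boxes[0].image_id])
        sub.boxes = sub.boxes[:2]
        sub.profiles.profiles = sub.profiles.profiles[:2]
        sub.h_index = sub.h_index[:2]
        sub.__post_init__()
        model = SpreadModel(sub)
        fp, fdp = fx.truth_fp, fx.truth_fdp
        planes = np.array([b.background_plane for b in sub.boxes])
        G = np.array([1.3])
        lb = model.total_loss(fp, fdp, G, planes)
        I = fx.sfset.intensities(fp, fdp)
        ref = 0.0
        for i, box in enumerate(sub.boxes):
            prof = sub.profiles.profiles[i]
            J0 = fx.spectra[box.image_id]
            p, q = box.local_pq()
            k = box.counts.ravel()
            for px in range(box.n_pixels):
                lam = planes[i][0] * p[px] + planes[i][1] * q[px] + planes[i][2]
                for c in range(fx.grid.n_channels):
                    lam += G[0] * J0[c] * I[sub.h_index[i], c] * prof[px, c]
                lam = max(lam, 1e-6)
                ref += lam - k[px] * np.log(lam)
        assert lb.data_nll == pytest.approx(ref, rel=1e-10)

    def test_gradients_match_finite_differences(self, small_fixture, small_model,
                                                small_data):
        fx = small_fixture
        rng = np.random.default_rng(5)
        fp = fx.truth_fp + rng.normal(0, 0.3, fx.truth_fp.shape)
        fdp = np.clip(fx.truth_fdp + rng.normal(0, 0.3, fx.truth_fdp.shape), 0.05, None)
        planes = np.array([b.background_plane for b in small_data.boxes])
        G = np.clip(rng.normal(1.0, 0.1, small_data.n_images), 0.5, None)
        lb = small_model.total_loss(fp, fdp, G, planes,
                                    grads=("scales", "planes", "curves"))

        def loss_at(fp_, fdp_, G_, planes_):
            return small_model.total_loss(fp_, fdp_, G_, planes_).total

        # scales
        for L in rng.choice(small_data.n_images, 3, replace=False):
            h = 1e-5 * max(G[L], 1.0)
            Gp, Gm = G.copy(), G.copy()
            Gp[L] += h
            Gm[L] -= h
            fd = (loss_at(fp, fdp, Gp, planes) - loss_at(fp, fdp, Gm, planes)) / (2 * h)
            assert fd == pytest.approx(lb.gradients["G"][L], rel=2e-4, abs=1e-3)
        # planes
        for bidx in rng.choice(small_data.n_boxes, 3, replace=False):
            for j in range(3):
                h = 1e-6
                Pp, Pm = planes.copy(), planes.copy()
                Pp[bidx, j] += h
                Pm[bidx, j] -= h
                fd = (loss_at(fp, fdp, G, Pp) - loss_at(fp, fdp, G, Pm)) / (2 * h)
                assert fd == pytest.approx(lb.gradients["planes"][bidx, j],
                                           rel=2e-4, abs=1e-3)
        # curves (interior channels)
        for m in (0, 1):
            for c in rng.choice(np.arange(1, fx.grid.n_channels - 1), 4, replace=False):
                h = 1e-4
                fpp, fpm = fp.copy(), fp.copy()
                fpp[m, c] += h
                fpm[m, c] -= h
                fd = (loss_at(fpp, fdp, G, planes) - loss_at(fpm, fdp, G, planes)) / (2 * h)
                assert fd == pytest.approx(lb.gradients["fp"][m, c], rel=2e-4, abs=2e-2)
                fdpp, fdpm = fdp.copy(), fdp.copy()
                fdpp[m, c] += h
                fdpm[m, c] -= h
                fd = (loss_at(fp, fdpp, G, planes) - loss_at(fp, fdpm, G, planes)) / (2 * h)
                assert fd == pytest.approx(lb.gradients["fdp"][m, c], rel=2e-4, abs=2e-2)

    def test_gradient_zero_when_model_equals_data(self, small_fixture, small_data):
        # if Lambda_i = k_i at every pixel the data gradient vanishes
        fx = small_fixture
        sub = small_data.subset([small_data.boxes[0].image_id])
        model = SpreadModel(sub)
        fp, fdp = fx.truth_fp.copy(), fx.truth_fdp.copy()
        planes = np.array([b.background_plane for b in sub.boxes])
        G = np.ones(sub.n_images)
        lam, B, clipped, I = model._model_terms(fp, fdp, G, planes)
        for i, box in enumerate(sub.boxes):
            box.counts = np.rint(lam[sub.slices[i]]).reshape(box.counts.shape).astype(int)
        sub.__post_init__()
        model2 = SpreadModel(sub)
        # set counts exactly equal to the (floored) model
        for i, box in enumerate(sub.boxes):
            sl = sub.slices[i]
            sub.k[sl] = lam[sl]
        lb = model2.total_loss(fp, fdp, G, planes, grads=("scales", "planes"))
        assert np.abs(lb.gradients["G"]).max() < 1e-6 * max(1.0, np.abs(lam).max())
        assert np.abs(lb.gradients["planes"]).max() < 1e-6


class TestScaleConventions:
    def test_gradients_with_background_inside_scale(self, small_fixture, small_data):
        # alternative convention Lambda = G (g + Bragg): gradients stay
        # consistent with finite differences
        fx = small_fixture
        model = SpreadModel(small_data, background_in_scale=True)
        rng = np.random.default_rng(9)
        fp, fdp = fx.truth_fp, fx.truth_fdp
        planes = np.array([b.background_plane for b in small_data.boxes])
        G = np.clip(rng.normal(1.0, 0.1, small_data.n_images), 0.5, None)
        lb = model.total_loss(fp, fdp, G, planes, grads=("scales", "planes"))

        def loss_at(G_, planes_):
            return model.total_loss(fp, fdp, G_, planes_).total

        for L in rng.choice(small_data.n_images, 2, replace=False):
            h = 1e-6
            Gp, Gm = G.copy(), G.copy()
            Gp[L] += h
            Gm[L] -= h
            fd = (loss_at(Gp, planes) - loss_at(Gm, planes)) / (2 * h)
            assert fd == pytest.approx(lb.gradients["G"][L], rel=5e-4, abs=1e-2)
        for bidx in rng.choice(small_data.n_boxes, 2, replace=False):
            h = 1e-6
            Pp, Pm = planes.copy(), planes.copy()
            Pp[bidx, 2] += h
            Pm[bidx, 2] -= h
            fd = (loss_at(G, Pp) - loss_at(G, Pm)) / (2 * h)
            assert fd == pytest.approx(lb.gradients["planes"][bidx, 2],
                                       rel=5e-4, abs=1e-2)


class TestRefinement:
    def test_truth_start_is_near_stationary(self, small_fixture, small_data):
        fx = small_fixture
        model = SpreadModel(small_data)
        res = model.fit(fx.system.truth_curves if hasattr(fx, "system")
                        else fx.truth["curves"], n_macrocycles=1,
                        truth=fx.truth["curves"])
        losses = [h["loss"] for h in res.loss_history]
        assert losses == sorted(losses, reverse=True)

    def test_background_only_planes_match_least_squares(self):
        # boxes with zero Bragg profile: Poisson plane refinement at high
        # counts converges to the weighted plane (near the LS solution)
        from spreadsim.inference import PrecomputedProfiles, SpreadData
        from spreadsim.shoeboxes import Shoebox
        from spreadsim.curves import make_grid
        rng = np.random.default_rng(2)
        grid = make_grid(5, 7100, 7150)
        cell = sp.UnitCell(10, 12, 14)
        atoms = [sp.AtomSite("Fe", (0.2, 0.3, 0.4), is_refinable_metal=True)]
        hkl = sp.generate_hkl(cell, 2.0, 4.0, anomalous=True)
        from spreadsim.sfcalc import build_sfset
        sfset = build_sfset(atoms, hkl, cell, grid)
        boxes, profs = [], []
        truth_planes = []
        for i in range(4):
            a, b, c = rng.uniform(-0.3, 0.3), rng.uniform(-0.3, 0.3), rng.uniform(40, 60)
            ny, nx = 21, 21
            p, q = np.meshgrid(np.arange(ny) - 10.0, np.arange(nx) - 10.0, indexing="ij")
            lam = a * p + b * q + c
            counts = rng.poisson(lam)
            boxes.append(Shoebox(image_id=0, spot_id=i, h0=tuple(hkl[0]),
                                 bounds=(0, nx, 0, ny), counts=counts))
            profs.append(np.zeros((ny * nx, 5)))
            truth_planes.append((a, b, c))
        data = SpreadData(sfset, np.zeros((1, 5)), boxes,
                          PrecomputedProfiles(profs, grid, 1),
                          np.zeros(4, dtype=int))
        model = SpreadModel(data)
        fp = np.zeros((1, 5))
        fdp = np.zeros((1, 5))
        planes0 = np.array([(0.0, 0.0, float(b.counts.mean())) for b in boxes])
        G, planes, _ = model.refine_scales_and_planes(fp, fdp, np.ones(1), planes0,
                                                      max_iter=200)
        for est, true in zip(planes, truth_planes):
            # 4-sigma least-squares tolerances: sd(c) ~ sqrt(50/441) ~ 0.34,
            # sd(a) = sd(b) ~ sqrt(50 / 16170) ~ 0.056
            assert est[2] == pytest.approx(true[2], abs=1.5)
            assert est[0] == pytest.approx(true[0], abs=0.25)
            assert est[1] == pytest.approx(true[1], abs=0.25)


class TestResultsApi:
    def test_summary_and_edges(self, small_fixture, small_data):
        fx = small_fixture
        model = SpreadModel(small_data)
        res = model.fit(fx.truth["curves"], n_macrocycles=1, truth=fx.truth["curves"])
        text = res.summary()
        assert "shoeboxes" in text and "edge energy" in text
        for m in (0, 1):
            e = res.edge_energy(m)
            assert fx.grid.e_min < e < fx.grid.e_max
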