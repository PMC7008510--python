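"""Shared fixtures: a small simulated dataset reused across unit tests."""
from __future__ import annotations

import numpy as np
import pytest

import spreadsim as sp
from spreadsim.inference import PrecomputedProfiles, SpreadData, build_profiles
from spreadsim.simulate import SimulationConfig
from spreadsim.synthetic import TOY_D_EFF_NM


def toy_config(**kw) -> SimulationConfig:
    kw.setdefault("d_eff_nm", TOY_D_EFF_NM)
    return SimulationConfig(**kw)


@pytest.fixture(scope="session")
def toy_system():
    return sp.make_toy_system(seed=1)


@pytest.fixture(scope="session")
def small_fixture(toy_system):
    """A 12-image simulated dataset with noise, for unit-level checks."""
    return sp.make_fixture(toy_system, n_images=12, seed=11, config=toy_config())


@pytest.fixture(scope="session")
def noiseless_fixture(toy_system):
    """A 6-image dataset without calibration or Poisson noise."""
    cfg = toy_config(apply_poisson=False, apply_calibration=False)
    return sp.make_fixture(toy_system, n_images=6, seed=12, config=cfg)


def boxes_by_image(fixture):
    out: dict[int, list] = {}
    for b in fixture.boxes:
        out.setdefault(b.image_id, []).append(b)
    return out


def assemble_data(fixture, ensemble, dtype=np.float32,
                  fine_grained: bool = True) -> SpreadData:
    """Build the flattened refinement payload from a fixture with an
    explicit ensemble (tests sometimes need the simulation ensemble or
    float64 profiles)."""
    from spreadsim.crystal import mean_orientation
    per_img = boxes_by_image(fixture)
    profiles, boxes, h_index = [], [], []
    for L in fixture.kept_images:
        o = fixture.orientations[L]
        if fine_grained:
            o = mean_orientation(o, fixture.ensemble_sim)
        prof = build_profiles(o, ensemble, fixture.panel,
                              per_img[L], fixture.sfset, fixture.config, dtype=dtype)
        profiles.extend(prof.profiles)
        boxes.extend(per_img[L])
        h_index.extend(fixture.sfset.lookup(b.h0) for b in per_img[L])
    return SpreadData(fixture.sfset, fixture.spectra, boxes,
                      PrecomputedProfiles(profiles, fixture.grid, ensemble.n_domains),
                      np.array(h_index))
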