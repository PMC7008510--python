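# spreadsim

Pixel-level simulation of polychromatic XFEL still-shot protein
diffraction, plus the Bayesian maximum-likelihood engine that recovers
per-metal-site, energy-dependent anomalous scattering corrections
Δf′(E), Δf″(E) directly from the pixel counts.

**Who it is for.**  The K absorption edge of a transition metal shifts
1–2 eV higher when the metal is oxidized, so the absorption curve of each
individual metal site — recovered crystallographically, which gives
spatial resolution — distinguishes Fe³⁺ from Fe²⁺ (spatially resolved
anomalous dispersion, SPREAD).  This package is for people studying
whether that measurement works with the broadband, stochastically spiky
self-amplified spontaneous emission (SASE) pulses of an X-ray free
electron laser: it provides an absolute-scale (photons/pixel) forward
simulator for mosaic-crystal still shots, and an inference engine that
fits per-site anomalous curves against every shoebox pixel at once.

## The model

Still-shot pixel intensities follow the kinematic model

    I_i = r_e² P_i ΔΩ_i Σ_c J0(c) |F(c; h₀)|² Σ_D F_latt²[S(c)]

summed over energy channels c (a measured or synthetic per-pulse spectrum
J0) and mosaic domains D (Gaussian reciprocal-lattice peaks,
F_latt = N_cells exp(−Δx²/0.63)).  The structure factor splits as
F = F_fixed + Σ_m q_m (f0 + Δf′_m + iΔf″_m) e^{2πih·r_m} e^{−B_m|S|²/4},
linear in the per-site corrections.  Inference minimizes the negative log
posterior

    L = Σ_i (Λ_i − k_i ln Λ_i)  +  smoothness prior on dΔf/dE,

with Λ_i = g_{x,i} + G_L Σ_c J0(c) |F_sim(c)|² · profile_i(c), by
alternating L-BFGS macrocycles over per-image scales + per-spot background
planes and over the curves themselves.  A two-parameter profile-based
orientation refinement (rotations about the horizontal and vertical lab
axes, scored by the same pixel likelihood) sharpens per-image orientations
to a few thousandths of a degree.  See `docs/methods.md` for the full
account.

## Worked example

```python
import spreadsim as sp
from spreadsim.curves import baseline_curve

system = sp.make_toy_system(seed=1)           # two Fe sites: +3 and +2
fx = sp.make_fixture(system, n_images=260, seed=3)
data = sp.assemble_dataset(fx)                # profiles, 200-member ensemble
model = sp.SpreadModel(data)
start = {m: baseline_curve("Fe", fx.grid) for m in range(2)}  # neutral iron
res = model.fit(start, n_macrocycles=3, truth=system.truth_curves)
print(res.summary())
```

Output (about six minutes, most of it profile precomputation):

```
SPREAD anomalous-curve refinement
================================================
images: 260   shoeboxes: 2888   pixels: 472503
channels: 50 over [7070, 7170] eV
final loss: -12669850.826

site      edge energy (eV)    max f'' (e-)
site0              7123.65           4.549
site1              7120.37           4.247

cycle     rmsd fp (e-)  rmsd fdp (e-)
0               1.3915         1.6243
1               0.7222         0.5920
2               0.4672         0.3673
3               0.3571         0.3114
```

Reading it: starting from neutral-iron curves (no edge information at
all), three macrocycles reduce the root-mean-square error of the fitted
Δf″ curves against the ground truth (over the 7105–7136 eV window) from
1.62 e⁻ to 0.31 e⁻, and the fitted absorption edges land at 7123.7 eV for
site 0 and 7120.4 eV for site 1 — the oxidized site's edge is higher, so
the valence assignment is read directly off the refined curves.
`res.plot_curves(truth=system.truth_curves)` overlays fit and truth.

A thin CLI wraps the same calls:

```bash
spreadsim simulate --n-images 2 --seed 7 --out run/
spreadsim refine --n-images 60 --seed 1 --start-valence 0,0 --out refined/
spreadsim evaluate --model refined/site0_refined.tsv --truth truth.tsv
```

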