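# Methods

`spreadsim` models one experiment end to end: serial femtosecond
crystallography of a metalloprotein with the full (self-amplified
spontaneous emission, SASE) bandwidth of an XFEL, followed by Bayesian
recovery of the energy-dependent anomalous scattering corrections
Δf′(E), Δf″(E) of each metal site directly from pixel intensities.  The
point of the exercise is spatially resolved valence discrimination: the
K absorption edge of a transition metal shifts 1–2 eV higher per unit of
oxidation, so per-site absorption curves recovered from diffraction can
tell an Fe³⁺ site from an Fe²⁺ site.

## Forward model

**Structure factors.**  The unit-cell structure factor is split into a
fixed part and a refinable metal part,

    F_model(λ, h) = F_fixed(h) + F_fit(λ, h),

    F_fit = Σ_m q_m [f0_m(|S|) + Δf′_m(E) + i Δf″_m(E)]
                e^{2πi h·r_m} e^{−B_m |S|²/4}.

F_fixed carries all other atoms with their own (weak, energy-independent
near 7.1 keV) anomalous terms evaluated once at 7122 eV.  Bulk solvent is
the multiplicative Babinet form `1 − k_sol exp(−B_sol |S|²/4)` with
k_sol = 0.435, B_sol = 46 Å² applied to the total; in the narrow 2.1–2.5 Å
analysis shell this is a small, smooth correction (≈0.95), which is why the
simpler multiplicative form is used instead of a mask-based FFT solvent.
Normal form factors are the 4-Gaussian parametrization via gemmi;
neutral-atom Δf′/Δf″ baselines are computed at run time with the
Cromer–Liberman algorithm (also via gemmi).  Because F_model is affine in
every (Δf′_m, Δf″_m) with constant complex coefficients, the inference
gradients are analytic.

**Pixel intensities.**  For pixel i on a still shot,

    I_i = r_e² P_i ΔΩ_i Σ_c J0(c) |F_model(c; h₀)|² Σ_D F_latt²[S(c)],

with J0 the per-channel incident fluence (photons/channel/m²), P the Kahn
polarization factor for a horizontally polarized beam, ΔΩ the pixel solid
angle with obliquity, h₀ the nearest integer Miller index to the pixel's
fractional reciprocal position h = A*⁻¹(s₁ − s₀), and F_latt the Gaussian
reciprocal-lattice-peak model

    F_latt = N_cells exp(−Δx²/0.63),
    Δx² = (Δh·Na)² + (Δk·Nb)² + (Δl·Nc)².

The 0.63 constant matches the Gaussian's FWHM and volume to the grating
function of a rectangular Na×Nb×Nc domain (verified to 6% against
sin²(πNx)/sin²(πx) in the tests).  Mosaicity is an ensemble of rigid
domains: axes uniform on the hemisphere, signed magnitudes N(0, η),
η = 0.05°; 25 domains for simulation (one fixed draw reused for every
image) and a 200-member ensemble for analysis profiles.  The sampled
domains stand in for the full illuminated volume (4 µm path × 1 µm²
focus), so the domain sum carries the volume ratio
illuminated-cells / (n_domains × cells-per-domain); the absolute scale is
absorbed by the per-image scale G_L during inference anyway.  The classical
electron radius defaults to the CODATA value and is exposed in
`SimulationConfig`.

Water (100 µm path) and air (10 mm) contribute a smooth radial background
— a parametric stand-in with the water ring peaking in the 3–4 Å band and
a forward-peaked air term, scaled to a few photons per pixel at 10¹²
photons/pulse.  It reproduces magnitude and shape class, not any measured
background curve.  Measurement noise is a fixed per-pixel calibration
pattern (gain factors N(1, 0.01), frozen per panel seed across shots)
followed by Poisson sampling.  Detector parallax, charge sharing, sample
absorption and diffuse scattering are all out of model.

**SASE spectra.**  Each pulse is a sum of narrow spikes (sd 0.6 eV,
exponential amplitudes) under a Gaussian envelope whose center jitters by
N(0, 6.3 eV) about the 7120 eV set point, low-pass filtered at ≈1 eV,
scaled to a lognormal total with run mean 10¹² photons, and binned onto
the working grid (100 channels × 1 eV over 7070–7170 eV by default;
values attach to bin centers, first center 7070.5 eV).  The per-pulse
envelope FWHM of 16 eV is a derived constant: envelope width and
mean-energy jitter add in quadrature to the ≈22 eV cumulative FWHM.  A
10⁴-pulse run reproduces mean-energy sd 6.3 eV (±2%), cumulative FWHM
22 eV (±2%) and the mean total fluence.

**Kramers–Kronig transform.**  Δf′ follows from Δf″ through the
principal-value dispersion integral (sign convention f′(0) → −Z),
evaluated by singularity subtraction plus trapezoid quadrature on a
non-uniform grid.  Truncation matters: reproducing the Cromer–Liberman
f′ for Fe to better than 0.3 e⁻ requires absorption input from ~30 eV to
~300 keV; parametric edge curves are therefore transformed on a grid
padded ±2 keV with their own asymptotes, which keeps the truncation bias
inside the working window far below the refinement precision while making
the flat-curve limit exact.

## Inference

Every shoebox pixel contributes a Poisson term to the negative log
posterior

    L = Σ_i (Λ_i − k_i ln Λ_i) + Σ_m Σ_n ½(ΔΔf′/ΔE/σ₁)² + ½(ΔΔf″/ΔE/σ₂)²

with Λ_i = g_{x,i} + G_L Σ_c J0(c) |F_sim(c; h₀)|² profile_i(c).  The
background plane g = a·p + b·q + c sits outside the scale G_L (the plane
fits observed photon levels directly; the alternative convention is
implemented behind a switch).  The geometric profile r_e² P ΔΩ w Σ_D
F_latt² is precomputed per (pixel, channel) with the 200-member ensemble
and shares its kernel with the simulator, so with identical ensembles the
two agree to machine precision.  Smoothness priors use σ₁ = 0.1 e⁻/eV
(Δf′) and σ₂ = 0.2 e⁻/eV (Δf″); the first and last channels stay frozen
at their starting values.  Λ is floored at 10⁻⁶ photons (the floor zeroes
the local gradient).  Δf″ is bounded below by 0 during optimization.

Fitting alternates L-BFGS-B macrocycles over {G_L, a_x, b_x, c_x} and
over the curves {Δf′_m(E), Δf″_m(E)}, 24 iterations per group per
macrocycle, three macrocycles by default.  Initial planes come from
least squares over non-peak shoebox pixels; initial G_L from a one-pass
least-squares ratio of background-subtracted counts to the unit-scale
Bragg model (images with no appreciable model signal keep G = 1, and G is
clamped to [10⁻¹⁰, 10⁶] — an unidentifiable scale must not run away).
All derivatives are analytic and validated against central finite
differences.

**Fine-grained orientations.**  A finite mosaic ensemble has a nonzero
mean rotation (≈η/√n ≈ 0.01° for 25 domains), so the effective
orientation of the simulated data — the average over the domain settings
— differs from the nominal one by a fixed rotation shared across images.
"Accurately known orientations" therefore means the fine-grained average
setting, and the analysis uses it throughout: profiles are built at the
ensemble-mean orientations, the analysis ensemble is re-centered so its
own mean is the identity, and orientation-recovery residuals are measured
against the fine-grained truth.  Ignoring this detail costs a constant
≈0.008–0.01° pseudo-misset on every image.

**Orientation refinement.**  Starting orientations carrying small errors
are corrected by a two-parameter search (rotations about the horizontal
and vertical lab axes) scored by the same pixel likelihood, with profiles
rebuilt per trial, the per-image scale profiled out by Newton steps on its
1-D conditional, and (pixel, channel) rows pruned once against the start
orientation (the search moves the reciprocal peaks by far less than their
width).  Because the spiky per-pulse spectrum makes the likelihood
multimodal at the few-millidegree scale, the search opens with a coarse
5 × 5 grid over ±0.025° and then polishes coordinate-wise with a parabolic
search (three points per axis, range shrinking 3× per round, three
rounds).
On the toy fixture this brings ~0.011°-scale injected errors down to a
median residual of ≈0.003–0.005°, which is also where refinement started
*at* the truth saturates — the floor set by scoring 25-domain data against
the smooth 200-member model.  Injected errors ride on the fine-grained
truth, since that is what data-derived orientation estimates track.

## The toy system and what it does (not) show

The synthetic study system is a P1 cell (40 × 32 × 24 Å) with 20 light
atoms and two Fe sites 3.2 Å apart, site 0 oxidized (+3), site 1 reduced
(+2).  Ground-truth curves are parametric: an arctan edge (width 1.5 eV,
step 3.5 e⁻ over a 0.5 e⁻ floor, plus a small pre-edge Gaussian) whose
center shifts 1.5 eV per unit charge from 7118 eV, with Δf′ from the
Kramers–Kronig transform.  The metal fraction of the total scattering is
deliberately much higher than in a real metalloprotein so that recovery
converges from hundreds of images instead of tens of thousands; the
swap-the-valences intensity contrast is ≈10% rms in the analysis shell
(versus ≈1.7% for a realistic protein).

The detector is a 288 × 512 wedge panel (0.11 mm pixels, 60 mm distance,
beam center far off-panel) imaging the 150–210° position-angle wedge of
the 2.1–2.5 Å annulus at ≈8 eV of radial energy dispersion per pixel,
with 50 energy channels of 2 eV — the deconvolution stays strongly
under-resolved per pixel, as in the full-scale geometry.  The toy's
mosaic domains are 60 nm FWHM: at this pulled-in geometry a pixel
subtends ≈10⁻³ Å⁻¹ of reciprocal space, and 60 nm domains give the
reciprocal peaks a comparable width, so 25 domains sample the mosaic
continuum quasi-smoothly — the same balance the 400 nm domains strike at
the full-scale detector distance.  (With 400 nm domains at the toy
geometry the domain ridges are deeply sub-pixel; the smooth-continuum
assumption behind the analysis profiles then fails visibly and the fit
acquires a large model-mismatch bias.)

Standard fixture sizes, chosen to exercise every stage at a desk scale:
260 images (~2,900 region-of-interest shoeboxes, ~470k pixels) for curve
recovery, 100 images for the orientation study.  With these conditions a
neutral-iron (Fe⁰) start recovers both sites' curves in three macrocycles
with monotonically falling error and the correct edge ordering; four
wrong-valence starts converge to mutually consistent optima (the Fe⁰
start approaches the common optimum from farthest away and lags the
valence-assignment starts, as it also does at full scale); the
(H, K, L+1) index swap degrades the curve error by more than an order of
magnitude; and the curve error falls monotonically with the image count
when the data-size ladder is run to convergence (five macrocycles — the
scaled-down data need more alternations than the full-scale protocol's
three).

What passing these tests shows: the estimator, its gradients, the
alternating optimization, the orientation refinement, and the
simulator/model consistency all work, and valence states separate under
honestly noisy (Poisson + 1% fixed-pattern) polychromatic data.  What it
does not show: convergence at realistic metal fractions and image counts
(which required ~5×10⁴ images and supercomputer time at full fidelity),
robustness to real SASE spectrometer calibration errors, real detector
systematics, or real (non-Gaussian, inhomogeneous) mosaic texture.

## Numerical choices

- Energy grid: equal bins with values at centers; `channel_of` uses
  right-open bins, so 7120.0 eV falls in channel 50 of the default grid.
- Resolution-shell bounds are inclusive (d_min ≤ d ≤ d_max).  The C2
  reference count for cell 67.2/59.8/47.2/110.3° in 2.1–2.5 Å is 8234
  (brute-force enumeration, cross-checked against gemmi's asymmetric
  unit); a shell boundary would have to move by ~4×10⁻⁴ Å to change the
  count by the handful of reflections separating published per-shell
  totals.
- Pixel centers sit at index + 0.5, recorded in the experiment metadata;
  a regression test re-derives the beam center from simulated spot
  centroids to < 0.01 px, so no half-pixel origin ambiguity can survive.
- The lexicographically largest orbit member represents each symmetry
  orbit in `generate_hkl`; ties (centrics) resolve automatically.
- L-BFGS-B uses a memory depth of 25; convergence is declared by the
  optimizer's own relative-decrease test or the 24-iteration cap.
- Shoebox margins are 3 px beyond the predicted streak envelope; peak
  masks flag pixels above 1% of the predicted noiseless spot maximum.
- Spot prediction accepts reflections whose Laue energy lies within
  n_sigma = 3 combined mosaic + domain-size half-widths of the spectral
  range; prediction covers ≥99% of simulated signal above 1 photon.

## Known limitations

- The Gaussian reciprocal-peak model and the discrete-domain mosaic are
  approximations with a measurable model-mismatch floor: fits from the
  ground truth drift to a nonzero plateau (≈0.24 e⁻ on the toy), and all
  starts converge to that maximum-likelihood optimum rather than to the
  exact truth.
- The background stand-in is qualitative; absolute background levels from
  measured water/air curves would change shoebox signal-to-background
  ratios.
- Anisotropic (tensor) anomalous corrections, altlocs, anisotropic B
  factors and twinning are out of scope; space-group support is limited
  to P1 and C2 plus centering/point-group reduction.
- Real measured per-pulse spectra are supported only through the TSV
  reader; no FEL physics is simulated.
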