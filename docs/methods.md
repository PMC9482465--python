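# Methods

`uedkit` simulates and reduces keV electron diffraction of small molecules in
two states of matter — isolated (gas-phase) molecules and nanoscale liquid
droplets — and quantifies the mixture of the two in an observed pattern.
This note records the models, the parameters that matter, and the design
choices made where more than one reasonable option existed.

## Scattering model

All diffraction is computed in the independent atom model: each atom
scatters with its isolated-atom elastic amplitude |f(s)|, and structure
enters only through interatomic distances.  For a system of N atoms on a
scattering-vector grid s = (4π/λ) sin(θ/2):

- atomic part: I_atom(s) = Σᵢ |fᵢ(s)|²  (no structural information),
- molecular part (Debye sum over ordered pairs):
  I_mol(s) = Σᵢ≠ⱼ |fᵢ||fⱼ| cos(ηᵢ−ηⱼ) sin(s rᵢⱼ)/(s rᵢⱼ),
  with the s→0 limit of sin(x)/x taken analytically as 1,
- total: I_tot = I_atom + I_mol (+ any background),
- reduced observable: sM(s) = s · I_mol / I_atom.

Amplitudes use the Peng–Ren–Dudarev–Whelan (1996) five-Gaussian
parametrization of elastic electron scattering factors (H, C, N, O
embedded; other elements can be registered).  Per-element phases η(s)
default to zero — phase differences between light elements at ~100 kV are
negligible — but the phase slot is implemented so the general form of the
pair sum is preserved.  The electron wavelength is the relativistic
de Broglie value, 0.0370 Å at the default 100 kV.

The default grid is 0–10 Å⁻¹ at 0.02 Å⁻¹ spacing.  For systems beyond
~200 000 pairs the pair sum switches to a per-element-pair distance
histogram (bin 0.005 Å); the binning error is below 10⁻³ relative at
s = 10 Å⁻¹ and the exact pairwise path remains available and is the one
checked against a literal double-loop oracle at 10⁻¹⁰ relative.

## The glycerol reference conformer

A single fixed conformer of glycerol (C₃H₈O₃, 14 atoms) is embedded as the
reference system: an MMFF94-optimized geometry with bonded C–O 1.42–1.44 Å,
C–C 1.53 Å and geminal heavy-atom distances clustered near 2.4 Å.
Conformer averaging is deliberately out of scope — the package simulates
with one theoretical structure, as mixture decomposition requires a single
gas basis.  Simulated observables for this conformer: the I·s² display
curve peaks at 3.23 and 5.35 Å⁻¹, and the damped sine transform of sM puts
its two dominant real-space peaks at 1.42 and 2.43 Å.

## The liquid model

No experimental liquid structure is consumed; the liquid state is emulated
by packing rigid copies of the conformer into a spherical droplet:

- droplet radius fixed by the target mass density (default 1.26 g/cm³,
  bulk glycerol) and the molecule count;
- uniformly random rigid orientations; hard heavy-atom contact at
  3.2 Å (van der Waals contact of C/O), which places the first
  intermolecular neighbour shell near 4 Å and hence a structure-factor
  ring near 2π/4 ≈ 1.6 Å⁻¹;
- packing by random placement in an inflated sphere followed by rigid-body
  overlap relaxation (pair forces and torques with capped steps) under
  stepwise compression to the target radius.  Pure rejection sampling
  (RSA) cannot reach the required packing fraction (≈0.59 for these
  contact spheres) and jams near two thirds of the target count; the
  relaxation scheme packs 200 molecules in well under a second and is
  deterministic per seed.  Infeasible parameter combinations fail with an
  explicit error reporting the iterations spent.

The liquid diffraction basis is the ensemble mean of the flattened-droplet
Debye sum over ≥10 seeds, divided by the molecule count so it is
per-molecule comparable to the gas basis.  Two finite-size artifacts of
the droplet construction deserve note: a steep small-angle rise (the
droplet form factor, negligible above ~0.6 Å⁻¹) and coherent surface
ripples spaced ≈2π/(droplet diameter) ≈ 0.17 Å⁻¹ that ride on the
intermolecular ring.  For measurements of the ring position the
acceptance computation averages droplets of varying size (200–300
molecules), which decoheres the ripples; a monodisperse ensemble leaves
the ring maximum hopping between ripple crests over a ±0.1 Å⁻¹ range.
What the droplet model does *not* reproduce: hydrogen-bond network
structure, conformational disorder, and the exact shape of the
experimental intermolecular peak — only its position and its
presence/absence, which is what the downstream decomposition uses.

## Detector model and reduction

Isotropic scattering is rendered onto a flat detector (default 1024²
pixels, 0.06 mm pitch, 500 mm camera length, 100 kV: s ≈ 10.4 Å⁻¹ at the
edge, 14.7 Å⁻¹ in the corners) by linear interpolation of the 1-D curve at
each pixel's s, normalized to a prescribed total electron count, with
optional per-pixel Poisson sampling.  Flat-detector/solid-angle
corrections are omitted (<1 % in this small-angle regime).  Radial
averaging bins usable pixels in annuli of 0.02 Å⁻¹ and reports per-bin
means, pixel counts and standard errors; empty bins are flagged, never
interpolated.  The mean pixel s per bin (rather than the nominal bin
centre) is carried as the abscissa, which makes the render → reduce round
trip accurate to <0.5 % RMS in shape.  Beam-centre refinement minimizes
the annular within-bin variance over a deterministic coarse-to-fine grid
search (±4 px at 1 px, then ±1 px at 0.25 px); flat images are refused.

## Real-space inversion

f(r) = ∫₀^smax sM(s) sin(s r) e^(−k s²) ds, evaluated by trapezoidal
quadrature on the uniform grid (no resampling).  Defaults: s_max = 10 Å⁻¹,
r ∈ [0, 8] Å at 0.01 Å, and k = ln(10)/s_max² ≈ 0.023 Å² so the Gaussian
window falls to 0.1 at the cutoff — the conventional "damp the truncation
ringing to 10 %" choice.  f(0) = 0 exactly.  Experimental curves lack the
small-angle region, so sM below a configurable s_min (default 0.8 Å⁻¹) is
replaced by theoretical sM with a 0.2 Å⁻¹ linear cross-fade.

Extracting sM from a total curve requires removing a smooth baseline.  The
baseline is a low-order polynomial in s (intensity units) fitted in ratio
space, where the basis functions are s^p/I_atom: I_atom decays by three
orders of magnitude over the grid, so any fit weighted in raw intensity
units is blind to the high-s oscillations and its errors are amplified in
sM by s/I_atom.  The fit is robust (iteratively reweighted) and, when the
detrended signal exposes enough oscillation extrema (≈3 per coefficient),
is refined through the averages of consecutive extrema — the literal
oscillation midline.  The fit is restricted to s ≥ 1.5 Å⁻¹ by default
because below that the molecular term is a broad one-sided lobe, not an
oscillation.  Accuracy on the glycerol reference: ~2 % RMS for a constant
baseline; for an order-3 background the recovered sM carries ~25 % RMS
distortion because glycerol's few oscillations cannot pin four baseline
coefficients — but the real-space peak positions derived from it remain
correct to <0.05 Å, which is the quantity the package reports.  Users
fitting richer baselines should prefer larger molecules or external
background measurements.

## Two-phase mixture decomposition

An observed radial curve is modelled as
I_obs ≈ c_g·I_gas + c_l·I_liq + B(s) and fitted by bounded weighted least
squares; reported percentages are the intensity fractions
100·c_i/(c_g+c_l) (the package does not convert to molecule fractions by
default; `MixtureResult.mole_fractions` does so given per-molecule
scattering powers).  Design choices that matter:

- **Background family.**  B(s) = A·exp(−s/s₀) + polynomial, all amplitudes
  constrained non-negative, with the decay constant s₀ profiled by a
  bounded scalar search (separable least squares; deterministic).  The
  constraint is statistical, not cosmetic: an unconstrained smooth
  dictionary can synthesize a bump at the liquid-ring position and absorbs
  most of the gas/liquid discrimination — measured recovery scatter grows
  from ~1.4 to ~5–6 percentage points at 10⁷ counts.  A non-negative cone
  of decaying shapes cannot imitate a ring.
- **Weighting.**  Poisson: per-bin variance ∝ model/n_pixels, iterated
  from the fitted model (three passes); per-bin pixel counts can be
  supplied by the radial average.  The observation is normalized
  internally so optimizer tolerances are scale-free, making the reported
  percentages invariant under rescaling of the input.
- **Fit range.**  Default s ∈ [0.8, 8.0] Å⁻¹: below 0.8 the synthetic
  droplet form factor (and, in experiments, the beam stop) dominates;
  above 8 the bases are nearly proportional.
- **Information limit.**  With a 20 %-of-signal exp+const background and
  10⁷ counts per 1024² image, the Cramér–Rao bound on the liquid
  percentage is σ ≈ 1.2–1.7 points per delay at Table-like fractions; the
  estimator operates at that bound.  Recovery claims tighter than ~±2σ per
  image are not statistically meaningful at these counts.

## Synthetic experiment generator

`generate_scenario` renders a delay-indexed image series with expected
curve (1−x)·gas + x·liquid + background and per-image Poisson seeds; the
defaults mirror a bubble-film delay series: delays (4, 6, 8, 10) µs with
liquid fractions (0.39, 0.41, 0.35, 0.26) at 10⁷ counts per image.  The
background defaults — 20 % of the signal integral, shape exp(−s/1.5 Å⁻¹)
plus a 0.2 constant — emulate the smooth inelastic/multiple-scattering
pedestal; they are amplitude- and shape-configurable.  Everything is
regenerable bit-identically from the config.  The generator emulates
isotropy, counting statistics and a smooth pedestal; it does not emulate
detector point-spread, readout noise, gain variation or shot-to-shot
jitter, so passing recovery tests bounds only the statistical and
algorithmic errors of the pipeline, not detector systematics.

`end_to_end_check` runs radial averaging and per-delay unmixing against
the bundle's own bases, using the exp+const background model (order 0)
that matches the generator's family, and flags the low-count regime
(mean expectation < 0.1 counts/pixel).  On noiseless expectation images
the recovery is exact to <0.1 point (the linear-algebra limit); at 10⁷
counts per image the per-delay error distribution has σ ≈ 1.2–1.7 points
(see above), so individual delays occasionally exceed 2 points — the
frozen default seeds realize a worst delay of ≈3 points.

## Numerical and degenerate-input policy

- sinc singularity at s = 0: analytic limit, never grid exclusion.
- Peak finding: 3-point local maxima with parabolic refinement; plateau
  edges fall back to the grid point; ties broken by height ordering.
- Uniform images: centre refinement refused (flag returned), radial
  averaging still defined.
- Packing: deterministic per seed; explicit `PackingError` with the
  iteration count when density/contact are infeasible.
- Consumption arithmetic: integer femtolitres internally, exact for
  inputs with ≤3 decimal places.

## Problem sizes

Defaults were chosen so a full simulation-plus-reduction cycle stays
interactive: 200-molecule droplets pack in ~0.5 s, a 10-seed liquid
ensemble takes ~10 s, a 1024² rendered image ~1 s, and the complete
four-delay recovery check ~25 s.
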