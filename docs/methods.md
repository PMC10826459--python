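# Methods

This note records the models implemented in `spheroflow`, their
assumptions, the defaults that matter, and the numerical and design choices
made where more than one reasonable option existed.

## Interstitial flow

**Model.** The gel channel is reduced to a 2D plan-view rectangle. Flow
through the crosslinked hydrogel is Darcy flow, `u = −(K/µ)∇p`;
incompressibility gives the heterogeneous pressure equation
`∇·((K/µ)∇p) = 0`. The spheroid is a circular inclusion with its own
permeability `K_s`; the open fluidic channels on either side of the gel are
not solved — they are near-isobaric compared with the gel, so they enter
only as Dirichlet pressures `P₁` (inlet edge) and `P₂` (outlet edge) on the
pillar-gap boundary segments. Side walls are no-flux. Pressures are
accepted in mbar (1 mbar = 100 Pa), lengths in µm, velocities reported in
µm/s, stresses in Pa.

**Parameters.**

| parameter | default | units | rationale |
|---|---|---|---|
| gel span × width | 1000 × 1000 | µm | flow-wise span of the gel between the pillar rows; configurable |
| spheroid radius | 100 | µm | 200 µm diameter aggregate |
| `K_s/K` | 0.01 | – | near-impermeable cell aggregate; selectable down to 10⁻⁴ |
| `µ` | 10⁻³ | Pa·s | interstitial fluid ≈ water |
| `µ_e` | `µ` | Pa·s | Brinkman effective viscosity for shear post-processing |
| grid spacing | 5 | µm | 20 cells per spheroid radius; convergence utility halves it |

**Discretization.** Conservative finite volumes on the regular grid with
harmonic averaging of `K/µ` at cell faces (exact for layered media, robust
at the gel–spheroid jump), Dirichlet faces at half-cell distance, and a
sparse direct solve. Face Darcy fluxes are stored on the staggered lattice,
so discrete mass conservation holds to machine precision; cell-center
velocities are face averages.

**Interfacial stresses.** Normal stress is the interface pressure minus the
outlet pressure, sampled bilinearly on the circle `r = R` at 360 stations.
Pure Darcy flow carries no intrinsic viscous shear, so shear is a
Brinkman-style post-processing: `µ_e |t·(2E)·n|` with `E` the symmetric
velocity-gradient tensor of the macroscopic Darcy velocity, evaluated one
grid shell outside the interface. This reproduces the order of magnitude of
a full Stokes–Brinkman solution without coupling the two systems; it is an
estimate, not a boundary-layer-resolved shear.

**Verification.** A homogeneous slab reproduces the closed form
`u = KΔP/(µL)` to 10⁻⁶ and the linear pressure profile to <1%; a
near-impermeable cylinder in far-field flow matches the analytic
dipole-perturbation solution `p = p_c + G(1+β)R sinθ`,
`β = (K−K_s)/(K+K_s)`, to <2% of the perturbation amplitude at 5 µm
spacing (75 µm inclusion in a 1.5 mm domain, so wall images are <1%).
Pressure stays within `[P₂, P₁]`, inflow equals outflow, and the field is
exactly linear in `ΔP` and in `K`.

**Operating-point results.** At `ΔP = 30 mbar` the peak interface normal
stress is 2.08 kPa; by linearity the 20 mbar peak is exactly 2/3 of that,
1.38 kPa. With the gel permeability calibrated so `u_m = 0.45 µm/s`
(`K = 1.54×10⁻¹⁶ m²`), the maximum interfacial shear is 0.068 mPa — four
orders of magnitude below the normal stress, which is the physically
important contrast: compression, not shear, dominates at the spheroid
surface. Note the measured `ΔP → u_m` pairs of such chips need not be
Darcy-linear (tubing losses, per-batch gel variation), so `K` is a per-run
input and a calibration helper inverts the linear map rather than assuming
one global permeability.

## Solute transport

**Model.** `∂C/∂t + u·∇C = ∇·(D∇C)` on the same lattice, with `C = C₀` on
the inlet segments, advective outflow (no diffusive flux) at the outlet,
no-flux walls, and `C(·,0) = 0`. No uptake or binding sink is included by
default: the observed behavior of such chips is saturation of the gel to
`C₀`, implying no persistent sink at these time scales (an optional
first-order uptake term inside the spheroid exists but is off).

**Defaults.** `D = 5×10⁻¹¹ m²/s` for a 20–25 kDa solute in a 5 wt%
gelatin-based gel (a literature-scale choice; the value used is always
reported alongside results), `D_s = D/2` inside the spheroid (hindered
diffusion), frames stored every 10 simulated minutes.

**Scheme.** Operator splitting: explicit first-order upwind advection on
the stored face fluxes with CFL-limited substeps, then backward-Euler
diffusion with harmonic face diffusivities, factorized once (`splu`). Both
half-steps are monotone, so concentrations stay in `[0, C₀]` and rise
monotonically under a constant inlet — the discrete maximum principle holds
by construction rather than by clipping. Boundary influx is accumulated
exactly (the implicit inlet flux is evaluated at the post-step state), so
interior mass gain equals net boundary influx to round-off; the suite
checks <1%.

**Verification.** Diffusion-only slabs match the analytic eigenfunction
series for a Dirichlet/no-flux slab to <0.5% at mid-depth; a high-Péclet
plug flow advances the half-height front at `u·t` within one cell; halving
`D` doubles the time to reach a fixed fraction within the expected
tolerance. First-order upwinding adds numerical diffusion of order `u·h/2
≈ 10⁻¹² m²/s` at the operating point — 2% of the physical `D`, acceptable
for these Péclet numbers (`Pe = u_m L/D ≈ 9`).

**Operating-point result.** With the 30 mbar field calibrated to
`u_m = 0.45 µm/s`, the minimum concentration on the spheroid interface
reaches 95% of `C₀` at 56 min; without flow the same criterion is not met
within 400 min (0.94 at the cutoff). Flow enhances the mean interface
concentration by a factor ~1.8 at 100 min — advection accelerates delivery,
but the end state is the same saturated gel.

## Time-lapse quantification

**Intensity kinetics.** The ROI is segmented once on the first frame
(Gaussian smoothing, Otsu threshold, hole filling, largest component;
polarity selectable) or supplied by the user, and held fixed across the
movie — re-centering on the intensity centroid is available but off, since
a clamped chip does not drift appreciably. "Intensity density" is read as
integrated density (sum over the ROI); a mean mode exists. The default
background correction subtracts the per-frame median of an annulus at
1.3–1.8 ROI radii; it can be disabled for strict raw-signal processing.
Normalization divides by the first frame, so `I(0)/I₀ = 1` identically and
the endpoint `I₇₀/I₀` is the fold change.

**Azimuthal profiles.** Frames are resampled onto an `(r, θ)` lattice about
the ROI centroid (bilinear interpolation, 360 θ bins, 1 px radial steps),
with θ counterclockwise and 90° at the image top (the inlet-facing pole).
The radial mean over `r ∈ (0, r_max]` (default `r_max` = ROI equivalent
radius) is taken per θ bin — an unweighted row mean of the polar image,
matching the standard polar-transform workflow. Each spheroid's profiles
are normalized by the scalar mean of its own t = 0 profile, and
multi-spheroid aggregation returns mean ± SD per bin. The asymmetry index
reports the bins containing θ = 90° and 270° and their ratio. The polar
resampling conserves area-weighted flux within the sampled disk to <2%.

**Motility maps.** The per-pixel temporal standard deviation of the
bright-field channel, population flavor (÷T; sample flavor switchable),
optionally after rigid phase-correlation registration (off by default).
The peripheral motility score divides the mean SD in an annulus extending a
band width (default 30 µm) outward from the ROI boundary by the mean SD
farther than three band widths away, giving ≈1 for a movie with no
localized motion.

## Synthetic-data generator

The generator emulates, not simulates: it reproduces the *statistical
signatures* of the study's movies so the pipeline can be validated against
known truth, without modelling reporter biochemistry or optics.

* **Kinetics** `f(t) = 1 + (A−1)(1 − e^(−t/τ))` — the simplest monotone
  saturating form consistent with observed reporter profiles; a logistic
  variant with an onset delay emulates the delayed response at low ligand
  dose. Defaults `A = 13`, `τ = 25 h`, 71 frames at 1 h, 100 µm radius at
  2 µm/px, keyed to the printed endpoint statistics of the strongest
  condition.
* **Asymmetry** is a linear intensity gradient along the flow axis, ramping
  over the movie. `g` is defined *operationally* as the ratio of radially
  averaged intensity at the top vs bottom pole at the final frame — exactly
  what the azimuthal pipeline measures — and the gradient slope is
  back-computed from `g` and the radial texture so the two agree. This
  decouples pipeline validation from any transport mechanism.
* **Noise**: Poisson shot noise (0.5 photons per intensity unit) plus
  Gaussian read noise (σ = 2 a.u.) on a background of 20 a.u.; condition
  sets additionally scatter per-spheroid amplitudes with CV 0.2, the
  between-spheroid spread the printed endpoint statistics imply.
* **Bright-field**: a disk with rim blobs straddling the boundary
  (protruding peripheral cells); in "motile" stacks a configurable fraction
  of rim blobs jitters by 1.5 px per frame, which is what the temporal-SD
  map detects.
* **Determinism**: one `numpy` Generator seeded per stack; identical seeds
  give byte-identical movies, distinct seeds give uncorrelated noise.

What passing the round-trip tests shows: the pipeline recovers known
kinetics (A within 10%, and to <1% without noise), known asymmetry (g
within 5%, <1% noiseless) and known motility contrasts under realistic
noise. What it does not show: robustness to optical artifacts the
generator omits — point-spread blur, photobleaching, uneven illumination,
focus drift, or cells detaching from the spheroid.

## Statistics

Welch's unequal-variance t-test, implemented from the textbook formula
(t statistic, Welch–Satterthwaite degrees of freedom, two-sided p), with
`scipy.stats.ttest_ind(equal_var=False)` retained as an independent
cross-check in the tests. Star labels use strict inequalities: `***`
p < 0.001, `**` p < 0.01, `*` p < 0.05, else `ns`. Two-sided p values are
assumed and no multiple-testing correction is applied; both conventions are
recorded in the output metadata. Condition summaries report mean ± SD, n,
and percentage differences as `100·(mean_a − mean_b)/mean_a`.

## Known limitations

* The flow model is 2D and plan-view; out-of-plane confinement (280 µm
  channel height) enters only as metadata. No poroelastic gel deformation.
* Interfacial shear is a macroscopic-gradient estimate, not a resolved
  Brinkman boundary layer; treat it as an order of magnitude.
* First-order upwinding smears sharp advective fronts at high Péclet;
  the operating regime here is low-Péclet, where the scheme's robustness
  and monotonicity matter more than front sharpness.
* The 20 mbar peak normal stress is, by the linearity of the model, exactly
  2/3 of the 30 mbar peak; chips whose measured velocity–pressure pairs are
  not proportional (e.g. 0.2 vs 0.45 µm/s at 20 vs 30 mbar) are telling you
  the effective permeability or losses differ between runs, and should be
  calibrated per condition rather than force-fit to one `K`.
* The generator's condition amplitudes emulate printed endpoint statistics;
  they are not predictions of reporter biology.
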