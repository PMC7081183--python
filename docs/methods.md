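# Methods

`pollengel` models the chemomechanics of pollen-derived microgel
particles: hollow bilayer shells in which a charged polyelectrolyte gel
(the intine, de-esterified pectin plus cellulose) swells against a stiff
hyperelastic envelope (the exine, sporopollenin) perforated by three
apertures.  This note records the models, the defaults and why they were
chosen, the numerics, and what the synthetic-data tests do and do not
demonstrate.

## AFM Hertz analysis

Force-distance curves are analyzed with the classical Hertz contact
model for a parabolic tip of end radius R_c:

    F = (4 √R_c / 3) · E/(1 − ν²) · δ^{3/2}

with Poisson ratio ν = 0.5 by default (incompressible biological
material; configurable).  Raw curves are piezo displacement z and
cantilever deflection d; indentation depth is the bending-corrected
displacement δ = (z − z_c) − (d − d_c) from the contact point, and force
is F = k·d.  Only the approach segment is analyzed; adhesion/retract
phenomena are out of scope.

**Contact-point detection.** The free-cantilever baseline (first 10% of
samples) sets a noise band; the first run of five samples above
mean + 3 s.d. is the coarse contact.  Because the Hertzian onset rises
as δ^{3/2}, the coarse crossing is systematically late, so it is refined
by a changepoint fit over one fixed data window: for every candidate
contact position, d is fit as baseline line plus Hertz rise and the
residual-minimizing candidate wins.  Two regressors exist for the rise:
(z − z_c)^{3/2}, which keeps measurement noise out of the regressor but
carries a small model bias (the true depth subtracts the bending), and
the exact bending-corrected depth, which is model-exact but puts noise
into the regressor (an errors-in-variables bias).  The global scan uses
the noise-free regressor; when measured baseline noise is below 2% of
the deflection range the exact regressor (on a lightly smoothed
deflection) polishes the result locally.  On synthetic curves this
recovers noise-free contacts exactly over four decades of modulus and
stays within ±5 samples at a signal-to-noise ratio of 20.

**Fitting.** F is linear in δ^{3/2}, so E follows from a closed-form
through-origin regression slope over a depth window — exact for
Hertzian data and free of optimizer nondeterminism.  The 10%-depth
substrate rule marks a fit valid only when its maximum depth is below
one tenth of the layer thickness (60 nm for the 0.6 μm exine); invalid
fits are flagged, never silently dropped.  The exine/intine modulus
ratio M_E/I is the ratio of layer means over valid fits with a seeded
nonparametric bootstrap (1000 resamples) for the standard error; the
mean-of-curves aggregation is a package choice, as is every absolute
modulus default — the experimental literature on this system reports
the ratio trend, not per-layer values, so absolute moduli here are
configuration, not claims.

## Intine swelling pressure

The intine is treated as an ideal Donnan gel.  At linear swelling ratio
λ (volume λ³ relative to the reference state) the total driving
pressure is

    P_i,swelling(λ) = π_ion + π_mix + π_elastic

* **Fixed charge.** Carboxyl groups ionize by Henderson–Hasselbalch,
  α = 1/(1 + 10^{pKa − pH}) with pKa = 3.5 (galacturonate; the value is
  configurable).  The fixed-charge concentration is
  c_f = −α·c_COO·(1 − θ)/λ³, diluted by swelling and neutralized by the
  bound-cation fraction θ.
* **Donnan partition.** The reduced potential y solves
  Σ_j z_j c_j exp(−z_j y) + c_f = 0 (bracketed Brent iteration,
  residual below 1e-12 of the ionic strength); interior concentrations
  follow Boltzmann factors, and π_ion = RT Σ (c_in − c_bath) (ideal
  van 't Hoff, activity coefficients 1, T = 298 K).  H⁺/OH⁻ act only
  through α, never as osmotic species — negligible at the millimolar
  salt levels modeled.
* **Mixing.** Flory–Huggins,
  π_mix = −(RT/V_m)[ln(1 − φ) + φ + χφ²] with φ = φ₀/λ³, solvent molar
  volume V_m = 1.8e-5 m³/mol, χ = 0.45, φ₀ = 0.05.
* **Network.** Gaussian affine, π_elastic = −G_i(λ − 1/λ), with
  G_i = 20 kPa the osmotic network shear modulus.  This is deliberately
  distinct from the indentation-scale intine Young's modulus
  E_i = 10 MPa used to define M_E/I: an AFM tip probes the composite
  cellulose/pectin wall, while the swelling network elasticity of the
  pectin matrix is orders of magnitude softer.  Both scale together
  under cation stiffening.

**Multivalent cations and chelation.** Divalent/trivalent cations bind
carboxylate pairs (egg-box association) with Langmuir occupancy
θ = K·c_free/(1 + K·c_free), K = 0.05 mM⁻¹.  Binding neutralizes fixed
charge by (1 − θ) and stiffens the network by (1 + s·θ).  The
stiffening factor s = 11.6 is the closed-form calibration that maps the
reference microgel (M_E/I = 1.6) to an effective ratio of 0.15 at
100 mM CaCl₂, the anchor condition for the de-swelling regime.  EDTA
sequesters multivalent cations 1:1; the chelated salt (complex plus an
equivalent charge of counter-anions) is treated as osmotically inert,
so a chelator dose matching the cation load restores the pre-salt
pressure curve exactly — this idealization is what makes the
cation/EDTA cycle strictly reversible, mirroring the observed
re-swelling.  No stability-constant speciation is attempted.

All three terms fall strictly with λ (charge dilution, mixing dilution,
network recoil), so the driving pressure crosses zero once: the free-
swelling ratio of the unconstrained gel is unique (λ ≈ 1.34 at pH 7,
10 mM KCl with the defaults).

## Exine inflation

The exine is an incompressible Gent membrane of reference radius
R0 = 17.5 μm (a 35 μm particle) and thickness t_e = 0.6 μm:

    P_e(λ) = 2 μ_e (t_e/R0) (λ⁻¹ − λ⁻⁷) · J_m / (J_m − (2λ² + λ⁻⁴ − 3))

The Gent limit J_m = 1.5 encodes finite extensibility and defines the
maximum swelling ratio λ_max (the root of 2λ² + λ⁻⁴ − 3 = J_m,
λ_max ≈ 1.463 at the default), where the pressure diverges.  A
neo-Hookean membrane was rejected because its inflation curve has a
pressure limit point and no finite λ_max; Gent locking gives the
monotone pressure curve and well-defined maximum ratio the bilayer
model needs.  This is the key reduced-order substitution for a resolved
finite-element shell.

The three apertures are not resolved geometrically.  They act as a
scalar pressure knockdown f_open = 0.3 for λ below the opening ratio
λ_open = 1.08, blended smoothly (smoothstep over width 0.02) to 1 at
λ_open so the pressure stays continuous and monotone.  This preserves
the two-phase energy signature — aperture opening is cheap, subsequent
stretching expensive — which the strain-energy density
W(λ) = ∫₁^λ P(s)·3s² ds (adaptive quadrature, relative tolerance 1e-8)
makes quantitative: the mean dW/dλ in the aperture phase is far below
the stretching-phase rate.  λ_open is a configured parameter because
the simulations it mimics report it per-condition without printed
values.

## Pressure-balance equilibrium

The layers are bonded, so a single λ describes both (λ_i = λ_e by
construction; no dual-λ state exists in the API).  Equilibrium solves
P_i,swelling(λ) = P_e,inflation(λ) by bracketed Brent iteration on
[1, λ_max), after verifying on a 64-point grid that the net driving
pressure is monotone decreasing (a violation raises an error carrying
the diagnostic curve, rather than silently returning a root).  The
residual tolerance is 1e-6 kPa; a driving pressure at λ = 1 below that
tolerance means the reference state itself is the equilibrium and
λ_eq = 1 is returned exactly.

M_E/I is realized by scaling the exine shear modulus
μ_e = M_E/I · E_i/3 at fixed intine; sweeping M_E/I over [0.15, 8]
yields a λ_eq curve that is monotone non-increasing, with a constrained
plateau (λ_eq within 5% of 1 for M_E/I > 2, where the stiff shell is
effectively a rigid boundary), a steeper rise below 2, and — under
100 mM CaCl₂, which raises the effective intine stiffness and drops the
effective ratio below 1 — equilibria below the pH-7 reference
(de-swelling).  The regime labels use the narrative thresholds 2 and 1
as labels only, never as model inputs; ties go to the larger-ratio
class.  De-swelling is always relative to the reference environment:
absolute λ never drops below 1, consistent with defining the dry state
as the volume minimum.

**Kinetics.** Stimulus sequences (pH steps, cation/EDTA additions) use
a first-order relaxation envelope: within each segment λ relaxes
exponentially toward that segment's equilibrium with τ_swell = 3 s when
rising and τ_deswell = 1 s when falling, matching the seconds-scale,
de-swelling-faster phenomenology of ionizable networks.  This is a
kinetic envelope, not a poroelastic transport model; because the
underlying equilibria are state-free, completed cycles (pH 2→12→2,
Ca then EDTA) return λ to its starting value exactly in the long-time
limit.

## Morphometry

Frames are thresholded (Otsu or fixed), labeled with 8-connectivity,
and filtered at a 50 px² minimum area (removed speck count reported);
border-touching regions are flagged, and touching particles are not
split (watershed separation is out of scope — scenes are generated
non-overlapping).  Per particle: area-based diameter ABD = 2√(A/π);
circularity 4πA/P² (ISO form); and an edge-gradient score defined as
the mean Sobel magnitude on the one-pixel boundary — a reimplementation
choice for a proprietary instrument metric, comparable only within this
package.  The perimeter P is the arc length of the sub-pixel
marching-squares contour after a 5-point circular moving average: the
raw staircase contour overestimates smooth boundaries (a digital disc
would score circularity ≈ 0.91), while the smoothed contour scores
discs ≈ 0.99 and large squares ≈ π/4 as the continuous formulas
require.  Area swelling ratios are per-frame areas normalized by a
reference frame, matching 2-D time-lapse quantification.

## Synthetic data

Generators are pure functions of their arguments including the seed
(bit-identical repeats) and always return the generating truth, so
recovery tests consume the truth bundle rather than re-deriving hidden
state.  Force curves follow the Hertz forward model with a baseline
segment, contact offset, Gaussian deflection noise, and a 4.8 μN load
cap (the instrument limit, enforced by truncating the depth ramp).
Particle scenes place non-overlapping discs by rejection sampling, then
blur and add noise.  Size populations are truncated-normal at zero,
defaulting to the 35 ± 3 μm (dry) and 43 ± 3 μm (swollen) conditions
with n = 500.  Stimulus schedules cover the pH 2→12→2 cycle and
calcium-then-EDTA protocol (100 mM CaCl₂, 10 mM EDTA default dose).

**What passing tests show.** Recovery tests demonstrate internal
consistency: the pipeline inverts its own forward models under
realistic noise.  They do not validate the constitutive substitutions
against wet-lab data — real force curves carry adhesion, drift and tip
imperfection; real gels are non-ideal (activities, specific binding
cooperativity); real exine is ornamented and anisotropic.  Magnitudes
of the swelling curve are therefore qualitative; the tested claims are
structural (monotonicity, regime ordering, reversibility, the two-phase
energy signature, the anchor calibrations).

## Numerical choices and degenerate inputs

- Root finders: Brent with xtol 1e-13–1e-15; the Donnan bracket is
  expanded geometrically from ±1.
- Quadrature: adaptive with breakpoints at the aperture-blend edges.
- Equilibrium uniqueness is asserted (monotone grid check), not assumed.
- Empty foregrounds segment to empty lists with a warning-free return;
  all-noise force curves raise a typed no-contact error and are meant to
  be excluded, not crash a batch.
- Fits with non-positive slope are flagged invalid; zero-width depth
  windows pass the depth rule vacuously.
- Boundary ties in regime classification resolve to the larger-ratio
  class.

## Problem sizes

Default analyses use 16 curves per layer, a 158-point modulus-ratio
grid, 46-point λ grids, 25 frames × 8 particles per population, and
100–1000-draw property checks; these sizes make every analysis and the
full test suite run in seconds on a laptop while keeping Monte-Carlo
standard errors well inside the asserted tolerances.

## Known limitations

- The Donnan/Flory–Huggins/network formulation stands in for a coupled
  chemo-electro-mechanical field model; parameters are calibrated to
  qualitative anchors, not fitted to data.
- No spatial fields: aperture mechanics are a scalar knockdown, and
  swelling fronts, water transport and 3-D stress contours are out of
  scope.
- EDTA chemistry is stoichiometric sequestration; pH-dependent
  speciation and competing equilibria are ignored.
- Kinetics are exponential envelopes with configured time constants.
- Morphometry does not split touching particles and its edge-gradient
  metric is self-referential by construction.
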