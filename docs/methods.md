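# Methods

This note documents the models behind `spiralsort`, the parameters that
matter, the numerical choices, and the limits of what the synthetic-data
checks demonstrate.

## Device model

The device is an Archimedean spiral, r(θ) = r₀ + (p/2π)·θ, with five
loops of rectangular section W×H = 500×130 μm and a wall-to-wall
interspace of 500 μm, so the pitch is p = W + interspace = 1000 μm (the
channel occupies part of each pitch). The spiral body ends in a 720 μm
conical channel feeding ten outlets. Three geometric quantities are not
published and are configuration options with documented defaults:

* **Innermost radius r₀** — default 2500 μm. The Dean number scales as
  R^(−1/2), so halving r₀ raises De at the first loop by ~40 %; the
  stress summary reports the secondary-flow strength at both the first
  and the final loop so this sensitivity is visible in every run.
* **Flow direction** — default outward (inlet at the centre), a flag.
* **Outlet geometry** — the built device has *asymmetric* outlets of
  unpublished widths; bins default to equal widths and accept a width
  vector summing to W. The cone's exit width (default 250 μm) sets the
  quasi-1-D taper term of the extensional stress; at these conditions
  that term is ~1 Pa, small against the curvature term, so the default
  is not critical.

Coordinates: lateral position as a fraction of W from the inner wall,
vertical z ∈ [−H/2, +H/2], arc length s from the inlet. SI units
internally; micrometres and mL/min are converted once at the boundary.

## Primary flow

At 1 mL/min the bulk velocity is Ū = Q/A ≈ 0.256 m/s and Re ≈ 53:
laminar, entrance lengths of millimetres against a 16 cm path, so the
cross-section carries the fully developed pressure-driven duct profile.
We evaluate the exact double series (cosine across the width,
hyperbolic cosine across the height; 51 odd terms by default) and set
the pressure gradient from the closed-form flux relation so that
∬u dA = Q identically; Simpson integration of the discrete field agrees
to ~10⁻⁶. Wall gradients are taken from the term-wise differentiated
series, not finite differences, so the stress maxima are not degraded
by grid error — the 64×64 default grid only samples the field. A
convergence guard re-evaluates the series with 16 extra terms and
raises if the field drifts by more than 0.1 %.

An independent finite-difference Poisson solve of the same duct problem
(assembled from scratch in the test suite) agrees with the series peak
velocity to < 1 %, and the wide-duct limit reproduces the
parallel-plate wall shear 6μŪ/H to 2 %.

## Secondary (Dean) flow

Curvature drives a pair of counter-rotating vortices. We compute the
first-order perturbation: a streamfunction ψ on the cross-section obeys
μ∇⁴ψ = −(ρ/R)·∂(u²)/∂z with clamped (no-slip) walls, discretised with
the standard 13-point biharmonic stencil and ghost-node reflection,
solved directly (sparse LU; residual checked to 10⁻⁸). The source is
odd in z, so the circulation is mirror-antisymmetric about the
mid-plane — two cells by construction. At the first loop (R = 3 mm,
De ≈ 9.8) the peak secondary speed is 7.0 mm/s against the empirical
correlation U_Dean = 1.8×10⁻⁴·De^1.63 = 7.4 mm/s; the test suite only
requires agreement within a factor of 3, since the linear perturbation
omits the inertial feedback that saturates the vortices at higher De.

## Fluid shear stress (FSS)

Two readings are computed and reported:

* the **literal secondary-flow component** μ(∂v/∂z + ∂w/∂y), which is
  ~0.1–1 Pa at these conditions, and
* the **full viscous shear magnitude** including the primary-flow
  gradients, whose maximum (~14 Pa at 1 mL/min, ~28 Pa at 2 mL/min)
  sits at the mid-points of the top and bottom walls.

Only the second can reach the tens-of-pascals level observed at those
walls in this device, so the headline `fss_max` uses the full
magnitude; the literal form is retained for audit. The flow-rate
ambiguity (two syringes driven together: 1 mL/min total or per
syringe?) is handled by defaulting to total and always computing the
doubled-flow sensitivity case alongside.

## Extensional flow stress (EFS)

EFS is 3μ·∂u/∂s along the path, extension positive. Two contributions:

* **Taper term** — quasi-1-D continuity u(s) = Q/A(s) through the
  outlet cone (the only place area changes); ~1 Pa at defaults.
* **Curvature term** — on the curved body, the flow axis rotates
  relative to a fixed laboratory frame, so a fixed-axis streamwise
  derivative samples the steep *lateral* gradient of the duct profile
  near the side walls: EFS = (3μ/2)·sin(2θ(s))·∂u/∂y, evaluated at the
  lesser- and greater-curvature walls. This term has no free
  parameters, peaks where the channel tangent makes 45° with the
  laboratory axis (~15 Pa at 1 mL/min), and is positive at one
  curvature and negative at the other — matching where extensional
  stress arises in this device and its sign pattern. A configuration
  switch turns it off, leaving the pure quasi-1-D profile.

An alternative model — modulating the quasi-1-D profile by a
Dean-number-dependent shift of the velocity peak — was evaluated and
rejected: with literature-plausible shift amplitudes and development
lengths it produces only ~3–5 Pa and cannot yield the observed sign
flip between the two curvatures without tuned constants.

## Inertial focusing

Dimensionless groups use the standard definitions: D_h = 2WH/(W+H),
Re = ρŪD_h/μ, De = Re√(D_h/2R) (the Dean number definition is a
documented choice; it is not uniquely fixed by the correlation it feeds).
The Dean-velocity correlation is treated as returning m/s from
dimensionless De. Dean drag is implemented in both printed forms —
3πμU_Dean·a_p and 5.4×10⁻⁴πμDe^1.63·a_p — which are one constant
(3π×1.8×10⁻⁴ = 5.4×10⁻⁴π) and must agree to machine precision.
Inertial lift is ρG²C_L·a_p⁴ with C_L = 0.5 (typical literature
magnitude) and G = 2Ū/D_h (Poiseuille scale) by default; both are
configuration options, neither is a device measurement.

The **equilibrium map** is a qualitative-order predictor, not a
trajectory simulator: the positional dependence of the lift in this
device is unknown, so the balance uses a monotone restoring profile
F_L·κ·(x − x₀) against the position-independent Dean drag, solved by
bracketed root finding. Two anchors fix it: a wall stand-off
x₀ = 0.1 (the focused streak sits a finite distance from the inner
wall) and κ chosen once so that a threshold-size cell
(a_p = 0.07·H = 9.1 μm) settles at x = 0.28, i.e. outlet III, where the
focused stream of this device is collected. Because F_D/F_L ∝ a_p⁻³,
x*(a_p) decreases strictly with size and lies in (0.1, 0.28] for every
focused diameter — so focused cells can only reach outlets II–III, and
outlets VI–X receive zero mass, for arbitrarily large cells. Unfocused
cells (ω < 0.07) are assigned by a seeded draw over outlets I–V,
uniform by default (the observed dispersal support without published
proportions).

## Viability assays

* **CMI** = width/length after sorting the extents (micrograph
  orientation is arbitrary; a swap warns). Necrotic wreckage is
  *unmeasurable*: encoded as value 0 plus an explicit flag, and the two
  never appear separately, so state-wise means can exclude wreckage
  exactly. The contour operator takes length as the maximal chord and
  width as the maximal perpendicular extent — rotation- and
  translation-invariant to < 0.5 %.
* **Hemocytometer** — concentration = (count/squares)·dilution·10⁴ per
  mL (standard chamber arithmetic; 10⁻⁴ mL per large square).
* **dsDNA** = 50 μg/mL × OD₂₆₀ × dilution factor, default dilution
  1:100, exact and linear.
* **CV** uses the sample standard deviation (n−1) from raw replicates;
  printed mean ± sd summaries are used verbatim. The published
  before-sorting pair (5200, 928.72) recomputes to 17.86 % against a
  printed 17.85 — the discrepancy is reported, not reconciled, since
  whether the source rounded an unprinted internal mean is unknowable.
* **Attrition** — percent lost = 100·(before−after)/before plus the
  after/before fold change; loss and survival sum to 100 exactly.

## Synthetic-data generator

The generator emulates a dissociated round-cell tumour suspension with
the statistical structure the assays assume; defaults are the study
conditions of the characterised device:

| parameter | default | rationale |
|---|---|---|
| size mixture | lognormal major, mean 16 μm sd 3.5; lognormal minor, mean 5.5 μm sd 0.8; minor weight 0.15 | major population spans ~10–25 μm; minor sub-7 μm (stem-like) fraction |
| necrosis fraction f | 0.40 | the device loses ~40 % of cells |
| deformation fraction (of survivors) | 0.30 | deformed CMI drawn uniformly from [0.22, 0.625] |
| membrane-damage probability | 0.30 | deformed-but-normal-looking cells may still stain trypan-positive |
| suspension | 4×10⁴ cells/mL; volume n/4×10⁴ mL | pre-sorting concentration |
| baseline supernatant dsDNA | 5200 μg/mL | trypsinisation itself releases DNA |
| DNA release per lysed cell | 0.4544 μg | the value implied by inverting the before/after means at f = 0.4 (note the printed concentrations are far above a single genome's ~6 pg; the generator reproduces the printed *scale*, not absolute genomics) |
| OD noise | lognormal, σ = 0.17, mean-one | reproduces the ~17 % replicate CV |
| counting | binomial thinning into 25 squares, 5 replicates | replicate count is unpublished; chamber maths above |

Necrotic cells lyse: they vanish from the after-arm counts and dump
their DNA into the supernatant. Identical config (the seed is part of
it) gives byte-identical CSVs. `exact_counts=True` replaces every
stochastic readout by its expectation; in that mode the assay pipeline
returns the configured parameters *exactly* (closed loop), which is the
calibration test separating model error from sampling noise.

**Recovery harness.** `recover_ground_truth` estimates the necrosis
fraction (share of unmeasurable-CMI records; binomial SE), percent lost
(hemocytometer before/after, delta-method SE from pooled counts), the
replicate CVs and the DNA fold change. At n = 500 the necrosis estimate
sits within 3 binomial standard errors of truth. A 5-replicate CV has a
sampling sd of ~35 % of its value, so single-draw CV recovery is
reported with its noise, while the estimator's *accuracy* (mean over
repeated draws within 15 % of the lognormal noise CV) is what the test
suite asserts.

**What passing these checks shows — and does not.** The synthetic
cohort validates the arithmetic and the statistical plumbing end to
end. It does not validate the biology: sizes are lognormal by choice
(only ranges are known), injury states are categorical labels with no
mechanistic link to the computed stress fields, DNA release per cell is
an effective value reproducing printed concentrations, and functional
(mitochondrial) viability enters only as a label. Agreement on
synthetic data therefore demonstrates correctness of the pipeline, not
predictive power for a particular cell line.

## Numerical choices and problem sizes

Default grids: 64×64 cross-section (the stress maxima move < 2 % at
128×128), 1200 path stations, 51 series terms. Finite differences are
second-order central with second-order one-sided stencils at walls.
The biharmonic solve is direct (sparse LU) with a residual check; the
equilibrium root find uses Brent's method to 10⁻¹². Degenerate inputs
(zero flow, zero area, unfocused cells, empty populations, overfull
counting chambers) raise explicit errors or return defined markers
rather than NaNs. All stochastic components take a seed; fixed seeds
give bit-reproducible outputs.

## Known limitations

* The secondary-flow model is linear in De; above De ≈ 20–30 the
  vortices saturate and the factor-3 magnitude agreement will degrade.
* EFS is evaluated on the duct profile of the local section; the
  redistribution of the profile by the Dean circulation feeds back on
  neither stress field.
* The equilibrium map is anchored to this device's observed collection
  outlets; transferring it to another geometry requires re-anchoring
  (or treating only its monotone ordering as meaningful).
* Injury thresholds from the cell-damage literature (0.2/0.5 Pa for
  adherent deformation/death, 150–400 Pa for suspended-cell lysis) are
  exposed only as annotation constants, not as a validated damage
  model.
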