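# spiralsort

**Hydrodynamic stress exposure and cell viability in spiral-microchannel
inertial cell sorters.**

Spiral microchannels sort cells by size without labels: in a curved
rectangular duct, the secondary (Dean) circulation drags suspended cells
across the primary streamlines while wall-induced inertial lift pushes
back, and cells large enough to focus (confinement ratio
ω = a_p/H ≥ 0.07) collect in a tight stream near the inner wall. The
same flow that sorts the cells, however, exposes them to hydrodynamic
shear: fluid shear stress (FSS) at the top and bottom walls and
extensional flow stress (EFS) at the curvatures and the outlet cone.
For fragile cells — here, dissociated canine mast-cell-tumour cells —
that exposure costs a large fraction of the sorted population.

`spiralsort` is a reduced-order analysis pipeline for quantifying that
trade-off. It is aimed at labs designing or characterising spiral
sorters who want desk-scale answers (seconds on one CPU) instead of a
full 3-D finite-element run. It provides:

* **Geometry** — the Archimedean spiral device (cross-section, loop
  path with local radius of curvature, conical outlet manifold) with
  strict JSON config validation.
* **Flow and stress** — the exact series solution for pressure-driven
  flow in a rectangular duct, rescaled to the prescribed flow rate; the
  first-order Dean circulation as a clamped-plate biharmonic solve;
  FSS in both the literal secondary-flow form μ(∂v/∂z + ∂w/∂y) and the
  full viscous shear magnitude; EFS = 3μ ∂u/∂s along the spiral path
  from quasi-1-D continuity plus the curvature (axis-rotation) term.
* **Inertial focusing** — Dean number De = Re √(D_h/2R), the Dean
  velocity correlation U_Dean = 1.8×10⁻⁴ De^1.63, Dean drag
  F_D = 3πμU_Dean·a_p, inertial lift F_L = ρG²C_L·a_p⁴, the
  ω ≥ 0.07 focusing criterion, and a qualitative-order equilibrium map
  predicting each cell's outlet.
* **Viability assays** — cell morphology index (CMI = width/length,
  also from raw contours), trypan-blue viability, hemocytometer
  concentrations, leaky-DNA spectrophotometry
  (dsDNA = 50 μg/mL × OD₂₆₀ × dilution), coefficients of variation,
  fold changes and percent cell loss.
* **Synthetic data** — a generator for cell cohorts with known ground
  truth (size mixture, latent injury states, binomial counting, noisy
  OD readings) and a recovery harness that closes the loop.

## Worked example

```python
from spiralsort import build_default_device, stress_summary, water_at_20c

channel = build_default_device()      # 500 x 130 um, 5 loops, 10 outlets
fluid = water_at_20c(1.0)             # 1 mL/min total

summ = stress_summary(channel, fluid)
print(f"FSS max {summ.fss_max_pa:.2f} Pa, EFS max {summ.efs_max_pa:.2f} Pa")
```

prints

```
FSS max 14.16 Pa, EFS max 15.48 Pa
```

— the shear maximum sits at the mid-points of the top/bottom walls and
the extensional maximum at the lesser/greater curvatures, both in the
tens-of-pascals range that the cell-damage literature associates with
deformation and lysis of wall-less mammalian cells. The
`examples/` directory holds five short narrative scripts (device and
flow, stress maps, outlet prediction, assay arithmetic, synthetic
parameter recovery); each prints the numbers it computes and a line on
what they mean. For instance `examples/04_viability_assays.py`:

```
concentration      : 40000 -> 24000 cells/mL
cells lost         : 40.0 %
supernatant dsDNA  : 5200 -> 12470 ug/mL (2.40-fold)
CV before sorting  : 17.86 %
CV after sorting   : 16.68 %
```

A 40 % drop in countable cells together with a ~2.4-fold rise in
supernatant DNA is the signature of lysis inside the channel.

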