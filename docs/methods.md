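# Methods

## Physical model

### Magnetostatics

Each magnet is a uniformly magnetized rectangle in the x–z plane (x along
the flow, z normal to the array, z = 0 at the magnet top surface). The
field outside the material is that of equivalent magnetic surface charges
σ = **M**·n̂ on the two faces where the magnetization has a normal
component; for a charged segment the 2D field is closed-form in logs and
arctangents, and an array is the superposition over all sheets. This is
exact for ideal magnets (no mutual demagnetization, relative recoil
permeability 1, no temperature dependence). The test suite checks the
closed form against independent adaptive quadrature over the charge
sheets (1e−6 relative), and against ∇·B = 0, ∇×B = 0 by finite
differences.

Remanence: magnet grades are mapped to typical datasheet mid-values,
Br(N52) = 1.45 T and Br(N45) = 1.35 T, config-overridable; magnetization
is M = Br/μ0. Real magnets of a given grade spread by a few percent,
which shifts full-capture thresholds by roughly their force share.

Arrays: `build_halbach` tiles a span with a 4-phase sequence (90° per
element) and auto-selects the rotation sense so the strong side faces the
channel; with mixed element heights the top faces are flush at z = 0 (the
channel rests on the array). `build_alternating` flips the vertical
magnetization every element and is symmetric above/below. The span is the
channel length plus a 10 mm overhang on each side; doubling the overhang
changes recovery by < 0.5 pp (tested), so end effects are immaterial.

Singularities: an evaluation point within 1 nm of a sheet corner is
nudged 1 nm away — six orders of magnitude below the cell radius, so the
regularization has no physical effect.

### Cell and forces

The cell plus its bound nanoparticles is a single point-like sphere
(default radius 5 µm, density 1077 kg/m³ — the density used by the
geometry-optimization runs; an alternative figure of 1070 appears in the
source material's force section and can be set in config). Its total
moment is parallel to the local field with magnitude

- `arctan`: m(B) = (2/π)·m_s·atan(B/Bs), Bs = 22 mT — the fit to the
  measured ferrofluid magnetization curve;
- `saturated`: m(B) = m_s (high-field limit);
- `linear`: m(B) = (2/π)·(m_s/Bs)·B — the low-field tangent of the arctan
  curve, deliberately uncapped, embodying the constant-susceptibility
  assumption common in the literature.

Moment bookkeeping is done directly as a total moment m (Am², usually
quoted in fAm² = 1e−15 Am²) rather than an effective magnetization times
cell volume; the two are equivalent and this avoids the effective-
permeability detour needed by FEM implementations. With m ∥ B the force
is **F** = m(|B|)·∇|B|; ∇|B| uses 1-µm central differences of the closed
form (configurable; agrees with a 4× finer stencil to 1e−4).

Gravity/buoyancy F_g = g·V_p·(ρ_c − ρ_f) points toward the array (the
channel lies on top of the magnets); for the default cell it contributes
a 4.7 µm/s settling drift, small against magnetophoretic drifts of tens
to hundreds of µm/s but not negligible near threshold.

### Flow

Plane-Poiseuille profile v(z) = 6 v̄ (z/h)(1 − z/h), v̄ = Q/(h·w), with
no side-wall correction: the default aspect ratio is 6.25 and the channel
Reynolds number ρ v̄ D/η ≈ 6.5 (hydraulic diameter D = 2hw/(h+w)), deep
in the laminar regime. Entrance development, non-Newtonian rheology and
cell crowding are out of scope.

### Trajectories and recovery

Cell inertia is negligible (Stokes number ≪ 1), so the dynamics are
overdamped: dx/dt = v_f(z) + F_mx/(6πηr), dz/dt = (F_mz + F_g)/(6πηr).
Cells are seeded at x = 0 at the inverse-CDF points of the volumetric
flux distribution (cumulative fractions (i − 0.5)/n, restricted to
[r, h − r] so the center cannot overlap a wall) with equal weights —
deterministic, so every result is bit-reproducible. A cell is captured
when its center reaches one capture standoff (default: one cell radius)
above the inner array-side wall, irreversibly ("freeze"); it exits at
x = L; it stalls if neither happens within 20 nominal transit times
(never observed in the shipped configurations). Recovery = captured/n.

## Numerics

- Population runs integrate all n cells as one vectorized ODE system
  (`solve_ivp`, RK45, rtol 1e−6 / atol 1e−9 on position); finished cells
  have their velocity frozen at zero, and a continuous terminal event
  (max over cells of distance-to-outcome) stops the run when the last
  cell finishes. Recovery changes < 0.5 pp when n doubles (500 → 1000) or
  rtol tightens 10× (tested).
- Inside the channel the field magnitude is cached on a bicubic spline
  over one magnetization period (the array overhangs the channel by many
  periods, making the interior field periodic to ~1e−3); gradients come
  from the spline's analytic derivatives. The cache agrees with direct
  closed-form evaluation to ~1e−3 relative, and cached trajectories
  reproduce exact-field trajectories' outcomes seed by seed (tested).
- Single-cell runs (`integrate_trajectory`) use per-cell terminal events
  and can record the full (t, x, z) path, or accept a replacement force
  field as a test hook.
- Full-capture thresholds are defined on the 1 fAm² moment grid; since
  recovery is monotone in moment (asserted in tests), the threshold scan
  is evaluated by bisection with both boundary grid points re-verified,
  which is exactly equivalent to a left-to-right scan.

## Geometry optimization

Element-width sweeps run 0.4–2.0 mm at 0.05 mm (alternating arrays
0.4–3.0 mm, so their optimum is interior), heights 0.5–3.0 mm at 0.25 mm;
reported optima are grid points with ties broken toward the smaller
value. Sweeps default to m_s = 10 fAm² (arctan). The width optimum is
only meaningful when the maximal recovery is close to, but not pinned
at, 100%: a configuration far above threshold shows a recovery plateau
over a range of widths and the reported optimum degenerates to the
plateau edge. For the optimal-width-versus-channel-height study the cell
moment is therefore re-calibrated per channel height (bisected so the
recovery at a reference width equals 0.98) before sweeping; n = 500
cells per grid point (n = 150 in the height-relation test, whose output
is a 4-point linear fit rather than a threshold).

In this implementation's calibration the 10 fAm² default sits above the
full-capture threshold of the stronger 1.5-mm Halbach geometries, so
those sweeps do plateau; the acceptance script reports the tie-broken
plateau edge for them as specified rather than re-calibrating.

## Population module

Fluorescence intensity I of bound label is assumed linear in the
magnetic moment: m = I/scale + offset (offset in fAm², absorbing
non-specific background staining; negative moments clamp to zero).
Population recovery is Σ w_i·R(m_i) with R interpolated linearly on the
moment grid, anchored at (0, R(0)) below it and constant at its top
value above (the curves plateau at 1). `fit_scaling` minimizes the
unweighted SSE between predicted and measured recoveries over all
population × array pairs, with one shared scale and one offset per
population, by a deterministic multi-start (log-spaced scale × coarse
offset grid) followed by Nelder-Mead.

The synthetic generator emulates what such cytometry histograms look
like: every cell draws a background intensity (normal around the
negative-control peak) and a labelled fraction adds a log-normal
ferrofluid signal. Defaults (control peak 1400, width 400; labelled
fraction 0.85; log-normal median 2500, shape 0.9; 20 000 cells, 120
linear bins) were chosen once so that, at a scale of ~120 intensity
units per fAm², the scaled moments span the recovery curves' dynamic
range and a few percent of cells clamp to zero moment. The generator
reproduces the qualitative features that matter to the fit — a
right-skewed labelled population overlapping a background peak — but
not instrument-specific effects (log-amplifier binning, spectral
spillover, autofluorescence outliers), so parameter-recovery tests
demonstrate correctness of the fitting machinery, not cytometer realism.

## Known limitations

- 2D fields (magnets infinite across the channel width) and a 2D flow
  profile; 3D edge effects across the 5 mm width are ignored.
- Ideal magnets: no recoil permeability, mutual demagnetization,
  assembly gaps or temperature dependence. These all reduce the real
  field by a few percent each.
- No unbound-ferrofluid dynamics (aggregation, magnetic shielding as
  material accumulates), no Brownian motion, hydrodynamic lift or
  cell–cell interactions; captured cells do not roll or detach.
- Absolute full-capture thresholds inherit every force-scale assumption
  (Br, wall thickness, capture standoff) roughly linearly; comparisons
  between arrays are much more robust than absolute values.
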