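# Methods

This note records the model assumptions, numerical choices and calibration
decisions behind `electrotick`, and what the synthetic-data generators do
and do not emulate.

## Electrostatic model

All scenes are solved as pure Dirichlet problems for Laplace's equation.
The host surface, electrode, plate, soil and vegetation are conductors held
at fixed potentials (vegetation and soil grounded, the host/electrode at
±V), so the air-gap field is determined entirely by geometry and the
boundary potentials.  Interior material constants (σ, ε_r of soil, tissue,
wood, grass) therefore never enter the solve; they are carried on scene
objects as metadata only.  This is why the wooden support rod behind the
electrode is excluded by default from the rig model: it is a dielectric
sitting behind an equipotential surface, and under the conductor-only
treatment it has exactly no effect on the gap field (setting
`include_rod=True` records it as metadata).

Exterior boundary conditions: the bottom face of every domain is ground
(0 V); side and top faces are zero-normal-flux, the common default for
truncating an open domain; axisymmetric scenes use ∂V/∂r = 0 on the axis.

Geometry simplifications, all exposed as parameters:

* The rectangular 200 × 130 mm plate becomes a disc of equal area
  (radius 91 mm).  The probe sits on the axis 0.5 mm above the plate, some
  90 mm from the plate edge, so the far-edge shape is irrelevant there.
  The plate is 1 mm thick and its top surface defines z = 0 for gap and
  probe heights.
* The grass blade's cross-section is stated only as "1 mm thick"; the
  default ribbon is 1 mm × 5 mm, exposed as a parameter.  A sensitivity
  test halves and doubles the 5 mm width and checks the probe field moves
  by less than ~10% (measured: +8%/−4%), inside the margin of the
  >300 kV/m result.
* The host ellipsoid (semi-axes 0.4 × 0.4 × 0.2 m, the 0.2 m axis
  vertical) approaches the blade along a 0.4 m horizontal semi-axis.  The
  1 m scene cannot contain a centred blade plus this ellipsoid, so the
  blade stands at x = −0.4 m; only the gap geometry matters locally.

## Discretisation and solvers

Finite differences on regular isotropic grids; conductor surfaces are
handled by first-order cut-cell assignment (a node inside a shape takes the
shape's potential, with a sub-nanometre inclusion tolerance so nodes that
fall exactly on a face are captured despite float rounding).

* **Axisymmetric** — the 5-point cylindrical stencil with the 1/r
  first-derivative term, 4(V₁−V₀)/h² on the axis.  The sparse system is
  solved directly (SuperLU); grids stay below ~2·10⁵ unknowns.
* **Cartesian 3-D** — the 7-point stencil with finite-volume half-cell
  weights on domain faces (this keeps the operator symmetric under the
  mirror treatment of zero-flux faces), solved by conjugate gradients with
  a geometric-multigrid V-cycle preconditioner: red-black Gauss-Seidel
  smoothing (one symmetric pre/post sweep), full-weighting restriction with
  zero padding — zero, not reflection, so the restriction is exactly
  proportional to the transpose of trilinear prolongation and the V-cycle
  is a symmetric positive-definite preconditioner — and a direct
  factorisation on the coarsest level (≲6000 nodes).  Stencil kernels are
  numba-jitted.  Relative-residual tolerance 1e-8, as everywhere.
* **Nesting** — both solvers take an optional refinement box: a coarse pass
  over the whole domain supplies Dirichlet boundary values (multilinear
  interpolation) for a fine pass on the box.  Conductors crossing the box
  boundary are pinned to their exact potentials, which overrides
  interpolation.  3-D axes snap their cell counts to multiples of 8 so the
  multigrid hierarchy is deep enough.
* **Fields and probes** — E = −∇V by centred differences (one-sided on
  grid edges); probes interpolate multilinearly and refuse points within
  one cell of a conductor, where the one-sided gradient is unreliable.
  On-axis force stencils use the axisymmetric mirror (|E| is even in r).

Default problem sizes were chosen to keep every solve on a single CPU in
seconds to a couple of minutes: rig solves use a 1 mm coarse grid with a
0.05 mm fine box around the gap (~2·10⁵ fine nodes); the vegetation scene
uses the 5 mm coarse / 0.1 mm fine pairing (201³ coarse, ~3·10⁶ fine
nodes).

### Verification

The solvers are checked against three independent references: the exact
parallel-plate solution (the discrete solution is exact for a linear
potential, |E| = V/d to machine precision); the classical image-charge
series for a charged sphere above a grounded plane (the rig solve agrees
within 2% along the gap axis; the series itself is truncated at 1e-12
relative term size); and the Coulomb field of an isolated sphere.
Property tests assert the discrete maximum principle, exact linearity in
the boundary data, polarity symmetry (V → −V negates the potential and
preserves |E|), and first-order-or-better grid convergence of the rig
probe value, with <1% change between the two finest spacings of the
default ladder (0.2/0.1/0.05 mm).

## Attraction model

Lift-off is modelled at the level of force balance for a point particle at
the probe height (0.5 mm, the mid-height of a nymph): the tick leaves the
surface when the electric force exceeds its weight mg (m = 0.1 mg,
g = 9.81 m/s²).  Because the electric force is linear in the local field,
the threshold voltage grows linearly with gap distance with a zero
intercept — by definition no voltage is needed across no gap — and the
regression slope G is the threshold field.  Following the forced-origin
convention, R² is computed about zero (uncentred) and the model F uses
df (1, n−1), so the six-distance, twelve-tick design yields F₁,₇₁.  The
free-intercept model is fitted alongside, with its intercept CI and the
nested-model ANOVA, to let the data veto the zero-intercept assumption.

`average_threshold_field` converts the voltage law into a field threshold
the way the original analysis did: solve the rig at each measured distance
with that distance's threshold voltage and average the probe fields.  The
rig field at the tick is ~12% below the parallel-plate value V/d (the
electrode is a sphere, not a plane), which is why the averaged field
threshold (~258 kV/m) sits below the voltage-law gradient (~290 kV/m).

The mechanism models are deliberately minimal: fixed charge **F** = q**E**
and induced dipole **F** = ½α∇|E|².  α has no measured value and is used
only for sign/direction contracts (the induced force is invariant under
V → −V and points up the |E| gradient, i.e. toward the electrode); no
quantitative force claims are made from it.  The minimum *effective*
charge for lift, q_eff = mg/E, is mechanism-agnostic and ≈3.8 pC at
258 kV/m.

## Statistics

Conventions the source analysis left unstated are fixed as follows:

* Two-tailed permutation p-values count arrangements whose statistic
  deviates from the null mean by at least the observed deviation, observed
  arrangement included (p is never 0); the null is enumerated exactly when
  C(n+m, n) ≤ 20 000, otherwise 10 000 random permutations by default.
* Adjusted standardized residuals (O−E)/√(E(1−r/N)(1−c/N)) get two-sided
  normal p-values Bonferroni-multiplied by the cell count (6 for the 2×3
  outcome table).
* Levene's test uses the classical mean-centred form, df (1, n−2).
* Wald z is 1.959964; bootstrap CIs are percentile intervals of 10 000
  resampled medians by default.

Two printed-versus-recomputed discrepancies are documented rather than
reproduced: the outcome table ((15,3,2),(0,1,19)) gives Pearson
χ² = 29.76 by direct formula where 29.6 was printed (0.5%; possibly a
rounding or variant in the original software), and its largest adjusted
residual is 4.90 where 4.6 was printed.  The package reports the standard
values.  Likewise the "±3.8%" interval printed for the 75% proportion is
not a Wald interval for 15/20 (which is ±19.0%); the Wald interval is
reported.

## Synthetic data

The generators emulate the *designs* and the published summary rates, not
the raw data (which live in an external deposit):

* **Staircase** — per tick, a true threshold voltage V* = E*·d·L with L a
  unit-median lognormal factor (CV 0.15 by default); the recorded value is
  the first staircase voltage (start 50 V, step 50 V) at or above V*.
  The lognormal is parameterized by its median so the only systematic bias
  in recorded voltages is the staircase's upward quantization; the fitted
  gradient then lands in [E*, E* + step/min(d)] in ≈99% of replicates, and
  parameter-recovery tests assert ≥95%.  E* defaults to 258 kV/m.  The CV
  and the lognormal form are modelling stand-ins — the study reports no
  between-tick distribution — chosen once for positivity and visual
  consistency with the published scatter.
* **Lift trials** — a treatment tick fully lifts when the applied
  probe-height field (V/d times the rig geometry factor, taken from the
  solver, ~0.88 at 3 mm) exceeds its drawn threshold, and partially lifts
  within a band just below threshold; controls show only a 5% spontaneous
  partial-movement rate (1 in 20, as observed).  The default population
  for this design is calibrated analytically (lognormal quantile
  equations) to the published 75%/15% rates, reflecting that the live
  ticks of the fixed-voltage experiment lifted at lower fields than the
  dead-tick staircase average.
* **Polarity groups** — both groups draw |thresholds| from the same
  distribution (the induced-polarization null, under which the permutation
  Mann–Whitney rejects at the nominal 5% rate); a `negative_scale` knob
  creates fixed-charge alternatives for power checks, and per-group
  humidity parameters emulate the humidity-confound conditions.

What passing these tests shows: the analysis pipeline recovers known
generating parameters under the stated designs and noise model.  What it
cannot show: anything about tick-to-tick threshold structure beyond the
assumed lognormal, humidity *effects* (humidity is generated as an inert
covariate), or behavioural effects (clinging, desiccation) that the
original experiments controlled procedurally.

## Known limitations

* First-order cut-cell conductor boundaries: field values within ~2 cells
  of a curved conductor are first-order accurate; probes are therefore
  kept ≥1 cell away, and published probe points (0.5 mm off a surface) are
  10+ cells away at default spacings.
* The vegetation probe point is placed on the blade-tip-to-host line; the
  original "0.5 mm from the plant surface" location is not specified more
  precisely.
* The coarse pass of a nested solve feeds boundary error into the fine
  box; with the default pairings the rig probe agrees with the analytic
  oracle within 1%, and a sensitivity test checks that halving the
  blade-scene coarse spacing moves the vegetation probe by under 5%
  (measured: ~3%).
* No trajectories, adhesion forces, finite-body field averaging or charge
  measurement; the detailed whole-animal host mesh is out of scope (the
  ellipsoid host is the quantitative stand-in).
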