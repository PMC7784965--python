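# Methods

## System and scope

The package models a thin (~6 mm) cyanobacterial mat under a ~1 mm water
column (free water plus diffusive boundary layer, DBL), sitting on an
N₂-purged bottom chamber. Transport is purely diffusive and one-dimensional;
porosity and tortuosity are taken as 1 (no porewater correction), and
advection, 2D/3D structure, carbonate-system feedbacks and population
dynamics are out of scope. Depths are reported in mm with 0 at the mat
surface, positive downward; concentrations in µmol L⁻¹ (≡ nmol cm⁻³),
fluxes in nmol cm⁻² s⁻¹ (positive downward), volumetric rates in
nmol cm⁻³ s⁻¹ (positive = production).

## Sulfide speciation

S_tot = [H₂S] + [HS⁻] (+ [S²⁻]) is reconstructed from the H₂S microsensor
signal and pH through the first dissociation equilibrium,
α₀ = 1/(1 + 10^(pH−pK1)). pK1 uses the Millero (1988) seawater
formulation, ln K1 = 225.838 − 13275.3/T − 34.6435 ln T + 0.3449√S − 0.0274S
(T in kelvin, S practical salinity), giving pK1 ≈ 6.98 at 25 °C in fresh
water; the constant can be overridden where an independent determination
exists. S²⁻ is neglected: with pK2 ≳ 12 its share is < 10⁻³ of the pool at
pH ≤ 9, far below sensor precision. The spring-water ionic strength is not
known precisely, so the salinity argument defaults to 0 and is exposed.

## Diffusion coefficients and time scales

The defaults are the incubation values: 1.35 × 10⁻⁵ cm² s⁻¹ for sulfide and
1.78 × 10⁻⁵ cm² s⁻¹ for O₂ (already temperature/salinity-corrected). Because
the exact incubation temperature is a property of the original measurements
rather than of this package, the reference temperature is fixed at 20 °C;
off-reference values are scaled by Stokes–Einstein (D ∝ T/µ(T)) with a
standard water-viscosity correlation, and salinity is carried as metadata
only (its direct effect on D is a few percent). Characteristic diffusion
times use t = L²/(2D); with D = 10⁻⁵ cm² s⁻¹ this gives 500 s ≈ 8 min for
the ~1 mm between the photosynthetic layer and the sulfide-production zone —
the time scale that lets the two processes couple within one light phase.
The alternative L²/D convention is exactly twice this and is documented but
not used.

## Profile preprocessing

Files are comma- or tab-delimited with `# key: value` metadata headers, in
wide (one column per analyte) or long (analyte column) form. Depths along
the sensor axis are converted to vertical depth by cos(angle), after which
the angle metadata is zeroed so the correction cannot be applied twice
silently. Negative concentration readings within −2× the sensor noise scale
(default 1 µmol L⁻¹) are clipped to zero with a warning — sensor baseline
drift is routine — while larger negatives are rejected as gross errors.
Steadiness of successive profiles is judged by the relative sup-norm
deviation after linear interpolation to common depths, with a 1 µmol L⁻¹
floor against division by near-zero concentrations; the default tolerance
of 0.05 is this package's choice (field practice states only a minimum
waiting time).

## Flux and rate inversion

Interfacial fluxes use Fick's first law on a least-squares slope; the DBL
window can be auto-detected as the longest near-linear run (R² ≥ 0.98)
ending at the interface. Windows with detectable curvature attach a warning
rather than failing, because the estimate is still meaningful — it refers
to the window's mean depth.

Volumetric net rates are *not* obtained by double finite-differencing.
Instead the steady profile is fitted with the piecewise-constant-rate model
(D C″ + R_i = 0 per zone, continuity of C and flux at zone knots, measured
end concentrations as Dirichlet conditions), the standard inverse approach
for porewater profiles at 180–450 µm spacing. The fit is linear: the model
profile is the straight-line (Laplace) solution plus a superposition of
analytic unit-rate responses, so the zone rates come from one ordinary
least-squares solve, and the fitted profile is flux-continuous by
construction. For every fit, ∫R dz over the domain equals the fitted
boundary-flux difference identically — flux conservation is a structural
property, and the test suite asserts it at 1e-8 relative.

Zonation, when not supplied, is chosen by BIC over 1…max_zones equal-width
and free-knot configurations (free knots drawn from the measured depths and
charged as extra parameters). Residual sums of squares are floored at
(10⁻⁹ × data scale)² per point so that numerically perfect fits are
compared by parameter count, not by log-of-rounding-noise; ties break
toward fewer zones.

Layer balances (net consumption = J(top) − J(bottom)) estimate the two
fluxes in windows just *outside* the layer, where the profile is not curved
by the layer's own reaction. When the adjacent region itself reacts (e.g.
the migrated SOB layer directly under the actively photosynthesizing
cyanobacteria), a short window limits the bias and the lack-of-fit warning
makes it visible.

Gross rates from light–dark shifts take the magnitude of the initial slope
over a 3 s window at 0.5 s sampling (sensor response < 2 s). On a diffusive
transient this estimator can only under-read, and monotonically so as the
window grows; the bias is negligible at mid-photic depths but reaches tens
of percent at the very edge of the photic zone, which is why the default
window is short. Both the recovery (within 10 %) and the bias direction are
asserted against the transient forward model.

## Stoichiometric carbon budget

Gross OP converts to CO₂ fixation with factor 1 (one CO₂ per O₂). For gross
AP, sulfide oxidized only to S⁰ donates 2 electrons, so two sulfide are
consumed per CO₂ and the default multiplier is 0.5 mol C per mol sulfide.
The multiplier is deliberately exposed (and logged when changed): written
method descriptions in this field are ambiguous between "×2" and "per 2
sulfide" conventions, and silently adopting either reading would bake an
interpretation into the numbers.

The SOB term mixes the two end members of aerobic sulfide oxidation at a
fixed energy-conservation efficiency of 16.9 % (carried as metadata — the
end-member C yields already embody it): per mol H₂S, 0.4 O₂ and 0.1 CH₂O
(incomplete, to S⁰) versus 1.5 O₂ and 0.5 CH₂O (complete, to SO₄²⁻). The
observed S_tot:O₂ consumption ratio r fixes the S⁰ fraction f via
0.4f + 1.5(1−f) = 1/r and the yield 0.1f + 0.5(1−f); r = 2.3 gives
f ≈ 0.97 and yield ≈ 0.113 mol C (mol S)⁻¹, r = 0.85 gives f ≈ 0.29
(predominantly complete oxidation). Ratios outside [2/3, 2.5] raise a typed
infeasibility error naming the nearest end member rather than clamping —
an infeasible imposed flux ratio is exactly the condition under which real
SOB relocate instead of adjusting. A Gibbs-energy derivation of the
end-member coefficients is a documented extension point only; the
coefficients are used as stated. The AP fraction of photosynthesis is
computed in C-fixation units by default, with an electron-equivalent option
(2 e⁻ per sulfide, 4 e⁻ per O₂).

## SIP arithmetic

Conversions use R_VPDB = 0.0111802. The bulk CO₂ assimilation flux is
F = (Δx_mat/Δt) · A / mean(x_DIC − x_nat), with A the areal carbon content
of the mat (a required user input — it is a property of the sampled mat,
not of the method) and x_nat the mat's own first time point. Slopes between
two samples are finite differences; an optional regression mode uses all
points in the interval. DOC is deliberately reported only as the ¹³C/¹²C
ratio relative to the first time point (persulfate conversion efficiency
varies across compounds, so absolute DOC quantification is not meaningful).
FA-RUR divides each fatty acid's Δδ¹³C/Δt by the group sum; negative rates
are kept signed, and a non-positive denominator yields an explicit
"undefined" result instead of a renormalized one — clipping would fabricate
signal. Guild tables (cyanobacterial, SRB with subgroups 1–3, SOB fatty
acids) are fixed data; the subgrouping was originally a manual clustering
and is shipped as-is, not re-derived.

## Forward models

The steady solver discretizes D C″ + R(z) = 0 on a uniform grid (default
20 µm, finer than the 180 µm measurement spacing so that downsampling to
"measured" resolution is a separate, explicit step) with Dirichlet
boundaries and a tridiagonal solve. Nodes on interior layer interfaces get
the mean of the adjacent layers' rates, which makes the scheme exact (to
rounding) for the piecewise-quadratic solutions these scenarios have; the
discrete boundary fluxes satisfy Σ R_i h = J_bottom − J_top identically.
Constant-rate zones can demand more than diffusion supplies; a solution
dipping below −0.5 µmol L⁻¹ is rejected with advice rather than clipped,
and the preset consumption rates are set just below the diffusion-limited
critical rate so O₂ vanishes where it should without unphysical negatives.

Transients use Crank–Nicolson (unconditionally stable, second order;
default dt 0.05 s for light–dark runs), with photosynthetic source terms
zeroed from the switch time. Immediately after the switch ∂C/∂t equals
minus the local photosynthetic rate — the physical basis of the light–dark
method — and as t → ∞ the fields converge to the photo-off steady solution
(the Crank–Nicolson fixed point is the steady discrete solution).

The diel SIP generator integrates, on a piecewise-constant phase schedule
(dark → AP at low light → OP at high light, mirroring the 7/19/89/315
µmol photons m⁻² s⁻¹ staircase): bulk-mat atom fraction by the linearized
label balance dx/dt = F(x_DIC − x_nat)/A with the DIC pool held at its
post-addition atom fraction (default 0.06); DOC label excess growing
proportionally to excretion × fixation during OP only and decaying
first-order (0.5 h⁻¹) in the dark; and per-FA δ¹³C by guild/subgroup
uptake rates (‰ h⁻¹), with SRB subgroup 1 active only under OP and
subgroup 3 dominant under AP and darkness. Replicate noise is Gaussian on
the δ scale under a mandatory seed.

### What the generator does and does not emulate

It reproduces the layered concave/convex steady profile shapes of the four
light regimes, light–dark transients, diel label trajectories, guild
switching, and measurement noise — enough to exercise every inverse method
against exact ground truth. It does not emulate: saturating (Monod-type)
uptake kinetics (rates are constant per zone, so very strong consumption
must be capped below the critical rate by hand), sensor drift or response
lag, mat growth or carbon-pool turnover (the label balance is linearized,
valid for small labeling), migration dynamics in time (migration is a
discrete scenario rule), or correlated replicate error. Passing tests
therefore demonstrate correctness of the analysis chain under the stated
transport model, not robustness to every artifact of field data.

## Problem sizes and defaults used in the checks

Steady solves use a 7 mm domain at 20 µm (351 nodes); light–dark runs 15 s
at dt 0.05 s; the convergence check runs a coarser dt 50 s to 8 × 10⁴ s;
diel SIP uses a 20 h schedule sampled half-hourly. Recovery tolerances:
zone rates 5 % noiseless and 25 % at σ = 1 µmol L⁻¹, layer balances 3 %,
gross rates 10 %, SIP fluxes 5 % — each asserted in the test suite at those
values. The zero-rate middle zone is judged against 5 %/25 % of the largest
imposed rate magnitude, since a relative error on zero is undefined.

## Known limitations

* No porosity/tortuosity correction: rates in real mat fabric would scale
  by the (unknown) porosity factor.
* The piecewise-constant-rate inversion assumes steadiness; profiles still
  drifting (e.g. after an inhibitor addition) should be screened with the
  steadiness check first, as rate estimates from transients are biased.
* The end-member mixing reconstructs the product split from one flux ratio;
  the original per-time-point adjustment may have used additional local
  concentration and pH information that a single ratio cannot recover.
* Absolute field rate magnitudes cannot be validated here because the
  underlying microsensor and isotope raw data are not publicly deposited;
  validation is against the forward models and the printed stoichiometric
  anchors instead.
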