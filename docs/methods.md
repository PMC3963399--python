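# Methods

This note records the model, the numerical choices, and the places where
the design was genuinely open, so that results produced with `iopsim` can
be interpreted — and challenged — precisely.

## Geometry construction

The corneoscleral cross-section lives in the (r, z) half-plane, z along
the optic axis, corneal apex at z = 0 (maximum z), lengths in mm.

* **Cornea.** A conic with apical radius of curvature R_c and eccentricity
  e, i.e. the prolate ellipse with semi-axes a_r = R_c/√(1−e²),
  a_z = R_c/(1−e²), trimmed at the white-to-white chord r = WTW/2.  This is
  the standard conic-cornea convention; R_c, e and WTW jointly
  over-determine an ellipse, so the apex curvature + eccentricity fix the
  shape and the WTW chord only selects the trim point.
* **Sclera.** An oblate ellipse with equatorial semi-axis equal to the
  scleral radius of curvature and axial semi-axis scaled by the
  posterior-to-equatorial radius ratio (0.86 at baseline).  Its centre on
  the axis is placed so the ellipse passes through the corneal trim point.
  The two ellipses meet with a tangent discontinuity of roughly 20° at the
  limbus; this kink is a property of the piecewise-ellipse construction,
  and is one reason the junction region gets a refined mesh and blended
  material properties (below).
* **Dividing line and transition zone.** Cornea and sclera are separated
  by the radial line through the scleral ellipse centre and the junction
  point (polar angle θ_j ≈ 35.8° at baseline).  The width of the
  transition band is not anatomically constrained; we default to a 5°
  angular band centred on the dividing line, within which the material
  properties blend linearly cornea↔sclera and the meridional mesh spacing
  is halved.  The blend avoids a stress singularity at an abrupt material
  jump; nothing downstream is sensitive to the exact width.
* **Wall thickness.** A monotone (PCHIP) spline in the polar angle about
  the scleral centre through the four printed stations — central cornea
  0.96, anterior sclera 0.89 (assigned at the junction), equatorial sclera
  0.58, posterior sclera 1.12 mm.  The inner boundary is the outer
  boundary offset inward along its normal by the local thickness.  Two
  consequences worth knowing: (i) at the limbal kink the *clearance*
  between the surfaces is ~2% below the station value even though the
  offset distance is exact, because the neighbouring thinner wall cuts
  closer; (ii) the thickness gradient near the posterior pole leaves the
  inner surface very slightly dimpled there.  Both are geometric facts of
  a variable-thickness offset, not construction errors.
* **Degenerate sphere.** Setting equal corneal/scleral radii, zero
  eccentricity, unit radius ratio and uniform thickness collapses the
  construction to concentric circles — the configuration used throughout
  verification.

## Constitutive model

Two-branch generalized Maxwell (Prony) solid:
E(t) = E_equ + E₁e^(−t/τ_s) + E₂e^(−t/τ_l), with the equal-branch rule
E₁ = E₂ = (E_inst − E_equ)/2 and hence E(0) = E_inst exactly.  Baselines
(cornea 1.1 / 0.265 MPa, τ 0.35 / 68 s; sclera 5× the corneal moduli with
the same spectrum) and the sweep ranges are the porcine parameter set the
studies are built around.

The uniaxial law is extended to 3D by holding Poisson's ratio constant in
time and letting the full stiffness tensor relax proportionally
(equivalently: bulk and shear share the Prony spectrum).  This is an
interpretation, not a measured fact — the alternative (deviatoric-only
relaxation) would make the late-time response stiffer in volumetric modes.
We default to ν = 0.49 ("nearly incompressible"); quadratic displacement
triangles carry this without locking (verified to 0.5% against the exact
thick-sphere solution), so no mixed formulation is used.  Raising ν much
closer to 0.5 would warrant revisiting that choice.

Internal variables follow the exact exponential recurrence
q_i(t+Δt) = e^(−Δt/τᵢ) q_i(t) + Eᵢ (τᵢ/Δt)(1 − e^(−Δt/τᵢ)) Δε,
which is the exact branch solution for strain varying linearly within the
step — unconditionally stable, and *exact* (to round-off) for the
constant-rate volume histories simulated here.  This is why the slow
protocol may take 1 s steps despite τ_s = 0.35 s: accuracy is controlled
by the linearity of the strain within a step, not by Δt/τ_s.  The general
precondition enforced is Δt ≤ duration/10; defaults are 0.01 / 0.1 / 1 s
for the fast / intermediate / slow protocols (≥ 100 steps each; halving Δt
moves the final ΔIOP by < 0.5%).

## Volume coupling

The infusion is a prescribed cavity-volume history, enforced directly:
with g = ∂V/∂u the discrete gradient of the linearised enclosed volume
over the inner surface (axisymmetric weight 2πr), each step solves the
bordered system K_eff u = p g + f_history, g·u = V(t).  The consistent
load of a uniform cavity pressure is exactly p g (virtual work p·δV), so
the constraint and the load share one vector.  The realized linearised
volume matches the prescription to machine precision at every step; the
second-order gap between the displaced-configuration enclosed volume and
the linearised one is ~0.08% of the 15 µL infusion — the size of the
geometric nonlinearity the model neglects.

A thermal-expansion analogue (heating an enclosed filler so it expands at
the infusion rate) is retained as a documented standalone operation.  The
implemented relation is the dimensionally consistent
P = (dV/dt)·C_p·ρ/α_V; note the product form sometimes quoted
(P = dV/dt·C_p·ρ·α_V) has units W·K⁻² and cannot be meant literally.  The
cavity constraint supersedes the filler device entirely: it needs no
filler properties and no filler mesh.

## Kinematics, constraints, units

Small-strain, geometrically linear.  The incremental response therefore
superposes on the 15 mmHg baseline (reported absolute IOP = baseline +
ΔIOP) and baseline prestress does not alter it.  Constraints: u_r = 0 on
the axis, u_z pinned at the inner posterior-pole node (removing the axial
rigid translation, to which the cavity pressure is provably insensitive).
Units: mm–MPa–s internally, volumes in mm³ ≡ µL, 1 mmHg = 133.322 Pa.

## Verification oracle

A thin uniform spherical shell under prescribed volume has the closed-form
pressure Δp(t) = 2h/(3(1−ν)RV₀) ∫ E(t−s) V̇ ds with V₀ = (4/3)πR³ at the
mid-surface radius: membrane equilibrium σ = pR/2h, equibiaxial kinematics
ε = ΔV/3V₀, equibiaxial stress–strain σ = Eε/(1−ν).  Against the exact
thick-wall (Lamé) solution at h/R = 1/12 the membrane form is 1.17% soft;
the FE solver lands on the Lamé value to < 0.1% and therefore sits a
time-independent ≈1.2% above the oracle for all three protocols (the
spatial and temporal parts of the uniform-shell problem separate exactly).
The oracle is single-material by design; as a fast engine for the studies
it carries the scleral (5× corneal) material on an equivalent sphere of
R = 12 mm, h = 0.8 mm, since the shell is predominantly sclera — a
deliberate reduced-order stand-in, adequate because every study quantity
is an ordering, span or correlation that the uniform sphere preserves.

## Structural properties worth knowing

Because the solve is linear with a prescribed volume, and the 5:1
sclera:cornea tie scales both tissues together, the stiffness field is a
single scalar multiple of a fixed spatial pattern at all times.  Two exact
consequences:

* End-of-infusion ΔIOP is **affine in any swept modulus**, so modulus
  sweeps have linear-fit R² = 1 and modulus-varied populations give
  exactly straight cross-rate relationships (R = 1).  Curvature in such
  plots can only come from a compliant cavity filler, geometric
  nonlinearity, or material nonlinearity — all outside this model.
  Time-constant-varied populations *do* curve (τ enters the response
  nonlinearly), which is how the nonlinearity diagnostics are exercised.
* The time constants act selectively: τ_s changes the fast-rate elevation
  by ~27% over its range but the slow-rate one by only 0.4%; τ_l changes
  the slow-rate elevation by ~62% but the fast one by 1.2%.  The residual
  τ_s effect at the intermediate rate is ~2.6% — small but not zero: under
  ongoing loading each branch contributes a persistent offset Eᵢε̇τᵢ, so a
  "flat" response at rates much slower than a branch is flat only to
  O(Eᵢτᵢ / E_equ·t).
* The equilibrium limit is approached slowly: at 150 s (≈ 2.2 τ_l) the
  final elevation still exceeds the E_equ elastic solve by ~64% because
  the long branch's steady offset E₂ε̇τ_l has not decayed; at 20 τ_l the
  gap is ~8%.  "Slow" infusion is not the equilibrium response.

## Calibration and identifiability

Calibration fits (E_inst, E_equ, τ_s, τ_l) by bounded least squares
(trust-region reflective) on the stacked ΔIOP residuals over all supplied
rates, on the observed volume grids; bounds default to the plausible
ranges.  Noise-free three-rate curves are recovered to optimizer precision
(≪ 2% moduli, ≪ 10% time constants).  The identifiability report uses the
Gauss–Newton covariance in relative parametrisation, with the noise scale
floored at 1% of the data rms so a perfect fit still yields a meaningful
uncertainty; parameters with relative standard deviation > 0.3 are flagged
weakly identifiable.  Single-rate data always flags both time constants —
rate contrast is what separates the spectrum.  Under 3% multiplicative
noise (20 replicates) the median recovery errors are ≈3% (E_inst),
≈15% (E_equ), ≈16% (τ_s), ≈21% (τ_l): E_equ and the time constants share a
collinear direction that noise excites.

## Synthetic data: what it emulates and what it does not

The generator produces a population of eyes with mean-one multiplicative
log-normal scatter on chosen parameters (default: CV 20% on E_inst only,
the variation pattern that reproduces linearly correlated cross-rate
elevations), measured as ΔIOP at 11 volume levels in [0, 15] µL per rate
with additive Gaussian noise (default 0.5 mmHg, optional multiplicative
2%).  The log-normal choice and the noise magnitudes are stand-ins — no
inter-eye parameter distribution or instrument noise model has been
measured — so passing closed-loop tests demonstrates the *pipeline's*
correctness, not fidelity to any real porcine dataset.  Real data would
add features deliberately absent here: pressure-dependent aqueous outflow
(a leaky shell), baseline-IOP variation between eyes, volume-delivery
error, and constitutive nonlinearity.  With the default conditions the
closed loop (generate → calibrate per eye → compare to hidden truth)
attains a 20-seed median Pearson R ≈ 0.84 between true and estimated
E_inst; the 0.5 mmHg noise on ~2–3.6 mmHg signals is the limiting factor,
and classical attenuation makes substantially higher values unreachable at
these settings.

## Problem sizes and defaults

Default target element size 0.25 mm (~1,200 quadratic triangles, ~5,600
DOF): the mesh-convergence study shows the final ΔIOP changing by < 0.1%
over the last refinement step at this density, and a 0.07 mm target
reproduces the ~11,900-element reference density when needed.  Sweeps
default to 5 grid points per parameter and populations to 5–11 eyes;
curves are sampled at ≥ 11 volume levels.  All study tables are
deterministic under fixed configuration and seed.

## Known limitations

No aqueous outflow, no optic nerve head or scleral canal, no contact
(tonometry), no large-deformation or fibre-reinforced constitutive
behaviour, single fixed baseline IOP, constant-ν proportional relaxation.
These bound the model to short-duration, small-volume perturbations of an
intact shell — exactly the micro-volumetric regime it was built for.
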