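# Methods

`pulseloop` simulates bidirectional ventricular–arterial coupling in the
systemic circulation with finite-element (FE) models of both deformable
chambers — the left ventricle (LV) and the aorta — embedded in a closed
lumped-parameter loop.  This note records the model equations, the
numerical choices, the calibrated defaults and their rationale, and the
known limitations.

## Model structure

Four storage compartments exchange blood through four resistive segments:

    veins -> (R_ven) -> left atrium -> (R_mv, diode) -> LV
          -> (R_ao, diode) -> aorta -> (R_per) -> veins

Volumes evolve by explicit (forward-Euler) bookkeeping of the segmental
flows; because the flows telescope around the loop, total blood volume is
conserved to round-off at every step, for any step size.  Pressures close
the system: the veins are a linear compliance `P = (V - V0)/C`; the left
atrium is a time-varying-elastance chamber interpolating between a linear
end-systolic and an exponential end-diastolic pressure–volume relation
with a sinusoidal-rise/exponential-decay driving function; the LV and
aorta pressures are *not* closed-form — at each step the FE problem for
each chamber is solved at the compartment volume handed over by the
circulation, and the Lagrange multiplier that enforces the cavity-volume
constraint is returned as the cavity pressure.  Explicit staggering
(volumes from old flows, pressures from new volumes, flows from new
pressures) follows the scheme the framework is built around.

The atrial activation clock starts at a configurable offset within the
ventricular cycle (default 560 ms of the 800 ms beat), so peak atrial
elastance falls just before ventricular activation at t = 0 — the atrial
kick tops up the LV at end-diastole.

## Chamber mechanics

Both chambers are quasistatic, incompressible, hyperelastic bodies
discretized with 10-node quadratic tetrahedra.  The mixed formulation
pairs P2 displacements with a continuous P1 pressure-multiplier field
(Taylor–Hood-type); a scalar multiplier constrains the cavity volume
computed as the deformed-surface functional
`V(u) = -(1/3) \int_{\Gamma_inner} x . n da` (closed by the base plane at
z = 0 for the LV and by planar end caps for the aorta); and scalar
multipliers remove the rigid modes left after the in-plane
(`u . n = 0`) conditions on the base/end planes.  Newton's method with an
analytic consistent tangent — including the exact follower-load Hessian
of the cavity-volume functional — solves each step, warm-started from a
linear extrapolation of the two previous converged states; the factorized
Jacobian is reused for chord iterations between refactorizations, and
failed load increments are bisected jointly in volume and activation
time.  Convergence is declared at a relative residual of 1e-9 measured
against the internal-force magnitude.

**LV constitutive law.** Passive: Fung-type transversely isotropic
exponential energy `W = C/2 (exp Q - 1)` with Q quadratic in the Green
strain in the fiber/sheet/normal frame (C = 0.10 kPa, b_ff = 29.9,
b_xx = 13.3, b_fx = 26.6).  Active: tension along the fiber direction,
`T = T_max Ca0^2/(Ca0^2 + ECa50(l)^2) Ct(t, l)`, with length-dependent
calcium sensitivity `ECa50 = Ca0_max / sqrt(exp(B(l - l0)) - 1)`, a
raised-cosine twitch Ct rising to its peak at t0 = 171 ms and relaxing
over `t_r = m l + b`, and sarcomere length `l = lambda_f l_r`.
T_max = 200.7 kPa.  The relaxation intercept is b = -1500 ms here
(t_r(l_r) ≈ 440 ms): a positive intercept of the same magnitude would put
t_r near 3.4 s, the twitch would never relax within the 800 ms beat and
no diastole could exist; the negative intercept matches the
active-contraction literature this law descends from and is exposed in
the configuration.

**Aorta constitutive law.** Mass-fraction-weighted mixture: neo-Hookean
elastin matrix (c1 = 160 kPa, phi_e = 0.306); four collagen fiber
families (longitudinal, circumferential, ±45°) sharing the exponential
fiber energy `(c2/4c3)(exp[c3 (lam^2-1)^2] - 1)` with the collagen mass
split 10/10/40/40 across the families; circumferential smooth muscle with
a passive exponential part (c4, c5) and an active-tone potential whose
Cauchy stress is `phi_m S_m lam [1 - ((lam_M - lam)/(lam_M - lam_0))^2]`
(zero slope at lam_0 = 0.8, maximal at lam_M = 1.4).  All constituent
energies are per unit reference volume: mass densities enter only as mass
fractions (M/rho), which makes the active term exactly
`phi_m S_m [...]`.  Setting S_m = 0 is the "no tone" case.

**Fiber fields.** LV: rule-based helix angle varying linearly across the
wall from +60° (endocardium) to -60° (epicardium).  Within a cylindrical
apex cap (radius 0.3 r_endo) the fiber direction blends smoothly into the
local longitudinal direction and the active tension tapers smoothly to
zero: the circumferential direction degenerates on the axis, and
circumferential tension at vanishing radius would crush the apex
elements.  Aorta: family 1 along the centerline tangent, family 2
circumferential (shared by the smooth muscle), families 3/4 at ±45°.

## Geometry

LV: truncated half prolate ellipsoid, base at z = 0, endocardial
semi-axes 2.8 × 5.8 cm, epicardial 3.8 × 6.6 cm (unloaded cavity 95 ml,
wall 104 ml); default mesh 1092 quadratic tets.  Aorta: swept annular
tube — 6 cm ascending segment, 180° arch of centerline radius 5 cm with
clothoid-like curvature ramps (4 cm) at both junctions, 30 cm descending
segment — unloaded inner radius 0.93 cm, uniform wall 0.31 cm, inner
radius tapering linearly from mid-arch to 90% distally; default mesh
1440 tets.  Meshes are structured hexahedral grids split into conforming
tetrahedra by the Freudenthal template with mid-edge nodes on the exact
parametric surfaces.

These unloaded dimensions are the package's one-time calibration: the
study conditions fix the *loaded* state (end-diastolic inner diameter
24 mm near 78 mmHg, end-systolic 27.5 mm near 128 mmHg, EDV ≈ 150 ml,
pulse pressure ≈ 50 mmHg), and with the wall constants above the
operating stretches that reproduce those numbers are
lambda_ED ≈ 1.3–1.35 and lambda_ES ≈ 1.45–1.5 — which pins the unloaded
radius and wall thickness essentially uniquely.  The smooth-muscle
passive exponential (c5 = 7.28) locks the wall sharply above
lambda ≈ 1.47, so end-systole sits at the knee of the
pressure–diameter curve and end-diastole on its compliant shoulder,
reproducing the S-shaped ex-vivo relation.  Two consequences of this
calibration are documented rather than hidden: the loaded end-diastolic
wall thickness comes to ≈ 2.3 mm (a thinner 1.8 mm wall cannot
simultaneously carry the diastolic pressure at the required diameter
with these constants), and the descending segment is long because this
single vessel is the *entire* arterial compliance of the loop — there is
no separate Windkessel capacitor to buffer the stroke volume.

**Aortic tethering.** In addition to the in-plane end conditions, the
volume-weighted mean displacement of every interior cross-section is
constrained to zero by multiplier triples.  This represents perivascular
tethering (spine, intercostal and supra-aortic branches).  It is not
optional: the net pressure force on a 180° bend (~2 P A) is not carried
by any physical cap in this formulation, and without distributed
tethering the pressurized U-tube balloons axially until the wall thins
unphysically.  The constraint freezes the centerline while leaving
radial distension — the physics of interest — free.

## Numerical choices

- 11-point degree-4 tetrahedral quadrature; degree-5 surface rules.
- Sparse LU (SuperLU, minimum-degree ordering) on the bordered saddle
  system; chord reuse of factorizations between steps.
- Volumetric stabilization for the LV: an augmented-Lagrangian term
  `kappa/2 (J-1)^2` with `kappa(t) = 10 kPa + 7 * T(t, l_r)` accompanies
  the pressure multiplier.  The weak (P1) constraint admits local
  element-collapse modes when 145 kPa of rank-one fiber tension rides on
  a 0.1 kPa matrix; the penalty is consistent (vanishes where J = 1),
  negligible in diastole, and its residual stiffening is absorbed by the
  geometry calibration.  The aorta needs none.
- Element assembly is compiled (numba); a pure-numpy implementation of
  identical element blocks is kept and the two are asserted equal in the
  test suite.
- Timestep 1 ms by default (explicit stability margin is ~10x); the
  reduced "coarse" mode used by the acceptance runs takes 2 ms with
  168 LV / 240 aorta tets.  Halving dt changes steady-state EF by
  < 0.5% (verified with elastance surrogates).
- Steady state: EDV, ESV and mean aortic pressure all changing < 0.5%
  between consecutive beats (at most 20 beats; typically 4–7 from the
  documented initial conditions: LV at its unloaded volume, aorta
  pre-pressurized near mean arterial pressure, LA 20 ml above its
  intercept, the veins carrying the rest of the 3900 ml total).
- Peak aortic stress is reported from the cell-averaged (piecewise-
  constant projected) Cauchy stress field, max over wall and beat, of
  the Frobenius norm.  The raw quadrature-point maximum of exponential
  fiber laws is dominated by the inner-surface stretch tail and does not
  settle to a mesh-independent value at coarse resolution.
- ED and ES time points are read from the diode flows (mitral/aortic
  valve closure); diameters are inner, area-equivalent, at the
  mid-ascending station.

## Parameter cases

Only the endpoints are fixed by the study design: tripled wall thickness
(T3), halved contractility (C2, T_max 200.7 -> 100.35 kPa), and the two
mass-fraction sets (M1 collagen-rich: 0.122/0.061/0.816; M2
elastin-rich: 0.49/0.24/0.272 — the printed rows are rounded and sum to
0.999/1.002, and are used verbatim).  The intermediates are this
package's choices: C1 contractility × 0.75; P1/P2 passive stiffness
× 2, 4; T1/T2 thickness × 2.0, 2.5.  The thickness intermediates are
deliberately not equally spaced from 1: because the baseline operating
window rides the smooth-muscle stiffening knee, a mildly thickened wall
(×1.5–1.7) slides its window onto the compliant elastin branch and pulse
pressure transiently *drops*; scales of 2.0/2.5 keep the series on the
reported monotone pulse-pressure progression, which is the qualitative
behavior the thickness study demonstrates.  "Without active" sets
S_m = 0 only.

## Problem sizes for reproduction

The validation suite and `scripts/acceptance.py` run the coupled studies
at the package's reduced problem size: 168 LV / 240 aorta quadratic
tets, dt = 2 ms, at most 8 beats per case (steady state typically in
4–7).  A beat takes ~20 s on one CPU; the ten-case battery completes in
roughly a quarter of an hour.  The default (finer) meshes are ~1100 and
~1400 tets with dt = 1 ms for production runs.

## What the idealized set-up does and does not show

The geometry is idealized (prolate-ellipsoid LV, swept-tube aorta with
uniform wall), material properties are homogeneous, the reference
configuration is stress-free (no residual stress/axial prestretch), and
there is no fluid dynamics — pressures are spatially uniform within each
cavity and wall shear is absent, so wave propagation, pulse-wave velocity
and spatial pressure gradients are outside the model.  The right heart
and pulmonary loop are absent.  Agreement of the test suite therefore
demonstrates the coupled solver and constitutive implementation on the
idealized study conditions, not patient-specific fidelity.  Because the
wall laws are exponential, quantities tied to the stretch tail (peak
stress above all) are sensitive to the operating point; diameters and
pressures are robust.
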