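# Methods

`apexfree` is a desk-scale simulator of left-ventricular (LV) mechanics
built to study one mechanism: how the longitudinal elasticity of the
ascending aorta (AA) loads the LV long axis, and how releasing the apex
from its pericardial confinement restores long-axis function when the AA
is stiff.  This note records the model, its assumptions, the numerical
choices, and what the synthetic setting can and cannot show.

## Geometry and microstructure

The LV is a truncated prolate ellipsoid: endocardial semi-axes
(a, c) = (22, 50) mm by default, uniform 10 mm wall, basal truncation
plane at half the endocardial long semi-axis, apex–base axis along +z.
A global similarity scale on all lengths is the single geometric
calibration knob; at the calibrated scale the unloaded cavity holds
~96 mL, consistent with the empirical single-beat EDPVR estimate of the
zero-pressure volume for an EDV near 158 mL.  The wall carries a
rule-based fiber field: helix angle linear across the wall from +60°
(endocardium) to −60° (epicardium), sheet direction transmural.  These
are standard idealized-LV conventions; nothing about the anatomy is
patient-specific.

Landmarks are the epicardial apex, the mitral-annulus-plane center
(centroid of the basal endocardial ring) and an aortic-root attachment
point offset from the annulus center toward the septal azimuth.  The
aortic-root offset is what breaks axisymmetry: the AA spring grabs the
base on the septal side, so aortic stiffening loads the septal wall
hardest — the mechanism behind the regional (septal vs. lateral)
longitudinal-strain asymmetry in the comparisons.

## Constitutive model

Passive myocardium is the orthotropic Holzapfel–Ogden energy
(isotropic + tension-only fiber and sheet terms + fiber–sheet shear),
evaluated on isochoric invariants, with a quadratic volumetric penalty
κ(J−1)²/2 enforcing near-incompressibility.  κ = 1 MPa (≥ 500× the
stress-like moduli) keeps the total wall-volume change below 2 % over a
beat.  Ventricular parameter values: a = 3.9e-4 MPa, b = 3.7,
a_f = 1.9e-3 MPa, b_f = 14, a_s = 1.1e-3 MPa, b_s = 11,
a_fs = 3.6e-7 MPa, b_fs = 7e-4.

Active contraction is a time-varying-elastance fiber stress

    sigma_a = T_max/2 · Ca0²/(Ca0² + ECa50(l)²) · (1 − cos ω(t, l)),

added along the reference fiber direction (a configurable fraction along
the sheet direction defaults to 0).  ECa50 = Ca0max/√(exp[B(l−l0)]−1)
encodes length-dependent activation (Frank–Starling): below the zero-force
sarcomere length l0 = 1.58 µm no force develops; the effective length is
l = l_r√(2E_ff+1) with resting length l_r = 1.85 µm.  The cosine phase
rises over t0 = 0.35 s and relaxes over tr(l) = m·l + b (m = 950 s/mm,
b = −1.5 s) — stretched fibers relax more slowly.  T_max = 0.2 MPa,
Ca0 = Ca0max = 4.35 mM, B = 4750 mm⁻¹.

Note a structural property of these numbers: at end-diastolic stretches
the twitch lasts t0 + tr ≈ 0.9 s.  The cycle length is therefore set to
1.0 s (60 bpm) so that a genuine diastole exists; at shorter cycles the
most-stretched fibers never fully relax.

## Mechanics discretization

The wall deformation is a global reduced-kinematics field: 18 smooth
polynomial displacement modes over the parametric wall (cylindrical-radial
scaling with transmural/axial variation, axial shortening and translation,
an apex bulge pair, torsion, and a septally biased axial pair that lets
the base tilt against the off-axis AA spring), plus a position-proportional
"spherical" family used for the spherical-shell verification problem.
The constitutive response is integrated on a Gauss grid over the wall
(default 3 transmural × 6 longitudinal × 8 circumferential regions; the
mode gradients at the Gauss points are precomputed).  Equilibrium is the
stationarity of total potential energy — strain energy + volumetric
penalty + spring energy − cavity-pressure work (+ active-stress virtual
work, which is not a potential) — solved as a root problem in the mode
coefficients.

The cavity is a hydrostatic fluid cavity: one uniform pressure on the
deformed endocardial surface, whose volume comes from the divergence
theorem with the flux referenced to the deformed basal-ring centroid
(making the basal cap contribute zero and the volume exactly
translation-invariant).

Boundary conditions:

* 49 pericardial spring clusters partition the epicardium (farthest-point
  seeding + Lloyd refinement, deterministic); each spring acts along the
  local epicardial surface normal — restraining normal motion while
  permitting tangential sliding inside the pericardial sack — with
  stiffness decreasing linearly from apex (0.6 N/mm by default) to base
  (0.005 N/mm).  At the apex cap the normal is axial, so the apical
  clusters anchor the apex.  "Freeing the apex" deactivates the clusters
  in the apical half of the normalized axial extent.
* one AA spring at the aortic-root attachment, acting along the apex–base
  axis only (the root is free to stretch, not to rotate): 0.5 N/mm
  (elastic AA) or 10 N/mm (stiff AA, operationally a stationary root).

## Equilibrium solver

The coupled step solves for (modes, pressure) with the cavity volume
constrained to the circulation's target.  The primary solver is a
quasi-Newton with an LU-factorized finite-difference Jacobian cached
across coupled steps (batched residual evaluation builds the Jacobian in
one vectorized call; the pressure column is analytic).  The activation's
length dependence is steep (B, and tr(l) near end-relaxation), so the
solver falls back progressively: Jacobian refresh per iteration →
volume-target ramping → Aitken-relaxed staggering of the active-stress
field (each inner solve sees a frozen, constant activation field — a
smooth problem) → hybrid-Powell and bounded trust-region root finders →
escalation of a small artificial step viscosity.  The viscosity
(2 N·mm per unit mode-coefficient change per step, with a sticky
escalation ladder) regularizes quasi-static snap-throughs during rapid
filling, when lengthening fibers re-cross the activation threshold; its
bias is orders of magnitude below the physical generalized forces except
transiently at the highest escalation levels, and it vanishes at
convergence of the subsequent steps.  Two further numerical guards: a
0.05 N·mm/unit quadratic regularization on all mode coefficients (bounds
the conditioning of the nearly unconstrained tangential directions), and
a 0.02 s floor on tr(l) where the linear law would make it non-positive
(fibers there produce no force anyway through ECa50 → ∞).

## Circulation and coupling

A minimal closed loop: left atrium (passive compliance 8 mL/mmHg),
diode-resistor mitral and aortic valves (0.01 mmHg·s/mL each),
two-element arterial Windkessel (1.7 mL/mmHg, systemic resistance
1.05 mmHg·s/mL) and a venous compartment (50 mL/mmHg, return resistance
0.05) feeding the atrium.  Volumes are stressed volumes; the update is
explicit (sub-steps ≤ 2 ms under a 25 ms mechanical step, with adaptive
splitting whenever more than 3 mL would move in one mechanical solve) and
exactly conservative.  Coupling is volume-driven: the net valve flow sets
the next cavity-volume target; during the sub-steps the LV pressure is
extrapolated linearly with a running dP/dV estimate.  Beats repeat until
the stroke volume changes by < 1 % between cycles (≤ 6–10 beats), and the
converged beat supplies all metrics.  ED is the end of the diastolic
volume plateau, ES the first step at the volume minimum (end of
ejection), both detected from the volume trace.

## Calibration

The study fixes the AA spring at 0.5 N/mm (baseline) and 10 N/mm
(stiff); everything else the source experiment leaves unprinted is
calibrated once against the baseline operating point and then frozen for
all three scenarios: (1) the geometry scale so passive inflation at
11.85 mmHg holds 158.3 mL; (2) the total stressed blood volume so the
coupled baseline beat reaches an EDV near 158.3 mL (secant search);
(3) the pericardial stiffness scale toward an 11 mm systolic root
descent.  All searches are bounded and deterministic.

Apex and root displacements are measured between the beat's apex–base
*length* extrema (the base keeps rising through isovolumic contraction,
so the length extrema — not the volume extrema — bracket the full
atrioventricular-plane excursion), projected on the apex–base axis.

The root-descent target deserves honesty: with this reduced kinematics
and boundary-condition idealization the baseline systolic root descent
calibrates to about 8.5–9 mm, not 11 mm.  The descent the model produces
is the release of the diastolic base elevation plus active long-axis
shortening; the reduced mode basis and the absence of atrial tethering
limit the atrioventricular-plane excursion.  The calibration therefore
reports its closest achieved value (raising an error only in strict
mode), and the package treats the 11 mm figure as a target the
simplified model approaches from below, with the correct sign and order
of magnitude.  Two related marginal effects: with the aortic spring at
10 N/mm the root excursion settles near 1.2 mm (not strictly below the
1 mm "stationary" operationalization), and the end-systolic myofiber
stress of the free-apex scenario tracks the baseline value to within
0.2 % (marginally below it) instead of sitting clearly between baseline
and stiff-aorta values.  All other inter-scenario comparisons are
unaffected, and the apical behaviour (≈ −1.5 mm at baseline, ≈ +15 mm
toward the base with the apex freed) matches the reference physiology
well.

## Scenarios and reports

A: elastic AA (0.5 N/mm); B: stiff AA (10 N/mm); C: stiff AA + apical
half of the pericardial clusters removed.  B and C differ from A only in
those two switches.  Reports per converged beat: PV metrics (EDP, EDV,
ESP, ESV, SV, MAP as the cycle-average arterial pressure, stroke work
SW = SV × MAP in mmHg·mL — about 1.2 J at baseline — plus the shoelace
loop area); strains at 12 locations (3 axial × 4 circumferential
sectors, endo- and epicardium pooled) measured as relative stretches of
material fiducials along the anatomical wall triad between ED and ES;
regional longitudinal strain by sector (septal/anterior/lateral/
posterior, with the septum at the aortic-root azimuth); volume-weighted
end-systolic myofiber Cauchy stress with element-wise percent changes
against baseline (mean ± SD over elements — the convention that matches
"± %" reporting, since the ratio of field means cannot reproduce it);
apex and root ED→ES displacements along the apex–base axis (apex
positive toward base, root positive toward apex).

## What the synthetic setting does not show

The geometry is an idealized ellipsoid, not the anatomy of a living
heart: no atrium, valves, trigones or papillary muscles (their stress
concentrations are absent, so absolute stress/strain values sit below
imaging-based models); activation is prescribed and synchronous
(no electrophysiology); the pericardium is a spring bed, not a contact
surface; the circulation has no right heart, and no neurohumoral feedback
adjusts contractility between scenarios.  Passing the acceptance suite
therefore demonstrates the mechanism — the direction and approximate
size of the stiff-AA penalty and the free-apex rescue — not quantitative
agreement with any individual heart.  Quantities reported as qualitative
bands (stroke volume between scenarios, strain and stress changes) should
be read as such.

## Problem sizes

Default runs use the 3 × 6 × 8 Gauss grid, 18 modes, 40 mechanical steps
per 1 s cycle and at most 6–10 beats per scenario; the calibration uses
shortened (2–4 beat) warm-chained runs.  These sizes were chosen as the
coarsest resolution at which the comparisons are stable; halving the
step or refining the grid changes the reported metrics by far less than
the inter-scenario differences.
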