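# Methods

## Scope and intent

`caaflow` is a reduced-order (0D circulation + quasi-1D lumen) model of
coronary artery aneurysm hemodynamics. It trades the 3D finite-element
fidelity of patient-specific CFD for a desk-scale pipeline whose every stage
is deterministic, fast and testable. Absolute shear magnitudes are therefore
approximate; the quantities the package is designed to get right are
*orderings and fractions* — how cases of equal maximum diameter but different
length rank against each other, and which invariants (area-fraction nesting,
OSI bounds, mass conservation) any valid hemodynamic summary must satisfy.

## Aneurysm morphing

A healthy vessel is a tube of radius `r0` along an arclength-parameterized
centerline. A morph with maximum diameter `D_max` and length `L` dilates the
span `[s0, s0 + L]`:

- smoothstep (cubic Hermite, zero end slopes) neck transitions of fixed axial
  extent `ℓ` (default 1.0 cm, capped at `L/2`) from `r0` up to `D_max/2` and
  back;
- a fully dilated cylindrical body `r = D_max/2` between the necks.

The profile is C1, interpolates `(s0, r0)`, `(s0 + L/2, D_max/2)` and
`(s0 + L, r0)` with zero slope at all three, and is bounded in
`[r0, D_max/2]`.

The *fixed* neck length is a deliberate design choice, not a convenience. An
interpolant built solely from the three control points is self-similar in
`s/L`: the distribution of radii over the normalized span — and with it every
area-normalized shear metric — becomes independent of `L`, which contradicts
both intuition and the observed behavior of long fusiform aneurysms (a giant
aneurysm is a dilated tube with ends, not a stretched sinusoid). With
caliber-scale necks, longer aneurysms spend proportionally more of their
surface at full dilation, producing the expected decrease of mean TAWSS and
increase of low-shear area with aspect ratio at fixed `D_max`.

Morphs are single-lobe and axisymmetric; real CAAs with multiple lobes or
centerline asymmetry are outside this geometry model. The aneurysm region
used as the denominator of all area metrics is exactly the morphed span.

Geometry is stored in CGS (cm); aneurysm specifications are accepted in mm
and converted on ingest. Surface areas and volumes are composite-Simpson
quadratures of the surface-of-revolution integrands at a default density of
400 samples per morph span (configurable); halving the step changes results
by well under 0.01%.

## Closed-loop circulation

Topology (units mmHg, mL, s): elastance ventricle → aortic valve → aortic
root compliance node → {three-element Windkessel systemic branch, coronary
branch `Ra–Ca–Ra_micro–Cim–Rv`} → venous reservoir → mitral valve →
ventricle. Design notes:

- **Elastance** `E(t) = E_min + (E_max − E_min)·a(t)` with a single-bump
  shifted-cosine activation `a(t) = ½(1 − cos 2πt/T_sys)` over a systolic
  interval `T_sys = 0.3·√T` s, zero elsewhere (C1 at the boundaries).
- **Valves** are ideal diodes with a C1 quadratic opening knee (0.1 mmHg) and
  *exactly zero* reverse flow. A leaky smooth diode (sigmoid/softplus) is not
  usable in a closed loop: the resistive path between the valve terminals
  sustains a spurious steady microcirculation of order 0.1 mL/s even with a
  flat elastance, while the hard-knee diode lets the no-pumping limit decay
  to identically zero flow.
- **Intramyocardial coupling**: the coronary bed's compliance `Cim` is
  referenced to `P_im = γ·P_lv` (default γ = 0.5). During systole the rising
  reference pressure discharges `Cim` backwards, throttling inlet flow;
  coronary perfusion becomes diastolic-dominant, and the diastolic share
  increases strictly with γ. The right heart and pulmonary circulation are
  lumped into the venous reservoir: aortic pressure and coronary flow — the
  outputs this package needs — do not require them at this scale.
- **Scaling of defaults** to clinical targets: total resistance `MAP/CO`
  (MAP = DBP + PP/3), split between a systemic branch carrying `(1 − f)` and
  a coronary branch carrying `f` of the output (current division); arterial
  compliance `SV/PP`; coronary internal splits 0.32/0.52/0.16 of the branch
  total with time constants `Ra·Ca = 0.02 s` and `Ra_micro·Cim = 0.35 s`;
  `E_min` set so the ventricle holds 2.5 stroke volumes at an 8 mmHg filling
  pressure (headroom for the stroke-volume knob); venous compliance 2×
  arterial. The venous reservoir sets the loop's slowest time constant, so
  it is deliberately small enough that the preload settles within the cycle
  budget — it lumps the right heart and pulmonary circulation and makes no
  claim to anatomical venous capacitance.

**Integration.** Adaptive RK45 (`rtol 1e-6`, `atol 1e-8`), cycle by cycle on
a uniform output grid of 800 steps/cycle, up to 40 cycles. Periodic steady
state is declared when (a) the maximum cycle-to-cycle change of aortic
pressure falls below the tolerance (default 0.03%) and (b) the *remaining*
drift of the end-of-cycle state — extrapolated from the geometric decay of
its cycle-to-cycle differences — is below the same tolerance. The second
check matters because the aortic waveform settles before the slow venous
mode; stopping on the waveform alone measures stroke volume off-attractor
by several percent. At this tolerance the cycle-net ventricular volume
drift is far below 0.5% of SV and the branch-flow balance closes to ~0.1%.
Typical runs converge in 4–12 cycles. Halving the output step changes
cycle-mean aortic pressure by < 0.2% (the integrator, not the grid,
controls accuracy).

**Tuning** is a damped multiplicative fixed-point loop, not a generic
optimizer: resistance ← MAP ratio, compliance ← pulse-pressure ratio, heart
elastance ← stroke-volume ratio (raising `E_max` and lowering `E_min`
together, so preload recruitment is available when ejection alone
saturates), coronary scale ← flow-fraction ratio, each with exponent 0.5.
Every iteration measures with the same cold-start simulation protocol a
standalone run uses, so the residuals the tuner accepts are exactly what
any later verification reproduces; the loop stops at a 3% internal margin
(contract: 5%) with a 40-iteration budget that raises a residual-carrying
error when exhausted. Deterministic given targets and initial parameters.
Across 40 random synthetic patients the tuned verification residuals stay
below 3%.

## Shear metrics

The WSS closure is quasi-steady Poiseuille: `τ(s,t) = 4μQ(t)/(πr(s)³)` with
the flow uniform along the segment (rigid wall, no side branches), signed by
flow direction; no Womersley (pulsatility) correction is applied. TAWSS
integrates `|τ|` over the cycle (trapezoid on the waveform grid); the
aneurysm mean is *surface-area-weighted* (weight `2πr√(1 + r′²)`), since the
reference quantity is an average over the aneurysm surface. Low-WSS area
fractions use the strict inequality `TAWSS < threshold` (ties count as
not-exposed), measuring contiguous below-threshold runs with the same
quadrature as the denominator; thresholds default to 4 and 1 dyn/cm². OSI
follows the standard definition and is defined as 0 where shear vanishes
identically. The residence time is the volume-turnover surrogate
`V_span / Q̄` — not a Lagrangian particle-tracking residence time — and is
labeled a surrogate wherever it is reported.

Under this closure TAWSS scales linearly with the flow amplitude and OSI is
independent of it; both properties are exploited in the tests.

## Synthetic data

The generator emulates the study conditions, not any real patient:

- **Cohort**: four morphs at fixed `D_max` — (a.1: 8/20), (a.2: 8/40),
  (b.1: 7/40), (b.2: 7/80) mm — plus an unmorphed control, sharing one
  centerline and one set of clinical targets. Baseline healthy diameter
  3.5 mm (typical adult LAD caliber; the source study does not state the
  morphed vessel's healthy caliber), morph onset 1 cm from the inlet with
  1 cm of distal run-out.
- **Patients**: uniform draws of heart rate 60–100 bpm, systolic 90–130 /
  diastolic 50–85 mmHg (≥ 10 mmHg pulse enforced), BSA 0.6–1.6 m² with
  stroke volume 35–45 mL/m², coronary fraction 3–5% of cardiac output —
  plausible for the older-child-to-adolescent range this disease context
  concerns. All generators are pure functions of their seed.
- **Fixture waveforms**: constant, sinusoid, and a biphasic coronary shape
  whose diastolic lobe dominates by construction.

What passing tests on these inputs do *not* show: agreement with 3D CFD shear
magnitudes, behavior on lobed/asymmetric real aneurysm geometry, or coronary
autoregulation. The synthetic centerline's gentle curvature has no
hemodynamic effect at all under the axisymmetric quasi-steady closure — it
exercises the 3D plumbing only.

## Degenerate inputs and tie-breaks

- `d_max = baseline` is a valid degenerate morph (uniform tube); the cohort
  control is exactly this, and its aspect ratio is reported as NA.
- Zero-length quadrature intervals return 0; inverted intervals raise.
- Samples exactly at a low-WSS threshold count as not-exposed.
- Cycle-total coronary flux of zero makes the diastolic fraction undefined
  (error), as does non-positive mean flow for the residence time.

## Known limitations

- Shear magnitudes inherit all Poiseuille assumptions (fully developed
  laminar axisymmetric flow); recirculation, neck shear-gradient spikes and
  intra-aneurysmal secondary flow are invisible to this closure.
- The circulation has no right heart, no autoregulation, no exercise states;
  γ is a fixed fraction rather than a transmural pressure model.
- The tuning loop matches four scalar targets; it does not reproduce any
  specific published parameter-estimation scheme.
- Problem sizes used throughout (800 steps/cycle, ≤ 20 cycles, 400 axial
  samples per span) are the package's defaults chosen for converged results
  at interactive speed; all are configurable.
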