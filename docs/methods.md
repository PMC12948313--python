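# Methods

`hepacirc` implements a closed-loop lumped-parameter (0D) model of the human
circulation with a dual-inflow liver, and the analysis pipeline built on it:
steady-cycle hemodynamic indices, calibration to normative aortic targets,
graded acute-liver-injury scenarios, and variance-based global sensitivity
analysis. This note records the model, the reconstruction decisions that
were genuinely open, the numerical scheme, and the known limitations.

## The model

**Electrical analogy.** Pressure ↔ voltage (Pa), volumetric flow ↔ current
(mm³/s), vessels ↔ resistors (R, Pa·s·mm⁻³), vessel distensibility ↔
capacitors (C, mm³·Pa⁻¹), blood inertia ↔ inductors (L, Pa·s²·mm⁻³).
Internal units are the SI-consistent set {Pa, mm³, s}; reports use
mmHg / mL / L·min⁻¹ (1 mmHg = 133.322 Pa).

**Ventricles.** Both ventricles are time-varying elastance chambers,
P(t) = E(t)·(V(t) − V0), with the triphasic elastance

    E(t) = E_min + (E_max − E_min)/2 · (1 − cos(π t / t_max)),       0 < t ≤ t_max
         = E_min + (E_max − E_min)/2 · (1 + cos(π (t − t_max)/t_toRelax)),
                                                       t_max < t ≤ t_max + t_toRelax
         = E_min,                                      otherwise (diastasis)

E(t) is continuous at both breakpoints. The timing parameters
(T = 0.684 s, t_max = 0.377 s, t_toRelax = 0.104 s) are shared by both
ventricles; E_max differs (left 0.394, right 0.152 Pa·mm⁻³; E_min = 9·10⁻⁵
for both; V0 = 10 mL). Chamber pressure may go negative when V < V0 — the
linear law is used without an unstressed-volume floor.

**Valves.** Each of the four valves is a smooth diode: openness
s(ΔP) = ½(1 + tanh(ΔP / w)) with transition width w = 0.1 mmHg, effective
resistance R_eff = R / max(s, 10⁻⁶), in series with a small inertance.
The width and the closed/open resistance ratio (10⁶) are modeling
constants of this package: narrower transitions (≤ 0.05 mmHg) destabilize
the 1 ms fixed step, wider ones blur valve timing.

**Network topology.** The left ventricle ejects through the aortic valve
into a systemic arterial junction feeding three parallel beds: the
hepatic-artery RCR, the digestive-organs RCR (whose outflow continues
through the portal vein RCR), and the other-organs RCR. Portal and
hepatic-arterial blood converge at the sinusoidal node (compliance C_hs),
which drains through the sinusoidal resistance R_hs and three parallel
hepatic veins into the central venous junction, joined there by the
other-organs outflow. The central-venous RCR (its compliance acting as the
right-atrial reservoir) feeds the right ventricle through the tricuspid
valve; the right ventricle ejects through the pulmonary valve into the lung
RCR, which drains into a pulmonary-venous reservoir and through the mitral
valve back into the left ventricle. Junction nodes without storage (the
arterial junction, the central-venous junction, the hepatic-vein junction)
are eliminated algebraically, leaving 14 states: 2 chamber volumes, 4 valve
branch flows, 8 capacitor node pressures.

**The pulmonary-venous / left-atrial reservoir (C_la = 12 mm³/Pa)** is the
one compartment of this network with no published parameter value, and it
is structurally necessary: both ventricles contract simultaneously, so
during systole the right-ventricular stroke (~50 mL) must be stored
downstream of the lungs while the mitral valve is shut. The lung
compliance alone (1.0 mm³/Pa ≈ 0.13 mL/mmHg) cannot store it — without the
reservoir the pulmonary pressure spikes above left-ventricular pressure,
the mitral valve shunts forward *during* ejection, and stroke volume
collapses to ~15 mL. C_la is set equal to the central-venous compliance
(12 mm³/Pa), i.e. the left-sided mirror of the right-atrial reservoir; a
scan over 6–30 mm³/Pa showed the baseline operating point is insensitive
to the exact value within this range while values below ~10 admit
period-doubled (alternans-like) cycles under severe injury.

**Where "portal pressure" is read.** The reported mean portal pressure is
measured at the sinusoidal inlet node — the presinusoidal point where
portal blood has traversed the distal portal resistance and converges with
arterial inflow. This matches the clinical convention that wedged hepatic
venous pressure approximates portal pressure at the sinusoid, and it is
the measurement site consistent with the reference values this model
reproduces (portal minus hepatic-vein pressure equals total hepatic flow
times R_hs in both health and severe injury). The pressure at the portal
compliance node upstream of R_pv_d is also exported (channel `P_pv`).

**Total blood volume.** A closed loop conserves total stressed volume
(Σ chamber volumes + Σ C·P), so the initial state is part of the model
specification, not a convenience: it fixes the operating volume of every
later steady cycle. The default initial state — all node pressures
10 mmHg, both ventricular volumes 120 mL, zero valve flows — encodes
286 mL of stressed volume and yields the healthy baseline operating point.
Consequently "initialization independence" holds only across initial
*distributions* at the same total volume (verified to within 1%), not
across arbitrary initial states.

## Numerics

The system is linear in the state once the four valve resistances
(functions of state through the tanh law) and the elastances (functions of
time) are frozen: x′ = A(t, x)·x + c(t, x). Closed valves make it stiff
(branch time constants ~L/R_closed ≈ 10⁻⁶ s against a 1 ms step), so the
fixed-step integrator is TR-BDF2 — a one-step, L-stable, second-order
composite of a trapezoidal half-stage (to t + γΔt, γ = 2 − √2) and a BDF2
stage. Each stage is a small linear solve; the valve nonlinearity is
handled by two fixed-point iterations per stage. The integrator carries a
batch dimension, so parameter sweeps (the Saltelli design) integrate as
batched 14×14 linear solves.

Verification: RC discharge matches e^(−t/RC) to ~10⁻⁷ after five time
constants; a sinusoidally driven two-element Windkessel matches the
analytic impedance amplitude/phase to ~10⁻⁵; halving Δt changes
final-cycle cardiac output by < 0.03%; the right-hand side conserves
total volume to machine precision at arbitrary states; total stressed
volume drifts < 10⁻¹² (relative) over the final cycles.

Default grid: Δt = 1 ms, 8000 steps (8 s ≈ 11.7 cardiac cycles). A run
counts as periodic when cycle-averaged aortic flow and pressure change
< 1% between consecutive cycles; the final cycle(s) are extracted aligned
to the elastance clock (cycle start at t mod T = 0).

## Cycle metrics

EDV/ESV are the extrema of left-ventricular volume over one steady cycle;
SV = EDV − ESV; LVEF = SV/EDV·100; CO is the cycle-mean aortic-valve flow;
SBP/DBP/MAP are the extrema and time-mean of the arterial-junction
pressure (MAP is the time average, not the (SBP+2·DBP)/3 estimate); stroke
work is the shoelace area of the left-ventricular pressure–volume loop
(positive counter-clockwise in the (V, P) plane, cross-checked against
−∮P dV to 0.5%). End-systole is detected as the instant after peak aortic
flow when the flow falls below 0.5% of its cycle peak (an aortic-valve
closure proxy); ESP is the left-ventricular pressure there and
Ea = ESP/SV. Hepatic flows are cycle means of the two sinusoidal inflows
and of the hepatic venous outflow; fractions are computed from unrounded
means.

## Calibration

The ten free parameters are seven elastance values (E_maxL, E_minL,
E_maxR, E_minR, T, t_max, t_toRelax) and three peripheral scalings — A1
(every distal resistance), A2 (every proximal resistance), A3 (every
vascular compliance, including the hepatic compartments and the
pulmonary-venous reservoir). Valve parameters are fixed. The loss is the
sum of absolute relative deviations of mean aortic flow (target 5 L/min),
systolic pressure (120 mmHg), diastolic pressure (80 mmHg), and peak
aortic flow (30 L/min). Minimization is multi-start Nelder–Mead (default
8 starts: the shipped parameter set plus seeded random draws strictly
inside the search ranges), max 300 evaluations and tolerance 10⁻⁴ per
start, with out-of-range proposals (including infeasible timing
t_max + t_toRelax ≥ T or E_min ≥ E_max) repelled by a 10⁶ penalty.
Bound proximity of the accepted solution is reported relative to the bound
value (the ranges span decades, so a linear-width criterion would flag any
small elastance). After the aortic fit, the distal hepatic-artery
resistance is adjusted by bisection until the portal vein carries 75 ± 1%
of hepatic inflow. The shipped default parameter set is the accepted
calibrated baseline; parameter-recovery tests regenerate targets from a
known model and verify the four target metrics are recovered within 2%
(the elastance/scaling parameters themselves trade off — only the four
aortic quantities are identified by this loss).

## Injury scenarios

Acute liver injury is assumed to act uniformly on the hepatic
microvasculature: the distal portal, distal hepatic-arterial, and
sinusoidal resistances are multiplied by a common factor (1, 5, 10, 15, 20
for scenarios M1–M20). Each scenario is re-simulated independently from
the same initial state. Expected physiology, asserted by the test suite:
CO, SV, SW, LVEF and both hepatic inflows fall monotonically with injury;
mean portal pressure and Ea rise monotonically; portal pressure stays
below the 20 mmHg portal-hypertension cap through M20; the arterial share
of hepatic inflow collapses from ~25% to ~3% because this model has no
hepatic arterial buffer response.

## Sensitivity analysis

Four factors scale their baselines multiplicatively: R_pv_d, R_ha_d, R_hs,
and R_hv (one factor jointly scaling the three parallel hepatic veins),
sampled uniformly (linear space; log-uniform available) on [0.5, 10] with
Saltelli's cross-sampling design over a scrambled Sobol' sequence —
N·(2K+2) model evaluations in blocks A, B, AB_j, BA_j. First-order
indices use the symmetrized Saltelli-2010 estimator, total-order indices
the symmetrized Jansen estimator, both applied to outputs centered on the
A/B mean (centering is essential here: the outputs' means exceed their
standard deviations a hundredfold, and the product-form estimator loses
all accuracy by cancellation on uncentered values). Confidence half-widths
come from bootstrap resampling of the Saltelli rows. The estimators are
validated against closed forms (single-factor, additive, and the Ishigami
function with a = 7, b = 0.1) to 0.05 at N ≤ 1024. Outputs are CO, MAP
(cycle-mean arterial pressure) and SW per evaluation; failed rows are
excluded with their cross-sample siblings, and > 1% failures aborts.
Problem sizes: the unit suite uses N = 64 (640 simulations, the smallest
base sample at which the estimator noise bands hold), the acceptance
analysis N = 128–256; indices change by < 0.05 on doubling N.

## Limitations

- The network is a reconstruction: the published tables fix every element
  value, but the wiring, the measurement sites, and C_la were inferred.
  Absolute baseline/severe-injury indices reproduce the reference results
  to within ±10%, and the sensitivity structure matches; however the
  *venous pressure floor* sits ~2 mmHg low at baseline (mean portal
  pressure 8.7 vs 10.7 mmHg), and the injury-induced *relative* drops of
  SV and SW are 3–8 points shallower than reported — the reconstructed
  venous reservoirs defend preload slightly more than the original model.
  Raising total blood volume lifts the venous floor but pushes baseline
  CO/SBP and severe-injury SW out of their bands, so it was not done.
- The smooth tanh diode passes a brief physical closure backflow; for the
  pulmonary valve (low peak forward flow, printed inertance) the
  instantaneous backflow transient reaches ~1.6% of peak forward flow,
  although the regurgitant volume is only ~0.2% per cycle.
- No atrial contraction, no hepatic arterial buffer response, no
  baroreflex/neurohormonal regulation, no valvular regurgitation, no 1D/3D
  vessel mechanics. Simultaneous ventricular timing and the venous-
  reservoir atria are parsimony choices, not physiology.
- LVEF is structurally bounded near ~54% at baseline by the printed
  E_maxL: with ESP ≈ 112 mmHg the end-systolic volume cannot fall below
  ESP/E_max + V0 ≈ 48 mL, which caps LVEF below the reported 59% at the
  reported stroke volume. The model reproduces LVEF within 10% but cannot
  do better under the printed elastance.
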