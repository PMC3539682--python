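# Methods

## Scope and model lineup

`atrialbench` characterises mathematical models of the human atrial
myocyte under a common set of protocols: single-cell pacing and feature
extraction, long-term stability, APD alternans, 1D-strand restitution of
APD90 / conduction velocity (CV) / effective refractory period (ERP) /
wavelength (WL), and 2D rotor initiation with phase-singularity tracking
and pseudo-ECG dominant-frequency analysis.

Three ionic models are implemented in full, each transcribed from its
original publication:

* **Courtemanche–Ramirez–Nattel 1998** (`courtemanche`): 21 states,
  Luo–Rudy-derived, two-compartment SR with a phenomenological,
  voltage-linked Ca release (the `u, v, w` gates driven by the flux signal
  F_n), algebraic Ca buffering.
* **Nygren et al. 1998** (`nygren`): 29 states, Lindblad-derived, with a
  restricted extracellular cleft compartment (Na, K, Ca exchange with the
  bulk at fixed time constants), a diadic space under the L-type channels,
  explicit ODE buffers, and a constant electroneutral Na influx that
  stabilises the long-term ion balance.
* **Maleckar et al. 2009** (`maleckar`): the Nygren framework with
  re-fitted transient-outward and ultrarapid (I_Kur) K currents, the
  electroneutral Na influx removed, and an acetylcholine-gated K current
  (zero at the default [ACh] = 0).

The Koivumäki 2011 and Grandi 2011 models are *plugin slots*: the registry
accepts third-party builders (`register_model`), and the generic stepper
factory already supports what they need beyond the built-ins — in
particular a per-state RK4 sub-integrator override for stiff SR-calcium
states (`stiff_index`).  Their full equation sets are out of scope here.

Chronic-AF (cAF) electrical remodeling is the fixed conductance scaling
reported for persistent AF: I_to and I_CaL −65%, I_Kur/I_sus −49%, I_K1
+110%, plus a 30% reduction of intracellular conductivity in tissue.
`apply_caf_remodeling` maps these four roles onto each model's own
parameter names and tags the variant so the scaling cannot be applied
twice.

## Numerics

* **Integration**: Rush–Larsen exponential update for every
  Hodgkin–Huxley gate (exact for frozen voltage over one step), forward
  Euler for voltage, concentrations and buffer states; default
  dt = 0.01 ms (10 µs).  The stepper factory also provides the RK4
  sub-integrator path used by stiff plugin states; the built-in models do
  not need it.  Gates are clamped to [0, 1] after every step; any NaN
  aborts the run with the offending voxel and time.
* **Monodomain tissue**: explicit finite differences, 3-point (1D) /
  5-point (2D) Laplacian, mirror (no-flux) boundaries, cubic voxels with
  dx = 0.1 mm by default.  The diffusion and reaction updates are added in
  the same step (first-order splitting, consistent with the explicit
  scheme).  A diffusion-number check (2·dim·D·dt/dx² ≤ 1) warns before
  unstable configurations.
* **One effective diffusivity**: the PDE is solved as
  dV/dt = D∇²V − I_ion/C_m + I_stim with D in mm²/ms.  Conductivity,
  surface-to-volume ratio and C_m enter only through D, and D is *tuned*
  per model so the control strand conducts at ≈750 mm/s at BCL 1 s —
  therefore the individual values of those constants affect no benchmarked
  quantity.  Tuning exploits the CV ∝ √D scaling of excitable wavefronts
  as a fixed-point predictor, converging in ~3 strand evaluations to the
  1% target; the cAF variant reuses the control D × 0.70.
* **Stimuli** are rectangular 2 ms transmembrane current pulses expressed
  in pA/pF.  Single-cell protocols use twice the diastolic threshold,
  tissue protocols 1.2× the tissue threshold; both thresholds are found by
  bracketing + bisection to 1% (threshold = smallest amplitude whose pulse
  drives peak V_m above 0 mV, i.e. a full AP).  The threshold reference
  state is the state from which the protocol delivers its first stimulus
  (the published rest state), and the strand amplitude is adapted once per
  model/variant — on the BCL 1 s pre-paced strand — not re-adapted per
  cycle length, so failure of the fixed stimulus to capture partially
  refractory tissue at fast pacing is a measured outcome of the
  restitution protocol.  The source does not print its stimulus duration
  or reference state, which is why the comparison tolerances below are
  not tighter.

## Measurement conventions

* RMP: V_m immediately before the stimulus; amplitude: peak − RMP.
* APD_x: from the time of maximum upstroke velocity to the first crossing
  of peak − x%·amplitude on the repolarizing limb (linearly interpolated);
  undefined (NaN) when that level is not reached before the next stimulus,
  as happens physiologically at short cycle lengths — APD50 is therefore
  the alternans metric.
* dV/dt_max from finite differences at the 0.05 ms sampling of the paced
  traces.  This estimate depends on the sample period (finer sampling
  gives larger values); cross-implementation comparisons of dV/dt_max
  carry that caveat.
* Capture: a beat counts as captured when its peak exceeds −40 mV with an
  upstroke > 5 V/s and amplitude > 30 mV — real APs at fast pacing may
  peak below 0 mV, while passive stimulus artifacts stay below rest+~35 mV.
* Activation time of a voxel: time of maximum dV/dt during the beat
  window, tracked at full integration resolution inside the solver.  CV
  divides the distance between the centers of the two strand halves (5 and
  15 mm on the 20 mm strand) by their activation-time difference.
* ERP: shortest S1–S2 coupling interval whose premature stimulus produces
  a *propagated* AP at the center of the distal strand half, at 1 ms
  resolution (coarse 10 ms scan bracketing, then bisection).  Propagation
  requires an upstroke above 10% of the S1 upstroke and a peak above
  −20 mV at the detection site, distinguishing conducted APs from
  electrotonic spread.  The S2 is applied after the final S1 of the
  5-beat train; the shared S1 segment is advanced once with 1 ms state
  snapshots so each trial only simulates the post-S2 window.
* Alternans classification of a steady APD50 window (last 10 s of a 30 s
  run): beat-to-beat variation < 2 ms is "none" (above numerical jitter,
  below any visible bifurcation); period-2 when successive differences
  alternate in sign for ≥70% of beats (tolerating occasional phase slips),
  with amplitude mean |ΔAPD|; period-3 by folding the drift-corrected
  sequence into 3-beat cycles; otherwise "irregular".
* Phase: analytic-signal (Hilbert) angle of mean-subtracted V_m per voxel,
  with a time-delay-embedding variant for cross-checks; phase is undefined
  where peak-to-peak V_m < 1 mV.  Singularity: ±2π winding of wrapped
  phase differences around an elementary 2×2 plaquette; tracks linked by
  nearest neighbour within a per-frame radius.
* Pseudo-ECG: Φ(e) = Σ_vox ∇²V/|r−e| for two electrodes 5 mm above the
  patch and 10 mm apart (infinite-volume-conductor lead field; the
  constant prefactor cancels in the difference signal and is irrelevant to
  the spectrum).  Dominant frequency: largest spectral peak in 1–30 Hz of
  the mean-removed, Hann-windowed signal, zero-padded to 0.1 Hz bins.

## Study conditions and problem sizes

Single-cell table values use 50 s of pacing at BCL 1 s (5×10⁶ steps at
dt = 10 µs), features from the terminal beat.  Current-extrema tables
track every integration step of the terminal beat and normalise by |I_K1|
after a 50 s clamp to −75 mV of the *control* variant — the printed I_K1
rows for control and cAF differ by exactly the 2.10 remodeling factor,
which identifies the control clamp as the common divisor.  Biphasic
I_NCX is reported as signed max and min; other currents as the signed
extremum of larger magnitude.

Strand restitution uses the 20 mm × 0.1 mm strand (200 voxels): 50
single-cell beats adapt the model to each BCL, the resulting state seeds
every voxel, 5 beats are stimulated from one end, and APD90/CV/ERP are
measured on beat 5 (APD90 at the voxel three-quarters down the strand).
Conductivity tuning and the dt-halving convergence figure measure CV on
shorter trains (beat 1 and beat 2 respectively): after 50 pre-paced beats
the strand CV is already at its steady value to well within the 1%
tuning target, and the convergence *ratio* between dt = 10 and 5 µs is
insensitive to the beat index.  The spatial-convergence check coarsens dx
to 0.2 mm with the stimulus amplitude held fixed so resolution is the only
difference.

The 2D cross-field protocol on the full 100×100 mm patch (10⁶ voxels,
seconds of activity) is an offline reproduction mode (`atrialbench rotor`).
The test suite exercises the identical code path on a scaled patch:
25×25 mm at dx = 0.25 mm with diffusivity reduced to ≈0.018 mm²/ms, which
shrinks the cAF wavelength into the patch; one planar S1, S2 over the
lower half ~170 ms later, ~0.7 s of observation.  On that movie the
package checks *properties* — detector-vs-oracle agreement, topological
charge bookkeeping, and consistency of the pseudo-ECG dominant frequency
with the local phase-rotation rate — rather than full-scale frequencies.

The 20-minute pacing stability run (≈1.2×10⁸ steps per model) is likewise
an offline mode of `long_term_stability` / the `stability` protocol; tests
cover the machinery on short schedules only.

## The synthetic fixtures

The mock cell is a two-variable excitable system (Mitchell–Schaeffer
style: cubic voltage nonlinearity, one recovery gate with
voltage-dependent open/close time constants) mapped onto a requested RMP
and amplitude.  Its APD is set by the gate closing time constant
(analytically APD ≈ τ_close·ln(τ_out/4τ_in), then refined by
simulate-and-adjust through the real pacing + feature-extraction path) and
its refractory period by the reopening time constant (secant iteration on
the real strand-ERP measurement).  It reproduces none of the ionic,
calcium or rate-dependent behavior of real myocytes — passing
fixture tests therefore validates the *protocol plumbing and measurement
code*, not physiological realism; the model-level claims rest on the
ionic-model tests.

Plane-wave movies have analytic activation times (activation-time
differences recover the configured speed exactly), and the ideal vortex
phase field has a known core, chirality and rotation frequency.  All
fixtures are deterministic; nothing in the package draws random numbers
at run time.

## Comparison tolerances

Reported values are compared to the published benchmark at: APD and ERP
±5% or ±5 ms (whichever is larger), RMP ±2 mV, CV ±3%, amplitude ±5%,
other quantities ±10%; WL is additionally required to be the exact
ERP × CV product.  Rationale: the source does not print its stimulus
shape, duration, threshold reference state, or the measurement sampling
rate, and each of these shifts features by a few percent.

## Known limitations

* dV/dt_max is sampling-dependent (see above); the package's values at
  0.05 ms sampling are systematically higher than coarser-sampled reports.
* The Nygren-model I_Ks is small here (its slow activation gate barely
  opens during the triangular AP); one published normalized-extremum table
  reports a much larger value for that single current while agreeing on
  every other current and on all AP features, so no I_Ks reference is
  asserted.
* Cleft-space states are per-voxel in tissue (no lateral cleft diffusion),
  consistent with the monodomain treatment of the extracellular space as
  grounded.
* Stimulus current is not assigned to a specific ion species; over tens of
  minutes this contributes to the slow drift some models show anyway.
* The explicit solver is single-threaded; full-patch 2D runs are hours of
  CPU, which is why they are an offline mode.
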