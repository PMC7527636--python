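# Methods

`olmcell` rebuilds, as a tested pipeline, the per-cell model-construction
workflow for hippocampal oriens-lacunosum/moleculare (OLM) interneurons:
multi-compartment conductance-based simulation, characterization of the
hyperpolarization-activated cation current (I_h) from voltage-clamp
families, passive-property fitting, a staggered re-fitting procedure that
weighs somatic-only against somatodendritic h-channel placement, and
evolutionary optimization of full spiking models.  A synthetic-data
generator supplies ground-truth cells and virtual recording sessions so
that every stage is validated by parameter recovery.

## Model

Each compartment obeys the cable equation

    C_m dV/dt = -g_pas (V - E_pas) - Σ_c ḡ_c Π_g x^p (V - E_c) + I_axial + I_inj

with uniform passive parameters (axial resistivity R_a in Ω·cm, specific
capacitance C_m in µF/cm², leak conductance G_pas in S/cm², leak reversal
E_pas in mV).  The h-current is

    I_h   = G_h · r · (V - E_h)
    dr/dt = (r_∞ - r) / τ_h
    r_∞   = 1 / (1 + exp((V - V_1/2)/k)),      k > 0
    τ_h   = 1 / (exp(-t1 - t2·V) + exp(-t3 + t4·V)) + t5

so r_∞ rises with hyperpolarization and τ_h is a smooth unimodal function
of voltage bounded below by t5.  Note that the maximum of τ_h lies where
t2·exp(-t1-t2V) = t4·exp(-t3+t4V), not where the two exponentials are
equal; with the first cell's parameters the peak is ≈346 ms at ≈-81 mV,
matching the qualitative "slowest component around 300 ms".

Transient sodium uses m³h gating with region-specific rate equations (the
somatic forms are the dendritic/axonal forms displaced 7 mV depolarized)
and a rigid per-region voltage shift V_shift ∈ [-7, +7] mV applied
identically to all four rates.  The printed current equation carries the
h-channel reversal symbol where the sodium reversal belongs; we treat that
as a typographical slip and use a configurable E_Na (default +90 mV, the
value used in the precursor OLM models).

The remaining spiking channels (fast/slow delayed-rectifier, A-type and
M-type potassium, T- and L-type calcium, and a calcium-dependent potassium
current) enter through a declarative channel-config interface (gates with
exponents and closed-form rate expressions, tabulated on a 0.05 mV grid
over [-150, 70] mV).  The bundled config is a stylized HH-type set authored
for this package — the precursor models' kinetics are not reproduced here —
with two deliberate properties: the potassium channels are nearly silent
below ≈-60 mV (so hyperpolarizing responses are governed by leak and I_h
alone, as observed in the study's current decompositions), and the A-type
current activates steeply around -47 mV, which both stabilizes the resting
state and suppresses rebound spiking after strong hyperpolarizing steps.
KCa is a voltage-gated surrogate (no intracellular calcium dynamics).

## Numerics

Backward Euler on the branched tree, solved exactly per step by
child-to-root (Hines) elimination; gates advance by the exact exponential
update at the previous step's voltage, with exp(-dt/τ(V)) pre-tabulated per
run.  The scheme is first-order (verified by a dt-halving slope test);
dt = 0.025–0.05 ms resolves spikes, 0.1–0.2 ms suffices for subthreshold
work, and dt = 0.01 ms reproduces the analytic RC step response to
< 0.01 mV.  Voltage clamp is a large clamp conductance (1 S ≈ ideal;
an optional series resistance reuses the same mechanism), so space-clamp
escape in the dendrites is emergent.  Each protocol settles 2 s at the
holding level before sweeps.

Discretization follows the d_λ rule (compartments ≤ 0.1·λ_100 per section,
odd counts, λ evaluated at the section midpoint diameter).  Geometry is
discretized once per cell at its reference passive parameters and cached;
axial resistances are stored per unit R_a, so fitting updates rescale the
electrical system without re-gridding (re-gridding mid-fit would make the
objective discontinuous).  Unit conversions use 1 pS/µm² = 1e-4 S/cm².

## I_h extraction

Mirrors the experimental chain: ZD7288-arm subtraction isolates I_h;
a robust local-linear smoother (tricube weights, one robustness iteration,
25 ms window, implemented as FFT convolutions) cleans the tails for the
"fixed" I-V method; mono-exponential fits extrapolated to the relaxation
onset give the "extrapolated" I-V and the deactivation time constants;
a line through the linear portion of the I-V yields E_h (zero-current
intercept) and the tail slope; end-of-step currents from the activation
family give the Boltzmann steady-state curve; and the merged
activation/deactivation time constants feed a 32-start bounded fit of the
five-parameter τ_h function, judged in curve space because t1..t5 are
mutually degenerate (a curve-sanity cap rejects fits that place a spurious
narrow peak between measured voltages).

Three points where this package sharpens the hand analysis:

- The tail slope equals G_h·r_∞(prepulse); a -120 mV prepulse leaves
  r_∞ ≈ 0.87 for these cells, so the slope is divided by the fitted
  Boltzmann at the prepulse command before reporting G_h.
- The steady-state normalization divides out the driving force (chord
  conductance, requires E_h) — normalizing raw currents biases V_1/2 by
  several mV.
- The fixed-vs-extrapolated choice is automatic (whichever I-V is more
  linear): on electrotonically extended cells the dendritic relaxation
  corrupts the mono-exponential tails and the fixed method is safer, the
  same per-cell judgement the original analysis made.
- Time constants are only kept from sweeps whose fitted amplitude exceeds
  five times the recording-noise estimate; low-amplitude sweeps near the
  activation foot otherwise contribute meaningless τ values.
- The fixed time point is found from the subtracted tails (first sample
  where |dI/dt| falls below 5 % of its post-onset peak, floor 5 ms): under
  an ideal clamp the blocked-arm capacitive transient lasts one sample and
  the real transient is the dendritic re-equilibration.

On a single-compartment ground-truth cell the full chain recovers E_h and
V_1/2 within 1 mV, G_h within 2 %, k within 5 % and the τ_h curve within
2 ms RMSE noise-free, and holds twice those tolerances in ≥90 % of noisy
sessions (σ = 2 pA with the late-session degradation enabled).

## Passive fitting and staggered re-fitting

The passive backbone (R_a, C_m, G_pas, E_pas) is fitted to the -120 pA
fully blocked ("ZD") trace by bounded trust-region least squares on the
weighted residual trace (log-scaled parameters, randomized restarts with an
agreement-based early stop).  Region weighting follows the recording
protocol: first 500 ms excluded, charging portions at step onset and
release weighted 10×, ~1 s of post-step release retained, and — for passive
fits only — a short post-charging window when a residual slow
depolarization contaminates the plateau.  For h-channel fitting the whole
steady state is kept: the sag is signal.

The staggered re-fit runs bounded stages in fixed order — passive →
total G_h → (V_1/2, k) → (t1..t5) — against the -120 pA TTX trace, with
-90/-60/-30 pA traces withheld for validation.  Two design choices proved
necessary and are this package's own:

- The stage sequence is cycled (block-coordinate descent, ≤3 cycles, 1 %
  convergence tolerance); a single pass leaves coupled parameters stranded.
- The passive stage is confined to a ±10 % trust region (E_pas ±1.5 mV)
  around the ZD-fitted backbone.  Unconstrained, the passive stage absorbs
  h-channel mismatch into dramatic R_a/C_m distortions that fit the single
  trace but validate poorly — precisely the compensating optima the
  staggered order is meant to avoid.  The published somatic-only re-fits
  show this compensation (R_a collapsing severalfold), which is why the
  somatic-only G_h underestimate reported there (≈50-80 %) is deeper than
  a self-consistent synthetic world reproduces: a 12-parameter joint probe
  at H_dist=0 on the most extended synthetic preset finds a flat valley of
  equally good fits spanning G_h -5 % to -18 % of truth, i.e. no deep
  low-G_h optimum exists without real-data model mismatch.  The direction
  (somatic-only placement always shrinks the re-fitted G_h) and the
  symmetric preference (soma-only ground truth is correctly preferred at
  H_dist=0) are robust; the published magnitude is not reproducible here
  and the corresponding acceptance check is expected to fail.

The H_dist evidence rule prefers, among candidates whose validation RMSEs
are within 20 % of the best, the one whose re-fitted total G_h lies closest
to the tail-current measurement; equal deviations flag a tie.

## Spiking optimization

Features per depolarizing step: spike count, mean frequency, latency, first
AP half-width and height (threshold = start of the ≥20 mV/ms upstroke),
AHP depth, and spike-frequency adaptation (first ISI / last ISI; the
published 0.4–0.6 range matches this convention).  Fitness is
Σ|Δfeature|/σ with hand-chosen σ (1–2 orders below each feature's leading
digit; count and frequency σ tightened after early runs under-performed on
them, the same hand-re-weighting strategy the original optimizations used)
plus 250 per baseline spike and 250 per absent-but-required feature (the
miss penalty must dominate, or "never spiking" outscores a poor spiking
match and selection collapses).

The optimizer is an in-package indicator-based evolutionary algorithm
(additive-ε IBEA; SBX crossover rate 0.85, η 0.5; polynomial mutation rate
0.15; binary tournaments; deterministic per seed) with two small-budget
aids: the scalar total joins the objective vector, and the scalar-best
individual is protected during environmental selection.  Full-size runs
(100 offspring × 200 generations) are supported; the acceptance check runs
20 × 30 with five free parameters (somatic/dendritic Na, somatic fast
delayed rectifier, somatic A-type, somatic V_shift) on a compact target
cell.

## Synthetic data

Toy morphologies: an area-matched cylindrical soma, 4–6 thin dendrites
bifurcating twice (1.6 → 0.6 µm taper, most membrane distal), one 1 µm
axon; somatodendritic areas match the reconstructed cells (20,000–36,000
µm²).  Presets `cell1`/`cell2` copy the published per-cell passive and I_h
parameter sets onto area-matched trees; `point` is a single-compartment
cell for clean extraction tests; `spiker` is a deliberately compact
(~16,000 µm², 37 compartments) optimization testbed carrying the stylized
spiking complement (dendritic/axonal Na shifted +5/+7 mV, as in the
published top models, to keep the left-shifted dendritic rate equations
from destabilizing rest); `random` samples within OLM-plausible ranges.

The session emulation runs the protocols in chronological order (control
current-clamp steps; I_h activation, TTX current-clamp, tail currents;
then the ZD repeats) with additive Gaussian noise (0.2 mV CC / 2 pA VC) and
a late-session degradation applied to the last-recorded protocols: noise
amplitude ramping ×1→×3 across sweeps plus a slow baseline drift
(0.5 mV/s, current-clamp only) — enough to reproduce the original
trace-selection logic (the -120 pA blocked trace ranks cleaner than the
-30 pA one).  Current-clamp protocols hold the soma at -72 mV: the nominal
-60 mV amplifier setting minus the 11.88 mV junction potential, the frame
all analyzed traces live in.  This is also what makes the hyperpolarization
non-interference property attainable: at -72 mV the sodium window current
prescribed by the fixed rate equations is ≈2 % of leak; at a true -60 mV it
is not.

What the generator does not emulate: electrode series resistance, bridge
balance or capacitance-compensation artifacts, channel noise, non-uniform
passive properties, or real reconstructed tree statistics (branch-order
distributions, diameter noise).  Passing recovery tests therefore shows the
pipeline is internally consistent and correctly implemented, not that it is
unbiased on real recordings — the dendritic presets already show the
realistic space-clamp bias in tail-current G_h measurements (≈10–20 %
underestimates).

## Problem sizes used in the test suite

Recovery and refit checks run at dt = 0.2 ms on suites generated at the
same dt (so integrator and data share one discretization); extraction
recovery uses the single-compartment preset at dt = 0.05 ms; the scaled
optimization check uses the compact spiker cell, 20 offspring × 30
generations.  Full-size equivalents (0.01–0.025 ms, full presets, 100 × 200
optimizations) run through the same interfaces.

## Known limitations

- The ε-indicator optimizer is a compact reimplementation, not a drop-in
  for large-scale optimization frameworks; at small budgets it relies on
  the scalar-elitism aid.
- E_h is never re-fitted (as in the original workflow), so extraction error
  in E_h propagates into re-fitted G_h as a driving-force bias.
- Somatic-only vs somatodendritic discrimination by total-G_h evidence is
  weaker on self-consistent synthetic cells than on the real recordings
  (see the staggered re-fitting section).
- Calcium dynamics are absent; the T/L-type and KCa entries in the bundled
  config are placeholders for structure, not fitted mechanisms.
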