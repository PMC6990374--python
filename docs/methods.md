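# Methods

## Model

Transmembrane voltage on a 2-D cardiac sheet obeys the monodomain
equation: the divergence of the conductive flux, ∇·(σ_m ∇V_m), equals
β I_m, where the transmembrane current I_m is C_m ∂V_m/∂t + I_ion −
I_stim.  The tissue is isotropic (σ_ml = σ_mt), β = 0.14 µm⁻¹, and
membrane kinetics I_ion(V_m, η) follow the ten Tusscher–Panfilov 2006
human ventricular myocyte model, endocardial parameter set (19 state
variables: V_m, twelve Hodgkin–Huxley-type gates, five ionic
concentrations, and the ryanodine-receptor adaptation variable).  The
variant name is recorded in configs and recording metadata
(`tentusscher_panfilov_2006_endo`).  A human ionic model standing in for
porcine tissue is a deliberate simplification carried over from the study
design this package reproduces; no porcine ventricular model exists.

Border-zone (BZ) remodeling phenotypes:

* `prolonged_apd` — G_Kr → 20%, G_Ks → 30% of control.  Raises the
  steady APD90 at 2 Hz pacing from 276.9 ms to 399.6 ms.
* `reduced_ina` — G_Na scaled by a factor in (0, 1].  Reduces upstroke
  velocity, excitability and conduction velocity without prolonging APD.
* structural remodeling — per-element conductivity scaling of the BZ, and
  fibrosis: a seeded uniform random subset of BZ elements made
  non-conducting.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| σ healthy | 0.143 | S/m | produces 0.6 m/s planar CV (calibration target) |
| σ reduced | 0.064 | S/m | produces 0.4 m/s (transverse-equivalent) |
| β | 0.14 | µm⁻¹ | stated surface-to-volume ratio |
| C_m | 1.0 | µF/cm² | unstated in the source; absorbed into the CV calibration |
| h | 200 | µm | reference element spacing (40,000 elements on 4 × 4 cm) |
| dt | 0.02 | ms | resolves the stiff upstroke; stability bound ≈ 0.08 ms |
| sheet | 40 × 40 | mm | reference geometry |
| isthmus width | 4 | mm | stated channel width |
| scar radii | 16 | mm | calibrated, see below |
| S1 | 3 × 500 | ms BCL | pacing protocol |
| S2 interval | 320 | ms | the capture boundary of the healthy sheet |
| stimulus | 100 × 1 | µA/cm² × ms | pacing protocol |
| prepacing | 2 Hz × 100 | beats | single-cell steady state used to initialize tissue |
| APD level | 90% repolarization | — | APD90; the source leaves the level open |
| RVI pairing radius | 2 | mm | proximal/distal pairing scale (config-exposed) |
| RVI block threshold | 30% of mean APD | — | stated block rule |

## Numerical scheme

**Space.** Node-based finite differences on the regular element grid.
Each edge between adjacent nodes carries the arithmetic mean conductivity
of its two flanking elements (non-conducting and exterior elements
contribute zero), and each node's rate of change is the net face flux
divided by its conducting control-volume fraction — the finite-volume
analogue of a lumped-mass Q1 finite-element operator.  Consequences that
matter for the science:

* a plane wave travels at the same speed along a no-flux boundary as in
  the bulk (without the volume weighting, boundary rows conduct ~3%
  slow);
* two conducting elements that share only a corner remain electrically
  coupled through the shared node, exactly as in a node-based FEM
  assembly.  Fibrotic conduction is therefore an 8-neighbor (not
  4-neighbor) site-percolation problem, which places the isthmus
  disconnection threshold between 50% and 55% fibrosis for the default
  channel — the harmonic-mean alternative (edges die when either
  flanking element is fibrotic) would move the cutoff to ~40% and was
  rejected for that reason;
* `assemble_diffusion(..., lumped=False)` exposes the symmetric flux
  matrix for verification; rows of the operator always sum to zero
  (no-flux conservation).

**Time.** Forward Euler for V_m, concentrations and the diffusion term;
Rush–Larsen exponential updates for all voltage-gated Hodgkin–Huxley
gates (unconditionally within [0, 1]); forward Euler for the
calcium-dependent gate (τ ≥ 2 ms).  One shared dt avoids splitting-order
artifacts.  Voltage-dependent rate expressions are tabulated on a
0.05 mV grid with the Rush–Larsen factors exp(−dt/τ) baked in, and
linearly interpolated; tables are rebuilt per dt.  The inward-rectifier
activation is tabulated on a V_m − E_K grid.  Integration aborts with
time and node index if |V_m| exceeds 200 mV.

**Single-cell accuracy.** Against an independent stiff-ODE integration
(LSODA at rtol 1e-8) of a plain transcription of the same equations, the
production path agrees to under 1 mV RMS over a 1 s stimulated trace
(asserted by the test suite; the observed error is a small fraction of
that bound).

## Conduction-velocity calibration

The conversion from conductivity to voltage diffusivity is
D = σ/(β C_m) × c, with a single dimensionless factor c = 1.193.  The
factor absorbs two unknowns at once: C_m (unstated) and the coarse-grid
wavefront error of the 5-point stencil at h = 200 µm (the discrete
upstroke spans only 2–3 elements, slowing the wave by ~7% at 0.143 S/m
and more at lower σ).  c was chosen to balance the two stated calibration
targets on the reference 200 µm / 0.02 ms discretization — measured
0.614 m/s at 0.143 S/m (+2.4%) and 0.390 m/s at 0.064 S/m (−2.5%).  One
scalar cannot zero both errors because the relative discretization loss
grows as the wave slows; both sit well inside the ±5% calibration
tolerance.  On refinement the scheme converges from below (halving the
spacing from 100 µm to 50 µm, with dt halved alongside, changes the
planar CV by under 3%); the CV ∝ √σ law holds to < 5% at 100 µm with a
free proportionality constant.

## Geometry

The idealized infarct is two mirror half-ellipse scar segments (semi-axes
`scar_depth` horizontally, `scar_half_length` vertically) flanking a
vertical 4 mm conducting channel, centered in the sheet.  The segment
radii are not stated by the study design; they set the re-entrant path
length and hence every block/re-entry timing.  The default (16 mm, the
largest value that keeps the stated 2 mm healthy margin on every side
with symmetric proportions) was fixed by requiring the canonical
mechanism sequence to complete: the premature beat blocks at the proximal
channel mouth, travels around the scar, and re-enters through the distal
mouth after the channel has recovered excitability.  With 14 mm segments
the circuit is ~30 ms too short and the prolonged-APD re-entry never
forms.  Absolute event times still differ from any particular larger-scale
realization of this geometry; only the mechanism sequence and parameter
trends are meaningful, and classifications are verified to be invariant
to halving the output sampling rate.

Fibrosis is sampled uniformly at random without replacement among BZ
elements — exactly round(density × n_BZ) elements per pattern,
deterministic per seed (NumPy `SeedSequence`; sweep seeds derive from one
root seed keyed by density index and replicate, so any row is
reproducible in isolation).  Spatially correlated ("patchy") textures are
deliberately not generated: the study conditions specify random
topologies.

## Protocol and classification

Tissue is initialized from the 2 Hz / 100-beat single-cell steady state
of each region's variant (control for healthy tissue, remodeled for BZ
nodes — a node is remodeled if it touches at least one BZ element); the
three S1 beats then equilibrate electrotonic coupling.  Capture is
detected as an upward crossing of −20 mV at probe nodes within 150 ms of
the stimulus; the choice is insensitive over ±20 mV and ±50 ms (tested).
The minimal capturing interval search simulates the S1 train once,
checkpoints the unstimulated evolution at every candidate S2 time, and
tests each interval from its checkpoint — the searched boundary is
310 ms on the healthy reference strip, so the 320 ms interval used for
the vulnerability experiments is the smallest tested interval that
captures.

Activation time is the first upward crossing of −20 mV in a beat window;
repolarization time the subsequent downward crossing of the per-node
90%-repolarization level; both sub-sample interpolated.  The RVI of a
node d is min over neighbors p within 2 mm with AT(p) < AT(d) of
RT(p) − AT(d).

Outcome classification of an S1–S2 run:

* `INEXCITABLE` — no BZ node activates during the last S1 beat (the
  statistics exclude these runs from P_B, as specified);
* S2 conduction through the isthmus: at least 80% of channel rows
  activate in the S2 window *and* the earliest-activated row lies in the
  bottom third.  A head-on collision between the S2 wave inside the
  channel and the around-scar wave still counts as conducted — there is
  no unidirectional block in that case.  Retrograde invasion after
  proximal block enters at the top and does not count;
* re-entrant cycles are counted at two sentinel nodes on the channel
  axis, 5 mm below and above the isthmus (clamped out of the electrode):
  threshold crossings with −60 mV reset hysteresis; at most one crossing
  inside each sentinel's direct window (150 ms below, 300 ms above,
  post-S2) is attributed to the stimulus, every later crossing is one
  completed circuit.  `REENTRY_SUSTAINED` iff more than one cycle;
* otherwise `NO_BLOCK` (conducted) or `BLOCK_NO_REENTRY`.

The RVI block rule (min RVI < 30% of the mean healthy-tissue APD of the
last S1 beat) is computed alongside and cross-validated in the tests:
re-entrant runs have negative minimum RVI, uncomplicated conduction keeps
it positive.

## What the synthetic data does and does not emulate

The generator reproduces the study conditions exactly: sheet and spacing,
idealized scar + isthmus labels, fibrosis densities 0–90% in 5% steps
with 10 seeded topologies per density, and the stated remodeling scales.
It does not emulate image-derived scar shapes, correlated fibrosis
texture, fiber anisotropy, 3-D wall structure, APD heterogeneity or
stochastic channel gating.  Passing tests therefore demonstrate the
mechanism logic (source–sink block, wavelength-limited re-entry,
percolation-limited isthmus conduction) on an idealized substrate, not
quantitative prediction for real infarcts.

## Problem sizes used by the test suite

Calibration quantities (conduction velocities, capture boundary, fibrotic
disconnection) always run on the reference 200 µm discretization.
Mechanism and sweep classifications in the test suite run the same
4 × 4 cm geometry at 400 µm — the package's chosen working resolution for
qualitative experiments, at which all classifications are unchanged under
output-sampling perturbations — and the isthmus-traversal experiment
isolates a vertical band around the channel (the lateral corridors are
made inert) so that activation above the channel can only arrive through
it.  The reduced default sweep grid is {0.1, 0.25, 0.5, 1.0}² scales ×
{0, 0.25, 0.5} fibrosis × 3 seeds; the full 0.05-step grid is available
via `SweepSpec.full()`.

## Known limitations

* Re-entries in this 2-D geometry complete one cycle before terminating
  on the refractory tail of their own circuit; longer sustained runs
  require a longer anatomical path than the 4 cm sheet affords.  The
  qualitative contrast between the remodeling arms (reduced-I_Na re-entry
  enters a fully excitable channel; prolonged-APD re-entry terminates by
  refractory collision) is preserved.
* The isthmus disconnection threshold is a finite-size percolation
  property: near 50–55% fibrosis individual seeded patterns may or may
  not conduct, and results at those densities are reported per seed set.
* Explicit time stepping only; no bidomain, no 3-D, no adaptive dt.
* The CV calibration factor is discretization-specific: changing h or dt
  away from the defaults changes absolute velocities by a few percent
  (the ∝ √σ scaling is unaffected).
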