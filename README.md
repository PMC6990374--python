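# infarctsim

Monodomain simulation of conduction block and re-entry in idealized infarct
border zones.

## The problem

Scar-related ventricular tachycardia is sustained by re-entrant circuits
through conducting isthmuses of surviving tissue inside myocardial scar.
Whether the *initial* unidirectional block that starts such a re-entry is
caused by prolonged repolarization (longer action potential duration, APD)
or by *conduction slowing* (reduced sodium current, gap-junction
uncoupling, fibrosis) in the border zone (BZ) changes how computational
risk-stratification models should be parameterized.  This package
implements a 2-D in-silico testbed for that question, for researchers in
computational cardiac electrophysiology: an idealized infarct sheet whose
isthmus can be remodeled functionally (sodium current scaling),
structurally (conductivity scaling, random fibrosis) or toward prolonged
APD, probed with a premature-stimulus protocol and classified into
block/re-entry outcomes.

## The model

Tissue electrophysiology follows the monodomain reaction–diffusion
equations

```
∇·(σ_m ∇V_m) = β I_m
C_m ∂V_m/∂t + I_ion(V_m, η) − I_stim = I_m
∂η/∂t = f(V_m, η)
```

with isotropic conductivity σ_m = 0.143 S/m (calibrated to a planar
conduction velocity of 0.6 m/s), surface-to-volume ratio β = 0.14 µm⁻¹,
and the ten Tusscher–Panfilov 2006 endocardial ventricular myocyte model
for the ionic current I_ion(V_m, η).  Border-zone remodeling modes:

* **prolonged APD** — I_Kr and I_Ks conductances reduced to 20% and 30%
  of control;
* **reduced I_Na** — sodium conductance scaled by 0.1–1.0 (step 0.05);
* **structural** — BZ conductivity scaled by 0.1–1.0 and/or a seeded
  random fraction (0–90%, step 5%) of BZ elements made non-conducting
  (fibrosis), with no-flux conditions at every scar/fibrosis interface.

The geometry is a 4 × 4 cm sheet at 200 µm spacing (40,000 quadrilateral
elements) with two mirror-image scar segments separated by a 4 mm
conducting isthmus.  Vulnerability is probed with an S1–S2 protocol
(three S1 at 500 ms cycle length, one premature S2; stimulus
100 µA/cm² × 1 ms at the lowermost tissue) and outcomes are classified
with activation/repolarization maps and the re-entry vulnerability index
RVI(d) = min over proximal neighbors p of [RT(p) − AT(d)]: regions with
RVI below 30% of the mean tissue APD mark conduction block, negative RVI
marks re-excitation.  The block probability over fibrosis topologies is
P_B = n/N with completely inexcitable runs excluded.

See `docs/methods.md` for the numerical scheme, calibration and design
choices.

## Worked example

```python
from infarctsim.cellmodel import CellParams, RemodelingSpec, pace_to_steady

control = pace_to_steady(CellParams())
remodeled = pace_to_steady(RemodelingSpec(mode="prolonged_apd").cell_params())
print(f"steady APD90 at 2 Hz: control {control.apd_per_beat[-1]:.1f} ms, "
      f"prolonged-APD border zone {remodeled.apd_per_beat[-1]:.1f} ms")

from infarctsim import geometry, monodomain, metrics

strip = geometry.build_strip(40.0, 6.0, h_um=200.0)
cond = monodomain.ConductivityField.from_grid(strip, sigma_healthy=0.143)
stim = monodomain.StimulusSpec.left_edge(strip, onsets=(0.0,))
rec = monodomain.run(strip, cond, stimuli=[stim],
                     config=monodomain.SimulationConfig(t_end=150.0))
maps = metrics.activation_repolarization_maps(rec, (0.0, 150.0))
row = strip.ny // 2
cv = metrics.conduction_velocity(maps, (row, 50), (row, 150))
print(f"planar conduction velocity at 0.143 S/m: {cv:.3f} m/s")
```

prints

```
steady APD90 at 2 Hz: control 276.9 ms, prolonged-APD border zone 399.6 ms
planar conduction velocity at 0.143 S/m: 0.620 m/s
```

The first line shows the single-cell effect of the prolonged-APD
border-zone phenotype (≈ +120 ms at 2 Hz pacing); the second confirms the
tissue-level conduction-velocity calibration (0.6 m/s within 5%) measured
between two probes 1 cm and 3 cm from the stimulated edge of a
homogeneous strip.

A full infarct-sheet experiment and a vulnerability sweep are available
from the command line:

```sh
infarctsim run --mode reduced_ina --ina-scale 0.3 --ci 320 --outdir run_out
infarctsim sweep --preset reduced --outdir sweep_out
infarctsim defaults        # every configuration default as JSON
```

`run` writes the classified outcome (`NO_BLOCK`, `BLOCK_NO_REENTRY`,
`REENTRY_NONSUSTAINED`, `REENTRY_SUSTAINED` or `INEXCITABLE`), the S2
activation/repolarization/APD/RVI maps (VTK legacy + CSV) and a JSON
manifest; `sweep` writes the outcome table and P_block / P_reentry
heatmaps (CSV matrices + PNG), resumable through its row cache.

## Conventions

The origin is the bottom-left node; x grows rightward, y upward; lengths
are mm unless suffixed `_um`.  Elements are indexed row-major from the
bottom-left; the node grid of an (ny × nx)-element sheet is
(ny+1) × (nx+1).  Stimuli are delivered at the bottom edge of sheets and
the left edge of strips.

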