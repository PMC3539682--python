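# atrialbench

Benchmarking framework for ionic models of the human atrial myocyte.

Mathematical models of atrial electrophysiology — systems of ODEs for the
membrane voltage V_m, Hodgkin–Huxley channel gates and intracellular ion
handling — differ substantially in AP morphology, rate dependence and
emergent tissue behavior, which matters when choosing a model to study
atrial fibrillation (AF).  `atrialbench` implements the
Courtemanche–Ramirez–Nattel (1998), Nygren (1998) and Maleckar (2009)
human atrial models with control and chronic-AF (cAF) variants and runs
them through one common protocol stack:

* **single cell** — pacing at a basic cycle length (BCL), AP/Ca-transient
  feature extraction (amplitude, RMP, APD₅₀, APD₉₀, dV/dt_max), long-term
  stability, APD alternans classification;
* **1D strand** — explicit monodomain reaction–diffusion
  (dV/dt = D∇²V − I_ion/C_m + I_stim; Rush–Larsen + forward Euler,
  dt = 10 µs, dx = 0.1 mm), conductivity tuned per model to CV ≈ 750 mm/s
  at BCL 1 s, steady-state restitution of APD₉₀, conduction velocity (CV),
  effective refractory period (ERP) and wavelength WL = ERP × CV;
* **2D patch** — S1–S2 cross-field rotor initiation, Hilbert-phase
  singularity detection (±2π plaquette winding) and trajectory tracking,
  pseudo-ECG and dominant frequency.

cAF electrical remodeling is the standard conductance scaling
(I_to, I_CaL ×0.35; I_Kur ×0.51; I_K1 ×2.10; tissue conductivity ×0.70).
A plugin registry accepts further models (e.g. Koivumäki, Grandi),
including a per-state RK4 sub-integrator override for stiff calcium
states.  Deterministic synthetic fixtures (a calibratable mock excitable
cell, analytic plane waves and vortex phase fields) ground-truth every
measurement stage.

## Worked example

```python
from atrialbench import get_model, pace, extract_ap_features

model = get_model("courtemanche")          # control; "courtemanche-caf" for cAF
trace = pace(model, bcl=1.0, duration=50.0)  # 50 s at BCL 1 s, 2x threshold
feats = extract_ap_features(trace, -1)       # terminal AP
print(f"APD90 {feats.apd90:.1f} ms, RMP {feats.rmp:.1f} mV, "
      f"amplitude {feats.amplitude:.1f} mV")
```

prints

```
APD90 293.8 ms, RMP -81.0 mV, amplitude 107.9 mV
```

i.e. the Courtemanche cell, paced to its 50 s reference point, repolarizes
to 90% in ~294 ms from an ~−81 mV resting potential — the spike-and-dome
AP this model is known for.  The same protocol on `courtemanche-caf`
yields APD90 ≈ 145 ms: the remodeled cell loses most of its plateau, the
substrate for re-entry.  On tissue:

```python
from atrialbench import tune_conductivity
from atrialbench.restitution_1d import run_strand_protocol, measure_erp

D = tune_conductivity(model)                    # ~0.23 mm^2/ms for CV ~750 mm/s
proto = run_strand_protocol(model, 0.4, diffusivity=D)
erp = measure_erp(model, 0.4, proto)
print(f"CV {proto.cv:.0f} mm/s, ERP {erp:.0f} ms")   # CV 758 mm/s, ERP 299 ms
```

The CLI wraps the same calls: `atrialbench table1 --compare`,
`atrialbench restitution --model courtemanche --variant caf`,
`atrialbench rotor --model nygren --patch-mm 100` (full-patch rotor runs
are offline-scale), `atrialbench run config.yaml`.  Published reference
tables ship with the package and `compare_to_reference` scores any
generated table against them.

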