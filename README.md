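# sncdev

Computational models and analysis tools for the postnatal development of
substantia nigra pars compacta (SNc) dopaminergic neurons.

SNc dopaminergic neurons are intrinsic pacemakers with an unusual
morphology: in most cells the axon arises from a dendrite — the
*axon-bearing dendrite* (ABD) — rather than from the soma, and the broad
somatic action potential (AP) is shaped by the dendritic arbor.  Across the
first three postnatal weeks (stages P3, P7, P14, P21) the ABD elongates
several-fold and the AP narrows, with most of the change concentrated
between P7 and P14.  This package provides, for modellers and
electrophysiologists studying that maturation:

- **Morphometry** of branched neuron reconstructions (SWC): dendritic
  segment counts and lengths split by ABD vs non-axon-bearing dendrites
  (nABDs), axon-initial-segment (AIS) geometry, soma volume
  (`sncdev.morphology`).
- A **synthetic morphology generator** that emulates the published
  per-stage population statistics, so every downstream analysis runs
  without the original reconstructions (`sncdev.synthetic`).
- A **multicompartment Hodgkin–Huxley model** on branched morphologies —
  seven conductances, homogeneous (Model 1) vs ABD-enriched (Model 2)
  dendritic Na/Ca density schemes, implicit Hines-solver integration of
  the cable equation

      Cm dV/dt = −Σ gᵢ (V − Eᵢ) − I_axial

  with Ra = 150 Ω·cm, Cm = 0.75 µF/cm², Rm = 100 kΩ·cm², leak reversal
  −50 mV (`sncdev.channels`, `sncdev.cable`).
- **AP waveform analysis**: threshold at the 20 mV/ms point of dV/dt,
  threshold-to-peak amplitude, half-width, and the initial-segment (IS) /
  somatodendritic (SD) decomposition from the second time derivative
  (`sncdev.waveform`).
- The **gNa screening procedure**: sweep somatodendritic sodium density,
  invert the half-width/gNa relation at a target half-width, and measure
  sensitivity as a coefficient of variation over a threefold gNa range
  (`sncdev.screen`).
- **Developmental statistics**: ANOVA/Tukey or Kruskal–Wallis/Dunn stage
  comparisons behind a normality gate, paired ABD-vs-nABD tests, Pearson
  regressions, the stage-pair significance stacking matrix, Ward-linkage
  hierarchical clustering with an automatic threshold, and linear
  discriminant analysis (`sncdev.devstats`).

See `docs/methods.md` for the model's assumptions, parameter tables, and
known limitations — in particular, the channel kinetics are a documented
reconstruction validated by property (pacemaking, AIS-first initiation,
AP shape), not transcribed rate equations.

## Worked example

```python
import numpy as np
from sncdev import (default_stage_params, sample_neuron, summarize,
                    build_scheme, run_protocol, SimulationConfig,
                    detect_spikes, average_ap, ap_shape)

rng = np.random.default_rng(101)
neuron = sample_neuron(default_stage_params("P21"), rng)
s = summarize(neuron)
print(f"ABD length {s.len_abd:.0f} µm of {s.len_total:.0f} µm total; "
      f"axon origin {s.axon_soma_distance:.1f} µm from the soma")

cfg = SimulationConfig(dt=0.02, duration=3000.0, steady_state_discard=1500.0,
                       max_compartment_length=15.0)
traces, firing = run_protocol(neuron, build_scheme(), cfg)
print(f"pacemaking at {firing.mean_rate:.2f} Hz (ISI CV {firing.isi_cv:.4f})")

soma = traces.site("soma")
keep = traces.t >= cfg.steady_state_discard
spikes = detect_spikes(soma[keep], traces.dt)
ap = ap_shape(average_ap(soma[keep], spikes, traces.dt), traces.dt)
print(f"AP threshold {ap.threshold:.1f} mV, amplitude {ap.amplitude:.1f} mV, "
      f"half-width {ap.half_width:.2f} ms")
```

Output:

```
ABD length 1012 µm of 2358 µm total; axon origin 8.0 µm from the soma
pacemaking at 8.18 Hz (ISI CV 0.0000)
AP threshold -48.0 mV, amplitude 61.1 mV, half-width 1.34 ms
```

The synthetic P21 neuron fires tonically and perfectly regularly without
any input (the model is deterministic, hence CV ≈ 0), the AP initiates in
the AIS and arrives at the soma with a half-width of 1.34 ms — against a
measured P21 population mean of 1.30 ± 0.19 ms — and raising ABD gNa
narrows the AP, which is what the screening procedure inverts.

A command-line interface mirrors the library:

```
sncdev synth  -n 20 --stage P21 --seed 1 --out pop/          # SWC + metrics
sncdev simulate pop/P21-0003.swc --variant model2 --out sim/  # pacemaking run
sncdev screen pop/*.swc --variant model2 --target 1.30 --out screen/
sncdev stats features.csv --out reports/
```

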