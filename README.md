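# ihdyn

Simulation and dynamical analysis of how the hyperpolarization-activated
cation current **I_h** (HCN channels) shapes the electrophysiology of a
hippocampal GABAergic interneuron: voltage sag and post-inhibitory rebound
(spikes), subthreshold membrane resonance, spike-timing precision under
noise — and the bifurcation structure in the (I_app, g_h) plane that
explains all three.  It is written for computational neuroscientists who
want a reproducible, tested reference implementation of this model family
and of the numerical machinery around it (ZAP impedance, ISI statistics,
equilibrium continuation, limit-cycle boundaries by simulation).

## The model

A 4-variable conductance-based membrane (time in ms, V in mV, currents in
µA/cm², conductances in mS/cm²):

```
C dV/dt = − g_Na m∞(V)³ h (V − E_Na) − g_K n⁴ (V − E_K)
          − g_h H (V − E_h) − g_L (V − E_L) + I_app + I_ext
 dh/dt  = φ [α_h(V)(1 − h) − β_h(V) h]
 dn/dt  = φ [α_n(V)(1 − n) − β_n(V) n]
 dH/dt  = [H∞(V) − H] / τ_H(V)
```

with `H∞(V) = 1/(1 + exp((V+80)/10))` (activated by hyperpolarization) and
`τ_H(V) = 200/(exp((V+70)/20) + exp(−(V+70)/20)) + 5` ms.  Standard
parameters: C = 1 µF/cm², g_Na = 35, E_Na = 55 mV, g_K = 9, E_K = −90 mV,
g_L = 0.1, E_L = −65 mV, E_h = −30 mV, φ = 5.  The two control parameters
are the applied current `Iapp` and the I_h conductance `gh`.

Around the model the package provides:

* `ihdyn.simulate` — forward Euler / Euler–Maruyama integration at
  dt = 0.001 ms with strided recording, a streaming spike detector, exact
  equilibrium settling and damped-oscillation frequency estimation;
* `ihdyn.stimulus` — square pulses, current ramps, single sines, the swept-
  sine ("ZAP") probe and the additive white-noise current `I_noise = D dW`;
* `ihdyn.impedance` — the FFT impedance profile |Z(f)| = |FFT(V)/FFT(I)|,
  resonance classification (typical / weak / non) and an analytic
  linearized-impedance oracle;
* `ihdyn.spike_stats` — ISI mean/STD/CV (N = 2000 intervals), first-spike
  jitter across ramp trials, ISI histograms and (Iapp, g_h) maps;
* `ihdyn.bifurcation` — equilibria by exact scalar reduction, analytic
  Jacobian eigen-classification (node / focus / saddle), folds (SN, SNIC),
  Hopf and node↔focus transitions bisected to 1e−7, limit-cycle boundaries
  by hysteresis simulation, two-parameter curve tracing, and the
  Bogdanov–Takens and saddle-node-homoclinic codim-2 points;
* `ihdyn.experiments` + an `ihdyn` CLI — config-driven drivers for each
  figure-level experiment.

## Worked example

```python
import numpy as np
from ihdyn import (ModelParameters, NoiseSpec, fold_points_gh, hopf_gh,
                   classify_fold_global, zap_impedance, isi_cv)

fold = fold_points_gh(0.08)[0]
print(f"fold of the resting branch at Iapp=0.08: gh = {fold.gh:.7f} "
      f"({classify_fold_global(0.08, fold.gh)})")
hopf = hopf_gh(-0.05, (0.055, 0.0623))
print(f"subcritical Hopf at Iapp=-0.05:          gh = {hopf.gh:.7f}")

prof = zap_impedance(ModelParameters(Iapp=-0.05, gh=0.05))
print(f"ZAP resonance at (Iapp=-0.05, gh=0.05): f_peak = {prof.f_peak:.2f} Hz, "
      f"|Z|_peak = {prof.Z_peak:.1f}, class = {prof.resonance_class}")

for gh in (0.0, 0.02):
    s = isi_cv(ModelParameters(Iapp=0.17, gh=gh), NoiseSpec(D=0.2, seed=101),
               2000, mean_isi_guess=210.0 if gh == 0 else 80.0)
    print(f"noisy firing (Iapp=0.17, D=0.2, gh={gh}): "
          f"mean ISI = {s.mean:6.2f} ms, CV = {s.cv:.3f}")
```

prints

```
fold of the resting branch at Iapp=0.08: gh = 0.0229919 (SNIC)
subcritical Hopf at Iapp=-0.05:          gh = 0.0620556
ZAP resonance at (Iapp=-0.05, gh=0.05): f_peak = 3.25 Hz, |Z|_peak = 30.0, class = typical
noisy firing (Iapp=0.17, D=0.2, gh=0.0): mean ISI = 203.35 ms, CV = 0.472
noisy firing (Iapp=0.17, D=0.2, gh=0.02): mean ISI =  76.96 ms, CV = 0.179
```

Reading: at Iapp = 0.08 µA/cm² the resting state dies in a saddle-node on
an invariant circle at g_h ≈ 0.023 mS/cm²; at Iapp = −0.05 firing instead
appears through a subcritical Hopf (with a bistable band below it).  With
I_h present the resting membrane resonates near 3 Hz, and in the firing
regime raising g_h from 0 to 0.02 cuts the ISI variability (CV) by a factor
of ~2.6 — I_h makes spike timing more precise because the firing sits
farther from its bifurcation and so resists the noise better.

The same experiments are available from the shell, e.g.

```
ihdyn impedance --iapp -0.05 --gh 0.05
ihdyn bifurcate --iapp 0.08
ihdyn rebound --iapp -0.05 --gh 0.05
```

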