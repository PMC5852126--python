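# Methods

This note documents the model, the numerical methods, the operational
definitions the package had to fix where the underlying quantities are only
defined up to a convention, and the known limitations.  Every number quoted
here is recomputed by the test suite or by `scripts/acceptance.py`.

## Model and units

The membrane model is a Wang–Buzsáki-type fast-spiking interneuron
(instantaneous Na⁺ activation m∞(V), Na⁺ inactivation h, delayed-rectifier
activation n, temperature-like factor φ = 5 on the h and n kinetics)
extended with a hyperpolarization-activated cation current
I_h = g_h·H·(V − E_h), E_h = −30 mV.  H activates below rest
(Boltzmann midpoint −80 mV, slope 10 mV) with a slow bell-shaped time
constant (5 ms floor, 105 ms peak at −70 mV).  Working units are ms, mV,
µA/cm², mS/cm², µF/cm²; the capacitance is C = 1 µF/cm² (a literal
"F/cm²" is dimensionally inconsistent at this scale and is read as the
customary µF/cm²), and the leak term is g_L(V − E_L) (the only reading
under which the printed parameter set reproduces the model's published
fixed-point structure, which we verify to six significant figures).  The
removable singularities of α_m at V = −35 mV and α_n at V = −34 mV are
filled with their analytic limits (1 and 0.1), so all gating functions are
C¹; no epsilon offsets are used anywhere.

The analytic Jacobian is hand-derived and pinned against central finite
differences (relative tolerance 1e−5, 100 random states) in the test
suite; the compiled (numba) inner-loop copy of the gating math is pinned
against the vectorized reference implementation to 1e−13.

## Integration and noise

Forward Euler with dt = 0.001 ms is the single integration scheme, as in
the original study conditions; gating variables are clipped to [0, 1]
after each step (the clip is a no-op except for O(dt) overshoot at the
boundaries).  Recording may be strided (the integrator still steps at full
resolution); long stochastic runs use a streaming kernel that detects
spikes on the fly and stores nothing else.

The noise current I_noise = D·dW enters the voltage equation as an
Euler–Maruyama increment (D/C)·√dt·ξ, ξ ~ N(0,1), per step.  With C = 1
the numerical value of D coincides with the intensity quoted in the
protocols (D then carries units µA·ms^½/cm²; the bare "µA/cm²" often
attached to D is not a consistent white-noise intensity).  The convention
lives in one function (`stimulus.noise_increment`) and one kernel branch,
so alternatives can be swapped for sensitivity analysis.  Runs are
bit-reproducible given (parameters, protocol, seed, dt).

Spikes are upward crossings of 0 mV with linear interpolation and a 2 ms
refractory gap.  The criterion is not part of the model definition; action
potentials here overshoot +10 mV by a wide margin, and the suite checks
that the detected period is invariant over thresholds in [−20, +10] mV.

## Equilibria and codimension-1 bifurcations

At a fixed point the three gating variables sit on explicit functions of
V, so the 4-D fixed-point problem reduces *exactly* to the scalar equation
Iapp = I_ss(V).  Equilibria come from a 0.01 mV sign-change scan refined
by Brent's method (residual ‖rhs‖ < 1e−9; a 10× finer scan finds the same
root set).  Classification (stable/unstable node, focus, saddle) uses the
eigenvalues of the analytic Jacobian; the "leading pair" is the two
eigenvalues of largest real part.

* **Folds (SN).**  I_ss is linear in g_h, so the fold conditions
  (I_ss = Iapp, dI_ss/dV = 0) collapse to one scalar equation in V.  Folds
  are therefore found in closed scalar form, with no continuation error.
* **Hopf.**  Sign change of Re of the leading complex pair along the lower
  (resting) branch, bisected to 1e−7 in g_h.
* **Node↔focus (NF).**  The *exact* collision of the two leading real
  eigenvalues (discriminant zero), bisected to 1e−7.  A caution: this
  transition is intrinsically sharp-edged — just past the collision the
  imaginary part grows like √(g_h − g_h*), so any detector that requires a
  *visible* imaginary part fires late.  A threshold of |Im λ| ≈ 5e−4/ms,
  for instance, shifts the detected point by about +1e−5 mS/cm² (0.06%).
  This package reports the exact collision.

## Limit-cycle boundaries and the fold character

No boundary-value continuation is used; the firing attractor itself is the
object of study.

`locate_cycle_boundary` finds where the stable limit cycle disappears by
hysteresis bisection: start on the firing attractor above the boundary,
step g_h down re-using the last on-cycle state, and test persistence.  The
persistence test discards a 1 s settle phase and then requires ≥ 2 spikes
in a 10 s window with the last spike inside the final 2 s.  The windows
are this long because near the homoclinic boundary the off-attractor
transients keep rotating (and spiking) for several seconds — with 2–3 s
windows the boundary estimate biases low by ~4e−5 mS/cm² — while the cycle
period itself stays below ~1 s arbitrarily close to the boundary, so the
criterion never misses a genuine cycle.  At Iapp = −0.05 the boundary
lands at g_h = 0.061018 at dt = 0.001 (Richardson extrapolation over dt
gives 0.061024): the *attractor* outlives the saddle connection by a few
parts in 10⁵ — direct shooting along the saddle's unstable manifold
locates the connection itself at 0.0610546 — so the boundary is quoted to
three significant figures, which is where all these definitions agree.

**SNIC vs SN.**  A fold of the resting branch is classified SNIC when
firing onset coincides with the fold, SN when a stable cycle persists
below it.  In this model that distinction is only meaningful relative to a
coincidence resolution δ: measured by two independent methods (cycle
persistence and unstable-manifold shooting, dt-independent down to
2.5e−4 ms), the cycle survives *below* the fold with a gap that shrinks
smoothly and roughly exponentially along the fold curve — 2.4e−4 mS/cm² at
Iapp = 0.05, 1.1e−4 at 0.0712, 7.4e−5 at 0.08, 1.3e−5 at 0.10 — instead of
vanishing at a sharp point.  The package uses δ = 1e−4 mS/cm² (≈ 0.5% of
g_h at the relevant folds): the coarsest-grained choice under which the
canonical labels of this model (plain SN at Iapp = 0.05, SNIC at
Iapp = 0.08) are both reproduced.  Any δ in (7.4e−5, 2.4e−4) gives the
same labels; smaller δ would call every fold in this range SN.

## Codimension-2 points

* **Bogdanov–Takens.**  Along the (closed-form) fold curve, bisect the
  sign change of the second-smallest eigenvalue: double zero at
  (Iapp, g_h) = (0.04239, 0.034128).  The g_h coordinate agrees with the
  published value of this model to 2e−6; the published Iapp coordinate
  (0.0432) is inconsistent with its own g_h — the point (0.0432, 0.03413)
  does not lie on the fold curve while (0.0424, 0.03413) does — and is
  almost certainly a digit transposition.
* **Saddle-node homoclinic (SNHO).**  The SNIC↔SN character switch along
  the fold curve, bisected in Iapp at resolution δ.  Because the
  fold-to-cycle gap decays smoothly (previous section), the located point
  moves with δ: at δ = 1e−4 it sits near (0.074, 0.0247), about 3% below
  the value obtained by boundary-value homoclinic continuation.  This is a
  genuine limitation of forward-simulation methods for this point, not a
  tolerance issue: there is no sharp dynamical event at the
  continuation-based location that a trajectory-based method could lock
  onto.
* **T point.**  The two branches of the stable node↔focus transition curve
  merge at the low-g_h edge near Iapp ≈ 0.157; conditioning there is poor
  (the curve is nearly tangent to g_h = 0) and the located Iapp is
  meaningful to about two significant figures.

## Impedance and resonance classes

A ZAP run drives the model from rest with I = Istim·sin(2π f(t)·t),
f(t) linear from 0 to 20 Hz over T = 20 s, Istim = 0.01 µA/cm² (the phase
is the literal product, so the instantaneous frequency runs ahead of f(t);
the pipeline is insensitive to the chirp convention because |Z| is an FFT
*ratio* on an absolute frequency axis).  V and I are recorded at 1 ms;
|Z(f)| = |FFT(V − ⟨V⟩)/FFT(I)| is restricted to 0.1–20 Hz and smoothed
with a 5-bin moving average; the low-frequency reference Z_low is the mean
over 0.1–0.3 Hz (the f = 0 bin sits at the sweep start and is unreliable).

The FFT profile is pinned against the analytic linearized impedance
|[(iωI − J)⁻¹ e_V/C]_V| to within 3% over 0.5–15 Hz *in the linear regime*
(Istim = 0.002).  At the standard probe amplitude 0.01 µA/cm² the response
carries ~3.5% genuine harmonic distortion near the resonance peak (the
deviation is amplitude-monotone and falls to ~1% at Istim = 0.001), which
also shifts the measured peak slightly: at (Iapp = −0.05, g_h = 0.05) the
FFT peak sits at 3.25 Hz versus 2.9 Hz for the linearization.  Note that
this resonance is *not* the eigenfrequency of the focus (1.57 Hz): the
leading pair there is strongly damped (|Re λ| ≈ 2|Im λ|), and for a
multivariable membrane the impedance peak and the damped-oscillation
frequency are distinct quantities.

**Classes.**  A profile is `non` when it has no genuine interior peak
(f_peak < 0.5 Hz or Z_peak/Z_low < 1.005).  Among resonant profiles,
`typical` versus `weak` follows the type of the resting equilibrium the
run started from (stable focus → typical, stable node → weak).  A
profile-shape threshold cannot make this split: the measured Z_peak/Z_low
grows monotonically toward the firing threshold on *both* sides of the
node–focus transition, and the ratio windows that would separate the two
classes at different Iapp values are disjoint (at Iapp = −0.05 the split
would need a cut inside (1.19, 1.29); at −0.3 inside (1.38, 1.55)).  The
focus/node criterion reproduces the canonical class assignments of this
model at all nine tested (Iapp, g_h) points and matches the mechanism that
generates the distinction in the first place.  The "strange" regime is
real and reproduced: nodes near the transition resonate weakly, and at
Iapp = 0.08 the narrow focus window near the codim-2 structure shows no
typical resonance.

`damped_frequency` estimates the focus frequency from the spacing of
successive V maxima of a perturbation decay (maxima of a damped cosine are
spaced by exactly one period regardless of damping).  The first inter-peak
interval is discarded (contaminated by the fast relaxation modes) and the
peak-prominence floor is 1e−11 mV, because at |Re λ| ≈ 2|Im λ| successive
maxima shrink by ~10⁶ while remaining far above double precision.  The
estimate matches |Im λ|/2π to 0.3% at (−0.05, 0.05).

## Spike statistics

CV = STD/mean over exactly N = 2000 ISIs (sample STD, n−1 denominator),
after discarding a 500 ms transient; the run length is sized adaptively
and the kernel stops once enough spikes are banked.  First-spike jitter:
1000 independent trials (noise stream seed + trial index) from the
deterministic resting state, ramp onset at t = 0, first 0 mV crossing;
trials without a spike in the window are counted and excluded (none occur
at the standard operating points).  Monte-Carlo standard errors quoted by
the package use the i.i.d. delta-method approximation for the CV.

## What the generator emulates — and does not

All inputs are synthetic by design: the stimulus module *is* the data
generator, and the study conditions (pulse amplitudes −0.4/−0.8/−1.2
µA/cm² for 100 ms, ramp rates 1 and 0.3 µA per 100 ms, ZAP 0–20 Hz / 20 s
/ 0.01 µA/cm², D = 0.2–0.6, N = 2000 ISIs, 1000 trials) are the package
defaults.  The model is a point neuron with additive current noise:
passing tests say nothing about dendritic filtering, conductance
(multiplicative) or synaptic noise, channel stochasticity, or temperature
effects beyond the fixed φ.  Real interneurons also express I_h with
cAMP-modulated kinetics; here the kinetics are fixed.

## Problem sizes

Default test and acceptance runs use: equilibrium scans of 10⁴ V-points;
persistence windows of 10 s simulated time per bisection step (~12 steps
per boundary); 20 s ZAP sweeps; 2000 ISIs per CV estimate (~7 min of
simulated time at the slowest operating point); 1000 ramp trials.  The
(Iapp, g_h) maps default to coarse grids (≤ 10×10) and scale to the full
plotted windows by configuration; a full 60×60 stochastic CV map is a
desk-scale (sub-hour) run with the compiled kernels.
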