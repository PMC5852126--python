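"""Numba inner loops for fixed-step integration.

The gating math is duplicated here in scalar njit form (the vectorized numpy
reference lives in :mod:`ihdyn.model`); a unit test pins the two against each
other.  Stimuli are evaluated analytically inside the loop so that
multi-hundred-second runs never materialize a per-step stimulus array.

Stimulus codes: 0 constant, 1 square pulse, 2 ramp, 3 ZAP chirp, 4 sine.
Parameter vector layout (ModelParameters.as_array()):
[C, gNa, ENa, gK, EK, gL, EL, gh, Eh, phi, Iapp].
"""

from __future__ import annotations

import numpy as np
from numba import njit

# stimulus kind codes
CONSTANT = 0
SQUARE = 1
RAMP = 2
ZAP = 3
SINE = 4


@njit(cache=True)
def _g(u):
    """u / (exp(u) - 1) with limit 1 at u = 0."""
    if u == 0.0:
        return 1.0
    return u / np.expm1(u)


@njit(cache=True)
def stim_value(kind, sp, t):
    """Deterministic stimulus current (uA/cm^2) at time t (ms)."""
    if kind == CONSTANT:
        return sp[0]
    if kind == SQUARE:
        # sp = (amplitude, onset, duration); half-open window
        if sp[1] <= t < sp[1] + sp[2]:
            return sp[0]
        return 0.0
    if kind == RAMP:
        # sp = (rate per ms, onset)
        if t < sp[1]:
            return 0.0
        return sp[0] * (t - sp[1])
    if kind == ZAP:
        # sp = (Istim, fmin Hz, fmax Hz, T ms); literal swept-sine
        # I = Istim sin(2 pi f(t) t) with f linear from fmin to fmax
        if t < 0.0 or t > sp[3]:
            return 0.0
        ts = t / 1000.0
        Ts = sp[3] / 1000.0
        f = sp[1] + (sp[2] - sp[1]) * ts / Ts
        return sp[0] * np.sin(2.0 * np.pi * f * ts)
    if kind == SINE:
        # sp = (amplitude, f1 Hz, onset ms)
        if t < sp[2]:
            return 0.0
        return sp[0] * np.sin(2.0 * np.pi * sp[1] * (t - sp[2]) / 1000.0)
    return 0.0


@njit(cache=True, inline="always")
def _deriv(V, h, n, H, par, I_ext):
    C = par[0]
    gNa = par[1]; ENa = par[2]
    gK = par[3]; EK = par[4]
    gL = par[5]; EL = par[6]
    gh = par[7]; Eh = par[8]
    phi = par[9]; Iapp = par[10]
    am = _g(-0.1 * (V + 35.0))
    bm = 4.0 * np.exp(-(V + 60.0) / 18.0)
    m = am / (am + bm)
    ah = 0.07 * np.exp(-(V + 58.0) / 20.0)
    bh = 1.0 / (np.exp(-0.1 * (V + 28.0)) + 1.0)
    an = 0.1 * _g(-0.1 * (V + 34.0))
    bn = 0.125 * np.exp(-(V + 44.0) / 80.0)
    Hinf = 1.0 / (1.0 + np.exp((V + 80.0) / 10.0))
    w = (V + 70.0) / 20.0
    tauH = 200.0 / (np.exp(w) + np.exp(-w)) + 5.0
    dV = (-gNa * m ** 3 * h * (V - ENa) - gK * n ** 4 * (V - EK)
          - gh * H * (V - Eh) - gL * (V - EL) + Iapp + I_ext) / C
    dh = phi * (ah * (1.0 - h) - bh * h)
    dn = phi * (an * (1.0 - n) - bn * n)
    dH = (Hinf - H) / tauH
    return dV, dh, dn, dH


@njit(cache=True)
def integrate_record(par, skind, sp, x0, n_steps, dt, stride, D, seed):
    """Forward Euler (Euler-Maruyama if D > 0) with strided state recording.

    Noise enters V only, as (D / C) * sqrt(dt) * xi per step.  Gating
    variables are clipped to [0, 1] after every step.  Returns
    (states (n_rec, 4), stim (n_rec,), ok) where ok is False when the state
    left the finite range (blow-up); the first recorded row is the initial
    condition at t = 0.
    """
    if seed >= 0:
        np.random.seed(seed)
    n_rec = n_steps // stride + 1
    out = np.empty((n_rec, 4))
    stim = np.empty(n_rec)
    V, h, n, H = x0[0], x0[1], x0[2], x0[3]
    out[0, 0] = V; out[0, 1] = h; out[0, 2] = n; out[0, 3] = H
    stim[0] = stim_value(skind, sp, 0.0)
    sq = D / par[0] * np.sqrt(dt)
    k = 1
    t = 0.0
    for i in range(n_steps):
        I = stim_value(skind, sp, t)
        dV, dh, dn, dH = _deriv(V, h, n, H, par, I)
        V = V + dt * dV
        if D > 0.0:
            V += sq * np.random.standard_normal()
        h = min(max(h + dt * dh, 0.0), 1.0)
        n = min(max(n + dt * dn, 0.0), 1.0)
        H = min(max(H + dt * dH, 0.0), 1.0)
        t += dt
        if (i + 1) % stride == 0:
            out[k, 0] = V; out[k, 1] = h; out[k, 2] = n; out[k, 3] = H
            stim[k] = stim_value(skind, sp, t)
            k += 1
        if not np.isfinite(V):
            return out[:k], stim[:k], False
    return out, stim, True


@njit(cache=True)
def integrate_spikes(par, skind, sp, x0, t_end, dt, D, seed, thr, refr, max_spk):
    """Integrate without storing the trajectory; collect upward threshold
    crossings (linear-interpolated times, refractory-gated).

    Stops early once ``max_spk`` spikes are collected.  Returns
    (spike_times, final_state, ok).
    """
    if seed >= 0:
        np.random.seed(seed)
    V, h, n, H = x0[0], x0[1], x0[2], x0[3]
    n_steps = int(round(t_end / dt))
    sq = D / par[0] * np.sqrt(dt)
    times = np.empty(max_spk)
    cnt = 0
    last = -1.0e18
    t = 0.0
    for i in range(n_steps):
        I = stim_value(skind, sp, t)
        dV, dh, dn, dH = _deriv(V, h, n, H, par, I)
        Vn = V + dt * dV
        if D > 0.0:
            Vn += sq * np.random.standard_normal()
        h = min(max(h + dt * dh, 0.0), 1.0)
        n = min(max(n + dt * dn, 0.0), 1.0)
        H = min(max(H + dt * dH, 0.0), 1.0)
        tn = t + dt
        if V < thr and Vn >= thr:
            tc = t + dt * (thr - V) / (Vn - V)
            if tc - last >= refr:
                times[cnt] = tc
                cnt += 1
                last = tc
        V = Vn
        t = tn
        if cnt == max_spk:
            break
        if not np.isfinite(V):
            st = np.empty(4)
            st[0] = V; st[1] = h; st[2] = n; st[3] = H
            return times[:cnt], st, False
    st = np.empty(4)
    st[0] = V; st[1] = h; st[2] = n; st[3] = H
    return times[:cnt], st, True


@njit(cache=True)
def warm_up():
    """Touch every kernel once so JIT compilation happens predictably."""
    par = np.array([1.0, 35.0, 55.0, 9.0, -90.0, 0.1, -65.0, 0.0, -30.0, 5.0, 0.0])
    sp = np.zeros(4)
    x0 = np.array([-64.0, 0.78, 0.09, 0.2])
    integrate_record(par, CONSTANT, sp, x0, 10, 0.001, 1, 0.0, -1)
    integrate_spikes(par, CONSTANT, sp, x0, 0.01, 0.001, 0.1, 1, 0.0, 2.0, 4)
    return 0
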