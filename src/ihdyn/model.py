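"""Conductance-based hippocampal interneuron model with a hyperpolarization-activated
cation current (I_h).

The membrane equation couples a fast spiking core (transient Na+ current with
instantaneous activation ``m_inf(V)``, delayed-rectifier K+ current, ohmic leak)
to the slow inward current I_h carried by HCN channels:

    C dV/dt = -g_Na m_inf(V)^3 h (V - E_Na) - g_K n^4 (V - E_K)
              - g_h H (V - E_h) - g_L (V - E_L) + I_app + I_ext
    dh/dt   = phi * (alpha_h(V) (1 - h) - beta_h(V) h)
    dn/dt   = phi * (alpha_n(V) (1 - n) - beta_n(V) n)
    dH/dt   = (H_inf(V) - H) / tau_H(V)

Units: time in ms, V in mV, currents in uA/cm^2, conductances in mS/cm^2,
capacitance in uF/cm^2.  ``H`` activates under hyperpolarization
(half-activation -80 mV, 10 mV slope) with a slow, voltage-dependent time
constant (minimum 5 ms, peak 105 ms at -70 mV), which is what produces the
voltage sag, post-inhibitory rebound and subthreshold resonance this package
studies.  The two control parameters throughout are ``Iapp`` and ``gh``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Iterable

import numpy as np

__all__ = [
    "ModelParameters",
    "State",
    "GatingRates",
    "gating_rates",
    "ionic_currents",
    "rhs",
    "jacobian",
    "steady_state_current",
    "d_steady_state_current_dV",
    "h_inf",
    "n_inf",
    "m_inf",
    "H_inf",
    "tau_H",
    "steady_gating",
]


@dataclass
class ModelParameters:
    """Membrane parameters.  Defaults are the standard published set for this
    interneuron model; ``Iapp`` and ``gh`` are the control parameters.

    The capacitance is in uF/cm^2 (the value "1 F/cm^2" sometimes quoted for
    this model is a unit typo; uF/cm^2 makes the membrane equation
    dimensionally consistent at the ms/mV scale used here).
    """

    C: float = 1.0        # uF/cm^2
    gNa: float = 35.0     # mS/cm^2
    ENa: float = 55.0     # mV
    gK: float = 9.0       # mS/cm^2
    EK: float = -90.0     # mV
    gL: float = 0.1       # mS/cm^2
    EL: float = -65.0     # mV
    gh: float = 0.0       # mS/cm^2
    Eh: float = -30.0     # mV
    phi: float = 5.0      # dimensionless rate factor on h and n kinetics
    Iapp: float = 0.0     # uA/cm^2

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("capacitance C must be positive")
        for name in ("gNa", "gK", "gL", "gh"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be non-negative")

    def with_(self, **kwargs) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def as_array(self) -> np.ndarray:
        """Flat parameter vector in the order the integration kernels expect."""
        return np.array(
            [self.C, self.gNa, self.ENa, self.gK, self.EK, self.gL, self.EL,
             self.gh, self.Eh, self.phi, self.Iapp]
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class State:
    """Dynamical state (V, h, n, H): membrane potential, Na+ inactivation,
    K+ activation and I_h activation."""

    V: float
    h: float
    n: float
    H: float

    def __post_init__(self) -> None:
        for name in ("h", "n", "H"):
            x = getattr(self, name)
            if not (0.0 <= x <= 1.0):
                raise ValueError(f"gating variable {name}={x} outside [0, 1]")
        if not np.isfinite(self.V):
            raise ValueError("V must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.h, self.n, self.H])

    @classmethod
    def from_array(cls, x: Iterable[float]) -> "State":
        V, h, n, H = np.asarray(x, dtype=float)
        return cls(V=float(V), h=float(h), n=float(n), H=float(H))


@dataclass
class GatingRates:
    """All voltage-dependent gating quantities evaluated at one (or an array
    of) membrane potential(s)."""

    alpha_m: np.ndarray
    beta_m: np.ndarray
    alpha_h: np.ndarray
    beta_h: np.ndarray
    alpha_n: np.ndarray
    beta_n: np.ndarray
    m_inf: np.ndarray
    h_inf: np.ndarray
    n_inf: np.ndarray
    H_inf: np.ndarray
    tau_H: np.ndarray  # ms


def _u_over_expm1(u):
    """u / (exp(u) - 1) with the removable singularity at u = 0 filled by its
    analytic limit (value 1).  Vectorized; exact at u == 0."""
    u = np.asarray(u, dtype=float)
    safe = np.where(u == 0.0, 1.0, u)
    out = np.where(u == 0.0, 1.0, safe / np.expm1(safe))
    return out


def _d_u_over_expm1(u):
    """Derivative of u/(exp(u)-1); limit -1/2 at u = 0."""
    u = np.asarray(u, dtype=float)
    safe = np.where(u == 0.0, 1.0, u)
    em = np.expm1(safe)
    out = np.where(u == 0.0, -0.5, (em - safe * np.exp(safe)) / em**2)
    return out


def alpha_m(V):
    # -0.1 (V+35) / (exp(-0.1 (V+35)) - 1); limit 1 at V = -35
    return _u_over_expm1(-0.1 * (np.asarray(V, float) + 35.0))


def beta_m(V):
    return 4.0 * np.exp(-(np.asarray(V, float) + 60.0) / 18.0)


def alpha_h(V):
    return 0.07 * np.exp(-(np.asarray(V, float) + 58.0) / 20.0)


def beta_h(V):
    return 1.0 / (np.exp(-0.1 * (np.asarray(V, float) + 28.0)) + 1.0)


def alpha_n(V):
    # -0.01 (V+34) / (exp(-0.1 (V+34)) - 1); limit 0.1 at V = -34
    return 0.1 * _u_over_expm1(-0.1 * (np.asarray(V, float) + 34.0))


def beta_n(V):
    return 0.125 * np.exp(-(np.asarray(V, float) + 44.0) / 80.0)


def m_inf(V):
    am = alpha_m(V)
    return am / (am + beta_m(V))


def h_inf(V):
    ah = alpha_h(V)
    return ah / (ah + beta_h(V))


def n_inf(V):
    an = alpha_n(V)
    return an / (an + beta_n(V))


def H_inf(V):
    # Boltzmann, half-activation -80 mV, slope 10 mV; -> 1 under hyperpolarization
    return 1.0 / (1.0 + np.exp((np.asarray(V, float) + 80.0) / 10.0))


def tau_H(V):
    # 200 / (exp((V+70)/20) + exp(-(V+70)/20)) + 5 : >= 5 ms, 105 ms at -70 mV
    w = (np.asarray(V, float) + 70.0) / 20.0
    return 200.0 / (np.exp(w) + np.exp(-w)) + 5.0


def steady_gating(V):
    """(h_inf, n_inf, H_inf) at V — the gating state of any equilibrium."""
    return h_inf(V), n_inf(V), H_inf(V)


def gating_rates(V) -> GatingRates:
    """Evaluate every gating rate, steady state and time constant at ``V``.

    Raises ``ValueError`` for non-finite input.  The removable singularities
    of alpha_m (V = -35) and alpha_n (V = -34) are filled with their analytic
    limits, so all quantities are C^1 in V.
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("membrane potential must be finite")
    return GatingRates(
        alpha_m=alpha_m(V), beta_m=beta_m(V),
        alpha_h=alpha_h(V), beta_h=beta_h(V),
        alpha_n=alpha_n(V), beta_n=beta_n(V),
        m_inf=m_inf(V), h_inf=h_inf(V), n_inf=n_inf(V),
        H_inf=H_inf(V), tau_H=tau_H(V),
    )


def ionic_currents(s: State, p: ModelParameters) -> dict:
    """Per-species membrane currents (uA/cm^2), with the sign convention of
    the membrane equation (these are the currents subtracted from C dV/dt)."""
    V = s.V
    return {
        "I_Na": p.gNa * m_inf(V) ** 3 * s.h * (V - p.ENa),
        "I_K": p.gK * s.n ** 4 * (V - p.EK),
        "I_h": p.gh * s.H * (V - p.Eh),
        "I_L": p.gL * (V - p.EL),
    }


def rhs(s: State | np.ndarray, p: ModelParameters, I_ext: float = 0.0) -> np.ndarray:
    """Vector field (dV/dt, dh/dt, dn/dt, dH/dt) in units per ms."""
    if isinstance(s, State):
        V, h, n, H = s.V, s.h, s.n, s.H
    else:
        V, h, n, H = np.asarray(s, dtype=float)
    I_ion = (p.gNa * m_inf(V) ** 3 * h * (V - p.ENa)
             + p.gK * n ** 4 * (V - p.EK)
             + p.gh * H * (V - p.Eh)
             + p.gL * (V - p.EL))
    dV = (-I_ion + p.Iapp + I_ext) / p.C
    dh = p.phi * (alpha_h(V) * (1.0 - h) - beta_h(V) * h)
    dn = p.phi * (alpha_n(V) * (1.0 - n) - beta_n(V) * n)
    dH = (H_inf(V) - H) / tau_H(V)
    return np.array([dV, dh, dn, dH], dtype=float)


# --- analytic derivatives (for the Jacobian and the linearized impedance) ---

def _d_alpha_m(V):
    return -0.1 * _d_u_over_expm1(-0.1 * (np.asarray(V, float) + 35.0))


def _d_beta_m(V):
    return -beta_m(V) / 18.0


def _d_alpha_h(V):
    return -alpha_h(V) / 20.0


def _d_beta_h(V):
    b = beta_h(V)
    return 0.1 * b * (1.0 - b)


def _d_alpha_n(V):
    return -0.01 * _d_u_over_expm1(-0.1 * (np.asarray(V, float) + 34.0))


def _d_beta_n(V):
    return -beta_n(V) / 80.0


def _d_m_inf(V):
    am, bm = alpha_m(V), beta_m(V)
    return (_d_alpha_m(V) * bm - am * _d_beta_m(V)) / (am + bm) ** 2


def _d_h_inf(V):
    a, b = alpha_h(V), beta_h(V)
    return (_d_alpha_h(V) * b - a * _d_beta_h(V)) / (a + b) ** 2


def _d_n_inf(V):
    a, b = alpha_n(V), beta_n(V)
    return (_d_alpha_n(V) * b - a * _d_beta_n(V)) / (a + b) ** 2


def _d_H_inf(V):
    Hi = H_inf(V)
    return -Hi * (1.0 - Hi) / 10.0


def _d_tau_H(V):
    w = (np.asarray(V, float) + 70.0) / 20.0
    return -(tau_H(V) - 5.0) * np.tanh(w) / 20.0


def jacobian(s: State | np.ndarray, p: ModelParameters) -> np.ndarray:
    """Analytic 4x4 Jacobian of :func:`rhs` at ``s`` (units 1/ms).

    Row/column order (V, h, n, H).  The H row couples only to V and H.
    """
    if isinstance(s, State):
        V, h, n, H = s.V, s.h, s.n, s.H
    else:
        V, h, n, H = np.asarray(s, dtype=float)
    m = m_inf(V)
    dm = _d_m_inf(V)
    J = np.zeros((4, 4))
    J[0, 0] = (-p.gNa * h * (3.0 * m * m * dm * (V - p.ENa) + m ** 3)
               - p.gK * n ** 4 - p.gh * H - p.gL) / p.C
    J[0, 1] = -p.gNa * m ** 3 * (V - p.ENa) / p.C
    J[0, 2] = -4.0 * p.gK * n ** 3 * (V - p.EK) / p.C
    J[0, 3] = -p.gh * (V - p.Eh) / p.C
    J[1, 0] = p.phi * (_d_alpha_h(V) * (1.0 - h) - _d_beta_h(V) * h)
    J[1, 1] = -p.phi * (alpha_h(V) + beta_h(V))
    J[2, 0] = p.phi * (_d_alpha_n(V) * (1.0 - n) - _d_beta_n(V) * n)
    J[2, 2] = -p.phi * (alpha_n(V) + beta_n(V))
    tH = tau_H(V)
    J[3, 0] = _d_H_inf(V) / tH - (H_inf(V) - H) * _d_tau_H(V) / tH ** 2
    J[3, 3] = -1.0 / tH
    return J


def steady_state_current(V, p: ModelParameters):
    """Total steady-state membrane current I_ss(V) with gating at its
    V-dependent fixed point.  Equilibria of the full system are exactly the
    roots of ``Iapp - I_ss(V)``: the scalar reduction is exact because h, n
    and H nullclines are explicit functions of V.

    Linear in gh: I_ss = A(V) + gh * B(V) with B = H_inf(V) (V - Eh).
    """
    V = np.asarray(V, dtype=float)
    return (p.gNa * m_inf(V) ** 3 * h_inf(V) * (V - p.ENa)
            + p.gK * n_inf(V) ** 4 * (V - p.EK)
            + p.gh * H_inf(V) * (V - p.Eh)
            + p.gL * (V - p.EL))


def d_steady_state_current_dV(V, p: ModelParameters):
    """Analytic dI_ss/dV.  Its zeros at a root of Iapp - I_ss are folds
    (zero-eigenvalue points) of the equilibrium branch."""
    V = np.asarray(V, dtype=float)
    m = m_inf(V)
    return (p.gNa * ((3.0 * m ** 2 * _d_m_inf(V) * h_inf(V)
                      + m ** 3 * _d_h_inf(V)) * (V - p.ENa)
                     + m ** 3 * h_inf(V))
            + p.gK * (4.0 * n_inf(V) ** 3 * _d_n_inf(V) * (V - p.EK)
                      + n_inf(V) ** 4)
            + p.gh * (_d_H_inf(V) * (V - p.Eh) + H_inf(V))
            + p.gL)
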