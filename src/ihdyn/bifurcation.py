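"""Equilibrium and bifurcation analysis of the interneuron model, from scratch.

The fixed-point system reduces exactly to a scalar equation in V (the h, n, H
nullclines are explicit functions of V), so equilibria are roots of
``Iapp - I_ss(V)`` and every codimension-1 condition becomes a 1-D
root-finding problem:

* folds (SN/SNIC): ``I_ss`` is linear in g_h, so the fold locus solves
  ``dI_ss/dV = 0`` together with ``I_ss = Iapp`` in closed scalar form;
* Hopf: sign change of the real part of the leading complex pair of the
  analytic Jacobian along the branch;
* node<->focus (NF) transitions: collision of the two leading real
  eigenvalues (the exact real-to-complex transition, bisected to 1e-7);
* homoclinic / cycle-disappearance boundaries: hysteresis bisection on
  limit-cycle persistence in direct simulation (no boundary-value
  continuation is used anywhere).

Codimension-2 points are then 1-D root finds along the traced curves: the
Bogdanov-Takens point is the double-zero condition along the fold curve and
the saddle-node homoclinic (SNHO) point is the SNIC<->SN character switch of
the fold.  Note (see docs/methods.md): in this model the stable cycle
persists *below* the fold with an exponentially shrinking parameter gap, so
the SNIC/SN distinction — and with it the SNHO location — is only defined
relative to a coincidence resolution, ``delta`` (default 1e-4 mS/cm^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .model import (
    ModelParameters,
    H_inf,
    _d_H_inf,
    d_steady_state_current_dV,
    jacobian,
    rhs,
    steady_gating,
    steady_state_current,
)

__all__ = [
    "Equilibrium", "BifurcationPoint", "ParamCurve", "Diagram1D",
    "find_equilibria", "classify_eigenvalues", "fold_points_gh",
    "hopf_gh", "nf_gh", "sweep_1d", "locate_cycle_boundary",
    "classify_fold_global", "classify_hopf", "trace_curve_2d",
    "locate_codim2", "stable_behavior_partition", "firing_onset_gh",
]

V_SCAN = (-100.0, 0.0)
V_SCAN_POINTS = 10001          # 0.01 mV grid
PARAM_TOL = 1e-7               # bisection tolerance in gh for eigen-conditions
CYCLE_TOL = 1e-6               # bisection tolerance for cycle boundaries
FOLD_COINCIDENCE = 1e-4        # SNIC vs SN resolution in gh (see module docs)


@dataclass
class Equilibrium:
    """Fixed point with its eigen-classification."""

    state: np.ndarray                 # (V, h, n, H)
    eigenvalues: np.ndarray           # 4 complex numbers, 1/ms
    etype: str                        # stable_node | stable_focus | unstable_node | unstable_focus | saddle

    @property
    def V(self) -> float:
        return float(self.state[0])

    @property
    def is_stable(self) -> bool:
        return self.etype.startswith("stable")

    @property
    def is_focus(self) -> bool:
        return self.etype.endswith("focus")


@dataclass
class BifurcationPoint:
    kind: str                         # SN | SNIC | Hopf_sub | Hopf_super | Hopf | NF | BHom | BT | SNHO | T
    Iapp: float
    gh: float
    eigenvalues: np.ndarray | None = None
    V: float | None = None


@dataclass
class ParamCurve:
    """A codimension-1 locus traced in the (Iapp, gh) plane."""

    kind: str                         # SN | Hopf | NF_S | cycle_boundary
    points: np.ndarray                # (n, 2) columns (Iapp, gh)
    truncated: str | None = None      # reason if tracing stopped early

    def gh_at(self, iapp: float) -> float:
        """Linear interpolation of the curve at ``iapp``."""
        pts = self.points[np.argsort(self.points[:, 0])]
        return float(np.interp(iapp, pts[:, 0], pts[:, 1]))


@dataclass
class Diagram1D:
    """One-parameter diagram in gh at fixed Iapp."""

    Iapp: float
    gh: np.ndarray
    branches: list                    # list of (gh_value, [Equilibrium, ...])
    points: list = field(default_factory=list)


def _params(iapp: float, gh: float, base: ModelParameters | None) -> ModelParameters:
    base = base if base is not None else ModelParameters()
    return base.with_(Iapp=iapp, gh=gh)


def classify_eigenvalues(eigs: np.ndarray) -> str:
    """Node / focus / saddle classification with stability.

    The leading pair is the two eigenvalues with largest real part; a focus
    has that pair complex-conjugate, a node has all-real same-sign spectrum,
    and a saddle has real parts of mixed sign with a real leading eigenvalue.
    """
    order = np.argsort(-eigs.real)
    eigs = eigs[order]
    stable = eigs.real.max() < 0
    if abs(eigs[0].imag) > 0:
        conj = np.abs(eigs - np.conj(eigs[0]))
        if np.min(conj) < 1e-9 * max(1.0, abs(eigs[0])):
            return "stable_focus" if stable else "unstable_focus"
    if eigs.real.max() > 0 and eigs.real.min() < 0:
        return "saddle"
    return "stable_node" if stable else "unstable_node"


def _equilibrium_at(V: float, p: ModelParameters) -> Equilibrium:
    h, n, H = steady_gating(V)
    x = np.array([V, float(h), float(n), float(H)])
    eigs = np.linalg.eigvals(jacobian(x, p))
    return Equilibrium(state=x, eigenvalues=eigs, etype=classify_eigenvalues(eigs))


def find_equilibria(p: ModelParameters, v_range=V_SCAN,
                    n_scan: int = V_SCAN_POINTS) -> list[Equilibrium]:
    """All equilibria, by sign-change scan of ``Iapp - I_ss(V)`` on a fine V
    grid refined with Brent's method, classified by the analytic Jacobian.

    Sorted by V (lower branch first).  Returns 1, 2 (exactly at a fold) or 3
    equilibria over the studied parameter window.
    """
    Vg = np.linspace(v_range[0], v_range[1], n_scan)
    F = p.Iapp - steady_state_current(Vg, p)
    roots: list[float] = []
    for i in np.nonzero(np.sign(F[:-1]) * np.sign(F[1:]) < 0)[0]:
        roots.append(brentq(lambda V: p.Iapp - float(steady_state_current(V, p)),
                            Vg[i], Vg[i + 1], xtol=1e-13, rtol=8.9e-16))
    for i in np.nonzero(F == 0.0)[0]:
        roots.append(float(Vg[i]))
    return [_equilibrium_at(V, p) for V in sorted(roots)]


def _lower_equilibrium(iapp: float, gh: float, base=None) -> Equilibrium:
    eqs = find_equilibria(_params(iapp, gh, base))
    if not eqs:
        raise RuntimeError(f"no equilibrium found at Iapp={iapp}, gh={gh}")
    return eqs[0]


# --- codim-1 conditions ----------------------------------------------------

def fold_points_gh(iapp: float, base: ModelParameters | None = None,
                   gh_max: float = 0.25, v_range=(-90.0, -35.0)) -> list[BifurcationPoint]:
    """Folds (zero-eigenvalue points) of the equilibrium set at fixed Iapp.

    Uses the exact linearity of I_ss in gh: a fold satisfies
    dI_ss/dV = 0 and I_ss = Iapp, i.e. gh = -A'(V)/B'(V) and
    A(V) + gh B(V) = Iapp with A = I_ss|_{gh=0}, B = H_inf (V - Eh);
    this collapses to one scalar equation in V, solved by bracketed Brent.
    """
    base = base if base is not None else ModelParameters()
    p0 = base.with_(Iapp=iapp, gh=0.0)

    def A(V):
        return steady_state_current(V, p0)

    def dA(V):
        return d_steady_state_current_dV(V, p0)

    def B(V):
        return H_inf(V) * (np.asarray(V, float) - base.Eh)

    def dB(V):
        return _d_H_inf(V) * (np.asarray(V, float) - base.Eh) + H_inf(V)

    def gh_of_V(V):
        return -dA(V) / dB(V)

    def F(V):
        return A(V) + gh_of_V(V) * B(V) - iapp

    Vg = np.linspace(v_range[0], v_range[1], 4001)
    vals = F(Vg)
    pts = []
    for i in np.nonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]:
        Vf = brentq(lambda V: float(F(V)), Vg[i], Vg[i + 1], xtol=1e-12)
        ghf = float(gh_of_V(Vf))
        if 0.0 <= ghf <= gh_max:
            eq = _equilibrium_at(Vf, _params(iapp, ghf, base))
            pts.append(BifurcationPoint(kind="SN", Iapp=iapp, gh=ghf,
                                        eigenvalues=eq.eigenvalues, V=Vf))
    return sorted(pts, key=lambda b: b.gh)


def _leading_pair_state(iapp: float, gh: float, base=None):
    """(is_complex, max_Re) of the leading eigenvalue pair on the lower branch."""
    eq = _lower_equilibrium(iapp, gh, base)
    eigs = eq.eigenvalues[np.argsort(-eq.eigenvalues.real)]
    is_complex = abs(eigs[0].imag) > 0.0
    return is_complex, float(eigs.real.max())


def _bisect_flag(f, lo: float, hi: float, tol: float) -> float:
    """Bisect the switch point of a boolean-valued function of one variable."""
    flo = f(lo)
    if f(hi) == flo:
        raise ValueError("bracket does not straddle a transition")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) == flo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def hopf_gh(iapp: float, bracket: tuple[float, float],
            base: ModelParameters | None = None, tol: float = PARAM_TOL) -> BifurcationPoint:
    """Hopf point of the lower branch: sign change of Re of the leading
    complex pair, bisected to ``tol`` in gh."""
    gh = _bisect_flag(lambda g: _leading_pair_state(iapp, g, base)[1] > 0,
                      bracket[0], bracket[1], tol)
    eq = _lower_equilibrium(iapp, gh, base)
    return BifurcationPoint(kind="Hopf", Iapp=iapp, gh=gh,
                            eigenvalues=eq.eigenvalues, V=eq.V)


def nf_gh(iapp: float, bracket: tuple[float, float],
          base: ModelParameters | None = None, tol: float = PARAM_TOL) -> BifurcationPoint:
    """Node<->focus transition of the lower branch: the exact collision of
    the two leading real eigenvalues (discriminant zero), bisected to ``tol``."""
    gh = _bisect_flag(lambda g: _leading_pair_state(iapp, g, base)[0],
                      bracket[0], bracket[1], tol)
    eq = _lower_equilibrium(iapp, gh, base)
    return BifurcationPoint(kind="NF", Iapp=iapp, gh=gh,
                            eigenvalues=eq.eigenvalues, V=eq.V)


def sweep_1d(iapp: float, gh_range=(0.0, 0.1), n_grid: int = 201,
             base: ModelParameters | None = None) -> Diagram1D:
    """One-parameter diagram in gh: all equilibrium branches on the grid plus
    refined fold / Hopf / NF points of the lower (resting) branch.

    Hopf and NF detections are seeded by classification changes between
    neighbouring grid points, so transitions narrower than the grid spacing
    need a dedicated call to :func:`nf_gh` / :func:`hopf_gh` with a tighter
    bracket.
    """
    gh_grid = np.linspace(gh_range[0], gh_range[1], n_grid)
    branches = []
    lower = []
    for gh in gh_grid:
        eqs = find_equilibria(_params(iapp, gh, base))
        branches.append((float(gh), eqs))
        lower.append(eqs[0] if eqs else None)
    points: list[BifurcationPoint] = []
    for bp in fold_points_gh(iapp, base):
        if gh_range[0] <= bp.gh <= gh_range[1]:
            points.append(bp)
    for i in range(n_grid - 1):
        a, b = lower[i], lower[i + 1]
        if a is None or b is None:
            continue
        ca, _ = _leading_pair_state(iapp, gh_grid[i], base)
        cb, _ = _leading_pair_state(iapp, gh_grid[i + 1], base)
        if ca != cb:
            points.append(nf_gh(iapp, (gh_grid[i], gh_grid[i + 1]), base))
        sa = a.eigenvalues.real.max() > 0
        sb = b.eigenvalues.real.max() > 0
        if sa != sb and (ca or cb):
            try:
                points.append(hopf_gh(iapp, (gh_grid[i], gh_grid[i + 1]), base))
            except ValueError:
                pass
    points.sort(key=lambda bp: bp.gh)
    return Diagram1D(Iapp=iapp, gh=gh_grid, branches=branches, points=points)


# --- limit-cycle boundaries (simulation) -----------------------------------

def _firing_state(iapp: float, gh: float, base=None, dt: float = 0.001):
    """A state on the firing attractor, from a suprathreshold start."""
    from .simulate import run_spikes

    p = _params(iapp, gh, base)
    x0 = np.array([-55.0, 0.6, 0.2, 0.2])
    st, xe = run_spikes(p, x0=x0, t_end=3000.0, dt=dt)
    if len(st) < 2:
        raise ValueError(f"no firing attractor found at Iapp={iapp}, gh={gh}")
    return xe


def _persists(iapp: float, gh: float, x0, base=None, dt: float = 0.001,
              settle: float = 1000.0, window: float = 10000.0,
              tail: float = 2000.0):
    """Does spiking persist at (iapp, gh) from state ``x0``?

    A settle phase of ``settle`` ms is discarded (transient rotations near a
    homoclinic ghost outlive several seconds, so this phase plus the
    last-spike criterion below are what make the boundary estimate honest);
    sustained firing then requires at least 2 spikes in the ``window`` with
    the last one inside the final ``tail`` ms.  Returns (bool, end_state).
    """
    from .simulate import run_spikes

    p = _params(iapp, gh, base)
    _, xs = run_spikes(p, x0=x0, t_end=settle, dt=dt)
    st, xe = run_spikes(p, x0=xs, t_end=window, dt=dt)
    ok = len(st) >= 2 and st.spike_times[-1] > window - tail
    return ok, xe


def locate_cycle_boundary(iapp: float, gh_hi: float, gh_lo: float,
                          base: ModelParameters | None = None,
                          tol: float = CYCLE_TOL, dt: float = 0.001,
                          settle: float = 1000.0, window: float = 10000.0) -> float:
    """gh at which the stable limit cycle disappears (firing lower boundary;
    the big-homoclinic point when the fold lies above it), by hysteresis
    bisection: continue downward from the firing attractor at ``gh_hi``,
    re-using the last on-cycle state, and bisect persistence to ``tol``."""
    if not gh_lo < gh_hi:
        raise ValueError("need gh_lo < gh_hi")
    xhi = _firing_state(iapp, gh_hi, base, dt)
    ok, xhi = _persists(iapp, gh_hi, xhi, base, dt, settle, window)
    if not ok:
        raise ValueError(f"no persistent cycle at the upper bracket gh={gh_hi}")
    lo, hi = gh_lo, gh_hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        ok, xm = _persists(iapp, mid, xhi, base, dt, settle, window)
        if ok:
            hi = mid
            xhi = xm
        else:
            lo = mid
    return 0.5 * (lo + hi)


def classify_fold_global(iapp: float, gh_fold: float,
                         base: ModelParameters | None = None,
                         delta: float = FOLD_COINCIDENCE,
                         dt: float = 0.001) -> str:
    """SNIC or SN character of a fold of the resting branch.

    SNIC: firing onset coincides with the fold at resolution ``delta`` —
    i.e. no stable cycle persists at gh = gh_fold - delta.  SN: the cycle
    persists below the fold (coexistence window wider than ``delta``).
    ``delta`` defaults to 1e-4 mS/cm^2; in this model the homoclinic
    boundary hugs the fold exponentially closely at depolarized Iapp, so the
    distinction is intrinsically resolution-dependent (see docs/methods.md).
    """
    x0 = _firing_state(iapp, gh_fold + 2e-3, base, dt)
    ok, _ = _persists(iapp, gh_fold - delta, x0, base, dt)
    return "SN" if ok else "SNIC"


def classify_hopf(iapp: float, gh_hopf: float,
                  base: ModelParameters | None = None,
                  offset: float = 5e-4, dt: float = 0.001) -> str:
    """Sub- vs supercritical character of a Hopf point, by the hysteresis
    test: subcritical iff a stable large-amplitude cycle coexists with the
    still-stable focus just below the Hopf (two attractors from rest-start
    and spike-start initial conditions)."""
    gh = gh_hopf - offset
    eq = _lower_equilibrium(iapp, gh, base)
    if not eq.is_stable:
        raise ValueError("equilibrium is not stable just below the Hopf point")
    try:
        x_fire = _firing_state(iapp, gh_hopf + 2e-3, base, dt)
    except ValueError:
        return "super"
    ok, _ = _persists(iapp, gh, x_fire, base, dt)
    return "sub" if ok else "super"


# --- two-parameter curves and codim-2 points -------------------------------

def _fold_near(iapp: float, gh_guess: float | None, base=None) -> BifurcationPoint:
    pts = fold_points_gh(iapp, base)
    if not pts:
        raise ValueError(f"no fold at Iapp={iapp}")
    if gh_guess is None:
        return pts[0]
    return min(pts, key=lambda b: abs(b.gh - gh_guess))


def trace_curve_2d(kind: str, iapp_values, base: ModelParameters | None = None,
                   gh_window: float = 5e-3, seed_gh: float | None = None,
                   **cycle_kw) -> ParamCurve:
    """Trace a codim-1 locus over ``iapp_values`` by re-solving the defining
    condition in gh at each step, seeded by the previous point (predictor-
    corrector with a trivial predictor; the curves here are smooth and
    monotone enough that this is robust).  Truncates, recording the reason,
    when the condition loses its root."""
    pts = []
    gh_prev = seed_gh
    reason = None
    for iapp in iapp_values:
        try:
            if kind == "SN":
                gh = _fold_near(iapp, gh_prev, base).gh
            elif kind == "Hopf":
                lo = (gh_prev - gh_window) if gh_prev is not None else 0.03
                hi = (gh_prev + gh_window) if gh_prev is not None else 0.12
                gh = hopf_gh(iapp, (max(lo, 0.0), hi), base).gh
            elif kind == "NF_S":
                lo = (gh_prev - gh_window) if gh_prev is not None else 0.0
                hi = (gh_prev + gh_window) if gh_prev is not None else 0.06
                gh = nf_gh(iapp, (max(lo, 0.0), hi), base).gh
            elif kind == "cycle_boundary":
                guess = gh_prev if gh_prev is not None else _fold_near(iapp, None, base).gh
                gh = locate_cycle_boundary(iapp, guess + 3e-3, max(guess - 4e-3, 0.0),
                                           base, **cycle_kw)
            else:
                raise ValueError(f"unknown curve kind {kind!r}")
        except (ValueError, RuntimeError) as err:
            reason = f"lost curve at Iapp={iapp}: {err}"
            break
        pts.append((iapp, gh))
        gh_prev = gh
    return ParamCurve(kind=kind, points=np.array(pts).reshape(-1, 2), truncated=reason)


def _fold_second_eig(iapp: float, base=None) -> tuple[float, float]:
    """(gh_fold, Re of the eigenvalue closest to zero after the fold zero)."""
    bp = _fold_near(iapp, None, base)
    eigs = bp.eigenvalues[np.argsort(np.abs(bp.eigenvalues))]
    return bp.gh, float(eigs[1].real)


def locate_codim2(kind: str, base: ModelParameters | None = None,
                  iapp_bracket: tuple[float, float] | None = None,
                  tol: float = 1e-6, delta: float = FOLD_COINCIDENCE,
                  dt: float = 0.001) -> BifurcationPoint:
    """Codimension-2 points as 1-D root finds along traced curves.

    BT — double-zero condition (sign change of the second-smallest
    eigenvalue) along the fold curve; SNHO — SNIC<->SN character switch of
    the fold at resolution ``delta``; T — merging of the two NF_S branches
    at the low-gh edge (poorly conditioned there: the Iapp coordinate is
    meaningful to about two significant figures).
    """
    if kind == "BT":
        lo, hi = iapp_bracket or (0.02, 0.06)
        iapp = _bisect_flag(lambda i: _fold_second_eig(i, base)[1] > 0, lo, hi, tol)
        gh = _fold_near(iapp, None, base).gh
        eq = _equilibrium_at(_fold_near(iapp, None, base).V, _params(iapp, gh, base))
        return BifurcationPoint(kind="BT", Iapp=iapp, gh=gh,
                                eigenvalues=eq.eigenvalues, V=eq.V)
    if kind == "SNHO":
        lo, hi = iapp_bracket or (0.05, 0.10)

        def is_snic(i):
            return classify_fold_global(i, _fold_near(i, None, base).gh,
                                        base, delta, dt) == "SNIC"

        iapp = _bisect_flag(is_snic, lo, hi, max(tol, 2e-5))
        bp = _fold_near(iapp, None, base)
        return BifurcationPoint(kind="SNHO", Iapp=iapp, gh=bp.gh,
                                eigenvalues=bp.eigenvalues, V=bp.V)
    if kind == "T":
        lo, hi = iapp_bracket or (0.14, 0.17)

        def has_nf(i):
            # two NF_S roots exist below the T point, none above
            gh_grid = np.linspace(0.0, 0.01, 501)
            flags = [_leading_pair_state(i, g, base)[0] for g in gh_grid]
            return any(f != flags[0] for f in flags)

        iapp = _bisect_flag(has_nf, lo, hi, max(tol, 1e-4))
        return BifurcationPoint(kind="T", Iapp=iapp, gh=0.0)
    raise ValueError(f"unknown codim-2 kind {kind!r}")


# --- stable-behavior partition ---------------------------------------------

def firing_onset_gh(iapp: float, i_bt: float,
                    base: ModelParameters | None = None) -> float:
    """Lower gh border of (mono-stable) firing at fixed Iapp: the Hopf point
    left of the BT point, the fold right of it."""
    if iapp < i_bt:
        bp = _fold_near(iapp, None, base)
        return hopf_gh(iapp, (max(bp.gh - 6e-3, 0.0), bp.gh), base).gh
    return _fold_near(iapp, None, base).gh


def stable_behavior_partition(iapp_grid, gh_grid,
                              base: ModelParameters | None = None,
                              delta: float = FOLD_COINCIDENCE,
                              dt: float = 0.001,
                              window: float = 6000.0) -> np.ndarray:
    """Label map over (Iapp, gh): ``firing`` / ``coexistence`` /
    ``stable_focus`` / ``stable_node``, combining equilibrium classification
    with the traced firing-onset and cycle-disappearance borders.

    Returns an object array of shape (len(gh_grid), len(iapp_grid)).
    Columns where the coexistence band is narrower than ``delta`` get no
    coexistence cells (the band is below the partition's resolution).
    """
    i_bt = locate_codim2("BT", base).Iapp
    labels = np.empty((len(gh_grid), len(iapp_grid)), dtype=object)
    for j, iapp in enumerate(iapp_grid):
        onset = firing_onset_gh(iapp, i_bt, base)
        try:
            floor = locate_cycle_boundary(iapp, onset + 3e-3,
                                          max(onset - 4e-3, 0.0), base,
                                          window=window, dt=dt)
        except ValueError:
            floor = onset
        if onset - floor <= delta:
            floor = onset
        for i, gh in enumerate(gh_grid):
            if gh >= onset:
                labels[i, j] = "firing"
            elif gh >= floor:
                labels[i, j] = "coexistence"
            else:
                eq = _lower_equilibrium(iapp, gh, base)
                labels[i, j] = "stable_focus" if eq.is_focus else "stable_node"
    return labels
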