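"""Minimal plotting helpers (matplotlib).  Styling is deliberately plain —
these exist for inspection, not publication."""

from __future__ import annotations

import numpy as np


def plot_trajectory(tr, ax=None):
    """Membrane potential (and stimulus, when non-trivial) against time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(tr.t, tr.V, lw=0.8)
    ax.set_xlabel("t (ms)")
    ax.set_ylabel("V (mV)")
    if np.ptp(tr.stim) > 0:
        ax2 = ax.twinx()
        ax2.plot(tr.t, tr.stim, color="gray", lw=0.5, alpha=0.6)
        ax2.set_ylabel("I (uA/cm$^2$)")
    return ax


def plot_impedance(profile, ax=None, **kw):
    """|Z(f)| with the peak marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(profile.f, profile.Zmag, **kw)
    ax.axvline(profile.f_peak, color="k", ls=":", lw=0.8)
    ax.set_xlabel("f (Hz)")
    ax.set_ylabel("|Z| (mV per uA/cm$^2$)")
    ax.set_title(f"{profile.resonance_class}-resonance, "
                 f"f_peak = {profile.f_peak:.2f} Hz")
    return ax


def plot_diagram_1d(diagram, ax=None):
    """Equilibrium branches in (gh, V) colored by stability/type, with the
    detected bifurcation points marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    style = {
        "stable_node": dict(color="k", marker="."),
        "stable_focus": dict(color="r", marker="."),
        "unstable_node": dict(color="k", marker="x"),
        "unstable_focus": dict(color="r", marker="x"),
        "saddle": dict(color="gray", marker="+"),
    }
    for gh, eqs in diagram.branches:
        for eq in eqs:
            s = style[eq.etype]
            ax.plot(gh, eq.V, ms=3, ls="none", **s)
    for bp in diagram.points:
        ax.axvline(bp.gh, color="b", ls="--", lw=0.6)
        ax.text(bp.gh, ax.get_ylim()[1], bp.kind, rotation=90,
                va="top", fontsize=7)
    ax.set_xlabel("$g_h$ (mS/cm$^2$)")
    ax.set_ylabel("V (mV)")
    ax.set_title(f"$I_{{app}}$ = {diagram.Iapp}")
    return ax
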