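"""Config-driven experiment drivers.

Each driver reproduces one figure-level experiment of the study (rebound
assay, behaviour maps, CV statistics, resonance families, one/two-parameter
bifurcation diagrams, focus-vs-node frequency response, ZAP envelopes,
ISI-moment decomposition) and returns a plain dict of its quantitative
outputs; :func:`run_experiment` additionally writes CSV tables, a JSON
summary and a manifest (resolved config + package version + seed) into the
output directory, and re-running with the same manifest reproduces the
outputs byte-identically.

Default grids here are deliberately coarse enough for a desk run; every
size is overridable through the config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .bifurcation import (
    classify_fold_global,
    classify_hopf,
    fold_points_gh,
    hopf_gh,
    locate_codim2,
    locate_cycle_boundary,
    nf_gh,
    sweep_1d,
    trace_curve_2d,
)
from .impedance import zap_envelope, zap_impedance, zap_response
from .model import ModelParameters
from .simulate import (
    damped_frequency,
    detect_spikes,
    integrate,
    settle_to_equilibrium,
)
from .spike_stats import (
    first_spike_ensemble,
    isi_cv,
    isi_histogram,
    param_map,
)
from .stimulus import NoiseSpec, SquarePulse, ZapSpec

__all__ = ["ExperimentConfig", "run_experiment", "rebound_assay", "EXPERIMENTS"]

REBOUND_WINDOW_MS = 200.0       # post-offset window for a rebound spike
REBOUND_OVERSHOOT_MV = 1.0      # overshoot above rest that counts as rebound


@dataclass
class ExperimentConfig:
    """Resolved experiment description.

    ``experiment`` selects a driver (fig1, fig2, ... or custom);
    ``params`` are ModelParameters overrides, ``options`` driver-specific
    knobs, ``seed`` the base RNG seed, ``outdir`` where to write results.
    """

    experiment: str
    params: dict = field(default_factory=dict)
    options: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        allowed = {"experiment", "params", "options", "seed", "outdir"}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "experiment" not in d:
            raise ValueError("config needs an 'experiment' key")
        bad = set(d.get("params", {})) - set(ModelParameters().to_dict())
        if bad:
            raise ValueError(f"unknown model parameters: {sorted(bad)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def model_params(self, **extra) -> ModelParameters:
        return ModelParameters(**{**self.params, **extra})


def rebound_assay(p: ModelParameters, amplitudes=(-0.4, -0.8, -1.2),
                  duration: float = 100.0, onset: float = 200.0,
                  dt: float = 0.001) -> list[dict]:
    """Hyperpolarizing-pulse assay: sag depth and rebound outcome per pulse.

    From rest, a square pulse of each (negative) amplitude is applied for
    ``duration`` ms.  Sag depth is V at pulse end minus the early minimum
    during the pulse (>= 0; zero means no sag).  Outcome is
    ``rebound_spike`` if a spike occurs within 200 ms after pulse offset,
    ``rebound`` if V overshoots rest by more than 1 mV without spiking,
    else ``no_rebound``.
    """
    x0 = settle_to_equilibrium(p)
    v_rest = float(x0[0])
    out = []
    for amp in amplitudes:
        proto = SquarePulse(amplitude=amp, onset=onset, duration=duration)
        tr = integrate(p, proto=proto, x0=x0,
                       t_end=onset + duration + REBOUND_WINDOW_MS + 100.0,
                       dt=dt, record_dt=0.05)
        in_pulse = (tr.t >= onset) & (tr.t < onset + duration)
        v_end = float(tr.V[in_pulse][-1])
        v_min = float(tr.V[in_pulse].min())
        sag = v_end - v_min
        post = (tr.t >= onset + duration) & (tr.t <= onset + duration + REBOUND_WINDOW_MS)
        spikes = detect_spikes(tr)
        spk_post = spikes.spike_times[(spikes.spike_times >= onset + duration)
                                      & (spikes.spike_times <= onset + duration + REBOUND_WINDOW_MS)]
        if len(spk_post):
            outcome = "rebound_spike"
            t_spike = float(spk_post[0] - (onset + duration))
        else:
            t_spike = None
            overshoot = float(tr.V[post].max() - v_rest)
            outcome = "rebound" if overshoot > REBOUND_OVERSHOOT_MV else "no_rebound"
        out.append({"amplitude": amp, "sag_depth_mV": sag, "outcome": outcome,
                    "rebound_spike_latency_ms": t_spike})
    return out


# --- drivers ---------------------------------------------------------------

def _fig1(cfg: ExperimentConfig) -> dict:
    """First-spike jitter under fast and slow current ramps (D = 0.2,
    Iapp = 0, gh = 0.02, 1000 trials)."""
    o = cfg.options
    p = cfg.model_params(Iapp=o.get("Iapp", 0.0), gh=o.get("gh", 0.02))
    noise = NoiseSpec(D=o.get("D", 0.2), seed=cfg.seed)
    n_trials = o.get("n_trials", 1000)
    res = {}
    for name, rate in {"fast": 0.01, "slow": 0.003}.items():
        ens = first_spike_ensemble(p, rate, noise, n_trials=n_trials,
                                   t_max=o.get("t_max", 400.0))
        res[name] = {"ramp_rate_uA_per_ms": rate, "mean_ms": ens.mean,
                     "std_ms": ens.std, "n": len(ens.times),
                     "n_failed": ens.n_failed}
    return res


def _fig2(cfg: ExperimentConfig) -> dict:
    """Sag and rebound (spike) vs pulse strength for gh = 0.05, 0.04, 0."""
    o = cfg.options
    res = {}
    for gh in o.get("gh_values", (0.05, 0.04, 0.0)):
        p = cfg.model_params(Iapp=o.get("Iapp", -0.05), gh=gh)
        res[f"gh={gh}"] = rebound_assay(p, amplitudes=o.get("amplitudes",
                                                            (-0.4, -0.8, -1.2)))
    return res


def _fig3(cfg: ExperimentConfig) -> dict:
    """Resting-potential and firing-frequency maps over (Iapp, gh)."""
    o = cfg.options
    iapp = np.linspace(*o.get("iapp_range", (-0.4, 0.4)), o.get("n_iapp", 9))
    gh = np.linspace(*o.get("gh_range", (0.0, 0.14)), o.get("n_gh", 8))
    rest = param_map("resting_V", iapp, gh)
    freq = param_map("firing_freq", iapp, gh)
    return {"iapp": iapp.tolist(), "gh": gh.tolist(),
            "resting_V": rest.values.filled(np.nan).tolist(),
            "firing_freq": freq.values.filled(np.nan).tolist()}


def _fig4(cfg: ExperimentConfig) -> dict:
    """CV of ISIs vs gh (and vs D) at Iapp = 0.17."""
    o = cfg.options
    n_isis = o.get("n_isis", 2000)
    iapp = o.get("Iapp", 0.17)
    out = {}
    for gh in o.get("gh_values", (0.0, 0.02)):
        for D in o.get("D_values", (0.2,)):
            p = cfg.model_params(Iapp=iapp, gh=gh)
            s = isi_cv(p, NoiseSpec(D=D, seed=cfg.seed), n_isis)
            out[f"gh={gh},D={D}"] = {"mean_ms": s.mean, "std_ms": s.std,
                                     "cv": s.cv, "n": s.n}
    return out


def _fig5(cfg: ExperimentConfig) -> dict:
    """ISI histograms with and without I_h at Iapp = 0.17, D = 0.2."""
    from .spike_stats import collect_isis

    o = cfg.options
    n_isis = o.get("n_isis", 2000)
    bin_w = o.get("bin_width", 10.0)
    out = {}
    for gh in o.get("gh_values", (0.0, 0.02)):
        p = cfg.model_params(Iapp=o.get("Iapp", 0.17), gh=gh)
        isis = collect_isis(p, NoiseSpec(D=o.get("D", 0.2), seed=cfg.seed), n_isis)
        counts, edges = isi_histogram(isis, bin_w)
        out[f"gh={gh}"] = {"bin_left_ms": edges[:-1].tolist(),
                           "count": counts.tolist(),
                           "peak_count": int(counts.max())}
    return out


def _resonance_family(cfg: ExperimentConfig, iapp: float, gh_values) -> dict:
    o = cfg.options
    zap = ZapSpec(T=o.get("T", 20.0))
    out = {}
    for gh in gh_values:
        p = cfg.model_params(Iapp=iapp, gh=gh)
        prof = zap_impedance(p, zap)
        out[f"gh={gh}"] = {"f_peak_Hz": prof.f_peak, "Z_peak": prof.Z_peak,
                           "Z_low": prof.Z_low, "class": prof.resonance_class}
    return out


def _fig6(cfg: ExperimentConfig) -> dict:
    """Resonance families at Iapp = -0.05 and -0.3."""
    o = cfg.options
    return {
        "Iapp=-0.05": _resonance_family(cfg, -0.05, o.get("gh_values_a", (0.05, 0.04, 0.03, 0.02, 0.0))),
        "Iapp=-0.3": _resonance_family(cfg, -0.3, o.get("gh_values_b", (0.12, 0.1, 0.08, 0.06, 0.0))),
    }


def _fig7(cfg: ExperimentConfig) -> dict:
    """Resonance family at Iapp = 0.08 (no typical resonance)."""
    o = cfg.options
    return {"Iapp=0.08": _resonance_family(cfg, 0.08, o.get("gh_values", (0.02, 0.01, 0.0)))}


def _fig8(cfg: ExperimentConfig) -> dict:
    """One-parameter diagrams in gh at Iapp = 0.08 and -0.05, with the
    printed bifurcation values recomputed (SNIC/NF at 0.08; NF, BHom, SubH,
    SN at -0.05)."""
    o = cfg.options
    out = {}
    # Iapp = 0.08: SNIC fold and NF transition
    d8 = sweep_1d(0.08, gh_range=o.get("gh_range_a", (0.0, 0.05)),
                  n_grid=o.get("n_grid", 101))
    folds = fold_points_gh(0.08)
    out["Iapp=0.08"] = {
        "fold_gh": folds[0].gh,
        "fold_kind": classify_fold_global(0.08, folds[0].gh),
        "NF_gh": nf_gh(0.08, (0.01, 0.02)).gh,
        "points": [(bp.kind, bp.gh) for bp in d8.points],
    }
    # Iapp = -0.05: NF, BHom, SubH, SN
    folds = fold_points_gh(-0.05)
    hopf = hopf_gh(-0.05, (0.055, folds[0].gh))
    out["Iapp=-0.05"] = {
        "NF_gh": nf_gh(-0.05, (0.04, 0.05)).gh,
        "BHom_gh": locate_cycle_boundary(-0.05, 0.07, 0.055),
        "SubH_gh": hopf.gh,
        "SubH_kind": classify_hopf(-0.05, hopf.gh),
        "SN_gh": folds[0].gh,
        "SN_kind": classify_fold_global(-0.05, folds[0].gh),
    }
    return out


def _fig9(cfg: ExperimentConfig) -> dict:
    """Two-parameter curves and the codim-2 points (BT, SNHO, T)."""
    o = cfg.options
    bt = locate_codim2("BT")
    snho = locate_codim2("SNHO")
    res = {"BT": {"Iapp": bt.Iapp, "gh": bt.gh},
           "SNHO": {"Iapp": snho.Iapp, "gh": snho.gh}}
    if o.get("locate_T", True):
        tpt = locate_codim2("T")
        res["T"] = {"Iapp": tpt.Iapp}
    if o.get("trace_curves", False):
        sn = trace_curve_2d("SN", np.arange(*o.get("sn_range", (0.02, 0.14, 0.005))))
        hopf = trace_curve_2d("Hopf", np.arange(*o.get("hopf_range", (-0.3, 0.04, 0.01))),
                              seed_gh=None)
        res["SN_curve"] = sn.points.tolist()
        res["Hopf_curve"] = hopf.points.tolist()
    return res


def _fig10(cfg: ExperimentConfig) -> dict:
    """Damped-oscillation frequency of the perturbed focus vs node, against
    the eigenvalue prediction |Im lambda| / 2 pi."""
    from .bifurcation import find_equilibria

    o = cfg.options
    out = {}
    for gh in o.get("gh_values", (0.05, 0.01)):
        p = cfg.model_params(Iapp=o.get("Iapp", -0.05), gh=gh)
        eq = min([e for e in find_equilibria(p) if e.is_stable], key=lambda e: e.V)
        x0 = eq.state.copy()
        x0[0] += o.get("perturbation_mV", 2.0)
        tr = integrate(p, x0=x0, t_end=o.get("t_end", 3000.0), record_dt=0.1)
        fhat = damped_frequency(tr)
        im = np.abs(eq.eigenvalues.imag).max()
        out[f"gh={gh}"] = {
            "etype": eq.etype,
            "damped_freq_Hz": fhat,
            "eigen_freq_Hz": float(im / (2 * np.pi) * 1000.0) if im > 0 else None,
        }
    return out


def _fig11(cfg: ExperimentConfig) -> dict:
    """ZAP-response envelope (peak-to-peak V) vs gh at fixed Iapp."""
    o = cfg.options
    zap = ZapSpec(T=o.get("T", 20.0))
    out = {}
    for iapp, ghs in o.get("families", {-0.05: (0.0, 0.02, 0.04, 0.05),
                                        0.08: (0.0, 0.01, 0.02)}).items():
        env = {}
        for gh in ghs:
            p = cfg.model_params(Iapp=float(iapp), gh=gh)
            tr, _ = zap_response(p, zap)
            env[f"gh={gh}"] = zap_envelope(tr)
        out[f"Iapp={iapp}"] = env
    return out


def _fig12_13(cfg: ExperimentConfig) -> dict:
    """Normalized mean and STD of ISIs vs gh: the STD falls faster than the
    mean, which is what drives the CV down with increasing gh."""
    o = cfg.options
    out = {}
    n_isis = o.get("n_isis", 500)
    for (iapp, D) in o.get("cases", ((0.17, 0.6), (-0.08, 0.2))):
        ghs = np.asarray(o.get("gh_values", (0.0, 0.01, 0.02, 0.03)))
        means, stds = [], []
        for gh in ghs:
            p = cfg.model_params(Iapp=iapp, gh=gh)
            s = isi_cv(p, NoiseSpec(D=D, seed=cfg.seed), n_isis)
            means.append(s.mean)
            stds.append(s.std)
        means = np.asarray(means)
        stds = np.asarray(stds)
        out[f"Iapp={iapp},D={D}"] = {
            "gh": ghs.tolist(),
            "mean_ms": means.tolist(), "std_ms": stds.tolist(),
            "norm_mean": (means / means[0]).tolist(),
            "norm_std": (stds / stds[0]).tolist(),
        }
    return out


EXPERIMENTS = {
    "fig1": _fig1, "fig2": _fig2, "fig3": _fig3, "fig4": _fig4,
    "fig5": _fig5, "fig6": _fig6, "fig7": _fig7, "fig8": _fig8,
    "fig9": _fig9, "fig10": _fig10, "fig11": _fig11, "fig12_13": _fig12_13,
}


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Dispatch a configured experiment; optionally write results + manifest.

    The summary dict contains every quantitative output the experiment
    produces.  When ``cfg.outdir`` is set, writes ``summary.json`` and
    ``manifest.json`` (resolved config, package version, seed) there.
    """
    if cfg.experiment == "custom":
        raise ValueError("custom experiments are driven through the library API")
    try:
        driver = EXPERIMENTS[cfg.experiment]
    except KeyError:
        raise ValueError(
            f"unknown experiment {cfg.experiment!r}; valid: {sorted(EXPERIMENTS)}"
        ) from None
    summary = driver(cfg)
    if cfg.outdir is not None:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        manifest = {"experiment": cfg.experiment, "params": cfg.params,
                    "options": cfg.options, "seed": cfg.seed,
                    "version": __version__}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return summary
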