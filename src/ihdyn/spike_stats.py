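"""Interspike-interval statistics, first-spike jitter and (Iapp, gh) maps.

The spike-timing-precision measure throughout is the coefficient of
variation CV = STD(ISI) / mean(ISI) over N = 2000 intervals of the noisy
firing (sample standard deviation, n-1 denominator), after a 500 ms
transient discard.  First-spike jitter is the across-trial STD of the time
of the first spike evoked by a current ramp from rest, measured from ramp
onset, over independent noise streams (seed + trial index).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ModelParameters
from .simulate import SpikeTrain, run_spikes, settle_to_equilibrium, NoRestingStateError
from .stimulus import NoiseSpec, Ramp

__all__ = [
    "ISIStats", "FirstSpikeEnsemble", "ParamMap",
    "isi_stats", "collect_isis", "isi_cv", "first_spike_ensemble",
    "isi_histogram", "param_map", "InsufficientSpikesError",
]

TRANSIENT_MS = 500.0
N_ISI_DEFAULT = 2000


class InsufficientSpikesError(RuntimeError):
    """Fewer spikes than required for the requested statistic."""


@dataclass
class ISIStats:
    n: int
    mean: float      # ms
    std: float       # ms
    cv: float

    @property
    def sem_cv(self) -> float:
        """Rough Monte-Carlo standard error of the CV estimate (delta
        method, treating ISIs as i.i.d.)."""
        return self.cv * np.sqrt((1.0 + 2.0 * self.cv ** 2) / (2.0 * self.n))


@dataclass
class FirstSpikeEnsemble:
    times: np.ndarray        # first-spike times from ramp onset, ms
    n_trials: int
    n_failed: int            # trials with no spike in the window (excluded)

    @property
    def mean(self) -> float:
        return float(np.mean(self.times))

    @property
    def std(self) -> float:
        return float(np.std(self.times, ddof=1))


@dataclass
class ParamMap:
    kind: str                # resting_V | firing_freq | cv
    iapp: np.ndarray
    gh: np.ndarray
    values: np.ndarray       # masked array, shape (len(gh), len(iapp))


def isi_stats(st: SpikeTrain | np.ndarray, n_target: int | None = None) -> ISIStats:
    """ISI statistics from a spike train (or raw ISI array).

    When ``n_target`` is given, exactly the first ``n_target`` ISIs are used
    and fewer available intervals raise :class:`InsufficientSpikesError`.
    """
    if isinstance(st, SpikeTrain):
        isis = st.isis()
    else:
        isis = np.asarray(st, dtype=float)
    if n_target is not None:
        if len(isis) < n_target:
            raise InsufficientSpikesError(
                f"need {n_target} ISIs, have {len(isis)}")
        isis = isis[:n_target]
    if len(isis) < 2:
        raise InsufficientSpikesError("need at least 2 ISIs")
    mean = float(np.mean(isis))
    std = float(np.std(isis, ddof=1))
    return ISIStats(n=len(isis), mean=mean, std=std, cv=std / mean)


def collect_isis(p: ModelParameters, noise: NoiseSpec,
                 n_isis: int = N_ISI_DEFAULT, transient: float = TRANSIENT_MS,
                 dt: float = 0.001, mean_isi_guess: float = 300.0,
                 x0=None) -> np.ndarray:
    """Run the stochastic model long enough to collect ``n_isis`` intervals
    after the transient discard; returns the ISI array.

    The run length is sized from ``mean_isi_guess`` with half-length growth
    retries, and the streaming spike kernel stops as soon as enough spikes
    are banked, so the guess only affects the allocation, not the result.
    """
    if x0 is None:
        try:
            x0 = settle_to_equilibrium(p)
        except NoRestingStateError:
            x0 = np.array([-55.0, 0.6, 0.2, 0.2])
    need = n_isis + 1
    guess = mean_isi_guess
    for _ in range(6):
        t_end = transient + 1.6 * need * guess
        st, _ = run_spikes(p, x0=x0, t_end=t_end, dt=dt, noise=noise,
                           max_spikes=int(need + transient / guess + 200))
        kept = st.spike_times[st.spike_times >= transient]
        if len(kept) >= need:
            return np.diff(kept[:need])
        if len(kept) >= 3:
            guess = float(np.mean(np.diff(kept)))
        else:
            guess *= 3.0
    raise InsufficientSpikesError(
        f"could not collect {n_isis} ISIs at Iapp={p.Iapp}, gh={p.gh}, D={noise.D}")


def isi_cv(p: ModelParameters, noise: NoiseSpec, n_isis: int = N_ISI_DEFAULT,
           **kw) -> ISIStats:
    """Convenience: collect ISIs and return their statistics."""
    return isi_stats(collect_isis(p, noise, n_isis, **kw), n_target=n_isis)


def first_spike_ensemble(p: ModelParameters, ramp_rate: float,
                         noise: NoiseSpec, n_trials: int = 1000,
                         onset: float = 0.0, t_max: float = 400.0,
                         dt: float = 0.001) -> FirstSpikeEnsemble:
    """First-spike times over independent ramp trials.

    Each trial starts from the deterministic resting state and uses noise
    stream ``seed + trial``; trials without a spike inside ``t_max`` ms are
    counted and excluded from the statistics.
    """
    x0 = settle_to_equilibrium(p)
    ramp = Ramp(rate=ramp_rate, onset=onset)
    times = []
    failed = 0
    for trial in range(n_trials):
        ns = NoiseSpec(D=noise.D, seed=noise.seed + trial)
        st, _ = run_spikes(p, proto=ramp, x0=x0, t_end=onset + t_max, dt=dt,
                           noise=ns, max_spikes=1)
        if len(st) == 0:
            failed += 1
            continue
        times.append(st.spike_times[0] - onset)
    return FirstSpikeEnsemble(times=np.asarray(times), n_trials=n_trials,
                              n_failed=failed)


def isi_histogram(isis, bin_width: float = 5.0):
    """Histogram of ISIs with fixed bin width (ms); returns (counts, edges)."""
    isis = np.asarray(isis, dtype=float)
    if isis.size == 0:
        raise ValueError("no ISIs to histogram")
    hi = np.ceil(isis.max() / bin_width) * bin_width
    edges = np.arange(0.0, hi + bin_width, bin_width)
    counts, edges = np.histogram(isis, bins=edges)
    return counts, edges


def param_map(kind: str, iapp_grid, gh_grid,
              noise: NoiseSpec | None = None,
              base: ModelParameters | None = None,
              n_isis: int = 200, dt: float = 0.001,
              det_window: float = 3000.0) -> ParamMap:
    """Map of resting potential, deterministic firing frequency, or CV over
    the (Iapp, gh) plane.

    Cells where the requested behaviour is absent are masked: resting-V maps
    mask the firing-only region, firing/CV maps mask the resting region.
    Firing frequency is 1000 / mean ISI of the deterministic model; CV needs
    ``noise`` and uses ``n_isis`` intervals per cell (keep grids coarse —
    every cell is a stochastic run).
    """
    from .bifurcation import find_equilibria

    base = base if base is not None else ModelParameters()
    iapp_grid = np.asarray(iapp_grid, dtype=float)
    gh_grid = np.asarray(gh_grid, dtype=float)
    vals = np.ma.masked_all((len(gh_grid), len(iapp_grid)))
    for j, iapp in enumerate(iapp_grid):
        for i, gh in enumerate(gh_grid):
            p = base.with_(Iapp=iapp, gh=gh)
            eqs = [e for e in find_equilibria(p) if e.is_stable]
            if kind == "resting_V":
                if eqs:
                    vals[i, j] = min(eqs, key=lambda e: e.V).V
                continue
            # firing-side quantities: run the deterministic model from a
            # suprathreshold state and ask whether firing sustains
            x0 = np.array([-55.0, 0.6, 0.2, 0.2])
            st, _ = run_spikes(p, x0=x0, t_end=det_window, dt=dt)
            kept = st.spike_times[st.spike_times >= TRANSIENT_MS]
            sustained = len(kept) >= 3 and kept[-1] > det_window - 1000.0
            if eqs and not sustained:
                continue
            if kind == "firing_freq":
                if sustained:
                    vals[i, j] = 1000.0 / float(np.mean(np.diff(kept)))
            elif kind == "cv":
                if noise is None:
                    raise ValueError("cv maps need a NoiseSpec")
                if not sustained and eqs:
                    continue
                try:
                    s = isi_cv(p, noise, n_isis, dt=dt,
                               mean_isi_guess=float(np.mean(np.diff(kept)))
                               if sustained else 300.0)
                    vals[i, j] = s.cv
                except InsufficientSpikesError:
                    pass
            else:
                raise ValueError(f"unknown map kind {kind!r}")
    return ParamMap(kind=kind, iapp=iapp_grid, gh=gh_grid, values=vals)
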