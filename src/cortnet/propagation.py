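"""Seizure propagation on cascading networks of cortical columns.

Each node (a single-layer column) rests either at the zero fixed point
(low-amplitude background) or on its stable limit cycle (high-amplitude
activity, the proxy for electrographic seizure).  A seizing node drifts a
connected quiet node's amplitude distribution at the Fokker–Planck rate

    mu(t) = mu(0) - h * cos(delta_phi) * t,

so the expected transition (onset) delay over a single link is
``distance / (-h cos(delta_phi))`` with ``distance`` the gap from the
resting state to the limit-cycle attractor.  The network is *cascading*:
nodes recruited later never project back onto nodes recruited earlier,
which supports onset propagation (not termination).

Onset-time data come from the full stochastic simulator; the analytic
drift model above is the fast forward map used for inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import KernelSpec
from .reduction import find_stationary_amplitudes, AmplitudeFlowModel
from .specs import ColumnSpec, NetworkSpec, PopulationSpec, SimConfig, _has_cycle
from .simulate import simulate_batch

__all__ = [
    "CascadeNetwork",
    "OnsetTable",
    "DriftSummary",
    "drift_mean",
    "transition_time",
    "detect_onset",
    "simulate_cascade",
    "onset_statistics",
    "predict_onset_times",
    "measure_drift_slope",
    "transition_fraction",
]


@dataclass(frozen=True)
class CascadeNetwork:
    """A cascading network of bistable single-layer columns.

    ``h[j, k]`` couples node k onto node j (amplitude-per-time units;
    excitatory links are negative because the P-type drive kernel is
    negative near the origin).  ``phase_lags[j, k]`` is the lag
    phi_j - phi_k gating the link; the default all-zero lags reflect the
    rapid phase synchronization that excitatory connections produce.

    ``omega``, ``p_scale``, ``p_self`` and ``kernel`` fix the intrinsic
    single-node dynamics; ``distance`` is how far the mean must drift for
    a detected transition.  The default is the half-amplitude point
    R_s/2, used both as the onset-detection threshold and as the forward
    model's drift distance: with the commitment point at half amplitude,
    the head start a child gains from drive during its parent's
    subthreshold ramp cancels the remaining half of the climb exactly
    (for a linear ramp), so the piecewise-linear onset model is unbiased
    with respect to the detected onsets.
    """

    h: np.ndarray
    onset_node: int = 0
    mu0: float = 0.0
    phase_lags: np.ndarray | None = None
    omega: float = 2.0 * np.pi
    p_scale: float = 0.01
    p_self: float = 1.0
    kernel: KernelSpec = field(default_factory=KernelSpec)
    distance: float | None = None

    def __post_init__(self) -> None:
        h = np.asarray(self.h, dtype=float)
        if h.ndim != 2 or h.shape[0] != h.shape[1]:
            raise ValueError("h must be a square matrix")
        if np.any(np.diag(h) != 0):
            raise ValueError("h is extrinsic: diagonal must be zero")
        if _has_cycle((h != 0).T):  # edge k -> j for h[j, k] != 0
            raise ValueError("cascade violation: connectivity graph has a cycle")
        object.__setattr__(self, "h", h)
        n = h.shape[0]
        if not 0 <= self.onset_node < n:
            raise ValueError(f"onset_node {self.onset_node} out of range")
        lags = (np.zeros((n, n)) if self.phase_lags is None
                else np.asarray(self.phase_lags, dtype=float))
        if lags.shape != (n, n):
            raise ValueError("phase_lags must match h's shape")
        object.__setattr__(self, "phase_lags", lags)
        if self.distance is None:
            sset = find_stationary_amplitudes(self.flow_model())
            object.__setattr__(self, "distance", 0.5 * sset.R_s)
        if self.distance <= 0:
            raise ValueError("distance must be > 0")

    @property
    def n_nodes(self) -> int:
        return self.h.shape[0]

    def flow_model(self) -> AmplitudeFlowModel:
        return AmplitudeFlowModel(kernel=self.kernel, omega=self.omega,
                                  p_scale=self.p_scale, p_self=self.p_self)

    def to_network_spec(self) -> NetworkSpec:
        """Full neural-mass network: one single-population column per node."""
        col = ColumnSpec(
            populations=(PopulationSpec(self.omega),),
            s_mat=np.zeros((1, 1)),
            p_mat=np.array([[self.p_self]]),
            eps=0.0,
            p_scale=self.p_scale,
            kernel=self.kernel,
        )
        return NetworkSpec(columns=(col,) * self.n_nodes,
                           h=self.h[None, :, :], cascading=True)


def drift_mean(mu0: float, h_val: float, delta_phi: float,
               t: float | np.ndarray) -> float | np.ndarray:
    """Mean displacement mu(t) = mu0 - h*cos(delta_phi)*t of the driven amplitude."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = mu0 - h_val * np.cos(delta_phi) * t
    return float(out) if out.ndim == 0 else out


def transition_time(h_val: float, delta_phi: float, distance: float,
                    g_val: float = 0.0, cos_tol: float = 1.0e-9) -> float:
    """Expected time for the mean to drift across ``distance``.

    ``distance / (-h*cos(delta_phi))`` when that drift is positive.  When
    the phase gate closes (|cos| below ``cos_tol``) the transition is
    carried by the intrinsic terms instead: ``distance / (-g_val)`` if
    positive.  +inf encodes "no transition".
    """
    if distance <= 0:
        raise ValueError("distance must be > 0")
    gate = np.cos(delta_phi)
    if abs(gate) >= cos_tol and h_val != 0.0:
        rate = -h_val * gate
    else:
        rate = -g_val
    return distance / rate if rate > 0 else np.inf


def detect_onset(R: np.ndarray, times: np.ndarray, r_low: float,
                 r_high: float, hold: float) -> float:
    """First time R exceeds ``r_high`` and stays above ``r_low`` for ``hold``.

    Returns NaN if no such time exists.  Near the end of the record the
    hold window is truncated to the available samples.
    """
    if not r_low < r_high:
        raise ValueError("need r_low < r_high")
    R = np.asarray(R, dtype=float)
    times = np.asarray(times, dtype=float)
    onsets = _detect_onsets_batch(R[None], times, r_low, r_high, hold)
    return float(onsets[0])


def _detect_onsets_batch(R: np.ndarray, times: np.ndarray, r_low: float,
                         r_high: float, hold: float) -> np.ndarray:
    """Vectorized onset detection on R of shape (..., n_times)."""
    n_t = R.shape[-1]
    dt = times[1] - times[0] if n_t > 1 else 1.0
    hold_n = max(int(np.ceil(hold / dt)), 1)
    ok = R >= r_low
    # run[..., i] = length of the True-run of `ok` starting at sample i
    run = np.zeros(R.shape, dtype=np.int64)
    run[..., -1] = ok[..., -1]
    for i in range(n_t - 2, -1, -1):
        run[..., i] = np.where(ok[..., i], run[..., i + 1] + 1, 0)
    needed = np.minimum(hold_n, n_t - np.arange(n_t))
    confirmed = (R > r_high) & (run >= needed)
    idx = np.argmax(confirmed, axis=-1)
    any_onset = np.take_along_axis(confirmed, idx[..., None], axis=-1)[..., 0]
    # refine the crossing below sample resolution by linear interpolation
    prev = np.maximum(idx - 1, 0)
    r_at = np.take_along_axis(R, idx[..., None], axis=-1)[..., 0]
    r_prev = np.take_along_axis(R, prev[..., None], axis=-1)[..., 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (r_high - r_prev) / (r_at - r_prev)
    frac = np.where((idx > 0) & (r_prev < r_high) & (r_at > r_prev),
                    np.clip(frac, 0.0, 1.0), 1.0)
    onset = times[prev] + frac * (times[idx] - times[prev])
    return np.where(any_onset, onset, np.nan)


def _cycle_average(R: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average over ``window`` samples along the last axis.

    Edge windows are truncated to the available samples (no zero
    padding), so a constant series is returned unchanged.
    """
    if window <= 1:
        return R
    n = R.shape[-1]
    cs = np.cumsum(R, axis=-1)
    cs = np.concatenate([np.zeros(R.shape[:-1] + (1,)), cs], axis=-1)
    half = window // 2
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + window - half, 0, n)
    return (cs[..., hi] - cs[..., lo]) / (hi - lo)


@dataclass(frozen=True)
class OnsetTable:
    """Seizure onset times, one row per trial and one column per node (NaN = none)."""

    onset: np.ndarray

    def __post_init__(self) -> None:
        o = np.atleast_2d(np.asarray(self.onset, dtype=float))
        object.__setattr__(self, "onset", o)

    @property
    def n_trials(self) -> int:
        return self.onset.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.onset.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.onset,
                          columns=[f"node_{j}" for j in range(self.n_nodes)])
        df.insert(0, "trial", np.arange(self.n_trials))
        return df

    def write_text(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="")

    @classmethod
    def read_text(cls, path) -> "OnsetTable":
        df = pd.read_csv(path, sep="\t")
        cols = [c for c in df.columns if c.startswith("node_")]
        return cls(df[cols].to_numpy(dtype=float))


@dataclass(frozen=True)
class DriftSummary:
    """Per-node drift parameters of the onset-time model.

    ``slope[j]`` is the asymptotic drift rate of node j's amplitude mean
    with every parent seizing; ``t_transit[j] = distance/slope[j]`` when
    the slope is positive, else +inf.  ``sigma`` holds the per-node onset
    dispersion when observed data are attached (NaN otherwise).
    """

    mu0: float
    slope: np.ndarray
    sigma: np.ndarray
    t_transit: np.ndarray

    @classmethod
    def from_cascade(cls, casc: CascadeNetwork,
                     table: OnsetTable | None = None) -> "DriftSummary":
        rates = -casc.h * np.cos(casc.phase_lags)
        slope = rates.sum(axis=1)
        with np.errstate(divide="ignore"):
            t_transit = np.where(slope > 0, casc.distance / slope, np.inf)
        sigma = np.full(casc.n_nodes, np.nan)
        if table is not None:
            stats = onset_statistics(table)
            sigma = stats["sd"].to_numpy()
        return cls(casc.mu0, slope, sigma, t_transit)


def simulate_cascade(
    casc: CascadeNetwork,
    cfg: SimConfig,
    n_trials: int,
    hold_periods: float = 5.0,
) -> OnsetTable:
    """Monte-Carlo onset times from the full neural-mass simulator.

    The onset node starts on its limit cycle, every other node at the
    origin; each trial uses an independent spawned noise stream.
    Detection runs on the cycle-averaged amplitude envelope (a
    one-period moving average — the amplitude variable of the adiabatic
    theory, free of the deterministic within-cycle modulation): onset is
    when the envelope crosses ``casc.distance`` (the half-amplitude
    commitment point by default, shared with the forward model's drift
    distance) and holds above half that level for ``hold_periods``
    oscillation periods.
    """
    net = casc.to_network_spec()
    sset = find_stationary_amplitudes(casc.flow_model())
    z0 = np.zeros((casc.n_nodes, 1), dtype=complex)
    z0[casc.onset_node, 0] = sset.R_s
    times, z = simulate_batch(net, cfg, z0, n_trials)
    R = np.moveaxis(np.abs(z[:, :, :, 0]), 1, 2)    # (trial, node, time)
    period = 2.0 * np.pi / casc.omega
    dt_rec = times[1] - times[0] if times.size > 1 else period
    R_env = _cycle_average(R, int(round(period / dt_rec)))
    hold = hold_periods * period
    onsets = _detect_onsets_batch(
        R_env, times, r_low=0.5 * casc.distance, r_high=casc.distance, hold=hold,
    )
    return OnsetTable(onsets)


def onset_statistics(tab: OnsetTable) -> pd.DataFrame:
    """Per-node mean, sd and missing count of observed onsets."""
    import warnings

    o = tab.onset
    with warnings.catch_warnings():
        # all-missing nodes are reported as NaN with a flag, not warned about
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(o, axis=0)
        sd = np.nanstd(o, axis=0, ddof=1)
    n_missing = np.isnan(o).sum(axis=0)
    all_missing = n_missing == tab.n_trials
    return pd.DataFrame({
        "node": np.arange(tab.n_nodes),
        "mean": np.where(all_missing, np.nan, mean),
        "sd": np.where(all_missing, np.nan, sd),
        "n_missing": n_missing,
        "all_missing": all_missing,
    })


def predict_onset_times(casc: CascadeNetwork, h: np.ndarray | None = None) -> np.ndarray:
    """Expected onset time per node from the piecewise-linear drift model.

    A node starts drifting when its first parent seizes; while parents
    {k} are seizing its mean moves at ``sum_k -h[j,k]*cos(lag_jk)``
    (drifts from simultaneously seizing parents add linearly).  The onset
    is the earliest time the mean reaches ``distance``; unreachable nodes
    get +inf.  Events are fixed in chronological order, which is exact
    for a cascading (acyclic) network.
    """
    h = casc.h if h is None else np.asarray(h, dtype=float)
    n = casc.n_nodes
    rates = -h * np.cos(casc.phase_lags)            # rates[j, k]: k seizing -> dmu_j/dt
    T = np.full(n, np.inf)
    T[casc.onset_node] = 0.0
    fixed = {casc.onset_node}
    for _ in range(n - 1):
        best_j, best_t = None, np.inf
        for j in range(n):
            if j in fixed:
                continue
            parents = [k for k in fixed if rates[j, k] != 0.0]
            if not parents:
                continue
            t_j = _first_crossing(casc.mu0, casc.distance,
                                  [(T[k], rates[j, k]) for k in parents])
            if t_j < best_t:
                best_j, best_t = j, t_j
        if best_j is None:
            break
        T[best_j] = best_t
        fixed.add(best_j)
    return T


def _first_crossing(mu0: float, distance: float,
                    events: list[tuple[float, float]]) -> float:
    """Earliest t with mu0 + sum_k rate_k*max(0, t - t_k) >= distance."""
    events = sorted(events)
    mu = mu0
    rate = 0.0
    for seg in range(len(events)):
        t_start, r_new = events[seg]
        if seg > 0:
            dt_seg = t_start - events[seg - 1][0]
            mu += rate * dt_seg
        rate += r_new
        t_end = events[seg + 1][0] if seg + 1 < len(events) else np.inf
        if rate > 0:
            t_hit = t_start + (distance - mu) / rate
            if mu >= distance:
                return t_start
            if t_hit <= t_end:
                return t_hit
    return np.inf


def _two_column_net(h_val: float, omega: float, p_scale_driver: float,
                    p_scale_driven: float, kernel: KernelSpec) -> NetworkSpec:
    """Driver (col 0) -> driven (col 1) single-layer pair, no feedback."""
    def col(ps: float) -> ColumnSpec:
        return ColumnSpec(populations=(PopulationSpec(omega),),
                          s_mat=np.zeros((1, 1)), p_mat=np.ones((1, 1)),
                          p_scale=ps, kernel=kernel)
    H = np.zeros((1, 2, 2))
    H[0, 1, 0] = h_val
    return NetworkSpec(columns=(col(p_scale_driver), col(p_scale_driven)), h=H)


def measure_drift_slope(
    h_val: float,
    delta_phi: float,
    n_trials: int = 200,
    seed: int = 0,
    noise_sigma: float = 0.05,
    omega: float = 2.0 * np.pi,
    p_scale_driver: float = 0.05,
    p_scale_driven: float = 0.002,
    dt: float = 1.0e-4,
    n_cycles: int = 2,
    kernel: KernelSpec | None = None,
) -> tuple[float, float]:
    """Monte-Carlo slope of the driven column's mean amplitude at a clamped lag.

    The driver sits on its limit cycle; the driven column starts at the
    mid-well amplitude R_s/2 (so negative drifts are measurable: the
    amplitude is nonnegative) with only a weak intrinsic self-coupling,
    honouring the regime where the extrinsic drive dominates the
    intrinsic terms.  The phase lag is pinned every step.  Each trial's
    drift slope is the difference of consecutive cycle-averaged
    amplitudes; returns the trial mean and its Monte-Carlo standard
    error.  The reduced theory predicts a slope of -h*cos(delta_phi).
    """
    kernel = kernel or KernelSpec()
    net = _two_column_net(h_val, omega, p_scale_driver, p_scale_driven, kernel)
    sset = find_stationary_amplitudes(
        AmplitudeFlowModel(kernel=kernel, omega=omega, p_scale=p_scale_driver))
    period = 2.0 * np.pi / omega
    samples_per_cycle = 100
    stride = max(int(round(period / samples_per_cycle / dt)), 1)
    cfg = SimConfig(dt=dt, t_end=(n_cycles + 0.001) * period,
                    noise_sigma=noise_sigma, seed=seed, record_stride=stride)
    z0 = np.array([[sset.R_s], [0.5 * sset.R_s]], dtype=complex)
    times, z = simulate_batch(net, cfg, z0, n_trials,
                              clamp=(0, 1, delta_phi))
    R = np.abs(z[:, :, 1, 0])
    n_per = int(round(period / (times[1] - times[0])))
    cyc = R[:, :n_cycles * n_per].reshape(n_trials, n_cycles, n_per).mean(axis=2)
    slopes = (cyc[:, -1] - cyc[:, 0]) / ((n_cycles - 1) * period)
    return float(slopes.mean()), float(slopes.std(ddof=1) / np.sqrt(n_trials))


def transition_fraction(
    h_val: float,
    delta_phi: float,
    horizon: float = 15.0,
    n_trials: int = 20,
    seed: int = 0,
    noise_sigma: float = 0.05,
    omega: float = 2.0 * np.pi,
    p_scale: float = 0.05,
    dt: float = 1.0e-3,
    kernel: KernelSpec | None = None,
) -> float:
    """Fraction of trials in which the driven column transitions to its limit cycle.

    Fixed-lag experiment: the driver oscillates on its limit cycle with
    no feedback, the driven bistable column starts at the origin, and
    the lag is pinned every step.  A transition is an onset of the
    cycle-averaged envelope past the half-amplitude commitment point
    within the horizon.  Phase-gating: for excitatory (negative) h the
    fraction is maximal at lag 0 and vanishes at lag pi; flipping the
    sign of h reverses the gating; at h = 0 there is no transition on
    this horizon.
    """
    kernel = kernel or KernelSpec()
    net = _two_column_net(h_val, omega, p_scale, p_scale, kernel)
    sset = find_stationary_amplitudes(
        AmplitudeFlowModel(kernel=kernel, omega=omega, p_scale=p_scale))
    period = 2.0 * np.pi / omega
    stride = max(int(round(period / 50 / dt)), 1)
    cfg = SimConfig(dt=dt, t_end=horizon, noise_sigma=noise_sigma, seed=seed,
                    record_stride=stride)
    z0 = np.array([[sset.R_s], [0.0]], dtype=complex)
    times, z = simulate_batch(net, cfg, z0, n_trials, clamp=(0, 1, delta_phi))
    R = np.abs(z[:, :, 1, 0])
    R_env = _cycle_average(R, int(round(period / (times[1] - times[0]))))
    threshold = 0.5 * sset.R_s
    onsets = _detect_onsets_batch(R_env, times, r_low=0.5 * threshold,
                                  r_high=threshold, hold=5.0 * period)
    return float(np.mean(np.isfinite(onsets)))
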