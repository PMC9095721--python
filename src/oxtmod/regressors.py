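"""Kernel-convolved stimulus and motor regressors, and trace correlation.

A regressor is the fluorescence time course predicted for a neuron that
fires at stimulus (or movement) times: an event indicator convolved with
the calcium-indicator impulse response. Tuning is then scored as the
zero-lag Pearson correlation between each neuron's smoothed dF/F trace and
each regressor; the kernel's onset delay makes an explicit lag search
redundant.

The GCaMP6s kernel is a delayed single exponential parameterised by its
response delay (0.48 s) and decay time constant (3 s), normalised to unit
peak::

    h(t) = 0                              t < delay
    h(t) = exp(-(t - delay) / tau_decay)  t >= delay
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import StimulusSchedule, TraceSet

__all__ = [
    "KernelParams",
    "RegressorBank",
    "gcamp_kernel",
    "kernel_value",
    "event_response",
    "build_stimulus_regressor",
    "build_motor_regressors",
    "correlate",
]


@dataclass(frozen=True)
class KernelParams:
    """GCaMP6s impulse-response parameters (seconds)."""

    delay: float = 0.48
    tau_decay: float = 3.0
    normalization: str = "unit_peak"

    def __post_init__(self) -> None:
        if self.delay < 0:
            raise ValueError("delay must be >= 0")
        if self.tau_decay <= 0:
            raise ValueError("tau_decay must be > 0")
        if self.normalization != "unit_peak":
            raise ValueError("only unit_peak normalization is supported")


def kernel_value(t, params: KernelParams = KernelParams()) -> np.ndarray:
    """Closed-form kernel h(t); vectorised over ``t``."""
    t = np.asarray(t, dtype=float)
    out = np.where(
        t >= params.delay, np.exp(-(np.maximum(t - params.delay, 0.0)) / params.tau_decay), 0.0
    )
    return out


def gcamp_kernel(params: KernelParams, dt: float, length: float) -> np.ndarray:
    """Sample the kernel on ``t = 0, dt, 2*dt, ... < length``.

    ``length >= delay + 5 * tau_decay`` is recommended so the tail is
    negligible. Peak value is 1 whenever the grid contains a point at or
    just after the delay (the exponential is maximal at ``t = delay``).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    t = np.arange(0.0, length, dt)
    return kernel_value(t, params)


def _kernel_grid(params: KernelParams, dt: float) -> np.ndarray:
    length = params.delay + 8.0 * params.tau_decay
    return gcamp_kernel(params, dt, length)


def event_response(
    onsets: np.ndarray,
    durations: np.ndarray,
    frame_times: np.ndarray,
    params: KernelParams = KernelParams(),
    dt_fine: float | None = None,
) -> np.ndarray:
    """Unit-peak kernel response to a set of events, sampled at frame times.

    Events are rendered on a fine internal grid as boxcars (height 1 over
    [onset, onset + duration)); events shorter than one fine-grid step —
    e.g. a 100-ms UV pulse — become single-sample impulses. The indicator
    is convolved with the kernel, linearly interpolated onto the frame
    timebase, and rescaled to unit peak. Returns all zeros if there are no
    events (callers flag such regressors unusable).

    Construction is relative to ``frame_times[0]``, so shifting the whole
    timebase by a constant shifts the response identically.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    durations = np.broadcast_to(np.asarray(durations, dtype=float), onsets.shape)
    if onsets.size == 0:
        return np.zeros_like(frame_times)

    if dt_fine is None:
        dt_fine = min(0.05, float(np.median(np.diff(frame_times))) / 2.0) if len(frame_times) > 1 else 0.05
    t0 = frame_times[0]
    span = frame_times[-1] - t0 + params.delay + 8.0 * params.tau_decay
    n_fine = int(np.ceil(span / dt_fine)) + 1
    indicator = np.zeros(n_fine)
    for onset, dur in zip(onsets, durations):
        i0 = int(round((onset - t0) / dt_fine))
        if i0 >= n_fine or i0 < 0 and i0 + max(dur, 0) / dt_fine < 0:
            continue
        if dur < dt_fine:
            if 0 <= i0 < n_fine:
                indicator[i0] = 1.0
        else:
            i1 = int(round((onset + dur - t0) / dt_fine))
            indicator[max(i0, 0) : min(max(i1, 0), n_fine)] = 1.0

    kern = _kernel_grid(params, dt_fine)
    resp_fine = np.convolve(indicator, kern)[:n_fine]
    fine_t = t0 + np.arange(n_fine) * dt_fine
    resp = np.interp(frame_times, fine_t, resp_fine)
    peak = resp.max()
    if peak > 0:
        resp = resp / peak
    return resp


@dataclass
class RegressorBank:
    """Named regressors on a common timebase plus correlation results.

    ``flags`` marks regressors unusable for correlation (all-zero, e.g.
    an empty motor category); their correlations are reported as 0 and
    flagged degenerate.
    """

    regressors: dict[str, np.ndarray]
    frame_times: np.ndarray
    flags: dict[str, bool] = field(default_factory=dict)
    corr: pd.DataFrame | None = None
    degenerate: pd.DataFrame | None = None

    def usable(self, name: str) -> bool:
        return self.flags.get(name, True)

    def names(self) -> list[str]:
        return list(self.regressors)

    def matrix(self) -> np.ndarray:
        return np.vstack([self.regressors[n] for n in self.regressors])

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.regressors)
        out.insert(0, "time_s", self.frame_times)
        return out


def build_stimulus_regressor(
    schedule: StimulusSchedule,
    label: str,
    timebase: np.ndarray,
    params: KernelParams = KernelParams(),
    allow_empty: bool = False,
) -> np.ndarray:
    """Boxcar(onset -> onset+duration) x kernel, unit peak, on ``timebase``."""
    ev = schedule.events[schedule.events["label"] == label]
    if ev.empty:
        if allow_empty:
            return np.zeros_like(np.asarray(timebase, dtype=float))
        raise ValueError(f"no events with label {label!r}")
    return event_response(
        ev["onset_s"].to_numpy(), ev["duration_s"].to_numpy(), timebase, params
    )


def build_motor_regressors(
    bouts: pd.DataFrame,
    schedule: StimulusSchedule,
    timebase: np.ndarray,
    params: KernelParams = KernelParams(),
    stim_window: float = 5.0,
    angle_cut: float = 50.0,
    stim_label: str = "uv_trpa1",
) -> tuple[dict[str, np.ndarray], dict[str, bool]]:
    """Impulse trains at bout onsets, split by stimulus association and size.

    A bout is ``motor_stim`` if its onset falls within ``stim_window``
    seconds after any event of ``stim_label``; all other bouts are
    ``motor_spon``, further split at ``angle_cut`` degrees into
    ``motor_spon_S`` (peak angle <= cut) and ``motor_spon_L`` (> cut).
    Each train is convolved with the kernel and unit-peak normalised;
    empty categories yield zero regressors flagged unusable.
    """
    timebase = np.asarray(timebase, dtype=float)
    onsets = bouts["onset_s"].to_numpy(float) if len(bouts) else np.array([])
    peaks = bouts["peak_angle_deg"].to_numpy(float) if len(bouts) else np.array([])
    stim_onsets = schedule.onsets(stim_label)

    if onsets.size and stim_onsets.size:
        rel = onsets[:, None] - stim_onsets[None, :]
        is_stim = np.any((rel >= 0) & (rel <= stim_window), axis=1)
    else:
        is_stim = np.zeros(onsets.shape, dtype=bool)

    groups = {
        "motor_stim": onsets[is_stim],
        "motor_spon": onsets[~is_stim],
        "motor_spon_S": onsets[~is_stim & (peaks <= angle_cut)] if onsets.size else onsets,
        "motor_spon_L": onsets[~is_stim & (peaks > angle_cut)] if onsets.size else onsets,
    }
    regs: dict[str, np.ndarray] = {}
    flags: dict[str, bool] = {}
    for name, ons in groups.items():
        if ons.size == 0:
            regs[name] = np.zeros_like(timebase)
            flags[name] = False
        else:
            regs[name] = event_response(ons, np.zeros_like(ons), timebase, params)
            flags[name] = True
    return regs, flags


def correlate(t: TraceSet, bank: RegressorBank) -> pd.DataFrame:
    """Zero-lag Pearson correlation, neuron x regressor.

    Traces should be dF/F and smoothed. Constant traces and unusable
    regressors get correlation 0 with the ``bank.degenerate`` flag set.
    Raises on a frame-timebase mismatch.
    """
    if t.frame_times.shape != np.asarray(bank.frame_times).shape or not np.allclose(
        t.frame_times, bank.frame_times
    ):
        raise ValueError("trace and regressor timebases differ")

    names = bank.names()
    x = t.values
    xm = x - x.mean(axis=1, keepdims=True)
    xs = xm.std(axis=1)
    trace_const = xs == 0

    n = x.shape[1]
    corr = np.zeros((x.shape[0], len(names)))
    degen = np.zeros_like(corr, dtype=bool)
    for j, name in enumerate(names):
        r = bank.regressors[name]
        rm = r - r.mean()
        rs = rm.std()
        if not bank.usable(name) or rs == 0:
            degen[:, j] = True
            continue
        c = (xm @ rm) / (n * np.where(xs == 0, 1.0, xs) * rs)
        c[trace_const] = 0.0
        degen[trace_const, j] = True
        corr[:, j] = np.clip(c, -1.0, 1.0)

    ids = t.neuron_meta["neuron_id"].to_numpy()
    bank.corr = pd.DataFrame(corr, index=ids, columns=names)
    bank.corr.index.name = "neuron_id"
    bank.degenerate = pd.DataFrame(degen, index=ids, columns=names)
    return bank.corr
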