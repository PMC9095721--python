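"""dF/F computation, smoothing, drift subtraction, and epoch summaries.

dF/F uses the per-neuron mean fluorescence over all frames strictly before
the first stimulus as the baseline F0. Event-to-frame alignment is
causal: a window anchored at time ``a`` starts at the first frame whose
timestamp is >= ``a`` (frames are 237-711 ms, so sub-frame onsets are
unavoidable).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import EpochSpec, StimulusSchedule, TraceSet, get_epoch

__all__ = [
    "compute_dff",
    "smooth_zero_phase",
    "subtract_background",
    "stimulus_triggered_average",
    "integrate_epoch",
    "anchor_onsets",
]


def compute_dff(raw: TraceSet, schedule: StimulusSchedule) -> TraceSet:
    """dF/F = (F - F0) / F0 with F0 the pre-stimulus mean per neuron.

    The baseline window is every frame strictly before the first scheduled
    event of any type. Raises if no pre-stimulus frames exist or any
    neuron's baseline mean is non-positive.
    """
    if raw.units != "raw":
        raise ValueError("compute_dff expects raw-fluorescence input")
    t0 = schedule.first_onset()
    pre = raw.frame_times < t0
    if not pre.any():
        raise ValueError("no frames before the first stimulus onset")
    f0 = raw.values[:, pre].mean(axis=1)
    bad = np.flatnonzero(f0 <= 0)
    if bad.size:
        nid = raw.neuron_meta["neuron_id"].iloc[bad[0]]
        raise ValueError(f"non-positive baseline for neuron {nid!r}")
    dff = (raw.values - f0[:, None]) / f0[:, None]
    return raw.with_values(dff, units="dff")


def _moving_average_reflect(x: np.ndarray, window: int) -> np.ndarray:
    """Causal ``window``-point moving average on a reflect-padded trace."""
    pad = window - 1
    xp = np.concatenate([x[:, pad:0:-1], x], axis=1)
    kern = np.ones(window) / window
    out = np.empty_like(x)
    for i in range(x.shape[0]):
        out[i] = np.convolve(xp[i], kern, mode="valid")
    return out


def smooth_zero_phase(t: TraceSet, window: int = 3) -> TraceSet:
    """Forward-backward moving average (zero phase), reflect padding.

    The causal ``window``-point mean is applied forward and then backward,
    so the combined response has zero phase: symmetric features keep their
    peak positions. Output length equals input length.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window > t.n_frames:
        raise ValueError("window exceeds trace length")
    if window == 1:
        return t.with_values(t.values.copy())
    fwd = _moving_average_reflect(t.values, window)
    bwd = _moving_average_reflect(fwd[:, ::-1], window)[:, ::-1]
    return t.with_values(bwd)


def subtract_background(t: TraceSet, background_trace: np.ndarray) -> tuple[TraceSet, float]:
    """Remove linear dye-accumulation drift estimated from a background ROI.

    Nose-exposed fish absorb the photoactive dye over the recording, which
    adds a slow linear ramp to every ROI including non-indicator tissue. A
    least-squares line is fitted to the background trace; its time-varying
    component ``slope * (t - t[0])`` is subtracted from every neuron so
    each neuron keeps its own baseline level (and raw values stay
    positive). Returns the corrected traces and the fitted slope
    (fluorescence units per second).
    """
    bg = np.asarray(background_trace, dtype=float)
    if bg.shape != t.frame_times.shape:
        raise ValueError("background trace length must match the timebase")
    tt = t.frame_times
    if np.ptp(tt) == 0:
        raise ValueError("degenerate fit: constant timebase")
    slope, _intercept = np.polyfit(tt, bg, 1)
    corrected = t.values - slope * (tt - tt[0])[None, :]
    return t.with_values(corrected), float(slope)


def anchor_onsets(
    schedule: StimulusSchedule,
    label: str,
    reference: str | None = None,
) -> np.ndarray:
    """Onsets that anchor analysis windows for trials of a given cue.

    With ``reference`` None (or equal to ``label``) these are simply the
    onsets of ``label`` events. Otherwise they are the onsets of
    ``reference`` events (e.g. the UV/TRPA1 pulse) belonging to trials of
    ``label``, i.e. whose most recent preceding non-reference event has
    that label.
    """
    if reference is None or reference in ("cue", label):
        out = schedule.onsets(label)
        if out.size == 0:
            raise ValueError(f"no events with label {label!r}")
        return out
    ev = schedule.events
    refs = ev[ev["label"] == reference]
    cues = ev[ev["label"] != reference]
    if refs.empty:
        raise ValueError(f"no events with label {reference!r}")
    out = []
    for onset in refs["onset_s"]:
        prior = cues[cues["onset_s"] <= onset]
        if not prior.empty and prior["label"].iloc[-1] == label:
            out.append(float(onset))
    if not out:
        raise ValueError(f"no {reference!r} events on {label!r} trials")
    return np.asarray(out)


def _window_frames(frame_times: np.ndarray, start: float, end: float) -> slice:
    i0 = int(np.searchsorted(frame_times, start, side="left"))
    i1 = int(np.searchsorted(frame_times, end, side="left"))
    return slice(i0, i1)


def stimulus_triggered_average(
    t: TraceSet,
    schedule: StimulusSchedule,
    label: str,
    window: EpochSpec | str,
) -> dict:
    """Per-neuron mean trace across repeats, aligned to event onsets.

    Every repeat is snapped to the first frame at or after
    ``onset + offset_start`` and a fixed number of frames (window length /
    median frame interval) is taken, giving a common relative timebase.
    Returns a dict with ``rel_times``, ``per_neuron`` (neuron x rel-frame),
    ``mean`` and ``sem`` across neurons, and ``n_events``.
    """
    window = get_epoch(window)
    onsets = anchor_onsets(schedule, label, window.reference)
    dt = t.frame_interval
    n_rel = max(int(round(window.length / dt)), 1)
    stacks = []
    for onset in onsets:
        i0 = int(np.searchsorted(t.frame_times, onset + window.offset_start, side="left"))
        if i0 + n_rel > t.n_frames:
            raise ValueError("window extends past the end of the recording")
        stacks.append(t.values[:, i0 : i0 + n_rel])
    per_neuron = np.mean(stacks, axis=0)
    mean = per_neuron.mean(axis=0)
    sem = per_neuron.std(axis=0, ddof=1) / np.sqrt(per_neuron.shape[0]) if per_neuron.shape[0] > 1 else np.zeros(n_rel)
    return {
        "rel_times": window.offset_start + np.arange(n_rel) * dt,
        "per_neuron": per_neuron,
        "mean": mean,
        "sem": sem,
        "n_events": len(onsets),
    }


def integrate_epoch(
    t: TraceSet,
    schedule: StimulusSchedule,
    label: str,
    window: EpochSpec | str,
) -> pd.DataFrame:
    """Mean dF/F over the window, per neuron and per event.

    The summary statistic is the mean (not the sum) over frames with
    ``onset + offset_start <= frame_time < onset + offset_end``, so values
    stay in dF/F units and are comparable across window lengths. Returns a
    long DataFrame (neuron_id, event_onset, value); average across events
    of the same label with :func:`per_neuron_mean`.
    """
    window = get_epoch(window)
    onsets = anchor_onsets(schedule, label, window.reference)
    ids = t.neuron_meta["neuron_id"].to_numpy()
    rows = []
    for onset in onsets:
        sl = _window_frames(t.frame_times, onset + window.offset_start, onset + window.offset_end)
        if sl.stop <= sl.start:
            raise ValueError(f"empty window after frame alignment at onset {onset}")
        vals = t.values[:, sl].mean(axis=1)
        rows.append(pd.DataFrame({"neuron_id": ids, "event_onset": onset, "value": vals}))
    return pd.concat(rows, ignore_index=True)


def per_neuron_mean(integrated: pd.DataFrame) -> pd.Series:
    """Average integrated values across events, per neuron (order preserved)."""
    return integrated.groupby("neuron_id", sort=False)["value"].mean()


def normalize_to_reference(values: pd.Series, reference: pd.Series) -> pd.Series:
    """Each neuron's response divided by its own mean reference response.

    Both series are indexed by neuron_id (e.g. outputs of
    :func:`per_neuron_mean` for a cue and for control water flow). Neurons
    with a zero reference get NaN.
    """
    ref = reference.reindex(values.index)
    return values / ref.where(ref != 0)
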