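"""Bout extraction from tail-angle traces and epoch-wise bout statistics.

A bout is a discrete tail movement: a peak in |cumulative tail angle|
detected with a prominence/separation criterion. Bouts with peak angle
above 50 degrees are "large" (the vigorous bends characteristic of
nocifensive responses); 50 degrees exactly is small. Bout frequencies are
summarised per trial epoch: the 90 s before cue delivery, the 30 s after
cue delivery, and the 5 s after the UV/TRPA1 pulse.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core import StimulusSchedule
from .synth import TailTrace

__all__ = [
    "extract_bouts",
    "epoch_bout_frequency",
    "bout_kinematics",
]

ANGLE_CUT = 50.0


def _smooth(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x
    pad = w // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, np.ones(w) / w, mode="valid")[: len(x)]


def extract_bouts(
    t: TailTrace,
    prominence: float = 10.0,
    min_separation: float = 0.1,
    rest_epsilon: float = 5.0,
    smooth_samples: int = 5,
) -> pd.DataFrame:
    """Detect bouts as prominent peaks of |angle|.

    Peak detection runs on a lightly smoothed |angle| (a ``smooth_samples``
    moving average — negligible for ~0.2-s bouts at 200 fps but it keeps
    frame noise below the prominence criterion); kinematic quantities are
    measured on the raw trace. The bout onset is the last pre-peak
    crossing into the rest band (|angle| < ``rest_epsilon``) and the bout
    end the first post-peak return to it. Overlapping detections are
    merged into the earlier bout. Returns a table with ``bout_id, onset_s,
    peak_time_s, peak_angle_deg, category, max_velocity, min_velocity``
    (velocities in deg/s); empty if nothing is detected.
    """
    angle = np.asarray(t.angle_deg, dtype=float)
    times = np.asarray(t.times, dtype=float)
    if not np.all(np.isfinite(angle)):
        raise ValueError("tail trace contains non-finite values")
    dt = float(np.median(np.diff(times))) if len(times) > 1 else 1.0
    absang = np.abs(_smooth(angle, smooth_samples))
    peaks, _ = find_peaks(
        absang, prominence=prominence, distance=max(int(round(min_separation / dt)), 1)
    )
    velocity = np.gradient(angle, times) if len(times) > 1 else np.zeros_like(angle)

    rows = []
    prev_end_idx = -1
    for p in peaks:
        below = np.flatnonzero(np.abs(angle[:p]) < rest_epsilon)
        onset_idx = int(below[-1]) if below.size else 0
        after = np.flatnonzero(np.abs(angle[p:]) < rest_epsilon)
        end_idx = int(p + after[0]) if after.size else len(angle) - 1
        if onset_idx <= prev_end_idx:  # overlaps previous bout
            continue
        prev_end_idx = end_idx
        span = slice(onset_idx, end_idx + 1)
        # peak angle from the raw trace within the bout span
        peak_rel = int(np.argmax(np.abs(angle[span])))
        peak_idx = onset_idx + peak_rel
        peak_angle = float(np.abs(angle[peak_idx]))
        rows.append(
            {
                "onset_s": times[onset_idx],
                "peak_time_s": times[peak_idx],
                "peak_angle_deg": peak_angle,
                "category": "large" if peak_angle > ANGLE_CUT else "small",
                "max_velocity": float(velocity[span].max()),
                "min_velocity": float(velocity[span].min()),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "onset_s",
            "peak_time_s",
            "peak_angle_deg",
            "category",
            "max_velocity",
            "min_velocity",
        ],
    )
    out.insert(0, "bout_id", np.arange(len(out)))
    return out


#: Epoch definitions relative to their anchoring event, and precedence
#: (most specific wins) when windows from a dense schedule overlap.
EPOCHS = {
    "post_trpa1": ("uv_trpa1", 0.0, 5.0),
    "post_cue": ("cue", 0.0, 30.0),
    "precue": ("cue", -90.0, 0.0),
}
PRECEDENCE = ("post_trpa1", "post_cue", "precue")


def epoch_bout_frequency(
    bouts: pd.DataFrame, schedule: StimulusSchedule
) -> pd.DataFrame:
    """Bout counts and rates (bouts/min) per epoch x size category.

    Each bout is assigned to at most one epoch instance; when windows
    overlap, post-TRPA1 beats post-cue beats precue (a warning is issued).
    The anchoring trial's cue label is carried along so kin- and
    water-trial epochs can be compared. Rates divide by the summed epoch
    duration of that epoch type (per cue label).
    """
    ev = schedule.events
    cue_ev = ev[ev["label"] != "uv_trpa1"]
    uv_ev = ev[ev["label"] == "uv_trpa1"]

    def _trial_label(onset: float) -> str:
        prior = cue_ev[cue_ev["onset_s"] <= onset]
        return str(prior["label"].iloc[-1]) if not prior.empty else "none"

    windows = []  # (epoch, cue_label, start, end)
    for name in PRECEDENCE:
        anchor, off0, off1 = EPOCHS[name]
        anchors = uv_ev if anchor == "uv_trpa1" else cue_ev
        for onset, label in zip(anchors["onset_s"], anchors["label"]):
            lab = label if anchor == "cue" else _trial_label(onset)
            windows.append((name, lab, onset + off0, onset + off1))

    spans = np.array([(w[2], w[3]) for w in windows]) if windows else np.empty((0, 2))
    if len(spans) > 1:
        order = np.argsort(spans[:, 0])
        s = spans[order]
        if np.any(s[1:, 0] < s[:-1, 1]):
            warnings.warn("epoch windows overlap; precedence applied", stacklevel=2)

    onsets = bouts["onset_s"].to_numpy(float) if len(bouts) else np.array([])
    assigned = np.full(len(onsets), "", dtype=object)
    assigned_label = np.full(len(onsets), "", dtype=object)
    for name, lab, start, end in windows:  # windows already in precedence order
        hit = (onsets >= start) & (onsets < end) & (assigned == "")
        assigned[hit] = name
        assigned_label[hit] = lab

    durations: dict[tuple[str, str], float] = {}
    for name, lab, start, end in windows:
        durations[(name, lab)] = durations.get((name, lab), 0.0) + (end - start)

    rows = []
    cats = ("all", "small", "large")
    bout_cat = bouts["category"].to_numpy() if len(bouts) else np.array([])
    for (name, lab), dur in sorted(durations.items()):
        in_epoch = (assigned == name) & (assigned_label == lab)
        for cat in cats:
            sel = in_epoch if cat == "all" else in_epoch & (bout_cat == cat)
            count = int(sel.sum())
            rows.append(
                {
                    "epoch": name,
                    "cue_label": lab,
                    "category": cat,
                    "count": count,
                    "duration_s": dur,
                    "rate_per_min": 60.0 * count / dur if dur > 0 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def bout_kinematics(
    t: TailTrace, bouts: pd.DataFrame, events: np.ndarray | None = None
) -> pd.DataFrame:
    """Kinematic features per bout, plus latency to the most recent event.

    Velocities come from finite differences of the raw angle over the bout
    span (recomputed here so the function works on externally supplied
    bout tables). ``latency_s`` is onset minus the latest event onset at
    or before it; NaN when no event precedes the bout.
    """
    angle = np.asarray(t.angle_deg, dtype=float)
    times = np.asarray(t.times, dtype=float)
    velocity = np.gradient(angle, times) if len(times) > 1 else np.zeros_like(angle)
    events = np.sort(np.asarray(events, dtype=float)) if events is not None else np.array([])

    rows = []
    for _, b in bouts.iterrows():
        i0 = int(np.searchsorted(times, b["onset_s"], side="left"))
        # span: onset to return to rest, approximated by the next bout or
        # 3x the onset->peak interval past the peak
        i_peak = int(np.searchsorted(times, b["peak_time_s"], side="left"))
        i1 = min(len(times) - 1, i_peak + max(3 * (i_peak - i0), 1))
        sl = slice(i0, i1 + 1)
        lat = np.nan
        if events.size:
            j = np.searchsorted(events, b["onset_s"], side="right") - 1
            if j >= 0:
                lat = float(b["onset_s"] - events[j])
        rows.append(
            {
                "bout_id": b.get("bout_id", np.nan),
                "max_velocity": float(velocity[sl].max()),
                "min_velocity": float(velocity[sl].min()),
                "peak_angle_deg": float(b["peak_angle_deg"]),
                "latency_s": lat,
            }
        )
    return pd.DataFrame(
        rows, columns=["bout_id", "max_velocity", "min_velocity", "peak_angle_deg", "latency_s"]
    )
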