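"""Threshold-based suppressed/enhanced/no-change response calls.

A neuron's response to a cue is its mean dF/F over an analysis window,
averaged across repeats; the call compares that response between test-cue
and control-water trials. If the difference exceeds a threshold (0.05
dF/F by default) the neuron is called enhanced or suppressed by the sign;
the boundary |delta| == threshold is "more than", i.e. strictly
exceeded, so an exact tie is no_change.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import EpochSpec, StimulusSchedule, TraceSet, get_epoch
from .sampling import two_stage_sample
from .traces import integrate_epoch, per_neuron_mean

__all__ = [
    "classify_responses",
    "threshold_sweep",
    "population_fractions",
    "overlap_matrix",
    "subsample_neurons",
    "call_from_delta",
]

CALLS = ("suppressed", "enhanced", "no_change")


def call_from_delta(delta: np.ndarray, threshold: float) -> np.ndarray:
    """enhanced iff delta > threshold; suppressed iff delta < -threshold."""
    delta = np.asarray(delta, dtype=float)
    return np.where(
        delta > threshold, "enhanced", np.where(delta < -threshold, "suppressed", "no_change")
    )


def classify_responses(
    t: TraceSet,
    schedule: StimulusSchedule,
    cue: str,
    control: str = "water",
    window: EpochSpec | str = "post_cue_60s",
    threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-neuron response table for one cue vs its control.

    For windows referenced to the UV/TRPA1 pulse, "cue" and "control"
    select the UV events on test-cue vs water trials (the trial a UV event
    belongs to is the most recent preceding cue). Columns: ``neuron_id,
    cue, mean_integrated_cue, mean_integrated_control, delta, call,
    threshold, window``.
    """
    if t.units != "dff":
        raise ValueError("classification expects dF/F traces")
    window = get_epoch(window)
    cue_vals = per_neuron_mean(integrate_epoch(t, schedule, cue, window))
    ctl_vals = per_neuron_mean(integrate_epoch(t, schedule, control, window))
    delta = cue_vals.to_numpy() - ctl_vals.to_numpy()
    return pd.DataFrame(
        {
            "neuron_id": cue_vals.index,
            "cue": cue,
            "mean_integrated_cue": cue_vals.to_numpy(),
            "mean_integrated_control": ctl_vals.to_numpy(),
            "delta": delta,
            "call": call_from_delta(delta, threshold),
            "threshold": threshold,
            "window": window.name or f"{window.reference}[{window.offset_start},{window.offset_end}]",
        }
    )


def threshold_sweep(
    t: TraceSet,
    schedule: StimulusSchedule,
    cue: str,
    control: str = "water",
    window: EpochSpec | str = "post_cue_60s",
    thresholds=(0.01, 0.025, 0.05, 0.075, 0.1, 0.15),
) -> pd.DataFrame:
    """Call fractions across a grid of thresholds.

    The deltas are computed once; the suppressed+enhanced fraction is
    non-increasing in the threshold by construction. Thresholds must be
    strictly increasing and non-negative.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds < 0) or np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be non-negative and strictly increasing")
    rt = classify_responses(t, schedule, cue, control, window, threshold=0.0)
    delta = rt["delta"].to_numpy()
    rows = []
    for thr in thresholds:
        calls = call_from_delta(delta, thr)
        n = len(calls)
        rows.append(
            {
                "threshold": thr,
                "frac_suppressed": np.mean(calls == "suppressed"),
                "frac_enhanced": np.mean(calls == "enhanced"),
                "frac_no_change": np.mean(calls == "no_change"),
                "n": n,
            }
        )
    return pd.DataFrame(rows)


def population_fractions(rt: pd.DataFrame, by=None) -> pd.DataFrame:
    """Fractions of each call (summing to 1 per group), with counts.

    ``by`` is an optional column (or list of columns) of the response
    table to group on, e.g. ``"cue"`` or a merged metadata column.
    """
    if rt.empty:
        raise ValueError("empty response table")
    keys = [by] if isinstance(by, str) else list(by or [])

    def _frac(group: pd.DataFrame) -> pd.Series:
        n = len(group)
        out = {}
        for call in CALLS:
            k = int((group["call"] == call).sum())
            out[f"frac_{call}"] = k / n
            out[f"n_{call}"] = k
        out["n"] = n
        return pd.Series(out)

    if keys:
        out = rt.groupby(keys, sort=True).apply(_frac, include_groups=False).reset_index()
    else:
        out = _frac(rt).to_frame().T
    count_cols = [c for c in out.columns if c.startswith("n")]
    out[count_cols] = out[count_cols].astype(int)
    return out


def overlap_matrix(rt_a: pd.DataFrame, rt_b: pd.DataFrame) -> pd.DataFrame:
    """Cross-tabulate two cues' calls over the same neurons (cells sum to n)."""
    merged = rt_a[["neuron_id", "call"]].merge(
        rt_b[["neuron_id", "call"]], on="neuron_id", suffixes=("_a", "_b")
    )
    return pd.crosstab(merged["call_a"], merged["call_b"]).reindex(
        index=CALLS, columns=CALLS, fill_value=0
    )


def subsample_neurons(
    t: TraceSet,
    per_fish: int = 25,
    per_group: int | None = 200,
    seed: int = 0,
    group_col: str | None = None,
) -> TraceSet:
    """Two-stage random subsample: per fish, then per treatment group.

    Sampling is without replacement at both stages and deterministic under
    ``seed``; see :func:`oxtmod.sampling.two_stage_sample` for truncation
    and error behaviour.
    """
    idx = two_stage_sample(
        t.neuron_meta, per_fish, per_group, seed, fish_col="fish_id", group_col=group_col
    )
    return t.select(idx)
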