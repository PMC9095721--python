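"""Core containers shared across the pipeline.

The pipeline starts from extracted ROI fluorescence traces (motion
correction and segmentation are upstream concerns), so the central objects
are small and tabular: a neuron x frame matrix with timestamps and
per-neuron metadata (:class:`TraceSet`), an ordered stimulus event list
(:class:`StimulusSchedule`), and a named analysis window relative to an
event type (:class:`EpochSpec`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Recognised anatomical region labels for neuron metadata.
REGIONS = ("PO", "PT", "OB", "aSPa", "pSPa", "other", "background")

#: Stimulus labels used throughout: control water flow, conspecific cues,
#: and the UV pulse that opens TRPA1 channels in optovin-treated fish.
CUE_LABELS = ("water", "kin", "nonkin", "adult", "uv_trpa1")


class ConfigurationError(ValueError):
    """Raised when a configuration cannot describe a valid experiment."""


@dataclass
class StimulusSchedule:
    """Ordered list of stimulus events.

    ``events`` columns: ``onset_s`` (float), ``duration_s`` (float),
    ``label`` (str). Events are sorted by onset and must not overlap.
    """

    events: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"onset_s", "duration_s", "label"}
        missing = req - set(self.events.columns)
        if missing:
            raise ValueError(f"schedule missing columns: {sorted(missing)}")
        self.events = self.events.sort_values("onset_s").reset_index(drop=True)
        onset = self.events["onset_s"].to_numpy(float)
        dur = self.events["duration_s"].to_numpy(float)
        if len(onset) > 1 and np.any(onset[1:] < (onset[:-1] + dur[:-1])):
            raise ValueError("schedule events overlap")

    def onsets(self, label: str | None = None) -> np.ndarray:
        ev = self.events
        if label is not None:
            ev = ev[ev["label"] == label]
        return ev["onset_s"].to_numpy(float)

    def first_onset(self) -> float:
        if self.events.empty:
            raise ValueError("schedule has no events")
        return float(self.events["onset_s"].iloc[0])

    def labels(self) -> list[str]:
        return list(dict.fromkeys(self.events["label"]))

    def to_csv(self, path) -> None:
        self.events.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StimulusSchedule":
        return cls(pd.read_csv(path))


@dataclass
class TraceSet:
    """Neuron x frame fluorescence with timestamps and per-neuron metadata.

    Parameters
    ----------
    values
        ``(n_neurons, n_frames)`` array, raw fluorescence (a.u.) or dF/F
        depending on ``units``.
    frame_times
        Strictly increasing frame timestamps in seconds.
    neuron_meta
        One row per neuron: ``neuron_id``, ``fish_id``, ``region``,
        ``ap_um`` (anterior-negative), ``x_um``/``y_um``/``z_um``.
    units
        ``"raw"`` or ``"dff"``.
    """

    values: np.ndarray
    frame_times: np.ndarray
    neuron_meta: pd.DataFrame
    units: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (neuron x frame)")
        if self.values.shape[1] != self.frame_times.shape[0]:
            raise ValueError("frame_times length must match frame axis")
        if self.values.shape[0] != len(self.neuron_meta):
            raise ValueError("neuron_meta rows must match neuron axis")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        if self.units not in ("raw", "dff"):
            raise ValueError("units must be 'raw' or 'dff'")
        if self.units == "raw" and np.any(self.values <= 0):
            raise ValueError("raw fluorescence must be strictly positive")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def frame_interval(self) -> float:
        """Median frame interval in seconds."""
        return float(np.median(np.diff(self.frame_times)))

    def with_values(self, values: np.ndarray, units: str | None = None) -> "TraceSet":
        return replace(self, values=values, units=units or self.units)

    def select(self, index) -> "TraceSet":
        """Subset neurons by positional index."""
        idx = np.asarray(index)
        return replace(
            self,
            values=self.values[idx],
            neuron_meta=self.neuron_meta.iloc[idx].reset_index(drop=True),
        )

    def to_long(self) -> pd.DataFrame:
        """Long CSV layout: neuron_id, frame, time_s, F."""
        n, m = self.values.shape
        ids = self.neuron_meta["neuron_id"].to_numpy()
        return pd.DataFrame(
            {
                "neuron_id": np.repeat(ids, m),
                "frame": np.tile(np.arange(m), n),
                "time_s": np.tile(self.frame_times, n),
                "F": self.values.ravel(),
            }
        )

    def to_csv(self, trace_path, meta_path=None) -> None:
        self.to_long().to_csv(trace_path, index=False)
        if meta_path is not None:
            self.neuron_meta.to_csv(meta_path, index=False)

    @classmethod
    def from_csv(cls, trace_path, meta_path, units: str = "raw") -> "TraceSet":
        long = pd.read_csv(trace_path)
        meta = pd.read_csv(meta_path)
        wide = long.pivot(index="neuron_id", columns="frame", values="F")
        wide = wide.loc[meta["neuron_id"]]
        times = (
            long.drop_duplicates("frame").sort_values("frame")["time_s"].to_numpy()
        )
        return cls(wide.to_numpy(), times, meta.reset_index(drop=True), units)


@dataclass(frozen=True)
class EpochSpec:
    """Analysis window relative to events of one label.

    ``reference`` of ``"cue"`` means the window is aligned to the cue (or
    control) events under comparison; any other value names an event label
    (e.g. ``"uv_trpa1"``) whose occurrences anchor the window.
    """

    reference: str
    offset_start: float
    offset_end: float
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.offset_end > self.offset_start:
            raise ValueError("offset_end must exceed offset_start")

    @property
    def length(self) -> float:
        return self.offset_end - self.offset_start


#: Named windows used by the headline analyses: 60 s after a chemosensory
#: cue; 5 s after the UV/TRPA1 pulse; the 30 s between cue onset and the UV
#: pulse; and the 10 s + 30 s split of the 40-s post-optogenetic window.
EPOCH_PRESETS: dict[str, EpochSpec] = {
    "post_cue_60s": EpochSpec("cue", 0.0, 60.0, name="post_cue_60s"),
    "post_trpa1_5s": EpochSpec("uv_trpa1", 0.0, 5.0, name="post_trpa1_5s"),
    "pre_trpa1_30s": EpochSpec("uv_trpa1", -30.0, 0.0, name="pre_trpa1_30s"),
    "opto_10s": EpochSpec("opto", 0.0, 10.0, name="opto_10s"),
    "opto_30s": EpochSpec("opto", 10.0, 40.0, name="opto_30s"),
}


def get_epoch(window: "EpochSpec | str") -> EpochSpec:
    if isinstance(window, EpochSpec):
        return window
    try:
        return EPOCH_PRESETS[window]
    except KeyError:
        raise KeyError(
            f"unknown epoch preset {window!r}; available: {sorted(EPOCH_PRESETS)}"
        ) from None
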