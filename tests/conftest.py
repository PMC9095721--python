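import numpy as np
import pandas as pd
import pytest

from oxtmod.core import StimulusSchedule, TraceSet
from oxtmod.synth import GeneratorConfig


def make_traceset(values, frame_times, units="dff", fish_ids=None):
    """TraceSet from a bare matrix, minimal metadata."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    meta = pd.DataFrame(
        {
            "neuron_id": [f"n{j:04d}" for j in range(n)],
            "fish_id": fish_ids if fish_ids is not None else np.zeros(n, dtype=int),
            "region": "PO",
            "ap_um": 0.0,
            "x_um": 0.0,
            "y_um": 0.0,
            "z_um": 0.0,
        }
    )
    return TraceSet(values, np.asarray(frame_times, dtype=float), meta, units)


def simple_schedule(onsets, labels, duration=10.0):
    return StimulusSchedule(
        pd.DataFrame(
            {"onset_s": list(onsets), "duration_s": duration, "label": list(labels)}
        )
    )


@pytest.fixture
def small_fig2_config():
    """A quick-to-generate cue-modulation experiment (40 neurons)."""
    return GeneratorConfig(
        n_fish=4,
        neurons_per_fish=10,
        cue_labels=("water", "kin"),
        isi=150.0,
        pulse_duration=10.0,
        duration=660.0,
        class_mixture={"cue_suppressed": 0.3, "cue_enhanced": 0.2, "cue_neutral": 0.5},
        effect_size=0.2,
        noise_sd=0.025,
        seed=11,
    )


@pytest.fixture
def fig6_noiseless_config():
    """TRPA1 experiment, no noise, for exact-recovery checks."""
    return GeneratorConfig(
        n_fish=4,
        neurons_per_fish=25,
        cue_labels=("water", "kin"),
        isi=300.0,
        pulse_duration=10.0,
        uv_after_cue=30.0,
        duration=1260.0,
        class_mixture={
            "trpa1_strong": 0.2,
            "trpa1_moderate": 0.3,
            "trpa1_weak": 0.1,
            "unresponsive": 0.3,
            "anticorrelated": 0.1,
        },
        modulation_mixture={
            "pre_trpa1_30s": {"suppressed": 0.4, "enhanced": 0.3, "none": 0.3},
            "post_trpa1_5s": {"suppressed": 0.5, "enhanced": 0.3, "none": 0.2},
        },
        effect_size=0.2,
        noise_sd=0.0,
        seed=3,
    )
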