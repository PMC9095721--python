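"""Generator presets for the headline population structures.

Each preset plants the suppressed/enhanced/no-change mixture observed for
one cue comparison in larval zebrafish OXT (or olfactory-bulb) imaging, so
parameter-recovery runs have a known answer with realistic structure:

``fig2-kin``
    Kin-conditioned water vs control water flow, 60-s post-cue window.
    Kin cues suppress the largest fraction of OXT neurons (~27.5%,
    reported range 25-30%) and enhance the smallest (~10%, range 9-11%).
``fig2-nonkin``
    Non-kin larval water: intermediate suppression (18%) and
    enhancement (23%).
``fig2-adult``
    Adult-conditioned water (a predator cue): the least suppression (14%)
    and by far the most enhancement (46%).
``fig6-trpa1``
    Alternating water/kin trials each followed by a UV/TRPA1 pulse at
    +30 s. Kin water suppresses 54% and enhances 32% of neurons'
    TRPA1-evoked activity (5-s post-UV window), and suppresses 43% /
    enhances 30% already in the 30 s after cue delivery, before the UV
    pulse. Tuning classes mirror the broad activity classes of the
    correlation-clustering analysis (strong/moderate/weak TRPA1-selective,
    mixed stimulus+motor, motor-only, unresponsive, anticorrelated) at
    their observed proportions (16/126/40/156/64/64/34 of 500 units,
    classes i_a..v with ii_a+ii_b pooled).

Effect size defaults to 0.2 dF/F (4x the 0.05 classification threshold)
with per-frame noise of 0.025 dF/F (effect/8).
"""

from __future__ import annotations

from dataclasses import replace

from .synth import GeneratorConfig

__all__ = ["GENERATOR_PRESETS", "preset_config", "FIG6_CLASS_MIXTURE"]

#: Broad-class proportions planted by ``fig6-trpa1`` (fractions of 500).
FIG6_CLASS_MIXTURE = {
    "trpa1_strong": 16 / 500,
    "trpa1_moderate": 126 / 500,
    "trpa1_weak": 40 / 500,
    "mixed_stim_motor": 156 / 500,
    "motor_spon_L": 64 / 500,
    "unresponsive": 64 / 500,
    "anticorrelated": 34 / 500,
}


def _fig2(cue: str, suppressed: float, enhanced: float) -> GeneratorConfig:
    return GeneratorConfig(
        n_fish=8,
        neurons_per_fish=25,
        cue_labels=("water", cue),
        isi=300.0,
        pulse_duration=10.0,
        duration=1260.0,
        class_mixture={
            "cue_suppressed": suppressed,
            "cue_enhanced": enhanced,
            "cue_neutral": round(1.0 - suppressed - enhanced, 12),
        },
        effect_size=0.2,
        noise_sd=0.025,
    )


GENERATOR_PRESETS: dict[str, GeneratorConfig] = {
    "fig2-kin": _fig2("kin", 0.275, 0.10),
    "fig2-nonkin": _fig2("nonkin", 0.18, 0.23),
    "fig2-adult": _fig2("adult", 0.14, 0.46),
    "fig6-trpa1": GeneratorConfig(
        n_fish=20,
        neurons_per_fish=25,
        cue_labels=("water", "kin"),
        isi=300.0,
        pulse_duration=10.0,
        uv_after_cue=30.0,
        duration=1260.0,
        class_mixture=FIG6_CLASS_MIXTURE,
        modulation_mixture={
            "pre_trpa1_30s": {"suppressed": 0.43, "enhanced": 0.30, "none": 0.27},
            "post_trpa1_5s": {"suppressed": 0.54, "enhanced": 0.32, "none": 0.14},
        },
        effect_size=0.2,
        noise_sd=0.025,
    ),
}


def preset_config(
    name: str, n_neurons: int | None = None, seed: int | None = None, **overrides
) -> GeneratorConfig:
    """A copy of a preset, optionally rescaled to ``n_neurons`` total.

    Rescaling keeps the number of fish and adjusts neurons per fish
    (``n_neurons`` must divide evenly). Unknown names raise with the list
    of available presets.
    """
    try:
        base = GENERATOR_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(GENERATOR_PRESETS)}"
        ) from None
    kwargs = dict(overrides)
    if n_neurons is not None:
        if n_neurons % base.n_fish:
            raise ValueError(f"n_neurons={n_neurons} not divisible by n_fish={base.n_fish}")
        kwargs["neurons_per_fish"] = n_neurons // base.n_fish
    if seed is not None:
        kwargs["seed"] = seed
    return replace(base, **kwargs)
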