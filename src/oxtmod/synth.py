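"""Synthetic experiments with planted ground truth.

Every analysis stage in this package is validated against data whose
answers are known. The generator builds the forward model the analyses
assume: pulsed chemosensory cue schedules (alternating control water and a
conspecific cue, optionally followed by a UV/TRPA1 pulse), GCaMP6s-kernel
responses of planted tuning classes with additive Gaussian noise and
optional linear dye drift, 200-fps tail-angle traces with half-sine bouts,
and control-vs-treatment pERK intensity tables.

Planting scheme
---------------
Each neuron gets one *tuning class* (what it responds to: the TRPA1 pulse
at one of three strengths, spontaneous movements, both, neither, or with
inverted sign) and, per analysis window, one *modulation label* (whether
the test cue suppresses, enhances, or leaves unchanged its activity in
that window relative to control-water trials). Tuning drives the
regressor-correlation structure; modulation drives the threshold
classification. Modulation is planted additively as a sustained response
on test-cue trials — a boxcar spanning (most of) the analysis window,
convolved with the same kernel the analysis uses — because a response
confined to the 10-s cue pulse would be diluted far below the 0.05
classification threshold when averaged over a 60-s window. Tonic
suppression/enhancement across the window is also what the modulation is
meant to emulate. The within-trial boxcar for the pre-TRPA1 window stops
20 s after cue onset so it has decayed (tau 3 s) before the UV pulse at
+30 s and does not leak into the post-TRPA1 window.

All stochastic choices flow from ``GeneratorConfig.seed`` through a
documented ``numpy`` SeedSequence split, so regeneration is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .core import ConfigurationError, StimulusSchedule, TraceSet
from .regressors import KernelParams, event_response

__all__ = [
    "GeneratorConfig",
    "PerkConfig",
    "TailTrace",
    "TUNING_CLASSES",
    "make_schedule",
    "make_traces",
    "make_tail_trace",
    "make_perk_table",
    "simulate_experiment",
    "SimulationResult",
]

#: Recognised tuning classes and their response gains. ``stim`` scales the
#: UV/TRPA1 impulse response, ``motor`` the spontaneous-bout response, in
#: units of ``effect_size`` (peak dF/F = gain * effect_size). Gains are
#: graded so that, at the default effect size and noise, strong/moderate/
#: weak stimulus tuning lands in the high (>=0.5), moderate (0.2-0.5) and
#: weak (0.05-0.2) correlation bands used by the cluster class rules.
TUNING_CLASSES: dict[str, dict] = {
    "cue_suppressed": {"stim": 0.0, "motor": 0.0, "bout_kind": None},
    "cue_enhanced": {"stim": 0.0, "motor": 0.0, "bout_kind": None},
    "cue_neutral": {"stim": 0.0, "motor": 0.0, "bout_kind": None},
    "trpa1_strong": {"stim": 1.0, "motor": 0.0, "bout_kind": None},
    "trpa1_moderate": {"stim": 0.35, "motor": 0.0, "bout_kind": None},
    "trpa1_weak": {"stim": 0.19, "motor": 0.0, "bout_kind": None},
    "motor_spon_L": {"stim": 0.0, "motor": 0.6, "bout_kind": "large"},
    "motor_spon_S": {"stim": 0.0, "motor": 0.6, "bout_kind": "small"},
    "mixed_stim_motor": {"stim": 0.6, "motor": 0.5, "bout_kind": "all"},
    "anticorrelated": {"stim": -0.35, "motor": 0.0, "bout_kind": None},
    "unresponsive": {"stim": 0.0, "motor": 0.0, "bout_kind": None},
}

MODULATION_LABELS = ("suppressed", "enhanced", "none")


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic experiment.

    Defaults follow the tethered OXT-imaging conditions: ~474 ms frames
    (two z-planes at ~237 ms each), a 5-min interstimulus interval with
    10-s cue pulses alternating control water and the test cue, a 60-s
    pre-stimulus baseline, and four presentations per run.
    """

    n_fish: int = 8
    neurons_per_fish: int = 25
    frame_interval: float = 0.474
    duration: float = 1260.0
    cue_labels: tuple[str, ...] = ("water", "kin")
    isi: float = 300.0
    pulse_duration: float = 10.0
    first_onset: float = 60.0
    #: UV/TRPA1 pulse this many seconds after each cue onset (None = no UV).
    uv_after_cue: float | None = None
    uv_duration: float = 0.1
    class_mixture: dict[str, float] = field(
        default_factory=lambda: {"cue_suppressed": 0.3, "cue_enhanced": 0.1, "cue_neutral": 0.6}
    )
    #: Per-window modulation mixtures, e.g.
    #: ``{"post_trpa1_5s": {"suppressed": .54, "enhanced": .32, "none": .14}}``.
    #: When empty, modulation is derived from the cue_* tuning classes for
    #: the 60-s post-cue window.
    modulation_mixture: dict[str, dict[str, float]] = field(default_factory=dict)
    #: Peak dF/F of the planted modulation response (and unit for tuning gains).
    effect_size: float = 0.2
    #: Per-frame Gaussian noise, dF/F units.
    noise_sd: float = 0.025
    baseline_f: float = 100.0
    #: Linear background drift, fluorescence units per second (dye uptake).
    drift_slope: float = 0.0
    #: Mild mechanosensory response to any water flow, peak dF/F (shared by
    #: control and cue trials, so it cancels in modulation deltas).
    flow_response: float = 0.05
    include_background_roi: bool = False
    kernel: KernelParams = field(default_factory=KernelParams)
    # --- tail-trace parameters (200 fps tethered monitoring) ---
    tail_fps: float = 200.0
    spon_bout_rate_per_min: float = 1.5
    stim_locked_bouts: int = 1
    bout_duration: float = 0.2
    small_angle_mean: float = 30.0
    small_angle_sd: float = 8.0
    large_angle_mean: float = 70.0
    large_angle_sd: float = 10.0
    large_fraction: float = 0.5
    tail_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"class_mixture sums to {total}, not 1")
        unknown = set(self.class_mixture) - set(TUNING_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown tuning classes: {sorted(unknown)}")
        for key, mix in self.modulation_mixture.items():
            if set(mix) - set(MODULATION_LABELS):
                raise ConfigurationError(f"bad modulation labels for {key}")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"modulation mixture for {key} does not sum to 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not self.pulse_duration < self.isi:
            raise ConfigurationError("pulse_duration must be < isi")
        if self.isi <= 0:
            raise ConfigurationError("isi must be > 0")

    @property
    def n_neurons(self) -> int:
        return self.n_fish * self.neurons_per_fish

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["cue_labels"] = list(self.cue_labels)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["cue_labels"] = tuple(data["cue_labels"])
        if isinstance(data.get("kernel"), dict):
            data["kernel"] = KernelParams(**data["kernel"])
        return cls(**data)

    def test_cue(self) -> str:
        """The non-water, non-UV cue under test."""
        for label in self.cue_labels:
            if label not in ("water", "uv_trpa1"):
                return label
        raise ConfigurationError("config has no test cue")


def _seeds(config: GeneratorConfig, n: int) -> list[np.random.Generator]:
    """Documented seed split: SeedSequence(seed).spawn in a fixed order."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(n)]


def _exact_count_labels(
    mixture: dict[str, float], n: int, rng: np.random.Generator
) -> np.ndarray:
    """Plant a mixture as exact counts (largest-remainder rounding),
    randomly permuted across neurons.

    Recovery benchmarks then measure classification error rather than the
    Monte Carlo error of an i.i.d. label draw; the expected composition is
    identical.
    """
    labels = np.array(list(mixture))
    probs = np.array(list(mixture.values()), dtype=float)
    counts = np.floor(probs * n).astype(int)
    remainder = probs * n - counts
    short = n - counts.sum()
    counts[np.argsort(-remainder)[:short]] += 1
    return rng.permutation(np.repeat(labels, counts))


def make_schedule(config: GeneratorConfig) -> StimulusSchedule:
    """Alternating cue schedule, optional UV pulse after each cue.

    Cue onsets are ``first_onset + k * isi`` for as long as a full cycle
    (onset + isi) fits inside ``duration``, cycling through ``cue_labels``
    in order. With ``uv_after_cue`` set, each cue event is followed by a
    UV/TRPA1 event exactly that many seconds after cue onset.
    """
    onsets = []
    onset = config.first_onset
    while onset + config.isi <= config.duration:
        onsets.append(onset)
        onset += config.isi
    labels = [config.cue_labels[i % len(config.cue_labels)] for i in range(len(onsets))]
    counts = pd.Series(labels).value_counts() if labels else pd.Series(dtype=int)
    if len(onsets) == 0 or any(counts.get(c, 0) < 2 for c in config.cue_labels):
        raise ConfigurationError(
            "duration too short: need at least 2 presentations of every cue"
        )
    rows = [
        {"onset_s": t, "duration_s": config.pulse_duration, "label": lab}
        for t, lab in zip(onsets, labels)
    ]
    if config.uv_after_cue is not None:
        rows += [
            {
                "onset_s": t + config.uv_after_cue,
                "duration_s": config.uv_duration,
                "label": "uv_trpa1",
            }
            for t in onsets
        ]
    return StimulusSchedule(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# tail traces


@dataclass
class TailTrace:
    """Cumulative tail angle at ~200 fps, degrees, signed."""

    times: np.ndarray
    angle_deg: np.ndarray

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times, "angle_deg": self.angle_deg}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "TailTrace":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(), df["angle_deg"].to_numpy())


def _draw_amplitude(rng: np.random.Generator, config: GeneratorConfig, large: bool) -> float:
    """Peak angle; small bouts clipped to <= 50, large strictly > 50."""
    if large:
        a = rng.normal(config.large_angle_mean, config.large_angle_sd)
        return float(np.clip(a, 50.0 + 1e-6, 120.0))
    a = rng.normal(config.small_angle_mean, config.small_angle_sd)
    return float(np.clip(a, 5.0, 50.0))


def make_tail_trace(
    config: GeneratorConfig,
    schedule: StimulusSchedule,
    seed: int | None = None,
) -> tuple[TailTrace, pd.DataFrame]:
    """Tail-angle trace with planted bouts and its truth table.

    Spontaneous bouts arrive at ``spon_bout_rate_per_min`` outside UV
    response windows; ``stim_locked_bouts`` extra bouts are planted within
    5 s of each UV event. Each bout is a half-sine angle envelope of
    amplitude straddling the 50-degree large/small boundary. Truth columns:
    ``onset_s, peak_time_s, peak_angle_deg, category, stim_locked``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    dt = 1.0 / config.tail_fps
    times = np.arange(0.0, config.duration, dt)
    angle = np.zeros_like(times)

    uv_onsets = schedule.onsets("uv_trpa1")
    n_spon = rng.poisson(config.spon_bout_rate_per_min * config.duration / 60.0)
    spon = rng.uniform(0.0, config.duration - config.bout_duration, size=n_spon)
    # keep spontaneous bouts out of the 5-s post-UV windows so the
    # stimulus-associated/spontaneous split in the truth table is exact
    for uv in uv_onsets:
        spon = spon[(spon < uv) | (spon > uv + 5.0)]
    locked = np.concatenate(
        [rng.uniform(uv + 0.3, uv + 4.5, size=config.stim_locked_bouts) for uv in uv_onsets]
    ) if uv_onsets.size and config.stim_locked_bouts else np.array([])

    rows = []
    for onset, is_locked in sorted(
        [(t, False) for t in spon] + [(t, True) for t in locked]
    ):
        if rows and onset < rows[-1]["onset_s"] + config.bout_duration + 0.05:
            continue  # enforce non-overlap
        large = bool(rng.random() < config.large_fraction)
        amp = _draw_amplitude(rng, config, large)
        sign = -1.0 if rng.random() < 0.5 else 1.0
        sl = slice(
            int(np.ceil(onset / dt)), min(int(np.ceil((onset + config.bout_duration) / dt)), len(times))
        )
        tt = times[sl] - onset
        angle[sl] += sign * amp * np.sin(np.pi * tt / config.bout_duration)
        peak_rel = config.bout_duration / 2.0
        rows.append(
            {
                "onset_s": onset,
                "peak_time_s": onset + peak_rel,
                "peak_angle_deg": amp,
                "category": "large" if amp > 50.0 else "small",
                "stim_locked": is_locked,
            }
        )
    if config.tail_noise_sd > 0:
        angle = angle + rng.normal(0.0, config.tail_noise_sd, size=angle.shape)
    truth = pd.DataFrame(
        rows,
        columns=["onset_s", "peak_time_s", "peak_angle_deg", "category", "stim_locked"],
    )
    return TailTrace(times, angle), truth


# ---------------------------------------------------------------------------
# fluorescence traces


def _modulation_windows(config: GeneratorConfig) -> dict[str, tuple[str, float, float]]:
    """Window key -> (shape, start offset from cue onset, duration).

    Shapes: ``boxcar`` (sustained response) or ``impulse`` (at the UV
    time). Offsets are relative to the *cue* onset of each test-cue trial.
    """
    out = {}
    keys = set(config.modulation_mixture) or (
        {"post_cue_60s"} if any(c.startswith("cue_") for c in config.class_mixture) else set()
    )
    for key in keys:
        if key == "post_cue_60s":
            out[key] = ("boxcar", 0.0, 60.0)
        elif key == "pre_trpa1_30s":
            if config.uv_after_cue is None:
                raise ConfigurationError("pre_trpa1_30s modulation requires uv_after_cue")
            # stop 10 s before the UV pulse so the response (tau 3 s) has
            # decayed before the post-TRPA1 window opens
            out[key] = ("boxcar", 0.0, config.uv_after_cue - 10.0)
        elif key == "post_trpa1_5s":
            if config.uv_after_cue is None:
                raise ConfigurationError("post_trpa1_5s modulation requires uv_after_cue")
            out[key] = ("impulse", config.uv_after_cue, 0.0)
        else:
            raise ConfigurationError(f"no modulation shape defined for window {key!r}")
    return out


def _sample_modulation(
    config: GeneratorConfig, classes: np.ndarray, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Per-window modulation labels, one per neuron."""
    n = len(classes)
    out: dict[str, np.ndarray] = {}
    if config.modulation_mixture:
        for key, mix in config.modulation_mixture.items():
            full = {l: mix.get(l, 0.0) for l in MODULATION_LABELS}
            out[key] = _exact_count_labels(full, n, rng)
    elif any(c.startswith("cue_") for c in config.class_mixture):
        derived = np.where(
            classes == "cue_suppressed",
            "suppressed",
            np.where(classes == "cue_enhanced", "enhanced", "none"),
        )
        out["post_cue_60s"] = derived
    return out


def make_traces(
    config: GeneratorConfig,
    schedule: StimulusSchedule,
    bout_truth: dict | None = None,
) -> tuple[TraceSet, pd.DataFrame]:
    """Raw fluorescence traces plus the planted ground truth.

    Raw F = baseline_f * (1 + dF/F signal + Gaussian noise) + drift * t,
    where the signal sums, per neuron: the flow response to every cue
    pulse, the tuning-class response (UV impulses and/or bout-onset
    impulses), and the per-window modulation response on test-cue trials —
    each a unit-peak kernel convolution scaled by its amplitude.

    ``bout_truth`` maps fish id -> truth table from :func:`make_tail_trace`;
    fish with motor-tuned neurons and no table provided get one generated
    internally (seeded from the master seed, so
    :func:`simulate_experiment` reproduces it exactly).

    Ground-truth columns: ``neuron_id, fish_id, tuning_class, effect_size``
    and one ``mod_<window>`` column per modulated analysis window.
    """
    rng_class, rng_mod, rng_noise = _seeds(config, 3)

    n = config.n_neurons
    frame_times = np.arange(0.0, config.duration, config.frame_interval)
    classes = _exact_count_labels(config.class_mixture, n, rng_class)
    fish_ids = np.repeat(np.arange(config.n_fish), config.neurons_per_fish)
    modulation = _sample_modulation(config, classes, rng_mod)
    mod_windows = _modulation_windows(config)

    test_cue = config.test_cue()
    cue_ev = schedule.events[~schedule.events["label"].isin(["uv_trpa1"])]
    test_onsets = schedule.onsets(test_cue)
    uv_onsets = schedule.onsets("uv_trpa1")

    # shared unit-peak response curves (all trials / test trials / UV / mods)
    flow = event_response(
        cue_ev["onset_s"].to_numpy(), cue_ev["duration_s"].to_numpy(), frame_times, config.kernel
    )
    responses: list[np.ndarray] = [flow]
    amps: list[np.ndarray] = [np.full(n, config.flow_response)]

    if uv_onsets.size:
        uv_resp = event_response(
            uv_onsets, np.full(uv_onsets.shape, config.uv_duration), frame_times, config.kernel
        )
        stim_gain = np.array([TUNING_CLASSES[c]["stim"] for c in classes])
        responses.append(uv_resp)
        amps.append(stim_gain * config.effect_size)

    sign_map = {"suppressed": -1.0, "enhanced": 1.0, "none": 0.0}
    for key, (shape, off, dur) in mod_windows.items():
        if shape == "impulse":
            resp = event_response(
                test_onsets + off, np.zeros_like(test_onsets), frame_times, config.kernel
            )
        else:
            resp = event_response(
                test_onsets + off, np.full(test_onsets.shape, dur), frame_times, config.kernel
            )
        signs = np.array([sign_map[m] for m in modulation[key]])
        responses.append(resp)
        amps.append(signs * config.effect_size)

    signal = np.stack(amps, axis=1) @ np.stack(responses, axis=0)

    # motor coupling: impulses at the fish's own bout onsets
    motor_gain = np.array([TUNING_CLASSES[c]["motor"] for c in classes])
    if np.any(motor_gain != 0):
        if bout_truth is None:
            bout_truth = {}
        tail_seeds = np.random.SeedSequence(config.seed + 1_000_003).generate_state(config.n_fish)
        for f in range(config.n_fish):
            sel = np.flatnonzero((fish_ids == f) & (motor_gain != 0))
            if sel.size == 0:
                continue
            if f not in bout_truth:
                _, bout_truth[f] = make_tail_trace(config, schedule, seed=int(tail_seeds[f]))
            truth = bout_truth[f]
            spon = truth[~truth["stim_locked"]]
            kinds = {
                "large": spon[spon["category"] == "large"]["onset_s"].to_numpy(),
                "small": spon[spon["category"] == "small"]["onset_s"].to_numpy(),
                "all": spon["onset_s"].to_numpy(),
            }
            for kind, onsets in kinds.items():
                idx = sel[
                    np.array([TUNING_CLASSES[classes[i]]["bout_kind"] == kind for i in sel])
                ]
                if idx.size == 0 or onsets.size == 0:
                    continue
                resp = event_response(onsets, np.zeros_like(onsets), frame_times, config.kernel)
                signal[idx] += (motor_gain[idx] * config.effect_size)[:, None] * resp[None, :]

    noise = (
        rng_noise.normal(0.0, config.noise_sd, size=signal.shape)
        if config.noise_sd > 0
        else 0.0
    )
    values = config.baseline_f * (1.0 + signal + noise) + config.drift_slope * frame_times[None, :]

    meta = pd.DataFrame(
        {
            "neuron_id": [f"n{j:05d}" for j in range(n)],
            "fish_id": fish_ids,
            "region": "PO",
            "ap_um": rng_noise.uniform(-100.0, 100.0, size=n).round(1),
            "x_um": rng_noise.uniform(0.0, 100.0, size=n).round(1),
            "y_um": rng_noise.uniform(0.0, 100.0, size=n).round(1),
            "z_um": rng_noise.uniform(0.0, 30.0, size=n).round(1),
        }
    )
    truth_df = pd.DataFrame(
        {
            "neuron_id": meta["neuron_id"],
            "fish_id": fish_ids,
            "tuning_class": classes,
            "effect_size": config.effect_size,
        }
    )
    for key, labels in modulation.items():
        truth_df[f"mod_{key}"] = labels

    if config.include_background_roi:
        bg = config.baseline_f + config.drift_slope * frame_times
        values = np.vstack([values, bg[None, :]])
        meta = pd.concat(
            [
                meta,
                pd.DataFrame(
                    {
                        "neuron_id": ["background"],
                        "fish_id": [-1],
                        "region": ["background"],
                        "ap_um": [0.0],
                        "x_um": [0.0],
                        "y_um": [0.0],
                        "z_um": [0.0],
                    }
                ),
            ],
            ignore_index=True,
        )

    return TraceSet(values, frame_times, meta, units="raw"), truth_df


# ---------------------------------------------------------------------------
# pERK tables


@dataclass
class PerkConfig:
    """Control-vs-treatment pERK intensity structure.

    Intensities are lognormal; each treatment group's location is the
    control location times a planted multiplier (the ground truth).
    """

    groups: dict[str, float] = field(
        default_factory=lambda: {"group": 1.0, "isolated": 1.3}
    )
    control_group: str = "group"
    n_fish_per_group: int = 11
    cells_per_fish: int = 70
    meanlog: float = 5.3
    sdlog: float = 0.4
    po_fraction: float = 0.85
    #: PO cells sit anterior (negative AP), PT posterior; cutoff at 0 um.
    ap_range_po: tuple[float, float] = (-120.0, 0.0)
    ap_range_pt: tuple[float, float] = (0.0, 80.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.control_group not in self.groups:
            raise ConfigurationError("control_group must be one of groups")


def make_perk_table(config: PerkConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell pERK intensities with a planted group shift.

    Returns the cell table (``cell_id, fish_id, group, region,
    oxt_positive, ap_um, intensity``) and the ground truth (per-group
    planted multiplier). Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    fish_counter = 0
    for group in sorted(config.groups):
        mult = config.groups[group]
        for _ in range(config.n_fish_per_group):
            fish_id = f"f{fish_counter:03d}"
            fish_counter += 1
            k = config.cells_per_fish
            is_po = rng.random(k) < config.po_fraction
            ap = np.where(
                is_po,
                rng.uniform(*config.ap_range_po, size=k),
                rng.uniform(*config.ap_range_pt, size=k),
            )
            intensity = mult * rng.lognormal(config.meanlog, config.sdlog, size=k)
            for j in range(k):
                rows.append(
                    {
                        "cell_id": f"{fish_id}c{j:03d}",
                        "fish_id": fish_id,
                        "group": group,
                        "region": "PO" if is_po[j] else "PT",
                        "oxt_positive": True,
                        "ap_um": round(float(ap[j]), 1),
                        "intensity": float(intensity[j]),
                    }
                )
    table = pd.DataFrame(rows)
    truth = pd.DataFrame(
        {"group": sorted(config.groups), "planted_multiplier": [config.groups[g] for g in sorted(config.groups)]}
    )
    return table, truth


# ---------------------------------------------------------------------------
# one-stop simulation


@dataclass
class SimulationResult:
    config: GeneratorConfig
    schedule: StimulusSchedule
    traces: TraceSet
    ground_truth: pd.DataFrame
    tail_traces: dict[int, TailTrace]
    bout_truth: dict[int, pd.DataFrame]


def simulate_experiment(config: GeneratorConfig, with_tail: bool | None = None) -> SimulationResult:
    """Generate a full, internally consistent synthetic experiment.

    Tail traces are generated per fish whenever the schedule includes UV
    events or the class mixture contains motor-tuned neurons (override
    with ``with_tail``), and the same bout tables drive the motor
    responses in the fluorescence traces.
    """
    schedule = make_schedule(config)
    needs_tail = any(
        TUNING_CLASSES[c]["motor"] != 0 for c in config.class_mixture
    ) or config.uv_after_cue is not None
    if with_tail is not None:
        needs_tail = with_tail

    tails: dict[int, TailTrace] = {}
    bouts: dict[int, pd.DataFrame] = {}
    if needs_tail:
        tail_seeds = np.random.SeedSequence(config.seed + 1_000_003).generate_state(config.n_fish)
        for f in range(config.n_fish):
            tails[f], bouts[f] = make_tail_trace(config, schedule, seed=int(tail_seeds[f]))
    traces, truth = make_traces(config, schedule, bout_truth=bouts if bouts else None)
    return SimulationResult(config, schedule, traces, truth, tails, bouts)
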