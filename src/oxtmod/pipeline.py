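"""End-to-end orchestration: presets in, tables + manifest out.

``run_figure_preset`` runs the full chain for a generator preset —
simulate, dF/F, smooth, classify, and (for the TRPA1 preset) regressor
correlation, k-means clustering, class assignment, bout extraction and
epoch statistics — and returns every intermediate table. With an output
directory it also writes the tables as CSV plus a JSON manifest (preset,
seed, full config echo, config hash, stage-by-stage counts) from which the
run can be reproduced exactly.

All randomness flows from the single master seed recorded in the manifest:
the generator splits it internally (numpy SeedSequence) and the k-means
seed is derived from it by a fixed offset.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, classify, cluster
from .core import EPOCH_PRESETS
from .regressors import (
    KernelParams,
    RegressorBank,
    build_motor_regressors,
    build_stimulus_regressor,
    correlate,
)
from .presets import preset_config
from .synth import SimulationResult, simulate_experiment
from .traces import compute_dff, smooth_zero_phase

__all__ = ["run_figure_preset", "run_manifest", "build_bank", "modulation_accuracy"]

MOD_TO_CALL = {"suppressed": "suppressed", "enhanced": "enhanced", "none": "no_change"}


def build_bank(
    sim: SimulationResult, fish: int, bouts: pd.DataFrame | None = None
) -> RegressorBank:
    """Stimulus + motor regressor bank for one fish.

    Stimulus regressors are built per cue label (and the UV pulse); motor
    regressors from the fish's bout table (detected bouts if ``bouts`` is
    given, otherwise the generator truth).
    """
    frame_times = sim.traces.frame_times
    params = sim.config.kernel
    regs: dict[str, np.ndarray] = {}
    flags: dict[str, bool] = {}
    for label in sim.schedule.labels():
        name = "stim_uv" if label == "uv_trpa1" else f"stim_{label}"
        regs[name] = build_stimulus_regressor(sim.schedule, label, frame_times, params)
        flags[name] = True
    if bouts is None:
        bouts = sim.bout_truth.get(fish, pd.DataFrame(columns=["onset_s", "peak_angle_deg"]))
    motor, motor_flags = build_motor_regressors(bouts, sim.schedule, frame_times, params)
    regs.update(motor)
    flags.update(motor_flags)
    return RegressorBank(regs, frame_times, flags)


def correlation_matrix(sim: SimulationResult, dff_smooth) -> pd.DataFrame:
    """Pooled neuron x regressor correlations, per-fish motor regressors."""
    parts = []
    for fish in sorted(dff_smooth.neuron_meta["fish_id"].unique()):
        if fish < 0:
            continue  # background ROI
        idx = np.flatnonzero(dff_smooth.neuron_meta["fish_id"].to_numpy() == fish)
        sub = dff_smooth.select(idx)
        bank = build_bank(sim, int(fish))
        parts.append(correlate(sub, bank))
    return pd.concat(parts)


def modulation_accuracy(rt: pd.DataFrame, truth: pd.DataFrame, window_key: str) -> float:
    """Fraction of neurons whose call matches the planted modulation label."""
    col = f"mod_{window_key}"
    if col not in truth.columns:
        raise KeyError(f"ground truth has no column {col}")
    merged = rt.merge(truth[["neuron_id", col]], on="neuron_id")
    expected = merged[col].map(MOD_TO_CALL)
    return float((merged["call"] == expected).mean())


def run_figure_preset(
    preset: str,
    seed: int = 0,
    outdir: str | Path | None = None,
    n_neurons: int | None = None,
    threshold: float = 0.05,
    k: int = 12,
    n_init: int = 50,
    **config_overrides,
) -> dict:
    """Run a preset end to end; deterministic under ``seed``.

    Returns a bundle dict with the config, schedule, ground truth,
    response table(s), call fractions, recovery accuracy, and — for the
    TRPA1 preset — the correlation matrix, cluster model, class fractions,
    detected bouts and epoch bout statistics. Writes CSVs + manifest when
    ``outdir`` is given.
    """
    cfg = preset_config(preset, n_neurons=n_neurons, seed=seed, **config_overrides)
    sim = simulate_experiment(cfg)
    dff = compute_dff(sim.traces, sim.schedule)
    cue = cfg.test_cue()

    bundle: dict = {
        "preset": preset,
        "seed": seed,
        "config": cfg,
        "schedule": sim.schedule.events,
        "ground_truth": sim.ground_truth,
    }
    counts = {"neurons_in": int(sim.traces.n_neurons)}

    windows = list(cfg.modulation_mixture) or ["post_cue_60s"]
    fractions_rows = []
    for wkey in windows:
        rt = classify.classify_responses(
            dff, sim.schedule, cue, "water", EPOCH_PRESETS[wkey], threshold
        )
        bundle[f"response_table_{wkey}"] = rt
        frac = classify.population_fractions(rt)
        frac.insert(0, "window", wkey)
        frac.insert(1, "cue", cue)
        fractions_rows.append(frac)
        bundle[f"accuracy_{wkey}"] = modulation_accuracy(rt, sim.ground_truth, wkey)
        counts[f"classified_{wkey}"] = int(len(rt))
    bundle["fractions"] = pd.concat(fractions_rows, ignore_index=True)

    if cfg.uv_after_cue is not None:
        smooth = smooth_zero_phase(dff, 3)
        corr = correlation_matrix(sim, smooth)
        bundle["correlations"] = corr
        model = cluster.fit_kmeans(corr, k=k, seed=seed + 7919, n_init=n_init)
        bundle["cluster_model"] = model
        bundle["cluster_summary"] = cluster.cluster_summary(model)["table"]
        mapping, class_fracs = cluster.assign_classes(model)
        bundle["class_map"] = mapping
        bundle["class_fractions"] = class_fracs
        counts["clustered"] = int(len(corr))

        bout_rows, epoch_rows = [], []
        for fish, tail in sim.tail_traces.items():
            bouts = behavior.extract_bouts(tail)
            bouts.insert(0, "fish_id", fish)
            bout_rows.append(bouts)
            freq = behavior.epoch_bout_frequency(bouts, sim.schedule)
            freq.insert(0, "fish_id", fish)
            epoch_rows.append(freq)
        if bout_rows:
            bundle["bouts"] = pd.concat(bout_rows, ignore_index=True)
            bundle["epoch_bout_frequency"] = pd.concat(epoch_rows, ignore_index=True)
            counts["bouts_detected"] = int(len(bundle["bouts"]))

    bundle["counts"] = counts
    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _config_dict(cfg) -> dict:
    d = asdict(cfg)
    d["cue_labels"] = list(d["cue_labels"])
    return d


def _write_bundle(bundle: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, obj in bundle.items():
        if isinstance(obj, pd.DataFrame):
            path = outdir / f"{name}.csv"
            obj.to_csv(path, index=isinstance(obj.index, pd.MultiIndex) or obj.index.name is not None)
            written[name] = {"file": path.name, "rows": int(len(obj))}
    model = bundle.get("cluster_model")
    if model is not None:
        model.assignment_frame().to_csv(outdir / "cluster_assignments.csv", index=False)
        model.centroid_frame().to_csv(outdir / "cluster_centroids.csv")
        written["cluster_assignments"] = {"file": "cluster_assignments.csv", "rows": int(len(model.assignments))}

    cfg_dict = _config_dict(bundle["config"])
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
    manifest = {
        "preset": bundle["preset"],
        "seed": bundle["seed"],
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "counts": bundle["counts"],
        "accuracies": {
            key.removeprefix("accuracy_"): bundle[key]
            for key in bundle
            if key.startswith("accuracy_")
        },
        "class_map": {str(k): v for k, v in bundle.get("class_map", {}).items()},
        "tables": written,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def run_manifest(manifest_path: str | Path, outdir: str | Path | None = None) -> dict:
    """Re-run the preset recorded in a manifest (same seed, same tables)."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    return run_figure_preset(
        manifest["preset"],
        seed=manifest["seed"],
        outdir=outdir,
        n_neurons=manifest["config"]["n_fish"] * manifest["config"]["neurons_per_fish"],
    )
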