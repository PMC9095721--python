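"""Threshold classification, sweeps, fractions, and subsampling."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_traceset, simple_schedule
from oxtmod.classify import (
    call_from_delta,
    classify_responses,
    overlap_matrix,
    population_fractions,
    subsample_neurons,
    threshold_sweep,
)
from oxtmod.core import EpochSpec
from oxtmod.synth import GeneratorConfig, simulate_experiment
from oxtmod.traces import compute_dff


def two_cue_traceset(deltas, base=0.0, n_frames=240, dt=0.5):
    """Traces whose kin-vs-water window-mean difference equals ``deltas``."""
    deltas = np.asarray(deltas, dtype=float)
    times = np.arange(n_frames) * dt
    sched = simple_schedule([20.0, 60.0], ["water", "kin"], duration=5.0)
    vals = np.zeros((len(deltas), n_frames))
    w = (times >= 20.0) & (times < 40.0)
    k = (times >= 60.0) & (times < 80.0)
    vals[:, w] = base
    vals[:, k] = base + deltas[:, None]
    return make_traceset(vals, times), sched, EpochSpec("cue", 0.0, 20.0)


class TestCalls:
    def test_boundary_convention(self):
        """delta > +thr enhanced, < -thr suppressed, ties are no_change."""
        ts, sched, window = two_cue_traceset([0.06, -0.06, 0.05, -0.05, 0.0])
        rt = classify_responses(ts, sched, "kin", "water", window, threshold=0.05)
        assert list(rt["call"]) == ["enhanced", "suppressed", "no_change", "no_change", "no_change"]
        np.testing.assert_allclose(
            rt["delta"], rt["mean_integrated_cue"] - rt["mean_integrated_control"], atol=0
        )

    def test_matches_brute_force_reimplementation(self):
        """Direct loops over events and frames agree to 1e-10."""
        rng = np.random.default_rng(10)
        for _ in range(30):
            n_neurons = int(rng.integers(2, 6))
            dt = 0.5
            times = np.arange(500) * dt
            onsets = [30.0, 90.0, 150.0, 210.0]
            labels = ["water", "kin", "water", "kin"]
            sched = simple_schedule(onsets, labels, duration=5.0)
            vals = rng.normal(0, 0.2, size=(n_neurons, len(times)))
            ts = make_traceset(vals, times)
            window = EpochSpec("cue", 0.0, 30.0)
            rt = classify_responses(ts, sched, "kin", "water", window, 0.05)

            for i in range(n_neurons):
                means = {"kin": [], "water": []}
                for onset, label in zip(onsets, labels):
                    acc = [
                        vals[i, j]
                        for j in range(len(times))
                        if onset <= times[j] < onset + 30.0
                    ]
                    means[label].append(sum(acc) / len(acc))
                delta = np.mean(means["kin"]) - np.mean(means["water"])
                assert rt["delta"].iloc[i] == pytest.approx(delta, abs=1e-10)
                expected = (
                    "enhanced" if delta > 0.05 else "suppressed" if delta < -0.05 else "no_change"
                )
                assert rt["call"].iloc[i] == expected

    def test_invariant_to_common_additive_constant(self):
        ts, sched, window = two_cue_traceset([0.08, -0.08, 0.01])
        rt1 = classify_responses(ts, sched, "kin", "water", window)
        rt2 = classify_responses(ts.with_values(ts.values + 5.0), sched, "kin", "water", window)
        np.testing.assert_allclose(rt1["delta"], rt2["delta"], atol=1e-12)
        assert list(rt1["call"]) == list(rt2["call"])

    def test_missing_control_raises(self):
        ts, sched, window = two_cue_traceset([0.0])
        with pytest.raises(ValueError):
            classify_responses(ts, sched, "kin", "adult", window)

    def test_trpa1_window_pairs_uv_events_by_trial(self):
        """UV-anchored windows compare kin-trial UV to water-trial UV."""
        cfg = GeneratorConfig(
            n_fish=1,
            neurons_per_fish=20,
            cue_labels=("water", "kin"),
            isi=300.0,
            duration=1260.0,
            uv_after_cue=30.0,
            class_mixture={"trpa1_moderate": 1.0},
            modulation_mixture={"post_trpa1_5s": {"suppressed": 0.5, "enhanced": 0.0, "none": 0.5}},
            noise_sd=0.0,
            seed=21,
        )
        sim = simulate_experiment(cfg)
        dff = compute_dff(sim.traces, sim.schedule)
        rt = classify_responses(dff, sim.schedule, "kin", "water", "post_trpa1_5s", 0.05)
        merged = rt.merge(sim.ground_truth, on="neuron_id")
        assert (
            merged.loc[merged["mod_post_trpa1_5s"] == "suppressed", "call"] == "suppressed"
        ).all()
        assert (merged.loc[merged["mod_post_trpa1_5s"] == "none", "call"] == "no_change").all()


class TestSweep:
    def test_monotone_and_limits(self):
        ts, sched, window = two_cue_traceset([0.2, -0.2, 0.1, -0.03, 0.0, 0.0])
        sweep = threshold_sweep(
            ts, sched, "kin", "water", window, thresholds=[0.0, 0.05, 0.15, 1.0]
        )
        responding = sweep["frac_suppressed"] + sweep["frac_enhanced"]
        assert (np.diff(responding) <= 1e-12).all()
        # at threshold 0 only exact ties are no_change
        assert sweep["frac_no_change"].iloc[0] == pytest.approx(2 / 6)
        # at a huge threshold everything is no_change
        assert sweep["frac_no_change"].iloc[-1] == 1.0

    def test_invalid_threshold_grid(self):
        ts, sched, window = two_cue_traceset([0.0])
        with pytest.raises(ValueError):
            threshold_sweep(ts, sched, "kin", "water", window, thresholds=[0.1, 0.05])

    def test_planted_fraction_stable_across_thresholds(self):
        """30% suppressed at effect 0.3, noise 0.02: every threshold in
        [0.02, 0.15] recovers the planted fraction within 3 points."""
        cfg = GeneratorConfig(
            n_fish=8,
            neurons_per_fish=125,
            cue_labels=("water", "kin"),
            isi=150.0,
            duration=660.0,
            class_mixture={"cue_suppressed": 0.3, "cue_enhanced": 0.1, "cue_neutral": 0.6},
            effect_size=0.3,
            noise_sd=0.02,
            seed=1,
        )
        sim = simulate_experiment(cfg)
        dff = compute_dff(sim.traces, sim.schedule)
        sweep = threshold_sweep(
            dff,
            sim.schedule,
            "kin",
            window="post_cue_60s",
            thresholds=[0.02, 0.05, 0.1, 0.15],
        )
        planted = (sim.ground_truth["mod_post_cue_60s"] == "suppressed").mean()
        assert np.all(np.abs(sweep["frac_suppressed"] - planted) <= 0.03)


class TestFractions:
    def test_single_neuron(self):
        rt = pd.DataFrame({"neuron_id": ["a"], "call": ["suppressed"]})
        out = population_fractions(rt)
        assert out["frac_suppressed"].iloc[0] == 1.0
        assert out["frac_enhanced"].iloc[0] == 0.0
        assert out["n"].iloc[0] == 1

    def test_fractions_sum_to_one_per_group(self):
        rng = np.random.default_rng(11)
        rt = pd.DataFrame(
            {
                "neuron_id": [f"n{i}" for i in range(300)],
                "call": rng.choice(["suppressed", "enhanced", "no_change"], 300),
                "cue": rng.choice(["kin", "adult"], 300),
            }
        )
        out = population_fractions(rt, by="cue")
        sums = out["frac_suppressed"] + out["frac_enhanced"] + out["frac_no_change"]
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_overlap_matrix_partitions_neurons(self):
        rng = np.random.default_rng(12)
        ids = [f"n{i}" for i in range(100)]
        rt_a = pd.DataFrame({"neuron_id": ids, "call": rng.choice(["suppressed", "enhanced", "no_change"], 100)})
        rt_b = pd.DataFrame({"neuron_id": ids, "call": rng.choice(["suppressed", "enhanced", "no_change"], 100)})
        mat = overlap_matrix(rt_a, rt_b)
        assert mat.to_numpy().sum() == 100

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            population_fractions(pd.DataFrame(columns=["call"]))


class TestSubsampling:
    def make_ts(self, neurons_per_fish, n_fish=12):
        n = n_fish * neurons_per_fish
        vals = np.zeros((n, 10))
        times = np.arange(10.0)
        fish = np.repeat(np.arange(n_fish), neurons_per_fish)
        return make_traceset(vals, times, fish_ids=fish)

    def test_two_stage_counts(self):
        """12 fish x 25 kept in stage 1, stage 2 draws exactly 200 of 300."""
        ts = self.make_ts(40)
        out = subsample_neurons(ts, per_fish=25, per_group=200, seed=0)
        assert out.n_neurons == 200
        assert (out.neuron_meta.groupby("fish_id").size() <= 25).all()

    def test_fish_with_exactly_per_fish_all_retained(self):
        ts = self.make_ts(25)
        out = subsample_neurons(ts, per_fish=25, per_group=None, seed=0)
        assert out.n_neurons == 300
        assert set(out.neuron_meta["neuron_id"]) == set(ts.neuron_meta["neuron_id"])

    def test_deterministic_under_seed(self):
        ts = self.make_ts(40)
        a = subsample_neurons(ts, 25, 200, seed=5)
        b = subsample_neurons(ts, 25, 200, seed=5)
        assert list(a.neuron_meta["neuron_id"]) == list(b.neuron_meta["neuron_id"])

    def test_truncation_warns_and_oversized_group_raises(self):
        ts = self.make_ts(10)
        with pytest.warns(UserWarning, match="keeping all"):
            out = subsample_neurons(ts, per_fish=25, per_group=None, seed=0)
        assert out.n_neurons == 120
        with pytest.raises(ValueError, match="per_group"):
            subsample_neurons(ts, per_fish=10, per_group=500, seed=0)


class TestParameterRecovery:
    def test_call_accuracy_at_4x_threshold(self):
        """Effect 4x threshold, noise effect/8: >= 99% correct calls."""
        accs = []
        for seed in range(10):
            cfg = GeneratorConfig(
                n_fish=8,
                neurons_per_fish=250,
                cue_labels=("water", "kin"),
                isi=150.0,
                duration=660.0,
                class_mixture={"cue_suppressed": 0.3, "cue_enhanced": 0.3, "cue_neutral": 0.4},
                effect_size=0.2,
                noise_sd=0.025,
                seed=seed,
            )
            sim = simulate_experiment(cfg)
            dff = compute_dff(sim.traces, sim.schedule)
            rt = classify_responses(dff, sim.schedule, "kin", "water", "post_cue_60s", 0.05)
            merged = rt.merge(sim.ground_truth, on="neuron_id")
            expected = merged["mod_post_cue_60s"].map(
                {"suppressed": "suppressed", "enhanced": "enhanced", "none": "no_change"}
            )
            accs.append((merged["call"] == expected).mean())
        assert min(accs) >= 0.99
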