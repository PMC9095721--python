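"""dF/F, smoothing, background subtraction, and epoch-summary behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_traceset, simple_schedule
from oxtmod.core import EpochSpec
from oxtmod.synth import GeneratorConfig, make_schedule, make_traces
from oxtmod.traces import (
    compute_dff,
    integrate_epoch,
    normalize_to_reference,
    per_neuron_mean,
    smooth_zero_phase,
    stimulus_triggered_average,
    subtract_background,
)

TIMES = np.arange(0.0, 50.0, 0.5)
SCHED = simple_schedule([20.0], ["water"], duration=5.0)


class TestDff:
    def test_constant_trace_gives_zero(self):
        ts = make_traceset(np.full((2, len(TIMES)), 100.0), TIMES, units="raw")
        dff = compute_dff(ts, SCHED)
        assert dff.units == "dff"
        assert np.allclose(dff.values, 0.0)

    def test_arithmetic(self):
        vals = np.full((1, len(TIMES)), 100.0)
        vals[0, 45] = 150.0
        dff = compute_dff(make_traceset(vals, TIMES, units="raw"), SCHED)
        assert dff.values[0, 45] == pytest.approx(0.5)

    def test_forward_inverse_consistency_with_generator(self):
        """Noiseless planted peak amplitude is recovered exactly by dF/F."""
        c = GeneratorConfig(
            n_fish=1,
            neurons_per_fish=3,
            cue_labels=("water", "kin"),
            isi=300.0,
            duration=1300.0,
            uv_after_cue=30.0,
            class_mixture={"trpa1_strong": 1.0},
            effect_size=0.25,
            noise_sd=0.0,
            flow_response=0.0,
        )
        sched = make_schedule(c)
        ts, _ = make_traces(c, sched)
        dff = compute_dff(ts, sched)
        assert dff.values.max() == pytest.approx(0.25, abs=1e-6)

    def test_roundtrip_reconstructs_raw(self):
        rng = np.random.default_rng(0)
        vals = 100.0 + rng.normal(0, 5, size=(4, len(TIMES)))
        ts = make_traceset(vals, TIMES, units="raw")
        f0 = vals[:, TIMES < 20.0].mean(axis=1)
        dff = compute_dff(ts, SCHED)
        np.testing.assert_allclose(dff.values * f0[:, None] + f0[:, None], vals, rtol=1e-12)

    def test_errors(self):
        ts = make_traceset(np.full((1, len(TIMES)), 100.0), TIMES, units="raw")
        with pytest.raises(ValueError, match="before the first stimulus"):
            compute_dff(ts, simple_schedule([0.0], ["water"]))
        ts_dff = make_traceset(np.zeros((1, len(TIMES))), TIMES, units="dff")
        with pytest.raises(ValueError, match="raw"):
            compute_dff(ts_dff, SCHED)


def brute_force_smooth(x: np.ndarray, window: int) -> np.ndarray:
    """Independent oracle: causal MA forward then backward, reflect padding."""

    def causal(arr):
        pad = np.concatenate([arr[window - 1 : 0 : -1], arr])
        return np.array(
            [pad[i : i + window].mean() for i in range(len(arr))]
        )

    fwd = causal(x)
    return causal(fwd[::-1])[::-1]


class TestSmoothing:
    def test_constant_unchanged(self):
        ts = make_traceset(np.full((1, 30), 3.0), np.arange(30.0))
        assert np.allclose(smooth_zero_phase(ts).values, 3.0)

    def test_zero_phase_preserves_symmetric_peak(self):
        tri = np.concatenate([np.arange(15.0), np.arange(15.0)[::-1]])
        ts = make_traceset(tri[None, :], np.arange(30.0))
        out = smooth_zero_phase(ts, 3)
        assert np.argmax(out.values[0]) == np.argmax(tri)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            x = rng.normal(size=40)
            ts = make_traceset(x[None, :], np.arange(40.0))
            np.testing.assert_allclose(
                smooth_zero_phase(ts, 3).values[0], brute_force_smooth(x, 3), atol=1e-12
            )
        impulse = np.zeros(21)
        impulse[10] = 1.0
        ts = make_traceset(impulse[None, :], np.arange(21.0))
        np.testing.assert_allclose(
            smooth_zero_phase(ts, 3).values[0], brute_force_smooth(impulse, 3), atol=1e-12
        )

    def test_interior_mass_conserved(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=200)
        x[:5] = x[5]  # constant-padded edges
        x[-5:] = x[-6]
        ts = make_traceset(x[None, :], np.arange(200.0))
        out = smooth_zero_phase(ts, 3)
        assert abs(out.values.sum() - x.sum()) < 1e-9

    def test_window_validation(self):
        ts = make_traceset(np.zeros((1, 5)), np.arange(5.0))
        with pytest.raises(ValueError):
            smooth_zero_phase(ts, 4)
        with pytest.raises(ValueError):
            smooth_zero_phase(ts, 7)


class TestBackgroundSubtraction:
    def test_zero_drift_identity(self):
        rng = np.random.default_rng(3)
        vals = 100.0 + rng.normal(0, 1, size=(3, len(TIMES)))
        ts = make_traceset(vals, TIMES, units="raw")
        bg = np.full(len(TIMES), 50.0)
        out, slope = subtract_background(ts, bg)
        assert slope == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(out.values, vals, atol=1e-9)

    def test_noiseless_slope_recovery(self):
        ts = make_traceset(np.full((2, len(TIMES)), 100.0) + 0.2 * TIMES, TIMES, units="raw")
        bg = 30.0 + 0.2 * TIMES
        out, slope = subtract_background(ts, bg)
        assert slope == pytest.approx(0.2, abs=1e-6)
        assert np.allclose(out.values, 100.0, atol=1e-9)

    def test_synthetic_dye_run_restores_flat_baseline(self):
        c = GeneratorConfig(
            n_fish=1,
            neurons_per_fish=4,
            cue_labels=("water", "kin"),
            isi=300.0,
            duration=1300.0,
            drift_slope=0.05,
            noise_sd=0.0,
            include_background_roi=True,
        )
        sched = make_schedule(c)
        ts, _ = make_traces(c, sched)
        is_bg = (ts.neuron_meta["region"] == "background").to_numpy()
        corrected, _ = subtract_background(ts.select(np.flatnonzero(~is_bg)), ts.values[is_bg][0])
        dff = compute_dff(corrected, sched)
        pre = dff.frame_times < sched.first_onset()
        assert np.abs(dff.values[:, pre].mean(axis=1)).max() < 1e-3

    def test_degenerate_background_raises(self):
        ts = make_traceset(np.full((1, len(TIMES)), 10.0), TIMES, units="raw")
        with pytest.raises(ValueError, match="length"):
            subtract_background(ts, np.zeros(3))


class TestSta:
    def test_identical_repeats_equal_single_trial(self):
        times = np.arange(0.0, 60.0, 0.5)
        resp = np.exp(-np.maximum(times - 10.0, 0)) * (times >= 10.0)
        resp += np.exp(-np.maximum(times - 40.0, 0)) * (times >= 40.0)
        ts = make_traceset(resp[None, :], times)
        sched = simple_schedule([10.0, 40.0], ["water", "water"], duration=1.0)
        sta = stimulus_triggered_average(ts, sched, "water", EpochSpec("cue", 0.0, 10.0))
        single = resp[(times >= 10.0) & (times < 20.0)]
        np.testing.assert_allclose(sta["per_neuron"][0], single, atol=1e-12)

    def test_response_plus_negation_averages_to_zero(self):
        times = np.arange(0.0, 60.0, 0.5)
        resp = np.zeros_like(times)
        pulse = np.hanning(10)
        resp[20:30] = pulse
        resp[80:90] = -pulse
        ts = make_traceset(resp[None, :], times)
        sched = simple_schedule([10.0, 40.0], ["water", "water"], duration=1.0)
        sta = stimulus_triggered_average(ts, sched, "water", EpochSpec("cue", 0.0, 10.0))
        np.testing.assert_allclose(sta["per_neuron"][0], 0.0, atol=1e-12)

    def test_averaging_reduces_noise(self):
        """STA RMSE vs the planted response beats the single-trial noise floor."""
        rng = np.random.default_rng(4)
        dt, n_rep, noise_sd = 0.5, 8, 0.1
        times = np.arange(0.0, 800.0, dt)
        onsets = 60.0 + 80.0 * np.arange(n_rep)
        truth = np.exp(-np.arange(0, 20.0, dt) / 3.0)
        signal = np.zeros_like(times)
        for onset in onsets:
            i = int(np.searchsorted(times, onset))
            signal[i : i + len(truth)] += truth
        ts = make_traceset((signal + rng.normal(0, noise_sd, len(times)))[None, :], times)
        sched = simple_schedule(onsets, ["water"] * n_rep, duration=1.0)
        sta = stimulus_triggered_average(ts, sched, "water", EpochSpec("cue", 0.0, 20.0))
        rmse = np.sqrt(np.mean((sta["per_neuron"][0] - truth) ** 2))
        assert rmse < noise_sd / np.sqrt(n_rep) * 1.5

    def test_missing_events_raise(self):
        ts = make_traceset(np.zeros((1, len(TIMES))), TIMES)
        with pytest.raises(ValueError, match="kin"):
            stimulus_triggered_average(ts, SCHED, "kin", EpochSpec("cue", 0.0, 5.0))


class TestIntegrateEpoch:
    def test_constant_window_value(self):
        ts = make_traceset(np.full((2, len(TIMES)), 0.7), TIMES)
        out = integrate_epoch(ts, SCHED, "water", EpochSpec("cue", 0.0, 10.0))
        assert np.allclose(out["value"], 0.7)

    def test_exponential_matches_geometric_series(self):
        """Mean of a sampled exponential equals its closed-form series sum."""
        dt, tau = 0.25, 3.0
        times = np.arange(0.0, 200.0, dt)
        onset = 50.0
        rel = times - onset
        decay = np.where(rel >= 0, np.exp(-rel / tau), 0.0)
        ts = make_traceset(decay[None, :], times)
        sched = simple_schedule([onset], ["water"], duration=1.0)
        out = integrate_epoch(ts, sched, "water", EpochSpec("cue", 0.0, 60.0))
        m = int(round(60.0 / dt))  # frames in window
        r = np.exp(-dt / tau)
        expected = (1 - r**m) / (1 - r) / m  # geometric series mean
        assert out["value"].iloc[0] == pytest.approx(expected, abs=1e-4)

    @settings(deadline=None, max_examples=25)
    @given(
        a=st.floats(-3, 3, allow_nan=False),
        b=st.floats(-3, 3, allow_nan=False),
    )
    def test_linearity(self, a, b):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(1, len(TIMES)))
        y = rng.normal(size=(1, len(TIMES)))
        w = EpochSpec("cue", 0.0, 15.0)

        def integ(v):
            return integrate_epoch(make_traceset(v, TIMES), SCHED, "water", w)["value"].iloc[0]

        assert integ(a * x + b * y) == pytest.approx(a * integ(x) + b * integ(y), abs=1e-9)

    def test_normalize_to_own_water_response(self):
        vals = per_neuron_mean(
            integrate_epoch(make_traceset(np.full((2, len(TIMES)), 0.4), TIMES), SCHED, "water", EpochSpec("cue", 0.0, 10.0))
        )
        ref = vals * 2
        out = normalize_to_reference(vals, ref)
        assert np.allclose(out, 0.5)
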