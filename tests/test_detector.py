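"""Bi-GRU detector: windows, soft targets, training, inference, peak picking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivusgate import (
    DetectorConfig,
    EndDiastoleGRU,
    MotionSignal,
    ProbabilitySeries,
    ReferenceAnnotation,
    SyntheticConfig,
    build_windows,
    hanning_smooth,
    load_model,
    normalize_signal,
    save_model,
    select_end_diastolic_frames,
    simulate_motion_trace,
    train_detector,
)
from ivusgate import _gru


def prepared_signal(values, fps=30.0):
    return MotionSignal(values=np.asarray(values, dtype=float), fps=fps,
                        smoothed=True, smoothing_window=13, normalized=True)


def smooth_trace(cfg: SyntheticConfig):
    trace, truth = simulate_motion_trace(cfg)
    window = 13 if len(trace) >= 14 else 3
    sig = normalize_signal(hanning_smooth(trace, window))
    ref = ReferenceAnnotation(ed_frames=truth.ed_frames, fps=cfg.fps)
    return sig, ref


class TestBuildWindows:
    def test_window_count_is_n_minus_63(self):
        sig = prepared_signal(np.linspace(0, 1, 100))
        ws = build_windows(sig, None, DetectorConfig())
        assert len(ws) == 37

    def test_minimum_length_sequence_gives_one_window(self):
        ws = build_windows(prepared_signal(np.zeros(64)), None, DetectorConfig())
        assert len(ws) == 1

    def test_soft_targets_follow_gaussian_of_anchor_distance(self):
        sig = prepared_signal(np.zeros(100))
        ref = ReferenceAnnotation(ed_frames=[31], fps=30)
        ws = build_windows(sig, ref, DetectorConfig(label_sigma=2.0))
        assert ws.targets[0] == pytest.approx(1.0)  # anchor 31 hits the ED exactly
        assert ws.targets[1] == pytest.approx(np.exp(-1 / 8))  # anchor 32, 1 frame off

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            build_windows(prepared_signal(np.zeros(50)), None, DetectorConfig())

    def test_unprepared_signal_rejected(self):
        raw = MotionSignal(values=np.zeros(100), fps=30)
        with pytest.raises(ValueError, match="smoothed"):
            build_windows(raw, None, DetectorConfig())


class TestTraining:
    def test_zero_epochs_returns_seeded_initialization(self):
        sig = prepared_signal(np.random.default_rng(0).uniform(size=128))
        ws = build_windows(sig, ReferenceAnnotation(ed_frames=[31], fps=30),
                           DetectorConfig())
        cfg = DetectorConfig(max_epochs=0, seed=42, hidden_size=8)
        result = train_detector(ws, cfg)
        expected = _gru.init_params(np.random.default_rng(42), 1, 8)
        for key in expected:
            assert np.array_equal(result.params[key], expected[key])

    def test_training_is_deterministic_given_seed(self):
        sig, ref = smooth_trace(SyntheticConfig(n_frames=200, noise_sigma=0.02, seed=1))
        cfg = DetectorConfig(hidden_size=8, max_epochs=2, batch_size=8, seed=5)
        ws = build_windows(sig, ref, cfg)
        a = train_detector(ws, cfg)
        b = train_detector(ws, cfg)
        for key in a.params:
            assert np.array_equal(a.params[key], b.params[key])

    def test_empty_window_set_rejected(self):
        from ivusgate.detector import WindowSet

        empty = WindowSet(windows=np.empty((0, 64)), targets=np.empty(0),
                          source_ids=[], start_indices=np.empty(0))
        with pytest.raises(ValueError, match="empty"):
            train_detector(empty)


@pytest.fixture(scope="module")
def overfit():
    cfg = SyntheticConfig(n_frames=263, fps=30, hr_mean=72, hr_jitter=0,
                          noise_sigma=0.0, seed=2)
    sig, ref = smooth_trace(cfg)
    dcfg = DetectorConfig(hidden_size=32, max_epochs=40, batch_size=8, seed=9)
    ws = build_windows(sig, ref, dcfg)
    assert len(ws) == 200
    model = train_detector(ws, dcfg)
    return model, sig, ref


class TestOverfitContract:
    """Training on ~200 windows of one noise-free trace must drive the MSE
    below 0.02 and localize end-diastole to within a frame on that trace."""

    def test_final_mse_below_contract(self, overfit):
        model, _, _ = overfit
        assert model.loss_trace[-1] < 0.02
        assert model.loss_trace[-1] < model.loss_trace[0]

    def test_within_cycle_argmax_near_truth(self, overfit):
        model, sig, ref = overfit
        probs = model.predict(sig).values
        eds = ref.ed_frames
        hits = 0
        interior = [e for e in eds if 12 < e < len(sig) - 13]
        for ed in interior:
            local = np.argmax(probs[ed - 12 : ed + 13]) - 12
            hits += abs(local) <= 1
        assert hits / len(interior) >= 0.9

    def test_summary_mentions_fit_quality(self, overfit):
        model, _, _ = overfit
        text = model.summary()
        assert "training windows" in text and "final epoch MSE" in text


class TestPrediction:
    def test_prediction_deterministic(self, trace_config):
        sig, ref = smooth_trace(trace_config)
        cfg = DetectorConfig(hidden_size=8, max_epochs=1, batch_size=32, seed=0)
        model = train_detector(build_windows(sig, ref, cfg), cfg)
        p1 = model.predict(sig)
        p2 = model.predict(sig)
        assert np.array_equal(p1.values, p2.values)
        assert len(p1.values) == len(sig)

    def test_constant_signal_gives_constant_series(self):
        sig = prepared_signal(np.zeros(128))
        ws = build_windows(prepared_signal(np.random.default_rng(3).uniform(size=128)),
                           ReferenceAnnotation(ed_frames=[40], fps=30),
                           DetectorConfig())
        cfg = DetectorConfig(hidden_size=8, max_epochs=1, seed=0, batch_size=16)
        model = train_detector(ws, cfg)
        p = model.predict(sig).values
        assert np.allclose(p, p[0])

    def test_short_sequence_rejected(self):
        cfg = DetectorConfig(hidden_size=8, max_epochs=0, seed=0)
        ws = build_windows(prepared_signal(np.zeros(64)), None, cfg)
        model = train_detector(ws, cfg)
        with pytest.raises(ValueError, match="too short"):
            model.predict(prepared_signal(np.zeros(30)))


class TestPeakSelection:
    def test_non_maximum_suppression_example(self):
        p = ProbabilitySeries(values=[0.1, 0.2, 0.9, 0.3, 0.1, 0.2, 0.8, 0.2], fps=30)
        out = select_end_diastolic_frames(p, min_distance=3, threshold=0.25)
        assert list(out.ed_frames) == [2, 6]

    def test_all_zero_probabilities_give_empty_output(self):
        p = ProbabilitySeries(values=np.zeros(50), fps=30)
        assert len(select_end_diastolic_frames(p)) == 0

    def test_single_interior_spike(self):
        v = np.zeros(50)
        v[20] = 0.9
        out = select_end_diastolic_frames(ProbabilitySeries(values=v, fps=30))
        assert list(out.ed_frames) == [20]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 20))
    def test_selected_peaks_respect_min_distance(self, seed, min_distance):
        rng = np.random.default_rng(seed)
        p = ProbabilitySeries(values=rng.uniform(size=100), fps=30)
        out = select_end_diastolic_frames(p, min_distance=min_distance, threshold=0.1)
        if len(out) > 1:
            assert np.diff(out.ed_frames).min() >= min_distance


class TestPersistence:
    def test_round_trip_preserves_predictions(self, tmp_path, trace_config):
        sig, ref = smooth_trace(trace_config)
        cfg = DetectorConfig(hidden_size=8, max_epochs=1, batch_size=32, seed=0)
        model = train_detector(build_windows(sig, ref, cfg), cfg)
        path = tmp_path / "model.npz"
        save_model(model, path)
        back = load_model(path)
        assert np.array_equal(model.predict(sig).values, back.predict(sig).values)
        assert back.config == model.config

    def test_version_mismatch_rejected(self, tmp_path):
        import json

        path = tmp_path / "old.npz"
        meta = {"version": "ivusgate-detector-0", "config": {}}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 loss_trace=np.empty(0))
        with pytest.raises(ValueError, match="version"):
            load_model(path)

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises((ValueError, FileNotFoundError)):
            load_model(tmp_path / "nope.npz")
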