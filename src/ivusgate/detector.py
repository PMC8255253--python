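"""End-diastolic frame detector: a bidirectional GRU over motion-signal windows.

The detector scores 64-frame windows of the smoothed, normalized motion
signal and outputs the probability that the window's anchor frame (0-based
offset 31, i.e. the 32nd frame) is end-diastolic. Sliding the window
frame-by-frame over a sequence of ``n`` frames yields ``n - 63`` windows;
training minimizes the mean square error between the predicted anchor
probability and a soft Gaussian label centred on the reference end-diastolic
frames. At inference the per-frame probability series is scanned for local
maxima with a minimum spacing, which become the detected end-diastolic
frames.

The public surface follows the model/results idiom: build an
:class:`EndDiastoleGRU` from a :class:`WindowSet`, call :meth:`fit`, and use
the returned :class:`DetectorResults` for prediction, persistence and
summaries. Functional wrappers (:func:`train_detector`,
:func:`predict_frame_probabilities`, ...) expose the same operations.
"""

from __future__ import annotations

import io as _stdio
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _gru
from .io import ReferenceAnnotation
from .motion import MotionSignal

MODEL_FORMAT_VERSION = "ivusgate-detector-1"

WINDOW_LEN = 64
ANCHOR = 31  # 0-based offset of the scored frame within the window


@dataclass
class DetectorConfig:
    """Hyperparameters of the windowed Bi-GRU detector.

    ``window_len`` and ``anchor`` are fixed by the method (a 64-frame window
    spans at least two cardiac cycles at 19–30 frames per cycle; the 32nd
    frame is scored). Training defaults: mean-square-error loss, learning
    rate 1e-3, at most 50 epochs, batch size 1, no validation split.
    """

    window_len: int = WINDOW_LEN
    anchor: int = ANCHOR
    label_sigma: float = 2.0
    hidden_size: int = 64
    num_layers: int = 1
    learning_rate: float = 1e-3
    max_epochs: int = 50
    batch_size: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_len < 2 or self.anchor < 0 or self.anchor >= self.window_len:
            raise ValueError("anchor must lie inside the window")
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be > 0, got {self.learning_rate}")
        if self.max_epochs < 0:
            raise ValueError(f"max_epochs must be >= 0, got {self.max_epochs}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.num_layers != 1:
            raise ValueError("only single-layer GRUs are supported (num_layers=1)")
        if self.hidden_size < 1:
            raise ValueError(f"hidden_size must be >= 1, got {self.hidden_size}")


@dataclass
class WindowSet:
    """Sliding windows of a motion signal plus their soft anchor targets."""

    windows: np.ndarray  # (N, window_len)
    targets: np.ndarray  # (N,)
    source_ids: list[str]
    start_indices: np.ndarray

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        self.start_indices = np.asarray(self.start_indices, dtype=np.int64)
        if self.windows.shape[0] != self.targets.shape[0]:
            raise ValueError("windows and targets must have matching counts")
        if self.targets.size and (self.targets.min() < 0 or self.targets.max() > 1):
            raise ValueError("targets must lie in [0, 1]")

    def __len__(self) -> int:
        return int(self.windows.shape[0])

    @classmethod
    def concat(cls, parts: list["WindowSet"]) -> "WindowSet":
        if not parts:
            raise ValueError("cannot concatenate an empty list of window sets")
        return cls(
            windows=np.concatenate([p.windows for p in parts]),
            targets=np.concatenate([p.targets for p in parts]),
            source_ids=[s for p in parts for s in p.source_ids],
            start_indices=np.concatenate([p.start_indices for p in parts]),
        )


@dataclass
class ProbabilitySeries:
    """Per-frame end-diastolic probability, one value per pullback frame."""

    values: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and (self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")


def soft_labels(n: int, ed_frames: np.ndarray, sigma: float) -> np.ndarray:
    """End-diastolic indicator blurred with a Gaussian of SD ``sigma`` frames."""
    g = np.zeros(n)
    idx = np.arange(n, dtype=float)
    for ed in np.asarray(ed_frames, dtype=float):
        g = np.maximum(g, np.exp(-((idx - ed) ** 2) / (2.0 * sigma**2)))
    return g


def build_windows(
    sig: MotionSignal,
    truth: ReferenceAnnotation | None,
    config: DetectorConfig,
) -> WindowSet:
    """All ``n - window_len + 1`` sliding windows of a signal with targets.

    The target of the window starting at ``s`` is the soft label of frame
    ``s + anchor``. With no reference annotation every target is 0
    (inference-only window sets).
    """
    n = len(sig)
    if n < config.window_len:
        raise ValueError(f"sequence too short: {n} frames < window length {config.window_len}")
    if not sig.smoothed or not sig.normalized:
        raise ValueError("detector windows require a smoothed, normalized motion signal")
    windows = np.lib.stride_tricks.sliding_window_view(sig.values, config.window_len).copy()
    starts = np.arange(windows.shape[0])
    if truth is None:
        targets = np.zeros(windows.shape[0])
    else:
        g = soft_labels(n, truth.ed_frames, config.label_sigma)
        targets = g[starts + config.anchor]
    sid = getattr(sig, "id", "")
    return WindowSet(
        windows=windows,
        targets=targets,
        source_ids=[sid] * windows.shape[0],
        start_indices=starts,
    )


class EndDiastoleGRU:
    """Bi-GRU scorer of motion-signal windows (model object).

    Parameters
    ----------
    windows : WindowSet
        Training windows and soft targets, typically the concatenation of
        :func:`build_windows` over several pullbacks of one vessel type.
    config : DetectorConfig
        Architecture and optimization settings.
    """

    def __init__(self, windows: WindowSet, config: DetectorConfig | None = None):
        if len(windows) == 0:
            raise ValueError("cannot train on an empty window set")
        self.windows = windows
        self.config = config or DetectorConfig()

    def fit(self) -> "DetectorResults":
        """Minimize the MSE between predicted and target anchor probabilities.

        Windows are shuffled every epoch and consumed in mini-batches of
        ``batch_size`` with Adam at the configured learning rate. With
        ``max_epochs=0`` the seeded initial parameters are returned
        untouched. Deterministic for a given config seed.
        """
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        params = _gru.init_params(rng, input_size=1, hidden_size=cfg.hidden_size)
        X = self.windows.windows[:, :, None]
        y = self.windows.targets
        opt = _gru.Adam(params, lr=cfg.learning_rate)
        trace = []
        for _ in range(cfg.max_epochs):
            perm = rng.permutation(len(y))
            epoch_loss = 0.0
            for lo in range(0, len(y), cfg.batch_size):
                batch = perm[lo : lo + cfg.batch_size]
                loss, _, grads = _gru.loss_and_grads(params, X[batch], y[batch])
                opt.step(params, grads)
                epoch_loss += loss * len(batch)
            trace.append(epoch_loss / len(y))
        return DetectorResults(
            params=params,
            config=cfg,
            loss_trace=np.asarray(trace),
            n_train_windows=len(y),
        )


@dataclass
class DetectorResults:
    """A fitted detector: parameters, training trace, prediction, persistence."""

    params: dict
    config: DetectorConfig
    loss_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_train_windows: int = 0

    def predict(self, sig: MotionSignal, pad_edges: bool = True) -> ProbabilitySeries:
        """Per-frame end-diastolic probability for a whole pullback.

        Frame ``i`` in ``[anchor, n - (window_len - anchor)]`` is scored from
        the window starting at ``i - anchor``. With ``pad_edges`` (default)
        the signal is reflect-padded so boundary frames get probabilities
        too; otherwise boundary frames score 0.
        """
        cfg = self.config
        n = len(sig)
        if n < cfg.window_len:
            raise ValueError(f"sequence too short: {n} frames < window length {cfg.window_len}")
        if not sig.smoothed or not sig.normalized:
            raise ValueError("prediction requires a smoothed, normalized motion signal")
        left = cfg.anchor
        right = cfg.window_len - cfg.anchor - 1
        if pad_edges:
            padded = np.pad(sig.values, (left, right), mode="reflect")
            wins = np.lib.stride_tricks.sliding_window_view(padded, cfg.window_len)
            probs = self._predict_windows(wins)
        else:
            wins = np.lib.stride_tricks.sliding_window_view(sig.values, cfg.window_len)
            inner = self._predict_windows(wins)
            probs = np.zeros(n)
            probs[left : left + inner.size] = inner
        return ProbabilitySeries(values=probs, fps=sig.fps)

    def _predict_windows(self, wins: np.ndarray, chunk: int = 1024) -> np.ndarray:
        out = np.empty(wins.shape[0])
        for lo in range(0, wins.shape[0], chunk):
            out[lo : lo + chunk] = _gru.predict(
                self.params, np.ascontiguousarray(wins[lo : lo + chunk, :, None])
            )
        return out

    def summary(self) -> str:
        """Human-readable fit report."""
        cfg = self.config
        n_params = sum(v.size for v in self.params.values())
        buf = _stdio.StringIO()
        buf.write("End-diastolic Bi-GRU detector\n")
        buf.write("=" * 46 + "\n")
        rows = [
            ("window length (frames)", cfg.window_len),
            ("anchor offset", cfg.anchor),
            ("hidden units / direction", cfg.hidden_size),
            ("parameters", n_params),
            ("training windows", self.n_train_windows),
            ("epochs run", len(self.loss_trace)),
            ("learning rate", cfg.learning_rate),
            ("batch size", cfg.batch_size),
        ]
        if len(self.loss_trace):
            rows.append(("initial epoch MSE", f"{self.loss_trace[0]:.6f}"))
            rows.append(("final epoch MSE", f"{self.loss_trace[-1]:.6f}"))
        for name, val in rows:
            buf.write(f"{name:<28}{val}\n")
        return buf.getvalue()

    def save(self, path) -> None:
        """Persist parameters + config + format version as a single .npz."""
        meta = {"version": MODEL_FORMAT_VERSION, "config": asdict(self.config),
                "n_train_windows": self.n_train_windows}
        np.savez(
            path,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            loss_trace=self.loss_trace,
            **self.params,
        )

    @classmethod
    def load(cls, path) -> "DetectorResults":
        try:
            archive = np.load(path)
        except Exception as exc:
            raise ValueError(f"cannot read model file {path}: {exc}") from exc
        if "__meta__" not in archive:
            raise ValueError(f"{path} is not a detector model file")
        meta = json.loads(archive["__meta__"].tobytes().decode())
        if meta.get("version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"model format version mismatch: file has {meta.get('version')!r}, "
                f"expected {MODEL_FORMAT_VERSION!r}"
            )
        params = {k: archive[k] for k in archive.files if k not in ("__meta__", "loss_trace")}
        return cls(
            params=params,
            config=DetectorConfig(**meta["config"]),
            loss_trace=archive["loss_trace"],
            n_train_windows=meta.get("n_train_windows", 0),
        )


def train_detector(train_windows: WindowSet, config: DetectorConfig | None = None) -> DetectorResults:
    """Fit the Bi-GRU detector on a window set (functional wrapper)."""
    return EndDiastoleGRU(train_windows, config).fit()


def predict_frame_probabilities(
    model: DetectorResults, sig: MotionSignal, pad_edges: bool = True
) -> ProbabilitySeries:
    """Per-frame end-diastolic probabilities (functional wrapper)."""
    return model.predict(sig, pad_edges=pad_edges)


def select_end_diastolic_frames(
    probs: ProbabilitySeries,
    min_distance: int = 13,
    threshold: float = 0.3,
) -> ReferenceAnnotation:
    """Greedy non-maximum suppression over the probability series.

    Candidates are local maxima above ``threshold`` (plateaus contribute
    their first frame); they are accepted in descending probability (ties
    toward the earlier frame) and any candidate closer than ``min_distance``
    frames to an accepted peak is discarded. The default spacing of 13
    frames matches the smoothing window and stays below the shortest
    plausible cardiac cycle at 30 fps.
    """
    p = probs.values
    n = p.size
    candidates = []
    for i in range(n):
        left_ok = i == 0 or p[i] > p[i - 1]
        right_ok = i == n - 1 or p[i] >= p[i + 1]
        if left_ok and right_ok and p[i] > threshold:
            candidates.append(i)
    # descending probability, earlier frame wins ties
    candidates.sort(key=lambda i: (-p[i], i))
    accepted: list[int] = []
    for i in candidates:
        if all(abs(i - j) >= min_distance for j in accepted):
            accepted.append(i)
    return ReferenceAnnotation(ed_frames=np.sort(accepted), fps=probs.fps)


def save_model(model: DetectorResults, path) -> None:
    model.save(path)


def load_model(path) -> DetectorResults:
    return DetectorResults.load(path)
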