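"""Synthetic IVUS pullbacks with known end-diastolic frames.

The simulator emulates the motion structure the detector relies on: a
cross-sectional lumen whose center and radius follow a smooth cardiac
waveform, quiescent during diastasis (the period ending at each
end-diastolic frame) and moving during systole/early diastole. Cycle lengths
are drawn around ``fps * 60 / hr_mean`` with a configurable per-cycle
fractional jitter, so a 30 fps pullback at 60–94 bpm produces the 19–30
frame cycles typical of clinical sequences. Speckle is modeled as
multiplicative Rayleigh-like noise on a smooth wall/lumen template.

By construction the R-peak coincides with the end-diastolic frame: cardiac
phase is zero exactly at each ``ed_frame`` and the noise-free motion
waveform has a local minimum there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import FrameSequence
from .motion import MotionSignal

# Duration of the mechanically active part of the cycle (systolic contraction
# + early-diastolic relaxation/rapid filling), roughly constant in absolute
# time across heart rates; rate changes mostly stretch the diastasis plateau
# that ends at the next end-diastolic frame.
_ACTIVE_SECONDS = 0.55

# Per-vessel-type multipliers on the motion amplitude. Invented: the right
# coronary artery moves most with the cardiac cycle, the LAD least.
VESSEL_MOTION_SCALE = {"LAD": 1.0, "LCx": 1.2, "RCA": 1.6}


@dataclass
class SyntheticConfig:
    """Operating regime of a simulated pullback.

    Defaults mirror a 30 fps clinical acquisition at a resting heart rate,
    with lumen pulsation up to ~10% of the baseline radius.
    """

    n_frames: int = 3000
    fps: float = 30.0
    image_size: int = 128
    hr_mean: float = 72.0
    hr_jitter: float = 0.05
    radius_base: float = 20.0
    radius_pulse_frac: float = 0.10
    center_amplitude: float = 3.0
    drift_per_frame: float = 0.0
    noise_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            ("n_frames", self.n_frames >= 64, ">= 64"),
            ("fps", self.fps > 0, "> 0"),
            ("hr_mean", 30 <= self.hr_mean <= 150, "in [30, 150]"),
            ("radius_pulse_frac", 0 <= self.radius_pulse_frac <= 0.2, "in [0, 0.2]"),
            ("hr_jitter", self.hr_jitter >= 0, ">= 0"),
            ("radius_base", self.radius_base >= 0, ">= 0"),
            ("center_amplitude", self.center_amplitude >= 0, ">= 0"),
            ("drift_per_frame", self.drift_per_frame >= 0, ">= 0"),
            ("noise_sigma", self.noise_sigma >= 0, ">= 0"),
            ("image_size", self.image_size >= 8, ">= 8"),
        ]
        for name, ok, rule in checks:
            if not ok:
                raise ValueError(f"SyntheticConfig.{name} must be {rule}, got {getattr(self, name)}")


@dataclass
class GroundTruth:
    """True end-diastolic frame indices and the per-cycle R-R durations."""

    ed_frames: np.ndarray
    rr_intervals_ms: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.ed_frames = np.asarray(self.ed_frames, dtype=np.int64)
        self.rr_intervals_ms = np.asarray(self.rr_intervals_ms, dtype=float)
        if self.ed_frames.size and np.any(np.diff(self.ed_frames) < 2):
            raise ValueError("consecutive end-diastolic frames must differ by >= 2")
        if self.rr_intervals_ms.size != max(0, self.ed_frames.size - 1):
            raise ValueError("rr_intervals_ms must have one entry per cycle")


def _draw_cycles(config: SyntheticConfig, rng: np.random.Generator):
    """End-diastolic frame indices and per-frame active-phase progress.

    Cycle lengths are drawn around ``fps * 60 / hr_mean`` with fractional SD
    ``hr_jitter``. Within each cycle the mechanically active period has a
    fixed absolute duration (:data:`_ACTIVE_SECONDS`, capped at the cycle
    length); the returned per-frame array ``a`` rises linearly 0 → 1 over
    the active period and stays at 1 on the diastasis plateau, so ``a = 0``
    exactly at each end-diastolic frame.
    """
    period = config.fps * 60.0 / config.hr_mean
    ed = [0]
    while True:
        length = period * (1.0 + config.hr_jitter * rng.standard_normal())
        length = max(2, int(round(length)))
        nxt = ed[-1] + length
        if nxt >= config.n_frames:
            trailing = length  # the trailing partial cycle keeps this length
            break
        ed.append(nxt)
    ed_frames = np.asarray(ed, dtype=np.int64)

    a = np.empty(config.n_frames)
    bounds = np.append(ed_frames, ed_frames[-1] + trailing)
    for start, stop in zip(bounds[:-1], bounds[1:]):
        hi = min(int(stop), config.n_frames)
        active_frames = max(2.0, min(stop - start - 1.0, _ACTIVE_SECONDS * config.fps))
        a[start:hi] = np.clip((np.arange(start, hi) - start) / active_frames, 0.0, 1.0)
    rr_ms = np.diff(ed_frames) * 1000.0 / config.fps
    return ed_frames, a, rr_ms


def _pulse(a: np.ndarray) -> np.ndarray:
    """Raised-cosine displacement bump over the active phase: zero at each
    end-diastolic frame and on the diastasis plateau, one smooth bump in
    between."""
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * a))


def _loop_progress(a: np.ndarray) -> np.ndarray:
    """Monotone progress 0 → 1 around the cardiac motion loop during the
    active phase (half-sine speed profile: brisk takeoff after the R-wave,
    single motion burst per cycle), constant 1 on the diastasis plateau.
    The lumen traces a closed loop relative to the catheter instead of
    retracing its path, so the frame-to-frame dissimilarity shows one
    quiescence and one burst per cycle."""
    return 0.5 * (1.0 - np.cos(np.pi * a))


def simulate_pullback(config: SyntheticConfig) -> tuple[FrameSequence, GroundTruth]:
    """Render a synthetic pullback as an 8-bit grayscale frame stack.

    Each frame shows a dark lumen inside a bright vessel-wall ring; the ring
    center and radius pulse with the cardiac waveform, an optional slow
    texture drift emulates catheter pullback, and multiplicative
    Rayleigh-like speckle is applied last. Bit-identical for a given config.
    """
    rng = np.random.default_rng(config.seed)
    ed_frames, a, rr_ms = _draw_cycles(config, rng)
    S = _loop_progress(a)

    size = config.image_size
    c0 = size / 2.0
    yy, xx = np.mgrid[0:size, 0:size].astype(float)

    # closed-loop center excursion: back at the start point by end-systole,
    # stationary on the diastasis plateau
    cx = c0 + 0.5 * config.center_amplitude * np.sin(2.0 * np.pi * S)
    cy = c0 + 0.3 * config.center_amplitude * (1.0 - np.cos(2.0 * np.pi * S))
    radius = config.radius_base * (
        1.0 + config.radius_pulse_frac * 0.5 * (1.0 - np.cos(2.0 * np.pi * S))
    )
    t = np.arange(config.n_frames)

    frames = np.empty((config.n_frames, size, size), dtype=np.uint8)
    chunk = 256
    for lo in range(0, config.n_frames, chunk):
        hi = min(lo + chunk, config.n_frames)
        d = np.sqrt(
            (xx[None] - cx[lo:hi, None, None]) ** 2
            + (yy[None] - cy[lo:hi, None, None]) ** 2
        )
        wall = radius[lo:hi, None, None] + 5.0
        img = 40.0 + 180.0 * np.exp(-(((d - wall) / 6.0) ** 2))
        if config.drift_per_frame > 0:
            # slow deterministic texture drift along the pullback axis
            shift = config.drift_per_frame * t[lo:hi, None, None]
            img += 12.0 * np.sin(2 * np.pi * (xx[None] + shift) / 17.0) * np.sin(
                2 * np.pi * yy[None] / 23.0
            )
        if config.noise_sigma > 0:
            ray = rng.rayleigh(scale=1.0, size=img.shape)
            ray_mean = np.sqrt(np.pi / 2.0)
            img = img * (1.0 + config.noise_sigma * (ray - ray_mean) / ray_mean)
        np.clip(img, 0, 255, out=img)
        frames[lo:hi] = img.astype(np.uint8)

    seq = FrameSequence(frames=frames, fps=config.fps, vessel_type="unknown", id="synthetic")
    return seq, GroundTruth(ed_frames=ed_frames, rr_intervals_ms=rr_ms)


def simulate_motion_trace(config: SyntheticConfig) -> tuple[MotionSignal, GroundTruth]:
    """Fast surrogate: the per-frame motion signal without image synthesis.

    A periodic non-negative bump train with minima at the end-diastolic
    frames, plus additive Gaussian noise clipped at zero. Shares the cycle
    machinery (and therefore ground truth) with :func:`simulate_pullback`.
    """
    rng = np.random.default_rng(config.seed)
    ed_frames, a, rr_ms = _draw_cycles(config, rng)
    amplitude = config.center_amplitude + config.radius_base * config.radius_pulse_frac
    values = amplitude * _pulse(a)
    if config.noise_sigma > 0:
        values = values + config.noise_sigma * rng.standard_normal(values.size)
    values = np.clip(values, 0.0, None)
    sig = MotionSignal(values=values, fps=config.fps, smoothed=False)
    return sig, GroundTruth(ed_frames=ed_frames, rr_intervals_ms=rr_ms)


def simulate_cohort(
    n_vessels_per_type: int,
    base_config: SyntheticConfig,
    seed: int,
) -> list[tuple[FrameSequence, GroundTruth]]:
    """A labeled cohort: ``n_vessels_per_type`` pullbacks per coronary artery.

    Vessel types get distinct motion-amplitude profiles (RCA largest) and
    each vessel draws its own heart rate within ±15% of ``hr_mean``. Fully
    deterministic from ``seed``.
    """
    if n_vessels_per_type < 2:
        raise ValueError(
            "need at least 2 vessels per type (leave-one-out needs >= 1 train + 1 test)"
        )
    master = np.random.default_rng(seed)
    cohort: list[tuple[FrameSequence, GroundTruth]] = []
    for vtype in ("LAD", "LCx", "RCA"):
        scale = VESSEL_MOTION_SCALE[vtype]
        for k in range(n_vessels_per_type):
            hr = base_config.hr_mean * master.uniform(0.85, 1.15)
            sub_seed = int(master.integers(0, 2**31 - 1))
            cfg = SyntheticConfig(
                n_frames=base_config.n_frames,
                fps=base_config.fps,
                image_size=base_config.image_size,
                hr_mean=hr,
                hr_jitter=base_config.hr_jitter,
                radius_base=base_config.radius_base,
                radius_pulse_frac=base_config.radius_pulse_frac,
                center_amplitude=base_config.center_amplitude * scale,
                drift_per_frame=base_config.drift_per_frame,
                noise_sigma=base_config.noise_sigma,
                seed=sub_seed,
            )
            seq, truth = simulate_pullback(cfg)
            seq.vessel_type = vtype
            seq.id = f"{vtype}-{k}"
            cohort.append((seq, truth))
    return cohort
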