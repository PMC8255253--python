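"""Per-frame lumen-motion signal from an IVUS frame stack.

The motion of the lumen relative to the imaging catheter is summarized by one
scalar per frame: after 2-D median filtering, the absolute grayscale
difference between corresponding pixels of consecutive frames is summed over
the whole image, and the resulting series is smoothed with a unit-sum Hanning
window (13 frames by default). End-diastolic frames sit at the minima of this
signal because the heart is quiescent just before the R-wave.

Conventions: the difference series is indexed so that ``values[i]`` describes
the motion *into* frame ``i`` (``values[0] = 0``), giving a signal of the same
length ``n`` as the stack — which in turn yields the ``n - 63`` sliding
windows the detector expects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .io import FrameSequence

DEFAULT_SMOOTHING_WINDOW = 13


@dataclass
class MotionSignal:
    """One non-negative motion scalar per frame of a pullback."""

    values: np.ndarray
    fps: float
    smoothed: bool = False
    smoothing_window: int | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("motion signal must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("motion signal contains non-finite values")
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if not self.normalized and self.values.size and self.values.min() < 0:
            raise ValueError("unnormalized motion signal must be non-negative")

    def __len__(self) -> int:
        return int(self.values.size)


def median_filter_frames(seq: FrameSequence, kernel: int = 3) -> FrameSequence:
    """2-D median filter every frame (reflect edge handling).

    ``kernel=1`` is the identity. The kernel must be odd so the filter is
    centred and unbiased.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"median kernel must be a positive odd integer, got {kernel}")
    if kernel == 1:
        return seq
    filtered = ndimage.median_filter(seq.frames, size=(1, kernel, kernel), mode="reflect")
    return replace(seq, frames=filtered)


def interframe_difference_signal(seq: FrameSequence) -> MotionSignal:
    """Sum of absolute pixel differences between consecutive frames.

    ``values[i] = sum |frame[i] - frame[i-1]|`` for ``i >= 1``; ``values[0]``
    is 0 by convention so the signal has one entry per frame.
    """
    if seq.n_frames < 2:
        raise ValueError("need at least 2 frames for an inter-frame difference signal")
    frames = seq.frames.astype(np.float64, copy=False)
    diffs = np.abs(np.diff(frames, axis=0)).sum(axis=(1, 2))
    values = np.concatenate([[0.0], diffs])
    return MotionSignal(values=values, fps=seq.fps, smoothed=False)


def hanning_smooth(sig: MotionSignal, window: int = DEFAULT_SMOOTHING_WINDOW) -> MotionSignal:
    """Smooth with a Hanning window normalized to unit sum (reflect padding).

    The output is a convex combination of input samples, so it never exceeds
    the input range and preserves constants exactly.
    """
    n = len(sig)
    if window % 2 == 0 or window < 3:
        raise ValueError(f"smoothing window must be odd and >= 3, got {window}")
    if window > n:
        raise ValueError(f"smoothing window {window} exceeds signal length {n}")
    weights = np.hanning(window)
    weights = weights / weights.sum()
    half = window // 2
    padded = np.pad(sig.values, half, mode="reflect")
    smoothed = np.convolve(padded, weights, mode="valid")
    return replace(sig, values=smoothed, smoothed=True, smoothing_window=window)


def normalize_signal(sig: MotionSignal) -> MotionSignal:
    """Per-sequence min–max scaling to [0, 1] (constant signals map to 0)."""
    v = sig.values
    span = v.max() - v.min() if v.size else 0.0
    scaled = (v - v.min()) / span if span > 0 else np.zeros_like(v)
    return replace(sig, values=scaled, normalized=True)


def extract_motion_signal(
    seq: FrameSequence,
    kernel: int = 3,
    window: int = DEFAULT_SMOOTHING_WINDOW,
    normalize: bool = True,
) -> MotionSignal:
    """Full pipeline: median filter → inter-frame difference → Hanning smooth.

    With ``normalize=True`` (the default used for detector training and
    inference) the smoothed signal is min–max scaled per sequence so that
    pullbacks with different intensity scales are comparable.
    """
    if seq.n_frames < window + 1:
        raise ValueError(
            f"need at least window+1 = {window + 1} frames, got {seq.n_frames}"
        )
    sig = interframe_difference_signal(median_filter_frames(seq, kernel))
    sig = hanning_smooth(sig, window)
    if normalize:
        sig = normalize_signal(sig)
    return sig
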