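"""Plot helpers for motion signals, probability series and Bland–Altman plots.

All functions draw onto a provided or freshly created matplotlib ``Axes``
and return it; figure saving is left to the caller.
"""

from __future__ import annotations

import numpy as np

from .detector import ProbabilitySeries
from .evaluation import AgreementStats, bland_altman
from .motion import MotionSignal


def _get_ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(9, 3))
    return ax


def plot_motion_signal(sig: MotionSignal, ed_frames=None, ax=None):
    """Motion signal over frame index, with optional end-diastolic markers."""
    ax = _get_ax(ax)
    ax.plot(sig.values, lw=0.8, color="C0")
    if ed_frames is not None:
        ed = np.asarray(ed_frames, dtype=int)
        ax.plot(ed, sig.values[ed], "v", color="C3", ms=5, label="end-diastole")
        ax.legend(loc="upper right", frameon=False)
    ax.set_xlabel("frame")
    ax.set_ylabel("motion signal")
    return ax


def plot_probabilities(probs: ProbabilitySeries, detections=None, ax=None):
    """Per-frame end-diastolic probability with detected peaks."""
    ax = _get_ax(ax)
    ax.plot(probs.values, lw=0.8, color="C0")
    if detections is not None:
        d = np.asarray(detections, dtype=int)
        ax.plot(d, probs.values[d], "o", color="C3", ms=4, label="detected")
        ax.legend(loc="upper right", frameon=False)
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("frame")
    ax.set_ylabel("P(end-diastole)")
    return ax


def plot_bland_altman(diffs_ms, ref_frames_ms=None, stats: AgreementStats | None = None, ax=None):
    """Differences against the reference with mean and limits of agreement."""
    ax = _get_ax(ax)
    d = np.asarray(diffs_ms, dtype=float)
    x = np.asarray(ref_frames_ms, dtype=float) if ref_frames_ms is not None else np.arange(d.size)
    stats = stats or bland_altman(d)
    ax.scatter(x, d, s=8, alpha=0.5)
    ax.axhline(stats.mean_diff_ms, color="C0", label=f"mean {stats.mean_diff_ms:+.0f} ms")
    for y in (stats.loa_low_ms, stats.loa_high_ms):
        ax.axhline(y, color="C3", ls="--", lw=1)
    ax.set_xlabel("reference time (ms)" if ref_frames_ms is not None else "pair index")
    ax.set_ylabel("difference (ms)")
    ax.legend(loc="upper right", frameon=False)
    return ax
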