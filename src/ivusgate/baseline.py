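"""Conventional image-based (CIB) gating baseline.

A deterministic, training-free comparator for the learned detector: it
estimates the dominant cardiac period from the autocorrelation of the
smoothed motion signal and then picks signal minima subject to a spacing
constraint around that period. End-diastole is the quiescent phase, so the
motion signal is lowest there.

This is an honest periodicity-constrained-minima gater (tagged
``cib-standin`` in its output metadata), built to reproduce the *structure*
of a conventional image-based comparison — deterministic, learning-free,
perfectly repeatable — not any particular commercial implementation.
"""

from __future__ import annotations

import numpy as np

from .io import ReferenceAnnotation
from .motion import MotionSignal

METHOD_TAG = "cib-standin"


def estimate_period(sig: MotionSignal, min_period: int = 15, max_period: int = 45) -> int:
    """Dominant cycle length (frames) from the autocorrelation peak in band.

    Raises ``ValueError`` when no positive autocorrelation peak exists in
    ``[min_period, max_period]`` (e.g. constant or aperiodic signals).
    """
    v = sig.values - sig.values.mean()
    n = v.size
    if n <= max_period:
        raise ValueError(f"signal too short ({n}) for max_period {max_period}")
    denom = float(v @ v)
    if denom == 0:
        raise ValueError("no periodicity detected (constant signal)")
    lags = np.arange(min_period, max_period + 1)
    ac = np.array([float(v[:-k] @ v[k:]) / denom for k in lags])
    best = int(np.argmax(ac))
    if ac[best] <= 0:
        raise ValueError("no periodicity detected (no positive autocorrelation peak in band)")
    return int(lags[best])


def cib_gate(
    sig: MotionSignal,
    min_period: int = 15,
    max_period: int = 45,
) -> ReferenceAnnotation:
    """Detect end-diastolic frames as periodicity-constrained signal minima.

    1. Estimate the dominant period ``P`` via :func:`estimate_period`.
    2. Greedily accept local minima in ascending signal value, rejecting any
       candidate closer than ``0.6 * P`` to an accepted one.
    3. Fill any remaining gap wider than ``1.6 * P`` with the lowest-valued
       frame that keeps the spacing valid, so consecutive detections always
       sit within ``[0.6 * P, 1.6 * P]`` of each other.

    No randomness is consumed anywhere; repeated runs are identical.
    """
    if not sig.smoothed:
        raise ValueError("CIB gating requires a smoothed motion signal")
    P = estimate_period(sig, min_period, max_period)
    v = sig.values
    n = v.size
    lo_space = max(2, int(np.ceil(0.6 * P)))
    hi_space = int(np.floor(1.6 * P))

    minima = [
        i
        for i in range(n)
        if (i == 0 or v[i] < v[i - 1]) and (i == n - 1 or v[i] <= v[i + 1])
    ]
    minima.sort(key=lambda i: (v[i], i))  # ascending value, earlier frame on ties
    accepted: list[int] = []
    for i in minima:
        if all(abs(i - j) >= lo_space for j in accepted):
            accepted.append(i)
    accepted.sort()

    # close gaps wider than 1.6 P with the best interior frame
    def fill(seq: list[int]) -> list[int]:
        out = [seq[0]]
        for right in seq[1:]:
            while right - out[-1] > hi_space:
                # the insertion point keeps both neighbouring gaps valid
                a = out[-1] + lo_space
                b = min(out[-1] + hi_space, right - lo_space)
                if a > b:  # unreachable for lo_space <= hi_space/2; safeguard
                    break
                k = a + int(np.argmin(v[a : b + 1]))
                out.append(k)
            out.append(right)
        return out

    if len(accepted) >= 2:
        accepted = fill(accepted)
    return ReferenceAnnotation(ed_frames=np.asarray(accepted, dtype=np.int64), fps=sig.fps)
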