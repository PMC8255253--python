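"""Frame-stack and annotation I/O, plus the 15 fps downsampling protocol.

IVUS pullbacks are handled as ordered grayscale frame stacks with a known
frame rate. Reference end-diastolic annotations (frame indices aligned to
ECG R-peaks) travel as CSV with a ``cycle_index,ed_frame[,rr_ms]`` header.
The half-rate protocol keeps every second frame (even 0-based indices) and
maps reference indices with floor division, so frame 0 stays aligned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile

VESSEL_TYPES = ("LAD", "LCx", "RCA", "unknown")


@dataclass
class FrameSequence:
    """An ordered stack of equal-sized 2-D grayscale IVUS frames.

    Parameters
    ----------
    frames : ndarray, shape (n, height, width)
        Grayscale pixel data, any integer or float dtype.
    fps : float
        Acquisition frame rate in frames per second.
    vessel_type : str
        One of ``LAD``, ``LCx``, ``RCA`` or ``unknown``.
    id : str
        Free-form sequence identifier.
    """

    frames: np.ndarray
    fps: float
    vessel_type: str = "unknown"
    id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a (n, height, width) stack, got ndim={self.frames.ndim}"
            )
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if self.vessel_type not in VESSEL_TYPES:
            raise ValueError(
                f"vessel_type must be one of {VESSEL_TYPES}, got {self.vessel_type!r}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class ReferenceAnnotation:
    """Strictly increasing 0-based end-diastolic frame indices (R-peak aligned)."""

    ed_frames: np.ndarray
    fps: float
    rr_ms: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.ed_frames = np.asarray(self.ed_frames, dtype=np.int64)
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if self.ed_frames.size:
            if self.ed_frames.min() < 0:
                raise ValueError("end-diastolic frame indices must be non-negative")
            if np.any(np.diff(self.ed_frames) <= 0):
                raise ValueError("end-diastolic frame indices must be strictly increasing")
        if self.rr_ms is not None:
            self.rr_ms = np.asarray(self.rr_ms, dtype=float)

    def __len__(self) -> int:
        return int(self.ed_frames.size)


def read_frame_stack(path, fps: float, vessel_type: str = "unknown", id: str = "") -> FrameSequence:
    """Read a multi-page grayscale TIFF into a :class:`FrameSequence`.

    Raises a ``ValueError`` for color stacks or stacks whose pages differ in
    size; intensities are preserved exactly.
    """
    with tifffile.TiffFile(str(path)) as tif:
        pages = [p.asarray() for p in tif.pages]
    if not pages:
        raise ValueError(f"{path}: empty image stack")
    shapes = {p.shape for p in pages}
    if any(p.ndim != 2 for p in pages):
        raise ValueError(f"{path}: color or non-2D pages; only grayscale stacks are supported")
    if len(shapes) != 1:
        raise ValueError(f"{path}: mixed frame sizes {sorted(shapes)}")
    frames = np.stack(pages, axis=0)
    if not id:
        id = str(path)
    return FrameSequence(frames=frames, fps=fps, vessel_type=vessel_type, id=id)


def write_frame_stack(seq: FrameSequence, path) -> None:
    """Write a :class:`FrameSequence` as a multi-page grayscale TIFF (lossless)."""
    if seq.n_frames == 0:
        raise ValueError("cannot write an empty frame sequence")
    frames = seq.frames
    if frames.dtype not in (np.uint8, np.uint16):
        # TIFF grayscale round-trip is defined for 8/16-bit; reject silent casts
        raise ValueError(f"frame dtype {frames.dtype} not supported for TIFF output; use uint8/uint16")
    tifffile.imwrite(str(path), frames, photometric="minisblack")


def read_annotations(path, fps: float) -> ReferenceAnnotation:
    """Read end-diastolic annotations from CSV (``cycle_index,ed_frame[,rr_ms]``)."""
    df = pd.read_csv(path)
    required = {"cycle_index", "ed_frame"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: annotation CSV must have columns {sorted(required)}")
    ed = df["ed_frame"].to_numpy(dtype=np.int64)
    if ed.size == 0:
        warnings.warn(f"{path}: empty annotation list", stacklevel=2)
    rr = df["rr_ms"].to_numpy(dtype=float) if "rr_ms" in df.columns else None
    return ReferenceAnnotation(ed_frames=ed, fps=fps, rr_ms=rr)


def write_annotations(ann: ReferenceAnnotation, path) -> None:
    """Write annotations as CSV with columns ``cycle_index,ed_frame,rr_ms``."""
    n = len(ann)
    rr = ann.rr_ms
    if rr is None:
        # per-cycle R-R to the next reference; last entry has none
        rr_full = np.full(n, np.nan)
        if n >= 2:
            rr_full[:-1] = np.diff(ann.ed_frames) * 1000.0 / ann.fps
    else:
        rr_full = np.full(n, np.nan)
        rr_full[: min(n, rr.size)] = rr[: min(n, rr.size)]
    df = pd.DataFrame(
        {"cycle_index": np.arange(n), "ed_frame": ann.ed_frames, "rr_ms": rr_full}
    )
    df.to_csv(path, index=False)


def downsample_sequence(seq: FrameSequence) -> FrameSequence:
    """Halve the frame rate by keeping frames at even 0-based indices.

    Emulates re-acquisition at half rate: a 30 fps pullback becomes a 15 fps
    pullback containing frames 0, 2, 4, ... of the original.
    """
    if seq.n_frames < 2:
        raise ValueError("need at least 2 frames to downsample")
    return replace(seq, frames=seq.frames[::2], fps=seq.fps / 2.0)


def halve_annotations(ann: ReferenceAnnotation) -> ReferenceAnnotation:
    """Map reference indices to the half-rate sequence (floor(index/2), fps/2).

    Neighbouring references that collapse onto the same half-rate frame are
    merged with a warning; the half-rate reference list stays strictly
    increasing.
    """
    halved = ann.ed_frames // 2
    unique = np.unique(halved)
    if unique.size < halved.size:
        warnings.warn(
            f"halving collapsed {halved.size - unique.size} duplicate reference indices",
            stacklevel=2,
        )
    return ReferenceAnnotation(ed_frames=unique, fps=ann.fps / 2.0)
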