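"""Matching detections to reference cardiac cycles and agreement statistics.

Every evaluated gating approach produces a list of estimated end-diastolic
frames; the reference is the set of R-peak-aligned frames. Bookkeeping
follows the matched / extra / missed convention: each estimate is assigned
to its nearest reference, the closest assigned estimate per reference is
*matched*, surplus assigned estimates are *extra*, and references without
any assigned estimate are *missed*. Signed differences (estimate − reference)
in milliseconds feed Bland–Altman limits of agreement, RMSE, and the two
accuracy definitions: a fixed ±100 ms cut-off around the R-peak, and a
heart-rate-relative cut-off of ±10% of the local R-R interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ReferenceAnnotation

# 3 frames at 30 fps is exactly 100 ms; the boundary is inclusive (with a tiny
# float slack) because the tolerance is three times the temporal resolution.
_BOUNDARY_SLACK = 1e-9


@dataclass
class EvaluationConfig:
    fixed_tol_ms: float = 100.0
    rr_frac: float = 0.10
    loa_z: float = 1.96

    def __post_init__(self) -> None:
        if self.fixed_tol_ms <= 0:
            raise ValueError(f"fixed_tol_ms must be > 0, got {self.fixed_tol_ms}")
        if not 0 < self.rr_frac < 1:
            raise ValueError(f"rr_frac must be in (0, 1), got {self.rr_frac}")


@dataclass
class MatchedPair:
    ref_frame: int
    est_frame: int
    diff_frames: int
    diff_ms: float


@dataclass
class MatchResult:
    """Per-cycle bookkeeping for one (reference, estimate) comparison."""

    matched: list[MatchedPair]
    extra: list[int]
    missed: list[int]
    fps: float

    @property
    def diffs_ms(self) -> np.ndarray:
        return np.asarray([m.diff_ms for m in self.matched])

    @property
    def counts(self) -> tuple[int, int, int]:
        return len(self.matched), len(self.extra), len(self.missed)


@dataclass
class AgreementStats:
    """Bland–Altman mean difference, limits of agreement and RMSE."""

    mean_diff_ms: float
    sd_ms: float
    loa_low_ms: float
    loa_high_ms: float
    rmse_ms: float
    n_pairs: int


def match_estimates_to_cycles(
    ref: ReferenceAnnotation, est: ReferenceAnnotation
) -> MatchResult:
    """Assign estimates to reference cycles (nearest reference wins).

    Each estimate goes to its nearest reference frame (ties to the earlier
    reference); per reference the closest assigned estimate (ties to the
    earlier estimate) becomes the matched pair, remaining assigned estimates
    are extra, and references with nothing assigned are missed.
    """
    if ref.fps != est.fps:
        raise ValueError(f"fps mismatch: reference {ref.fps} vs estimate {est.fps}")
    fps = ref.fps
    r = ref.ed_frames
    e = est.ed_frames
    assigned: dict[int, list[int]] = {i: [] for i in range(r.size)}
    if r.size:
        for x in e:
            d = np.abs(r - x)
            assigned[int(np.argmin(d))].append(int(x))  # argmin ties -> earlier ref
    matched: list[MatchedPair] = []
    extra: list[int] = [int(x) for x in e] if r.size == 0 else []
    missed: list[int] = []
    for i in range(r.size):
        cands = assigned[i]
        if not cands:
            missed.append(int(r[i]))
            continue
        best = min(cands, key=lambda x: (abs(x - r[i]), x))  # earlier estimate on ties
        df = int(best - r[i])
        matched.append(
            MatchedPair(ref_frame=int(r[i]), est_frame=best, diff_frames=df,
                        diff_ms=df * 1000.0 / fps)
        )
        extra.extend(x for x in cands if x != best)
    extra.sort()
    return MatchResult(matched=matched, extra=extra, missed=missed, fps=fps)


def classify_correct_fixed(
    match: MatchResult, config: EvaluationConfig | None = None
) -> tuple[np.ndarray, int]:
    """Correct ⇔ |difference| ≤ fixed tolerance (default ±100 ms, inclusive)."""
    config = config or EvaluationConfig()
    ok = np.abs(match.diffs_ms) <= config.fixed_tol_ms + _BOUNDARY_SLACK
    return ok, int(ok.sum())


def classify_correct_relative(
    match: MatchResult,
    ref: ReferenceAnnotation,
    config: EvaluationConfig | None = None,
) -> tuple[np.ndarray, int]:
    """Correct ⇔ |difference| ≤ rr_frac × local R-R interval.

    The R-R interval of a reference is the gap to the next reference; the
    last reference reuses the preceding interval.
    """
    config = config or EvaluationConfig()
    r = ref.ed_frames
    if r.size < 2:
        raise ValueError("relative classification needs at least 2 reference frames")
    gaps_ms = np.diff(r) * 1000.0 / ref.fps
    rr_by_ref = {int(r[i]): gaps_ms[min(i, gaps_ms.size - 1)] for i in range(r.size)}
    ok = np.array(
        [
            abs(m.diff_ms) <= config.rr_frac * rr_by_ref[m.ref_frame] + _BOUNDARY_SLACK
            for m in match.matched
        ],
        dtype=bool,
    )
    return ok, int(ok.sum())


def compute_accuracy(
    correct_count: int, match: MatchResult, denominator: str = "matched"
) -> float:
    """Percentage of correct detections.

    ``denominator="matched"`` divides by the estimates matched to a cardiac
    cycle; ``denominator="all_estimates"`` divides by every emitted estimate
    (matched + extra).
    """
    n_matched, n_extra, _ = match.counts
    if denominator == "matched":
        denom = n_matched
    elif denominator == "all_estimates":
        denom = n_matched + n_extra
    else:
        raise ValueError(f"denominator must be 'matched' or 'all_estimates', got {denominator!r}")
    if denom == 0:
        raise ValueError("zero denominator: no estimates to score")
    return 100.0 * correct_count / denom


def table_percentages(match: MatchResult) -> tuple[float, float, float]:
    """Matched / extra / missed as percentages of all bookkeeping entries (1 d.p.)."""
    n_matched, n_extra, n_missed = match.counts
    total = n_matched + n_extra + n_missed
    if total == 0:
        raise ValueError("empty match result")
    return tuple(round(100.0 * c / total, 1) for c in (n_matched, n_extra, n_missed))


def bland_altman(diffs_ms, loa_z: float = 1.96) -> AgreementStats:
    """Mean difference, sample SD (n−1) and limits of agreement mean ± z·SD."""
    d = np.asarray(diffs_ms, dtype=float)
    if d.size < 2:
        raise ValueError("Bland–Altman analysis needs at least 2 differences")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementStats(
        mean_diff_ms=mean,
        sd_ms=sd,
        loa_low_ms=mean - loa_z * sd,
        loa_high_ms=mean + loa_z * sd,
        rmse_ms=rmse(d),
        n_pairs=int(d.size),
    )


def rmse(diffs_ms) -> float:
    """Root mean square of the signed differences."""
    d = np.asarray(diffs_ms, dtype=float)
    if d.size == 0:
        raise ValueError("RMSE of an empty difference list is undefined")
    return float(np.sqrt(np.mean(d**2)))


def chi_square_table(counts) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on an r×c table."""
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate margins: a row or column sums to zero")
    stat, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return float(stat), int(dof), float(p)


@dataclass
class VesselEvaluation:
    """One vessel's detections scored against its reference."""

    vessel_id: str
    vessel_type: str
    match: MatchResult
    correct_fixed: int
    correct_relative: int | None = None


def build_results_table(evaluations: list[VesselEvaluation]) -> pd.DataFrame:
    """Per-vessel-type and overall summary of counts, percentages and agreement.

    Rows: one per vessel type present plus ``all``. Columns: matched / extra /
    missed counts and percentages, accuracy under both denominators, mean
    difference, SD, limits of agreement and RMSE.
    """
    if not evaluations:
        raise ValueError("no vessel evaluations to summarize")
    rows = []
    groups: dict[str, list[VesselEvaluation]] = {}
    for ev in evaluations:
        groups.setdefault(ev.vessel_type, []).append(ev)
    for name, group in [("all", evaluations)] + sorted(groups.items()):
        n_matched = sum(len(ev.match.matched) for ev in group)
        n_extra = sum(len(ev.match.extra) for ev in group)
        n_missed = sum(len(ev.match.missed) for ev in group)
        total = n_matched + n_extra + n_missed
        correct = sum(ev.correct_fixed for ev in group)
        diffs = np.concatenate([ev.match.diffs_ms for ev in group]) if n_matched else np.empty(0)
        row = {
            "group": name,
            "n_vessels": len(group),
            "matched": n_matched,
            "extra": n_extra,
            "missed": n_missed,
            "matched_pct": round(100.0 * n_matched / total, 1) if total else np.nan,
            "extra_pct": round(100.0 * n_extra / total, 1) if total else np.nan,
            "missed_pct": round(100.0 * n_missed / total, 1) if total else np.nan,
            "correct_fixed": correct,
            "accuracy_matched_pct": 100.0 * correct / n_matched if n_matched else np.nan,
            "accuracy_all_pct": 100.0 * correct / (n_matched + n_extra)
            if (n_matched + n_extra)
            else np.nan,
            "mean_diff_ms": float(diffs.mean()) if diffs.size else np.nan,
            "sd_ms": float(diffs.std(ddof=1)) if diffs.size > 1 else np.nan,
            "rmse_ms": rmse(diffs) if diffs.size else np.nan,
        }
        if diffs.size > 1:
            ba = bland_altman(diffs)
            row["loa_low_ms"] = ba.loa_low_ms
            row["loa_high_ms"] = ba.loa_high_ms
        else:
            row["loa_low_ms"] = row["loa_high_ms"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
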