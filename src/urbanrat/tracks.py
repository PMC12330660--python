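"""Tracklet movement statistics and coordinated-movement detection.

A tracklet is one contiguous fragment of an animal's ground-plane
trajectory, from first detection until the track is lost; tracklets
shorter than 5 seconds are excluded from analysis.  The statistics here
compare movement speed across the animal-size distribution (size-quartile
speed comparison), detect epochs of coordinated group movement (how many
animals are simultaneously moving faster than a threshold), and compare
participants of such epochs to non-participants — each comparison scored
with a two-sample Kolmogorov-Smirnov test.

The KS test is self-contained: the statistic is the exact supremum ECDF
distance, and the p-value is computed exactly (lattice-path counting over
all orderings, valid when there are no cross-sample ties) whenever
``n1 * n2 <= 1e6``, falling back to the asymptotic Kolmogorov distribution
with the Stephens small-sample correction otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.special import kolmogorov

__all__ = [
    "Tracklet",
    "CoordinationEpoch",
    "KSResult",
    "extract_and_filter_tracklets",
    "tracklet_speed",
    "instantaneous_speeds",
    "normalize_sizes",
    "ks_two_sample",
    "quartile_speed_comparison",
    "detect_coordination",
    "participant_size_comparison",
]

_EXACT_LIMIT = 1_000_000  # n1*n2 budget for exact path-counting p-values


@dataclass
class Tracklet:
    """A contiguous ground-plane trajectory fragment of one animal."""

    id: str
    track_id: object
    frames: np.ndarray
    positions: np.ndarray  # (n, 2) ground-plane coordinates
    frame_rate: float
    relative_size: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.frames), 2):
            raise ValueError("positions must have shape (n_frames, 2)")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> float:
        """Spanned duration in seconds, counting both endpoint frames."""
        return (self.frames[-1] - self.frames[0] + 1) / self.frame_rate

    @property
    def median_speed(self) -> float:
        return tracklet_speed(self)


@dataclass
class CoordinationEpoch:
    """A maximal run of frames with >= count_threshold fast-moving animals."""

    start: int
    end: int
    participants: frozenset
    peak_count: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("epoch end must be >= start")
        if not self.participants:
            raise ValueError("epoch must have participants")


@dataclass(frozen=True)
class KSResult:
    """Two-sample Kolmogorov-Smirnov outcome."""

    statistic: float
    pvalue: float
    n1: int
    n2: int
    method: str = "exact"

    def __post_init__(self) -> None:
        if not 0.0 <= self.statistic <= 1.0:
            raise ValueError("D must lie in [0, 1]")


# ---------------------------------------------------------------------------
# tracklet extraction and speeds


def extract_and_filter_tracklets(
    tracks: Mapping[object, pd.DataFrame],
    frame_rate: float,
    *,
    min_duration_s: float = 5.0,
    max_gap_s: float = 1.0,
    relative_sizes: Mapping[object, float] | None = None,
) -> list[Tracklet]:
    """Split ground tracks into tracklets and drop short ones.

    ``tracks`` maps track id to a frame-indexed table with columns
    ``frame, g1, g2`` (the output of
    :func:`urbanrat.movement.reconstruct_ground_tracks`).  Each id's series
    is split wherever consecutive observed frames are more than
    ``max_gap_s`` apart; fragments strictly shorter than ``min_duration_s``
    (spanned frames / frame rate) are excluded.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be > 0")
    max_gap = max_gap_s * frame_rate
    out: list[Tracklet] = []
    for tid, df in tracks.items():
        frames = df["frame"].to_numpy(dtype=np.int64)
        pos = df[["g1", "g2"]].to_numpy(dtype=float)
        if len(frames) == 0:
            continue
        breaks = np.nonzero(np.diff(frames) > max_gap)[0] + 1
        size = None if relative_sizes is None else relative_sizes.get(tid)
        for part, (lo, hi) in enumerate(
            zip(np.r_[0, breaks], np.r_[breaks, len(frames)])
        ):
            t = Tracklet(
                id=f"{tid}/{part}", track_id=tid, frames=frames[lo:hi],
                positions=pos[lo:hi], frame_rate=frame_rate, relative_size=size,
            )
            if t.duration >= min_duration_s:
                out.append(t)
    return out


def tracklet_speed(tracklet: Tracklet, smooth_window: int | None = None) -> float:
    """Median ground-plane speed (length units / s) over per-frame steps.

    Steps across observation gaps are divided by the gap length so each
    contributes a per-frame displacement; the median makes the summary
    robust to single tracker glitches.
    """
    if tracklet.n_frames < 2:
        raise ValueError("tracklet needs at least 2 positions for a speed")
    pos = tracklet.positions
    if smooth_window and smooth_window > 1:
        pos = median_filter(pos, size=(smooth_window, 1), mode="nearest")
    gaps = np.diff(tracklet.frames).astype(float)
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1) / gaps
    return float(np.median(steps) * tracklet.frame_rate)


def instantaneous_speeds(tracklet: Tracklet, smooth_window: int = 5) -> np.ndarray:
    """Per-observed-frame speed via central differences on smoothed positions."""
    if tracklet.n_frames < 2:
        raise ValueError("tracklet needs at least 2 positions")
    pos = tracklet.positions
    if smooth_window and smooth_window > 1:
        pos = median_filter(pos, size=(smooth_window, 1), mode="nearest")
    t = tracklet.frames.astype(float) / tracklet.frame_rate
    vel = np.gradient(pos, t, axis=0)
    return np.linalg.norm(vel, axis=1)


def normalize_sizes(
    sizes: Sequence[float],
    *,
    exclude_outliers: bool = False,
    outlier_factor: float = 3.0,
) -> np.ndarray:
    """Scale sizes so the normalization set has mean 1.

    With ``exclude_outliers``, values larger than ``outlier_factor`` times
    the median are excluded from the mean (an off-species intruder such as
    a squirrel should not shift "the average rat") but are still returned,
    scaled by the same factor.
    """
    arr = np.asarray(sizes, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot normalize an empty size set")
    if np.any(arr <= 0) or not np.isfinite(arr).all():
        raise ValueError("sizes must be positive and finite")
    if exclude_outliers:
        keep = arr <= outlier_factor * np.median(arr)
        if not keep.any():
            raise ValueError("outlier exclusion removed every size")
        mean = arr[keep].mean()
    else:
        mean = arr.mean()
    return arr / mean


# ---------------------------------------------------------------------------
# two-sample Kolmogorov-Smirnov


def _ks_statistic(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """Return (D, h) where D = h / (n*m) with integer height h."""
    n, m = len(a), len(b)
    a_sorted = np.sort(a)
    b_sorted = np.sort(b)
    pooled = np.concatenate([a_sorted, b_sorted])
    ca = np.searchsorted(a_sorted, pooled, side="right").astype(np.int64)
    cb = np.searchsorted(b_sorted, pooled, side="right").astype(np.int64)
    h = int(np.max(np.abs(ca * m - cb * n)))
    return h / (n * m), h


def _exact_pvalue(n: int, m: int, h: int) -> float:
    """P(D >= h/(n m)) by counting monotone lattice paths with |i m - j n| < h.

    Exact under continuity (no ties): all C(n+m, n) interleavings are
    equally likely; a path visits (i, j) after i observations from the
    first sample and j from the second.
    """
    if h <= 0:
        return 1.0
    # counts[j] = number of admissible paths reaching (i, j); python ints (exact)
    counts = [0] * (m + 1)
    counts[0] = 1
    for i in range(n + 1):
        if i > 0:
            prev = counts
            counts = [0] * (m + 1)
            for j in range(m + 1):
                if abs(i * m - j * n) < h:
                    counts[j] = prev[j]
        for j in range(1, m + 1):
            if abs(i * m - j * n) < h and counts[j - 1]:
                counts[j] += counts[j - 1]
    total = math.comb(n + m, n)
    return 1.0 - counts[m] / total


def _asymptotic_pvalue(n: int, m: int, d: float) -> float:
    en = math.sqrt(n * m / (n + m))
    return float(kolmogorov((en + 0.12 + 0.11 / en) * d))


def ks_two_sample(a, b, *, method: str = "auto") -> KSResult:
    """Two-sample KS test: D = sup |ECDF_a - ECDF_b| plus a p-value.

    ``method``: "exact" (path counting; requires no cross-sample ties),
    "asymp", or "auto" (exact when tie-free and ``n1*n2`` is small enough).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    d, h = _ks_statistic(a, b)
    n, m = len(a), len(b)
    has_ties = bool(np.intersect1d(a, b).size)
    if method == "auto":
        method = "exact" if (not has_ties and n * m <= _EXACT_LIMIT) else "asymp"
    if method == "exact":
        if has_ties:
            raise ValueError("exact method requires no ties across samples")
        p = _exact_pvalue(n, m, h)
    elif method == "asymp":
        p = _asymptotic_pvalue(n, m, d)
    else:
        raise ValueError(f"unknown method {method!r}")
    return KSResult(statistic=d, pvalue=min(1.0, max(0.0, p)), n1=n, n2=m,
                    method=method)


# ---------------------------------------------------------------------------
# the movement comparisons


def _sizes_and_speeds(tracklets: Sequence[Tracklet],
                      smooth_window: int | None = None):
    sizes = np.array([t.relative_size for t in tracklets], dtype=float)
    if np.isnan(sizes).any():
        raise ValueError("all tracklets need a relative_size")
    speeds = np.array([tracklet_speed(t, smooth_window) for t in tracklets])
    return sizes, speeds


def quartile_speed_comparison(tracklets: Sequence[Tracklet],
                              smooth_window: int | None = None) -> KSResult:
    """KS comparison of median speeds between lower and upper size quartiles.

    ``smooth_window`` median-filters positions before differencing, which
    suppresses tracker/back-projection jitter when per-frame noise is
    comparable to the per-frame step.
    """
    if len(tracklets) < 8:
        raise ValueError("need at least 8 tracklets for a quartile comparison")
    sizes, speeds = _sizes_and_speeds(tracklets, smooth_window)
    q1, q3 = np.quantile(sizes, [0.25, 0.75])
    low = speeds[sizes <= q1]
    high = speeds[sizes >= q3]
    return ks_two_sample(low, high)


def detect_coordination(
    tracklets: Sequence[Tracklet],
    speed_threshold: float | None = None,
    count_threshold: int = 3,
    frame_rate: float | None = None,
    *,
    merge_gap_s: float = 1.0,
    smooth_window: int = 5,
) -> tuple[pd.Series, list[CoordinationEpoch]]:
    """Count fast-moving animals per frame and extract coordination epochs.

    An animal is "fast" at a frame when its instantaneous speed exceeds
    ``speed_threshold`` (default: the 75th percentile of all per-frame
    speeds).  Epochs are maximal frame runs with at least
    ``count_threshold`` fast animals, where runs separated by less than
    ``merge_gap_s`` are merged; participants are the ids that were fast at
    some frame of the epoch.
    """
    if count_threshold <= 0:
        raise ValueError("count_threshold must be > 0")
    if not tracklets:
        return pd.Series(dtype=int), []
    if frame_rate is None:
        frame_rate = tracklets[0].frame_rate
    per_track = [(t, instantaneous_speeds(t, smooth_window)) for t in tracklets]
    if speed_threshold is None:
        speed_threshold = float(
            np.percentile(np.concatenate([s for _, s in per_track]), 75)
        )
    if speed_threshold <= 0:
        raise ValueError("speed_threshold must be > 0")

    lo = min(int(t.frames[0]) for t in tracklets)
    hi = max(int(t.frames[-1]) for t in tracklets)
    counts = np.zeros(hi - lo + 1, dtype=int)
    fast_frames: dict[object, np.ndarray] = {}
    for t, sp in per_track:
        fast = t.frames[sp > speed_threshold]
        fast_frames[t.id] = fast
        counts[fast - lo] += 1

    frames = np.arange(lo, hi + 1)
    series = pd.Series(counts, index=frames, name="fast_count")

    active = counts >= count_threshold
    idx = np.nonzero(active)[0]
    epochs: list[CoordinationEpoch] = []
    if idx.size:
        merge_gap = merge_gap_s * frame_rate
        splits = np.nonzero(np.diff(idx) >= merge_gap)[0] + 1
        for seg in np.split(idx, splits):
            start, end = int(frames[seg[0]]), int(frames[seg[-1]])
            participants = frozenset(
                t.id for t, _ in per_track
                if np.any((fast_frames[t.id] >= start) & (fast_frames[t.id] <= end))
            )
            if participants:
                epochs.append(CoordinationEpoch(
                    start=start, end=end, participants=participants,
                    peak_count=int(counts[seg].max()),
                ))
    return series, epochs


def participant_size_comparison(
    tracklets: Sequence[Tracklet],
    epochs: Sequence[CoordinationEpoch],
    *,
    mode: str = "fast_during",
) -> KSResult:
    """KS comparison of relative sizes: coordination participants vs the rest.

    ``mode="fast_during"`` takes participants as recorded in the epochs
    (animals moving fast during an epoch); ``mode="present_during"`` takes
    every tracklet observed during any epoch's frame range.
    """
    if mode == "fast_during":
        members = set().union(*(e.participants for e in epochs)) if epochs else set()
    elif mode == "present_during":
        members = {
            t.id for t in tracklets for e in epochs
            if t.frames[0] <= e.end and t.frames[-1] >= e.start
        }
    else:
        raise ValueError(f"unknown mode {mode!r}")
    part = [t.relative_size for t in tracklets if t.id in members]
    rest = [t.relative_size for t in tracklets if t.id not in members]
    if not part or not rest:
        raise ValueError("both participant and non-participant groups must be non-empty")
    return ks_two_sample(part, rest)
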