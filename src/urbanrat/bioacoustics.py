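"""Ultrasonic-vocalization bout segmentation and acoustic features.

Rat calls arrive in bouts: sequences of syllables whose silent gaps are
all shorter than 250 ms.  Given syllable onset/offset annotations this
module groups them into bouts, estimates each syllable's time-varying
fundamental frequency (F0) from the spectrogram, summarizes bouts as
median frequency +/- sd, compares environment loudness in dB, and projects
calls into the duration-frequency feature space used to compare wild
recordings with the laboratory literature (22 kHz and 50 kHz call
classes).

The F0 estimator is a band-limited spectral-peak tracker: per spectrogram
frame the peak-magnitude frequency within the analysis band, with a frame
declared voiced when its band peak exceeds the median band magnitude by a
configurable margin (default 6 dB).  It is validated on synthetic tones
and chirps; on a pure tone its error is bounded by one frequency-bin width
(sample_rate / nfft, 93.75 Hz at 192 kHz / 2048).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import spectrogram as _spectrogram
from shapely.geometry import Point, Polygon

__all__ = [
    "Syllable",
    "Bout",
    "SpectrogramConfig",
    "F0Track",
    "OverlapError",
    "NoVoicedFramesError",
    "SilentInputError",
    "segment_bouts",
    "estimate_f0",
    "bout_summary",
    "level_difference_db",
    "project_feature_space",
]


class OverlapError(ValueError):
    """Consecutive syllables overlap in time."""


class NoVoicedFramesError(ValueError):
    """No spectrogram frame exceeded the voicing threshold in the band."""


class SilentInputError(ValueError):
    """A waveform is identically zero; no level can be computed."""


@dataclass
class Syllable:
    """One vocal unit: [onset, offset) seconds, label and optional F0 features."""

    onset: float
    offset: float
    label: str = ""
    median_f0: float | None = None
    f0_track: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValueError(f"offset must exceed onset ({self.onset}, {self.offset})")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class Bout:
    """An ordered run of syllables with all internal gaps below the threshold."""

    syllables: list[Syllable]

    def __post_init__(self) -> None:
        if not self.syllables:
            raise ValueError("a bout needs at least one syllable")

    @property
    def onset(self) -> float:
        return self.syllables[0].onset

    @property
    def offset(self) -> float:
        return self.syllables[-1].offset

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    def __len__(self) -> int:
        return len(self.syllables)


@dataclass(frozen=True)
class SpectrogramConfig:
    """STFT settings; defaults match the study's analysis settings."""

    nfft: int = 2048
    noverlap: int = 256
    sample_rate: float = 192_000.0

    def __post_init__(self) -> None:
        if not 0 <= self.noverlap < self.nfft:
            raise ValueError("noverlap must satisfy 0 <= noverlap < nfft")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")

    @property
    def bin_width_hz(self) -> float:
        return self.sample_rate / self.nfft


@dataclass
class F0Track:
    """Per-frame F0 estimates with frame times and the voicing mask."""

    times: np.ndarray
    f0: np.ndarray        # Hz, NaN on unvoiced frames
    voiced: np.ndarray
    median: float


def segment_bouts(syllables: Sequence[Syllable], gap_threshold: float = 0.250) -> list[Bout]:
    """Greedy left-to-right grouping of syllables into bouts.

    A gap of silence >= ``gap_threshold`` seconds (default 250 ms) starts a
    new bout; a strictly shorter gap joins.  Syllables must be sorted by
    onset and non-overlapping.
    """
    if gap_threshold <= 0:
        raise ValueError("gap_threshold must be > 0")
    syllables = list(syllables)
    if not syllables:
        return []
    bouts: list[list[Syllable]] = [[syllables[0]]]
    for prev, cur in zip(syllables, syllables[1:]):
        if cur.onset < prev.onset:
            raise ValueError("syllables must be sorted by onset")
        if prev.offset > cur.onset:
            raise OverlapError(
                f"syllable at {prev.onset:.3f}s overlaps the next at {cur.onset:.3f}s"
            )
        if cur.onset - prev.offset < gap_threshold:
            bouts[-1].append(cur)
        else:
            bouts.append([cur])
    return [Bout(b) for b in bouts]


def estimate_f0(
    waveform: np.ndarray,
    cfg: SpectrogramConfig | None = None,
    band: tuple[float, float] = (15_000.0, 96_000.0),
    *,
    voicing_db: float = 6.0,
) -> F0Track:
    """Track the fundamental frequency as the band-limited spectral peak.

    ``band`` must lie within the Nyquist range.  Raises
    :class:`NoVoicedFramesError` when no frame's band peak clears the
    voicing margin over the median band magnitude.
    """
    cfg = cfg or SpectrogramConfig()
    wave = np.asarray(waveform, dtype=float)
    if wave.ndim != 1:
        raise ValueError("waveform must be mono (1-D)")
    lo, hi = band
    if not 0.0 <= lo < hi:
        raise ValueError("band must satisfy 0 <= lo < hi")
    if hi > cfg.sample_rate / 2:
        raise ValueError("band top exceeds the Nyquist frequency")
    freqs, times, mag = _spectrogram(
        wave, fs=cfg.sample_rate, window="hann", nperseg=cfg.nfft,
        noverlap=cfg.noverlap, mode="magnitude",
    )
    sel = (freqs >= lo) & (freqs <= hi)
    band_mag = mag[sel]
    band_freqs = freqs[sel]
    peaks = band_mag.max(axis=0)
    floor = float(np.median(band_mag))
    voiced = peaks > floor * 10.0 ** (voicing_db / 20.0)
    if not voiced.any():
        raise NoVoicedFramesError("band energy never exceeded the voicing threshold")
    f0 = np.where(voiced, band_freqs[np.argmax(band_mag, axis=0)], np.nan)
    median = float(np.median(f0[voiced]))
    return F0Track(times=times, f0=f0, voiced=voiced, median=median)


def bout_summary(bout: Bout, *, pool_frames: bool = False):
    """Summarize a bout as (median frequency, frequency sd, syllable durations).

    By default the median/sd are taken over the syllables' median-F0
    values; with ``pool_frames`` all voiced F0 frames across syllables are
    pooled first.  The sd is the sample standard deviation (n-1), zero for
    a single value.
    """
    if pool_frames:
        frames = [
            s.f0_track[np.isfinite(s.f0_track)] for s in bout.syllables
            if s.f0_track is not None
        ]
        values = np.concatenate(frames) if frames else np.array([])
    else:
        values = np.array([
            s.median_f0 for s in bout.syllables if s.median_f0 is not None
        ], dtype=float)
    if values.size == 0:
        raise ValueError("bout has no F0 information")
    median = float(np.median(values))
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    durations = np.array([s.duration for s in bout.syllables])
    return median, sd, durations


def level_difference_db(wave_a: np.ndarray, wave_b: np.ndarray) -> float:
    """RMS level of a relative to b: 20 log10(RMS_a / RMS_b) dB.

    An amplitude ratio of 4 gives ~12.04 dB.  Antisymmetric in its
    arguments; raises :class:`SilentInputError` on an all-zero input.
    """
    a = np.asarray(wave_a, dtype=float)
    b = np.asarray(wave_b, dtype=float)
    rms_a = math.sqrt(float(np.mean(a * a)))
    rms_b = math.sqrt(float(np.mean(b * b)))
    if rms_a == 0.0 or rms_b == 0.0:
        raise SilentInputError("cannot compare levels of a silent signal")
    return 20.0 * math.log10(rms_a / rms_b)


def project_feature_space(
    bouts: Sequence[Bout],
    reference_regions: dict[str, Sequence[tuple[float, float]]] | None = None,
) -> pd.DataFrame:
    """Place each syllable at (duration s, median F0 Hz) and test region membership.

    ``reference_regions`` maps a region name to polygon vertices in
    (duration, frequency) space; membership uses closed regions (boundary
    points are members).  Returns a table with one row per syllable:
    bout index, duration, frequency, one boolean column per region, and
    ``outside_all``.
    """
    regions: dict[str, Polygon] = {}
    for name, verts in (reference_regions or {}).items():
        try:
            poly = Polygon(verts)
        except Exception as exc:  # malformed vertex list
            raise ValueError(f"malformed region {name!r}: {exc}") from exc
        if not poly.is_valid or poly.is_empty:
            raise ValueError(f"malformed region {name!r}: invalid polygon")
        regions[name] = poly
    rows = []
    for bi, bout in enumerate(bouts):
        for s in bout.syllables:
            if s.median_f0 is None:
                raise ValueError("every syllable needs a median F0")
            row = {"bout": bi, "duration_s": s.duration, "frequency_hz": s.median_f0,
                   "label": s.label}
            pt = Point(s.duration, s.median_f0)
            inside_any = False
            for name, poly in regions.items():
                member = bool(poly.covers(pt))
                row[f"in_{name}"] = member
                inside_any = inside_any or member
            row["outside_all"] = not inside_any
            rows.append(row)
    return pd.DataFrame(rows)
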