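"""Pupillary unrest index (PUI) from raw 25-Hz pupil diameter traces.

The pupillographic sleepiness test records dark-adapted pupil diameter for
11 minutes at 25 Hz.  After artifact removal and linear interpolation the
trace is block-averaged over sets of 16 consecutive samples (a simple
low-pass filter, yielding a 1.5625 Hz series).  Within each 82.5-s segment
the absolute differences between consecutive block means (127 differences
per segment) are summed and normalised to one minute; the total PUI is the
mean over the eight segments of the recording.  A perfectly stable pupil
gives 0 mm/min; slow high-amplitude "fatigue waves" of a drowsy subject
give high values.

Segment bookkeeping: 82.5 s at 25 Hz spans 2062.5 samples.  Each segment
uses 2048 samples (128 blocks of 16, hence 127 differences) and successive
segment origins advance by 82.5 s with the start index rounded to the
nearest sample, which keeps 8 segments inside a 660-s recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PupilTrace",
    "PUIResult",
    "UnusableTraceError",
    "preprocess_trace",
    "block_average",
    "pui_segment",
    "compute_pui",
    "BLOCK_SIZE",
    "SEGMENT_DURATION_S",
]

BLOCK_SIZE = 16
SEGMENT_DURATION_S = 82.5
#: blocks per segment: 2048 samples at 25 Hz -> 128 block means, 127 differences
BLOCKS_PER_SEGMENT = 128


class UnusableTraceError(ValueError):
    """Raised when a trace holds no usable samples."""


@dataclass
class PupilTrace:
    """A monocular pupil diameter time series.

    Attributes
    ----------
    diameter_mm : ndarray
        Pupil diameter in mm per sample.
    valid : ndarray of bool
        False where the sample is an artifact (blink, movement, missing).
    sampling_rate_hz : float
        Samples per second (25 for the pupillographic sleepiness test).
    """

    diameter_mm: np.ndarray
    valid: np.ndarray | None = None
    sampling_rate_hz: float = 25.0
    n_interpolated: int = 0
    long_gap_spans: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.diameter_mm = np.asarray(self.diameter_mm, dtype=float)
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")
        if self.diameter_mm.size == 0:
            raise ValueError("trace is empty")
        if self.valid is None:
            self.valid = np.ones(self.diameter_mm.size, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.diameter_mm.shape:
                raise ValueError("valid mask must match diameter series length")

    @property
    def duration_s(self) -> float:
        return self.diameter_mm.size / self.sampling_rate_hz


@dataclass
class PUIResult:
    segment_puis: np.ndarray      # mm/min per 82.5-s segment; NaN where excluded
    total_pui: float              # mm/min, mean over valid segments
    mean_pd: float                # mm, mean diameter over valid samples
    n_segments_used: int
    n_samples_interpolated: int
    flagged: bool                 # True when fewer than 8 segments were usable


def _gap_spans(bad: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index spans of consecutive True values."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], bad, [False])).astype(int)))
    return list(zip(idx[0::2], idx[1::2]))


def preprocess_trace(
    raw: PupilTrace,
    max_gap_s: float = 3.0,
    min_plausible_mm: float = 1.5,
    max_plausible_mm: float = 9.0,
    max_jump_mm: float = 1.0,
) -> PupilTrace:
    """Remove artifacts and linearly interpolate the gaps.

    Samples flagged invalid, outside the plausibility bounds, or following a
    jump larger than ``max_jump_mm`` per sample are treated as gaps and
    linearly interpolated between the nearest valid neighbours (edge gaps are
    held at the nearest valid value).  Gaps longer than ``max_gap_s`` — e.g.
    eye closures beyond 3 s — are interpolated too but recorded so that the
    overlapping segments can be excluded from PUI averaging.
    """
    d = raw.diameter_mm.astype(float).copy()
    bad = ~raw.valid | ~np.isfinite(d)
    bad |= (d < min_plausible_mm) | (d > max_plausible_mm)
    # a large sample-to-sample jump flags the later sample; jumps leaving an
    # already-flagged sample (e.g. the recovery after a spike) are not new
    # artifacts, so scan sequentially
    for i in np.flatnonzero(np.abs(np.diff(d)) > max_jump_mm):
        if not bad[i]:
            bad[i + 1] = True
    if bad.all():
        raise UnusableTraceError("trace has no valid samples")

    spans = _gap_spans(bad)
    good_idx = np.flatnonzero(~bad)
    d[bad] = np.interp(np.flatnonzero(bad), good_idx, d[good_idx])
    max_gap_samples = max_gap_s * raw.sampling_rate_hz
    long_spans = [(a, b) for a, b in spans if (b - a) > max_gap_samples]
    return PupilTrace(
        diameter_mm=d,
        valid=~bad,
        sampling_rate_hz=raw.sampling_rate_hz,
        n_interpolated=int(bad.sum()),
        long_gap_spans=long_spans,
    )


def block_average(series: np.ndarray, block: int = BLOCK_SIZE) -> np.ndarray:
    """Non-overlapping means of ``block`` consecutive samples.

    The trailing partial block is discarded; the output rate is the input
    rate divided by ``block`` (25 Hz -> 1.5625 Hz).
    """
    series = np.asarray(series, dtype=float)
    if series.size < block:
        raise ValueError(f"need at least {block} samples, got {series.size}")
    n = series.size // block
    return series[: n * block].reshape(n, block).mean(axis=1)


def pui_segment(block_means: np.ndarray, segment_duration_s: float = SEGMENT_DURATION_S) -> float:
    """PUI of one segment: sum of |successive block-mean differences|, per minute."""
    block_means = np.asarray(block_means, dtype=float)
    if block_means.size < 2:
        raise ValueError("segment needs at least two block means")
    return float(np.abs(np.diff(block_means)).sum() * 60.0 / segment_duration_s)


def compute_pui(
    trace: PupilTrace,
    max_interpolated_fraction: float = 0.25,
) -> PUIResult:
    """Total PUI and mean pupil diameter of a preprocessed recording.

    The trace is partitioned into consecutive 82.5-s segments from the start
    of the recording.  A segment overlapping a gap longer than the blink
    limit, or containing more than ``max_interpolated_fraction`` interpolated
    samples, is excluded; the total PUI averages the remaining segments.
    """
    fs = trace.sampling_rate_hz
    seg_samples_exact = SEGMENT_DURATION_S * fs          # 2062.5 at 25 Hz
    seg_used = BLOCKS_PER_SEGMENT * BLOCK_SIZE           # 2048 samples
    n_segments = int(trace.diameter_mm.size // seg_samples_exact)
    if n_segments < 1:
        raise UnusableTraceError(
            f"recording shorter than one {SEGMENT_DURATION_S}-s segment"
        )
    puis = np.full(n_segments, np.nan)
    for i in range(n_segments):
        start = int(round(i * seg_samples_exact))
        stop = start + seg_used
        if stop > trace.diameter_mm.size:
            break
        if any(a < stop and b > start for a, b in trace.long_gap_spans):
            continue
        interp = (~trace.valid[start:stop]).sum()
        if interp > max_interpolated_fraction * seg_used:
            continue
        means = block_average(trace.diameter_mm[start:stop])
        puis[i] = pui_segment(means)
    used = int(np.isfinite(puis).sum())
    if used < 1:
        raise UnusableTraceError("no valid segments for PUI computation")
    mean_pd = float(trace.diameter_mm[trace.valid].mean()) if trace.valid.any() else float(
        trace.diameter_mm.mean()
    )
    return PUIResult(
        segment_puis=puis,
        total_pui=float(np.nanmean(puis)),
        mean_pd=mean_pd,
        n_segments_used=used,
        n_samples_interpolated=trace.n_interpolated,
        flagged=used < 8,
    )
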