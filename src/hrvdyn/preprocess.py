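"""Beat-interval preprocessing: segment compilation, artifact filtering, and
gap-aware resampling onto uniform 1 Hz / 4 Hz grids.

The task clock is the cumulative time of the inter-beat-interval (IBI) series:
beat ``j`` occurs at the running sum of all accepted intervals plus the span of
any missing 30-s segments before it.  Artifact removal never shifts the clock
of surviving beats; dropped segments become explicit gap intervals rather than
deleted time, so downstream per-second series stay aligned with behavior logs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "BeatSeries",
    "UniformSeries",
    "FilterReport",
    "compile_segments",
    "filter_outliers",
    "interpolate_uniform",
    "person_mean",
    "mask_interval",
    "contiguous_runs",
]

#: physiologically admissible IBI range, seconds
DEFAULT_HARD_RANGE = (0.2, 2.0)
#: a span this long without an accepted beat becomes a gap (s)
DEFAULT_MAX_SILENCE = 3.0
#: nominal duration of one recording segment (s)
SEGMENT_LENGTH = 30.0


@dataclass
class BeatSeries:
    """Inter-beat intervals on the task clock.

    ``ibis[j]`` is the interval (s) ending at ``beat_times[j]``.
    ``gap_intervals`` are half-open ``[start, end)`` spans of lost recording;
    they occupy clock time but contain no beats.
    """

    beat_times: np.ndarray
    ibis: np.ndarray
    gap_intervals: list[tuple[float, float]] = field(default_factory=list)
    task_length: float | None = None

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.ibis = np.asarray(self.ibis, dtype=float)
        if self.beat_times.shape != self.ibis.shape:
            raise ValueError("beat_times and ibis must have equal length")
        if self.beat_times.size and np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        if np.any(self.ibis <= 0):
            raise ValueError("all inter-beat intervals must be positive")
        for (a, b) in self.gap_intervals:
            if b <= a:
                raise ValueError(f"degenerate gap interval ({a}, {b})")
        if self.task_length is None:
            end = self.beat_times[-1] if self.beat_times.size else 0.0
            for (_, b) in self.gap_intervals:
                end = max(end, b)
            self.task_length = float(end)

    @property
    def n_beats(self) -> int:
        return int(self.beat_times.size)


@dataclass
class UniformSeries:
    """Uniformly sampled series with an explicit missing mask.

    Samples sit at exact multiples of ``1/fs`` starting at ``start`` (default
    0), so second ``s`` of a 1 Hz series is the sample at clock time ``s``.
    """

    values: np.ndarray
    missing: np.ndarray
    fs: float
    start: float = 0.0
    unit: str = "s"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.values.shape != self.missing.shape:
            raise ValueError("values and missing mask must have equal length")

    def times(self) -> np.ndarray:
        return self.start + np.arange(self.values.size) / self.fs

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass
class FilterReport:
    """Counts of beats removed by each artifact rule."""

    n_input: int
    n_hard_range: int
    n_adaptive: int

    @property
    def n_removed(self) -> int:
        return self.n_hard_range + self.n_adaptive


def compile_segments(
    segments: list[np.ndarray | list[float] | None],
    unit: str = "s",
    segment_length: float = SEGMENT_LENGTH,
) -> BeatSeries:
    """Concatenate per-segment beat intervals into one series on the task clock.

    Parameters
    ----------
    segments
        Ordered beat-interval records, one entry per 30-s recording segment.
        ``None`` (or an empty record) marks a lost segment, which contributes a
        ``segment_length`` gap interval so the clock of later beats is
        preserved.
    unit
        ``"s"`` or ``"ms"``; millisecond inputs are converted to seconds.
    """
    if unit not in ("s", "ms"):
        raise ValueError(f"unit must be 's' or 'ms', got {unit!r}")
    scale = 1e-3 if unit == "ms" else 1.0

    times: list[np.ndarray] = []
    ibis: list[np.ndarray] = []
    gaps: list[tuple[float, float]] = []
    clock = 0.0
    for k, seg in enumerate(segments):
        if seg is None or len(seg) == 0:
            gaps.append((clock, clock + segment_length))
            clock += segment_length
            continue
        arr = np.asarray(seg, dtype=float) * scale
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-numeric record in segment {k}")
        if np.any(arr <= 0):
            raise ValueError(f"non-positive interval in segment {k}")
        t = clock + np.cumsum(arr)
        times.append(t)
        ibis.append(arr)
        clock = float(t[-1])
    if not times:
        return BeatSeries(np.array([]), np.array([]), gaps, task_length=clock)
    return BeatSeries(
        np.concatenate(times), np.concatenate(ibis), gaps, task_length=clock
    )


def filter_outliers(
    beats: BeatSeries,
    hard_range: tuple[float, float] = DEFAULT_HARD_RANGE,
    adaptive_rel_change: float = 0.25,
    median_window: int = 11,
) -> tuple[BeatSeries, FilterReport]:
    """Remove artifact beats without disturbing the task clock.

    Two rules are applied: a hard physiological range (default 0.2-2 s), and an
    adaptive rule rejecting a beat whose interval differs by more than
    ``adaptive_rel_change`` from the running median of the last
    ``median_window`` accepted intervals.  Surviving beats keep their original
    ``beat_times``, so removal consumes no clock time.
    """
    lo, hi = hard_range
    if not lo < hi:
        raise ValueError("hard_range low must be below high")

    t, x = beats.beat_times, beats.ibis
    keep = np.ones(t.size, dtype=bool)
    n_hard = 0
    n_adapt = 0
    recent: list[float] = []
    for j in range(t.size):
        v = x[j]
        if not (lo < v < hi):
            keep[j] = False
            n_hard += 1
            continue
        if recent:
            ref = float(np.median(recent))
            if abs(v - ref) > adaptive_rel_change * ref:
                keep[j] = False
                n_adapt += 1
                continue
        recent.append(v)
        if len(recent) > median_window:
            recent.pop(0)
    out = replace(beats, beat_times=t[keep], ibis=x[keep])
    return out, FilterReport(n_input=t.size, n_hard_range=n_hard, n_adaptive=n_adapt)


def _merged_gaps(
    beats: BeatSeries, max_silence: float
) -> list[tuple[float, float]]:
    """Declared gaps plus silent spans (> max_silence without an accepted beat)."""
    gaps = [tuple(g) for g in beats.gap_intervals]
    t = beats.beat_times
    # silent spans between consecutive beats, excluding time already in gaps
    edges = np.concatenate(([0.0], t, [beats.task_length]))
    for a, b in zip(edges[:-1], edges[1:]):
        span = b - a
        covered = sum(
            max(0.0, min(b, g1) - max(a, g0)) for g0, g1 in beats.gap_intervals
        )
        if span - covered > max_silence:
            eps = np.nextafter(0.0, 1.0)
            gaps.append((a + eps, b))
    gaps.sort()
    merged: list[tuple[float, float]] = []
    for g in gaps:
        if merged and g[0] <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], g[1]))
        else:
            merged.append(g)
    return merged


def contiguous_runs(
    beats: BeatSeries, max_silence: float = DEFAULT_MAX_SILENCE
) -> list[tuple[float, float]]:
    """Half-open clock spans ``[start, end)`` not interrupted by any gap."""
    runs = []
    pos = 0.0
    for g0, g1 in _merged_gaps(beats, max_silence):
        if g0 > pos:
            runs.append((pos, min(g0, beats.task_length)))
        pos = max(pos, g1)
    if pos < beats.task_length:
        runs.append((pos, beats.task_length))
    return [r for r in runs if r[1] > r[0]]


def interpolate_uniform(
    beats: BeatSeries,
    fs: float,
    min_run_beats: int = 4,
    max_silence: float = DEFAULT_MAX_SILENCE,
) -> UniformSeries:
    """Cubic-spline resample the beat series onto a uniform grid.

    A natural cubic spline is fit through the ``(beat time, interval)`` pairs of
    each contiguous run (the stretches of clock between gaps) and evaluated at
    every grid point inside that run's span.  Grid points inside gaps, or in
    runs with fewer than ``min_run_beats`` beats, are missing; the spline is
    never evaluated across a gap.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    n = int(round(beats.task_length * fs))
    grid = np.arange(n) / fs
    values = np.full(n, np.nan)
    missing = np.ones(n, dtype=bool)

    any_run = False
    for r0, r1 in contiguous_runs(beats, max_silence):
        sel = (beats.beat_times >= r0) & (beats.beat_times < r1)
        tb, xb = beats.beat_times[sel], beats.ibis[sel]
        if tb.size < min_run_beats:
            continue
        any_run = True
        spline = CubicSpline(tb, xb, bc_type="natural", extrapolate=True)
        gsel = (grid >= r0) & (grid < r1)
        values[gsel] = spline(grid[gsel])
        missing[gsel] = False
    if not any_run:
        raise ValueError(
            f"no contiguous run with >= {min_run_beats} beats to interpolate"
        )
    return UniformSeries(values=values, missing=missing, fs=fs, unit="s")


def person_mean(series: UniformSeries) -> float:
    """Arithmetic mean over non-missing samples (the person's task average)."""
    ok = ~series.missing
    if not ok.any():
        raise ValueError("cannot take the person mean of an all-missing series")
    return float(series.values[ok].mean())


def mask_interval(beats: BeatSeries, start: float, end: float) -> BeatSeries:
    """Return a copy with beats in ``[start, end)`` removed and the span
    recorded as a gap interval (lost recording, not deleted time)."""
    if end <= start:
        raise ValueError("end must exceed start")
    tol = 1e-9
    keep = ~((beats.beat_times >= start - tol) & (beats.beat_times < end - tol))
    gaps_raw = sorted(beats.gap_intervals + [(float(start), float(end))])
    gaps: list[tuple[float, float]] = []
    for g in gaps_raw:
        if gaps and g[0] <= gaps[-1][1] + tol:
            gaps[-1] = (gaps[-1][0], max(gaps[-1][1], g[1]))
        else:
            gaps.append(g)
    return replace(
        beats,
        beat_times=beats.beat_times[keep],
        ibis=beats.ibis[keep],
        gap_intervals=gaps,
    )
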