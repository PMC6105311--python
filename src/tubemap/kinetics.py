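"""Apical-constriction kinetics from paired junction-spot tracks.

Pipeline: pairwise distance series -> double unweighted sliding-average
(20 min window, 2 passes) -> closing speed (central difference, positive
when the distance shrinks) -> prominence-filtered local minima
(> 0.01 um/min) -> cycle durations between successive minima.

Gaps split a series into contiguous runs by default; smoothing and
differentiation then never bridge a gap, and minima at run edges are
excluded.  Alternative gap policies ("bridge", "interpolate") are available
for dropout-heavy data; see :func:`analyze_track_pair`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import SeriesError
from .io import SpotTrack

DEFAULT_WINDOW = 20.0        # minutes
DEFAULT_PASSES = 2
DEFAULT_PROMINENCE = 0.01    # um/min
_T_ATOL = 1e-9


@dataclass
class DistanceSeries:
    """(t, d) samples in minutes / um; missing timepoints are simply absent."""

    t: np.ndarray
    d: np.ndarray
    sampling_interval: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        if self.t.size == 0:
            raise SeriesError("empty distance series")
        if self.t.shape != self.d.shape:
            raise SeriesError("t and d must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise SeriesError("timepoints must be strictly increasing")
        if np.any(self.d < 0):
            raise SeriesError("distances must be >= 0")
        if self.sampling_interval <= 0:
            raise SeriesError("sampling_interval must be > 0")

    def runs(self, gap_policy: str = "split") -> list[slice]:
        """Maximal contiguous stretches (consecutive samples one interval apart).

        ``gap_policy="bridge"`` treats the whole series as one run (gaps are
        simply absent samples, as when analysing the sampled vector directly).
        """
        return _runs(self.t, self.sampling_interval, gap_policy)


def _runs(t: np.ndarray, interval: float, gap_policy: str) -> list[slice]:
    if gap_policy not in ("split", "bridge"):
        raise SeriesError(f"unknown gap_policy {gap_policy!r}")
    if gap_policy == "bridge" or t.size == 1:
        return [slice(0, t.size)]
    gaps = np.flatnonzero(np.diff(t) > interval + _T_ATOL)
    starts = np.concatenate([[0], gaps + 1])
    stops = np.concatenate([gaps + 1, [t.size]])
    return [slice(int(a), int(b)) for a, b in zip(starts, stops)]


@dataclass
class SpeedSeries:
    """Closing speed in um/min; positive when the distance is decreasing."""

    t: np.ndarray
    v: np.ndarray
    sampling_interval: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)

    def runs(self, gap_policy: str = "split") -> list[slice]:
        return _runs(self.t, self.sampling_interval, gap_policy)


@dataclass
class OscillationSummary:
    minima_times: np.ndarray
    cycle_durations: np.ndarray
    mean_period: float
    sem_period: float
    prominence_threshold: float = DEFAULT_PROMINENCE
    window: float = DEFAULT_WINDOW
    passes: int = DEFAULT_PASSES

    @property
    def n_cycles(self) -> int:
        return int(self.cycle_durations.size)


def pair_distance(
    anterior: SpotTrack,
    posterior: SpotTrack,
    sampling_interval: float | None = None,
) -> DistanceSeries:
    """Euclidean distance at every timepoint present in *both* tracks.

    Timepoints missing from either track become gaps in the series.
    """
    t_common, ia, ip = np.intersect1d(anterior.t, posterior.t, return_indices=True)
    if t_common.size == 0:
        raise SeriesError("tracks share no common timepoints")
    d = np.hypot(anterior.x[ia] - posterior.x[ip], anterior.y[ia] - posterior.y[ip])
    if sampling_interval is None:
        dt = np.diff(t_common)
        sampling_interval = float(dt.min()) if dt.size else 1.0
    return DistanceSeries(t=t_common, d=d, sampling_interval=sampling_interval)


def fill_gaps(series: DistanceSeries) -> DistanceSeries:
    """Fill missing timepoints by linear interpolation onto the regular grid.

    Returns a gap-free series spanning the same time range; robustifies
    minima-based period recovery against sporadic dropouts.
    """
    t_full = np.arange(
        series.t[0], series.t[-1] + series.sampling_interval / 2, series.sampling_interval
    )
    d_full = np.interp(t_full, series.t, series.d)
    return DistanceSeries(t=t_full, d=d_full, sampling_interval=series.sampling_interval)


def smooth_distance(
    series: DistanceSeries,
    window: float = DEFAULT_WINDOW,
    passes: int = DEFAULT_PASSES,
    gap_policy: str = "split",
) -> DistanceSeries:
    """Repeated unweighted sliding average with a centred, time-based window.

    Each pass replaces ``d(t)`` by the mean of the samples of the same
    contiguous run whose time lies within ``[t - window/2, t + window/2]``;
    near run edges the window simply truncates.  With
    ``gap_policy="bridge"`` the window averages across gaps.
    """
    if window < series.sampling_interval:
        raise SeriesError(
            f"window ({window} min) must be >= sampling interval ({series.sampling_interval} min)"
        )
    d = series.d.copy()
    half = window / 2 + _T_ATOL
    for _ in range(passes):
        out = np.empty_like(d)
        for run in series.runs(gap_policy):
            t_run, d_run = series.t[run], d[run]
            out[run] = [d_run[np.abs(t_run - ti) <= half].mean() for ti in t_run]
        d = out
    return DistanceSeries(t=series.t.copy(), d=d, sampling_interval=series.sampling_interval)


def closing_speed(smoothed: DistanceSeries, gap_policy: str = "split") -> SpeedSeries:
    """Closing speed ``v = -dd/dt`` on each contiguous run of >= 3 samples.

    Central differences on run interiors, one-sided at run edges; runs
    shorter than 3 samples are dropped.
    """
    ts, vs = [], []
    for run in smoothed.runs(gap_policy):
        t_run, d_run = smoothed.t[run], smoothed.d[run]
        n = t_run.size
        if n < 3:
            continue
        v = np.empty(n)
        v[1:-1] = -(d_run[2:] - d_run[:-2]) / (t_run[2:] - t_run[:-2])
        v[0] = -(d_run[1] - d_run[0]) / (t_run[1] - t_run[0])
        v[-1] = -(d_run[-1] - d_run[-2]) / (t_run[-1] - t_run[-2])
        ts.append(t_run)
        vs.append(v)
    if not ts:
        raise SeriesError("no contiguous run with >= 3 samples")
    return SpeedSeries(
        t=np.concatenate(ts), v=np.concatenate(vs), sampling_interval=smoothed.sampling_interval
    )


def _local_minima_indices(v: np.ndarray) -> list[int]:
    """Interior local minima; a low plateau is reported at its first sample."""
    n = v.size
    minima = []
    i = 1
    while i < n - 1:
        if v[i] < v[i - 1]:
            j = i
            while j + 1 < n and v[j + 1] == v[i]:
                j += 1
            if j < n - 1 and v[j + 1] > v[i]:
                minima.append(i)
            i = j + 1
        else:
            i += 1
    return minima


def _prominence(v: np.ndarray, idx: int) -> float:
    """Topographic prominence of the minimum at ``idx`` (mirrored peak rule).

    Walk outward until a strictly lower value or the series end; the wall on
    each side is the highest value encountered; prominence is the lower wall
    minus the minimum value.
    """
    val = v[idx]
    left_wall = -math.inf
    for j in range(idx - 1, -1, -1):
        if v[j] < val:
            break
        left_wall = max(left_wall, v[j])
    if left_wall == -math.inf:  # idx at the very start (cannot happen for interior minima)
        left_wall = val
    right_wall = -math.inf
    for j in range(idx + 1, v.size):
        if v[j] < val:
            break
        right_wall = max(right_wall, v[j])
    if right_wall == -math.inf:
        right_wall = val
    return float(min(left_wall, right_wall) - val)


def find_cycle_minima(
    speed: SpeedSeries,
    prominence_threshold: float = DEFAULT_PROMINENCE,
    gap_policy: str = "split",
) -> np.ndarray:
    """Times of closing-speed local minima with prominence above threshold.

    Minima are sought within each contiguous run independently (run edges
    are never minima); prominence saddles never cross a gap.
    """
    if prominence_threshold <= 0:
        raise SeriesError("prominence_threshold must be > 0")
    times = []
    for run in speed.runs(gap_policy):
        v_run, t_run = speed.v[run], speed.t[run]
        for idx in _local_minima_indices(v_run):
            if _prominence(v_run, idx) > prominence_threshold:
                times.append(t_run[idx])
    return np.array(sorted(times))


def summarize_cycles(
    minima_times: np.ndarray,
    prominence_threshold: float = DEFAULT_PROMINENCE,
    window: float = DEFAULT_WINDOW,
    passes: int = DEFAULT_PASSES,
) -> OscillationSummary:
    """Cycle durations (successive minima differences) with mean +- SEM."""
    minima_times = np.asarray(minima_times, dtype=float)
    durations = np.diff(minima_times) if minima_times.size >= 2 else np.array([])
    if durations.size == 0:
        mean = sem = math.nan
    else:
        mean = float(durations.mean())
        sem = float(durations.std(ddof=1) / math.sqrt(durations.size)) if durations.size > 1 else math.nan
    return OscillationSummary(
        minima_times=minima_times,
        cycle_durations=durations,
        mean_period=mean,
        sem_period=sem,
        prominence_threshold=prominence_threshold,
        window=window,
        passes=passes,
    )


def track_span(track: SpotTrack) -> float:
    """Axial span of a track: max(x) - min(x), um."""
    if len(track) == 0:
        raise SeriesError("empty track")
    return float(track.x.max() - track.x.min())


def analyze_track_pair(
    anterior: SpotTrack,
    posterior: SpotTrack,
    window: float = DEFAULT_WINDOW,
    passes: int = DEFAULT_PASSES,
    prominence_threshold: float = DEFAULT_PROMINENCE,
    gap_policy: str = "split",
) -> dict:
    """Full kinetics pipeline for one spot-track pair.

    ``gap_policy`` is one of ``"split"`` (never bridge gaps; default),
    ``"bridge"`` (treat the sampled vector as contiguous) or
    ``"interpolate"`` (linearly fill gaps first; most robust to dropouts).
    """
    raw = pair_distance(anterior, posterior)
    if gap_policy == "interpolate":
        smooth = smooth_distance(fill_gaps(raw), window=window, passes=passes)
        speed = closing_speed(smooth)
        minima = find_cycle_minima(speed, prominence_threshold=prominence_threshold)
    else:
        smooth = smooth_distance(raw, window=window, passes=passes, gap_policy=gap_policy)
        speed = closing_speed(smooth, gap_policy=gap_policy)
        minima = find_cycle_minima(speed, prominence_threshold=prominence_threshold,
                                   gap_policy=gap_policy)
    summary = summarize_cycles(
        minima, prominence_threshold=prominence_threshold, window=window, passes=passes
    )
    return {
        "distance": raw,
        "smoothed": smooth,
        "speed": speed,
        "summary": summary,
        "span_anterior": track_span(anterior),
        "span_posterior": track_span(posterior),
    }
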