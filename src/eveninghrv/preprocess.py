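"""Artifact filtering and segment extraction for beat-interval recordings.

Raw chest-strap exports contain spurious beats (sensor dropouts, ectopic
complexes). Cleaning follows the standard normal-to-normal (NN) convention:
hard physiological bounds plus a running-median deviation rule, applied in a
single left-to-right pass. Cleaned series are then cut into fixed-length
"breakless" analysis segments aligned to an evening clock grid, and
questionnaire rows are matched to the same grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "RRSeries",
    "FilterConfig",
    "NNSeries",
    "SegmentSpec",
    "Segment",
    "filter_nn",
    "extract_segment",
    "align_questionnaire",
    "clock_to_ms",
]

# Removal reasons logged by filter_nn
BELOW_MIN = "below_min"
ABOVE_MAX = "above_max"
MEDIAN_DEVIATION = "median_deviation"


def clock_to_ms(clock: str, origin: str) -> float:
    """Milliseconds from wall-clock `origin` ("HH:MM") to `clock` ("HH:MM").

    Recordings are assumed to fit in a single day (no midnight wrap).
    """
    h1, m1 = (int(x) for x in origin.split(":"))
    h2, m2 = (int(x) for x in clock.split(":"))
    return float(((h2 * 60 + m2) - (h1 * 60 + m1)) * 60_000)


@dataclass(frozen=True)
class RRSeries:
    """Beat-interval series: beat times (ms since recording start, strictly
    increasing) and the RR interval (ms) ending at each beat time."""

    beat_time: np.ndarray
    rr: np.ndarray
    participant_id: str = ""

    def __post_init__(self) -> None:
        bt = np.asarray(self.beat_time, dtype=float)
        rr = np.asarray(self.rr, dtype=float)
        object.__setattr__(self, "beat_time", bt)
        object.__setattr__(self, "rr", rr)
        if bt.shape != rr.shape or bt.ndim != 1:
            raise ValueError("beat_time and rr must be 1-D and equal length")
        if len(bt) and (np.any(rr <= 0) or np.any(np.diff(bt) <= 0)):
            raise ValueError("rr must be positive and beat_time strictly increasing")

    def __len__(self) -> int:
        return len(self.rr)


@dataclass(frozen=True)
class FilterConfig:
    """NN-interval artifact filter parameters.

    Beats outside [min_nn, max_nn] ms are removed (bounds inclusive on the
    retained side: a beat exactly at a bound is kept), as are beats deviating
    from the running median of the previous `median_window` retained
    intervals by more than `deviation_fraction` of that median.
    """

    min_nn: float = 400.0
    max_nn: float = 1300.0
    deviation_fraction: float = 0.70
    median_window: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.min_nn < self.max_nn):
            raise ValueError("need 0 < min_nn < max_nn")
        if self.deviation_fraction <= 0:
            raise ValueError("deviation_fraction must be > 0")
        if self.median_window < 1:
            raise ValueError("median_window must be >= 1")


@dataclass(frozen=True)
class NNSeries(RRSeries):
    """Filtered series plus a removal log of (source_index, reason)."""

    removal_log: tuple = ()


@dataclass(frozen=True)
class SegmentSpec:
    """Evening grid and segment-window parameters.

    window_s is the analysis-segment length; questionnaire_tolerance_s is the
    maximal offset between a grid time and a matched questionnaire row (and
    between a grid time and an accepted window start); max_gap_ms
    operationalizes "breakless": no inter-beat gap above it.
    """

    time_points: tuple[str, ...] = ("20:00", "20:30", "21:00", "21:30", "22:00")
    window_s: float = 240.0
    questionnaire_tolerance_s: float = 900.0
    max_gap_ms: float = 2000.0

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be > 0")
        if self.questionnaire_tolerance_s < 0:
            raise ValueError("questionnaire_tolerance_s must be >= 0")


@dataclass(frozen=True)
class Segment:
    """A window of consecutive retained beats for one (participant, grid time)."""

    participant_id: str
    time_point: str
    nn: NNSeries
    window_start: float
    window_end: float


def filter_nn(rr: RRSeries, cfg: FilterConfig = FilterConfig()) -> NNSeries:
    """Single left-to-right artifact-removal pass.

    Beat i is removed if its interval is below min_nn, above max_nn, or
    deviates from M_i by more than deviation_fraction * M_i, where M_i is the
    median of the most recent `median_window` *retained* intervals. The
    deviation rule is inactive while fewer than `median_window` intervals
    have been retained, so a reference median always exists and a single
    artifact cannot poison it. The removal log records every dropped beat.
    """
    n = len(rr)
    keep = np.zeros(n, dtype=bool)
    log: list[tuple[int, str]] = []
    recent: list[float] = []  # ring of last `median_window` retained intervals
    w = cfg.median_window
    for i in range(n):
        x = rr.rr[i]
        if x < cfg.min_nn:
            log.append((i, BELOW_MIN))
            continue
        if x > cfg.max_nn:
            log.append((i, ABOVE_MAX))
            continue
        if len(recent) >= w:
            m = float(np.median(recent[-w:]))
            if abs(x - m) > cfg.deviation_fraction * m:
                log.append((i, MEDIAN_DEVIATION))
                continue
        keep[i] = True
        recent.append(x)
        if len(recent) > w:
            recent.pop(0)
    return NNSeries(
        beat_time=rr.beat_time[keep],
        rr=rr.rr[keep],
        participant_id=rr.participant_id,
        removal_log=tuple(log),
    )


def _validate_filtered(nn: NNSeries, cfg: FilterConfig) -> None:
    if len(nn) and (np.any(nn.rr < cfg.min_nn) or np.any(nn.rr > cfg.max_nn)):
        raise ValueError("input is not a filtered NN series (intervals out of bounds)")


def extract_segment(
    nn: NNSeries,
    target_ms: float,
    spec: SegmentSpec = SegmentSpec(),
    cfg: FilterConfig = FilterConfig(),
    participant_id: Optional[str] = None,
    time_point: str = "",
) -> Optional[Segment]:
    """Select the breakless window of `window_s` seconds nearest `target_ms`.

    Candidate windows start at the onset of each retained interval
    (beat_time - rr). A candidate qualifies if consecutive retained beats up
    to window_start + window_s are never separated by more than max_gap_ms
    and the window is fully covered by beats. Among qualifying windows whose
    start lies within the questionnaire tolerance of the target, the one
    minimizing |window_start - target| is returned (ties -> earlier). None if
    no window qualifies.
    """
    _validate_filtered(nn, cfg)
    n = len(nn)
    if n == 0:
        return None
    win = spec.window_s * 1000.0
    tol = spec.questionnaire_tolerance_s * 1000.0
    starts = nn.beat_time - nn.rr  # onset of each interval
    best: Optional[tuple[float, float, int, int]] = None  # (dist, start, i, j)
    j = 0
    for i in range(n):
        s = starts[i]
        if abs(s - target_ms) > tol:
            continue
        # first beat must begin within the window seamlessly
        if j < i:
            j = i
        # advance j to the first beat covering s + win
        while j < n and nn.beat_time[j] < s + win:
            j += 1
        if j >= n:
            break  # later starts only make coverage worse
        # gap check across beats i..j (interval onsets are contiguous in time
        # only if consecutive beat times are close)
        seg_bt = nn.beat_time[i : j + 1]
        gaps = np.diff(seg_bt)
        if seg_bt[0] - s > cfg.max_nn or (len(gaps) and gaps.max() > spec.max_gap_ms):
            continue
        d = abs(s - target_ms)
        if best is None or d < best[0] - 1e-9:
            best = (d, s, i, j)
    if best is None:
        return None
    _, s, i, j = best
    sub = NNSeries(
        beat_time=nn.beat_time[i : j + 1],
        rr=nn.rr[i : j + 1],
        participant_id=nn.participant_id,
        removal_log=(),
    )
    return Segment(
        participant_id=participant_id if participant_id is not None else nn.participant_id,
        time_point=time_point,
        nn=sub,
        window_start=s,
        window_end=s + win,
    )


def align_questionnaire(
    rows,
    spec: SegmentSpec = SegmentSpec(),
    *,
    warn=None,
) -> dict:
    """Match questionnaire rows to the evening grid, per participant.

    `rows` is an iterable of (participant_id, clock "HH:MM", kss, sss).
    Returns {(participant_id, grid_time): (kss, sss)}. Each grid time is
    matched to at most one row and vice versa; the assignment minimizes the
    total absolute clock offset subject to the per-match tolerance. Grid
    times with no row inside the tolerance are absent from the result.
    Out-of-range scores reject the row (warn callback, default silent).
    """
    by_pid: dict[str, list[tuple[float, str, int, int]]] = {}
    for pid, clock, kss, sss in rows:
        kss, sss = int(kss), int(sss)
        if not (1 <= kss <= 9 and 1 <= sss <= 7):
            if warn:
                warn(f"participant {pid} @ {clock}: score out of range, row dropped")
            continue
        t = clock_to_ms(clock, "00:00")
        by_pid.setdefault(str(pid), []).append((t, clock, kss, sss))

    tol = spec.questionnaire_tolerance_s * 1000.0
    grid = [(tp, clock_to_ms(tp, "00:00")) for tp in spec.time_points]
    big = 1e15
    out: dict[tuple[str, str], tuple[int, int]] = {}
    for pid, recs in by_pid.items():
        cost = np.full((len(grid), len(recs)), big)
        for gi, (_, gt) in enumerate(grid):
            for ri, (t, *_rest) in enumerate(recs):
                d = abs(t - gt)
                if d <= tol:
                    cost[gi, ri] = d
        gi_idx, ri_idx = linear_sum_assignment(cost)
        for gi, ri in zip(gi_idx, ri_idx):
            if cost[gi, ri] < big:
                tp = grid[gi][0]
                _, _, kss, sss = recs[ri]
                out[(pid, tp)] = (kss, sss)
        if len(recs) > len(grid) and warn:
            warn(f"participant {pid}: more questionnaire rows than grid times")
    return out
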