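"""Convergence-event detection via piecewise aggregate approximation (PAA).

The instantaneous frequency ratio of a pair is noisy at full resolution, so
it is first reduced with PAA: the series is cut into equal frames of length
``w`` seconds and each frame is replaced by the mean of its valid samples.
Frames whose reduced ratio lies within a tolerance band ``(p/q)(1 +/- delta)``
around a small-integer ratio are marked convergent; maximal runs of convergent
frames separated by gaps of at most ``delta_tau`` are merged, and merged runs
shorter than ``tau`` are discarded.  The surviving intervals are the
convergence events.  Default parameters: w = 0.5 s, delta = +/-1%, tau = 1 s,
delta_tau = 1 s.

Event boundaries are reported at frame resolution; the full-resolution ratio
samples within an event remain available for downstream metrics via
:func:`event_samples`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .pairing import RatioSeries
from .signals import FrequencyTrace

__all__ = [
    "PAASeries",
    "DetectionConfig",
    "ConvergenceEvent",
    "CohortEventSummary",
    "DurationSummary",
    "paa_reduce",
    "tolerance_band",
    "detect_events",
    "event_samples",
    "summarize_cohort",
    "aggregate_durations",
    "MALE_FEMALE_RATIOS",
    "MALE_MALE_RATIOS",
]

#: Harmonic ratios at which opposite-sex convergence is assessed.  The
#: prominent 7:6 population peak is deliberately not part of the default set
#: (harmonics above the male fourth / female fifth carry too little acoustic
#: energy to be behaviourally relevant); add it explicitly if needed.
MALE_FEMALE_RATIOS: tuple[tuple[int, int], ...] = ((1, 1), (5, 4), (4, 3), (3, 2), (5, 3), (2, 1))
MALE_MALE_RATIOS: tuple[tuple[int, int], ...] = ((1, 1),)


def tolerance_band(p: int, q: int, delta: float) -> tuple[float, float]:
    """Tolerance interval ``(p/q)(1 - delta), (p/q)(1 + delta)`` around p:q."""
    if not (int(p) == p and int(q) == q and p >= q >= 1):
        raise ValueError("require integer p >= q >= 1")
    if not 0 < delta < 1:
        raise ValueError("delta must be in (0, 1)")
    r = p / q
    return (r * (1.0 - delta), r * (1.0 + delta))


@dataclass
class PAASeries:
    """Piecewise aggregate approximation of a series.

    ``frame_means[i]`` is the mean of frame i's valid source samples; a frame
    is invalid when fewer than ``min_valid_fraction`` of its samples were
    valid.  The trailing frame may be partial and is averaged over the
    samples it has.
    """

    frame_means: np.ndarray
    frame_valid: np.ndarray
    frame_length_s: float
    n_source: int
    source_rate_hz: float

    @property
    def n_frames(self) -> int:
        return self.frame_means.size

    def frame_bounds_s(self, i: int) -> tuple[float, float]:
        """Half-open time interval [start, end) covered by frame i."""
        m = int(round(self.frame_length_s * self.source_rate_hz))
        start = i * m
        end = min((i + 1) * m, self.n_source)
        return start / self.source_rate_hz, end / self.source_rate_hz


def paa_reduce(
    series,
    window_s: float,
    sample_rate_hz: float | None = None,
    valid_mask: np.ndarray | None = None,
    min_valid_fraction: float = 0.5,
) -> PAASeries:
    """Reduce a series to per-frame means (PAA).

    ``series`` may be a :class:`~wingbeat.pairing.RatioSeries`, a
    :class:`~wingbeat.signals.FrequencyTrace`, or a plain array (in which
    case ``sample_rate_hz`` is required).  Frames with fewer than
    ``min_valid_fraction`` valid samples are flagged invalid.
    """
    if isinstance(series, RatioSeries):
        values, mask, fs = series.r, series.valid_mask, series.sample_rate_hz
    elif isinstance(series, FrequencyTrace):
        values, mask, fs = series.omega_hz, series.valid_mask, series.sample_rate_hz
    else:
        values = np.asarray(series, dtype=float)
        if sample_rate_hz is None:
            raise ValueError("sample_rate_hz is required for a plain array")
        fs = float(sample_rate_hz)
        mask = np.ones(values.size, dtype=bool)
    if valid_mask is not None:
        mask = np.asarray(valid_mask, dtype=bool)
    n = values.size
    if n == 0:
        raise ValueError("series is empty")
    if window_s <= 0:
        raise ValueError("window_s must be positive")

    m = int(round(window_s * fs))
    if m >= n:
        if m > n:
            warnings.warn("PAA window longer than the series; returning a single frame")
        m = n
    n_frames = math.ceil(n / m)

    vals = np.where(mask, values, 0.0)
    edges = np.arange(n_frames) * m
    sums = np.add.reduceat(vals, edges)
    counts = np.add.reduceat(mask.astype(np.int64), edges)
    sizes = np.diff(np.r_[edges, n])
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    valid = counts >= min_valid_fraction * sizes
    valid &= counts > 0
    means = np.where(counts > 0, means, np.nan)
    return PAASeries(means, valid, m / fs, n, fs)


@dataclass(frozen=True)
class DetectionConfig:
    """Parameters of the convergence-event detector."""

    w: float = 0.5
    delta: float = 0.01
    tau: float = 1.0
    delta_tau: float = 1.0
    ratios: tuple[tuple[int, int], ...] = MALE_FEMALE_RATIOS
    min_valid_fraction: float = 0.5
    gap_mode: str = "merge"  # "merge": bridge gaps <= delta_tau; "discard": keep runs apart

    def __post_init__(self) -> None:
        if min(self.w, self.tau, self.delta_tau) <= 0:
            raise ValueError("w, tau and delta_tau must be positive")
        if self.gap_mode not in ("merge", "discard"):
            raise ValueError("gap_mode must be 'merge' or 'discard'")
        bands = sorted(tolerance_band(p, q, self.delta) for p, q in self.ratios)
        for (lo1, hi1), (lo2, hi2) in zip(bands, bands[1:]):
            if hi1 >= lo2:
                raise ValueError(
                    f"tolerance bands overlap at delta={self.delta}: "
                    f"[{lo1:.4f}, {hi1:.4f}] and [{lo2:.4f}, {hi2:.4f}]"
                )

    def bands(self) -> list[tuple[tuple[int, int], tuple[float, float]]]:
        return [((p, q), tolerance_band(p, q, self.delta)) for p, q in self.ratios]


@dataclass(frozen=True)
class ConvergenceEvent:
    """One detected convergence event at integer ratio p:q."""

    p: int
    q: int
    start_s: float
    end_s: float
    pair_id: str = ""
    recording_id: str = ""

    @property
    def label(self) -> str:
        return f"{self.p}:{self.q}"

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open index intervals."""
    if not flags.any():
        return []
    d = np.diff(flags.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if flags[0]:
        starts = np.r_[0, starts]
    if flags[-1]:
        ends = np.r_[ends, flags.size]
    return list(zip(starts.tolist(), ends.tolist()))


def detect_events(
    ratio: RatioSeries,
    config: DetectionConfig | None = None,
    pair_id: str = "",
    recording_id: str = "",
) -> list[ConvergenceEvent]:
    """Detect convergence events in a ratio series.

    The series is PAA-reduced with window ``w``; per target ratio, frames
    whose reduced value lies in the tolerance band form binary runs (invalid
    frames break runs and count toward separation).  Runs separated by at
    most ``delta_tau`` are merged (default) and merged runs shorter than
    ``tau`` are dropped.  Events are returned in time order with
    frame-resolution, half-open [start_s, end_s) boundaries.
    """
    config = config or DetectionConfig()
    paa = paa_reduce(
        ratio, config.w, valid_mask=None, min_valid_fraction=config.min_valid_fraction
    )
    events: list[ConvergenceEvent] = []
    for (p, q), (lo, hi) in config.bands():
        with np.errstate(invalid="ignore"):
            in_band = paa.frame_valid & (paa.frame_means >= lo) & (paa.frame_means <= hi)
        runs = _runs(in_band)
        if not runs:
            continue
        spans = [(paa.frame_bounds_s(s)[0], paa.frame_bounds_s(e - 1)[1]) for s, e in runs]
        if config.gap_mode == "merge":
            merged = [list(spans[0])]
            for start, end in spans[1:]:
                if start - merged[-1][1] <= config.delta_tau:
                    merged[-1][1] = end
                else:
                    merged.append([start, end])
        else:
            merged = [list(s) for s in spans]
        kept = [(s, e) for s, e in merged if e - s >= config.tau]
        if config.gap_mode == "discard":
            separated: list[tuple[float, float]] = []
            for s, e in kept:
                if separated and s - separated[-1][1] <= config.delta_tau:
                    continue
                separated.append((s, e))
            kept = separated
        events.extend(
            ConvergenceEvent(p, q, s, e, pair_id=pair_id, recording_id=recording_id)
            for s, e in kept
        )
    events.sort(key=lambda ev: (ev.start_s, ev.label))
    return events


def event_samples(ratio: RatioSeries, event: ConvergenceEvent) -> np.ndarray:
    """Full-resolution valid ratio samples within an event's bounds."""
    i0 = int(round(event.start_s * ratio.sample_rate_hz))
    i1 = int(round(event.end_s * ratio.sample_rate_hz))
    sl = slice(max(i0, 0), min(i1, len(ratio)))
    return ratio.r[sl][ratio.valid_mask[sl]]


# --- cohort summaries -------------------------------------------------------


def _format_rate(rate: float) -> float:
    """One decimal below 10; two significant figures at 10 and above."""
    if rate >= 10:
        return float(f"{rate:.2g}")
    return round(rate, 1)


@dataclass
class CohortEventSummary:
    """Cohort-level convergence-event counts and rates.

    Proportions are fractions of the respective totals; ``as_row`` renders
    them the way summary tables print them (whole percent, rates to one
    decimal or two significant figures above 10).
    """

    n_recordings: int
    recordings_with_event: int
    recordings_with_multiple_events: int
    recordings_with_multiple_ratios: int
    n_pairs: int
    pairs_with_event: int
    pairs_with_multiple_ratios: int
    total_events: int

    @property
    def events_per_recording(self) -> float:
        return self.total_events / self.n_recordings if self.n_recordings else 0.0

    @property
    def events_per_pair(self) -> float:
        return self.total_events / self.n_pairs if self.n_pairs else 0.0

    def as_row(self) -> dict:
        def pct(k: int, n: int) -> int:
            return int(round(100.0 * k / n)) if n else 0

        return {
            "recordings_total": self.n_recordings,
            "recordings_at_least_1": self.recordings_with_event,
            "recordings_at_least_1_pct": pct(self.recordings_with_event, self.n_recordings),
            "recordings_more_than_1": self.recordings_with_multiple_events,
            "recordings_more_than_1_pct": pct(
                self.recordings_with_multiple_events, self.n_recordings
            ),
            "recordings_multiple_ratio": self.recordings_with_multiple_ratios,
            "recordings_multiple_ratio_pct": pct(
                self.recordings_with_multiple_ratios, self.n_recordings
            ),
            "pairs_total": self.n_pairs,
            "pairs_at_least_1": self.pairs_with_event,
            "pairs_at_least_1_pct": pct(self.pairs_with_event, self.n_pairs),
            "pairs_multiple_ratio": self.pairs_with_multiple_ratios,
            "pairs_multiple_ratio_pct": pct(self.pairs_with_multiple_ratios, self.n_pairs),
            "events_total": self.total_events,
            "events_per_recording": _format_rate(self.events_per_recording),
            "events_per_pair": _format_rate(self.events_per_pair),
        }


def summarize_cohort(
    events: list[ConvergenceEvent],
    recording_to_pair: dict[str, str],
) -> CohortEventSummary:
    """Tabulate convergence-event statistics over a cohort.

    ``recording_to_pair`` maps every recording id in the cohort (with or
    without events) to its unique-pair id; repeat recordings of the same pair
    share a pair id.
    """
    by_recording: dict[str, list[ConvergenceEvent]] = {rid: [] for rid in recording_to_pair}
    for ev in events:
        if ev.recording_id not in by_recording:
            raise ValueError(f"event references unknown recording {ev.recording_id!r}")
        by_recording[ev.recording_id].append(ev)

    pair_ids = sorted(set(recording_to_pair.values()))
    by_pair: dict[str, list[ConvergenceEvent]] = {pid: [] for pid in pair_ids}
    for rid, evs in by_recording.items():
        by_pair[recording_to_pair[rid]].extend(evs)

    return CohortEventSummary(
        n_recordings=len(by_recording),
        recordings_with_event=sum(1 for evs in by_recording.values() if len(evs) >= 1),
        recordings_with_multiple_events=sum(1 for evs in by_recording.values() if len(evs) > 1),
        recordings_with_multiple_ratios=sum(
            1 for evs in by_recording.values() if len({e.label for e in evs}) > 1
        ),
        n_pairs=len(by_pair),
        pairs_with_event=sum(1 for evs in by_pair.values() if len(evs) >= 1),
        pairs_with_multiple_ratios=sum(
            1 for evs in by_pair.values() if len({e.label for e in evs}) > 1
        ),
        total_events=len(events),
    )


@dataclass
class DurationSummary:
    """Per-recording aggregated convergence durations and event-level stats."""

    gamma_by_recording: dict[str, float] = field(default_factory=dict)
    event_durations_s: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def gamma_values(self) -> np.ndarray:
        """Aggregated durations of recordings where convergence was observed."""
        return np.array([g for g in self.gamma_by_recording.values() if g > 0])

    @property
    def event_mean_s(self) -> float:
        return float(np.mean(self.event_durations_s)) if self.event_durations_s.size else 0.0

    @property
    def event_sem_s(self) -> float:
        n = self.event_durations_s.size
        return float(np.std(self.event_durations_s, ddof=1) / np.sqrt(n)) if n > 1 else 0.0

    def event_quantiles(self, qs=(0.25, 0.5, 0.75)) -> dict[float, float]:
        if not self.event_durations_s.size:
            return {q: 0.0 for q in qs}
        return {q: float(np.quantile(self.event_durations_s, q)) for q in qs}


def aggregate_durations(
    events: list[ConvergenceEvent],
    recording_ids: list[str] | None = None,
) -> DurationSummary:
    """Aggregate event durations per recording (gamma) and per event.

    Recordings without convergence have gamma = 0 and are excluded from the
    ``gamma_values`` population.
    """
    gamma: dict[str, float] = {rid: 0.0 for rid in (recording_ids or [])}
    for ev in events:
        gamma[ev.recording_id] = gamma.get(ev.recording_id, 0.0) + ev.duration_s
    durations = np.array([ev.duration_s for ev in events], dtype=float)
    return DurationSummary(gamma_by_recording=gamma, event_durations_s=durations)
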