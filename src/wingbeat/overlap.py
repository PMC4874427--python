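"""Windowed histogram overlap and local flight-tone variability.

During harmonic convergence the short-time frequency distributions of the two
mosquitoes' convergent overtones increasingly share support.  The overlap
fraction ``alpha`` between two normalized m-bin histograms a and b is their
histogram intersection, ``sum_i min(a_i, b_i)``, which lies in [0, 1], equals
1 for identical distributions and 0 for disjoint ones.  Waterfall analysis
uses non-overlapping 1-s windows at 1-Hz frequency resolution.

Local flight-tone variability is the windowed coefficient of variation
``c_v(t) = sigma(t)/mu(t)`` (rectangular sliding window, 0.25 s), a
scale-free dispersion measure that allows comparison across individuals with
very different mean wing-beat frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signals import FrequencyTrace

__all__ = [
    "WindowedHistogramSeries",
    "OverlapSeries",
    "CvSeries",
    "CohortSummary",
    "windowed_histograms",
    "overlap_series",
    "local_cv",
    "cohort_flight_stats",
]


@dataclass
class WindowedHistogramSeries:
    """Per-window normalized frequency histograms on an integer-aligned grid.

    ``counts[w, i]`` is the fraction of window w's valid samples in bin i;
    each valid window's counts sum to 1.  Bin edges are multiples of the bin
    width starting from zero so that grids from different traces align.
    """

    counts: np.ndarray  # (n_windows, m)
    bin_edges: np.ndarray  # (m + 1,)
    window_starts_s: np.ndarray
    window_s: float
    bin_hz: float
    window_valid: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.counts.shape[0]


@dataclass
class OverlapSeries:
    """Histogram-intersection overlap alpha(t) per window, in [0, 1]."""

    alpha: np.ndarray
    window_starts_s: np.ndarray
    valid: np.ndarray


@dataclass
class CvSeries:
    """Local coefficient of variation c_v(t) = sigma(t)/mu(t)."""

    cv: np.ndarray
    valid_mask: np.ndarray
    sample_rate_hz: float

    @property
    def valid_values(self) -> np.ndarray:
        return self.cv[self.valid_mask]


def windowed_histograms(
    trace: FrequencyTrace,
    k: int = 1,
    window_s: float = 1.0,
    bin_hz: float = 1.0,
    hop_s: float | None = None,
) -> WindowedHistogramSeries:
    """Short-time frequency histograms of the k-th harmonic trace.

    Windows are non-overlapping by default (hop = window).  Windows without
    any valid sample are flagged invalid.  Raises if the trace has no valid
    samples at all.
    """
    if window_s <= 0 or bin_hz <= 0:
        raise ValueError("window_s and bin_hz must be positive")
    if int(k) != k or k < 1:
        raise ValueError("harmonic index k must be an integer >= 1")
    f = trace.omega_hz * int(k)
    mask = trace.valid_mask
    if not mask.any():
        raise ValueError("trace has no valid samples")
    fs = trace.sample_rate_hz
    m = max(1, int(round(window_s * fs)))
    hop = m if hop_s is None else max(1, int(round(hop_s * fs)))
    starts = np.arange(0, max(len(trace) - m, 0) + 1, hop)
    if starts.size == 0:
        starts = np.array([0])

    vmin = f[mask].min()
    vmax = f[mask].max()
    lo = np.floor(vmin / bin_hz) * bin_hz
    hi = np.ceil(vmax / bin_hz) * bin_hz
    hi = hi if hi > lo else lo + bin_hz
    edges = lo + bin_hz * np.arange(int(round((hi - lo) / bin_hz)) + 1)

    counts = np.zeros((starts.size, edges.size - 1))
    valid = np.zeros(starts.size, dtype=bool)
    for wi, s in enumerate(starts):
        seg = f[s : s + m][mask[s : s + m]]
        if seg.size:
            c, _ = np.histogram(seg, bins=edges)
            counts[wi] = c / c.sum()
            valid[wi] = True
    return WindowedHistogramSeries(counts, edges, starts / fs, m / fs, bin_hz, valid)


def _embed(h: WindowedHistogramSeries, lo: float, n_bins: int) -> np.ndarray:
    """Place a histogram series onto a wider shared integer-aligned grid."""
    offset = int(round((h.bin_edges[0] - lo) / h.bin_hz))
    out = np.zeros((h.n_windows, n_bins))
    out[:, offset : offset + h.counts.shape[1]] = h.counts
    return out


def overlap_series(h_a: WindowedHistogramSeries, h_b: WindowedHistogramSeries) -> OverlapSeries:
    """Per-window overlap fraction between two windowed-histogram series.

    The two series must share window placement and bin width; bin ranges are
    merged onto a common grid (both are integer-aligned, so bins coincide).
    """
    if h_a.bin_hz != h_b.bin_hz:
        raise ValueError("bin widths differ")
    if h_a.n_windows != h_b.n_windows or not np.allclose(
        h_a.window_starts_s, h_b.window_starts_s
    ):
        raise ValueError("window grids differ")
    lo = min(h_a.bin_edges[0], h_b.bin_edges[0])
    hi = max(h_a.bin_edges[-1], h_b.bin_edges[-1])
    n_bins = int(round((hi - lo) / h_a.bin_hz))
    a = _embed(h_a, lo, n_bins)
    b = _embed(h_b, lo, n_bins)
    alpha = np.minimum(a, b).sum(axis=1)
    valid = h_a.window_valid & h_b.window_valid
    alpha[~valid] = np.nan
    return OverlapSeries(alpha, h_a.window_starts_s.copy(), valid)


def local_cv(trace: FrequencyTrace, window_s: float = 0.25) -> CvSeries:
    """Local coefficient of variation over a centred rectangular window.

    c_v(t) is the sample standard deviation divided by the mean of the
    window centred at t.  It is undefined (masked) wherever the window
    touches an invalid sample or the record edge.  Scale-invariant:
    c_v of k*omega equals c_v of omega for any k > 0.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    fs = trace.sample_rate_hz
    m = max(3, int(round(window_s * fs)) | 1)  # odd length: well-defined centre
    vals = pd.Series(np.where(trace.valid_mask, trace.omega_hz, np.nan))
    roll = vals.rolling(m, center=True, min_periods=m)
    mu = roll.mean().to_numpy()
    sigma = roll.std(ddof=1).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = sigma / mu
    valid = np.isfinite(cv) & np.isfinite(mu)
    nonpos = valid & (mu <= 0)
    if nonpos.any():
        warnings.warn("windows with non-positive mean frequency were masked")
        valid &= mu > 0
    cv = np.where(valid, cv, np.nan)
    return CvSeries(cv, valid, fs)


@dataclass
class CohortSummary:
    """Cohort flight-tone statistics: location and dispersion.

    ``sigma_intra`` is the mean within-recording SD; ``sigma_inter`` the SD
    of recording means (NaN when fewer than two recordings); ``iqr_intra``
    the mean within-recording inter-quartile range with its range across
    recordings.
    """

    n_recordings: int
    mean_hz: float
    mean_range_hz: tuple[float, float]
    sigma_intra_hz: float
    sigma_inter_hz: float
    iqr_intra_hz: float
    iqr_range_hz: tuple[float, float]


def cohort_flight_stats(traces_by_recording: dict[str, FrequencyTrace]) -> CohortSummary:
    """Summarize fundamental-frequency statistics across recordings.

    Recordings without any valid sample are excluded with a warning.
    """
    means, sds, iqrs = [], [], []
    for rid, trace in traces_by_recording.items():
        v = trace.valid_values
        if v.size == 0:
            warnings.warn(f"recording {rid!r} has no valid samples; excluded")
            continue
        means.append(float(np.mean(v)))
        sds.append(float(np.std(v, ddof=1)) if v.size > 1 else 0.0)
        q75, q25 = np.percentile(v, [75, 25])
        iqrs.append(float(q75 - q25))
    if not means:
        raise ValueError("no recording has valid samples")
    means_arr = np.array(means)
    sigma_inter = float(np.std(means_arr, ddof=1)) if means_arr.size > 1 else float("nan")
    return CohortSummary(
        n_recordings=len(means),
        mean_hz=float(means_arr.mean()),
        mean_range_hz=(float(means_arr.min()), float(means_arr.max())),
        sigma_intra_hz=float(np.mean(sds)),
        sigma_inter_hz=sigma_inter,
        iqr_intra_hz=float(np.mean(iqrs)),
        iqr_range_hz=(float(np.min(iqrs)), float(np.max(iqrs))),
    )
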