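"""Pairwise frequency-ratio and separation analysis, and the randomization null.

Harmonic convergence shows up as the instantaneous ratio between two
fundamentals sitting at a small-integer fraction.  The ratio is computed per
sample with the lower frequency as the denominator (``max/min``), so r(t) >= 1
always and 1:1 convergence between crossing traces is representable.

The non-interacting null is built by pairing recordings of lone individuals
("artificial pairs"): such pairs cannot have modulated their wing beats in
response to each other, so any structure in their pooled ratio distribution is
what chance alone produces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signals import FrequencyTrace

__all__ = [
    "RatioSeries",
    "SeparationSeries",
    "CohortDistribution",
    "ratio_series",
    "separation_series",
    "cohort_ratio_distribution",
    "make_artificial_pairs",
    "peak_to_background",
]


@dataclass
class RatioSeries:
    """Instantaneous pairwise frequency ratio r(t) >= 1 with validity mask."""

    r: np.ndarray
    valid_mask: np.ndarray
    sample_rate_hz: float

    def __len__(self) -> int:
        return self.r.size

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self)) / self.sample_rate_hz

    @property
    def valid_values(self) -> np.ndarray:
        return self.r[self.valid_mask]


@dataclass
class SeparationSeries:
    """Absolute instantaneous frequency separation |f_a - f_b| in Hz."""

    delta_hz: np.ndarray
    valid_mask: np.ndarray
    sample_rate_hz: float

    @property
    def valid_values(self) -> np.ndarray:
        return self.delta_hz[self.valid_mask]


@dataclass
class CohortDistribution:
    """Pooled, density-normalized histogram over a cohort of pairs."""

    bin_edges: np.ndarray
    density: np.ndarray
    n_pairs: int
    total_valid_seconds: float

    @property
    def bin_centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def _common_support(a: FrequencyTrace, b: FrequencyTrace):
    if a.sample_rate_hz != b.sample_rate_hz:
        raise ValueError("traces must share a sampling rate")
    n = min(len(a), len(b))
    if n == 0:
        raise ValueError("traces have no common support")
    valid = a.valid_mask[:n] & b.valid_mask[:n]
    fa, fb = a.omega_hz[:n], b.omega_hz[:n]
    if np.any(fa[valid] <= 0) or np.any(fb[valid] <= 0):
        raise ValueError("non-positive frequency at a valid sample")
    return fa, fb, valid, a.sample_rate_hz


def ratio_series(a: FrequencyTrace, b: FrequencyTrace) -> RatioSeries:
    """Instantaneous ratio with the lower frequency as denominator.

    Symmetric in its arguments; invalid wherever either trace is invalid.
    """
    fa, fb, valid, fs = _common_support(a, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.maximum(fa, fb) / np.minimum(fa, fb)
    r = np.where(valid, r, 1.0)
    return RatioSeries(r, valid, fs)


def separation_series(a: FrequencyTrace, b: FrequencyTrace) -> SeparationSeries:
    """Absolute frequency separation between two fundamentals."""
    fa, fb, valid, fs = _common_support(a, b)
    return SeparationSeries(np.abs(fa - fb), valid, fs)


def cohort_ratio_distribution(
    pairs: list[RatioSeries],
    bin_width: float = 0.005,
    weighting: str = "equal-pair",
    r_min: float = 1.0,
    r_max: float | None = None,
) -> CohortDistribution:
    """Pooled ratio distribution over a cohort of pairs.

    With ``weighting='equal-pair'`` (default) each pair's histogram is
    normalized before pooling, so long recordings do not dominate;
    ``'pooled-sample'`` pools all valid samples directly.  The result is
    density-normalized (integrates to 1 over the binned domain).
    """
    if weighting not in ("equal-pair", "pooled-sample"):
        raise ValueError("weighting must be 'equal-pair' or 'pooled-sample'")
    samples = [p.valid_values for p in pairs]
    samples = [s for s in samples if s.size]
    if not samples:
        raise ValueError("no valid ratio samples in the cohort")
    if r_max is None:
        r_max = max(float(s.max()) for s in samples)
    n_bins = max(1, int(np.ceil((r_max - r_min) / bin_width + 1e-9)))
    edges = r_min + bin_width * np.arange(n_bins + 1)

    if weighting == "equal-pair":
        mass = np.zeros(n_bins)
        for s in samples:
            counts, _ = np.histogram(s, bins=edges)
            total = counts.sum()
            if total:
                mass += counts / total
        mass /= len(samples)
    else:
        pooled = np.concatenate(samples)
        counts, _ = np.histogram(pooled, bins=edges)
        mass = counts / counts.sum()

    in_domain = mass.sum()
    density = mass / (in_domain * bin_width) if in_domain > 0 else mass
    total_seconds = sum(s.size / p.sample_rate_hz for s, p in zip(samples, pairs))
    return CohortDistribution(edges, density, n_pairs=len(samples), total_valid_seconds=total_seconds)


def make_artificial_pairs(
    lone_a: list[FrequencyTrace],
    lone_b: list[FrequencyTrace],
    count: int,
    seed=None,
) -> list[tuple[FrequencyTrace, FrequencyTrace]]:
    """Draw ``count`` distinct cross pairs of lone recordings, seeded.

    Index pairs are sampled uniformly without replacement from the full
    cross product; each pair is truncated to the common duration.
    """
    total = len(lone_a) * len(lone_b)
    if count > total:
        raise ValueError(f"count={count} exceeds the {total} available cross pairs")
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(seed)
    flat = rng.choice(total, size=count, replace=False)
    out = []
    for idx in flat:
        i, j = divmod(int(idx), len(lone_b))
        a, b = lone_a[i], lone_b[j]
        n = min(len(a), len(b))
        out.append((a.truncated(n), b.truncated(n)))
    return out


def peak_to_background(
    dist: CohortDistribution,
    ratio: float,
    delta: float = 0.01,
    background_halfwidth: float = 0.1,
) -> float:
    """Height of the +/-delta band around ``ratio`` relative to local background.

    Peak is the maximum density inside ``ratio*(1 +/- delta)``; background is
    the median density over ``ratio +/- background_halfwidth`` excluding the
    band.  Returns inf when the local background is empty but the band is not.
    """
    c = dist.bin_centres
    band = (c >= ratio * (1 - delta)) & (c <= ratio * (1 + delta))
    local = (c >= ratio - background_halfwidth) & (c <= ratio + background_halfwidth) & ~band
    if not band.any() or not local.any():
        return float("nan")
    peak = float(dist.density[band].max())
    background = float(np.median(dist.density[local]))
    if background <= 0:
        return float("inf") if peak > 0 else 1.0
    return peak / background
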