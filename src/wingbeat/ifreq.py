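"""Instantaneous fundamental-frequency extraction from flight-tone audio.

The fundamental wing-beat frequency is isolated with a two-pass, time-varying
scheme: a coarse short-time-Fourier ridge tracks the strongest spectral peak
inside the admissible search band, and the signal is then complex-demodulated
against that ridge (multiplication by ``exp(-i * integral 2*pi*c(t) dt)``
followed by a zero-phase low-pass whose cutoff is a fixed fraction of the
tracked fundamental).  This realizes a band-pass centred on the moving
fundamental together with the analytic-signal transform in one step; the
instantaneous frequency is the ridge plus the scaled derivative of the
unwrapped baseband phase, so the result has the full time resolution of the
audio.  The raw phase derivative is noise-dominated and is smoothed with a
short median filter and a low-pass well above any plausible wing-beat
modulation bandwidth.

Flight-cessation gaps are detected from the amplitude envelope and masked,
together with filter edge zones, in the returned trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from scipy.integrate import cumulative_trapezoid

from .signals import AudioRecording, FrequencyTrace

__all__ = [
    "FilterSpec",
    "NoFlightToneError",
    "track_fundamental",
    "harmonic_trace",
    "detect_flight_gaps",
    "MALE_SEARCH_BAND_HZ",
    "FEMALE_SEARCH_BAND_HZ",
]

#: Admissible fundamental ranges for tethered A. aegypti, by sex.
MALE_SEARCH_BAND_HZ = (550.0, 900.0)
FEMALE_SEARCH_BAND_HZ = (350.0, 600.0)


class NoFlightToneError(ValueError):
    """No spectral peak found inside the fundamental search band."""


@dataclass(frozen=True)
class FilterSpec:
    """Parameters of the time-varying fundamental-tracking filter."""

    coarse_window_s: float = 0.25
    coarse_hop_s: float = 0.05
    relative_bandwidth: float = 0.15
    search_band_hz: tuple[float, float] = (350.0, 900.0)
    peak_snr_threshold: float = 30.0
    if_median_s: float = 0.005
    if_lowpass_hz: float = 50.0

    def __post_init__(self) -> None:
        if not 0 < self.relative_bandwidth < 0.5:
            raise ValueError("relative_bandwidth must be in (0, 0.5)")
        lo, hi = self.search_band_hz
        if not 0 < lo < hi:
            raise ValueError("search_band_hz must satisfy 0 < low < high")
        if self.coarse_window_s <= 0 or self.coarse_hop_s <= 0:
            raise ValueError("coarse window and hop must be positive")


def _envelope(x: np.ndarray, fs: float, window_s: float = 0.005) -> np.ndarray:
    """Moving-RMS amplitude envelope."""
    size = max(1, int(round(window_s * fs)))
    power = ndimage.uniform_filter1d(x * x, size=size, mode="nearest")
    # the running-sum filter can leave tiny negative residues over silence
    return np.sqrt(np.maximum(power, 0.0))


def detect_flight_gaps(
    recording: AudioRecording,
    envelope_threshold_fraction: float = 0.1,
    min_gap_s: float = 0.05,
    channel: int = 0,
) -> np.ndarray:
    """Boolean gap mask (True = flight cessation) for one channel.

    A sample belongs to a gap when the RMS envelope stays below
    ``envelope_threshold_fraction`` times the median envelope for at least
    ``min_gap_s``.  On an all-silent recording the whole record is flagged
    and a warning is raised.
    """
    x = recording.channel(channel)
    fs = recording.sample_rate_hz
    env = _envelope(x, fs)
    med = float(np.median(env))
    if med <= np.finfo(float).tiny:
        warnings.warn("recording is silent; whole record flagged as a gap")
        return np.ones(x.size, dtype=bool)
    below = env < envelope_threshold_fraction * med
    min_run = max(1, int(round(min_gap_s * fs)))
    gap = np.zeros(x.size, dtype=bool)
    # runs of consecutive below-threshold samples
    edges = np.flatnonzero(np.diff(below.astype(np.int8)))
    starts = np.r_[0, edges + 1]
    ends = np.r_[edges + 1, below.size]
    for s, e in zip(starts, ends):
        if below[s] and e - s >= min_run:
            gap[s:e] = True
    return gap


def _coarse_ridge(
    x: np.ndarray, fs: float, spec: FilterSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Track the strongest in-band spectral peak per STFT frame.

    Returns frame centre times, ridge frequencies (parabolically interpolated
    around the peak bin) and a per-frame tracked flag (peak sufficiently
    above the in-band noise floor).
    """
    nperseg = int(round(spec.coarse_window_s * fs))
    hop = max(1, int(round(spec.coarse_hop_s * fs)))
    if x.size <= nperseg:
        raise ValueError("recording shorter than the coarse tracking window")
    freqs, times, sxx = signal.spectrogram(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg - hop
    )
    lo, hi = spec.search_band_hz
    band = (freqs >= lo) & (freqs <= hi)
    if not band.any():
        raise NoFlightToneError("search band contains no STFT bins")
    fb = freqs[band]
    sb = sxx[band]
    peak_idx = np.argmax(sb, axis=0)
    cols = np.arange(sb.shape[1])
    peak_pow = sb[peak_idx, cols]
    noise = np.median(sb, axis=0)
    tracked = peak_pow > spec.peak_snr_threshold * np.maximum(noise, np.finfo(float).tiny)

    # parabolic (log-power) interpolation for sub-bin frequency accuracy
    ridge = fb[peak_idx].astype(float)
    interior = (peak_idx > 0) & (peak_idx < sb.shape[0] - 1)
    ii = np.flatnonzero(interior)
    if ii.size:
        with np.errstate(divide="ignore"):
            lp = np.log(np.maximum(sb, np.finfo(float).tiny))
        y0 = lp[peak_idx[ii] - 1, ii]
        y1 = lp[peak_idx[ii], ii]
        y2 = lp[peak_idx[ii] + 1, ii]
        denom = y0 - 2 * y1 + y2
        shift = np.where(np.abs(denom) > 0, 0.5 * (y0 - y2) / np.where(denom == 0, 1, denom), 0.0)
        shift = np.clip(shift, -0.5, 0.5)
        ridge[ii] = ridge[ii] + shift * (freqs[1] - freqs[0])
    return times, ridge, tracked


def track_fundamental(
    recording: AudioRecording,
    spec: FilterSpec | None = None,
    channel: int = 0,
) -> FrequencyTrace:
    """Extract the instantaneous fundamental frequency of one channel.

    Returns a :class:`FrequencyTrace` at the audio sampling rate.  Samples
    inside flight gaps, within half a coarse window of record edges or gap
    boundaries, or in untrackable regions are flagged invalid.

    Raises
    ------
    NoFlightToneError
        If no frame shows a spectral peak in the search band.
    """
    spec = spec or FilterSpec()
    x = recording.channel(channel).astype(float)
    fs = recording.sample_rate_hz
    if spec.search_band_hz[1] > fs / 2 / 5:
        raise ValueError("search band must lie below one fifth of Nyquist")

    times, ridge, tracked = _coarse_ridge(x, fs, spec)
    if not tracked.any():
        raise NoFlightToneError("no spectral peak in the fundamental search band")
    if not tracked.all():
        good = np.flatnonzero(tracked)
        ridge = np.interp(np.arange(ridge.size), good, ridge[good])

    n = x.size
    t = np.arange(n) / fs
    centre = np.interp(t, times, ridge)

    # complex demodulation against the ridge: time-varying band-pass + analytic signal
    phase_c = 2.0 * np.pi * cumulative_trapezoid(centre, dx=1.0 / fs, initial=0.0)
    baseband = x * np.exp(-1j * phase_c)
    cutoff = spec.relative_bandwidth * float(np.median(centre))
    sos = signal.butter(4, cutoff, btype="low", fs=fs, output="sos")
    baseband = signal.sosfiltfilt(sos, baseband.real) + 1j * signal.sosfiltfilt(
        sos, baseband.imag
    )
    dphase = np.gradient(np.unwrap(np.angle(baseband))) * fs / (2.0 * np.pi)
    omega = centre + dphase

    # smooth the raw phase derivative: short median filter, then low-pass
    med_k = max(1, int(round(spec.if_median_s * fs)) | 1)
    omega = ndimage.median_filter(omega, size=med_k, mode="nearest")
    lp = signal.butter(4, spec.if_lowpass_hz, btype="low", fs=fs, output="sos")
    omega = signal.sosfiltfilt(lp, omega)

    gap = detect_flight_gaps(recording, channel=channel)
    valid = ~gap
    edge = int(round(spec.coarse_window_s * fs / 2))
    valid[:edge] = False
    if edge:
        valid[-edge:] = False
    # widen every gap by half a coarse window to cover filter transients
    if gap.any():
        valid &= ~ndimage.binary_dilation(gap, structure=np.ones(2 * edge + 1, dtype=bool))
    # physically implausible output is masked rather than clipped
    lo, hi = spec.search_band_hz
    valid &= np.isfinite(omega) & (omega > 0.5 * lo) & (omega < 2.0 * hi)
    return FrequencyTrace(np.where(valid, omega, 1.0), valid, fs)


def harmonic_trace(trace: FrequencyTrace, k: int) -> FrequencyTrace:
    """Trace of the k-th harmonic: frequencies times k, mask unchanged."""
    if int(k) != k or k < 1:
        raise ValueError("harmonic index k must be an integer >= 1")
    return FrequencyTrace(trace.omega_hz * int(k), trace.valid_mask.copy(), trace.sample_rate_hz)
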