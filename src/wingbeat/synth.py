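"""Seeded generator of synthetic mosquito flight tones.

No public corpus of paired tethered-flight recordings exists, so analyses are
exercised on synthetic data whose statistics emulate tethered *Aedes aegypti*:
lone males beat their wings around 691 Hz and lone females around 480 Hz, with
a within-recording wander of roughly 10-15 Hz (approximately normally
distributed) and a much larger spread between individuals.  The wander is
modelled as a discrete-time Ornstein-Uhlenbeck (mean-reverting Gaussian)
process, which reproduces the approximately normal lone-flight frequency
distribution; flight-cessation gaps and scripted harmonic-convergence episodes
(one partner steered onto a small-integer frequency ratio p:q with the other)
are injected on top.

Frequency traces are generated at a 1 kHz control rate — wing-beat modulation
is far slower than the audio rate — and interpolated up to the audio rate only
when rendering waveforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import lfilter

from .signals import AudioRecording, ChannelInfo, FrequencyTrace

__all__ = [
    "FlightToneProfile",
    "ScriptedEvent",
    "ConvergenceScript",
    "SyntheticPair",
    "simulate_trace",
    "simulate_pair",
    "render_waveform",
    "sample_cohort_profiles",
    "LONE_MALE",
    "LONE_FEMALE",
    "DEFAULT_HARMONIC_AMPLITUDES",
]

#: Harmonic overtones decay in amplitude; 1/k for k = 1..5 is the default model.
DEFAULT_HARMONIC_AMPLITUDES: tuple[float, ...] = tuple(1.0 / k for k in range(1, 6))


@dataclass(frozen=True)
class FlightToneProfile:
    """Statistical description of one mosquito's flight tone.

    Parameters
    ----------
    baseline_hz:
        Mean fundamental wing-beat frequency of the individual.
    wander_sd_hz:
        Stationary standard deviation of the within-recording frequency
        wander (Ornstein-Uhlenbeck process around the baseline).
    reversion_rate:
        Mean-reversion constant of the wander, 1/s.  Its reciprocal is the
        correlation time of the wander; the default 10 /s (0.1 s correlation
        time) reflects modulations rapid enough to defeat short-time Fourier
        analysis, as observed in tethered flight.
    gaps:
        Flight-cessation intervals as ``(start_s, duration_s)`` pairs.
    duration_s:
        Recording length in seconds (60 s is the standard protocol length).
    sample_rate_hz:
        Audio sampling rate used when rendering a waveform (40 kHz standard).
    control_rate_hz:
        Sampling rate of the generated frequency trace.
    modulation_bandwidth_hz:
        Upper band limit of the frequency wander: wing inertia keeps
        modulation far slower than the wing-beat itself.
    """

    baseline_hz: float
    wander_sd_hz: float = 10.0
    reversion_rate: float = 10.0
    gaps: tuple[tuple[float, float], ...] = ()
    duration_s: float = 60.0
    sample_rate_hz: float = 40_000.0
    control_rate_hz: float = 1_000.0
    modulation_bandwidth_hz: float = 50.0

    def __post_init__(self) -> None:
        if self.baseline_hz <= 0:
            raise ValueError("baseline_hz must be positive")
        if self.wander_sd_hz < 0:
            raise ValueError("wander_sd_hz must be non-negative")
        if self.reversion_rate <= 0:
            raise ValueError("reversion_rate must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.sample_rate_hz <= 0 or self.control_rate_hz <= 0:
            raise ValueError("sampling rates must be positive")
        # the rendered waveform must keep the default five harmonics below Nyquist
        if self.sample_rate_hz <= 2 * (5 * self.baseline_hz):
            raise ValueError("sample_rate_hz must exceed twice the fifth harmonic")
        for start, dur in self.gaps:
            if dur <= 0 or start < 0 or start + dur > self.duration_s:
                raise ValueError("gap intervals must lie within [0, duration_s]")


# Table-style population anchors for tethered A. aegypti lone flight.
LONE_MALE = FlightToneProfile(baseline_hz=691.2, wander_sd_hz=11.1)
LONE_FEMALE = FlightToneProfile(baseline_hz=479.8, wander_sd_hz=9.7)

#: Between-individual SD and observed range of mean fundamentals, lone cohorts.
MALE_INTER_SD_HZ = 90.5
FEMALE_INTER_SD_HZ = 31.3
MALE_BASELINE_RANGE_HZ = (492.1, 880.2)
FEMALE_BASELINE_RANGE_HZ = (415.9, 527.0)


@dataclass(frozen=True)
class ScriptedEvent:
    """One ground-truth convergence episode at integer ratio p:q (p >= q)."""

    p: int
    q: int
    onset_s: float
    duration_s: float
    ramp_tau_s: float = 0.015
    jitter_frac: float = 0.003

    def __post_init__(self) -> None:
        if not (int(self.p) == self.p and int(self.q) == self.q):
            raise ValueError("p and q must be integers")
        if not self.p >= self.q >= 1:
            raise ValueError("require p >= q >= 1")
        if self.onset_s < 0 or self.duration_s <= 0:
            raise ValueError("onset_s must be >= 0 and duration_s > 0")
        if self.ramp_tau_s <= 0:
            raise ValueError("ramp_tau_s must be positive")
        if not 0 <= self.jitter_frac < 0.01:
            raise ValueError("jitter_frac must be below the 1% detection tolerance")

    @property
    def label(self) -> str:
        return f"{self.p}:{self.q}"

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s

    @property
    def ratio(self) -> float:
        return self.p / self.q


@dataclass(frozen=True)
class ConvergenceScript:
    """Ground-truth list of non-overlapping convergence episodes."""

    events: tuple[ScriptedEvent, ...] = ()

    def __post_init__(self) -> None:
        ordered = sorted(self.events, key=lambda e: e.onset_s)
        for prev, nxt in zip(ordered, ordered[1:]):
            if nxt.onset_s < prev.end_s:
                raise ValueError(
                    f"scripted events overlap: {prev.label}@{prev.onset_s}s and "
                    f"{nxt.label}@{nxt.onset_s}s"
                )
        object.__setattr__(self, "events", tuple(ordered))


@dataclass
class SyntheticPair:
    """A simulated pair of frequency traces with its ground-truth script."""

    trace_a: FrequencyTrace
    trace_b: FrequencyTrace
    truth: ConvergenceScript
    seed: int | None = None


def _gap_mask(profile: FlightToneProfile, n: int) -> np.ndarray:
    """Validity mask with scripted flight-cessation gaps set False.

    Gap boundaries are snapped to the sample grid so that the invalid fraction
    equals total gap time / duration exactly.
    """
    valid = np.ones(n, dtype=bool)
    rate = profile.control_rate_hz
    for start, dur in profile.gaps:
        i0 = int(round(start * rate))
        i1 = i0 + int(round(dur * rate))
        valid[i0:i1] = False
    return valid


def _band_limited_innovations(
    sd_innov: float, n: int, rng: np.random.Generator, rate: float, bandwidth_hz: float
) -> np.ndarray:
    """White innovations low-passed to the physical modulation bandwidth.

    Wing-beat frequency cannot change appreciably within a few wing strokes,
    so the wander's driving noise is band-limited; the low-pass commutes with
    the AR recursion, leaving the steering logic unaffected.
    """
    e = rng.normal(0.0, sd_innov, size=n)
    if bandwidth_hz and bandwidth_hz < rate / 2:
        from scipy.signal import butter, sosfilt

        sos = butter(2, bandwidth_hz, btype="low", fs=rate, output="sos")
        e = sosfilt(sos, e)
    return e


def _ou_path(
    baseline: float,
    sd: float,
    phi: float,
    n: int,
    rng: np.random.Generator,
    rate: float,
    bandwidth_hz: float,
) -> np.ndarray:
    """Stationary AR(1) (discretized Ornstein-Uhlenbeck) path of length n."""
    if sd == 0:
        return np.full(n, baseline)
    innov_sd = sd * math.sqrt(1.0 - phi * phi)
    start = rng.normal(0.0, sd)  # stationary start
    e = _band_limited_innovations(innov_sd, n, rng, rate, bandwidth_hz)
    e[0] += start
    dev = lfilter([1.0], [1.0, -phi], e)
    return baseline + dev


def simulate_trace(profile: FlightToneProfile, seed=None) -> FrequencyTrace:
    """Simulate one lone-flight fundamental-frequency trace.

    The trace is sampled at ``profile.control_rate_hz``; samples inside
    flight-cessation gaps are flagged invalid (frequency values are still
    generated there so the process is continuous across gaps).  The same
    ``(profile, seed)`` yields a bit-identical trace.
    """
    rng = np.random.default_rng(seed)
    n = int(round(profile.duration_s * profile.control_rate_hz))
    if n < 1:
        raise ValueError("duration_s times control_rate_hz must be >= 1 sample")
    phi = math.exp(-profile.reversion_rate / profile.control_rate_hz)
    omega = _ou_path(
        profile.baseline_hz,
        profile.wander_sd_hz,
        phi,
        n,
        rng,
        profile.control_rate_hz,
        profile.modulation_bandwidth_hz,
    )
    return FrequencyTrace(omega, _gap_mask(profile, n), profile.control_rate_hz)


def _check_achievable(
    profile_a: FlightToneProfile, profile_b: FlightToneProfile, script: ConvergenceScript
) -> bool:
    """Validate scripted targets; returns True when trace A is the higher voice."""
    a_higher = profile_a.baseline_hz >= profile_b.baseline_hz
    for ev in script.events:
        factor = ev.q / ev.p if a_higher else ev.p / ev.q
        target = profile_a.baseline_hz * factor
        if abs(target - profile_b.baseline_hz) > 0.30 * profile_b.baseline_hz:
            raise ValueError(
                f"scripted ratio {ev.label} is not achievable: steering target "
                f"{target:.1f} Hz is more than 30% away from the partner "
                f"baseline {profile_b.baseline_hz:.1f} Hz"
            )
        if ev.end_s > min(profile_a.duration_s, profile_b.duration_s):
            raise ValueError(f"scripted event {ev.label} extends past the recording")
    return a_higher


def simulate_pair(
    profile_a: FlightToneProfile,
    profile_b: FlightToneProfile,
    script: ConvergenceScript,
    seed=None,
    steer: str = "b",
) -> SyntheticPair:
    """Simulate a pair of traces with scripted convergence episodes.

    Outside scripted events the two traces evolve as independent OU wanders.
    Inside an event the steered partner (``steer='b'`` by default) tracks the
    frequency that puts the pair ratio at p:q, approaching exponentially with
    time constant ``ramp_tau_s``; once the ramp has settled (3 time constants)
    the residual ratio error is held strictly inside ``jitter_frac``.
    """
    if steer not in ("a", "b"):
        raise ValueError("steer must be 'a' or 'b'")
    if steer == "a":
        swapped = simulate_pair(profile_b, profile_a, script, seed=seed, steer="b")
        return SyntheticPair(swapped.trace_b, swapped.trace_a, script, seed)
    if profile_a.control_rate_hz != profile_b.control_rate_hz:
        raise ValueError("profiles must share a control rate")

    a_higher = _check_achievable(profile_a, profile_b, script)
    ss = np.random.SeedSequence(seed)
    rng_a, rng_b, rng_j = (np.random.default_rng(s) for s in ss.spawn(3))

    trace_a = FrequencyTrace(
        _ou_path(
            profile_a.baseline_hz,
            profile_a.wander_sd_hz,
            math.exp(-profile_a.reversion_rate / profile_a.control_rate_hz),
            int(round(profile_a.duration_s * profile_a.control_rate_hz)),
            rng_a,
            profile_a.control_rate_hz,
            profile_a.modulation_bandwidth_hz,
        ),
        _gap_mask(profile_a, int(round(profile_a.duration_s * profile_a.control_rate_hz))),
        profile_a.control_rate_hz,
    )

    rate = profile_b.control_rate_hz
    dt = 1.0 / rate
    n = int(round(profile_b.duration_s * rate))
    n = min(n, len(trace_a))
    phi = math.exp(-profile_b.reversion_rate * dt)
    sd = profile_b.wander_sd_hz
    innov_sd = sd * math.sqrt(1.0 - phi * phi)
    e = (
        _band_limited_innovations(
            innov_sd, n, rng_b, rate, profile_b.modulation_bandwidth_hz
        )
        if sd > 0
        else np.zeros(n)
    )

    omega_b = np.empty(n)
    baseline = profile_b.baseline_hz
    # segment boundaries: alternate free / steered
    bounds: list[tuple[int, int, ScriptedEvent | None]] = []
    cursor = 0
    for ev in script.events:
        i0 = min(int(round(ev.onset_s * rate)), n)
        i1 = min(int(round(ev.end_s * rate)), n)
        if i0 > cursor:
            bounds.append((cursor, i0, None))
        if i1 > i0:
            bounds.append((i0, i1, ev))
        cursor = max(cursor, i1)
    if cursor < n:
        bounds.append((cursor, n, None))

    dev_prev = rng_b.normal(0.0, sd) if sd > 0 else 0.0
    b_prev = baseline + dev_prev
    phi_j = math.exp(-dt / 0.2)  # jitter correlation time 0.2 s
    for i0, i1, ev in bounds:
        m = i1 - i0
        if ev is None:
            dev = lfilter([1.0], [1.0, -phi], e[i0:i1], zi=[phi * (b_prev - baseline)])[0]
            omega_b[i0:i1] = baseline + dev
        else:
            factor = ev.q / ev.p if a_higher else ev.p / ev.q
            target = trace_a.omega_hz[i0:i1] * factor
            cap = 0.95 * ev.jitter_frac
            if ev.jitter_frac > 0:
                je = rng_j.normal(0.0, ev.jitter_frac / 3.0 * math.sqrt(1 - phi_j**2), size=m)
                eps = np.clip(lfilter([1.0], [1.0, -phi_j], je), -cap, cap)
            else:
                eps = np.zeros(m)
            base = target * (1.0 + eps)
            d0 = b_prev - base[0]
            decay = d0 * np.exp(-np.arange(m) * dt / ev.ramp_tau_s)
            seg = base + decay
            settled = np.arange(m) * dt >= 3.0 * ev.ramp_tau_s
            seg[settled] = np.clip(
                seg[settled], target[settled] * (1 - cap), target[settled] * (1 + cap)
            )
            omega_b[i0:i1] = seg
        b_prev = omega_b[i1 - 1] if m else b_prev

    trace_b = FrequencyTrace(omega_b, _gap_mask(profile_b, n), rate)
    return SyntheticPair(trace_a.truncated(n), trace_b, script, seed)


def render_waveform(
    trace: FrequencyTrace,
    harmonic_amplitudes=DEFAULT_HARMONIC_AMPLITUDES,
    noise_sd: float = 0.0,
    seed=None,
    sample_rate_hz: float | None = None,
    channel_info: ChannelInfo | None = None,
) -> AudioRecording:
    """Render a frequency trace as a harmonic-stack audio waveform.

    The waveform is ``sum_k a_k cos(k * phi(t))`` where ``phi`` is the running
    integral of ``2*pi*omega(t)`` — overtones are exact integer multiples of
    the fundamental.  Amplitude is zeroed inside flight-cessation gaps;
    additive Gaussian microphone noise covers the whole record.
    """
    amps = np.asarray(harmonic_amplitudes, dtype=float)
    if amps.size < 1:
        raise ValueError("at least one harmonic amplitude is required")
    fs = float(sample_rate_hz) if sample_rate_hz else max(40_000.0, trace.sample_rate_hz)
    if fs < trace.sample_rate_hz:
        raise ValueError("audio rate must not be below the trace rate")

    if fs == trace.sample_rate_hz:
        omega = trace.omega_hz.astype(float)
        gate = trace.valid_mask.astype(float)
    else:
        n_audio = int(round(trace.duration_s * fs))
        t_audio = np.arange(n_audio) / fs
        omega = np.interp(t_audio, trace.times_s, trace.omega_hz)
        gate = (
            np.interp(t_audio, trace.times_s, trace.valid_mask.astype(float)) >= 1.0 - 1e-9
        ).astype(float)

    k_max = amps.size
    if k_max * np.max(omega) >= fs / 2:
        raise ValueError(
            f"highest harmonic ({k_max} x {np.max(omega):.0f} Hz) exceeds Nyquist ({fs / 2:.0f} Hz)"
        )

    phase = 2.0 * np.pi * cumulative_trapezoid(omega, dx=1.0 / fs, initial=0.0)
    wave = np.zeros_like(phase)
    for k, a_k in enumerate(amps, start=1):
        if a_k != 0:
            wave += a_k * np.cos(k * phase)
    wave *= gate
    if noise_sd > 0:
        wave = wave + np.random.default_rng(seed).normal(0.0, noise_sd, size=wave.size)
    info = channel_info or ChannelInfo()
    return AudioRecording(wave, fs, channels=(info,))


def sample_cohort_profiles(
    n: int,
    baseline_hz: float,
    inter_sd_hz: float,
    wander_sd_hz: float,
    seed=None,
    duration_s: float = 60.0,
    baseline_range_hz: tuple[float, float] | None = None,
    **profile_kwargs,
) -> list[FlightToneProfile]:
    """Draw ``n`` individuals' profiles from a population.

    Baselines are normal with mean ``baseline_hz`` and SD ``inter_sd_hz``
    (the between-individual spread), optionally clipped to the observed
    population range; every individual shares the within-recording wander SD.
    """
    rng = np.random.default_rng(seed)
    baselines = rng.normal(baseline_hz, inter_sd_hz, size=n)
    if baseline_range_hz is not None:
        baselines = np.clip(baselines, *baseline_range_hz)
    return [
        FlightToneProfile(
            baseline_hz=float(b),
            wander_sd_hz=wander_sd_hz,
            duration_s=duration_s,
            **profile_kwargs,
        )
        for b in baselines
    ]
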