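"""Core in-memory containers shared across the analysis pipeline.

Two objects travel through every stage: the raw two-channel audio of a
tethered-flight recording (:class:`AudioRecording`) and the instantaneous
fundamental wing-beat frequency trace extracted from one channel
(:class:`FrequencyTrace`).  A trace carries a validity mask so that
flight-cessation gaps and filter edge zones are excluded from every
downstream statistic without altering the time base.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ChannelInfo", "AudioRecording", "FrequencyTrace"]


@dataclass(frozen=True)
class ChannelInfo:
    """Metadata for one audio channel (one mosquito)."""

    subject_id: str = ""
    sex: str = ""  # "male" | "female" | ""
    treatment: str = ""  # e.g. "live-pair", "playback", "lone"


@dataclass
class AudioRecording:
    """PCM audio, one mosquito per channel.

    ``samples`` is float, shape ``(n,)`` for mono or ``(n, n_channels)``;
    amplitudes are nominally in [-1, 1] but unscaled data is accepted.
    """

    samples: np.ndarray
    sample_rate_hz: float
    channels: tuple[ChannelInfo, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples[:, None]
        if self.samples.ndim != 2 or self.samples.shape[0] == 0:
            raise ValueError("samples must be a non-empty 1-D or 2-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if not self.channels:
            self.channels = tuple(ChannelInfo() for _ in range(self.n_channels))
        if len(self.channels) != self.n_channels:
            raise ValueError("channel metadata count must match channel count")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def channel(self, index: int) -> np.ndarray:
        return self.samples[:, index]


@dataclass
class FrequencyTrace:
    """Instantaneous fundamental wing-beat frequency ω_i(t) with validity mask.

    ``omega_hz[t]`` is meaningful only where ``valid_mask[t]`` is True;
    masked samples (flight gaps, filter edges) are retained to preserve the
    uniform time grid.
    """

    omega_hz: np.ndarray
    valid_mask: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        self.omega_hz = np.asarray(self.omega_hz, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.omega_hz.ndim != 1 or self.valid_mask.shape != self.omega_hz.shape:
            raise ValueError("omega_hz and valid_mask must be 1-D and equal length")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        valid = self.omega_hz[self.valid_mask]
        if valid.size and (not np.all(np.isfinite(valid)) or np.any(valid <= 0)):
            raise ValueError("omega_hz must be positive and finite at valid samples")

    def __len__(self) -> int:
        return self.omega_hz.size

    @property
    def duration_s(self) -> float:
        return len(self) / self.sample_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self)) / self.sample_rate_hz

    @property
    def valid_values(self) -> np.ndarray:
        return self.omega_hz[self.valid_mask]

    def truncated(self, n_samples: int) -> "FrequencyTrace":
        """First ``n_samples`` samples as a new trace."""
        n = min(n_samples, len(self))
        return replace(
            self, omega_hz=self.omega_hz[:n].copy(), valid_mask=self.valid_mask[:n].copy()
        )
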