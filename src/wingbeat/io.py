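"""File formats, pipeline configuration and the end-to-end batch pipeline.

Standard formats only: PCM WAV for audio (via :mod:`scipy.io.wavfile`),
UTF-8 CSV with a header row for all series and event tables, JSON/YAML for
configuration and summaries.  All times are seconds from recording start,
all frequencies Hz, and event intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from . import __version__
from .detect import (
    ConvergenceEvent,
    DetectionConfig,
    aggregate_durations,
    detect_events,
    summarize_cohort,
)
from .ifreq import (
    FEMALE_SEARCH_BAND_HZ,
    MALE_SEARCH_BAND_HZ,
    FilterSpec,
    harmonic_trace,
    track_fundamental,
)
from .overlap import cohort_flight_stats, local_cv, overlap_series, windowed_histograms
from .pairing import cohort_ratio_distribution, ratio_series, separation_series
from .signals import AudioRecording, ChannelInfo, FrequencyTrace

logger = logging.getLogger("wingbeat")

__all__ = [
    "read_wav",
    "read_pair_wav",
    "write_wav",
    "trace_to_csv",
    "trace_from_csv",
    "events_to_csv",
    "PipelineConfig",
    "RunManifest",
    "run_pipeline",
]

_FLOAT_FMT = "%.6f"

# full-scale positive PCM values; dividing by these makes write/read round-trips
# bit-exact for data that was written by write_wav
_PCM_SCALE = {np.dtype("int16"): 32767.0, np.dtype("int32"): 2147483647.0}


def read_wav(path) -> AudioRecording:
    """Read a PCM WAV file into float samples in [-1, 1]."""
    rate, data = wavfile.read(path)
    data = np.atleast_2d(data.T).T  # (n,) -> (n, 1)
    if data.dtype.kind == "f":
        samples = data.astype(float)
    elif data.dtype == np.dtype("uint8"):
        samples = (data.astype(float) - 128.0) / 127.0
    elif data.dtype in _PCM_SCALE:
        samples = data.astype(float) / _PCM_SCALE[data.dtype]
    else:
        raise ValueError(f"unsupported WAV encoding: {data.dtype} in {path}")
    return AudioRecording(samples, float(rate))


def read_pair_wav(path, subjects: tuple[ChannelInfo, ChannelInfo] | None = None):
    """Read a two-channel pair recording as two mono recordings on one time base."""
    rec = read_wav(path)
    if rec.n_channels != 2:
        raise ValueError(
            f"pair recording {path} must have exactly 2 channels, found {rec.n_channels}"
        )
    infos = subjects or (ChannelInfo(), ChannelInfo())
    return tuple(
        AudioRecording(rec.channel(i), rec.sample_rate_hz, channels=(infos[i],))
        for i in range(2)
    )


def write_wav(path, recording: AudioRecording) -> None:
    """Write a recording as 16-bit PCM WAV (amplitudes clipped to [-1, 1])."""
    peak = float(np.max(np.abs(recording.samples))) or 1.0
    scaled = recording.samples / max(peak, 1.0)
    pcm = np.clip(np.round(scaled * 32767), -32768, 32767).astype(np.int16)
    if pcm.shape[1] == 1:
        pcm = pcm[:, 0]
    wavfile.write(path, int(recording.sample_rate_hz), pcm)


def trace_to_csv(path, trace: FrequencyTrace) -> None:
    pd.DataFrame(
        {
            "time_s": trace.times_s,
            "omega_hz": trace.omega_hz,
            "valid": trace.valid_mask.astype(int),
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def trace_from_csv(path) -> FrequencyTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError(f"trace {path} too short")
    fs = 1.0 / float(np.median(np.diff(t)))
    return FrequencyTrace(
        df["omega_hz"].to_numpy(float), df["valid"].to_numpy(bool), round(fs, 6)
    )


def series_to_csv(path, times_s, values, valid, value_name: str) -> None:
    pd.DataFrame({"time_s": times_s, value_name: values, "valid": np.asarray(valid, int)}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def events_to_csv(path, events: list[ConvergenceEvent]) -> None:
    pd.DataFrame(
        [
            {
                "pair_id": ev.pair_id,
                "recording_id": ev.recording_id,
                "ratio": ev.label,
                "start_s": ev.start_s,
                "end_s": ev.end_s,
                "duration_s": ev.duration_s,
            }
            for ev in events
        ],
        columns=["pair_id", "recording_id", "ratio", "start_s", "end_s", "duration_s"],
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def _parse_ratio(label) -> tuple[int, int]:
    if isinstance(label, str):
        p, q = label.split(":")
        return int(p), int(q)
    p, q = label
    return int(p), int(q)


_SEARCH_BANDS = {"male": MALE_SEARCH_BAND_HZ, "female": FEMALE_SEARCH_BAND_HZ}


@dataclass
class RecordingSpec:
    """One input recording: either a 2-channel WAV or two trace CSVs."""

    id: str
    pair_id: str
    wav: str | None = None
    traces: tuple[str, str] | None = None
    subjects: tuple[dict, dict] = ({}, {})

    def __post_init__(self) -> None:
        if (self.wav is None) == (self.traces is None):
            raise ValueError(f"recording {self.id}: provide exactly one of wav/traces")


@dataclass
class PipelineConfig:
    """Full configuration of a cohort analysis run."""

    recordings: list[RecordingSpec]
    output_dir: str = "wingbeat_out"
    seed: int = 0
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    overlap_window_s: float = 1.0
    overlap_bin_hz: float = 1.0
    overlap_harmonics: tuple[int, int] = (2, 3)
    cv_window_s: float = 0.25
    ratio_bin_width: float = 0.005
    ratio_weighting: str = "equal-pair"

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        det = dict(raw.get("detection", {}))
        if "ratios" in det:
            det["ratios"] = tuple(_parse_ratio(r) for r in det["ratios"])
        filt = dict(raw.get("filter", {}))
        if "search_band_hz" in filt:
            filt["search_band_hz"] = tuple(filt["search_band_hz"])
        recs = [
            RecordingSpec(
                id=str(r["id"]),
                pair_id=str(r.get("pair_id", r["id"])),
                wav=r.get("wav"),
                traces=tuple(r["traces"]) if r.get("traces") else None,
                subjects=tuple(r.get("subjects", ({}, {}))),
            )
            for r in raw.get("recordings", [])
        ]
        ov = raw.get("overlap", {})
        return cls(
            recordings=recs,
            output_dir=raw.get("output_dir", "wingbeat_out"),
            seed=int(raw.get("seed", 0)),
            detection=DetectionConfig(**det),
            filter_spec=FilterSpec(**filt),
            overlap_window_s=float(ov.get("window_s", 1.0)),
            overlap_bin_hz=float(ov.get("bin_hz", 1.0)),
            overlap_harmonics=tuple(ov.get("harmonics", (2, 3))),
            cv_window_s=float(raw.get("cv_window_s", 0.25)),
            ratio_bin_width=float(raw.get("ratio_bin_width", 0.005)),
            ratio_weighting=str(raw.get("ratio_weighting", "equal-pair")),
        )

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        return cls.from_dict(raw)

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "recordings": [asdict(r) for r in self.recordings],
                "seed": self.seed,
                "detection": asdict(self.detection),
                "filter": asdict(self.filter_spec),
                "overlap": [self.overlap_window_s, self.overlap_bin_hz, list(self.overlap_harmonics)],
                "cv_window_s": self.cv_window_s,
                "ratio_bin_width": self.ratio_bin_width,
                "ratio_weighting": self.ratio_weighting,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class RunManifest:
    """Record of one pipeline run: what was processed, how, and with what outcome."""

    config_hash: str
    version: str
    statuses: dict[str, str] = field(default_factory=dict)
    warnings: dict[str, list[str]] = field(default_factory=dict)

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "config_hash": self.config_hash,
                    "version": self.version,
                    "recordings": self.statuses,
                    "warnings": self.warnings,
                },
                indent=2,
                sort_keys=True,
            )
        )


def _load_recording_traces(spec: RecordingSpec, config: PipelineConfig):
    """Two frequency traces for one recording, extracting from audio if needed."""
    if spec.traces is not None:
        return trace_from_csv(spec.traces[0]), trace_from_csv(spec.traces[1])
    infos = tuple(
        ChannelInfo(
            subject_id=str(s.get("id", f"{spec.id}-ch{i}")),
            sex=str(s.get("sex", "")),
            treatment=str(s.get("treatment", "")),
        )
        for i, s in enumerate(spec.subjects)
    )
    rec_a, rec_b = read_pair_wav(spec.wav, subjects=infos)
    traces = []
    for rec in (rec_a, rec_b):
        fspec = config.filter_spec
        band = _SEARCH_BANDS.get(rec.channels[0].sex)
        if band is not None:
            fspec = FilterSpec(
                coarse_window_s=fspec.coarse_window_s,
                coarse_hop_s=fspec.coarse_hop_s,
                relative_bandwidth=fspec.relative_bandwidth,
                search_band_hz=band,
                peak_snr_threshold=fspec.peak_snr_threshold,
                if_median_s=fspec.if_median_s,
                if_lowpass_hz=fspec.if_lowpass_hz,
            )
        traces.append(track_fundamental(rec, fspec))
    return tuple(traces)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run the full per-pair and cohort analysis described by ``config``.

    Per recording: frequency traces, ratio and separation series, convergence
    events, windowed-histogram overlap and local c_v, written as CSV.  Per
    cohort: pooled ratio distribution, flight statistics and event summary
    (JSON).  Failures on individual recordings are logged and skipped; the
    run fails only if every recording fails.
    """
    if not config.recordings:
        raise ValueError("configuration lists no recordings")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash(), version=__version__)

    all_events: list[ConvergenceEvent] = []
    ratios = []
    rec_to_pair: dict[str, str] = {}
    traces_a: dict[str, FrequencyTrace] = {}
    traces_b: dict[str, FrequencyTrace] = {}

    for spec in config.recordings:
        t0 = time.perf_counter()
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                trace_a, trace_b = _load_recording_traces(spec, config)
                rdir = out / spec.id
                rdir.mkdir(exist_ok=True)
                trace_to_csv(rdir / "trace_a.csv", trace_a)
                trace_to_csv(rdir / "trace_b.csv", trace_b)

                rs = ratio_series(trace_a, trace_b)
                series_to_csv(rdir / "ratio.csv", rs.times_s, rs.r, rs.valid_mask, "ratio")
                sep = separation_series(trace_a, trace_b)
                series_to_csv(
                    rdir / "separation.csv", rs.times_s, sep.delta_hz, sep.valid_mask, "delta_hz"
                )
                events = detect_events(
                    rs, config.detection, pair_id=spec.pair_id, recording_id=spec.id
                )
                events_to_csv(rdir / "events.csv", events)

                ka, kb = config.overlap_harmonics
                ha = windowed_histograms(
                    harmonic_trace(trace_a, ka), 1, config.overlap_window_s, config.overlap_bin_hz
                )
                hb = windowed_histograms(
                    harmonic_trace(trace_b, kb), 1, config.overlap_window_s, config.overlap_bin_hz
                )
                ov = overlap_series(ha, hb)
                pd.DataFrame(
                    {"window_start_s": ov.window_starts_s, "alpha": ov.alpha}
                ).to_csv(rdir / "overlap.csv", index=False, float_format=_FLOAT_FMT)

                for tag, tr in (("a", trace_a), ("b", trace_b)):
                    cv = local_cv(tr, config.cv_window_s)
                    series_to_csv(
                        rdir / f"cv_{tag}.csv",
                        np.arange(len(cv.cv)) / cv.sample_rate_hz,
                        np.where(cv.valid_mask, cv.cv, 0.0),
                        cv.valid_mask,
                        "cv",
                    )

                frac_masked = 1.0 - rs.valid_mask.mean()
                if frac_masked > 0.20:
                    warnings.warn(f"{frac_masked:.0%} of ratio samples are masked")

            manifest.statuses[spec.id] = "ok"
            msgs = [str(w.message) for w in caught]
            if msgs:
                manifest.warnings[spec.id] = msgs
            all_events.extend(events)
            ratios.append(rs)
            rec_to_pair[spec.id] = spec.pair_id
            traces_a[spec.id] = trace_a
            traces_b[spec.id] = trace_b
            logger.info("%s processed in %.2fs", spec.id, time.perf_counter() - t0)
        except Exception as exc:  # per-recording failures are isolated
            manifest.statuses[spec.id] = f"failed: {exc}"
            logger.error("%s failed: %s", spec.id, exc)

    if not ratios:
        manifest.write(out / "manifest.json")
        raise RuntimeError("all recordings failed; see manifest for details")

    dist = cohort_ratio_distribution(
        ratios, bin_width=config.ratio_bin_width, weighting=config.ratio_weighting
    )
    pd.DataFrame(
        {
            "bin_left": dist.bin_edges[:-1],
            "bin_right": dist.bin_edges[1:],
            "density": dist.density,
        }
    ).to_csv(out / "ratio_distribution.csv", index=False, float_format=_FLOAT_FMT)

    summary = summarize_cohort(all_events, rec_to_pair)
    durations = aggregate_durations(all_events, recording_ids=list(rec_to_pair))
    flight = {
        tag: asdict(cohort_flight_stats(traces))
        for tag, traces in (("channel_a", traces_a), ("channel_b", traces_b))
    }
    (out / "cohort_summary.json").write_text(
        json.dumps(
            {
                "events": summary.as_row(),
                "flight_stats": flight,
                "gamma_by_recording": durations.gamma_by_recording,
                "event_duration_mean_s": durations.event_mean_s,
                "event_duration_sem_s": durations.event_sem_s,
            },
            indent=2,
            sort_keys=True,
        )
    )
    events_to_csv(out / "events.csv", all_events)
    manifest.write(out / "manifest.json")
    return manifest
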