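# Methods

This note documents the models and procedures implemented in `wingbeat`, the
parameter choices that matter, and what the synthetic-data validation does and
does not establish.

## Instantaneous-frequency extraction (`wingbeat.ifreq`)

The fundamental wing-beat frequency is a narrow-band, frequency-modulated
component, typically 350–600 Hz for female and 550–900 Hz for male
*Aedes aegypti*; overtones are integer multiples of it. Extraction proceeds in
two passes:

1. **Coarse ridge.** A short-time Fourier transform (Hann window, 0.25 s,
   hop 0.05 s) tracks the strongest spectral peak inside the configured search
   band, with parabolic log-power interpolation for sub-bin accuracy. Frames
   whose peak is less than `peak_snr_threshold` (default 30) times the median
   in-band power are treated as untracked; if no frame is tracked the recording
   has no flight tone and an error is raised.
2. **Complex demodulation.** The signal is multiplied by
   `exp(-i * ∫ 2π c(t) dt)` where c(t) is the interpolated ridge, then
   low-passed (zero-phase Butterworth, cutoff = `relative_bandwidth` × median
   ridge frequency, default 0.15). This simultaneously realizes a band-pass
   centred on the moving fundamental and the analytic-signal transform. The
   instantaneous frequency is c(t) plus the scaled derivative of the unwrapped
   baseband phase, so the output has the time resolution of the audio.

The raw phase derivative is noise-dominated and is smoothed with a 5-ms median
filter followed by a 50-Hz zero-phase low-pass — far above any plausible
wing-beat modulation bandwidth, far below the fundamental. Half a coarse
window at each record edge and around each detected flight gap is marked
invalid (filter transients), as are samples whose extracted frequency is
implausible for the search band.

Flight-cessation gaps are detected from a 5-ms moving-RMS envelope: samples
below `envelope_threshold_fraction` (default 0.1) of the median envelope for at
least `min_gap_s` (default 50 ms) form a gap. Enlarging the threshold can only
enlarge the gap mask.

## Ratio analysis and the randomization null (`wingbeat.pairing`)

The instantaneous ratio is computed **per sample** with the lower frequency as
the denominator, r(t) = max(ω_a, ω_b)/min(ω_a, ω_b) ≥ 1. The per-sample
convention (rather than per-recording orientation) keeps 1:1 convergence
representable when traces cross, as they do in male–male pairs; for
non-crossing opposite-sex traces the two conventions coincide.

Cohort ratio distributions weight each pair equally by default (per-pair
histogram normalization before pooling) so that long recordings do not
dominate; sample-pooled weighting is available (`weighting="pooled-sample"`).
Bins are 0.005 wide starting at r = 1.

The non-interacting null pairs recordings of lone individuals ("artificial
pairs"), drawn uniformly **without replacement** from the full cross product
and truncated to common duration. Any apparent convergence in such pairs is
chance, since neither individual could hear the other.

## Event detection (`wingbeat.detect`)

The ratio series is reduced by piecewise aggregate approximation: frames of
w seconds are replaced by the mean of their valid samples. Frames with fewer
than 50 % valid samples are invalid and **break** runs (a flight gap must not
silently bridge an event); the trailing partial frame is kept and averaged
over the samples it has (dropping it would discard up to w of signal).

Per target ratio p:q, frames whose reduced ratio lies in
[(p/q)(1−δ), (p/q)(1+δ)] are convergent. Maximal convergent runs separated by
gaps ≤ Δτ are merged first, and merged runs shorter than τ are then discarded
(merge-then-threshold; a discard variant is available via
`gap_mode="discard"`). Defaults are w = 0.5 s, δ = 0.01, τ = 1 s, Δτ = 1 s.
Event boundaries are reported at frame resolution as half-open [start, end)
intervals; full-resolution ratio samples within an event remain available via
`event_samples` for downstream metrics.

Tolerance bands must be pairwise disjoint: each event carries exactly one
label, and a configuration whose bands overlap at the chosen δ is rejected up
front rather than tie-broken. The default opposite-sex ratio set is
{1:1, 5:4, 4:3, 3:2, 5:3, 2:1} (male–male analysis uses {1:1}); the fairly
prominent 7:6 ratio is excluded by default because harmonics that high carry
little acoustic energy and lie at the edge of the animals' hearing range, but
it can be added through the configuration.

Cohort summaries report recording- and unique-pair-level occupancy counts and
rates. Proportions are rendered as whole percents; rates to one decimal place,
or two significant figures above 10 (so 96 events over 7 pairs prints as 14).
Per-recording aggregated convergence duration γ is the sum of event durations;
recordings without convergence are excluded from the γ population (they carry
γ = 0, not a small positive value).

## Overlap and variability (`wingbeat.overlap`)

The waterfall overlap uses non-overlapping 1-s windows at 1-Hz frequency
resolution. Each window's histogram of the selected harmonic trace is
normalized to unit mass on a **shared integer-aligned bin grid** (edges at
multiples of the bin width starting from 0, so grids from different traces
coincide). The overlap is the histogram intersection
α = Σ_i min(a_i, b_i) ∈ [0, 1]: 1 for identical distributions, 0 for disjoint
ones, symmetric in its arguments. On simulated convergence episodes with a
slow approach, α rises from ~0.2 toward ~0.85 — sustained convergence is
imperfect even by construction, because residual jitter keeps the two
distributions from coinciding exactly.

The local coefficient of variation c_v(t) = σ(t)/μ(t) uses a centred
rectangular window of 0.25 s (forced to an odd number of samples so the centre
is well defined), sample (n−1) standard deviation, and is masked wherever the
window touches an invalid sample or a record edge. It is scale-free:
c_v(kω) = c_v(ω).

Cohort flight statistics: the recording mean is the mean over valid samples;
μ is the mean of recording means with its (min, max) range; σ_intra is the
mean within-recording SD; σ_inter the SD of recording means (undefined for a
single recording); IQR_intra the mean within-recording inter-quartile range.
σ_inter is deliberately computed over recording means, not pooled samples,
since it measures between-individual dispersion.

## The synthetic flight-tone generator (`wingbeat.synth`)

The generator provides ground truth for validating the detector and the null
analysis. Its defaults emulate tethered *A. aegypti* lone-flight statistics:

| parameter | default | meaning |
|---|---|---|
| baseline_hz | 691.2 (♂) / 479.8 (♀) | cohort mean fundamental |
| wander_sd_hz | 11.1 (♂) / 9.7 (♀) | within-recording SD |
| reversion_rate | 10 /s | OU mean reversion (0.1-s correlation time) |
| modulation_bandwidth_hz | 50 | band limit of the wander |
| duration_s | 60 | protocol recording length |
| sample_rate_hz | 40 000 | audio rate for rendering |
| control_rate_hz | 1 000 | frequency-trace rate |

Within-recording wander is a discrete-time Ornstein–Uhlenbeck process, which
yields the approximately normal lone-flight frequency distribution observed in
this system. The driving noise is low-passed at 50 Hz: wing inertia bounds how
fast the beat frequency can change, and an unfiltered AR(1) at 1 kHz would
carry ~1.5 Hz RMS of physically meaningless power spread to 500 Hz that no
band-limited extractor could recover. The 0.1-s correlation time encodes
modulations rapid relative to STFT windows, which is why instantaneous
frequency (rather than a spectrogram ridge alone) is needed downstream.
Between-individual spread is modelled by drawing baselines from a normal
population (♂ SD 90.5 Hz, ♀ 31.3 Hz, clipped to the observed ranges) via
`sample_cohort_profiles`.

Scripted convergence episodes steer one partner (configurable) onto the
frequency that puts the pair ratio at p:q, with exponential approach
(ramp_tau_s, default 15 ms) and a residual multiplicative jitter held strictly
inside `jitter_frac` (default 0.3 %) once the ramp has settled. The ramp is
deliberately short relative to the PAA frame: ground-truth event boundaries
are only meaningful at frame resolution if band entry occupies a small
fraction of one frame (the first in-event frame's mean is displaced by roughly
D·ramp_tau/w, where D is the initial ratio offset — up to ~28 % for a 2:1
event — and this must stay below δ = 1 %). Residual jitter is a free choice:
no within-event residual statistics are published for live pairs beyond the
observation that convergence is imperfect.

Scripts should leave comfortably more than Δτ + w between consecutive events:
the steering ramp between two episodes sweeps the ratio through intermediate
values, and a frame whose mean transits another target's band can otherwise be
merged into the preceding event.

Rendering sums cosines of k× the running phase integral of ω(t) with
amplitudes decaying as 1/k for k = 1..5 (overtone amplitudes are known to be
successively weaker; exact values are not published), gates amplitude to zero
inside flight gaps, and adds white microphone noise.

## What the synthetic validation does and does not show

The simulator reproduces the first- and second-order statistics of lone flight
(means, within/between dispersion, approximate normality), harmonic structure,
gaps and scripted ratio locking. It does **not** model amplitude modulation,
frequency "hunting" dynamics, bidirectional feedback during convergence (one
partner is steered, the other wanders freely), room acoustics, or non-OU
features of real wander (drift, bouts). Passing the validation suite therefore
establishes that the pipeline detects ratio locking correctly under realistic
noise and dispersion — not that live mosquitoes behave like the generator.

In particular, the null-contrast check uses lone cohorts at the cohort-mean
baselines. With the full between-individual spread, roughly one in six random
male/female pairs has a *baseline* ratio that happens to sit within ±1 % of
some small-integer ratio; such pairs are "converged" by construction for much
of a recording, which is a property of the population geometry, not detector
leakage. Distinguishing chance baseline coincidence from active convergence in
real cohorts is exactly what the ratio-distribution comparison against
artificial pairs is for.

## Numerical choices and degenerate inputs

- All times are seconds from record start, all frequencies Hz; event intervals
  are half-open [start, end).
- Ratio/PAA/cv computations ignore invalid samples rather than interpolating
  across them.
- A PAA window longer than the series yields a single frame with a warning; an
  all-silent recording yields a whole-record gap with a warning; a cohort with
  no valid samples is an error.
- Detection problem sizes in the validation suite (20 pairs × 60 s at the
  1-kHz control rate for event recovery; 50 artificial pairs for the null) are
  chosen to give stable Monte-Carlo estimates while keeping the whole suite
  fast to run routinely.
- Determinism: every stochastic component takes an explicit seed;
  `run_pipeline` output is byte-identical under a fixed config and seed.

## Known limitations

- Single-channel recordings of multiple animals are out of scope: the tracker
  assumes one fundamental per channel.
- The extractor's edge masking discards half a coarse window (0.125 s) at each
  record/gap boundary; very short flight bouts (< ~0.5 s) are effectively
  unusable.
- `DetectionConfig` rejects overlapping tolerance bands rather than resolving
  ties, so δ larger than ~3 % is incompatible with the default ratio set.
- The published whole-percent/one-decimal table formatting is reproduced by
  `CohortEventSummary.as_row`; raw fractions are available on the dataclass
  for anyone doing further arithmetic.
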