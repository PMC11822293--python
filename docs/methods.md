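# Methods

This note documents the models, parameter choices and numerical decisions
behind `meghfo`, and what the synthetic validation does and does not show.

## Signal model and simulator

Each channel's background is spectrally shaped Gaussian noise with power
spectral density ∝ 1/f^α (α = 1 by default), normalized to unit SD, plus
power-line harmonics: sinusoids at k·60 Hz (k = 1…8 by default, peak
amplitude 0.5 in background-SD units, random phase per channel and
harmonic). This is the simplest background reproducing the two noise
features that matter to the detector — the steep 1/f rolloff across the
80–500 Hz band and strong narrowband power at multiples of 60 Hz. No
physiological rhythms, sensor correlations, heartbeat or eye artifacts are
modelled; broadband transients (50-ms white-noise bursts hitting ~80% of
channels at 8× channel SD) stand in for generic movement/electronic
artifacts.

HFO events are Hann-tapered sinusoids of `n_cycles` cycles at a peak
frequency, with peak amplitude `amplitude_sd_units` × the SD of the
channel's 80-Hz-high-passed **background** in the 400 ms around the event.
Calibrating amplitude in these units makes the two filter operating points
directly probeable: the detector's threshold behaviour and the ratio-3
amplitude filter both act on exactly this quantity. The amplitude the
literature reports for real MEG HFOs is only qualitative ("low
signal-to-noise"); the simulator's default of 6 SD units was chosen once as
the regime where events are clearly present in the time-frequency map yet
far from saturating single-trial visibility, and the sensitivity claims
below are stated at that operating point. Cohort generation draws
per-region event counts as Poisson with mean `rate × duration / 600 s`,
places events uniformly in time (1-s guard bands; same-channel overlaps are
re-drawn, never summed, so ground truth stays unambiguous) and uniformly in
frequency within the class band.

EDF export uses plain EDF (not EDF+): one data record per second, all
channels at one rate, int16 samples with a symmetric per-channel physical
range written so that its 8-character ASCII header field parses back
exactly; a write/read round trip is then accurate to one quantization step.
Physical units are labelled "fT" but values are model units.

## Detector

The time-frequency transform is a constant-Q complex Morlet bank on a
log-spaced grid: `voices_per_octave` = 12 bins per octave, 3 octaves from
80 Hz (36 bins; the grid tops out at ~604 Hz, and bins above 500 Hz provide
spectral context but can neither seed events nor suppress in-band maxima).
The `tf_resolution` balance parameter (default 20) maps onto the wavelet's
cycle count as `n_cycles = tf_resolution / 2` = 10, constant across
frequency; larger values narrow each band (better frequency precision,
worse time precision). Segments are tapered with a Tukey window whose ramps
span 1 s per edge before transforming; kernels are truncated at ±5σ and
convolved via FFT.

Normalization is per frequency band: samples outside Tukey's fences
[Q1 − 1.5·IQR, Q3 + 1.5·IQR] are excluded, a normal distribution is fitted
to the rest, and the whole band is z-scored by the fitted parameters. The
trimmed SD is divided by 0.97106 — the SD of a standard normal truncated at
the ±2.698σ fences — so an already-standardized Gaussian band is a fixed
point. Because a steady sinusoid inflates its own band's fitted mean and
SD, power-line harmonics are absorbed by the normalization itself and no
notch filter is needed (one consequence: frequency estimates for events
peaking near a harmonic, e.g. 240 Hz, are deflected away from it). A band
with zero IQR or zero trimmed variance (e.g. an all-zero signal) is an
error naming the offending frequency.

Event seeds are cells whose score strictly exceeds all of their (up to)
eight time-frequency neighbours — plateaus produce no maximum — and reaches
the threshold score of 20. Event support along time (at the seed's band)
and frequency (at the seed's time) is the contiguous span scoring at least
half the seed's own score, floored at half the threshold: a half-maximum
width. A fixed absolute support level was rejected because support width
then grows with event SNR, making strong events fail the frequency-spread
cap. Events are discarded if their duration is under 1.4 cycles at the peak
frequency, their spread exceeds 10 frequency divisions, their support
touches the segment edge, or the surrounding 1-s window is abnormal: after
removing the event's own supra-threshold connected component
(8-connectivity), more than 0.5% (`unusual_pattern_threshold` = 0.005) of
the remaining cells exceed the threshold. The veto deliberately excludes
the event's own component — a compact genuine event's footprint alone can
exceed 0.5% of the window — so it measures the *context*, not the event.
Classification is by peak-frequency bin alone with half-open bands:
[80, 250) Hz ripple, [250, 500] Hz fast ripple.

Calibration on the default synthetic background (measured by the test
suite): false positives ≤ 1 event/min/channel at threshold 20 (in practice
≪ 1), sensitivity ≥ 90% with 100% correct band labels for 4–6-cycle bursts
at 6 SD units with peaks ≥ 20 Hz from the 250-Hz boundary. Peak-frequency
estimates carry the log-grid quantization (±3%) plus a small upward bias
for short bursts whose bandwidth exceeds a bin; both shrink with longer
bursts or more voices per octave.

## Artifact filters

The density filter clusters candidates of *all* channels by peak time with
single-linkage chaining: a gap above 400 ms starts a new cluster. Clusters
of ≤ 5 pass intact; larger clusters collapse to their single highest-power
candidate (ties: earlier peak, then lexicographic channel label). Whether
the historical procedure slid or tumbled its window, and whether small
clusters were also collapsed, is not documented; both alternatives are
available (`clustering="tumbling"`, `overfull_policy="top_n"`). Chaining
guarantees the output never holds more than 5 events in any 400-ms sliding
window. The amplitude-ratio filter high-passes the recording at 80 Hz,
takes per-channel SDs over consecutive (non-overlapping) 400-ms windows,
and drops candidates whose maximum absolute high-passed amplitude within
the event span is below 3× the SD of the window containing the peak. Note
the window SD includes the event itself, so the measured ratio
under-reports the injected amplitude for strong events.

## Preprocessing

Recordings above 1200 Hz are decimated by polyphase resampling (anti-alias
FIR at 0.45× the target rate); upsampling is refused. The 80-Hz high-pass
is a linear-phase Hamming FIR applied with group-delay compensation
(zero-phase); its transition band is cutoff/40 (2 Hz), which keeps repeated
application idempotent to < 1% RMS even for 1/f inputs whose transition
band carries real energy. Segment screening drops segments whose raw
candidate count exceeds 700 per 275-channel 1-min segment — calibrated once
on a reference cohort with typical per-channel event rates (~1.2/channel
/min), where clean segments scored ~400 ± 55 raw candidates (scaled from a
25-channel run) and artifact-saturated segments several thousand; the
ceiling sits > 5 SD above the clean distribution so that the ~5% of
contaminated segments are the ones excluded.

## Statistics

The statistical unit is the channel: each subject's per-channel rate
(events/min; × 10 for per-10-min figures) is averaged across a cohort's
subjects, and the channel values of a region (19–34 channels) are compared
between cohorts. This mirrors the sensor-level design it reproduces, and
inherits its caveat — channels are not independent samples, so effective n
is inflated; a subject-level analysis is possible by passing per-subject
tables directly. Test selection is gated by the D'Agostino-Pearson
normality test at α = 0.05 per sample (a constant sample counts as
non-normal; fewer than 8 values per sample is an error): all samples normal
→ Student's t (2 groups) or one-way ANOVA with Tukey's HSD (3); otherwise
Mann-Whitney (2) or Kruskal-Wallis with Dunn's post hoc (3), all
two-tailed. Dunn's test is implemented in-house (no installed package
provides it): pooled tie-averaged ranks, the standard tie-corrected
variance, two-sided normal p-values with Bonferroni adjustment over the
pairwise family — matching common statistical-package behaviour. No
correction is applied across regions (only within Tukey/Dunn families).
Comparisons whose pooled values are constant are flagged `degenerate` with
a NaN p-value rather than fabricating a statistic.

The asymmetry index for a lobar pair uses the mean channel rate of the left
and right region; `All` averages the five regional means per hemisphere
with equal regional weight (paired regions differ slightly in channel
count — 33 vs 34 temporal channels — and equal weighting keeps a
left/right-symmetric subject at exactly AI = 0). Midline (CF) sensors never
contribute. AI is undefined (an error, not 0) when both hemispheric rates
are zero. Group-level AI inference: two-tailed one-sample t against zero
within groups, unpaired t between groups; zero-variance AI samples are an
error.

## Validation scales and what they show

The test suite and `scripts/acceptance.py` run everything on synthetic data
at desk scale, chosen to keep the full suite in minutes: detector
calibration uses 12 single-channel background minutes and 60 injected
bursts; the band-boundary sweep uses three seeds × 21 frequencies with
16-cycle bursts on a harmonic-free background and a 48-voice analysis grid
(both choices reduce frequency-estimation bias of the *measurement*; the
250-Hz decision rule itself is untouched); the end-to-end recovery study
uses 10 replicates of two 8-subject groups recorded for 15 s over the
temporal-left (33 channels) and occipital-right (19) regions, with a 2×
left-temporal ripple-rate contrast at paper-scale per-channel rates
(≈ 1–2 events/min/channel). Passing these suites shows the chain is
self-consistent and recovers known ground truth under the stated noise
model; it does not certify performance on real MEG, whose artifacts,
sensor correlations and event morphologies are richer than the simulator's.
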