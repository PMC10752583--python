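# Methods

This note documents the models, conventions and numerical choices
behind `songpref`, in the order the pipeline runs.

## Units and indexing

Times are seconds from clip or session start; sample indices are
0-based with half-open `[onset, offset)` syllable windows; coordinates
are millimetres after calibration (`mm = px × mm_per_px`). All
stochastic operations take a single integer seed and are bitwise
reproducible.

## Syllable analysis

**High-pass filtering.** Order-8 Butterworth, run forward-backward
(`sosfiltfilt`), default cutoff 40 kHz. The zero-phase double pass
gives > 90 dB attenuation one octave below the cutoff while leaving
syllable-band tones (68–84 kHz) essentially untouched; phase linearity
matters because syllable boundaries are read off the envelope.

**Syllable detection.** The recordings this pipeline targets were
originally segmented with commercial software and checked by hand, so
the detector here is a standard energy-envelope recipe with exposed
parameters rather than a reimplementation of any specific product: the
signal is high-pass filtered at the band floor, squared and smoothed
over 0.5 ms to an RMS envelope; the noise floor is the envelope
median; samples more than `threshold_db` (default 15 dB) above the
floor are active; active runs closer than `min_gap_s` (10 ms) are
merged and runs shorter than `min_duration_s` (5 ms) dropped. On
synthetic songs at 20 dB SNR this yields perfect precision/recall with
boundary errors well below 1 ms (the envelope window bounds the
attainable boundary accuracy at roughly half its width).

**Peak frequency.** Maximum-magnitude bin of a Hann spectrogram, FFT
size 512 at 250 kHz (≈ 488 Hz bins), 50% overlap; windows shrink for
syllables shorter than one frame. For frequency-modulated syllables
the reported value is quantised by both the bin width and the sweep
covered by half an analysis window.

**Inter-syllable intervals.** Onset-to-onset, included only when the
next syllable starts within 2 s. The onset-to-onset convention is the
one consistent with the super-regular construction (onsets on a grid
of the median interval); an offset-based reading of "interval" appears
in some descriptions of this assay but is not self-consistent, and is
not used. The same 2 s cutoff defines bout boundaries.

**Distribution summaries.** Duration densities use a Gaussian kernel
with a fixed absolute bandwidth (default 5 ms) on a 0–250 ms grid at
1 ms steps; all interior local maxima are reported, the antimode is
the minimum between the two tallest modes, and `fraction_short` is the
fraction of durations below it. Reported mode locations are therefore
quantised to the grid step. Quartiles use linear interpolation between
order statistics (numpy default) — the IQR depends on this convention,
so it is fixed and documented.

## Song manipulations

All six manipulations conserve total song duration exactly (integer
sample bookkeeping throughout). The unit decomposition pairs each
syllable waveform with its following silent pause (the last pause runs
to the end of the song); it assumes pauses are silent, which holds for
denoised playback stimuli and for the synthetic generator's ground
truth.

* **Randomisation** permutes the (syllable + pause) units uniformly,
  with one deliberate refinement: the final unit stays in place.
  Permuting all units cannot conserve the ISI multiset exactly,
  because whichever unit lands last contributes no ISI; anchoring the
  last unit makes "the ISI distribution is preserved" an exact
  invariant rather than an approximate one, at a negligible cost in
  shuffling freedom.
* **Reversal** flips the sample order; the full-clip magnitude
  spectrum is preserved exactly and frequency trajectories reverse.
* **Phase scrambling** randomises the phase of every interior rFFT bin
  of the whole song (DC/Nyquist kept real), then gates the resulting
  noise into the original syllable windows with flat (constant-RMS)
  envelopes and 0.5 ms linear ramps. Scrambling once per song and
  gating afterwards — rather than scrambling each syllable separately —
  is the reading that reconciles a per-song phase randomisation with
  per-syllable ramping; the choice is documented here because the
  alternative is defensible.
* **Pure-tone replacement** substitutes each syllable with a 76 kHz
  constant-amplitude tone of identical onset/offset and 0.5 ms ramps.
  For both phase-scrambled and pure-tone songs a single per-song gain
  is applied after ramping so the mean per-syllable RMS matches the
  original exactly (matching before ramping would leave a bias of
  roughly the ramp-to-syllable length ratio).
* **Irregularisation** keeps syllables in place and order and redraws
  the pauses as i.i.d. Uniform(0, 1) weights rescaled to the original
  total pause budget (largest-remainder integer rounding, so the
  budget — and hence song duration — is conserved to the sample). The
  uniform family is the simplest exactly-budget-conserving choice and
  broadens the ISI IQR from ≈ 60 ms to ≈ 85 ms on synthetic songs; the
  magnitude of broadening depends on the pause distribution, which is
  pluggable.
* **Super-regularisation** computes the per-song median within-bout
  ISI *m* (even counts: mean of the central order statistics, then
  rounded to samples) and places each within-bout onset at k·m after
  its predecessor, k the smallest positive integer with k·m strictly
  greater than the predecessor's duration — k = 1 normally, k = 2 "skip
  a cycle" for syllables longer than m, and k > 2 as the natural
  extension for extreme durations. Total duration is restored by
  adding the correction to the largest adjustable silence (inter-bout
  gaps and the terminal silence), falling back to proportional
  redistribution across all of them; if the correction cannot be
  absorbed without a negative pause, an explicit infeasibility error
  is raised.

**Trial programs.** Each session holds four trials; each trial plays
the seven-song set in an independent uniform order. The playback side
is drawn once per session and strictly alternates; the onset jitter
between the paired intact/manipulated streams is uniform on
[20, 90] ms per song with a random leading stream per trial. Playback
export at 260,420 Hz is an optional resampling step and is never
applied to analysis audio.

## Place-preference analysis

**Geometry.** The box is 227 × 252 mm. The published zone geometry is
trapezoidal in the camera view but only one dimension is stated — the
86 mm depth into each arm — so zones are modelled as axis-aligned
rectangles spanning each arm's width from the mesh wall to the
configurable depth. Boundary points count as inside; the two zones are
kept disjoint by a 5 mm half-width exclusion at the partition.

**Dwell times.** Each frame contributes the interval to the next
timestamp (the last frame contributes the median interval). This
timestamp weighting reduces to the usual count-divided-by-frame-rate
rule at constant rate and is robust to dropped frames. Gaps in
tracking hold the last valid position; leading gaps take the first
valid position.

**Preference index.** PI = (t_song − t_manip)/(t_song + t_manip),
stored as a fraction in [−1, 1] (rendered ×100 when displayed as a
percentage). A trial in which both zone times are zero has an
undefined PI: it is flagged, excluded from the session median, and a
warning is emitted. The session PI is the median of the four trial
PIs. Side bias — grounds for excluding a session — is all four trials
sharing the same sign of t_left − t_right; an exactly tied trial
breaks the streak.

**Cumulative profiles.** Per frame: +dt in the song-side zone, −dt in
the opposite zone, 0 elsewhere; the cumulative sum over each 160 s
trial is linearly interpolated onto a common 1 s grid (the resampling
grid is a package choice; nothing downstream is sensitive to it at
30 Hz frame rates). The trial-median trace is normalised by its
maximum absolute value. The unnormalised endpoint of each trial trace
equals t_song − t_manip for that trial to within one frame interval —
this cross-operation identity is asserted on every synthetic session
in the tests.

**Cohort statistics.** Normality is checked first (Lilliefors and
Shapiro–Wilk at α = 0.05) and reported; the one-sample two-tailed
t-test against zero (df = n − 1) and the 95% CI of the mean are always
computed, with a Wilcoxon signed-rank p-value added as a flagged
fallback when normality is rejected — the original analysis gates on
normality without stating its fallback, so both are exposed.
Zero-variance cohorts are handled explicitly (t = 0, p = 1 at zero
mean; p → 0 with a warning otherwise). Per-time-bin significance of
the normalised profiles uses uncorrected α = 0.05 per bin, matching
the assay's convention; the sustained-onset readout requires three
consecutive significant bins by default.

## Synthetic data

**Songs.** Durations come from a two-component log-normal mixture
(weights 0.86/0.14, σ = 0.25/0.20) whose component modes sit exactly
at 23 and 88 ms (mode = median·e^(−σ²)); the resulting antimode falls
near 60 ms and the short fraction at ≈ 0.86. ISIs are log-normal with
median 104 ms and σ chosen in closed form so the IQR is 61 ms
(IQR = 2·median·sinh(z₇₅σ)). Because an ISI must exceed its syllable's
duration plus a 20 ms minimum pause, conflicting draws are not clipped
(which would bias the median upward by several ms) but *assigned*:
the drawn ISI multiset is kept and matched to positions, largest
floors first, each taking a random still-available draw above its
floor — so the marginal ISI distribution is preserved exactly at the
cost of a mild duration–ISI dependence, which real songs share for the
same physical reason. Syllables are linear FM sweeps with random
direction and extent inside 68–84 kHz, centres ~N(76 kHz, 2 kHz), flat
envelopes with 0.5 ms ramps (the same convention as the manipulated
stimuli), amplitudes log-normal around 0.9 (σ = 0.1), over a Gaussian
noise floor (default RMS 0.003 ≈ 46 dB SNR). Trailing silence is
padded to the next fast FFT length so whole-song spectral operations
stay cheap. The generator does **not** model within-syllable harmonic
structure, frequency jumps, or realistic amplitude envelopes — passing
tests demonstrate correctness of the pipeline's bookkeeping and
statistics, not detector performance on real recordings.

**Sessions.** A semi-Markov occupancy process alternates neutral and
zone visits with exponential dwell times (zone mean 3 s — a plausible
speaker-zone visit length for an exploring mouse — and neutral mean
set by the 0.35 neutral time fraction). During a playback trial the
song-side zone is chosen with probability q = (1 + p)/2; because both
zones share the same dwell distribution, the expected trial PI equals
the injected p (given the visit counts, the dwell-time ratio is a
Beta-distributed quantity whose mean is the count ratio). Sessions
follow the study schedule: 10 min habituation, then four 160 s trials
separated by 3 min breaks, sides alternating from a random first side.
Frame positions are drawn uniformly inside the occupied region at
30 Hz and a configurable fraction of frames is dropped to exercise gap
interpolation. The generator does not model continuous locomotion —
positions jump within regions — so it validates occupancy accounting,
not tracking smoothness assumptions.

**Cohorts.** Session-level true preferences are drawn
Normal(effect_mean, effect_sd), clipped to ±0.95. Three realisation
modes trade fidelity for speed: `exact` (session PI equals the drawn
effect; isolates the cohort-statistics stage and is used for t-test
calibration at thousands of cohorts), `trials` (summary-level
occupancy process per trial), and `trajectory` (full tracked sessions
through the complete pipeline). Calibration checks in the tests use
`exact`; end-to-end recovery uses `trajectory` at 800 sessions.

## Problem sizes in the shipped checks

Songs for manipulation checks: 100 songs × 145 syllables (the median
syllable count of the recorded stimulus set). PI recovery: 200 seeded
sessions at each of p ∈ {−0.5, 0, 0.25, 0.5}. Side-bias null: 10,000
summary-level sessions. Cohort calibration: 1,000 cohorts of n = 29 in
the tests (4,000 in the acceptance script, for a tighter Monte-Carlo
error on the reported rate). Segmentation fidelity: 12 songs × 60
syllables at 20 dB SNR.

## Known limitations

* The detector is tuned for high-SNR, band-limited recordings; it has
  no noise-reduction stage beyond high-pass filtering and will not
  match hand-curated segmentation on noisy field recordings.
* Zone rectangles approximate the trapezoidal camera-view zones; PI is
  insensitive to this for trajectories that go near the mesh, and the
  depth sweep quantifies the residual sensitivity.
* The irregular-pause distribution is a convention (uniform weights);
  the published irregular stimulus set reports a larger IQR broadening
  (to ≈ 134 ms) than the uniform family produces on synthetic songs —
  the qualitative property (robust broadening) is what the pipeline
  guarantees.
* `cohort_stats` requires n ≥ 3 sessions and treats the t-test as
  primary even when normality is rejected (flagged, with the Wilcoxon
  p-value alongside).
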