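"""The six acoustic manipulations of courtship songs and trial assembly.

Each playback contrast pits an intact song against one manipulated
version.  The manipulations, all conserving total song duration to the
sample, are:

* ``randomised``  - shuffle the order of (syllable + following pause)
  units, so sequential organisation is destroyed while the ISI
  distribution is preserved exactly.
* ``reversed``    - time-flip the waveform; long-term magnitude spectrum
  is untouched, frequency trajectories run backwards.
* ``phase_scrambled`` - keep the full-song magnitude spectrum, randomise
  spectral phase, gate the resulting noise back into the original
  syllable windows with flat envelopes and 0.5 ms linear ramps.
* ``pure_tone``   - replace each syllable by a constant-amplitude tone
  (default 76 kHz, the median syllable peak frequency) of identical
  onset/offset, with 0.5 ms ramps.
* ``irregular``   - keep syllables in place and order, resample the
  silent pauses (total pause budget conserved exactly), broadening the
  ISI distribution.
* ``super_regular`` - rewrite pauses so that within each bout successive
  onsets fall on an exact grid of the song's median ISI ("skip a cycle"
  for syllables longer than the grid step); total duration is restored
  by adjusting inter-bout silences.

Phase-scrambled and pure-tone songs use a single per-song amplitude,
scaled so the mean per-syllable RMS matches the original song's.

All integer bookkeeping is done in samples so duration conservation is
exact; stochastic manipulations are deterministic given a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    EmptyInputError,
    InfeasibleAdjustmentError,
    InsufficientDataError,
    InvalidParameterError,
    InvalidSegmentationError,
)
from .syllables import AudioClip, SongSegmentation, Syllable

__all__ = [
    "SyllablePauseUnit",
    "UnitizedSong",
    "ManipulatedSong",
    "TrialProgram",
    "to_units",
    "from_units",
    "randomise_syllable_order",
    "reverse_song",
    "phase_scramble",
    "phase_scrambled_waveform",
    "pure_tone_song",
    "irregularise",
    "super_regularise",
    "build_session_programs",
    "RAMP_S",
]

#: Linear rise/fall time applied to synthetic syllable envelopes (seconds).
RAMP_S = 0.0005

MANIPULATIONS = (
    "intact",
    "randomised",
    "reversed",
    "phase_scrambled",
    "pure_tone",
    "irregular",
    "super_regular",
)


@dataclass(frozen=True)
class SyllablePauseUnit:
    """One syllable waveform plus its subsequent silent interval (samples)."""

    waveform: np.ndarray
    pause_n: int

    def __post_init__(self):
        if self.pause_n < 0:
            raise InvalidSegmentationError("pause must be non-negative")

    @property
    def duration_n(self) -> int:
        return self.waveform.size


@dataclass(frozen=True)
class UnitizedSong:
    """A song decomposed into leading silence + (syllable, pause) units."""

    lead_n: int
    units: tuple[SyllablePauseUnit, ...]
    sample_rate: int
    total_n: int


@dataclass(frozen=True)
class ManipulatedSong:
    audio: AudioClip
    seg: SongSegmentation
    manipulation: str
    rng_seed: int | None = None

    def __post_init__(self):
        if self.manipulation not in MANIPULATIONS:
            raise InvalidParameterError(f"unknown manipulation tag {self.manipulation!r}")


@dataclass(frozen=True)
class TrialProgram:
    """Playback order, jitter, and side assignment for one trial."""

    song_order: tuple[int, ...]
    jitter_s: tuple[float, ...]
    leading_stream: str  # "intact" | "manipulated"
    playback_side: str  # "left" | "right"

    def __post_init__(self):
        if self.leading_stream not in ("intact", "manipulated"):
            raise InvalidParameterError("leading_stream must be 'intact' or 'manipulated'")
        if self.playback_side not in ("left", "right"):
            raise InvalidParameterError("playback_side must be 'left' or 'right'")
        if any(not (0.020 <= j <= 0.090) for j in self.jitter_s):
            raise InvalidParameterError("jitter must lie within [0.020, 0.090] s")


def _sample_bounds(audio: AudioClip, seg: SongSegmentation) -> tuple[np.ndarray, np.ndarray]:
    sr = audio.sample_rate
    onsets = np.array([audio.index_of(s.onset_s) for s in seg], dtype=np.int64)
    offsets = np.array([audio.index_of(s.offset_s) for s in seg], dtype=np.int64)
    if onsets.size:
        if onsets[0] < 0 or offsets[-1] > audio.n_samples:
            raise InvalidSegmentationError("segmentation extends beyond audio")
        if np.any(offsets[:-1] > onsets[1:]):
            raise InvalidSegmentationError("overlapping syllables")
        if np.any(offsets <= onsets):
            raise InvalidSegmentationError("non-positive syllable length")
    return onsets, offsets


def to_units(audio: AudioClip, seg: SongSegmentation) -> UnitizedSong:
    """Split a song into (syllable waveform, following pause) units.

    The pause of the last unit runs to the end of the song, so
    concatenating the leading silence and all units reconstructs the
    original timeline sample-for-sample.
    """
    onsets, offsets = _sample_bounds(audio, seg)
    units = []
    for i in range(onsets.size):
        next_onset = onsets[i + 1] if i + 1 < onsets.size else audio.n_samples
        units.append(
            SyllablePauseUnit(
                waveform=audio.samples[onsets[i] : offsets[i]].copy(),
                pause_n=int(next_onset - offsets[i]),
            )
        )
    lead = int(onsets[0]) if onsets.size else audio.n_samples
    return UnitizedSong(
        lead_n=lead, units=tuple(units), sample_rate=audio.sample_rate, total_n=audio.n_samples
    )


def from_units(us: UnitizedSong) -> tuple[AudioClip, SongSegmentation]:
    """Reassemble audio and segmentation from a unit decomposition."""
    out = np.zeros(us.total_n)
    sr = us.sample_rate
    cursor = us.lead_n
    syllables = []
    for unit in us.units:
        out[cursor : cursor + unit.duration_n] = unit.waveform
        syllables.append(Syllable(onset_s=cursor / sr, offset_s=(cursor + unit.duration_n) / sr))
        cursor += unit.duration_n + unit.pause_n
    audio = AudioClip(out, sr)
    return audio, SongSegmentation(tuple(syllables), duration_s=audio.duration_s)


def _syllable_rms(samples: np.ndarray, onsets: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    return np.array(
        [np.sqrt(np.mean(samples[i0:i1] ** 2)) for i0, i1 in zip(onsets, offsets)]
    )


def _apply_ramps(segment: np.ndarray, ramp_n: int) -> np.ndarray:
    n = segment.size
    if 2 * ramp_n > n:
        warnings.warn("syllable shorter than two ramps; ramp truncated to half the syllable")
        ramp_n = n // 2
    if ramp_n > 0:
        ramp = np.linspace(0.0, 1.0, ramp_n, endpoint=False)
        segment = segment.copy()
        segment[:ramp_n] *= ramp
        segment[n - ramp_n :] *= ramp[::-1]
    return segment


def randomise_syllable_order(
    audio: AudioClip, seg: SongSegmentation, seed: int | None = None
) -> ManipulatedSong:
    """Shuffle (syllable + pause) units uniformly at random.

    The final unit is anchored in place so the multiset of onset-to-onset
    intervals is conserved exactly (the unit placed last contributes no
    ISI); every other unit order is equally likely.
    """
    us = to_units(audio, seg)
    if len(us.units) < 2:
        warnings.warn("fewer than 2 syllables: nothing to shuffle, returning identity")
        new_audio, new_seg = from_units(us)
        return ManipulatedSong(new_audio, new_seg, "randomised", seed)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(us.units) - 1)
    new_units = tuple(us.units[i] for i in order) + (us.units[-1],)
    new_audio, new_seg = from_units(
        UnitizedSong(us.lead_n, new_units, us.sample_rate, us.total_n)
    )
    return ManipulatedSong(new_audio, new_seg, "randomised", seed)


def reverse_song(audio: AudioClip, seg: SongSegmentation | None = None) -> ManipulatedSong:
    """Play the song backwards (sample order reversed)."""
    if audio.n_samples == 0:
        raise EmptyInputError("cannot reverse empty audio")
    rev = AudioClip(audio.samples[::-1].copy(), audio.sample_rate)
    if seg is None:
        new_seg = SongSegmentation((), duration_s=rev.duration_s)
    else:
        d = audio.duration_s
        new_seg = SongSegmentation(
            tuple(
                Syllable(onset_s=d - s.offset_s, offset_s=d - s.onset_s)
                for s in reversed(seg.syllables)
            ),
            duration_s=rev.duration_s,
        )
    return ManipulatedSong(rev, new_seg, "reversed")


def phase_scrambled_waveform(audio: AudioClip, seed: int | None = None) -> AudioClip:
    """Full-song phase randomisation preserving the magnitude spectrum.

    The rFFT phase of every interior bin is replaced by an independent
    uniform draw; DC and Nyquist stay real so the output is real-valued.
    """
    if audio.n_samples == 0:
        raise EmptyInputError("cannot scramble empty audio")
    from scipy.fft import irfft, rfft  # handles awkward lengths efficiently

    rng = np.random.default_rng(seed)
    mag = np.abs(rfft(audio.samples))
    phases = rng.uniform(0.0, 2 * np.pi, mag.size)
    phases[0] = 0.0
    if audio.n_samples % 2 == 0:
        phases[-1] = 0.0
    scrambled = irfft(mag * np.exp(1j * phases), n=audio.n_samples)
    return AudioClip(scrambled, audio.sample_rate)


def phase_scramble(
    audio: AudioClip, seg: SongSegmentation, seed: int | None = None
) -> ManipulatedSong:
    """Phase-scramble the song, then gate noise into the syllable windows.

    Outside the original syllable windows the output is exactly zero.
    Within each window the scrambled noise is flattened to constant RMS,
    ramped over 0.5 ms at both edges, and a single per-song gain matches
    the mean per-syllable RMS to the original's.
    """
    onsets, offsets = _sample_bounds(audio, seg)
    scrambled = phase_scrambled_waveform(audio, seed).samples
    out = np.zeros_like(audio.samples)
    ramp_n = int(round(RAMP_S * audio.sample_rate))
    for i0, i1 in zip(onsets, offsets):
        chunk = scrambled[i0:i1]
        rms = np.sqrt(np.mean(chunk**2))
        if rms > 0:
            chunk = chunk / rms
        out[i0:i1] = _apply_ramps(chunk, ramp_n)
    if onsets.size:
        target = _syllable_rms(audio.samples, onsets, offsets).mean()
        achieved = _syllable_rms(out, onsets, offsets).mean()
        if achieved > 0:
            out *= target / achieved
    new_seg = SongSegmentation(tuple(seg.syllables), duration_s=audio.duration_s)
    return ManipulatedSong(AudioClip(out, audio.sample_rate), new_seg, "phase_scrambled", seed)


def pure_tone_song(
    seg: SongSegmentation,
    reference: AudioClip,
    tone_hz: float = 76_000.0,
) -> ManipulatedSong:
    """Replace each syllable with a constant-amplitude pure tone.

    Tone frequency defaults to 76 kHz, the median peak frequency of the
    recorded syllables.  Onsets/offsets are unchanged; 0.5 ms linear
    ramps are applied; one per-song amplitude matches the mean syllable
    RMS of the reference audio.
    """
    if tone_hz >= reference.sample_rate / 2:
        raise InvalidParameterError("tone frequency must be below Nyquist")
    if tone_hz <= 0:
        raise InvalidParameterError("tone frequency must be positive")
    onsets, offsets = _sample_bounds(reference, seg)
    out = np.zeros_like(reference.samples)
    sr = reference.sample_rate
    ramp_n = int(round(RAMP_S * sr))
    for i0, i1 in zip(onsets, offsets):
        t = np.arange(i1 - i0) / sr
        out[i0:i1] = _apply_ramps(np.sin(2 * np.pi * tone_hz * t), ramp_n)
    if onsets.size:
        target = _syllable_rms(reference.samples, onsets, offsets).mean()
        achieved = _syllable_rms(out, onsets, offsets).mean()
        if achieved > 0:
            out *= target / achieved
    new_seg = SongSegmentation(tuple(seg.syllables), duration_s=reference.duration_s)
    return ManipulatedSong(AudioClip(out, sr), new_seg, "pure_tone")


def _integer_partition(budget: int, weights: np.ndarray) -> np.ndarray:
    """Split an integer budget proportionally to weights, exactly."""
    if budget == 0:
        return np.zeros(weights.size, dtype=np.int64)
    raw = weights / weights.sum() * budget
    base = np.floor(raw).astype(np.int64)
    remainder = budget - base.sum()
    order = np.argsort(raw - base)[::-1]
    base[order[:remainder]] += 1
    return base


def irregularise(
    audio: AudioClip, seg: SongSegmentation, seed: int | None = None
) -> ManipulatedSong:
    """Resample silent pauses, conserving the total pause budget exactly.

    Syllable waveforms and order are untouched.  New pauses are drawn as
    i.i.d. Uniform(0, 1) weights rescaled to the original total pause
    duration (integer samples, largest-remainder rounding), which
    broadens the ISI distribution while keeping song duration identical.
    """
    us = to_units(audio, seg)
    if len(us.units) < 2:
        warnings.warn("fewer than 2 syllables: nothing to irregularise, returning identity")
        new_audio, new_seg = from_units(us)
        return ManipulatedSong(new_audio, new_seg, "irregular", seed)
    rng = np.random.default_rng(seed)
    budget = sum(u.pause_n for u in us.units)
    weights = rng.uniform(size=len(us.units))
    new_pauses = _integer_partition(budget, weights)
    new_units = tuple(
        SyllablePauseUnit(u.waveform, int(p)) for u, p in zip(us.units, new_pauses)
    )
    new_audio, new_seg = from_units(
        UnitizedSong(us.lead_n, new_units, us.sample_rate, us.total_n)
    )
    return ManipulatedSong(new_audio, new_seg, "irregular", seed)


def super_regularise(
    audio: AudioClip, seg: SongSegmentation, bout_gap_s: float = 2.0
) -> ManipulatedSong:
    """Place within-bout syllable onsets on an exact median-ISI grid.

    Within each bout (runs separated by onset gaps > ``bout_gap_s``) the
    onset-to-onset interval between successive syllables becomes k*m,
    where m is the song's median within-bout ISI and k is the smallest
    positive integer with k*m strictly greater than the earlier
    syllable's duration ("skip a cycle" when a syllable outlasts the
    grid step).  Total song duration is restored by adjusting inter-bout
    silences (largest gap first, then proportional redistribution); if
    no non-negative adjustment exists an infeasibility error is raised.
    """
    onsets, offsets = _sample_bounds(audio, seg)
    if onsets.size < 2:
        raise InsufficientDataError("need at least 2 syllables to super-regularise")
    sr = audio.sample_rate
    isis = np.diff(onsets)
    bout_gap_n = int(round(bout_gap_s * sr))
    breaks = np.flatnonzero(isis > bout_gap_n)
    within = np.delete(isis, breaks)
    if within.size == 0:
        raise InsufficientDataError("no within-bout intervals (all gaps exceed bout gap)")
    m = int(round(float(np.median(within))))

    # bouts as index ranges [a, b)
    bounds = [0, *(breaks + 1), onsets.size]
    bouts = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]

    rel_layouts = []  # per bout: onset offsets relative to bout start
    bout_lengths = []
    for a, b in bouts:
        rel = [0]
        for j in range(a, b - 1):
            dur = int(offsets[j] - onsets[j])
            k = dur // m + 1  # smallest k with k*m > dur
            rel.append(rel[-1] + k * m)
        rel_layouts.append(np.array(rel, dtype=np.int64))
        bout_lengths.append(int(rel[-1] + (offsets[b - 1] - onsets[b - 1])))

    lead = int(onsets[0])
    tail = int(audio.n_samples - offsets[-1])
    gaps = [int(onsets[a] - offsets[a - 1]) for a, _ in bouts[1:]]
    adjustable = np.array(gaps + [tail], dtype=np.int64)
    required = audio.n_samples - lead - sum(bout_lengths)
    delta = int(required - adjustable.sum())

    i_max = int(np.argmax(adjustable))
    if adjustable[i_max] + delta >= 0:
        adjustable[i_max] += delta
    else:
        total = adjustable.sum() + delta
        if total < 0:
            raise InfeasibleAdjustmentError(
                "cannot restore song duration without negative silent pauses"
            )
        adjustable = _integer_partition(int(total), adjustable.astype(np.float64) + 1e-9)

    out = np.zeros_like(audio.samples)
    syllables = []
    cursor = lead
    for (a, b), rel, length, gap_after in zip(
        bouts, rel_layouts, bout_lengths, list(adjustable[:-1]) + [adjustable[-1]]
    ):
        for j, r in zip(range(a, b), rel):
            i0 = cursor + int(r)
            i1 = i0 + int(offsets[j] - onsets[j])
            out[i0:i1] = audio.samples[onsets[j] : offsets[j]]
            syllables.append(Syllable(onset_s=i0 / sr, offset_s=i1 / sr))
        cursor += length + int(gap_after)

    new_audio = AudioClip(out, sr)
    new_seg = SongSegmentation(tuple(syllables), duration_s=new_audio.duration_s)
    return ManipulatedSong(new_audio, new_seg, "super_regular")


def build_session_programs(
    n_trials: int = 4, n_songs: int = 7, seed: int | None = None
) -> list[TrialProgram]:
    """Assemble the playback programs for one behavioural session.

    Each trial plays the full stimulus set in an independent uniform
    random order.  The playback side is drawn once at the start of the
    session and strictly alternates across trials.  Per-song onset
    jitter between the paired streams is uniform on [20, 90] ms with a
    random leading stream per trial.
    """
    if n_trials < 1 or n_songs < 1:
        raise InvalidParameterError("n_trials and n_songs must be positive")
    rng = np.random.default_rng(seed)
    first_side = "left" if rng.random() < 0.5 else "right"
    sides = [first_side if i % 2 == 0 else ("right" if first_side == "left" else "left")
             for i in range(n_trials)]
    programs = []
    for i in range(n_trials):
        programs.append(
            TrialProgram(
                song_order=tuple(int(j) for j in rng.permutation(n_songs)),
                jitter_s=tuple(float(j) for j in rng.uniform(0.020, 0.090, n_songs)),
                leading_stream="intact" if rng.random() < 0.5 else "manipulated",
                playback_side=sides[i],
            )
        )
    return programs
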