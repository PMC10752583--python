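"""Synthetic songs and tracking sessions with known ground truth.

The song generator emulates the acoustic statistics of recorded
C57Bl/6 male courtship songs: bimodal syllable durations (modes near
23 ms and 88 ms, an 86%/14% split around the 63 ms antimode), syllable
peak frequencies centred on 76 kHz within the 68-84 kHz band, and
onset-to-onset inter-syllable intervals with median 104 ms and IQR
61 ms.  Durations come from a two-component log-normal mixture whose
component modes sit at the target modes; ISIs from a log-normal
parameterised by (median, IQR) through closed-form quantile matching.
Syllables are linear FM sweeps with flat envelopes and 0.5 ms linear
ramps, at 250 kHz sampling.

The trajectory generator emulates a place-preference session: a
semi-Markov occupancy process alternates neutral-zone and speaker-zone
visits (exponential dwell times); during a playback trial the song-side
zone is chosen with probability q = (1 + p) / 2, which makes the
expected preference index equal to the target p.  Frames at ~30 Hz are
positioned uniformly inside the occupied region, and a configurable
fraction is dropped to exercise gap interpolation.

All randomness in one call flows from a single seeded generator, so
every artefact is bitwise reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .errors import InvalidParameterError
from .manipulations import RAMP_S, _apply_ramps
from .preference import SessionLayout, Trajectory, preference_index
from .syllables import AudioClip, SongSegmentation, Syllable

__all__ = [
    "SongModelParams",
    "TrajectoryModelParams",
    "sample_durations",
    "sample_isis",
    "sample_song_timeline",
    "generate_song",
    "generate_session",
    "simulate_trial_times",
    "generate_cohort",
    "CohortSimulation",
]

_Z75 = stats.norm.ppf(0.75)  # 0.6745, used in the IQR <-> sigma mapping


@dataclass(frozen=True)
class SongModelParams:
    """Targets and conventions for synthetic courtship songs."""

    n_syllables: int = 145
    dur_modes_s: tuple[float, float] = (0.023, 0.088)
    dur_mix: tuple[float, float] = (0.86, 0.14)
    dur_sigmas: tuple[float, float] = (0.25, 0.20)
    dur_antimode_s: float = 0.063
    isi_median_s: float = 0.104
    isi_iqr_s: float = 0.061
    freq_center_hz: float = 76_000.0
    freq_center_sd_hz: float = 2_000.0
    freq_band_hz: tuple[float, float] = (68_000.0, 84_000.0)
    max_sweep_halfwidth_hz: float = 8_000.0
    amplitude: float = 0.9
    amplitude_sigma: float = 0.10
    noise_rms: float = 0.003
    min_pause_s: float = 0.020
    lead_s: float = 0.5
    tail_s: float = 0.5
    sample_rate: int = 250_000

    def __post_init__(self):
        if abs(sum(self.dur_mix) - 1.0) > 1e-9:
            raise InvalidParameterError("duration mixture weights must sum to 1")
        if self.freq_band_hz[1] >= self.sample_rate / 2:
            raise InvalidParameterError("frequency band must lie below Nyquist")
        if min(self.isi_median_s, self.isi_iqr_s, *self.dur_modes_s) <= 0:
            raise InvalidParameterError("all scales must be positive")


@dataclass(frozen=True)
class TrajectoryModelParams:
    """Occupancy-process parameters for synthetic tracking sessions."""

    preference_p: float = 0.0
    zone_dwell_mean_s: float = 3.0
    neutral_fraction: float = 0.35
    dropout_rate: float = 0.02
    frame_rate_hz: float = 30.0
    habituation_s: float = 600.0
    trial_s: float = 160.0
    break_s: float = 180.0
    n_trials: int = 4

    def __post_init__(self):
        if not (-1.0 < self.preference_p < 1.0):
            raise InvalidParameterError("preference_p must lie in (-1, 1)")
        if not (0.0 <= self.neutral_fraction < 1.0):
            raise InvalidParameterError("neutral_fraction must lie in [0, 1)")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise InvalidParameterError("dropout_rate must lie in [0, 1)")
        if self.zone_dwell_mean_s <= 0:
            raise InvalidParameterError("zone dwell mean must be positive")


def _lognormal_sigma_from_iqr(median: float, iqr: float) -> float:
    """Sigma of a log-normal with the given median and interquartile range.

    Quartiles are median * exp(+-z75 * sigma), so
    IQR = 2 * median * sinh(z75 * sigma).
    """
    return float(np.arcsinh(iqr / (2.0 * median)) / _Z75)


def sample_durations(n: int, params: SongModelParams, rng: np.random.Generator) -> np.ndarray:
    """Draw syllable durations from the two-component log-normal mixture.

    Each component's mode sits at the target (mode = median * exp(-sigma^2)),
    so the smoothed density peaks recover the 23/88 ms figure.
    """
    comp = (rng.random(n) >= params.dur_mix[0]).astype(int)
    modes = np.array(params.dur_modes_s)
    sigmas = np.array(params.dur_sigmas)
    medians = modes * np.exp(sigmas**2)
    return np.exp(rng.normal(np.log(medians[comp]), sigmas[comp]))


def sample_isis(n: int, params: SongModelParams, rng: np.random.Generator) -> np.ndarray:
    """Draw onset-to-onset intervals from the quantile-matched log-normal."""
    sigma = _lognormal_sigma_from_iqr(params.isi_median_s, params.isi_iqr_s)
    return np.exp(rng.normal(np.log(params.isi_median_s), sigma, n))


def _match_isis(
    floors: np.ndarray, isis: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Assign drawn ISIs to positions subject to per-position floors.

    An onset-to-onset interval must exceed the earlier syllable's
    duration plus the minimum pause (its "floor").  Clipping conflicting
    draws upward would bias the ISI median, so instead the drawn ISI
    multiset is kept intact and assigned to positions: floors are
    processed in descending order and each receives a uniformly random
    ISI from the still-unassigned draws at or above it.  Only when no
    eligible draw remains (rare) is a value clipped to its floor.
    """
    import bisect

    order = np.argsort(floors)[::-1]
    pool = sorted(isis.tolist())
    out = np.empty(floors.size)
    clipped = 0
    for i in order:
        k = bisect.bisect_left(pool, floors[i])
        if k == len(pool):
            pool.pop()
            out[i] = floors[i]
            clipped += 1
        else:
            out[i] = pool.pop(k + int(rng.integers(len(pool) - k)))
    return out, clipped


def sample_song_timeline(
    params: SongModelParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, int]:
    """Sample syllable onset/offset sample indices for one song.

    Durations come from the bimodal mixture, onset-to-onset gaps from
    the quantile-matched log-normal (assigned so syllables never
    overlap, see _match_isis).  Returns (onsets_n, offsets_n, n_clipped)
    in samples.
    """
    sr = params.sample_rate
    n = params.n_syllables
    durations = sample_durations(n, params, rng)
    clipped = 0
    onsets_n = np.empty(n, dtype=np.int64)
    onsets_n[0] = int(round(params.lead_s * sr))
    if n > 1:
        isis = sample_isis(n - 1, params, rng)
        floors = durations[:-1] + params.min_pause_s
        isis, clipped = _match_isis(floors, isis, rng)
        if clipped:
            warnings.warn(f"clipped {clipped} inter-syllable interval(s) to the overlap floor")
        onsets_n[1:] = onsets_n[0] + np.cumsum(np.round(isis * sr).astype(np.int64))
    durations_n = np.maximum(np.round(durations * sr).astype(np.int64), 2)
    offsets_n = onsets_n + durations_n
    return onsets_n, offsets_n, clipped


def generate_song(
    params: SongModelParams | None = None, seed: int | None = None
) -> tuple[AudioClip, SongSegmentation, dict]:
    """Synthesise one song; returns (audio, segmentation, ground truth).

    Syllables are linear FM sweeps with random direction and extent
    inside the 68-84 kHz band, flat envelopes with 0.5 ms ramps, and
    mildly varying amplitudes over a low Gaussian noise floor.  ISIs
    shorter than the syllable plus a minimum pause are repaired upward
    (with a warning) so syllables never overlap.
    """
    if params is None:
        params = SongModelParams()
    rng = np.random.default_rng(seed)
    sr = params.sample_rate
    n = params.n_syllables

    if n == 0:
        total_n = int(round((params.lead_s + params.tail_s) * sr))
        noise = rng.normal(0.0, params.noise_rms, total_n) if params.noise_rms else np.zeros(total_n)
        clip = AudioClip(noise, sr)
        return clip, SongSegmentation((), clip.duration_s), {
            "onsets_s": np.array([]), "offsets_s": np.array([]), "n_repaired": 0,
        }

    onsets_n, offsets_n, repaired = sample_song_timeline(params, rng)
    durations_n = offsets_n - onsets_n
    # pad the trailing silence to an FFT-friendly length so whole-song
    # spectral operations (e.g. phase scrambling) stay fast
    from scipy.fft import next_fast_len

    total_n = next_fast_len(int(offsets_n[-1] + round(params.tail_s * sr)))

    samples = (
        rng.normal(0.0, params.noise_rms, total_n)
        if params.noise_rms
        else np.zeros(total_n)
    )
    band_lo, band_hi = params.freq_band_hz
    ramp_n = int(round(RAMP_S * sr))
    centers = np.clip(
        rng.normal(params.freq_center_hz, params.freq_center_sd_hz, n), band_lo, band_hi
    )
    halfwidths = np.minimum(
        rng.uniform(0.0, params.max_sweep_halfwidth_hz, n),
        np.minimum(centers - band_lo, band_hi - centers),
    )
    directions = rng.choice([-1.0, 1.0], n)
    amps = params.amplitude * np.exp(rng.normal(0.0, params.amplitude_sigma, n))
    f_start = centers - directions * halfwidths
    f_end = centers + directions * halfwidths

    for i in range(n):
        m = durations_n[i]
        t = np.arange(m) / sr
        # linear chirp: phase integral of f(t) = f0 + (f1-f0) * t / T
        sweep_rate = (f_end[i] - f_start[i]) / (m / sr)
        phase = 2 * np.pi * (f_start[i] * t + 0.5 * sweep_rate * t**2)
        tone = amps[i] * np.sin(phase)
        samples[onsets_n[i] : offsets_n[i]] += _apply_ramps(tone, ramp_n)

    clip = AudioClip(samples, sr)
    seg = SongSegmentation(
        tuple(
            Syllable(onset_s=int(o) / sr, offset_s=int(f) / sr)
            for o, f in zip(onsets_n, offsets_n)
        ),
        duration_s=clip.duration_s,
    )
    ground_truth = {
        "onsets_s": onsets_n / sr,
        "offsets_s": offsets_n / sr,
        "durations_s": durations_n / sr,
        "freq_start_hz": f_start,
        "freq_end_hz": f_end,
        "freq_center_hz": centers,
        "amplitudes": amps,
        "n_repaired": repaired,
        "seed": seed,
    }
    return clip, seg, ground_truth


def _simulate_visits(
    total_s: float,
    zone_prob_fn,
    params: TrajectoryModelParams,
    rng: np.random.Generator,
):
    """Alternating neutral/zone visits covering [0, total_s].

    Returns (start times, states) where state is 'neutral', 'left' or
    'right'.  ``zone_prob_fn(t)`` gives the probability of choosing the
    left zone for a visit starting at time t.
    """
    f = params.neutral_fraction
    mu_zone = params.zone_dwell_mean_s
    mu_neutral = mu_zone * f / (1.0 - f) if f > 0 else 0.0
    times, states = [], []
    t = 0.0
    while t < total_s:
        if mu_neutral > 0:
            times.append(t)
            states.append("neutral")
            t += rng.exponential(mu_neutral)
            if t >= total_s:
                break
        times.append(t)
        states.append("left" if rng.random() < zone_prob_fn(t) else "right")
        t += rng.exponential(mu_zone)
    return np.array(times), states


def generate_session(
    params: TrajectoryModelParams | None = None,
    layout: SessionLayout | None = None,
    seed: int | None = None,
) -> tuple[Trajectory, SessionLayout, dict]:
    """Simulate one tracked behavioural session.

    Returns (trajectory, layout-with-trial-windows, ground truth).  The
    ground truth records the injected preference, the exact per-trial
    zone dwell times of the underlying occupancy process, and the trial
    playback sides.
    """
    if params is None:
        params = TrajectoryModelParams()
    if layout is None:
        layout = SessionLayout()
    rng = np.random.default_rng(seed)

    first_side = "left" if rng.random() < 0.5 else "right"
    other = "right" if first_side == "left" else "left"
    sides = [first_side if i % 2 == 0 else other for i in range(params.n_trials)]
    windows = []
    t0 = params.habituation_s
    for i in range(params.n_trials):
        windows.append((t0, t0 + params.trial_s, sides[i]))
        t0 += params.trial_s + params.break_s
    total_s = t0

    q = (1.0 + params.preference_p) / 2.0
    win_arr = np.array([(a, b) for a, b, _ in windows])

    def left_prob(t: float) -> float:
        for (a, b), side in zip(win_arr, sides):
            if a <= t < b:
                return q if side == "left" else 1.0 - q
        return 0.5

    starts, states = _simulate_visits(total_s, left_prob, params, rng)

    # frame grid and per-frame state
    n_frames = int(np.floor(total_s * params.frame_rate_hz))
    t_frames = np.arange(n_frames) / params.frame_rate_hz
    state_idx = np.searchsorted(starts, t_frames, side="right") - 1
    frame_states = np.array([states[i] for i in state_idx])

    left, right = layout.zones()
    margin = 2.0
    x = np.empty(n_frames)
    y = np.empty(n_frames)
    for name, rect in (("left", left), ("right", right)):
        m = frame_states == name
        x[m] = rng.uniform(rect.x0 + margin, rect.x1 - margin, m.sum())
        y[m] = rng.uniform(rect.y0 + margin, rect.y1 - margin, m.sum())
    m = frame_states == "neutral"
    x[m] = rng.uniform(margin, layout.box_w_mm - margin, m.sum())
    y[m] = rng.uniform(layout.zone_depth_mm + margin, layout.box_h_mm - margin, m.sum())

    valid = rng.random(n_frames) >= params.dropout_rate
    if not valid.any():
        valid[0] = True

    traj = Trajectory(
        t_s=t_frames, x_mm=x, y_mm=y, valid=valid, nominal_rate_hz=params.frame_rate_hz
    )
    layout = replace(layout, trial_windows=tuple(windows))

    # exact dwell times of the latent process per trial window
    ends = np.append(starts[1:], total_s)
    gt_trials = []
    for (a, b), side in zip(win_arr, sides):
        overlap = np.clip(np.minimum(ends, b) - np.maximum(starts, a), 0.0, None)
        t_left = float(overlap[[s == "left" for s in states]].sum())
        t_right = float(overlap[[s == "right" for s in states]].sum())
        t_song = t_left if side == "left" else t_right
        t_manip = t_right if side == "left" else t_left
        gt_trials.append(
            {
                "side": side,
                "t_song_s": t_song,
                "t_manip_s": t_manip,
                "pi": preference_index(t_song, t_manip) if t_song + t_manip > 0 else float("nan"),
            }
        )
    ground_truth = {
        "preference_p": params.preference_p,
        "trials": gt_trials,
        "sides": sides,
        "seed": seed,
        "n_dropped_frames": int((~valid).sum()),
    }
    return traj, layout, ground_truth


def simulate_trial_times(
    q_left: float, params: TrajectoryModelParams, rng: np.random.Generator
) -> tuple[float, float]:
    """Left/right zone dwell times for one trial of the occupancy process.

    Fast summary-level path (no trajectory): the same alternating
    neutral/zone visit process as generate_session, truncated at the
    trial length.
    """
    f = params.neutral_fraction
    mu_zone = params.zone_dwell_mean_s
    mu_neutral = mu_zone * f / (1.0 - f) if f > 0 else 0.0
    t = 0.0
    t_left = t_right = 0.0
    while t < params.trial_s:
        if mu_neutral > 0:
            t += rng.exponential(mu_neutral)
            if t >= params.trial_s:
                break
        d = min(rng.exponential(mu_zone), params.trial_s - t)
        if rng.random() < q_left:
            t_left += d
        else:
            t_right += d
        t += d
    return t_left, t_right


@dataclass(frozen=True)
class CohortSimulation:
    """A simulated cohort: injected effects and realised session PIs."""

    true_p: np.ndarray
    session_pis: np.ndarray
    mode: str
    seed: int | None


def generate_cohort(
    n_sessions: int,
    effect_mean: float,
    effect_sd: float,
    seed: int | None = None,
    mode: str = "trials",
    params: TrajectoryModelParams | None = None,
) -> CohortSimulation:
    """Simulate a cohort of sessions with Normal(effect_mean, effect_sd) effects.

    ``mode`` selects how each session's PI is realised:

    * ``"exact"``  - the session PI equals the drawn effect (isolates the
      cohort-statistics stage; used for t-test calibration).
    * ``"trials"`` - four trials of the summary-level occupancy process;
      the session PI is the median of the four trial PIs.
    * ``"trajectory"`` - full tracked sessions via generate_session and
      the zone-occupancy pipeline (slowest, end-to-end).
    """
    if n_sessions < 1:
        raise InvalidParameterError("need at least 1 session")
    if mode not in ("exact", "trials", "trajectory"):
        raise InvalidParameterError(f"unknown cohort mode {mode!r}")
    if params is None:
        params = TrajectoryModelParams()
    rng = np.random.default_rng(seed)
    true_p = np.clip(rng.normal(effect_mean, effect_sd, n_sessions), -0.95, 0.95)

    if mode == "exact":
        pis = true_p.copy()
    elif mode == "trials":
        pis = np.empty(n_sessions)
        for i in range(n_sessions):
            q = (1.0 + true_p[i]) / 2.0
            trial_pis = []
            for _ in range(params.n_trials):
                t_song, t_manip = simulate_trial_times(q, params, rng)
                total = t_song + t_manip
                trial_pis.append((t_song - t_manip) / total if total > 0 else np.nan)
            pis[i] = np.nanmedian(trial_pis)
    else:
        from .preference import interpolate_gaps, session_result

        pis = np.empty(n_sessions)
        for i in range(n_sessions):
            p_i = replace(params, preference_p=float(true_p[i]))
            traj, layout, _ = generate_session(p_i, seed=int(rng.integers(2**31)))
            pis[i] = session_result(interpolate_gaps(traj), layout).session_pi
    return CohortSimulation(true_p=true_p, session_pis=pis, mode=mode, seed=seed)
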