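"""Place-preference analysis of female approach behaviour.

A behavioural session puts a female mouse in a two-compartment box with
a loudspeaker at each end; four 160 s playback trials contrast an intact
song set from one side with a manipulated set (or silence) from the
other, with the playback side alternating across trials.  The analysis
turns body-centroid tracking into:

* per-trial speaker-zone dwell times and a preference index
  PI = (t_song - t_manip) / (t_song + t_manip), in [-1, 1];
* a session PI (median of the four trial PIs);
* a side-bias exclusion flag (all four trials favouring the same
  physical side regardless of playback side);
* cumulative approach profiles (+1 per frame in the song zone, -1 in
  the manipulated zone, scaled by the inter-frame interval), resampled
  to a common 160 s grid and normalised to the maximum absolute value
  of the trial-median trace;
* cohort statistics: normality diagnostics (Lilliefors, Shapiro-Wilk)
  followed by a one-sample two-tailed t-test against zero with a 95% CI,
  and per-time-bin significance of the cumulative profiles.

Frame dwell time uses the timestamp difference to the next frame (the
last frame contributes the median interval), which reduces to the
nominal-frame-rate rule of thumb when sampling is uniform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .errors import (
    EmptyInputError,
    InsufficientDataError,
    InvalidParameterError,
)

__all__ = [
    "Trajectory",
    "Rect",
    "SessionLayout",
    "TrialResult",
    "SessionResult",
    "ProfileResult",
    "CohortStats",
    "interpolate_gaps",
    "zone_occupancy",
    "preference_index",
    "side_bias_flag",
    "trial_results",
    "session_result",
    "cumulative_profile",
    "cohort_stats",
    "timecourse_significance",
    "zone_length_sensitivity",
]

#: Duration of one playback trial (seconds): the seven-song stimulus set.
TRIAL_DURATION_S = 160.0


@dataclass(frozen=True)
class Trajectory:
    """Timestamped 2-D body-centroid positions (mm), with validity flags."""

    t_s: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    valid: np.ndarray
    nominal_rate_hz: float = 30.0

    def __post_init__(self):
        t = np.asarray(self.t_s, dtype=np.float64)
        if t.size == 0:
            raise EmptyInputError("trajectory has no frames")
        if np.any(np.diff(t) <= 0):
            raise InvalidParameterError("timestamps must be strictly increasing")
        object.__setattr__(self, "t_s", t)
        object.__setattr__(self, "x_mm", np.asarray(self.x_mm, dtype=np.float64))
        object.__setattr__(self, "y_mm", np.asarray(self.y_mm, dtype=np.float64))
        object.__setattr__(self, "valid", np.asarray(self.valid, dtype=bool))

    @property
    def n_frames(self) -> int:
        return self.t_s.size

    @property
    def frame_dt_s(self) -> np.ndarray:
        """Per-frame dwell interval: diff to next frame, median for the last."""
        dt = np.diff(self.t_s)
        last = np.median(dt) if dt.size else 1.0 / self.nominal_rate_hz
        return np.append(dt, last)


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle; the boundary counts as inside."""

    x0: float
    x1: float
    y0: float
    y1: float

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (x >= self.x0) & (x <= self.x1) & (y >= self.y0) & (y <= self.y1)


@dataclass(frozen=True)
class SessionLayout:
    """Box geometry (mm), speaker zones, and per-trial playback windows.

    The box is 227 x 252 mm; a central partition divides the speaker end
    into two arms with mesh openings at y = 0.  Each speaker zone spans
    its arm's width and extends ``zone_depth_mm`` (default 86) into the
    arm from the mesh wall.
    """

    box_w_mm: float = 227.0
    box_h_mm: float = 252.0
    zone_depth_mm: float = 86.0
    partition_halfwidth_mm: float = 5.0
    arm_length_mm: float = 126.0
    mm_per_px: float = 1.0
    trial_windows: tuple = ()  # (t_on_s, t_off_s, song_side) triples

    def zones(self, depth_mm: float | None = None) -> tuple[Rect, Rect]:
        depth = self.zone_depth_mm if depth_mm is None else depth_mm
        if depth <= 0:
            raise InvalidParameterError("zone depth must be positive")
        if depth > self.arm_length_mm:
            warnings.warn("zone depth exceeds arm length; clipped")
            depth = self.arm_length_mm
        mid = self.box_w_mm / 2
        left = Rect(0.0, mid - self.partition_halfwidth_mm, 0.0, depth)
        right = Rect(mid + self.partition_halfwidth_mm, self.box_w_mm, 0.0, depth)
        return left, right


@dataclass(frozen=True)
class TrialResult:
    t_song_s: float
    t_manip_s: float
    t_left_s: float
    t_right_s: float
    song_side: str
    preference_index: float  # nan when both dwell times are zero


@dataclass(frozen=True)
class ProfileResult:
    """Cumulative approach profiles on a common uniform time grid."""

    grid_s: np.ndarray
    per_trial: np.ndarray  # unnormalised, (n_trials, n_grid), seconds
    median_trace: np.ndarray  # pointwise median across trials, unnormalised
    normalised_median: np.ndarray  # median_trace / max |median_trace|

    @property
    def endpoints_s(self) -> np.ndarray:
        return self.per_trial[:, -1]


@dataclass(frozen=True)
class SessionResult:
    trial_results: tuple[TrialResult, ...]
    session_pi: float
    side_bias: bool
    profile: ProfileResult


@dataclass(frozen=True)
class CohortStats:
    n: int
    mean: float
    ci95: tuple[float, float]
    t: float
    df: int
    p: float
    lilliefors_p: float
    shapiro_p: float
    normal: bool
    wilcoxon_p: float | None = None


def interpolate_gaps(traj: Trajectory) -> Trajectory:
    """Fill invalid frames by holding the most recent valid position.

    Leading invalid frames take the first valid position (a documented
    extension of the hold-last-position rule, which has no earlier
    position to repeat).
    """
    if not traj.valid.any():
        raise EmptyInputError("trajectory has no valid frames")
    if traj.valid.all():
        return traj
    idx = np.where(traj.valid, np.arange(traj.n_frames), -1)
    idx = np.maximum.accumulate(idx)
    first_valid = int(np.flatnonzero(traj.valid)[0])
    idx[idx < 0] = first_valid
    return Trajectory(
        t_s=traj.t_s,
        x_mm=traj.x_mm[idx],
        y_mm=traj.y_mm[idx],
        valid=np.ones(traj.n_frames, dtype=bool),
        nominal_rate_hz=traj.nominal_rate_hz,
    )


def _window_mask(traj: Trajectory, window: tuple[float, float]) -> np.ndarray:
    t0, t1 = window
    if t0 >= t1:
        raise InvalidParameterError("window must have positive length")
    dt = traj.frame_dt_s
    if t0 < traj.t_s[0] - dt[-1] or t1 > traj.t_s[-1] + dt[-1]:
        raise InvalidParameterError("window lies outside the trajectory span")
    return (traj.t_s >= t0) & (traj.t_s < t1)


def zone_occupancy(
    traj: Trajectory,
    layout: SessionLayout,
    window: tuple[float, float],
    zone_depth_mm: float | None = None,
) -> dict:
    """Dwell time (s) in the left zone, right zone, and elsewhere.

    Each frame inside the window contributes its inter-frame interval to
    exactly one bucket by point-in-rectangle test (boundaries count as
    inside); the buckets sum to the window length to within one frame
    interval.  The trajectory must be gap-free (see interpolate_gaps).
    """
    if not traj.valid.all():
        raise InvalidParameterError("trajectory contains invalid frames; interpolate first")
    mask = _window_mask(traj, window)
    left, right = layout.zones(zone_depth_mm)
    dt = traj.frame_dt_s[mask]
    x, y = traj.x_mm[mask], traj.y_mm[mask]
    in_left = left.contains(x, y)
    in_right = right.contains(x, y) & ~in_left
    return {
        "t_left_s": float(dt[in_left].sum()),
        "t_right_s": float(dt[in_right].sum()),
        "t_neutral_s": float(dt[~(in_left | in_right)].sum()),
    }


def preference_index(t_song_s: float, t_manip_s: float) -> float:
    """(t_song - t_manip) / (t_song + t_manip); nan when both are zero."""
    if t_song_s < 0 or t_manip_s < 0:
        raise InvalidParameterError("dwell times must be non-negative")
    total = t_song_s + t_manip_s
    if total == 0:
        warnings.warn("both dwell times are zero: preference index undefined for this trial")
        return float("nan")
    return (t_song_s - t_manip_s) / total


def side_bias_flag(trials: tuple[TrialResult, ...] | list[TrialResult]) -> bool:
    """True iff all four trials favour the same physical side.

    A trial with exactly equal left/right dwell times breaks the streak
    (flag False).
    """
    if len(trials) != 4:
        raise InvalidParameterError("side-bias evaluation requires exactly 4 trials")
    diffs = np.array([tr.t_left_s - tr.t_right_s for tr in trials])
    return bool(np.all(diffs > 0) or np.all(diffs < 0))


def trial_results(
    traj: Trajectory,
    layout: SessionLayout,
    zone_depth_mm: float | None = None,
) -> tuple[TrialResult, ...]:
    """Per-trial dwell times and preference indices for a session."""
    if not layout.trial_windows:
        raise InvalidParameterError("layout has no trial windows")
    results = []
    for t_on, t_off, side in layout.trial_windows:
        if side not in ("left", "right"):
            raise InvalidParameterError(f"unknown song side {side!r}")
        occ = zone_occupancy(traj, layout, (t_on, t_off), zone_depth_mm)
        t_song = occ["t_left_s"] if side == "left" else occ["t_right_s"]
        t_manip = occ["t_right_s"] if side == "left" else occ["t_left_s"]
        results.append(
            TrialResult(
                t_song_s=t_song,
                t_manip_s=t_manip,
                t_left_s=occ["t_left_s"],
                t_right_s=occ["t_right_s"],
                song_side=side,
                preference_index=preference_index(t_song, t_manip),
            )
        )
    return tuple(results)


def cumulative_profile(
    traj: Trajectory,
    layout: SessionLayout,
    zone_depth_mm: float | None = None,
    grid_duration_s: float = TRIAL_DURATION_S,
    grid_step_s: float = 1.0,
) -> ProfileResult:
    """Cumulative approach traces per trial, on a common uniform grid.

    Each frame weighs +dt in the song-side zone, -dt in the opposite
    zone, 0 elsewhere; the cumulative sum over a trial is linearly
    interpolated onto a 0..160 s grid (1 s bins).  The trial-median
    trace is computed pointwise and normalised by its maximum absolute
    value.  The endpoint of each unnormalised trace equals that trial's
    t_song - t_manip.
    """
    if not layout.trial_windows:
        raise InvalidParameterError("layout has no trial windows")
    left, right = layout.zones(zone_depth_mm)
    grid = np.arange(0.0, grid_duration_s + grid_step_s / 2, grid_step_s)
    traces = []
    dt_all = traj.frame_dt_s
    for t_on, t_off, side in layout.trial_windows:
        if side not in ("left", "right"):
            raise InvalidParameterError(f"missing or unknown song side {side!r}")
        mask = _window_mask(traj, (t_on, t_off))
        x, y, dt = traj.x_mm[mask], traj.y_mm[mask], dt_all[mask]
        in_left = left.contains(x, y)
        in_right = right.contains(x, y) & ~in_left
        sign = 1.0 if side == "left" else -1.0
        w = np.where(in_left, sign, 0.0) - np.where(in_right, sign, 0.0)
        cum = np.cumsum(w * dt)
        t_rel = traj.t_s[mask] - t_on
        if cum.size:
            traces.append(np.interp(grid, t_rel, cum, left=0.0, right=cum[-1]))
        else:
            traces.append(np.zeros_like(grid))
    per_trial = np.vstack(traces)
    median_trace = np.median(per_trial, axis=0)
    peak = np.max(np.abs(median_trace))
    normalised = median_trace / peak if peak > 0 else median_trace.copy()
    return ProfileResult(
        grid_s=grid,
        per_trial=per_trial,
        median_trace=median_trace,
        normalised_median=normalised,
    )


def session_result(
    traj: Trajectory,
    layout: SessionLayout,
    zone_depth_mm: float | None = None,
) -> SessionResult:
    """Full per-session quantification: trial PIs, session PI, bias, profile."""
    trials = trial_results(traj, layout, zone_depth_mm)
    pis = np.array([tr.preference_index for tr in trials])
    defined = pis[~np.isnan(pis)]
    if defined.size < pis.size:
        warnings.warn("trial(s) with undefined PI excluded from the session median")
    session_pi = float(np.median(defined)) if defined.size else float("nan")
    return SessionResult(
        trial_results=trials,
        session_pi=session_pi,
        side_bias=side_bias_flag(trials) if len(trials) == 4 else False,
        profile=cumulative_profile(traj, layout, zone_depth_mm),
    )


def cohort_stats(session_pis, alpha: float = 0.05) -> CohortStats:
    """Cohort-level test of place preference against zero.

    Normality is checked first (Lilliefors and Shapiro-Wilk at
    ``alpha``); the one-sample two-tailed t-test and 95% CI of the mean
    are always reported, with a Wilcoxon signed-rank p-value added when
    normality is rejected.  Zero-variance input is handled explicitly
    (t = 0, p = 1 when the common value is 0; p -> 0 otherwise).
    """
    x = np.asarray(session_pis, dtype=np.float64)
    if x.size < 3:
        raise InsufficientDataError("need at least 3 sessions for cohort statistics")
    n = int(x.size)
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    df = n - 1

    if sd == 0.0:
        if mean == 0.0:
            t_stat, p = 0.0, 1.0
        else:
            warnings.warn("zero-variance cohort with nonzero mean: p set to 0")
            t_stat, p = float(np.sign(mean)) * float("inf"), 0.0
        return CohortStats(
            n=n, mean=mean, ci95=(mean, mean), t=t_stat, df=df, p=p,
            lilliefors_p=float("nan"), shapiro_p=float("nan"), normal=False,
        )

    from statsmodels.stats.diagnostic import lilliefors as _lilliefors

    try:
        _, lf_p = _lilliefors(x, dist="norm")
    except Exception:  # tiny-n pathologies
        lf_p = float("nan")
    try:
        _, sw_p = stats.shapiro(x)
    except Exception:
        sw_p = float("nan")
    normal = bool(
        (np.isnan(lf_p) or lf_p >= alpha) and (np.isnan(sw_p) or sw_p >= alpha)
    )

    res = stats.ttest_1samp(x, 0.0)
    sem = sd / np.sqrt(n)
    ci = stats.t.interval(0.95, df, loc=mean, scale=sem)
    wilcoxon_p = None
    if not normal:
        warnings.warn("normality rejected; t-test reported with Wilcoxon fallback")
        try:
            wilcoxon_p = float(stats.wilcoxon(x).pvalue)
        except Exception:
            wilcoxon_p = float("nan")
    return CohortStats(
        n=n, mean=mean, ci95=(float(ci[0]), float(ci[1])),
        t=float(res.statistic), df=df, p=float(res.pvalue),
        lilliefors_p=float(lf_p), shapiro_p=float(sw_p), normal=normal,
        wilcoxon_p=wilcoxon_p,
    )


def timecourse_significance(
    traces: np.ndarray, alpha: float = 0.05, sustain_bins: int = 3
) -> dict:
    """Per-bin one-sample t-test of normalised session traces against zero.

    ``traces`` is (n_sessions, n_bins) on a common grid.  Tests are
    uncorrected at ``alpha``.  Bins where every session is exactly zero
    are non-significant; zero-variance bins with a nonzero common value
    count as significant.  The sustained-significance onset is the first
    bin starting a run of at least ``sustain_bins`` significant bins.
    """
    traces = np.asarray(traces, dtype=np.float64)
    if traces.ndim != 2 or traces.shape[0] < 3:
        raise InsufficientDataError("need >= 3 sessions on a common grid")
    n_bins = traces.shape[1]
    pvals = np.ones(n_bins)
    for j in range(n_bins):
        col = traces[:, j]
        if np.std(col, ddof=1) == 0.0:
            pvals[j] = 1.0 if col[0] == 0.0 else 0.0
        else:
            pvals[j] = stats.ttest_1samp(col, 0.0).pvalue
    mask = pvals < alpha
    onset = None
    run = 0
    for j in range(n_bins):
        run = run + 1 if mask[j] else 0
        if run >= sustain_bins:
            onset = j - sustain_bins + 1
            break
    return {"significant": mask, "pvalues": pvals, "onset_bin": onset}


def zone_length_sensitivity(
    sessions: list[tuple[Trajectory, SessionLayout]],
    depths_mm,
) -> np.ndarray:
    """Session PIs recomputed over a sweep of speaker-zone depths.

    Returns a (n_sessions, n_depths) matrix.  Depths exceeding the arm
    length are clipped with a warning (inside ``SessionLayout.zones``).
    """
    depths = np.asarray(depths_mm, dtype=np.float64)
    if np.any(depths <= 0):
        raise InvalidParameterError("zone depths must be positive")
    out = np.empty((len(sessions), depths.size))
    for i, (traj, layout) in enumerate(sessions):
        for j, depth in enumerate(depths):
            trials = trial_results(traj, layout, zone_depth_mm=float(depth))
            pis = np.array([tr.preference_index for tr in trials])
            out[i, j] = np.nanmedian(pis)
    return out
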