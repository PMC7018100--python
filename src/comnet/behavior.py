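"""Mouse-cursor trajectory processing and synthetic trajectory generation.

Implements the trajectory-based behavioural rules of the mouse-tracking
paradigm on a 1920 x 1080 screen (origin top-left, y increasing
downward):

* change-of-mind labelling — a trial is a change-of-mind when the
  cursor deviates from the implicit vertical centre line toward the
  unchosen target by more than 100 px, unless that crossing happens
  while the cursor is still in the bottom 10% of the response area
  (early erratic movement); trials with more than one change are
  flagged for exclusion;
* response-onset timing — the onset of the first movement segment whose
  cumulative path length exceeds 100 px; response time is onset minus
  stimulus offset and may be negative;
* a minimum-jerk synthetic trajectory generator emitting ground-truth
  labels, so both rules are testable without the original recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScreenGeometry",
    "CursorTrajectory",
    "BehavioralLabel",
    "label_change_of_mind",
    "response_onset_time",
    "generate_synthetic_trajectory",
    "summarize_behaviour",
    "write_trajectories",
    "read_trajectories",
]


@dataclass
class ScreenGeometry:
    """Screen layout of the mouse-tracking task.

    The response area spans from the target row down to the start
    button; its lowest ``bottom_band_fraction`` (in screen coordinates,
    the region of largest y) is the exclusion band for early erratic
    movements.
    """

    width: float = 1920.0
    height: float = 1080.0
    target_offset_px: float = 760.0
    target_y: float = 120.0
    target_radius: float = 90.0
    start_x: float = 960.0
    start_y: float = 1000.0
    com_threshold_px: float = 100.0
    bottom_band_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.target_y < self.start_y <= self.height):
            raise ValueError("response area must lie within the screen")
        if self.centre_x - self.target_offset_px < 0:
            raise ValueError("targets must lie within the screen")

    @property
    def centre_x(self) -> float:
        return self.width / 2.0

    @property
    def band_y(self) -> float:
        """y above which (greater y = lower on screen) crossings are ignored."""
        extent = self.start_y - self.target_y
        return self.start_y - self.bottom_band_fraction * extent

    def target_position(self, side: str) -> tuple[float, float]:
        if side == "left":
            return self.centre_x - self.target_offset_px, self.target_y
        if side == "right":
            return self.centre_x + self.target_offset_px, self.target_y
        raise ValueError("side must be 'left' or 'right'")


@dataclass
class CursorTrajectory:
    """Timestamped cursor samples for one trial.

    Timestamps are ms from stimulus onset; sampling is 60 Hz during the
    stimulus and 100 Hz on the response screen, so intervals are not
    uniform — all processing is timestamp-based.
    """

    trial_id: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    stimulus_offset: float
    chosen_side: str
    correct_side: str
    coherence: float = 0.0
    ground_truth: "BehavioralLabel | None" = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) < 2:
            raise ValueError("trajectory needs at least two samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")


@dataclass
class BehavioralLabel:
    """Trajectory-derived labels for one trial."""

    is_com: bool
    n_com: int
    excluded_multi_com: bool
    response_onset_time: float | None = None
    response_time: float | None = None


def label_change_of_mind(traj: CursorTrajectory,
                         geom: ScreenGeometry | None = None) -> BehavioralLabel:
    """Apply the 100 px centre-line rule to label changes-of-mind.

    Dominance episodes are maximal runs of samples more than
    ``com_threshold_px`` from the vertical centre line, with samples in
    the bottom 10% of the response area discarded first.  ``n_com`` is
    the number of side alternations between successive episodes (an
    excursion to the unchosen side and back counts once; repeated
    same-side excursions do not accumulate).
    """
    geom = geom or ScreenGeometry()
    tx, ty = geom.target_position(traj.chosen_side)
    end = np.hypot(traj.x[-1] - tx, traj.y[-1] - ty)
    if end > geom.target_radius:
        raise ValueError(
            f"trajectory ends {end:.0f} px from the chosen target; "
            "cannot label an unfinished trial")

    above_band = traj.y < geom.band_y
    dev = traj.x[above_band] - geom.centre_x
    sides = np.sign(dev) * (np.abs(dev) > geom.com_threshold_px)
    episodes = sides[sides != 0]
    if episodes.size:
        episodes = episodes[np.r_[True, np.diff(episodes) != 0]]
    n_com = max(0, episodes.size - 1)
    return BehavioralLabel(
        is_com=n_com >= 1,
        n_com=int(n_com),
        excluded_multi_com=n_com > 1,
    )


#: Speed (px/ms) below which a sample counts as stationary, and the
#: minimum stationary duration (ms) that delimits movement segments.
SPEED_THRESHOLD_PX_MS = 0.05
STATIONARY_MIN_MS = 50.0
ONSET_DISPLACEMENT_PX = 100.0


def response_onset_time(traj: CursorTrajectory,
                        speed_threshold: float = SPEED_THRESHOLD_PX_MS,
                        stationary_min: float = STATIONARY_MIN_MS
                        ) -> tuple[float, float]:
    """Response onset and response time from a cursor trajectory.

    Movement segments are maximal runs of inter-sample intervals with
    speed >= ``speed_threshold``, delimited by stationary periods of at
    least ``stationary_min`` ms.  The onset is the start time of the
    first segment whose cumulative path length exceeds 100 px; small
    movements (hand tremor) below that displacement never set the
    onset.  Response time = onset - stimulus offset (negative when the
    movement began before offset).
    """
    dt = np.diff(traj.t)
    step = np.hypot(np.diff(traj.x), np.diff(traj.y))
    moving = step / dt >= speed_threshold

    # merge movement runs separated by stationary gaps shorter than the
    # minimum: such pauses do not end a movement segment
    segments = []  # (first_interval, last_interval) inclusive
    i = 0
    n = len(moving)
    while i < n:
        if not moving[i]:
            i += 1
            continue
        j = i
        while j + 1 < n:
            if moving[j + 1]:
                j += 1
                continue
            k = j + 1
            while k < n and not moving[k]:
                k += 1
            gap = traj.t[k] - traj.t[j + 1]
            if k < n and gap < stationary_min:
                j = k
            else:
                break
        segments.append((i, j))
        i = j + 1

    for a, b in segments:
        if step[a:b + 1].sum() > ONSET_DISPLACEMENT_PX:
            onset = float(traj.t[a])
            return onset, onset - traj.stimulus_offset
    raise ValueError("no movement segment exceeds 100 px; onset undefined")


# ---------------------------------------------------------------------------
# synthetic trajectory generation


def _min_jerk(p0, p1, n):
    """Minimum-jerk path from p0 to p1 sampled at n points (excluding p0)."""
    tau = np.linspace(0.0, 1.0, n + 1)[1:]
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    return p0 + np.outer(s, np.asarray(p1) - np.asarray(p0))


TRAJECTORY_KINDS = ("direct", "com", "multi_com", "early_start", "tremor")


def generate_synthetic_trajectory(kind: str, rng, trial_id: int = 0,
                                  geom: ScreenGeometry | None = None,
                                  coherence: float = 0.0,
                                  chosen_side: str | None = None,
                                  correct_side: str | None = None,
                                  stimulus_offset: float = 800.0,
                                  jitter_sd: float = 0.0
                                  ) -> CursorTrajectory:
    """Emit one synthetic cursor trajectory with its ground-truth label.

    Reaches are minimum-jerk legs between via-points; the cursor is
    sampled at 60 Hz before ``stimulus_offset`` and 100 Hz after, with
    optional additive Gaussian jitter.  ``kind`` selects the scripted
    behaviour: a straight reach, a single or double change-of-mind, an
    early (pre-offset) movement start, or tremor before a straight
    reach.
    """
    if kind not in TRAJECTORY_KINDS:
        raise ValueError(f"unknown kind {kind!r}")
    geom = geom or ScreenGeometry()
    rng = np.random.default_rng(rng)
    chosen = chosen_side or ("left" if rng.random() < 0.5 else "right")
    correct = correct_side or ("left" if rng.random() < 0.5 else "right")
    other = "left" if chosen == "right" else "right"
    start = np.array([geom.start_x, geom.start_y])
    target = np.array(geom.target_position(chosen))
    sgn_opp = -1.0 if chosen == "right" else 1.0  # x-direction of unchosen side

    # onset on the post-offset 10 ms grid (or pre-offset 60 Hz grid)
    if kind == "early_start":
        onset = stimulus_offset - (1000.0 / 60.0) * rng.integers(6, 12)
    else:
        onset = stimulus_offset + 10.0 * rng.integers(10, 40)

    mid_y = (geom.target_y + geom.start_y) / 2.0
    excurs = geom.com_threshold_px + 120.0 + 60.0 * rng.random()
    legs: list[tuple[np.ndarray, float]] = []  # (via point, duration ms)
    if kind in ("direct", "tremor", "early_start"):
        legs = [(target, 600.0)]
        n_com = 0
    elif kind == "com":
        via = np.array([geom.centre_x + sgn_opp * excurs, mid_y])
        legs = [(via, 450.0), (target, 450.0)]
        n_com = 1
    else:  # multi_com: chosen-side excursion, opposite, back to target
        via1 = np.array([geom.centre_x - sgn_opp * excurs, mid_y + 150.0])
        via2 = np.array([geom.centre_x + sgn_opp * excurs, mid_y - 100.0])
        legs = [(via1, 350.0), (via2, 400.0), (target, 350.0)]
        n_com = 2

    # stimulus phase: stationary at the start button, 60 Hz
    t_pre = np.arange(0.0, stimulus_offset, 1000.0 / 60.0)
    t_post = np.arange(stimulus_offset, stimulus_offset + 4000.0, 10.0)
    t_all = np.concatenate([t_pre, t_post])

    pos = np.tile(start, (len(t_all), 1))
    if kind == "tremor":
        # sub-100 px wiggle well before onset: must not set the onset
        wob = (t_all > 200.0) & (t_all < 320.0)
        pos[wob, 0] += 12.0 * np.sin(np.linspace(0, 2 * np.pi, wob.sum()))

    cursor = start.copy()
    t_leg = onset
    for via, dur in legs:
        in_leg = (t_all > t_leg) & (t_all <= t_leg + dur)
        if in_leg.any():
            pos[in_leg] = _min_jerk(cursor, via, in_leg.sum())
        pos[t_all > t_leg + dur] = via
        cursor = via
        t_leg += dur
    end_idx = np.searchsorted(t_all, t_leg + 100.0)
    t_all = t_all[:end_idx]
    pos = pos[:end_idx]

    # ground-truth onset: the first sampled interval of the reach whose
    # speed reaches the stationary threshold (a minimum-jerk reach
    # accelerates from zero, so the nominal leg start itself is not yet
    # a detectable movement); the tremor wiggle is not part of the reach
    speed = np.hypot(np.diff(pos[:, 0]), np.diff(pos[:, 1])) / np.diff(t_all)
    cand = np.nonzero((t_all[:-1] >= onset - 1e-9)
                      & (speed >= SPEED_THRESHOLD_PX_MS))[0]
    true_onset = float(t_all[cand[0]]) if cand.size else onset

    if jitter_sd > 0:
        pos = pos + rng.normal(0.0, jitter_sd, pos.shape)
        pos[:, 0] = np.clip(pos[:, 0], 0, geom.width)
        pos[:, 1] = np.clip(pos[:, 1], 0, geom.height)
    # the final sample must sit on the target for the label precondition
    pos[-1] = target

    truth = BehavioralLabel(
        is_com=n_com >= 1, n_com=n_com, excluded_multi_com=n_com > 1,
        response_onset_time=true_onset,
        response_time=true_onset - stimulus_offset)
    return CursorTrajectory(
        trial_id=trial_id, t=t_all, x=pos[:, 0], y=pos[:, 1],
        stimulus_offset=stimulus_offset, chosen_side=chosen,
        correct_side=correct, coherence=coherence, ground_truth=truth)


# ---------------------------------------------------------------------------
# summaries and file IO


def summarize_behaviour(trials: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Summary tables from labelled behavioural trials.

    ``trials`` needs columns ``coherence``, ``chosen_side``,
    ``correct_side``, ``is_com``, ``n_com``, ``response_time``.  The
    output tables use the same schemas as the simulation analyses
    (:func:`comnet.analysis.psychometric_by_com` and
    :func:`comnet.analysis.com_probability_by`), so model and data are
    directly comparable.
    """
    from . import analysis

    t = pd.DataFrame({
        "coherence": trials["coherence"],
        "correct": (trials["chosen_side"] == trials["correct_side"]).astype(float),
        "is_com": trials["is_com"].astype(bool),
        "com_excluded": trials["n_com"] > 1,
        "non_decision": False,
        "response_time": trials["response_time"],
    })
    return {
        "com_probability": analysis.com_probability_by(t, "coherence"),
        "com_overall": float(
            t.loc[~t.com_excluded, "is_com"].mean()) if len(t) else float("nan"),
        "accuracy": analysis.psychometric_by_com(t),
    }


_TRAJ_COLUMNS = ["trial_id", "t_ms", "x_px", "y_px", "stimulus_offset_ms",
                 "chosen_side", "correct_side", "coherence"]


def write_trajectories(trajectories, path) -> None:
    """Write trajectories to a delimited file, one row per sample."""
    rows = []
    for tr in trajectories:
        rows.append(pd.DataFrame({
            "trial_id": tr.trial_id, "t_ms": tr.t, "x_px": tr.x,
            "y_px": tr.y, "stimulus_offset_ms": tr.stimulus_offset,
            "chosen_side": tr.chosen_side, "correct_side": tr.correct_side,
            "coherence": tr.coherence}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_trajectories(path) -> list[CursorTrajectory]:
    """Read a delimited trajectory file written by :func:`write_trajectories`."""
    df = pd.read_csv(path)
    missing = set(_TRAJ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory file missing columns: {sorted(missing)}")
    out = []
    for tid, grp in df.groupby("trial_id", sort=True):
        out.append(CursorTrajectory(
            trial_id=int(tid), t=grp["t_ms"].to_numpy(),
            x=grp["x_px"].to_numpy(), y=grp["y_px"].to_numpy(),
            stimulus_offset=float(grp["stimulus_offset_ms"].iloc[0]),
            chosen_side=str(grp["chosen_side"].iloc[0]),
            correct_side=str(grp["correct_side"].iloc[0]),
            coherence=float(grp["coherence"].iloc[0])))
    return out
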