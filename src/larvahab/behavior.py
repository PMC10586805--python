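"""Behavior labels, trajectories, and the four-way response classifier.

Crawling larvae respond to a vibration pulse with one of four actions, in
ascending order of avoidance strength: continuation (CONT), pause (PAUSE),
turn (TURN), reverse crawl (REV).  The classifier works on 2D trajectories:

* a *stop* is flagged when the (smoothed) crawl speed drops below a fraction
  of the larva's median run speed for a sustained interval;
* the event is a *reversal* if, during or just after the stop, the
  head-orientation vector and the velocity vector point in opposing
  directions (negative dot product) for a sustained interval;
* otherwise the heading change between the pre-stop and post-resumption runs
  decides: below 30 degrees is a *pause*, above is a *turn*;
* with no stop at all, the larva *continued*.

Each larva is then assigned one label per stimulus pulse based on the first
seconds after pulse onset: an action already in progress at onset counts as
the response, unless forward crawling transitions into a new action inside
the window, in which case the new action is assigned.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .stimulus import StimulusProtocol

__all__ = [
    "BehaviorLabel",
    "ResponseRecord",
    "Trajectory",
    "ClassifierConfig",
    "detect_stops",
    "classify_event",
    "state_intervals",
    "assign_pulse_response",
    "classify_trajectory",
    "read_trajectories_csv",
    "write_trajectories_csv",
    "read_records_csv",
    "write_records_csv",
]


class BehaviorLabel(str, enum.Enum):
    """One response per larva per pulse.  STOP is derived, never stored."""

    CONT = "CONT"
    PAUSE = "PAUSE"
    TURN = "TURN"
    REV = "REV"

    @property
    def is_stop(self) -> bool:
        """True for any avoidance behavior (pause, turn, or reversal)."""
        return self is not BehaviorLabel.CONT


#: Canonical label ordering used by transition matrices and fraction tables.
LABEL_ORDER = (
    BehaviorLabel.CONT,
    BehaviorLabel.PAUSE,
    BehaviorLabel.TURN,
    BehaviorLabel.REV,
)


@dataclass(frozen=True)
class ResponseRecord:
    """A single (larva, pulse) response.

    ``label is None`` marks a missing/unresolved window, which is excluded
    from the active count N in every downstream fraction.
    """

    larva_id: str
    pulse_n: int
    label: Optional[BehaviorLabel]
    window: Tuple[float, float] = (0.0, 0.0)


@dataclass
class Trajectory:
    """Per-larva kinematic time series.

    Attributes
    ----------
    larva_id : identifier.
    t : frame times (s), strictly increasing.
    x, y : position (mm).
    head : (n, 2) unit head-orientation vectors.
    collision : optional boolean per-frame collision flag; windows containing
        a flagged frame are excluded from response assignment.
    """

    larva_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    head: np.ndarray
    collision: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.head = np.asarray(self.head, dtype=float)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.head) == n):
            raise ValueError("t, x, y, head must have equal length")
        if n >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("frame times must be strictly increasing")
        if self.head.ndim != 2 or self.head.shape[1] != 2:
            raise ValueError("head must be an (n, 2) array")
        norms = np.linalg.norm(self.head, axis=1)
        if np.any(norms == 0):
            raise ValueError("head vectors must be non-zero")
        self.head = self.head / norms[:, None]

    def __len__(self) -> int:
        return len(self.t)

    def velocity(self) -> np.ndarray:
        """(n, 2) velocity by central differences (one-sided at the ends)."""
        v = np.empty((len(self.t), 2))
        v[:, 0] = np.gradient(self.x, self.t)
        v[:, 1] = np.gradient(self.y, self.t)
        return v

    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.velocity(), axis=1)


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunable thresholds of the classifier.

    speed_frac
        Stop threshold as a fraction of the larva's median (smoothed) speed;
        per-larva normalization is robust to body-size speed variation.
    min_stop_duration
        Minimum sustained low-speed interval flagged as a stop (s).
    theta_threshold_deg
        Pause/turn boundary on the heading change (degrees); exactly at the
        boundary ties toward the stronger behavior (turn).
    smooth_frames
        Centered moving-average window applied to speed before thresholding.
    rev_min_duration
        Minimum sustained negative head.velocity dot product to call a
        reversal (s); rejects single-frame noise.
    rev_search_after
        How far past the end of a stop to look for reverse motion (s).
    heading_window
        Averaging window for pre-stop / post-resumption headings (s).
    heading_skip_frames
        Frames skipped right at the stop edges before heading averaging, so
        blended central-difference frames do not contaminate the mean.
    response_window
        Length of the per-pulse response window (s).
    """

    speed_frac: float = 0.2
    speed_threshold: Optional[float] = None  # absolute mm/s; overrides speed_frac
    min_stop_duration: float = 0.5
    theta_threshold_deg: float = 30.0
    smooth_frames: int = 5
    rev_min_duration: float = 0.5
    rev_search_after: float = 2.0
    heading_window: float = 1.0
    heading_skip_frames: int = 2
    response_window: float = 3.0


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.concatenate([np.full(pad, x[0]), x, np.full(window - 1 - pad, x[-1])])
    return np.convolve(padded, kernel, mode="valid")


def _stop_threshold(speed: np.ndarray, config: ClassifierConfig) -> float:
    if config.speed_threshold is not None:
        return config.speed_threshold
    return config.speed_frac * float(np.median(speed))


def detect_stops(
    traj: Trajectory,
    config: ClassifierConfig = ClassifierConfig(),
    speed_threshold: Optional[float] = None,
    min_duration: Optional[float] = None,
) -> List[Tuple[float, float]]:
    """Maximal intervals where smoothed speed stays below threshold.

    By default the threshold is ``speed_frac`` times the larva's median
    smoothed speed (per-larva normalization); an absolute threshold in mm/s
    can be given instead.  Intervals shorter than the minimum duration are
    discarded.  Returns ordered, non-overlapping ``(t_start, t_end)``
    tuples.
    """
    if len(traj) < 3:
        raise ValueError("trajectory must have at least 3 frames")
    if speed_threshold is not None or min_duration is not None:
        config = replace(
            config,
            speed_threshold=(
                speed_threshold if speed_threshold is not None else config.speed_threshold
            ),
            min_stop_duration=(
                min_duration if min_duration is not None else config.min_stop_duration
            ),
        )
    speed = _smooth(traj.speed(), config.smooth_frames)
    threshold = _stop_threshold(speed, config)
    below = speed < threshold
    stops: List[Tuple[float, float]] = []
    i = 0
    n = len(below)
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            if traj.t[j] - traj.t[i] >= config.min_stop_duration:
                stops.append((float(traj.t[i]), float(traj.t[j])))
            i = j + 1
        else:
            i += 1
    return stops


def _reverse_mask(traj: Trajectory) -> np.ndarray:
    """Frames where the head vector opposes the velocity vector."""
    v = traj.velocity()
    dot = np.einsum("ij,ij->i", traj.head, v)
    return dot < 0


def _sustained_true(t: np.ndarray, mask: np.ndarray, min_duration: float):
    """First interval of `mask` sustained for at least min_duration, else None."""
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            if t[j] - t[i] >= min_duration:
                return float(t[i]), float(t[j])
            i = j + 1
        else:
            i += 1
    return None


def _mean_heading(
    traj: Trajectory, t0: float, t1: float, moving: np.ndarray
) -> Optional[np.ndarray]:
    """Mean unit-velocity direction over moving frames in [t0, t1)."""
    sel = (traj.t >= t0) & (traj.t < t1) & moving
    if not np.any(sel):
        return None
    v = traj.velocity()[sel]
    norms = np.linalg.norm(v, axis=1)
    units = v[norms > 0] / norms[norms > 0, None]
    if len(units) == 0:
        return None
    mean = units.mean(axis=0)
    norm = np.linalg.norm(mean)
    return mean / norm if norm > 0 else None


def classify_event(
    traj: Trajectory,
    stop: Tuple[float, float],
    config: ClassifierConfig = ClassifierConfig(),
) -> Optional[BehaviorLabel]:
    """Label a stop interval as PAUSE, TURN, or REV.

    Returns ``None`` (unresolved) when the stop runs off the end of the
    record with no resumption, or when headings cannot be measured.
    """
    t0, t1 = stop
    speed = _smooth(traj.speed(), config.smooth_frames)
    moving = speed >= _stop_threshold(speed, config)
    dt_frame = float(np.median(np.diff(traj.t))) if len(traj) > 1 else 0.0

    # reversal: sustained negative head.velocity during/just after the stop
    search = (traj.t >= t0) & (traj.t <= t1 + config.rev_search_after)
    rev = _reverse_mask(traj) & search
    if _sustained_true(traj.t, rev, config.rev_min_duration) is not None:
        return BehaviorLabel.REV

    skip = config.heading_skip_frames * dt_frame
    pre = _mean_heading(traj, t0 - config.heading_window - skip, t0 - skip, moving)
    post = _mean_heading(traj, t1 + skip, t1 + skip + config.heading_window, moving)
    if pre is None or post is None:
        return None  # unresolved: no resumption (or no run before the stop)
    cos = float(np.clip(np.dot(pre, post), -1.0, 1.0))
    dtheta = np.degrees(np.arccos(cos))
    if dtheta >= config.theta_threshold_deg:  # tie at threshold -> stronger behavior
        return BehaviorLabel.TURN
    return BehaviorLabel.PAUSE


def _events(traj: Trajectory, config: ClassifierConfig):
    """All labelled events as (t_start, t_end, label).

    A reversal's interval is extended to cover the sustained backward-motion
    span, so that a pulse landing mid-reversal sees an ongoing reversal.
    """
    out = []
    rev_mask = _reverse_mask(traj)
    for stop in detect_stops(traj, config):
        label = classify_event(traj, stop, config)
        t0, t1 = stop
        if label is BehaviorLabel.REV:
            search = (traj.t >= t0) & (traj.t <= t1 + config.rev_search_after)
            span = _sustained_true(traj.t, rev_mask & search, config.rev_min_duration)
            if span is not None:
                t1 = max(t1, span[1])
        out.append((t0, t1, label))
    return out


def assign_pulse_response(
    traj: Trajectory,
    protocol: StimulusProtocol,
    pulse_n: int,
    config: ClassifierConfig = ClassifierConfig(),
) -> ResponseRecord:
    """One response label for pulse ``pulse_n``.

    Mid-action rule: an event ongoing at pulse onset counts as the response;
    a larva crawling forward at onset that starts a new event inside the
    window is assigned that new action; otherwise CONT.  Windows the
    trajectory does not span (or containing collision frames) yield a
    missing record (``label=None``).
    """
    if pulse_n >= protocol.n_pulses:
        raise ValueError(f"pulse_n={pulse_n} out of range for protocol")
    onset = float(protocol.pulse_onsets()[pulse_n])
    window = (onset, onset + config.response_window)
    if traj.t[0] > onset or traj.t[-1] < window[1]:
        return ResponseRecord(traj.larva_id, pulse_n, None, window)
    if traj.collision is not None:
        in_window = (traj.t >= window[0]) & (traj.t <= window[1])
        if np.any(np.asarray(traj.collision, dtype=bool) & in_window):
            return ResponseRecord(traj.larva_id, pulse_n, None, window)

    ongoing = None
    first_new = None
    for t0, t1, label in _events(traj, config):
        if label is None:
            continue
        if t0 <= onset <= t1:
            ongoing = label
            break
        if onset < t0 <= window[1] and first_new is None:
            first_new = label
    label = ongoing if ongoing is not None else first_new
    if label is None:
        label = BehaviorLabel.CONT
    return ResponseRecord(traj.larva_id, pulse_n, label, window)


def classify_trajectory(
    traj: Trajectory,
    protocol: StimulusProtocol,
    config: ClassifierConfig = ClassifierConfig(),
) -> List[ResponseRecord]:
    """Responses of one larva to every pulse in the protocol."""
    return [
        assign_pulse_response(traj, protocol, n, config)
        for n in range(protocol.n_pulses)
    ]


def state_intervals(
    traj: Trajectory, config: ClassifierConfig = ClassifierConfig()
) -> List[Tuple[float, float, str]]:
    """(t_start, t_end, kind) intervals with kind in {"stop", "rev"}.

    Reversal intervals are the sustained backward-motion spans; stop
    intervals are the low-speed spans.  Used to build instantaneous-state
    fraction time series.
    """
    out = [(t0, t1, "stop") for t0, t1 in detect_stops(traj, config)]
    rev = _reverse_mask(traj)
    t = traj.t
    i = 0
    while i < len(rev):
        if rev[i]:
            j = i
            while j + 1 < len(rev) and rev[j + 1]:
                j += 1
            if t[j] - t[i] >= config.rev_min_duration:
                out.append((float(t[i]), float(t[j]), "rev"))
            i = j + 1
        else:
            i += 1
    return sorted(out)


# -- CSV dialects ------------------------------------------------------------


def write_trajectories_csv(trajectories: Sequence[Trajectory], path) -> None:
    """One row per frame: larva_id, t_s, x_mm, y_mm, head_dx, head_dy."""
    frames = []
    for traj in trajectories:
        df = pd.DataFrame(
            {
                "larva_id": traj.larva_id,
                "t_s": traj.t,
                "x_mm": traj.x,
                "y_mm": traj.y,
                "head_dx": traj.head[:, 0],
                "head_dy": traj.head[:, 1],
            }
        )
        if traj.collision is not None:
            df["collision"] = np.asarray(traj.collision, dtype=int)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def read_trajectories_csv(path) -> List[Trajectory]:
    df = pd.read_csv(path)
    required = {"larva_id", "t_s", "x_mm", "y_mm", "head_dx", "head_dy"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    out = []
    for larva_id, group in df.groupby("larva_id", sort=False):
        collision = None
        if "collision" in group.columns:
            collision = group["collision"].to_numpy().astype(bool)
        out.append(
            Trajectory(
                larva_id=str(larva_id),
                t=group["t_s"].to_numpy(),
                x=group["x_mm"].to_numpy(),
                y=group["y_mm"].to_numpy(),
                head=group[["head_dx", "head_dy"]].to_numpy(),
                collision=collision,
            )
        )
    return out


def write_records_csv(records: Sequence[ResponseRecord], path) -> None:
    """ResponseRecord CSV: larva_id, pulse_n, label (empty label = missing)."""
    pd.DataFrame(
        {
            "larva_id": [r.larva_id for r in records],
            "pulse_n": [r.pulse_n for r in records],
            "label": [r.label.value if r.label is not None else "" for r in records],
        }
    ).to_csv(path, index=False)


def read_records_csv(path) -> List[ResponseRecord]:
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        label = BehaviorLabel(row.label) if row.label else None
        out.append(ResponseRecord(str(row.larva_id), int(row.pulse_n), label))
    return out
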