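"""Running speed, track linearization, trial segmentation and running masks.

Velocity follows the sliding-window definition used for the recordings: the
instantaneous sample-to-sample displacement rate is averaged over a 1 s
window stepped every 0.1 s and interpolated back onto the camera timestamps.
Only periods with speed >= 2 cm/s ("running") enter any spatial analysis.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    CCW,
    CW,
    DirectionSchedule,
    PositionTrace,
    TrackGeometry,
    direction_name,
    wrapped_diff,
)


@dataclass
class VelocitySeries:
    timestamps: np.ndarray
    speed: np.ndarray  # cm/s, NaN where undefined


@dataclass
class LinearizedTrace:
    """Per-sample linearized position with trial/epoch/direction labels.

    ``direction`` is +1 (CW, increasing arc), -1 (CCW) or 0 (undetermined);
    ``trial_index`` is -1 outside any trial; ``epoch_index`` counts blocks of
    ``trials_per_epoch`` same-direction trials (-1 outside trials).
    """

    timestamps: np.ndarray
    lin_pos: np.ndarray
    direction: np.ndarray
    trial_index: np.ndarray
    epoch_index: np.ndarray
    running: np.ndarray
    track: TrackGeometry
    trial_table: pd.DataFrame | None = None
    session_valid: bool | None = None


def compute_velocity(
    position: PositionTrace, window: float = 1.0, step: float = 0.1
) -> VelocitySeries:
    """Windowed running speed on the position timestamps.

    Instantaneous displacement rates between successive defined samples are
    averaged in centered windows of ``window`` seconds placed every ``step``
    seconds; the window means are linearly interpolated back onto the original
    timestamps. Samples whose position is missing get NaN speed.
    """
    t = position.timestamps
    if len(t) < 2:
        return VelocitySeries(t, np.full(len(t), np.nan))
    dx = np.diff(position.x)
    dy = np.diff(position.y)
    dt = np.diff(t)
    inst = np.hypot(dx, dy) / dt  # NaN when either endpoint missing
    mid = t[:-1] + dt / 2.0

    ok = np.isfinite(inst)
    mid_ok = mid[ok]
    inst_ok = inst[ok]
    centers = np.arange(t[0], t[-1] + step / 2, step)
    if len(mid_ok) == 0:
        return VelocitySeries(t, np.full(len(t), np.nan))
    # windowed means via cumulative sums over the sorted midpoints
    csum = np.concatenate([[0.0], np.cumsum(inst_ok)])
    lo = np.searchsorted(mid_ok, centers - window / 2.0, side="left")
    hi = np.searchsorted(mid_ok, centers + window / 2.0, side="right")
    n = hi - lo
    with np.errstate(invalid="ignore"):
        wmean = np.where(n > 0, (csum[hi] - csum[lo]) / np.maximum(n, 1), np.nan)
    defined = n > 0
    if defined.sum() == 0:
        speed = np.full(len(t), np.nan)
    else:
        speed = np.interp(t, centers[defined], wmean[defined])
    speed = np.where(position.missing, np.nan, speed)
    return VelocitySeries(t, speed)


def linearize_position(
    position: PositionTrace, track: TrackGeometry, max_dist_cm: float = 10.0
) -> LinearizedTrace:
    """Project (x, y) onto the track loop and map to arc length.

    Points farther than ``max_dist_cm`` from the path are marked missing, as
    are samples with lost tracking.
    """
    arc, dist = track.xy_to_arc(position.x, position.y)
    off = dist > max_dist_cm
    arc[off] = np.nan
    n = len(arc)
    return LinearizedTrace(
        timestamps=position.timestamps,
        lin_pos=arc,
        direction=np.zeros(n, dtype=np.int8),
        trial_index=np.full(n, -1, dtype=np.int64),
        epoch_index=np.full(n, -1, dtype=np.int64),
        running=np.zeros(n, dtype=bool),
        track=track,
    )


def _unwrap_arc(lin_pos: np.ndarray, period: float) -> np.ndarray:
    """Cumulative signed arc; missing samples carry the last defined value."""
    filled = pd.Series(lin_pos).ffill().bfill().to_numpy()
    d = wrapped_diff(filled[1:], filled[:-1], period)
    return np.concatenate([[filled[0]], filled[0] + np.cumsum(d)])


def infer_schedule(
    lin: LinearizedTrace,
    trials_per_epoch: int = 10,
    reversal_tolerance_cm: float = 20.0,
) -> DirectionSchedule:
    """Infer trial boundaries from reward-zone (0 cm) crossings.

    A trial is one full traversal from the reward zone back to the reward
    zone; a boundary is registered each time the unwrapped arc advances one
    full lap past the previous boundary (hysteresis makes small jitter at the
    reward zone harmless). Trials whose within-trial retracing exceeds
    ``reversal_tolerance_cm`` against the net travel direction are flagged
    invalid.
    """
    period = lin.track.total_length
    u = _unwrap_arc(lin.lin_pos, period)
    t = lin.timestamps
    level = np.round(u[0] / period) * period
    boundaries = [0]
    levels = [level]
    i = 0
    n = len(u)
    while i < n:
        up = np.argmax(u[i:] >= level + period) if np.any(u[i:] >= level + period) else -1
        dn = np.argmax(u[i:] <= level - period) if np.any(u[i:] <= level - period) else -1
        candidates = [c for c in (up, dn) if c >= 0]
        if not candidates:
            break
        j = i + min(candidates)
        level = level + period if (up >= 0 and i + up == j) else level - period
        boundaries.append(j)
        levels.append(level)
        i = j
    rows = []
    for k in range(len(boundaries) - 1):
        a, b = boundaries[k], boundaries[k + 1]
        seg = u[a : b + 1]
        net = seg[-1] - seg[0]
        direction = "CW" if net > 0 else "CCW"
        # retracing against net travel within the trial
        runs = np.diff(seg)
        against = -runs[runs < 0].sum() if net > 0 else runs[runs > 0].sum()
        rows.append(
            dict(
                trial_index=k,
                direction=direction,
                start_time=t[a],
                end_time=t[b],
                clean=bool(against <= reversal_tolerance_cm),
            )
        )
    table = pd.DataFrame(
        rows, columns=["trial_index", "direction", "start_time", "end_time", "clean"]
    )
    return DirectionSchedule(table, trials_per_epoch=trials_per_epoch)


def segment_trials(
    lin: LinearizedTrace,
    schedule: DirectionSchedule | None = None,
    trials_per_epoch: int = 10,
    min_valid_trials: int = 60,
    session_limit_s: float = 1800.0,
) -> LinearizedTrace:
    """Label every sample with trial, direction and epoch; set session validity.

    Epochs group ``trials_per_epoch`` consecutive same-direction trials,
    counted separately per direction. The session is valid iff
    ``min_valid_trials`` trials were completed within ``session_limit_s`` of
    the first trial's start.
    """
    if schedule is None:
        schedule = infer_schedule(lin, trials_per_epoch=trials_per_epoch)
    trials = schedule.trials.reset_index(drop=True)
    t = lin.timestamps
    trial_index = np.full(len(t), -1, dtype=np.int64)
    direction = np.zeros(len(t), dtype=np.int8)
    epoch_index = np.full(len(t), -1, dtype=np.int64)

    per_dir_count = {"CW": 0, "CCW": 0}
    rows = []
    for _, tr in trials.iterrows():
        k = int(tr["trial_index"])
        d = str(tr["direction"])
        epoch = per_dir_count[d] // trials_per_epoch
        per_dir_count[d] += 1
        clean = bool(tr.get("clean", True))
        mask = (t >= tr["start_time"]) & (t < tr["end_time"])
        if clean:
            trial_index[mask] = k
            direction[mask] = CW if d == "CW" else CCW
            epoch_index[mask] = epoch
        rows.append(
            dict(
                trial_index=k,
                direction=d,
                epoch=epoch,
                start=float(tr["start_time"]),
                end=float(tr["end_time"]),
                duration=float(tr["end_time"] - tr["start_time"]),
                valid=clean,
            )
        )
    table = pd.DataFrame(
        rows, columns=["trial_index", "direction", "epoch", "start", "end", "duration", "valid"]
    )
    if len(table) >= min_valid_trials:
        elapsed = table["end"].iloc[min_valid_trials - 1] - table["start"].iloc[0]
        session_valid = bool(elapsed <= session_limit_s)
    else:
        session_valid = False
    return LinearizedTrace(
        timestamps=lin.timestamps,
        lin_pos=lin.lin_pos,
        direction=direction,
        trial_index=trial_index,
        epoch_index=epoch_index,
        running=lin.running,
        track=lin.track,
        trial_table=table,
        session_valid=session_valid,
    )


def running_mask(v: VelocitySeries, threshold: float = 2.0) -> np.ndarray:
    """True where speed >= threshold; missing speed counts as not running."""
    with np.errstate(invalid="ignore"):
        return np.where(np.isnan(v.speed), False, v.speed >= threshold)
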