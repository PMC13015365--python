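"""Shared data model for linearized-track place-cell sessions.

All timestamps are seconds (float64) on a single session clock. Linearized
position lives on [0, total_length) cm with the reward zone at 0 cm; spatial
bins are half-open: bin i covers [i * bin_width, (i + 1) * bin_width).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

CW = 1
CCW = -1

DIRECTION_NAMES = {CW: "CW", CCW: "CCW"}
DIRECTION_CODES = {"CW": CW, "CCW": CCW}


@dataclass(frozen=True)
class TrackGeometry:
    """Rectangular-track geometry and its linearization.

    The track is an outer rectangular loop (the outer path of a figure-8 maze
    with the central arm blocked). Linearized arc length increases in the CW
    travel direction, with the reward zone (front-center of the rectangle) at
    0 cm, the left-arm center at one quarter lap and the right-arm center at
    three quarters.  The defaults give a 264 cm lap, so arm centers fall at
    66 cm and 198 cm.
    """

    width: float = 84.0   # cm, x extent of the loop
    height: float = 48.0  # cm, y extent
    bin_width: float = 4.0

    @property
    def total_length(self) -> float:
        return 2.0 * (self.width + self.height)

    @property
    def n_bins(self) -> int:
        return int(round(self.total_length / self.bin_width))

    @property
    def reward_position(self) -> float:
        return 0.0

    @property
    def left_arm_center(self) -> float:
        return self.total_length / 4.0

    @property
    def right_arm_center(self) -> float:
        return 3.0 * self.total_length / 4.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("track dimensions must be positive")
        n = self.total_length / self.bin_width
        if abs(n - round(n)) > 1e-9:
            raise ValueError("bin_width must divide the track length")

    # -- linearization ------------------------------------------------------
    # Corner sequence starting from the reward zone at (0, -h), walking CW
    # (decreasing x first): reward -> left-front corner -> left arm -> back
    # -> right arm -> reward.

    def _segments(self) -> list[tuple[np.ndarray, np.ndarray]]:
        w, h = self.width / 2.0, self.height / 2.0
        pts = [(0.0, -h), (-w, -h), (-w, h), (w, h), (w, -h), (0.0, -h)]
        return [
            (np.asarray(pts[i], float), np.asarray(pts[i + 1], float))
            for i in range(5)
        ]

    def arc_to_xy(self, arc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map arc length (cm, any real; wrapped mod lap) to (x, y)."""
        s = np.asarray(arc, float) % self.total_length
        x = np.empty_like(s)
        y = np.empty_like(s)
        offset = 0.0
        for a, b in self._segments():
            seg_len = float(np.abs(b - a).sum())
            m = (s >= offset) & (s < offset + seg_len)
            frac = (s[m] - offset) / seg_len
            x[m] = a[0] + frac * (b[0] - a[0])
            y[m] = a[1] + frac * (b[1] - a[1])
            offset += seg_len
        return x, y

    def xy_to_arc(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Project points onto the loop; return (arc length, distance to path).

        NaN inputs give NaN outputs.
        """
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        p = np.stack([x, y], axis=-1)
        best_d = np.full(x.shape, np.inf)
        best_s = np.full(x.shape, np.nan)
        offset = 0.0
        for a, b in self._segments():
            ab = b - a
            seg_len = float(np.abs(ab).sum())
            t = np.clip(((p - a) @ ab) / (seg_len ** 2), 0.0, 1.0)
            proj = a + t[..., None] * ab
            d = np.hypot(p[..., 0] - proj[..., 0], p[..., 1] - proj[..., 1])
            m = d < best_d
            best_d[m] = d[m]
            best_s[m] = offset + t[m] * seg_len
            offset += seg_len
        bad = np.isnan(x) | np.isnan(y)
        best_s[bad] = np.nan
        best_d[bad] = np.nan
        return best_s % self.total_length, best_d


@dataclass
class PositionTrace:
    """Camera position samples at a fixed rate; NaN marks lost tracking."""

    timestamps: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, float)
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        if not (len(self.timestamps) == len(self.x) == len(self.y)):
            raise ValueError("position arrays must have equal length")
        if len(self.timestamps) > 1:
            dt = np.diff(self.timestamps)
            if np.any(dt <= 0):
                i = int(np.argmax(dt <= 0))
                raise ValueError(f"non-monotonic position timestamps at index {i + 1}")
            if np.ptp(dt) > 0.25 * np.median(dt):
                raise ValueError("position timestamps are not uniformly sampled")

    @property
    def sample_period(self) -> float:
        return float(np.median(np.diff(self.timestamps)))

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.x) | np.isnan(self.y)

    @property
    def fraction_missing(self) -> float:
        return float(np.mean(self.missing))


@dataclass
class SpikeTrain:
    unit_id: str
    tetrode_id: str
    spike_times: np.ndarray
    genotype_label: str = "unknown"  # unknown | WT | KO | excluded

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, float)
        if len(self.spike_times):
            d = np.diff(self.spike_times)
            if np.any(d <= 0):
                i = int(np.argmax(d <= 0))
                raise ValueError(
                    f"unit {self.unit_id}: spike times not strictly increasing "
                    f"at index {i + 1}"
                )
            if self.spike_times[0] < 0:
                raise ValueError(f"unit {self.unit_id}: negative spike time")

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)


@dataclass
class LfpChannel:
    tetrode_id: str
    sampling_rate: float
    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    def timestamps(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.sampling_rate

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate


@dataclass
class DirectionSchedule:
    """Known trial boundaries: one row per reward-to-reward traversal."""

    trials: pd.DataFrame  # columns: trial_index, direction (CW/CCW), start_time, end_time
    trials_per_epoch: int = 10

    def __post_init__(self) -> None:
        t = self.trials
        required = {"trial_index", "direction", "start_time", "end_time"}
        if not required.issubset(t.columns):
            raise ValueError(f"schedule missing columns {required - set(t.columns)}")
        if len(t) and (
            np.any(np.diff(t["start_time"].to_numpy()) <= 0)
            or np.any(t["end_time"].to_numpy()[:-1] > t["start_time"].to_numpy()[1:])
        ):
            raise ValueError("schedule trials must be time-ordered and non-overlapping")

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass
class Session:
    """One recording day: sorted units, position, LFP, light pulses, metadata."""

    session_id: str
    units: list[SpikeTrain]
    position: PositionTrace
    lfp: list[LfpChannel]
    stim_onsets: np.ndarray
    track: TrackGeometry = field(default_factory=TrackGeometry)
    schedule: DirectionSchedule | None = None

    def __post_init__(self) -> None:
        self.stim_onsets = np.asarray(self.stim_onsets, float)
        if len(self.stim_onsets) > 1 and np.any(np.diff(self.stim_onsets) <= 0):
            raise ValueError("stim_onsets must be strictly increasing")
        tetrodes = {c.tetrode_id for c in self.lfp}
        for u in self.units:
            if u.tetrode_id not in tetrodes:
                raise ValueError(
                    f"unit {u.unit_id} references unknown tetrode {u.tetrode_id}"
                )

    def lfp_for(self, tetrode_id: str) -> LfpChannel:
        for c in self.lfp:
            if c.tetrode_id == tetrode_id:
                return c
        raise KeyError(tetrode_id)


@dataclass
class AnalysisConfig:
    """All thresholds of the pipeline; defaults are the published values."""

    # behavior
    velocity_window_s: float = 1.0
    velocity_step_s: float = 0.1
    run_speed_cms: float = 2.0
    max_path_dist_cm: float = 10.0
    trials_per_epoch: int = 10
    min_valid_trials: int = 60
    session_limit_s: float = 30.0 * 60.0
    # rate maps
    kernel_weights: tuple = (0.02, 0.10, 0.16, 0.10, 0.02)
    kernel_normalize: bool = True
    mean_rate_cutoff_hz: float = 0.1
    max_rate_cutoff_hz: float = 1.0
    # place fields
    field_low_frac: float = 0.1
    field_high_frac: float = 0.5
    span_fraction: float = 0.5
    align_half_window_bins: int = 15
    # stability
    n_shuffles: int = 100
    min_shift_cm: float = 10.0
    # theta
    theta_band: tuple = (4.0, 12.0)
    filter_order: int = 4
    mvl_profile_bins: int = 10
    mvl_profile_min_spikes: int = 5
    # precession
    shift_step_deg: float = 5.0
    min_precession_spikes: int = 5
    min_theta_cycles: float = 3.0
    precession_alpha: float = 0.05
    # classification
    psth_bin_ms: float = 1.0
    psth_window_s: float = 2.0
    pulse_dur_ms: float = 10.0
    rate_exclusion_hz: float = 5.0
    opto_threshold: float = 1.0
    opto_epsilon: float = 0.0

    def replace(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)


def direction_name(code: int) -> str:
    return DIRECTION_NAMES[int(code)]


def wrapped_diff(a: np.ndarray, b: np.ndarray, period: float) -> np.ndarray:
    """Signed circular difference a - b mapped to [-period/2, period/2)."""
    return (np.asarray(a, float) - np.asarray(b, float) + period / 2) % period - period / 2
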