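"""Per-trial linearized rate maps, smoothing, trial averaging and rate cutoffs.

A raw map divides running-period spike counts by running occupancy in 4 cm
bins; bins the animal never occupied (while running) in a trial are missing
(NaN). Maps are smoothed with a five-point symmetric kernel (default weights
[0.02, 0.10, 0.16, 0.10, 0.02], renormalized to unit sum so rates are
conserved) that wraps across the 0 cm reward boundary, since the track is a
closed loop.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .behavior import LinearizedTrace
from .types import SpikeTrain, TrackGeometry, direction_name


@dataclass
class SmoothingKernel:
    weights: np.ndarray = None
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.weights is None:
            self.weights = np.array([0.02, 0.10, 0.16, 0.10, 0.02])
        self.weights = np.asarray(self.weights, float)
        if len(self.weights) % 2 != 1:
            raise ValueError("kernel must have odd length")
        if not np.allclose(self.weights, self.weights[::-1]):
            raise ValueError("kernel must be symmetric")


@dataclass
class TrialRateMap:
    unit_id: str
    direction: str
    trial_index: int
    epoch_index: int
    occupancy_s: np.ndarray   # running occupancy per bin (s)
    spike_count: np.ndarray   # running-period spikes per bin
    rate: np.ndarray          # Hz, NaN where occupancy is zero

    @property
    def occupancy_p(self) -> np.ndarray:
        """Occupancy probability p_i over occupied bins (sums to 1)."""
        total = self.occupancy_s.sum()
        if total <= 0:
            return np.full_like(self.occupancy_s, np.nan)
        return self.occupancy_s / total

    @property
    def mean_rate(self) -> float:
        """Overall mean rate lambda = sum_i p_i lambda_i."""
        total = self.occupancy_s.sum()
        if total <= 0:
            return np.nan
        return float(self.spike_count.sum() / total)


def spike_sample_indices(spike_times: np.ndarray, timestamps: np.ndarray) -> np.ndarray:
    """Index of the position sample nearest in time to each spike."""
    idx = np.searchsorted(timestamps, spike_times)
    idx = np.clip(idx, 1, len(timestamps) - 1)
    left = idx - 1
    choose_left = (spike_times - timestamps[left]) <= (timestamps[idx] - spike_times)
    return np.where(choose_left, left, idx)


def build_trial_ratemaps(
    unit: SpikeTrain, lin: LinearizedTrace, track: TrackGeometry
) -> list[TrialRateMap]:
    """One raw rate map per completed trial.

    Spikes are assigned to the linearized bin of the nearest position sample;
    only samples (and hence spikes) with running == True inside a trial
    contribute. Returns maps sorted by trial index.
    """
    n_bins = track.n_bins
    dt = float(np.median(np.diff(lin.timestamps))) if len(lin.timestamps) > 1 else np.nan
    use = lin.running & (lin.trial_index >= 0) & np.isfinite(lin.lin_pos)
    bins = np.full(len(lin.lin_pos), -1, dtype=np.int64)
    bins[use] = np.minimum(
        (lin.lin_pos[use] / track.bin_width).astype(np.int64), n_bins - 1
    )
    trial_ids = np.unique(lin.trial_index[lin.trial_index >= 0])

    # spikes -> nearest sample -> (trial, bin)
    spk_idx = (
        spike_sample_indices(unit.spike_times, lin.timestamps)
        if unit.n_spikes
        else np.empty(0, dtype=np.int64)
    )
    spk_use = use[spk_idx] if unit.n_spikes else np.empty(0, dtype=bool)
    spk_trial = lin.trial_index[spk_idx[spk_use]] if unit.n_spikes else np.empty(0, dtype=np.int64)
    spk_bin = bins[spk_idx[spk_use]] if unit.n_spikes else np.empty(0, dtype=np.int64)

    maps = []
    for k in trial_ids:
        sample_sel = use & (lin.trial_index == k)
        occ = np.bincount(bins[sample_sel], minlength=n_bins).astype(float) * dt
        counts = np.bincount(
            spk_bin[spk_trial == k], minlength=n_bins
        ).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(occ > 0, counts / np.where(occ > 0, occ, 1.0), np.nan)
        d = lin.direction[sample_sel]
        dcode = int(np.sign(d.sum())) or 1
        epoch = int(lin.epoch_index[sample_sel][0]) if sample_sel.any() else -1
        maps.append(
            TrialRateMap(
                unit_id=unit.unit_id,
                direction=direction_name(dcode),
                trial_index=int(k),
                epoch_index=epoch,
                occupancy_s=occ,
                spike_count=counts,
                rate=rate,
            )
        )
    return maps


def smooth_map(rate: np.ndarray, kernel: SmoothingKernel | None = None) -> np.ndarray:
    """Circular masked convolution of a rate vector.

    Missing bins stay missing and are excluded from both numerator and the
    weight sum of their neighbours (partial-kernel renormalization). With
    ``normalize=True`` the kernel acts as a density, conserving the mean of
    fully defined maps exactly.
    """
    if kernel is None:
        kernel = SmoothingKernel()
    rate = np.asarray(rate, float)
    n = len(rate)
    if n < len(kernel.weights):
        raise ValueError("map shorter than kernel")
    w = kernel.weights
    half = len(w) // 2
    defined = np.isfinite(rate)
    filled = np.where(defined, rate, 0.0)
    num = np.zeros(n)
    den = np.zeros(n)
    for j, wj in enumerate(w):
        shift = j - half
        num += wj * np.roll(filled, -shift)
        den += wj * np.roll(defined.astype(float), -shift)
    out = np.full(n, np.nan)
    good = defined & (den > 0)
    if kernel.normalize:
        out[good] = num[good] / den[good]
    else:
        # literal weights: compensate masked mass but keep the literal scale
        out[good] = num[good] * (w.sum() / den[good])
    return out


def trial_average(maps: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Per-bin mean over trials ignoring missing entries.

    A bin is missing in the average only if missing in every trial.
    """
    arr = np.asarray(maps, float)
    if arr.ndim == 1:
        arr = arr[None, :]
    defined = np.isfinite(arr)
    n = defined.sum(axis=0)
    total = np.where(defined, arr, 0.0).sum(axis=0)
    return np.where(n > 0, total / np.maximum(n, 1), np.nan)


def classify_firing_rate(
    avg_map: np.ndarray,
    mean_cutoff_hz: float = 0.1,
    max_cutoff_hz: float = 1.0,
) -> str:
    """"high" iff the trial-averaged map's mean exceeds ``mean_cutoff_hz``
    AND its max exceeds ``max_cutoff_hz``; otherwise "low".

    The control variant of the cutoff (0.5 / 5 Hz) is selected by passing
    those values.
    """
    avg_map = np.asarray(avg_map, float)
    if not np.any(np.isfinite(avg_map)):
        return "low"
    mean_rate = float(np.nanmean(avg_map))
    max_rate = float(np.nanmax(avg_map))
    return "high" if (mean_rate > mean_cutoff_hz and max_rate > max_cutoff_hz) else "low"
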