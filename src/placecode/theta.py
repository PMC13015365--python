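"""Theta-band LFP filtering, spike phase assignment and circular statistics.

The LFP of the tetrode a unit was recorded on is band-pass filtered
(Butterworth, 4-12 Hz, zero-phase forward-backward) and the instantaneous
phase taken from the analytic (Hilbert) signal. The convention follows the
recordings: 0 deg at the theta peak, 180 deg at the trough, phase advancing
through the cycle.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .types import LfpChannel


@dataclass
class CircularSummary:
    mvl: float
    preferred_phase: float  # degrees in [0, 360)
    n: int


def filter_theta(
    lfp: LfpChannel, band: tuple[float, float] = (4.0, 12.0), order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass of the LFP samples."""
    nyq = lfp.sampling_rate / 2.0
    if not (0 < band[0] < band[1] < nyq):
        raise ValueError(f"band {band} outside (0, Nyquist={nyq}) Hz")
    sos = butter(order, band, btype="bandpass", fs=lfp.sampling_rate, output="sos")
    return sosfiltfilt(sos, lfp.samples)


def instantaneous_phase(filtered: np.ndarray, unwrapped: bool = False) -> np.ndarray:
    """Analytic-signal phase in degrees; 0 at local maxima, 180 at minima.

    With ``unwrapped=True`` the phase accumulates monotonically (360 deg per
    cycle), which is what the theta-cycle span criterion needs.
    """
    ang = np.angle(hilbert(np.asarray(filtered, float)))
    if unwrapped:
        return np.degrees(np.unwrap(ang))
    return np.degrees(ang) % 360.0


def spike_phases(
    filtered: np.ndarray,
    sampling_rate: float,
    spike_times: np.ndarray,
    t0: float = 0.0,
    unwrapped: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Theta phase at the LFP sample nearest each spike.

    Returns (phases, in_span) where ``in_span`` flags spikes inside the LFP
    time span; out-of-span spikes get NaN phase.
    """
    spike_times = np.asarray(spike_times, float)
    phase = instantaneous_phase(filtered, unwrapped=unwrapped)
    idx = np.round((spike_times - t0) * sampling_rate).astype(np.int64)
    in_span = (idx >= 0) & (idx < len(phase))
    out = np.full(len(spike_times), np.nan)
    out[in_span] = phase[idx[in_span]]
    return out, in_span


def circular_summary(phases_deg: np.ndarray) -> CircularSummary:
    """Mean vector length and preferred phase of a circular sample."""
    ph = np.asarray(phases_deg, float)
    ph = ph[np.isfinite(ph)]
    if len(ph) == 0:
        return CircularSummary(mvl=np.nan, preferred_phase=np.nan, n=0)
    z = np.exp(1j * np.radians(ph)).mean()
    return CircularSummary(
        mvl=float(np.abs(z)),
        preferred_phase=float(np.degrees(np.angle(z)) % 360.0),
        n=len(ph),
    )


def mvl_field_profile(
    norm_positions: np.ndarray,
    phases_deg: np.ndarray,
    n_pos_bins: int = 10,
    min_spikes: int = 5,
) -> np.ndarray:
    """MVL as a function of normalized field position (0 entrance, 1 exit).

    In-field spikes are binned into ``n_pos_bins`` equal slices of the
    traversal; bins with fewer than ``min_spikes`` phases are NaN.
    """
    pos = np.asarray(norm_positions, float)
    ph = np.asarray(phases_deg, float)
    ok = np.isfinite(pos) & np.isfinite(ph) & (pos >= 0) & (pos <= 1)
    pos, ph = pos[ok], ph[ok]
    bins = np.minimum((pos * n_pos_bins).astype(int), n_pos_bins - 1)
    out = np.full(n_pos_bins, np.nan)
    for b in range(n_pos_bins):
        sel = bins == b
        if sel.sum() >= min_spikes:
            out[b] = circular_summary(ph[sel]).mvl
    return out
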