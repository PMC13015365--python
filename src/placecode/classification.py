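"""Optotag unit classification, PSTHs, ISI histograms and burst indices.

Units are sorted into putative WT / KO / excluded from their response to
10 ms light pulses delivered at 0.5 Hz: spikes are aligned to pulse onset in
2 s trials, binned at 1 ms, and the opto-response is the maximum bin count
during the pulse minus the maximum bin count outside it. Responses > 1
mark ChR2-expressing (KO) units, responses < 1 mark WT units; ambiguous
units and units with a mean rate above 5 Hz (putative interneurons or
overlapping clusters) are excluded.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Psth:
    unit_id: str
    counts: np.ndarray      # spikes per bin summed over pulses
    bin_edges_ms: np.ndarray  # len(counts) + 1, pulse onset at 0
    n_pulses: int
    bin_width_ms: float = 1.0


@dataclass
class OptoCall:
    unit_id: str
    opto_response: float
    call: str       # WT | KO | excluded
    mean_rate: float
    reason: str = ""


def isi_burst_index(
    spike_times: np.ndarray,
    bin_ms: float = 10.0,
    max_isi_ms: float = 500.0,
    burst_cut_ms: float = 10.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """ISI histogram (counts, edges in ms) and burst index.

    ISIs are the differences between each spike and the one after it; the
    burst index is the number of ISIs below ``burst_cut_ms`` normalized by
    the unit's total spike count.
    """
    t = np.asarray(spike_times, float)
    edges = np.arange(0.0, max_isi_ms + bin_ms, bin_ms)
    if len(t) < 2:
        return np.zeros(len(edges) - 1), edges, 0.0
    isis_ms = np.diff(t) * 1000.0
    counts, _ = np.histogram(isis_ms, bins=edges)
    burst_index = float(np.sum(isis_ms < burst_cut_ms) / len(t))
    return counts.astype(float), edges, burst_index


def build_psth(
    spike_times: np.ndarray,
    stim_onsets: np.ndarray,
    unit_id: str = "",
    trial_len_s: float = 2.0,
    bin_ms: float = 1.0,
) -> Psth:
    """Pulse-aligned PSTH; window [-trial_len/2, +trial_len/2) around onset.

    At 0.5 Hz stimulation the 2 s windows tile the session without overlap.
    """
    onsets = np.asarray(stim_onsets, float)
    if len(onsets) == 0:
        raise ValueError("no stimulation pulses: cannot build PSTH")
    t = np.asarray(spike_times, float)
    half = trial_len_s / 2.0
    edges = np.arange(-half * 1000.0, half * 1000.0 + bin_ms, bin_ms)
    counts = np.zeros(len(edges) - 1)
    lo = np.searchsorted(t, onsets - half)
    hi = np.searchsorted(t, onsets + half)
    for o, a, b in zip(onsets, lo, hi):
        rel_ms = (t[a:b] - o) * 1000.0
        c, _ = np.histogram(rel_ms, bins=edges)
        counts += c
    return Psth(
        unit_id=unit_id,
        counts=counts,
        bin_edges_ms=edges,
        n_pulses=len(onsets),
        bin_width_ms=bin_ms,
    )


def opto_response(psth: Psth, pulse_dur_ms: float = 10.0) -> float:
    """Max bin count during the light pulse minus max bin count outside it."""
    centers = (psth.bin_edges_ms[:-1] + psth.bin_edges_ms[1:]) / 2.0
    on = (centers >= 0) & (centers < pulse_dur_ms)
    if not on.any() or on.all():
        raise ValueError("pulse window does not split the PSTH bins")
    max_on = float(psth.counts[on].max())
    max_off = float(psth.counts[~on].max())
    return max_on - max_off


def classify_unit(
    opto_resp: float,
    mean_rate_hz: float,
    unit_id: str = "",
    rate_exclusion_hz: float = 5.0,
    threshold: float = 1.0,
    epsilon: float = 0.0,
) -> OptoCall:
    """WT / KO / excluded call from the opto-response and mean firing rate.

    Excluded if the session mean rate exceeds ``rate_exclusion_hz``
    (interneuron / overlapping-cluster rule) or if the response falls inside
    [threshold - epsilon, threshold + epsilon] (ambiguous). Otherwise KO if
    the response exceeds the threshold, WT below it.
    """
    if mean_rate_hz > rate_exclusion_hz:
        return OptoCall(unit_id, opto_resp, "excluded", mean_rate_hz, "mean_rate")
    if threshold - epsilon <= opto_resp <= threshold + epsilon:
        return OptoCall(unit_id, opto_resp, "excluded", mean_rate_hz, "ambiguous")
    call = "KO" if opto_resp > threshold else "WT"
    return OptoCall(unit_id, opto_resp, call, mean_rate_hz)
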