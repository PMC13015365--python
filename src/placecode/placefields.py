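"""Place-field detection and spatial-tuning statistics.

A place field is a maximal run of contiguous bins (wrapping across the
0 cm reward boundary — the track is a loop) whose rate is strictly above 10%
of the map maximum and which contains at least one bin strictly above 50% of
the maximum. Spatial information (Skaggs, bits/spike) and sparsity use the
occupancy probabilities p_i:

    info     = sum_i p_i (l_i / l) log2(l_i / l)
    sparsity = (sum_i p_i l_i)^2 / sum_i p_i l_i^2

with l_i the bin rate and l = sum_i p_i l_i the overall mean rate.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import wrapped_diff


@dataclass
class PlaceField:
    bins: np.ndarray          # contiguous (mod n_bins) bin indices, traversal order ascending arc
    peak_bin: int
    peak_rate: float
    bin_width: float = 4.0
    unit_id: str = ""
    direction: str = ""
    source: str = "session_average"

    @property
    def size_cm(self) -> float:
        return len(self.bins) * self.bin_width

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def mask(self, n_total: int) -> np.ndarray:
        m = np.zeros(n_total, dtype=bool)
        m[self.bins] = True
        return m


@dataclass
class TuningMetrics:
    spatial_information: float
    sparsity: float
    snr: float
    in_field_rate: float
    out_field_rate: float
    in_field_spike_fraction: float


def detect_place_fields(
    avg_map: np.ndarray,
    low_frac: float = 0.1,
    high_frac: float = 0.5,
    bin_width: float = 4.0,
) -> list[PlaceField]:
    """Threshold-based field detection on a (smoothed) rate map.

    Candidate regions are maximal contiguous runs of bins strictly above
    ``low_frac`` * max; regions lacking a bin strictly above ``high_frac`` *
    max are discarded. Missing (NaN) bins break contiguity. Runs wrap across
    the map boundary; an all-above map yields a single field covering every
    bin. Fields are returned in order of descending peak rate, so the "best
    field" (the one containing the map maximum) is first.
    """
    m = np.asarray(avg_map, float)
    n = len(m)
    finite = np.isfinite(m)
    if not finite.any():
        return []
    mx = np.nanmax(m)
    if mx <= 0:
        return []
    above = finite & (m > low_frac * mx)
    if not above.any():
        return []
    fields: list[PlaceField] = []
    if above.all():
        runs = [np.arange(n)]
    else:
        # rotate so position 0 is not inside a run, then split plain runs
        start = int(np.argmax(~above))
        rot = np.roll(above, -start)
        idx = np.flatnonzero(rot)
        splits = np.flatnonzero(np.diff(idx) > 1) + 1
        runs = [(chunk + start) % n for chunk in np.split(idx, splits)]
    for run in runs:
        rates = m[run]
        if not np.any(rates > high_frac * mx):
            continue
        peak = int(run[int(np.nanargmax(rates))])
        fields.append(
            PlaceField(
                bins=np.asarray(run, dtype=np.int64),
                peak_bin=peak,
                peak_rate=float(m[peak]),
                bin_width=bin_width,
            )
        )
    fields.sort(key=lambda f: -f.peak_rate)
    return fields


def spatial_tuning_metrics(
    rate: np.ndarray, occupancy_s: np.ndarray
) -> tuple[float, float]:
    """(spatial information in bits/spike, sparsity) over defined bins."""
    rate = np.asarray(rate, float)
    occ = np.asarray(occupancy_s, float)
    ok = np.isfinite(rate) & (occ > 0)
    if not ok.any():
        return np.nan, np.nan
    p = occ[ok] / occ[ok].sum()
    lam_i = rate[ok]
    lam = float(np.sum(p * lam_i))
    if lam <= 0:
        return np.nan, np.nan
    ratio = lam_i / lam
    pos = ratio > 0
    info = float(np.sum(p[pos] * ratio[pos] * np.log2(ratio[pos])))
    sparsity = lam ** 2 / float(np.sum(p * lam_i ** 2))
    return info, float(sparsity)


def field_rate_stats(
    fields: list[PlaceField],
    avg_map: np.ndarray,
    occupancy_s: np.ndarray,
    spike_count: np.ndarray,
    occupancy_weighted: bool = True,
) -> TuningMetrics:
    """In/out-of-field rates, SNR and the in-field spike fraction.

    The in/out masks come from the session-average fields; rates are
    occupancy-weighted bin means by default (simple bin means via
    ``occupancy_weighted=False``). SNR = in_rate / out_rate.
    """
    avg_map = np.asarray(avg_map, float)
    occ = np.asarray(occupancy_s, float)
    counts = np.asarray(spike_count, float)
    n = len(avg_map)
    in_mask = np.zeros(n, dtype=bool)
    for f in fields:
        in_mask |= f.mask(n)
    info, sparsity = spatial_tuning_metrics(avg_map, occ)

    def _mean(mask: np.ndarray) -> float:
        ok = mask & np.isfinite(avg_map) & (occ > 0)
        if not ok.any():
            return np.nan
        if occupancy_weighted:
            return float(np.sum(occ[ok] * avg_map[ok]) / occ[ok].sum())
        return float(np.mean(avg_map[ok]))

    in_rate = _mean(in_mask)
    out_rate = _mean(~in_mask)
    snr = in_rate / out_rate if (np.isfinite(out_rate) and out_rate > 0) else np.nan
    total = counts.sum()
    frac = float(counts[in_mask].sum() / total) if total > 0 else np.nan
    return TuningMetrics(
        spatial_information=info,
        sparsity=sparsity,
        snr=snr,
        in_field_rate=in_rate,
        out_field_rate=out_rate,
        in_field_spike_fraction=frac,
    )


def align_fields_to_peak(
    maps: list[np.ndarray],
    peak_bins: list[int],
    half_window_bins: int = 15,
    normalize: bool = False,
    flip: list[bool] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Peak-centred rate profiles and their population mean.

    Row r is ``maps[r]`` extracted wrap-aware over peak ± ``half_window_bins``
    (column ``half_window_bins`` is the peak). ``flip[r]`` reverses the row so
    that columns always read in the direction of travel (set for CCW maps).
    ``normalize`` divides each row by its peak rate. The population mean is a
    per-column mean over defined entries.
    """
    w = half_window_bins
    rows = []
    for r, (m, pk) in enumerate(zip(maps, peak_bins)):
        m = np.asarray(m, float)
        n = len(m)
        cols = (pk + np.arange(-w, w + 1)) % n
        row = m[cols]
        if flip is not None and flip[r]:
            row = row[::-1]
        if normalize:
            peak_val = m[pk]
            row = row / peak_val if peak_val > 0 else np.full_like(row, np.nan)
        rows.append(row)
    mat = np.array(rows) if rows else np.empty((0, 2 * w + 1))
    with np.errstate(invalid="ignore"):
        colmean = np.nanmean(mat, axis=0) if len(mat) else np.full(2 * w + 1, np.nan)
    return mat, colmean


def normalized_field_position(
    lin_pos: np.ndarray, fld: PlaceField, direction: str, total_length: float
) -> np.ndarray:
    """Position within a field on [0, 1]: 0 = entrance, 1 = exit, travel-relative.

    For CW travel (increasing arc) the entrance is the low-arc edge of the
    field; for CCW it is the high-arc edge. Positions outside the field map
    outside [0, 1] and are left to the caller to mask.
    """
    lin_pos = np.asarray(lin_pos, float)
    size = fld.size_cm
    bw = fld.bin_width
    if direction == "CW":
        entrance = fld.bins[0] * bw
        along = (lin_pos - entrance) % total_length
    else:
        entrance = (fld.bins[-1] + 1) * bw
        along = (entrance - lin_pos) % total_length
    return along / size
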