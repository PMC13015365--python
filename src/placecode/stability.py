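"""Across-epoch stability: Pearson correlations, shuffle nulls, peak shifts
and epoch difference maps.

Stability compares trial-averaged maps of successive 10-trial epochs with
the Pearson correlation coefficient (PCC) on pairwise-complete bins. The
null rotates every trial's map by an independent random circular shift of at
least 10 cm (3 bins at 4 cm), re-averages per epoch and re-correlates;
the mean over 100 shuffles is reported per cell.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .placefields import PlaceField, detect_place_fields
from .types import wrapped_diff

EPOCH_PAIRS = [(0, 1), (1, 2), (2, 3)]


@dataclass
class EpochComparison:
    pair: tuple[int, int]
    pcc: float
    n_bins_used: int
    shuffle_pcc_mean: float = np.nan


@dataclass
class PeakShift:
    pair: tuple[int, int]
    shift_bins: float
    shift_class: str  # toward_entrance | stable | toward_exit


def pairwise_complete_pcc(a: np.ndarray, b: np.ndarray, min_bins: int = 3) -> tuple[float, int]:
    """Pearson r on bins defined in both vectors; NaN if fewer than min_bins."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ok = np.isfinite(a) & np.isfinite(b)
    n = int(ok.sum())
    if n < min_bins:
        return np.nan, n
    x, y = a[ok], b[ok]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan, n
    r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    return r, n


def epoch_correlation(epoch_maps: np.ndarray) -> list[EpochComparison]:
    """PCC between each epoch's trial-averaged map and the next epoch's."""
    epoch_maps = np.asarray(epoch_maps, float)
    out = []
    for a, b in EPOCH_PAIRS:
        if a >= len(epoch_maps) or b >= len(epoch_maps):
            continue
        r, n = pairwise_complete_pcc(epoch_maps[a], epoch_maps[b])
        out.append(EpochComparison(pair=(a, b), pcc=r, n_bins_used=n))
    return out


def shuffle_correlation(
    trial_maps: np.ndarray,
    trial_epochs: np.ndarray,
    n_shuffles: int = 100,
    min_shift_bins: int = 3,
    rng: np.random.Generator | None = None,
) -> dict[tuple[int, int], float]:
    """Mean successive-pair PCC over circularly shifted trial maps.

    Each shuffle draws an independent whole-bin rotation per trial with
    magnitude >= ``min_shift_bins`` in either direction, re-averages each
    epoch, and recomputes the successive-epoch PCCs; values are averaged over
    shuffles (NaN comparisons ignored).
    """
    if rng is None:
        rng = np.random.default_rng()
    trial_maps = np.asarray(trial_maps, float)
    trial_epochs = np.asarray(trial_epochs)
    n_trials, n_bins = trial_maps.shape
    allowed = np.arange(min_shift_bins, n_bins - min_shift_bins + 1)
    epochs = np.unique(trial_epochs[trial_epochs >= 0])
    acc: dict[tuple[int, int], list[float]] = {p: [] for p in EPOCH_PAIRS}
    cols = np.arange(n_bins)
    for _ in range(n_shuffles):
        shifts = rng.choice(allowed, size=n_trials)
        rolled = trial_maps[
            np.arange(n_trials)[:, None], (cols[None, :] - shifts[:, None]) % n_bins
        ]
        epoch_maps = np.full((int(epochs.max()) + 1 if len(epochs) else 0, n_bins), np.nan)
        for e in epochs:
            with np.errstate(invalid="ignore"):
                epoch_maps[int(e)] = np.nanmean(rolled[trial_epochs == e], axis=0)
        for comp in epoch_correlation(epoch_maps):
            if np.isfinite(comp.pcc):
                acc[comp.pair].append(comp.pcc)
    return {
        p: (float(np.mean(v)) if v else np.nan) for p, v in acc.items()
    }


def match_field(reference: PlaceField, candidates: list[PlaceField], n_bins: int) -> PlaceField | None:
    """Field with greatest bin overlap with ``reference``; ties -> nearer peak."""
    if not candidates:
        return None
    ref_mask = reference.mask(n_bins)
    best = None
    best_key = None
    for f in candidates:
        overlap = int(np.sum(ref_mask & f.mask(n_bins)))
        peak_dist = abs(
            float(wrapped_diff(f.peak_bin, reference.peak_bin, n_bins))
        )
        key = (-overlap, peak_dist)
        if best is None or key < best_key:
            best, best_key = f, key
    if best is not None and int(np.sum(ref_mask & best.mask(n_bins))) == 0:
        return None
    return best


def peak_shift_classify(
    epoch_maps: np.ndarray,
    direction: str,
    low_frac: float = 0.1,
    high_frac: float = 0.5,
    bin_width: float = 4.0,
) -> list[PeakShift]:
    """Signed peak shifts of the E1-matched field between consecutive epochs.

    The E1 best field is matched in each later epoch by maximal bin overlap.
    The shift is the wrap-aware change of the matched peak bin measured along
    the direction of travel: negative = toward the field entrance (opposite
    travel, the Mehta direction), positive = toward the exit. Shifts in
    (-1, +1) bins inclusive are "stable".
    """
    epoch_maps = np.asarray(epoch_maps, float)
    n_epochs, n_bins = epoch_maps.shape
    fields_per_epoch = [
        detect_place_fields(epoch_maps[e], low_frac, high_frac, bin_width)
        for e in range(n_epochs)
    ]
    if not fields_per_epoch[0]:
        return []
    ref = fields_per_epoch[0][0]  # best E1 field
    matched: list[PlaceField | None] = [ref]
    for e in range(1, n_epochs):
        matched.append(match_field(ref, fields_per_epoch[e], n_bins))
    out = []
    sign = 1.0 if direction == "CW" else -1.0
    for a, b in EPOCH_PAIRS:
        if b >= n_epochs or matched[a] is None or matched[b] is None:
            continue
        raw = float(wrapped_diff(matched[b].peak_bin, matched[a].peak_bin, n_bins))
        shift = sign * raw
        if shift < -1:
            cls = "toward_entrance"
        elif shift > 1:
            cls = "toward_exit"
        else:
            cls = "stable"
        out.append(PeakShift(pair=(a, b), shift_bins=shift, shift_class=cls))
    return out


def difference_maps(epoch_maps: np.ndarray, e1_peak_bin: int) -> np.ndarray:
    """Later-minus-earlier epoch maps, rolled so the E1 peak is column 0.

    Rows correspond to the pairs (E2-E1, E3-E2, E4-E3).
    """
    epoch_maps = np.asarray(epoch_maps, float)
    rows = []
    for a, b in EPOCH_PAIRS:
        if b >= len(epoch_maps):
            continue
        rows.append(np.roll(epoch_maps[b] - epoch_maps[a], -int(e1_peak_bin)))
    return np.array(rows)


def difference_map_order_key(epoch_maps: np.ndarray) -> float:
    """Population-display ordering key: mean E2-E1 change on defined bins."""
    epoch_maps = np.asarray(epoch_maps, float)
    if len(epoch_maps) < 2:
        return np.nan
    d = epoch_maps[1] - epoch_maps[0]
    with np.errstate(invalid="ignore"):
        return float(np.nanmean(d))
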