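"""Phase precession: per-trial circular-shift linear fits, inclusion
criteria, per-neuron aggregation, regressions, shuffles and bootstrap.

The fit linearizes the circular phase axis by exhaustively shifting all
spike phases in 5 deg increments, picking the shift whose Pearson
correlation of (shifted phase) vs (normalized field position) is most
negative, and fitting an ordinary least-squares line at that shift. A trial
enters the per-neuron statistic only with >= 5 in-field spikes, a traversal
spanning >= 3 theta cycles, and a significant fit (p < 0.05); the median
slope across included trials represents the neuron.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm


@dataclass
class PrecessionFit:
    unit_id: str = ""
    direction: str = ""
    trial_index: int = -1
    applied_shift: float = np.nan  # degrees, multiple of the shift step
    slope: float = np.nan          # degrees per unit normalized field position
    intercept: float = np.nan
    r: float = np.nan
    p_value: float = np.nan
    n_spikes: int = 0
    span_cycles: float = np.nan
    included: bool = False
    exclusion_reason: str = ""


@dataclass
class NeuronPrecession:
    unit_id: str
    direction: str
    median_slope: float
    mean_slope: float
    n_included_trials: int
    per_trial_field_size_mean: float = np.nan


def fit_trial_precession(
    phases_deg: np.ndarray,
    norm_positions: np.ndarray,
    shift_step_deg: float = 5.0,
) -> PrecessionFit:
    """Circular-shift search plus OLS fit for one traversal.

    For each shift s in {0, step, ..., 360-step} the phases are rotated to
    (phase + s) mod 360 and the Pearson correlation with position computed;
    the shift giving the most negative correlation wins (ties -> smallest
    shift). Slope/intercept/r/p come from the linear fit at that shift.
    """
    ph = np.asarray(phases_deg, float)
    x = np.asarray(norm_positions, float)
    ok = np.isfinite(ph) & np.isfinite(x)
    ph, x = ph[ok], x[ok]
    n = len(ph)
    fit = PrecessionFit(n_spikes=n)
    if n < 2 or np.ptp(x) == 0:
        fit.exclusion_reason = "degenerate_positions"
        return fit
    shifts = np.arange(0.0, 360.0, shift_step_deg)
    shifted = (ph[None, :] + shifts[:, None]) % 360.0
    xc = x - x.mean()
    sx = np.sqrt(np.mean(xc ** 2))
    yc = shifted - shifted.mean(axis=1, keepdims=True)
    sy = np.sqrt(np.mean(yc ** 2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r_all = (yc @ xc) / n / np.where(sy * sx > 0, sy * sx, np.nan)
    if not np.any(np.isfinite(r_all)):
        fit.exclusion_reason = "degenerate_phases"
        return fit
    best = int(np.nanargmin(r_all))
    res = stats.linregress(x, shifted[best])
    fit.applied_shift = float(shifts[best])
    fit.slope = float(res.slope)
    fit.intercept = float(res.intercept)
    fit.r = float(res.rvalue)
    fit.p_value = float(res.pvalue)
    return fit


def trial_criteria(
    fit: PrecessionFit,
    span_cycles: float,
    min_spikes: int = 5,
    min_cycles: float = 3.0,
    alpha: float = 0.05,
) -> PrecessionFit:
    """Apply the inclusion gate; sets ``included`` and ``exclusion_reason``.

    ``span_cycles`` is the elapsed unwrapped theta phase between the first
    and last in-field spike of the traversal, in cycles.
    """
    fit.span_cycles = float(span_cycles)
    reasons = []
    if fit.n_spikes < min_spikes:
        reasons.append("n_spikes")
    if not (np.isfinite(span_cycles) and span_cycles >= min_cycles):
        reasons.append("theta_span")
    if not (np.isfinite(fit.p_value) and fit.p_value < alpha):
        reasons.append("fit_p")
    fit.included = not reasons
    fit.exclusion_reason = ",".join(reasons)
    return fit


def neuron_precession(
    fits: list[PrecessionFit],
    per_trial_field_sizes: dict[int, float] | None = None,
) -> NeuronPrecession | None:
    """Median (and mean) slope over included trials; None if none included.

    ``per_trial_field_sizes`` maps trial_index -> field size (cm) from
    per-trial field re-detection; it is averaged over the included trials.
    """
    inc = [f for f in fits if f.included]
    if not inc:
        return None
    slopes = np.array([f.slope for f in inc])
    sizes = np.nan
    if per_trial_field_sizes:
        vals = [
            per_trial_field_sizes[f.trial_index]
            for f in inc
            if f.trial_index in per_trial_field_sizes
            and np.isfinite(per_trial_field_sizes[f.trial_index])
        ]
        if vals:
            sizes = float(np.mean(vals))
    return NeuronPrecession(
        unit_id=inc[0].unit_id,
        direction=inc[0].direction,
        median_slope=float(np.median(slopes)),
        mean_slope=float(np.mean(slopes)),
        n_included_trials=len(inc),
        per_trial_field_size_mean=sizes,
    )


def slope_transform(slope: np.ndarray) -> np.ndarray:
    """-log10(-slope), defined for negative slopes only (NaN otherwise)."""
    s = np.asarray(slope, float)
    out = np.full(s.shape, np.nan)
    neg = s < 0
    out[neg] = -np.log10(-s[neg])
    return out


def precession_regressions(neurons: pd.DataFrame) -> dict:
    """Field-size/slope correlation and the genotype regression models.

    ``neurons`` needs columns: unit_id, genotype (WT/KO), median_slope,
    field_size_cm, mvl. Returns Spearman rho of field size vs slope per
    genotype, a simple OLS of transformed slope on log10 field size, and a
    multiple regression transformed_slope ~ genotype + log10(size) + mvl
    with the coefficient table and adjusted R^2. Neurons with non-negative
    slopes cannot be log-transformed and are dropped from the transformed
    fits (count reported).
    """
    df = neurons.dropna(subset=["median_slope", "field_size_cm", "mvl"]).copy()
    out: dict = {"n_neurons": len(df)}
    out["spearman"] = {}
    for g, sub in df.groupby("genotype"):
        if len(sub) >= 3:
            rho, p = stats.spearmanr(sub["field_size_cm"], sub["median_slope"])
            out["spearman"][g] = {"rho": float(rho), "p": float(p), "n": len(sub)}
    df["log_size"] = np.log10(df["field_size_cm"])
    df["t_slope"] = slope_transform(df["median_slope"].to_numpy())
    fit_df = df.dropna(subset=["t_slope"])
    out["n_dropped_nonnegative_slope"] = int(len(df) - len(fit_df))
    if len(fit_df) < 10:
        out["simple"] = None
        out["multiple"] = None
        return out
    X1 = sm.add_constant(fit_df[["log_size"]])
    m1 = sm.OLS(fit_df["t_slope"], X1).fit()
    out["simple"] = {
        "slope": float(m1.params["log_size"]),
        "intercept": float(m1.params["const"]),
        "r2": float(m1.rsquared),
        "p": float(m1.pvalues["log_size"]),
    }
    fit_df = fit_df.copy()
    fit_df["genotype_ko"] = (fit_df["genotype"] == "KO").astype(float)
    X2 = sm.add_constant(fit_df[["genotype_ko", "log_size", "mvl"]])
    m2 = sm.OLS(fit_df["t_slope"], X2).fit()
    out["multiple"] = {
        "params": {k: float(v) for k, v in m2.params.items()},
        "pvalues": {k: float(v) for k, v in m2.pvalues.items()},
        "tvalues": {k: float(v) for k, v in m2.tvalues.items()},
        "adj_r2": float(m2.rsquared_adj),
        "n": int(m2.nobs),
    }
    return out


def precession_nulls(
    trial_data: list[dict],
    mode: str,
    n_reps: int = 100,
    seed: int = 0,
    min_spikes: int = 5,
    min_cycles: float = 3.0,
    alpha: float = 0.05,
    shift_step_deg: float = 5.0,
) -> pd.DataFrame:
    """Shuffle / bootstrap distributions of per-genotype mean slopes.

    ``trial_data`` holds one dict per (neuron, trial):
    {unit_id, genotype, trial_index, phases, positions, span_cycles}.

    mode="shuffle_phase"    : permute spike phases within each trial, refit.
    mode="shuffle_position" : permute spike positions within each trial.
    mode="bootstrap"        : resample neurons with replacement per genotype
                              (original per-genotype sample size), no refit.

    Returns a table (rep, genotype, mean_slope, n_neurons).
    """
    rng = np.random.default_rng(seed)
    rows = []
    if mode == "bootstrap":
        base = _neuron_slopes(trial_data, min_spikes, min_cycles, alpha, shift_step_deg)
        for rep in range(n_reps):
            for g, sub in base.groupby("genotype"):
                pick = rng.integers(0, len(sub), size=len(sub))
                rows.append(
                    dict(
                        rep=rep,
                        genotype=g,
                        mean_slope=float(sub["median_slope"].to_numpy()[pick].mean()),
                        n_neurons=len(sub),
                    )
                )
        return pd.DataFrame(rows)
    if mode not in {"shuffle_phase", "shuffle_position"}:
        raise ValueError(f"unknown mode {mode!r}")
    for rep in range(n_reps):
        shuffled = []
        for td in trial_data:
            ph = np.asarray(td["phases"], float)
            pos = np.asarray(td["positions"], float)
            if mode == "shuffle_phase":
                ph = rng.permutation(ph)
            else:
                pos = rng.permutation(pos)
            shuffled.append({**td, "phases": ph, "positions": pos})
        res = _neuron_slopes(shuffled, min_spikes, min_cycles, alpha, shift_step_deg)
        for g, sub in res.groupby("genotype"):
            rows.append(
                dict(
                    rep=rep,
                    genotype=g,
                    mean_slope=float(sub["median_slope"].mean()),
                    n_neurons=len(sub),
                )
            )
    return pd.DataFrame(rows, columns=["rep", "genotype", "mean_slope", "n_neurons"])


def _neuron_slopes(
    trial_data: list[dict],
    min_spikes: int,
    min_cycles: float,
    alpha: float,
    shift_step_deg: float,
) -> pd.DataFrame:
    by_unit: dict[tuple[str, str], list[PrecessionFit]] = {}
    for td in trial_data:
        fit = fit_trial_precession(td["phases"], td["positions"], shift_step_deg)
        fit.unit_id = td["unit_id"]
        fit.trial_index = int(td.get("trial_index", -1))
        fit = trial_criteria(fit, td["span_cycles"], min_spikes, min_cycles, alpha)
        by_unit.setdefault((td["unit_id"], td["genotype"]), []).append(fit)
    rows = []
    for (uid, g), fits in by_unit.items():
        agg = neuron_precession(fits)
        if agg is not None:
            rows.append(dict(unit_id=uid, genotype=g, median_slope=agg.median_slope))
    return pd.DataFrame(rows, columns=["unit_id", "genotype", "median_slope"])
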