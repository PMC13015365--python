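"""Full-session analysis pipeline.

Order of stages: optotag classification -> behavior (velocity,
linearization, trial segmentation, running filter) -> per-trial rate maps
-> place fields and tuning metrics -> epoch stability with shuffle null ->
theta phase coupling -> phase precession -> cohort regressions. Every
excluded (unit, direction) keeps a row with an explicit exclusion reason.

The pipeline is a pure function of (session, config, seed): identical
inputs give identical result tables.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, classification, placefields, precession, ratemaps, stability, theta
from .ratemaps import SmoothingKernel
from .types import AnalysisConfig, Session, direction_name

PAIR_LABELS = {(0, 1): "E1-E2", (1, 2): "E2-E3", (2, 3): "E3-E4"}


@dataclass
class ResultsBundle:
    valid: bool
    session_id: str
    seed: int
    config: AnalysisConfig
    trials: pd.DataFrame = None
    unit_metrics: pd.DataFrame = None
    fields: pd.DataFrame = None
    stability_table: pd.DataFrame = None
    precession_trials: pd.DataFrame = None
    precession_neurons: pd.DataFrame = None
    regressions: dict = None
    exclusions: pd.DataFrame = None
    ratemap_matrices: dict = field(default_factory=dict)   # (unit, dir) -> trials x bins
    difference_map_rows: dict = field(default_factory=dict)  # (unit, dir) -> 3 x bins

    def write(self, out_dir: str | Path) -> Path:
        """Write all result tables plus a run manifest; fully deterministic."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "trials": self.trials,
            "unit_metrics": self.unit_metrics,
            "fields": self.fields,
            "stability": self.stability_table,
            "precession_trials": self.precession_trials,
            "precession_neurons": self.precession_neurons,
            "exclusions": self.exclusions,
        }
        for name, df in tables.items():
            if df is not None:
                df.to_csv(out / f"{name}.csv", index=False, float_format="%.17g")
        for (uid, d), mat in sorted(self.ratemap_matrices.items()):
            np.savetxt(out / f"ratemap_{uid}_{d}.csv", mat, fmt="%.17g", delimiter=",")
        manifest = {
            "session_id": self.session_id,
            "seed": self.seed,
            "valid": self.valid,
            "config": dataclasses.asdict(self.config),
            "missing_sentinel": "nan",
            "regressions": self.regressions,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
        return out


def _empty_bundle(session: Session, config: AnalysisConfig, seed: int, trials=None) -> ResultsBundle:
    return ResultsBundle(
        valid=False,
        session_id=session.session_id,
        seed=seed,
        config=config,
        trials=trials if trials is not None else pd.DataFrame(),
        unit_metrics=pd.DataFrame(),
        fields=pd.DataFrame(),
        stability_table=pd.DataFrame(),
        precession_trials=pd.DataFrame(),
        precession_neurons=pd.DataFrame(),
        regressions={},
        exclusions=pd.DataFrame(columns=["unit_id", "direction", "stage", "reason"]),
    )


def _burst_membership(times: np.ndarray, cut_s: float = 0.010) -> np.ndarray:
    """True for spikes participating in a burst (ISI < cut to a neighbour)."""
    if len(times) < 2:
        return np.zeros(len(times), dtype=bool)
    d = np.diff(times)
    lead = np.concatenate([d < cut_s, [False]])
    trail = np.concatenate([[False], d < cut_s])
    return lead | trail


def classify_units(session: Session, config: AnalysisConfig) -> pd.DataFrame:
    """Optotag classification plus ISI/burst statistics for every unit.

    Without stimulation pulses the genotype stays "unknown"; the 5 Hz mean
    rate exclusion still applies.
    """
    rows = []
    duration = session.position.timestamps[-1] - session.position.timestamps[0]
    for u in session.units:
        track_spikes = u.spike_times[
            (u.spike_times >= session.position.timestamps[0])
            & (u.spike_times <= session.position.timestamps[-1])
        ]
        mean_rate = len(track_spikes) / duration if duration > 0 else np.nan
        _, _, burst_idx = classification.isi_burst_index(track_spikes)
        if len(session.stim_onsets):
            psth = classification.build_psth(
                u.spike_times,
                session.stim_onsets,
                unit_id=u.unit_id,
                trial_len_s=config.psth_window_s,
                bin_ms=config.psth_bin_ms,
            )
            resp = classification.opto_response(psth, config.pulse_dur_ms)
            call = classification.classify_unit(
                resp,
                mean_rate,
                unit_id=u.unit_id,
                rate_exclusion_hz=config.rate_exclusion_hz,
                threshold=config.opto_threshold,
                epsilon=config.opto_epsilon,
            )
            genotype, reason, resp_val = call.call, call.reason, call.opto_response
        else:
            genotype, reason, resp_val = "unknown", "no_stimulation", np.nan
            if mean_rate > config.rate_exclusion_hz:
                genotype, reason = "excluded", "mean_rate"
        u.genotype_label = genotype
        rows.append(
            dict(
                unit_id=u.unit_id,
                tetrode_id=u.tetrode_id,
                genotype=genotype,
                opto_response=resp_val,
                mean_session_rate_hz=mean_rate,
                burst_index=burst_idx,
                classification_reason=reason,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "unit_id", "tetrode_id", "genotype", "opto_response",
            "mean_session_rate_hz", "burst_index", "classification_reason",
        ],
    )


def run_pipeline(
    session: Session, config: AnalysisConfig | None = None, seed: int = 0
) -> ResultsBundle:
    config = config or AnalysisConfig()
    track = session.track
    n_bins = track.n_bins
    kernel = SmoothingKernel(
        np.asarray(config.kernel_weights, float), config.kernel_normalize
    )
    ss = np.random.SeedSequence(seed)

    # ---- classification --------------------------------------------------
    class_table = classify_units(session, config)

    # ---- behavior --------------------------------------------------------
    vel = behavior.compute_velocity(
        session.position, config.velocity_window_s, config.velocity_step_s
    )
    lin = behavior.linearize_position(session.position, track, config.max_path_dist_cm)
    lin.running = behavior.running_mask(vel, config.run_speed_cms)
    lin = behavior.segment_trials(
        lin,
        session.schedule,
        trials_per_epoch=config.trials_per_epoch,
        min_valid_trials=config.min_valid_trials,
        session_limit_s=config.session_limit_s,
    )
    trials_table = lin.trial_table
    if not lin.session_valid:
        bundle = _empty_bundle(session, config, seed, trials_table)
        bundle.unit_metrics = class_table
        return bundle

    # ---- theta phase per tetrode ----------------------------------------
    phase_by_tetrode: dict[str, tuple[np.ndarray, np.ndarray, float, float]] = {}
    for chan in session.lfp:
        filt = theta.filter_theta(chan, config.theta_band, config.filter_order)
        ph = theta.instantaneous_phase(filt)
        ph_unwrapped = theta.instantaneous_phase(filt, unwrapped=True)
        phase_by_tetrode[chan.tetrode_id] = (ph, ph_unwrapped, chan.sampling_rate, chan.t0)

    min_shift_bins = int(np.ceil(config.min_shift_cm / track.bin_width))
    unit_rows = []
    field_rows = []
    stab_rows = []
    prec_trial_rows = []
    prec_neuron_rows = []
    excl_rows = []
    ratemap_matrices = {}
    diff_rows = {}

    genotype_of = dict(zip(class_table["unit_id"], class_table["genotype"]))

    for u in session.units:
        base = class_table[class_table["unit_id"] == u.unit_id].iloc[0].to_dict()
        if genotype_of[u.unit_id] == "excluded":
            excl_rows.append(
                dict(unit_id=u.unit_id, direction="", stage="classification",
                     reason=base["classification_reason"])
            )
        maps = ratemaps.build_trial_ratemaps(u, lin, track)
        spk_idx = (
            ratemaps.spike_sample_indices(u.spike_times, lin.timestamps)
            if u.n_spikes
            else np.empty(0, dtype=np.int64)
        )
        spk_running = (
            lin.running[spk_idx] & (lin.trial_index[spk_idx] >= 0)
            & np.isfinite(lin.lin_pos[spk_idx])
            if u.n_spikes
            else np.empty(0, dtype=bool)
        )
        spk_dir = lin.direction[spk_idx] if u.n_spikes else np.empty(0, dtype=np.int8)
        spk_trial = lin.trial_index[spk_idx] if u.n_spikes else np.empty(0, dtype=np.int64)
        spk_lin = lin.lin_pos[spk_idx] if u.n_spikes else np.empty(0)
        if u.tetrode_id in phase_by_tetrode:
            ph, ph_un, fs, t0 = phase_by_tetrode[u.tetrode_id]
            lidx = np.round((u.spike_times - t0) * fs).astype(np.int64)
            ok = (lidx >= 0) & (lidx < len(ph))
            spk_phase = np.where(ok, ph[np.clip(lidx, 0, len(ph) - 1)], np.nan)
            spk_phase_un = np.where(ok, ph_un[np.clip(lidx, 0, len(ph) - 1)], np.nan)
        else:
            spk_phase = np.full(u.n_spikes, np.nan)
            spk_phase_un = np.full(u.n_spikes, np.nan)
        burst_member = _burst_membership(u.spike_times)

        for dcode in (1, -1):
            dname = direction_name(dcode)
            row = dict(
                unit_id=u.unit_id,
                tetrode_id=u.tetrode_id,
                direction=dname,
                genotype=genotype_of[u.unit_id],
                opto_response=base["opto_response"],
                mean_session_rate_hz=base["mean_session_rate_hz"],
                burst_index=base["burst_index"],
            )
            dmaps = [m for m in maps if m.direction == dname]
            if not dmaps:
                row.update(rate_class="low", exclusion_reason="no_trials")
                unit_rows.append(row)
                continue
            smoothed = np.array(
                [ratemaps.smooth_map(m.rate, kernel) for m in dmaps]
            )
            avg = ratemaps.trial_average(smoothed)
            occ_total = np.sum([m.occupancy_s for m in dmaps], axis=0)
            count_total = np.sum([m.spike_count for m in dmaps], axis=0)
            rate_class = ratemaps.classify_firing_rate(
                avg, config.mean_rate_cutoff_hz, config.max_rate_cutoff_hz
            )
            row.update(
                rate_class=rate_class,
                mean_map_rate_hz=float(np.nanmean(avg)) if np.isfinite(avg).any() else np.nan,
                max_map_rate_hz=float(np.nanmax(avg)) if np.isfinite(avg).any() else np.nan,
            )
            ratemap_matrices[(u.unit_id, dname)] = smoothed
            if rate_class == "low" or genotype_of[u.unit_id] == "excluded":
                reason = "low_firing" if rate_class == "low" else "classification"
                row["exclusion_reason"] = reason
                excl_rows.append(
                    dict(unit_id=u.unit_id, direction=dname, stage="rate_class", reason=reason)
                )
                unit_rows.append(row)
                continue
            row["exclusion_reason"] = ""

            # -- place fields and tuning ---------------------------------
            fields = placefields.detect_place_fields(
                avg, config.field_low_frac, config.field_high_frac, track.bin_width
            )
            for f in fields:
                f.unit_id, f.direction = u.unit_id, dname
            tuning = placefields.field_rate_stats(fields, avg, occ_total, count_total)
            row.update(
                n_fields=len(fields),
                field_size_cm=fields[0].size_cm if fields else np.nan,
                spatial_information=tuning.spatial_information,
                sparsity=tuning.sparsity,
                snr=tuning.snr,
                in_field_rate_hz=tuning.in_field_rate,
                out_field_rate_hz=tuning.out_field_rate,
                in_field_spike_fraction=tuning.in_field_spike_fraction,
            )
            for fi, f in enumerate(fields):
                field_rows.append(
                    dict(
                        unit_id=u.unit_id,
                        direction=dname,
                        field_id=fi,
                        peak_bin=f.peak_bin,
                        peak_rate_hz=f.peak_rate,
                        size_cm=f.size_cm,
                        bins="|".join(map(str, f.bins)),
                        spans_majority=bool(
                            f.size_cm > config.span_fraction * track.total_length
                        ),
                    )
                )

            # -- epoch stability -----------------------------------------
            epochs = sorted({m.epoch_index for m in dmaps if m.epoch_index >= 0})
            n_epochs = (max(epochs) + 1) if epochs else 0
            epoch_maps = np.full((max(n_epochs, 1), n_bins), np.nan)
            for e in epochs:
                sel = np.array([m.epoch_index == e for m in dmaps])
                epoch_maps[e] = ratemaps.trial_average(smoothed[sel])
            comps = stability.epoch_correlation(epoch_maps)
            shuffle_rng = np.random.default_rng(ss.spawn(1)[0])
            shuffle_means = stability.shuffle_correlation(
                smoothed,
                np.array([m.epoch_index for m in dmaps]),
                n_shuffles=config.n_shuffles,
                min_shift_bins=min_shift_bins,
                rng=shuffle_rng,
            )
            shifts = {
                s.pair: s
                for s in stability.peak_shift_classify(
                    epoch_maps, dname, config.field_low_frac,
                    config.field_high_frac, track.bin_width,
                )
            }
            for comp in comps:
                sh = shifts.get(comp.pair)
                stab_rows.append(
                    dict(
                        unit_id=u.unit_id,
                        direction=dname,
                        pair=PAIR_LABELS[comp.pair],
                        pcc=comp.pcc,
                        shuffle_pcc_mean=shuffle_means.get(comp.pair, np.nan),
                        n_bins_used=comp.n_bins_used,
                        peak_shift_bins=sh.shift_bins if sh else np.nan,
                        shift_class=sh.shift_class if sh else "",
                    )
                )
            if fields and n_epochs >= 2:
                diff_rows[(u.unit_id, dname)] = stability.difference_maps(
                    epoch_maps, fields[0].peak_bin
                )

            # -- theta phase coupling ------------------------------------
            sel_dir = spk_running & (spk_dir == dcode)
            phases_dir = spk_phase[sel_dir]
            row.update(_circ(phases_dir, "all"))
            if fields:
                best = fields[0]
                in_mask = best.mask(n_bins)
                union_mask = np.zeros(n_bins, dtype=bool)
                for f in fields:
                    union_mask |= f.mask(n_bins)
                spk_bin = np.minimum(
                    (spk_lin[sel_dir] / track.bin_width).astype(np.int64), n_bins - 1
                )
                row.update(_circ(phases_dir[union_mask[spk_bin]], "in_field"))
                row.update(_circ(phases_dir[~union_mask[spk_bin]], "out_field"))
                row.update(_circ(phases_dir[in_mask[spk_bin]], "best_field"))
                bm = burst_member[sel_dir]
                row.update(_circ(phases_dir[bm], "burst"))
                row.update(_circ(phases_dir[~bm], "single"))
                norm_pos_all = placefields.normalized_field_position(
                    spk_lin[sel_dir], best, dname, track.total_length
                )
                profile = theta.mvl_field_profile(
                    norm_pos_all[in_mask[spk_bin]],
                    phases_dir[in_mask[spk_bin]],
                    config.mvl_profile_bins,
                    config.mvl_profile_min_spikes,
                )
                for b, v in enumerate(profile):
                    row[f"mvl_pos_{b}"] = v

                # -- phase precession ---------------------------------------
                fit_rows, neuron = _precession_for_field(
                    u, best, dname, dcode, dmaps, smoothed, lin, track, config,
                    spk_idx, spk_running, spk_dir, spk_trial, spk_lin,
                    spk_phase, spk_phase_un,
                )
                prec_trial_rows.extend(fit_rows)
                if neuron is not None:
                    prec_neuron_rows.append(
                        dict(
                            unit_id=u.unit_id,
                            direction=dname,
                            genotype=genotype_of[u.unit_id],
                            median_slope=neuron.median_slope,
                            mean_slope=neuron.mean_slope,
                            n_included_trials=neuron.n_included_trials,
                            per_trial_field_size_mean=neuron.per_trial_field_size_mean,
                            session_field_size_cm=best.size_cm,
                            mvl_best=row.get("mvl_best_field", np.nan),
                        )
                    )
                else:
                    excl_rows.append(
                        dict(unit_id=u.unit_id, direction=dname,
                             stage="precession", reason="no_included_trials")
                    )
            unit_rows.append(row)

    unit_metrics = pd.DataFrame(unit_rows)
    prec_neurons = pd.DataFrame(prec_neuron_rows)
    regressions = {}
    if len(prec_neurons) >= 10:
        reg_in = prec_neurons.rename(
            columns={"per_trial_field_size_mean": "field_size_cm", "mvl_best": "mvl"}
        )[["unit_id", "genotype", "median_slope", "field_size_cm", "mvl"]]
        reg_in = reg_in[reg_in["genotype"].isin(["WT", "KO"])]
        if len(reg_in) >= 10:
            regressions = precession.precession_regressions(reg_in)

    return ResultsBundle(
        valid=True,
        session_id=session.session_id,
        seed=seed,
        config=config,
        trials=trials_table,
        unit_metrics=unit_metrics,
        fields=pd.DataFrame(field_rows),
        stability_table=pd.DataFrame(stab_rows),
        precession_trials=pd.DataFrame(prec_trial_rows),
        precession_neurons=prec_neurons,
        regressions=regressions,
        exclusions=pd.DataFrame(
            excl_rows, columns=["unit_id", "direction", "stage", "reason"]
        ),
        ratemap_matrices=ratemap_matrices,
        difference_map_rows=diff_rows,
    )


def _circ(phases: np.ndarray, label: str) -> dict:
    s = theta.circular_summary(phases)
    return {
        f"mvl_{label}": s.mvl,
        f"pref_phase_{label}": s.preferred_phase,
        f"n_{label}": s.n,
    }


def _precession_for_field(
    u, best, dname, dcode, dmaps, smoothed, lin, track, config,
    spk_idx, spk_running, spk_dir, spk_trial, spk_lin, spk_phase, spk_phase_un,
):
    """Per-trial precession fits for a unit's best field, plus aggregation."""
    n_bins = track.n_bins
    in_mask = best.mask(n_bins)
    fit_rows = []
    fits = []
    per_trial_sizes = {}
    for m, smap in zip(dmaps, smoothed):
        k = m.trial_index
        sel = spk_running & (spk_dir == dcode) & (spk_trial == k)
        sbin = np.minimum(
            (spk_lin[sel] / track.bin_width).astype(np.int64), n_bins - 1
        )
        infield = in_mask[sbin]
        ph = spk_phase[sel][infield]
        ph_un = spk_phase_un[sel][infield]
        pos = placefields.normalized_field_position(
            spk_lin[sel][infield], best, dname, track.total_length
        )
        ok = np.isfinite(ph) & np.isfinite(pos)
        ph, ph_un, pos = ph[ok], ph_un[ok], pos[ok]
        fit = precession.fit_trial_precession(ph, pos, config.shift_step_deg)
        fit.unit_id, fit.direction, fit.trial_index = u.unit_id, dname, k
        span = (
            (np.nanmax(ph_un) - np.nanmin(ph_un)) / 360.0 if len(ph_un) else np.nan
        )
        fit = precession.trial_criteria(
            fit, span, config.min_precession_spikes,
            config.min_theta_cycles, config.precession_alpha,
        )
        fits.append(fit)
        # per-trial field size: re-detect on this trial's smoothed map
        tfields = placefields.detect_place_fields(
            smap, config.field_low_frac, config.field_high_frac, track.bin_width
        )
        match = stability.match_field(best, tfields, n_bins)
        per_trial_sizes[k] = match.size_cm if match is not None else np.nan
        fit_rows.append(
            dict(
                unit_id=u.unit_id,
                direction=dname,
                trial_index=k,
                applied_shift_deg=fit.applied_shift,
                slope_deg_per_field=fit.slope,
                intercept_deg=fit.intercept,
                r=fit.r,
                p_value=fit.p_value,
                n_spikes=fit.n_spikes,
                span_cycles=fit.span_cycles,
                included=fit.included,
                exclusion_reason=fit.exclusion_reason,
                trial_field_size_cm=per_trial_sizes[k],
            )
        )
    neuron = precession.neuron_precession(fits, per_trial_sizes)
    return fit_rows, neuron
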