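"""Synthetic sessions with known ground truth.

Emulates the recorded task at desk scale: a rectangular-track trajectory
with alternating 10-trial direction blocks and brief reward-zone pauses,
theta-band LFP (8 Hz sinusoid on a 1/f background), place-cell spike trains
drawn from an inhomogeneous Poisson process (Gaussian spatial field x
von Mises theta-phase gain with linear phase precession across the field,
plus doublet bursts), and optotagging responses to 10 ms light pulses at
0.5 Hz.

Every random component is driven by a single integer seed through
numpy's SeedSequence tree, so identical configs reproduce identical
sessions; spike times are reproducible to well under 1 microsecond.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import i0, i1

from .types import (
    DirectionSchedule,
    LfpChannel,
    PositionTrace,
    Session,
    SpikeTrain,
    TrackGeometry,
    wrapped_diff,
)

# Ground-truth field edge = the 10% isocontour of the Gaussian envelope,
# matching the analysis's field definition when the out-of-field floor is
# small: exp(-d^2 / 2 sigma^2) = 0.1 at d = sigma * sqrt(2 ln 10).
FIELD_EXTENT_SIGMAS = float(np.sqrt(2.0 * np.log(10.0)))


@dataclass
class UnitSpec:
    """Ground-truth parameters of one simulated unit."""

    unit_id: str
    genotype: str = "WT"            # WT | KO
    field_center: float = 100.0     # cm on the linearized track
    field_width_sigma: float = 9.0  # cm
    peak_rate: float = 10.0         # Hz at the field center (spatial envelope)
    out_field_rate: float = 0.2     # Hz floor everywhere else
    theta_kappa: float = 1.0        # von Mises concentration of phase locking
    preferred_phase: float = 180.0  # deg; phase at the field entrance
    precession_slope: float = -180.0  # deg per unit normalized field position
    burst_prob: float = 0.3         # doublet probability per emitted spike
    opto_reliability: float = 0.0   # per-pulse spike probability (KO only)
    opto_latency_ms: float = 4.0
    direction: str = "both"         # CW | CCW | both

    def __post_init__(self) -> None:
        if not (self.peak_rate > self.out_field_rate >= 0):
            raise ValueError("need peak_rate > out_field_rate >= 0")
        if self.field_width_sigma <= 0:
            raise ValueError("field_width_sigma must be positive")

    def expected_mvl(self) -> float:
        """Population MVL implied by the von Mises gain: I1(k)/I0(k)."""
        k = self.theta_kappa
        return float(i1(k) / i0(k)) if k > 0 else 0.0


@dataclass
class SimConfig:
    n_trials: int = 80
    trials_per_epoch: int = 10
    mean_speed: float = 20.0   # cm/s
    speed_noise: float = 5.0   # cm/s (sd of the smoothed fluctuation)
    position_rate: float = 30.0  # Hz camera rate
    missing_frac: float = 0.02   # fraction of lost-tracking samples
    theta_freq: float = 8.0
    lfp_rate: float = 1000.0
    lfp_theta_amp: float = 100.0   # uV
    lfp_noise_amp: float = 50.0    # uV (sd of the 1/f background)
    lfp_noise_exponent: float = 2.0
    stim_rate: float = 0.5     # Hz
    stim_pulse_ms: float = 10.0
    n_pulses: int = 600
    stim_gap_s: float = 10.0   # silence between track end and first pulse
    n_tetrodes: int = 2
    seed: int = 0
    units: list[UnitSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_trials % self.trials_per_epoch != 0:
            raise ValueError("n_trials must be a multiple of trials_per_epoch")
        if not (4.0 <= self.theta_freq <= 12.0):
            raise ValueError("theta_freq must lie in the 4-12 Hz analysis band")
        if self.mean_speed <= 0:
            raise ValueError("mean_speed must be positive")


@dataclass
class TrajectoryTruth:
    """Noise-free trajectory state used to drive spike generation."""

    timestamps: np.ndarray
    unwrapped_arc: np.ndarray  # signed, CW positive
    lin_pos: np.ndarray        # arc mod lap, never missing
    direction: np.ndarray      # +1 CW / -1 CCW / 0 pause
    trial_index: np.ndarray    # -1 between trials
    speed: np.ndarray


@dataclass
class GroundTruth:
    specs: dict[str, UnitSpec]
    theta_freq: float
    in_field: dict[str, np.ndarray] = field(default_factory=dict)  # per-spike flags
    is_opto: dict[str, np.ndarray] = field(default_factory=dict)

    def genotype(self, unit_id: str) -> str:
        return self.specs[unit_id].genotype

    def to_json_dict(self) -> dict:
        return {
            "theta_freq": self.theta_freq,
            "units": {
                uid: dataclasses.asdict(spec) for uid, spec in self.specs.items()
            },
            "in_field_fraction": {
                uid: (float(np.mean(v)) if len(v) else None)
                for uid, v in self.in_field.items()
            },
        }


def generate_trajectory(
    track: TrackGeometry, sim: SimConfig, rng: np.random.Generator
) -> tuple[PositionTrace, DirectionSchedule, TrajectoryTruth]:
    """Laps around the loop with alternating direction blocks and pauses.

    Speed fluctuates around ``mean_speed`` with an AR(1)-smoothed noise of sd
    ``speed_noise`` (floored at 4 cm/s so the running filter keeps laps);
    after each lap the animal pauses 1-3 s at the reward zone below the
    2 cm/s running threshold. Direction alternates every
    ``trials_per_epoch`` trials, starting CW.
    """
    if sim.mean_speed <= 0:
        raise ValueError("mean_speed must be positive")
    dt = 1.0 / sim.position_rate
    lap = track.total_length
    t_list: list[np.ndarray] = []
    arc_list: list[np.ndarray] = []
    dir_list: list[np.ndarray] = []
    trial_list: list[np.ndarray] = []
    speed_list: list[np.ndarray] = []
    sched_rows = []
    t_now = 0.0
    arc_now = 0.0
    rho = 0.9  # AR(1) smoothness of the speed fluctuation
    for k in range(sim.n_trials):
        d = 1 if (k // sim.trials_per_epoch) % 2 == 0 else -1
        n_max = int(np.ceil(2.5 * lap / (sim.mean_speed * dt))) + 20
        eps = rng.standard_normal(n_max) * sim.speed_noise * np.sqrt(1 - rho ** 2)
        noise = lfilter([1.0], [1.0, -rho], eps)  # AR(1), stationary sd = speed_noise
        v = np.maximum(sim.mean_speed + noise, 4.0)
        dist = np.cumsum(v * dt)
        stop = int(np.argmax(dist >= lap))
        if dist[stop] < lap:  # pathologically slow draw; rescale
            v *= lap / dist[-1] * 1.05
            dist = np.cumsum(v * dt)
            stop = int(np.argmax(dist >= lap))
        v = v[: stop + 1]
        dist = dist[: stop + 1]
        dist[-1] = lap  # land exactly on the reward zone
        tt = t_now + dt * np.arange(1, len(v) + 1)
        t_start = t_now
        t_now = tt[-1]
        t_list.append(tt)
        arc_list.append(arc_now + d * dist)
        dir_list.append(np.full(len(tt), d, dtype=np.int8))
        trial_list.append(np.full(len(tt), k, dtype=np.int64))
        speed_list.append(v)
        arc_now = arc_now + d * lap
        sched_rows.append(
            dict(
                trial_index=k,
                direction="CW" if d > 0 else "CCW",
                start_time=t_start,
                end_time=t_now + dt / 2.0,
            )
        )
        # reward-zone pause below the running threshold
        pause_s = rng.uniform(1.0, 3.0)
        n_pause = max(int(round(pause_s / dt)), 1)
        jitter = rng.uniform(0.0, 1.0, size=n_pause)  # cm/s, sub-threshold
        tt = t_now + dt * np.arange(1, n_pause + 1)
        wiggle = np.cumsum((jitter - jitter.mean()) * dt)
        t_list.append(tt)
        arc_list.append(arc_now + wiggle)
        dir_list.append(np.zeros(n_pause, dtype=np.int8))
        trial_list.append(np.full(n_pause, -1, dtype=np.int64))
        speed_list.append(jitter)
        t_now = tt[-1]
    timestamps = np.concatenate([[0.0], *t_list])
    arc = np.concatenate([[0.0], *arc_list])
    direction = np.concatenate([[0], *dir_list]).astype(np.int8)
    trial_index = np.concatenate([[-1], *trial_list])
    speed = np.concatenate([[0.0], *speed_list])
    lin = arc % lap
    x, y = track.arc_to_xy(lin)
    # lost-tracking samples
    if sim.missing_frac > 0:
        miss = rng.random(len(x)) < sim.missing_frac
        x = np.where(miss, np.nan, x)
        y = np.where(miss, np.nan, y)
    pos = PositionTrace(timestamps=timestamps, x=x, y=y)
    schedule = DirectionSchedule(
        pd.DataFrame(sched_rows), trials_per_epoch=sim.trials_per_epoch
    )
    truth = TrajectoryTruth(
        timestamps=timestamps,
        unwrapped_arc=arc,
        lin_pos=lin,
        direction=direction,
        trial_index=trial_index,
        speed=speed,
    )
    return pos, schedule, truth


def theta_phase_at(t: np.ndarray, theta_freq: float) -> np.ndarray:
    """Ground-truth theta phase (deg, 0 = peak) of the simulated oscillator."""
    return (np.asarray(t, float) * theta_freq * 360.0) % 360.0


def generate_lfp(
    sim: SimConfig,
    duration: float,
    rng: np.random.Generator,
    tetrode_id: str = "tt1",
) -> tuple[LfpChannel, np.ndarray]:
    """Theta sinusoid plus 1/f^exponent background; returns (channel, phase).

    The returned ground-truth phase array matches the channel's sample grid.
    The cosine convention puts the theta peak at phase 0 and the trough at
    180, matching the analysis convention.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    fs = sim.lfp_rate
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    phase = theta_phase_at(t, sim.theta_freq)
    theta = sim.lfp_theta_amp * np.cos(np.radians(phase))
    if sim.lfp_noise_amp > 0:
        white = rng.standard_normal(n)
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, d=1.0 / fs)
        scale = np.zeros_like(freqs)
        scale[1:] = freqs[1:] ** (-sim.lfp_noise_exponent / 2.0)
        noise = np.fft.irfft(spec * scale, n=n)
        sd = noise.std()
        if sd > 0:
            noise *= sim.lfp_noise_amp / sd
    else:
        noise = 0.0
    return (
        LfpChannel(tetrode_id=tetrode_id, sampling_rate=fs, samples=theta + noise),
        phase,
    )


def _rate_function(
    spec: UnitSpec,
    t: np.ndarray,
    truth: TrajectoryTruth,
    theta_freq: float,
    track: TrackGeometry,
) -> tuple[np.ndarray, np.ndarray]:
    """Intensity (Hz) at times t, and the ground-truth in-field flag."""
    lap = track.total_length
    idx = np.clip(
        np.searchsorted(truth.timestamps, t), 0, len(truth.timestamps) - 1
    )
    lin = truth.lin_pos[idx]
    d = truth.direction[idx]
    in_trial = truth.trial_index[idx] >= 0
    if spec.direction == "both":
        active = in_trial
    else:
        want = 1 if spec.direction == "CW" else -1
        active = in_trial & (d == want)
    dist = wrapped_diff(lin, spec.field_center, lap)
    extent_cm = FIELD_EXTENT_SIGMAS * spec.field_width_sigma
    # Gaussian envelope truncated at the field boundary: outside the field
    # the rate is exactly the out-of-field floor.
    g = np.where(
        np.abs(dist) <= extent_cm,
        np.exp(-(dist ** 2) / (2.0 * spec.field_width_sigma ** 2)),
        0.0,
    )
    spatial = np.where(
        active, spec.out_field_rate + (spec.peak_rate - spec.out_field_rate) * g,
        spec.out_field_rate,
    )
    in_field = active & (np.abs(dist) <= extent_cm)
    # phase gain: von Mises with position-dependent preferred phase,
    # normalized field position measured along the current travel direction
    extent = FIELD_EXTENT_SIGMAS * spec.field_width_sigma
    along_cw = (lin - (spec.field_center - extent)) % lap
    along_ccw = ((spec.field_center + extent) - lin) % lap
    q = np.where(d >= 0, along_cw, along_ccw) / (2.0 * extent)
    q = np.clip(q, 0.0, 1.0)
    mu = spec.preferred_phase + np.where(in_field, spec.precession_slope * q, 0.0)
    phase = theta_phase_at(t, theta_freq)
    kappa = spec.theta_kappa
    if kappa > 0:
        gain = np.exp(kappa * np.cos(np.radians(phase - mu))) / i0(kappa)
    else:
        gain = np.ones_like(phase)
    # theta modulation accompanies locomotion; home-cage/stim-period
    # baseline firing is unmodulated
    gain = np.where(in_trial, gain, 1.0)
    return spatial * gain, in_field


def generate_unit_spikes(
    spec: UnitSpec,
    truth: TrajectoryTruth,
    sim: SimConfig,
    track: TrackGeometry,
    duration: float,
    stim_onsets: np.ndarray,
    rng: np.random.Generator,
) -> tuple[SpikeTrain, dict]:
    """Inhomogeneous-Poisson spike train for one unit, by thinning.

    Candidate events are drawn homogeneously at the intensity bound
    peak_rate * e^kappa / I0(kappa) and accepted with probability
    rate(t)/bound. Accepted spikes spawn a doublet follower (ISI uniform
    3-8 ms) with probability ``burst_prob``. KO units additionally fire
    ``opto_latency_ms`` after each light pulse with probability
    ``opto_reliability``.
    """
    if duration <= truth.timestamps[-1] - 1e-9:
        raise ValueError("duration must cover the trajectory span")
    kappa = spec.theta_kappa
    gain_max = float(np.exp(kappa) / i0(kappa)) if kappa > 0 else 1.0
    lam_max = spec.peak_rate * gain_max
    n_cand = rng.poisson(lam_max * duration)
    cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
    accept_u = rng.uniform(0.0, 1.0, size=n_cand)
    rate, _ = _rate_function(spec, cand, truth, sim.theta_freq, track)
    spikes = cand[accept_u < rate / lam_max]
    # doublet bursts
    follow = rng.random(len(spikes)) < spec.burst_prob
    isi = rng.uniform(0.003, 0.008, size=len(spikes))
    followers = spikes[follow] + isi[follow]
    # optotag responses
    opto_times = np.empty(0)
    if spec.genotype == "KO" and spec.opto_reliability > 0 and len(stim_onsets):
        fired = rng.random(len(stim_onsets)) < spec.opto_reliability
        jitter = rng.uniform(-0.5, 0.5, size=len(stim_onsets)) * 1e-3
        opto_times = stim_onsets[fired] + spec.opto_latency_ms * 1e-3 + jitter[fired]
    all_times = np.sort(np.concatenate([spikes, followers, opto_times]))
    all_times = all_times[(all_times >= 0) & (all_times < duration)]
    if len(all_times) > 1:  # enforce strictly increasing (1 us resolution)
        keep = np.concatenate([[True], np.diff(all_times) > 1e-6])
        all_times = all_times[keep]
    _, in_field = _rate_function(spec, all_times, truth, sim.theta_freq, track)
    is_opto = np.zeros(len(all_times), dtype=bool)
    if len(opto_times):
        is_opto = np.isin(all_times, opto_times)
    train = SpikeTrain(
        unit_id=spec.unit_id, tetrode_id="", spike_times=all_times
    )
    record = {"in_field": in_field, "is_opto": is_opto}
    return train, record


def default_units(n_wt: int = 8, n_ko: int = 8, track_length: float = 264.0) -> list[UnitSpec]:
    """A mixed cohort with fields tiling the track.

    WT units get compact fields (sigma 9 cm -> ~39 cm at the 10% threshold),
    strong theta locking (kappa 1.5) and steep precession; KO units broader
    fields (sigma 12 cm -> ~51 cm), weaker locking, shallower precession,
    more out-of-field firing and reliable opto responses — the qualitative
    contrasts the analysis is meant to resolve.
    """
    units = []
    n = n_wt + n_ko
    for i in range(n):
        ko = i >= n_wt
        center = (i + 0.5) * track_length / n
        units.append(
            UnitSpec(
                unit_id=f"u{i:03d}",
                genotype="KO" if ko else "WT",
                field_center=center,
                field_width_sigma=12.0 if ko else 9.0,
                peak_rate=10.0,
                out_field_rate=0.5 if ko else 0.2,
                theta_kappa=0.8 if ko else 1.5,
                preferred_phase=180.0,
                precession_slope=-120.0 if ko else -180.0,
                burst_prob=0.15 if ko else 0.3,
                opto_reliability=0.9 if ko else 0.0,
                opto_latency_ms=4.0,
                direction="CW" if i % 2 == 0 else "CCW",
            )
        )
    return units


def generate_session(
    sim: SimConfig, track: TrackGeometry | None = None
) -> tuple[Session, GroundTruth]:
    """Assemble a full synthetic session plus its ground truth."""
    if track is None:
        track = TrackGeometry()
    ss = np.random.SeedSequence(sim.seed)
    keys = ["trajectory", "lfp", "units", "stim"]
    children = dict(zip(keys, ss.spawn(len(keys))))
    rng_traj = np.random.default_rng(children["trajectory"])
    pos, schedule, truth = generate_trajectory(track, sim, rng_traj)

    track_end = truth.timestamps[-1]
    stim_start = track_end + sim.stim_gap_s
    stim_onsets = stim_start + np.arange(sim.n_pulses) / sim.stim_rate
    duration = float(stim_onsets[-1] + 2.0) if sim.n_pulses else float(track_end + 2.0)

    units = sim.units if sim.units else default_units()
    tetrode_ids = [f"tt{i + 1}" for i in range(sim.n_tetrodes)]
    lfp_children = children["lfp"].spawn(len(tetrode_ids))
    lfp = []
    for tid, child in zip(tetrode_ids, lfp_children):
        chan, _ = generate_lfp(sim, duration, np.random.default_rng(child), tid)
        lfp.append(chan)

    unit_children = children["units"].spawn(len(units))
    trains = []
    gt = GroundTruth(specs={u.unit_id: u for u in units}, theta_freq=sim.theta_freq)
    for i, (spec, child) in enumerate(zip(units, unit_children)):
        train, record = generate_unit_spikes(
            spec, truth, sim, track, duration, stim_onsets,
            np.random.default_rng(child),
        )
        train.tetrode_id = tetrode_ids[i % len(tetrode_ids)]
        trains.append(train)
        gt.in_field[spec.unit_id] = record["in_field"]
        gt.is_opto[spec.unit_id] = record["is_opto"]

    session = Session(
        session_id=f"sim-{sim.seed}",
        units=trains,
        position=pos,
        lfp=lfp,
        stim_onsets=stim_onsets,
        track=track,
        schedule=schedule,
    )
    return session, gt
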