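"""Session directory reading/writing.

A session directory holds plain-text files:

    spikes.csv          unit_id,tetrode_id,time_s  (sorted within unit)
    position.csv        time_s,x_cm,y_cm           (empty field = missing)
    lfp_<tetrode>.csv   one sample (uV) per line
    lfp_<tetrode>.json  {"tetrode_id", "sampling_rate", "t0"}
    stim.txt            one light-pulse onset time (s) per line
    session.yaml        session_id, track geometry, trial schedule, labels

Floats are written with 17 significant digits so a write -> load round trip
reproduces every value bit-exactly.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    DirectionSchedule,
    LfpChannel,
    PositionTrace,
    Session,
    SpikeTrain,
    TrackGeometry,
)

FLOAT_FMT = "%.17g"


def write_session(session: Session, out_dir: str | Path) -> Path:
    """Write a session to a directory in the package's text formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for u in session.units:
        for t in u.spike_times:
            rows.append((u.unit_id, u.tetrode_id, t))
    with open(out / "spikes.csv", "w") as f:
        f.write("unit_id,tetrode_id,time_s\n")
        for uid, tid, t in rows:
            f.write(f"{uid},{tid},{t:.17g}\n")

    pos = session.position
    with open(out / "position.csv", "w") as f:
        f.write("time_s,x_cm,y_cm\n")
        for t, x, y in zip(pos.timestamps, pos.x, pos.y):
            xs = "" if np.isnan(x) else f"{x:.17g}"
            ys = "" if np.isnan(y) else f"{y:.17g}"
            f.write(f"{t:.17g},{xs},{ys}\n")

    for chan in session.lfp:
        np.savetxt(out / f"lfp_{chan.tetrode_id}.csv", chan.samples, fmt=FLOAT_FMT)
        meta = {
            "tetrode_id": chan.tetrode_id,
            "sampling_rate": chan.sampling_rate,
            "t0": chan.t0,
        }
        (out / f"lfp_{chan.tetrode_id}.json").write_text(
            json.dumps(meta, sort_keys=True, indent=1)
        )

    np.savetxt(out / "stim.txt", session.stim_onsets, fmt=FLOAT_FMT)

    meta = {
        "session_id": session.session_id,
        "track": {
            "width": session.track.width,
            "height": session.track.height,
            "bin_width": session.track.bin_width,
        },
        "units": [
            {
                "unit_id": u.unit_id,
                "tetrode_id": u.tetrode_id,
                "genotype_label": u.genotype_label,
            }
            for u in session.units
        ],
    }
    if session.schedule is not None:
        meta["schedule"] = {
            "trials_per_epoch": int(session.schedule.trials_per_epoch),
            "trials": [
                {
                    "trial_index": int(r["trial_index"]),
                    "direction": str(r["direction"]),
                    "start_time": float(r["start_time"]),
                    "end_time": float(r["end_time"]),
                }
                for _, r in session.schedule.trials.iterrows()
            ],
        }
    with open(out / "session.yaml", "w") as f:
        yaml.safe_dump(meta, f, sort_keys=True)
    return out


def _resolve(paths: dict[str, Path], role: str) -> Path:
    p = paths.get(role)
    if p is None or not Path(p).exists():
        raise FileNotFoundError(f"session file for role '{role}' not found: {p}")
    return Path(p)


def load_session(source: str | Path | dict) -> Session:
    """Load a session from a directory (or an explicit role->path mapping).

    Validates all container invariants; a spike file whose times are not
    strictly increasing within a unit raises an error naming the offending
    file row. Units with zero spikes listed in session.yaml are retained.
    """
    if isinstance(source, (str, Path)):
        d = Path(source)
        paths = {
            "spikes": d / "spikes.csv",
            "position": d / "position.csv",
            "stim": d / "stim.txt",
            "session": d / "session.yaml",
        }
        lfp_files = sorted(d.glob("lfp_*.json"))
    else:
        paths = {k: Path(v) for k, v in source.items() if not str(k).startswith("lfp")}
        lfp_files = sorted(
            Path(v) for k, v in source.items() if str(k).startswith("lfp") and str(v).endswith(".json")
        )

    meta = yaml.safe_load(_resolve(paths, "session").read_text())
    track_meta = meta.get("track", {})
    track = TrackGeometry(
        width=float(track_meta.get("width", 84.0)),
        height=float(track_meta.get("height", 48.0)),
        bin_width=float(track_meta.get("bin_width", 4.0)),
    )

    spikes = pd.read_csv(
        _resolve(paths, "spikes"),
        dtype={"unit_id": str, "tetrode_id": str},
        float_precision="round_trip",
    )
    declared = {
        u["unit_id"]: u for u in meta.get("units", [])
    }
    units = []
    seen = set()
    order = list(declared) if declared else list(dict.fromkeys(spikes["unit_id"]))
    for uid in order:
        sub = spikes[spikes["unit_id"] == uid]
        times = sub["time_s"].to_numpy(float)
        if len(times) > 1:
            bad = np.flatnonzero(np.diff(times) <= 0)
            if len(bad):
                row = int(sub.index[bad[0] + 1]) + 2  # header + 1-based
                raise ValueError(
                    f"spikes.csv: non-increasing time for unit {uid} at file row {row}"
                )
        info = declared.get(uid, {})
        tetrode = info.get("tetrode_id") or (
            str(sub["tetrode_id"].iloc[0]) if len(sub) else ""
        )
        units.append(
            SpikeTrain(
                unit_id=uid,
                tetrode_id=tetrode,
                spike_times=times,
                genotype_label=info.get("genotype_label", "unknown"),
            )
        )
        seen.add(uid)
    for uid in dict.fromkeys(spikes["unit_id"]):
        if uid not in seen:
            sub = spikes[spikes["unit_id"] == uid]
            units.append(
                SpikeTrain(
                    unit_id=uid,
                    tetrode_id=str(sub["tetrode_id"].iloc[0]),
                    spike_times=sub["time_s"].to_numpy(float),
                )
            )

    posf = pd.read_csv(_resolve(paths, "position"), float_precision="round_trip")
    position = PositionTrace(
        timestamps=posf["time_s"].to_numpy(float),
        x=posf["x_cm"].to_numpy(float),
        y=posf["y_cm"].to_numpy(float),
    )

    stim_path = _resolve(paths, "stim")
    text = stim_path.read_text().split()
    stim = np.array([float(v) for v in text]) if text else np.empty(0)

    lfp = []
    for jp in lfp_files:
        info = json.loads(jp.read_text())
        csv_path = jp.with_suffix(".csv")
        if not csv_path.exists():
            raise FileNotFoundError(f"session file for role 'lfp' not found: {csv_path}")
        samples = pd.read_csv(
            csv_path, header=None, dtype=float, float_precision="round_trip"
        ).to_numpy().ravel()
        lfp.append(
            LfpChannel(
                tetrode_id=str(info["tetrode_id"]),
                sampling_rate=float(info["sampling_rate"]),
                samples=np.atleast_1d(samples),
                t0=float(info.get("t0", 0.0)),
            )
        )

    schedule = None
    if "schedule" in meta:
        trials = pd.DataFrame(meta["schedule"]["trials"])
        schedule = DirectionSchedule(
            trials, trials_per_epoch=int(meta["schedule"].get("trials_per_epoch", 10))
        )

    return Session(
        session_id=str(meta.get("session_id", "session")),
        units=units,
        position=position,
        lfp=lfp,
        stim_onsets=stim,
        track=track,
        schedule=schedule,
    )
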