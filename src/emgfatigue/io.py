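"""CSV readers/writers for recordings, session events and feature tables.

All timestamps are seconds with 6-decimal precision; round-trips are lossless
to 1e-9 relative.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .synthgen import (EmgRecording, FatigueTrajectory, ForceRecording,
                       SessionBundle, SessionRecord)

__all__ = ["read_emg_csv", "write_emg_csv", "read_force_csv",
           "write_force_csv", "read_session_csv", "write_session_csv",
           "read_features_csv", "write_features_csv",
           "write_trajectory_csv", "read_trajectory_csv",
           "write_bundle", "read_bundle", "load_reference_cohort"]

def _read_csv(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty input file") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    bad = df[df.isna().any(axis=1)]
    if len(bad):
        lines = (bad.index + 2).tolist()[:5]  # +2: header + 1-based
        raise ValueError(f"{path}: malformed/missing values at line(s) {lines}")
    return df


def write_emg_csv(path, rec: EmgRecording) -> None:
    df = pd.DataFrame({"time_s": np.round(rec.times, 6)})
    for j, ch in enumerate(rec.channel_labels):
        df[ch] = rec.samples[j]
    df.to_csv(path, index=False)


def read_emg_csv(path, sample_rate: float | None = None) -> EmgRecording:
    df = _read_csv(path, ["time_s"])
    channels = [c for c in df.columns if c != "time_s"]
    if not channels:
        raise ValueError(f"{path}: no channel columns besides time_s")
    t = df["time_s"].to_numpy(float)
    rate = sample_rate or 1.0 / np.median(np.diff(t))
    return EmgRecording(rate, channels,
                        np.vstack([df[c].to_numpy(float) for c in channels]),
                        t0=float(t[0]))


def write_force_csv(path, rec: ForceRecording) -> None:
    pd.DataFrame({"time_s": np.round(rec.times, 6),
                  "force_N": rec.force}).to_csv(path, index=False)


def read_force_csv(path, sample_rate: float | None = None) -> ForceRecording:
    df = _read_csv(path, ["time_s", "force_N"])
    t = df["time_s"].to_numpy(float)
    rate = sample_rate or 1.0 / np.median(np.diff(t))
    return ForceRecording(rate, df["force_N"].to_numpy(float), t0=float(t[0]))


def write_session_csv(path, session: SessionRecord) -> None:
    rows = [("mvc_i", 0.0, session.mvc_i), ("mvc_f", 0.0, session.mvc_f)]
    rows += [("mvc_t", t, v) for t, v in session.mvc_trials]
    for start, end, target in session.steady_segments:
        rows.append(("steady_start", start, target))
        rows.append(("steady_end", end, target))
    rows.append(("terminated", 0.0, float(session.terminated)))
    df = pd.DataFrame(rows, columns=["event_type", "time_s", "value_N"])
    df["time_s"] = np.round(df["time_s"], 6)
    df.to_csv(path, index=False)


def read_session_csv(path) -> SessionRecord:
    df = _read_csv(path, ["event_type", "time_s", "value_N"])
    get = lambda kind: df[df.event_type == kind]
    try:
        mvc_i = float(get("mvc_i")["value_N"].iloc[0])
        mvc_f = float(get("mvc_f")["value_N"].iloc[0])
    except IndexError:
        raise ValueError(f"{path}: needs mvc_i and mvc_f events") from None
    trials = [(float(t), float(v)) for t, v in
              zip(get("mvc_t")["time_s"], get("mvc_t")["value_N"])]
    starts = get("steady_start").reset_index()
    ends = get("steady_end").reset_index()
    segments = [(float(s.time_s), float(e.time_s), float(s.value_N))
                for s, e in zip(starts.itertuples(), ends.itertuples())]
    term = get("terminated")
    terminated = bool(term["value_N"].iloc[0]) if len(term) else False
    return SessionRecord(mvc_i, mvc_f, trials, segments, terminated)


def write_features_csv(path, fm: FeatureMatrix) -> None:
    fm.to_frame().to_csv(path, index=False)


def read_features_csv(path) -> FeatureMatrix:
    return FeatureMatrix.from_frame(_read_csv(path, ["time_s", "force_N"]))


def write_trajectory_csv(path, traj: FatigueTrajectory) -> None:
    pd.DataFrame({"time_s": np.round(traj.times, 6),
                  "mfl_true": traj.mfl_true,
                  "condition": traj.condition_label}).to_csv(path, index=False)


def read_trajectory_csv(path) -> FatigueTrajectory:
    df = _read_csv(path, ["time_s", "mfl_true"])
    cond = str(df["condition"].iloc[0]) if "condition" in df.columns else ""
    return FatigueTrajectory(df["time_s"].to_numpy(float),
                             df["mfl_true"].to_numpy(float), cond)


def write_bundle(outdir, bundle: SessionBundle, prefix: str = "") -> dict:
    """Write a session bundle as four CSVs; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / f"{prefix}{k}.csv"
             for k in ("emg", "force", "session", "trajectory")}
    write_emg_csv(paths["emg"], bundle.emg)
    write_force_csv(paths["force"], bundle.force)
    write_session_csv(paths["session"], bundle.session)
    write_trajectory_csv(paths["trajectory"], bundle.fatigue)
    return {k: str(v) for k, v in paths.items()}


def read_bundle(outdir, prefix: str = "",
                emg_rate: float = 1000.0, force_rate: float = 100.0
                ) -> SessionBundle:
    outdir = Path(outdir)
    traj = read_trajectory_csv(outdir / f"{prefix}trajectory.csv")
    return SessionBundle(
        emg=read_emg_csv(outdir / f"{prefix}emg.csv", emg_rate),
        force=read_force_csv(outdir / f"{prefix}force.csv", force_rate),
        session=read_session_csv(outdir / f"{prefix}session.csv"),
        fatigue=traj, condition_label=traj.condition_label)


def load_reference_cohort() -> pd.DataFrame:
    """Best-node R^2 values of a 10-subject reference grasp-force cohort.

    Columns: subject, then per-method mean and sd of the best-node R^2 for
    the three feature configurations.  Used for comparison-arithmetic demos
    and validation of the reporting stage.
    """
    with resources.files("emgfatigue.data").joinpath(
            "reference_cohort.csv").open() as fh:
        return pd.read_csv(fh)
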