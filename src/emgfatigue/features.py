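"""Per-window sEMG features and feature-matrix assembly.

Features per channel per 300 ms window: RMS, ARV (average rectified value),
MNF (power-spectrum-weighted mean frequency of the mean-detrended window) and
the MNF/ARV fatigue index, alongside the windowed mean grasp force.  Windows
with degenerate (zero-power) content yield NaN markers and are dropped from
the assembled matrix rather than zero-filled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .preprocess import (FilterSpec, WindowSpec, align_force, bandpass, notch,
                         segment, window_starts)
from .synthgen import SessionBundle

logger = logging.getLogger(__name__)

__all__ = ["FeatureMatrix", "rms", "arv", "mnf", "mnf_arv",
           "extract_features", "select_steady"]


def _window_array(window) -> np.ndarray:
    x = np.asarray(window, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    return x


def rms(window) -> float:
    """Root mean square, sqrt(mean(x^2))."""
    x = _window_array(window)
    return float(np.sqrt(np.mean(x * x)))


def arv(window) -> float:
    """Average rectified value, mean(|x|)."""
    x = _window_array(window)
    return float(np.mean(np.abs(x)))


def mnf(window, sample_rate: float) -> float:
    """Mean frequency: sum(f * P(f)) / sum(P(f)) over the periodogram.

    The window is mean-detrended before spectral estimation (rectangular
    taper).  A zero-power window returns NaN, propagated as missing rather
    than raised, so downstream assembly can drop it.
    """
    x = _window_array(window)
    if x.size < 2:
        raise ValueError("mnf needs at least 2 samples")
    if sample_rate <= 0:
        raise ValueError("sample_rate must be > 0")
    f, p = _signal.periodogram(x, fs=sample_rate, detrend="constant",
                               window="boxcar")
    total = p.sum()
    if total <= 0:
        return float("nan")
    return float((f * p).sum() / total)


def mnf_arv(window, sample_rate: float) -> float:
    """MNF/ARV fatigue index; NaN when ARV is 0 or MNF undefined."""
    a = arv(window)
    if a == 0:
        return float("nan")
    return mnf(window, sample_rate) / a


@dataclass
class FeatureMatrix:
    """Per-window features (n windows x c channels) plus targets.

    ``mfl`` is NaN until assigned by the fatigue module.
    """

    window_times: np.ndarray          # window centres, seconds
    channel_labels: list[str]
    rms: np.ndarray                   # (n, c)
    arv: np.ndarray
    mnf: np.ndarray                   # Hz
    mnf_arv: np.ndarray               # Hz per signal unit
    mean_force: np.ndarray            # (n,), newtons
    mfl: np.ndarray = field(default=None)  # (n,), [0, 1]
    condition_label: str = ""

    def __post_init__(self) -> None:
        if self.mfl is None:
            self.mfl = np.full(len(self.window_times), np.nan)
        n = len(self.window_times)
        for name in ("rms", "arv", "mnf", "mnf_arv"):
            if getattr(self, name).shape != (n, len(self.channel_labels)):
                raise ValueError(f"{name} must be (n_windows, n_channels)")
        if self.mean_force.shape != (n,) or self.mfl.shape != (n,):
            raise ValueError("mean_force and mfl must have length n_windows")

    @property
    def n_windows(self) -> int:
        return len(self.window_times)

    def subset(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(self.window_times[mask], self.channel_labels,
                             self.rms[mask], self.arv[mask], self.mnf[mask],
                             self.mnf_arv[mask], self.mean_force[mask],
                             self.mfl[mask], self.condition_label)

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_s": self.window_times}
        for j, ch in enumerate(self.channel_labels):
            cols[f"rms_{ch}"] = self.rms[:, j]
            cols[f"arv_{ch}"] = self.arv[:, j]
            cols[f"mnf_{ch}"] = self.mnf[:, j]
            cols[f"mnfarv_{ch}"] = self.mnf_arv[:, j]
        cols["force_N"] = self.mean_force
        cols["mfl"] = self.mfl
        cols["condition"] = self.condition_label
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        channels = [c[len("rms_"):] for c in df.columns if c.startswith("rms_")]
        if not channels or "time_s" not in df.columns:
            raise ValueError("not a feature table: need time_s and rms_* columns")
        stack = lambda p: np.column_stack([df[f"{p}_{ch}"].to_numpy()
                                           for ch in channels])
        cond = str(df["condition"].iloc[0]) if "condition" in df.columns else ""
        return cls(df["time_s"].to_numpy(float), channels, stack("rms"),
                   stack("arv"), stack("mnf"), stack("mnfarv"),
                   df["force_N"].to_numpy(float),
                   df["mfl"].to_numpy(float) if "mfl" in df.columns else None,
                   cond)


def extract_features(bundle: SessionBundle,
                     filter_spec: FilterSpec = FilterSpec(),
                     window_spec: WindowSpec = WindowSpec()) -> FeatureMatrix:
    """Run the conditioning chain and compute the per-window feature matrix.

    sEMG is band-passed and notch-filtered, each channel segmented with the
    overlapped windowing scheme, and the four features computed per window;
    the force trace is averaged over the same [start, start+length) intervals.
    Windows containing any undefined feature are dropped (count logged).
    """
    emg = notch(bandpass(bundle.emg, filter_spec), filter_spec)
    rate = emg.sample_rate
    starts = window_starts(emg.samples.shape[1], rate, window_spec)
    n = starts.size
    c = emg.n_channels
    R = np.empty((n, c)); A = np.empty((n, c))
    M = np.empty((n, c)); MA = np.empty((n, c))
    centers = None
    for j in range(c):
        wins, centers = segment(emg.samples[j], rate, window_spec)
        R[:, j] = np.sqrt(np.mean(wins**2, axis=1))
        A[:, j] = np.mean(np.abs(wins), axis=1)
        f, p = _signal.periodogram(wins, fs=rate, detrend="constant",
                                   window="boxcar", axis=1)
        tot = p.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            M[:, j] = np.where(tot > 0, (p * f).sum(axis=1) / tot, np.nan)
            MA[:, j] = np.where(A[:, j] > 0, M[:, j] / A[:, j], np.nan)

    force_wins = align_force(bundle.force, window_spec, starts)
    mean_force = np.array([np.mean(w) for w in force_wins])

    keep = ~(np.isnan(M).any(axis=1) | np.isnan(MA).any(axis=1)
             | np.isnan(mean_force))
    dropped = int(n - keep.sum())
    if dropped:
        logger.info("extract_features: dropped %d/%d windows with undefined "
                    "features", dropped, n)
    if keep.sum() == 0:
        raise ValueError("no analysis windows survived feature extraction")
    fm = FeatureMatrix(centers[keep], list(emg.channel_labels), R[keep],
                       A[keep], M[keep], MA[keep], mean_force[keep],
                       condition_label=bundle.condition_label)
    return fm


def select_steady(fm: FeatureMatrix, bundle: SessionBundle,
                  window_spec: WindowSpec = WindowSpec()) -> FeatureMatrix:
    """Keep only windows fully inside steady-contraction segments.

    MVC probe windows are reserved for fatigue anchoring; training on them
    would leak the fatigue label into the force target.
    """
    half = window_spec.length_ms / 2000.0
    mask = np.zeros(fm.n_windows, dtype=bool)
    for start, end, _ in bundle.session.steady_segments:
        mask |= ((fm.window_times - half >= start - 1e-9)
                 & (fm.window_times + half <= end + 1e-9))
    return fm.subset(mask)
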