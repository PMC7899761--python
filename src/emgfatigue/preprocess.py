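"""Signal conditioning: band-pass, power-line notch, overlapped windowing.

All filtering is zero-phase (forward-backward), appropriate for an offline
pipeline and keeping features aligned in time with the force trace.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .synthgen import EmgRecording, ForceRecording

__all__ = ["FilterSpec", "WindowSpec", "bandpass", "notch", "segment",
           "align_force"]


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass + notch configuration.

    The analog acquisition band of the emulated hardware is 20-500 Hz; at
    1000 Hz sampling a digital edge at Nyquist is ill-posed, so the default
    upper edge is 450 Hz (>99% of typical sEMG power lies below it).
    """

    low_hz: float = 20.0
    high_hz: float = 450.0
    order: int = 4
    notch_hz: float = 50.0
    notch_q: float = 30.0

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError("need 0 < low_hz < high_hz")
        if self.order < 2:
            raise ValueError("order must be >= 2")
        if self.notch_q <= 0:
            raise ValueError("notch_q must be > 0")


@dataclass(frozen=True)
class WindowSpec:
    """Overlapped analysis windows: 300 ms length, 100 ms shift by default."""

    length_ms: float = 300.0
    shift_ms: float = 100.0

    def __post_init__(self) -> None:
        if not (0 < self.shift_ms <= self.length_ms):
            raise ValueError("need 0 < shift_ms <= length_ms")

    def length_samples(self, rate: float) -> int:
        return int(round(self.length_ms * rate / 1000.0))

    def shift_samples(self, rate: float) -> int:
        return int(round(self.shift_ms * rate / 1000.0))


def _check_edges(spec: FilterSpec, rate: float) -> None:
    nyq = rate / 2.0
    if spec.high_hz >= nyq:
        raise ValueError(
            f"band edge high_hz={spec.high_hz} Hz is at or above Nyquist "
            f"({nyq} Hz)")
    if spec.notch_hz >= nyq:
        raise ValueError(
            f"notch_hz={spec.notch_hz} Hz is at or above Nyquist ({nyq} Hz)")


def bandpass(rec: EmgRecording, spec: FilterSpec = FilterSpec()) -> EmgRecording:
    """Zero-phase Butterworth band-pass, applied per channel."""
    _check_edges(spec, rec.sample_rate)
    sos = signal.butter(spec.order, [spec.low_hz, spec.high_hz],
                        btype="bandpass", fs=rec.sample_rate, output="sos")
    out = signal.sosfiltfilt(sos, rec.samples, axis=1)
    return replace(rec, samples=out)


def notch(rec: EmgRecording, spec: FilterSpec = FilterSpec()) -> EmgRecording:
    """Zero-phase IIR notch at the power-line frequency, applied per channel."""
    _check_edges(spec, rec.sample_rate)
    b, a = signal.iirnotch(spec.notch_hz, spec.notch_q, fs=rec.sample_rate)
    out = signal.filtfilt(b, a, rec.samples, axis=1)
    return replace(rec, samples=out)


def segment(x: np.ndarray, sample_rate: float,
            spec: WindowSpec = WindowSpec()) -> tuple[np.ndarray, np.ndarray]:
    """Split a single-channel vector into overlapped windows.

    Window k covers samples [k*S, k*S + W) (0-based, half-open); trailing
    samples that do not fill a window are discarded.  Returns (windows, centers)
    where windows is (n, W) and centers are window-centre times in seconds.
    """
    x = np.asarray(x, dtype=float)
    W = spec.length_samples(sample_rate)
    S = spec.shift_samples(sample_rate)
    if x.size < W:
        raise ValueError(
            f"signal of {x.size} samples is too short for a {W}-sample window")
    n = (x.size - W) // S + 1
    idx = np.arange(W)[None, :] + S * np.arange(n)[:, None]
    centers = (S * np.arange(n) + W / 2.0) / sample_rate
    return x[idx], centers


def window_starts(n_samples: int, sample_rate: float,
                  spec: WindowSpec = WindowSpec()) -> np.ndarray:
    """Start times (s) of the windows `segment` would produce."""
    W = spec.length_samples(sample_rate)
    S = spec.shift_samples(sample_rate)
    n = (n_samples - W) // S + 1
    return S * np.arange(n) / sample_rate


def align_force(force: ForceRecording, spec: WindowSpec,
                emg_window_starts: np.ndarray) -> list[np.ndarray]:
    """Force samples falling in each sEMG analysis window.

    For each window start t the samples with timestamps in [t, t + length)
    are returned (30 samples per 300 ms window at 100 Hz).
    """
    starts = np.asarray(emg_window_starts, dtype=float)
    length_s = spec.length_ms / 1000.0
    t = force.times
    out: list[np.ndarray] = []
    for k, s in enumerate(starts):
        i0 = int(np.searchsorted(t, s - 1e-12, side="left"))
        i1 = int(np.searchsorted(t, s + length_s - 1e-12, side="left"))
        if i0 >= i1 or i1 > t.size:
            raise ValueError(
                f"window {k} ([{s:.3f}, {s + length_s:.3f}) s) lies outside "
                f"the force recording span")
        out.append(force.force[i0:i1])
    return out
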