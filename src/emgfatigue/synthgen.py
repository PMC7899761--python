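"""Synthetic sEMG / grasp-force fatigue-session generator.

Simulates the static-contraction protocol used for force-based fatigue
assessment: an initial 5 s maximal voluntary contraction (MVC), then repeated
loops of a 10 s steady hold at x% of the initial MVC followed by a 5 s MVC
probe, continuing without rest until the measured MVC falls below the required
force level.  Ground-truth fatigue is expressed as Maximum Force Loss (MFL),
growing linearly with accumulated contraction time at a configurable rate.

The sEMG model captures the two phenomenological fatigue signatures relied on
downstream: at fixed activation the signal RMS rises with MFL (factor
``1 + alpha*mfl``) and its spectral mean frequency falls (factor
``1 - beta*mfl``).  Segments are band-limited Gaussian noise synthesised in
the frequency domain with a Gaussian-bump power spectrum centred on the target
mean frequency, then rescaled so the segment RMS matches its analytic target
exactly before baseline noise is added.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ChannelModel",
    "SessionProtocolSpec",
    "EmgRecording",
    "ForceRecording",
    "SessionRecord",
    "FatigueTrajectory",
    "SessionBundle",
    "DEFAULT_CHANNELS",
    "TABLE_GRADIENTS",
    "synth_emg_segment",
    "synth_force_segment",
    "simulate_session",
    "simulate_cohort",
]

#: Fitted MFL-per-second fatigue rates at the three static-contraction levels.
TABLE_GRADIENTS: dict[float, float] = {0.5: 0.0077, 0.6: 0.0108, 0.7: 0.0532}


def _require_finite(**params: float) -> None:
    for name, value in params.items():
        if not np.isfinite(value):
            raise ValueError(f"parameter {name!r} must be finite, got {value!r}")


@dataclass(frozen=True)
class ChannelModel:
    """sEMG generation model for one muscle channel.

    gain is the segment RMS per unit activation in the non-fatigued state;
    alpha and beta are the fractional RMS increase and mean-frequency decrease
    per unit MFL; noise_floor is the RMS of additive baseline noise.

    level_exp models the synergy shift across forearm muscles: during steady
    holds the channel's share of the drive scales as
    ``(target_level / 0.75)**level_exp``, so muscles with larger exponents
    contribute relatively more at stronger grasps.  Without such a shift the
    capacity-relative drive of every session converges to 1 at exhaustion and
    the force level becomes unrecoverable from the signals by construction.
    """

    muscle_label: str
    gain: float = 0.5
    center_freq: float = 110.0
    alpha: float = 0.8
    beta: float = 0.3
    noise_floor: float = 0.01
    level_exp: float = 0.0

    def __post_init__(self) -> None:
        _require_finite(gain=self.gain, center_freq=self.center_freq,
                        alpha=self.alpha, beta=self.beta,
                        noise_floor=self.noise_floor,
                        level_exp=self.level_exp)
        if self.level_exp < 0:
            raise ValueError("level_exp must be >= 0")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if not (0 <= self.beta < 1):
            raise ValueError("beta must lie in [0, 1)")
        if not (20 < self.center_freq < 450):
            raise ValueError("center_freq must lie in (20, 450) Hz")
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be >= 0")


#: One channel per target muscle of the grasp task.
DEFAULT_CHANNELS: tuple[ChannelModel, ...] = (
    ChannelModel("palmaris_longus", gain=0.45, center_freq=105.0,
                 level_exp=0.0),
    ChannelModel("flexor_carpi_ulnaris", gain=0.60, center_freq=95.0,
                 level_exp=1.0),
    ChannelModel("extensor_digitorum", gain=0.50, center_freq=120.0,
                 level_exp=2.0),
)


@dataclass(frozen=True)
class SessionProtocolSpec:
    """Protocol parameters for one static-contraction session.

    target_level is the steady-hold force as a fraction of the initial MVC;
    gradient is the fatigue rate in MFL per second of active contraction.
    """

    target_level: float = 0.7
    mvc_i: float = 500.0
    mvc_hold_s: float = 5.0
    steady_hold_s: float = 10.0
    gradient: float = TABLE_GRADIENTS[0.7]
    tremor_sd: float = 3.0
    mvc_noise_sd: float = 2.0
    max_loops: int = 200
    seed: int = 0
    emg_rate: float = 1000.0
    force_rate: float = 100.0

    def __post_init__(self) -> None:
        _require_finite(target_level=self.target_level, mvc_i=self.mvc_i,
                        gradient=self.gradient, tremor_sd=self.tremor_sd,
                        mvc_noise_sd=self.mvc_noise_sd)
        if not (0 < self.target_level < 1):
            raise ValueError("target_level must lie in (0, 1)")
        if self.mvc_i <= 0:
            raise ValueError("mvc_i must be > 0")
        if self.gradient < 0:
            raise ValueError("gradient must be >= 0")
        if self.max_loops < 1:
            raise ValueError("max_loops must be >= 1")
        if self.mvc_hold_s <= 0 or self.steady_hold_s <= 0:
            raise ValueError("phase durations must be > 0")


@dataclass
class EmgRecording:
    """Multichannel sEMG samples on a common clock (channels x time)."""

    sample_rate: float
    channel_labels: list[str]
    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError("channel_labels must match the number of rows")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.shape[1]) / self.sample_rate


@dataclass
class ForceRecording:
    """Grasp-force trace in newtons."""

    sample_rate: float
    force: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if np.any(self.force < 0):
            raise ValueError("force values must be >= 0")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.force.size) / self.sample_rate


@dataclass
class SessionRecord:
    """MVC bookkeeping for one session.

    mvc_trials holds (time_s, measured MVC_t) pairs, the first being the
    initial trial; steady_segments holds (start_s, end_s, target_force_N).
    """

    mvc_i: float
    mvc_f: float
    mvc_trials: list[tuple[float, float]]
    steady_segments: list[tuple[float, float, float]]
    terminated: bool = False


@dataclass
class FatigueTrajectory:
    """Ground-truth MFL over session time, clipped to [0, 1]."""

    times: np.ndarray
    mfl_true: np.ndarray
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mfl_true = np.asarray(self.mfl_true, dtype=float)
        if self.times.shape != self.mfl_true.shape:
            raise ValueError("times and mfl_true must have equal length")


@dataclass
class SessionBundle:
    emg: EmgRecording
    force: ForceRecording
    session: SessionRecord
    fatigue: FatigueTrajectory
    condition_label: str = ""


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def synth_emg_segment(activation: float, mfl: float, channel: ChannelModel,
                      duration_s: float, sample_rate: float = 1000.0,
                      seed: int | np.random.Generator = 0) -> np.ndarray:
    """Synthesise one stationary sEMG segment.

    The segment is Gaussian noise with a Gaussian-bump power spectrum centred
    at ``center_freq * (1 - beta*mfl)`` (bump width = a quarter of the centre,
    so the spectral mean equals the centre to well under 1%).  It is rescaled
    so its RMS equals ``gain * activation * (1 + alpha*mfl)`` exactly, then
    white baseline noise of RMS ``noise_floor`` is added.
    """
    _require_finite(activation=activation, mfl=mfl, duration_s=duration_s,
                    sample_rate=sample_rate)
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    if not (0 <= activation <= 1) or not (0 <= mfl <= 1):
        raise ValueError("activation and mfl must lie in [0, 1]")
    rng = _rng(seed)
    n = int(round(duration_s * sample_rate))
    target_rms = channel.gain * activation * (1 + channel.alpha * mfl)
    if target_rms > 0:
        fc = channel.center_freq * (1 - channel.beta * mfl)
        sigma = fc / 4.0
        freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
        amp = np.exp(-((freqs - fc) ** 2) / (4.0 * sigma**2))  # sqrt of PSD
        coeff = amp * (rng.standard_normal(freqs.size)
                       + 1j * rng.standard_normal(freqs.size))
        coeff[0] = 0.0  # no DC component
        x = np.fft.irfft(coeff, n=n)
        x *= target_rms / np.sqrt(np.mean(x**2))
    else:
        x = np.zeros(n)
    if channel.noise_floor > 0:
        x = x + channel.noise_floor * rng.standard_normal(n)
    return x


def synth_force_segment(target_force: float, duration_s: float,
                        sample_rate: float = 100.0, tremor_sd: float = 0.0,
                        seed: int | np.random.Generator = 0) -> np.ndarray:
    """Steady force-tracking trace: target plus Gaussian tremor, floored at 0 N."""
    _require_finite(target_force=target_force, tremor_sd=tremor_sd)
    if target_force < 0:
        raise ValueError("target_force must be >= 0")
    if tremor_sd < 0:
        raise ValueError("tremor_sd must be >= 0")
    rng = _rng(seed)
    n = int(round(duration_s * sample_rate))
    out = np.full(n, float(target_force))
    if tremor_sd > 0:
        out = out + tremor_sd * rng.standard_normal(n)
    return np.clip(out, 0.0, None)


def _mfl_true(t: np.ndarray | float, gradient: float) -> np.ndarray | float:
    return np.clip(gradient * np.asarray(t, dtype=float), 0.0, 1.0)


def simulate_session(spec: SessionProtocolSpec,
                     channels: tuple[ChannelModel, ...] = DEFAULT_CHANNELS,
                     ) -> SessionBundle:
    """Simulate one full static-contraction session.

    Rest periods carry no signal and are compressed out, so session time is
    the active-contraction clock and ground-truth MFL(t) = min(1, gradient*t).
    The achievable maximum force is ``mvc_i - MFL*(mvc_i - mvc_f)``; the MVC
    probes measure the *unclipped* linear decline (a subject past exhaustion
    fails the required force) plus measurement noise, and the session ends
    when a measured MVC_t falls below MVC_f.  During steady holds the neural
    drive rises with fatigue (activation = target force / remaining capacity),
    which is what makes amplitude features fatigue-confounded at fixed force.
    """
    if len(channels) < 1:
        raise ValueError("at least one channel model is required")
    rng = np.random.default_rng(spec.seed)
    g = spec.gradient
    mvc_f = spec.target_level * spec.mvc_i
    span = spec.mvc_i - mvc_f

    def measured_capacity(t: float) -> float:
        raw = spec.mvc_i - g * t * span  # unclipped decline
        noise = rng.normal(0.0, spec.mvc_noise_sd) if spec.mvc_noise_sd > 0 else 0.0
        return max(0.0, raw + noise)

    # phase plan: (kind, start_s, duration_s); MVC probe value measured at the
    # phase start (the peak of a declining maximal effort)
    phases: list[tuple[str, float, float]] = []
    mvc_trials: list[tuple[float, float]] = []
    steady_segments: list[tuple[float, float, float]] = []
    terminated = False

    t = 0.0
    mvc_trials.append((t, measured_capacity(t)))
    phases.append(("mvc", t, spec.mvc_hold_s))
    t += spec.mvc_hold_s
    for _ in range(spec.max_loops):
        phases.append(("steady", t, spec.steady_hold_s))
        steady_segments.append((t, t + spec.steady_hold_s, mvc_f))
        t += spec.steady_hold_s
        mvc_t = measured_capacity(t)
        mvc_trials.append((t, mvc_t))
        phases.append(("mvc", t, spec.mvc_hold_s))
        t += spec.mvc_hold_s
        if mvc_t < mvc_f:
            terminated = True
            break
    total_s = t

    # force trace
    n_force = int(round(total_s * spec.force_rate))
    force = np.empty(n_force)
    ft = np.arange(n_force) / spec.force_rate
    for kind, start, dur in phases:
        i0 = int(round(start * spec.force_rate))
        i1 = int(round((start + dur) * spec.force_rate))
        seg_t = ft[i0:i1]
        if kind == "steady":
            base = np.full(seg_t.size, mvc_f)
        else:
            base = np.maximum(0.0, spec.mvc_i - g * seg_t * span)
        if spec.tremor_sd > 0:
            base = base + spec.tremor_sd * rng.standard_normal(seg_t.size)
        force[i0:i1] = np.clip(base, 0.0, None)

    # sEMG: per channel, per phase, in ~1 s stationary blocks with the
    # mid-block fatigue state
    n_emg = int(round(total_s * spec.emg_rate))
    samples = np.empty((len(channels), n_emg))
    for ci, ch in enumerate(channels):
        sig = np.empty(n_emg)
        for kind, start, dur in phases:
            pos = start
            end = start + dur
            while pos < end - 1e-9:
                block = min(1.0, end - pos)
                mid = pos + block / 2.0
                m = float(_mfl_true(mid, g))
                if kind == "mvc":
                    act = 1.0
                else:
                    capacity = spec.mvc_i - m * span
                    act = min(1.0, mvc_f / capacity)
                    act *= (spec.target_level / 0.75) ** ch.level_exp
                seg = synth_emg_segment(act, m, ch, block, spec.emg_rate, rng)
                i0 = int(round(pos * spec.emg_rate))
                sig[i0:i0 + seg.size] = seg[:n_emg - i0]
                pos += block
        samples[ci] = sig

    label = f"{int(round(spec.target_level * 100))}%MVC"
    traj_t = np.arange(n_force) / spec.force_rate
    bundle = SessionBundle(
        emg=EmgRecording(spec.emg_rate, [c.muscle_label for c in channels], samples),
        force=ForceRecording(spec.force_rate, force),
        session=SessionRecord(spec.mvc_i, mvc_f, mvc_trials, steady_segments,
                              terminated),
        fatigue=FatigueTrajectory(traj_t, _mfl_true(traj_t, g), label),
        condition_label=label,
    )
    return bundle


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject multiplicative jitter applied to channel and rate parameters."""

    gain_factor: np.ndarray
    alpha_factor: np.ndarray
    beta_factor: np.ndarray
    gradient_factor: float


def simulate_cohort(n_subjects: int,
                    base_spec: SessionProtocolSpec = SessionProtocolSpec(),
                    jitter: float = 0.1,
                    seed: int = 0,
                    channels: tuple[ChannelModel, ...] = DEFAULT_CHANNELS,
                    levels: tuple[float, ...] = (0.5, 0.6, 0.7),
                    gradients: dict[float, float] | None = None,
                    ) -> list[list[SessionBundle]]:
    """Simulate a cohort: one session per target level per subject.

    Subject individuality is a single multiplicative lognormal-ish jitter
    (1 + jitter*z, floored at 0.2) on channel gain/alpha/beta and on the
    per-level fatigue gradients, drawn once per subject.  Returns a list of
    per-subject session lists, ordered by level.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    gradients = dict(TABLE_GRADIENTS) if gradients is None else gradients
    root = np.random.SeedSequence(seed)
    cohort: list[list[SessionBundle]] = []
    for si, ss in enumerate(root.spawn(n_subjects)):
        sub_rng = np.random.default_rng(ss)

        def factor(size=None):
            return np.maximum(0.2, 1.0 + jitter * sub_rng.standard_normal(size))

        chs = tuple(
            replace(ch,
                    gain=ch.gain * factor(),
                    alpha=ch.alpha * factor(),
                    beta=min(0.99, ch.beta * factor()))
            for ch in channels
        )
        grad_factor = factor()
        sessions = []
        for li, level in enumerate(levels):
            grad = gradients.get(level, base_spec.gradient) * grad_factor
            sess_seed = int(sub_rng.integers(0, 2**31 - 1))
            spec = replace(base_spec, target_level=level, gradient=float(grad),
                           seed=sess_seed)
            sessions.append(simulate_session(spec, chs))
        cohort.append(sessions)
    return cohort
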