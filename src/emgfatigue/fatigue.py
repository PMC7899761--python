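"""Maximum Force Loss (MFL): the force-based muscle-fatigue metric.

MFL quantifies fatigue as the normalised decline of maximal voluntary
contraction.  The basic form is (MVC_i - MVC_t)/MVC_i; under static
contraction at a required force MVC_f the operative form is

    MFL = (MVC_i - MVC_t) / (MVC_i - MVC_f),

which runs from 0 (fresh) to 1 (exhausted: the maximal force has fallen to
the required level).  This module computes MFL from session MVC probes,
assigns it to analysis windows, fits its linear growth rate against
contraction time, and fits the nonlinear rate-vs-level model
MFL = a*exp(b*level)*t + c across contraction levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .synthgen import SessionBundle, SessionRecord

logger = logging.getLogger(__name__)

__all__ = ["GradientFit", "NonlinearFatigueModel", "mfl_basic", "mfl_static",
           "anchor_mfl", "assign_mfl", "fit_gradient",
           "fit_session_gradient", "fit_nonlinear"]


def mfl_basic(mvc_i: float, mvc_t) -> np.ndarray | float:
    """Basic maximum force loss, (MVC_i - MVC_t)/MVC_i."""
    if mvc_i <= 0:
        raise ValueError("mvc_i must be > 0")
    return (mvc_i - np.asarray(mvc_t, dtype=float)) / mvc_i \
        if np.ndim(mvc_t) else (mvc_i - mvc_t) / mvc_i


def mfl_static(mvc_i: float, mvc_t, mvc_f: float, clip: bool = True):
    """Static-contraction MFL, (MVC_i - MVC_t)/(MVC_i - MVC_f).

    0 marks the non-fatigued state (MVC_t = MVC_i) and 1 the exhausted state
    (MVC_t = MVC_f).  Measurement noise can push the raw ratio outside [0, 1];
    by default values are clipped and clip events logged.  ``clip=False``
    returns the raw ratio, which is what slope fitting should use (saturated
    anchors would bias the rate estimate).
    """
    if mvc_i <= mvc_f:
        raise ValueError("degenerate session: need mvc_i > mvc_f")
    if mvc_f < 0:
        raise ValueError("mvc_f must be >= 0")
    raw = (mvc_i - np.asarray(mvc_t, dtype=float)) / (mvc_i - mvc_f)
    if not clip:
        return raw if np.ndim(mvc_t) else float(raw)
    clipped = np.clip(raw, 0.0, 1.0)
    n_clip = int(np.sum(raw != clipped))
    if n_clip:
        logger.info("mfl_static: clipped %d/%d values into [0, 1]",
                    n_clip, raw.size)
    return clipped if np.ndim(mvc_t) else float(clipped)


def anchor_mfl(session: SessionRecord, clip: bool = True
               ) -> tuple[np.ndarray, np.ndarray]:
    """(times, MFL) at each MVC probe of a session."""
    if len(session.mvc_trials) < 1:
        raise ValueError("session has no MVC trials to anchor on")
    t = np.array([tt for tt, _ in session.mvc_trials])
    v = np.array([vv for _, vv in session.mvc_trials])
    return t, mfl_static(session.mvc_i, v, session.mvc_f, clip=clip)


def assign_mfl(session: SessionRecord, window_times) -> np.ndarray:
    """Per-window MFL by piecewise-linear interpolation between MVC anchors.

    MFL grows linearly during sustained contraction, so anchors are joined
    linearly; before the first anchor the muscle is taken as fresh (0), after
    the last anchor the last value is held.
    """
    t, m = anchor_mfl(session, clip=True)
    w = np.asarray(window_times, dtype=float)
    return np.interp(w, t, m, left=0.0, right=float(m[-1]))


@dataclass(frozen=True)
class GradientFit:
    """OLS fit of MFL against contraction time."""

    slope: float
    intercept: float
    r2_fit: float
    ci95_slope: tuple[float, float]
    n: int


def fit_gradient(times, mfl) -> GradientFit:
    """Ordinary least squares of MFL on time, with a 95% CI on the slope."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(mfl, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 points to fit a gradient")
    if np.ptp(t) == 0:
        raise ValueError("singular fit: all times are equal")
    res = stats.linregress(t, y)
    half = stats.t.ppf(0.975, t.size - 2) * res.stderr
    return GradientFit(float(res.slope), float(res.intercept),
                       float(res.rvalue**2), (float(res.slope - half),
                                              float(res.slope + half)),
                       int(t.size))


def fit_session_gradient(bundle: SessionBundle,
                         source: str = "anchors") -> GradientFit:
    """Fit the fatigue rate of one simulated or recorded session.

    source="anchors" fits the per-probe MFL computed from measured MVC values
    (raw ratio, unclipped, so saturated probes do not bias the slope);
    source="trajectory" fits the ground-truth trajectory over its
    pre-saturation span (mfl_true < 1).
    """
    if source == "anchors":
        t, m = anchor_mfl(bundle.session, clip=False)
        return fit_gradient(t, m)
    if source == "trajectory":
        keep = bundle.fatigue.mfl_true < 1.0
        return fit_gradient(bundle.fatigue.times[keep],
                            bundle.fatigue.mfl_true[keep])
    raise ValueError(f"unknown source {source!r}")


@dataclass(frozen=True)
class NonlinearFatigueModel:
    """MFL = a * exp(b * level) * t + c across contraction levels."""

    a: float
    b: float
    c: float
    rss: float

    def predict(self, level, t) -> np.ndarray:
        out = self.a * np.exp(self.b * np.asarray(level, dtype=float)) \
            * np.asarray(t, dtype=float) + self.c
        return np.clip(out, 0.0, 1.0)


def fit_nonlinear(datasets) -> NonlinearFatigueModel:
    """Joint least-squares fit of the rate-vs-level fatigue model.

    ``datasets`` is a list of (target_level, times, mfl) triples, one per
    contraction level.  The per-level linear rate a*exp(b*level) is exactly
    log-linear in level, so the initial point comes from regressing
    log(per-level OLS slope) on level; bounds keep a > 0 and |c| <= 0.1.
    """
    if len(datasets) < 2:
        raise ValueError("need data at >= 2 distinct target levels "
                         "(b is unidentifiable from one level)")
    levels, slopes = [], []
    L, T, Y = [], [], []
    for level, t, y in datasets:
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        if t.size < 3:
            raise ValueError("each level needs >= 3 points")
        levels.append(float(level))
        slopes.append(fit_gradient(t, y).slope)
        L.append(np.full(t.size, float(level))); T.append(t); Y.append(y)
    if len(set(levels)) < 2:
        raise ValueError("target levels must be distinct")
    L = np.concatenate(L); T = np.concatenate(T); Y = np.concatenate(Y)

    lv = np.array(levels)
    sl = np.maximum(np.array(slopes), 1e-12)
    b0, loga0 = np.polyfit(lv, np.log(sl), 1)
    p0 = [float(np.exp(loga0)), float(b0), 0.0]

    def model(x, a, b, c):
        level, t = x
        return a * np.exp(b * level) * t + c

    try:
        popt, _ = optimize.curve_fit(
            model, (L, T), Y, p0=p0,
            bounds=([1e-12, -np.inf, -0.1], [np.inf, np.inf, 0.1]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"nonlinear fatigue fit did not converge (start {p0}, "
            f"levels {sorted(set(levels))}): {exc}") from exc
    rss = float(np.sum((model((L, T), *popt) - Y) ** 2))
    return NonlinearFatigueModel(float(popt[0]), float(popt[1]),
                                 float(popt[2]), rss)
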