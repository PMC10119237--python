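"""Time-activity curve fitting and time-integrated activity coefficients.

A measured time-activity curve (TAC) — activity concentration in a volume of
interest, blood concentration, or whole-body retention as fraction of
injected activity (FIA) — is reduced to a time-integrated activity
coefficient (TIAC, hours) by one of three routes:

* mono-exponential least squares (organs and tumours),
* bi-exponential least squares with curve-stripping initialisation
  (blood and whole body),
* trapezoidal integration with an analytic exponential tail, used as a
  fallback when the mono-exponential model does not describe the data.

Time constants ``t`` are related to effective half-lives by
``T_eff = t * ln 2``; a mono-exponential TIAC is ``A * t`` and a
bi-exponential TIAC is ``A1*t1 + A2*t2``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .constants import LN2, LU177_DECAY_RATE_PER_H, LU177_HALF_LIFE_H

__all__ = [
    "MeasurementSeries",
    "RetentionFit",
    "FitFailure",
    "monoexp",
    "biexp",
    "fit_monoexp",
    "fit_biexp",
    "integrate_trapezoid_tail",
    "choose_tail_rate",
    "select_tac_model",
    "fit_series",
    "PHYSICAL_TAU_H",
    "compute_tiac",
    "effective_half_life",
]

KINDS = ("voi", "blood", "wb")

#: Upper bound on fitted time constants (h); far beyond any physical
#: retention for 177Lu, used only to keep the optimiser bounded.
_TAU_MAX = 1e5


class FitFailure(RuntimeError):
    """A TAC could not be described by the requested parametric model."""


@dataclass(frozen=True)
class MeasurementSeries:
    """Timed activity measurements for one source region in one cycle.

    ``values`` are MBq/mL for ``voi`` and ``blood`` series and dimensionless
    fraction of injected activity for ``wb`` series.
    """

    patient_id: str
    cycle: int
    kind: str
    region: str
    times_h: np.ndarray
    values: np.ndarray
    volume_ml: float | None = None
    unit: str = "MBq/mL"

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "values", v)
        if self.kind not in KINDS:
            raise ValueError(f"unknown series kind {self.kind!r}")
        if not (1 <= int(self.cycle) <= 4):
            raise ValueError(f"cycle must be 1-4, got {self.cycle}")
        if t.size < 2 or t.size != v.size:
            raise ValueError("need >= 2 (time, value) samples")
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing and > 0")
        if np.any(v < 0):
            raise ValueError("activity values must be >= 0")
        if self.kind == "voi" and (self.volume_ml is None or self.volume_ml <= 0):
            raise ValueError("voi series require a positive volume_ml")


@dataclass
class RetentionFit:
    """A fitted retention model and its TIAC.

    ``amplitudes``/``time_constants`` are empty for the trapezoid+tail
    route, whose TIAC is stored numerically.
    """

    model: str  # "monoexp" | "biexp" | "trapezoid_tail"
    amplitudes: tuple[float, ...]
    time_constants: tuple[float, ...]
    rss: float
    r_squared: float
    tiac_h: float
    flags: tuple[str, ...] = ()
    series: MeasurementSeries | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be >= 0")
        if any(t <= 0 for t in self.time_constants):
            raise ValueError("time constants must be > 0")
        if self.model == "biexp" and len(self.time_constants) == 2:
            if not self.time_constants[0] < self.time_constants[1]:
                raise ValueError("biexp components must be ordered t1 < t2")
        if self.tiac_h < 0:
            raise ValueError("tiac must be >= 0")


def monoexp(t, amplitude, tau):
    """``A * exp(-t / tau)``; ``tau`` is the time constant in hours."""
    return amplitude * np.exp(-np.asarray(t, dtype=float) / tau)


def biexp(t, a1, a2, tau1, tau2):
    """``A1 exp(-t/t1) + A2 exp(-t/t2)`` with time constants in hours."""
    t = np.asarray(t, dtype=float)
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)


def _r_squared(y: np.ndarray, resid: np.ndarray) -> float:
    rss = float(np.sum(resid**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0.0:
        return 1.0 if rss <= 1e-12 * max(1.0, float(np.max(np.abs(y))) ** 2) else 0.0
    return 1.0 - rss / sst


def fit_monoexp(series: MeasurementSeries, log_scale: bool = False,
                tau_max: float = _TAU_MAX) -> RetentionFit:
    """Least-squares mono-exponential fit of a decaying series.

    Raises :class:`FitFailure` for non-decaying data (last value above the
    first), which directs model selection to the trapezoid route.  An
    all-zero series returns a flagged zero-amplitude fit with TIAC 0.
    ``tau_max`` bounds the fitted time constant; pass the 177Lu physical
    time constant to forbid retention slower than physical decay.
    """
    t, y = series.times_h, series.values
    if np.all(y == 0.0):
        return RetentionFit("monoexp", (0.0,), (1.0,), 0.0, 1.0, 0.0,
                            flags=("all_zero",), series=series)
    if y[-1] > y[0]:
        raise FitFailure("series does not decay (last value above first)")

    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        tau0 = -1.0 / slope if slope < 0 else t[-1]
        a0 = math.exp(intercept)
    else:
        tau0, a0 = t[-1], float(y.max())
    tau0 = min(max(tau0, 1e-3), tau_max)

    if log_scale:
        def model(tt, a, tau):
            return np.log(np.clip(monoexp(tt, a, tau), 1e-300, None))
        ydata = np.log(np.clip(y, 1e-300, None))
    else:
        model, ydata = monoexp, y
    try:
        popt, _ = curve_fit(model, t, ydata, p0=(a0, tau0),
                            bounds=([0.0, 1e-3], [np.inf, tau_max]),
                            maxfev=20000, xtol=1e-13, ftol=1e-13)
    except RuntimeError as exc:  # pragma: no cover - scipy rarely fails here
        raise FitFailure(f"mono-exponential fit did not converge: {exc}") from exc
    a, tau = float(popt[0]), float(popt[1])
    resid = y - monoexp(t, a, tau)
    return RetentionFit("monoexp", (a,), (tau,), float(np.sum(resid**2)),
                        _r_squared(y, resid), a * tau, series=series)


def _strip_init(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Curve-stripping (peel-off) start values: tail from the last two
    positive points, head from the tail-subtracted early points."""
    pos = np.where(y > 0)[0]
    if pos.size < 2:
        return float(y.max()), float(y.max()), 1.0, 50.0
    i2, i1 = pos[-1], pos[-2]
    dt = t[i2] - t[i1]
    if y[i1] > y[i2] > 0:
        lam = math.log(y[i1] / y[i2]) / dt
        tau2 = min(1.0 / lam, _TAU_MAX)
    else:
        tau2 = 2.0 * t[i2]
    a2 = y[i2] * math.exp(min(t[i2] / tau2, 500.0))
    head = y - a2 * np.exp(-t / tau2)
    hmask = (head > 0) & (t < t[i1])
    if hmask.sum() >= 2:
        hs, hi = np.polyfit(t[hmask], np.log(head[hmask]), 1)
        tau1 = -1.0 / hs if hs < 0 else tau2 / 10.0
        a1 = math.exp(hi)
    else:
        tau1, a1 = tau2 / 10.0, max(float(head.max()), 1e-6 * a2)
    tau1 = min(max(tau1, 1e-3), tau2 * 0.99)
    return max(a1, 0.0), max(a2, 0.0), tau1, tau2


def fit_biexp(series: MeasurementSeries, tau_max: float = _TAU_MAX,
              amp_max: float | None = None) -> RetentionFit:
    """Four-parameter bi-exponential least squares with peel-off start.

    Requires at least 4 samples (``ValueError`` directs the caller to
    :func:`fit_monoexp` otherwise); convergence failure across all starting
    points raises :class:`FitFailure`.  Components are returned ordered
    ``t1 < t2`` (fast first).  ``tau_max`` bounds both time constants (the
    pipeline passes the 177Lu physical time constant so noisy tails cannot
    fit slower than physical decay); ``amp_max`` bounds the amplitudes
    (default 50x the observed maximum) so a component faster than the first
    sample time — invisible to the data but unbounded in its TIAC — cannot
    run away.
    """
    t, y = series.times_h, series.values
    if t.size < 4:
        raise ValueError("bi-exponential fit needs >= 4 samples; use fit_monoexp")
    if np.all(y == 0.0):
        return RetentionFit("biexp", (0.0, 0.0), (1.0, 2.0), 0.0, 1.0, 0.0,
                            flags=("all_zero",), series=series)

    ymax = float(y.max())
    if amp_max is None:
        amp_max = 50.0 * ymax
    inits = [_strip_init(t, y)]
    for tau1, tau2 in ((1.0, 50.0), (2.5, 90.0), (0.5, 20.0), (8.0, 150.0)):
        inits.append((0.6 * ymax, 0.4 * ymax, tau1, tau2))

    best = None
    for p0 in inits:
        p0 = (min(p0[0], 0.99 * amp_max), min(p0[1], 0.99 * amp_max),
              min(p0[2], 0.9 * tau_max), min(p0[3], tau_max))
        try:
            popt, _ = curve_fit(
                biexp, t, y, p0=p0,
                bounds=([0.0, 0.0, 1e-3, 1e-3],
                        [amp_max, amp_max, tau_max, tau_max]),
                maxfev=40000, xtol=1e-13, ftol=1e-13)
        except RuntimeError:
            continue
        resid = y - biexp(t, *popt)
        rss = float(np.sum(resid**2))
        if best is None or rss < best[1]:
            best = (popt, rss)
        if rss <= 1e-20 * max(1.0, ymax**2):
            break
    if best is None:
        raise FitFailure("bi-exponential fit did not converge from any start")
    (a1, a2, tau1, tau2), rss = best
    if tau1 > tau2:
        a1, a2, tau1, tau2 = a2, a1, tau2, tau1
    resid = y - biexp(t, a1, a2, tau1, tau2)
    return RetentionFit("biexp", (float(a1), float(a2)),
                        (float(min(tau1, tau2 * (1 - 1e-12))), float(tau2)),
                        rss, _r_squared(y, resid),
                        float(a1 * tau1 + a2 * tau2), series=series)


def integrate_trapezoid_tail(series: MeasurementSeries, tail_rate: float) -> float:
    """Trapezoid TIAC with analytic exponential tail.

    The first measured value is held constant back to t=0 (conservative
    left edge); beyond the last sample the curve decays as
    ``exp(-tail_rate * t)`` so the tail contributes ``last_value /
    tail_rate``.  ``tail_rate`` is a decay constant in 1/h.
    """
    if tail_rate <= 0:
        raise ValueError("tail_rate must be > 0 (decay constant in 1/h)")
    t, y = series.times_h, series.values
    area = float(t[0] * y[0])              # flat extrapolation to t = 0
    area += float(np.trapezoid(y, t))
    area += float(y[-1] / tail_rate)
    return area


def choose_tail_rate(series: MeasurementSeries) -> float:
    """Tail decay constant: terminal slope of the last two points or 177Lu
    physical decay, whichever yields the larger (conservative) TIAC."""
    y, t = series.values, series.times_h
    if y[-2] > y[-1] > 0:
        lam = math.log(y[-2] / y[-1]) / (t[-1] - t[-2])
        return min(lam, LU177_DECAY_RATE_PER_H)
    return LU177_DECAY_RATE_PER_H


def select_tac_model(series: MeasurementSeries, r2_threshold: float = 0.95) -> str:
    """Choose between ``monoexp`` and ``trapezoid_tail`` for an organ/tumour TAC.

    The parametric model wins when the fit converges with R^2 at or above
    the threshold (ties go to the parametric model) on a decaying series;
    anything else — a visible uptake phase, a flat or rising curve, poor
    fit — falls back to the trapezoid with a physical-decay tail.
    """
    if np.all(series.values == 0.0):
        return "monoexp"  # flagged zero fit, TIAC 0
    if not series.values[-1] < series.values[0]:
        return "trapezoid_tail"
    try:
        fit = fit_monoexp(series)
    except FitFailure:
        return "trapezoid_tail"
    return "monoexp" if fit.r_squared >= r2_threshold else "trapezoid_tail"


#: Physical time constant of 177Lu (h): no retention decays slower.
PHYSICAL_TAU_H = LU177_HALF_LIFE_H / LN2


def fit_series(series: MeasurementSeries, r2_threshold: float = 0.95,
               tau_max: float = PHYSICAL_TAU_H) -> RetentionFit:
    """Fit one measurement series with the kind-appropriate model.

    Blood and whole-body series get the bi-exponential model (falling back
    to mono-exponential, flagged, when under-determined or non-convergent);
    VOI series go through :func:`select_tac_model`.  Time constants are
    capped at the 177Lu physical time constant by default: biological
    clearance can only speed up, never slow down, the physical decay.
    """
    if series.kind in ("blood", "wb"):
        amp_max = 1.0 if series.kind == "wb" else None  # FIA cannot exceed 1
        try:
            if series.times_h.size >= 4:
                return fit_biexp(series, tau_max=tau_max, amp_max=amp_max)
        except FitFailure:
            pass
        try:
            fit = fit_monoexp(series, tau_max=tau_max)
        except FitFailure:
            return _trapezoid_fit(series, ("biexp_fallback",))
        fit.flags = fit.flags + ("biexp_fallback",)
        return fit
    if select_tac_model(series, r2_threshold) == "monoexp":
        return fit_monoexp(series, tau_max=tau_max)
    return _trapezoid_fit(series)


def _trapezoid_fit(series: MeasurementSeries, flags: tuple[str, ...] = ()) -> RetentionFit:
    rate = choose_tail_rate(series)
    tiac = integrate_trapezoid_tail(series, rate)
    return RetentionFit("trapezoid_tail", (), (), math.nan, math.nan, tiac,
                        flags=flags + ("tail_rate=%.6g" % rate,), series=series)


def compute_tiac(fit: RetentionFit) -> float:
    """TIAC (h per unit administered activity) of a fitted model."""
    if fit.model == "monoexp":
        return fit.amplitudes[0] * fit.time_constants[0]
    if fit.model == "biexp":
        a1, a2 = fit.amplitudes
        t1, t2 = fit.time_constants
        return a1 * t1 + a2 * t2
    if fit.model == "trapezoid_tail":
        return fit.tiac_h
    raise ValueError(f"unknown model {fit.model!r}")


def effective_half_life(fit: RetentionFit) -> list[float]:
    """Effective half-lives (h), one per fitted component: ``t * ln 2``."""
    if not fit.time_constants:
        warnings.warn("trapezoid fit has no time constants", stacklevel=2)
        return []
    return [tc * LN2 for tc in fit.time_constants]
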