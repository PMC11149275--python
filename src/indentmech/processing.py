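"""Curve smoothing, loading-slope fitting, QC gating and equilibrium load.

The tangent-modulus slope is an ordinary least-squares fit of load on
displacement restricted to the upper 35% of the loading phase's
displacement span; fits with R^2 < 0.80 are discarded.  The equilibrium
load is the mean over the final 10% of the hold phase, with a residual
relaxation-rate diagnostic so incomplete relaxation is visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from scipy.stats import linregress

from .curves import IndentationCurve
from .errors import FitError, ParameterError

DEFAULT_UPPER_FRACTION = 0.35
DEFAULT_R2_THRESHOLD = 0.80
DEFAULT_TAIL_FRACTION = 0.10


@dataclass(frozen=True)
class LinearFit:
    """OLS fit of load (N) on displacement (um) over a stated window."""

    slope_n_per_um: float
    intercept_n: float
    r_squared: float
    n_points: int
    window: str

    def __post_init__(self):
        if self.n_points < 10:
            raise FitError(f"linear fit needs >= 10 points, got {self.n_points}")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise FitError(f"R^2 out of [0,1]: {self.r_squared}")


@dataclass(frozen=True)
class QCDecision:
    accepted: bool
    reason: str | None = None


@dataclass(frozen=True)
class EquilibriumResult:
    """Relaxed hold-phase state: mean load/displacement over the tail."""

    p_eq_n: float
    x0_eq_um: float
    relaxation_rate_n_per_s: float
    n_tail: int


def default_sg_window(n_samples: int, minimum: int = 11) -> int:
    """Odd window nearest 5% of the series length, at least ``minimum``."""
    w = max(minimum, int(round(0.05 * n_samples)))
    return w if w % 2 == 1 else w + 1


def smooth_curve(curve: IndentationCurve, window_length: int | None = None,
                 polyorder: int = 3, smooth_displacement: bool = False) -> IndentationCurve:
    """Savitzky-Golay smooth the load (and optionally displacement) channel.

    Endpoints are handled by the filter's one-sided polynomial fit
    (``mode="interp"``), so the array length never changes.
    """
    n = len(curve)
    if window_length is None:
        window_length = min(default_sg_window(n), n if n % 2 == 1 else n - 1)
    if window_length % 2 == 0:
        raise ParameterError(f"window_length must be odd, got {window_length}")
    if window_length > n:
        raise ParameterError(
            f"window_length {window_length} exceeds series length {n}")
    if polyorder >= window_length:
        raise ParameterError("polyorder must be < window_length")
    load = savgol_filter(curve.load, window_length, polyorder, mode="interp")
    disp = curve.displacement
    if smooth_displacement:
        disp = savgol_filter(disp, window_length, polyorder, mode="interp")
    return curve.with_arrays(load=load, displacement=disp)


def fit_loading_slope(loading: IndentationCurve,
                      upper_fraction: float = DEFAULT_UPPER_FRACTION) -> LinearFit:
    """OLS slope of load vs displacement over the upper-fraction window.

    The window keeps samples whose displacement is at least
    ``(1 - upper_fraction) * max(displacement)`` of the phase.
    """
    if not (0.0 < upper_fraction < 1.0):
        raise ParameterError(f"upper_fraction must lie in (0,1), got {upper_fraction}")
    x = loading.displacement
    p = loading.load
    xmax = float(np.max(x))
    if xmax <= 0:
        raise FitError("loading phase has no positive displacement span")
    cut = (1.0 - upper_fraction) * xmax
    sel = x >= cut
    if int(sel.sum()) < 10:
        raise FitError(
            f"only {int(sel.sum())} samples in upper-{upper_fraction:.0%} window")
    xw, pw = x[sel], p[sel]
    if np.ptp(xw) == 0.0:
        raise FitError("zero displacement variance in fit window")
    res = linregress(xw, pw)
    r2 = float(res.rvalue ** 2) if np.isfinite(res.rvalue) else 0.0
    return LinearFit(slope_n_per_um=float(res.slope), intercept_n=float(res.intercept),
                     r_squared=min(r2, 1.0), n_points=int(sel.sum()),
                     window=f"displacement in [{cut:.3g}, {xmax:.3g}] um")


def qc_gate(fit: LinearFit, r2_threshold: float = DEFAULT_R2_THRESHOLD) -> QCDecision:
    """Accept the fit unless R^2 < threshold (strict less-than)."""
    if fit.r_squared < r2_threshold:
        return QCDecision(accepted=False,
                          reason=f"R^2 = {fit.r_squared:.4f} < {r2_threshold}")
    return QCDecision(accepted=True)


def equilibrium_load(hold: IndentationCurve,
                     tail_fraction: float = DEFAULT_TAIL_FRACTION) -> EquilibriumResult:
    """Mean load/displacement over the final ``tail_fraction`` of the hold.

    Also reports the residual |dP/dt| over the tail as a
    relaxation-completeness diagnostic.
    """
    if not (0.0 < tail_fraction <= 1.0):
        raise ParameterError(f"tail_fraction must lie in (0,1], got {tail_fraction}")
    t = hold.time
    dur = float(t[-1] - t[0])
    if dur < 1.0:
        raise FitError(f"hold phase lasts {dur:.2f} s; need >= 1 s for equilibrium")
    sel = t >= t[-1] - tail_fraction * dur
    if int(sel.sum()) < 5:
        raise FitError(f"equilibrium tail has {int(sel.sum())} samples; need >= 5")
    tw, pw = t[sel], hold.load[sel]
    rate = float(np.polyfit(tw, pw, 1)[0]) if np.ptp(tw) > 0 else 0.0
    return EquilibriumResult(p_eq_n=float(np.mean(pw)),
                             x0_eq_um=float(np.mean(hold.displacement[sel])),
                             relaxation_rate_n_per_s=rate,
                             n_tail=int(sel.sum()))
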