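"""Summary statistics of sigmoidal polymerization kinetics.

A ThT trace (or a simulated polymer-mass series) is reduced to the
half-time t1/2 (when half of the final polymerized mass is reached),
the maximal slope k_max at the inflexion, and the lag time obtained from
the tangent at the inflexion.  The apparent nucleus size is inferred
from the log-log scaling of t1/2 with the initial monomer concentration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import savgol_filter

__all__ = [
    "KineticTrace",
    "SigmoidFit",
    "half_time",
    "max_slope",
    "lag_time",
    "fit_sigmoid",
    "apparent_nucleus_size",
]


class TraceError(ValueError):
    """Raised on traces that do not admit the requested observable."""


@dataclass
class KineticTrace:
    """One kinetic measurement: signal versus time, with a replicate id."""

    times: np.ndarray
    signal: np.ndarray
    replicate: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape or self.times.ndim != 1:
            raise TraceError("times and signal must be 1-D arrays of equal length")
        if not np.all(np.diff(self.times) > 0):
            raise TraceError("times must be strictly increasing")
        if not np.isfinite(self.signal).all():
            raise TraceError("signal contains NaN or Inf")


@dataclass
class SigmoidFit:
    """Boltzmann sigmoid fit  y = baseline + amplitude/(1 + exp(-(t - t_mid)/width))."""

    plateau: float
    t_mid: float
    width: float
    baseline: float
    residual_norm: float

    @property
    def k_max(self) -> float:
        """Maximal slope of the fitted sigmoid (at t_mid)."""
        return (self.plateau - self.baseline) / (4.0 * self.width)


def _plateau(trace: KineticTrace, tail_fraction: float, flat_tol: float) -> float:
    n_tail = max(2, int(np.ceil(tail_fraction * trace.times.size)))
    tail = trace.signal[-n_tail:]
    level = float(tail.mean())
    if level <= 0:
        raise TraceError("trace does not rise above zero; half-time undefined")
    if (tail.max() - tail.min()) > flat_tol * abs(level):
        raise TraceError(
            "trace has not reached a plateau (final "
            f"{tail_fraction:.0%} of points vary by more than {flat_tol:.1%})"
        )
    return level


def half_time(
    trace: KineticTrace,
    *,
    tail_fraction: float = 0.10,
    flat_tol: float = 0.01,
    return_plateau: bool = False,
):
    """First time the signal crosses half of its final plateau.

    The plateau is the mean of the final ``tail_fraction`` of points,
    which must vary by less than ``flat_tol`` relative (otherwise the
    run has not converged and a :class:`TraceError` is raised).  The
    crossing is located by linear interpolation.
    """
    plateau = _plateau(trace, tail_fraction, flat_tol)
    target = 0.5 * plateau
    above = trace.signal >= target
    if not above.any():
        raise TraceError("signal never reaches half of its plateau")
    k = int(np.argmax(above))
    if k == 0:
        t_half = float(trace.times[0])
    else:
        t0, t1 = trace.times[k - 1], trace.times[k]
        s0, s1 = trace.signal[k - 1], trace.signal[k]
        t_half = float(t0 + (target - s0) * (t1 - t0) / (s1 - s0))
    if return_plateau:
        return t_half, plateau
    return t_half


def _uniform_grid(trace: KineticTrace) -> tuple[np.ndarray, np.ndarray]:
    dt = np.diff(trace.times)
    if np.allclose(dt, dt[0], rtol=1e-8, atol=0.0):
        return trace.times, trace.signal
    t = np.linspace(trace.times[0], trace.times[-1], trace.times.size)
    return t, np.interp(t, trace.times, trace.signal)


def max_slope(
    trace: KineticTrace, *, window_fraction: float = 0.05
) -> tuple[float, float]:
    """Maximal slope of the (smoothed) trace and the time it occurs.

    The derivative is estimated with a Savitzky-Golay local quadratic
    smoother whose window defaults to 5% of the trace length (at least
    5 points); non-uniform grids are resampled first.
    """
    if trace.times.size < 5:
        raise TraceError("max_slope needs at least 5 points")
    t, s = _uniform_grid(trace)
    window = max(5, int(round(window_fraction * t.size)))
    if window % 2 == 0:
        window += 1
    window = min(window, t.size if t.size % 2 == 1 else t.size - 1)
    order = 3 if window > 3 else 2
    deriv = savgol_filter(s, window_length=window, polyorder=order, deriv=1, delta=t[1] - t[0])
    k = int(np.argmax(deriv))
    return float(deriv[k]), float(t[k])


def lag_time(t_half: float, k_max: float, plateau: float) -> float:
    """Lag time from the tangent at the inflexion.

    For a curve symmetric about its half-time, the tangent of slope
    ``k_max`` through (t1/2, plateau/2) crosses the baseline at
    ``t1/2 - plateau/(2 k_max)``; the lag is floored at zero.
    """
    if not k_max > 0:
        raise ValueError(f"k_max must be positive, got {k_max}")
    return max(0.0, t_half - plateau / (2.0 * k_max))


def _boltzmann(t, baseline, amplitude, t_mid, width):
    return baseline + amplitude / (1.0 + np.exp(-(t - t_mid) / width))


def fit_sigmoid(trace: KineticTrace, *, max_nfev: int = 2000) -> SigmoidFit:
    """Least-squares Boltzmann-sigmoid fit of a kinetic trace.

    The trace must span a baseline and a plateau (at least 6 points and
    a nonzero dynamic range).  Initial guesses come from the data range
    and the steepest observed rise.
    """
    if trace.times.size < 6:
        raise TraceError("fit_sigmoid needs at least 6 points")
    t, s = trace.times, trace.signal
    s_min, s_max = float(s.min()), float(s.max())
    span = s_max - s_min
    if span <= 0 or span < 1e-12 * max(abs(s_max), 1.0):
        raise TraceError("trace is constant; sigmoid fit is degenerate")

    half_level = s_min + 0.5 * span
    t_mid0 = float(np.interp(half_level, s, t)) if np.all(np.diff(s) >= 0) else float(
        t[np.argmin(np.abs(s - half_level))]
    )
    ds = np.gradient(s, t)
    slope0 = max(float(ds.max()), span / (t[-1] - t[0]))
    width0 = span / (4.0 * slope0)

    def resid(p):
        return _boltzmann(t, *p) - s

    p0 = np.array([s_min, span, t_mid0, width0])
    sol = least_squares(resid, p0, max_nfev=max_nfev)
    if not sol.success:
        raise TraceError(f"sigmoid fit did not converge: {sol.message}")
    baseline, amplitude, t_mid, width = sol.x
    return SigmoidFit(
        plateau=float(baseline + amplitude),
        t_mid=float(t_mid),
        width=float(abs(width)),
        baseline=float(baseline),
        residual_norm=float(np.linalg.norm(sol.fun)),
    )


def apparent_nucleus_size(
    c0_values: Sequence[float],
    half_times: Sequence[float],
    *,
    convention: str = "2s",
) -> tuple[float, float]:
    """Apparent nucleus size from the t1/2 versus c0 power law.

    Fits the ordinary least-squares slope ``s`` of log t1/2 against
    log c0 and returns ``(s, n_app)``.  The default convention
    ``n_app = 2*|s|`` follows the classical scaling t1/2 ~ c0^(-n/2);
    ``convention="2s-1"`` uses ``2*|s| - 1`` instead.
    """
    c0 = np.asarray(c0_values, dtype=float)
    th = np.asarray(half_times, dtype=float)
    if c0.size < 3:
        raise ValueError("apparent_nucleus_size needs at least 3 concentrations")
    if (c0 <= 0).any() or (th <= 0).any():
        raise ValueError("concentrations and half-times must be positive")
    slope = float(np.polyfit(np.log(c0), np.log(th), 1)[0])
    if convention == "2s":
        n_app = 2.0 * abs(slope)
    elif convention == "2s-1":
        n_app = 2.0 * abs(slope) - 1.0
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return slope, n_app
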