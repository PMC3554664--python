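"""Non-compartmental analysis: AUC, terminal slope, half-life, Cmax/Tmax.

Used to seed the compartmental fits with model-free initial estimates and to
summarize concentration-time tables the way a spreadsheet NCA would.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NCAResult",
    "TerminalFit",
    "linear_trapezoid_auc",
    "run_nca",
    "terminal_slope",
]

_R2_WARN = 0.8


@dataclass(frozen=True)
class TerminalFit:
    lambda_z: float
    terminal_half_life: float
    intercept: float            # extrapolated log-concentration at t = 0
    r_squared: float
    n_points: int
    low_r2: bool = False


@dataclass(frozen=True)
class NCAResult:
    auc_0_t: float
    auc_0_inf: float
    lambda_z: float
    terminal_half_life: float
    cmax: float
    tmax: float
    n_lambda_points: int
    r_squared: float
    low_r2: bool = False


def _check_profile(times, concentrations) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.ndim != 1 or t.shape != c.shape:
        raise ValueError("times and concentrations must be 1-D and equal length")
    if len(t) < 2:
        raise ValueError("need at least 2 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    return t, c


def linear_trapezoid_auc(times, concentrations) -> float:
    """Linear trapezoidal AUC from the first to the last sampling time."""
    t, c = _check_profile(times, concentrations)
    return float(np.trapezoid(c, t))


def terminal_slope(times, concentrations, n_points: int = 4) -> TerminalFit:
    """Log-linear least-squares on the final ``n_points`` of the profile.

    Returns the first-order terminal rate ``lambda_z`` (1/h) and the
    half-life ln 2 / lambda_z.  Concentrations in the window must be
    positive and on balance decaying; a window R-squared below 0.8 sets the
    ``low_r2`` flag.
    """
    t, c = _check_profile(times, concentrations)
    if n_points < 3:
        raise ValueError("terminal regression needs n_points >= 3")
    if n_points > len(t):
        raise ValueError("n_points exceeds the number of samples")
    tw, cw = t[-n_points:], c[-n_points:]
    if np.any(cw <= 0):
        raise ValueError("non-positive concentration in the terminal window")
    slope, intercept = np.polyfit(tw, np.log(cw), 1)
    if slope >= 0:
        raise ValueError("terminal window is not decaying (lambda_z <= 0)")
    lam = -slope
    logc = np.log(cw)
    ss_res = float(np.sum((logc - (slope * tw + intercept)) ** 2))
    ss_tot = float(np.sum((logc - logc.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return TerminalFit(
        lambda_z=float(lam),
        terminal_half_life=math.log(2.0) / lam,
        intercept=float(intercept),
        r_squared=r2,
        n_points=n_points,
        low_r2=r2 < _R2_WARN,
    )


def run_nca(times, concentrations, max_window: int = 8) -> NCAResult:
    """Full NCA of one mean concentration-time profile.

    The terminal window starts at the last 4 positive post-peak points and
    expands (up to ``max_window`` points, never crossing Cmax) keeping the
    window with the best log-linear R-squared.  AUC(0-inf) adds the
    extrapolation term C_last / lambda_z to the linear-trapezoid AUC(0-t).
    """
    t, c = _check_profile(times, concentrations)
    i_max = int(np.argmax(c))
    cmax, tmax = float(c[i_max]), float(t[i_max])
    auc_t = linear_trapezoid_auc(t, c)

    n_after_peak = len(t) - i_max - 1      # candidate points strictly past Cmax
    best: TerminalFit | None = None
    for n in range(4, min(max_window, n_after_peak) + 1):
        try:
            fit = terminal_slope(t, c, n_points=n)
        except ValueError:
            continue
        if best is None or fit.r_squared > best.r_squared:
            best = fit
    if best is None:
        # fall back to the minimal window even if it spans the peak
        best = terminal_slope(t, c, n_points=min(4, len(t)))
    c_last = c[-1]
    auc_inf = auc_t + (float(c_last) / best.lambda_z if c_last > 0 else 0.0)
    return NCAResult(
        auc_0_t=auc_t,
        auc_0_inf=auc_inf,
        lambda_z=best.lambda_z,
        terminal_half_life=best.terminal_half_life,
        cmax=cmax,
        tmax=tmax,
        n_lambda_points=best.n_points,
        r_squared=best.r_squared,
        low_r2=best.low_r2,
    )
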