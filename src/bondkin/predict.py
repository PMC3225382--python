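"""Model predictions: survival families vs force, long-lived-state
occupancy time courses and peak times, and the catch–slip mean-lifetime
profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import kinetics
from .force import ConditionModel
from .params import ApparentParams, IntrinsicRates, NoLongLivedStateError

__all__ = [
    "default_time_grid",
    "p3_time_course",
    "p3_peak",
    "mean_lifetime",
    "survival_family",
    "catch_slip_profile",
    "CatchSlipProfile",
]


def default_time_grid(t_max: float = 30.0, n: int = 600) -> np.ndarray:
    """Log-spaced time grid from 0 to ``t_max`` seconds (first point 0),
    matching the lifetime range of force-clamp experiments."""
    return np.concatenate([[0.0], np.logspace(-3, np.log10(t_max), n - 1)])


def p3_time_course(r: IntrinsicRates, t_grid) -> np.ndarray:
    """Occupancy p3(t) of the long-lived state on ``t_grid``.

    Starts at 0; rises then decays (single interior maximum) whenever
    k12, k23 and kr3 are all positive.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    return kinetics.state_trajectories(r, t_grid)[2]


def _dp3_dt(r: IntrinsicRates):
    """Closed-form derivative of p3: dp3/dt = k23 p2 - kr3 p3."""

    def deriv(t):
        p = kinetics.state_trajectories(r, np.atleast_1d(t))
        return r.k23 * p[1] - r.kr3 * p[2]

    return deriv


# Bracket for peak finding (s): generous around experimental timescales.
_T_LO, _T_HI = 1e-4, 1e3


def p3_peak(r: IntrinsicRates) -> tuple[float, float]:
    """Time and height of the maximum of p3(t).

    Found by bracketing the sign change of dp3/dt = k23 p2 - kr3 p3 on a
    log-spaced grid and polishing with a root solve; grids alone are too
    coarse for sharp peaks.

    Raises
    ------
    NoLongLivedStateError
        If k12 = 0 or k23 = 0 (C3 is never populated) or kr3 = 0 with no
        decay (p3 is then monotone increasing, no interior peak).
    """
    if r.k12 <= 0.0 or r.k23 <= 0.0:
        raise NoLongLivedStateError(
            "p3 is identically zero (k12 or k23 is zero): no long-lived "
            "occupancy peak exists"
        )
    if r.kr3 <= 0.0:
        raise NoLongLivedStateError(
            "kr3 = 0: p3 increases monotonically to its asymptote and has "
            "no interior maximum"
        )
    deriv = _dp3_dt(r)
    grid = np.logspace(np.log10(_T_LO), np.log10(_T_HI), 400)
    vals = np.array([float(deriv(t)[0]) for t in grid])
    sign_change = np.nonzero((vals[:-1] > 0) & (vals[1:] <= 0))[0]
    if len(sign_change) == 0:
        raise RuntimeError(
            "no sign change of dp3/dt found in the bracket "
            f"[{_T_LO}, {_T_HI}] s; peak outside supported range"
        )
    i = sign_change[0]
    t_peak = brentq(lambda t: float(deriv(t)[0]), grid[i], grid[i + 1],
                    xtol=1e-14, rtol=1e-14)
    p_peak = float(kinetics.state_trajectories(r, np.array([t_peak]))[2, 0])
    return float(t_peak), p_peak


def mean_lifetime(p: ApparentParams) -> float:
    """Mean bond lifetime: integral of the survival mixture,
    sum_i w_i / k_i (s)."""
    return float(np.sum(p.weights / p.rates))


def survival_family(model: ConditionModel, forces, t_grid=None) -> pd.DataFrame:
    """One survival curve per clamp force, as a long-format table with
    columns ``force_pN``, ``t_s``, ``survival`` (ordered by force)."""
    forces = np.sort(np.asarray(forces, dtype=float))
    if np.any(forces < 0):
        raise ValueError("forces must be >= 0")
    if t_grid is None:
        t_grid = default_time_grid()
    t_grid = np.asarray(t_grid, dtype=float)
    frames = []
    for f in forces:
        r = model.intrinsic_at(float(f))
        s = kinetics.survival_intrinsic(r, t_grid)
        frames.append(pd.DataFrame(
            {"force_pN": f, "t_s": t_grid, "survival": np.atleast_1d(s)}))
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class CatchSlipProfile:
    """Mean lifetime vs force, with the detected regime.

    ``classification`` is ``"catch-slip"`` when the profile has an
    interior maximum, ``"slip"`` when monotone decreasing and ``"catch"``
    when monotone increasing over the grid.  ``peak_force`` is the grid
    force of the interior maximum (None unless catch-slip).
    """

    forces: np.ndarray
    mean_lifetimes: np.ndarray
    classification: str
    peak_force: float | None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"force_pN": self.forces,
                             "mean_lifetime_s": self.mean_lifetimes})


def catch_slip_profile(model: ConditionModel, force_grid) -> CatchSlipProfile:
    """Mean bond lifetime at each force of the grid, classified as catch,
    slip, or catch–slip (interior lifetime maximum)."""
    forces = np.sort(np.asarray(force_grid, dtype=float))
    if len(forces) < 3:
        raise ValueError("force grid must cover at least 3 forces")
    lifetimes = np.empty_like(forces)
    for i, f in enumerate(forces):
        r = model.intrinsic_at(float(f))
        try:
            p = kinetics.apparent_from_intrinsic(r)
            lifetimes[i] = mean_lifetime(p)
        except Exception:
            # degenerate / improper-mixture point: integrate numerically
            t = np.linspace(0, 2000.0, 400001)
            s = kinetics.survival_intrinsic(r, t)
            lifetimes[i] = float(np.trapezoid(s, t))
    i_max = int(np.argmax(lifetimes))
    if 0 < i_max < len(forces) - 1:
        cls = "catch-slip"
        peak: float | None = float(forces[i_max])
    else:
        d = np.diff(lifetimes)
        cls = "catch" if np.all(d >= 0) else (
            "slip" if np.all(d <= 0) else "catch-slip")
        peak = float(forces[i_max]) if cls == "catch-slip" else None
    return CatchSlipProfile(forces=forces, mean_lifetimes=lifetimes,
                            classification=cls, peak_force=peak)
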