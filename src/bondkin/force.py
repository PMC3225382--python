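"""Force dependence of the kinetic rates.

Dissociation (reverse) rates follow the Bell model, k(f) = k0 exp(f/f_scale)
— log-linear in force.  The forward conformational transition rates vanish
at zero force and grow with it; the default law is the zero-intercept
exponential k(f) = k_a (exp(f/f_scale) - 1), and a monotone tabulated law
(piecewise-linear interpolation of log-rate) is available when only
per-force values are known.

A :class:`ConditionModel` bundles one force law per rate (k12, k23, kr1,
kr2, kr3) for one experimental condition and composes them into
:class:`~bondkin.params.IntrinsicRates` at any clamp force.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .params import BellParams, IntrinsicRates, InvalidRateError

__all__ = [
    "RATE_NAMES",
    "CONDITIONS",
    "bell_rate",
    "fit_bell",
    "transition_rate",
    "fit_transition",
    "BellLaw",
    "ForceActivatedLaw",
    "TabulatedLaw",
    "ZeroLaw",
    "ConditionModel",
    "intrinsic_at_force",
    "law_from_dict",
]

RATE_NAMES = ("k12", "k23", "kr1", "kr2", "kr3")

#: Closed vocabulary of experimental condition labels: three cation buffers,
#: each with or without the allosteric antagonist XVA143.
CONDITIONS = (
    "CaMg", "MgEGTA", "Mn",
    "CaMg+XVA143", "MgEGTA+XVA143", "Mn+XVA143",
)


def bell_rate(b: BellParams, f) -> np.ndarray | float:
    """Bell-model rate k0 * exp(f / f_scale) at force ``f`` (pN)."""
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr < 0):
        raise ValueError("force must be >= 0")
    out = b.k0 * np.exp(f_arr / b.f_scale)
    return float(out) if np.ndim(f) == 0 else out


def fit_bell(forces, rates, *, se=None, weighted: bool = False) -> BellParams:
    """Least-squares Bell fit: a line on (force, ln rate).

    Zero/negative rates cannot enter the log and are excluded with a
    warning.  ``weighted=True`` uses inverse-variance weights derived from
    ``se`` (standard errors of the rates, propagated to log scale).
    A negative fitted slope (rate decreasing with force) yields a negative
    ``f_scale``; check :attr:`BellParams.is_slip` for the
    "not-a-slip-bond" flag.

    Requires at least two positive-rate points.
    """
    forces = np.asarray(forces, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if forces.shape != rates.shape or forces.ndim != 1:
        raise ValueError("forces and rates must be matching 1-D arrays")
    pos = rates > 0
    if not np.all(pos):
        warnings.warn(
            f"excluding {int((~pos).sum())} non-positive rate(s) from the "
            "Bell fit (log of zero rate undefined)",
            stacklevel=2,
        )
    f, r = forces[pos], rates[pos]
    if len(f) < 2:
        raise ValueError("Bell fit needs at least two positive-rate points")
    y = np.log(r)
    if weighted:
        if se is None:
            raise ValueError("weighted=True requires standard errors")
        se = np.asarray(se, dtype=float)[pos]
        w = (r / se) ** 2  # var(ln k) ~ (se/k)^2
        W = np.sum(w)
        fbar, ybar = np.sum(w * f) / W, np.sum(w * y) / W
        slope = np.sum(w * (f - fbar) * (y - ybar)) / np.sum(w * (f - fbar) ** 2)
        intercept = ybar - slope * fbar
    else:
        res = linregress(f, y)
        slope, intercept = res.slope, res.intercept
    if slope == 0.0:
        raise ValueError("zero slope: rate is force-independent, f_scale undefined")
    return BellParams(k0=float(np.exp(intercept)), f_scale=float(1.0 / slope))


def transition_rate(k_a: float, f_scale: float, f) -> np.ndarray | float:
    """Force-activated transition law k_a * (exp(f / f_scale) - 1).

    Vanishes at zero force — transitions between bound states are driven
    by force — and increases monotonically for f_scale > 0.
    """
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr < 0):
        raise ValueError("force must be >= 0")
    out = k_a * np.expm1(f_arr / f_scale)
    return float(out) if np.ndim(f) == 0 else out


def fit_transition(forces, rates, *, p0=(1.0, 5.0)) -> tuple[float, float]:
    """Fit (k_a, f_scale) of the force-activated law by nonlinear least
    squares; returns the two parameters."""
    forces = np.asarray(forces, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if len(forces) < 2:
        raise ValueError("need at least two points")
    popt, _ = curve_fit(
        lambda f, ka, fs: ka * np.expm1(f / fs),
        forces, rates, p0=p0, maxfev=20000,
        bounds=([0.0, 1e-3], [np.inf, np.inf]),
    )
    return float(popt[0]), float(popt[1])


# ---------------------------------------------------------------------------
# Serializable force-law objects


@dataclass(frozen=True)
class BellLaw:
    """Bell (slip-bond) law for a dissociation rate."""

    k0: float
    f_scale: float

    def rate(self, f: float) -> float:
        return bell_rate(BellParams(self.k0, self.f_scale), f)

    def to_dict(self) -> dict:
        return {"law": "bell", "k0": self.k0, "f_scale": self.f_scale}


@dataclass(frozen=True)
class ForceActivatedLaw:
    """Zero-at-zero-force exponential law for a transition rate."""

    k_a: float
    f_scale: float

    def rate(self, f: float) -> float:
        return transition_rate(self.k_a, self.f_scale, f)

    def to_dict(self) -> dict:
        return {"law": "activated", "k_a": self.k_a, "f_scale": self.f_scale}


@dataclass(frozen=True)
class ZeroLaw:
    """Identically zero rate (e.g. a transition blocked by an antagonist)."""

    def rate(self, f: float) -> float:
        if f < 0:
            raise ValueError("force must be >= 0")
        return 0.0

    def to_dict(self) -> dict:
        return {"law": "zero"}


class TabulatedLaw:
    """Monotone interpolation of tabulated (force, rate) values.

    Interpolates piecewise-linearly in log-rate between positive tabulated
    points; zero tabulated rates at the low-force end are honoured exactly
    up to the first positive point (the rate stays 0 there).  Outside the
    tabulated range the boundary value is held constant.
    """

    def __init__(self, forces, rates):
        forces = np.asarray(forces, dtype=float)
        rates = np.asarray(rates, dtype=float)
        order = np.argsort(forces)
        self.forces = forces[order]
        self.rates = rates[order]
        if np.any(self.rates < 0) or np.any(self.forces < 0):
            raise InvalidRateError("tabulated forces and rates must be >= 0")
        if len(self.forces) < 2:
            raise ValueError("tabulated law needs at least two points")
        self._pos = self.rates > 0

    def rate(self, f: float) -> float:
        f = float(f)
        if f < 0:
            raise ValueError("force must be >= 0")
        fp, rp = self.forces[self._pos], self.rates[self._pos]
        if len(fp) == 0:
            return 0.0
        if f < fp[0]:
            # below first positive point: zero if a zero point precedes it
            if np.any(~self._pos) and f <= self.forces[~self._pos].max():
                return 0.0
            return float(rp[0])
        if f >= fp[-1]:
            return float(rp[-1])
        return float(np.exp(np.interp(f, fp, np.log(rp))))

    def to_dict(self) -> dict:
        return {"law": "tabulated", "forces": self.forces.tolist(),
                "rates": self.rates.tolist()}


def law_from_dict(d: dict):
    """Deserialize a force law from its dict form (see each law's
    ``to_dict``)."""
    kind = d.get("law")
    if kind == "bell":
        return BellLaw(float(d["k0"]), float(d["f_scale"]))
    if kind == "activated":
        return ForceActivatedLaw(float(d["k_a"]), float(d["f_scale"]))
    if kind == "zero":
        return ZeroLaw()
    if kind == "tabulated":
        return TabulatedLaw(d["forces"], d["rates"])
    raise ValueError(f"unknown force law {kind!r}")


@dataclass(frozen=True)
class ConditionModel:
    """One force law per rate for one experimental condition."""

    condition: str
    k12: object
    k23: object
    kr1: object
    kr2: object
    kr3: object

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; expected one of "
                f"{CONDITIONS}"
            )

    def law(self, name: str):
        if name not in RATE_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def intrinsic_at(self, f: float) -> IntrinsicRates:
        return IntrinsicRates(*(self.law(n).rate(f) for n in RATE_NAMES))

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "rates": {n: self.law(n).to_dict() for n in RATE_NAMES},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConditionModel":
        laws = {n: law_from_dict(d["rates"][n]) for n in RATE_NAMES}
        return cls(condition=d["condition"], **laws)


def intrinsic_at_force(model: ConditionModel, f: float) -> IntrinsicRates:
    """Compose the per-rate force laws of a condition into one
    :class:`IntrinsicRates` at clamp force ``f`` (pN)."""
    return model.intrinsic_at(f)
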