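"""Domain parameter types for the three-state bond-kinetics model.

The bond is modelled as a chain of three bound states C1 -> C2 -> C3.
Force drives the forward conformational transitions (rates ``k12``,
``k23``) while the ligand can dissociate irreversibly from any state
(reverse-rates ``kr1``, ``kr2``, ``kr3``).  The observable lifetime
distribution is a mixture of (at most) three exponentials whose decay
rates and weights are the *apparent* off-rates and fractions.

Units are fixed package-wide: time in seconds, rates in s^-1, force in pN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IntrinsicRates",
    "ApparentParams",
    "StateProbabilities",
    "SolutionCoefficients",
    "BellParams",
    "BondKineticsError",
    "InvalidRateError",
    "InfeasibleParametersError",
    "DegenerateRatesError",
    "NoLongLivedStateError",
]


class BondKineticsError(Exception):
    """Base class for model errors."""


class InvalidRateError(BondKineticsError, ValueError):
    """A rate constant violates its sign or finiteness constraints."""


class InfeasibleParametersError(BondKineticsError, ValueError):
    """Apparent parameters imply a negative intrinsic rate (or an improper
    mixture); carries the name and value of the offending quantity."""

    def __init__(self, message: str, quantity: str | None = None,
                 value: float | None = None):
        super().__init__(message)
        self.quantity = quantity
        self.value = value


class DegenerateRatesError(BondKineticsError, ValueError):
    """Two apparent decay rates coincide (within tolerance), so the survival
    curve is not a proper three-exponential mixture."""


class NoLongLivedStateError(BondKineticsError, ValueError):
    """The long-lived state C3 is never populated (k12 = 0 or k23 = 0)."""


def _check_rate(name: str, value: float) -> float:
    value = float(value)
    if not np.isfinite(value) or value < 0.0:
        raise InvalidRateError(f"{name} must be finite and >= 0, got {value!r}")
    return value


@dataclass(frozen=True)
class IntrinsicRates:
    """The five mechanistic rate constants of the scheme at one clamp force.

    Parameters
    ----------
    k12, k23 : float
        Forward interstate transition rates C1->C2 and C2->C3 (s^-1).
    kr1, kr2, kr3 : float
        Dissociation (reverse) rates from C1, C2, C3 (s^-1).
    """

    k12: float
    k23: float
    kr1: float
    kr2: float
    kr3: float

    def __post_init__(self):
        for name in ("k12", "k23", "kr1", "kr2", "kr3"):
            object.__setattr__(self, name, _check_rate(name, getattr(self, name)))
        if not self.has_absorbing_path:
            raise InvalidRateError(
                "no dissociation pathway is reachable from C1: the bond "
                "would never rupture"
            )

    @property
    def has_absorbing_path(self) -> bool:
        """True if rupture is reachable from the initial state C1."""
        if self.kr1 > 0:
            return True
        if self.k12 > 0 and (self.kr2 > 0 or (self.k23 > 0 and self.kr3 > 0)):
            return True
        return False

    def scaled(self, c: float) -> "IntrinsicRates":
        """All five rates multiplied by ``c`` (time-rescaling symmetry)."""
        if c <= 0:
            raise InvalidRateError(f"scale factor must be > 0, got {c}")
        return IntrinsicRates(self.k12 * c, self.k23 * c, self.kr1 * c,
                              self.kr2 * c, self.kr3 * c)

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.k12, self.k23, self.kr1, self.kr2, self.kr3)


# Tolerance for the weight-sum invariant of ApparentParams.
_WSUM_TOL = 1e-6


@dataclass(frozen=True)
class ApparentParams:
    """Apparent off-rates and fractions of the observable survival mixture.

    The survival probability of the bond is S(t) = sum_i w_i exp(-k_i t)
    with ``k1 >= k2 >= k3 > 0`` (fastest mode first, matching the
    short-lived-first state labelling) and weights summing to one.

    ``permutation`` records how the natural state-ordered rates were
    permuted to enforce the descending convention (identity when the
    short/intermediate/long-lived ordering already held).
    """

    k1: float
    k2: float
    k3: float
    w1: float
    w2: float
    w3: float
    permutation: tuple[int, int, int] = field(default=(0, 1, 2), compare=False)

    def __post_init__(self):
        for name in ("k1", "k2", "k3", "w1", "w2", "w3"):
            v = float(getattr(self, name))
            if not np.isfinite(v):
                raise InvalidRateError(f"{name} must be finite, got {v!r}")
            object.__setattr__(self, name, v)
        if not (self.k1 >= self.k2 >= self.k3 > 0.0):
            raise InvalidRateError(
                f"apparent rates must satisfy k1 >= k2 >= k3 > 0, got "
                f"({self.k1}, {self.k2}, {self.k3})"
            )
        for name in ("w1", "w2", "w3"):
            w = getattr(self, name)
            if w < -1e-9 or w > 1.0 + 1e-9:
                raise InfeasibleParametersError(
                    f"fraction {name} = {w} outside [0, 1]", quantity=name, value=w
                )
        s = self.w1 + self.w2 + self.w3
        if abs(s - 1.0) > _WSUM_TOL:
            raise InfeasibleParametersError(
                f"fractions must sum to 1 (got {s})", quantity="w1+w2+w3", value=s
            )

    @classmethod
    def from_unsorted(cls, rates, weights, *, renormalize: bool = False
                      ) -> "ApparentParams":
        """Build from possibly unsorted (rates, weights), sorting fastest
        first and recording the permutation applied."""
        rates = np.asarray(rates, dtype=float)
        weights = np.asarray(weights, dtype=float)
        if rates.shape != (3,) or weights.shape != (3,):
            raise InvalidRateError("expected exactly three rates and weights")
        if renormalize:
            weights = weights / weights.sum()
        order = tuple(int(i) for i in np.argsort(-rates, kind="stable"))
        r = rates[list(order)]
        w = weights[list(order)]
        return cls(r[0], r[1], r[2], w[0], w[1], w[2], permutation=order)

    @property
    def rates(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.k3])

    @property
    def weights(self) -> np.ndarray:
        return np.array([self.w1, self.w2, self.w3])


@dataclass(frozen=True)
class StateProbabilities:
    """Occupancies (p1, p2, p3) of the bound states at time ``t``."""

    t: float
    p1: float
    p2: float
    p3: float

    @property
    def total(self) -> float:
        """Total survival probability p1 + p2 + p3."""
        return self.p1 + self.p2 + self.p3


@dataclass(frozen=True)
class SolutionCoefficients:
    """Amplitudes of the exponential modes in the closed-form solution.

    p1(t) = a1 e^{-K1 t}  (a2 = a3 = 0 in the sequential scheme, kept for
    the general mode-sum layout);
    p2(t) = b2 e^{-K2 t} + b1 e^{-K1 t}  with b1 = -b2 (p2(0) = 0);
    p3(t) = c1 e^{-K1 t} + c2 e^{-K2 t} + c3 e^{-K3 t}.

    ``rates`` holds (K1, K2, K3) in natural state order
    (k12 + kr1, k23 + kr2, kr3), not sorted.
    """

    rates: tuple[float, float, float]
    a: tuple[float, float, float]
    b: tuple[float, float, float]
    c: tuple[float, float, float]

    @property
    def mode_weights(self) -> np.ndarray:
        """Per-mode weights of the total survival S(t) = p1 + p2 + p3."""
        return np.array([self.a[i] + self.b[i] + self.c[i] for i in range(3)])


@dataclass(frozen=True)
class BellParams:
    """Exponential (Bell-type) force dependence of one rate:
    k(f) = k0 * exp(f / f_scale).

    ``f_scale`` (pN) is the force scale k_B T / x_beta; positive for a slip
    bond (rate grows with force).  A fit can legitimately return a negative
    scale (rate falling with force) — flagged, not rejected.
    """

    k0: float
    f_scale: float

    def __post_init__(self):
        object.__setattr__(self, "k0", _check_rate("k0", self.k0))
        f = float(self.f_scale)
        if not np.isfinite(f) or f == 0.0:
            raise InvalidRateError(f"f_scale must be finite and nonzero, got {f!r}")
        object.__setattr__(self, "f_scale", f)

    @property
    def is_slip(self) -> bool:
        return self.f_scale > 0
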