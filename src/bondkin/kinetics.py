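"""Analytic solution of the three-state irreversible bond scheme.

The occupancies p = (p1, p2, p3) of the bound states obey dp/dt = A p with
the lower-bidiagonal generator

    A = [[-(k12 + kr1),        0,       0],
         [        k12,  -(k23 + kr2),   0],
         [          0,         k23,  -kr3]]

and initial condition p(0) = (1, 0, 0): without force the bond starts — and
stays — in the short-lived state C1.  Because A is triangular its
eigenvalues are the diagonal entries, so the three apparent decay rates are

    K1 = k12 + kr1,   K2 = k23 + kr2,   K3 = kr3,

and the solution is the classical sequential-decay (Bateman) form.  The
total survival S(t) = p1 + p2 + p3 is a three-exponential mixture whose
weights are the apparent fractions; this module converts exactly between
the five intrinsic rates and the six apparent parameters, in both
directions.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .params import (
    ApparentParams,
    DegenerateRatesError,
    InfeasibleParametersError,
    IntrinsicRates,
    InvalidRateError,
    SolutionCoefficients,
    StateProbabilities,
)

__all__ = [
    "rate_matrix",
    "apparent_rates",
    "natural_rates",
    "solution_coefficients",
    "state_probabilities",
    "state_trajectories",
    "survival",
    "survival_intrinsic",
    "apparent_from_intrinsic",
    "intrinsic_from_apparent",
    "splitting_probabilities",
    "ode_reference",
    "DEGENERACY_RTOL",
]

# Relative eigen-rate gap below which the Bateman denominators are treated
# as degenerate and the analytic limit (t e^{-kt}) forms are used instead.
DEGENERACY_RTOL = 1e-9


def rate_matrix(r: IntrinsicRates) -> np.ndarray:
    """Generator A of dp/dt = A p for the sequential scheme."""
    return np.array(
        [
            [-(r.k12 + r.kr1), 0.0, 0.0],
            [r.k12, -(r.k23 + r.kr2), 0.0],
            [0.0, r.k23, -r.kr3],
        ]
    )


def natural_rates(r: IntrinsicRates) -> tuple[float, float, float]:
    """Decay rates (K1, K2, K3) in natural state order (unsorted)."""
    return (r.k12 + r.kr1, r.k23 + r.kr2, r.kr3)


def apparent_rates(r: IntrinsicRates) -> tuple[float, float, float]:
    """The three apparent off-rates: negated eigenvalues of the generator,
    sorted descending (fastest mode first)."""
    k = sorted(natural_rates(r), reverse=True)
    return (k[0], k[1], k[2])


def _rel_gap(a: float, b: float) -> float:
    scale = max(abs(a), abs(b), 1e-300)
    return abs(a - b) / scale


def _degenerate_pairs(K: tuple[float, float, float], rtol: float
                      ) -> list[tuple[int, int]]:
    return [(i, j) for i in range(3) for j in range(i + 1, 3)
            if _rel_gap(K[i], K[j]) < rtol]


def solution_coefficients(r: IntrinsicRates,
                          *, rtol: float = DEGENERACY_RTOL
                          ) -> SolutionCoefficients:
    """Mode amplitudes of the closed-form solution (separated eigen-rates).

    Raises
    ------
    DegenerateRatesError
        If two eigen-rates coincide within ``rtol`` (the solution then
        contains secular t e^{-kt} terms; use :func:`state_probabilities`,
        which handles that limit).
    """
    K1, K2, K3 = K = natural_rates(r)
    if _degenerate_pairs(K, rtol) and r.k12 > 0:
        raise DegenerateRatesError(
            f"eigen-rates {K} are degenerate within rtol={rtol}; the "
            "exponential-mode decomposition does not exist"
        )
    a = (1.0, 0.0, 0.0)
    if r.k12 == 0.0:
        return SolutionCoefficients(rates=K, a=a, b=(0.0,) * 3, c=(0.0,) * 3)
    b2 = r.k12 / (K1 - K2)
    b = (-b2, b2, 0.0)
    if r.k23 == 0.0:
        c = (0.0, 0.0, 0.0)
    else:
        q = r.k12 * r.k23
        c = (
            q / ((K2 - K1) * (K3 - K1)),
            q / ((K1 - K2) * (K3 - K2)),
            q / ((K1 - K3) * (K2 - K3)),
        )
    return SolutionCoefficients(rates=K, a=a, b=b, c=c)


def _bateman3(t: np.ndarray, K1: float, K2: float, K3: float,
              rtol: float) -> np.ndarray:
    """sum_i e^{-Ki t} / prod_{j != i} (Kj - Ki), with analytic limits when
    rates coincide.  Symmetric in (K1, K2, K3)."""
    pairs = _degenerate_pairs((K1, K2, K3), rtol)
    if not pairs:
        return (
            np.exp(-K1 * t) / ((K2 - K1) * (K3 - K1))
            + np.exp(-K2 * t) / ((K1 - K2) * (K3 - K2))
            + np.exp(-K3 * t) / ((K1 - K3) * (K2 - K3))
        )
    if len(pairs) >= 2:
        # all three coincide: limit is t^2 e^{-kt} / 2
        k = (K1 + K2 + K3) / 3.0
        return 0.5 * t * t * np.exp(-k * t)
    (i, j) = pairs[0]
    rates = [K1, K2, K3]
    m = rates[3 - i - j]            # the separated rate
    k = 0.5 * (rates[i] + rates[j])  # the (near-)double rate
    d = m - k
    return (t * np.exp(-k * t) / d
            + (np.exp(-m * t) - np.exp(-k * t)) / (d * d))


def state_trajectories(r: IntrinsicRates, t: np.ndarray,
                       *, rtol: float = DEGENERACY_RTOL) -> np.ndarray:
    """Closed-form (p1, p2, p3)(t) on an array of times; shape (3, len(t)).

    Uses the separated Bateman form when the eigen-rates are distinct and
    switches to the analytic t e^{-kt} limit forms below the relative-gap
    tolerance, so near-degenerate inputs never hit catastrophic
    cancellation.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    K1, K2, K3 = natural_rates(r)
    p1 = np.exp(-K1 * t)
    if r.k12 == 0.0:
        zero = np.zeros_like(t)
        return np.vstack([p1, zero, zero])
    if _rel_gap(K1, K2) < rtol:
        k = 0.5 * (K1 + K2)
        p2 = r.k12 * t * np.exp(-k * t)
    else:
        p2 = r.k12 * (np.exp(-K2 * t) - np.exp(-K1 * t)) / (K1 - K2)
    if r.k23 == 0.0:
        p3 = np.zeros_like(t)
    else:
        p3 = r.k12 * r.k23 * _bateman3(t, K1, K2, K3, rtol)
    return np.vstack([p1, p2, p3])


def state_probabilities(r: IntrinsicRates, t: float,
                        *, rtol: float = DEGENERACY_RTOL
                        ) -> StateProbabilities:
    """Occupancies of the three bound states at a single time ``t >= 0``."""
    tf = float(t)
    if tf < 0:
        raise ValueError(f"time must be >= 0, got {tf}")
    p = state_trajectories(r, np.array([tf]), rtol=rtol)[:, 0]
    return StateProbabilities(t=tf, p1=float(p[0]), p2=float(p[1]),
                              p3=float(p[2]))


def survival(p: ApparentParams, t) -> np.ndarray | float:
    """Total survival probability S(t) = sum_i w_i exp(-k_i t)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("times must be >= 0")
    s = (p.w1 * np.exp(-p.k1 * t_arr)
         + p.w2 * np.exp(-p.k2 * t_arr)
         + p.w3 * np.exp(-p.k3 * t_arr))
    return float(s) if np.isscalar(t) or t_arr.ndim == 0 else s


def survival_intrinsic(r: IntrinsicRates, t,
                       *, rtol: float = DEGENERACY_RTOL) -> np.ndarray | float:
    """S(t) = p1 + p2 + p3 directly from the intrinsic rates (robust at
    degenerate eigen-rates, where no proper mixture representation exists)."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    s = state_trajectories(r, t_arr, rtol=rtol).sum(axis=0)
    return float(s[0]) if np.isscalar(t) or np.ndim(t) == 0 else s


def _mixture_weights(r: IntrinsicRates) -> np.ndarray:
    """Weights of (e^{-K1 t}, e^{-K2 t}, e^{-K3 t}) in p1 + p2 + p3,
    natural state order, assuming separated rates."""
    K1, K2, K3 = natural_rates(r)
    if r.k12 == 0.0:
        return np.array([1.0, 0.0, 0.0])
    w2 = r.k12 / (K1 - K2)
    w1 = 1.0 - w2
    if r.k23 > 0.0:
        q = r.k12 * r.k23
        w1 += q / ((K2 - K1) * (K3 - K1))
        w2 += q / ((K1 - K2) * (K3 - K2))
        w3 = q / ((K1 - K3) * (K2 - K3))
    else:
        w3 = 0.0
    return np.array([w1, w2, w3])


def apparent_from_intrinsic(r: IntrinsicRates,
                            *, rtol: float = DEGENERACY_RTOL
                            ) -> ApparentParams:
    """Exact forward mapping: intrinsic rates -> apparent off-rates and
    fractions, sorted fastest-first with the permutation recorded.

    Raises
    ------
    DegenerateRatesError
        If eigen-rates coincide (no proper mixture exists).
    InfeasibleParametersError
        If a weight falls outside [0, 1].  This happens when a later state
        dissociates faster than an earlier one (e.g. kr3 > kr2): S(t) is
        then a signed exponential sum, not an observable fraction mixture.
    """
    K = natural_rates(r)
    if r.k12 > 0 and _degenerate_pairs(K, rtol):
        raise DegenerateRatesError(
            f"eigen-rates {K} coincide within rtol={rtol}: the survival "
            "curve contains t*exp(-kt) terms and has no proper "
            "three-exponential mixture form"
        )
    w = _mixture_weights(r)
    return ApparentParams.from_unsorted(K, w)


def intrinsic_from_apparent(p: ApparentParams, *, project: bool = False,
                            atol: float = 1e-12) -> IntrinsicRates:
    """Exact inverse mapping: apparent parameters -> intrinsic rates.

    Inverts the mode-weight formulas under the natural ordering
    (k1, k2, k3) = (k12 + kr1, k23 + kr2, kr3):

        kr3 = k3
        k12 = w2 (k1 - k2) + w3 (k1 - k3)
        k23 = w3 (k1 - k3)(k2 - k3) / k12     (0 when w3 = 0)
        kr1 = k1 - k12
        kr2 = k2 - k23

    When ``w3 = 0`` the C3 branch is unpopulated and ``k23 = 0`` is the
    unique continuous extension; ``w2 = w3 = 0`` likewise gives
    ``k12 = 0``.

    Parameters
    ----------
    project : bool
        If True, implied rates in (-atol-ish negative territory beyond
        roundoff) are clamped to 0 instead of raising, and the adjustment
        is reported in the exception-free return.  Default False: any
        implied negative rate raises :class:`InfeasibleParametersError`
        naming the offending quantity.
    """
    k1, k2, k3 = p.k1, p.k2, p.k3
    kr3 = k3
    k12 = p.w2 * (k1 - k2) + p.w3 * (k1 - k3)
    if p.w3 <= 0.0 or k12 <= 0.0:
        k23 = 0.0
        if p.w2 <= 0.0:
            k12 = 0.0
    else:
        k23 = p.w3 * (k1 - k3) * (k2 - k3) / k12
    kr1 = k1 - k12
    kr2 = k2 - k23

    implied = {"k12": k12, "k23": k23, "kr1": kr1, "kr2": kr2}
    for name, value in implied.items():
        if value < -atol * max(1.0, k1):
            if project:
                implied[name] = 0.0
            else:
                raise InfeasibleParametersError(
                    f"apparent parameters imply {name} = {value} < 0; not in "
                    "the image of the forward mapping",
                    quantity=name,
                    value=value,
                )
        elif value < 0.0:
            implied[name] = 0.0  # roundoff-scale negativity
    return IntrinsicRates(implied["k12"], implied["k23"], implied["kr1"],
                          implied["kr2"], kr3)


def splitting_probabilities(r: IntrinsicRates) -> np.ndarray:
    """Probability of rupturing from C1, C2, C3 (first-step analysis).

    P(exit C1) = kr1 / (kr1 + k12); conditioned on reaching C2,
    P(exit C2) = kr2 / (kr2 + k23); the remainder exits from C3.
    States with zero total exit rate trap probability mass (only possible
    off the absorbing path, e.g. k23 = kr2 = 0 with mass reaching C2 —
    the scheme validity check excludes rates with no absorbing path).
    """
    out1 = r.kr1 + r.k12
    e1 = r.kr1 / out1 if out1 > 0 else 1.0
    reach2 = 1.0 - e1
    out2 = r.kr2 + r.k23
    e2 = reach2 * (r.kr2 / out2) if out2 > 0 else 0.0
    reach3 = reach2 * (r.k23 / out2) if out2 > 0 else 0.0
    return np.array([e1, e2, reach3])


def ode_reference(r: IntrinsicRates, t_grid,
                  *, rtol: float = 1e-10, atol: float = 1e-12) -> np.ndarray:
    """High-accuracy numerical integration of the kinetic equations from
    (1, 0, 0) — the independent brute-force oracle used in tests.

    Returns an array of shape (3, len(t_grid)).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) == 0:
        raise ValueError("t_grid must be a non-empty 1-D array")
    if np.any(np.diff(t_grid) < 0) or t_grid[0] < 0:
        raise ValueError("t_grid must be sorted and nonnegative")
    A = rate_matrix(r)

    sol = solve_ivp(
        lambda _, p: A @ p,
        t_span=(0.0, float(t_grid[-1]) if t_grid[-1] > 0 else 1.0),
        y0=[1.0, 0.0, 0.0],
        t_eval=t_grid,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y
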