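"""Estimation of apparent off-rates and fractions from measured bond
lifetimes at one clamp force.

The observable at a fixed force is a sample of rupture times whose survival
function is (under the three-state model) a mixture of up to three
exponentials, S(t) = sum_i w_i exp(-k_i t).  The default estimator is a
censoring-aware maximum-likelihood fit of that mixture to the raw
lifetimes; a least-squares fit to the log empirical survival curve is
provided for comparability with histogram/curve-based analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax

from .force import CONDITIONS
from .params import ApparentParams, InvalidRateError

__all__ = [
    "LifetimeDataset",
    "SurvivalCurve",
    "empirical_survival",
    "fit_apparent",
    "select_n_states",
    "ks_gof",
    "bootstrap_apparent",
    "FitResult",
    "MIN_EVENTS_DEFAULT",
    "MERGE_RATIO",
]

#: Minimum number of uncensored rupture events required for a mixture fit.
MIN_EVENTS_DEFAULT = 30

#: Components whose rate ratio falls below this are statistically
#: indistinguishable on realistic sample sizes and are merged.
MERGE_RATIO = 1.5

_COLUMNS = ("force_pN", "lifetime_s", "censored", "condition")


@dataclass(frozen=True)
class LifetimeDataset:
    """Rupture-time records from force-clamp measurements.

    Backed by a DataFrame with columns ``force_pN`` (clamp force, pN),
    ``lifetime_s`` (bond lifetime, s, strictly positive), ``censored``
    (True if the bond outlived the observation window) and ``condition``
    (one of the closed condition vocabulary).
    """

    table: pd.DataFrame

    def __post_init__(self):
        df = self.table
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        bad = df.index[~(df["lifetime_s"] > 0)].tolist()
        if bad:
            raise ValueError(f"non-positive lifetimes at rows {bad}")
        bad = df.index[df["force_pN"] < 0].tolist()
        if bad:
            raise ValueError(f"negative forces at rows {bad}")
        bad = df.index[~df["condition"].isin(CONDITIONS)].tolist()
        if bad:
            raise ValueError(
                f"unknown condition labels at rows {bad}; allowed: {CONDITIONS}"
            )
        object.__setattr__(
            self, "table",
            df.reset_index(drop=True).astype(
                {"force_pN": float, "lifetime_s": float, "censored": bool}),
        )

    @classmethod
    def from_arrays(cls, force_pN, lifetime_s, censored=None,
                    condition="MgEGTA") -> "LifetimeDataset":
        lifetime_s = np.asarray(lifetime_s, dtype=float)
        n = len(lifetime_s)
        force_pN = np.broadcast_to(np.asarray(force_pN, dtype=float), (n,))
        if censored is None:
            censored = np.zeros(n, dtype=bool)
        condition = np.broadcast_to(np.asarray(condition, dtype=object), (n,))
        return cls(pd.DataFrame({
            "force_pN": force_pN, "lifetime_s": lifetime_s,
            "censored": np.asarray(censored, dtype=bool),
            "condition": condition}))

    def __len__(self) -> int:
        return len(self.table)

    @property
    def lifetimes(self) -> np.ndarray:
        return self.table["lifetime_s"].to_numpy()

    @property
    def censored(self) -> np.ndarray:
        return self.table["censored"].to_numpy()

    @property
    def forces(self) -> np.ndarray:
        return self.table["force_pN"].to_numpy()

    def at_force(self, f: float, atol: float = 1e-9) -> "LifetimeDataset":
        """Records in the force bin ``f`` (exact match within ``atol``)."""
        m = np.abs(self.forces - f) <= atol
        return LifetimeDataset(self.table[m])

    def single_force(self) -> float:
        """The common clamp force; raises if more than one bin present."""
        u = np.unique(self.forces)
        if len(u) != 1:
            raise ValueError(
                f"records span {len(u)} force bins ({u}); fit per bin")
        return float(u[0])


@dataclass(frozen=True)
class SurvivalCurve:
    """Step estimate of the survival function with at-risk counts."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.diff(self.survival) > 1e-12) or np.any(self.survival > 1):
            raise ValueError("survival must be non-increasing from <= 1")


def empirical_survival(d: LifetimeDataset) -> SurvivalCurve:
    """Product-limit (Kaplan–Meier) estimate of the survival function.

    Equals 1 - ECDF when no record is censored.  Requires at least one
    uncensored rupture event.
    """
    if len(d) == 0:
        raise ValueError("empty dataset")
    events = ~d.censored
    if not events.any():
        raise ValueError("all records are censored: no rupture events")
    kmf = KaplanMeierFitter()
    kmf.fit(d.lifetimes, event_observed=events)
    tab = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 \
        else kmf.event_table
    times = tab.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.reindex(tab.index)["KM_estimate"].to_numpy()
    return SurvivalCurve(times=times, survival=surv,
                         at_risk=tab["at_risk"].to_numpy())


# ---------------------------------------------------------------------------
# Exponential-mixture maximum likelihood


def _unpack(theta: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    rates = np.exp(theta[:n])
    if n == 1:
        return rates, np.array([1.0])
    logits = np.concatenate([[0.0], theta[n:]])
    return rates, softmax(logits)


def _nll(theta: np.ndarray, t: np.ndarray, cens: np.ndarray, n: int) -> float:
    rates, w = _unpack(theta, n)
    logw = np.log(np.maximum(w, 1e-300))
    # uncensored: log sum_j w_j k_j e^{-k_j t}; censored: log sum_j w_j e^{-k_j t}
    z = -np.outer(t, rates) + logw
    ll_unc = logsumexp(z[~cens] + np.log(rates), axis=1)
    ll_cen = logsumexp(z[cens], axis=1)
    val = -(ll_unc.sum() + ll_cen.sum())
    return val if np.isfinite(val) else 1e300


def _initial_points(t_events: np.ndarray, n: int, n_restarts: int,
                    rng: np.random.Generator) -> list[np.ndarray]:
    """Quantile-anchored, log-spaced starting points plus random
    perturbations."""
    qs = np.quantile(t_events, np.linspace(0.15, 0.85, n))
    base_rates = np.sort(1.0 / np.maximum(qs, 1e-12))[::-1]
    # spread the anchors apart on log scale so components start separated
    spread = np.logspace(0.5 * (n - 1), -0.5 * (n - 1), n)
    base = np.log(base_rates * spread)
    inits = [np.concatenate([base, np.zeros(n - 1)])]
    for _ in range(max(0, n_restarts - 1)):
        jitter = rng.normal(scale=0.8, size=n)
        logits = rng.normal(scale=1.0, size=n - 1)
        inits.append(np.concatenate([base + jitter, logits]))
    return inits


def _merge_close(rates: np.ndarray, w: np.ndarray,
                 ratio: float = MERGE_RATIO) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(-rates)
    rates, w = rates[order], w[order]
    out_r, out_w = [rates[0]], [w[0]]
    merged = False
    for r, wi in zip(rates[1:], w[1:]):
        if out_r[-1] / max(r, 1e-300) < ratio:
            tot = out_w[-1] + wi
            out_r[-1] = (out_r[-1] * out_w[-1] + r * wi) / max(tot, 1e-300)
            out_w[-1] = tot
            merged = True
        else:
            out_r.append(r)
            out_w.append(wi)
    if merged:
        warnings.warn(
            f"merged mixture components closer than rate ratio {ratio} "
            "(not identifiable at this sample size)", stacklevel=3)
    return np.array(out_r), np.array(out_w)


def _embed3(rates: np.ndarray, w: np.ndarray) -> ApparentParams:
    """Embed an n<=3 component estimate into the three-slot layout by
    padding with zero-weight duplicates of the slowest rate."""
    rates = list(rates)
    w = list(w)
    while len(rates) < 3:
        rates.append(rates[-1])
        w.append(0.0)
    return ApparentParams.from_unsorted(rates[:3], w[:3], renormalize=True)


@dataclass(frozen=True)
class FitResult:
    """Apparent-parameter estimate with fit diagnostics."""

    params: ApparentParams
    n_components: int
    log_likelihood: float
    aic: float
    bic: float
    n_events: int
    n_censored: int
    converged: bool
    method: str
    restarts: list = field(default_factory=list, repr=False, compare=False)

    #: rates/weights before zero-weight padding, fastest first
    component_rates: tuple = ()
    component_weights: tuple = ()


def _fit_mle(t: np.ndarray, cens: np.ndarray, n: int, n_restarts: int,
             rng: np.random.Generator,
             extra_inits: list | None = None) -> tuple[np.ndarray, float, list]:
    inits = _initial_points(t[~cens], n, n_restarts, rng)
    if extra_inits:
        inits = extra_inits + inits
    best_theta, best_val, trace = None, np.inf, []
    for x0 in inits:
        res = minimize(_nll, x0, args=(t, cens, n), method="L-BFGS-B",
                       options={"maxiter": 500})
        trace.append((res.fun, res.success))
        if res.fun < best_val:
            best_val, best_theta = res.fun, res.x
    if best_theta is None:
        raise RuntimeError(f"mixture fit failed to converge; trace: {trace}")
    return best_theta, best_val, trace


def _fit_ls_logsurv(d: LifetimeDataset, n: int, n_restarts: int,
                    rng: np.random.Generator) -> tuple[np.ndarray, float, list]:
    curve = empirical_survival(d)
    keep = curve.survival > 0
    ts, logS = curve.times[keep], np.log(curve.survival[keep])

    def obj(theta):
        rates, w = _unpack(theta, n)
        model = np.log(np.maximum(
            (w[None, :] * np.exp(-np.outer(ts, rates))).sum(axis=1), 1e-300))
        return float(np.sum((model - logS) ** 2))

    inits = _initial_points(d.lifetimes[~d.censored], n, n_restarts, rng)
    best_theta, best_val, trace = None, np.inf, []
    for x0 in inits:
        res = minimize(obj, x0, method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12})
        trace.append((res.fun, res.success))
        if res.fun < best_val:
            best_val, best_theta = res.fun, res.x
    return best_theta, best_val, trace


def fit_apparent(d: LifetimeDataset, n_states: int = 3, *,
                 min_events: int = MIN_EVENTS_DEFAULT,
                 n_restarts: int = 10, seed: int = 0,
                 method: str = "mle") -> FitResult:
    """Fit an ``n_states``-component exponential mixture to the lifetimes
    of one force bin.

    Parameters
    ----------
    d : LifetimeDataset
        Records sharing a single force bin.
    n_states : 1, 2 or 3
        Number of exponential components (bound states) to fit.
    min_events : int
        Minimum number of uncensored events required.
    n_restarts : int
        Optimizer restarts from quantile-anchored + jittered starting
        points (label-switching and local-optimum guard).
    seed : int
        Seed of the restart-jitter stream.
    method : {"mle", "ls-logsurv"}
        Censoring-aware maximum likelihood on raw lifetimes (default), or
        least squares on the log product-limit survival curve.

    Returns
    -------
    FitResult
        With ``params`` always in the three-slot layout (zero-weight
        padding when fewer components are supported), components sorted
        fastest first.
    """
    if n_states not in (1, 2, 3):
        raise ValueError("n_states must be 1, 2 or 3")
    d.single_force()
    t, cens = d.lifetimes, d.censored
    n_events = int((~cens).sum())
    if n_events < min_events:
        raise ValueError(
            f"only {n_events} rupture events; at least {min_events} required "
            "for a stable mixture fit")
    rng = np.random.default_rng(seed)

    if method == "mle":
        extra = []
        if n_states > 1:
            # embed the (n-1)-component solution: guarantees the likelihood
            # never decreases as components are added
            sub = fit_apparent(d, n_states - 1, min_events=min_events,
                               n_restarts=max(3, n_restarts // 2), seed=seed,
                               method="mle")
            r_new = np.array(sub.component_rates)
            w_new = np.array(sub.component_weights)
            while len(r_new) < n_states:  # sub-fit may itself have merged
                r_new = np.concatenate([r_new, [r_new.min() * 0.3]])
                w_new = np.concatenate([w_new * (1 - 1e-4), [1e-4]])
            theta0 = np.concatenate([
                np.log(r_new), np.log(w_new[1:] / w_new[0])])
            extra = [theta0]
        theta, nll, trace = _fit_mle(t, cens, n_states, n_restarts, rng,
                                     extra_inits=extra)
        loglik = -nll
    elif method == "ls-logsurv":
        theta, _, trace = _fit_ls_logsurv(d, n_states, n_restarts, rng)
        loglik = -_nll(theta, t, cens, n_states)
    else:
        raise ValueError(f"unknown method {method!r}")

    rates, w = _unpack(theta, n_states)
    rates, w = _merge_close(rates, w)
    if len(rates) < n_states:
        warnings.warn(
            f"data support only {len(rates)} of {n_states} requested "
            "components; returning the reduced model", stacklevel=2)
    k_free = 2 * len(rates) - 1
    params = _embed3(rates, w)
    n_tot = len(t)
    return FitResult(
        params=params,
        n_components=len(rates),
        log_likelihood=float(loglik),
        aic=2 * k_free - 2 * loglik,
        bic=k_free * np.log(n_tot) - 2 * loglik,
        n_events=n_events,
        n_censored=int(cens.sum()),
        converged=any(ok for _, ok in trace),
        method=method,
        restarts=trace,
        component_rates=tuple(rates),
        component_weights=tuple(w / w.sum()),
    )


def bootstrap_apparent(d: LifetimeDataset, n_states: int = 3, *,
                       n_boot: int = 200, seed: int = 0,
                       **fit_kwargs) -> pd.DataFrame:
    """Nonparametric bootstrap CIs (2.5/97.5 percentiles) for the apparent
    parameters; returns one row per quantity."""
    rng = np.random.default_rng(seed)
    rows = []
    n = len(d)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        db = LifetimeDataset(d.table.iloc[idx])
        try:
            res = fit_apparent(db, n_states, seed=int(rng.integers(2**31)),
                               **fit_kwargs)
        except (ValueError, RuntimeError):
            continue
        p = res.params
        rows.append([p.k1, p.k2, p.k3, p.w1, p.w2, p.w3])
    arr = np.array(rows)
    names = ["k1", "k2", "k3", "w1", "w2", "w3"]
    return pd.DataFrame({
        "quantity": names,
        "lo": np.percentile(arr, 2.5, axis=0),
        "hi": np.percentile(arr, 97.5, axis=0),
        "n_boot_ok": len(rows),
    })


def ks_gof(d: LifetimeDataset, params: ApparentParams,
           alpha: float = 0.01) -> tuple[float, float, bool]:
    """Kolmogorov–Smirnov goodness of fit of a fitted mixture against the
    uncensored lifetimes of one bin: (statistic, critical value, reject).

    Uses the asymptotic critical value, which is conservative when the
    parameters were estimated from the same sample.
    """
    from scipy.stats import kstwobign

    from . import kinetics

    t = np.sort(d.lifetimes[~d.censored])
    if len(t) == 0:
        raise ValueError("no uncensored events")
    cdf = 1.0 - kinetics.survival(params, t)
    hi = np.arange(1, len(t) + 1) / len(t)
    lo = np.arange(0, len(t)) / len(t)
    ks = float(max(np.max(np.abs(hi - cdf)), np.max(np.abs(lo - cdf))))
    crit = float(kstwobign.ppf(1 - alpha) / np.sqrt(len(t)))
    return ks, crit, ks > crit


def select_n_states(d: LifetimeDataset, *, threshold: float = 10.0,
                    criterion: str = "bic", **fit_kwargs) -> int:
    """Smallest number of components whose information-criterion
    improvement over the next-simpler model exceeds ``threshold``.

    The model assumed by the kinetic scheme has three states; this check
    asks how many the data can actually support.
    """
    attr = {"bic": "bic", "aic": "aic"}[criterion]
    fits = {}
    n = 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fits[1] = fit_apparent(d, 1, **fit_kwargs)
        while n < 3:
            fits[n + 1] = fit_apparent(d, n + 1, **fit_kwargs)
            if (getattr(fits[n], attr) - getattr(fits[n + 1], attr)
                    > threshold and fits[n + 1].n_components > n):
                n += 1
            else:
                break
    return n
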