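# Methods

## Model and assumptions

`bondkin` models a receptor–ligand bond that can occupy three bound
conformational states C₁, C₂, C₃ under a constant tensile force.  The
scheme is sequential and fully irreversible: forward transitions
C₁ → C₂ → C₃ with rates k₁₂, k₂₃ (no reverse transitions), and
dissociation from state Cᵢ with reverse-rate k_ri to an absorbing unbound
state (no rebinding under load).  All rates are constant within one
lifetime — the clamp holds force fixed, and force-ramp protocols are out
of scope.  The initial condition is p(0) = (1, 0, 0): transitions require
force, so a freshly loaded bond starts in the short-lived state.

Irreversibility makes the generator lower-bidiagonal, so its eigenvalues
are the diagonal entries −K₁, −K₂, −K₃ with

K₁ = k₁₂ + k_r1, K₂ = k₂₃ + k_r2, K₃ = k_r3,

and the occupancies take the classical sequential-decay (Bateman) form.
Summing them gives the observable survival S(t) = Σ ωᵢ e^(−Kᵢt) with

ω₁ = 1 − k₁₂/(K₁−K₂) + k₁₂k₂₃/((K₂−K₁)(K₃−K₁)),
ω₂ = k₁₂/(K₁−K₂) + k₁₂k₂₃/((K₁−K₂)(K₃−K₂)),
ω₃ = k₁₂k₂₃/((K₁−K₃)(K₂−K₃)).

These sum to one identically.  The mapping is inverted exactly under the
natural ordering (state i ↔ rate Kᵢ):

k_r3 = k₃; k₁₂ = ω₂(k₁−k₂) + ω₃(k₁−k₃); k₂₃ = ω₃(k₁−k₃)(k₂−k₃)/k₁₂;
k_r1 = k₁ − k₁₂; k_r2 = k₂ − k₂₃.

Worked fixed point used throughout the tests: (k₁₂, k₂₃, k_r1, k_r2, k_r3)
= (2, 1, 3, 1, 0.5) s⁻¹ ⇒ k = (5, 2, 0.5) s⁻¹, ω = (13, 6, 8)/27.

### Properties of the feasible set

Two results shape the API:

* **The inverse of any valid mixture is feasible.**  For sorted rates
  k₁ ≥ k₂ ≥ k₃ > 0 and weights in [0, 1] summing to one, the implied
  rates are automatically nonnegative (e.g. k_r1 = ω₁k₁ + ω₂k₂ + ω₃k₃ > 0).
  `intrinsic_from_apparent` therefore only raises its feasibility error
  for inputs that bypass the validated `ApparentParams` type (raw tables);
  a `project=True` mode clamps roundoff-scale negativity instead.
* **Not every intrinsic parameter set yields a proper mixture.**  ω₂ has
  the sign of (k_r3 − k_r2)·(…): when a later state dissociates faster
  than an earlier one, or when k₁₂ exceeds the K₁−K₂ gap, some ωᵢ leaves
  [0, 1] and S(t) is a signed exponential sum.  The bijection therefore
  holds on the physically ordered regime (short-lived first, proper
  weights); property tests sample from exactly that set, and
  `apparent_from_intrinsic` raises a structured error outside it.

### Ordering and degeneracy

Fitted mixtures suffer label switching, so apparent parameters are always
reported fastest-mode-first, with the permutation from natural state order
recorded on the `ApparentParams`.  The Bateman denominators (Kᵢ−Kⱼ) vanish
at eigen-rate degeneracy; below a relative gap of 1e−9 the trajectory
evaluator switches to the analytic limits (t·e^(−Kt), and t²e^(−Kt)/2 for
a triple root), which keeps `state_probabilities` continuous across the
tolerance (verified against the ODE oracle to 1e−6).  The
exponential-mode *decomposition*, by contrast, does not exist at
degeneracy — the weights diverge as the secular terms appear — so
`apparent_from_intrinsic` raises `DegenerateRatesError` there rather than
returning exploding pseudo-weights.  Degenerate rates occupy a measure-zero
set never produced by fitting; the error path exists for constructed
inputs.

## Lifetime fitting

At one clamp force the data are i.i.d. rupture times, optionally
right-censored by the observation window.  The default estimator is
maximum likelihood on the raw lifetimes with the censored likelihood
(density for events, survival for censored records), parameterized by
log-rates and softmax weights and optimized with L-BFGS-B from
quantile-anchored, log-spread starting points plus seeded random restarts
(10 by default).  For n > 1 components the (n−1)-component solution is
embedded as an extra start, which guarantees the maximized likelihood is
non-decreasing in the component count.  Because the original analysis
pipeline for such data is not fully specified by the experiments
themselves, a least-squares mode on the log product-limit survival curve
(`method="ls-logsurv"`) is provided for comparability; the product-limit
(Kaplan–Meier) estimator comes from `lifelines`.

Guards: a minimum of 30 uncensored events per fit (configurable);
components closer than a rate ratio of 1.5 are merged with a warning —
they are not identifiable at realistic sample sizes — and the model is
reported as reduced.  `select_n_states` picks the smallest component count
whose BIC improvement over the next-simpler model exceeds 10 (a
conventional "very strong evidence" threshold).  A Kolmogorov–Smirnov
goodness-of-fit flag (asymptotic critical value, conservative for fitted
parameters) marks bins the mixture cannot describe, e.g. data generated
with a fourth well-separated scale.

## Force laws

Reverse-rates follow the Bell model k(f) = k⁰e^(f/f_β), fitted as a line
on (f, ln k) — unweighted by default, inverse-variance weighted on request
(whether the original analyses weighted these fits is not documented, so
both modes exist).  Zero rates cannot enter the log and are excluded with
an explicit warning rather than pseudo-counted.  A fitted negative slope
is returned flagged (`is_slip = False`), not rejected: "not a slip bond"
is a finding, not an input error.

Transition rates must vanish at zero force and increase with it; no
specific functional form is dictated by the observations, so the package
defaults to the zero-intercept exponential k_a(e^(f/f_β) − 1) — the
simplest law satisfying both constraints and reducing to Bell-like
behaviour at high force — and also offers a monotone tabulated law
(piecewise-linear in log-rate) when only per-force values are known.  A
`ConditionModel` bundles one law per rate; the six condition labels
({Ca²⁺/Mg²⁺, Mg²⁺/EGTA, Mn²⁺} × ±XVA143) form a closed vocabulary.

## Synthetic reference model

The original force-clamp datasets and their per-force fitted parameter
tables are not redistributed, so `bondkin.reference` defines a *synthetic*
condition model whose parameters were chosen once, analytically, to
satisfy the reported constraints simultaneously: the reverse-rate
hierarchy and its force-sensitivity ordering (k_r1 largest/least
sensitive, k_r3 smallest/most sensitive), transitions zero at zero force
with k₁₂ > k₂₃, activation times 1/k₁₂ and 1/k₂₃ running from seconds at
low force to tens of milliseconds near 20 pN, a proper mixture at every
tabulated force bin, a catch–slip mean-lifetime peak just above the
5.9 pN bin, and a ~tenfold-or-more drop of the C₃ peak time from >3 s at
the lowest nonzero bin to ~0.3 s at 17.1 pN.  Final calibration (rates in
s⁻¹, forces in pN):

| rate | law | parameters |
|---|---|---|
| k_r1 | Bell | k⁰ = 1.8, f_β = 12.0 |
| k_r2 | Bell | k⁰ = 0.35, f_β = 7.0 |
| k_r3 | Bell | k⁰ = 0.015, f_β = 4.4 |
| k₁₂ | activated | k_a = 0.55, f_β = 4.0 |
| k₂₃ | activated | k_a = 0.15, f_β = 4.6 |
| k₁₂ (+XVA143) | activated | k_a = 0.15, f_β = 5.5 |
| k₂₃ (+XVA143) | zero | — |

Intrinsic rates are modelled as cation-indifferent (all three buffers
share the laws; the label only tags data).  The XVA143 variants zero k₂₃
and suppress k₁₂, which converts the catch–slip profile to slip-only
while leaving dissociation untouched.  Tabulated force bins are
(0, 2.3, 5.9, 9.0, 13.2, 17.1) pN.

## Simulator

`draw_lifetime` realizes the scheme as a continuous-time Markov chain by
direct competing-clocks sampling: in state i, draw Exp(k_forward) and
Exp(k_dissoc), take the minimum — the simplest provably correct scheme
for a three-state chain (uniformization would buy nothing here).  The
vectorized `draw_lifetimes` uses the equivalent dwell-then-branch form
(Exp(total rate), branch with probability k_d/total).  Exit-state
fractions converge to the first-step-analysis splitting probabilities,
and the empirical survival matches the analytic mixture (KS-tested).
Seeding: one master seed; per-force-bin streams are spawned via
`numpy.random.SeedSequence`, so any bin is reproducible independently of
which other bins are generated.  Right-censoring at a fixed observation
window is supported and off by default.

What the simulator does *not* emulate: instrument noise, probe thermal
fluctuation, bead–cell attachment statistics, multiple bonds, or
force-ramp loading.  Passing recovery tests therefore demonstrates
statistical correctness of the estimator chain under the model, not
robustness to instrumental artifacts in real data.

## Numerical choices

* Peak finding for p₃(t): bracket the sign change of the closed-form
  derivative dp₃/dt = k₂₃p₂ − k_r3p₃ on a 400-point log grid over
  [1e−4, 1e3] s, then polish with Brent root-finding (xtol 1e−14); bare
  grids mislocate sharp peaks.  Requested when k₁₂, k₂₃, k_r3 > 0;
  otherwise a structured "no long-lived occupancy" error.
* ODE oracle: LSODA at rtol 1e−10/atol 1e−12; used only in tests as the
  independent check on the closed form (agreement ≤1e−8 on t ∈ [0, 50]).
* Default export time grid: log-spaced, 600 points over 0–30 s, matching
  the lifetime range of clamp experiments.
* Mean lifetime: Σωᵢ/kᵢ, cross-checked against quadrature of S(t).
* Table I/O: floats written with `%.17g` and parsed with pandas'
  `round_trip` precision so write→read is bit-exact; weight sums are
  renormalized with a warning, unsorted rows re-sorted with a permutation
  warning, genuinely infeasible rows rejected with line numbers.

## Problem sizes used in validation

The shipped validation uses 100 random parameter sets for the
closed-form/ODE comparison, 1000 for the mapping round trip, 10⁴
lifetimes per simulator fidelity check (5 parameter sets), and
2000 lifetimes per force at 8 forces for end-to-end recovery — sizes at
which the Monte-Carlo error of each check sits well below its tolerance.

## Known limitations

* The three-state, strictly sequential, irreversible topology is fixed;
  reversible or branched schemes and N > 3 states are out of scope.
* Apparent parameters are undefined (not merely ill-conditioned) at
  eigen-rate degeneracy; callers hitting the structured error should use
  the survival/trajectory evaluators, which remain exact there.
* The mixture fitter assumes i.i.d. lifetimes within a force bin; drift
  within an experiment maps into apparent extra components.
* The reference condition model is a synthetic calibration, not fitted
  experimental parameters; quantitative agreement with any particular
  dataset is not implied.
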