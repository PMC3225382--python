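"""Synthetic reference condition models.

The original single-bond force-clamp datasets and their fitted per-force
parameter tables are not redistributed with this package, so the reference
models here are *synthetic*: force-law parameters chosen once so that the
model reproduces the qualitative and order-of-magnitude behaviour reported
for the LFA-1/ICAM-1 bond under a clamped load below 20 pN —

* dissociation from each single state is a slip bond (Bell law), with the
  short-lived state C1 rupturing fastest but least force-sensitively and
  the long-lived state C3 slowest but most force-sensitively;
* both conformational transition rates are zero at zero force and grow
  with it, k12 faster than k23, with characteristic activation times
  1/k12 and 1/k23 running from seconds at low force to tens of
  milliseconds near 20 pN;
* the resulting mean bond lifetime is catch–slip: it rises with force
  through roughly 6 pN and falls beyond (interior maximum);
* the time for the long-lived state's occupancy to peak drops about
  tenfold, from > 3 s at the lowest nonzero bin to ~0.3 s at ~17 pN;
* the XVA143 variants block the C2 -> C3 transition entirely and suppress
  (but do not abolish) C1 -> C2, converting the catch–slip bond to
  slip-only, while leaving the dissociation rates untouched.

Intrinsic dissociation and transition rates are taken as indifferent to
the cation condition, so all three cation buffers share the same laws;
the condition label still tags generated data.
"""

from __future__ import annotations

from .force import BellLaw, ConditionModel, ForceActivatedLaw, ZeroLaw

__all__ = [
    "reference_condition_model",
    "REFERENCE_FORCES_PN",
]

#: Representative clamp-force bins (pN) spanning the analysed 0–20 pN
#: range, including the catch-regime boundary (5.9 pN) and the high-force
#: bin (17.1 pN) used for the activation-time prediction.
REFERENCE_FORCES_PN = (0.0, 2.3, 5.9, 9.0, 13.2, 17.1)

# Shared (cation-indifferent) force laws, synthetic calibration.
_KR1 = BellLaw(k0=1.8, f_scale=12.0)     # C1: fastest, least force-sensitive
_KR2 = BellLaw(k0=0.35, f_scale=7.0)     # C2: intermediate
_KR3 = BellLaw(k0=0.015, f_scale=4.4)    # C3: slowest, most force-sensitive
_K12 = ForceActivatedLaw(k_a=0.55, f_scale=4.0)
_K23 = ForceActivatedLaw(k_a=0.15, f_scale=4.6)
# XVA143 suppresses the C1->C2 transition and blocks C2->C3.
_K12_XVA = ForceActivatedLaw(k_a=0.15, f_scale=5.5)


def reference_condition_model(condition: str = "MgEGTA") -> ConditionModel:
    """Synthetic condition model for any of the six condition labels.

    Cation buffers share identical laws; ``"+XVA143"`` variants swap in
    the suppressed k12 and a zero k23.
    """
    if condition.endswith("+XVA143"):
        return ConditionModel(condition=condition, k12=_K12_XVA, k23=ZeroLaw(),
                              kr1=_KR1, kr2=_KR2, kr3=_KR3)
    return ConditionModel(condition=condition, k12=_K12, k23=_K23,
                          kr1=_KR1, kr2=_KR2, kr3=_KR3)
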