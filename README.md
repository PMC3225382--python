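# bondkin

Coupled kinetics of force-induced conformational transitions and ligand
dissociation in three-state receptor–ligand bonds.

Single-molecule force-clamp experiments (e.g. with a biomembrane force
probe) on integrin–ligand bonds such as LFA-1/ICAM-1 show lifetime
distributions with up to three exponential scales, and mean lifetimes that
first *rise* with tensile force (catch bond) before falling (slip bond).
`bondkin` implements the mechanistic model behind those observations: the
bond occupies one of three conformational states C₁ → C₂ → C₃
(short-, intermediate-, long-lived), force drives the irreversible forward
transitions, and the ligand dissociates irreversibly from any state.  The
package is for biophysicists analysing bond-lifetime data and for anyone
who needs a tested reference implementation of sequential-decay survival
analysis with exact parameter mappings.

## The model

State occupancies p = (p₁, p₂, p₃) with p(0) = (1, 0, 0) obey dp/dt = A·p,

```
      ⎡ −(k₁₂+k_r1)        0        0   ⎤
  A = ⎢     k₁₂       −(k₂₃+k_r2)   0   ⎥
      ⎣      0             k₂₃    −k_r3 ⎦
```

where k₁₂, k₂₃ are interstate transition rates and k_r1–k_r3 the intrinsic
reverse-rates (all s⁻¹).  Because A is triangular, the observable total
survival is a three-exponential mixture

S(t) = p₁+p₂+p₃ = ω₁e^(−k₁t) + ω₂e^(−k₂t) + ω₃e^(−k₃t),
with apparent off-rates (k₁, k₂, k₃) = (k₁₂+k_r1, k₂₃+k_r2, k_r3)
and fractions ωᵢ given in closed (Bateman) form.  The mapping
intrinsic → apparent is inverted exactly:

k_r3 = k₃,  k₁₂ = ω₂(k₁−k₂) + ω₃(k₁−k₃),
k₂₃ = ω₃(k₁−k₃)(k₂−k₃)/k₁₂,  k_r1 = k₁−k₁₂,  k_r2 = k₂−k₂₃.

Force dependence: reverse-rates follow the Bell model
k(f) = k⁰·exp(f/f_β); transition rates vanish at zero force and follow
k(f) = k_a·(exp(f/f_β) − 1).  Composing these laws yields force-resolved
intrinsic rates, survival families, the occupancy of the long-lived state
p₃(t) with its peak time (the activation time of the high-affinity state),
and the catch–slip mean-lifetime profile ⟨t⟩(f) = Σωᵢ/kᵢ.

The package also contains a censoring-aware maximum-likelihood
exponential-mixture fitter for measured lifetimes, and a stochastic
(competing-clocks CTMC) simulator that emulates force-clamp experiments so
the whole pipeline can be validated end to end without external data.
Because the original experiment's fitted parameter tables are not
redistributed, `bondkin.reference` ships a clearly-labelled *synthetic*
condition model calibrated to the reported qualitative behaviour.

## Worked example

```python
import bondkin as bk

r = bk.IntrinsicRates(k12=2.0, k23=1.0, kr1=3.0, kr2=1.0, kr3=0.5)
p = bk.apparent_from_intrinsic(r)
print(p.rates)    # [5.  2.  0.5]      apparent off-rates, s^-1
print(p.weights)  # [0.481481 0.222222 0.296296]   apparent fractions
print(bk.intrinsic_from_apparent(p).as_tuple())  # (2.0, 1.0, 3.0, 1.0, 0.5)
```

The three observable decay rates are the diagonal of A (5, 2, 0.5 s⁻¹);
48.1% / 22.2% / 29.6% of ruptures follow each mode; the inverse mapping
returns the generating rates exactly.  With the synthetic reference
condition model (`examples/04_catch_slip_predictions.py`):

```
profile: catch-slip, mean lifetime peaks at 6.00 pN (2.72 s)

force (pN)  mean lifetime (s)  C3 peak time (s)  C3 peak height
      0.0           0.556            (C3 never populated)
      2.3           1.745            6.059           0.024
      5.9           2.718            2.897           0.108
     17.1           0.793            0.306           0.409
```

Mean bond lifetime rises from 0.56 s to 2.72 s at ~6 pN (catch regime)
then falls (slip regime), and the time for the long-lived state to reach
maximal occupancy drops about twentyfold — from >3 s at the lowest nonzero
force to ~0.3 s at 17.1 pN — while its peak height grows: force
accelerates activation of the high-affinity state.

The `examples/` directory holds one short script per capability
(closed form & mappings, lifetime fitting, force-law fitting, predictions,
end-to-end recovery).  A thin CLI mirrors the pipeline:

```sh
bondkin simulate --forces 5.9,9.0 --n-per-force 500 --seed 1 --out lt.csv
bondkin fit --in lt.csv --seed 1 --out apparent.csv
bondkin map --in apparent.csv --direction apparent-to-intrinsic --out intrinsic.csv
bondkin bellfit --in intrinsic.csv --rate kr1
```

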