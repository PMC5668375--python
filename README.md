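# bcrsurv

A kinetic model of how B cells integrate two survival inputs through the
B-cell receptor (BCR): the constitutive **tonic** signal transmitted by
free surface BCR, and the **antigen-triggered** signal produced when BCR
are crosslinked by a multivalent ligand (here the antigen surrogate
F(ab′)₂ α-IgM antibody). The package is written for systems
immunologists who want to simulate primary-B-cell survival under
antibody stimulation, refit the model to their own viability data, or
study the identifiability of its parameters on synthetic ground truth.

## The model

Each cell carries three dimensionless state variables on [0, 1]: its
total surface BCR level *B* (max-normalized MFI), the crosslinked
fraction *b*, and the survival signal *S* (the "on" pool of a
signal that is conserved: Signal_on + Signal_off = 1):

```
dB/dt = −d₁·B                                        (receptor turnover)
db/dt = k₂·A·(B − b) − k₃·b                          (antibody binding, dose A in µg/ml)
dS/dt = k₁·(1−S)·(B − b) + k₄·(1−S)·f − d₂·S         (survival signal)
 f    = max(0, b − B·offset)                         (activation threshold)
```

A cell **dies** when *S* drops below a floor (`deadline`); cohort
viability is the fraction of cells still alive. Crosslinked BCR stop
feeding the tonic term, and only occupancy *above* the threshold
fraction `offset` generates antigen-triggered signal — which is why low
antibody doses *reduce* survival (they subtract tonic substrate without
paying back) while near-saturating doses enhance it.

At constant total BCR the binding equation has the closed form
`b(t) = k₂A(1 − e^{−(k₂A+k₃)t})/(k₂A + k₃)`, whose plateau is the
isotherm `A/(A + k₃/k₂)`.

Parameters are estimated in two stages, mirroring how the underlying
experiments constrain them: `d₁`, `k₂`, `k₃` by weighted least squares
(J = Σ(yᵢ−f(xᵢ))²/σᵢ²) on MFI-decay and antibody-occupancy data, and
`k₁`, `d₂`, `deadline`, `k₄`, `offset` by a real-coded genetic
algorithm (UNDX crossover, Minimal Generation Gap replacement) on
cohort-viability data, with multi-seed consensus. The packaged
consensus fit gives k₄/k₁ ≈ 4.3 (a crosslinked receptor signals about
four times as strongly as a free one) and offset ≈ 0.61 (61% of the
surface BCR must be occupied before any effective triggered signal).

## Worked example

```python
>>> import bcrsurv as b
>>> p = b.ModelParameters.published()        # packaged consensus fit
>>> round(100 * b.saturation_fraction(1.0, 0.5, p.k2, p.k3))
95
```

95% of the equilibrium occupancy is reached within 30 min at 1 µg/ml —
binding equilibrates far faster than survival evolves.

```python
>>> cohort = b.default_cohort(seed=0)        # 200-cell calibrated cohort
>>> b.simulate_cohort(cohort, 0.0, p, [0, 18, 48, 72])
array([0.88, 0.47, 0.32, 0.2 ])
>>> b.simulate_cohort(cohort, 3.0, p, [0, 18, 48, 72])
array([0.88 , 0.43 , 0.245, 0.085])
>>> b.simulate_cohort(cohort, 10.0, p, [0, 18, 48, 72])
array([0.88, 0.53, 0.38, 0.31])
```

Unstimulated viability falls from 88% to 20% over three days of
culture (cells whose initial signal already sits below the death floor
count as dead at t = 0). A 3 µg/ml dose — about 73% receptor
occupancy, barely above the 61% threshold — *costs* viability (8.5%
vs 20% at 72 h), while 10 µg/ml rescues it (31%). That non-monotone
dose response is the model's central prediction.

The numbered scripts under `analysis/` run the full study: generate
synthetic inputs (`01`), fit the directly identifiable rates by
weighted least squares (`02`), run the two-stage GA with multi-seed
consensus (`03`), and simulate the dose × time surface with the
low-dose-dip and BTK-inhibitor-mimic summaries (`04`). Outputs land
under `results/`. A `bcrsurv` CLI exposes the same steps
(`simulate`, `synth`, `fit`, `validate`).

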