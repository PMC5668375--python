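# Methods

## Model

Per cell, three coupled ODEs on a dimensionless [0, 1] scale (time in
hours, antibody dose in µg/ml):

* **Receptor turnover.** Total surface BCR decays exponentially,
  `dB/dt = −d₁B`. Synthesis, internalization, recycling and
  degradation are collapsed into one net first-order loss; there is no
  re-synthesis term because the modeled cultures lack the stimuli that
  would drive it.
* **Antibody binding.** Mass action between free receptor and a
  constant antibody bath: `db/dt = k₂A(B−b) − k₃b`. Binding is fast
  (equilibration < 1 h at ≥ 1 µg/ml) relative to both receptor decay
  and survival dynamics.
* **Survival signal.** The signal is a conserved two-state pool
  (on + off = 1). Free BCR converts off→on at rate `k₁·(B−b)`;
  crosslinked BCR above the activation threshold converts off→on at
  rate `k₄·f`, with `f = max(0, b − B·offset)`; the on pool is
  consumed at rate `d₂`. Both generation terms draw on the single
  shared off pool. A cell dies — irreversibly — when the signal drops
  below `deadline`.

Key structural assumptions: bound BCR carries no extra degradation
term (the binding subsystem conserves `B = free + bound` up to the
`d₁` decay of `B`; `b` is clamped to ≤ `B` after each step, a clamp
that is essentially never active because binding equilibrates in
< 1 h while `B` loses only ~1.4%/h); the antibody dose is constant for
the whole culture (no washout); and the triggered signal below the
offset is lost, not banked.

The model with no activation threshold is the `offset = 0` special
case; the tonic-only model is the `A = 0` (or `k₄ = 0`) special case,
to which the combined equations reduce exactly.

## Parameters

| name | meaning | unit | packaged consensus value |
|---|---|---|---|
| d₁ | BCR degradation rate | /h | 0.01435 |
| k₁ | tonic signal generation per free BCR | /h | 0.02980 |
| k₂ | antibody–BCR association | ml/µg/h | 2.779 |
| k₃ | antibody–BCR dissociation | /h | 3.145 |
| k₄ | signal generation per crosslinked BCR above threshold | /h | 0.1294 |
| d₂ | signal consumption | /h | 0.1543 |
| offset | activation threshold (fraction of total BCR) | — | 0.6097 |
| deadline | survival-signal death floor | — | 0.01032 |

Two fitted sets ship as fixtures: the full consensus set above
(`ModelParameters.published()`) and the earlier tonic-only fit
(`ModelParameters.tonic_fit()`: k₁ = 0.02381, d₂ = 0.1239,
deadline = 0.01034, with k₄ = 0 and offset = 1 so the stimulated terms
are inert). The two differ because they were obtained against
different data (4 unstimulated points vs the full 16-point grid); both
are useful, the first as simulation truth, the second as the
warm-start origin of the two-stage fit. `IBRUTINIB_K1 = 0.009523 /h`
(40% of the tonic-fit k₁) reproduces the survival decline seen under
100 nM of the BTK inhibitor Ibrutinib.

## Integration and the death rule

Classical fixed-step RK4 on a 0.01 h grid over 0–72 h. Initial state:
`B = bcr0`, `b = 0`, `S = bcr0` (the pre-culture signal is taken to
track the initial receptor level). Conventions, each a deliberate
choice where the procedure admits alternatives:

* the death test is **strict** (`S < deadline`), applied after every
  step *and at t = 0*, so simulated t = 0 viability can be below 100%
  (measured viability is normalized at time 0, simulated viability is
  not);
* death is absorbing; a dead cell's remaining trajectory is irrelevant
  to viability and is not integrated further in the cohort kernel;
* state variables are clamped to their invariant ranges after each
  full step (never mid-stage): `B` to [0, 1], `b` to [0, B], `S` to
  [0, 1];
* query times are snapped to the nearest grid point, not interpolated.

The cohort integrator exploits two exact structural facts rather than
approximations: the (B, b) subsystem is linear, signal-independent and
homogeneous in `bcr0`, so its RK4 stage values are computed once per
dose and shared by all cells; and a cell's fate is monotone in `bcr0`
(initial signal and forcing both scale with it), so the alive count at
a query time is found by binary search over the sorted cohort. Unit
tests pin the fast path to the cell-by-cell scan and the compiled
kernel to the pure-Python integrator. Halving `dt` to 0.005 flips no
cell's fate in the calibrated scenarios.

## Synthetic data

No raw dataset from the underlying study is deposited, so every input
is generated, with the generators treated as fixed study conditions:

* **BCR (MFI) distribution.** 8342 cells, max-normalized. Log
  fluorescence is a three-component normal mixture: a main body
  (SD 0.95 log units), a brighter shoulder (25% of cells, +1.68 SD,
  narrower spread 0.26 SD) as seen in splenic B-cell MFI histograms,
  and a dim tail (3% of cells, −3 SD). The mixture was calibrated
  once, by moment matching over repeated draws, to the three facts
  known about the parent sample: normalized mean ≈ 0.0746, median
  ≈ 0.0436, brightness range > 1000-fold. A single log-normal cannot
  satisfy all three: under max-normalization its mean/median ratio and
  its median-to-max distance are controlled by the same spread
  parameter and the targets disagree (ratio 1.71 wants SD ≈ 1.04, the
  median wants ≈ 0.83). Because the normalizing maximum is a single
  order statistic, the realized mean and median scatter by roughly
  ±15% across seeds; the defaults center them on the targets.
* **Cohort.** The 200 representative cells are the (i−0.5)/200
  empirical quantiles (nearest order statistics) of the parent draw —
  deterministic, and distribution-matched by construction.
* **Observations.** MFI decay, occupancy titrations (plateau
  normalized to the top dose), occupancy time courses, and dose × time
  viability tables are evaluated from the model and perturbed with
  additive Gaussian noise truncated to [0, 1] (σ = 0.02 by default,
  the scale of duplicate-experiment spread; the study gives no
  distributional detail beyond mean ± SD). All generators are pure
  functions of (parameters, seed), using NumPy's MT19937
  Mersenne-Twister generator.

What the generators do **not** emulate: FACS measurement artifacts
(spillover, debris, gating), biological correlation between a cell's
BCR level and other survival covariates, inter-experiment batch
effects, and any real-data misspecification of the model family
itself. Passing recovery tests therefore shows the *procedure* is
correct and the parameters are identifiable under the stated designs —
not that the model is true of real B cells.

## Fitting

* **Weighted least squares** (J = Σ(yᵢ−fᵢ)²/σᵢ²) for the directly
  identifiable constants: `d₁` by bounded 1-D minimization of the
  exponential-decay fit; the ratio `k₃/k₂` from the titration isotherm
  (model normalized so the top design dose reads 100%, matching the
  plateau-defines-saturation convention); then the absolute scale `k₂`
  from the time course with the ratio held fixed. Both 1-D searches
  run on a log scale over [10⁻⁴, 10⁴].
* **Genetic algorithm** for the simulation-identified parameters.
  UNDX: children are normal along the axis of two parents
  (σ_ξ = 0.5·|x₂−x₁|) plus an orthogonal normal component scaled by
  the third parent's distance from that axis (σ_η = 0.35/√n per
  component) — standard literature spreads, since the source procedure
  does not specify them. MGG replacement: each generation a random
  parent pair is removed, 50 children are bred (third parents drawn
  from the rest of the population of 100), and the family's best plus
  one inverse-rank roulette pick re-enter. Offspring are clipped to
  the search box (deterministic and simple); non-finite objective
  values are ranked worst rather than dropped. Termination when the
  population's mean objective comes within a relative 10⁻³ of its
  best (the "mean ≈ best" criterion made quantitative), with a
  generation cap as safeguard.
* **Two stages.** Tonic: (k₁, d₂, deadline) on [0, 0.2]³ against
  dose-0 viability. Stimulated: those three warm-started in a 50–150%
  band around the tonic optimum, plus k₄ on [0, 0.2] and offset on
  [0, 1], against the full 16-point grid. The GA objective is the
  plain sum of squared viability differences (the procedure it
  follows used the unweighted form there; SD-weighting is available
  via a flag). Multi-seed runs are summarized as the per-parameter
  mean with the sample (n−1) SD expressed as percent of the mean.

Identifiability: 4 dose-0 points only softly constrain
(k₁, d₂, deadline) — near-compensating combinations fit equally well —
so recovery is judged predictively (the fitted model's surface vs the
truth surface) rather than per parameter. The offset and the k₄/k₁
ratio are well identified by the 16-point design; dropping the
10 µg/ml rows would leave k₄ nearly unconstrained, since every
remaining dose sits near or below the threshold. The viability
objective is piecewise constant (counts over 200 cells, steps of
0.005), which the rank-based GA handles naturally but gradient methods
would not.

## Problem sizes and numerical choices

Default study design: 200-cell cohort, dt = 0.01 h, 0–72 h, doses
{0, 0.3, 3, 10} × times {0, 18, 48, 72}. GA runs in the tests and
analysis scripts use 400 generations × 50 children (≈ 20 000
evaluations per stage) — enough for the tonic stage to reach an exact
interpolating optimum on noiseless data and for the stimulated stage
to localize the offset to within ~0.01 of truth (surface MAE ≈ 0.005);
the analysis driver defaults to 3 seeds for the consensus, with the
full 10 available by flag. Floating-point excursions outside invariant
ranges are absorbed by the post-step clamps; the convergence test is
written multiplicatively so the worst-rank sentinel (10³⁰⁰) cannot
overflow.

## Known limitations

* No proliferation, differentiation, receptor re-synthesis or
  co-stimulation (CD40/cytokines); the model describes BCR-only
  survival in culture.
* The two-state conserved signal is a deliberate minimal abstraction —
  `deadline` and the signal scale are only defined relative to it.
* Binding treats the antibody bath as unchanging (no depletion,
  internalization of complexes, or bivalent-binding cooperativity).
* The synthetic parent distribution matches three summary statistics
  of the real one, not its shape; conclusions that depend on fine
  distributional structure (e.g., exact t = 0 viability) should not be
  read quantitatively.
* The GA's UNDX/MGG internals beyond the population size, boxes and
  termination idea are this package's own (documented) choices.
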