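# Methods

## Model

`dynml` implements a *multiplexed* reservoir computer. The reservoir is an
ensemble of N independent, non-interacting 3-D chaotic flows — Lorenz units

    dx_i/dt = σ_i (y_i − x_i) / τ_i
    dy_i/dt = (x_i (ρ_i − z_i) − y_i) / τ_i
    dz_i/dt = (x_i y_i − β_i z_i) / τ_i

for time-series prediction, or Rössler units
(ẋ = −y − z, ẏ = x + a y, ż = b + z(x − c), likewise scaled by 1/τ_i) for
static classification. An input vector u ∈ R^M is mapped to the reservoir's
initial condition by a fixed random projection, x0 = R u with
R ∈ R^{3N×M}; the ensemble is integrated for a fixed horizon (30 time
units), and the final state x* ∈ R^{3N} is the feature embedding. A single
global linear readout ŷ = S x*, S ∈ R^{P×3N}, is trained by ordinary least
squares over *all* pooled temporal transitions,

    S = argmin_S ‖Y − S X‖_F²,

where X stacks the embeddings of every training (input-at-t) sample and Y
the corresponding next-step targets. One S serves every transition;
per-(variable, transition) metrics are evaluation slices of this single
fit. A per-transition readout mode exists but is off by default.

Because the units do not interact, integration cost is O(N · T_int) per
sample and dynamical diversity is added channel-by-channel, which is why
the entropy of the ensemble (below) grows roughly with log N rather than
combinatorially.

## Parameters and defaults

| parameter | default | units | why |
|---|---|---|---|
| σ_i, ρ_i, β_i | U[9.9, 10.1], U[27.9, 28.1], U[2.65, 2.70] | — | narrow windows around the canonical chaotic Lorenz point (10, 28, 8/3); heterogeneity decorrelates units without leaving the chaotic regime |
| τ_i | log-uniform [20, 200] | time | see below; the single most consequential default |
| horizon | 30 | time | fixed embedding window |
| integrator | fixed-step RK4, dt = 0.01 | time | bitwise-reproducible, vectorizes over (sample, unit); adaptive RK45 (rtol 1e−6, atol 1e−9) available per config |
| R entries | N(0, (scale/√M)²), scale = 1 | — | keeps ‖x0‖ ≈ O(1) independent of input dimension |
| OLS solver | SVD minimum-norm (`gelsd`), no ridge | — | the objective is plain least squares; rank deficiency is handled by minimum-norm, not regularization |
| split | 80/20 at the trajectory (or cell/sample) level | — | all transitions of one trajectory share one side of the split; no leakage across time within a unit |

### The timescale range τ

The horizon H = 30 is fixed, so τ_i sets how many *intrinsic* time units
H/τ_i a unit realizes. With τ ≈ O(1) a Lorenz unit traverses tens of
Lyapunov times: x* becomes an effectively chaotic hash of x0, the readout
cannot generalize, and benchmark correlations collapse (we measured min
task r < 0 on the Rössler benchmark). With τ log-uniform on [20, 200] each
unit realizes between 0.15 and 1.5 intrinsic time units: the slowest units
stay nearly linear in x0 (preserving the input), the fastest develop
strong nonlinear transients (supplying curvature), and the ensemble spans
that spectrum. This transient, information-preserving regime is what makes
a *chaotic* reservoir usable as a feature map, and it is where all
defaults live.

### Scaling convention

Inputs are standardized by one per-variable scaler fitted on pooled
training rows. Targets are standardized per (variable, transition) on
training rows, and predictions are inverse-transformed to original units
before MSE is computed (Pearson r is affine-invariant and indifferent to
this). The per-transition target scaling matters: transition slices of a
chaotic observable can differ in variance by orders of magnitude (the
Rössler z variable is near-constant between spikes), and pooled scaling
lets the Frobenius objective ignore the thin slices — their test r then
stalls around 0.6 no matter the ensemble. Giving every task slice unit
variance weights all 18/24 tasks equally in the single pooled fit. This is
also the convention implied by feeding the row-per-(variable, timepoint)
benchmark data layout through a standard scaler. Scalers are always fitted
on the training partition only.

## Topological entropy estimator

The Bowen–Dinaburg entropy (growth rate of maximal (n, ε)-separated sets
under the metric d_n) is intractable in 3N dimensions, so the package
implements only its finite-time box-counting surrogate. A saved reservoir
trajectory {x(t_i)}, i = 1..T, is symbolized by s(t_i) = ⌊x(t_i)/ε⌋
componentwise (floor, so negative coordinates bin correctly); N_n(ε)
counts distinct symbols, and

    h_n(ε) = ln N_n(ε) / T        (nats per saved time point).

Hence 0 ≤ h_n(ε) ≤ ln(T)/T, with the ceiling reached when every saved
state has its own box — which is certain at very fine resolutions
(ε = 1e−10) for any non-repeating trajectory. Boxes are taken in raw state
units; a per-dimension normalization toggle exists but is off by default.

**Choice of T.** A box change occurs whenever *any* of the 3N coordinates
crosses an ε-boundary between consecutive saved states, so the estimator
only discriminates while the per-step motion is comparable to ε. With few
saved points the estimate pins to the ceiling for every N of interest. The
default saves every RK4 step over the 30-unit horizon (T = 3001), which
places the discrimination knee inside N ∈ [4, 128] for ε ∈ [0.05, 0.9]:
entropy then rises approximately linearly in ln N before saturating, and
the ranking of ensemble sizes is stable across ε — the behavior the
entropy–performance analysis relies on. Entropy is averaged over input
samples (by default the experiment's own scaled training inputs), and
trajectories reuse the embedding horizon.

## Benchmark protocols

*Rössler*: (a, b, c) = (0.2, 0.2, 5.7), base state (0.1, 0, 0), Gaussian
perturbation sd 1e−3, 2000 trajectories, t_total = 120 with the first 70
units discarded, 7 equidistant samples on [70, 120] (both endpoints
included; spacing 50/6), RK45 at rtol 1e−9 / atol 1e−12. Reference
ensemble N = 30.

*Double pendulum*: m1 = m2 = L1 = L2 = 1, g = 9.81, base state
(π/2, π/2 + 0.1, 0, 0), perturbation sd 5e−3, 2000 trajectories, 10-unit
transient, 7 equidistant samples, same tolerances. Reference ensemble
N = 200. The frictionless equations of motion conserve energy, which the
integration respects to a relative drift ≤ 1e−6 over the full 40-unit
span — trajectories are integrated through `solve_ivp` in chunks of at
most 200 at a time, because a single joint system dilutes the
per-trajectory error norm by √(batch).

**Pendulum sampling window.** The default window is (10, 13), i.e.
samples 0.5 time units apart. This is a deliberate design choice: at this
energy the second arm swings over the top and the largest Lyapunov
exponent is λ ≈ 1.07 per time unit (twin-trajectory measurement), so a
Δt = 0.5 spacing matches the Rössler protocol's dimensionless sampling
difficulty (λ·Δt ≈ 0.55 for both). Spreading the 7 samples over the whole
(10, 40) span instead (available via `sample_window=(10.0, 40.0)`) puts
λ·Δt ≈ 5.4 between consecutive samples; successive sampled states are
then chaotically decorrelated and next-step regression collapses for
*any* model — we verified that per-task tuned RBF kernel ridge, a
strictly stronger model class than one pooled linear readout, also fails
there (r ≈ 0–0.3 for most tasks). Even at Δt = 0.5 the hardest tasks (ω2
at the last transitions, r ≈ 0.68–0.70) sit at the same kernel-ridge
ceiling (0.57–0.74): the perturbation cloud has already decohered during
the 10-unit transient (λ·10 ≈ 10.7), and the folding of that filament
bounds what any smooth regressor can recover. Reported benchmark minima
should be read with that information limit in mind.

Consecutive samples form pooled (t → t+1) pairs; a *task* is one
(variable, transition) slice, giving 18 Rössler and 24 pendulum tasks.
Both systems are chaotic over the sampled window (a 1e−8 perturbation of
θ2 grows to order-1 separation before t = 40), so the per-transition maps
are genuinely nonlinear and increasingly dispersed for later transitions.

## Synthetic biological data

Two generators reproduce the *shapes* and temporal character of the
biological settings the pipeline targets, so the full stack runs without
downloads. They are synthetic stand-ins, not fits to any measured data.

*Embryo-like atlas* (default 500 cells × 27 genes × 6 timepoints + 3-D
coordinates): each cell carries a latent 3-D state initialized smoothly
from its position and evolving under a contracting flow
dl/dt = 0.4 (tanh(W l + c) − l); genes are softplus readouts of the latent
state with smooth spatial gains, plus optional log-scale noise (default sd
0.05). Inputs to the prediction task are the 27 genes *plus* the cell
coordinates (M = 30); targets the 27 genes at the next stage; splits are
at the cell level. Expression is non-negative and temporally smooth
(one-step displacements are smaller than three-step ones).

*Regeneration-like panel* (default 6000 samples × 15 clusters × 13 ordinal
stages): each cluster has a smooth mean time course (3-harmonic cosine
series) and one deviation shape; member genes are mean + gene-specific
scale × shape + small smooth wiggle + light noise, and every sample draws
one gene per cluster. Because deviations are one-dimensional per cluster,
a gene's level at one stage determines its next stage up to noise — the
analogue of co-expression cluster membership being informative. Stage
transitions are selected by ordinal index (no calendar arithmetic) and
split at the sample level.

What passing on these generators shows: the pipeline recovers smooth
nonlinear flows from pooled transitions without leakage, at the
dimensionalities of the target applications. What it does not show:
performance on real atlases, which have measurement noise structure,
missingness, and regulatory dynamics these generators do not model.

## Numerical and design notes

- **Determinism.** A master seed spawns named SeedSequence substreams
  (dataset / split / params / projection), so runs are bitwise
  reproducible and e.g. the split can be varied without moving the sampled
  reservoir parameters.
- **Divergence guard.** Any non-finite state aborts with an error naming
  the sample; NaNs never propagate into the readout. (Lorenz ensembles are
  dissipative and bounded; Rössler units can diverge from far-out initial
  states.)
- **Degenerate inputs.** Constant data columns are scaled with guard sd 1
  (transform to 0, round-trip exactly); constant evaluation slices report
  r as NaN and are excluded from aggregates; classification requires at
  least two training classes, and exact score ties resolve to the lowest
  class index.
- **Problem sizes in the test suite.** The suite exercises the scaled-down
  protocol (500 trajectories, N = 100) on three seeds, the full Rössler
  protocol (2000 trajectories, N = 30), and the entropy–performance sweep
  at 500 trajectories with 7 seeds; the full pendulum protocol (2000
  trajectories, N = 200) lives in `scripts/acceptance.py`. These sizes are
  the package's reference configurations for routine validation.
- **Known limitations.** The estimator's h_n(ε) is a finite-time surrogate,
  not the Bowen–Dinaburg limit: it is ceiling-bounded by ln(T)/T and its
  absolute value depends on T and ε; only comparisons at fixed (T, ε) are
  meaningful. Wall-clock columns are recorded for reporting and never
  asserted on. MNIST-scale classification (N ≈ 1500) is supported by the
  same code path but not exercised by the test suite; `classify_demo`
  accepts any user-supplied feature/label arrays and downloads nothing.
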