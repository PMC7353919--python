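# Methods

## Model and assumptions

The package models one gene's RNA life cycle by three time-varying
rates in amount units (expression/min): transcription α(t), processing
γ(t) and degradation β(t). Mass balance for the pre-mRNA pool P and the
mature pool M = T − P gives dP/dt = α − γ and dM/dt = γ − β, so the
observable series are integrals of the rates. Each rate follows the
six-parameter pulse curve (product of two logistics, shared steepness),
which encodes exactly one transient departure from steady state: level
h0 before the stimulus, excursion through h1, new steady level h2.
Implied assumptions:

- The population is at steady state at the first sample, and settles to
  a new steady state; oscillatory programs are out of scope.
- RNA is not degraded during the short labeling window, so the labeled
  observation is carryover plus the nascent transcription integral:
  TL(t) = c1·T(t) + c2·∫[t−tL, t] α. For the first sample the window is
  clipped at t = 0 — no transcription before the experiment is
  attributed to it — which makes TL(0) pure carryover. Simulation and
  fitting use the same convention, and it is what lets the carryover
  fraction c1 be read off the first sample.
- Initial conditions P(0), T(0) are taken from the observed first
  sample rather than fitted.
- Pre-mRNA is measured by intronic signal of the total libraries, total
  RNA by exonic signal, labeled RNA by exonic signal of the labeled
  libraries. This mapping follows the convention of prior intron/exon
  kinetic methods; genes without introns are flagged un-fittable.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `FitConfig.n_restarts` | 100 | random starts per gene (tests use 5–20; the benchmark uses 20) |
| `FitConfig.steady_tie_mode` | `hard` | share h0 and h2 across α, γ, β (14 free parameters); `soft` penalizes differences with weight 10; `none` fits 18 |
| `FitConfig.normalization` | `none` | optional per-gene min–max or log1p standardization; `none` keeps amount units so fitted rates are comparable across genes |
| `SimConfig.times` | 0–180 min by 15 | sampling design |
| `SimConfig.tL` | 10 min | 4sU pulse before each sample |
| `SimConfig.mu`, `sigma` | 1.0, 0.5 expr/min | normal distribution of true transcription pulse levels (truncated > 0) |
| `SimConfig.kt` | 0.8 | transcription–degradation coupling: rate-constant levels are drawn from N(mu/kt, (sigma/kt)²) with Gaussian-copula correlation kt to the transcription draws |
| `SimConfig.noise_cv` | 0.1 | mean-preserving multiplicative lognormal noise per matrix cell |
| `SimConfig.c1`, `c2` | 0.2, 0.8 | embedded scale factors |

## Scale factors and identifiability

Only two combinations of the three library proportionality constants
are identifiable (c1 = w2/w, c2 = w1 − w2); the package reports only
those. More fundamentally, **the data pin down c1 and the product
c2·α(t), but not c2 alone**: replacing (c2, α, γ, β) by
(c2/k, kα, γ−(1−k)α, β−(1−k)α) changes the forward model only through
the inability of a single pulse to represent the shifted curves
exactly. Under the default study design (15-min sampling, rate
constants around 1/min) that residual rigidity is far too weak for
reliable estimation — profiling the fitted objective over c2 was
evaluated and found biased and seed-unstable, and lag-based estimates
of the processing timescale are unresolvable at this sampling.

The default estimator (`estimate_scale_factors(method="anchored")`) is
therefore deterministic and explicit about its convention:

- **c1** = median over genes of TL(0)/T(0) (the clipped first labeling
  window makes the first labeled sample pure carryover). Accurate to a
  few percent at 200 genes.
- **c2** = median over genes and later samples of (TL − c1·T)/(tL·P),
  divided by a **nominal processing constant of 1/min**. Under
  first-order processing α = γᵏ·P, so the median ratio equals c2 times
  the typical γᵏ; the nominal constant fixes the absolute scale. A
  mis-specified nominal constant rescales all reported rates by a
  common factor (a shift on the log scale) and leaves rate *ratios*,
  correlations and temporal shapes unchanged.

`method="proxy"` instead regresses TL on T and a first-difference
nascent proxy Ŝⱼ = max(0, ΔT·tL/Δt) by multi-start bounded
quasi-Newton. It is exact when total RNA grows without degradation but
near-degenerate when genes sit close to kinetic equilibrium (ΔT ≈ 0),
and is kept for data where the total pool moves strongly.

## Optimization

Per gene, bounded quasi-Newton (L-BFGS-B) minimizes the half
sum-of-squares objective; the transition times are parameterized as
(t1, Δt ≥ 0) so t1 ≤ t2 throughout. Starts are the configured number of
random initializations (levels log-uniform within bounds, transitions
uniform on [0, 2·t_end] then ordered, steepness log-uniform on
[0.005, 5]) plus deterministic data-driven starts of two kinds:

- **Profile starts.** The carryover-corrected labeled profile
  q = (TL − c1·T)/(c2·tL) is a direct transcription profile, and mass
  balance gives processing and degradation profiles q − dP/dt and
  q − dT/dt (spline derivatives); a pulse is pre-fit to each profile
  (cheap one-series least squares, transition candidates at the two
  largest profile changes) and assembled into start vectors at three
  scalings of q (0.75, 1.0, 1.4) to explore the weakly identified scale
  direction.
- **Staged start.** Exploiting the model's triangular structure: the
  transcription curve is fit alone to its labeling-window integrals
  (which the labeled series pins directly), then each inter-sample
  increment of P becomes a target integral for the processing curve and
  of T for the degradation curve. For model-consistent noiseless data
  this lands essentially on the global optimum; the narrow basins it
  reaches (e.g. transitions at the window edges) are rarely found by
  random multistart.

All starts get a short screening run (≤ 80 iterations); the best five
are polished to convergence. In soft-tie mode the converged hard-tie
solution is added as a start, because a large penalty weight makes the
18-parameter landscape too stiff to traverse from generic starts. The
final objective value is recomputed with the panel-split quadrature of
the public forward model.

Box bounds: rate levels in [10⁻⁴·H, H] with H = 10× the gene's largest
finite-difference rate estimate (prevents runaway plateaus);
transitions within [0, 2·t_end]; steepness capped at 8/Δt_min — a
logistic transition completing within half a sampling interval is
indistinguishable from a step, and permitting steeper slopes lets the
optimizer hide unconstrained jumps between samples (degenerate corner
fits). The correction pass refits genes with objective values above the
90th percentile (or failed) with doubled restarts and widened bounds,
keeping the refit only if it lowers J.

## Numerical choices

- **Quadrature.** Public pulse integrals use 64-node Gauss–Legendre
  with deterministic panel splits at each transition centre and at
  ±6/slope around it, giving ≤ 1e-8 relative error against adaptive
  quadrature over the full admissible slope range. Inside the fitting
  kernel the nodes are fixed per inter-sample segment (24 nodes) and
  per labeling window (12 nodes) so the quadrature is a smooth function
  of the transition times; the two agree to ~1e-6 and the reported J
  always comes from the public quadrature.
- **ODE integration.** The simulator uses classic RK4 with a 0.25-min
  step, comfortably inside the stability region of the fastest drawn
  rate constants (h·λ < 1.2); order-4 convergence and the
  constant-coefficient closed form are verified by tests.
- **Noise.** Observation noise is lognormal with mean exactly 1 and the
  configured coefficient of variation, independent per cell.
- **Logs and floors.** Recovery metrics use log10 with a 1e-6 pseudo
  floor. Rate-constant conversion guards divisions with a 1e-9
  expression-unit floor and returns NaN with a flag for empty pools.
- **Degenerate inputs.** All-zero genes and genes without introns are
  skipped with status `degenerate`; constant series under min–max
  standardization map to zeros with a warning; exactly proportional TL
  and T trigger the identifiability warning and the degenerate scale
  factors (ratio, 0).
- **Determinism.** Per-gene seeds derive from the configured seed and a
  CRC of the gene name, so results are invariant to gene order and
  thread count; simulation is fully reproducible from its config.

## What the generator emulates — and what it does not

The generator reproduces the structure of a pulsed-stimulation 4sU
study: 13 samples at 15-min spacing, a 10-min labeling pulse, ~1,000
genes (scaled down in tests), equilibrium initial conditions, coupled
transcription/degradation levels, embedded global scale factors and
multiplicative noise. It does **not** emulate: count noise
(negative-binomial sampling at low expression), replicate structure,
mappability and positional biases in read assignment, genes drifting
between multiple states, or oscillatory programs. Recovery results on
synthetic data therefore demonstrate correctness of the estimation
machinery under the model's own assumptions, not performance on any
real library preparation.

The true processing/degradation amount rates in the simulation are
rate-constant pulses multiplied by the simulated pools, which a single
pulse curve can only approximate; the benchmark therefore also measures
robustness to this mild model mismatch. Degradation is consistently the
hardest class — the total pool moves slowly relative to its turnover —
matching the ordering of the recovery correlations.

## Known limitations

- Absolute rate scale requires an external convention (see scale
  factors above); cross-dataset comparisons of absolute rates should
  fix the nominal processing constant or use spike-in calibration.
- Three or more pulse-shaped episodes per gene (repeated stimulation)
  are outside the single-pulse family.
- The chi-square goodness of fit uses a pooled residual-variance
  estimate across genes per series (or a second-difference noise
  estimate for single genes); with unmodeled heteroscedasticity the
  p-values are approximate and best used for ranking.
- With fewer than six time points the hard-tie model has no residual
  degrees of freedom for the chi-square test, and fits need at least
  five points.
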