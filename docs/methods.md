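# Methods

## Model

`tdlbm` co-clusters three-way time-dependent data: `n` subjects (rows) by
`d` variables (columns), each cell `(i, j)` holding a curve `x_ij(t)`
observed at time points that may be subject-specific and sparse (missing
entries are allowed and simply dropped from all likelihood sums).

The model is a latent block model: row labels `z_i ∈ {1..K}` and column
labels `w_j ∈ {1..L}` are independent multinomials with proportions `π` and
`ρ`, and cells are independent given the labels, with a density that
depends only on the block `(k, l)`. The block density is a shape-invariant
model: conditional on cell-specific Gaussian random effects
`α = (α₁, α₂, α₃) ~ N₃(μ_kl, Σ_kl)`,

    x_ij(t) = α₁ + exp(α₂) · m(t − α₃; β_kl) + ε_ij(t),
    ε_ij(t) ~ N(0, σ²_ε,kl),

where `m(·; β_kl) = B(·) β_kl` is a B-spline mean shape. The three effects
are an amplitude (vertical) shift, a log-scale factor (parameterised
through `exp` so the scale is positive), and a time (phase) shift. Any
effect can be switched off — constrained to a point mass at zero — which
changes the notion of cluster: with the time shift off, two otherwise
identical but phase-shifted evolutions belong to different clusters.
Configurations are named by three letters (T = on, F = off) in the order
(amplitude, scale, time shift): `TFT`, `FFF`, ...

The complete-data log-likelihood is

    ℓ_c(Θ, z, w) = Σ_ik z_ik log π_k + Σ_jl w_jl log ρ_l
                 + Σ_ijkl z_ik w_jl log p(x_ij; θ_kl),

with `p(x_ij; θ_kl)` the marginal cell density after integrating the
random effects out.

## Estimation: marginalized SEM-Gibbs

Each iteration alternates three steps.

**Marginalization step.** The marginal cell densities are intractable for
nonlinear configurations. The reference scheme (`marginal_logdensity_mc`)
is plain Monte Carlo over prior draws of all switched-on effects — a random
Gaussian quadrature. The engine's production scheme
(`engine.marginalization_step`) refines this: the amplitude effect enters
the conditional mean *linearly*, so conditional on the nonlinear effects
the cell is Gaussian with compound-symmetric covariance
`σ²_ε I + σ²_α1 11ᵀ`, and the amplitude is integrated exactly; Monte Carlo
(`M` shared draws per block, default 30) is used only for the scale and
time-shift effects. This matters: with a 15-point curve and `σ_ε = 0.3`,
the conditional likelihood is so sharp in the amplitude that prior-draw MC
at practical `M` understates every tight block's density by tens of log
units per cell, enough to invert the ranking between a correct and a merged
partition. Configurations without nonlinear effects (`FFF`, `TFF`) are
evaluated exactly. Draws are shared across the cells of a block
(`MSEMControl.shared_draws=False` switches to fresh per-cell draws through
the reference scheme).

**SE step.** Gibbs sampling of `z | w` then `w | z` from their multinomial
conditionals, `gibbs_inner` times (default 5), computed in log space with
max-subtraction; an all-degenerate conditional falls back to uniform with
a warning.

**M step.** `π, ρ` are label frequencies (zero-frequency clusters floored
at `1/(10n)` and renormalized). Each block's `θ_kl` is fit by an
approximate-maximum-likelihood alternation in the Lindstrom–Bates style:
a penalised nonlinear least-squares step over `β` and the per-cell
posterior modes of `α` (vectorised penalised Gauss–Newton across cells,
with a small grid of candidate time-shift initialisations to escape
registration local optima), then an EM update of `(Σ, σ²_ε)` on the model
linearised at the posterior modes. Numerical safeguards, each adopted
after observed failures on simulated data:

* The outer alternation is not an ascent algorithm, so the fitter tracks
  the incumbent (best linearized marginal log-likelihood) and stops after
  3 iterations without improvement; the reported objective trace is the
  incumbent's and is monotone by construction.
* An EM variance update that scores worse than the pre-update components
  is rejected (pseudo-data blowups under poor linearization).
* Basis coefficients of tail basis functions that no shifted observation
  supports are pinned to 0; otherwise they are free directions that blow
  up the fitted shape outside the observed window.
* Variance floors: `1e-8` on `σ_ε` (SD scale) and on the diagonal of `Σ`.
* Means of switched-on effects are fixed at 0: an amplitude mean is
  confounded with the intercept freedom of `β`, a time-shift mean with its
  horizontal placement, a scale mean with its norm. `Σ` is diagonal by
  default.

Within the SEM loop the M step is *partial* (one outer iteration,
warm-started from the previous iteration's `θ_kl` and stored per-cell
posterior modes), in the generalized-EM spirit; the first M step after
initialisation runs up to 8 outer iterations from scratch. Empty and
under-identified blocks carry their previous `θ_kl` forward unchanged.

**Convergence, averaging, final partition.** The run stops when the sum of
absolute changes of `ℓ_c` over the last three iterations falls below
`delta` (default 1e-3; checked only after burn-in — Monte Carlo jitter in
`ℓ_c` means long runs typically use the full iteration budget), or after
`n_iterations` (default 100; burn-in 30). Because labels can switch across
SEM samples, post-burn-in parameter samples are aligned to the first
post-burn-in partition (optimal assignment on the label confusion
matrices) before averaging; variances are averaged on the variance scale.
The final partition is the elementwise mode of `n_final_samples` (default
20) SE samples drawn at the averaged `θ̂`, ties broken toward the lower
label; `ℓ_c(Θ̂, ẑ, ŵ)` is then re-evaluated with a dedicated larger number
of MC draws (`M_score`, default 200) to reduce score jitter.

**Initialisation and restarts.** The first start initialises labels by two
independent k-means runs (rows on their `d·T` profiles, columns on their
`n·T` profiles; missing values mean-imputed for this step only); additional
starts (`n_starts`) use *perturbed* k-means partitions (a random quarter
of the rows and columns reassigned uniformly). Plain k-means lands on
essentially the same partition for every seed, and fully random labels
destroy all structure and tend to re-find the same local optima, so
perturbations of a decent partition are the effective diversity
mechanism. Every start runs the full iteration budget and the one with
the best smoothed final `ℓ_c` is retained. Early elimination of chains by mid-run `ℓ_c` was tried and
rejected: a single chain can be absorbed by a merge-and-split local
optimum (two row clusters merged, another split in two) in roughly a third
of baseline-scenario replicates, and those doomed chains *converge
faster* than eventually-good chains — which spend many early iterations
sorting labels — so mid-run comparisons systematically keep the wrong
chain. `n_starts = 3` is the protocol for the fixed-(K, L) accuracy
studies, `n_starts = 2` for the model-selection grids.

## B-spline basis

Cubic by default, with interior knots equispaced on a *padded* domain
`[t_lo − pad, t_hi + pad]` so that `m(t − α₃)` stays defined for plausible
shifts; beyond the pad the shape is clamped to its boundary value (with
the time-shift sensitivity set to zero there). The default pad is 1.0 when
the time-shift effect is on (covering |α₃| up to 3 prior SDs for
`σ²_α3 ≤ 0.11`) and 0 otherwise. The default of 16 interior knots keeps
the spline approximation error well below the residual noise for shapes
with curvature at the scale of the benchmark library. This matters beyond
parameter recovery: residual approximation misfit is exploitable by an
extra row cluster, enough at coarser defaults to make ICL prefer K+1
clusters on data generated with K; at 16 knots the true K fits strictly
better. Knot count, degree and pad are parameters of `TimeDependentLBM` /
`BasisSpec`.

## Model selection

`ν = (#basis coefficients) + (#switched-on effects, diagonal Σ; q(q+1)/2
if full) + 1` per block (random-effect means are counted only when the
estimate-μ option is on, which it is not by default). Models are ranked by

    ICL = ℓ_c(Θ̂, ẑ, ŵ) − (K−1)/2 log n − (L−1)/2 log d − (K L ν)/2 log(nd).

The first term is the MC-approximated value at `M_score` draws, so the
score inherits some marginalization-scheme dependence. ICL's validity with
random effects is an open question in this model class (the effective
sample size entering the penalty is unclear), and it is known to lean
toward over-parameterised models; grid results should be read as modal
selections across replicates, not certainties per dataset. Ties break
toward smaller `K·L·ν`.

## Synthetic benchmark

The generator reproduces the reference simulation design: `K_true = 4` row
clusters, `L_true = 3` column clusters (balanced, randomly permuted),
`T = 15` equispaced points on [0, 1], noise SD `σ_ε = 0.3`, zero-mean
random effects with `Σ = diag(1, 0, 0.1)` and the `TFT` configuration
(amplitude and time shift on, scale off); baseline size `n = 100`,
`d = 20`, with `(n, d) = (100, 50)` and `(500, 20)` variants. The
block-to-shape assignment uses four shape functions in the published
layout (with its one inconsistency resolved so that every block gets
exactly one shape and all rows/columns remain distinguishable).

The exact published mean-shape formulas are not available, so the library
ships four of its own, fixed in `synthetic.py`:

    m1(t) = 3 sin(2πt)          m2(t) = 1.5 − 6 (t − 0.5)²
    m3(t) = 6t − 3              m4(t) = 4 exp(−(t − 0.5)²/0.045)

They are pairwise L2-separated by ≥ 1 on [0, 1] and chosen so no pair
coincides under the amplitude/time-shift transformations that the TFT
configuration treats as within-cluster variation (e.g. sine and cosine
would alias under a quarter-period shift). Two caveats of this library are
themselves informative about the model: `m1` is one full period of a
sinusoid, so cell time shifts are only identified modulo the period and
the fitted time-shift variance in `m1` blocks estimates the *wrapped*
shift variance; `m3` is affine, so a time shift of it is indistinguishable
from an amplitude shift and its blocks push time-shift variance into the
amplitude component. Clustering accuracy is unaffected (the block marginal
remains well-defined), but single-block parameter-recovery checks use the
non-degenerate `m2`.

What passing the benchmark does and does not show: the generator draws
from exactly the fitted model family on a common complete grid, so it
validates the estimation machinery (label recovery, parameter recovery,
selection behaviour) under correct specification. It does not emulate
model misspecification, irregular/sparse sampling (supported by the
machinery but not exercised by the default scenarios), heteroskedastic
blocks, or outliers. Because the shapes differ from the unavailable
published ones, benchmark numbers are expected to be *consistent with*
(not equal to) the published ones: CARI near but not identically at the
published means; the true configuration and the true `(K, L)` modal under
ICL.

CARI (co-clustering adjusted Rand index) applies the adjusted-Rand formula
to the cell-level block contingency table, which factorises exactly as the
Kronecker product of the row-label and column-label contingency tables;
value 1 means block agreement up to relabelling, ~0 chance level. The
double-k-means baseline crosses independent row and column k-means
partitions of the raw profiles.

## Study sizes used by the shipped tests and acceptance script

Chosen as desk-scale versions of the reference study: fixed-(K, L)
accuracy at the baseline scenario uses B = 10 replicates (60 SEM
iterations, burn-in 20, M = 30, 3 starts); the larger scenarios at
reduced B (2 starts); configuration selection B = 5 and the (K, L) grid
{3,4,5} × {2,3,4} B = 3, both at 25 iterations (burn-in 10, 2 starts);
double k-means B = 100. The acceptance script uses the same
protocol with its replicate counts printed in its output.

## Known limitations

* The SEM chain has no split–merge move; a merged local optimum is escaped
  only via restarts. Chains on data with near-aliasing shape pairs can
  need several.
* The Lindstrom–Bates alternation with partial M steps trades per-step
  optimality for speed; variance components in blocks with weakly
  identified shifts (periodic or affine shapes) inherit the
  identifiability caveats above.
* ICL is used as published despite its unclear footing under random
  effects; no corrected criterion is implemented. On the shipped benchmark
  its over-parameterisation lean is visible concretely: because the
  sinusoidal shape identifies time shifts only modulo its period, cells
  with wrapped shifts are systematically mis-fit under the generative
  partition, and an extra (small) row cluster that absorbs them buys more
  log-likelihood than the ICL penalty charges. Grid searches on this
  benchmark therefore often select one row cluster too many, with the
  extra cluster small and the block structure otherwise intact (CARI
  against the truth stays near 1).
* The scale effect (`α₂`) is the most fragile in estimation, consistent
  with general experience with multiplicative random effects; the
  benchmark's generative setting keeps it off.
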