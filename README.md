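# tdlbm — co-clustering of time-dependent data

`tdlbm` simultaneously clusters the rows (subjects) and columns
(variables) of three-way time-dependent data — `n` subjects × `d`
variables, each cell a curve observed over time — into homogeneous blocks.
It is aimed at functional and longitudinal studies alike (biomarker
panels, epidemic indicators, environmental monitoring): time grids may be
subject-specific and sparse, with gaps handled as missing values.

## Model

The package embeds a *shape invariant model* inside a *latent block
model*. Row labels `z` and column labels `w` are latent multinomials with
proportions `π, ρ`; given its block `(k, l)`, the cell curve is a randomly
transformed copy of a block mean shape:

    x_ij(t) | z_ik = w_jl = 1  =  α₁ + e^{α₂} m(t − α₃; β_kl) + ε_ij(t)

with `m(·; β_kl)` a B-spline curve, cell-specific random effects
`(α₁, α₂, α₃) ~ N₃(μ_kl, Σ_kl)` (amplitude shift, log-scale, time shift)
and Gaussian noise `ε`. Each effect can be switched off (a point mass at
zero), written as a three-letter code: `TFT` means amplitude and time
shift on, scale off. Switching an effect off changes what counts as "one
cluster" — e.g. with the time shift off, identical but phase-shifted
evolutions separate.

Estimation is a *marginalized SEM-Gibbs* algorithm: a Monte Carlo
marginalization of the random effects, Gibbs sampling of the labels, and
per-block nonlinear mixed-effects fits (Lindstrom–Bates style). Model
choice — the number of clusters `(K, L)` and the random-effect
configuration — is by the ICL criterion

    ICL = ℓ_c(Θ̂, ẑ, ŵ) − (K−1)/2 log n − (L−1)/2 log d − (KLν)/2 log nd.

See `docs/methods.md` for the estimation details and numerical choices.

## Worked example

Simulate the baseline benchmark scenario (100 subjects × 20 variables ×
15 time points, 4 × 3 blocks, `TFT` effects) and recover its structure:

```python
import numpy as np
from tdlbm import TimeDependentLBM, BlockPartition, cari
from tdlbm.synthetic import scenario_table1, simulate_dataset

sim = simulate_dataset(scenario_table1(), np.random.default_rng(7))

est = TimeDependentLBM(n_row_clusters=4, n_col_clusters=3,
                       random_effects="TFT", n_iterations=60,
                       burn_in=20, n_starts=3, random_state=0)
est.fit(sim.data)

pred = BlockPartition(est.row_labels_, est.column_labels_, 4, 3)
print(f"CARI vs truth: {cari(pred, sim.truth):.3f}")
print(f"ICL: {est.icl_:.1f}")
print("block noise SDs:",
      np.round([[est.theta_.theta[k][l].sigma_eps for l in range(3)]
                for k in range(4)], 2))
```

Output from this exact run:

```
CARI vs truth: 1.000
ICL: -19465.1
block noise SDs: [[0.3  0.3  0.3 ]
 [0.33 0.3  0.3 ]
 [0.29 0.36 0.3 ]
 [0.3  0.3  0.29]]
```

A CARI (co-clustering adjusted Rand index) of 1 means the fitted block
partition matches the generative one up to relabelling; the recovered
per-block noise SDs sit at the generative σ_ε = 0.3.

The same workflow is available from the shell:

```bash
tdlbm simulate --scenario s1.yaml --seed 7 --out data/
tdlbm fit --data data/data.csv --k 4 --l 3 --config TFT --out fit/
tdlbm select --data data/data.csv --k-range 2:5 --l-range 2:4 --out sel/
tdlbm evaluate --truth data/truth.csv --pred fit/labels.csv
```

Curve data travel as long-format CSV (`row_id,col_id,time,value`; missing
observations simply omitted), labels as `unit_id,axis,cluster` sidecars.

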