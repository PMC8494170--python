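"""scikit-learn style estimators for time-dependent co-clustering."""

from __future__ import annotations

import numbers

import numpy as np
from sklearn.base import BaseEstimator

from .basis import BasisSpec
from .data import BlockPartition, as_curve_matrix
from .effects import RandomEffectConfig
from .engine import MSEMControl, run_msem
from .selection import count_block_params, icl_score


def _as_seed(random_state) -> int | None:
    if random_state is None or isinstance(random_state, numbers.Integral):
        return None if random_state is None else int(random_state)
    if isinstance(random_state, np.random.Generator):
        return int(random_state.integers(2 ** 31 - 1))
    raise ValueError("random_state must be None, an int, or a Generator")


class TimeDependentLBM(BaseEstimator):
    """Co-clustering of curve matrices by a shape-invariant latent block model.

    Rows (subjects) and columns (variables) of an ``(n, d, T)`` curve array
    are partitioned simultaneously; each block carries a B-spline mean shape
    and Gaussian random effects (amplitude shift, log-scale, time shift) that
    individual cells realise independently.  Estimation is by a marginalized
    SEM-Gibbs algorithm; see the ``engine`` module.

    Parameters
    ----------
    n_row_clusters, n_col_clusters : int
        Number of row (K) and column (L) clusters.
    random_effects : str
        Three-letter on/off code for (amplitude, scale, time shift), e.g.
        "TFT".  Switching an effect off makes curves differing in that
        respect land in different clusters.
    degree, n_interior_knots : int
        B-spline mean-shape flexibility.
    pad : float or "auto"
        Domain enlargement absorbing time shifts; "auto" uses 1.0 when the
        time-shift effect is on, else 0.
    n_iterations, burn_in, gibbs_inner, n_mc, n_mc_score, delta,
    init_method, n_starts, max_nlme_iter, n_final_samples, shared_mc_draws :
        M-SEM controls, passed through to :class:`~tdlbm.engine.MSEMControl`.
    random_state : int, Generator or None
        Seed for all stochastic steps; fits are reproducible given the seed.

    Attributes
    ----------
    row_labels_, column_labels_ : int arrays
        Modal row / column cluster labels (0-based).
    theta_ : LBMTheta
        Post-burn-in averaged parameter estimate.
    llc_trace_ : ndarray
        Complete-data log-likelihood per iteration.
    icl_ : float
        ICL of the fitted model.
    converged_, n_iter_ : convergence diagnostics.
    result_ : FitResult with the full sampling history.
    """

    def __init__(self, n_row_clusters=2, n_col_clusters=2,
                 random_effects="TTT", degree=3, n_interior_knots=16,
                 pad="auto", n_iterations=100, burn_in=30, gibbs_inner=5,
                 n_mc=30, n_mc_score=200, delta=1e-3, init_method="kmeans",
                 n_starts=1, max_nlme_iter=1, n_final_samples=20,
                 shared_mc_draws=True, random_state=None):
        self.n_row_clusters = n_row_clusters
        self.n_col_clusters = n_col_clusters
        self.random_effects = random_effects
        self.degree = degree
        self.n_interior_knots = n_interior_knots
        self.pad = pad
        self.n_iterations = n_iterations
        self.burn_in = burn_in
        self.gibbs_inner = gibbs_inner
        self.n_mc = n_mc
        self.n_mc_score = n_mc_score
        self.delta = delta
        self.init_method = init_method
        self.n_starts = n_starts
        self.max_nlme_iter = max_nlme_iter
        self.n_final_samples = n_final_samples
        self.shared_mc_draws = shared_mc_draws
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _basis_spec(self, data) -> BasisSpec:
        config = RandomEffectConfig.from_name(self.random_effects)
        if self.pad == "auto":
            pad = 1.0 if config.on_timeshift else 0.0
        else:
            pad = float(self.pad)
        lo, hi = data.time_range
        return BasisSpec.equispaced(n_interior=self.n_interior_knots,
                                    degree=self.degree, domain=(lo, hi),
                                    pad=pad)

    def _control(self) -> MSEMControl:
        return MSEMControl(
            n_iterations=self.n_iterations, burn_in=self.burn_in,
            gibbs_inner=self.gibbs_inner, M=self.n_mc,
            M_score=self.n_mc_score, delta=self.delta,
            seed=_as_seed(self.random_state), init_method=self.init_method,
            n_starts=self.n_starts, max_nlme_iter=self.max_nlme_iter,
            n_final_samples=self.n_final_samples,
            shared_draws=self.shared_mc_draws)

    def fit(self, X, y=None, times=None):
        """Fit the co-clustering to a CurveMatrix or (n, d, T) array."""
        data = as_curve_matrix(X, times)
        config = RandomEffectConfig.from_name(self.random_effects)
        spec = self._basis_spec(data)
        result = run_msem(data, self.n_row_clusters, self.n_col_clusters,
                          config, spec, self._control())
        self.basis_spec_ = spec
        self.config_ = config
        self.result_ = result
        self.theta_ = result.theta_hat
        self.row_labels_ = result.partition.z
        self.column_labels_ = result.partition.w
        self.llc_trace_ = result.llc_trace
        self.converged_ = result.converged
        self.n_iter_ = result.n_iterations_run
        nu = count_block_params(config, spec)
        self.nu_ = nu
        self.icl_ = icl_score(result, nu, data.n, data.d)
        return self

    def score(self, X=None, y=None) -> float:
        """ICL of the fitted model (higher is better)."""
        return self.icl_

    def block_partition_(self) -> BlockPartition:
        return self.result_.partition


class DoubleKMeans(BaseEstimator):
    """Baseline: independent k-means on rows and columns, crossed into blocks.

    Rows are clustered on their concatenated (d * T) profiles and columns on
    their concatenated (n * T) profiles; missing values are mean-imputed
    for the clustering only.
    """

    def __init__(self, n_row_clusters=2, n_col_clusters=2, random_state=None):
        self.n_row_clusters = n_row_clusters
        self.n_col_clusters = n_col_clusters
        self.random_state = random_state

    def fit(self, X, y=None, times=None):
        from .engine import init_partitions
        data = as_curve_matrix(X, times)
        part = init_partitions(data, self.n_row_clusters, self.n_col_clusters,
                               method="kmeans",
                               seed=_as_seed(self.random_state))
        self.row_labels_ = part.z
        self.column_labels_ = part.w
        return self

    def block_partition_(self) -> BlockPartition:
        return BlockPartition(self.row_labels_, self.column_labels_,
                              self.n_row_clusters, self.n_col_clusters)
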