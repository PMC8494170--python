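"""Marginalized SEM-Gibbs estimation of the time-dependent latent block model.

The latent block model places every cell (i, j) of an n x d curve matrix in
a block (k, l) given row labels z and column labels w.  Each iteration of
the marginalized SEM-Gibbs (M-SEM) loop alternates:

* **Marginalization step** — Monte Carlo integration of the random effects
  out of every cell density, giving the (n, d, K, L) table of block
  log-marginals;
* **SE step** — Gibbs sampling of z given w and w given z from their
  multinomial conditionals;
* **M step** — closed-form mixture-proportion updates and per-block
  nonlinear mixed-effects fits (warm-started from the previous iteration).

Convergence is declared when the sum of changes of the complete-data
log-likelihood over the last three iterations falls below ``delta`` (only
checked after burn-in).  The parameter estimate is the label-aligned mean of
the post-burn-in samples; the final partition is the elementwise mode of SE
samples drawn at that estimate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp

from .basis import BasisSpec, clamp_times, eval_mean_shape
from .data import BlockPartition, CurveMatrix
from .effects import RandomEffectConfig
from .nlme import fit_block_arrays
from .sim_model import LOG_2PI, BlockTheta, draw_random_effects, \
    marginal_logdensity_mc, zero_block_theta

logger = logging.getLogger(__name__)


@dataclass
class LBMTheta:
    """Full model state: mixing proportions and the K x L grid of BlockTheta."""

    pi: np.ndarray
    rho: np.ndarray
    theta: list  # K x L nested list of BlockTheta

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if np.any(self.pi <= 0) or np.any(self.rho <= 0):
            raise ValueError("mixing proportions must be strictly positive")
        if abs(self.pi.sum() - 1) > 1e-9 or abs(self.rho.sum() - 1) > 1e-9:
            raise ValueError("mixing proportions must sum to 1")

    @property
    def K(self) -> int:
        return self.pi.size

    @property
    def L(self) -> int:
        return self.rho.size

    def copy(self) -> "LBMTheta":
        return LBMTheta(self.pi.copy(), self.rho.copy(),
                        [[t.copy() for t in row] for row in self.theta])


@dataclass
class MSEMControl:
    """Tuning knobs of the M-SEM loop."""

    n_iterations: int = 100
    burn_in: int = 30
    gibbs_inner: int = 5
    M: int = 30              # MC draws per marginalization step
    M_score: int = 200       # MC draws for the final scored log-likelihood
    delta: float = 1e-3
    seed: int | None = None
    init_method: str = "kmeans"
    n_starts: int = 1
    max_nlme_iter: int = 1
    nlme_tol: float = 1e-6
    n_final_samples: int = 20
    shared_draws: bool = True

    def __post_init__(self):
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.gibbs_inner < 1:
            raise ValueError("gibbs_inner must be >= 1")
        if self.delta <= 0:
            raise ValueError("delta must be positive")


@dataclass
class FitResult:
    """Outcome of one M-SEM run."""

    theta_hat: LBMTheta
    partition: BlockPartition
    llc_trace: np.ndarray
    partition_samples: list
    converged: bool
    n_iterations_run: int
    llc_hat: float
    K: int
    L: int
    n: int
    d: int
    seed: int | None = None
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _impute_for_kmeans(flat: np.ndarray) -> np.ndarray:
    """Mean-impute NaN columns of a flattened profile matrix (init only)."""
    out = flat.copy()
    col_mean = np.nanmean(np.where(np.isnan(out), np.nan, out), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    idx = np.where(np.isnan(out))
    out[idx] = col_mean[idx[1]]
    return out


def init_partitions(data: CurveMatrix, K: int, L: int, method: str = "kmeans",
                    seed=None) -> BlockPartition:
    """Initial row/column labels.

    Methods: "kmeans" (double k-means on row/column profiles), "random"
    (uniform labels), "perturbed" (k-means with a random quarter of the
    rows and columns reassigned uniformly — used for restart diversity:
    uniform-random starts destroy all structure and mostly re-find the
    same local optima, while perturbations explore the neighbourhood of a
    decent partition).
    """
    if not (1 <= K <= data.n and 1 <= L <= data.d):
        raise ValueError("need 1 <= K <= n and 1 <= L <= d")
    rng = np.random.default_rng(seed)
    if K == 1 and L == 1:
        return BlockPartition(np.zeros(data.n, int), np.zeros(data.d, int), 1, 1)
    if method == "random":
        z = rng.integers(0, K, size=data.n)
        w = rng.integers(0, L, size=data.d)
        return BlockPartition(z, w, K, L)
    if method == "perturbed":
        base = init_partitions(data, K, L, "kmeans",
                               seed=rng.integers(2 ** 31 - 1))
        z, w = base.z.copy(), base.w.copy()
        ridx = rng.random(data.n) < 0.25
        cidx = rng.random(data.d) < 0.25
        z[ridx] = rng.integers(0, K, size=int(ridx.sum()))
        w[cidx] = rng.integers(0, L, size=int(cidx.sum()))
        return BlockPartition(z, w, K, L)
    if method != "kmeans":
        raise ValueError(f"unknown init method {method!r}")
    from sklearn.cluster import KMeans
    rows = _impute_for_kmeans(data.values.reshape(data.n, -1))
    cols = _impute_for_kmeans(
        data.values.transpose(1, 0, 2).reshape(data.d, -1))
    ks = int(rng.integers(0, 2 ** 31 - 1))
    z = KMeans(n_clusters=K, n_init=10, random_state=ks).fit_predict(rows) \
        if K > 1 else np.zeros(data.n, int)
    w = KMeans(n_clusters=L, n_init=10, random_state=ks + 1).fit_predict(cols) \
        if L > 1 else np.zeros(data.d, int)
    return BlockPartition(z, w, K, L)


# ---------------------------------------------------------------------------
# marginalization step
# ---------------------------------------------------------------------------

def _block_marginal_table(data: CurveMatrix, theta_kl: BlockTheta, M: int,
                          rng, spec: BasisSpec) -> np.ndarray:
    """(n, d) log p(x_ij; theta_kl), amplitude integrated analytically.

    The amplitude random effect enters the conditional mean linearly, so
    conditional on the nonlinear effects (scale, time shift) the cell is a
    Gaussian with compound-symmetric covariance ``sigma_eps^2 I +
    sigma_a1^2 11'`` and its density is closed-form.  Monte Carlo is only
    needed over the nonlinear effects (M shared draws per block); prior
    draws for the amplitude would otherwise dominate the approximation
    error, because the conditional likelihood is extremely sharp in it.
    Configurations without nonlinear effects are therefore exact.
    """
    config = theta_kl.config
    nonlinear = config.on_scale or config.on_timeshift
    if nonlinear:
        draws = draw_random_effects(theta_kl, M, rng)
        draws[:, 0] = 0.0
    else:
        draws = np.zeros((1, 3))
    Md = draws.shape[0]
    x = data.values
    obs = ~np.isnan(x)
    xz = np.where(obs, x, 0.0)
    # mean shapes per draw per row grid: (Md, n, T)
    shifted = data.times[None, :, :] - draws[:, 2][:, None, None]
    ts = clamp_times(shifted, spec)
    m = eval_mean_shape(ts.ravel(), theta_kl.beta, spec).reshape(ts.shape)
    s = np.exp(draws[:, 1])                    # (Md,)
    n_ij = obs.sum(axis=2).astype(float)       # (n, d)
    if not data.has_missing:
        Sx = x.sum(axis=2)                     # (n, d)
        Sx2 = (x * x).sum(axis=2)
        Sm = m.sum(axis=2)[:, :, None]         # (Md, n, 1)
        Sm2 = (m * m).sum(axis=2)[:, :, None]
        Sxm = np.einsum("ijt,mit->mij", x, m)  # (Md, n, d)
    else:
        maskf = obs.astype(float)
        Sx = xz.sum(axis=2)
        Sx2 = (xz * xz).sum(axis=2)
        Sm = np.einsum("ijt,mit->mij", maskf, m)
        Sm2 = np.einsum("ijt,mit->mij", maskf, m * m)
        Sxm = np.einsum("ijt,mit->mij", xz, m)
    se = s[:, None, None]
    # residual moments of r = x - s * m per (draw, i, j)
    Sr = Sx[None] - se * Sm
    Sr2 = Sx2[None] - 2 * se * Sxm + se ** 2 * Sm2
    s2 = theta_kl.sigma_eps ** 2
    sig1 = theta_kl.sigma_alpha[0, 0] if config.on_amplitude else 0.0
    denom = s2 + n_ij * sig1                   # (n, d)
    shrink = sig1 / denom
    quad = (Sr2 - shrink[None] * Sr ** 2) / s2
    logdet = (np.where(n_ij > 0, (n_ij - 1) * np.log(s2) + np.log(denom), 0.0))
    logdens = -0.5 * (n_ij[None] * LOG_2PI + logdet[None] + quad)
    out = logsumexp(logdens, axis=0) - np.log(Md)
    return np.where(n_ij > 0, out, 0.0)


def marginalization_step(data: CurveMatrix, theta: LBMTheta, M: int, rng,
                         spec: BasisSpec, shared_draws: bool = True
                         ) -> np.ndarray:
    """(n, d, K, L) table of MC-marginalized block log-densities."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    K, L = theta.K, theta.L
    table = np.empty((data.n, data.d, K, L))
    for k in range(K):
        for l in range(L):
            if shared_draws:
                table[:, :, k, l] = _block_marginal_table(
                    data, theta.theta[k][l], M, rng, spec)
            else:
                for i in range(data.n):
                    for j in range(data.d):
                        table[i, j, k, l] = marginal_logdensity_mc(
                            data.cell(i, j), theta.theta[k][l], M, rng, spec)
    if not np.all(np.isfinite(table)):
        raise FloatingPointError("non-finite entries in the marginal table")
    return table


# ---------------------------------------------------------------------------
# SE step
# ---------------------------------------------------------------------------

def _sample_categorical(logits: np.ndarray, rng) -> tuple:
    """Sample one label per row of a log-probability matrix.

    Returns (labels, probs); rows that are entirely -inf fall back to a
    uniform draw with a warning.
    """
    logits = logits.copy()
    bad = ~np.isfinite(logits).any(axis=1)
    if np.any(bad):
        warnings.warn("degenerate conditional in SE step; uniform fallback",
                      RuntimeWarning)
        logits[bad] = 0.0
    mx = logits.max(axis=1, keepdims=True)
    p = np.exp(logits - mx)
    p /= p.sum(axis=1, keepdims=True)
    cum = np.cumsum(p, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(logits.shape[0])
    labels = (u[:, None] < cum).argmax(axis=1)
    return labels, p


def se_step(table: np.ndarray, theta: LBMTheta, partition: BlockPartition,
            gibbs_inner: int = 5, rng=None, return_probs: bool = False):
    """Gibbs-sample (z | w) then (w | z) ``gibbs_inner`` times."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n, d, K, L = table.shape
    z = partition.z.copy()
    w = partition.w.copy()
    logpi = np.log(theta.pi)
    logrho = np.log(theta.rho)
    zp = wp = None
    for _ in range(gibbs_inner):
        # rows given columns: sum_j table[i, j, k, w_j]
        tw = table[:, np.arange(d), :, w]          # (d, n, K)
        z, zp = _sample_categorical(logpi[None, :] + tw.sum(axis=0), rng)
        # columns given rows: sum_i table[i, j, z_i, l]
        tz = table[np.arange(n), :, z, :]          # (n, d, L)
        w, wp = _sample_categorical(logrho[None, :] + tz.sum(axis=0), rng)
    out = BlockPartition(z, w, K, L)
    return (out, zp, wp) if return_probs else out


# ---------------------------------------------------------------------------
# M step
# ---------------------------------------------------------------------------

def m_step(data: CurveMatrix, partition: BlockPartition,
           prev: LBMTheta | None, config: RandomEffectConfig,
           spec: BasisSpec, control: MSEMControl | None = None,
           alpha_store: np.ndarray | None = None) -> LBMTheta:
    """Proportion updates plus per-block NLME fits on the pooled cells.

    ``alpha_store`` is an optional (n, d, 3) array of per-cell random-effect
    modes, used to warm-start and updated in place across M-SEM iterations.
    """
    control = control or MSEMControl()
    K, L = partition.K, partition.L
    n, d = data.n, data.d
    pi = np.bincount(partition.z, minlength=K).astype(float) / n
    rho = np.bincount(partition.w, minlength=L).astype(float) / d
    for vec, size in ((pi, n), (rho, d)):
        zero = vec == 0
        if np.any(zero):
            logger.info("zero-frequency cluster floored in proportions")
            vec[zero] = 1.0 / (10.0 * size)
            vec /= vec.sum()
    theta_grid = []
    for k in range(K):
        row = []
        for l in range(L):
            ridx = np.flatnonzero(partition.z == k)
            cidx = np.flatnonzero(partition.w == l)
            init = prev.theta[k][l] if prev is not None else None
            if ridx.size == 0 or cidx.size == 0:
                # empty block: carry the previous parameters forward
                logger.info("empty block (%d, %d): carrying theta over", k, l)
                row.append(init.copy() if init is not None
                           else zero_block_theta(spec, config))
                continue
            x = data.values[np.ix_(ridx, cidx)].reshape(-1, data.T)
            times = np.repeat(data.times[ridx], cidx.size, axis=0)
            mask = ~np.isnan(x)
            if mask.sum() < spec.n_basis + config.n_on + 1:
                # under-identified block: treat like an empty one
                logger.info("block (%d, %d) too small to fit; carrying "
                            "theta over", k, l)
                row.append(init.copy() if init is not None
                           else zero_block_theta(spec, config))
                continue
            a0 = (alpha_store[np.ix_(ridx, cidx)].reshape(-1, 3)
                  if alpha_store is not None else None)
            # cold start (first M step) does the full search; warm-started
            # iterations take short partial steps -- the stochastic EM loop
            # itself supplies the outer iteration
            warm = init is not None and a0 is not None
            theta_kl, a_hat = fit_block_arrays(
                times, np.where(mask, x, 0.0), mask, config, spec,
                init=init,
                max_outer=control.max_nlme_iter if warm
                else max(8, control.max_nlme_iter),
                tol=control.nlme_tol, alphas0=a0,
                pnls_rounds=1 if warm else 2,
                gn_iter=3 if warm else 6,
                em_iter=4 if warm else 8,
                shift_grid_init=not warm,
                return_alphas=True)
            if alpha_store is not None:
                alpha_store[np.ix_(ridx, cidx)] = a_hat.reshape(
                    ridx.size, cidx.size, 3)
            row.append(theta_kl)
        theta_grid.append(row)
    return LBMTheta(pi, rho, theta_grid)


# ---------------------------------------------------------------------------
# complete-data log-likelihood, label alignment, averaging
# ---------------------------------------------------------------------------

def complete_data_loglik(table: np.ndarray, partition: BlockPartition,
                         theta: LBMTheta) -> float:
    """Proportion terms plus the sum of assigned-block cell log-densities."""
    n, d, K, L = table.shape
    z, w = partition.z, partition.w
    cell = table[np.arange(n)[:, None], np.arange(d)[None, :],
                 z[:, None], w[None, :]]
    return float(np.log(theta.pi)[z].sum() + np.log(theta.rho)[w].sum()
                 + cell.sum())


def _match_labels(ref: np.ndarray, sample: np.ndarray, size: int) -> np.ndarray:
    """Permutation p with p[s] = r maximising label agreement."""
    conf = np.zeros((size, size))
    np.add.at(conf, (ref, sample), 1.0)
    r_ind, s_ind = linear_sum_assignment(-conf)
    perm = np.empty(size, dtype=int)
    perm[s_ind] = r_ind
    return perm


def align_labels(reference: BlockPartition, sample: BlockPartition,
                 theta_sample: LBMTheta):
    """Relabel a sampled state to best agree with the reference partition."""
    if (reference.K, reference.L) != (sample.K, sample.L):
        raise ValueError("partitions must share (K, L)")
    pz = _match_labels(reference.z, sample.z, sample.K)
    pw = _match_labels(reference.w, sample.w, sample.L)
    new_part = BlockPartition(pz[sample.z], pw[sample.w], sample.K, sample.L)
    K, L = sample.K, sample.L
    pi = np.empty(K)
    pi[pz] = theta_sample.pi
    rho = np.empty(L)
    rho[pw] = theta_sample.rho
    grid = [[None] * L for _ in range(K)]
    for k in range(K):
        for l in range(L):
            grid[pz[k]][pw[l]] = theta_sample.theta[k][l]
    return new_part, LBMTheta(pi, rho, grid)


def average_thetas(samples: list) -> LBMTheta:
    """Elementwise mean of aligned LBMTheta samples (variances averaged
    on the variance scale)."""
    K, L = samples[0].K, samples[0].L
    pi = np.mean([s.pi for s in samples], axis=0)
    rho = np.mean([s.rho for s in samples], axis=0)
    grid = []
    for k in range(K):
        row = []
        for l in range(L):
            ts = [s.theta[k][l] for s in samples]
            row.append(BlockTheta(
                beta=np.mean([t.beta for t in ts], axis=0),
                mu_alpha=np.mean([t.mu_alpha for t in ts], axis=0),
                sigma_alpha=np.mean([t.sigma_alpha for t in ts], axis=0),
                sigma_eps=float(np.sqrt(np.mean(
                    [t.sigma_eps ** 2 for t in ts]))),
                config=ts[0].config))
        grid.append(row)
    return LBMTheta(pi / pi.sum(), rho / rho.sum(), grid)


# ---------------------------------------------------------------------------
# the full loop
# ---------------------------------------------------------------------------

def _modal_labels(samples: list, size: int) -> np.ndarray:
    stack = np.stack(samples)  # (S, units)
    counts = np.zeros((stack.shape[1], size), dtype=int)
    for s in stack:
        np.add.at(counts, (np.arange(stack.shape[1]), s), 1)
    return counts.argmax(axis=1)  # argmax breaks ties toward lower label


class _Chain:
    """One M-SEM chain whose iterations can be advanced in stages."""

    def __init__(self, data, K, L, config, spec, control, seed, init_method):
        self.data, self.K, self.L = data, K, L
        self.config, self.spec, self.control = config, spec, control
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.partition = init_partitions(
            data, K, L, init_method, seed=self.rng.integers(2 ** 31 - 1))
        self.alpha_store = np.zeros((data.n, data.d, 3))
        self.theta = m_step(data, self.partition, None, config, spec,
                            control, self.alpha_store)
        self.llc_trace = []
        self.partition_samples = []
        self.aligned_thetas = []
        self.reference = None
        self.converged = False
        self.h = 0

    def advance(self, until: int) -> None:
        c = self.control
        while self.h < until and not self.converged:
            table = marginalization_step(self.data, self.theta, c.M,
                                         self.rng, self.spec,
                                         shared_draws=c.shared_draws)
            self.partition = se_step(table, self.theta, self.partition,
                                     c.gibbs_inner, self.rng)
            self.theta = m_step(self.data, self.partition, self.theta,
                                self.config, self.spec, c, self.alpha_store)
            self.llc_trace.append(
                complete_data_loglik(table, self.partition, self.theta))
            self.partition_samples.append(self.partition.copy())
            if self.h >= c.burn_in:
                if self.reference is None:
                    self.reference = self.partition.copy()
                    self.aligned_thetas.append(self.theta.copy())
                else:
                    _, th_al = align_labels(self.reference, self.partition,
                                            self.theta)
                    self.aligned_thetas.append(th_al)
            if (self.h >= c.burn_in + 2 and len(self.llc_trace) >= 4
                    and np.abs(np.diff(self.llc_trace[-4:])).sum() < c.delta):
                self.converged = True
            self.h += 1

    def score(self) -> float:
        """Pilot ranking score: smoothed recent complete-data log-lik."""
        return float(np.mean(self.llc_trace[-3:]))

    def finalize(self) -> FitResult:
        c = self.control
        theta_hat = (average_thetas(self.aligned_thetas)
                     if self.aligned_thetas else self.theta)
        table_hat = marginalization_step(self.data, theta_hat, c.M, self.rng,
                                         self.spec,
                                         shared_draws=c.shared_draws)
        p = self.partition
        zs, ws = [], []
        for _ in range(c.n_final_samples):
            p = se_step(table_hat, theta_hat, p, 1, self.rng)
            zs.append(p.z)
            ws.append(p.w)
        final = BlockPartition(_modal_labels(zs, self.K),
                               _modal_labels(ws, self.L), self.K, self.L)
        # scored complete-data log-likelihood at (theta_hat, z_hat, w_hat)
        table_score = marginalization_step(self.data, theta_hat, c.M_score,
                                           self.rng, self.spec,
                                           shared_draws=c.shared_draws)
        llc_hat = complete_data_loglik(table_score, final, theta_hat)
        return FitResult(theta_hat=theta_hat, partition=final,
                         llc_trace=np.asarray(self.llc_trace),
                         partition_samples=self.partition_samples,
                         converged=self.converged,
                         n_iterations_run=len(self.llc_trace),
                         llc_hat=llc_hat, K=self.K, L=self.L,
                         n=self.data.n, d=self.data.d, seed=self.seed)


def run_msem(data: CurveMatrix, K: int, L: int, config: RandomEffectConfig,
             spec: BasisSpec, control: MSEMControl | None = None) -> FitResult:
    """Run the M-SEM loop and return the fitted state.

    With ``n_starts > 1``, all starts are run as short pilot chains up to
    mid-burn-in and the one with the best smoothed complete-data
    log-likelihood continues to the full iteration budget (merged local
    optima announce themselves early and by a wide log-likelihood margin).
    The first start initialises by k-means, later ones by random labels —
    k-means lands on nearly the same partition for every seed, so random
    restarts provide the actual diversity.
    """
    control = control or MSEMControl()
    if data.n < K or data.d < L:
        raise ValueError("need at least K rows and L columns")
    master = np.random.default_rng(control.seed)
    chains = []
    for s in range(control.n_starts):
        seed = int(master.integers(2 ** 31 - 1))
        init = control.init_method
        if s > 0 and init == "kmeans":
            init = "perturbed"
        chains.append(_Chain(data, K, L, config, spec, control, seed, init))
    # Every start runs the full budget and the best smoothed final llc is
    # retained.  Early (pilot) elimination is deliberately not used: merged
    # local optima converge fast while eventually-good chains spend many
    # iterations sorting labels, so mid-run llc comparisons systematically
    # favour the doomed chains.
    for ch in chains:
        ch.advance(control.n_iterations)
    best = max(chains, key=lambda ch: ch.score())
    return best.finalize()
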