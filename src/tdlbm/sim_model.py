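"""Shape-invariant block densities.

Conditional on its random effects alpha = (alpha1, alpha2, alpha3), a cell
curve in block (k, l) is Gaussian around

    f(t) = alpha1 + exp(alpha2) * m(t - alpha3; beta_kl)

with i.i.d. residual noise of standard deviation sigma_eps.  The block
marginal density integrates alpha out over its Gaussian law; for nonlinear
configurations that integral has no closed form and is approximated by
Monte Carlo:

    p(x) ~= (1/M) sum_m p(x | alpha^(m)),   alpha^(m) ~ N3(mu, Sigma),

a random version of Gaussian quadrature.  Switched-off effects are point
masses at zero, so their draws are identically zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp

from .basis import BasisSpec, clamp_times, eval_mean_shape, _check_domain
from .data import CellCurve
from .effects import RandomEffectConfig

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class BlockTheta:
    """Per-block parameters (beta, mu_alpha, Sigma_alpha, sigma_eps)."""

    beta: np.ndarray
    mu_alpha: np.ndarray
    sigma_alpha: np.ndarray
    sigma_eps: float
    config: RandomEffectConfig
    converged: bool = True
    n_iter: int = 0
    objective_trace: tuple = ()

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.mu_alpha = np.asarray(self.mu_alpha, dtype=float).reshape(3)
        self.sigma_alpha = np.asarray(self.sigma_alpha, dtype=float).reshape(3, 3)
        if self.sigma_eps <= 0:
            raise ValueError("sigma_eps must be positive")
        off = ~self.config.mask
        if np.any(self.mu_alpha[off] != 0):
            raise ValueError("mu_alpha entries of switched-off effects must be 0")
        if np.any(self.sigma_alpha[off, :] != 0) or np.any(self.sigma_alpha[:, off] != 0):
            raise ValueError("Sigma_alpha rows/cols of switched-off effects must be 0")

    def copy(self) -> "BlockTheta":
        return replace(self, beta=self.beta.copy(),
                       mu_alpha=self.mu_alpha.copy(),
                       sigma_alpha=self.sigma_alpha.copy())


def zero_block_theta(spec: BasisSpec, config: RandomEffectConfig,
                     sigma_eps: float = 1.0) -> BlockTheta:
    """A neutral BlockTheta (flat shape, unit-ish variances) for warm starts."""
    sig = np.zeros((3, 3))
    sig[config.mask, config.mask] = 0.1
    return BlockTheta(beta=np.zeros(spec.n_basis), mu_alpha=np.zeros(3),
                      sigma_alpha=sig, sigma_eps=sigma_eps, config=config)


def cell_mean(t, alpha, beta, spec: BasisSpec, config: RandomEffectConfig,
              extrapolate: str = "raise") -> np.ndarray:
    """Conditional mean curve ``alpha1 + exp(alpha2) m(t - alpha3; beta)``.

    ``extrapolate`` controls shifted times leaving the padded basis domain:
    "raise" (default, contract for direct use) or "clamp" (boundary value,
    used inside the likelihood machinery).
    """
    alpha = np.asarray(alpha, dtype=float).reshape(3)
    if np.any(alpha[~config.mask] != 0):
        raise ValueError("switched-off effects must be zero in alpha")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    ts = t - alpha[2]
    if extrapolate == "clamp":
        ts = clamp_times(ts, spec)
    else:
        _check_domain(ts, spec)
    return alpha[0] + np.exp(alpha[1]) * eval_mean_shape(ts, beta, spec)


def conditional_logdensity(cell: CellCurve, alpha, theta: BlockTheta,
                           spec: BasisSpec, extrapolate: str = "raise") -> float:
    """log p(x | alpha; theta): independent Gaussians at the observed points.

    Missing values are skipped; an all-missing cell contributes 0 (the log of
    an empty product).
    """
    if theta.sigma_eps <= 0:
        raise ValueError("sigma_eps must be positive")
    obs = cell.observed
    n_t = int(obs.sum())
    if n_t == 0:
        return 0.0
    mu = cell_mean(cell.times[obs], alpha, theta.beta, spec, theta.config,
                   extrapolate=extrapolate)
    r = cell.values[obs] - mu
    s2 = theta.sigma_eps ** 2
    return float(-0.5 * n_t * (LOG_2PI + np.log(s2)) - 0.5 * np.sum(r * r) / s2)


def draw_random_effects(theta: BlockTheta, M: int, rng) -> np.ndarray:
    """Draw M alpha vectors from N3(mu, Sigma); off effects are exactly 0."""
    if M < 1:
        raise ValueError("M must be a positive integer")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = np.zeros((M, 3))
    on = theta.config.mask
    q = int(on.sum())
    if q == 0:
        return out
    sub = theta.sigma_alpha[np.ix_(on, on)]
    mu = theta.mu_alpha[on]
    out[:, on] = rng.multivariate_normal(mu, sub, size=M, method="cholesky",
                                         check_valid="ignore")
    return out


def marginal_logdensity_mc(cell: CellCurve, theta: BlockTheta, M: int, rng,
                           spec: BasisSpec) -> float:
    """Monte Carlo estimate of log p(x; theta), stabilised in log space.

    With all effects off every draw is the zero vector and the value equals
    the conditional log-density at alpha = 0 exactly.
    """
    draws = draw_random_effects(theta, M, rng)
    lds = np.array([
        conditional_logdensity(cell, a, theta, spec, extrapolate="clamp")
        for a in draws
    ])
    return float(logsumexp(lds) - np.log(M))
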