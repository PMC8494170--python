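"""Per-block nonlinear mixed-effects estimation (Lindstrom-Bates style).

Given the curves pooled in one block, the fitter maximises an approximate
marginal likelihood for the shape-invariant model by alternating

* a penalised nonlinear least-squares (PNLS) step over the basis
  coefficients ``beta`` and the per-cell posterior modes of the random
  effects ``alpha`` (per-cell penalised Gauss-Newton, vectorised across
  cells), and
* a linear mixed-effects step on the model linearised around the current
  posterior modes, where the variance components ``(Sigma_alpha,
  sigma_eps^2)`` are updated by EM on the pseudo-response
  ``w_c = x_c - f(alpha_c) + Z_c alpha_c``.

The recorded objective is the marginal log-likelihood of the linearised
model.  Since the alternation does not guarantee ascent in general, an
iteration that would decrease the objective is reverted and the algorithm
stops there, so the reported trace is monotone non-decreasing.

Means of the switched-on random effects are fixed at zero: an estimated
amplitude mean is confounded with the intercept freedom of ``beta``, a time
shift mean with its horizontal placement, and a scale mean with its norm.
"""

from __future__ import annotations

import warnings

import numpy as np

from .basis import BasisSpec, clamp_times, eval_mean_shape, eval_mean_shape_deriv
from .data import CellCurve
from .effects import RandomEffectConfig
from .sim_model import LOG_2PI, BlockTheta

# variance floors: sigma_eps floored on the SD scale, Sigma_alpha on variances
SIGMA_EPS_FLOOR = 1e-8
VAR_FLOOR = 1e-8


def cells_to_arrays(cells):
    """Pad a collection of CellCurve into (times, values, mask) arrays."""
    cells = list(cells)
    if not cells:
        raise ValueError("need at least one cell")
    T = max(c.times.size for c in cells)
    C = len(cells)
    times = np.empty((C, T))
    x = np.full((C, T), np.nan)
    for i, c in enumerate(cells):
        t = c.times
        times[i, :t.size] = t
        times[i, t.size:] = t[-1]
        x[i, :t.size] = c.values
    mask = ~np.isnan(x)
    return times, np.where(mask, x, 0.0), mask


def _shape_on_grid(times_shifted, beta, spec):
    ts = clamp_times(times_shifted, spec)
    m = eval_mean_shape(ts.ravel(), beta, spec).reshape(ts.shape)
    return m


def _shape_and_deriv(times_shifted, beta, spec):
    ts = clamp_times(times_shifted, spec)
    flat = ts.ravel()
    m = eval_mean_shape(flat, beta, spec).reshape(ts.shape)
    md = eval_mean_shape_deriv(flat, beta, spec).reshape(ts.shape)
    # beyond the pad the shape is held at its boundary value, so its
    # sensitivity to the time shift is zero there
    md = np.where(ts == times_shifted, md, 0.0)
    return m, md


def _design_rows(times, a, beta, spec, config):
    """Conditional mean pieces for all cells: m, f at current alphas."""
    ts = times - a[:, 2][:, None]
    m = _shape_on_grid(ts, beta, spec)
    f = a[:, 0][:, None] + np.exp(a[:, 1])[:, None] * m
    return m, f


def _beta_ls(times, x, mask, a, spec):
    """Least-squares update of beta given the current alphas.

    Basis functions whose support no (shifted) observation reaches -- they
    live in the padded tails -- are excluded from the solve and their
    coefficients pinned at 0; otherwise noise along those directions blows
    the fitted shape up outside the observed window.
    """
    C, T = x.shape
    ts = clamp_times(times - a[:, 2][:, None], spec)
    from .basis import eval_basis
    B = eval_basis(ts.ravel(), spec)            # (C*T, nb)
    scale = np.repeat(np.exp(a[:, 1]), T)
    design = B * scale[:, None]
    target = (x - a[:, 0][:, None]).ravel()
    rows = mask.ravel()
    D = design[rows]
    col_norm = np.linalg.norm(D, axis=0)
    keep = col_norm > 1e-3 * max(col_norm.max(), 1e-300)
    beta = np.zeros(spec.n_basis)
    sol, *_ = np.linalg.lstsq(D[:, keep], target[rows], rcond=1e-7)
    beta[keep] = sol
    return beta


def _penalized_obj(r, mask, a_on, Sinv, sigma2):
    rr = np.where(mask, r, 0.0)
    return (rr * rr).sum(axis=1) / sigma2 + np.einsum(
        "cq,qp,cp->c", a_on, Sinv, a_on)


def _jacobian(times, a, beta, spec, config, m=None):
    """d f / d alpha_on, (C, T, q); also returns m and f."""
    C, T = times.shape
    ts = times - a[:, 2][:, None]
    if config.on_timeshift:
        m, md = _shape_and_deriv(ts, beta, spec)
    else:
        if m is None:
            m = _shape_on_grid(ts, beta, spec)
        md = None
    s = np.exp(a[:, 1])[:, None]
    f = a[:, 0][:, None] + s * m
    cols = []
    if config.on_amplitude:
        cols.append(np.ones((C, T)))
    if config.on_scale:
        cols.append(s * m)
    if config.on_timeshift:
        cols.append(-s * md)
    Z = np.stack(cols, axis=2) if cols else np.zeros((C, T, 0))
    return Z, m, f


def _gn_alphas(times, x, mask, beta, a, Sinv, sigma2, config, spec,
               n_iter=6, n_halvings=2, shift_grid=None):
    """Penalised Gauss-Newton for the posterior modes, vectorised over cells.

    ``shift_grid`` optionally seeds the time-shift component per cell from
    the best of several candidate offsets before the Newton iterations —
    registration objectives are multimodal when a localised feature is
    badly misaligned, and a gradient step cannot cross the flat region
    between modes.
    """
    on = config.mask
    q = int(on.sum())
    if q == 0:
        return a
    a = a.copy()
    _, m0, f0 = _jacobian(times, a, beta, spec, config)
    r = x - f0
    obj = _penalized_obj(r, mask, a[:, on], Sinv, sigma2)
    if shift_grid is not None and config.on_timeshift:
        for s in shift_grid:
            cand = a.copy()
            cand[:, 2] = s
            _, fc = _design_rows(times, cand, beta, spec, config)
            objc = _penalized_obj(x - fc, mask, cand[:, on], Sinv, sigma2)
            better = objc < obj
            a = np.where(better[:, None], cand, a)
            obj = np.where(better, objc, obj)
    for _ in range(n_iter):
        Z, m0, f0 = _jacobian(times, a, beta, spec, config)
        r = x - f0
        Zm = np.where(mask[:, :, None], Z, 0.0)
        rm = np.where(mask, r, 0.0)
        A = np.einsum("ctq,ctp->cqp", Zm, Zm) / sigma2 + Sinv[None]
        g = np.einsum("ctq,ct->cq", Zm, rm) / sigma2 - a[:, on] @ Sinv
        try:
            delta = np.linalg.solve(A, g[..., None])[..., 0]
        except np.linalg.LinAlgError:  # pragma: no cover - defensive
            delta = np.linalg.lstsq(
                A.reshape(-1, q, q)[0], g.T, rcond=None)[0].T
        step = np.ones(a.shape[0])
        best_a = a
        best_obj = obj
        improved_any = False
        for _h in range(n_halvings + 1):
            cand = a.copy()
            cand[:, on] = a[:, on] + step[:, None] * delta
            _, fc = _design_rows(times, cand, beta, spec, config)
            objc = _penalized_obj(x - fc, mask, cand[:, on], Sinv, sigma2)
            better = objc < best_obj - 1e-12
            if np.any(better):
                improved_any = True
                best_a = np.where(better[:, None], cand, best_a)
                best_obj = np.where(better, objc, best_obj)
            step = np.where(better, step, step * 0.5)
            if np.all(better):
                break
        a, obj = best_a, best_obj
        if not improved_any or np.max(np.abs(delta)) < 1e-9:
            break
    return a


def _em_variances(ZtZ, Ztw, ww, n_obs_total, Sigma_on, sigma2, n_em=8,
                  diagonal=True):
    q = Sigma_on.shape[0]
    for _ in range(n_em):
        Sinv = np.linalg.inv(_floored(Sigma_on, diagonal))
        A = ZtZ / sigma2 + Sinv[None]
        P = np.linalg.inv(A)
        mpost = np.einsum("cqp,cp->cq", P, Ztw) / sigma2
        Sigma_on = (np.einsum("cq,cp->cqp", mpost, mpost) + P).mean(axis=0)
        if diagonal:
            Sigma_on = np.diag(np.diag(Sigma_on))
        resid = (ww - 2 * np.einsum("cq,cq->c", mpost, Ztw)
                 + np.einsum("cq,cqp,cp->c", mpost, ZtZ, mpost))
        tr = np.einsum("cqp,cpq->c", ZtZ, P)
        sigma2 = max((resid.sum() + tr.sum()) / n_obs_total,
                     SIGMA_EPS_FLOOR ** 2)
    return _floored(Sigma_on, diagonal), sigma2


def _floored(Sigma_on, diagonal=True):
    S = Sigma_on.copy()
    d = np.diag(S).copy()
    low = d < VAR_FLOOR
    if np.any(low):
        d[low] = VAR_FLOOR
        S[np.diag_indices_from(S)] = d
        if diagonal:
            S = np.diag(d)
    return S


def _lin_marg_loglik(ZtZ, Ztw, ww, n_obs_c, Sigma_on, sigma2):
    """Marginal log-lik of the linearised LME, via q x q Woodbury algebra."""
    q = Sigma_on.shape[0]
    if q == 0:
        quad = ww.sum() / sigma2
        n_tot = n_obs_c.sum()
        return -0.5 * (n_tot * (LOG_2PI + np.log(sigma2)) + quad)
    eye = np.eye(q)
    Mmat = eye[None] + (Sigma_on[None] @ ZtZ) / sigma2
    sign, logdet = np.linalg.slogdet(Mmat)
    Sinv = np.linalg.inv(Sigma_on)
    A = ZtZ + sigma2 * Sinv[None]
    sol = np.linalg.solve(A, Ztw[..., None])[..., 0]
    quad = (ww - np.einsum("cq,cq->c", Ztw, sol)) / sigma2
    ll = -0.5 * (n_obs_c * (LOG_2PI + np.log(sigma2)) + logdet + quad)
    return float(ll.sum())


def _embed_sigma(Sigma_on, config):
    S = np.zeros((3, 3))
    on = np.flatnonzero(config.mask)
    S[np.ix_(on, on)] = Sigma_on
    return S


def fit_block_arrays(times, x, mask, config: RandomEffectConfig,
                     spec: BasisSpec, init: BlockTheta | None = None,
                     max_outer: int = 50, tol: float = 1e-6,
                     pnls_rounds: int = 2, gn_iter: int = 6, em_iter: int = 8,
                     diagonal_sigma: bool = True,
                     alphas0: np.ndarray | None = None,
                     shift_grid_init: bool = True,
                     return_alphas: bool = False):
    """Fit one block's shape-invariant mixed model on padded arrays.

    ``times``/``x``/``mask`` are (C, T); masked-out entries are ignored
    everywhere.  Returns a :class:`BlockTheta` whose ``converged`` flag and
    ``objective_trace`` report the outer iteration diagnostics.
    """
    C, T = x.shape
    n_obs_c = mask.sum(axis=1).astype(float)
    n_obs_total = float(n_obs_c.sum())
    if n_obs_total < spec.n_basis + config.n_on + 1:
        raise ValueError("not enough observed points to identify the block model")
    on = config.mask
    q = config.n_on

    a = np.zeros((C, 3)) if alphas0 is None else alphas0.copy()

    # ---- pure fixed-effects case: plain least squares --------------------
    if q == 0:
        beta = _beta_ls(times, x, mask, a, spec)
        _, f = _design_rows(times, a, beta, spec, config)
        r = np.where(mask, x - f, 0.0)
        sigma2 = max((r * r).sum() / n_obs_total, SIGMA_EPS_FLOOR ** 2)
        ll = _lin_marg_loglik(np.zeros((C, 0, 0)), np.zeros((C, 0)),
                              (r * r).sum(axis=1), n_obs_c,
                              np.zeros((0, 0)), sigma2)
        theta = BlockTheta(beta=beta, mu_alpha=np.zeros(3),
                           sigma_alpha=np.zeros((3, 3)),
                           sigma_eps=float(np.sqrt(sigma2)), config=config,
                           converged=True, n_iter=1, objective_trace=(ll,))
        return (theta, a) if return_alphas else theta

    # ---- initialisation ---------------------------------------------------
    if init is not None and init.config.name == config.name:
        beta = init.beta.copy()
        Sigma_on = _floored(init.sigma_alpha[np.ix_(on, on)], diagonal_sigma)
        sigma2 = max(init.sigma_eps ** 2, SIGMA_EPS_FLOOR ** 2)
    else:
        beta = _beta_ls(times, x, mask, a, spec)
        _, f = _design_rows(times, a, beta, spec, config)
        r = np.where(mask, x - f, 0.0)
        sigma2 = max((r * r).sum() / n_obs_total, SIGMA_EPS_FLOOR ** 2)
        d0 = np.full(3, 0.02)
        if config.on_amplitude:
            cm = r.sum(axis=1) / np.maximum(n_obs_c, 1.0)
            d0[0] = max(np.var(cm), VAR_FLOOR)
        Sigma_on = np.diag(d0[on])

    # candidate shift offsets for escaping registration local optima
    width = spec.domain[1] - spec.domain[0]
    grid0 = np.linspace(-0.45, 0.45, 7) * min(width, 2 * spec.pad) \
        if (shift_grid_init and config.on_timeshift and spec.pad > 0) else None

    # The alternation is not an ascent algorithm, so we track the incumbent:
    # the reported trace is the best objective seen after each outer
    # iteration (monotone by construction) and the returned parameters are
    # the incumbent's.  Stopping: three consecutive iterations without an
    # improvement larger than tol (relative).
    trace = []
    best_ll = -np.inf
    best_state = None
    stall = 0
    converged = False
    for outer in range(max_outer):
        Sinv = np.linalg.inv(_floored(Sigma_on, diagonal_sigma))
        for rnd in range(pnls_rounds):
            a = _gn_alphas(times, x, mask, beta, a, Sinv, sigma2, config,
                           spec, n_iter=gn_iter,
                           shift_grid=grid0 if outer == 0 and rnd == 0 else None)
            beta = _beta_ls(times, x, mask, a, spec)
        Z, m, f = _jacobian(times, a, beta, spec, config)
        Zm = np.where(mask[:, :, None], Z, 0.0)
        w = np.where(mask, x - f, 0.0) + np.einsum("ctq,cq->ct", Zm, a[:, on])
        ZtZ = np.einsum("ctq,ctp->cqp", Zm, Zm)
        Ztw = np.einsum("ctq,ct->cq", Zm, w)
        ww = (w * w).sum(axis=1)
        # guard against pseudo-data blowups when the linearization is poor:
        # keep the pre-EM variance components if they score better
        ll_pre = _lin_marg_loglik(ZtZ, Ztw, ww, n_obs_c, Sigma_on, sigma2)
        Sigma_new, sigma2_new = _em_variances(ZtZ, Ztw, ww, n_obs_total,
                                              Sigma_on, sigma2, n_em=em_iter,
                                              diagonal=diagonal_sigma)
        ll = _lin_marg_loglik(ZtZ, Ztw, ww, n_obs_c, Sigma_new, sigma2_new)
        if ll >= ll_pre:
            Sigma_on, sigma2 = Sigma_new, sigma2_new
        else:
            ll = ll_pre
        if ll > best_ll + tol * max(1.0, abs(best_ll)):
            stall = 0
        else:
            stall += 1
        if ll > best_ll:
            best_ll = ll
            best_state = (beta.copy(), a.copy(), Sigma_on.copy(), sigma2)
        trace.append(best_ll)
        if stall >= 3:
            converged = True
            break
    if best_state is not None:
        beta, a, Sigma_on, sigma2 = best_state
    if not converged and max_outer >= 20:
        warnings.warn("block NLME fit did not converge within max_outer "
                      "iterations; returning best iterate", RuntimeWarning)
    theta = BlockTheta(beta=beta, mu_alpha=np.zeros(3),
                       sigma_alpha=_embed_sigma(Sigma_on, config),
                       sigma_eps=float(np.sqrt(max(sigma2, SIGMA_EPS_FLOOR ** 2))),
                       config=config, converged=converged,
                       n_iter=len(trace), objective_trace=tuple(trace))
    return (theta, a) if return_alphas else theta


def fit_block_nlme(cells, config: RandomEffectConfig, spec: BasisSpec,
                   init: BlockTheta | None = None, **kwargs) -> BlockTheta:
    """Fit the block model to a collection of :class:`CellCurve`.

    Thin wrapper over :func:`fit_block_arrays`; see its docstring.
    """
    times, x, mask = cells_to_arrays(cells)
    return fit_block_arrays(times, x, mask, config, spec, init=init, **kwargs)
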