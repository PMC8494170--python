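"""B-spline bases for block mean-shape functions.

Each block of the co-clustering model carries a smooth mean shape
``m(t; beta) = B(t) beta`` where ``B(t)`` is a row vector of B-spline basis
functions and ``beta`` the coefficient vector.  Because curves inside a block
may be shifted in time by a random effect, the basis lives on a *padded*
domain ``[t_lo - pad, t_hi + pad]`` so that ``m(t - alpha3)`` stays defined
for plausible shifts; evaluation beyond the pad either raises or clamps to
the boundary, depending on the caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline


class DomainError(ValueError):
    """Raised when a time point falls outside the padded basis domain."""


@dataclass(frozen=True)
class BasisSpec:
    """Specification of a clamped B-spline basis.

    Parameters
    ----------
    degree : int
        Polynomial degree of the spline pieces (3 = cubic, the default).
    interior_knots : tuple of float
        Strictly interior knots, non-decreasing, inside the padded domain.
    domain : (float, float)
        The observation window ``[t_lo, t_hi]``.
    pad : float
        Symmetric enlargement of the domain absorbing time shifts.

    The number of basis functions is ``len(interior_knots) + degree + 1``
    and the basis forms a partition of unity on the padded domain.
    """

    degree: int = 3
    interior_knots: tuple = ()
    domain: tuple = (0.0, 1.0)
    pad: float = 0.0

    def __post_init__(self):
        if self.degree < 0:
            raise ValueError("degree must be a non-negative integer")
        if self.pad < 0:
            raise ValueError("pad must be non-negative")
        lo, hi = self.padded_domain
        if not lo < hi:
            raise ValueError("domain must be a non-empty interval")
        ik = np.asarray(self.interior_knots, dtype=float)
        if ik.size:
            if np.any(np.diff(ik) < 0):
                raise ValueError("interior knots must be non-decreasing")
            if ik[0] <= lo or ik[-1] >= hi:
                raise ValueError("interior knots must lie strictly inside the padded domain")
        # freeze as plain tuple of floats
        object.__setattr__(self, "interior_knots", tuple(float(t) for t in ik))
        object.__setattr__(self, "domain", (float(self.domain[0]), float(self.domain[1])))

    @classmethod
    def equispaced(cls, n_interior: int = 5, degree: int = 3,
                   domain: tuple = (0.0, 1.0), pad: float = 0.0) -> "BasisSpec":
        """Equispaced interior knots on the padded domain (the default layout)."""
        lo, hi = domain[0] - pad, domain[1] + pad
        if n_interior > 0:
            ik = tuple(np.linspace(lo, hi, n_interior + 2)[1:-1])
        else:
            ik = ()
        return cls(degree=degree, interior_knots=ik, domain=domain, pad=pad)

    @property
    def padded_domain(self) -> tuple:
        return (self.domain[0] - self.pad, self.domain[1] + self.pad)

    @property
    def n_basis(self) -> int:
        return len(self.interior_knots) + self.degree + 1

    def knot_vector(self) -> np.ndarray:
        lo, hi = self.padded_domain
        return np.concatenate([
            np.full(self.degree + 1, lo),
            np.asarray(self.interior_knots, dtype=float),
            np.full(self.degree + 1, hi),
        ])

    def to_dict(self) -> dict:
        return {
            "degree": self.degree,
            "interior_knots": list(self.interior_knots),
            "domain": list(self.domain),
            "pad": self.pad,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BasisSpec":
        return cls(degree=int(d["degree"]),
                   interior_knots=tuple(d.get("interior_knots", ())),
                   domain=tuple(d.get("domain", (0.0, 1.0))),
                   pad=float(d.get("pad", 0.0)))


def _check_domain(t: np.ndarray, spec: BasisSpec) -> None:
    lo, hi = spec.padded_domain
    bad = (t < lo) | (t > hi) | ~np.isfinite(t)
    if np.any(bad):
        t_bad = np.asarray(t)[bad].ravel()[0]
        raise DomainError(
            f"time {t_bad!r} outside padded basis domain [{lo}, {hi}]")


def clamp_times(t: np.ndarray, spec: BasisSpec, warn: bool = False) -> np.ndarray:
    """Clamp times into the padded domain (boundary-value extrapolation)."""
    lo, hi = spec.padded_domain
    t = np.asarray(t, dtype=float)
    if warn and (np.any(t < lo) or np.any(t > hi)):
        warnings.warn("time points beyond the padded basis domain were clamped "
                      "to the boundary", RuntimeWarning, stacklevel=2)
    return np.clip(t, lo, hi)


def eval_basis(t, spec: BasisSpec) -> np.ndarray:
    """Evaluate the basis at ``t``; rows sum to 1 on the padded domain.

    Returns a dense ``(len(t), spec.n_basis)`` matrix.  Raises
    :class:`DomainError` for points outside the padded domain.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    _check_domain(t, spec)
    kv = spec.knot_vector()
    # design_matrix rejects x == right endpoint in some scipy versions only
    # via extrapolate handling; nudging is unnecessary since extrapolate=False
    # accepts the closed interval.
    dm = BSpline.design_matrix(t, kv, spec.degree, extrapolate=False)
    return np.asarray(dm.todense())


def build_basis(spec: BasisSpec):
    """Return a basis evaluator ``f(t) -> (len(t), n_basis)`` for ``spec``."""
    return lambda t: eval_basis(t, spec)


def eval_mean_shape(t, beta, spec: BasisSpec) -> np.ndarray:
    """Evaluate ``m(t; beta) = B(t) beta`` elementwise."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (spec.n_basis,):
        raise ValueError(
            f"beta has shape {beta.shape}, expected ({spec.n_basis},)")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    _check_domain(t, spec)
    sp = BSpline(spec.knot_vector(), beta, spec.degree, extrapolate=False)
    out = sp(t)
    # BSpline returns nan at the right closed endpoint in no-extrapolate mode
    # for some versions; patch via design matrix where needed.
    if np.any(np.isnan(out)):
        mask = np.isnan(out)
        out[mask] = eval_basis(t[mask], spec) @ beta
    return out


def eval_mean_shape_deriv(t, beta, spec: BasisSpec) -> np.ndarray:
    """First derivative ``m'(t; beta)`` (used by the Gauss-Newton steps)."""
    beta = np.asarray(beta, dtype=float)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    _check_domain(t, spec)
    sp = BSpline(spec.knot_vector(), beta, spec.degree, extrapolate=False)
    der = sp.derivative()
    out = der(t)
    if np.any(np.isnan(out)):
        # right closed endpoint: evaluate one-sided from the left
        lo, hi = spec.padded_domain
        eps = 1e-9 * max(1.0, abs(hi))
        mask = np.isnan(out)
        out[mask] = der(np.clip(t[mask], lo, hi - eps))
    return out
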