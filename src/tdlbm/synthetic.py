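"""Synthetic three-way curve data, the CARI metric, and benchmark studies.

The generator reproduces the study conditions of the simulation design the
model was evaluated under: a 4 x 3 grid of blocks whose mean shapes are
drawn from a library of four smooth functions, T = 15 equispaced time
points on [0, 1], residual noise sd 0.3, and TFT random effects with
variances diag(1, 0, 0.1) (amplitude and time shift on, scale off),
zero-mean.  The four mean-shape formulas are this package's own (visually
distinct, pairwise L2-separated by at least 1 on [0, 1]) and are chosen so
that no pair coincides under the amplitude/time-shift transformations the
TFT configuration leaves free; they are overridable via ScenarioSpec.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import BlockPartition, CurveMatrix
from .effects import RandomEffectConfig


# ---------------------------------------------------------------------------
# mean-shape library
# ---------------------------------------------------------------------------

def _m1(t):
    return 3.0 * np.sin(2.0 * np.pi * t)


def _m2(t):
    return 1.5 - 6.0 * (t - 0.5) ** 2


def _m3(t):
    return 6.0 * t - 3.0


def _m4(t):
    return 4.0 * np.exp(-((t - 0.5) ** 2) / 0.045)


#: block (k, l) -> shape id (0-based), for the K=4 x L=3 baseline design
DEFAULT_ASSIGNMENT = np.array([
    [0, 1, 0],
    [2, 3, 2],
    [1, 1, 0],
    [1, 2, 3],
])


def default_shapes():
    """Four smooth mean shapes on [0, 1] and the baseline block assignment.

    The shapes: a one-period sinusoid, a broad concave arc, a linear ramp,
    and a narrow Gaussian peak.
    """
    return [_m1, _m2, _m3, _m4], DEFAULT_ASSIGNMENT.copy()


# ---------------------------------------------------------------------------
# scenario spec and simulator
# ---------------------------------------------------------------------------

@dataclass
class ScenarioSpec:
    """Generative configuration for one simulation scenario."""

    n: int = 100
    d: int = 20
    T: int = 15
    K_true: int = 4
    L_true: int = 3
    shape_assignment: np.ndarray = field(
        default_factory=lambda: DEFAULT_ASSIGNMENT.copy())
    shapes: list = field(default_factory=lambda: [_m1, _m2, _m3, _m4])
    sigma_eps: float = 0.3
    mu_alpha: np.ndarray = field(default_factory=lambda: np.zeros(3))
    sigma_alpha: np.ndarray = field(
        default_factory=lambda: np.diag([1.0, 0.0, 0.1]))
    config: RandomEffectConfig = field(
        default_factory=lambda: RandomEffectConfig.from_name("TFT"))
    seed: int | None = None

    def __post_init__(self):
        self.shape_assignment = np.asarray(self.shape_assignment, dtype=int)
        if self.shape_assignment.shape != (self.K_true, self.L_true):
            raise ValueError("shape_assignment must be K_true x L_true")
        if self.shape_assignment.max() >= len(self.shapes) or \
                self.shape_assignment.min() < 0:
            raise ValueError("invalid shape ids in assignment")
        if self.T < 2:
            raise ValueError("need at least 2 time points")
        if self.sigma_eps < 0:
            raise ValueError("sigma_eps must be non-negative")
        self.mu_alpha = np.asarray(self.mu_alpha, dtype=float).reshape(3)
        self.sigma_alpha = np.asarray(self.sigma_alpha, dtype=float).reshape(3, 3)

    @property
    def time_grid(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.T)


def scenario_table1(n: int = 100, d: int = 20, seed=None) -> ScenarioSpec:
    """The baseline benchmark scenario (variants change only n and d)."""
    return ScenarioSpec(n=n, d=d, seed=seed)


@dataclass
class SimulatedData:
    data: CurveMatrix
    truth: BlockPartition
    alphas: np.ndarray  # (n, d, 3) realized random effects


def _balanced_labels(n_units: int, n_groups: int, rng) -> np.ndarray:
    lab = np.arange(n_units) % n_groups
    return rng.permutation(lab)


def simulate_dataset(spec: ScenarioSpec, rng=None) -> SimulatedData:
    """Draw one dataset from the block-specific shape-invariant model.

    Rows/columns are assigned to clusters in balanced (randomly permuted)
    fashion; each cell draws alpha ~ N3(mu, Sigma) with switched-off
    components forced to zero, then emits
    ``alpha1 + exp(alpha2) m_kl(t - alpha3) + eps`` on the common grid.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    z = _balanced_labels(spec.n, spec.K_true, rng)
    w = _balanced_labels(spec.d, spec.L_true, rng)
    t = spec.time_grid
    on = spec.config.mask
    alphas = np.zeros((spec.n, spec.d, 3))
    q = int(on.sum())
    if q:
        sub = spec.sigma_alpha[np.ix_(on, on)]
        draws = rng.multivariate_normal(spec.mu_alpha[on], sub,
                                        size=(spec.n, spec.d),
                                        method="cholesky",
                                        check_valid="ignore")
        alphas[:, :, on] = draws
    values = np.empty((spec.n, spec.d, spec.T))
    for k in range(spec.K_true):
        for l in range(spec.L_true):
            ridx = np.flatnonzero(z == k)
            cidx = np.flatnonzero(w == l)
            if ridx.size == 0 or cidx.size == 0:
                continue
            m = spec.shapes[spec.shape_assignment[k, l]]
            a = alphas[np.ix_(ridx, cidx)]          # (nk, dl, 3)
            ts = t[None, None, :] - a[:, :, 2:3]    # (nk, dl, T)
            curves = a[:, :, 0:1] + np.exp(a[:, :, 1:2]) * m(ts)
            values[np.ix_(ridx, cidx)] = curves
    if spec.sigma_eps > 0:
        values = values + rng.normal(0.0, spec.sigma_eps, size=values.shape)
    data = CurveMatrix(values, t)
    return SimulatedData(data=data,
                         truth=BlockPartition(z, w, spec.K_true, spec.L_true),
                         alphas=alphas)


# ---------------------------------------------------------------------------
# co-clustering adjusted Rand index
# ---------------------------------------------------------------------------

def _pair_counts(labels: np.ndarray) -> np.ndarray:
    return np.bincount(labels)


def cari(a: BlockPartition, b: BlockPartition) -> float:
    """Co-clustering adjusted Rand index between two block partitions.

    The cell-level contingency table of block labels factorises as the
    Kronecker product of the row-label and column-label contingency tables;
    the adjusted Rand formula is applied to that product.  Equals 1 iff the
    partitions agree up to block relabelling; near 0 for independent ones.
    """
    if (a.n, a.d) != (b.n, b.d):
        raise ValueError("partitions must cover the same matrix")
    conf_z = np.zeros((a.K, b.K))
    np.add.at(conf_z, (a.z, b.z), 1.0)
    conf_w = np.zeros((a.L, b.L))
    np.add.at(conf_w, (a.w, b.w), 1.0)
    conf = np.kron(conf_z, conf_w)
    N = a.n * a.d

    def c2(x):
        return x * (x - 1) / 2.0

    sum_ij = c2(conf).sum()
    sum_a = c2(conf.sum(axis=1)).sum()
    sum_b = c2(conf.sum(axis=0)).sum()
    total = c2(N)
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


# ---------------------------------------------------------------------------
# double k-means baseline
# ---------------------------------------------------------------------------

def double_kmeans(data: CurveMatrix, K: int, L: int, seed=None
                  ) -> BlockPartition:
    """Independent k-means on row and column profiles, crossed into blocks."""
    from .engine import init_partitions
    return init_partitions(data, K, L, method="kmeans", seed=seed)


# ---------------------------------------------------------------------------
# benchmark harness
# ---------------------------------------------------------------------------

def _fit_tdlbm(sim: SimulatedData, spec: ScenarioSpec, control, seed: int
               ) -> BlockPartition:
    from .estimators import TimeDependentLBM
    params = dict(control or {})
    est = TimeDependentLBM(
        n_row_clusters=spec.K_true, n_col_clusters=spec.L_true,
        random_effects=spec.config.name, random_state=seed, **params)
    est.fit(sim.data)
    return BlockPartition(est.row_labels_, est.column_labels_,
                          spec.K_true, spec.L_true)


def run_benchmark(scenario: ScenarioSpec, B: int, methods=("tdlbm", "kmeans"),
                  fit_controls=None, seed=None) -> pd.DataFrame:
    """Monte Carlo CARI study with (K, L) fixed at the truth.

    ``methods`` may contain "tdlbm", "kmeans", or callables
    ``f(sim, scenario, seed) -> BlockPartition``.  Returns one row per
    method with the mean, SD and standard error of CARI against the truth,
    plus the number of failed replicates (excluded from the summaries).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    master = np.random.default_rng(seed if seed is not None else scenario.seed)
    rep_seeds = master.integers(2 ** 31 - 1, size=B)
    scores = {m: [] for m in methods}
    failures = {m: 0 for m in methods}
    for b in range(B):
        rng = np.random.default_rng(rep_seeds[b])
        sim = simulate_dataset(scenario, rng)
        for m in methods:
            try:
                if m == "tdlbm":
                    part = _fit_tdlbm(sim, scenario, fit_controls,
                                      int(rep_seeds[b]))
                elif m == "kmeans":
                    part = double_kmeans(sim.data, scenario.K_true,
                                         scenario.L_true,
                                         seed=int(rep_seeds[b]))
                else:
                    part = m(sim, scenario, int(rep_seeds[b]))
                scores[m].append(cari(part, sim.truth))
            except Exception:  # noqa: BLE001 - replicate failures recorded
                failures[m] += 1
    rows = []
    for m in methods:
        name = m if isinstance(m, str) else getattr(m, "__name__", "custom")
        s = np.asarray(scores[m])
        rows.append({
            "method": name,
            "B": len(s),
            "cari_mean": s.mean() if s.size else np.nan,
            "cari_sd": s.std(ddof=1) if s.size > 1 else 0.0,
            "cari_se": (s.std(ddof=1) / np.sqrt(s.size)) if s.size > 1 else 0.0,
            "failures": failures[m],
        })
    return pd.DataFrame(rows)


def config_selection_rates(scenario: ScenarioSpec, B: int, configs=None,
                           fit_controls=None, seed=None) -> pd.DataFrame:
    """Per replicate, fit all configurations at the true (K, L) and select
    by ICL; returns the selection rate of each configuration."""
    from .basis import BasisSpec
    from .engine import MSEMControl
    from .selection import model_search
    from .effects import ALL_CONFIGS
    configs = list(configs) if configs is not None else [c.name for c in ALL_CONFIGS]
    master = np.random.default_rng(seed if seed is not None else scenario.seed)
    rep_seeds = master.integers(2 ** 31 - 1, size=B)
    params = dict(fit_controls or {})
    counts = {c if isinstance(c, str) else c.name: 0 for c in configs}
    for b in range(B):
        rng = np.random.default_rng(rep_seeds[b])
        sim = simulate_dataset(scenario, rng)
        spec = _default_basis_for(scenario)
        ctrl = MSEMControl(seed=int(rep_seeds[b]), **params)
        cards = model_search(sim.data, [scenario.K_true], [scenario.L_true],
                             configs, spec, ctrl)
        counts[cards[0].config.name] += 1
    return pd.DataFrame([{"config": c, "rate": counts[c] / B}
                         for c in counts])


def kl_selection_rates(scenario: ScenarioSpec, B: int, K_range, L_range,
                       fit_controls=None, seed=None) -> pd.DataFrame:
    """Per replicate, fit the (K, L) grid at the generative configuration
    and select by ICL; returns selection rates per pair."""
    from .engine import MSEMControl
    from .selection import model_search
    master = np.random.default_rng(seed if seed is not None else scenario.seed)
    rep_seeds = master.integers(2 ** 31 - 1, size=B)
    params = dict(fit_controls or {})
    counts = {}
    for b in range(B):
        rng = np.random.default_rng(rep_seeds[b])
        sim = simulate_dataset(scenario, rng)
        spec = _default_basis_for(scenario)
        ctrl = MSEMControl(seed=int(rep_seeds[b]), **params)
        cards = model_search(sim.data, K_range, L_range,
                             [scenario.config.name], spec, ctrl)
        key = (cards[0].K, cards[0].L)
        counts[key] = counts.get(key, 0) + 1
    return pd.DataFrame([{"K": k, "L": l, "rate": c / B}
                         for (k, l), c in sorted(counts.items())])


def _default_basis_for(scenario: ScenarioSpec):
    from .basis import BasisSpec
    sd3 = float(np.sqrt(max(scenario.sigma_alpha[2, 2], 0.0)))
    pad = 3.0 * sd3 if scenario.config.on_timeshift and sd3 > 0 else 0.0
    return BasisSpec.equispaced(n_interior=16, degree=3, domain=(0.0, 1.0),
                                pad=pad)
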