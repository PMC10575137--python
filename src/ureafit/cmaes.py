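"""Covariance Matrix Adaptation Evolution Strategy (CMA-ES).

A self-contained, bounded black-box minimizer. Each generation samples
``lambda`` candidates from a multivariate normal ``N(m, sigma^2 C)``, ranks
them by objective value, and adapts the mean, the global step size
``sigma`` (via the conjugate evolution path ``p_sigma``) and the covariance
matrix ``C`` (via the path ``p_c`` for the rank-one term plus a rank-mu
term over the selected steps).

Update rules, in the order applied each generation:

    m       <- m + sigma * ybar,         ybar = sum_i w_i y_{i:lambda}
    p_sigma <- (1-c_sigma) p_sigma
               + sqrt(c_sigma (2-c_sigma) mu_w) C^{-1/2} ybar
    sigma   <- sigma * exp((c_sigma/d_sigma) (||p_sigma||/chi_n - 1))
    p_c     <- (1-c_c) p_c + sqrt(c_c (2-c_c) mu_w) ybar
    C       <- (1-c_1-c_mu) C + c_1 p_c p_c^T
               + c_mu sum_i w_i y_{i:lambda} y_{i:lambda}^T

``C^{-1/2}`` is the symmetric inverse square root, recomputed by
eigendecomposition every generation (cheap at the dimensions this package
targets). The stall indicator (h_sigma) of canonical CMA-ES is deliberately
omitted: the update equations are applied exactly as written above; see the
methods note for the consequences of this simplification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "StrategyParameters",
    "EvolutionState",
    "ObjectiveSpec",
    "OptimizeResult",
    "default_parameters",
    "sample_population",
    "rank_and_select",
    "update_mean",
    "update_step_size",
    "update_covariance",
    "minimize",
]

_SYM_TOL = 1e-10
_RESAMPLE_LIMIT = 10


@dataclass(frozen=True)
class StrategyParameters:
    """Fixed strategy constants for one optimization run.

    ``mu_w`` (variance-effective selection mass) is ``1 / sum(w_i^2)``;
    ``chi_n`` approximates ``E||N(0, I_n)||``.
    """

    n: int
    lam: int
    mu: int
    weights: np.ndarray
    mu_w: float
    c_sigma: float
    d_sigma: float
    c_c: float
    c_1: float
    c_mu: float
    chi_n: float

    def __post_init__(self) -> None:
        if not (1 <= self.mu <= self.lam):
            raise ValueError("need 1 <= mu <= lambda")
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (self.mu,):
            raise ValueError("need exactly mu weights")
        if np.any(w <= 0) or np.any(np.diff(w) > 0):
            raise ValueError("weights must be positive and non-increasing")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")
        if not (0 < self.c_sigma <= 1 and 0 < self.c_c <= 1):
            raise ValueError("cumulation rates must lie in (0, 1]")
        if self.c_1 + self.c_mu > 1:
            raise ValueError("c_1 + c_mu must not exceed 1")


def default_parameters(n: int, lam: int | None = None, mu: int | None = None) -> StrategyParameters:
    """Standard strategy constants for dimension ``n``.

    lambda defaults to ``4 + floor(3 ln n)`` and mu to ``lambda // 2`` with
    log-rank weights ``w_i ∝ ln(mu + 1/2) - ln(i)``; learning rates are
    ``c_sigma = c_c = 4/n``, ``c_1 = 2/n^2``, ``c_mu = min(mu_w/n^2,
    1 - c_1)`` and damping ``d_sigma = 1 + sqrt(mu_w/n)``. With these
    weights ``mu_w ≈ 0.3 lambda``.
    """
    if n < 1:
        raise ValueError("dimension must be >= 1")
    if lam is None:
        lam = 4 + int(math.floor(3 * math.log(n))) if n > 1 else 4
    if lam < 2:
        raise ValueError("population size must be >= 2")
    if mu is None:
        mu = lam // 2
    raw = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    weights = raw / raw.sum()
    mu_w = 1.0 / float(np.sum(weights**2))
    c_sigma = min(4.0 / n, 1.0)
    c_c = min(4.0 / n, 1.0)
    c_1 = 2.0 / n**2
    c_mu = min(mu_w / n**2, 1.0 - c_1)
    d_sigma = 1.0 + math.sqrt(mu_w / n)
    chi_n = math.sqrt(n) * (1.0 - 1.0 / (4.0 * n) + 1.0 / (21.0 * n**2))
    return StrategyParameters(
        n=n, lam=lam, mu=mu, weights=weights, mu_w=mu_w,
        c_sigma=c_sigma, d_sigma=d_sigma, c_c=c_c, c_1=c_1, c_mu=c_mu,
        chi_n=chi_n,
    )


@dataclass
class EvolutionState:
    """Mutable search-distribution state: mean, step size, covariance, paths."""

    m: np.ndarray
    sigma: float
    C: np.ndarray
    p_sigma: np.ndarray
    p_c: np.ndarray
    generation: int = 0
    evaluations: int = 0
    best_x: np.ndarray | None = None
    best_f: float = math.inf

    @classmethod
    def initial(cls, m0: Sequence[float], sigma0: float) -> "EvolutionState":
        """Fresh state: C = I, p_c = 0, p_sigma = 0."""
        m = np.asarray(m0, dtype=float).copy()
        if sigma0 <= 0:
            raise ValueError("initial step size must be positive")
        n = m.size
        return cls(m=m, sigma=float(sigma0), C=np.eye(n),
                   p_sigma=np.zeros(n), p_c=np.zeros(n))

    def _factorize(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigendecomposition of C; raises on loss of positive definiteness.

        Eigenvalues within float roundoff of zero (relative to the largest)
        are clamped to a tiny positive floor; a genuinely negative spectrum
        is treated as state corruption.
        """
        if np.max(np.abs(self.C - self.C.T)) > _SYM_TOL:
            raise RuntimeError("covariance matrix lost symmetry")
        eigval, eigvec = np.linalg.eigh(self.C)
        top = float(eigval[-1])
        if top <= 0 or float(eigval[0]) < -1e-12 * top:
            raise RuntimeError(
                f"covariance matrix not positive definite (min eig {eigval[0]:.3g})"
            )
        eigval = np.maximum(eigval, 1e-30 * top)
        return eigval, eigvec


@dataclass(frozen=True)
class ObjectiveSpec:
    """A bounded minimization problem with an evaluation budget."""

    objective: Callable[[np.ndarray], float]
    bounds: np.ndarray  # shape (n, 2)
    budget: int
    f_tol: float = 1e-12  # best-value stagnation threshold
    stagnation_generations: int = 50
    sigma_tol: float = 1e-14

    def __post_init__(self) -> None:
        b = np.asarray(self.bounds, dtype=float)
        if b.ndim != 2 or b.shape[1] != 2:
            raise ValueError("bounds must have shape (n, 2)")
        if np.any(b[:, 0] >= b[:, 1]):
            raise ValueError("each lower bound must be below its upper bound")
        object.__setattr__(self, "bounds", b)
        if self.budget <= 0:
            raise ValueError("evaluation budget must be positive")

    @property
    def n(self) -> int:
        return self.bounds.shape[0]


def sample_population(
    state: EvolutionState,
    params: StrategyParameters,
    rng: np.random.Generator,
    bounds: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``lambda`` candidates ``x_i = m + sigma y_i``, ``y_i ~ N(0, C)``.

    Returns ``(X, Y)`` with shapes (lambda, n). An out-of-bounds candidate
    is redrawn up to 10 times, then clamped to the boundary (its ``y``
    recomputed so the update equations stay consistent with ``x``).
    """
    eigval, eigvec = state._factorize()
    sqrt_ev = np.sqrt(eigval)

    def draw() -> np.ndarray:
        z = rng.standard_normal(params.n)
        return eigvec @ (sqrt_ev * z)

    X = np.empty((params.lam, params.n))
    Y = np.empty((params.lam, params.n))
    for i in range(params.lam):
        y = draw()
        x = state.m + state.sigma * y
        if bounds is not None:
            for _ in range(_RESAMPLE_LIMIT):
                if np.all(x >= bounds[:, 0]) and np.all(x <= bounds[:, 1]):
                    break
                y = draw()
                x = state.m + state.sigma * y
            else:
                x = np.clip(x, bounds[:, 0], bounds[:, 1])
                if state.sigma > 0:
                    y = (x - state.m) / state.sigma
        X[i] = x
        Y[i] = y
    return X, Y


def rank_and_select(
    Y: np.ndarray, values: Sequence[float], params: StrategyParameters
) -> tuple[np.ndarray, np.ndarray]:
    """Stable ascending sort by value; returns (order, ybar).

    ``order`` indexes all lambda candidates best-first (ties broken by
    candidate index); ``ybar`` is the weighted mean of the best mu steps.
    NaN objective values are rejected by name.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (params.lam,):
        raise ValueError("need exactly lambda objective values")
    nan = np.flatnonzero(np.isnan(values))
    if nan.size:
        raise ValueError(f"objective returned NaN for candidate {int(nan[0])}")
    order = np.argsort(values, kind="stable")
    y_bar = params.weights @ Y[order[: params.mu]]
    return order, y_bar


def update_mean(state: EvolutionState, y_bar: np.ndarray, params: StrategyParameters) -> np.ndarray:
    """``m <- m + sigma * ybar``; returns the new mean (state updated in place)."""
    state.m = state.m + state.sigma * y_bar
    return state.m


def update_step_size(
    state: EvolutionState, y_bar: np.ndarray, params: StrategyParameters
) -> None:
    """Cumulate ``p_sigma`` with ``C^{-1/2} ybar``, then rescale ``sigma``."""
    eigval, eigvec = state._factorize()
    c_inv_half = eigvec @ ((1.0 / np.sqrt(eigval))[:, None] * eigvec.T)
    cs = params.c_sigma
    state.p_sigma = (1 - cs) * state.p_sigma + math.sqrt(
        cs * (2 - cs) * params.mu_w
    ) * (c_inv_half @ y_bar)
    state.sigma *= math.exp(
        (cs / params.d_sigma)
        * (float(np.linalg.norm(state.p_sigma)) / params.chi_n - 1.0)
    )


def update_covariance(
    state: EvolutionState,
    y_bar: np.ndarray,
    y_selected: np.ndarray,
    params: StrategyParameters,
) -> None:
    """Rank-one (via ``p_c``) plus rank-mu covariance update; re-symmetrized."""
    cc = params.c_c
    state.p_c = (1 - cc) * state.p_c + math.sqrt(cc * (2 - cc) * params.mu_w) * y_bar
    rank_mu = (params.weights[:, None] * y_selected).T @ y_selected
    C = (
        (1 - params.c_1 - params.c_mu) * state.C
        + params.c_1 * np.outer(state.p_c, state.p_c)
        + params.c_mu * rank_mu
    )
    state.C = (C + C.T) / 2.0


@dataclass(frozen=True)
class OptimizeResult:
    """Outcome of :func:`minimize` with a per-generation trace."""

    x: np.ndarray
    fun: float
    evaluations: int
    generations: int
    stop_reason: str
    trace: list[dict] = field(default_factory=list)


def minimize(
    spec: ObjectiveSpec,
    params: StrategyParameters | None = None,
    seed: int | np.random.Generator = 0,
    m0: Sequence[float] | None = None,
    sigma0: float | None = None,
) -> OptimizeResult:
    """Run CMA-ES on a bounded problem until budget, stagnation or collapse.

    Defaults: ``m0`` at the centre of the bounds box and ``sigma0`` a
    quarter of the largest bound width. Deterministic given ``seed``.
    """
    if params is None:
        params = default_parameters(spec.n)
    if m0 is None:
        m0 = spec.bounds.mean(axis=1)
    if sigma0 is None:
        sigma0 = float(np.max(spec.bounds[:, 1] - spec.bounds[:, 0])) / 4.0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = EvolutionState.initial(m0, sigma0)

    trace: list[dict] = []
    stop_reason = "budget"
    stagnant = 0
    last_best = math.inf
    while state.evaluations < spec.budget:
        X, Y = sample_population(state, params, rng, spec.bounds)
        values = np.array([spec.objective(x) for x in X], dtype=float)
        state.evaluations += params.lam
        order, y_bar = rank_and_select(Y, values, params)
        gen_best = int(order[0])
        if values[gen_best] < state.best_f:
            state.best_f = float(values[gen_best])
            state.best_x = X[gen_best].copy()
        update_mean(state, y_bar, params)
        update_step_size(state, y_bar, params)
        update_covariance(state, y_bar, Y[order[: params.mu]], params)
        state.generation += 1
        trace.append(
            {
                "generation": state.generation,
                "evals": state.evaluations,
                "best_value": state.best_f,
                "sigma": state.sigma,
            }
        )
        if last_best - state.best_f < spec.f_tol:
            stagnant += 1
        else:
            stagnant = 0
        last_best = state.best_f
        if stagnant >= spec.stagnation_generations:
            stop_reason = "stagnation"
            break
        if state.sigma < spec.sigma_tol:
            stop_reason = "sigma_collapse"
            break

    assert state.best_x is not None, "no evaluations performed"
    return OptimizeResult(
        x=state.best_x,
        fun=state.best_f,
        evaluations=state.evaluations,
        generations=state.generation,
        stop_reason=stop_reason,
        trace=trace,
    )
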