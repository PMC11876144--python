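"""Hyperparameter search strategies over a shared search-space abstraction.

Three maximizers with a common ``OptResult`` contract:

* :func:`random_search` — independent uniform draws (log-uniform on log-scaled
  parameters).
* :func:`pso_optimize` — canonical particle swarm with inertia/cognitive/social
  update, positions clipped to bounds; numeric parameters only.
* :func:`bayes_optimize` — Gaussian-process surrogate (Matérn kernel) with
  expected-improvement acquisition over a sampled candidate pool.

All three are deterministic under a fixed seed and record every evaluation in
``history``, so the running best is monotone in the budget by construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern

logger = logging.getLogger(__name__)

Params = dict[str, Any]
Objective = Callable[[Params], float]


@dataclass(frozen=True)
class Param:
    """One search dimension: integer/real with bounds, or categorical choices."""

    name: str
    kind: str  # "integer" | "real" | "categorical"
    low: float | None = None
    high: float | None = None
    choices: tuple | None = None
    scale: str = "linear"  # "linear" | "log"

    def __post_init__(self) -> None:
        if self.kind not in ("integer", "real", "categorical"):
            raise ValueError(f"unknown parameter kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.choices:
                raise ValueError(f"{self.name}: choices must be non-empty")
        else:
            if self.low is None or self.high is None:
                raise ValueError(f"{self.name}: bounds required")
            if not (math.isfinite(self.low) and math.isfinite(self.high)):
                raise ValueError(f"{self.name}: bounds must be finite")
            if not self.low < self.high:
                raise ValueError(f"{self.name}: need low < high")
            if self.scale == "log" and self.low <= 0:
                raise ValueError(f"{self.name}: log scale needs positive bounds")

    # -- continuous embedding used by PSO / BO ---------------------------

    def to_unit(self, value: float) -> float:
        lo, hi = self._t(self.low), self._t(self.high)
        return (self._t(value) - lo) / (hi - lo)

    def from_unit(self, z: float) -> float | int:
        lo, hi = self._t(self.low), self._t(self.high)
        v = lo + float(np.clip(z, 0.0, 1.0)) * (hi - lo)
        if self.scale == "log":
            v = math.exp(v)
        if self.kind == "integer":
            return int(round(np.clip(v, self.low, self.high)))
        return float(np.clip(v, self.low, self.high))

    def _t(self, v: float) -> float:
        return math.log(v) if self.scale == "log" else float(v)

    def sample(self, rng: np.random.Generator):
        if self.kind == "categorical":
            return self.choices[rng.integers(len(self.choices))]
        return self.from_unit(rng.uniform())


@dataclass
class SearchSpace:
    params: list[Param]

    def __post_init__(self) -> None:
        names = [p.name for p in self.params]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names in search space")

    @property
    def numeric(self) -> bool:
        return all(p.kind != "categorical" for p in self.params)

    def sample(self, rng: np.random.Generator) -> Params:
        return {p.name: p.sample(rng) for p in self.params}

    def contains(self, params: Params) -> bool:
        for p in self.params:
            v = params[p.name]
            if p.kind == "categorical":
                if v not in p.choices:
                    return False
            elif not p.low <= v <= p.high:
                return False
        return True

    def midpoint(self) -> Params:
        """Center of the space (geometric center on log scales); categorical
        parameters take their first choice."""
        out = {}
        for p in self.params:
            out[p.name] = p.choices[0] if p.kind == "categorical" else p.from_unit(0.5)
        return out

    def decode_unit(self, z: np.ndarray) -> Params:
        return {p.name: p.from_unit(zi) for p, zi in zip(self.params, z)}


@dataclass
class OptResult:
    best_params: Params
    best_objective: float
    history: list[tuple[Params, float]] = field(default_factory=list)


def _safe_eval(objective: Objective, params: Params) -> float:
    try:
        v = float(objective(params))
        if math.isnan(v):
            return -math.inf
        return v
    except Exception as exc:  # noqa: BLE001 - a failed draw must not kill the search
        logger.warning("objective failed on %s: %s", params, exc)
        return -math.inf


def _result(history: list[tuple[Params, float]]) -> OptResult:
    best_i = int(np.argmax([h[1] for h in history]))
    return OptResult(
        best_params=history[best_i][0],
        best_objective=history[best_i][1],
        history=history,
    )


def random_search(
    objective: Objective, space: SearchSpace, n_iter: int, rng: np.random.Generator | int
) -> OptResult:
    """Maximize by ``n_iter`` independent uniform draws from the space."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    history = []
    for _ in range(n_iter):
        params = space.sample(rng)
        history.append((params, _safe_eval(objective, params)))
    return _result(history)


def pso_optimize(
    objective: Objective,
    space: SearchSpace,
    n_particles: int = 10,
    n_iter: int = 20,
    inertia: float = 0.72,
    c1: float = 1.49,
    c2: float = 1.49,
    rng: np.random.Generator | int = 0,
    init_positions: np.ndarray | None = None,
) -> OptResult:
    """Canonical particle swarm in the unit-cube embedding of the space.

    Velocity update ``v <- inertia*v + c1*r1*(pbest - x) + c2*r2*(gbest - x)``,
    positions clipped to [0, 1]^d (i.e. the parameter bounds).  Integer and
    log-scaled parameters are handled by the embedding; categorical parameters
    are rejected.  ``init_positions`` (unit coordinates) overrides the random
    initialization; initial velocities are zero, so a swarm started exactly at
    an optimum stays there.
    """
    if not space.numeric:
        raise ValueError("pso_optimize supports integer/real parameters only")
    if n_particles < 2:
        raise ValueError("n_particles must be >= 2")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    d = len(space.params)

    x = (
        np.clip(np.asarray(init_positions, dtype=float), 0.0, 1.0)
        if init_positions is not None
        else rng.uniform(size=(n_particles, d))
    )
    v = np.zeros_like(x)
    history: list[tuple[Params, float]] = []

    def evaluate(row: np.ndarray) -> float:
        params = space.decode_unit(row)
        val = _safe_eval(objective, params)
        history.append((params, val))
        return val

    pbest = x.copy()
    pbest_val = np.array([evaluate(row) for row in x])
    g = int(np.argmax(pbest_val))
    gbest, gbest_val = pbest[g].copy(), pbest_val[g]

    for _ in range(n_iter):
        r1 = rng.uniform(size=(n_particles, d))
        r2 = rng.uniform(size=(n_particles, d))
        v = inertia * v + c1 * r1 * (pbest - x) + c2 * r2 * (gbest - x)
        x = np.clip(x + v, 0.0, 1.0)
        vals = np.array([evaluate(row) for row in x])
        improved = vals > pbest_val
        pbest[improved] = x[improved]
        pbest_val[improved] = vals[improved]
        g = int(np.argmax(pbest_val))
        if pbest_val[g] > gbest_val:
            gbest, gbest_val = pbest[g].copy(), pbest_val[g]
    return _result(history)


def _expected_improvement(mu: np.ndarray, sigma: np.ndarray, best: float) -> np.ndarray:
    sigma = np.maximum(sigma, 1e-12)
    z = (mu - best) / sigma
    return (mu - best) * stats.norm.cdf(z) + sigma * stats.norm.pdf(z)


def bayes_optimize(
    objective: Objective,
    space: SearchSpace,
    n_init: int = 5,
    n_iter: int = 20,
    rng: np.random.Generator | int = 0,
    n_candidates: int = 512,
) -> OptResult:
    """GP-surrogate Bayesian optimization with expected improvement.

    ``n_init`` uniform evaluations seed the history; each subsequent round
    fits a Gaussian process (Matérn 5/2) to all unit-cube points with finite
    objective and evaluates the candidate with maximal expected improvement
    among ``n_candidates`` uniform draws.  A surrogate failure falls back to a
    random proposal for that round.  ``len(history) == n_init + n_iter``.
    """
    if n_init < 2:
        raise ValueError("n_init must be >= 2")
    if not space.numeric:
        raise ValueError("bayes_optimize supports integer/real parameters only")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    d = len(space.params)

    history: list[tuple[Params, float]] = []
    X_unit: list[np.ndarray] = []

    def evaluate(z: np.ndarray) -> None:
        params = space.decode_unit(z)
        history.append((params, _safe_eval(objective, params)))
        X_unit.append(np.asarray(z, dtype=float))

    for _ in range(n_init):
        evaluate(rng.uniform(size=d))

    for _ in range(n_iter):
        y = np.array([h[1] for h in history])
        finite = np.isfinite(y)
        z_next = None
        if finite.sum() >= 2:
            try:
                import warnings

                gp = GaussianProcessRegressor(
                    kernel=ConstantKernel(1.0) * Matern(length_scale=np.full(d, 0.2), nu=2.5),
                    alpha=1e-6,
                    normalize_y=True,
                    random_state=int(rng.integers(2**31)),
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    gp.fit(np.vstack(X_unit)[finite], y[finite])
                cand = rng.uniform(size=(n_candidates, d))
                mu, sigma = gp.predict(cand, return_std=True)
                ei = _expected_improvement(mu, sigma, float(y[finite].max()))
                z_next = cand[int(np.argmax(ei))]
            except Exception as exc:  # noqa: BLE001
                logger.warning("GP surrogate failed (%s); random proposal", exc)
        if z_next is None:
            z_next = rng.uniform(size=d)
        evaluate(z_next)
    return _result(history)
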