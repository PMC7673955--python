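"""Hyperparameter tuning: Bayesian optimization and grid search.

The tuner minimizes a black-box objective (here typically the negated
cross-validated F-measure of the classifier) over a mixed real / integer /
categorical space. Bayesian optimization fits a Gaussian-process surrogate
(Matérn 5/2 kernel with per-dimension length scales plus observation
noise, hyperparameters fit by marginal-likelihood maximization) to the
observations and proposes the candidate maximizing Expected Improvement

    γ(x)    = (f(x_best) − μ(x)) / σ(x)
    a_PI(x) = Φ(γ(x))
    a_EI(x) = σ(x) · (γ(x)·Φ(γ(x)) + φ(γ(x)))

where f(x_best) is the lowest observed objective value and Φ, φ are the
standard normal CDF and PDF. At σ = 0 the limits apply: a_EI =
max(f_best − μ, 0) and a_PI is 1 or 0 by the sign of the improvement.

Acquisition maximization uses seeded random candidate sampling (2048
candidates per round) — simple, reproducible, and adequate for spaces of
this dimensionality. Integer parameters are sampled on their grid and
rounded inside the GP's unit-cube encoding; categoricals are one-hot
encoded.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel


@dataclass(frozen=True)
class Param:
    """One search dimension: real (optionally log-scaled), integer, or
    categorical."""

    name: str
    kind: str  # "real" | "integer" | "categorical"
    low: float | None = None
    high: float | None = None
    choices: tuple = ()
    log: bool = False

    def __post_init__(self) -> None:
        if self.kind in ("real", "integer"):
            if self.low is None or self.high is None or self.low >= self.high:
                raise ValueError(f"{self.name}: bounds must satisfy low < high")
            if self.log and self.low <= 0:
                raise ValueError(f"{self.name}: log scale requires low > 0")
        elif self.kind == "categorical":
            if not self.choices:
                raise ValueError(f"{self.name}: empty choice list")
        else:
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")

    def sample(self, rng: np.random.Generator):
        if self.kind == "categorical":
            return self.choices[rng.integers(len(self.choices))]
        if self.kind == "integer":
            return int(rng.integers(int(self.low), int(self.high) + 1))
        if self.log:
            return float(np.exp(rng.uniform(math.log(self.low), math.log(self.high))))
        return float(rng.uniform(self.low, self.high))

    def contains(self, value) -> bool:
        if self.kind == "categorical":
            return value in self.choices
        return self.low <= value <= self.high


@dataclass(frozen=True)
class HyperparameterSpace:
    params: tuple[Param, ...]

    def __post_init__(self) -> None:
        names = [p.name for p in self.params]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names")

    def sample(self, rng: np.random.Generator) -> dict:
        return {p.name: p.sample(rng) for p in self.params}

    def contains(self, point: dict) -> bool:
        return all(p.contains(point[p.name]) for p in self.params)

    def encode(self, point: dict) -> np.ndarray:
        """Map a point to the GP's representation: reals/integers scaled to
        [0, 1] (log-scaled where declared), categoricals one-hot."""
        parts: list[float] = []
        for p in self.params:
            v = point[p.name]
            if p.kind == "categorical":
                parts.extend(1.0 if v == c else 0.0 for c in p.choices)
            elif p.log:
                parts.append((math.log(v) - math.log(p.low))
                             / (math.log(p.high) - math.log(p.low)))
            else:
                parts.append((v - p.low) / (p.high - p.low))
        return np.array(parts)


def default_space(num_leaves_min: int = 2) -> HyperparameterSpace:
    """The classifier search space used for succinylation-site tuning.

    Ranges: learning_rate (0.01, 1.0); max_depth (1, 50); max_bin
    (10, 100); reg_alpha (1e-9, 1.0), log-scaled; boosting_type in
    {gbdt, goss, rf, dart}; num_leaves (1, 50); n_estimators (100, 600).
    A num_leaves lower bound below 2 is meaningless for leaf-wise trees
    and is clamped with a warning.
    """
    if num_leaves_min < 2:
        warnings.warn("num_leaves lower bound clamped to 2 (a tree needs >= 2 leaves)")
        num_leaves_min = 2
    return HyperparameterSpace((
        Param("learning_rate", "real", 0.01, 1.0),
        Param("max_depth", "integer", 1, 50),
        Param("max_bin", "integer", 10, 100),
        Param("reg_alpha", "real", 1e-9, 1.0, log=True),
        Param("boosting_type", "categorical", choices=("gbdt", "goss", "rf", "dart")),
        Param("num_leaves", "integer", num_leaves_min, 50),
        Param("n_estimators", "integer", 100, 600),
    ))


@dataclass(frozen=True)
class AcquisitionEval:
    gamma: float
    pi: float
    ei: float


def acquisition(mu: float, sigma: float, f_best: float) -> AcquisitionEval:
    """PI and EI of a candidate under a Gaussian posterior (minimization)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    improvement = f_best - mu
    if sigma == 0.0:
        if improvement > 0:
            return AcquisitionEval(gamma=math.inf, pi=1.0, ei=improvement)
        return AcquisitionEval(gamma=(-math.inf if improvement < 0 else 0.0),
                               pi=0.0, ei=0.0)
    gamma = improvement / sigma
    pi = float(norm.cdf(gamma))
    ei = float(sigma * (gamma * norm.cdf(gamma) + norm.pdf(gamma)))
    return AcquisitionEval(gamma=gamma, pi=pi, ei=ei)


@dataclass
class SurrogateState:
    """Observations and fitted GP posterior over the encoded space."""

    X: list[dict] = field(default_factory=list)
    y: list[float] = field(default_factory=list)
    gp: GaussianProcessRegressor | None = None

    @property
    def f_best(self) -> float:
        return min(self.y)

    @property
    def incumbent(self) -> dict:
        return self.X[int(np.argmin(self.y))]


@dataclass(frozen=True)
class BOResult:
    best_point: dict
    best_value: float
    points: tuple[dict, ...]
    values: tuple[float, ...]

    @property
    def incumbent_trace(self) -> tuple[float, ...]:
        return tuple(np.minimum.accumulate(self.values))


def _fit_gp(space: HyperparameterSpace, state: SurrogateState, seed: int) -> None:
    Xe = np.array([space.encode(p) for p in state.X])
    y = np.array(state.y)
    kernel = (
        ConstantKernel(1.0, (1e-3, 1e3))
        * Matern(length_scale=np.ones(Xe.shape[1]),
                 length_scale_bounds=(1e-2, 1e2), nu=2.5)
        + WhiteKernel(noise_level=1e-6, noise_level_bounds=(1e-10, 1e-1))
    )
    gp = GaussianProcessRegressor(
        kernel=kernel, normalize_y=True, n_restarts_optimizer=2,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        gp.fit(Xe, y)
    state.gp = gp


def bo_minimize(objective, space: HyperparameterSpace, n_init: int = 10,
                n_iter: int = 50, seed: int = 0,
                n_candidates: int = 2048,
                acquisition_name: str = "ei") -> BOResult:
    """Minimize a black-box objective by GP-based Bayesian optimization.

    ``n_init`` seeded random evaluations, then ``n_iter`` rounds of
    fit-GP / maximize-acquisition / evaluate. Pass a maximization problem
    by negating its objective.
    """
    if n_init < 2:
        raise ValueError("n_init must be >= 2 (GP unfittable otherwise)")
    if acquisition_name not in ("ei", "pi"):
        raise ValueError(f"unknown acquisition {acquisition_name!r}")
    rng = np.random.default_rng(seed)
    state = SurrogateState()
    for _ in range(n_init):
        point = space.sample(rng)
        state.X.append(point)
        state.y.append(float(objective(point)))

    for round_idx in range(n_iter):
        _fit_gp(space, state, seed=seed + round_idx)
        candidates = [space.sample(rng) for _ in range(n_candidates)]
        Xe = np.array([space.encode(p) for p in candidates])
        mu, sigma = state.gp.predict(Xe, return_std=True)
        f_best = state.f_best
        scores = [
            getattr(acquisition(m, max(s, 0.0), f_best), acquisition_name)
            for m, s in zip(mu, sigma)
        ]
        best = candidates[int(np.argmax(scores))]
        state.X.append(best)
        state.y.append(float(objective(best)))

    i = int(np.argmin(state.y))
    return BOResult(
        best_point=state.X[i], best_value=state.y[i],
        points=tuple(state.X), values=tuple(state.y),
    )


@dataclass(frozen=True)
class GridSearchResult:
    best_point: dict
    best_value: float
    table: tuple[tuple[dict, float], ...]


def grid_search(objective, grid: dict[str, list]) -> GridSearchResult:
    """Exhaustively evaluate the cartesian product of per-parameter value
    lists; ties resolve to the first point in lexicographic grid order."""
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must list at least one value per parameter")
    names = list(grid.keys())
    table: list[tuple[dict, float]] = []
    best_point, best_value = None, math.inf
    for combo in itertools.product(*(grid[n] for n in names)):
        point = dict(zip(names, combo))
        value = float(objective(point))
        table.append((point, value))
        if value < best_value:
            best_point, best_value = point, value
    return GridSearchResult(best_point=best_point, best_value=best_value,
                            table=tuple(table))


def cv_fitness_objective(X, y, k: int = 10, seed: int = 0,
                         metric: str = "f_measure"):
    """Objective factory: negated cross-validated fitness of the classifier
    built from a hyperparameter point (lower is better)."""
    from .evaluation import cross_validate, default_classifier

    def objective(point: dict) -> float:
        params = dict(point)
        if params.get("boosting_type") == "rf":
            # random-forest mode requires bagging to be enabled
            params.setdefault("subsample", 0.8)
            params.setdefault("subsample_freq", 1)
        clf = default_classifier(seed=seed, **params)
        res = cross_validate(X, y, classifier=clf, k=k, seed=seed)
        return -res.pooled[metric]

    return objective
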