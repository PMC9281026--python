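"""Equilibrium Optimizer (EO) and SAE hyperparameter tuning.

EO is a physics-inspired population metaheuristic modelling mass balance
in a control volume. Candidate solutions are "concentrations" C that
relax toward an equilibrium pool — the four best solutions found so far
plus their elementwise mean. Each particle update draws a pool member
C_eq, a turnover-rate vector lambda ~ U(0,1)^d, and applies

    F = a1 * sign(r - 0.5) * (exp(-lambda * t) - 1),
    t = (1 - Iter/Max_iter)^(a2 * Iter/Max_iter),
    G = GCP * (C_eq - lambda ∘ C) ∘ F,   GCP = 0.5*r1 if r2 >= GP else 0,
    C <- C_eq + (C - C_eq) ∘ F + G / (lambda * V) ∘ (1 - F),

clamped to the search box. a1 and a2 (defaults 2 and 1) trade off global
versus local search; the generation probability GP gates the
exploitation term.

The tuning objective for the classifier is the stratified k-fold (k=10
by default) cross-validated error rate on the training data: fitness =
1 - mean fold accuracy, so a perfect cross-validated classifier reaches
fitness 0. :class:`HyperSpace` maps the optimizer's box to named SAE
hyperparameters, log-scaling those that span decades and rounding
integer-valued ones.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .autoencoder import SAEClassifier, SAEConfig, TrainingDivergence
from .data import Dataset, stratified_kfold

__all__ = [
    "EOConfig",
    "EOState",
    "Dimension",
    "HyperSpace",
    "default_hyperspace",
    "initialize_population",
    "time_param",
    "exponential_term",
    "generation_rate",
    "update_concentration",
    "run_eo",
    "cv_fitness",
    "tune_sae",
]

Objective = Callable[[np.ndarray], float]
_LAMBDA_FLOOR = 1e-12  # guards the G/(lambda·V) division against a zero draw


@dataclass(frozen=True)
class EOConfig:
    """EO control parameters and the search box."""

    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    n_particles: int = 30
    max_iter: int = 100
    a1: float = 2.0
    a2: float = 1.0
    generation_prob: float = 0.5
    volume: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower_bounds, dtype=float)
        hi = np.asarray(self.upper_bounds, dtype=float)
        if lo.shape != hi.shape or lo.ndim != 1:
            raise ValueError("bounds must be 1-D vectors of equal length")
        if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
            raise ValueError("bounds must be finite")
        if np.any(lo > hi):
            raise ValueError("lower bound exceeds upper bound")
        if self.n_particles < 1 or self.max_iter < 1:
            raise ValueError("n_particles and max_iter must be positive")
        if not 0.0 <= self.generation_prob <= 1.0:
            raise ValueError("generation_prob must lie in [0, 1]")
        if self.volume <= 0:
            raise ValueError("volume must be positive")
        object.__setattr__(self, "lower_bounds", lo)
        object.__setattr__(self, "upper_bounds", hi)

    @property
    def n_dims(self) -> int:
        return self.lower_bounds.size


@dataclass
class EOState:
    """Particle concentrations, their costs, and the equilibrium pool."""

    concentrations: np.ndarray  # (n, d)
    costs: np.ndarray  # (n,)
    pool: np.ndarray  # (4, d), cost-sorted ascending
    pool_costs: np.ndarray  # (4,)
    iteration: int = 0

    @property
    def pool_mean(self) -> np.ndarray:
        return self.pool.mean(axis=0)


def _build_pool(C: np.ndarray, costs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(costs, kind="stable")[: min(4, costs.size)]
    pool = C[order]
    pool_costs = costs[order]
    while pool.shape[0] < 4:  # small populations replicate the best member
        pool = np.vstack([pool, pool[-1]])
        pool_costs = np.append(pool_costs, pool_costs[-1])
    return pool.copy(), pool_costs.copy()


def initialize_population(config: EOConfig, rng: np.random.Generator, objective: Objective) -> EOState:
    """Uniform initialisation C_i = C_min + rand_i · (C_max − C_min),
    cost evaluation, and equilibrium-pool construction."""
    span = config.upper_bounds - config.lower_bounds
    C = config.lower_bounds + rng.uniform(size=(config.n_particles, config.n_dims)) * span
    costs = np.array([float(objective(c)) for c in C])
    if not np.all(np.isfinite(costs)):
        raise ValueError("objective returned a non-finite value at initialisation")
    pool, pool_costs = _build_pool(C, costs)
    return EOState(C, costs, pool, pool_costs, iteration=0)


def time_param(iteration: int, config: EOConfig, as_printed: bool = False) -> float:
    """Iteration-dependent time t = (1 − Iter/Max_iter)^(a2·Iter/Max_iter),
    decreasing from 1 toward 0 over the run. ``as_printed`` selects the
    product form (1 − Iter/Max)·(a2·Iter/Max) instead."""
    if not 0 <= iteration <= config.max_iter:
        raise ValueError("iteration out of range")
    frac = iteration / config.max_iter
    if as_printed:
        return (1.0 - frac) * (config.a2 * frac)
    return float((1.0 - frac) ** (config.a2 * frac))


def exponential_term(
    lambda_vec: np.ndarray, t: float, config: EOConfig, rng: np.random.Generator
) -> np.ndarray:
    """F = a1 · sign(r − 0.5) · (e^(−λt) − 1), elementwise with fresh
    r ~ U(0,1) per dimension; sign(0) is taken as 0."""
    if t < 0:
        raise ValueError("t must be non-negative")
    lam = np.asarray(lambda_vec, dtype=float)
    r = rng.uniform(size=lam.shape)
    return config.a1 * np.sign(r - 0.5) * (np.exp(-lam * t) - 1.0)


def generation_rate(
    C: np.ndarray,
    C_eq: np.ndarray,
    lambda_vec: np.ndarray,
    F: np.ndarray,
    config: EOConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """G = GCP · (C_eq − λ∘C) ∘ F, where the scalar generation-rate
    control GCP is 0.5·r1 when r2 ≥ GP and 0 otherwise."""
    r1, r2 = rng.uniform(), rng.uniform()
    gcp = 0.5 * r1 if r2 >= config.generation_prob else 0.0
    G0 = gcp * (np.asarray(C_eq) - np.asarray(lambda_vec) * np.asarray(C))
    return G0 * np.asarray(F)


def update_concentration(
    C: np.ndarray,
    C_eq: np.ndarray,
    F: np.ndarray,
    G: np.ndarray,
    lambda_vec: np.ndarray,
    config: EOConfig,
) -> np.ndarray:
    """Concentration update C_eq + (C − C_eq)∘F + G/(λV)·(1 − F),
    clamped to the search box."""
    lam = np.maximum(np.asarray(lambda_vec, dtype=float), _LAMBDA_FLOOR)
    new = (
        np.asarray(C_eq)
        + (np.asarray(C) - np.asarray(C_eq)) * np.asarray(F)
        + (np.asarray(G) / (lam * config.volume)) * (1.0 - np.asarray(F))
    )
    return np.clip(new, config.lower_bounds, config.upper_bounds)


def run_eo(
    objective: Objective, config: EOConfig
) -> tuple[np.ndarray, float, np.ndarray]:
    """Run the optimizer; returns (best point, best cost, best-cost
    history of length max_iter). The pool is updated greedily, so the
    history is non-increasing; fully reproducible from config.seed."""
    rng = np.random.default_rng(config.seed)
    state = initialize_population(config, rng, objective)
    history = np.empty(config.max_iter)
    for it in range(config.max_iter):
        t = time_param(it, config)
        for i in range(config.n_particles):
            pick = int(rng.integers(5))
            C_eq = state.pool_mean if pick == 4 else state.pool[pick]
            lam = rng.uniform(size=config.n_dims)
            F = exponential_term(lam, t, config, rng)
            G = generation_rate(state.concentrations[i], C_eq, lam, F, config, rng)
            new = update_concentration(state.concentrations[i], C_eq, F, G, lam, config)
            cost = float(objective(new))
            if not np.isfinite(cost):
                raise ValueError(f"objective returned non-finite cost at iteration {it}")
            state.concentrations[i] = new
            state.costs[i] = cost
            worst = int(state.pool_costs.argmax())
            if cost < state.pool_costs[worst]:
                state.pool[worst] = new
                state.pool_costs[worst] = cost
                order = np.argsort(state.pool_costs, kind="stable")
                state.pool = state.pool[order]
                state.pool_costs = state.pool_costs[order]
        state.iteration = it + 1
        history[it] = state.pool_costs[0]
    return state.pool[0].copy(), float(state.pool_costs[0]), history


# ---------------------------------------------------------------------------
# Hyperparameter space


@dataclass(frozen=True)
class Dimension:
    """One named search dimension with bounds, scale and rounding rule."""

    name: str
    low: float
    high: float
    scale: str = "linear"  # "linear" | "log"
    integer: bool = False

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log"):
            raise ValueError("scale must be 'linear' or 'log'")
        if self.scale == "log" and self.low <= 0:
            raise ValueError("log-scaled dimensions need positive bounds")
        if not self.low < self.high:
            raise ValueError("low must be < high")

    def encode(self, value: float) -> float:
        return float(np.log10(value)) if self.scale == "log" else float(value)

    def decode(self, x: float) -> float | int:
        v = 10.0**x if self.scale == "log" else x
        return int(round(v)) if self.integer else float(v)

    @property
    def encoded_bounds(self) -> tuple[float, float]:
        if self.scale == "log":
            return float(np.log10(self.low)), float(np.log10(self.high))
        return float(self.low), float(self.high)


# SAEConfig fields a decoded dimension may set; hidden_size expands to a
# single-layer hidden_sizes tuple.
_SCALAR_FIELDS = {
    "weight_decay",
    "sparsity_weight",
    "sparsity_target",
    "learning_rate",
    "pretrain_epochs",
    "finetune_epochs",
    "batch_size",
}


@dataclass(frozen=True)
class HyperSpace:
    """A named box over SAE hyperparameters, decodable to SAEConfig."""

    dimensions: tuple[Dimension, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "dimensions", tuple(self.dimensions))
        for d in self.dimensions:
            if d.name not in _SCALAR_FIELDS and d.name != "hidden_size":
                raise ValueError(f"unknown hyperparameter {d.name!r}")

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.dimensions]

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = zip(*(d.encoded_bounds for d in self.dimensions))
        return np.asarray(lo), np.asarray(hi)

    def decode(self, point: np.ndarray) -> dict:
        return {d.name: d.decode(float(x)) for d, x in zip(self.dimensions, point)}

    def encode(self, values: dict) -> np.ndarray:
        return np.asarray([d.encode(values[d.name]) for d in self.dimensions])

    def decode_config(self, point: np.ndarray, base: SAEConfig) -> SAEConfig:
        """Overlay the decoded point onto a base SAEConfig."""
        values = self.decode(point)
        kw = {}
        for name, v in values.items():
            if name == "hidden_size":
                kw["hidden_sizes"] = (int(v),)
            else:
                kw[name] = int(v) if name in ("pretrain_epochs", "finetune_epochs", "batch_size") else v
        return base.replace(**kw)

    def midpoint(self) -> np.ndarray:
        lo, hi = self.bounds()
        return (lo + hi) / 2.0

    @classmethod
    def from_dicts(cls, dims: Sequence[dict]) -> "HyperSpace":
        return cls(tuple(Dimension(**d) for d in dims))


def default_hyperspace() -> HyperSpace:
    """Tuning box used by the pipeline: decade-spanning rates on a log
    scale, sparsity target linear, one rounded hidden width."""
    return HyperSpace(
        (
            Dimension("weight_decay", 1e-6, 1e-2, scale="log"),
            Dimension("sparsity_weight", 1e-3, 3.0, scale="log"),
            Dimension("sparsity_target", 0.02, 0.5),
            Dimension("learning_rate", 0.01, 1.0, scale="log"),
            Dimension("hidden_size", 8, 64, integer=True),
        )
    )


def cv_fitness(
    hyper_point: np.ndarray,
    space: HyperSpace,
    dataset: Dataset,
    base_config: SAEConfig,
    k: int = 10,
    seed: int = 0,
) -> float:
    """k-fold cross-validated error of the SAE decoded from a search
    point: fitness = 1 − mean fold fraction-correct, in [0, 1].

    A training divergence inside any fold is assigned the worst fitness
    (1.0) with a warning so the surrounding search can continue.
    """
    cfg = space.decode_config(np.asarray(hyper_point, dtype=float), base_config)
    folds = stratified_kfold(dataset.labels, k, seed=seed)
    accs = []
    for f in range(k):
        train = dataset.subset_rows(folds.train_indices(f))
        test = dataset.subset_rows(folds.test_indices(f))
        try:
            clf = SAEClassifier(cfg.replace(seed=seed + f)).fit(train)
        except TrainingDivergence as exc:
            warnings.warn(f"fold {f} diverged ({exc}); assigning worst fitness")
            return 1.0
        accs.append(clf.score(test))
    return float(1.0 - np.mean(accs))


def tune_sae(
    dataset: Dataset,
    space: HyperSpace,
    eo_config: EOConfig | None = None,
    base_config: SAEConfig | None = None,
    k: int = 10,
    seed: int = 0,
) -> tuple[SAEConfig, np.ndarray, dict]:
    """EO search over the hyperparameter box with the CV-error fitness.

    Returns the decoded best configuration, the best-fitness history,
    and a report dict (decoded best values + history) suitable for JSON.
    """
    base_config = base_config or SAEConfig()
    lo, hi = space.bounds()
    if eo_config is None:
        eo_config = EOConfig(lower_bounds=lo, upper_bounds=hi, n_particles=10, max_iter=10, seed=seed)
    else:
        eo_config = dataclasses.replace(eo_config, lower_bounds=lo, upper_bounds=hi)

    def objective(point: np.ndarray) -> float:
        return cv_fitness(point, space, dataset, base_config, k=k, seed=seed)

    best_point, best_cost, history = run_eo(objective, eo_config)
    best_cfg = space.decode_config(best_point, base_config)
    report = {
        "best_fitness": best_cost,
        "best_hyperparameters": space.decode(best_point),
        "fitness_history": history.tolist(),
    }
    return best_cfg, history, report
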