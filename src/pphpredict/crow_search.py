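"""Oppositional binary crow search for wrapper feature selection.

The crow search algorithm (CSA) is a population metaheuristic in which
each crow i holds a position x_i and a memory M_i of the best position it
has found. At every step a crow follows a randomly chosen flockmate j
toward that crow's memory,

    x_i <- x_i + tau * fl * (M_j - x_i),    tau ~ U(0,1),

unless the followed crow "notices" (with awareness probability AP), in
which case the follower jumps to a fresh uniform random position. Here
positions are continuous in [0,1]^d over the feature axes and are
binarized at a strict threshold for evaluation; a feature is selected
when its coordinate exceeds the threshold.

Opposition-based learning is applied to the flight length fl: each move
is tried both with fl and with its reflection fl_min + fl_max - fl inside
the admissible range, and the cheaper candidate is kept. The wrapper cost
balances cross-validated classification accuracy against subset size:

    cost(mask) = (1 - C) + W * (|mask| / d),

lower being better, with C the evaluator's cross-validated accuracy on
the masked features and W a small parsimony weight.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from .data import Dataset

__all__ = [
    "FSConfig",
    "FlockState",
    "FSResult",
    "binarize",
    "opposite_fl",
    "crow_update",
    "fs_cost",
    "surrogate_evaluate",
    "make_surrogate_evaluator",
    "run_obcsa",
]

Evaluator = Callable[[Dataset, np.ndarray], float]


@dataclass(frozen=True)
class FSConfig:
    """Search hyperparameters. Defaults follow the standard CSA setup:
    25 crows, awareness probability 0.3, flight length in [0.1, 1.8],
    100 iterations."""

    n_crows: int = 25
    awareness_prob: float = 0.3
    fl_min: float = 0.1
    fl_max: float = 1.8
    t_max: int = 100
    subset_weight: float = 0.01
    binarize_threshold: float = 0.5
    as_printed: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_crows < 1 or self.t_max < 1:
            raise ValueError("n_crows and t_max must be positive")
        if not 0.0 <= self.awareness_prob <= 1.0:
            raise ValueError("awareness_prob must lie in [0, 1]")
        if not 0.0 < self.fl_min < self.fl_max:
            raise ValueError("require 0 < fl_min < fl_max")
        if not 0.0 <= self.subset_weight <= 1.0:
            raise ValueError("subset_weight must lie in [0, 1]")
        if not 0.0 < self.binarize_threshold < 1.0:
            raise ValueError("binarize_threshold must lie in (0, 1)")


@dataclass
class FlockState:
    """Positions, memories and memory costs of the flock at one iteration."""

    positions: np.ndarray
    memories: np.ndarray
    memory_costs: np.ndarray
    iteration: int = 0


@dataclass(frozen=True)
class FSResult:
    """Outcome of a feature-selection run."""

    best_mask: np.ndarray
    best_cost: float
    cost_history: np.ndarray
    n_selected: int

    def selected_names(self, dataset: Dataset) -> list[str]:
        return [n for n, m in zip(dataset.feature_names, self.best_mask) if m]

    def to_json(self, dataset: Dataset | None = None) -> str:
        obj = {
            "mask": self.best_mask.astype(int).tolist(),
            "best_cost": self.best_cost,
            "cost_history": self.cost_history.tolist(),
            "n_selected": self.n_selected,
        }
        if dataset is not None:
            obj["selected_features"] = self.selected_names(dataset)
        return json.dumps(obj)


def binarize(position: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Map a continuous position to a feature-inclusion mask.

    A coordinate selects its feature iff it strictly exceeds the
    threshold (an exact tie excludes)."""
    position = np.asarray(position, dtype=float)
    if not np.all(np.isfinite(position)):
        raise ValueError("position entries must be finite")
    return position > threshold


def opposite_fl(fl: float, fl_min: float = 0.1, fl_max: float = 1.8) -> float:
    """Reflect a flight length inside [fl_min, fl_max]: fl_min + fl_max - fl."""
    if not fl_min <= fl <= fl_max:
        raise ValueError(f"fl={fl} outside [{fl_min}, {fl_max}]")
    return fl_min + fl_max - fl


def _follow_step(position: np.ndarray, memory: np.ndarray, fl: float, tau: float) -> np.ndarray:
    """Deterministic core of the follow move, clamped to [0,1]."""
    return np.clip(position + tau * fl * (memory - position), 0.0, 1.0)


def crow_update(
    position: np.ndarray,
    memory: np.ndarray,
    fl: float,
    rng: np.random.Generator,
    awareness_prob: float = 0.3,
) -> np.ndarray:
    """One stochastic position update for a single crow.

    Draws theta ~ U(0,1) once; with theta >= AP the crow follows the
    memory with a fresh step size tau ~ U(0,1), otherwise it escapes to a
    uniform random position.
    """
    position = np.asarray(position, dtype=float)
    memory = np.asarray(memory, dtype=float)
    if position.shape != memory.shape:
        raise ValueError("position and memory must have the same shape")
    theta = rng.uniform()
    if theta >= awareness_prob:
        tau = rng.uniform()
        return _follow_step(position, memory, fl, tau)
    return rng.uniform(size=position.shape)


def fs_cost(
    mask: np.ndarray,
    dataset: Dataset,
    evaluator: Evaluator,
    subset_weight: float = 0.01,
    as_printed: bool = False,
) -> float:
    """Wrapper cost of a feature mask; lower is better.

    cost = (1 - C) + W * (F_sub / F_all) with C the evaluator's
    cross-validated accuracy on the masked features. An empty mask is
    infeasible and gets cost +inf. ``as_printed`` switches to the
    alternative form C + W * (1 - F_all / F_sub).
    """
    mask = np.asarray(mask, dtype=bool)
    f_sub = int(mask.sum())
    if f_sub == 0:
        return np.inf
    f_all = mask.size
    c = float(evaluator(dataset, mask))
    if as_printed:
        return c + subset_weight * (1.0 - f_all / f_sub)
    return (1.0 - c) + subset_weight * (f_sub / f_all)


def surrogate_evaluate(dataset: Dataset, mask: np.ndarray, k: int = 5, seed: int = 0) -> float:
    """Cross-validated accuracy of a cheap 1-nearest-neighbour reference
    classifier on standardized masked features.

    Serves as the classification-performance term C of the wrapper cost;
    deterministic given the seed.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("mask selects no features")
    counts = np.bincount(dataset.labels, minlength=2)
    if counts.min() < k:
        raise ValueError(f"minority class ({counts.min()}) smaller than k={k}")
    X = dataset.features[:, mask]
    y = dataset.labels
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    correct = 0
    for train_idx, test_idx in skf.split(X, y):
        mu = X[train_idx].mean(axis=0)
        sd = X[train_idx].std(axis=0)
        sd[sd == 0] = 1.0
        clf = KNeighborsClassifier(n_neighbors=1)
        clf.fit((X[train_idx] - mu) / sd, y[train_idx])
        correct += int((clf.predict((X[test_idx] - mu) / sd) == y[test_idx]).sum())
    return correct / len(y)


def make_surrogate_evaluator(k: int = 5, seed: int = 0) -> Evaluator:
    """Bind the surrogate's CV depth and seed into an Evaluator callable."""

    def _eval(dataset: Dataset, mask: np.ndarray) -> float:
        return surrogate_evaluate(dataset, mask, k=k, seed=seed)

    return _eval


def run_obcsa(
    dataset: Dataset,
    config: FSConfig,
    evaluator: Evaluator | None = None,
) -> FSResult:
    """Run the oppositional binary crow search over the feature space.

    Positions start uniform in [0,1]^d. Each iteration every crow picks a
    random flockmate to follow and, unless the awareness escape fires,
    proposes candidate moves under both a drawn flight length and its
    opposite, keeping the lower-cost candidate; memories are updated when
    the accepted position beats the crow's remembered best.
    ``cost_history[t]`` records the best memory cost entering iteration t
    (so a single-iteration run reports the minimum over the initial
    flock); ``best_cost`` reflects all updates, including the last
    iteration's. Fully reproducible from ``config.seed``.
    """
    if evaluator is None:
        evaluator = make_surrogate_evaluator(seed=config.seed)
    rng = np.random.default_rng(config.seed)
    d = dataset.n_features
    cache: dict[bytes, float] = {}

    def cost_of(position: np.ndarray) -> float:
        mask = binarize(position, config.binarize_threshold)
        key = np.packbits(mask).tobytes()
        if key not in cache:
            cache[key] = fs_cost(
                mask, dataset, evaluator, config.subset_weight, config.as_printed
            )
        return cache[key]

    positions = rng.uniform(size=(config.n_crows, d))
    memories = positions.copy()
    memory_costs = np.array([cost_of(p) for p in positions])

    history = np.empty(config.t_max)
    for t in range(config.t_max):
        history[t] = memory_costs.min()
        for i in range(config.n_crows):
            j = int(rng.integers(config.n_crows))
            theta = rng.uniform()
            if theta < config.awareness_prob:
                new_pos = rng.uniform(size=d)
                new_cost = cost_of(new_pos)
            else:
                tau = rng.uniform()
                fl = rng.uniform(config.fl_min, config.fl_max)
                cand_a = _follow_step(positions[i], memories[j], fl, tau)
                cand_b = _follow_step(
                    positions[i],
                    memories[j],
                    opposite_fl(fl, config.fl_min, config.fl_max),
                    tau,
                )
                cost_a, cost_b = cost_of(cand_a), cost_of(cand_b)
                if cost_a <= cost_b:
                    new_pos, new_cost = cand_a, cost_a
                else:
                    new_pos, new_cost = cand_b, cost_b
            positions[i] = new_pos
            if new_cost < memory_costs[i]:
                memories[i] = new_pos
                memory_costs[i] = new_cost

    best = int(memory_costs.argmin())
    best_mask = binarize(memories[best], config.binarize_threshold)
    if not best_mask.any():
        # Can only happen if every evaluated mask was empty (infinite cost);
        # fall back to the full mask so downstream stages stay feasible.
        warnings.warn("search never found a non-empty mask; returning all features")
        best_mask = np.ones(d, dtype=bool)
    return FSResult(
        best_mask=best_mask,
        best_cost=float(memory_costs[best]),
        cost_history=history,
        n_selected=int(best_mask.sum()),
    )
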