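"""Bio-inspired wrapper feature selection over reduced features.

Two population metaheuristics search the space of feature subsets:

* **EHO** (elephant herd): every agent moves toward the herd best, the best
  agent is reset to ``beta`` times the herd centroid, and the worst agent is
  randomly re-seeded each iteration.
* **CS** (cuckoo search): nests move under the combined pull of their
  personal best and the global best, perturbed by heavy-tailed Levy-flight
  steps; a fraction of the worst nests is abandoned and re-seeded each
  iteration.

Agent positions live in [0, 1]^n_features and binarize to a mask by
thresholding (> 0.5 by default).  Fitness is the mean squared error of a
nearest-centroid surrogate regressor against the class regression targets
(0.1 for Meso, 0.95 for Adeno), evaluated on internal held-out splits so the
outer test fold is never touched.  Both optimizers are elitist: the global
best fitness history is monotonically non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigError
from .io_formats import ADENO, MESO, RunConfig

Fitness = Callable[[np.ndarray], float]


@dataclass
class SelectionMask:
    """Feature indices kept by a metaheuristic, with its convergence history."""

    selected: np.ndarray
    score: float
    method: str
    seed: int
    history: list[float] = field(default_factory=list)

    def __post_init__(self):
        self.selected = np.asarray(sorted(set(int(i) for i in self.selected)), dtype=int)
        if self.selected.size == 0:
            raise ConfigError("a selection mask must keep at least one feature")


@dataclass
class OptimizerState:
    """Population snapshot: positions, per-agent bests and the elitist best."""

    positions: np.ndarray
    fitness: np.ndarray
    personal_best: np.ndarray
    personal_best_fitness: np.ndarray
    global_best: np.ndarray
    global_best_fitness: float
    iteration: int
    history: list[float]


# ---------------------------------------------------------------------------
# fitness


def positions_to_mask(position: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binarize a [0,1]-coordinate position to selected feature indices."""
    return np.flatnonzero(np.asarray(position) > threshold)


def _feature_array(features) -> np.ndarray:
    return features.values if hasattr(features, "values") else np.asarray(features, dtype=float)


def _centroid_scores(X_tr, y_tr, X_val, t_meso, t_adeno) -> np.ndarray:
    """Nearest-centroid surrogate: continuous output in [t_meso, t_adeno].

    A sample at the Adeno centroid maps exactly to t_adeno, at the Meso
    centroid to t_meso, and in between proportionally to its relative
    distances.
    """
    c_a = X_tr[y_tr == ADENO].mean(axis=0)
    c_m = X_tr[y_tr == MESO].mean(axis=0)
    d_a = np.linalg.norm(X_val - c_a, axis=1)
    d_m = np.linalg.norm(X_val - c_m, axis=1)
    denom = d_a + d_m
    mid = 0.5 * (t_meso + t_adeno)
    with np.errstate(invalid="ignore", divide="ignore"):
        o = (t_adeno * d_m + t_meso * d_a) / denom
    return np.where(denom == 0, mid, o)


def fitness_mse(
    mask: np.ndarray,
    features,
    labels: Sequence[str],
    targets: tuple[float, float] = (0.1, 0.95),
    n_splits: int = 3,
) -> float:
    """MSE of the surrogate's held-out continuous outputs against the targets.

    ``targets`` is ``(t_meso, t_adeno)``.  An empty mask returns ``+inf`` so
    it can never be selected as best.  The internal split is deterministic
    (round-robin within each class), independent of any outer CV seed.
    """
    mask = np.asarray(mask, dtype=int)
    if mask.size == 0:
        return float("inf")
    t_meso, t_adeno = targets
    X = _feature_array(features)[:, mask]
    y = np.asarray(labels)
    t = np.where(y == ADENO, t_adeno, t_meso)

    # round-robin stratified assignment: fold of k-th member of a class = k % n_splits
    fold = np.empty(y.size, dtype=int)
    for lab in (ADENO, MESO):
        idx = np.flatnonzero(y == lab)
        fold[idx] = np.arange(idx.size) % n_splits

    counts = min(np.sum(y == ADENO), np.sum(y == MESO))
    if counts < n_splits:
        # too few minority samples to hold out: resubstitution fallback
        o = _centroid_scores(X, y, X, t_meso, t_adeno)
        return float(np.mean((o - t) ** 2))

    sq = 0.0
    for f in range(n_splits):
        tr, va = fold != f, fold == f
        o = _centroid_scores(X[tr], y[tr], X[va], t_meso, t_adeno)
        sq += float(np.sum((o - t[va]) ** 2))
    return sq / y.size


def _make_default_fitness(features, labels, config: RunConfig) -> Fitness:
    X = _feature_array(features)
    lab = list(labels)
    targets = (config.t_meso, config.t_adeno)

    def fn(mask: np.ndarray) -> float:
        return fitness_mse(mask, X, lab, targets=targets)

    return fn


class _CachedFitness:
    """Mask-level memoisation: agents revisiting a subset pay nothing."""

    def __init__(self, fn: Fitness, threshold: float):
        self.fn = fn
        self.threshold = threshold
        self.cache: dict[bytes, float] = {}

    def of_position(self, position: np.ndarray) -> float:
        mask = positions_to_mask(position, self.threshold)
        key = mask.tobytes()
        if key not in self.cache:
            self.cache[key] = float(self.fn(mask))
        return self.cache[key]

    def of_population(self, positions: np.ndarray) -> np.ndarray:
        return np.array([self.of_position(p) for p in positions])


# ---------------------------------------------------------------------------
# elephant herd optimization


def eho_move(positions: np.ndarray, best: np.ndarray, alpha: float, r: np.ndarray) -> np.ndarray:
    """Herd update: x_new = x_old + alpha * (X_best - x_old) * r."""
    return positions + alpha * (best - positions) * r


def eho_best_update(positions: np.ndarray, beta: float) -> np.ndarray:
    """Replacement position for the best agent: beta times the herd centroid."""
    return beta * positions.mean(axis=0)


def eho_worst_update(rng: np.random.Generator, n_features: int,
                     x_min: float = 0.0, x_max: float = 1.0) -> np.ndarray:
    """Re-seed the worst agent across the search range.

    The update's ``+1`` widens the draw past x_max, so the result is clipped
    back into [x_min, x_max].
    """
    pos = x_min + (x_max - x_min + 1.0) * rng.random(n_features)
    return np.clip(pos, x_min, x_max)


def _run_swarm(method, features, labels, config, fitness, seed):
    if config is None:
        config = RunConfig()
    if config.population < 2:
        raise ConfigError("population must be >= 2")
    if not 0 <= config.cs_abandon_fraction < 1:
        raise ConfigError("abandonment fraction must lie in [0, 1)")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    fn = fitness if fitness is not None else _make_default_fitness(features, labels, config)
    cached = _CachedFitness(fn, config.selection_threshold)
    n_features = _feature_array(features).shape[1] if features is not None else None
    return config, rng, cached, n_features, seed


def eho_select(
    features,
    labels=None,
    config: RunConfig | None = None,
    *,
    fitness: Fitness | None = None,
    n_features: int | None = None,
    seed: int | None = None,
) -> SelectionMask:
    """Elephant-herd wrapper selection; returns the elitist best mask.

    ``fitness`` may be injected (a callable on index masks) for custom
    landscapes; by default the MSE surrogate on ``(features, labels)`` is
    used.  ``n_features`` is only needed when ``features`` is None.
    """
    config, rng, cached, d, seed = _run_swarm("EHO", features, labels, config, fitness, seed)
    if d is None:
        d = n_features
    pop = config.population

    positions = rng.random((pop, d))
    fit = cached.of_population(positions)
    gbest_i = int(np.argmin(fit))
    gbest, gbest_fit = positions[gbest_i].copy(), float(fit[gbest_i])
    history = [gbest_fit]

    for _ in range(config.iterations):
        herd_best = positions[int(np.argmin(fit))].copy()
        r = rng.random((pop, d))
        positions = np.clip(eho_move(positions, herd_best, config.eho_alpha, r), 0.0, 1.0)
        best_i = int(np.argmin(fit))
        positions[best_i] = eho_best_update(positions, config.eho_beta)
        worst_i = int(np.argmax(fit))
        positions[worst_i] = eho_worst_update(rng, d)
        fit = cached.of_population(positions)
        it_best = int(np.argmin(fit))
        if fit[it_best] < gbest_fit:
            gbest_fit = float(fit[it_best])
            gbest = positions[it_best].copy()
        history.append(gbest_fit)

    selected = positions_to_mask(gbest, config.selection_threshold)
    if selected.size == 0:  # elitist best can only be empty if every mask was empty
        selected = np.array([int(np.argmax(gbest))])
    return SelectionMask(selected=selected, score=gbest_fit, method="EHO",
                         seed=seed, history=history)


# ---------------------------------------------------------------------------
# cuckoo search


def levy_step(rng: np.random.Generator, sigma: float = 1.0, mu: float = 1.3) -> float:
    """Heavy-tailed Levy-flight step: s = sigma * r^(-1/mu), r ~ U(0, 1].

    The tail is an exact power law: P(S > t) = (t / sigma)^(-mu) for
    t > sigma, and every draw is >= sigma.
    """
    if sigma <= 0:
        raise ConfigError("levy sigma must be > 0")
    if mu <= 1:
        raise ConfigError("levy mu must be > 1 (infinite-mean boundary)")
    r = 1.0 - rng.random()  # in (0, 1]
    return sigma * r ** (-1.0 / mu)


def cs_position_update(
    x_old: np.ndarray,
    x_best: np.ndarray,
    x_globalbest: np.ndarray,
    alpha: float,
    beta: float,
    r1: np.ndarray,
    r2: np.ndarray,
) -> np.ndarray:
    """Deterministic terms of the nest update:
    x_new = x_old + alpha*(r1-0.5)*(x_best-x_old) + beta*(r2-0.5)*(x_globalbest-x_old).
    ``x_best`` is the nest's personal best; when both bests coincide with
    x_old the position is unchanged.
    """
    return (x_old
            + alpha * (r1 - 0.5) * (x_best - x_old)
            + beta * (r2 - 0.5) * (x_globalbest - x_old))


def cs_select(
    features,
    labels=None,
    config: RunConfig | None = None,
    *,
    fitness: Fitness | None = None,
    n_features: int | None = None,
    seed: int | None = None,
    levy_scale: float = 0.1,
) -> SelectionMask:
    """Cuckoo-search wrapper selection with Levy-flight perturbation.

    Each iteration every nest moves per the personal/global-best pull with a
    Levy-scaled Gaussian perturbation, then ``cs_abandon_fraction`` of the
    worst nests are abandoned and re-seeded; the best nest is retained.
    """
    config, rng, cached, d, seed = _run_swarm("CS", features, labels, config, fitness, seed)
    if d is None:
        d = n_features
    pop = config.population
    n_abandon = int(config.cs_abandon_fraction * pop)

    positions = rng.random((pop, d))
    fit = cached.of_population(positions)
    pbest = positions.copy()
    pbest_fit = fit.copy()
    gbest_i = int(np.argmin(fit))
    gbest, gbest_fit = positions[gbest_i].copy(), float(fit[gbest_i])
    history = [gbest_fit]

    for _ in range(config.iterations):
        r1 = rng.random((pop, d))
        r2 = rng.random((pop, d))
        steps = np.array([levy_step(rng, config.levy_sigma, config.levy_mu) for _ in range(pop)])
        noise = rng.standard_normal((pop, d))
        cand = cs_position_update(positions, pbest, gbest, config.cs_alpha,
                                  config.cs_beta, r1, r2)
        cand = np.clip(cand + levy_scale * steps[:, None] * noise, 0.0, 1.0)
        cand_fit = cached.of_population(cand)
        improved = cand_fit <= fit
        positions[improved] = cand[improved]
        fit[improved] = cand_fit[improved]

        if n_abandon > 0:
            worst = np.argsort(fit)[::-1][:n_abandon]
            positions[worst] = rng.random((n_abandon, d))
            fit[worst] = cached.of_population(positions[worst])

        better = fit < pbest_fit
        pbest[better] = positions[better]
        pbest_fit[better] = fit[better]
        it_best = int(np.argmin(fit))
        if fit[it_best] < gbest_fit:
            gbest_fit = float(fit[it_best])
            gbest = positions[it_best].copy()
        history.append(gbest_fit)

    selected = positions_to_mask(gbest, config.selection_threshold)
    if selected.size == 0:
        selected = np.array([int(np.argmax(gbest))])
    return SelectionMask(selected=selected, score=gbest_fit, method="CS",
                         seed=seed, history=history)


def select_features(method: str, features, labels, config: RunConfig,
                    seed: int | None = None) -> SelectionMask:
    """Dispatch on the configured metaheuristic."""
    if method == "EHO":
        return eho_select(features, labels, config, seed=seed)
    if method == "CS":
        return cs_select(features, labels, config, seed=seed)
    raise ConfigError(f"unknown feature-selection method {method!r}")
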