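"""Variable-length particle swarm wrapper feature selection with KNN fitness.

Particles span prefixes of a relevance-ranked feature list; divisions give
the swarm a spread of lengths. Per-dimension exemplar learning follows the
comprehensive-learning update, with exemplar refresh on personal-best
stagnation and a length-changing step on global-best stagnation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import StratifiedKFold

from ._knn import KNNVote

__all__ = [
    "SwarmConfig",
    "SelectionResult",
    "rank_relevance",
    "symmetric_uncertainty",
    "decode",
    "subset_fitness",
    "vlpso_run",
]


@dataclass(frozen=True)
class SwarmConfig:
    population_size: int = 30
    n_divisions: int = 8
    threshold: float = 0.6
    inertia_start: float = 0.9
    inertia_end: float = 0.4
    acceleration: float = 1.49445
    max_velocity: float = 0.6
    refresh_gap: int = 7
    renewal_gap: int = 3
    max_iterations: int = 100
    knn_k: int = 5
    fitness_folds: int = 10
    seed: int = 0
    fitness_seed: int | None = None  # defaults to `seed`; fix it to compare swarms

    @property
    def effective_fitness_seed(self) -> int:
        return self.seed if self.fitness_seed is None else self.fitness_seed

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.n_divisions > self.population_size:
            raise ValueError("n_divisions must not exceed population_size")
        for name in (
            "population_size", "n_divisions", "refresh_gap", "renewal_gap",
            "max_iterations", "knn_k", "fitness_folds",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if self.max_velocity <= 0:
            raise ValueError("max_velocity must be > 0")


@dataclass(frozen=True)
class SelectionResult:
    selected_names: tuple[str, ...]
    selected_indices: tuple[int, ...]
    best_fitness: float
    fitness_trace: tuple[float, ...]
    n_evaluations: int
    seed: int
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.selected_indices) == 0:
            raise ValueError("selected set must be nonempty")
        trace = np.asarray(self.fitness_trace)
        if np.any(np.diff(trace) > 1e-12):
            raise ValueError("gbest fitness trace must be non-increasing")


def _entropy(codes: np.ndarray) -> float:
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log(p)))


def _discretize(x: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Equal-frequency discretization; degenerate edges collapse gracefully."""
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="left")


def symmetric_uncertainty(x: np.ndarray, y: np.ndarray, n_bins: int = 10) -> float:
    """SU(X;Y) = 2 I(X;Y) / (H(X) + H(Y)), X discretized into equal-frequency bins."""
    cx = _discretize(np.asarray(x, dtype=float), n_bins)
    cy = np.asarray(y)
    hx, hy = _entropy(cx), _entropy(cy)
    if hx + hy == 0 or hx == 0 or hy == 0:
        return 0.0
    joint = _entropy(cx.astype(np.int64) * (cy.max() + 1) + cy.astype(np.int64))
    mi = max(hx + hy - joint, 0.0)
    return float(2.0 * mi / (hx + hy))


def rank_relevance(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Feature ordering by descending symmetric uncertainty with the label.

    Ties (including constant features, which score 0) break toward the
    lower original column index.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    for cls in (0, 1):
        if (y == cls).sum() < 2:
            raise ValueError("need >= 2 subjects per class")
    su = np.array([symmetric_uncertainty(X[:, j], y) for j in range(X.shape[1])])
    return np.lexsort((np.arange(X.shape[1]), -su))


def decode(position: np.ndarray, threshold: float) -> np.ndarray:
    """Indices (into the ranked prefix) whose position strictly exceeds threshold."""
    return np.flatnonzero(np.asarray(position) > threshold)


def _balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    pos, neg = y_true == 1, y_true == 0
    sens = (y_pred[pos] == 1).mean() if pos.any() else 0.0
    spec = (y_pred[neg] == 0).mean() if neg.any() else 0.0
    return 0.5 * (sens + spec)


def subset_fitness(
    X: np.ndarray,
    y: np.ndarray,
    subset: np.ndarray,
    knn_k: int = 5,
    folds: int = 10,
    seed: int = 0,
) -> float:
    """1 - balanced accuracy of KNN under seeded stratified k-fold CV.

    Columns are z-scored with training-fold statistics inside each fold.
    The empty subset scores 1.0 by convention.
    """
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        return 1.0
    X = np.atleast_2d(np.asarray(X, dtype=float))[:, subset]
    y = np.asarray(y, dtype=int)
    minority = int(min((y == 1).sum(), (y == 0).sum()))
    if minority < 2:
        raise ValueError("need >= 2 subjects in the minority class")
    if folds > minority:
        warnings.warn(f"reducing fitness folds from {folds} to minority size {minority}")
        folds = minority
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty_like(y)
    for train, test in skf.split(X, y):
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0)
        sd[sd == 0] = 1.0
        knn = KNNVote(k=knn_k).fit((X[train] - mu) / sd, y[train])
        pred[test] = knn.predict((X[test] - mu) / sd)
    return float(1.0 - _balanced_accuracy(y, pred))


class _Particle:
    __slots__ = (
        "length", "position", "velocity", "pbest_pos", "pbest_fit",
        "pbest_size", "exemplar", "stall",
    )

    def __init__(self, length: int, rng: np.random.Generator, vmax: float):
        self.length = length
        self.position = rng.random(length)
        self.velocity = rng.uniform(-vmax, vmax, length)
        self.pbest_pos = self.position.copy()
        self.pbest_fit = np.inf
        self.pbest_size = np.inf
        self.exemplar = np.full(length, -1, dtype=int)
        self.stall = 0


def _division_lengths(n_features: int, n_divisions: int) -> list[int]:
    return [max(1, math.ceil((d + 1) * n_features / n_divisions)) for d in range(n_divisions)]


def vlpso_run(
    X: np.ndarray,
    y: np.ndarray,
    config: SwarmConfig | None = None,
    feature_names: list[str] | None = None,
) -> SelectionResult:
    """Run the variable-length swarm and return the best decoded subset."""
    config = config or SwarmConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    n_features = X.shape[1]
    if n_features < 2:
        raise ValueError("need at least 2 features")
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(n_features)]

    rng = np.random.default_rng(config.seed)
    ranked = rank_relevance(X, y)
    pop, ndiv = config.population_size, min(config.n_divisions, n_features)
    div_lengths = _division_lengths(n_features, ndiv)
    division = np.array([i * ndiv // pop for i in range(pop)])
    particles = [_Particle(div_lengths[division[i]], rng, config.max_velocity) for i in range(pop)]

    # Comprehensive-learning probability: increases across the swarm.
    if pop > 1:
        pc = 0.05 + 0.45 * (np.exp(10 * np.arange(pop) / (pop - 1)) - 1) / (np.exp(10) - 1)
    else:
        pc = np.array([0.5])

    cache: dict[tuple[int, ...], float] = {}
    n_evaluations = 0

    def evaluate(position: np.ndarray) -> tuple[float, int]:
        nonlocal n_evaluations
        n_evaluations += 1
        local = decode(position, config.threshold)
        subset = tuple(sorted(int(ranked[j]) for j in local))
        if subset not in cache:
            cache[subset] = subset_fitness(
                X, y, np.array(subset, dtype=int),
                knn_k=config.knn_k, folds=config.fitness_folds,
                seed=config.effective_fitness_seed,
            )
        return cache[subset], len(subset)

    def assign_exemplar(i: int) -> None:
        p = particles[i]
        p.exemplar = np.full(p.length, i, dtype=int)
        learned = False
        for dim in range(p.length):
            if rng.random() < pc[i]:
                candidates = [j for j in range(pop) if j != i and particles[j].length > dim]
                if not candidates:
                    continue
                r1, r2 = rng.choice(candidates), rng.choice(candidates)
                best = r1 if particles[r1].pbest_fit <= particles[r2].pbest_fit else r2
                p.exemplar[dim] = best
                learned = True
        if not learned and p.length > 0:
            dim = int(rng.integers(p.length))
            candidates = [j for j in range(pop) if j != i and particles[j].length > dim]
            if candidates:
                p.exemplar[dim] = int(rng.choice(candidates))
        p.stall = 0

    gbest_fit, gbest_size = np.inf, np.inf
    gbest_pos: np.ndarray | None = None

    def update_best(i: int, fit: float, size: int) -> bool:
        """Update pbest/gbest; returns True on strict pbest improvement."""
        nonlocal gbest_fit, gbest_size, gbest_pos
        p = particles[i]
        improved = fit < p.pbest_fit
        if improved or (fit == p.pbest_fit and size < p.pbest_size):
            p.pbest_fit, p.pbest_size = fit, size
            p.pbest_pos = p.position.copy()
        if size > 0 and (fit < gbest_fit or (fit == gbest_fit and size < gbest_size)):
            gbest_fit, gbest_size = fit, size
            gbest_pos = p.position.copy()
        return improved

    for i in range(pop):
        assign_exemplar(i)
        fit, size = evaluate(particles[i].position)
        update_best(i, fit, size)

    trace: list[float] = []
    gbest_stall = 0
    for t in range(config.max_iterations):
        w = config.inertia_start - (config.inertia_start - config.inertia_end) * t / max(
            config.max_iterations - 1, 1
        )
        prev_gbest = gbest_fit
        for i in range(pop):
            p = particles[i]
            for dim in range(p.length):
                ex = particles[p.exemplar[dim]]
                target = ex.pbest_pos[dim] if dim < len(ex.pbest_pos) else p.pbest_pos[dim]
                p.velocity[dim] = w * p.velocity[dim] + config.acceleration * rng.random() * (
                    target - p.position[dim]
                )
            np.clip(p.velocity, -config.max_velocity, config.max_velocity, out=p.velocity)
            p.position = np.clip(p.position + p.velocity, 0.0, 1.0)
            fit, size = evaluate(p.position)
            if update_best(i, fit, size):
                p.stall = 0
            else:
                p.stall += 1
                if p.stall >= config.refresh_gap:
                    assign_exemplar(i)
        if gbest_fit < prev_gbest:
            gbest_stall = 0
        else:
            gbest_stall += 1

        if gbest_stall >= config.renewal_gap:
            gbest_stall = 0
            per_div = [
                np.mean([particles[i].pbest_fit for i in range(pop) if division[i] == d])
                for d in range(ndiv)
            ]
            new_max = div_lengths[int(np.argmin(per_div))]
            if new_max < max(div_lengths):
                div_lengths = _division_lengths(new_max, ndiv)
                for i in range(pop):
                    p = particles[i]
                    new_len = div_lengths[division[i]]
                    if p.length > new_len:
                        p.length = new_len
                        p.position = p.position[:new_len]
                        p.velocity = p.velocity[:new_len]
                        p.pbest_pos = p.pbest_pos[:new_len]
                        fit, size = evaluate(p.pbest_pos)
                        p.pbest_fit, p.pbest_size = fit, size
                        if size > 0 and (
                            fit < gbest_fit or (fit == gbest_fit and size < gbest_size)
                        ):
                            gbest_fit, gbest_size, gbest_pos = fit, size, p.pbest_pos.copy()
                for i in range(pop):
                    assign_exemplar(i)
        trace.append(gbest_fit)

    if gbest_pos is None:  # pathological: every decoded subset was empty
        selected = (int(ranked[0]),)
        gbest_fit, _ = evaluate(np.ones(1))
        trace = [gbest_fit] * len(trace)
    else:
        local = decode(gbest_pos, config.threshold)
        selected = tuple(sorted(int(ranked[j]) for j in local))
    return SelectionResult(
        selected_names=tuple(feature_names[j] for j in selected),
        selected_indices=selected,
        best_fitness=float(gbest_fit),
        fitness_trace=tuple(float(v) for v in trace),
        n_evaluations=n_evaluations,
        seed=config.seed,
        config=asdict(config),
    )
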