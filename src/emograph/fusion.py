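"""Feature-level fusion and genetic-algorithm wrapper feature selection.

Fusion is plain concatenation: the peripheral-statistics block first, the
graph-measure block second, with block prefixes so names can never collide.
The GA searches binary feature masks; a chromosome's fitness is the
held-out accuracy of a classifier trained on the masked features of an
inner stratified split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from .core import dichotomize
from .graphs import GraphFeatureBlock
from .models import make_classifier
from .peripheral import PeripheralFeatureBlock

__all__ = ["FeatureVector", "GAConfig", "SelectionResult", "concatenate", "ga_select"]

PERIPHERAL_PREFIX = "periph__"
GRAPH_PREFIX = "graph__"


@dataclass
class FeatureVector:
    """Fused per-window features plus raw and dichotomized labels."""

    values: np.ndarray
    names: list[str]
    valence: float
    arousal: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.names),):
            raise ValueError("values and names must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    @property
    def label_valence(self) -> str:
        return dichotomize(self.valence)

    @property
    def label_arousal(self) -> str:
        return dichotomize(self.arousal)


def concatenate(
    peripheral: PeripheralFeatureBlock,
    graph: GraphFeatureBlock | None,
    valence: float,
    arousal: float,
) -> FeatureVector:
    """Peripheral block first, graph block second, prefixed names."""
    names = [PERIPHERAL_PREFIX + n for n in peripheral.names]
    values = [peripheral.values]
    if graph is not None:
        names += [GRAPH_PREFIX + n for n in graph.names]
        values.append(graph.values)
    return FeatureVector(
        values=np.concatenate(values), names=names,
        valence=valence, arousal=arousal,
    )


@dataclass
class GAConfig:
    """GA parameters; defaults follow the published run settings
    (200 generations, population 100, 10 parents, pool 4, 3 mutations)."""

    n_generations: int = 200
    population_size: int = 100
    n_parents: int = 10
    pool_size: int = 4
    n_mutations: int = 3
    seed: int = 0
    fitness_split: float = 0.15
    crossover: str = "single_point"  # or "uniform"

    def __post_init__(self) -> None:
        if not self.population_size >= self.n_parents >= 2:
            raise ValueError("need population_size >= n_parents >= 2")
        if self.n_mutations < 0:
            raise ValueError("n_mutations must be >= 0")
        if not 0.0 < self.fitness_split < 1.0:
            raise ValueError("fitness_split must be in (0, 1)")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        if self.crossover not in ("single_point", "uniform"):
            raise ValueError(f"unknown crossover {self.crossover!r}")


@dataclass
class SelectionResult:
    mask: np.ndarray
    best_fitness_trace: list[float]
    selected_names: list[str]
    config: GAConfig

    def to_dict(self) -> dict:
        return {
            "mask": self.mask.astype(int).tolist(),
            "trace": list(self.best_fitness_trace),
            "selected_names": list(self.selected_names),
            "config": vars(self.config).copy(),
        }


def _repair(chrom: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if not chrom.any():
        chrom = chrom.copy()
        chrom[rng.integers(chrom.size)] = True
    return chrom


def _crossover(
    a: np.ndarray, b: np.ndarray, mode: str, rng: np.random.Generator
) -> np.ndarray:
    if mode == "uniform":
        pick = rng.random(a.size) < 0.5
        return np.where(pick, a, b)
    point = int(rng.integers(1, a.size))
    return np.concatenate([a[:point], b[point:]])


def ga_select(
    X: np.ndarray,
    y: np.ndarray,
    classifier_kind: str = "svm",
    cfg: GAConfig | None = None,
    feature_names: list[str] | None = None,
    classifier_params: dict | None = None,
) -> SelectionResult:
    """Wrapper selection of a binary feature mask maximizing inner accuracy.

    Elitist generational GA: rank the population by fitness, keep the top
    ``n_parents`` as parents, breed offspring by crossover between parents
    drawn as winners of random pools of size ``pool_size``, flip
    ``n_mutations`` random genes per offspring.  The single best chromosome
    is carried over unchanged, so the best-fitness trace is non-decreasing.
    """
    cfg = cfg or GAConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be [windows x features] aligned with y")
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    if np.unique(y).size < 2:
        raise ValueError("need >= 2 classes for wrapper selection")
    n_features = X.shape[1]
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(n_features)]
    classifier_params = classifier_params or {}

    rng = np.random.default_rng(cfg.seed)
    X_tr, X_ev, y_tr, y_ev = train_test_split(
        X, y, test_size=cfg.fitness_split, stratify=y,
        random_state=int(rng.integers(2**31 - 1)),
    )

    cache: dict[bytes, float] = {}

    def fitness(chrom: np.ndarray) -> float:
        key = np.packbits(chrom).tobytes()
        if key not in cache:
            clf = make_classifier(
                classifier_kind, seed=cfg.seed, **classifier_params
            )
            clf.fit(X_tr[:, chrom], y_tr)
            cache[key] = float(np.mean(clf.predict(X_ev[:, chrom]) == y_ev))
        return cache[key]

    population = [
        _repair(rng.random(n_features) < 0.5, rng)
        for _ in range(cfg.population_size)
    ]
    best_chrom: np.ndarray | None = None
    best_fit = -np.inf
    trace: list[float] = []

    def evaluate(pop: list[np.ndarray]) -> list[float]:
        nonlocal best_chrom, best_fit
        fits = [fitness(c) for c in pop]
        top = int(np.argmax(fits))
        if fits[top] > best_fit:
            best_fit = fits[top]
            best_chrom = pop[top].copy()
        return fits

    fits = evaluate(population)
    trace.append(best_fit)

    for _ in range(cfg.n_generations):
        ranked = [population[i] for i in np.argsort(fits)[::-1]]
        parents = ranked[: cfg.n_parents]

        def pick_parent() -> np.ndarray:
            pool = rng.integers(len(parents), size=cfg.pool_size)
            return parents[int(pool.min())]  # parents are fitness-sorted

        next_pop = [best_chrom.copy()]
        while len(next_pop) < cfg.population_size:
            child = _crossover(pick_parent(), pick_parent(), cfg.crossover, rng)
            if cfg.n_mutations:
                flip = rng.choice(n_features, size=min(cfg.n_mutations, n_features),
                                  replace=False)
                child = child.copy()
                child[flip] = ~child[flip]
            next_pop.append(_repair(child, rng))
        population = next_pop
        fits = evaluate(population)
        trace.append(best_fit)

    mask = best_chrom.astype(bool)
    return SelectionResult(
        mask=mask,
        best_fitness_trace=trace,
        selected_names=[n for n, keep in zip(feature_names, mask) if keep],
        config=cfg,
    )
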