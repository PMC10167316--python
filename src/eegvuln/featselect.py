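"""Binary wrapper feature-subset selection with GWO, GA and PSO.

Each optimizer searches over binary masks; by default a bit switches one
*biomarker block* — all columns of one (measure, band) combination — on or
off, since selection operates at the biomarker level ("HFD in delta")
rather than on single channels.  Column-level selection is available with
``mode='column'``.

Fitness of a mask is the cross-validated (or held-out) accuracy of a Gini
decision tree on the selected columns, minus an optional sparsity penalty
``lambda * (fraction of bits set)``.  An empty mask gets a defined worst
fitness of -1 so optimizers can traverse it.

Encodings follow standard binary-metaheuristic practice: GWO keeps
continuous wolf positions in [0, 1] driven toward the alpha/beta/delta
leaders with the control parameter a decreasing linearly 2 -> 0, and maps
positions to bits through a stochastic sigmoid transfer centred at 0.5;
PSO uses clamped velocities and sigmoid sampling; the GA is a classic
tournament / one-point crossover / per-bit mutation scheme with elitism of
one.  All three track an elitist global best, so the reported
best-fitness trace never worsens.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureTable

__all__ = [
    "OptimizerConfig",
    "SelectionResult",
    "subset_fitness",
    "run_gwo",
    "run_ga",
    "run_pso",
    "run_selection",
    "exhaustive_best",
]

EMPTY_MASK_FITNESS = -1.0


@dataclass(frozen=True)
class OptimizerConfig:
    algorithm: str = "gwo"  # 'gwo' | 'ga' | 'pso'
    population: int = 10
    iterations: int = 20
    seed: int = 0
    feature_penalty: float = 0.0  # lambda
    mode: str = "biomarker"  # 'biomarker' | 'column'
    # GA
    crossover_prob: float = 0.9
    mutation_prob: float = 0.05
    tournament_size: int = 3
    # PSO
    inertia: float = 0.7
    cognitive: float = 1.5
    social: float = 1.5
    velocity_clamp: float = 4.0
    # fitness evaluation
    eval_protocol: str = "kfold"  # 'kfold' | 'holdout'
    k: int = 5
    tree_depth: int = 40

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.algorithm not in ("gwo", "ga", "pso"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.feature_penalty < 0:
            raise ValueError("feature_penalty must be >= 0")


@dataclass(frozen=True)
class SelectionResult:
    best_mask: np.ndarray  # bool over bits
    best_fitness: float
    trace: np.ndarray  # best fitness so far, per iteration
    bit_names: tuple[str, ...]
    n_selected: int
    config: OptimizerConfig

    @property
    def selected(self) -> list[str]:
        return [n for n, b in zip(self.bit_names, self.best_mask) if b]

    def to_text(self, path: str | Path) -> Path:
        path = Path(path)
        lines = [
            f"algorithm\t{self.config.algorithm}",
            f"seed\t{self.config.seed}",
            f"best_fitness\t{self.best_fitness:.6f}",
            f"n_selected\t{self.n_selected}",
        ]
        lines += [f"bit\t{n}\t{int(b)}" for n, b in zip(self.bit_names, self.best_mask)]
        lines += [f"trace\t{i}\t{v:.6f}" for i, v in enumerate(self.trace)]
        path.write_text("\n".join(lines) + "\n")
        return path


def _bit_columns(ft: FeatureTable, mode: str) -> tuple[tuple[str, ...], list[list[str]]]:
    if mode == "column":
        cols = ft.descriptors
        return tuple(cols), [[c] for c in cols]
    if mode == "biomarker":
        blocks = ft.blocks()
        return tuple(blocks.keys()), list(blocks.values())
    raise ValueError(f"unknown selection mode {mode!r}")


def subset_fitness(
    ft: FeatureTable,
    mask: Sequence[bool],
    *,
    eval_protocol: str = "kfold",
    k: int = 5,
    tree_depth: int = 40,
    feature_penalty: float = 0.0,
    seed: int = 0,
    mode: str = "biomarker",
) -> float:
    """Decision-tree accuracy of the masked feature subset, minus the sparsity penalty."""
    mask = np.asarray(mask, dtype=bool)
    bit_names, columns = _bit_columns(ft, mode)
    if mask.shape != (len(bit_names),):
        raise ValueError(f"mask length {mask.size} != number of bits {len(bit_names)}")
    if not mask.any():
        return EMPTY_MASK_FITNESS
    cols = list(itertools.chain.from_iterable(c for c, b in zip(columns, mask) if b))
    x = ft.values[cols].to_numpy()
    _, y = ft.xy()
    clf = DecisionTreeClassifier(max_depth=tree_depth, criterion="gini", random_state=seed)
    if eval_protocol == "kfold":
        # folds cannot exceed the minority class count
        k_eff = int(min(k, np.bincount(y).min()))
        if k_eff < 2:
            raise ValueError("need at least 2 observations per class for k-fold fitness")
        cv = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
        accs = []
        for tr, te in cv.split(x, y):
            clf.fit(x[tr], y[tr])
            accs.append(float((clf.predict(x[te]) == y[te]).mean()))
        acc = float(np.mean(accs))
    elif eval_protocol == "holdout":
        xtr, xte, ytr, yte = train_test_split(x, y, test_size=0.25, stratify=y, random_state=seed)
        clf.fit(xtr, ytr)
        acc = float((clf.predict(xte) == yte).mean())
    else:
        raise ValueError(f"unknown eval protocol {eval_protocol!r}")
    return acc - feature_penalty * mask.mean()


def _make_fitness(ft: FeatureTable, config: OptimizerConfig) -> tuple[Callable[[np.ndarray], float], tuple[str, ...]]:
    bit_names, _ = _bit_columns(ft, config.mode)
    cache: dict[bytes, float] = {}

    def fit(mask: np.ndarray) -> float:
        key = np.packbits(mask).tobytes()
        if key not in cache:
            cache[key] = subset_fitness(
                ft,
                mask,
                eval_protocol=config.eval_protocol,
                k=config.k,
                tree_depth=config.tree_depth,
                feature_penalty=config.feature_penalty,
                seed=config.seed,
                mode=config.mode,
            )
        return cache[key]

    return fit, bit_names


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class _Elite:
    mask: Optional[np.ndarray] = None
    fitness: float = -np.inf
    trace: list[float] = field(default_factory=list)

    def update(self, masks: np.ndarray, fits: np.ndarray) -> None:
        i = int(np.argmax(fits))
        if fits[i] > self.fitness:
            self.fitness = float(fits[i])
            self.mask = masks[i].copy()

    def record(self) -> None:
        self.trace.append(self.fitness)


def _result(elite: _Elite, bit_names: tuple[str, ...], config: OptimizerConfig) -> SelectionResult:
    mask = elite.mask if elite.mask is not None else np.zeros(len(bit_names), dtype=bool)
    return SelectionResult(
        best_mask=mask,
        best_fitness=elite.fitness,
        trace=np.asarray(elite.trace),
        bit_names=bit_names,
        n_selected=int(mask.sum()),
        config=config,
    )


def run_gwo(ft: FeatureTable, config: OptimizerConfig) -> SelectionResult:
    """Binary grey-wolf optimization of the feature mask."""
    fit, bit_names = _make_fitness(ft, config)
    d = len(bit_names)
    rng = np.random.default_rng([config.seed % (2**31), 0x6F])
    pos = rng.random((config.population, d))
    elite = _Elite()
    for it in range(config.iterations):
        # sigmoid transfer around 0.5: bits sampled with P(1) = s(10(x - 0.5)),
        # the stochastic binarization of standard binary-GWO practice
        masks = rng.random((config.population, d)) < _sigmoid(10.0 * (pos - 0.5))
        fits = np.array([fit(m) for m in masks])
        elite.update(masks, fits)
        elite.record()
        order = np.argsort(fits)[::-1]
        leaders = pos[order[:3]]
        a = 2.0 * (1.0 - it / max(1, config.iterations - 1))
        new_pos = np.zeros_like(pos)
        for leader in leaders:
            r1 = rng.random((config.population, d))
            r2 = rng.random((config.population, d))
            A = 2 * a * r1 - a
            C = 2 * r2
            D = np.abs(C * leader - pos)
            new_pos += leader - A * D
        pos = np.clip(new_pos / 3.0, 0.0, 1.0)
    return _result(elite, bit_names, config)


def run_ga(ft: FeatureTable, config: OptimizerConfig) -> SelectionResult:
    """Genetic algorithm: tournament selection, one-point crossover, bit mutation, elitism of 1."""
    fit, bit_names = _make_fitness(ft, config)
    d = len(bit_names)
    rng = np.random.default_rng([config.seed % (2**31), 0x9A])
    pop = rng.random((config.population, d)) < 0.5
    elite = _Elite()
    for _ in range(config.iterations):
        fits = np.array([fit(m) for m in pop])
        elite.update(pop, fits)
        elite.record()

        def tournament() -> np.ndarray:
            idx = rng.integers(0, config.population, size=config.tournament_size)
            return pop[idx[np.argmax(fits[idx])]]

        children = [elite.mask.copy()]  # elitism
        while len(children) < config.population:
            p1, p2 = tournament(), tournament()
            c1, c2 = p1.copy(), p2.copy()
            if rng.random() < config.crossover_prob and d > 1:
                cut = int(rng.integers(1, d))
                c1 = np.concatenate([p1[:cut], p2[cut:]])
                c2 = np.concatenate([p2[:cut], p1[cut:]])
            for c in (c1, c2):
                flips = rng.random(d) < config.mutation_prob
                c[flips] = ~c[flips]
                if len(children) < config.population:
                    children.append(c)
        pop = np.array(children[: config.population])
    return _result(elite, bit_names, config)


def run_pso(ft: FeatureTable, config: OptimizerConfig) -> SelectionResult:
    """Binary particle swarm: clamped velocities, sigmoid transfer, global-best topology."""
    fit, bit_names = _make_fitness(ft, config)
    d = len(bit_names)
    rng = np.random.default_rng([config.seed % (2**31), 0xB5])
    vel = rng.uniform(-1, 1, (config.population, d))
    pos = rng.random((config.population, d)) < _sigmoid(vel)
    pbest = pos.copy()
    pbest_fit = np.array([fit(m) for m in pos])
    elite = _Elite()
    elite.update(pbest, pbest_fit)
    elite.record()
    gbest = elite.mask.copy()
    for _ in range(config.iterations - 1):
        r1 = rng.random((config.population, d))
        r2 = rng.random((config.population, d))
        vel = (
            config.inertia * vel
            + config.cognitive * r1 * (pbest.astype(float) - pos.astype(float))
            + config.social * r2 * (gbest.astype(float)[None, :] - pos.astype(float))
        )
        vel = np.clip(vel, -config.velocity_clamp, config.velocity_clamp)
        pos = rng.random((config.population, d)) < _sigmoid(vel)
        fits = np.array([fit(m) for m in pos])
        improved = fits > pbest_fit
        pbest[improved] = pos[improved]
        pbest_fit[improved] = fits[improved]
        elite.update(pos, fits)
        elite.record()
        gbest = elite.mask.copy()
    return _result(elite, bit_names, config)


_RUNNERS = {"gwo": run_gwo, "ga": run_ga, "pso": run_pso}


def run_selection(ft: FeatureTable, config: OptimizerConfig) -> SelectionResult:
    return _RUNNERS[config.algorithm](ft, config)


def exhaustive_best(ft: FeatureTable, config: OptimizerConfig) -> tuple[np.ndarray, float]:
    """Brute-force best mask over all 2^d - 1 non-empty masks (small d only)."""
    fit, bit_names = _make_fitness(ft, config)
    d = len(bit_names)
    if d > 16:
        raise ValueError("exhaustive search limited to d <= 16")
    best_mask, best_fit = None, -np.inf
    for bits in range(1, 2**d):
        mask = np.array([(bits >> i) & 1 for i in range(d)], dtype=bool)
        f = fit(mask)
        if f > best_fit:
            best_fit, best_mask = f, mask
    return best_mask, float(best_fit)
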