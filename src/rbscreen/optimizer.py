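"""Binary Arithmetic Optimization Algorithm (BAOA-S / BAOA-V) feature selection.

The Arithmetic Optimization Algorithm (AOA) is a population metaheuristic
whose candidate positions are real vectors.  Each iteration the Math
Optimizer Accelerated probability

    MOA(L) = Min + L * (Max - Min) / N

decides between exploration (division / multiplication operators) and
exploitation (subtraction / addition operators), while the math-optimizer
probability

    MOP(L) = 1 - L^(1/alpha) / N^(1/alpha)

scales the operator magnitude.  Every coordinate is regenerated around the
best-so-far position:

    exploration:   best / (MOP + eps) * ((ub - lb) * mu + lb)   or
                   best * MOP * ((ub - lb) * mu + lb)
    exploitation:  best - MOP * ((ub - lb) * mu + lb)           or
                   best + MOP * ((ub - lb) * mu + lb)

For feature selection the best-so-far solution is a bit vector; its
continuous counterpart (the attractor the operators regenerate around) is
the soft embedding center + (bit - 1/2) * spread, which keeps every operator
productive in both bit directions.  Positions are binarized each iteration
by a transfer function: the S-shaped rule samples bit = 1 with probability
sigmoid(gain * (x - center)); the V-shaped rule flips bits of the incumbent
best solution with probability |tanh(gain * (x - attractor))|, the
step-magnitude analogue of velocity-based binarization.  A literal
hill-climbing mode is also provided (single-bit flip for S, XOR with a
sparse random vector for V, improvement-only acceptance).  The optimizer
minimizes throughout; the wrapper fitness is

    f(bits) = w * err(bits) + (1 - w) * |S| / D

with err the mean misclassification rate of a k-NN classifier under seeded
stratified inner cross-validation restricted to the selected columns
(an empty subset is charged err = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from .core import FeatureTable

__all__ = [
    "AOAConfig",
    "FitnessConfig",
    "BinarySolution",
    "OptimizationResult",
    "init_population",
    "moa_value",
    "mop_value",
    "aoa_position_update",
    "transfer_probability",
    "binarize_position",
    "literal_neighbor",
    "wrapper_fitness",
    "optimize_bits",
    "optimize_selection",
]


@dataclass(frozen=True)
class AOAConfig:
    population_size: int = 20
    max_iterations: int = 100
    moa_min: float = 0.2
    moa_max: float = 0.9
    mu: float = 0.499
    alpha: float = 5.0
    epsilon: float = 1e-6
    lower_bound: float = 0.0
    upper_bound: float = 1.0
    update_mode: str = "transfer"  # or "literal"
    transfer_kind: str = "S"  # or "V"
    transfer_gain: float | None = None  # None -> 12.0 for S, 1.0 for V
    attractor_spread: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not 0.0 <= self.moa_min < self.moa_max <= 1.0:
            raise ValueError("need 0 <= moa_min < moa_max <= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.lower_bound > self.upper_bound:
            raise ValueError("lower_bound must not exceed upper_bound")
        if self.update_mode not in ("transfer", "literal"):
            raise ValueError("update_mode must be 'transfer' or 'literal'")
        if self.transfer_kind not in ("S", "V"):
            raise ValueError("transfer_kind must be 'S' or 'V'")
        if not 0.0 < self.attractor_spread <= 1.0:
            raise ValueError("attractor_spread must lie in (0, 1]")

    @property
    def magnitude(self) -> float:
        """The operator magnitude term ((ub - lb) * mu + lb)."""
        return (self.upper_bound - self.lower_bound) * self.mu + self.lower_bound

    @property
    def effective_transfer_gain(self) -> float:
        if self.transfer_gain is not None:
            return self.transfer_gain
        return 12.0 if self.transfer_kind == "S" else 1.0


@dataclass(frozen=True)
class FitnessConfig:
    penalty_weight: float = 0.99
    n_neighbors: int = 5
    inner_folds: int = 5
    empty_subset_error: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.penalty_weight <= 1.0:
            raise ValueError("penalty_weight must lie in (0, 1]")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")


@dataclass
class BinarySolution:
    """A fixed-length bit vector (1 = feature kept) with attached fitness."""

    bits: np.ndarray
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.int8)
        if self.bits.ndim != 1 or not np.isin(self.bits, (0, 1)).all():
            raise ValueError("bits must be a 1-D 0/1 vector")

    @property
    def n_selected(self) -> int:
        return int(self.bits.sum())


@dataclass
class OptimizationResult:
    best: BinarySolution
    history: np.ndarray
    n_evaluations: int
    seed: int

    @property
    def best_fitness(self) -> float:
        return float(self.best.fitness)


def init_population(config: AOAConfig, D: int,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """M x D positions, each coordinate uniform in [lower, upper]."""
    if D < 1:
        raise ValueError("D must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    s = rng.random((config.population_size, D))
    return config.lower_bound + s * (config.upper_bound - config.lower_bound)


def moa_value(L_i: int, config: AOAConfig) -> float:
    """Explore/exploit switching probability, linear from Min to Max."""
    if not 0 <= L_i <= config.max_iterations:
        raise ValueError("iteration index out of range")
    return config.moa_min + L_i * (config.moa_max - config.moa_min) / config.max_iterations


def mop_value(L_i: int, config: AOAConfig) -> float:
    """Operator magnitude schedule, decaying from ~1 to 0."""
    return 1.0 - (L_i ** (1.0 / config.alpha)) / (config.max_iterations ** (1.0 / config.alpha))


def aoa_position_update(coord: float, best_coord: float, moa: float, mop: float,
                        config: AOAConfig, rng: np.random.Generator) -> float:
    """One coordinate update: explore (divide/multiply) when r1 > MOA, else
    exploit (subtract/add); the branch within each pair is an even coin."""
    lb, ub = config.lower_bound, config.upper_bound
    mag = config.magnitude
    r1 = rng.random()
    if r1 > moa:
        r2 = rng.random()
        if r2 < 0.5:
            new = best_coord / (mop + config.epsilon) * mag
        else:
            new = best_coord * mop * mag
    else:
        r3 = rng.random()
        if r3 < 0.5:
            new = best_coord - mop * mag
        else:
            new = best_coord + mop * mag
    return float(np.clip(new, lb, ub))


def transfer_probability(x: np.ndarray | float, kind: str) -> np.ndarray | float:
    """S: sigmoid(x); V: |tanh(x)| — both map reals to [0, 1]."""
    if kind == "S":
        return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))
    if kind == "V":
        return np.abs(np.tanh(np.asarray(x, dtype=float)))
    raise ValueError("kind must be 'S' or 'V'")


def binarize_position(position: np.ndarray, kind: str, current_bits: np.ndarray,
                      rng: np.random.Generator, config: AOAConfig | None = None,
                      reference: np.ndarray | None = None) -> np.ndarray:
    """Map a continuous position to bits.

    S rule: bit = 1 with probability sigmoid(gain * (coord - center)).
    V rule: each bit of ``current_bits`` is complemented with probability
    |tanh(gain * (coord - reference))|, where ``reference`` defaults to the
    domain center (lb + ub) / 2 and, inside the optimizer, is the attractor
    position so that vanishing steps mean vanishing flip probability.
    """
    config = config or AOAConfig()
    position = np.asarray(position, dtype=float)
    current_bits = np.asarray(current_bits, dtype=np.int8)
    if position.shape != current_bits.shape:
        raise ValueError("position and current_bits must have equal length")
    center = (config.lower_bound + config.upper_bound) / 2.0
    gain = config.effective_transfer_gain if config.transfer_kind == kind else (
        12.0 if kind == "S" else 1.0)
    if kind == "S":
        prob = transfer_probability(gain * (position - center), "S")
        return (rng.random(position.shape) < prob).astype(np.int8)
    if kind == "V":
        ref = center if reference is None else np.asarray(reference, dtype=float)
        prob = transfer_probability(gain * (position - ref), "V")
        flip = rng.random(position.shape) < prob
        return np.where(flip, 1 - current_bits, current_bits).astype(np.int8)
    raise ValueError("kind must be 'S' or 'V'")


def literal_neighbor(bits: np.ndarray, kind: str, rng: np.random.Generator,
                     p_flip: float | None = None) -> np.ndarray:
    """Hill-climbing move: S flips one uniformly chosen bit; V XORs with a
    sparse random vector (per-bit probability ``p_flip``, default 1/D, at
    least one flip enforced by redraw)."""
    bits = np.asarray(bits, dtype=np.int8)
    D = bits.size
    if D < 1:
        raise ValueError("bits must be non-empty")
    if kind == "S":
        out = bits.copy()
        b = int(rng.integers(D))
        out[b] = 1 - out[b]
        return out
    if kind == "V":
        p = 1.0 / D if p_flip is None else p_flip
        v = rng.random(D) < p
        while not v.any():
            v = rng.random(D) < p
        return (bits ^ v.astype(np.int8)).astype(np.int8)
    raise ValueError("kind must be 'S' or 'V'")


class _WrapperEvaluator:
    """Cached wrapper fitness: penalized k-NN inner-CV misclassification."""

    def __init__(self, table: FeatureTable, config: FitnessConfig):
        if np.unique(table.labels).size < 2:
            raise ValueError("wrapper fitness requires at least two classes")
        self.X = table.X
        self.y = table.labels
        self.config = config
        skf = StratifiedKFold(n_splits=config.inner_folds, shuffle=True,
                              random_state=config.seed)
        self.folds = list(skf.split(self.X, self.y))
        self._cache: dict[bytes, float] = {}

    def cv_error(self, bits: np.ndarray) -> float:
        bits = np.asarray(bits, dtype=bool)
        if not bits.any():
            return self.config.empty_subset_error
        key = np.packbits(bits).tobytes()
        if key in self._cache:
            return self._cache[key]
        Xs = self.X[:, bits]
        errs = []
        for train, test in self.folds:
            mu = Xs[train].mean(axis=0)
            sd = Xs[train].std(axis=0)
            sd[sd == 0] = 1.0
            clf = KNeighborsClassifier(n_neighbors=self.config.n_neighbors)
            clf.fit((Xs[train] - mu) / sd, self.y[train])
            pred = clf.predict((Xs[test] - mu) / sd)
            errs.append(float(np.mean(pred != self.y[test])))
        err = float(np.mean(errs))
        self._cache[key] = err
        return err

    def __call__(self, bits: np.ndarray) -> float:
        w = self.config.penalty_weight
        D = self.X.shape[1]
        k = int(np.asarray(bits).sum())
        return w * self.cv_error(bits) + (1.0 - w) * k / D


def wrapper_fitness(bits: np.ndarray, table: FeatureTable,
                    config: FitnessConfig | None = None) -> float:
    """One-shot evaluation of the penalized wrapper fitness (lower is better)."""
    return _WrapperEvaluator(table, config or FitnessConfig())(bits)


def _transfer_run(fitness, D: int, config: AOAConfig,
                  rng: np.random.Generator) -> tuple[np.ndarray, float, list[float], int]:
    M = config.population_size
    lb, ub = config.lower_bound, config.upper_bound
    center = (lb + ub) / 2.0
    mag = config.magnitude
    gain = config.effective_transfer_gain
    spread = config.attractor_spread * (ub - lb)

    def embed(bits_vec: np.ndarray) -> np.ndarray:
        # continuous attractor encoding of the best bit string
        return center + (bits_vec.astype(float) - 0.5) * spread

    pos = init_population(config, D, rng)
    bits = (pos > center).astype(np.int8)
    fit = np.array([fitness(b) for b in bits], dtype=float)
    n_evals = M
    elite_idx = int(np.argmin(fit))
    elite_bits = bits[elite_idx].copy()
    elite_f = float(fit[elite_idx])
    best_pos = embed(elite_bits)
    history = [elite_f]

    for L in range(1, config.max_iterations + 1):
        moa = moa_value(L, config)
        mop = mop_value(L, config)
        r1 = rng.random((M, D))
        r23 = rng.random((M, D))
        b = best_pos[None, :]
        explore = r1 > moa
        low_branch = r23 < 0.5
        new_pos = np.where(
            explore,
            np.where(low_branch, b / (mop + config.epsilon) * mag, b * mop * mag),
            np.where(low_branch, b - mop * mag, b + mop * mag),
        )
        pos = np.clip(new_pos, lb, ub)

        if config.transfer_kind == "S":
            prob = transfer_probability(gain * (pos - center), "S")
            bits = (rng.random((M, D)) < prob).astype(np.int8)
        else:
            # flip probability from the step off the attractor: small steps
            # reproduce the best bits, large steps explore around them
            prob = transfer_probability(gain * (pos - b), "V")
            flip = rng.random((M, D)) < prob
            bits = np.where(flip, 1 - elite_bits[None, :], elite_bits[None, :]).astype(np.int8)

        fit = np.array([fitness(b_) for b_ in bits], dtype=float)
        n_evals += M
        m = int(np.argmin(fit))
        if fit[m] < elite_f:
            elite_f = float(fit[m])
            elite_bits = bits[m].copy()
            best_pos = embed(elite_bits)
        history.append(elite_f)
    return elite_bits, elite_f, history, n_evals


def _literal_run(fitness, D: int, config: AOAConfig,
                 rng: np.random.Generator) -> tuple[np.ndarray, float, list[float], int]:
    M = config.population_size
    center = (config.lower_bound + config.upper_bound) / 2.0
    pos = init_population(config, D, rng)
    bits = (pos > center).astype(np.int8)
    fit = np.array([fitness(b) for b in bits], dtype=float)
    n_evals = M
    elite_idx = int(np.argmin(fit))
    elite_bits = bits[elite_idx].copy()
    elite_f = float(fit[elite_idx])
    history = [elite_f]

    for _ in range(config.max_iterations):
        for m in range(M):
            cand = literal_neighbor(bits[m], config.transfer_kind, rng)
            fc = float(fitness(cand))
            n_evals += 1
            if fc < fit[m]:  # improvement-only acceptance (minimization)
                bits[m] = cand
                fit[m] = fc
                if fc < elite_f:
                    elite_f = fc
                    elite_bits = cand.copy()
        history.append(elite_f)
    return elite_bits, elite_f, history, n_evals


def optimize_bits(fitness, D: int, config: AOAConfig | None = None) -> OptimizationResult:
    """Minimize ``fitness`` over length-D bit vectors with the configured
    BAOA variant.  All randomness flows from ``config.seed``."""
    config = config or AOAConfig()
    if D < 1:
        raise ValueError("D must be >= 1")
    rng = np.random.default_rng(config.seed)
    if config.update_mode == "transfer":
        bits, f, history, n_evals = _transfer_run(fitness, D, config, rng)
    else:
        bits, f, history, n_evals = _literal_run(fitness, D, config, rng)
    return OptimizationResult(best=BinarySolution(bits=bits, fitness=f),
                              history=np.asarray(history), n_evaluations=n_evals,
                              seed=config.seed)


def optimize_selection(table: FeatureTable, aoa: AOAConfig | None = None,
                       fit: FitnessConfig | None = None) -> OptimizationResult:
    """Wrapper feature selection on a feature table (lower fitness is better)."""
    aoa = aoa or AOAConfig()
    fit = fit or FitnessConfig()
    evaluator = _WrapperEvaluator(table, fit)
    return optimize_bits(evaluator, table.n_features, aoa)
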