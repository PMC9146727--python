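"""Binary particle-swarm wrapper feature selection.

Each particle is a d-bit inclusion mask.  Velocities follow the classic
inertia + cognitive + social update; a sigmoid transfer maps each velocity
component to an inclusion probability which is thresholded against a uniform
draw.  Subset quality (the paper-style wrapper objective) is stratified
k-fold 1-nearest-neighbour accuracy minus a small sparsity penalty.

One deliberate refinement of the plain threshold rule: a velocity component
that is exactly zero carries no preference, so the particle keeps its current
bit instead of re-randomising it.  This makes the degenerate swarm
(a1 = a2 = 0, zero velocities) stationary, as a selector should be.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

__all__ = [
    "SwarmState",
    "SelectionResult",
    "update_velocity",
    "transfer_sigmoid",
    "binarize_position",
    "wrapper_fitness",
    "pso_select",
    "PSOSelector",
]


@dataclass
class SelectionResult:
    """Outcome of a feature-selection run."""

    mask: np.ndarray            # d booleans
    scores: np.ndarray          # d method-specific scores
    method: str                 # 'pso' | 'acs' | 'ebs'
    seed: int
    fitness_trace: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        self.scores = np.asarray(self.scores, dtype=float)
        self.fitness_trace = np.asarray(self.fitness_trace, dtype=float)
        if self.mask.sum() < 1:
            raise ValueError("a selection must keep at least one feature")
        if self.scores.shape != self.mask.shape:
            raise ValueError("one score per feature required")

    @property
    def indices(self) -> np.ndarray:
        """Sorted indices of the selected columns."""
        return np.flatnonzero(self.mask)

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())


@dataclass
class SwarmState:
    """Positions, velocities and bests of a binary swarm."""

    positions: np.ndarray       # P x d binary (0/1 floats)
    velocities: np.ndarray      # P x d reals
    pbest_positions: np.ndarray
    pbest_fitness: np.ndarray   # P reals
    gbest_position: np.ndarray  # d binary
    gbest_fitness: float
    inertia: float
    a1: float
    a2: float
    rng: np.random.Generator
    iteration: int = 0

    def __post_init__(self):
        if self.positions.shape[0] < 2:
            raise ValueError("a swarm needs at least 2 particles")


def update_velocity(state: SwarmState, rm1=None, rm2=None,
                    v_max: float = 6.0) -> SwarmState:
    """Inertia + cognitive + social velocity update, clamped to [-v_max, v_max].

    ``rm1``/``rm2`` are the uniform [0, 1) draws; when omitted they are drawn
    per particle and component from the state's generator.
    """
    shape = state.velocities.shape
    if rm1 is None:
        rm1 = state.rng.random(shape)
    if rm2 is None:
        rm2 = state.rng.random(shape)
    vel = (state.inertia * state.velocities
           + state.a1 * np.asarray(rm1) * (state.pbest_positions - state.positions)
           + state.a2 * np.asarray(rm2) * (state.gbest_position - state.positions))
    state.velocities = np.clip(vel, -v_max, v_max)
    return state


def transfer_sigmoid(velocity):
    """Map a velocity to an inclusion probability in (0, 1)."""
    return expit(velocity)


def binarize_position(probabilities, random_vector):
    """Bit = 1 where the inclusion probability meets or exceeds the draw."""
    probabilities = np.asarray(probabilities, dtype=float)
    random_vector = np.asarray(random_vector, dtype=float)
    if probabilities.shape != random_vector.shape:
        raise ValueError("probability and draw vectors must have equal length")
    return (probabilities >= random_vector).astype(float)


def wrapper_fitness(X, y, mask, folds: int = 3, seed: int = 0,
                    penalty: float = 0.01) -> float:
    """Stratified k-fold 1-NN accuracy on the masked columns, minus
    ``penalty`` times the selected fraction."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 1:
        raise ValueError("fitness of an empty mask is undefined")
    Xm = X[:, mask]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(Xm, y):
        clf = KNeighborsClassifier(n_neighbors=1).fit(Xm[tr], y[tr])
        accs.append((clf.predict(Xm[te]) == y[te]).mean())
    return float(np.mean(accs)) - penalty * mask.mean()


def _repair(bits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Force one random bit on in any all-zero row."""
    for i in np.flatnonzero(bits.sum(axis=1) == 0):
        bits[i, rng.integers(bits.shape[1])] = 1.0
    return bits


def pso_select(X, y, n_particles: int = 20, n_iter: int = 30,
               inertia: float = 0.7, a1: float = 1.5, a2: float = 1.5,
               v_max: float = 6.0, penalty: float = 0.01, folds: int = 3,
               seed: int = 0) -> SelectionResult:
    """Run the binary swarm and return the global-best mask.

    The global best is elitist (its fitness trace is non-decreasing); ties on
    fitness are broken toward the smaller mask for reproducibility.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, d = X.shape
    if d < 2 or n_particles < 2 or n_iter < 1:
        raise ValueError("need d >= 2, n_particles >= 2, n_iter >= 1")
    rng = np.random.default_rng(seed)
    positions = _repair((rng.random((n_particles, d)) < 0.5).astype(float), rng)
    state = SwarmState(
        positions=positions,
        velocities=np.zeros((n_particles, d)),
        pbest_positions=positions.copy(),
        pbest_fitness=np.full(n_particles, -np.inf),
        gbest_position=positions[0].copy(),
        gbest_fitness=-np.inf,
        inertia=inertia, a1=a1, a2=a2, rng=rng,
    )
    gbest_hits = np.zeros(d)
    trace = []
    for it in range(n_iter):
        for p in range(n_particles):
            f = wrapper_fitness(X, y, state.positions[p] > 0.5,
                                folds=folds, seed=seed, penalty=penalty)
            better = (f > state.pbest_fitness[p]
                      or (f == state.pbest_fitness[p]
                          and state.positions[p].sum() < state.pbest_positions[p].sum()))
            if better:
                state.pbest_fitness[p] = f
                state.pbest_positions[p] = state.positions[p].copy()
            if (f > state.gbest_fitness
                    or (f == state.gbest_fitness
                        and state.positions[p].sum() < state.gbest_position.sum())):
                state.gbest_fitness = f
                state.gbest_position = state.positions[p].copy()
        trace.append(state.gbest_fitness)
        gbest_hits += state.gbest_position
        state.iteration = it + 1
        if it == n_iter - 1:
            break
        update_velocity(state, v_max=v_max)
        probs = transfer_sigmoid(state.velocities)
        draws = rng.random(probs.shape)
        new_bits = binarize_position(probs, draws)
        keep = state.velocities == 0.0  # no preference: retain current bit
        new_bits[keep] = state.positions[keep]
        state.positions = _repair(new_bits, rng)
    return SelectionResult(mask=state.gbest_position > 0.5,
                           scores=gbest_hits / n_iter, method="pso",
                           seed=seed, fitness_trace=np.asarray(trace))


class PSOSelector(SelectorMixin, BaseEstimator):
    """Binary particle-swarm feature selector (scikit-learn transformer).

    ``fit(X, y)`` runs the swarm; the selected columns are exposed through
    ``get_support`` / ``transform``.  ``result_`` holds the full
    :class:`SelectionResult` including the elitist fitness trace.
    """

    def __init__(self, n_particles: int = 20, n_iter: int = 30,
                 inertia: float = 0.7, a1: float = 1.5, a2: float = 1.5,
                 v_max: float = 6.0, penalty: float = 0.01, cv: int = 3,
                 random_state: int = 0):
        self.n_particles = n_particles
        self.n_iter = n_iter
        self.inertia = inertia
        self.a1 = a1
        self.a2 = a2
        self.v_max = v_max
        self.penalty = penalty
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        self.result_ = pso_select(
            X, y, n_particles=self.n_particles, n_iter=self.n_iter,
            inertia=self.inertia, a1=self.a1, a2=self.a2, v_max=self.v_max,
            penalty=self.penalty, folds=self.cv, seed=self.random_state)
        return self

    def _get_support_mask(self):
        return self.result_.mask
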