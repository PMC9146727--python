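"""Ant-colony-system feature subset selection.

Ants build fixed-size feature subsets by sampling, without replacement, from
inclusion probabilities proportional to pheromone^alpha * heuristic^beta over
the remaining (feasible) features.  The per-feature heuristic is the Fisher
score; the pheromone receives an elitist global update each iteration:
evaporation everywhere plus a deposit proportional to the iteration-best
subset's wrapper fitness on its features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from .pso import SelectionResult, wrapper_fitness

__all__ = [
    "ColonyState",
    "inclusion_probability",
    "heuristic_fisher",
    "fisher_score",
    "acs_select",
    "ACSSelector",
]

PHEROMONE_FLOOR = 1e-6


@dataclass
class ColonyState:
    """Pheromone, heuristic and the ants' partial subsets."""

    pheromone: np.ndarray       # d strictly positive reals
    heuristic: np.ndarray       # d non-negative reals
    alpha: float = 1.0
    beta: float = 2.0
    evaporation: float = 0.1
    ants: list = field(default_factory=list)   # one list of chosen indices per ant
    subset_size: int = 1

    def __post_init__(self):
        self.pheromone = np.asarray(self.pheromone, dtype=float)
        self.heuristic = np.asarray(self.heuristic, dtype=float)
        if (self.pheromone <= 0).any():
            raise ValueError("pheromone must stay strictly positive")
        if not 0 < self.evaporation < 1:
            raise ValueError("evaporation must lie in (0, 1)")

    def feasible(self, ant: int) -> np.ndarray:
        """Features the given ant may still add."""
        taken = np.zeros(self.pheromone.size, dtype=bool)
        taken[list(self.ants[ant])] = True
        return np.flatnonzero(~taken)


def _weights(state: ColonyState) -> np.ndarray:
    # tiny heuristic floor keeps zero-score features reachable rather than
    # making the feasible distribution degenerate
    return (state.pheromone ** state.alpha
            * (state.heuristic + 1e-12) ** state.beta)


def inclusion_probability(state: ColonyState, ant: int, feature: int) -> float:
    """Probability that ``ant`` adds ``feature`` next; 0 if infeasible."""
    feas = state.feasible(ant)
    if feas.size == 0:
        raise RuntimeError("ant has no feasible features left")
    if feature not in feas:
        return 0.0
    w = _weights(state)
    return float(w[feature] / w[feas].sum())


def fisher_score(X, y, eps: float = 1e-12) -> np.ndarray:
    """Per-feature between-class variance of class means over pooled
    within-class variance."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("Fisher score needs at least 2 classes")
    n = X.shape[0]
    grand = X.mean(axis=0)
    between = np.zeros(X.shape[1])
    within = np.zeros(X.shape[1])
    for c in classes:
        Xc = X[y == c]
        nc = Xc.shape[0]
        between += nc * (Xc.mean(axis=0) - grand) ** 2
        within += ((Xc - Xc.mean(axis=0)) ** 2).sum(axis=0)
    return (between / n) / (within / n + eps)


#: the colony's per-feature desirability heuristic
heuristic_fisher = fisher_score


def _build_subset(weights: np.ndarray, subset_size: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Sequentially sample ``subset_size`` features without replacement from
    the (renormalised) inclusion probabilities."""
    w = weights.copy()
    chosen = np.empty(subset_size, dtype=int)
    for step in range(subset_size):
        total = w.sum()
        if total <= 0:  # all remaining weights zero: fall back to uniform
            p = (w >= 0).astype(float)
            p[chosen[:step]] = 0.0
            p /= p.sum()
        else:
            p = w / total
        j = rng.choice(w.size, p=p)
        chosen[step] = j
        w[j] = 0.0
    return np.sort(chosen)


def acs_select(X, y, n_ants: int = 15, n_iter: int = 25, alpha: float = 1.0,
               beta: float = 2.0, rho: float = 0.1, subset_size: int | None = None,
               folds: int = 3, penalty: float = 0.01,
               seed: int = 0) -> SelectionResult:
    """Run the colony and return the best subset found (elitist).

    ``subset_size`` defaults to d/5 (at least 1).  Deterministic per seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, d = X.shape
    if subset_size is None:
        subset_size = max(1, d // 5)
    if not 1 <= subset_size <= d:
        raise ValueError("need 1 <= subset_size <= d")
    rng = np.random.default_rng(seed)
    state = ColonyState(pheromone=np.ones(d), heuristic=fisher_score(X, y),
                        alpha=alpha, beta=beta, evaporation=rho,
                        subset_size=subset_size)
    best_subset, best_fit = None, -np.inf
    trace = []
    for _ in range(n_iter):
        weights = _weights(state)
        it_best, it_fit = None, -np.inf
        for _a in range(n_ants):
            if subset_size == d:
                subset = np.arange(d)
            else:
                subset = _build_subset(weights, subset_size, rng)
            mask = np.zeros(d, dtype=bool)
            mask[subset] = True
            f = wrapper_fitness(X, y, mask, folds=folds, seed=seed,
                                penalty=penalty)
            if f > it_fit:
                it_best, it_fit = subset, f
        if it_fit > best_fit:
            best_subset, best_fit = it_best, it_fit
        trace.append(best_fit)
        state.pheromone *= (1.0 - rho)
        state.pheromone[it_best] += rho * max(it_fit, 0.0)
        np.clip(state.pheromone, PHEROMONE_FLOOR, None, out=state.pheromone)
    mask = np.zeros(d, dtype=bool)
    mask[best_subset] = True
    return SelectionResult(mask=mask, scores=state.pheromone.copy(),
                           method="acs", seed=seed,
                           fitness_trace=np.asarray(trace))


class ACSSelector(SelectorMixin, BaseEstimator):
    """Ant-colony-system feature selector (scikit-learn transformer)."""

    def __init__(self, n_ants: int = 15, n_iter: int = 25, alpha: float = 1.0,
                 beta: float = 2.0, rho: float = 0.1,
                 subset_size: int | None = None, penalty: float = 0.01,
                 cv: int = 3, random_state: int = 0):
        self.n_ants = n_ants
        self.n_iter = n_iter
        self.alpha = alpha
        self.beta = beta
        self.rho = rho
        self.subset_size = subset_size
        self.penalty = penalty
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        self.result_ = acs_select(
            X, y, n_ants=self.n_ants, n_iter=self.n_iter, alpha=self.alpha,
            beta=self.beta, rho=self.rho, subset_size=self.subset_size,
            folds=self.cv, penalty=self.penalty, seed=self.random_state)
        return self

    def _get_support_mask(self):
        return self.result_.mask
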