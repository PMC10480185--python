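"""Elementary dynamics of bounded-confidence opinion exchange with algorithmic bias
and stubborn mass-media agents.

The population holds continuous opinions :math:`x_i \\in [0, 1]`. At each discrete
step a randomly picked agent *i* interacts with a peer *j* drawn with probability

.. math:: p_i(j) \\propto d_{ij}^{-\\gamma}, \\qquad d_{ij} = |x_i - x_j|,

so that a larger bias exponent :math:`\\gamma` concentrates interactions on
like-minded peers (:math:`\\gamma = 0` is uniform choice, the classical
Deffuant-Weisbuch limit). If the pair is within the confidence bound
:math:`\\epsilon`, both move a fraction :math:`\\mu` towards each other.
With probability :math:`p_m` the same agent then consumes one item from a set of
*M* stubborn media agents (fixed opinions), selected with the same biased kernel,
and moves towards it if it falls inside the agent's confidence bound.

Random-stream protocol
----------------------
Every run consumes a single :class:`numpy.random.Generator` in a fixed order so
that trajectories are replayable and a naive external implementation can be
seed-matched against this one:

1. ``i = rng.integers(N)`` — the focal agent.
2. Peer choice: for ``gamma == 0`` a single ``rng.integers(n_neighbors)`` draw
   (with skip-``i`` index mapping in the mean-field case); for ``gamma > 0`` one
   ``rng.random()`` draw located in the cumulative weight vector.
3. The pair update itself consumes no randomness.
4. Only when ``p_m > 0`` and at least one medium exists, ``u = rng.random()`` is
   drawn; if ``u < p_m`` the medium is picked (no draw for a single medium,
   ``rng.integers(M)`` for ``gamma == 0``, one ``rng.random()`` otherwise) and the
   one-sided update applied. A ``p_m = 0`` run is therefore stream-identical to
   the media-free model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "OpinionState",
    "MediaLandscape",
    "ModelConfig",
    "IsolatedNodeError",
    "opinion_distance",
    "selection_weights",
    "pair_update",
    "heterogeneous_pair_update",
    "media_update",
    "simulation_step",
]

DEFAULT_DISTANCE_FLOOR = 1e-4


class IsolatedNodeError(RuntimeError):
    """Raised when the focal agent has no interaction partners."""

    def __init__(self, node: int):
        self.node = node
        super().__init__(f"agent {node} has no neighbors to interact with")


def _check_unit_interval(value: float, name: str) -> float:
    value = float(value)
    if not (0.0 <= value <= 1.0) or not np.isfinite(value):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
    return value


@dataclass
class OpinionState:
    """Per-agent continuous opinions plus the simulation clock.

    Parameters
    ----------
    opinions
        One value per agent, each in ``[0, 1]``. Stored as a float64 array.
    time
        Number of elapsed simulation steps (one step = one pair event).
    """

    opinions: np.ndarray
    time: int = 0

    def __post_init__(self) -> None:
        self.opinions = np.asarray(self.opinions, dtype=np.float64)
        if self.opinions.ndim != 1 or self.opinions.size < 2:
            raise ValueError("opinions must be a 1-D sequence of length >= 2")
        if np.any(~np.isfinite(self.opinions)):
            raise ValueError("opinions must be finite")
        if self.opinions.min() < 0.0 or self.opinions.max() > 1.0:
            raise ValueError("every opinion must lie in [0, 1]")
        self.time = int(self.time)
        if self.time < 0:
            raise ValueError("time must be non-negative")

    @property
    def n(self) -> int:
        return self.opinions.size

    def copy(self) -> "OpinionState":
        return OpinionState(self.opinions.copy(), self.time)


@dataclass(frozen=True)
class MediaLandscape:
    """Fixed opinions of M stubborn media agents (M = 0 is the media-free model)."""

    media_opinions: tuple = ()

    def __post_init__(self) -> None:
        ops = tuple(_check_unit_interval(v, "media opinion") for v in self.media_opinions)
        object.__setattr__(self, "media_opinions", ops)

    @property
    def m(self) -> int:
        return len(self.media_opinions)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.media_opinions, dtype=np.float64)


@dataclass
class ModelConfig:
    """All scalar parameters of a run.

    ``epsilon`` is either a single confidence bound shared by the population or a
    per-agent sequence (heterogeneous mode, which switches the update gate from
    ``<=`` to the strict ``<`` used with data-estimated bounds).
    """

    epsilon: float | Sequence[float]
    gamma: float = 0.0
    mu: float = 0.5
    p_m: float = 0.0
    distance_floor: float = DEFAULT_DISTANCE_FLOOR
    max_iterations: int = 1_000_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if np.ndim(self.epsilon) == 0:
            self.epsilon = _check_unit_interval(self.epsilon, "epsilon")
        else:
            eps = np.asarray(self.epsilon, dtype=np.float64)
            if eps.ndim != 1 or eps.size == 0:
                raise ValueError("heterogeneous epsilon must be a 1-D sequence")
            if eps.min() < 0.0 or eps.max() > 1.0:
                raise ValueError("every per-agent epsilon must lie in [0, 1]")
            self.epsilon = eps
        self.gamma = float(self.gamma)
        if self.gamma < 0.0:
            raise ValueError("gamma must be >= 0")
        self.mu = float(self.mu)
        if not (0.0 < self.mu <= 0.5):
            raise ValueError("mu must lie in (0, 0.5]")
        self.p_m = _check_unit_interval(self.p_m, "p_m")
        self.distance_floor = float(self.distance_floor)
        if self.distance_floor <= 0.0:
            raise ValueError("distance_floor must be positive")
        self.max_iterations = int(self.max_iterations)
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")

    @property
    def heterogeneous(self) -> bool:
        return np.ndim(self.epsilon) == 1

    def epsilon_array(self, n: int) -> np.ndarray:
        """Per-agent confidence bounds broadcast to population size ``n``."""
        if self.heterogeneous:
            eps = np.asarray(self.epsilon, dtype=np.float64)
            if eps.size != n:
                raise ValueError(
                    f"heterogeneous epsilon has length {eps.size}, expected {n}"
                )
            return eps
        return np.full(n, float(self.epsilon))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def opinion_distance(x_a: float, x_b: float) -> float:
    """Absolute opinion distance ``|x_a - x_b|`` between two agents."""
    x_a = _check_unit_interval(x_a, "x_a")
    x_b = _check_unit_interval(x_b, "x_b")
    return abs(x_a - x_b)


def selection_weights(
    focal_opinion: float,
    candidate_opinions: Sequence[float],
    gamma: float,
    distance_floor: float = DEFAULT_DISTANCE_FLOOR,
) -> np.ndarray:
    """Biased partner-selection probabilities ``p(j) ∝ d_j^(-gamma)``.

    Distances are clamped from below at ``distance_floor`` so that identical
    opinions do not produce an undefined weight. ``gamma = 0`` returns an exactly
    uniform distribution.
    """
    candidates = np.asarray(candidate_opinions, dtype=np.float64)
    if candidates.size == 0:
        raise ValueError("candidate_opinions must be non-empty")
    gamma = float(gamma)
    if gamma < 0.0:
        raise ValueError("gamma must be >= 0")
    if distance_floor <= 0.0:
        raise ValueError("distance_floor must be positive")
    if gamma == 0.0:
        return np.full(candidates.size, 1.0 / candidates.size)
    d = np.maximum(np.abs(candidates - float(focal_opinion)), distance_floor)
    w = d ** (-gamma)
    return w / w.sum()


def pair_update(
    x_i: float, x_j: float, epsilon: float, mu: float
) -> tuple[float, float]:
    """Symmetric bounded-confidence update (homogeneous gate ``<= epsilon``).

    If ``|x_i - x_j| <= epsilon`` both agents move a fraction ``mu`` towards each
    other (``mu = 0.5``: both adopt the pair mean); otherwise nothing happens.
    """
    if abs(x_i - x_j) <= epsilon:
        return x_i + mu * (x_j - x_i), x_j + mu * (x_i - x_j)
    return x_i, x_j


def heterogeneous_pair_update(
    x_i: float, x_j: float, eps_i: float, eps_j: float, mu: float
) -> tuple[float, float]:
    """Per-agent-bound update: each side moves iff the distance is strictly below
    its own confidence bound; both conditions use the pre-update opinions."""
    d = abs(x_i - x_j)
    new_i = x_i + mu * (x_j - x_i) if d < eps_i else x_i
    new_j = x_j + mu * (x_i - x_j) if d < eps_j else x_j
    return new_i, new_j


def media_update(
    x_i: float, x_m: float, epsilon_i: float, mu: float, strict: bool = False
) -> float:
    """One-sided update towards a stubborn medium; the medium never moves.

    ``strict`` selects the ``< epsilon`` gate used in heterogeneous-bound runs
    (the homogeneous model gates on ``<=``).
    """
    d = abs(x_i - x_m)
    inside = d < epsilon_i if strict else d <= epsilon_i
    if inside:
        return x_i + mu * (x_m - x_i)
    return x_i


def _pick_weighted(d: np.ndarray, gamma: float, rng: np.random.Generator) -> int:
    """Locate one biased draw in the cumulative weight vector of distances ``d``."""
    w = d ** (-gamma)
    c = np.cumsum(w)
    r = rng.random() * c[-1]
    return min(int(np.searchsorted(c, r, side="right")), d.size - 1)


def _step_inplace(
    x: np.ndarray,
    eps: float | np.ndarray,
    heterogeneous: bool,
    gamma: float,
    mu: float,
    p_m: float,
    floor: float,
    media: np.ndarray,
    rng: np.random.Generator,
    adjacency=None,
) -> float:
    """Execute one step in place; returns the maximum absolute opinion change.

    ``adjacency`` is ``None`` for the mean-field (complete-graph) fast path, or a
    callable ``i -> ndarray of neighbor indices`` for an explicit topology.
    """
    n = x.size
    i = int(rng.integers(n))

    if adjacency is None:
        if gamma == 0.0:
            k = int(rng.integers(n - 1))
            j = k if k < i else k + 1
        else:
            d = np.maximum(np.abs(x - x[i]), floor)
            w = d ** (-gamma)
            w[i] = 0.0
            c = np.cumsum(w)
            r = rng.random() * c[-1]
            j = min(int(np.searchsorted(c, r, side="right")), n - 1)
    else:
        nbrs = adjacency(i)
        if nbrs.size == 0:
            raise IsolatedNodeError(i)
        if gamma == 0.0:
            j = int(nbrs[int(rng.integers(nbrs.size))])
        else:
            d = np.maximum(np.abs(x[nbrs] - x[i]), floor)
            j = int(nbrs[_pick_weighted(d, gamma, rng)])

    x_i, x_j = x[i], x[j]
    d_ij = abs(x_i - x_j)
    change = 0.0
    if heterogeneous:
        if d_ij < eps[i]:
            x[i] = x_i + mu * (x_j - x_i)
        if d_ij < eps[j]:
            x[j] = x_j + mu * (x_i - x_j)
        change = max(abs(x[i] - x_i), abs(x[j] - x_j))
    else:
        if d_ij <= eps:
            x[i] = x_i + mu * (x_j - x_i)
            x[j] = x_j + mu * (x_i - x_j)
            change = abs(x[i] - x_i)

    m = media.size
    if p_m > 0.0 and m > 0 and rng.random() < p_m:
        if m == 1:
            mi = 0
        elif gamma == 0.0:
            mi = int(rng.integers(m))
        else:
            d_m = np.maximum(np.abs(media - x[i]), floor)
            mi = _pick_weighted(d_m, gamma, rng)
        x_m = media[mi]
        eps_i = eps[i] if heterogeneous else eps
        d_m_i = abs(x[i] - x_m)
        inside = d_m_i < eps_i if heterogeneous else d_m_i <= eps_i
        if inside:
            delta = mu * (x_m - x[i])
            x[i] += delta
            change = max(change, abs(delta))
    return change


def simulation_step(
    state: OpinionState,
    neighbors_of,
    media: MediaLandscape,
    config: ModelConfig,
    rng: np.random.Generator,
) -> OpinionState:
    """Execute one simulation step and return the successor state.

    ``neighbors_of`` is ``None`` (mean-field) or a callable mapping an agent index
    to an array of neighbor indices. The input state is not modified.
    """
    x = state.opinions.copy()
    n = x.size
    eps = config.epsilon_array(n) if config.heterogeneous else float(config.epsilon)
    _step_inplace(
        x,
        eps,
        config.heterogeneous,
        config.gamma,
        config.mu,
        config.p_m,
        config.distance_floor,
        media.as_array(),
        rng,
        adjacency=neighbors_of,
    )
    return OpinionState(x, state.time + 1)
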