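"""Dynamic stochastic patch occupancy model (SPOM) on a pulsing stream network.

The metapopulation is a discrete-time Markov chain on the binary occupancy
vector w_i(t). Every day, a vacant patch i is colonized with probability
Φ_C,i = 1 − exp(−C_i Δt) and an occupied patch goes extinct with probability
Φ_E,i = 1 − exp(−E_i Δt), where

    C_i(t) = c · Σ_{j≠i} exp(−d_ij(t)/δ) · S_j(t) · w_j(t−Δt)
    E_i(t) = e / S_i(t)            (Φ_E,i = 1 exactly when node i is dry)

with habitat suitability S_i(t) = Δl_i·W_i·X_i(t) (wetted stream-bed area,
m²), dispersal distance δ (m), colonization rate c (1/(m² d)) and extinction
rate e (m²/d). The pairwise distance d_ij(t) is the along-channel distance
between node centres and is finite only if every node on the tree path
between i and j (endpoints included) is active on day t, so dispersal cannot
cross dry reaches; a dry node can be neither a source (S=0) nor a target (its
own endpoint blocks the path). Updates are synchronous: all draws use the
occupancy of the previous day only.

Because hierarchical activation makes every daily active set a prefix of one
fixed node order, the active-subgraph distances and dispersal kernels are
cached per prefix size (:class:`DispersalCache`), which makes year-long
Monte-Carlo ensembles cheap. An exact 2^N state-distribution propagator is
provided as an independent oracle for small networks.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .activation import ActivationSeries
from .errors import ContractViolationError, ParameterError, SizeError
from .network_gen import StreamNetwork

__all__ = [
    "SpeciesTraits",
    "OccupancyTrajectory",
    "DispersalCache",
    "suitability",
    "active_path_distances",
    "active_path_distance_matrix",
    "colonization_rates",
    "extinction_rates",
    "spom_step",
    "simulate_spom",
    "simulate_spom_ensemble",
    "exact_occupancy_distribution",
]

#: kernel cutoff in units of δ; exp(-23) ≈ 1e-10 bounds the relative
#: truncation error of any colonization rate
KERNEL_CUTOFF_DELTAS = 23.0


@dataclasses.dataclass(frozen=True)
class SpeciesTraits:
    """Species trait triple: colonization rate c (1/(m² d)), extinction rate
    e (m²/d) and dispersal distance δ (m)."""

    c: float
    e: float
    delta: float

    def __post_init__(self):
        if self.c <= 0 or self.e <= 0 or self.delta <= 0:
            raise ParameterError("c, e and delta must all be > 0")
        if not (1e-5 <= self.c <= 1e2):
            warnings.warn(f"c={self.c} outside the usual sweep range [1e-5, 1e2]", stacklevel=2)
        if not (1e-3 <= self.e <= 1e3):
            warnings.warn(f"e={self.e} outside the usual sweep range [1e-3, 1e3]", stacklevel=2)

    @classmethod
    def focal(cls, nnd: float) -> "SpeciesTraits":
        """The representative virtual species: c=0.015 1/(m² d), e=20 m²/d,
        δ = 4 × the network's nearest-neighbour distance."""
        return cls(c=0.015, e=20.0, delta=4.0 * nnd)


@dataclasses.dataclass
class OccupancyTrajectory:
    """Daily occupancy matrix w_i(t) with its provenance."""

    w: np.ndarray  # (T, N) bool
    traits: SpeciesTraits
    seed: object = None
    acts: ActivationSeries | None = None

    @property
    def T(self) -> int:
        return int(self.w.shape[0])

    def occupied_length(self, net: StreamNetwork) -> np.ndarray:
        return self.w @ net.reach_length


def suitability(net: StreamNetwork, active) -> np.ndarray:
    """Habitat suitability S_i = Δl_i · W_i · X_i (m²); zero exactly when dry."""
    if net.width is None:
        raise ParameterError("channel widths must be assigned before suitability")
    return net.reach_length * net.width * np.asarray(active, dtype=float)


def _tree_adjacency(net: StreamNetwork) -> csr_matrix:
    e = net.edges
    w = net.edge_lengths
    n = net.n_nodes
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    return csr_matrix((np.concatenate([w, w]), (rows, cols)), shape=(n, n))


def active_path_distance_matrix(
    net: StreamNetwork, active_mask: np.ndarray, cutoff: float = np.inf
) -> np.ndarray:
    """Full N×N along-channel distance matrix on the active subgraph.

    Entries are ``inf`` whenever the tree path between the two nodes leaves
    the active set (endpoints included) or exceeds ``cutoff``.
    """
    n = net.n_nodes
    D = np.full((n, n), np.inf)
    idx = np.flatnonzero(np.asarray(active_mask, dtype=bool))
    if idx.size == 0:
        return D
    sub = _tree_adjacency(net)[idx][:, idx]
    d = dijkstra(sub, directed=False, limit=cutoff)
    D[np.ix_(idx, idx)] = d
    return D


def active_path_distances(
    net: StreamNetwork,
    active_set,
    sources=None,
    cutoff: float = np.inf,
) -> dict[tuple[int, int], float]:
    """Distances from ``sources`` to every reachable active node.

    Returns a map (source, node) → distance (m) containing only finite
    entries within ``cutoff``. Sources must themselves be active.
    """
    active = np.zeros(net.n_nodes, dtype=bool)
    active[np.asarray(list(active_set), dtype=int)] = True
    if sources is None:
        src = np.flatnonzero(active)
    else:
        src = np.asarray(sorted(set(int(s) for s in sources)), dtype=int)
        if not np.all(active[src]):
            raise ContractViolationError("all source nodes must be active")
    idx = np.flatnonzero(active)
    pos = {int(v): p for p, v in enumerate(idx)}
    sub = _tree_adjacency(net)[idx][:, idx]
    d = dijkstra(sub, directed=False, indices=[pos[int(s)] for s in src], limit=cutoff)
    out: dict[tuple[int, int], float] = {}
    for row, s in zip(d, src):
        finite = np.flatnonzero(np.isfinite(row))
        for p in finite:
            out[(int(s), int(idx[p]))] = float(row[p])
    return out


class DispersalCache:
    """Per-prefix-size cache of active-subgraph distances and kernels.

    Hierarchical activation means every active set is ``order_desc[:size]``;
    distances depend only on the size and are computed once per size, and the
    dispersal kernel exp(−d/δ) (zero diagonal, zero beyond 23·δ) is cached
    per (size, δ).
    """

    def __init__(self, net: StreamNetwork, order_desc: np.ndarray):
        self.net = net
        self.order_desc = np.asarray(order_desc)
        self._adj = _tree_adjacency(net)
        self._dist: dict[int, np.ndarray] = {}
        self._kernel: dict[tuple[int, float], np.ndarray] = {}

    def active_nodes(self, size: int) -> np.ndarray:
        return self.order_desc[:size]

    def distances(self, size: int) -> np.ndarray:
        """Distance matrix among the first ``size`` active nodes (activation order)."""
        D = self._dist.get(size)
        if D is None:
            idx = self.order_desc[:size]
            sub = self._adj[idx][:, idx]
            D = dijkstra(sub, directed=False)
            self._dist[size] = D
        return D

    def kernel(self, size: int, delta: float) -> np.ndarray:
        key = (size, float(delta))
        K = self._kernel.get(key)
        if K is None:
            D = self.distances(size)
            with np.errstate(over="ignore"):
                K = np.where(D <= KERNEL_CUTOFF_DELTAS * delta, np.exp(-D / delta), 0.0)
            np.fill_diagonal(K, 0.0)
            self._kernel[key] = K
        return K


def colonization_rates(
    net: StreamNetwork,
    S: np.ndarray,
    w_prev: np.ndarray,
    traits: SpeciesTraits,
    distances: np.ndarray,
) -> np.ndarray:
    """Colonization rate C_i = c Σ_{j≠i} exp(−d_ij/δ) S_j w_j(prev), 1/d.

    ``distances`` is a full N×N matrix with ``inf`` for blocked pairs;
    ``w_prev`` may carry leading batch dimensions.
    """
    with np.errstate(over="ignore"):
        K = np.where(np.isfinite(distances), np.exp(-distances / traits.delta), 0.0)
    np.fill_diagonal(K, 0.0)
    src = np.asarray(w_prev, dtype=float) * S
    return traits.c * (src @ K)


def extinction_rates(S: np.ndarray, traits: SpeciesTraits, dt: float = 1.0):
    """Extinction rate E_i = e/S_i (1/d) and probability Φ_E = 1 − e^{−E Δt}.

    Dry nodes (S=0) get Φ_E = 1 exactly and an infinite rate — the designated
    guard for the vanishing-suitability limit.
    """
    S = np.asarray(S, dtype=float)
    with np.errstate(divide="ignore"):
        E = np.where(S > 0, traits.e / np.where(S > 0, S, 1.0), np.inf)
    phi_e = np.where(S > 0, -np.expm1(-np.where(np.isfinite(E), E, 0.0) * dt), 1.0)
    return E, phi_e


def spom_step(w_prev: np.ndarray, phi_c: np.ndarray, phi_e: np.ndarray, rng) -> np.ndarray:
    """One synchronous Markov update: vacant→occupied w.p. Φ_C, occupied→vacant
    w.p. Φ_E, independently per node."""
    w_prev = np.asarray(w_prev, dtype=bool)
    p_next = np.where(w_prev, 1.0 - phi_e, phi_c)
    return rng.random(p_next.shape) < p_next


def _update_probability(S_act, K_act, w_prev_act, traits, dt=1.0):
    """P(occupied next | previous state) for the active nodes.

    Shared by the Monte-Carlo engine and the exact oracle so that both
    propagate the identical per-step law. ``w_prev_act`` may carry leading
    batch dimensions.
    """
    src = np.asarray(w_prev_act, dtype=float) * S_act
    C = traits.c * (src @ K_act)
    phi_c = -np.expm1(-C * dt)
    phi_e = -np.expm1(-(traits.e / S_act) * dt)
    return np.where(np.asarray(w_prev_act, dtype=bool), 1.0 - phi_e, phi_c)


def _day_geometry(net, acts, cache, traits, t, memo=None):
    """(active index array, S restricted, kernel restricted) for day t.

    Hierarchical series hit the prefix-size cache; arbitrary wet/dry
    schedules are memoised by activation pattern within one simulation.
    """
    if acts.counts is not None and acts.field is not None and cache is not None:
        size = int(acts.counts[t])
        idx = cache.active_nodes(size)
        K = cache.kernel(size, traits.delta)
    else:
        key = acts.X[t].tobytes()
        hit = memo.get(key) if memo is not None else None
        if hit is None:
            idx = np.flatnonzero(acts.X[t])
            D = active_path_distance_matrix(
                net, acts.X[t], cutoff=KERNEL_CUTOFF_DELTAS * traits.delta
            )
            with np.errstate(over="ignore"):
                K = np.where(np.isfinite(D), np.exp(-D / traits.delta), 0.0)
            np.fill_diagonal(K, 0.0)
            K = K[np.ix_(idx, idx)]
            if memo is not None:
                memo[key] = (idx, K)
        else:
            idx, K = hit
    S = net.reach_length[idx] * net.width[idx]
    return idx, S, K


def _resolve_w0(acts: ActivationSeries, w0) -> np.ndarray:
    if w0 is None:
        w = acts.X[0].copy()
    else:
        w = np.asarray(w0, dtype=bool).copy()
        if np.any(w & ~acts.X[0]):
            raise ContractViolationError("initial occupancy includes a dry node")
    return w


def simulate_spom(
    net: StreamNetwork,
    acts: ActivationSeries,
    traits: SpeciesTraits,
    w0=None,
    seed=0,
    cache: DispersalCache | None = None,
    dt: float = 1.0,
) -> OccupancyTrajectory:
    """Run one daily-resolution SPOM trajectory over an activation series.

    ``w0`` defaults to "every initially active node occupied". The static
    model is the same engine run on a time-constant activation series.
    Whole-network extinction is absorbing, so the loop exits early once no
    node is occupied.
    """
    if net.width is None:
        raise ParameterError("channel widths must be assigned before running the SPOM")
    if cache is None and acts.counts is not None and acts.field is not None:
        cache = DispersalCache(net, acts.field.order_desc)
    rng = np.random.default_rng(seed)
    T, n = acts.X.shape
    w = np.zeros((T, n), dtype=bool)
    w[0] = _resolve_w0(acts, w0)
    memo: dict = {}
    for t in range(1, T):
        if not w[t - 1].any():
            break
        idx, S, K = _day_geometry(net, acts, cache, traits, t, memo)
        if idx.size == 0:
            continue
        p = _update_probability(S, K, w[t - 1, idx], traits, dt)
        w[t, idx] = rng.random(idx.size) < p
    return OccupancyTrajectory(w=w, traits=traits, seed=seed, acts=acts)


def simulate_spom_ensemble(
    net: StreamNetwork,
    acts: ActivationSeries,
    traits: SpeciesTraits,
    n_rep: int,
    w0=None,
    seed=0,
    cache: DispersalCache | None = None,
    dt: float = 1.0,
) -> np.ndarray:
    """Vectorised Monte-Carlo ensemble: ``n_rep`` independent trajectories.

    Uses the same per-step update law as :func:`simulate_spom`, drawing all
    replicates' Bernoulli variables in lockstep; returns a (n_rep, T, N)
    boolean array.
    """
    if cache is None and acts.counts is not None and acts.field is not None:
        cache = DispersalCache(net, acts.field.order_desc)
    rng = np.random.default_rng(seed)
    T, n = acts.X.shape
    w = np.zeros((n_rep, T, n), dtype=bool)
    w[:, 0, :] = _resolve_w0(acts, w0)
    memo: dict = {}
    for t in range(1, T):
        idx, S, K = _day_geometry(net, acts, cache, traits, t, memo)
        if idx.size == 0:
            continue
        p = _update_probability(S, K, w[:, t - 1, idx], traits, dt)
        w[:, t, idx] = rng.random(p.shape) < p
    return w


def exact_occupancy_distribution(
    net: StreamNetwork,
    acts: ActivationSeries,
    traits: SpeciesTraits,
    w0=None,
    dt: float = 1.0,
):
    """Propagate the full 2^N occupancy-state distribution exactly.

    Returns ``(probs, marginals)``: probs[t] is the probability vector over
    the 2^N occupancy states (bit i of the state index = occupancy of node
    i), marginals[t, i] = P(node i occupied on day t). Only feasible for
    N ≤ 12 nodes.
    """
    T, n = acts.X.shape
    if n > 12:
        raise SizeError(f"exact enumeration limited to 12 nodes, got {n}")
    if net.width is None:
        raise ParameterError("channel widths must be assigned")
    states = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(bool)  # (2^n, n)
    probs = np.zeros((T, 2**n))
    w_init = _resolve_w0(acts, w0)
    init_index = int(np.sum(w_init.astype(np.int64) << np.arange(n)))
    probs[0, init_index] = 1.0
    memo: dict = {}
    for t in range(1, T):
        idx, S, K = _day_geometry(net, acts, None, traits, t, memo)
        p_full = np.zeros((2**n, n))
        if idx.size:
            p_full[:, idx] = _update_probability(S, K, states[:, idx], traits, dt)
        # product-form transition: fold one node at a time
        dist = probs[t - 1]
        alive = np.flatnonzero(dist > 0)
        nxt = np.zeros(2**n)
        for s in alive:
            row = np.array([1.0])
            for i in range(n):
                pi = p_full[s, i]
                row = np.concatenate([row * (1.0 - pi), row * pi])
            nxt += dist[s] * row
        probs[t] = nxt
    marginals = probs @ states
    return probs, marginals
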