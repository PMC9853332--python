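"""Hierarchical activation of the stream network by discharge thresholds.

Each reach carries an activation threshold Q*_i: the reach flows on day t iff
Q(t) ≥ Q*_i. Thresholds are assigned by ranking the reaches with a persistency
proxy (random field, TWI or contributing area) and mapping the ranks through
the quantiles of a reference climate's stationary flow distribution, so that
under the reference climate the node persistencies P_i = 1 − F_Q(Q*_i) are the
uniform plotting positions (r + offset)/N and their mean is 0.5. Because all
reaches respond to the same scalar Q(t), activation is hierarchical: reaches
always activate from the most to the least persistent and deactivate in the
reverse order, so the daily active set is a prefix of the persistency-ordered
node list and is fully described by its size.

The module also provides the derived network statistics used to characterise
the pulsing habitat: active length L(t), the length of the largest continuous
portion (LCP) of the active network, exceedance duration curves, and the
static-equivalent network (the most-persistent prefix matching a target
length) used by the static metapopulation runs.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import ParameterError
from .hydrology import ClimateParams, DischargeSeries, stationary_flow_distribution
from .network_gen import ProxyRanking, StreamNetwork

__all__ = [
    "PersistencyField",
    "ActivationSeries",
    "calibrate_thresholds",
    "persistency_under",
    "activate",
    "empirical_persistency",
    "lcp_series",
    "largest_component_length",
    "prefix_lcp_table",
    "duration_curve",
    "static_equivalent",
]


@dataclasses.dataclass
class PersistencyField:
    """Per-node activation thresholds and reference-climate persistencies.

    ``q_star[i]`` (mm/d) is node i's activation threshold and ``p_ref[i]`` its
    persistency under the reference climate (P_i = 1 − F_ref(Q*_i)). Most
    persistent nodes have the lowest thresholds; the persistency ordering
    follows the proxy ranking by construction.
    """

    q_star: np.ndarray
    p_ref: np.ndarray
    ranking: ProxyRanking
    reference: ClimateParams
    net: StreamNetwork
    rank_offset: float = 0.5

    @property
    def order_desc(self) -> np.ndarray:
        """Nodes from most to least persistent (activation order)."""
        return self.ranking.order_desc

    @property
    def thresholds_ascending(self) -> np.ndarray:
        """Q* sorted ascending, i.e. in activation order."""
        return self.q_star[self.order_desc]


@dataclasses.dataclass
class ActivationSeries:
    """Binary wet/dry state of every reach over time.

    ``X`` is the T×N boolean matrix, ``L`` the active length Σ Δl_i X_i(t) in
    metres. When the series comes from hierarchical activation, ``counts[t]``
    is the size of the active prefix (in ``field.order_desc`` order), which
    the SPOM engine uses for caching.
    """

    X: np.ndarray
    L: np.ndarray
    counts: np.ndarray | None = None
    field: PersistencyField | None = None

    @property
    def T(self) -> int:
        return int(self.X.shape[0])

    @property
    def n_nodes(self) -> int:
        return int(self.X.shape[1])

    @classmethod
    def from_matrix(cls, net: StreamNetwork, X: np.ndarray) -> "ActivationSeries":
        X = np.asarray(X, dtype=bool)
        return cls(X=X, L=X @ net.reach_length)


def calibrate_thresholds(
    net: StreamNetwork,
    ranking: ProxyRanking,
    reference_climate: ClimateParams,
    rank_offset: float = 0.5,
) -> PersistencyField:
    """Assign activation thresholds from persistency ranks.

    The node with ascending-persistency rank r gets target persistency
    u_r = (r + rank_offset)/N under the reference climate and threshold
    Q*_i = F_ref^{-1}(1 − u_r); the most persistent node gets the lowest
    threshold and the mean persistency under the reference climate is 0.5
    (for the default half-offset scheme).
    """
    n = net.n_nodes
    order = np.asarray(ranking.order)
    if order.size != n or np.unique(order).size != n:
        raise ParameterError("ranking must be a permutation of all node identifiers")
    if not (0.0 < rank_offset < 1.0):
        raise ParameterError(f"rank_offset must be in (0, 1), got {rank_offset}")
    ranks = ranking.ranks()
    u = (ranks + rank_offset) / n
    dist = stationary_flow_distribution(reference_climate)
    q_star = dist.ppf(1.0 - u)
    return PersistencyField(
        q_star=q_star,
        p_ref=u,
        ranking=ranking,
        reference=reference_climate,
        net=net,
        rank_offset=rank_offset,
    )


def persistency_under(field: PersistencyField, climate: ClimateParams) -> np.ndarray:
    """Node persistencies 1 − F_climate(Q*) when the same physical thresholds
    are driven by a different climate's flow regime."""
    dist = stationary_flow_distribution(climate)
    return 1.0 - dist.cdf(field.q_star)


def activate(q: DischargeSeries, field: PersistencyField) -> ActivationSeries:
    """Map a discharge series to the daily wet/dry matrix X_i(t) = [Q(t) ≥ Q*_i]."""
    thresholds = field.thresholds_ascending
    counts = np.searchsorted(thresholds, q.q, side="right")
    ranks_desc = np.empty(field.net.n_nodes, dtype=np.int64)
    ranks_desc[field.order_desc] = np.arange(field.net.n_nodes)
    X = ranks_desc[None, :] < counts[:, None]
    return ActivationSeries(X=X, L=X @ field.net.reach_length, counts=counts, field=field)


def empirical_persistency(acts: ActivationSeries) -> np.ndarray:
    """Time-mean of X_i(t): the empirical marginal probability of being active."""
    return acts.X.mean(axis=0)


def _adjacency(net: StreamNetwork) -> csr_matrix:
    e = net.edges
    w = net.edge_lengths
    n = net.n_nodes
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    return csr_matrix((np.concatenate([w, w]), (rows, cols)), shape=(n, n))


def largest_component_length(net: StreamNetwork, active_mask: np.ndarray) -> float:
    """Summed reach length of the largest connected active component, m.

    Components are taken on the node-induced subgraph: an edge is active iff
    both endpoints are active. Returns 0 when nothing is active.
    """
    idx = np.flatnonzero(active_mask)
    if idx.size == 0:
        return 0.0
    sub = _adjacency(net)[idx][:, idx]
    _, labels = connected_components(sub, directed=False)
    lengths = np.bincount(labels, weights=net.reach_length[idx])
    return float(lengths.max())


def prefix_lcp_table(net: StreamNetwork, order_desc: np.ndarray) -> np.ndarray:
    """LCP length after activating the first s nodes of ``order_desc``, s=0..N.

    Incremental union-find over the activation order; because nodes are only
    ever added, the running maximum is exact for every prefix.
    """
    n = net.n_nodes
    parent = np.arange(n)
    comp_len = np.zeros(n)
    active = np.zeros(n, dtype=bool)
    ups = net.upstream_lists()
    ds = net.downstream

    def find(i):
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    table = np.zeros(n + 1)
    best = 0.0
    for s, node in enumerate(np.asarray(order_desc), start=1):
        active[node] = True
        comp_len[node] = net.reach_length[node]
        neighbours = list(ups[node])
        if ds[node] >= 0:
            neighbours.append(int(ds[node]))
        for nb in neighbours:
            if active[nb]:
                ra, rb = find(node), find(nb)
                if ra != rb:
                    parent[rb] = ra
                    comp_len[ra] += comp_len[rb]
        best = max(best, comp_len[find(node)])
        table[s] = best
    return table


def lcp_series(net: StreamNetwork, acts: ActivationSeries) -> np.ndarray:
    """Per-day length of the largest continuous portion of active network, m."""
    if acts.counts is not None and acts.field is not None:
        table = prefix_lcp_table(net, acts.field.order_desc)
        return table[acts.counts]
    return np.array([largest_component_length(net, row) for row in acts.X])


def duration_curve(series: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exceedance duration curve of a daily series.

    Returns (values sorted descending, exceedance fraction (j+1)/T): point j
    gives the value equalled or exceeded for that fraction of the time.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 1:
        raise ParameterError("duration_curve needs at least one value")
    values = np.sort(series)[::-1]
    exceedance = np.arange(1, values.size + 1) / values.size
    return values, exceedance


def static_equivalent(
    net: StreamNetwork,
    field: PersistencyField,
    target_length: float,
    T: int = 1,
) -> ActivationSeries:
    """Time-constant active set matching a target flowing length.

    The smallest persistency-descending prefix whose cumulative reach length
    reaches ``target_length``, replicated over ``T`` days.
    """
    total = net.total_length
    if not (0.0 < target_length <= total):
        raise ParameterError(
            f"target_length must be in (0, {total}], got {target_length}"
        )
    order = field.order_desc
    cum = np.cumsum(net.reach_length[order])
    m = int(np.searchsorted(cum, target_length, side="left")) + 1
    mask = np.zeros(net.n_nodes, dtype=bool)
    mask[order[:m]] = True
    X = np.broadcast_to(mask, (T, net.n_nodes)).copy()
    L = np.full(T, float(cum[m - 1]))
    return ActivationSeries(X=X, L=L, counts=np.full(T, m), field=field)


# ---------------------------------------------------------------------------
# export helpers


def activation_to_csv(acts: ActivationSeries, path) -> None:
    """Day × node 0/1 matrix as CSV with a day index column."""
    import pandas as pd

    df = pd.DataFrame(acts.X.astype(int))
    df.insert(0, "day", np.arange(acts.T))
    df.to_csv(path, index=False)


def activation_to_rle_json(acts: ActivationSeries, path=None):
    """Compact per-node run-length encoding: {node: [[start, length], ...]}."""
    runs: dict[str, list[list[int]]] = {}
    for i in range(acts.n_nodes):
        col = acts.X[:, i]
        changes = np.flatnonzero(np.diff(col.astype(np.int8)))
        starts = np.concatenate([[0], changes + 1])
        ends = np.concatenate([changes + 1, [col.size]])
        runs[str(i)] = [
            [int(s), int(e - s)] for s, e in zip(starts, ends) if col[s]
        ]
    payload = {"T": acts.T, "n_nodes": acts.n_nodes, "runs": runs}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(payload, fh)
    return payload


def activation_from_rle_json(payload, net: StreamNetwork) -> ActivationSeries:
    X = np.zeros((payload["T"], payload["n_nodes"]), dtype=bool)
    for node, runs in payload["runs"].items():
        for start, length in runs:
            X[start : start + length, int(node)] = True
    return ActivationSeries.from_matrix(net, X)


def field_to_csv(field: PersistencyField, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "node_id": np.arange(field.net.n_nodes),
            "q_star": field.q_star,
            "p_ref": field.p_ref,
        }
    ).to_csv(path, index=False, float_format="%.17g")
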