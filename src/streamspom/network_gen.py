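"""Synthetic dendritic stream networks and persistency proxies.

A stream network is a rooted drainage tree: each node stands for one uniform
stream reach of length ``reach_length`` and drains to exactly one downstream
neighbour, except the single outlet. Nodes live on a square lattice of spacing
``cell_size`` and each drains the area of its own cell; contributing area is
accumulated down the tree. The geomorphic attributes attached per node
(contributing area A, local slope tanβ, topographic wetness index TWI, channel
width W) drive the persistency ranking of the reaches and the habitat
suitability of the occupancy model.

Two generators are provided:

``lattice_random_tree``
    Invasion-style growth on the 8-neighbour lattice starting from the outlet
    cell: at every step a random frontier cell is attached to a random adjacent
    tree cell, which becomes its downstream neighbour. Produces a compact,
    dendritic drainage blob with an exact node count.

``scheidegger``
    A classic directed-random-walk drainage pattern on a strip: every node
    drains diagonally to one of its two downslope neighbours at random, and the
    bottom row forms a trunk channel collecting into a corner outlet.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .errors import DataError, NetworkStructureError, ParameterError

__all__ = [
    "StreamNetwork",
    "ProxyRanking",
    "generate_network",
    "compute_contributing_area",
    "compute_twi",
    "assign_slopes",
    "compute_width",
    "proxy_ranking",
    "write_network",
    "read_network",
]

_NEIGHBOURS_8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclasses.dataclass
class StreamNetwork:
    """A rooted drainage tree with per-reach geomorphic attributes.

    Attributes
    ----------
    downstream
        Integer array of shape (N,); ``downstream[i]`` is the node that reach
        ``i`` drains into, or ``-1`` for the outlet.
    xy
        Node-centre planar coordinates in metres, shape (N, 2).
    reach_length
        Reach length Δl_i in metres (the length of the outflow link; the
        outlet is assigned one cell size).
    cell_area
        Own lattice-cell area per node, m².
    cell_size
        Lattice spacing in metres (also the contour width used by the TWI).
    area, slope, twi, width
        Contributing area A_i (m²), local slope tanβ_i (-), topographic
        wetness index (-), channel width W_i (m). ``area`` is filled by the
        generator; the others are attached by :func:`assign_slopes`,
        :func:`compute_twi` and :func:`compute_width`.
    """

    downstream: np.ndarray
    xy: np.ndarray
    reach_length: np.ndarray
    cell_area: np.ndarray
    cell_size: float
    area: np.ndarray | None = None
    slope: np.ndarray | None = None
    twi: np.ndarray | None = None
    width: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return int(self.downstream.size)

    @property
    def outlet(self) -> int:
        outlets = np.flatnonzero(self.downstream < 0)
        if outlets.size != 1:
            raise NetworkStructureError(f"expected exactly one outlet, found {outlets.size}")
        return int(outlets[0])

    @property
    def edges(self) -> np.ndarray:
        """(N-1, 2) array of (upstream, downstream) node pairs."""
        up = np.flatnonzero(self.downstream >= 0)
        return np.column_stack([up, self.downstream[up]])

    @property
    def edge_lengths(self) -> np.ndarray:
        """Along-channel separation of adjacent node centres, m."""
        e = self.edges
        return np.linalg.norm(self.xy[e[:, 0]] - self.xy[e[:, 1]], axis=1)

    @property
    def nnd(self) -> float:
        """Nearest-neighbour distance: mean separation of adjacent nodes, m."""
        return float(self.edge_lengths.mean())

    @property
    def total_length(self) -> float:
        return float(self.reach_length.sum())

    def upstream_lists(self) -> list[list[int]]:
        ups: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, j in self.edges:
            ups[j].append(i)
        return ups

    def leaves(self) -> np.ndarray:
        """Headwater nodes: nodes with no upstream neighbour."""
        indeg = np.zeros(self.n_nodes, dtype=int)
        np.add.at(indeg, self.downstream[self.downstream >= 0], 1)
        return np.flatnonzero(indeg == 0)

    def validate(self) -> None:
        """Raise if the structural invariants do not hold."""
        _ = self.outlet  # exactly one outlet
        compute_contributing_area(self)  # raises on cycles
        if np.any(self.reach_length <= 0):
            raise NetworkStructureError("non-positive reach length")
        if self.area is not None:
            recomputed = compute_contributing_area(self)
            if not np.allclose(self.area, recomputed):
                raise NetworkStructureError("stored contributing areas are inconsistent")


@dataclasses.dataclass(frozen=True)
class ProxyRanking:
    """Node ordering by a persistency proxy.

    ``order`` lists node identifiers from lowest to highest persistency proxy;
    position in ``order`` is the ascending persistency rank.
    """

    scenario: str
    order: np.ndarray

    def ranks(self) -> np.ndarray:
        """ranks[i] = ascending-persistency rank of node i (0 = least persistent)."""
        r = np.empty_like(self.order)
        r[self.order] = np.arange(self.order.size)
        return r

    @property
    def order_desc(self) -> np.ndarray:
        """Nodes from most to least persistent (hierarchical activation order)."""
        return self.order[::-1]


def generate_network(
    n_nodes: int,
    cell_size: float = 100.0,
    seed=0,
    style: str = "lattice_random_tree",
) -> StreamNetwork:
    """Generate a synthetic drainage tree with ``n_nodes`` reaches.

    Deterministic for a fixed ``seed``. Reach lengths are ``cell_size`` for
    axis-aligned drainage steps and ``cell_size·√2`` for diagonal ones.
    Contributing areas are filled on return.
    """
    if n_nodes < 2:
        raise ParameterError(f"n_nodes must be >= 2, got {n_nodes}")
    if cell_size <= 0:
        raise ParameterError(f"cell_size must be > 0, got {cell_size}")
    rng = np.random.default_rng(seed)
    if style == "lattice_random_tree":
        cells, downstream = _lattice_random_tree(n_nodes, rng)
    elif style == "scheidegger":
        cells, downstream = _scheidegger(n_nodes, rng)
    else:
        raise ParameterError(f"unknown network style {style!r}")

    xy = cells.astype(float) * cell_size
    ds = np.asarray(downstream, dtype=np.int64)
    reach_length = np.full(n_nodes, cell_size, dtype=float)
    up = np.flatnonzero(ds >= 0)
    reach_length[up] = np.linalg.norm(xy[up] - xy[ds[up]], axis=1)
    net = StreamNetwork(
        downstream=ds,
        xy=xy,
        reach_length=reach_length,
        cell_area=np.full(n_nodes, cell_size**2, dtype=float),
        cell_size=float(cell_size),
    )
    net.area = compute_contributing_area(net)
    return net


def _lattice_random_tree(n_nodes: int, rng) -> tuple[np.ndarray, list[int]]:
    """Invasion growth of a drainage tree on the 8-neighbour lattice."""
    node_of: dict[tuple[int, int], int] = {(0, 0): 0}
    downstream = [-1]
    cells = [(0, 0)]
    frontier = list(_NEIGHBOURS_8)
    in_frontier = set(frontier)
    while len(cells) < n_nodes:
        idx = int(rng.integers(len(frontier)))
        cell = frontier[idx]
        frontier[idx] = frontier[-1]
        frontier.pop()
        in_frontier.discard(cell)
        occ = [node_of[(cell[0] + dr, cell[1] + dc)]
               for dr, dc in _NEIGHBOURS_8
               if (cell[0] + dr, cell[1] + dc) in node_of]
        target = occ[int(rng.integers(len(occ)))]
        node_of[cell] = len(cells)
        downstream.append(target)
        cells.append(cell)
        for dr, dc in _NEIGHBOURS_8:
            nb = (cell[0] + dr, cell[1] + dc)
            if nb not in node_of and nb not in in_frontier:
                frontier.append(nb)
                in_frontier.add(nb)
    return np.asarray(cells), downstream


def _scheidegger(n_nodes: int, rng) -> tuple[np.ndarray, list[int]]:
    """Directed-random-walk drainage on a strip with a bottom trunk channel."""
    w = max(2, int(round(math.sqrt(n_nodes / 2.0))))
    w = min(w, n_nodes - 1)
    cells: list[tuple[int, int]] = []
    node_of: dict[tuple[int, int], int] = {}
    # bottom trunk row, outlet at (0, 0) draining leftwards
    for c in range(min(w, n_nodes)):
        node_of[(0, c)] = len(cells)
        cells.append((0, c))
    r = 1
    while len(cells) < n_nodes:
        row_w = min(w, n_nodes - len(cells))
        for c in range(row_w):
            node_of[(r, c)] = len(cells)
            cells.append((r, c))
        r += 1
    downstream = []
    for (r, c) in cells:
        if r == 0:
            downstream.append(-1 if c == 0 else node_of[(0, c - 1)])
        else:
            step = int(rng.choice((-1, 1)))
            tc = c + step
            if (r - 1, tc) not in node_of:
                tc = c - step
            if (r - 1, tc) not in node_of:
                tc = c  # degenerate narrow row: drain straight down
            downstream.append(node_of[(r - 1, tc)])
    return np.asarray(cells), downstream


def compute_contributing_area(net: StreamNetwork) -> np.ndarray:
    """Accumulate contributing area down the tree.

    Returns the map node → A_i (m²): the node's own cell area plus the areas
    of all immediately-upstream nodes. Idempotent (always recomputed from the
    cell areas). Raises :class:`NetworkStructureError` on cycles.
    """
    n = net.n_nodes
    ds = net.downstream
    indeg = np.zeros(n, dtype=np.int64)
    np.add.at(indeg, ds[ds >= 0], 1)
    area = net.cell_area.astype(float).copy()
    stack = list(np.flatnonzero(indeg == 0))
    seen = 0
    deg = indeg.copy()
    while stack:
        i = stack.pop()
        seen += 1
        j = ds[i]
        if j >= 0:
            area[j] += area[i]
            deg[j] -= 1
            if deg[j] == 0:
                stack.append(int(j))
    if seen != n:
        raise NetworkStructureError("cycle detected in downstream map")
    return area


def compute_twi(net: StreamNetwork, contour_width: float | None = None) -> np.ndarray:
    """Topographic wetness index TWI_i = ln((A_i / w_c) / tanβ_i).

    ``w_c`` defaults to the lattice cell size. Requires areas and slopes.
    """
    if net.area is None or net.slope is None:
        raise ParameterError("areas and slopes must be assigned before computing TWI")
    w_c = net.cell_size if contour_width is None else contour_width
    if w_c <= 0:
        raise ParameterError("contour width must be > 0")
    if np.any(net.area <= 0) or np.any(net.slope <= 0):
        raise ParameterError("TWI requires strictly positive areas and slopes")
    return np.log((net.area / w_c) / net.slope)


def assign_slopes(
    net: StreamNetwork,
    seed=0,
    exponent: float = -0.5,
    noise_sd: float = 0.5,
    s0: float = 0.05,
) -> np.ndarray:
    """Local slope tanβ_i = s0·(A_i/A_outlet)^exponent · exp(ε_i), ε~N(0, sd²).

    The power law makes slopes decline downstream; the lognormal noise makes
    the TWI an imperfect (rank-scrambled) proxy of contributing area, which is
    what lets TWI-ranked persistency produce occasional network disconnections.
    """
    if net.area is None:
        raise ParameterError("areas must be assigned before slopes")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rel = net.area / net.area[net.outlet]
    eps = rng.normal(0.0, noise_sd, net.n_nodes) if noise_sd > 0 else np.zeros(net.n_nodes)
    return s0 * rel**exponent * np.exp(eps)


def compute_width(net: StreamNetwork, k_w: float | None = None, b_w: float = 0.5) -> np.ndarray:
    """Channel width from contributing area: W_i = k_w · A_i^{b_w}.

    By default ``k_w`` is calibrated so that a 10 km² (1e7 m²) catchment has a
    15 m wide outlet channel.
    """
    if net.area is None:
        raise ParameterError("areas must be assigned before widths")
    if k_w is None:
        k_w = 15.0 / (1.0e7**b_w)
    if k_w <= 0:
        raise ParameterError("k_w must be > 0")
    return k_w * net.area**b_w


def proxy_ranking(net: StreamNetwork, scenario: str, seed=0) -> ProxyRanking:
    """Rank nodes by a persistency proxy, ascending (least persistent first).

    ``scenario`` is one of ``random`` (uniform draws), ``twi`` or ``area``.
    Ties are broken by node identifier; deterministic per seed.
    """
    n = net.n_nodes
    if scenario == "random":
        key = np.random.default_rng(seed).random(n)
    elif scenario == "twi":
        if net.twi is None:
            raise ParameterError("TWI must be assigned for the twi scenario")
        key = net.twi
    elif scenario == "area":
        if net.area is None:
            raise ParameterError("areas must be assigned for the area scenario")
        key = net.area
    else:
        raise ParameterError(f"unknown persistency scenario {scenario!r}")
    order = np.lexsort((np.arange(n), key))
    return ProxyRanking(scenario=scenario, order=order)


_COLUMNS = ["node_id", "downstream_id", "x", "y", "reach_length_m", "area_m2", "slope", "twi", "width_m"]


def network_to_frame(net: StreamNetwork) -> pd.DataFrame:
    n = net.n_nodes
    ds = pd.array([int(d) if d >= 0 else pd.NA for d in net.downstream], dtype="Int64")

    def col(a):
        return a if a is not None else np.full(n, np.nan)

    return pd.DataFrame(
        {
            "node_id": np.arange(n),
            "downstream_id": ds,
            "x": net.xy[:, 0],
            "y": net.xy[:, 1],
            "reach_length_m": net.reach_length,
            "area_m2": col(net.area),
            "slope": col(net.slope),
            "twi": col(net.twi),
            "width_m": col(net.width),
        }
    )


def network_from_frame(df: pd.DataFrame, cell_size: float) -> StreamNetwork:
    df = df.sort_values("node_id").reset_index(drop=True)
    ds = df["downstream_id"].to_numpy(dtype=object)
    downstream = np.array([-1 if pd.isna(d) else int(d) for d in ds], dtype=np.int64)

    def opt(name):
        a = df[name].to_numpy(dtype=float)
        return None if np.all(np.isnan(a)) else a

    return StreamNetwork(
        downstream=downstream,
        xy=np.column_stack([df["x"].to_numpy(float), df["y"].to_numpy(float)]),
        reach_length=df["reach_length_m"].to_numpy(float),
        cell_area=np.full(len(df), cell_size**2, dtype=float),
        cell_size=float(cell_size),
        area=opt("area_m2"),
        slope=opt("slope"),
        twi=opt("twi"),
        width=opt("width_m"),
    )


def write_network(net: StreamNetwork, path) -> None:
    """Write the node table as CSV (lossless float round-trip)."""
    df = network_to_frame(net)
    with open(path, "w") as fh:
        fh.write(f"# cell_size_m={net.cell_size!r}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_network(path) -> StreamNetwork:
    """Read a node-table CSV written by :func:`write_network`."""
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# cell_size_m="):
            raise DataError(f"not a streamspom network file (first line {first!r})")
        cell_size = float(first.split("=", 1)[1])
        df = pd.read_csv(fh, dtype={"downstream_id": "Int64"}, float_precision="round_trip")
    return network_from_frame(df, cell_size)
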