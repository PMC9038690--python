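"""Hexagonal lattice over a circular domain.

Nodes form a triangular point lattice (each interior node has six
neighbours), which is the node set of a hexagonal tiling.  Axial
coordinates with flat-topped orientation are used throughout; the
centre-to-centre distance between adjacent nodes is ``sqrt(3) * side_length``.

The lattice is immutable once built.  Occupancy (which strain, if any,
sits on each node) is a separate mutable structure so that one lattice can
back many simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EMPTY",
    "PRODUCER",
    "CONSUMER",
    "HexLattice",
    "Occupancy",
    "build_lattice",
    "frontier_nodes",
    "shortest_path_to_edge",
]

#: strain labels used in every occupancy array
EMPTY, PRODUCER, CONSUMER = 0, 1, 2

#: axial-coordinate offsets of the six neighbours
_AXIAL_DIRS = ((1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1))


class InvalidConfigurationError(ValueError):
    """Raised for geometrically impossible or inconsistent configuration."""


@dataclass(frozen=True, eq=False)
class HexLattice:
    """Immutable node geometry and adjacency of the simulation disk.

    Attributes
    ----------
    side_length : float
        Hexagon side length in µm.  Adjacent node centres are
        ``sqrt(3) * side_length`` apart.
    domain_diameter : float
        Diameter of the circular domain in µm.
    positions : ndarray, shape (n_nodes, 2)
        Node centre coordinates in µm, origin at the domain centre.
    neighbors : ndarray, shape (n_nodes, 6), dtype int32
        Neighbouring node ids, padded with -1 where a node has fewer than
        six neighbours (domain periphery).
    axial : ndarray, shape (n_nodes, 2), dtype int64
        Axial (q, r) coordinates of each node.
    """

    side_length: float
    domain_diameter: float
    positions: np.ndarray
    neighbors: np.ndarray
    axial: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.positions.shape[0]

    @property
    def spacing(self) -> float:
        """Centre-to-centre distance of adjacent nodes, µm."""
        return np.sqrt(3.0) * self.side_length

    @property
    def node_area(self) -> float:
        """Area of the Voronoi cell of one node, µm²."""
        return 0.5 * np.sqrt(3.0) * self.spacing**2

    @property
    def degrees(self) -> np.ndarray:
        return (self.neighbors >= 0).sum(axis=1)

    def boundary_nodes(self) -> np.ndarray:
        """Ids of peripheral nodes (fewer than six neighbours)."""
        return np.flatnonzero(self.degrees < 6)

    def radii(self) -> np.ndarray:
        """Distance of every node centre from the domain centre, µm."""
        return np.hypot(self.positions[:, 0], self.positions[:, 1])

    def to_csv(self, path) -> None:
        """Write node geometry as CSV (node_id, x_um, y_um)."""
        pd.DataFrame(
            {
                "node_id": np.arange(self.n_nodes),
                "x_um": self.positions[:, 0],
                "y_um": self.positions[:, 1],
            }
        ).to_csv(path, index=False)


def build_lattice(domain_diameter: float, side_length: float) -> HexLattice:
    """Build the hexagonal lattice covering a circular domain.

    Parameters
    ----------
    domain_diameter : float
        Diameter of the disk in µm.
    side_length : float
        Hexagon side length in µm.

    Returns
    -------
    HexLattice

    Raises
    ------
    InvalidConfigurationError
        If ``side_length <= 0`` or ``domain_diameter <= 2 * side_length``.
    """
    if side_length <= 0:
        raise InvalidConfigurationError(f"side_length must be > 0, got {side_length}")
    if domain_diameter <= 2 * side_length:
        raise InvalidConfigurationError(
            f"domain_diameter ({domain_diameter}) must exceed 2 x side_length "
            f"({2 * side_length})"
        )

    spacing = np.sqrt(3.0) * side_length
    radius = domain_diameter / 2.0
    # enumerate axial coordinates in a bounding box, keep nodes inside the disk
    m = int(np.ceil(radius / spacing * 2.0)) + 2
    q, r = np.meshgrid(np.arange(-m, m + 1), np.arange(-m, m + 1), indexing="ij")
    q = q.ravel()
    r = r.ravel()
    x = spacing * (q + 0.5 * r)
    y = spacing * (np.sqrt(3.0) / 2.0) * r
    inside = x * x + y * y <= radius * radius + 1e-9
    q, r, x, y = q[inside], r[inside], x[inside], y[inside]

    order = np.lexsort((q, r))  # deterministic node numbering
    q, r, x, y = q[order], r[order], x[order], y[order]
    n = q.size
    index = {(int(qq), int(rr)): i for i, (qq, rr) in enumerate(zip(q, r))}

    neighbors = np.full((n, 6), -1, dtype=np.int32)
    for i, (qq, rr) in enumerate(zip(q, r)):
        for k, (dq, dr) in enumerate(_AXIAL_DIRS):
            j = index.get((int(qq) + dq, int(rr) + dr))
            if j is not None:
                neighbors[i, k] = j

    return HexLattice(
        side_length=float(side_length),
        domain_diameter=float(domain_diameter),
        positions=np.column_stack([x, y]).astype(float),
        neighbors=neighbors,
        axial=np.column_stack([q, r]).astype(np.int64),
    )


@dataclass
class Occupancy:
    """Mutable per-node cell state: one strain per node plus pseudo-3D layers.

    ``strain`` holds EMPTY/PRODUCER/CONSUMER; ``biomass`` is the dry mass
    (kg) of the lattice-resident cell; ``layers`` counts stacked daughter
    cells aggregated above the node and ``stacked_biomass`` their total
    mass.  Strain mutual exclusivity is structural: there is a single
    strain label per node.
    """

    strain: np.ndarray
    biomass: np.ndarray
    layers: np.ndarray
    stacked_biomass: np.ndarray

    @classmethod
    def empty(cls, lattice: HexLattice) -> "Occupancy":
        n = lattice.n_nodes
        return cls(
            strain=np.zeros(n, dtype=np.int8),
            biomass=np.zeros(n, dtype=float),
            layers=np.zeros(n, dtype=np.int32),
            stacked_biomass=np.zeros(n, dtype=float),
        )

    def copy(self) -> "Occupancy":
        return Occupancy(
            self.strain.copy(),
            self.biomass.copy(),
            self.layers.copy(),
            self.stacked_biomass.copy(),
        )

    def occupied(self) -> np.ndarray:
        return np.flatnonzero(self.strain != EMPTY)

    def cell_count(self) -> int:
        """Lattice-resident cells plus stacked layers."""
        return int((self.strain != EMPTY).sum() + self.layers.sum())

    def total_biomass(self) -> float:
        return float(self.biomass.sum() + self.stacked_biomass.sum())

    def validate(self) -> None:
        empty = self.strain == EMPTY
        if self.layers[empty].any() or self.biomass[empty].any():
            raise ValueError("empty nodes must carry no biomass or layers")
        if (self.layers < 0).any():
            raise ValueError("negative layer count")

    def to_csv(self, path) -> None:
        occ = self.occupied()
        pd.DataFrame(
            {
                "node_id": occ,
                "strain": self.strain[occ],
                "biomass_kg": self.biomass[occ],
                "layers": self.layers[occ],
                "stacked_biomass_kg": self.stacked_biomass[occ],
            }
        ).to_csv(path, index=False)


def frontier_nodes(occupancy: Occupancy, lattice: HexLattice) -> np.ndarray:
    """Ids of occupied nodes having at least one empty neighbouring node.

    Missing neighbours (off the domain) do not count as empty.
    """
    nb = lattice.neighbors
    nb_strain = occupancy.strain[np.clip(nb, 0, None)]
    empty_nb = (nb_strain == EMPTY) & (nb >= 0)
    return np.flatnonzero((occupancy.strain != EMPTY) & empty_nb.any(axis=1))


def _has_empty_neighbor(node: int, strain: np.ndarray, neighbors: np.ndarray) -> bool:
    for j in neighbors[node]:
        if j >= 0 and strain[j] == EMPTY:
            return True
    return False


def shortest_path_to_edge(
    node: int,
    occupancy: Occupancy,
    lattice: HexLattice,
    rng: np.random.Generator,
    max_depth: int | None = None,
) -> tuple[list[int], int] | None:
    """Shortest occupied path from ``node`` to the expansion edge.

    The expansion edge is the set of frontier nodes (occupied with an
    empty neighbour).  Returns ``(path, length)`` where ``path`` goes from
    ``node`` to a frontier node through occupied nodes and ``length`` is
    the hop count (0 if ``node`` is itself on the frontier).  Ties between
    equally short frontier targets and between predecessors are broken
    uniformly at random with ``rng``.

    Returns None if no frontier node is reachable within ``max_depth``
    hops (or at all, for a colony that has filled the domain).

    Raises
    ------
    ValueError
        If ``node`` is empty.
    """
    strain = occupancy.strain
    if strain[node] == EMPTY:
        raise ValueError(f"node {node} is empty")
    nb = lattice.neighbors
    if _has_empty_neighbor(node, strain, nb):
        return [int(node)], 0

    # BFS through occupied nodes; first depth at which a frontier node
    # appears is the shortest distance.
    dist = {int(node): 0}
    layer = [int(node)]
    depth = 0
    hits: list[int] = []
    while layer and not hits:
        depth += 1
        if max_depth is not None and depth > max_depth:
            return None
        nxt = []
        for u in layer:
            for v in nb[u]:
                v = int(v)
                if v < 0 or v in dist or strain[v] == EMPTY:
                    continue
                dist[v] = depth
                if _has_empty_neighbor(v, strain, nb):
                    hits.append(v)
                else:
                    nxt.append(v)
        layer = nxt
    if not hits:
        return None

    target = int(hits[rng.integers(len(hits))]) if len(hits) > 1 else hits[0]
    # walk back choosing uniformly among predecessors one hop closer
    path = [target]
    cur = target
    for d in range(depth - 1, -1, -1):
        preds = [int(v) for v in nb[cur] if v >= 0 and dist.get(int(v)) == d]
        cur = int(preds[rng.integers(len(preds))]) if len(preds) > 1 else preds[0]
        path.append(cur)
    path.reverse()
    return path, depth
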