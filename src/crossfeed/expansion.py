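"""Cell division, edge-directed shoving, and pseudo-3D stacking.

When a cell reaches its division mass it splits 50/50.  The daughter
goes to a uniformly chosen empty neighbour if one exists; otherwise the
shortest occupied path to the expansion edge is found and, if shorter
than the shoving threshold (100 µm ≙ 5 grid nodes by default), every
cell on the path is shoved one node outward, the frontier cell steps
into a random empty neighbour, and the daughter takes the vacated node
next to the divider.  If the edge is too far the daughter is stacked in
a layer above the divider's node.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lattice_domain import (
    EMPTY,
    HexLattice,
    Occupancy,
    shortest_path_to_edge,
)

__all__ = [
    "DEFAULT_SHOVE_CUTOFF_UM",
    "shove_threshold_nodes",
    "ShoveResult",
    "DivisionOutcome",
    "shove_toward_edge",
    "attempt_division",
]

#: maximum divider-to-edge distance at which shoving is attempted, µm
DEFAULT_SHOVE_CUTOFF_UM = 100.0


def shove_threshold_nodes(cutoff_um: float = DEFAULT_SHOVE_CUTOFF_UM, side_length_um: float = 20.0) -> int:
    """Shoving-eligibility threshold in whole grid nodes.

    A divider is eligible when its graph distance to the expansion edge
    is strictly below this threshold.  The distance cutoff is expressed
    in grid nodes at one side length per hop (100 µm on a 20 µm lattice
    gives 5 nodes).
    """
    if cutoff_um <= 0 or side_length_um <= 0:
        raise ValueError("cutoff and side length must be positive")
    return int(np.floor(cutoff_um / side_length_um + 1e-12))


@dataclass
class ShoveResult:
    """Outcome of a shove attempt.

    ``chain`` lists the node ids whose occupants moved, from the node
    nearest the divider to the frontier node; ``vacated`` is the node
    freed for the daughter and ``target`` the empty node the frontier
    cell stepped into.
    """

    success: bool
    chain: list[int] = field(default_factory=list)
    vacated: int | None = None
    target: int | None = None
    path_length: int | None = None


def _empty_neighbors(node: int, occupancy: Occupancy, lattice: HexLattice) -> list[int]:
    return [
        int(j)
        for j in lattice.neighbors[node]
        if j >= 0 and occupancy.strain[j] == EMPTY
    ]


def shove_toward_edge(
    node: int,
    occupancy: Occupancy,
    lattice: HexLattice,
    rng: np.random.Generator,
    threshold: int = None,
) -> ShoveResult:
    """Shove the occupied chain between ``node`` and the edge one step out.

    On success the occupancy is modified in place: strain labels and
    biomass travel with their cells, and exactly one node (returned as
    ``vacated``) becomes empty.  Fails without state change when the
    edge is farther than the threshold or unreachable.
    """
    if threshold is None:
        threshold = shove_threshold_nodes(side_length_um=lattice.side_length)
    if occupancy.strain[node] == EMPTY:
        raise ValueError(f"node {node} is empty")

    found = shortest_path_to_edge(node, occupancy, lattice, rng, max_depth=threshold - 1)
    if found is None:
        return ShoveResult(success=False)
    path, length = found
    if length >= threshold:
        return ShoveResult(success=False, path_length=length)

    frontier = path[-1]
    empties = _empty_neighbors(frontier, occupancy, lattice)
    if not empties:  # cannot happen for a frontier node, kept as a guard
        return ShoveResult(success=False, path_length=length)
    target = int(empties[rng.integers(len(empties))]) if len(empties) > 1 else empties[0]

    # move cells outward starting from the frontier; the divider (path[0])
    # moves only in the degenerate length-0 case
    chain = path if length == 0 else path[1:]
    dests = chain[1:] + [target]
    strain, biomass = occupancy.strain, occupancy.biomass
    layers, stacked = occupancy.layers, occupancy.stacked_biomass
    for src, dst in zip(reversed(chain), reversed(dests)):
        strain[dst] = strain[src]
        biomass[dst] = biomass[src]
        layers[dst] = layers[src]
        stacked[dst] = stacked[src]
    vacated = chain[0]
    strain[vacated] = EMPTY
    biomass[vacated] = 0.0
    layers[vacated] = 0
    stacked[vacated] = 0.0
    return ShoveResult(True, chain=list(chain), vacated=vacated, target=target, path_length=length)


@dataclass
class DivisionOutcome:
    """How (and whether) a division was resolved."""

    kind: str  # "none", "placed-adjacent", "shoved", "stacked"
    daughter_node: int | None = None
    shove: ShoveResult | None = None


def attempt_division(
    node: int,
    occupancy: Occupancy,
    lattice: HexLattice,
    rng: np.random.Generator,
    division_mass: float,
    threshold: int = None,
) -> DivisionOutcome:
    """Divide the cell at ``node`` if it has reached its division mass.

    The mother keeps half the biomass on its node.  The daughter is
    placed in a uniformly chosen empty neighbour, or via shoving, or —
    if the edge is beyond the shove threshold — stacked in a layer above
    the node.  Total biomass is conserved exactly.
    """
    if occupancy.strain[node] == EMPTY:
        raise ValueError(f"node {node} is empty")
    if occupancy.biomass[node] < division_mass:
        return DivisionOutcome("none")

    half = occupancy.biomass[node] / 2.0
    strain = int(occupancy.strain[node])

    empties = _empty_neighbors(node, occupancy, lattice)
    if empties:
        daughter = int(empties[rng.integers(len(empties))]) if len(empties) > 1 else empties[0]
        occupancy.biomass[node] = half
        occupancy.strain[daughter] = strain
        occupancy.biomass[daughter] = half
        return DivisionOutcome("placed-adjacent", daughter_node=daughter)

    shove = shove_toward_edge(node, occupancy, lattice, rng, threshold=threshold)
    if shove.success:
        occupancy.biomass[node] = half
        occupancy.strain[shove.vacated] = strain
        occupancy.biomass[shove.vacated] = half
        return DivisionOutcome("shoved", daughter_node=shove.vacated, shove=shove)

    occupancy.biomass[node] = half
    occupancy.layers[node] += 1
    occupancy.stacked_biomass[node] += half
    return DivisionOutcome("stacked", daughter_node=node)
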