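"""Solute fields on the lattice: carbon, nitrate and nitrite.

Transport is node-to-node Fickian diffusion in finite-volume form: the
exchange coefficient between two adjacent nodes is derived from the
diffusion coefficient, the shared Voronoi edge length, the centre
distance and the node area, so mass balance is exact by construction.

Two integrators are provided:

* :func:`diffuse` — explicit Euler, internally sub-stepped below the
  stability limit (safety factor 0.2) so any outer ``dt`` is safe.  This
  is the reference scheme.
* :class:`ImplicitDiffusion` — backward Euler with a pre-factorised
  sparse operator.  Unconditionally stable, mass-conserving and
  positivity-preserving; used by the simulator for speed on large
  lattices.

Concentrations are mM; diffusivities µm²/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .lattice_domain import HexLattice

__all__ = [
    "SOLUTES",
    "NutrientField",
    "diffuse",
    "apply_sources",
    "ImplicitDiffusion",
]

SOLUTES = ("carbon", "no3", "no2")

#: default diffusivities, µm²/s — small solutes in ~1.5 % agar at room
#: temperature (acetate/nitrate/nitrite class, ~0.8–1.2e-9 m²/s in water,
#: reduced ~10–20 % by the gel).  Configurable; order of magnitude is what
#: matters for the qualitative substrate landscapes.
DEFAULT_DIFFUSIVITY = {"carbon": 600.0, "no3": 1200.0, "no2": 1200.0}


class InvalidStateError(ValueError):
    """Raised when a field holds physically impossible values."""


@dataclass
class NutrientField:
    """Per-node concentrations of the three solutes plus boundary sources."""

    conc: dict[str, np.ndarray]
    diffusivity: dict[str, float]
    boundary_nodes: np.ndarray
    boundary_values: dict[str, float]

    @classmethod
    def uniform(
        cls,
        lattice: HexLattice,
        values: dict[str, float],
        diffusivity: dict[str, float] | None = None,
        boundary_nodes: np.ndarray | None = None,
        boundary_values: dict[str, float] | None = None,
    ) -> "NutrientField":
        n = lattice.n_nodes
        return cls(
            conc={s: np.full(n, float(values.get(s, 0.0))) for s in SOLUTES},
            diffusivity=dict(diffusivity or DEFAULT_DIFFUSIVITY),
            boundary_nodes=(
                np.asarray(boundary_nodes, dtype=np.int64)
                if boundary_nodes is not None
                else np.empty(0, dtype=np.int64)
            ),
            boundary_values=dict(boundary_values or {}),
        )

    def copy(self) -> "NutrientField":
        return NutrientField(
            conc={s: c.copy() for s, c in self.conc.items()},
            diffusivity=dict(self.diffusivity),
            boundary_nodes=self.boundary_nodes.copy(),
            boundary_values=dict(self.boundary_values),
        )

    def total(self, solute: str) -> float:
        """Summed concentration over all nodes (mM · node)."""
        return float(self.conc[solute].sum())

    def total_moles(self, solute: str, node_volume_l: float) -> float:
        """Total amount in mol, given the volume (litres) of one node."""
        return self.total(solute) * 1e-3 * node_volume_l

    def validate(self) -> None:
        for s, c in self.conc.items():
            if (c < 0).any():
                raise InvalidStateError(f"negative {s} concentration")

    def to_csv(self, path) -> None:
        frames = [
            pd.DataFrame(
                {"node_id": np.arange(c.size), "solute": s, "conc_mM": c}
            )
            for s, c in self.conc.items()
        ]
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def exchange_coefficient(lattice: HexLattice, diffusivity: float) -> float:
    """Finite-volume exchange rate k (1/s) between adjacent nodes.

    k = D * edge_length / (centre_distance * node_area); for the hexagonal
    Voronoi cell this reduces to 2 D / (3 s²) with s the node spacing.
    """
    s = lattice.spacing
    edge = s / np.sqrt(3.0)
    return diffusivity * edge / (s * lattice.node_area)


@lru_cache(maxsize=8)
def _laplacian(lattice: HexLattice) -> sp.csr_matrix:
    """Symmetric graph Laplacian-like operator A - deg on the lattice."""
    nb = lattice.neighbors
    n = lattice.n_nodes
    rows, cols = np.nonzero(nb >= 0)
    j = nb[rows, cols]
    adj = sp.coo_matrix((np.ones(rows.size), (rows, j)), shape=(n, n)).tocsr()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    return (adj - sp.diags(deg)).tocsr()


def _pin_boundary(field: NutrientField, solute: str) -> None:
    if field.boundary_nodes.size and solute in field.boundary_values:
        field.conc[solute][field.boundary_nodes] = field.boundary_values[solute]


def diffuse(field: NutrientField, lattice: HexLattice, dt: float) -> NutrientField:
    """Explicit sub-stepped diffusion over ``dt`` seconds (in place).

    Sub-step size is held at 20 % of the explicit stability limit, so the
    scheme is stable and positivity-preserving for any outer ``dt``.  With
    an empty boundary set, total solute amount is conserved to machine
    precision; boundary nodes, when present, are re-pinned to their source
    values after every sub-step.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    field.validate()
    lap = _laplacian(lattice)
    for s in SOLUTES:
        k = exchange_coefficient(lattice, field.diffusivity[s])
        if k == 0:
            continue
        # stability: dt_sub * k * lambda_max <= 2, lambda_max <= 12
        dt_max = 1.0 / (6.0 * k)
        n_sub = max(1, int(np.ceil(dt / (0.2 * dt_max))))
        dt_sub = dt / n_sub
        c = field.conc[s]
        _pin_boundary(field, s)
        for _ in range(n_sub):
            c += (dt_sub * k) * lap.dot(c)
            _pin_boundary(field, s)
    return field


def apply_sources(field: NutrientField, scenario_values: dict[str, float] | None = None) -> NutrientField:
    """Pin boundary nodes to their configured source concentrations.

    ``scenario_values`` overrides the field's own boundary values (e.g.
    the nitrite-supplemented scenario sets a positive NO2 source).
    """
    if field.boundary_nodes.size == 0:
        raise InvalidStateError("field has no boundary nodes")
    values = dict(field.boundary_values)
    if scenario_values:
        values.update(scenario_values)
    for s, v in values.items():
        if v < 0:
            raise InvalidStateError(f"negative boundary value for {s}: {v}")
    field.boundary_values = values
    for s in values:
        _pin_boundary(field, s)
    return field


class ImplicitDiffusion:
    """Backward-Euler diffusion with one pre-factorised operator per solute.

    Solves (I - dt k L) c' = c.  The operator is an M-matrix, so the
    update is unconditionally stable, preserves non-negativity, and —
    because L is symmetric with zero column sums — conserves total mass
    exactly when the boundary set is empty.
    """

    def __init__(self, lattice: HexLattice, diffusivity: dict[str, float], dt: float):
        if dt <= 0:
            raise ValueError("dt must be > 0")
        self.dt = float(dt)
        lap = _laplacian(lattice).tocsc()
        eye = sp.identity(lattice.n_nodes, format="csc")
        self._lu = {}
        for s in SOLUTES:
            k = exchange_coefficient(lattice, diffusivity[s])
            self._lu[s] = splu((eye - (dt * k) * lap).tocsc())

    def step(self, field: NutrientField) -> NutrientField:
        """Advance all solutes by one dt (in place); re-pins boundaries."""
        for s in SOLUTES:
            _pin_boundary(field, s)
            c = self._lu[s].solve(field.conc[s])
            np.maximum(c, 0.0, out=c)  # clip float roundoff only
            field.conc[s] = c
            _pin_boundary(field, s)
        return field
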