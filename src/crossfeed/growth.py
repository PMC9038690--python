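"""Growth kinetics, nitrite-dependent yield, and nutrient stoichiometry.

Rates are Monod-type.  Under oxic conditions both strains are limited by
carbon only.  Under anoxic conditions the producer gains a nitrate term
and the consumer a nitrite term (dual-Monod, multiplicative).  Nitrite
toxicity acts on the biomass yield coefficient, not the rate: at pH 6.5

    Y = (Y_max - Y_min) * K_inh / (K_inh + C_NO2) + Y_min

while at pH 7.5 the yield is Y_max regardless of nitrite.  The yield is
applied to both genotypes.

Stoichiometry: under anoxia the producer reduces nitrate to nitrite
mol-for-mol (configurable ratio) and the consumer removes nitrite; carbon
is drawn down through a separate carbon yield in both conditions.  Growth
at a node is capped by local substrate availability — a cell never drives
a concentration negative.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .lattice_domain import CONSUMER, PRODUCER
from .nutrients import NutrientField

__all__ = [
    "StrainParams",
    "CellAgent",
    "growth_rate",
    "yield_coefficient",
    "euler_update",
    "consume_and_produce",
    "growth_step_arrays",
]

OXIC, ANOXIC = "oxic", "anoxic"


@dataclass(frozen=True)
class StrainParams:
    """Kinetic and stoichiometric parameters of one strain.

    Units: mu_max 1/h; half-saturation constants mM; yields kg dry
    weight per mol; division_mass kg dry weight.
    """

    strain: int  # PRODUCER or CONSUMER
    mu_max: float
    k_carbon: float
    k_n: float  # K_NO3 for the producer, K_NO2 for the consumer
    y_max: float
    y_min: float
    k_inh: float
    y_carbon: float
    division_mass: float
    no2_per_no3: float = 1.0  # producer stoichiometric ratio, mol/mol

    def __post_init__(self):
        # mu_max == 0 is allowed as a degenerate "no growth" configuration
        if self.mu_max < 0:
            raise ValueError("mu_max must be >= 0")
        if self.k_carbon <= 0 or self.k_n <= 0 or self.k_inh <= 0:
            raise ValueError("half-saturation and inhibition constants must be > 0")
        if self.y_min > self.y_max:
            raise ValueError("y_min must not exceed y_max")
        if self.division_mass <= 0 or self.y_carbon <= 0:
            raise ValueError("division_mass and y_carbon must be > 0")


@dataclass
class CellAgent:
    """Super-agent: the cell cluster resident on one lattice node."""

    strain: int
    biomass: float
    node: int
    stacked: int = 0


def growth_rate(strain: StrainParams, condition: str, c: float, no3: float, no2: float):
    """Monod growth rate in 1/h.  Accepts scalars or arrays.

    Oxic: mu = mu_max * C/(K_C + C) for both strains.
    Anoxic: the producer multiplies in NO3/(K_NO3+NO3), the consumer
    NO2/(K_NO2+NO2).
    """
    c, no3, no2 = np.asarray(c, float), np.asarray(no3, float), np.asarray(no2, float)
    if (c < 0).any() or (no3 < 0).any() or (no2 < 0).any():
        raise ValueError("concentrations must be non-negative")
    mu = strain.mu_max * c / (strain.k_carbon + c)
    if condition == ANOXIC:
        n = no3 if strain.strain == PRODUCER else no2
        mu = mu * n / (strain.k_n + n)
    elif condition != OXIC:
        raise ValueError(f"unknown condition {condition!r}")
    return mu if mu.ndim else float(mu)


def yield_coefficient(strain: StrainParams, c_no2: float, ph: float):
    """Biomass yield (kg dry weight/mol of the strain's N acceptor).

    pH 7.5: Y_max.  pH 6.5: hyperbolic inhibition between Y_max (no
    nitrite) and Y_min (saturating nitrite), half-way at C_NO2 = K_inh.
    """
    c_no2 = np.asarray(c_no2, float)
    if (c_no2 < 0).any():
        raise ValueError("C_NO2 must be non-negative")
    if ph == 7.5:
        y = np.broadcast_to(strain.y_max, c_no2.shape).copy() if c_no2.ndim else strain.y_max
        return y if c_no2.ndim else float(y)
    if ph != 6.5:
        raise ValueError(f"pH must be 6.5 or 7.5, got {ph}")
    if np.isinf(strain.k_inh):  # no inhibition: identical to the pH 7.5 branch
        factor = np.ones_like(c_no2)
    else:
        factor = strain.k_inh / (strain.k_inh + c_no2)
    y = (strain.y_max - strain.y_min) * factor + strain.y_min
    return y if c_no2.ndim else float(y)


def euler_update(biomass: float, mu: float, dt: float) -> float:
    """Explicit Euler biomass update; mu in 1/h, dt in seconds."""
    if mu < 0:
        raise ValueError("mu must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return biomass * (1.0 + mu * dt / 3600.0)


def consume_and_produce(
    node: int,
    cell: CellAgent,
    delta_biomass: float,
    field: NutrientField,
    condition: str,
    ph: float,
    params: StrainParams,
    node_volume_l: float,
) -> float:
    """Apply one cell's growth increment to the local concentrations.

    Growth is capped so that no local concentration goes negative; the
    realised (possibly capped) biomass increment is returned and the
    field is updated in place.
    """
    if delta_biomass < 0:
        raise ValueError("delta_biomass must be >= 0")
    grown = _consume_arrays(
        np.array([node]),
        np.array([cell.strain], dtype=np.int8),
        np.array([delta_biomass]),
        field,
        condition,
        ph,
        {cell.strain: params},
        node_volume_l,
    )
    return float(grown[0])


def _consume_arrays(nodes, strains, delta, field, condition, ph, params_by_strain, node_volume_l, ledger=None):
    """Vectorised core of consume_and_produce; returns realised increments.

    ``ledger``, if given, is a dict accumulating ``no3_reduced_mol``,
    ``no2_produced_mol`` and ``no2_consumed_mol`` for nitrogen
    bookkeeping across a run.
    """
    grown = np.zeros(delta.shape)
    for sid, p in params_by_strain.items():
        m = strains == sid
        if not m.any():
            continue
        idx = nodes[m]
        want = delta[m]
        c_loc = field.conc["carbon"][idx]
        # carbon cap in all conditions
        allowed = np.minimum(want, c_loc * 1e-3 * node_volume_l * p.y_carbon)
        if condition == ANOXIC:
            sol = "no3" if sid == PRODUCER else "no2"
            n_loc = field.conc[sol][idx]
            y_n = np.asarray(yield_coefficient(p, field.conc["no2"][idx], ph))
            allowed = np.minimum(allowed, n_loc * 1e-3 * node_volume_l * y_n)
            n_mol = allowed / y_n
            dn = n_mol / node_volume_l * 1e3  # mol -> mM in node volume
            if sid == PRODUCER:
                field.conc["no3"][idx] -= dn
                field.conc["no2"][idx] += dn * p.no2_per_no3
                if ledger is not None:
                    ledger["no3_reduced_mol"] += float(n_mol.sum())
                    ledger["no2_produced_mol"] += float(n_mol.sum()) * p.no2_per_no3
            else:
                field.conc["no2"][idx] -= dn
                if ledger is not None:
                    ledger["no2_consumed_mol"] += float(n_mol.sum())
        field.conc["carbon"][idx] -= allowed / p.y_carbon / node_volume_l * 1e3
        grown[m] = allowed
    for s in ("carbon", "no3", "no2"):
        np.maximum(field.conc[s], 0.0, out=field.conc[s])  # roundoff guard
    return grown


def growth_step_arrays(
    occ_nodes: np.ndarray,
    strains: np.ndarray,
    biomass: np.ndarray,
    field: NutrientField,
    condition: str,
    ph: float,
    params_by_strain: dict[int, StrainParams],
    dt: float,
    node_volume_l: float,
    ledger: dict | None = None,
    yield_couples_rate: bool = True,
) -> np.ndarray:
    """One growth/consumption step for all occupied nodes at once.

    Returns the updated biomass array (same order as ``occ_nodes``);
    the nutrient field is updated in place.

    With ``yield_couples_rate`` (default), anoxic biomass gain is
    yield x uptake: the Monod-type uptake kinetics are unchanged by
    nitrite, but the realised growth rate scales with Y_i/Y_max, so
    nitrite toxicity at pH 6.5 slows growth while N turnover per unit
    biomass is unaffected.  At pH 7.5 (Y_i = Y_max) the factor is 1.
    """
    mu = np.zeros(occ_nodes.shape)
    for sid, p in params_by_strain.items():
        m = strains == sid
        if not m.any():
            continue
        idx = occ_nodes[m]
        mu[m] = growth_rate(
            p,
            condition,
            field.conc["carbon"][idx],
            field.conc["no3"][idx],
            field.conc["no2"][idx],
        )
        if yield_couples_rate and condition == ANOXIC:
            y_i = np.asarray(yield_coefficient(p, field.conc["no2"][idx], ph))
            mu[m] *= y_i / p.y_max
    demand = biomass * mu * dt / 3600.0
    grown = _consume_arrays(
        occ_nodes, strains, demand, field, condition, ph, params_by_strain,
        node_volume_l, ledger=ledger,
    )
    return biomass + grown
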