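"""Full-run orchestration: schedule, inoculation, and the 60 s outer loop.

Each outer step applies the peripheral sources, diffuses all three
solutes, computes Monod rates and nitrite-dependent yields for every
occupied node under the current redox phase, performs the explicit Euler
biomass update with availability-capped consumption, and then resolves
divisions through adjacent placement, edge-directed shoving, or
stacking.  Snapshots are taken at every phase transition and at the end
of the run.

Redox state is a global switch (anoxic/oxic) rather than an explicit
oxygen field.  All randomness flows from a single root seed through
deterministic per-subsystem streams, so a run is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import nutrients
from .growth import ANOXIC, OXIC, StrainParams, growth_step_arrays
from .expansion import attempt_division, shove_threshold_nodes, DEFAULT_SHOVE_CUTOFF_UM
from .lattice_domain import (
    CONSUMER,
    EMPTY,
    PRODUCER,
    HexLattice,
    Occupancy,
    build_lattice,
)
from .nutrients import ImplicitDiffusion, NutrientField, diffuse

__all__ = [
    "EnvironmentSchedule",
    "SimulationConfig",
    "Snapshot",
    "Trajectory",
    "make_schedule",
    "init_inoculum",
    "run_simulation",
    "default_strain_params",
    "reduced_config",
]

SCENARIOS = ("anoxic-start", "oxic-start", "nitrite-supplemented")


class InvalidConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class EnvironmentSchedule:
    """Alternating redox phases: ordered (phase, duration in h) pairs."""

    intervals: tuple[tuple[str, float], ...]

    @property
    def total_h(self) -> float:
        return sum(d for _, d in self.intervals)

    def phase_at(self, t_h: float) -> str:
        """Phase active at time t (intervals are left-closed)."""
        acc = 0.0
        for phase, d in self.intervals:
            acc += d
            if t_h < acc - 1e-9:
                return phase
        return self.intervals[-1][0]

    def transition_times(self) -> list[float]:
        """End time of every interval, including the run end."""
        times, acc = [], 0.0
        for _, d in self.intervals:
            acc += d
            times.append(acc)
        return times

    def count(self, phase: str) -> int:
        return sum(1 for p, _ in self.intervals if p == phase)


def make_schedule(
    total_h: float,
    interval: float | tuple[float, float],
    first_phase: str = ANOXIC,
) -> EnvironmentSchedule:
    """Build the alternating anoxic/oxic schedule.

    ``interval`` is either a single duration (equal alternation, e.g.
    6 h for the default 72 h run giving six intervals per condition) or
    an (anoxic_h, oxic_h) pair for asymmetric cycles such as 36/12.
    ``total_h`` must be an exact multiple of the cycle length.
    """
    if first_phase not in (ANOXIC, OXIC):
        raise InvalidConfigurationError(f"unknown phase {first_phase!r}")
    second = OXIC if first_phase == ANOXIC else ANOXIC
    if np.isscalar(interval):
        if interval <= 0:
            raise InvalidConfigurationError("interval must be positive")
        n = total_h / interval
        if abs(n - round(n)) > 1e-9:
            raise InvalidConfigurationError(
                f"total {total_h} h is not a multiple of the {interval} h interval"
            )
        n = int(round(n))
        phases = [(first_phase if i % 2 == 0 else second, float(interval)) for i in range(n)]
    else:
        # interval is (anoxic_h, oxic_h) regardless of which phase starts
        anox_h, ox_h = float(interval[0]), float(interval[1])
        d_first, d_second = (anox_h, ox_h) if first_phase == ANOXIC else (ox_h, anox_h)
        if d_first <= 0 or d_second <= 0:
            raise InvalidConfigurationError("interval durations must be positive")
        cycle = d_first + d_second
        n = total_h / cycle
        if abs(n - round(n)) > 1e-9:
            raise InvalidConfigurationError(
                f"total {total_h} h is not a multiple of the {cycle} h cycle"
            )
        phases = []
        for _ in range(int(round(n))):
            phases.append((first_phase, d_first))
            phases.append((second, d_second))
    return EnvironmentSchedule(tuple(phases))


def default_strain_params() -> dict[int, StrainParams]:
    """Default kinetic parameters.

    Not fully constrained by measurement — chosen in the literature range
    for heterotrophic denitrifiers (mu_max ~1/h aerobic, half-saturation
    ~0.1 mM for N oxides, denitrification yields ~0.01-0.03 kg DW/mol,
    nitrite inhibition at sub-mM levels for low pH).  All acceptance
    properties are parameter-robust orderings, not absolute values.
    """
    common = dict(
        mu_max=0.5,
        k_carbon=2.0,
        y_max=0.02,
        y_min=0.004,
        k_inh=0.25,
        y_carbon=0.05,
        division_mass=2e-14,
    )
    # the consumer's nitrite half-saturation exceeds the producer's
    # nitrate one: nitrite must build up behind the front before the
    # consumer can follow, which produces the producer-led anoxic front
    return {
        PRODUCER: StrainParams(strain=PRODUCER, k_n=0.05, **common),
        CONSUMER: StrainParams(strain=CONSUMER, k_n=0.3, **common),
    }


@dataclass
class SimulationConfig:
    """Everything needed to reproduce one run."""

    ph: float = 6.5
    domain_diameter_um: float = 10_000.0
    side_length_um: float = 20.0
    total_h: float = 72.0
    interval_h: float | tuple[float, float] = 6.0
    scenario: str = "anoxic-start"
    dt_s: float = 60.0
    seed: int = 0
    inoculum_radius_um: float = 2_000.0
    producer_fraction: float = 0.5
    boundary_carbon_mm: float = 22.0
    boundary_no3_mm: float = 1.0
    boundary_no2_mm: float = 0.0
    node_depth_um: float = 200.0
    diffusivity: dict = field(default_factory=lambda: dict(nutrients.DEFAULT_DIFFUSIVITY))
    producer: StrainParams = None
    consumer: StrainParams = None
    diffusion_method: str = "implicit"  # "implicit" | "explicit"
    shove_cutoff_um: float = DEFAULT_SHOVE_CUTOFF_UM
    closed_boundary: bool = False  # no peripheral sources (testing)
    stacked_layers_grow: bool = False
    toxicity_slows_growth: bool = True  # growth = yield x uptake coupling

    def __post_init__(self):
        defaults = default_strain_params()
        if self.producer is None:
            self.producer = defaults[PRODUCER]
        if self.consumer is None:
            self.consumer = defaults[CONSUMER]
        if self.scenario not in SCENARIOS:
            raise InvalidConfigurationError(f"unknown scenario {self.scenario!r}")
        if self.dt_s <= 0:
            raise InvalidConfigurationError("dt_s must be positive")
        if self.ph not in (6.5, 7.5):
            raise InvalidConfigurationError("ph must be 6.5 or 7.5")
        n_steps = self.total_h * 3600.0 / self.dt_s
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise InvalidConfigurationError("total_h must be a multiple of dt_s")
        if self.scenario == "nitrite-supplemented" and self.boundary_no2_mm == 0.0:
            self.boundary_no2_mm = 1.0

    @property
    def first_phase(self) -> str:
        return OXIC if self.scenario == "oxic-start" else ANOXIC

    def schedule(self) -> EnvironmentSchedule:
        return make_schedule(self.total_h, self.interval_h, self.first_phase)

    def boundary_values(self) -> dict[str, float]:
        """Peripheral source concentrations.

        Carbon and nitrate have constant peripheral sources; nitrite is
        produced solely by the producer's metabolism, so the boundary is
        left free for NO2 unless the scenario supplies it exogenously.
        """
        values = {
            "carbon": self.boundary_carbon_mm,
            "no3": self.boundary_no3_mm,
        }
        if self.boundary_no2_mm > 0:
            values["no2"] = self.boundary_no2_mm
        return values

    def node_volume_l(self, lattice: HexLattice) -> float:
        return lattice.node_area * self.node_depth_um * 1e-15

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["producer"] = asdict(self.producer)
        d["consumer"] = asdict(self.consumer)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("producer", "consumer"):
            if isinstance(d.get(key), dict):
                d[key] = StrainParams(**d[key])
        if isinstance(d.get("interval_h"), list):
            d["interval_h"] = tuple(d["interval_h"])
        return cls(**d)


def reduced_config(**overrides) -> SimulationConfig:
    """Reduced-domain preset (3 mm, 24 h) for CI and desk-scale runs."""
    base = dict(
        domain_diameter_um=3_600.0,
        inoculum_radius_um=500.0,
        total_h=24.0,
        interval_h=6.0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def init_inoculum(
    lattice: HexLattice,
    rng: np.random.Generator,
    radius_um: float,
    producer_fraction: float = 0.5,
    division_mass: float | dict[int, float] = 2e-14,
) -> Occupancy:
    """Occupy every node within ``radius_um`` of the centre.

    Strain labels are i.i.d. Bernoulli (producer with probability
    ``producer_fraction``); initial masses are uniform on 10-100 % of the
    division mass.
    """
    if radius_um >= lattice.domain_diameter / 2.0:
        raise InvalidConfigurationError("inoculum radius must be inside the domain")
    occ = Occupancy.empty(lattice)
    nodes = np.flatnonzero(lattice.radii() <= radius_um)
    draws = rng.random(nodes.size)
    strains = np.where(draws < producer_fraction, PRODUCER, CONSUMER).astype(np.int8)
    occ.strain[nodes] = strains
    if not isinstance(division_mass, dict):
        division_mass = {PRODUCER: division_mass, CONSUMER: division_mass}
    mdiv = np.array([division_mass[int(s)] for s in strains])
    occ.biomass[nodes] = rng.uniform(0.1, 1.0, size=nodes.size) * mdiv
    return occ


@dataclass
class Snapshot:
    time_h: float
    phase: str  # phase that just ended
    occupancy: Occupancy
    conc: dict[str, np.ndarray]


@dataclass
class Trajectory:
    config: SimulationConfig
    lattice: HexLattice
    snapshots: list[Snapshot]
    totals: pd.DataFrame  # per-step domain totals (mol) per solute
    nitrogen_ledger: dict

    @property
    def final(self) -> Snapshot:
        return self.snapshots[-1]


def run_simulation(config: SimulationConfig, progress: bool = False) -> Trajectory:
    """Run one full simulation and return its trajectory."""
    lattice = build_lattice(config.domain_diameter_um, config.side_length_um)
    schedule = config.schedule()
    if abs(schedule.total_h - config.total_h) > 1e-9:
        raise InvalidConfigurationError("schedule does not cover total_h")

    root = np.random.SeedSequence(config.seed)
    rng_inoc, rng_order, rng_shove = (np.random.default_rng(s) for s in root.spawn(3))

    params = {PRODUCER: config.producer, CONSUMER: config.consumer}
    occ = init_inoculum(
        lattice,
        rng_inoc,
        config.inoculum_radius_um,
        config.producer_fraction,
        {s: p.division_mass for s, p in params.items()},
    )

    boundary = np.empty(0, dtype=np.int64) if config.closed_boundary else lattice.boundary_nodes()
    init_values = {
        "carbon": config.boundary_carbon_mm,
        "no3": config.boundary_no3_mm,
        "no2": config.boundary_no2_mm,
    }
    fld = NutrientField.uniform(
        lattice,
        init_values,
        diffusivity=config.diffusivity,
        boundary_nodes=boundary,
        boundary_values=config.boundary_values() if not config.closed_boundary else {},
    )

    solver = None
    if config.diffusion_method == "implicit":
        solver = ImplicitDiffusion(lattice, config.diffusivity, config.dt_s)
    elif config.diffusion_method != "explicit":
        raise InvalidConfigurationError(f"unknown diffusion method {config.diffusion_method!r}")

    threshold = shove_threshold_nodes(config.shove_cutoff_um, config.side_length_um)
    node_volume = config.node_volume_l(lattice)
    dt_h = config.dt_s / 3600.0
    n_steps = int(round(config.total_h * 3600.0 / config.dt_s))
    transition_times = schedule.transition_times()

    ledger = {"no3_reduced_mol": 0.0, "no2_produced_mol": 0.0, "no2_consumed_mol": 0.0}
    totals_rows = []
    snapshots: list[Snapshot] = []
    next_transition = 0

    def record_totals(t_h, phase):
        totals_rows.append(
            (
                t_h,
                phase,
                fld.total_moles("carbon", node_volume),
                fld.total_moles("no3", node_volume),
                fld.total_moles("no2", node_volume),
                occ.total_biomass(),
                occ.cell_count(),
            )
        )

    record_totals(0.0, schedule.phase_at(0.0))
    for step in range(n_steps):
        t_h = step * dt_h
        phase = schedule.phase_at(t_h)

        if not config.closed_boundary:
            nutrients.apply_sources(fld)
        if solver is not None:
            solver.step(fld)
        else:
            diffuse(fld, lattice, config.dt_s)

        occ_nodes = occ.occupied()
        if occ_nodes.size:
            strains = occ.strain[occ_nodes]
            occ.biomass[occ_nodes] = growth_step_arrays(
                occ_nodes,
                strains,
                occ.biomass[occ_nodes],
                fld,
                phase,
                config.ph,
                params,
                config.dt_s,
                node_volume,
                ledger=ledger,
                yield_couples_rate=config.toxicity_slows_growth,
            )
            mdiv = np.where(
                strains == PRODUCER,
                params[PRODUCER].division_mass,
                params[CONSUMER].division_mass,
            )
            dividers = occ_nodes[occ.biomass[occ_nodes] >= mdiv]
            if dividers.size:
                for node in rng_order.permutation(dividers):
                    node = int(node)
                    attempt_division(
                        node,
                        occ,
                        lattice,
                        rng_shove,
                        params[int(occ.strain[node])].division_mass,
                        threshold=threshold,
                    )

        t_end = (step + 1) * dt_h
        record_totals(t_end, phase)
        if (
            next_transition < len(transition_times)
            and t_end >= transition_times[next_transition] - 1e-9
        ):
            snapshots.append(
                Snapshot(
                    time_h=t_end,
                    phase=phase,
                    occupancy=occ.copy(),
                    conc={s: c.copy() for s, c in fld.conc.items()},
                )
            )
            next_transition += 1
        if progress and step % 60 == 0:
            print(f"t={t_end:7.2f} h phase={phase} cells={occ.cell_count()}")

    totals = pd.DataFrame(
        totals_rows,
        columns=["time_h", "phase", "carbon_mol", "no3_mol", "no2_mol", "biomass_kg", "cells"],
    )
    return Trajectory(config, lattice, snapshots, totals, ledger)
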