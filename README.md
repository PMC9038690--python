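# crossfeed

Agent-based simulation of a two-strain nitrite cross-feeding microbial
range expansion under fluctuating anoxic/oxic conditions, together with
the spatial-pattern metrics (edge-ring consumer:producer ratio,
intermixing index, spatial-jackpot counting) and the statistical layer
(two-phase linear regression, parametric tests, transition-stability
analysis) used to analyse such colonies. A synthetic colony generator
provides ground-truth-labelled rasters so the whole pipeline is testable
offline.

## Model in brief

* Hexagonal lattice (20 µm side length) over a circular domain
  (default 1 cm); carbon, nitrate and nitrite diffuse node-to-node in
  finite-volume form with constant peripheral sources for carbon
  (22 mM) and nitrate (1 mM).
* Super-agent cells, one strain per node. Monod growth: carbon-limited
  under oxic conditions; under anoxic conditions the producer adds a
  nitrate term (reducing NO3⁻ to NO2⁻ mol-for-mol) and the consumer a
  nitrite term. Nitrite lowers the biomass yield at pH 6.5
  (hyperbolic inhibition between Y_max and Y_min, half-way at K_inh);
  growth is yield × uptake, so toxicity also slows growth.
* Explicit Euler biomass update on a 60 s outer step (default 72 h,
  alternating phases every 6 h). Division at a threshold mass with
  50/50 split; daughters go to an empty neighbour, are shoved along the
  shortest path to the expansion edge when it is < 5 grid nodes
  (100 µm) away, or stack in a pseudo-3D layer.

## CLI

```bash
# one simulation: rasters per phase transition, solute totals, metrics
crossfeed simulate --config run.yaml --seed 3 --out out/

# pattern metrics for a directory of label rasters (TIFF/PNG)
crossfeed quantify --in out/ --pixel-size 3.027 --ring 50 --out metrics.csv

# two-phase regression of a metric column
crossfeed fit --metrics metrics.csv --column consumer_to_producer_ratio --out fits.csv

# synthetic ground-truth data
crossfeed synth colony --radius-px 300 --jackpots 3 --noise 0.01 --out colony.tiff
crossfeed synth series --replicates 4 --transitions 15 --out series.csv
```

A config YAML is written by `SimulationConfig.to_yaml()`; every kinetic
parameter, the schedule (symmetric interval or an asymmetric
anoxic/oxic pair such as 36/12), the scenario (`anoxic-start`,
`oxic-start`, `nitrite-supplemented`) and the RNG seed live there.
`crossfeed.simulator.reduced_config()` gives the 3.6 mm / 24 h preset
used in CI.

## Layout

```
src/crossfeed/
  lattice_domain.py   hexagonal lattice, occupancy, frontier, shortest paths
  nutrients.py        solute fields, explicit + implicit diffusion, sources
  growth.py           Monod rates, nitrite-dependent yield, stoichiometry
  expansion.py        division, edge-directed shoving, stacking
  simulator.py        schedules, inoculation, the outer loop, scenarios
  quantify.py         rasterisation, edge profile, ratio/intermixing/jackpots
  stats.py            two-phase regression, t-tests, assumption checks,
                      transition stability
  synthetic_data.py   wedge-colony and two-phase-series generators
  cli.py              `crossfeed` console entry point
```
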