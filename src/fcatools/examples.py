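"""Built-in worked examples and random synthetic scenarios.

Two small systems with known-by-hand results are provided for teaching and
testing:

- :func:`toy_two_clinics` — three population centers of 100 people and two
  clinics of 10 physicians each, every center inside both catchments. Under
  balanced allocation each clinic serves exactly 150 people and every
  center's accessibility is 0.044 physicians per person.
- :func:`simulated_nine_centers` — nine centers (total population 4,500)
  and three clinics (supplies 1, 3, 2; regional ratio 1.33 physicians per
  1,000), with partially overlapping catchments that produce strong demand
  inflation under unadjusted methods (total nominal binary demand 9,750).

Both fixtures are defined by their impedance *weight* patterns. The cost
matrices here encode those patterns exactly: costs 3 / 8 / 12 minutes fall
in the stepwise brackets (0,5], (5,10], (10,15] and inside the binary
15-minute threshold, and unreachable pairs fall outside both. Evaluating
the bundled binary and stepwise specs on the costs therefore reproduces
the intended weight matrices bit for bit.

:func:`random_scenario` draws reproducible random scenarios (uniform
placement in a square, log-uniform populations, small integer supplies)
for property testing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .impedance import ImpedanceSpec, binary, stepwise
from .scenario import UNREACHABLE, CostMatrix, EntityTable, Scenario

__all__ = [
    "RandomScenarioConfig",
    "toy_two_clinics",
    "simulated_nine_centers",
    "random_scenario",
    "export_scenario",
]


def _costs_from_steps(step_weights: np.ndarray, level_costs: dict[float, float]) -> np.ndarray:
    """Map a stepwise weight pattern to representative costs (0 -> inf)."""
    cost = np.full(step_weights.shape, UNREACHABLE)
    for w, c in level_costs.items():
        cost[np.isclose(step_weights, w)] = c
    return cost


def toy_two_clinics() -> tuple[Scenario, dict[str, ImpedanceSpec]]:
    """Three centers of 100 people, two clinics of 10 physicians.

    Returns the scenario plus ``{"binary": ..., "stepwise": ...}`` impedance
    specs. The binary weights are all ones; the stepwise weights are
    ``[[0.8, 0.8], [0.8, 0.4], [0.4, 0.8]]`` (center 1 is mid-distance from
    both clinics, centers 2 and 3 each close to one clinic and far from the
    other).
    """
    step_pattern = np.array([[0.8, 0.8], [0.8, 0.4], [0.4, 0.8]])
    cost = _costs_from_steps(step_pattern, {0.8: 8.0, 0.4: 12.0})
    centers = EntityTable(ids=["c1", "c2", "c3"], size=[100, 100, 100])
    facilities = EntityTable(ids=["f1", "f2"], size=[10, 10])
    scenario = Scenario(centers, facilities, CostMatrix(centers.ids, facilities.ids, cost))
    specs = {
        "binary": binary(15.0),
        "stepwise": stepwise([5.0, 10.0, 15.0], [0.9, 0.8, 0.4]),
    }
    return scenario, specs


# Stepwise weight pattern of the nine-center system (rows: centers 1..9,
# columns: clinics 1..3). Zeros are out of catchment under binary impedance
# too — the two patterns share their zero structure.
_NINE_STEPWISE = np.array(
    [
        [0.242, 0.000, 0.000],
        [0.600, 0.242, 0.000],
        [0.242, 0.600, 0.242],
        [0.600, 0.600, 0.242],
        [0.000, 0.600, 0.945],
        [0.000, 0.242, 0.600],
        [0.000, 0.242, 0.242],
        [0.000, 0.600, 0.242],
        [0.000, 0.242, 0.242],
    ]
)

_NINE_POPULATIONS = [250, 250, 500, 500, 1000, 500, 1000, 250, 250]
_NINE_SUPPLIES = [1, 3, 2]


def simulated_nine_centers() -> tuple[Scenario, dict[str, ImpedanceSpec]]:
    """Nine centers, three clinics: the standard inflation demonstration.

    Total population 4,500; supplies (1, 3, 2); regional provider-to-
    population ratio 1.33 per 1,000. Stepwise decay uses weights
    (0.945, 0.600, 0.242) on the brackets (0,5], (5,10], (10,15] minutes
    and the binary threshold is 15 minutes.
    """
    cost = _costs_from_steps(_NINE_STEPWISE, {0.945: 3.0, 0.600: 8.0, 0.242: 12.0})
    centers = EntityTable(
        ids=[f"c{i}" for i in range(1, 10)], size=_NINE_POPULATIONS
    )
    facilities = EntityTable(ids=["f1", "f2", "f3"], size=_NINE_SUPPLIES)
    scenario = Scenario(centers, facilities, CostMatrix(centers.ids, facilities.ids, cost))
    specs = {
        "binary": binary(15.0),
        "stepwise": stepwise([5.0, 10.0, 15.0], [0.945, 0.600, 0.242]),
    }
    return scenario, specs


@dataclass
class RandomScenarioConfig:
    """Parameters of the random scenario generator.

    Centers and facilities are placed uniformly in a ``region_size`` x
    ``region_size`` square and costs are Euclidean distances (interpreted
    as minutes). Populations are log-uniform in ``population_range`` —
    echoing the few-hundred-to-few-thousand magnitudes typical of census
    units — and supplies are integer-uniform in ``supply_range`` (a few
    physicians per clinic). Identical seeds give identical scenarios.
    """

    n_centers: int = 9
    n_facilities: int = 3
    region_size: float = 30.0
    population_range: tuple[float, float] = (100.0, 2000.0)
    supply_range: tuple[int, int] = (1, 5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_centers < 1 or self.n_facilities < 1:
            raise ValueError("counts must be at least 1")
        if self.region_size <= 0:
            raise ValueError("region_size must be positive")
        lo, hi = self.population_range
        if lo <= 0 or hi < lo:
            raise ValueError("population_range must be positive and ordered")
        if self.supply_range[0] < 1 or self.supply_range[1] < self.supply_range[0]:
            raise ValueError("supply_range must be ordered integers >= 1")


def random_scenario(config: RandomScenarioConfig | None = None, **kwargs) -> Scenario:
    """Draw a reproducible random scenario; see :class:`RandomScenarioConfig`."""
    if config is None:
        config = RandomScenarioConfig(**kwargs)
    rng = np.random.default_rng(config.seed)
    n, j, side = config.n_centers, config.n_facilities, config.region_size
    cx, cy = rng.uniform(0, side, n), rng.uniform(0, side, n)
    fx, fy = rng.uniform(0, side, j), rng.uniform(0, side, j)
    lo, hi = config.population_range
    pop = np.round(np.exp(rng.uniform(np.log(lo), np.log(hi), n)))
    sup = rng.integers(config.supply_range[0], config.supply_range[1] + 1, j).astype(float)
    centers = EntityTable(
        ids=[f"c{i+1}" for i in range(n)], size=pop, x=cx, y=cy
    )
    facilities = EntityTable(
        ids=[f"f{k+1}" for k in range(j)], size=sup, x=fx, y=fy
    )
    from .scenario import euclidean_costs

    return Scenario(centers, facilities, euclidean_costs(centers, facilities))


def export_scenario(scenario: Scenario, outdir) -> dict[str, str]:
    """Write a scenario as centers.csv, facilities.csv and a wide costs.csv.

    Unreachable pairs are written as ``inf`` (read back as unreachable).
    Returns the paths keyed by table name.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "centers": os.path.join(outdir, "centers.csv"),
        "facilities": os.path.join(outdir, "facilities.csv"),
        "costs": os.path.join(outdir, "costs.csv"),
    }
    scenario.centers.to_frame("population").to_csv(paths["centers"], index=False)
    scenario.facilities.to_frame("supply").to_csv(paths["facilities"], index=False)
    wide = pd.DataFrame(
        scenario.costs.cost, columns=scenario.costs.dest_ids
    )
    wide.insert(0, "origin", scenario.costs.origin_ids)
    wide.to_csv(paths["costs"], index=False)
    return paths
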