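"""Inflation diagnostics, conservation accounting and equity measures.

Unadjusted FCA methods double-count population wherever facility catchments
overlap (demand inflation) and hand the same level of service to many
centers (service inflation). These diagnostics make the effect visible:

- :func:`conservation_report` compares total nominal demand against the
  actual population and total accessibility against total level of service,
  and counts for each center how many catchments it falls into.
- :func:`inflation_factors` takes an unadjusted and a balanced run of the
  same scenario and reports facility-level demand ratios and center-level
  accessibility ratios.
- :func:`disparity` turns balanced accessibility into equity measures: the
  difference from an equitable share of the total level of service, or the
  spatial access ratio (SPAR, accessibility over mean accessibility).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import AccessibilityResult, FCAResult
from .scenario import Scenario

__all__ = [
    "ConservationReport",
    "InflationFactors",
    "DisparityTable",
    "conservation_report",
    "inflation_factors",
    "disparity",
]


@dataclass
class ConservationReport:
    """System-wide totals for one method run.

    ``regional_ppr`` is total supply over total population and
    ``implied_ppr`` total supply over total *nominal* demand, both reported
    per ``scale`` people; the two coincide exactly when demand is
    conserved. ``coverage_counts`` K_i is the number of facilities whose
    catchment (positive weight) includes center i.
    """

    total_population: float
    total_nominal_demand: float
    total_supply: float
    total_los: float              # per person, summed over defined facilities
    total_accessibility: float    # per person, summed over centers
    regional_ppr: float           # per `scale` people
    implied_ppr: float            # per `scale` people; NaN if demand is 0
    coverage_counts: np.ndarray   # K_i per center
    scale: float = 1000.0

    def summary(self) -> str:
        return (
            f"population {self.total_population:g} vs nominal demand "
            f"{self.total_nominal_demand:g}; supply {self.total_supply:g}; "
            f"regional PPR {self.regional_ppr:.4g} vs implied PPR "
            f"{self.implied_ppr:.4g} (per {self.scale:g}); total LOS "
            f"{self.total_los * self.scale:.4g} vs total accessibility "
            f"{self.total_accessibility * self.scale:.4g} (per {self.scale:g})"
        )


@dataclass
class InflationFactors:
    """Unadjusted-to-adjusted ratios; NaN where the denominator is zero."""

    demand_ratio: np.ndarray      # per facility: D_j / D*_j
    access_ratio: np.ndarray      # per center: A_i / A*_i
    facility_ids: list[str]
    center_ids: list[str]

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        return (
            pd.DataFrame({"id": self.facility_ids, "demand_ratio": self.demand_ratio}),
            pd.DataFrame({"id": self.center_ids, "access_ratio": self.access_ratio}),
        )


@dataclass
class DisparityTable:
    """Per-center equity measures derived from accessibility."""

    equitable_share: float        # L-bar, per person
    disparity: np.ndarray         # A_i - L-bar, per person
    spar: np.ndarray              # A_i / mean(A)
    center_ids: list[str]
    mode: str = "equitable_share"

    def to_frame(self, scale: float = 1000.0) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.center_ids,
                "disparity": self.disparity * scale,
                "spar": self.spar,
            }
        )


def conservation_report(scenario: Scenario, result: FCAResult) -> ConservationReport:
    """Totals and coverage counts for one run."""
    scale = result.los.scale
    total_pop = float(scenario.centers.size.sum())
    total_supply = float(scenario.facilities.size.sum())
    total_demand = float(result.demand.facility_demand.sum())
    return ConservationReport(
        total_population=total_pop,
        total_nominal_demand=total_demand,
        total_supply=total_supply,
        total_los=result.los.total,
        total_accessibility=float(result.access.accessibility.sum()),
        regional_ppr=total_supply / total_pop * scale,
        implied_ppr=(total_supply / total_demand * scale) if total_demand > 0 else np.nan,
        coverage_counts=(result.weights.values > 0).sum(axis=1),
        scale=scale,
    )


def inflation_factors(unadjusted: FCAResult, adjusted: FCAResult) -> InflationFactors:
    """Per-facility demand ratios and per-center accessibility ratios.

    Both runs must be on the same scenario (same id orders); typically
    ``unadjusted`` is a 2SFCA/E2SFCA run and ``adjusted`` the balanced run
    under the same impedance. Ratios with a zero denominator are NaN.
    """
    if (unadjusted.demand.dest_ids != adjusted.demand.dest_ids
            or unadjusted.access.origin_ids != adjusted.access.origin_ids):
        raise ValueError("runs are not on the same scenario")
    with np.errstate(divide="ignore", invalid="ignore"):
        d_ratio = np.where(
            adjusted.demand.facility_demand > 0,
            unadjusted.demand.facility_demand / adjusted.demand.facility_demand,
            np.nan,
        )
        a_ratio = np.where(
            adjusted.access.accessibility > 0,
            unadjusted.access.accessibility / adjusted.access.accessibility,
            np.nan,
        )
    return InflationFactors(
        demand_ratio=d_ratio,
        access_ratio=a_ratio,
        facility_ids=list(unadjusted.demand.dest_ids),
        center_ids=list(unadjusted.access.origin_ids),
    )


def disparity(access: AccessibilityResult | FCAResult,
              mode: str = "equitable_share",
              los=None) -> DisparityTable:
    """Equity measures from an accessibility result.

    ``equitable_share`` mode: the total level of service (for balanced runs
    this equals total accessibility) divided by the number of centers is
    each center's equitable share L-bar; the disparity index is
    ``A_i - L-bar``, positive where a center receives more than its share.
    ``spar`` mode reports ``A_i / mean(A)``. Designed for balanced runs,
    where totals are conserved; accepted for any run.
    """
    if isinstance(access, FCAResult):
        los = access.los
        access = access.access
    n = len(access.origin_ids)
    if n == 0:
        raise ValueError("no centers")
    if mode not in ("equitable_share", "spar"):
        raise ValueError(f"unknown disparity mode {mode!r}")
    total_los = los.total if los is not None else float(access.accessibility.sum())
    lbar = total_los / n
    mean_a = float(access.accessibility.mean())
    with np.errstate(divide="ignore", invalid="ignore"):
        spar = (access.accessibility / mean_a if mean_a > 0
                else np.full(n, np.nan))
    return DisparityTable(
        equitable_share=lbar,
        disparity=access.accessibility - lbar,
        spar=spar,
        center_ids=list(access.origin_ids),
        mode=mode,
    )
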