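"""Floating catchment area computations.

All FCA variants share the same two-step skeleton. Step 1 aggregates
population into facility demand through some N x J allocation matrix
``W1`` and converts it into a level of service (a local provider-to-
population ratio):

    D_j = sum_i P_i * W1_ij          L_j = S_j / D_j

Step 2 floats the catchments back to population centers and aggregates the
levels of service through an allocation matrix ``W2``:

    A_i = sum_j L_j * W2_ij

The variants differ only in which matrices play ``W1`` and ``W2``:

=============  ==============================  ==============================
method         W1 (demand)                     W2 (service)
=============  ==============================  ==============================
``2sfca``      raw impedance W                 raw impedance W
``e2sfca``     raw impedance W (stepwise)      raw impedance W
``3sfca``      G (x) W (selection-weighted)    Gj (x) W (reversed selection)
``m2sfca``     raw impedance W                 W (x) W (squared impedance)
``balanced``   row-standardized W              column-standardized W
=============  ==============================  ==============================

``2sfca`` and ``e2sfca`` are the same computation — they differ only in the
impedance spec supplied — and both map to the unadjusted path. The balanced
method is the mass-conserving variant: row shares allocate each covered
center's population exactly once (total adjusted demand equals the covered
population) and column shares allocate each patronized facility's level of
service exactly once (total accessibility equals total level of service).
The unadjusted methods instead inflate demand wherever catchments overlap.

Everything is dense double-precision linear algebra; results are bitwise
deterministic given inputs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .impedance import ImpedanceSpec, WeightMatrix, evaluate
from .scenario import Scenario
from .standardize import SlackFactors, StandardizedWeights, column_standardize, row_standardize

__all__ = [
    "METHODS",
    "DemandAllocation",
    "ServiceLevels",
    "SelectionWeights",
    "AccessibilityResult",
    "FCAResult",
    "step1_demand",
    "step1_los",
    "step2_accessibility",
    "selection_weights",
    "run_method",
]

logger = logging.getLogger(__name__)

#: Recognized method tags.
METHODS = ("2sfca", "e2sfca", "3sfca", "m2sfca", "balanced")


@dataclass
class DemandAllocation:
    """Disaggregated demand D_ij and facility totals D_j = sum_i D_ij."""

    pair_demand: np.ndarray           # N x J person-units
    facility_demand: np.ndarray       # length J
    origin_ids: list[str]
    dest_ids: list[str]


@dataclass
class ServiceLevels:
    """Level of service L_j = S_j / D_j (supply per person).

    Stored per person; ``per_scale`` reports per ``scale`` people (default
    per 1,000). Facilities with zero demand have undefined LOS, stored as
    NaN, listed in ``undefined``, and contribute nothing downstream.
    """

    los: np.ndarray                   # length J, per person, NaN = undefined
    dest_ids: list[str]
    scale: float = 1000.0
    undefined: list[str] = field(default_factory=list)

    @property
    def per_scale(self) -> np.ndarray:
        return self.los * self.scale

    @property
    def total(self) -> float:
        """Sum of defined levels of service (per person)."""
        return float(np.nansum(self.los))


@dataclass
class SelectionWeights:
    """Row-normalized shares G_ij: center i's propensity to pick facility j."""

    values: np.ndarray
    origin_ids: list[str]
    dest_ids: list[str]


@dataclass
class AccessibilityResult:
    """Per-center accessibility A_i with its facility-by-center allocation."""

    accessibility: np.ndarray         # length N, per person
    allocation: np.ndarray            # N x J, per person; A_i = row sums
    origin_ids: list[str]
    dest_ids: list[str]
    method: str = ""
    impedance: str = ""
    scale: float = 1000.0

    @property
    def per_scale(self) -> np.ndarray:
        return self.accessibility * self.scale


@dataclass
class FCAResult:
    """Bundle of one method run: weights, demand, service levels, access."""

    method: str
    weights: WeightMatrix             # raw impedance weights
    demand: DemandAllocation
    los: ServiceLevels
    access: AccessibilityResult


def _values(W) -> np.ndarray:
    return W.values if hasattr(W, "values") else np.asarray(W, dtype=float)


def step1_demand(P: np.ndarray, W, *, origin_ids=None, dest_ids=None) -> DemandAllocation:
    """Allocate population through a weight matrix: D_ij = P_i * W_ij.

    ``W`` may be raw impedance weights, standardized shares, or the
    selection-weighted product used by 3SFCA; facility totals are column
    sums.
    """
    P = np.asarray(P, dtype=float)
    V = _values(W)
    if V.shape[0] != P.shape[0]:
        raise ValueError(
            f"population length {P.shape[0]} does not match weight rows {V.shape[0]}"
        )
    pair = P[:, None] * V
    return DemandAllocation(
        pair_demand=pair,
        facility_demand=pair.sum(axis=0),
        origin_ids=list(getattr(W, "origin_ids", None) or range(V.shape[0])),
        dest_ids=list(getattr(W, "dest_ids", None) or range(V.shape[1])),
    )


def step1_los(S: np.ndarray, D: DemandAllocation, scale: float = 1000.0) -> ServiceLevels:
    """Level of service L_j = S_j / D_j; zero-demand facilities get NaN."""
    S = np.asarray(S, dtype=float)
    if S.shape[0] != D.facility_demand.shape[0]:
        raise ValueError("supply length does not match demand")
    with np.errstate(divide="ignore", invalid="ignore"):
        los = np.where(D.facility_demand > 0, S / D.facility_demand, np.nan)
    undefined = [j for j, d in zip(D.dest_ids, D.facility_demand) if d <= 0]
    if undefined:
        logger.warning("facilities with zero demand (LOS undefined): %s", undefined)
    return ServiceLevels(los=los, dest_ids=list(D.dest_ids), scale=scale,
                         undefined=undefined)


def step2_accessibility(L: ServiceLevels, W2, *, method: str = "",
                        impedance: str = "") -> AccessibilityResult:
    """Aggregate service levels to centers: A_i = sum_j L_j * W2_ij.

    ``W2`` is the step-2 allocation matrix (raw, squared, or column-
    standardized weights). Undefined-LOS facilities contribute 0.
    """
    V = _values(W2)
    los = np.nan_to_num(L.los, nan=0.0)
    if V.shape[1] != los.shape[0]:
        raise ValueError("weight columns do not match service levels")
    allocation = V * los[None, :]
    return AccessibilityResult(
        accessibility=allocation.sum(axis=1),
        allocation=allocation,
        origin_ids=list(getattr(W2, "origin_ids", None) or range(V.shape[0])),
        dest_ids=list(L.dest_ids),
        method=method,
        impedance=impedance,
        scale=L.scale,
    )


def selection_weights(T) -> SelectionWeights:
    """Row-normalize a weight matrix into selection shares G_ij.

    Numerically the same as row standardization with unit slack, but kept
    as its own named operation because 3SFCA composes it multiplicatively
    with the impedance weights rather than using it as the allocation
    matrix itself. Zero rows stay zero.
    """
    V = _values(T)
    sums = V.sum(axis=1)
    out = np.zeros_like(V)
    covered = sums > 0
    out[covered] = V[covered] / sums[covered, None]
    return SelectionWeights(
        values=out,
        origin_ids=list(getattr(T, "origin_ids", None) or range(V.shape[0])),
        dest_ids=list(getattr(T, "dest_ids", None) or range(V.shape[1])),
    )


def _column_selection(T) -> np.ndarray:
    """Column-wise analogue of the selection weights (subindices reversed)."""
    V = _values(T)
    sums = V.sum(axis=0)
    out = np.zeros_like(V)
    patronized = sums > 0
    out[:, patronized] = V[:, patronized] / sums[None, patronized]
    return out


def run_method(
    scenario: Scenario,
    impedance,
    method: str = "2sfca",
    *,
    slack: SlackFactors | None = None,
    selection_impedance=None,
    scale: float = 1000.0,
) -> FCAResult:
    """Run one FCA variant end to end on a scenario.

    Parameters
    ----------
    scenario
        Centers, facilities and costs.
    impedance
        An :class:`~fcatools.impedance.ImpedanceSpec` evaluated over the
        scenario's costs, or a precomputed
        :class:`~fcatools.impedance.WeightMatrix` (useful when the weights
        themselves are the given data).
    method
        One of ``2sfca``, ``e2sfca``, ``3sfca``, ``m2sfca``, ``balanced``.
        ``2sfca``/``e2sfca`` are the same unadjusted computation under
        different impedance kinds.
    slack
        Balanced method only: per-center demand and per-facility supply
        slack factors (default exact proportional allocation).
    selection_impedance
        3SFCA only: a separate spec or weight matrix for the selection
        weights ``T`` (e.g. a Gaussian); defaults to the same weights as
        the impedance.
    scale
        Reporting scale for LOS and accessibility (default per 1,000).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if isinstance(impedance, WeightMatrix):
        W = impedance
        tag = "precomputed"
    elif isinstance(impedance, ImpedanceSpec):
        W = evaluate(scenario.costs, impedance)
        tag = impedance.tag
    else:
        raise TypeError("impedance must be an ImpedanceSpec or WeightMatrix")
    if W.shape != (scenario.n_centers, scenario.n_facilities):
        raise ValueError("weight matrix shape does not match scenario")
    if slack is not None and method != "balanced":
        warnings.warn(f"slack factors are ignored by method {method!r}")

    P = scenario.centers.size
    S = scenario.facilities.size

    if method in ("2sfca", "e2sfca"):
        W1: object = W
        W2: object = W
    elif method == "m2sfca":
        W1 = W
        W2 = WeightMatrix(W.values**2, W.origin_ids, W.dest_ids)
    elif method == "3sfca":
        if selection_impedance is None:
            T = W
        elif isinstance(selection_impedance, WeightMatrix):
            T = selection_impedance
        else:
            T = evaluate(scenario.costs, selection_impedance)
        G = selection_weights(T)
        W1 = WeightMatrix(G.values * W.values, W.origin_ids, W.dest_ids)
        Gj = _column_selection(T)
        W2 = Gj * W.values
    else:  # balanced
        W1 = row_standardize(W, slack)
        W2 = column_standardize(W, slack)

    demand = step1_demand(P, W1)
    demand.origin_ids = list(scenario.centers.ids)
    demand.dest_ids = list(scenario.facilities.ids)
    los = step1_los(S, demand, scale=scale)
    access = step2_accessibility(los, W2, method=method, impedance=tag)
    access.origin_ids = list(scenario.centers.ids)
    return FCAResult(method=method, weights=W, demand=demand, los=los, access=access)
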