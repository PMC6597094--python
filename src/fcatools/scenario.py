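"""Scenario containers and tabular I/O.

A *scenario* binds together the three ingredients of a floating catchment
area analysis: a table of population centers (demand side), a table of
service facilities (supply side), and the origin-destination travel-cost
matrix that links them. Costs are travel minutes by convention, but any
non-negative cost works; pairs that cannot interact at all are recorded as
``inf`` ("unreachable") and receive weight zero under every impedance
function.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "UNREACHABLE",
    "EntityTable",
    "CostMatrix",
    "Scenario",
    "ScenarioError",
    "read_entities",
    "read_cost_matrix",
    "euclidean_costs",
    "write_results",
]

#: Sentinel cost for origin-destination pairs that cannot interact.
UNREACHABLE = np.inf

#: Size-column names tried, in order, when none is given explicitly.
_SIZE_COLUMN_CANDIDATES = {
    "centers": ("population", "size", "pop"),
    "facilities": ("supply", "size"),
}


class ScenarioError(ValueError):
    """Raised when scenario inputs fail validation."""


@dataclass
class EntityTable:
    """Population centers or facilities: ids, sizes, optional coordinates.

    Parameters
    ----------
    ids
        Unique, non-empty string identifiers; order is preserved everywhere.
    size
        Non-negative counts: population :math:`P_i` for centers, supply
        :math:`S_j` (e.g. physicians) for facilities.
    x, y
        Optional planar coordinates, used only to derive Euclidean costs.
    """

    ids: list[str]
    size: np.ndarray
    x: np.ndarray | None = None
    y: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = [str(i).strip() for i in self.ids]
        self.size = np.asarray(self.size, dtype=float)
        if len(self.ids) == 0:
            raise ScenarioError("no entities")
        for row, ident in enumerate(self.ids):
            if not ident:
                raise ScenarioError(f"empty id at row {row}")
        seen: dict[str, int] = {}
        for row, ident in enumerate(self.ids):
            if ident in seen:
                raise ScenarioError(
                    f"duplicate id {ident!r} at rows {seen[ident]} and {row}"
                )
            seen[ident] = row
        if self.size.shape != (len(self.ids),):
            raise ScenarioError("size vector does not match id list")
        bad = np.where(~np.isfinite(self.size) | (self.size < 0))[0]
        if bad.size:
            raise ScenarioError(
                f"negative or non-finite size at row {bad[0]} (id {self.ids[bad[0]]!r})"
            )
        for name in ("x", "y"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (len(self.ids),):
                    raise ScenarioError(f"{name} does not match id list")
                setattr(self, name, v)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def has_coords(self) -> bool:
        return self.x is not None and self.y is not None

    def to_frame(self, size_name: str = "size") -> pd.DataFrame:
        data = {"id": self.ids, size_name: self.size}
        if self.has_coords:
            data["x"] = self.x
            data["y"] = self.y
        return pd.DataFrame(data)


@dataclass
class CostMatrix:
    """Dense N x J travel-cost matrix aligned to explicit id orders."""

    origin_ids: list[str]
    dest_ids: list[str]
    cost: np.ndarray

    def __post_init__(self) -> None:
        self.origin_ids = [str(i).strip() for i in self.origin_ids]
        self.dest_ids = [str(i).strip() for i in self.dest_ids]
        self.cost = np.asarray(self.cost, dtype=float)
        if self.cost.shape != (len(self.origin_ids), len(self.dest_ids)):
            raise ScenarioError(
                f"cost matrix shape {self.cost.shape} does not match "
                f"{len(self.origin_ids)} origins x {len(self.dest_ids)} destinations"
            )
        finite = np.isfinite(self.cost)
        if np.any(self.cost[finite] < 0) or np.any(np.isnan(self.cost)):
            raise ScenarioError("costs must be non-negative (inf = unreachable)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cost.shape


@dataclass
class Scenario:
    """Centers, facilities and the cost matrix binding them."""

    centers: EntityTable
    facilities: EntityTable
    costs: CostMatrix

    def __post_init__(self) -> None:
        if self.costs.origin_ids != self.centers.ids:
            raise ScenarioError("cost matrix origins do not match center ids")
        if self.costs.dest_ids != self.facilities.ids:
            raise ScenarioError("cost matrix destinations do not match facility ids")

    @property
    def n_centers(self) -> int:
        return self.centers.n

    @property
    def n_facilities(self) -> int:
        return self.facilities.n


def read_entities(
    path,
    role: str = "centers",
    *,
    id_col: str = "id",
    size_col: str | None = None,
    x_col: str = "x",
    y_col: str = "y",
) -> EntityTable:
    """Read a center or facility table from CSV.

    The file must have a header with an id column and a size column
    (population for centers, supply for facilities). Column names are
    configurable; when ``size_col`` is omitted, common names are tried
    (``population``/``size`` for centers, ``supply``/``size`` for
    facilities). Optional ``x``/``y`` columns carry planar coordinates.
    """
    if role not in ("centers", "facilities"):
        raise ValueError(f"role must be 'centers' or 'facilities', got {role!r}")
    df = pd.read_csv(path, dtype={id_col: str})
    if id_col not in df.columns:
        raise ScenarioError(f"missing id column {id_col!r} in {path}")
    if size_col is None:
        for cand in _SIZE_COLUMN_CANDIDATES[role]:
            if cand in df.columns:
                size_col = cand
                break
        else:
            raise ScenarioError(
                f"missing size column in {path}; tried "
                f"{_SIZE_COLUMN_CANDIDATES[role]}"
            )
    elif size_col not in df.columns:
        raise ScenarioError(f"missing size column {size_col!r} in {path}")
    if df.empty:
        raise ScenarioError("no entities")
    size = pd.to_numeric(df[size_col], errors="coerce").to_numpy()
    bad = np.where(np.isnan(size))[0]
    if bad.size:
        raise ScenarioError(f"non-numeric size at row {bad[0]}")
    kwargs = {}
    if x_col in df.columns and y_col in df.columns:
        kwargs["x"] = df[x_col].to_numpy(dtype=float)
        kwargs["y"] = df[y_col].to_numpy(dtype=float)
    return EntityTable(ids=list(df[id_col]), size=size, **kwargs)


def read_cost_matrix(
    path,
    layout: str = "wide",
    *,
    origin_ids: list[str] | None = None,
    dest_ids: list[str] | None = None,
    origin_col: str = "origin",
    dest_col: str = "destination",
    cost_col: str = "cost",
) -> CostMatrix:
    """Read a travel-cost matrix from CSV in wide or long layout.

    Wide layout: first column holds origin ids, remaining column headers are
    facility ids. Long layout: one row per (origin, destination, cost)
    triple; pairs absent from the file are unreachable. When id lists are
    given, rows/columns are re-aligned to those orders and unknown ids are
    an error.
    """
    if layout == "wide":
        df = pd.read_csv(path, dtype={0: str})
        first = df.columns[0]
        file_origins = [str(v).strip() for v in df[first]]
        file_dests = [str(c).strip() for c in df.columns[1:]]
        cost = df.iloc[:, 1:].to_numpy(dtype=float)
        cm = CostMatrix(file_origins, file_dests, cost)
        if origin_ids is not None or dest_ids is not None:
            cm = _align(cm, origin_ids or file_origins, dest_ids or file_dests)
        return cm
    if layout == "long":
        df = pd.read_csv(path, dtype={origin_col: str, dest_col: str})
        for col in (origin_col, dest_col, cost_col):
            if col not in df.columns:
                raise ScenarioError(f"missing column {col!r} in long cost file")
        o = df[origin_col].str.strip()
        d = df[dest_col].str.strip()
        dup = df.duplicated(subset=[origin_col, dest_col])
        if dup.any():
            row = int(np.where(dup)[0][0])
            raise ScenarioError(
                f"duplicate pair ({o.iloc[row]}, {d.iloc[row]}) at row {row}"
            )
        origins = origin_ids if origin_ids is not None else list(dict.fromkeys(o))
        dests = dest_ids if dest_ids is not None else list(dict.fromkeys(d))
        o_index = {k: i for i, k in enumerate(origins)}
        d_index = {k: j for j, k in enumerate(dests)}
        cost = np.full((len(origins), len(dests)), UNREACHABLE)
        vals = pd.to_numeric(df[cost_col], errors="coerce").to_numpy()
        for row, (oo, dd, c) in enumerate(zip(o, d, vals)):
            if oo not in o_index:
                raise ScenarioError(f"unknown origin id {oo!r} at row {row}")
            if dd not in d_index:
                raise ScenarioError(f"unknown destination id {dd!r} at row {row}")
            if np.isnan(c) or c < 0:
                raise ScenarioError(f"non-numeric or negative cost at row {row}")
            cost[o_index[oo], d_index[dd]] = c
        return CostMatrix(list(origins), list(dests), cost)
    raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")


def _align(cm: CostMatrix, origin_ids: list[str], dest_ids: list[str]) -> CostMatrix:
    o_index = {k: i for i, k in enumerate(cm.origin_ids)}
    d_index = {k: j for j, k in enumerate(cm.dest_ids)}
    missing = [i for i in origin_ids if i not in o_index]
    missing += [j for j in dest_ids if j not in d_index]
    if missing:
        raise ScenarioError(f"ids absent from cost matrix: {missing}")
    unknown = [i for i in cm.origin_ids if i not in set(origin_ids)]
    unknown += [j for j in cm.dest_ids if j not in set(dest_ids)]
    if unknown:
        raise ScenarioError(f"unknown ids in cost matrix: {unknown}")
    rows = [o_index[i] for i in origin_ids]
    cols = [d_index[j] for j in dest_ids]
    return CostMatrix(list(origin_ids), list(dest_ids), cm.cost[np.ix_(rows, cols)])


def euclidean_costs(centers: EntityTable, facilities: EntityTable) -> CostMatrix:
    """Planar Euclidean distances between center and facility coordinates.

    Units are those of the coordinates; intended for synthetic scenarios
    (real studies would use network travel times).
    """
    if not centers.has_coords or not facilities.has_coords:
        raise ScenarioError("both tables need x/y coordinates for euclidean costs")
    dx = centers.x[:, None] - facilities.x[None, :]
    dy = centers.y[:, None] - facilities.y[None, :]
    return CostMatrix(centers.ids, facilities.ids, np.hypot(dx, dy))


def _fmt(df: pd.DataFrame, precision: int) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else f"{v:.{precision}g}"
            )
    return out


def write_results(
    scenario: Scenario,
    result,
    outdir,
    *,
    disparity=None,
    allocation: bool = True,
    geojson: bool = False,
    precision: int = 6,
) -> list[str]:
    """Write per-center, per-facility and allocation CSVs (optionally GeoJSON).

    ``result`` is an :class:`~fcatools.engine.FCAResult`. Numeric columns are
    written with ``precision`` significant digits (full precision is retained
    in memory). Returns the list of paths written.
    """
    import os
    import warnings

    os.makedirs(outdir, exist_ok=True)
    written: list[str] = []

    centers = pd.DataFrame(
        {
            "id": scenario.centers.ids,
            "population": scenario.centers.size,
            "accessibility": result.access.per_scale,
        }
    )
    if disparity is not None:
        centers["disparity"] = disparity.disparity * result.los.scale
    path = os.path.join(outdir, "centers.csv")
    _fmt(centers, precision).to_csv(path, index=False)
    written.append(path)

    facilities = pd.DataFrame(
        {
            "id": scenario.facilities.ids,
            "supply": scenario.facilities.size,
            "demand": result.demand.facility_demand,
            "level_of_service": result.los.per_scale,
        }
    )
    path = os.path.join(outdir, "facilities.csv")
    _fmt(facilities, precision).to_csv(path, index=False)
    written.append(path)

    if allocation:
        n, j = result.demand.pair_demand.shape
        long = pd.DataFrame(
            {
                "center": np.repeat(scenario.centers.ids, j),
                "facility": np.tile(scenario.facilities.ids, n),
                "demand": result.demand.pair_demand.ravel(),
                "service": (result.access.allocation * result.los.scale).ravel(),
            }
        )
        path = os.path.join(outdir, "allocation.csv")
        _fmt(long, precision).to_csv(path, index=False)
        written.append(path)

    if geojson:
        if not scenario.centers.has_coords:
            warnings.warn("scenario has no coordinates; GeoJSON skipped")
        else:
            features = []
            for row in range(scenario.n_centers):
                features.append(
                    {
                        "type": "Feature",
                        "geometry": {
                            "type": "Point",
                            "coordinates": [
                                float(scenario.centers.x[row]),
                                float(scenario.centers.y[row]),
                            ],
                        },
                        "properties": {
                            "id": scenario.centers.ids[row],
                            "population": float(scenario.centers.size[row]),
                            "accessibility": float(result.access.per_scale[row]),
                        },
                    }
                )
            path = os.path.join(outdir, "centers.geojson")
            with open(path, "w") as fh:
                json.dump({"type": "FeatureCollection", "features": features}, fh)
            written.append(path)
    return written
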