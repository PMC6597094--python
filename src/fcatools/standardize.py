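"""Row- and column-standardization of impedance weight matrices.

Standardizing the impedance matrix — dividing each weight by its row sum
(over facilities) or column sum (over centers) — turns raw catchment
weights into proportional allocation shares, the same device used for
spatial weights matrices in spatial statistics and econometrics. Row
shares sum to 1 for every covered center, so a center's population is
allocated to facilities without double counting; column shares sum to 1
for every patronized facility, so a facility's level of service is handed
out exactly once. Optional *slack factors* rescale a unit's shares to model
deliberate over- or under-use (a factor of 1.10 inflates a center's demand
by 10%).

Standardization always operates on raw impedance weights; standardizing an
already-standardized matrix is a pipeline error (though row-standardization
is idempotent with unit slack).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .impedance import WeightMatrix

__all__ = [
    "SlackFactors",
    "StandardizedWeights",
    "row_standardize",
    "column_standardize",
]


@dataclass
class SlackFactors:
    """Positive multiplicative factors on standardized shares.

    ``demand`` has one entry per center (applied to row shares) and
    ``supply`` one per facility (applied to column shares); default all 1,
    i.e. exact proportional allocation.
    """

    demand: np.ndarray | None = None
    supply: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("demand", "supply"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if np.any(v <= 0) or np.any(~np.isfinite(v)):
                    raise ValueError(f"{name} slack factors must be positive")
                setattr(self, name, v)

    @classmethod
    def uniform(cls, n_centers: int, n_facilities: int,
                demand: float = 1.0, supply: float = 1.0) -> "SlackFactors":
        return cls(np.full(n_centers, demand), np.full(n_facilities, supply))


@dataclass
class StandardizedWeights:
    """A standardized weight matrix with bookkeeping.

    ``uncovered`` lists ids of zero rows (centers reaching no facility) or
    zero columns (facilities reached by no center); those rows/columns stay
    all-zero rather than raising, since real systems legitimately leave a
    small share of the population out of catchment.
    """

    values: np.ndarray
    orientation: str  # 'row' or 'column'
    origin_ids: list[str]
    dest_ids: list[str]
    slack_applied: bool = False
    uncovered: list[str] = field(default_factory=list)


def _slack_vector(slack, attr: str, n: int) -> np.ndarray | None:
    if slack is None:
        return None
    v = getattr(slack, attr)
    if v is None:
        return None
    if v.shape != (n,):
        raise ValueError(f"{attr} slack length {v.shape} does not match {n}")
    return v


def row_standardize(W: WeightMatrix, slack: SlackFactors | None = None) -> StandardizedWeights:
    """Divide each weight by its row sum: shares of a center's demand.

    Entry (i, j) becomes ``k_i * W_ij / sum_j W_ij`` where ``k_i`` is the
    center's demand slack (default 1). Rows summing to zero are returned as
    zeros and their center ids reported in ``uncovered``.
    """
    k = _slack_vector(slack, "demand", len(W.origin_ids))
    sums = W.values.sum(axis=1)
    covered = sums > 0
    out = np.zeros_like(W.values)
    out[covered] = W.values[covered] / sums[covered, None]
    if k is not None:
        out *= k[:, None]
    return StandardizedWeights(
        values=out,
        orientation="row",
        origin_ids=W.origin_ids,
        dest_ids=W.dest_ids,
        slack_applied=k is not None,
        uncovered=[i for i, c in zip(W.origin_ids, covered) if not c],
    )


def column_standardize(W: WeightMatrix, slack: SlackFactors | None = None) -> StandardizedWeights:
    """Divide each weight by its column sum: shares of a facility's service.

    Entry (i, j) becomes ``k_j * W_ij / sum_i W_ij``. Columns summing to
    zero are returned as zeros and their facility ids reported in
    ``uncovered`` (unpatronized facilities).
    """
    k = _slack_vector(slack, "supply", len(W.dest_ids))
    sums = W.values.sum(axis=0)
    patronized = sums > 0
    out = np.zeros_like(W.values)
    out[:, patronized] = W.values[:, patronized] / sums[None, patronized]
    if k is not None:
        out *= k[None, :]
    return StandardizedWeights(
        values=out,
        orientation="column",
        origin_ids=W.origin_ids,
        dest_ids=W.dest_ids,
        slack_applied=k is not None,
        uncovered=[j for j, c in zip(W.dest_ids, patronized) if not c],
    )
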